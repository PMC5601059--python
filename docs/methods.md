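# Methods

## Measurement model and reconstruction

An IgA-seq experiment measures, per sample, three family-level
compositions: the unsorted community (pre-sort), the IgA-coated sorted
fraction, and the IgA-uncoated sorted fraction, plus the IgA-binding
ability r — the flow-cytometric percentage of cells that are IgA-coated.
Each sorted fraction is a renormalized composition, so a taxon's coated
abundance confounds its true coating level with the sample's overall
coating level. Multiplying the coated composition by r/100 and the
uncoated composition by (1 − r/100) removes that confound and expresses
both fractions per whole community:

    a⁺[s,t] = coated[s,t] · r[s]/100
    a⁻[s,t] = uncoated[s,t] · (1 − r[s]/100)

Each sample's own r is used, never a group mean. When the two input rows
each sum to 1, the reconstruction conserves mass exactly: Σ_t a⁺ =
r/100, Σ_t (a⁺ + a⁻) = 1. If the community is modelled as taxon
proportions p with per-taxon coating probabilities c, then coated ∝ p·c,
uncoated ∝ p·(1−c) and r/100 = Σ p·c, and the reconstruction inverts the
sorting exactly: a⁺ = p·c, a⁻ = p·(1−c). This identity is what the
exact-mode synthetic tests check to 1e-12.

## The IgA-index

    index = −(log a⁺ − log a⁻) / (log a⁺ + log a⁻)

For abundances in (0, 1) both logs are negative, so |numerator| ≤
|denominator| and the index lies in [−1, 1]; it is antisymmetric under
swapping a⁺ and a⁻, strictly increasing in a⁺, and invariant to the log
base (both parts scale by the same constant). Base-10 logs are used
internally. The extremes are attained only in the limit: as a⁻ → 0 with
a⁺ fixed the index → +1 (taxon absent from the IgA⁻ fraction), and
symmetrically → −1. Convergence is harmonic in −log a (at a⁻ = 1e-15 the
value is still 0.875), so the acceptance script estimates the limit by
Neville polynomial extrapolation in x = 1/(−log₁₀ a⁻), in which variable
the index is analytic at x = 0; thirteen geometric points (1e-3…1e-15)
give the limit to ~1e-10.

### Zero handling

Relative abundances of zero make the logs diverge. Three policies:

- `pseudocount` (default): abundances below ε are replaced by ε before
  the logs. Default ε = 1e-5 sits below the detection floor implied by
  ~46,000 reads/sample (1/46171 ≈ 2.2e-5), so no observed nonzero value
  is ever perturbed.
- `drop`: a zero abundance yields a missing index value, excluded from
  means and tests downstream.
- `none`: the raw formula, with an exact zero mapped to its analytic
  limit ±1 (NaN if both are zero). Used for analytic work, not for data.

Under every policy abundances are clamped to at most 1 − ε, which keeps
the denominator nonzero in the (unrealistic) monoculture case.

## Taxon filter

Taxa whose median pre-sort abundance over all samples pooled is
strictly greater than the threshold (default 0.1%) are retained; the
surviving set is applied to every fraction so all comparisons share one
taxon universe. Strict inequality, no renormalization after filtering.
Filtering is idempotent and never alters values of retained taxa.

## Statistical tests

Between-group comparisons use the two-sided Mann–Whitney U test
(U reported as min(U₁, U₂)); within-group IgA⁺ vs IgA⁻ enrichment uses
the two-sided Wilcoxon signed-rank test on paired reconstructed
abundances, with zero differences discarded and their count reported.

Exact p-values are permutation p-values over mid-ranked data: the
fraction of the C(n₁+n₂, n₁) group labelings (resp. 2ⁿ sign patterns)
whose min-statistic is at least as extreme as observed. They are
computed by an integer subset-sum recursion over doubled mid-ranks
(doubling makes tied mid-ranks integral), which reproduces full
enumeration exactly while remaining polynomial in n; counts are exact
integers and the division is done once, as a rational. The test suite
checks bit-level agreement against a literal itertools enumeration for
all inputs with ≤ 8 observations, and against scipy's exact
distributions on tie-free data.

In `auto` mode the exact distribution is used up to 25 total
observations (Mann–Whitney) or 20 nonzero pairs (signed-rank), with a
tie-corrected normal approximation (scipy) beyond; a 20-vs-20 design
therefore gets the asymptotic U test and the exact signed-rank test.
Both modes can be forced. Degenerate inputs follow the usual
conventions: all values identical (or all differences zero) → p = 1,
with the signed-rank W reported missing. Significance is two-sided at
α (default 0.05) with an additional p < 0.01 flag; enrichment direction
combines significance with the sign of the *median* paired difference
(robust under skew). No multiple-testing correction is applied by
default, matching the per-taxon presentation the pipeline reproduces; a
Benjamini–Hochberg column (statsmodels) can be switched on.

## Synthetic cohorts

Per subject: composition p ~ Dirichlet(α_group); coating probabilities c
are group-level constants per taxon (optionally jittered per subject on
the logit scale, sd default 0.3 when enabled); coated fraction ∝ p·c,
uncoated ∝ p·(1−c); binding ability = 100·Σ p·c (optionally with
truncated-normal measurement error, sd 2 pp, off by default); observed
tables are multinomial counts at a common read depth per fraction
(default 46,000) divided by depth, or the exact probabilities in
`exact` mode. Everything is reproducible from one integer seed.

Default parameters (versioned in `src/igaseq/data/default_params.yaml`):
14 family-level taxa, 20 subjects per group, Dirichlet total
concentration 200 per group. The elderly composition encodes the
qualitative two-group structure — Bifidobacteriaceae 8%→2%,
Clostridiaceae 0.8%→3%, Clostridiales;f__ 2%→5%, Enterobacteriaceae
0.5%→3% — with Lachnospiraceae absorbing the compensating mass so every
other taxon has an identical marginal Beta distribution in both groups
(important for null-calibration tests). Coating probabilities differ
between groups only for Clostridiaceae (0.55 vs 0.30) and
Enterobacteriaceae (0.60 vs 0.20), the modelled decrease of the
taxon-specific IgA response. Desulfovibrionaceae (0.06% mean) sits below
the 0.1% median filter to exercise it. The total concentration of 200
was chosen so that rare headline taxa (Enterobacteriaceae at 0.5% adult
mean) keep a reasonably stable presence across subjects; real
family-level data are typically more overdispersed, so effect detection
on real cohorts will have lower power than on these defaults.

What the generator does **not** emulate: read-level artifacts (PCR bias,
chimeras), sorting impurity distinct from coating probability,
per-fraction depth variation, covariance between taxa beyond the
Dirichlet's, or longitudinal structure. Passing tests therefore
demonstrate correctness of the computations and calibration under this
model, not performance on real sequencing data.

Two deliberate consequences of the defaults worth knowing:

- Binding ability is derived deterministically from p and c, so its
  small systematic group difference (~0.7 pp, from the composition
  shift) is statistically detectable at n = 20/20. Enabling
  `binding_noise_sd` ≈ 2 pp makes the binding comparison behave like a
  noisy assay.
- The IgA-index of a taxon depends on its abundance through the log
  denominator, so taxa with matched coating but shifted abundance
  (e.g. Bifidobacteriaceae) can show a between-group index difference.
  Only taxa with matched abundance *and* coating (e.g. Ruminococcaceae,
  Bacteroidaceae) are true nulls for the index comparison.

## Pipeline

Stages run in order: median filter (on pre-sort; surviving taxa applied
everywhere) → pre-sort group comparison → fecal-IgA / binding-ability
comparison → reconstruction → IgA⁺ and IgA⁻ group comparisons →
IgA-index table and its group comparison → per-group enrichment summary.
All stages compute in memory; files (TSV tables, JSON manifest recording
config, versions and seed) are written only after every stage succeeds,
so failures leave no partial outputs. Identical config + seed gives
byte-identical tables. Figures (grouped boxplots on a log axis floored
at ε, and the enrichment bubble plot where circle area encodes
|mean index| and fill encodes significance) are a convenience layer;
all testing targets the numeric tables.

## Problem sizes used in the test suite

Oracle-equivalence checks enumerate all labelings/sign patterns up to 8
observations (500 random instances per test, ties included); index
property tests use 10⁴ random abundance pairs; power and null
calibration run 200 replicates of the full study-scale design
(20 vs 20 subjects, 14 taxa, 46,000 reads per fraction), where the
Enterobacteriaceae coating difference must be detected in ≥ 80% of
replicates and every matched taxon's rejection rate must stay within
three Monte-Carlo standard errors of 0.05.
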