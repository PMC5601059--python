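"""Synthetic IgA-seq cohorts with known ground truth.

The generative model mirrors the measurement chain of an IgA-seq study:

1. Each subject's true family-level composition p is drawn from a
   group-specific Dirichlet.
2. Each taxon has a coating probability c (per group; optionally
   jittered per subject on the logit scale): the chance that a cell of
   that taxon is IgA-coated.
3. The sorter splits the community: coated-fraction composition is
   proportional to p*c, uncoated to p*(1-c); the flow-cytometric
   IgA-binding ability is 100 * sum_t p_t c_t percent.
4. Sequencing draws multinomial counts at a fixed read depth from each
   fraction's composition (mode ``multinomial``), or reports the exact
   probabilities (mode ``exact``) for algebraic tests.

Because the whole-community reconstruction multiplies the coated
composition by binding/100, it inverts step 3 exactly: in ``exact`` mode
the reconstructed IgA+ abundance equals p*c elementwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import AbundanceTable, MetadataTable, SampleMetadata

__all__ = [
    "SyntheticParams",
    "SyntheticCohort",
    "simulate_cohort",
    "default_study_params",
    "load_params_yaml",
    "write_cohort",
]

DEPTH_MODES = ("multinomial", "exact")


@dataclass
class SyntheticParams:
    """Parameters of the two-group synthetic IgA-seq cohort.

    ``alpha_by_group`` maps each group label to a per-taxon Dirichlet
    concentration vector; ``coating_prob_by_group`` to per-taxon coating
    probabilities in (0, 1). ``coating_jitter_sd`` (logit scale) and
    ``binding_noise_sd`` (percentage points, truncated to [0, 100]) are
    optional realism knobs, both disabled by default.
    """

    taxa: list[str]
    alpha_by_group: dict[str, np.ndarray]
    coating_prob_by_group: dict[str, np.ndarray]
    n_per_group: int = 20
    read_depth: int = 46000
    depth_mode: str = "multinomial"
    seed: int = 0
    coating_jitter_sd: float = 0.0
    binding_noise_sd: float = 0.0
    fecal_iga_log_mean: float = 6.2
    fecal_iga_log_sd: float = 0.4

    def __post_init__(self) -> None:
        if self.depth_mode not in DEPTH_MODES:
            raise ValueError(f"depth_mode must be one of {DEPTH_MODES}")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.read_depth < 1:
            raise ValueError("read_depth must be >= 1")
        if set(self.alpha_by_group) != set(self.coating_prob_by_group):
            raise ValueError("group labels of alpha and coating maps differ")
        if len(self.alpha_by_group) != 2:
            raise ValueError("exactly two groups are required")
        k = len(self.taxa)
        for g in self.alpha_by_group:
            a = np.asarray(self.alpha_by_group[g], dtype=float)
            c = np.asarray(self.coating_prob_by_group[g], dtype=float)
            if a.shape != (k,) or c.shape != (k,):
                raise ValueError(f"group {g!r}: parameter vectors must have length {k}")
            if (a <= 0).any():
                raise ValueError(f"group {g!r}: Dirichlet concentrations must be > 0")
            if (c <= 0).any() or (c >= 1).any():
                raise ValueError(f"group {g!r}: coating probabilities must be in (0, 1)")
            self.alpha_by_group[g] = a
            self.coating_prob_by_group[g] = c

    @property
    def groups(self) -> list[str]:
        return list(self.alpha_by_group)


@dataclass
class SyntheticCohort:
    """A simulated cohort: ground truth plus observed tables/metadata."""

    params: SyntheticParams
    true_composition: pd.DataFrame  # samples x taxa, the p vectors
    true_coating: pd.DataFrame  # samples x taxa, the c vectors
    metadata: MetadataTable
    presort: AbundanceTable
    coated: AbundanceTable
    uncoated: AbundanceTable


def _observe(rng: np.random.Generator, probs: np.ndarray, depth: int, mode: str) -> np.ndarray:
    """One fraction's observed relative abundances for all samples."""
    if mode == "exact":
        return probs.copy()
    counts = np.vstack([rng.multinomial(depth, row) for row in probs])
    return counts / float(depth)


def simulate_cohort(params: SyntheticParams) -> SyntheticCohort:
    """Draw a reproducible synthetic cohort under ``params``.

    Sample ids are ``<group>_<k>``. Binding ability is the generative
    value 100 * sum(p*c) unless ``binding_noise_sd`` adds truncated
    Gaussian measurement error.
    """
    rng = np.random.default_rng(params.seed)
    taxa = list(params.taxa)
    rows_p, rows_c, sample_ids, groups = [], [], [], []
    for g in params.groups:
        alpha = params.alpha_by_group[g]
        c_base = params.coating_prob_by_group[g]
        for k in range(params.n_per_group):
            sample_ids.append(f"{g}_{k + 1:02d}")
            groups.append(g)
            rows_p.append(rng.dirichlet(alpha))
            if params.coating_jitter_sd > 0:
                logit = np.log(c_base / (1.0 - c_base))
                logit = logit + rng.normal(0.0, params.coating_jitter_sd, size=len(taxa))
                rows_c.append(1.0 / (1.0 + np.exp(-logit)))
            else:
                rows_c.append(c_base.copy())
    p = np.vstack(rows_p)
    c = np.vstack(rows_c)

    coated_prob = p * c
    binding = coated_prob.sum(axis=1)  # fraction of cells coated, per subject
    coated_prob = coated_prob / binding[:, None]
    uncoated_prob = p * (1.0 - c)
    uncoated_prob = uncoated_prob / uncoated_prob.sum(axis=1)[:, None]

    presort_obs = _observe(rng, p, params.read_depth, params.depth_mode)
    coated_obs = _observe(rng, coated_prob, params.read_depth, params.depth_mode)
    uncoated_obs = _observe(rng, uncoated_prob, params.read_depth, params.depth_mode)

    binding_pct = 100.0 * binding
    if params.binding_noise_sd > 0:
        noisy = binding_pct + rng.normal(0.0, params.binding_noise_sd, size=binding_pct.size)
        binding_pct = np.clip(noisy, 0.0, 100.0)
    fecal_iga = rng.lognormal(
        params.fecal_iga_log_mean, params.fecal_iga_log_sd, size=binding_pct.size
    )

    idx = pd.Index(sample_ids, name="sample_id")
    metadata = MetadataTable(
        [
            SampleMetadata(
                sample_id=s,
                group=g,
                binding_ability_pct=float(b),
                fecal_iga_ug_per_ml=float(f),
            )
            for s, g, b, f in zip(sample_ids, groups, binding_pct, fecal_iga)
        ]
    )
    return SyntheticCohort(
        params=params,
        true_composition=pd.DataFrame(p, index=idx, columns=taxa),
        true_coating=pd.DataFrame(c, index=idx, columns=taxa),
        metadata=metadata,
        presort=AbundanceTable(pd.DataFrame(presort_obs, index=idx, columns=taxa), "presort"),
        coated=AbundanceTable(pd.DataFrame(coated_obs, index=idx, columns=taxa), "coated"),
        uncoated=AbundanceTable(pd.DataFrame(uncoated_obs, index=idx, columns=taxa), "uncoated"),
    )


def load_params_yaml(source: str | Path | None = None, **overrides) -> SyntheticParams:
    """Build :class:`SyntheticParams` from a YAML defaults file.

    With no ``source``, the packaged defaults are used. Keyword
    overrides replace top-level fields (``seed``, ``depth_mode``, ...).
    """
    if source is None:
        text = resources.files("igaseq").joinpath("data/default_params.yaml").read_text()
    else:
        text = Path(source).read_text()
    raw = yaml.safe_load(text)
    taxa = [str(t) for t in raw["taxa"]]
    total = float(raw.get("total_concentration", 200.0))
    alpha = {
        g: total * np.array([comp[t] for t in taxa], dtype=float)
        for g, comp in raw["mean_composition"].items()
    }
    coating = {
        g: np.array([probs[t] for t in taxa], dtype=float)
        for g, probs in raw["coating_prob"].items()
    }
    params = SyntheticParams(
        taxa=taxa,
        alpha_by_group=alpha,
        coating_prob_by_group=coating,
        n_per_group=int(raw.get("n_per_group", 20)),
        read_depth=int(raw.get("read_depth", 46000)),
        depth_mode=str(raw.get("depth_mode", "multinomial")),
        fecal_iga_log_mean=float(raw.get("fecal_iga_log_mean", 6.2)),
        fecal_iga_log_sd=float(raw.get("fecal_iga_log_sd", 0.4)),
    )
    return replace(params, **overrides) if overrides else params


def default_study_params(**overrides) -> SyntheticParams:
    """Parameters emulating the two-group aging study design.

    Twenty subjects per group, 14 family-level taxa, ~46,000 reads per
    fraction; the elderly composition has less Bifidobacteriaceae and
    more Clostridiaceae, Clostridiales;f__ and Enterobacteriaceae, and
    the elderly coating probabilities of Clostridiaceae and
    Enterobacteriaceae sit below the adult values (a decreased
    taxon-specific IgA response). Exact values live in the packaged
    ``data/default_params.yaml``.
    """
    return load_params_yaml(None, **overrides)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write a cohort's observed tables and metadata as pipeline inputs."""
    from .io import write_abundance_table, write_metadata

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "presort": outdir / "presort_abundance.tsv",
        "coated": outdir / "coated_abundance.tsv",
        "uncoated": outdir / "uncoated_abundance.tsv",
        "metadata": outdir / "metadata.tsv",
    }
    write_abundance_table(cohort.presort, paths["presort"])
    write_abundance_table(cohort.coated, paths["coated"])
    write_abundance_table(cohort.uncoated, paths["uncoated"])
    write_metadata(cohort.metadata, paths["metadata"])
    return paths
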