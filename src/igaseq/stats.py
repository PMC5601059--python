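"""Exact and asymptotic nonparametric tests and the two comparison procedures.

Between-group comparisons (taxon abundances, IgA-indices, fecal IgA,
binding ability) use the two-sided Mann-Whitney U test; within-group
IgA+ vs IgA- enrichment uses the two-sided Wilcoxon signed-rank test on
paired reconstructed abundances.

Exact p-values are permutation p-values: the Mann-Whitney p counts, among
all C(n1+n2, n1) assignments of the pooled mid-ranks to group 1, those
whose min(U1, U2) is at least as extreme as observed; the signed-rank p
counts, among all 2^n sign assignments to the ranked absolute
differences, those whose min(W+, W-) is at least as extreme. Both counts
are computed with an integer subset-sum recursion over doubled mid-ranks
(doubling makes tied mid-ranks integral), which is exact arithmetic and
equivalent to full enumeration. Asymptotic modes use the tie-corrected
normal approximation via scipy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
import scipy.stats

from .core import FractionPair, IgAIndexTable
from .io import MetadataTable, ValidationError

__all__ = [
    "MannWhitneyResult",
    "WilcoxonResult",
    "GroupComparisonResult",
    "EnrichmentResult",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "compare_groups",
    "summarize_enrichment",
    "benjamini_hochberg",
    "EXACT_MWU_MAX_N",
    "EXACT_WILCOXON_MAX_N",
]

#: largest n1+n2 for which the exact Mann-Whitney distribution is used in
#: 'auto' mode; the 20-vs-20 study design therefore uses the asymptotic test
EXACT_MWU_MAX_N = 25
#: largest number of nonzero pairs for the exact signed-rank distribution;
#: the 20-pair study design uses the exact test
EXACT_WILCOXON_MAX_N = 20


@dataclass
class MannWhitneyResult:
    u_statistic: float  # min(U1, U2)
    p_two_sided: float
    mode_used: str  # 'exact' or 'normal-approx'


@dataclass
class WilcoxonResult:
    w_statistic: float  # min(W+, W-); NaN when every difference is zero
    p_two_sided: float
    n_zero_dropped: int
    mode_used: str


def _doubled_midranks(values: np.ndarray) -> np.ndarray:
    """Mid-ranks times two, as exact integers (mid-ranks are half-integral)."""
    ranks = scipy.stats.rankdata(values, method="average")
    doubled = np.rint(ranks * 2).astype(np.int64)
    return doubled


def _subset_sum_counts(weights: list[int]) -> dict[int, int]:
    """Number of subsets of ``weights`` attaining each possible sum."""
    counts: dict[int, int] = {0: 1}
    for w in weights:
        new = counts.copy()
        for s, c in counts.items():
            new[s + w] = new.get(s + w, 0) + c
        counts = new
    return counts


def _sized_subset_sum_counts(weights: list[int], k: int) -> dict[int, int]:
    """Number of k-subsets of ``weights`` attaining each possible sum."""
    # counts[j][s] = number of j-subsets summing to s
    counts: list[dict[int, int]] = [{} for _ in range(k + 1)]
    counts[0][0] = 1
    for w in weights:
        for j in range(min(k, len(weights)), 0, -1):
            lower = counts[j - 1]
            if not lower:
                continue
            tgt = counts[j]
            for s, c in lower.items():
                tgt[s + w] = tgt.get(s + w, 0) + c
    return counts[k]


def mann_whitney_u(x, y, mode: str = "auto") -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test; U reported as min(U1, U2).

    mode 'exact' enumerates the permutation distribution of the pooled
    mid-ranks (requires n1+n2 <= 25; larger samples fall back to the
    tie-corrected normal approximation, as does mode 'auto' above that
    size); mode 'normal-approx' forces the asymptotic test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("mann_whitney_u: both groups must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return MannWhitneyResult(u_statistic=n1 * n2 / 2.0, p_two_sided=1.0, mode_used="degenerate")

    d2 = _doubled_midranks(pooled)  # doubled mid-ranks, exact ints
    r1_d = int(d2[:n1].sum())
    # doubled U1 = doubled R1 - n1(n1+1); doubled U2 = 2 n1 n2 - doubled U1
    u1_d = r1_d - n1 * (n1 + 1)
    u2_d = 2 * n1 * n2 - u1_d
    u_min_d = min(u1_d, u2_d)

    if mode not in ("exact", "normal-approx", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    use_exact = mode == "exact" or (mode == "auto" and n1 + n2 <= EXACT_MWU_MAX_N)
    if use_exact and n1 + n2 > EXACT_MWU_MAX_N:
        use_exact = False  # automatic fallback

    if use_exact:
        counts = _sized_subset_sum_counts([int(v) for v in d2], n1)
        total = math.comb(n1 + n2, n1)
        extreme = 0
        off = n1 * (n1 + 1)
        for s, c in counts.items():
            u1 = s - off
            if min(u1, 2 * n1 * n2 - u1) <= u_min_d:
                extreme += c
        p = float(Fraction(extreme, total))
        return MannWhitneyResult(u_statistic=u_min_d / 2.0, p_two_sided=min(p, 1.0), mode_used="exact")

    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return MannWhitneyResult(
        u_statistic=u_min_d / 2.0,
        p_two_sided=float(min(res.pvalue, 1.0)),
        mode_used="normal-approx",
    )


def wilcoxon_signed_rank(a, b, mode: str = "auto") -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are discarded (their count is reported); ranks of
    absolute differences use mid-ranks for ties; W = min(W+, W-). Exact
    mode enumerates all 2^n sign assignments (n <= 20 after zero
    removal, with automatic fallback to the tie-corrected normal
    approximation above that).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("wilcoxon_signed_rank: unequal lengths")
    d = a - b
    n_zero = int(np.sum(d == 0.0))
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return WilcoxonResult(
            w_statistic=float("nan"), p_two_sided=1.0, n_zero_dropped=n_zero, mode_used="degenerate"
        )

    d2 = _doubled_midranks(np.abs(d))
    t_d = int(d2.sum())  # doubled total rank sum
    w_pos_d = int(d2[d > 0].sum())
    w_min_d = min(w_pos_d, t_d - w_pos_d)

    if mode not in ("exact", "normal-approx", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    use_exact = mode == "exact" or (mode == "auto" and n <= EXACT_WILCOXON_MAX_N)
    if use_exact and n > EXACT_WILCOXON_MAX_N:
        use_exact = False

    if use_exact:
        counts = _subset_sum_counts([int(v) for v in d2])
        extreme = sum(c for s, c in counts.items() if min(s, t_d - s) <= w_min_d)
        p = float(Fraction(extreme, 2**n))
        return WilcoxonResult(
            w_statistic=w_min_d / 2.0, p_two_sided=min(p, 1.0), n_zero_dropped=n_zero, mode_used="exact"
        )

    res = scipy.stats.wilcoxon(d, zero_method="wilcox", correction=True, method="approx")
    return WilcoxonResult(
        w_statistic=w_min_d / 2.0,
        p_two_sided=float(min(res.pvalue, 1.0)),
        n_zero_dropped=n_zero,
        mode_used="normal-approx",
    )


@dataclass
class GroupComparisonResult:
    """Between-group comparison of one per-sample scalar statistic."""

    taxon_id: str | None
    statistic_name: str  # abundance | iga_index | fecal_iga | binding_ability
    group_medians: dict[str, float]
    u_statistic: float
    p_two_sided: float
    significant: bool  # p < alpha
    highly_significant: bool  # p < 0.01 (the two-star flag)
    untestable: bool
    mode_used: str


def compare_groups(
    values_by_sample: pd.Series,
    metadata: MetadataTable,
    alpha: float = 0.05,
    statistic_name: str = "abundance",
    taxon_id: str | None = None,
    mode: str = "auto",
) -> GroupComparisonResult:
    """Mann-Whitney comparison of a per-sample scalar between two groups.

    ``values_by_sample`` is indexed by sample id; missing values are
    dropped before testing. A group with fewer than two non-missing
    values marks the result untestable (p = NaN).
    """
    groups = metadata.groups
    if len(groups) != 2:
        raise ValidationError(
            f"between-group comparison requires exactly 2 groups, found {groups}"
        )
    labels = pd.Series(
        metadata.group_of(list(values_by_sample.index)), index=values_by_sample.index
    )
    clean = values_by_sample.dropna()
    by_group = {g: clean[labels.loc[clean.index] == g].to_numpy() for g in groups}
    medians = {
        g: (float(np.median(v)) if v.size else float("nan")) for g, v in by_group.items()
    }
    if any(v.size < 2 for v in by_group.values()):
        return GroupComparisonResult(
            taxon_id=taxon_id,
            statistic_name=statistic_name,
            group_medians=medians,
            u_statistic=float("nan"),
            p_two_sided=float("nan"),
            significant=False,
            highly_significant=False,
            untestable=True,
            mode_used="none",
        )
    res = mann_whitney_u(by_group[groups[0]], by_group[groups[1]], mode=mode)
    return GroupComparisonResult(
        taxon_id=taxon_id,
        statistic_name=statistic_name,
        group_medians=medians,
        u_statistic=res.u_statistic,
        p_two_sided=res.p_two_sided,
        significant=res.p_two_sided < alpha,
        highly_significant=res.p_two_sided < 0.01,
        untestable=False,
        mode_used=res.mode_used,
    )


@dataclass
class EnrichmentResult:
    """Per-taxon, per-group IgA+ vs IgA- enrichment call."""

    taxon_id: str
    group: str
    mean_iga_index: float  # magnitude drives the bubble size
    w_statistic: float
    p_two_sided: float
    direction: str  # iga_pos_enriched | iga_neg_enriched | not_significant
    n_zero_dropped: int
    low_power: bool  # fewer than 5 informative pairs
    mode_used: str


def summarize_enrichment(
    pair: FractionPair,
    index_table: IgAIndexTable,
    metadata: MetadataTable,
    alpha: float = 0.05,
    mode: str = "auto",
) -> list[EnrichmentResult]:
    """Within-group enrichment of each taxon in the IgA+ or IgA- fraction.

    For each group and taxon, a Wilcoxon signed-rank test on the paired
    reconstructed (IgA+, IgA-) abundances across the group's samples;
    direction comes from significance at ``alpha`` together with the
    sign of the median paired difference (pos - neg). The mean IgA-index
    over non-missing per-sample values summarises the magnitude.
    """
    if pair.sample_ids != index_table.sample_ids or pair.taxon_ids != index_table.taxon_ids:
        raise ValidationError("fraction pair and index table are not aligned")
    labels = np.array(metadata.group_of(pair.sample_ids))
    out: list[EnrichmentResult] = []
    for group in metadata.groups:
        mask = labels == group
        pos = pair.iga_pos.data.loc[mask, :]
        neg = pair.iga_neg.data.loc[mask, :]
        idx = index_table.data.loc[mask, :]
        for taxon in pair.taxon_ids:
            a = pos[taxon].to_numpy()
            b = neg[taxon].to_numpy()
            res = wilcoxon_signed_rank(a, b, mode=mode)
            informative = a.size - res.n_zero_dropped
            diffs = a - b
            med_diff = float(np.median(diffs))
            if np.isnan(res.p_two_sided) or res.p_two_sided >= alpha:
                direction = "not_significant"
            elif med_diff > 0:
                direction = "iga_pos_enriched"
            else:
                direction = "iga_neg_enriched"
            mean_idx = float(np.nanmean(idx[taxon].to_numpy())) if np.any(
                ~np.isnan(idx[taxon].to_numpy())
            ) else float("nan")
            out.append(
                EnrichmentResult(
                    taxon_id=taxon,
                    group=group,
                    mean_iga_index=mean_idx,
                    w_statistic=res.w_statistic,
                    p_two_sided=res.p_two_sided,
                    direction=direction,
                    n_zero_dropped=res.n_zero_dropped,
                    low_power=informative < 5,
                    mode_used=res.mode_used,
                )
            )
    return out


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional, off by default in
    the pipeline, which mirrors the per-taxon presentation of raw p's)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out
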