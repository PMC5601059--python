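"""Whole-community IgA fraction reconstruction and the IgA-index.

IgA-seq sorts a fecal community into IgA-coated and IgA-uncoated
fractions and sequences each. Because the two sorted fractions are each
renormalized compositions, their taxon abundances are not directly
comparable across samples with different overall coating levels. The
reconstruction here rescales each fraction by the sample's IgA-binding
ability r (the flow-cytometric percentage of coated cells), putting both
on the whole-community scale:

    a+[s, t] = coated[s, t]   * r[s] / 100
    a-[s, t] = uncoated[s, t] * (1 - r[s] / 100)

so that, per sample, sum_t a+ = r/100, sum_t a- = 1 - r/100, and the two
reconstructed fractions jointly sum to 1.

The IgA-index of a taxon quantifies its differential representation
between the two reconstructed fractions:

    index = -(log a+ - log a-) / (log a+ + log a-)

It ranges from +1 (taxon absent from the IgA- fraction) through 0
(equal abundance) to -1 (absent from the IgA+ fraction), and is
invariant to the base of the logarithm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AbundanceTable, MetadataTable, ValidationError

__all__ = [
    "FractionPair",
    "IgAIndexTable",
    "ZERO_POLICIES",
    "DEFAULT_EPSILON",
    "reconstruct_fraction_abundances",
    "compute_iga_index",
    "compute_iga_index_table",
    "filter_taxa_by_median",
]

#: zero-abundance handling before taking logs:
#:   pseudocount — replace abundances below epsilon by epsilon (default)
#:   drop        — emit a missing value wherever an abundance is zero
#:   none        — raw formula; an exact zero yields the analytic limit +/-1
ZERO_POLICIES = ("pseudocount", "drop", "none")

#: default pseudocount; below the detection floor of ~46,000 reads/sample
#: (1/46171 ~ 2.2e-5), so observed nonzero abundances are never perturbed
DEFAULT_EPSILON = 1e-5


@dataclass
class FractionPair:
    """Reconstructed whole-community IgA+ and IgA- abundance tables."""

    iga_pos: AbundanceTable
    iga_neg: AbundanceTable

    def __post_init__(self) -> None:
        if self.iga_pos.sample_ids != self.iga_neg.sample_ids:
            raise ValidationError("fraction pair: sample ids differ")
        if self.iga_pos.taxon_ids != self.iga_neg.taxon_ids:
            raise ValidationError("fraction pair: taxon ids differ")

    @property
    def sample_ids(self) -> list[str]:
        return self.iga_pos.sample_ids

    @property
    def taxon_ids(self) -> list[str]:
        return self.iga_pos.taxon_ids

    def select_taxa(self, taxa) -> "FractionPair":
        return FractionPair(self.iga_pos.select_taxa(taxa), self.iga_neg.select_taxa(taxa))


@dataclass
class IgAIndexTable:
    """Per-sample, per-taxon IgA-index values in [-1, 1], possibly missing.

    ``zero_policy_used`` and ``epsilon_used`` record how zero abundances
    were handled; entries are NaN only where ``zero_policy='drop'`` met a
    zero abundance.
    """

    data: pd.DataFrame
    zero_policy_used: str
    epsilon_used: float

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)


def reconstruct_fraction_abundances(
    coated: AbundanceTable,
    uncoated: AbundanceTable,
    metadata: MetadataTable,
) -> FractionPair:
    """Rescale sorted-fraction abundances to the whole-community scale.

    Each sample's own binding ability is used — the correction for
    inter-individual differences in overall IgA coating — never a group
    mean. Sample and taxon order is preserved.
    """
    if coated.fraction_label != "coated" or uncoated.fraction_label != "uncoated":
        raise ValidationError(
            "reconstruction expects a 'coated' and an 'uncoated' table, got "
            f"{coated.fraction_label!r} and {uncoated.fraction_label!r}"
        )
    if coated.sample_ids != uncoated.sample_ids:
        raise ValidationError("coated and uncoated tables: sample ids differ")
    if coated.taxon_ids != uncoated.taxon_ids:
        raise ValidationError("coated and uncoated tables: taxon ids differ")
    r = metadata.binding_ability(coated.sample_ids) / 100.0
    pos = coated.data.mul(r, axis=0)
    neg = uncoated.data.mul(1.0 - r, axis=0)
    return FractionPair(
        AbundanceTable(pos, "iga_pos"), AbundanceTable(neg, "iga_neg")
    )


def _adjust(values: np.ndarray, zero_policy: str, epsilon: float) -> np.ndarray:
    """Apply the zero/one policy to abundances before taking logs."""
    if zero_policy not in ZERO_POLICIES:
        raise ValueError(f"unknown zero_policy {zero_policy!r}; expected {ZERO_POLICIES}")
    if not 0.0 < epsilon < 1.0:
        raise ValueError(f"epsilon must be in (0, 1), got {epsilon}")
    v = np.asarray(values, dtype=float)
    if (v < 0).any() or (v > 1).any():
        raise ValueError("abundances must lie in [0, 1]")
    # log(1) = 0 would zero the denominator for a monoculture pair;
    # clamp to 1 - epsilon under every policy to keep the formula defined
    out = np.minimum(v, 1.0 - epsilon)
    if zero_policy == "pseudocount":
        out = np.maximum(out, epsilon)
    elif zero_policy == "drop":
        out = np.where(v == 0.0, np.nan, out)
    return out


def compute_iga_index(
    pos_abundance,
    neg_abundance,
    zero_policy: str = "pseudocount",
    epsilon: float = DEFAULT_EPSILON,
):
    """IgA-index of a taxon: -(log a+ - log a-) / (log a+ + log a-).

    Accepts scalars or arrays of whole-community-scale abundances in
    [0, 1]; returns values in [-1, 1] (NaN where the policy drops a
    zero). Base-10 logs are used internally; the value is base-invariant
    because numerator and denominator scale by the same constant.
    """
    scalar = np.isscalar(pos_abundance) and np.isscalar(neg_abundance)
    a = _adjust(pos_abundance, zero_policy, epsilon)
    b = _adjust(neg_abundance, zero_policy, epsilon)
    a, b = np.broadcast_arrays(a, b)
    with np.errstate(divide="ignore", invalid="ignore"):
        la = np.log10(a)
        lb = np.log10(b)
        idx = -(la - lb) / (la + lb)
    if zero_policy == "none":
        # analytic limits as one abundance tends to zero with the other fixed
        pos_zero = (a == 0.0) & (b > 0.0)
        neg_zero = (b == 0.0) & (a > 0.0)
        idx = np.where(pos_zero, -1.0, idx)
        idx = np.where(neg_zero, 1.0, idx)
    return float(idx) if scalar else idx


def compute_iga_index_table(
    pair: FractionPair,
    zero_policy: str = "pseudocount",
    epsilon: float = DEFAULT_EPSILON,
) -> IgAIndexTable:
    """Elementwise IgA-index over a reconstructed fraction pair."""
    values = compute_iga_index(
        pair.iga_pos.values, pair.iga_neg.values, zero_policy=zero_policy, epsilon=epsilon
    )
    df = pd.DataFrame(values, index=pair.iga_pos.data.index, columns=pair.iga_pos.data.columns)
    return IgAIndexTable(df, zero_policy_used=zero_policy, epsilon_used=epsilon)


def filter_taxa_by_median(table: AbundanceTable, threshold: float) -> AbundanceTable:
    """Retain taxa whose median abundance across samples is > threshold.

    The inequality is strict ("more than"), the median is taken over all
    samples pooled, taxon order is preserved, and surviving rows are not
    renormalized.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    medians = table.data.median(axis=0)
    keep = [t for t in table.taxon_ids if medians[t] > threshold]
    if keep == table.taxon_ids:
        return AbundanceTable(
            table.data.copy(), table.fraction_label, subcomposition=table.subcomposition
        )
    return table.select_taxa(keep)
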