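"""Reading and writing abundance tables, sample metadata and result tables.

All on-disk formats are tab-separated UTF-8 text. Abundance tables are
oriented samples x taxa with the first header cell ``sample_id``; taxon
labels are opaque strings, so QIIME-style labels such as
``Clostridiales;f__`` round-trip verbatim. Missing values are serialized
as ``NA``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "SampleMetadata",
    "MetadataTable",
    "ValidationError",
    "FRACTION_LABELS",
    "CLOSED_FRACTIONS",
    "read_abundance_table",
    "read_metadata",
    "write_abundance_table",
    "write_metadata",
    "write_result_table",
    "read_result_table",
]

#: fractions whose rows must individually sum to 1 (closed compositions)
CLOSED_FRACTIONS = frozenset({"presort", "coated", "uncoated"})
#: all recognised fraction labels; iga_pos / iga_neg rows sum jointly to 1
FRACTION_LABELS = CLOSED_FRACTIONS | {"iga_pos", "iga_neg"}

#: rows whose sum deviates from 1 by no more than this are silently
#: renormalized (sequencing round-off); larger deviations are data errors
ROW_SUM_RENORM_TOL = 1e-3
ROW_SUM_STRICT_TOL = 1e-6

NA_SENTINEL = "NA"


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class AbundanceTable:
    """A samples x taxa relative-abundance matrix for one fraction.

    Parameters
    ----------
    data
        DataFrame indexed by sample identifier with taxon labels as
        columns; entries are dimensionless fractions.
    fraction_label
        One of ``presort``, ``coated``, ``uncoated`` (rows sum to 1) or
        ``iga_pos``, ``iga_neg`` (rows of the reconstructed pair sum
        jointly to 1, so each row sums to at most 1).
    subcomposition
        True for a table restricted to a taxon subset (e.g. after the
        median filter); relaxes the row-sum-equals-1 requirement of the
        closed fractions to row-sum <= 1.
    """

    data: pd.DataFrame
    fraction_label: str
    subcomposition: bool = False

    def __post_init__(self) -> None:
        if self.fraction_label not in FRACTION_LABELS:
            raise ValidationError(
                f"unknown fraction label {self.fraction_label!r}; "
                f"expected one of {sorted(FRACTION_LABELS)}"
            )
        self.data = self.data.astype(float)
        validate_abundance_frame(self.data, self.fraction_label, self.subcomposition)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def select_taxa(self, taxa: Sequence[str]) -> "AbundanceTable":
        """Return a copy restricted to ``taxa`` (order as given)."""
        missing = [t for t in taxa if t not in self.data.columns]
        if missing:
            raise ValidationError(f"taxa not present in table: {missing}")
        sub = self.subcomposition or list(taxa) != self.taxon_ids
        return AbundanceTable(
            self.data.loc[:, list(taxa)].copy(), self.fraction_label, subcomposition=sub
        )


def validate_abundance_frame(
    df: pd.DataFrame, fraction_label: str, subcomposition: bool = False
) -> None:
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise ValidationError(f"duplicate sample ids: {dups}")
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].tolist()
        raise ValidationError(f"duplicate taxon ids: {dups}")
    arr = df.to_numpy()
    if np.isnan(arr).any():
        bad = df.index[np.isnan(arr).any(axis=1)].tolist()
        raise ValidationError(f"missing values in abundance rows: {bad}")
    if (arr < 0).any():
        bad = df.index[(arr < 0).any(axis=1)].tolist()
        raise ValidationError(f"negative abundances in rows: {bad}")
    sums = arr.sum(axis=1)
    if fraction_label in CLOSED_FRACTIONS and not subcomposition:
        off = np.abs(sums - 1.0) > ROW_SUM_STRICT_TOL
        if off.any():
            bad = {str(s): float(v) for s, v in zip(df.index[off], sums[off])}
            raise ValidationError(
                f"rows of a {fraction_label} table must sum to 1: {bad}"
            )
    else:
        # sub-compositions and reconstructed fractions: rows sum to at most 1
        over = sums > 1.0 + ROW_SUM_STRICT_TOL
        if over.any():
            bad = {str(s): float(v) for s, v in zip(df.index[over], sums[over])}
            raise ValidationError(
                f"rows of a {fraction_label} table must sum to at most 1: {bad}"
            )


@dataclass
class SampleMetadata:
    """Per-sample metadata: group label, IgA-binding ability, fecal IgA.

    ``binding_ability_pct`` is the flow-cytometric percentage of
    IgA-coated bacteria in the whole community, in [0, 100].
    ``fecal_iga_ug_per_ml`` is optional (NaN when absent).
    """

    sample_id: str
    group: str
    binding_ability_pct: float
    fecal_iga_ug_per_ml: float = float("nan")

    def __post_init__(self) -> None:
        if not 0.0 <= self.binding_ability_pct <= 100.0:
            raise ValidationError(
                f"sample {self.sample_id!r}: binding_ability_pct "
                f"{self.binding_ability_pct} outside [0, 100]"
            )
        if not np.isnan(self.fecal_iga_ug_per_ml) and self.fecal_iga_ug_per_ml < 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: negative fecal IgA concentration"
            )


@dataclass
class MetadataTable:
    """An ordered collection of :class:`SampleMetadata`."""

    samples: list[SampleMetadata] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dups = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate sample ids in metadata: {dups}")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def groups(self) -> list[str]:
        """Distinct group labels in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.group, None)
        return list(seen)

    def binding_ability(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Binding abilities (percent) aligned to ``sample_ids``."""
        lut = {s.sample_id: s.binding_ability_pct for s in self.samples}
        missing = [i for i in sample_ids if i not in lut]
        if missing:
            raise ValidationError(f"samples without metadata: {missing}")
        return np.array([lut[i] for i in sample_ids], dtype=float)

    def group_of(self, sample_ids: Sequence[str]) -> list[str]:
        lut = {s.sample_id: s.group for s in self.samples}
        missing = [i for i in sample_ids if i not in lut]
        if missing:
            raise ValidationError(f"samples without metadata: {missing}")
        return [lut[i] for i in sample_ids]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": [s.group for s in self.samples],
                "binding_ability_pct": [s.binding_ability_pct for s in self.samples],
                "fecal_iga_ug_per_ml": [s.fecal_iga_ug_per_ml for s in self.samples],
            },
            index=pd.Index(self.sample_ids, name="sample_id"),
        )


def read_abundance_table(path: str | Path, fraction_label: str) -> AbundanceTable:
    """Read a tab-separated samples x taxa abundance table.

    The first column holds sample identifiers and the header row taxon
    labels. Rows of closed fractions (presort/coated/uncoated) whose sum
    deviates from 1 by at most 1e-3 are renormalized (sequencing
    round-off); larger deviations raise :class:`ValidationError`.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dups = sorted({t for t in header if header.count(t) > 1})
        raise ValidationError(f"{path}: duplicate taxon ids {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError):
        # locate the offending cell for the error message
        for col in df.columns:
            for row, raw in df[col].items():
                try:
                    float(raw)
                except (ValueError, TypeError):
                    raise ValidationError(
                        f"{path}: malformed numeric value {raw!r} "
                        f"at sample {row!r}, taxon {col!r}"
                    ) from None
        raise
    if df.index.duplicated().any() or df.columns.duplicated().any():
        validate_abundance_frame(df, fraction_label)  # raises with detail
    if fraction_label in CLOSED_FRACTIONS:
        sums = df.to_numpy().sum(axis=1)
        off = np.abs(sums - 1.0) > ROW_SUM_RENORM_TOL
        if off.any():
            bad = {str(s): float(v) for s, v in zip(df.index[off], sums[off])}
            raise ValidationError(
                f"{path}: rows sum outside [1-{ROW_SUM_RENORM_TOL}, "
                f"1+{ROW_SUM_RENORM_TOL}]: {bad}"
            )
        needs = np.abs(sums - 1.0) > 0
        if needs.any():
            df = df.div(sums, axis=0)
    return AbundanceTable(df, fraction_label)


REQUIRED_METADATA_COLUMNS = ("sample_id", "group", "binding_ability_pct")


def read_metadata(path: str | Path) -> MetadataTable:
    """Read tab-separated per-sample metadata.

    Required columns: ``sample_id``, ``group``, ``binding_ability_pct``;
    ``fecal_iga_ug_per_ml`` is optional. The number of group levels is
    not restricted here — two-group structure is enforced at the
    comparison stage.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing metadata columns {missing}")
    has_iga = "fecal_iga_ug_per_ml" in df.columns
    samples = [
        SampleMetadata(
            sample_id=str(row.sample_id),
            group=str(row.group),
            binding_ability_pct=float(row.binding_ability_pct),
            fecal_iga_ug_per_ml=float(row.fecal_iga_ug_per_ml)
            if has_iga
            else float("nan"),
        )
        for row in df.itertuples(index=False)
    ]
    return MetadataTable(samples)


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    """Write an abundance table in the format read_abundance_table expects."""
    df = table.data.copy()
    df.index.name = "sample_id"
    df.to_csv(Path(path), sep="\t", float_format="%.17g")


def write_metadata(metadata: MetadataTable, path: str | Path) -> None:
    df = metadata.to_frame()
    df.to_csv(Path(path), sep="\t", float_format="%.17g", na_rep=NA_SENTINEL)


def write_result_table(results: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as tab-separated text with an ``NA`` sentinel.

    Values survive a write/read round trip to 12 significant digits.
    """
    if results is None or len(results) == 0:
        raise ValidationError("refusing to write an empty result table")
    results.to_csv(
        Path(path),
        sep="\t",
        float_format="%.17g",
        na_rep=NA_SENTINEL,
        index=not isinstance(results.index, pd.RangeIndex),
    )


def read_result_table(path: str | Path, index_col: int | None = None) -> pd.DataFrame:
    """Read back a table written by :func:`write_result_table`."""
    return pd.read_csv(
        Path(path), sep="\t", index_col=index_col, na_values=[NA_SENTINEL], keep_default_na=False
    )
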