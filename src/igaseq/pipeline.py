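"""End-to-end IgA-seq analysis pipeline.

Stages, in order: (1) median-abundance taxon filter on the pre-sort
table, with the surviving taxon set applied to every fraction so all
downstream comparisons share one taxon universe; (2) between-group
comparison of pre-sort abundances; (3) between-group comparison of
fecal IgA and binding ability; (4) whole-community IgA+/IgA-
reconstruction; (5) between-group comparison of the reconstructed
fraction abundances; (6) the IgA-index table and its between-group
comparison; (7) per-group IgA+/IgA- enrichment summary. All results are
written as TSV tables together with a JSON run manifest; figures are an
optional convenience layer.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (
    DEFAULT_EPSILON,
    FractionPair,
    IgAIndexTable,
    ZERO_POLICIES,
    compute_iga_index_table,
    filter_taxa_by_median,
    reconstruct_fraction_abundances,
)
from .io import (
    AbundanceTable,
    MetadataTable,
    ValidationError,
    read_abundance_table,
    read_metadata,
    write_abundance_table,
    write_result_table,
)
from .stats import (
    EnrichmentResult,
    GroupComparisonResult,
    benjamini_hochberg,
    compare_groups,
    summarize_enrichment,
)
from .synthetic import SyntheticParams, default_study_params, simulate_cohort

__all__ = ["RunConfig", "ReportBundle", "PipelineError", "run_pipeline", "make_figures"]

logger = logging.getLogger("igaseq.pipeline")


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of file inputs (``presort_path``/``coated_path``/
    ``uncoated_path``/``metadata_path``) or a ``simulate`` block must be
    provided.
    """

    output_dir: str | Path = "igaseq_results"
    presort_path: str | Path | None = None
    coated_path: str | Path | None = None
    uncoated_path: str | Path | None = None
    metadata_path: str | Path | None = None
    simulate: SyntheticParams | None = None
    median_filter_threshold: float = 0.001
    zero_policy: str = "pseudocount"
    epsilon: float = DEFAULT_EPSILON
    alpha: float = 0.05
    mwu_mode: str = "auto"
    wilcoxon_mode: str = "auto"
    bh_correction: bool = False
    make_plots: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        paths = [self.presort_path, self.coated_path, self.uncoated_path, self.metadata_path]
        have_paths = all(p is not None for p in paths)
        some_paths = any(p is not None for p in paths)
        if self.simulate is None and not have_paths:
            missing = [
                n
                for n, p in zip(
                    ("presort_path", "coated_path", "uncoated_path", "metadata_path"), paths
                )
                if p is None
            ]
            raise ValidationError(f"config: missing input tables {missing} and no simulate block")
        if self.simulate is not None and some_paths:
            raise ValidationError("config: provide input paths or a simulate block, not both")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"config: alpha must be in (0, 1), got {self.alpha}")
        if self.zero_policy not in ZERO_POLICIES:
            raise ValidationError(f"config: unknown zero_policy {self.zero_policy!r}")
        if self.median_filter_threshold < 0:
            raise ValidationError("config: median_filter_threshold must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a run configuration from a YAML file."""
        from .synthetic import load_params_yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_block = raw.pop("simulate", None)
        simulate = None
        if sim_block is not None:
            if isinstance(sim_block, str):
                simulate = load_params_yaml(sim_block)
            elif sim_block.get("defaults", True):
                keys = {
                    k: v
                    for k, v in sim_block.items()
                    if k in ("n_per_group", "read_depth", "depth_mode", "seed",
                             "coating_jitter_sd", "binding_noise_sd")
                }
                simulate = default_study_params(**keys)
            else:
                raise ValidationError(
                    "config: inline non-default simulate blocks must point to a params YAML"
                )
        raw.update(overrides)
        return cls(simulate=simulate, **raw)


@dataclass
class ReportBundle:
    """All numeric outputs of one pipeline run."""

    config: RunConfig
    taxa_retained: list[str]
    presort: AbundanceTable
    pair: FractionPair
    index_table: IgAIndexTable
    metadata: MetadataTable
    presort_comparison: pd.DataFrame
    metadata_comparison: pd.DataFrame | None
    iga_pos_comparison: pd.DataFrame
    iga_neg_comparison: pd.DataFrame
    index_comparison: pd.DataFrame
    enrichment: pd.DataFrame
    output_files: dict[str, Path] = field(default_factory=dict)


def _comparison_frame(results: list[GroupComparisonResult], bh: bool) -> pd.DataFrame:
    groups = list(results[0].group_medians) if results else []
    df = pd.DataFrame(
        {
            "taxon": [r.taxon_id for r in results],
            "statistic": [r.statistic_name for r in results],
            **{f"median_{g}": [r.group_medians.get(g) for r in results] for g in groups},
            "u_statistic": [r.u_statistic for r in results],
            "p_two_sided": [r.p_two_sided for r in results],
            "significant": [r.significant for r in results],
            "highly_significant": [r.highly_significant for r in results],
            "untestable": [r.untestable for r in results],
            "mode": [r.mode_used for r in results],
        }
    )
    if bh and len(df):
        df["p_bh"] = benjamini_hochberg(df["p_two_sided"].to_numpy())
    return df


def _enrichment_frame(results: list[EnrichmentResult], bh: bool) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "taxon": [r.taxon_id for r in results],
            "group": [r.group for r in results],
            "mean_iga_index": [r.mean_iga_index for r in results],
            "w_statistic": [r.w_statistic for r in results],
            "p_two_sided": [r.p_two_sided for r in results],
            "direction": [r.direction for r in results],
            "n_zero_dropped": [r.n_zero_dropped for r in results],
            "low_power": [r.low_power for r in results],
            "mode": [r.mode_used for r in results],
        }
    )
    if bh and len(df):
        df["p_bh"] = benjamini_hochberg(df["p_two_sided"].to_numpy())
    return df


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name."""

    class _Ctx:
        def __init__(self) -> None:
            self.t0 = 0.0

        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                logger.info("stage %s finished in %.3fs", name, dt)
                return False
            raise PipelineError(f"stage {name!r}: {exc}") from exc

    return _Ctx()


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full analysis and write the report bundle.

    All stages compute in memory first; files are written only after
    every stage succeeds, so a failure leaves no partial outputs.
    """
    with _stage("load-inputs"):
        if config.simulate is not None:
            from dataclasses import replace

            params = replace(config.simulate, seed=config.seed)
            cohort = simulate_cohort(params)
            presort, coated, uncoated = cohort.presort, cohort.coated, cohort.uncoated
            metadata = cohort.metadata
        else:
            presort = read_abundance_table(config.presort_path, "presort")
            coated = read_abundance_table(config.coated_path, "coated")
            uncoated = read_abundance_table(config.uncoated_path, "uncoated")
            metadata = read_metadata(config.metadata_path)
        logger.info(
            "inputs: %d samples x %d taxa", len(presort.sample_ids), len(presort.taxon_ids)
        )
        if len(metadata.groups) != 2:
            raise ValidationError(f"exactly two groups required, found {metadata.groups}")

    with _stage("median-filter"):
        filtered_presort = filter_taxa_by_median(presort, config.median_filter_threshold)
        taxa = filtered_presort.taxon_ids
        if not taxa:
            raise ValidationError(
                f"no taxon passes the median filter at {config.median_filter_threshold}"
            )
        coated_f = coated.select_taxa(taxa)
        uncoated_f = uncoated.select_taxa(taxa)

    with _stage("presort-group-comparison"):
        presort_cmp = _comparison_frame(
            [
                compare_groups(
                    filtered_presort.data[t],
                    metadata,
                    alpha=config.alpha,
                    statistic_name="abundance",
                    taxon_id=t,
                    mode=config.mwu_mode,
                )
                for t in taxa
            ],
            config.bh_correction,
        )

    with _stage("metadata-group-comparison"):
        meta_df = metadata.to_frame()
        rows = [
            compare_groups(
                meta_df["binding_ability_pct"],
                metadata,
                alpha=config.alpha,
                statistic_name="binding_ability",
                mode=config.mwu_mode,
            )
        ]
        if meta_df["fecal_iga_ug_per_ml"].notna().any():
            rows.append(
                compare_groups(
                    meta_df["fecal_iga_ug_per_ml"],
                    metadata,
                    alpha=config.alpha,
                    statistic_name="fecal_iga",
                    mode=config.mwu_mode,
                )
            )
        metadata_cmp = _comparison_frame(rows, config.bh_correction)

    with _stage("reconstruction"):
        pair = reconstruct_fraction_abundances(coated_f, uncoated_f, metadata)

    with _stage("fraction-group-comparison"):
        pos_cmp = _comparison_frame(
            [
                compare_groups(
                    pair.iga_pos.data[t], metadata, alpha=config.alpha,
                    statistic_name="iga_pos_abundance", taxon_id=t, mode=config.mwu_mode,
                )
                for t in taxa
            ],
            config.bh_correction,
        )
        neg_cmp = _comparison_frame(
            [
                compare_groups(
                    pair.iga_neg.data[t], metadata, alpha=config.alpha,
                    statistic_name="iga_neg_abundance", taxon_id=t, mode=config.mwu_mode,
                )
                for t in taxa
            ],
            config.bh_correction,
        )

    with _stage("iga-index"):
        index_table = compute_iga_index_table(
            pair, zero_policy=config.zero_policy, epsilon=config.epsilon
        )
        index_cmp = _comparison_frame(
            [
                compare_groups(
                    index_table.data[t], metadata, alpha=config.alpha,
                    statistic_name="iga_index", taxon_id=t, mode=config.mwu_mode,
                )
                for t in taxa
            ],
            config.bh_correction,
        )

    with _stage("enrichment-summary"):
        enrichment = _enrichment_frame(
            summarize_enrichment(
                pair, index_table, metadata, alpha=config.alpha, mode=config.wilcoxon_mode
            ),
            config.bh_correction,
        )

    bundle = ReportBundle(
        config=config,
        taxa_retained=taxa,
        presort=filtered_presort,
        pair=pair,
        index_table=index_table,
        metadata=metadata,
        presort_comparison=presort_cmp,
        metadata_comparison=metadata_cmp,
        iga_pos_comparison=pos_cmp,
        iga_neg_comparison=neg_cmp,
        index_comparison=index_cmp,
        enrichment=enrichment,
    )

    with _stage("write-outputs"):
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        files: dict[str, Path] = {}

        def _write(name: str, df: pd.DataFrame) -> None:
            path = outdir / f"{name}.tsv"
            write_result_table(df, path)
            files[name] = path

        write_abundance_table(pair.iga_pos, outdir / "iga_pos_abundance.tsv")
        files["iga_pos_abundance"] = outdir / "iga_pos_abundance.tsv"
        write_abundance_table(pair.iga_neg, outdir / "iga_neg_abundance.tsv")
        files["iga_neg_abundance"] = outdir / "iga_neg_abundance.tsv"
        idx_df = index_table.data.copy()
        idx_df.index.name = "sample_id"
        _write("iga_index", idx_df)
        _write("presort_group_comparison", presort_cmp)
        _write("metadata_group_comparison", metadata_cmp)
        _write("iga_pos_group_comparison", pos_cmp)
        _write("iga_neg_group_comparison", neg_cmp)
        _write("iga_index_group_comparison", index_cmp)
        _write("enrichment_summary", enrichment)

        manifest: dict[str, Any] = {
            "igaseq_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "seed": config.seed,
            "alpha": config.alpha,
            "median_filter_threshold": config.median_filter_threshold,
            "zero_policy": config.zero_policy,
            "epsilon": config.epsilon,
            "mwu_mode": config.mwu_mode,
            "wilcoxon_mode": config.wilcoxon_mode,
            "bh_correction": config.bh_correction,
            "simulated": config.simulate is not None,
            "taxa_retained": taxa,
            "n_samples": len(presort.sample_ids),
            "groups": metadata.groups,
        }
        (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        files["run_manifest"] = outdir / "run_manifest.json"
        bundle.output_files = files

    if config.make_plots:
        with _stage("figures"):
            make_figures(bundle, outdir)

    return bundle


def make_figures(bundle: ReportBundle, outdir: str | Path) -> list[Path]:
    """Render the convenience figures for a completed run.

    Boxplots of per-taxon abundances by group on a log axis (floored at
    the configured pseudocount), boxplots of fecal IgA / binding ability
    and of the IgA-index by group, and a bubble plot of the enrichment
    summary where circle area encodes |mean IgA-index| and fill encodes
    significance.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    groups = bundle.metadata.groups
    labels = np.array(bundle.metadata.group_of(bundle.presort.sample_ids))
    eps = bundle.config.epsilon

    def _grouped_box(df: pd.DataFrame, title: str, fname: str, log: bool) -> None:
        taxa = list(df.columns)
        if not taxa:
            logger.warning("figure %s skipped: empty table", fname)
            return
        ncol = min(5, len(taxa))
        nrow = int(np.ceil(len(taxa) / ncol))
        fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.6 * nrow), squeeze=False)
        for ax, taxon in zip(axes.ravel(), taxa):
            data = [df.loc[labels == g, taxon].dropna().to_numpy() for g in groups]
            if log:
                data = [np.maximum(d, eps) for d in data]
            ax.boxplot(data, tick_labels=groups)
            if log:
                ax.set_yscale("log")
            ax.set_title(taxon, fontsize=8)
        for ax in axes.ravel()[len(taxa):]:
            ax.set_visible(False)
        fig.suptitle(title)
        fig.tight_layout()
        path = outdir / fname
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    _grouped_box(
        bundle.presort.data, "Pre-sort family abundances by group", "presort_abundance_box.png", True
    )
    _grouped_box(bundle.index_table.data, "IgA-index by group", "iga_index_box.png", False)

    meta_df = bundle.metadata.to_frame()
    fig, axes = plt.subplots(1, 2, figsize=(7, 3.2))
    for ax, col, title in zip(
        axes, ("fecal_iga_ug_per_ml", "binding_ability_pct"),
        ("Fecal IgA (ug/ml)", "IgA-binding ability (%)"),
    ):
        data = [meta_df.loc[meta_df["group"] == g, col].dropna().to_numpy() for g in groups]
        if all(len(d) for d in data):
            ax.boxplot(data, tick_labels=groups)
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    path = outdir / "metadata_box.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    enr = bundle.enrichment
    if len(enr):
        taxa = list(dict.fromkeys(enr["taxon"]))
        fig, ax = plt.subplots(figsize=(max(6, 0.55 * len(taxa)), 2.8))
        for gi, g in enumerate(groups):
            sub = enr[enr["group"] == g].set_index("taxon")
            xs = np.arange(len(taxa))
            sizes = 2000.0 * np.abs(sub.loc[taxa, "mean_iga_index"].to_numpy()) + 10.0
            sig = sub.loc[taxa, "direction"].to_numpy() != "not_significant"
            colors = np.where(
                sub.loc[taxa, "mean_iga_index"].to_numpy() >= 0, "tab:red", "tab:blue"
            )
            face = [c if s else "none" for c, s in zip(colors, sig)]
            ax.scatter(xs, np.full_like(xs, gi, dtype=float), s=sizes,
                       facecolors=face, edgecolors=colors)
        ax.set_yticks(range(len(groups)), groups)
        ax.set_xticks(range(len(taxa)), taxa, rotation=60, ha="right", fontsize=7)
        ax.set_ylim(-0.7, len(groups) - 0.3)
        ax.set_title("IgA+/IgA- enrichment (area = |mean IgA-index|; filled = significant)")
        fig.tight_layout()
        path = outdir / "enrichment_bubble.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    else:
        logger.warning("enrichment bubble plot skipped: empty table")
    return written
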