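"""End-to-end orchestration: simulate/load → QC → metrics → statistics → report.

The pipeline mirrors how a contouring-training study is analysed:

1. obtain masks — either simulated (:mod:`ctveval.simulate`) or loaded
   from a manifest CSV pointing at NIfTI files;
2. quality control with an exclusion log (:func:`ctveval.cohort.qc_filter`);
3. per-(observer, phase, structure) metric computation against the
   reference (:func:`ctveval.cohort.evaluate_cohort`);
4. per-metric paired pre/post comparison with a normality-gated test
   choice and matching effect size;
5. interobserver-variability tables per phase;
6. optional Likert-vs-metric correlation matrices.

Everything is a pure function of the configuration (including the master
seed), so a second run with an identical config reproduces all numbers
exactly.  Outputs are tidy CSVs plus a JSON run manifest recording the
config, seed and package version.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import MaskRecord, evaluate_cohort, qc_filter
from .exceptions import (
    DegenerateDataError,
    EmptyCohortError,
    InvalidParameterError,
)
from .mask import VoxelMask, load_mask
from .stats import (
    LikertRecord,
    PairedTestResult,
    correlation_matrix,
    iov_summary,
    paired_compare,
)

logger = logging.getLogger("ctveval")

__all__ = [
    "RunConfig",
    "load_manifest",
    "load_likert_csv",
    "compare_metrics",
    "iov_tables",
    "summarize_table",
    "plot_correlation_heatmap",
    "run_pipeline",
]

#: Metric columns of the tidy cohort table, keyed by canonical metric name.
METRIC_COLUMNS = {
    "dsc": "dsc",
    "ci": "ci",
    "inclusion": "inclusion",
    "rvd": "rvd",
    "asd": "asd_mm",
    "dc": "dc_mm",
    "hd95": "hd95_mm",
    "volume": "volume_cm3",
}


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``manifest`` (a CSV of real mask files) or
    ``simulation`` (a :class:`~ctveval.simulate.CohortSpec`) must be
    given.  ``reference_paths`` maps (case_id, structure) to reference
    NIfTI files when a manifest is used.
    """

    output_dir: Path
    seed: int = 0
    manifest: Path | None = None
    reference_paths: dict[tuple[str, str], Path] = field(default_factory=dict)
    simulation: "object | None" = None  # CohortSpec; kept loose to avoid cycle
    likert: Path | None = None
    item_structure_map: dict[str, str] = field(default_factory=dict)
    normality_alpha: float = 0.05
    hd_percentile: float = 95.0
    heatmap: bool = False

    def __post_init__(self) -> None:
        if (self.manifest is None) == (self.simulation is None):
            raise InvalidParameterError(
                "exactly one of manifest or simulation must be provided"
            )


def load_manifest(
    manifest_csv: str | Path,
) -> list[MaskRecord]:
    """Read a cohort manifest CSV into mask records.

    Expected columns: ``observer_id, case_id, phase, structure,
    mask_path``.  Unreadable files do not raise; the record carries the
    error message and is weeded out (and logged) by QC.
    """
    df = pd.read_csv(manifest_csv, dtype=str)
    required = {"observer_id", "case_id", "phase", "structure", "mask_path"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidParameterError(
            f"manifest {manifest_csv} is missing columns: {sorted(missing)}"
        )
    records = []
    for row in df.itertuples(index=False):
        mask, error = None, None
        try:
            mask = load_mask(row.mask_path)
        except Exception as exc:  # any unreadable file is a QC matter
            error = f"{type(exc).__name__}: {exc}"
        records.append(
            MaskRecord(
                observer_id=row.observer_id,
                case_id=row.case_id,
                phase=row.phase,
                structure=row.structure,
                mask=mask,
                error=error,
            )
        )
    return records


def load_likert_csv(path: str | Path) -> list[LikertRecord]:
    """Read a questionnaire CSV with columns observer_id, item_id, pre, post."""
    df = pd.read_csv(path, dtype={"observer_id": str, "item_id": str})
    return [
        LikertRecord(
            observer_id=row.observer_id,
            item_id=row.item_id,
            pre=int(row.pre),
            post=int(row.post),
        )
        for row in df.itertuples(index=False)
    ]


def _paired_frame(df: pd.DataFrame, value_col: str) -> pd.DataFrame:
    """Observers x {pre, post} for one metric, keeping complete pairs only."""
    wide = df.pivot_table(
        index="observer_id", columns="phase", values=value_col, aggfunc="first"
    )
    return wide.dropna(subset=["pre", "post"]) if {"pre", "post"} <= set(wide.columns) else wide.iloc[0:0]


def compare_metrics(
    cohort: pd.DataFrame,
    metrics: tuple[str, ...] = tuple(METRIC_COLUMNS),
    normality_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-metric paired pre/post comparison table.

    One row per (case, structure, metric) with descriptive statistics for
    both phases and the outcome of :func:`~ctveval.stats.paired_compare`.
    """
    rows = []
    for (case_id, structure), group in cohort.groupby(
        ["case_id", "structure"], sort=True
    ):
        for metric in metrics:
            col = METRIC_COLUMNS[metric]
            wide = _paired_frame(group, col)
            if len(wide) < 3:
                logger.warning(
                    "skipping %s/%s/%s: only %d complete pairs",
                    case_id, structure, metric, len(wide),
                )
                continue
            try:
                res = paired_compare(
                    wide["pre"].to_numpy(),
                    wide["post"].to_numpy(),
                    metric_name=metric,
                    normality_alpha=normality_alpha,
                )
            except DegenerateDataError as exc:
                logger.warning(
                    "skipping %s/%s/%s: %s", case_id, structure, metric, exc
                )
                continue
            rows.append(
                {
                    "case_id": case_id,
                    "structure": structure,
                    "metric": metric,
                    "n": res.n,
                    "pre_mean": wide["pre"].mean(),
                    "pre_sd": wide["pre"].std(ddof=1),
                    "pre_min": wide["pre"].min(),
                    "pre_max": wide["pre"].max(),
                    "post_mean": wide["post"].mean(),
                    "post_sd": wide["post"].std(ddof=1),
                    "post_min": wide["post"].min(),
                    "post_max": wide["post"].max(),
                    "test_used": res.test_used,
                    "statistic": res.statistic,
                    "z": res.z,
                    "p_value": res.p_value,
                    "effect_size": res.effect_size,
                    "effect_kind": res.effect_kind,
                }
            )
    return pd.DataFrame(rows)


def iov_tables(cohort: pd.DataFrame) -> pd.DataFrame:
    """Interobserver-variability table per (case, structure, phase)."""
    rows = []
    for (case_id, structure, phase), group in cohort.groupby(
        ["case_id", "structure", "phase"], sort=True
    ):
        s = iov_summary(group["volume_cm3"].to_numpy())
        rows.append(
            {
                "case_id": case_id,
                "structure": structure,
                "phase": phase,
                "n": s.n,
                "mean_volume_cm3": s.mean_volume,
                "sd_cm3": s.sd,
                "cv": s.cv,
                "vmax_cm3": s.vmax,
                "vmin_cm3": s.vmin,
                "mvr": s.mvr,
            }
        )
    return pd.DataFrame(rows)


def _fmt_mean_sd_range(mean, sd, lo, hi, nd=2) -> str:
    return f"{mean:.{nd}f} ± {sd:.{nd}f} ({lo:.{nd}f}–{hi:.{nd}f})"


def summarize_table(comparisons: pd.DataFrame, nd: int = 2) -> pd.DataFrame:
    """Human-readable comparison table.

    Renders each phase as ``mean ± SD (min–max)``, stars p-values below
    0.05 (raw p is always printed alongside), and labels the effect size
    with its kind (d for paired t, r for Wilcoxon).
    """
    rows = []
    for row in comparisons.itertuples(index=False):
        star = "*" if row.p_value < 0.05 else ""
        rows.append(
            {
                "case_id": row.case_id,
                "structure": row.structure,
                "metric": row.metric,
                "pre": _fmt_mean_sd_range(
                    row.pre_mean, row.pre_sd, row.pre_min, row.pre_max, nd
                ),
                "post": _fmt_mean_sd_range(
                    row.post_mean, row.post_sd, row.post_min, row.post_max, nd
                ),
                "test": row.test_used,
                "statistic": f"{row.statistic:.3f}",
                "p": f"{row.p_value:.3f}{star}",
                "effect_size": f"{row.effect_kind} = {row.effect_size:.3f}",
            }
        )
    return pd.DataFrame(rows)


def plot_correlation_heatmap(corr: pd.DataFrame, path: str | Path) -> None:
    """Heatmap of adjusted correlations: red = improvement-aligned,
    blue = anti-aligned, stars for p below 0.05/0.01."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    pivot = corr.pivot(index="metric", columns="item_id", values="rho_adjusted")
    pvals = corr.pivot(index="metric", columns="item_id", values="p_value")
    annot = pivot.round(2).astype(str)
    annot = annot.where(pvals > 0.05, annot + "*")
    annot = annot.where(pvals > 0.01, annot + "*")
    fig, ax = plt.subplots(figsize=(1.2 * pivot.shape[1] + 2, 0.6 * pivot.shape[0] + 2))
    sns.heatmap(
        pivot, annot=annot, fmt="", cmap="RdBu_r", vmin=-1, vmax=1,
        cbar_kws={"label": "adjusted Spearman ρ"}, ax=ax,
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> dict[str, object]:
    """Execute the full analysis and write the report bundle.

    Returns a dict with the in-memory tables (``metrics``,
    ``comparisons``, ``iov``, ``exclusions``, optionally
    ``correlations_*``) and writes the corresponding CSVs, the formatted
    summary, and ``run_manifest.json`` into ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulation is not None:
        from .simulate import make_reference_mask, simulate_cohort

        spec = config.simulation
        reference = make_reference_mask(spec.reference_shape, spec.grid)
        ref_masks = {(spec.case_id, spec.structure): reference}
        _, mask_records, likert_records = simulate_cohort(spec, config.seed)
        logger.info("simulated cohort: %d mask records", len(mask_records))
    else:
        mask_records = load_manifest(config.manifest)
        ref_masks = {
            key: load_mask(path) for key, path in config.reference_paths.items()
        }
        likert_records = (
            load_likert_csv(config.likert) if config.likert is not None else []
        )
        logger.info("loaded %d mask records from manifest", len(mask_records))

    retained_masks, retained_likert, exclusions = qc_filter(
        mask_records, likert_records, reference_masks=ref_masks
    )
    logger.info(
        "QC: retained %d mask records, excluded %d observers/cells",
        len(retained_masks), len(exclusions),
    )
    if not retained_masks:
        raise EmptyCohortError("no observers survive quality control")

    metrics = evaluate_cohort(
        retained_masks, ref_masks, hd_percentile=config.hd_percentile
    )
    comparisons = compare_metrics(metrics, normality_alpha=config.normality_alpha)
    iov = iov_tables(metrics)
    summary = summarize_table(comparisons)

    results: dict[str, object] = {
        "metrics": metrics,
        "comparisons": comparisons,
        "iov": iov,
        "summary": summary,
        "exclusions": exclusions,
    }

    if retained_likert and config.item_structure_map:
        likert_df = pd.DataFrame(
            [dataclasses.asdict(r) for r in retained_likert]
        )
        for mode in ("pre", "post", "delta"):
            corr = correlation_matrix(
                likert_df, metrics, mode, config.item_structure_map
            )
            results[f"correlations_{mode}"] = corr
            corr.to_csv(out / f"correlations_{mode}.csv", index=False)
            if config.heatmap:
                plot_correlation_heatmap(
                    corr, out / f"correlations_{mode}.png"
                )

    metrics.to_csv(out / "metrics.csv", index=False)
    comparisons.to_csv(out / "comparisons.csv", index=False)
    iov.to_csv(out / "iov.csv", index=False)
    summary.to_csv(out / "summary.csv", index=False)
    exclusions.to_csv(out / "exclusions.csv", index=False)

    manifest = {
        "package": "ctveval",
        "version": __version__,
        "seed": config.seed,
        "normality_alpha": config.normality_alpha,
        "hd_percentile": config.hd_percentile,
        "mode": "simulation" if config.simulation is not None else "manifest",
        "config": _jsonable_config(config),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return results


def _jsonable_config(config: RunConfig) -> dict:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (Path, np.generic)):
            return str(o)
        return str(o)

    raw = dataclasses.asdict(config)
    raw["reference_paths"] = {
        f"{case}/{structure}": str(path)
        for (case, structure), path in config.reference_paths.items()
    }
    return json.loads(json.dumps(raw, default=default))
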