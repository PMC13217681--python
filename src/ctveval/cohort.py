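"""Cohort containers, quality-control filters and metric-table building.

A contouring cohort is a set of observers, each contributing one mask per
(case, phase, structure) cell plus a questionnaire.  Before any statistic
is computed the cohort passes a quality-control filter mirroring the
inclusion rules of prospective delineation studies:

* observers missing either phase of a (case, structure) cell are excluded
  from that case's contour analysis;
* observers whose pre- and post-training masks are voxel-for-voxel
  identical across all structures of a case are excluded (a re-submitted
  contour carries no training signal);
* observers whose pre-training questionnaire sits entirely at the scale
  maximum are excluded from the questionnaire analysis (ceiling effect:
  no measurable improvement is possible);
* unreadable, empty or grid-mismatched masks exclude the observer from
  that case with an "invalid file" reason.

Filtering is total: problems never raise, they land in the exclusion log,
one row per excluded observer with a machine-readable reason code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mask import VoxelMask
from .metrics import metric_set
from .stats import LikertRecord

__all__ = [
    "MaskRecord",
    "ExclusionLog",
    "qc_filter",
    "evaluate_cohort",
    "REASON_MISSING_PHASE",
    "REASON_IDENTICAL",
    "REASON_INVALID_FILE",
    "REASON_CEILING",
]

REASON_MISSING_PHASE = "missing_phase"
REASON_IDENTICAL = "identical_submission"
REASON_INVALID_FILE = "invalid_file"
REASON_CEILING = "ceiling"

PHASES = ("pre", "post")


@dataclass(frozen=True, eq=False)
class MaskRecord:
    """One submitted mask (or a note of its unreadability)."""

    observer_id: str
    case_id: str
    phase: str  # "pre" | "post"
    structure: str
    mask: VoxelMask | None = None
    error: str | None = None

    def is_valid(self) -> bool:
        return self.error is None and self.mask is not None and not self.mask.is_empty()


ExclusionLog = pd.DataFrame  # columns: observer_id, case_id, analysis, reason, detail


def _case_grid_reference(records: list[MaskRecord]) -> VoxelMask | None:
    for rec in records:
        if rec.mask is not None:
            return rec.mask
    return None


def qc_filter(
    mask_records: list[MaskRecord],
    likert_records: list[LikertRecord] | None = None,
    reference_masks: dict[tuple[str, str], VoxelMask] | None = None,
) -> tuple[list[MaskRecord], list[LikertRecord], pd.DataFrame]:
    """Apply the study inclusion rules.

    Parameters
    ----------
    mask_records
        All submitted masks, valid or not.
    likert_records
        Questionnaire rows; may be ``None`` if no questionnaire was run.
    reference_masks
        Optional ``(case_id, structure) -> reference`` mapping; when given,
        masks whose grid does not match the reference are treated as
        invalid files.

    Returns
    -------
    (retained mask records, retained likert records, exclusion log)
        The log has one row per excluded (observer, case) contour cell or
        (observer,) questionnaire, with columns ``observer_id, case_id,
        analysis, reason, detail``.
    """
    log_rows: list[dict] = []
    retained_masks: list[MaskRecord] = []

    df = pd.DataFrame(
        [
            {
                "observer_id": r.observer_id,
                "case_id": r.case_id,
                "phase": r.phase,
                "structure": r.structure,
                "rec": r,
            }
            for r in mask_records
        ]
    )
    if not df.empty:
        for (case_id, observer_id), group in df.groupby(
            ["case_id", "observer_id"], sort=True
        ):
            records = list(group["rec"])
            reason = _contour_exclusion_reason(case_id, records, reference_masks)
            if reason is None:
                retained_masks.extend(records)
            else:
                log_rows.append(
                    {
                        "observer_id": observer_id,
                        "case_id": case_id,
                        "analysis": "contour",
                        "reason": reason[0],
                        "detail": reason[1],
                    }
                )

    retained_likert: list[LikertRecord] = []
    if likert_records:
        by_obs: dict[str, list[LikertRecord]] = {}
        for rec in likert_records:
            by_obs.setdefault(rec.observer_id, []).append(rec)
        for observer_id in sorted(by_obs):
            recs = by_obs[observer_id]
            if all(r.pre == 5 for r in recs):
                log_rows.append(
                    {
                        "observer_id": observer_id,
                        "case_id": "",
                        "analysis": "questionnaire",
                        "reason": REASON_CEILING,
                        "detail": "all pre-training scores at scale maximum",
                    }
                )
            else:
                retained_likert.extend(recs)

    log = pd.DataFrame(
        log_rows, columns=["observer_id", "case_id", "analysis", "reason", "detail"]
    )
    return retained_masks, retained_likert, log


def _contour_exclusion_reason(
    case_id: str,
    records: list[MaskRecord],
    reference_masks: dict[tuple[str, str], VoxelMask] | None,
) -> tuple[str, str] | None:
    by_cell: dict[tuple[str, str], MaskRecord] = {
        (r.phase, r.structure): r for r in records
    }
    structures = sorted({r.structure for r in records})

    for rec in records:
        if rec.error is not None or rec.mask is None:
            return REASON_INVALID_FILE, f"{rec.phase}/{rec.structure}: {rec.error or 'missing mask object'}"
        if rec.mask.is_empty():
            return REASON_INVALID_FILE, f"{rec.phase}/{rec.structure}: empty mask"
        if reference_masks is not None:
            ref = reference_masks.get((case_id, rec.structure))
            if ref is not None and not rec.mask.same_grid(ref):
                return (
                    REASON_INVALID_FILE,
                    f"{rec.phase}/{rec.structure}: grid mismatch with reference",
                )

    for structure in structures:
        for phase in PHASES:
            if (phase, structure) not in by_cell:
                return REASON_MISSING_PHASE, f"missing {phase} mask for {structure}"

    identical = all(
        np.array_equal(
            by_cell[("pre", s)].mask.occupancy, by_cell[("post", s)].mask.occupancy
        )
        for s in structures
    )
    if identical:
        return REASON_IDENTICAL, "pre and post masks voxel-identical for all structures"
    return None


def evaluate_cohort(
    mask_records: list[MaskRecord],
    reference_masks: dict[tuple[str, str], VoxelMask],
    hd_percentile: float = 95.0,
) -> pd.DataFrame:
    """Score every retained mask against its reference.

    Returns the tidy cohort table with one row per (observer, case, phase,
    structure) and columns ``dsc, ci, inclusion, rvd, asd_mm, dc_mm,
    hd95_mm, volume_cm3``.  Records without a matching reference raise
    ``KeyError``; run :func:`qc_filter` first to weed out invalid masks.
    """
    rows = []
    for rec in mask_records:
        ref = reference_masks[(rec.case_id, rec.structure)]
        ms = metric_set(rec.mask, ref, hd_percentile=hd_percentile)
        rows.append(
            {
                "observer_id": rec.observer_id,
                "case_id": rec.case_id,
                "phase": rec.phase,
                "structure": rec.structure,
                "dsc": ms.dsc,
                "ci": ms.ci,
                "inclusion": ms.inclusion,
                "rvd": ms.rvd,
                "asd_mm": ms.asd,
                "dc_mm": ms.dc,
                "hd95_mm": ms.hd95,
                "volume_cm3": ms.volume,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "observer_id",
            "case_id",
            "phase",
            "structure",
            "dsc",
            "ci",
            "inclusion",
            "rvd",
            "asd_mm",
            "dc_mm",
            "hd95_mm",
            "volume_cm3",
        ],
    )
    dup = df.duplicated(subset=["observer_id", "case_id", "phase", "structure"])
    if dup.any():
        raise ValueError(
            "duplicate (observer, case, phase, structure) records: "
            + ", ".join(map(str, df[dup][["observer_id", "case_id", "phase", "structure"]].itertuples(index=False)))
        )
    return df
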