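"""Cohort-level statistics for pre/post contouring studies.

Covers four needs of a delineation-training analysis:

* interobserver variability (IOV) of structure volumes — sample SD,
  coefficient of variation, and the maximum-to-minimum volume ratio (MVR);
* paired pre/post hypothesis tests with effect sizes — a Shapiro-Wilk
  normality gate selects between the paired t-test (effect size
  d = |t|/sqrt(n)) and the Wilcoxon signed-rank test (effect size
  r = |Z|/sqrt(n));
* Spearman rank correlation between 5-point Likert self-assessments and
  objective metrics, with a directional adjustment that negates the
  correlations of lower-is-better metrics (95%HD, ASD, DC, RVD) so that
  positive values always mean "better self-rating goes with better
  contours";
* tidy containers for the observer x case x phase x structure records.

Statistical conventions follow mainstream packages: the Wilcoxon test
drops zero differences, applies the tie-corrected normal approximation and
no continuity correction; Z carries the sign of the rank-sum difference
(negative when post exceeds pre).  No multiple-testing adjustment is
applied; p-values are reported unadjusted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import (
    DegenerateDataError,
    InsufficientDataError,
    InvalidDataError,
    InvalidParameterError,
)

__all__ = [
    "IOVSummary",
    "PairedTestResult",
    "LikertRecord",
    "NEGATED_METRICS",
    "POSITIVE_METRICS",
    "iov_summary",
    "wilcoxon_signed_rank",
    "paired_t",
    "effect_size_r",
    "effect_size_d",
    "paired_compare",
    "spearman_rho",
    "directional_adjust",
    "correlation_matrix",
]

#: Metrics where a *lower* value means better contour quality; their
#: correlations with self-assessment are negated for display.
NEGATED_METRICS = frozenset({"hd95", "asd", "dc", "rvd"})
#: Metrics where a higher value means better quality; left unchanged.
POSITIVE_METRICS = frozenset({"dsc", "ci", "inclusion"})


@dataclass(frozen=True)
class IOVSummary:
    """Volume-dispersion indices of one structure across a cohort."""

    n: int
    mean_volume: float  # cm3
    sd: float  # cm3, sample SD (n-1)
    cv: float  # unitless, sd / mean
    vmax: float  # cm3
    vmin: float  # cm3
    mvr: float  # unitless, vmax / vmin


@dataclass(frozen=True)
class PairedTestResult:
    """Outcome of one metric's paired pre/post comparison."""

    metric_name: str
    n: int
    test_used: str  # "wilcoxon" | "paired_t"
    statistic: float  # W or t
    z: float | None  # normal-approximation Z (wilcoxon only)
    p_value: float
    effect_size: float
    effect_kind: str  # "r" | "d"
    shapiro_p: float | None = None


@dataclass(frozen=True)
class LikertRecord:
    """One questionnaire item for one observer, scored 1-5 pre and post."""

    observer_id: str
    item_id: str
    pre: int
    post: int

    def __post_init__(self) -> None:
        for phase, score in (("pre", self.pre), ("post", self.post)):
            if not (isinstance(score, (int, np.integer)) and 1 <= score <= 5):
                raise InvalidDataError(
                    f"{phase} score for {self.observer_id}/{self.item_id} "
                    f"must be an integer in [1, 5], got {score!r}"
                )


def iov_summary(volumes) -> IOVSummary:
    """Interobserver variability of a list of structure volumes (cm3).

    Uses the sample standard deviation (n-1 denominator); requires at
    least two strictly positive volumes.
    """
    v = np.asarray(volumes, dtype=float)
    if v.size < 2:
        raise InsufficientDataError(
            f"IOV needs at least 2 volumes, got {v.size}"
        )
    if np.any(v <= 0) or not np.all(np.isfinite(v)):
        raise InvalidDataError("volumes must all be finite and positive")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    return IOVSummary(
        n=int(v.size),
        mean_volume=mean,
        sd=sd,
        cv=sd / mean,
        vmax=float(v.max()),
        vmin=float(v.min()),
        mvr=float(v.max() / v.min()),
    )


def _paired_diffs(pre, post) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise InvalidParameterError(
            "pre and post must be 1-D arrays of equal length"
        )
    return pre, post, post - pre


def wilcoxon_signed_rank(pre, post) -> tuple[float, float, float]:
    """Wilcoxon signed-rank test on paired samples.

    Returns ``(W, z, p)``: the smaller signed-rank sum, the tie-corrected
    normal-approximation Z (no continuity correction; sign of the rank-sum
    difference, negative when post exceeds pre), and the two-sided p-value.
    Zero differences are dropped; at least 5 nonzero pairs are required.
    """
    pre, post, diff = _paired_diffs(pre, post)
    d = -diff[diff != 0]  # pre - post: improvement gives negative differences
    if d.size == 0:
        raise DegenerateDataError(
            "all paired differences are zero; Wilcoxon test is degenerate"
        )
    if d.size < 5:
        raise InsufficientDataError(
            f"need >= 5 nonzero paired differences, got {d.size}"
        )
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    r_plus = float(ranks[d > 0].sum())
    r_minus = n * (n + 1) / 2.0 - r_plus
    mn = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= (counts**3 - counts).sum() / 48.0  # tie correction
    z = (r_plus - mn) / np.sqrt(var)
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return min(r_plus, r_minus), float(z), p


def paired_t(pre, post) -> tuple[float, float]:
    """Paired-sample t-test; returns ``(t, p)``.

    t is negative when post exceeds pre.  Zero-variance differences raise
    a degenerate-data error rather than returning an infinite statistic.
    """
    pre, post, diff = _paired_diffs(pre, post)
    if diff.size < 2:
        raise InsufficientDataError("paired t-test needs at least 2 pairs")
    if np.isclose(diff.std(ddof=1), 0.0):
        raise DegenerateDataError(
            "paired differences have zero variance; t-test is degenerate"
        )
    res = sps.ttest_rel(pre, post)
    return float(res.statistic), float(res.pvalue)


def effect_size_r(z: float, n: int) -> float:
    """Wilcoxon effect size r = |Z| / sqrt(n), n the number of pairs."""
    if n < 1:
        raise InvalidParameterError(f"n must be >= 1, got {n}")
    return abs(z) / np.sqrt(n)


def effect_size_d(t: float, n: int) -> float:
    """Paired-t effect size d = |t| / sqrt(n), n the number of pairs."""
    if n < 1:
        raise InvalidParameterError(f"n must be >= 1, got {n}")
    return abs(t) / np.sqrt(n)


def paired_compare(
    pre, post, metric_name: str = "", normality_alpha: float = 0.05
) -> PairedTestResult:
    """Pre/post comparison with a data-driven test choice.

    A Shapiro-Wilk test on the paired differences at ``normality_alpha``
    selects the paired t-test (differences consistent with normality) or
    the Wilcoxon signed-rank test (normality rejected).  The effect size
    uses the formula matching the chosen test: d = |t|/sqrt(n) or
    r = |Z|/sqrt(n).
    """
    pre, post, diff = _paired_diffs(pre, post)
    n = diff.size
    if n < 3:
        raise InsufficientDataError("paired_compare needs at least 3 pairs")
    if np.all(diff == 0):
        raise DegenerateDataError("all paired differences are zero")
    if np.isclose(np.std(diff, ddof=0), 0.0):
        raise DegenerateDataError(
            "paired differences are constant; no distributional test applies"
        )
    shapiro_p = float(sps.shapiro(diff).pvalue)
    if shapiro_p > normality_alpha:
        t, p = paired_t(pre, post)
        return PairedTestResult(
            metric_name=metric_name,
            n=n,
            test_used="paired_t",
            statistic=t,
            z=None,
            p_value=p,
            effect_size=effect_size_d(t, n),
            effect_kind="d",
            shapiro_p=shapiro_p,
        )
    w, z, p = wilcoxon_signed_rank(pre, post)
    return PairedTestResult(
        metric_name=metric_name,
        n=n,
        test_used="wilcoxon",
        statistic=w,
        z=z,
        p_value=p,
        effect_size=effect_size_r(z, n),
        effect_kind="r",
        shapiro_p=shapiro_p,
    )


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    Returns ``(rho, p)``; raises on constant inputs where the correlation
    is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise InsufficientDataError(
            "spearman_rho needs two equal-length 1-D vectors with n >= 3"
        )
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateDataError(
            "correlation is undefined for a constant input vector"
        )
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def directional_adjust(metric_name: str, rho: float) -> float:
    """Flip the sign of correlations of lower-is-better metrics.

    95%HD, ASD, DC and RVD improve downwards, so their correlations with
    self-assessment are negated; DSC, CI and Inclusion pass through.
    """
    if metric_name in NEGATED_METRICS:
        return -rho
    if metric_name in POSITIVE_METRICS:
        return rho
    raise InvalidParameterError(
        f"unknown metric {metric_name!r}; expected one of "
        f"{sorted(NEGATED_METRICS | POSITIVE_METRICS)}"
    )


def correlation_matrix(
    likert: pd.DataFrame,
    metrics: pd.DataFrame,
    mode: str,
    item_structure_map: dict[str, str],
    metric_names=("dsc", "ci", "inclusion", "rvd", "asd", "dc", "hd95"),
) -> pd.DataFrame:
    """Directionally-adjusted Spearman correlations, item x metric.

    Parameters
    ----------
    likert
        Tidy frame with columns ``observer_id, item_id, pre, post``.
    metrics
        Tidy frame with columns ``observer_id, phase, structure`` plus one
        column per metric name.
    mode
        ``"pre"``, ``"post"`` or ``"delta"``; delta correlates the
        per-observer (post - pre) changes on both sides.
    item_structure_map
        Maps each questionnaire item to the structure label whose metrics
        it is correlated against.

    Returns a tidy frame with columns ``item_id, structure, metric,
    rho, rho_adjusted, p_value, n``.
    """
    if mode not in {"pre", "post", "delta"}:
        raise InvalidParameterError(f"mode must be pre|post|delta, got {mode!r}")

    # accept the tidy cohort table's unit-suffixed column names
    metrics = metrics.rename(
        columns={"asd_mm": "asd", "dc_mm": "dc", "hd95_mm": "hd95", "volume_cm3": "volume"}
    )
    wide = metrics.pivot_table(
        index=["observer_id", "structure"], columns="phase",
        values=list(metric_names), aggfunc="first",
    )
    rows = []
    for item_id, structure in item_structure_map.items():
        item_scores = likert[likert["item_id"] == item_id].set_index("observer_id")
        for metric in metric_names:
            pairs = []
            for obs, scores in item_scores.iterrows():
                try:
                    m_pre = wide.loc[(obs, structure), (metric, "pre")]
                    m_post = wide.loc[(obs, structure), (metric, "post")]
                except KeyError:
                    continue
                if pd.isna(m_pre) or pd.isna(m_post):
                    continue
                if mode == "pre":
                    pairs.append((scores["pre"], m_pre))
                elif mode == "post":
                    pairs.append((scores["post"], m_post))
                else:
                    pairs.append((scores["post"] - scores["pre"], m_post - m_pre))
            if len(pairs) < 3:
                raise InsufficientDataError(
                    f"item {item_id!r} x metric {metric!r}: only {len(pairs)} "
                    "observers have both data sources (need >= 3)"
                )
            subj, obj = map(np.asarray, zip(*pairs))
            rho, p = spearman_rho(subj, obj)
            rows.append(
                {
                    "item_id": item_id,
                    "structure": structure,
                    "metric": metric,
                    "rho": rho,
                    "rho_adjusted": directional_adjust(metric, rho),
                    "p_value": p,
                    "n": len(pairs),
                }
            )
    return pd.DataFrame(rows)
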