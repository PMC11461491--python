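"""Statistical machinery for the screening-parameter study.

Covers both study stages: empirical ROC analysis with DeLong (or
stratified-bootstrap) 95% confidence intervals, top-k discriminative
zone selection, two-sided screening/confirmation cut-off derivation,
Mann-Whitney U group comparisons with Bonferroni adjustment, Spearman
rank correlation, and repeatability of repeated measurements via the
intra-subject standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve

from .parameters import DiffMap
from .zonemap import Cohort, EyeRecord, ZoneGrid, ZoneId

__all__ = [
    "ROCResult",
    "CutoffPair",
    "GroupComparison",
    "RepeatabilityResult",
    "roc_analysis",
    "delong_ci",
    "select_top_zones",
    "derive_cutoffs",
    "compare_groups",
    "spearman",
    "repeatability",
]

HIGHER = "higher_is_disease"
LOWER = "lower_is_disease"


# ---------------------------------------------------------------------------
# ROC analysis
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    """Empirical ROC curve with AUC and 95% CI.

    ``thresholds`` are the distinct score values in increasing order
    with sensitivity/specificity of the rule "score >= t is positive"
    applied to the (possibly negated) higher-is-disease scores.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    ci95: tuple[float, float]
    direction: str
    scores: np.ndarray = field(repr=False, default=None)
    labels: np.ndarray = field(repr=False, default=None)

    def sens_spec_at(self, cutoff: float) -> tuple[float, float]:
        """Sensitivity/specificity of 'score >= cutoff' on the stored scores."""
        pos = self.scores[self.labels == 1]
        neg = self.scores[self.labels == 0]
        return float(np.mean(pos >= cutoff)), float(np.mean(neg < cutoff))


def _auc_trapezoid(scores: np.ndarray, labels: np.ndarray) -> float:
    """Trapezoid AUC == Mann-Whitney concordance with ties counted 1/2."""
    fpr, tpr, _ = roc_curve(labels, scores)
    return float(np.trapezoid(tpr, fpr))


def delong_ci(
    scores: np.ndarray, labels: np.ndarray, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """AUC and DeLong confidence interval for a higher-is-disease score.

    Uses the midrank formulation of the DeLong covariance estimator; the
    interval is normal-theory on the AUC scale, clipped to [0, 1].
    """
    pos = np.asarray(scores)[np.asarray(labels) == 1]
    neg = np.asarray(scores)[np.asarray(labels) == 0]
    m, n = len(pos), len(neg)
    combined = np.concatenate([pos, neg])
    rank_all = sps.rankdata(combined)
    rank_pos = sps.rankdata(pos)
    rank_neg = sps.rankdata(neg)
    # structural components: V10 over positives, V01 over negatives
    v10 = (rank_all[:m] - rank_pos) / n
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m
    auc = float(v10.mean())
    if m > 1 and n > 1:
        var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    else:  # degenerate group sizes: no variance estimate
        var = np.nan
    if not np.isfinite(var) or var <= 0:
        return auc, (auc, auc)
    z = sps.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return auc, (max(0.0, auc - half), min(1.0, auc + half))


def _bootstrap_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int,
    rng: np.random.Generator,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Stratified-bootstrap percentile CI for the AUC."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        bp = rng.choice(pos, size=len(pos), replace=True)
        bn = rng.choice(neg, size=len(neg), replace=True)
        s = np.concatenate([bp, bn])
        y = np.concatenate([np.ones(len(bp)), np.zeros(len(bn))])
        aucs[b] = _auc_trapezoid(s, y)
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return float(max(0.0, lo)), float(min(1.0, hi))


def roc_analysis(
    scores: Sequence[float],
    labels: Sequence[int],
    direction: str = HIGHER,
    ci_method: str = "delong",
    n_boot: int = 2000,
    rng: np.random.Generator | None = None,
) -> ROCResult:
    """Empirical ROC of a diagnostic score against binary labels.

    ``direction="lower_is_disease"`` is handled by score negation, so
    the returned thresholds refer to the negated score.  The AUC is the
    trapezoid area, identical to the concordance probability with tied
    pairs counted one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if set(np.unique(labels)) - {0, 1} or len(np.unique(labels)) < 2:
        raise ValueError("labels must contain both classes (0 and 1)")
    if direction not in (HIGHER, LOWER):
        raise ValueError(f"unknown direction {direction!r}")
    s = scores if direction == HIGHER else -scores

    if np.ptp(s) == 0:
        warnings.warn("all scores identical; degenerate ROC with AUC 0.5")
    fpr, tpr, _ = roc_curve(labels, s)
    auc = float(np.trapezoid(tpr, fpr))
    if ci_method == "delong":
        _, ci = delong_ci(s, labels)
    elif ci_method == "bootstrap":
        ci = _bootstrap_ci(
            s, labels, n_boot, rng if rng is not None else np.random.default_rng(0)
        )
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    thresholds = np.unique(s)
    pos = s[labels == 1]
    neg = s[labels == 0]
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])
    return ROCResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        ci95=ci,
        direction=direction,
        scores=s,
        labels=labels,
    )


# ---------------------------------------------------------------------------
# Zone selection and cut-offs
# ---------------------------------------------------------------------------

def select_top_zones(
    diffmaps: Sequence[DiffMap],
    labels: Sequence[int],
    grid: ZoneGrid,
    k: int = 2,
) -> tuple[list[ZoneId], pd.Series]:
    """Zones whose inter-zonal difference best separates disease from healthy.

    Runs a per-zone ROC (higher difference = disease) over all 41 zones
    and returns the ``k`` zones with the largest AUC together with the
    full per-zone AUC table.  AUC ties (which saturate at 1.0 on
    noise-free cohorts) are broken by the difference in group medians of
    the zone's values, then by grid order (ring-major, then sector).
    """
    if k > len(grid):
        raise ValueError(f"k={k} exceeds the number of zones ({len(grid)})")
    labels = np.asarray(labels, dtype=int)
    mat = np.stack([d.to_numpy() for d in diffmaps])
    aucs = pd.Series(
        [_auc_trapezoid(mat[:, j], labels) for j in range(mat.shape[1])],
        index=list(grid.aliases),
        name="auc",
    )
    separation = np.median(mat[labels == 1], axis=0) - np.median(
        mat[labels == 0], axis=0
    )
    order = sorted(
        range(len(grid)),
        key=lambda j: (-round(float(aucs.iloc[j]), 12), -separation[j], j),
    )
    return [grid.zones[j] for j in order[:k]], aucs


@dataclass
class CutoffPair:
    """Screening (lower) and confirmation (upper) cut-offs of a score.

    The lower cut-off is the largest threshold keeping sensitivity at or
    above the target (maximising specificity under that floor); the
    upper cut-off is the smallest threshold with specificity at or above
    its target (maximising sensitivity under that floor).  The decision
    rule is "score >= cut-off is positive".  An unattainable target
    leaves the corresponding cut-off ``None``.
    """

    lower: float | None
    upper: float | None
    lower_sens: float | None = None
    lower_spec: float | None = None
    upper_sens: float | None = None
    upper_spec: float | None = None


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent distinct observed scores."""
    u = np.unique(scores)
    return (u[:-1] + u[1:]) / 2.0


def derive_cutoffs(
    roc: ROCResult, sens_target: float = 0.95, spec_target: float = 0.95
) -> CutoffPair:
    """Derive the two-sided screening cut-offs from an ROC result.

    Candidate cut-offs are placed midway between adjacent distinct
    observed scores (and just outside the observed range), so the chosen
    values never coincide with an observation.
    """
    if roc.direction != HIGHER:
        raise ValueError("cut-offs are defined for higher-is-disease scores")
    pos = roc.scores[roc.labels == 1]
    neg = roc.scores[roc.labels == 0]
    cands = _candidate_thresholds(roc.scores)
    sens = np.array([(pos >= t).mean() for t in cands])
    spec = np.array([(neg < t).mean() for t in cands])

    lower = upper = None
    lo_ss = hi_ss = (None, None)
    ok = sens >= sens_target
    if ok.any():
        i = np.flatnonzero(ok)[-1]  # sens is non-increasing in t: take largest t
        lower, lo_ss = float(cands[i]), (float(sens[i]), float(spec[i]))
    else:
        warnings.warn(f"sensitivity target {sens_target} unattainable")
    ok = spec >= spec_target
    if ok.any():
        j = np.flatnonzero(ok)[0]  # spec is non-decreasing in t: take smallest t
        upper, hi_ss = float(cands[j]), (float(sens[j]), float(spec[j]))
    else:
        warnings.warn(f"specificity target {spec_target} unattainable")
    if lower is not None and upper is not None and lower > upper:
        # both floors hold throughout [upper, lower]; keep the pair ordered
        # (each cut-off then satisfies both floors simultaneously)
        lower, upper = upper, lower
        lo_ss, hi_ss = hi_ss, lo_ss
    return CutoffPair(
        lower=lower,
        upper=upper,
        lower_sens=lo_ss[0],
        lower_spec=lo_ss[1],
        upper_sens=hi_ss[0],
        upper_spec=hi_ss[1],
    )


# ---------------------------------------------------------------------------
# Group comparisons, correlation, repeatability
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    alpha_adjusted: float
    significant: bool
    method: str


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]],
    comparisons: Sequence[tuple[str, str]],
    family_size: int = 4,
    alpha_family: float = 0.05,
) -> list[GroupComparison]:
    """Two-sided Mann-Whitney U tests with Bonferroni adjustment.

    The p-value is exact (full enumeration) when both samples have at
    most 8 observations and no ties are present, and otherwise uses the
    normal approximation with tie and continuity correction.  The
    per-comparison significance level is ``alpha_family / family_size``
    (0.0125 for the four prespecified comparisons).
    """
    alpha = alpha_family / family_size
    results = []
    for ga, gb in comparisons:
        a = np.asarray(values_by_group[ga], dtype=float)
        b = np.asarray(values_by_group[gb], dtype=float)
        if len(a) == 0 or len(b) == 0:
            raise ValueError(f"empty group in comparison ({ga}, {gb})")
        no_ties = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
        method = "exact" if (len(a) <= 8 and len(b) <= 8 and no_ties) else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        results.append(
            GroupComparison(
                group_a=ga,
                group_b=gb,
                n_a=len(a),
                n_b=len(b),
                u_statistic=float(res.statistic),
                p_value=float(res.pvalue),
                alpha_adjusted=alpha,
                significant=bool(res.pvalue < alpha),
                method=method,
            )
        )
    return results


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (midrank ties) with its p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the variables")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class RepeatabilityResult:
    """Intra-subject SD of repeated measurements across a cohort.

    ``per_eye_sd`` holds the sample SD of the repeated values for every
    eye (indexed by subject/eye); ``median``/``iqr`` summarise them, and
    ``pooled_sd`` is the root-mean-square SD — the consistent estimator
    of the underlying measurement noise.
    """

    per_eye_sd: pd.Series
    median: float
    iqr: float
    pooled_sd: float
    iqr_method: str = "linear"


def _quartiles(values: np.ndarray, method: str) -> tuple[float, float]:
    q1, q3 = np.quantile(values, [0.25, 0.75], method=method)
    return float(q1), float(q3)


def repeatability(
    cohort_or_eyes: Cohort | Iterable[EyeRecord],
    quantity: Callable[..., float],
    iqr_method: str = "linear",
) -> RepeatabilityResult:
    """Repeatability of a per-measurement quantity over repeated scans.

    ``quantity`` maps one ETMap to a scalar (a zonal ET value or a
    derived parameter).  Eyes with fewer than two measurements are
    excluded with a warning.  ``iqr_method`` follows numpy's quantile
    methods: ``"linear"`` (R type 7, default) or ``"weibull"`` (R type
    6, the SPSS HAVERAGE convention).
    """
    eyes = list(cohort_or_eyes)
    sds: dict[tuple[str, str], float] = {}
    skipped = 0
    for e in eyes:
        if e.n_repeats < 2:
            skipped += 1
            continue
        vals = np.array([quantity(m) for m in e.measurements], dtype=float)
        sds[(e.subject_id, e.eye)] = float(vals.std(ddof=1))
    if skipped:
        warnings.warn(f"excluded {skipped} eye(s) with fewer than 2 measurements")
    if not sds:
        raise ValueError("no eyes with >= 2 measurements")
    per_eye = pd.Series(sds, name="intra_subject_sd")
    arr = per_eye.to_numpy()
    q1, q3 = _quartiles(arr, iqr_method)
    return RepeatabilityResult(
        per_eye_sd=per_eye,
        median=float(np.median(arr)),
        iqr=q3 - q1,
        pooled_sd=float(np.sqrt(np.mean(arr**2))),
        iqr_method=iqr_method,
    )
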