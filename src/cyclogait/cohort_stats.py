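"""Rank-based cohort comparison: Mann-Whitney U, effect size, ROC, thresholds.

The evaluation rests on the identity between the Mann-Whitney U statistic
and the area under the ROC curve. With S = U/(n1*n2) taken for the smaller
orientation (U < 0.5*n1*n2), the rank-based effect size is r = 1 - 2S and
AUC = 1 - S, hence AUC = (1 + r)/2. Effect sizes are labeled very small /
small / medium / large with the large threshold at r > 0.37 (AUC > 0.685);
only large-effect parameters qualify as classifiers and get an optimal
threshold, chosen to maximize the geometric mean of sensitivity and
specificity, G = sqrt(TPR * TNR).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateROCError

#: Effect-size label boundaries (upper bounds, inclusive).
EFFECT_BOUNDS = (("very small", 0.1), ("small", 0.3), ("medium", 0.37), ("large", 1.0))
#: Classifier qualification rule: large effect only.
LARGE_EFFECT_R = 0.37


def mann_whitney(x, y, method: str = "asymptotic"):
    """Two-sided Mann-Whitney U test.

    U is the midrank statistic for the first sample's orientation (ties
    count 1/2). The default p-value uses the normal approximation with tie
    and continuity corrections, appropriate at the cohort sizes used here;
    ``method="exact"`` is available for small tie-free samples.

    Returns ``(U, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def separation(U: float, n1: int, n2: int):
    """Separation constant S and the derived effect size and AUC.

    S = U/(n1*n2) with U folded to the smaller orientation; r = 1 - 2S;
    AUC = 1 - S (equivalently (1 + r)/2).

    Returns ``(S, r, AUC)``.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    prod = n1 * n2
    if not 0 <= U <= prod:
        raise ValueError(f"U = {U} outside [0, n1*n2 = {prod}]")
    u_small = min(U, prod - U)
    s = u_small / prod
    return s, 1.0 - 2.0 * s, 1.0 - s


def effect_label(r: float) -> str:
    """Label a rank-based effect size (large when r > 0.37)."""
    if not 0 <= r <= 1:
        raise ValueError(f"effect size r = {r} outside [0, 1]")
    for label, hi in EFFECT_BOUNDS:
        if r <= hi:
            return label
    raise AssertionError("unreachable")


@dataclass
class ROCResult:
    """ROC sweep of a two-cohort score.

    ``orientation`` is ``"high"`` when larger scores flag the positive
    (diabetic) class, ``"low"`` otherwise; chosen so AUC >= 0.5.
    ``thresholds`` run from the all-negative to the all-positive sentinel,
    so TPR and FPR are non-decreasing along the sweep with endpoints (0,0)
    and (1,1). ``auc_trapezoid`` integrates the curve; ``auc_u`` comes from
    the Mann-Whitney relation — identical on tie-free data.
    """

    orientation: str
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc_trapezoid: float
    auc_u: float
    pooled_median: float
    n_pos: int
    n_neg: int


def roc_curve(scores_d, scores_h) -> ROCResult:
    """ROC curve for diabetic (positive) vs healthy (negative) scores.

    Candidate thresholds are the midpoints of consecutive sorted unique
    pooled values plus sentinels beyond both extremes.
    """
    d = np.asarray(scores_d, dtype=float)
    h = np.asarray(scores_h, dtype=float)
    if d.size < 1 or h.size < 1:
        raise ValueError("need >= 1 score per cohort")
    pooled = np.concatenate([d, h])
    uniq = np.unique(pooled)
    if uniq.size < 2:
        raise DegenerateROCError("all pooled scores identical; ROC undefined")

    u1 = float(stats.mannwhitneyu(d, h, alternative="two-sided").statistic)
    prod = d.size * h.size
    orientation = "high" if u1 >= prod / 2 else "low"

    mids = (uniq[:-1] + uniq[1:]) / 2.0
    gap = max(uniq[-1] - uniq[0], 1.0)
    if orientation == "high":
        # sweep from strict (above max: nothing positive) to permissive
        thresholds = np.concatenate([[uniq[-1] + gap], mids[::-1], [uniq[0] - gap]])
        tpr = (d[None, :] >= thresholds[:, None]).mean(axis=1)
        fpr = (h[None, :] >= thresholds[:, None]).mean(axis=1)
    else:
        thresholds = np.concatenate([[uniq[0] - gap], mids, [uniq[-1] + gap]])
        tpr = (d[None, :] <= thresholds[:, None]).mean(axis=1)
        fpr = (h[None, :] <= thresholds[:, None]).mean(axis=1)

    auc_trap = float(np.trapezoid(tpr, fpr))
    s, _, auc_u = separation(min(u1, prod - u1), d.size, h.size)
    return ROCResult(
        orientation=orientation,
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        auc_trapezoid=auc_trap,
        auc_u=float(auc_u),
        pooled_median=float(np.median(pooled)),
        n_pos=d.size,
        n_neg=h.size,
    )


def optimal_threshold(roc: ROCResult):
    """Threshold maximizing G = sqrt(TPR * TNR).

    Ties are broken by the larger Youden J = TPR + TNR - 1, then by the
    threshold closest to the pooled median. Returns ``(THR, G)``.
    """
    tnr = 1.0 - roc.fpr
    g = np.sqrt(roc.tpr * tnr)
    j = roc.tpr + tnr - 1.0
    dist = np.abs(roc.thresholds - roc.pooled_median)
    best = min(range(len(g)), key=lambda i: (-g[i], -j[i], dist[i]))
    return float(roc.thresholds[best]), float(g[best])


def confusion(scores_d, scores_h, thr: float, orientation: str = "high"):
    """Confusion percentages at a threshold.

    TP/FN are percentages of the positive (diabetic) cohort, TN/FP of the
    negative (healthy) cohort, rounded to 2 decimals.

    Returns ``(TP%, FN%, TN%, FP%)``.
    """
    d = np.asarray(scores_d, dtype=float)
    h = np.asarray(scores_h, dtype=float)
    if d.size == 0 or h.size == 0:
        raise ValueError("both cohorts must be non-empty")
    if orientation == "high":
        tp, fp = int((d >= thr).sum()), int((h >= thr).sum())
    elif orientation == "low":
        tp, fp = int((d <= thr).sum()), int((h <= thr).sum())
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    tp_pct = round(100.0 * tp / d.size, 2)
    fn_pct = round(100.0 * (d.size - tp) / d.size, 2)
    tn_pct = round(100.0 * (h.size - fp) / h.size, 2)
    fp_pct = round(100.0 * fp / h.size, 2)
    return tp_pct, fn_pct, tn_pct, fp_pct


COMPARISON_COLUMNS = [
    "parameter", "median_D", "median_H", "U", "S", "p", "r", "effect",
    "AUC", "THR", "TP_pct", "FN_pct", "TN_pct", "FP_pct", "SE", "SP",
]


def compare_cohorts(
    params_d: pd.DataFrame,
    params_h: pd.DataFrame,
    parameters: list[str] | None = None,
    threshold_r: float = LARGE_EFFECT_R,
) -> pd.DataFrame:
    """Per-parameter cohort comparison table.

    One row per parameter: cohort medians, Mann-Whitney U and p, separation
    S, effect size r with label, AUC; the optimal threshold and confusion
    percentages are filled only for large effects (r > ``threshold_r``),
    mirroring the rule that only large-effect parameters qualify as
    classifiers. Non-finite values are dropped per parameter with a
    warning; a parameter with fewer than 2 finite values per cohort yields
    an all-NA row.
    """
    if parameters is None:
        parameters = [c for c in params_d.columns if c in params_h.columns]
    if len(params_d) < 2 or len(params_h) < 2:
        raise ValueError("need >= 2 datasets per cohort")
    rows = []
    for name in parameters:
        d = params_d[name].to_numpy(dtype=float)
        h = params_h[name].to_numpy(dtype=float)
        nd, nh = np.isfinite(d), np.isfinite(h)
        if (~nd).any() or (~nh).any():
            warnings.warn(
                f"parameter {name}: dropped {int((~nd).sum())} D and {int((~nh).sum())} H "
                "non-finite values",
                stacklevel=2,
            )
        d, h = d[nd], h[nh]
        row = {c: np.nan for c in COMPARISON_COLUMNS}
        row["parameter"] = name
        if d.size < 2 or h.size < 2:
            rows.append(row)
            continue
        u, p = mann_whitney(d, h)
        s, r, auc = separation(u, d.size, h.size)
        row.update(
            median_D=float(np.median(d)),
            median_H=float(np.median(h)),
            U=u, S=s, p=p, r=r, effect=effect_label(r), AUC=auc,
        )
        if r > threshold_r:
            try:
                roc = roc_curve(d, h)
                thr, _ = optimal_threshold(roc)
                tp, fn, tn, fp = confusion(d, h, thr, roc.orientation)
                row.update(THR=thr, TP_pct=tp, FN_pct=fn, TN_pct=tn, FP_pct=fp, SE=tp, SP=tn)
            except DegenerateROCError:
                warnings.warn(f"parameter {name}: degenerate ROC, no threshold", stacklevel=2)
        rows.append(row)
    return pd.DataFrame(rows, columns=COMPARISON_COLUMNS)


@dataclass
class CorrelationResult:
    """OLS fit of (transformed) BI against a (transformed) parameter."""

    transform: tuple[str, str]
    slope: float
    intercept: float
    r_squared: float
    p: float
    n: int


_TRANSFORMS = {"identity": lambda v: v, "log10": np.log10}


def correlate_with_bi(values, bi_values, transform=("identity", "log10")) -> CorrelationResult:
    """Least-squares correlation of a parameter with the Balance Index.

    ``transform`` names the per-axis transforms ``(parameter, BI)``; the BI
    is conventionally log-transformed. The regression is BI-transform on
    parameter-transform; R^2 and the two-sided slope p-value are reported.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(bi_values, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError(f"need >= 3 paired finite values, got {x.size}")
    tx, ty = transform
    for name, v in ((tx, x), (ty, y)):
        if name not in _TRANSFORMS:
            raise ValueError(f"unknown transform {name!r}")
        if name == "log10" and np.any(v <= 0):
            raise ValueError("log10 transform requires positive values")
    x, y = _TRANSFORMS[tx](x), _TRANSFORMS[ty](y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance on an axis; R^2 undefined")
    fit = stats.linregress(x, y)
    return CorrelationResult(
        transform=(tx, ty),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p=float(fit.pvalue),
        n=int(x.size),
    )
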