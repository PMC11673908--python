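"""The fifteen cyclogram parameters, including the Balance Index.

Geometry parameters are computed from per-side cluster mean positions:
marker positions (side-averaged), the distances AE (gait line), BD
(single-support line), AB, BC, CD, DE, and the ratios Ra = BC/AB and
Rp = CD/DE. The B-C and C-D distances pair markers by temporal adjacency on
the cyclogram (B_L with C_LR, C_LR with D_R, and mirrored), then average
the two sides.

The Balance Index (BI) summarizes marker scatter: for each cluster the
product sigma_x * sigma_y (sample standard deviations) measures its
scattering area; left and right areas are summed per zone (both C clusters
for zone C) and the BI is the sum of the five zone areas, optionally
rescaled so that its ROC-optimal threshold sits at 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .errors import CalibrationError, ClusteringError

PARAM_NAMES = [
    "AE", "BD", "ap_C", "lat_C", "ap_A", "ap_B", "ap_D", "ap_E",
    "AB", "BC", "CD", "DE", "Ra", "Rp", "BI",
]

ZONES = ("A", "B", "C", "D", "E")


@dataclass
class ClusterStats:
    """Scatter statistics of one marker cluster."""

    label: str
    mean_x: float
    mean_y: float
    sigma_x: float
    sigma_y: float

    @property
    def area(self) -> float:
        """Scattering area sigma_x * sigma_y."""
        return self.sigma_x * self.sigma_y

    @property
    def mean(self) -> np.ndarray:
        return np.array([self.mean_x, self.mean_y])


def cluster_stats(points, label: str = "") -> ClusterStats:
    """Mean and sample standard deviations (n-1 denominator) of a cluster."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ClusteringError(f"cluster {label or '?'}: expected (n, 2) points")
    if len(pts) < 2:
        raise ClusteringError(f"cluster {label or '?'}: need >= 2 points for standard deviations")
    mx, my = pts.mean(axis=0)
    sx, sy = pts.std(axis=0, ddof=1)
    return ClusterStats(label=label, mean_x=mx, mean_y=my, sigma_x=sx, sigma_y=sy)


@dataclass
class BalanceIndexResult:
    """Zone scattering areas and their sum, raw and rescaled."""

    zone_areas: dict[str, float]  # A..E, each left + right cluster area
    bi_raw: float
    scale: float
    percent: dict[str, float]  # contribution per zone, NaN when BI = 0

    @property
    def bi(self) -> float:
        return self.scale * self.bi_raw


_ZONE_CLUSTERS = {
    "A": ("A_L", "A_R"),
    "B": ("B_L", "B_R"),
    "C": ("C_LR", "C_RL"),
    "D": ("D_L", "D_R"),
    "E": ("E_L", "E_R"),
}


def balance_index(clusters: dict[str, np.ndarray], scale: float = 1.0) -> BalanceIndexResult:
    """Balance Index from the ten marker clusters.

    Zone areas sum the two corresponding clusters' sigma_x * sigma_y; the
    raw BI is the sum over the five zones and ``bi = scale * bi_raw``.
    Percent contributions are NaN (with a warning) when the BI is zero.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    zone_areas = {}
    for zone, labels in _ZONE_CLUSTERS.items():
        areas = []
        for lab in labels:
            if lab not in clusters:
                raise ClusteringError(f"missing cluster {lab} for zone {zone}")
            areas.append(cluster_stats(clusters[lab], lab).area)
        zone_areas[zone] = float(sum(areas))
    bi_raw = float(sum(zone_areas.values()))
    if bi_raw > 0:
        percent = {z: 100.0 * a / bi_raw for z, a in zone_areas.items()}
    else:
        warnings.warn("BI is zero; percent contributions undefined", stacklevel=2)
        percent = {z: float("nan") for z in zone_areas}
    return BalanceIndexResult(zone_areas=zone_areas, bi_raw=bi_raw, scale=scale, percent=percent)


def calibrate_bi_scale(raw_bi_d, raw_bi_h) -> float:
    """Scale constant putting the raw-BI ROC-optimal threshold at 100.

    Follows the study convention of reporting the BI in units where the
    optimal diabetic/healthy discrimination threshold equals 100.
    """
    from .cohort_stats import optimal_threshold, roc_curve
    from .errors import DegenerateROCError

    raw_bi_d = np.asarray(raw_bi_d, dtype=float)
    raw_bi_h = np.asarray(raw_bi_h, dtype=float)
    try:
        roc = roc_curve(raw_bi_d, raw_bi_h)
        thr, _ = optimal_threshold(roc)
    except DegenerateROCError as exc:
        raise CalibrationError(f"cannot calibrate BI scale: {exc}") from exc
    if thr <= 0:
        raise CalibrationError(f"raw optimal threshold {thr} is not positive")
    return 100.0 / thr


@dataclass
class ParameterVector:
    """The 15 cyclogram parameters of one dataset (insole-length units)."""

    AE: float
    BD: float
    ap_C: float
    lat_C: float
    ap_A: float
    ap_B: float
    ap_D: float
    ap_E: float
    AB: float
    BC: float
    CD: float
    DE: float
    Ra: float
    Rp: float
    BI: float

    def to_series(self) -> pd.Series:
        return pd.Series({f.name: getattr(self, f.name) for f in fields(self)})


def _dist(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.hypot(*(a - b)))


def geometry_parameters(clusters: dict[str, np.ndarray]) -> dict[str, float]:
    """The 14 geometry parameters (positions, distances, ratios).

    Distances are computed between per-side cluster mean positions and then
    averaged over sides; positions are side-averaged cluster means (ap_C and
    lat_C average the two C clusters).
    """
    m = {lab: cluster_stats(pts, lab).mean for lab, pts in clusters.items()}
    for lab in _required_labels():
        if lab not in m:
            raise ClusteringError(f"missing cluster {lab}")

    def side_avg(pair):
        return 0.5 * (pair[0] + pair[1])

    out = {
        "ap_C": float(side_avg((m["C_LR"][1], m["C_RL"][1]))),
        "lat_C": float(side_avg((m["C_LR"][0], m["C_RL"][0]))),
        "ap_A": float(side_avg((m["A_L"][1], m["A_R"][1]))),
        "ap_B": float(side_avg((m["B_L"][1], m["B_R"][1]))),
        "ap_D": float(side_avg((m["D_L"][1], m["D_R"][1]))),
        "ap_E": float(side_avg((m["E_L"][1], m["E_R"][1]))),
        "AE": side_avg((_dist(m["A_L"], m["E_L"]), _dist(m["A_R"], m["E_R"]))),
        "BD": side_avg((_dist(m["B_L"], m["D_L"]), _dist(m["B_R"], m["D_R"]))),
        "AB": side_avg((_dist(m["A_L"], m["B_L"]), _dist(m["A_R"], m["B_R"]))),
        # temporal adjacency on the cyclogram: B_L -> C_LR -> D_R, B_R -> C_RL -> D_L
        "BC": side_avg((_dist(m["B_L"], m["C_LR"]), _dist(m["B_R"], m["C_RL"]))),
        "CD": side_avg((_dist(m["C_LR"], m["D_R"]), _dist(m["C_RL"], m["D_L"]))),
        "DE": side_avg((_dist(m["D_L"], m["E_L"]), _dist(m["D_R"], m["E_R"]))),
    }
    if out["AB"] == 0:
        raise ZeroDivisionError("Ra undefined: distance AB is zero")
    if out["DE"] == 0:
        raise ZeroDivisionError("Rp undefined: distance DE is zero")
    out["Ra"] = out["BC"] / out["AB"]
    out["Rp"] = out["CD"] / out["DE"]
    return out


def _required_labels():
    labels = set()
    for pair in _ZONE_CLUSTERS.values():
        labels.update(pair)
    return labels


def compute_parameters(clusters: dict[str, np.ndarray], bi_scale: float = 1.0) -> ParameterVector:
    """Full 15-parameter vector for one dataset's marker clusters."""
    geom = geometry_parameters(clusters)
    bi = balance_index(clusters, scale=bi_scale)
    return ParameterVector(**geom, BI=bi.bi)


def parameters_table(vectors, meta: list[dict] | None = None) -> pd.DataFrame:
    """One row per dataset: metadata columns then the 15 parameters."""
    rows = []
    for i, v in enumerate(vectors):
        row = dict(meta[i]) if meta else {}
        row.update(v.to_series().to_dict())
        rows.append(row)
    return pd.DataFrame(rows)
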