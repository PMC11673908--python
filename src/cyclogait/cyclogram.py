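"""Combined-COP cyclogram construction and marker-point extraction.

The cyclogram (butterfly diagram) is the path of the force-weighted average
of the two feet's COPs:

    x_C = (F_R x_R + F_L x_L) / (F_R + F_L),  and likewise for y.

During single support it coincides with the loaded foot's gait line; during
double support it traces the transfer diagonals whose crossings are the
intersection markers C.

Ten marker points are extracted per stride, five per side:

* ``E`` — rearmost own-foot COP over the stance (minimum antero-posterior
  coordinate);
* ``A`` — frontmost own-foot COP (maximum antero-posterior coordinate);
* ``D`` — the minimum-ap combined-COP sample of the single-support window
  (the cyclogram's turning point at contralateral toe-off);
* ``B`` — the maximum-ap combined-COP sample of that window (the turning
  point at contralateral heel strike);
* ``C_LR``/``C_RL`` — intersections of each double-support transfer path
  with the temporally preceding opposite transfer.

Ties in extremum searches are broken by the earliest sample. When two
transfer polylines do not properly cross (pathological gait), the midpoint
of their closest-approach pair is used instead and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ClusteringError, MarkerError
from .gait_events import GaitCycle
from .io_formats import InsoleRecording

CLUSTER_LABELS = ("A_L", "A_R", "B_L", "B_R", "C_LR", "C_RL", "D_L", "D_R", "E_L", "E_R")


def combine_cop(f_l, x_l, y_l, f_r, x_r, y_r):
    """Force-weighted average of the two feet's COPs (vectorized).

    Samples where a foot's force is (numerically) zero ignore that foot's
    COP, so single support collapses to the loaded foot's COP. Samples with
    zero total force are returned as NaN (undefined during flight), not
    raised.

    Returns ``(x, y)`` arrays (scalars in, scalars out).
    """
    f_l, x_l, y_l, f_r, x_r, y_r = map(np.asarray, (f_l, x_l, y_l, f_r, x_r, y_r))
    scalar = f_l.ndim == 0
    f_l, x_l, y_l, f_r, x_r, y_r = map(np.atleast_1d, (f_l, x_l, y_l, f_r, x_r, y_r))
    if np.any(f_l < 0) or np.any(f_r < 0):
        raise ValueError("forces must be non-negative")
    fmax = max(f_l.max(initial=0.0), f_r.max(initial=0.0))
    tol = 1e-9 * fmax
    wl = np.where(f_l > tol, f_l, 0.0)
    wr = np.where(f_r > tol, f_r, 0.0)
    tot = wl + wr
    with np.errstate(invalid="ignore", divide="ignore"):
        x = np.where(tot > 0, (wr * np.nan_to_num(x_r) + wl * np.nan_to_num(x_l)) / tot, np.nan)
        y = np.where(tot > 0, (wr * np.nan_to_num(y_r) + wl * np.nan_to_num(y_l)) / tot, np.nan)
    # a loaded foot with an invalid COP poisons the combined point
    bad = ((wl > 0) & ~np.isfinite(x_l + y_l)) | ((wr > 0) & ~np.isfinite(x_r + y_r))
    x, y = np.where(bad, np.nan, x), np.where(bad, np.nan, y)
    if scalar:
        return float(x[0]), float(y[0])
    return x, y


def cyclogram_path(rec: InsoleRecording) -> np.ndarray:
    """Combined-COP path for a whole recording, shape (n, 2); NaN in flight."""
    x, y = combine_cop(
        rec.left.f, rec.left.cop_x, rec.left.cop_y, rec.right.f, rec.right.cop_x, rec.right.cop_y
    )
    return np.column_stack([x, y])


@dataclass
class MarkerSet:
    """The ten 2-D marker points of one stride.

    ``points`` maps cluster label to an (x, y) array; ``c_method`` records
    per C marker whether a true polyline crossing was found
    (``"intersection"``) or the closest-approach fallback was used.
    """

    points: dict[str, np.ndarray]
    c_method: dict[str, str] = field(default_factory=dict)

    def ap_ordering_ok(self) -> bool:
        """Physiological check: ap(E) <= ap(D) <= ap(B) <= ap(A) per side."""
        ok = True
        for s in ("L", "R"):
            e, d, b, a = (self.points[f"{k}_{s}"][1] for k in "EDBA")
            ok &= e <= d <= b <= a
        return bool(ok)


def _own_extrema(rec: InsoleRecording, side: str, start: int, stop: int):
    """(E, A) = rearmost/frontmost valid own-foot COP in [start, stop)."""
    tr = rec.left if side == "L" else rec.right
    idx = np.arange(start, stop)
    valid = tr.valid()[start:stop]
    if valid.sum() < 3:
        raise MarkerError(
            f"{side} stance [{start}, {stop}) has {int(valid.sum())} valid COP samples (< 3)"
        )
    idx = idx[valid]
    ap = tr.cop_y[idx]
    i_e = idx[np.argmin(ap)]  # argmin/argmax return the first (earliest) tie
    i_a = idx[np.argmax(ap)]
    pts = np.column_stack([tr.cop_x, tr.cop_y])
    return pts[i_e], pts[i_a]


def _window_extrema(path: np.ndarray, start: int, stop: int):
    """(D, B) = min/max-ap combined-COP samples in the half-open window."""
    seg = path[start:stop]
    valid = np.isfinite(seg).all(axis=1)
    if valid.sum() < 2:
        raise MarkerError(f"single-support window [{start}, {stop}) has < 2 valid samples")
    idx = np.flatnonzero(valid)
    ap = seg[idx, 1]
    return seg[idx[np.argmin(ap)]], seg[idx[np.argmax(ap)]]


def extract_foot_markers(cycle: GaitCycle, rec: InsoleRecording, path: np.ndarray | None = None):
    """Extract the eight per-foot markers E, A, D, B (both sides) of a stride.

    E/A are extremes of the own-foot COP over its stance; D/B are extremes
    of the combined COP over the single-support window bounded by the
    contralateral toe-off and heel-strike events.
    """
    if path is None:
        path = cyclogram_path(rec)
    out = {}
    out["E_L"], out["A_L"] = _own_extrema(rec, "L", cycle.hs_l, cycle.to_l)
    out["E_R"], out["A_R"] = _own_extrema(rec, "R", cycle.hs_r, cycle.to_r)
    out["D_L"], out["B_L"] = _window_extrema(path, *cycle.ss_l)
    out["D_R"], out["B_R"] = _window_extrema(path, *cycle.ss_r)
    return out


def _seg_intersection(p0, p1, q0, q1):
    """Parameters (t, u) of the crossing of segments p0-p1 and q0-q1, or None."""
    d1, d2 = p1 - p0, q1 - q0
    denom = d1[0] * d2[1] - d1[1] * d2[0]
    scale = max(abs(d1).max(), abs(d2).max(), 1e-300)
    if abs(denom) <= 1e-12 * scale * scale:
        return None  # parallel or degenerate
    w = q0 - p0
    t = (w[0] * d2[1] - w[1] * d2[0]) / denom
    u = (w[0] * d1[1] - w[1] * d1[0]) / denom
    if -1e-12 <= t <= 1 + 1e-12 and -1e-12 <= u <= 1 + 1e-12:
        return t, u
    return None


def _closest_approach(p: np.ndarray, q: np.ndarray):
    """Midpoint of the closest pair of points between two polylines.

    Evaluated on a dense resampling of each segment; adequate as a fallback
    for near-miss transfer paths.
    """
    def densify(poly):
        out = [poly[0]]
        for a, b in zip(poly[:-1], poly[1:]):
            for s in np.linspace(0, 1, 21)[1:]:
                out.append(a + s * (b - a))
        return np.asarray(out)

    dp, dq = densify(p), densify(q)
    d2 = ((dp[:, None, :] - dq[None, :, :]) ** 2).sum(axis=2)
    i, j = np.unravel_index(np.argmin(d2), d2.shape)
    return (dp[i] + dq[j]) / 2.0


def intersect_transfers(p, q):
    """First proper crossing of transfer polyline ``p`` with polyline ``q``.

    Segments of ``p`` are scanned in temporal order (then by position along
    the segment); the first crossing with any segment of ``q`` is returned
    with method ``"intersection"``. If no crossing exists the midpoint of
    the closest-approach pair is returned with method ``"closest_approach"``.

    Returns ``(point, method)``.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    p = p[np.isfinite(p).all(axis=1)]
    q = q[np.isfinite(q).all(axis=1)]
    if len(p) < 2 or len(q) < 2:
        raise MarkerError("transfer polylines need >= 2 valid points to intersect")
    for i in range(len(p) - 1):
        hits = []
        for j in range(len(q) - 1):
            res = _seg_intersection(p[i], p[i + 1], q[j], q[j + 1])
            if res is not None:
                hits.append((res[0], j))
        if hits:
            t, _ = min(hits)
            return p[i] + t * (p[i + 1] - p[i]), "intersection"
    return _closest_approach(p, q), "closest_approach"


def extract_marker_set(cycle: GaitCycle, rec: InsoleRecording, path: np.ndarray | None = None) -> MarkerSet:
    """All ten markers of one stride, including the C intersections.

    ``C_LR`` is the crossing of the stride's left-to-right transfer with the
    right-to-left transfer that opens the stride; ``C_RL`` the crossing of
    the closing right-to-left transfer with that left-to-right transfer.
    """
    if path is None:
        path = cyclogram_path(rec)
    pts = extract_foot_markers(cycle, rec, path)
    tr_rl_prev = path[slice(*cycle.ds_rl_prev)]
    tr_lr = path[slice(*cycle.ds_lr)]
    tr_rl = path[slice(*cycle.ds_rl)]
    c_method = {}
    pts["C_LR"], c_method["C_LR"] = intersect_transfers(tr_lr, tr_rl_prev)
    pts["C_RL"], c_method["C_RL"] = intersect_transfers(tr_rl, tr_lr)
    return MarkerSet(points=pts, c_method=c_method)


def collect_clusters(marker_sets: list[MarkerSet]) -> dict[str, np.ndarray]:
    """Stack per-stride markers into the ten labeled clusters.

    Returns a mapping label -> (n_strides, 2) array. Every cluster needs at
    least 2 points (standard deviations are taken downstream).
    """
    if len(marker_sets) < 2:
        raise ClusteringError(f"need >= 2 accepted strides to form clusters, got {len(marker_sets)}")
    clusters = {}
    for label in CLUSTER_LABELS:
        pts = [ms.points[label] for ms in marker_sets if label in ms.points]
        if len(pts) < 2:
            raise ClusteringError(f"cluster {label} has {len(pts)} points (< 2)")
        clusters[label] = np.asarray(pts, dtype=float)
    return clusters


def cluster_counts(clusters: dict[str, np.ndarray]) -> dict[str, int]:
    return {k: int(len(v)) for k, v in clusters.items()}
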