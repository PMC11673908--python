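"""Reading, writing and basic conversions for dual-insole recordings.

A recording holds synchronized per-foot vertical-force and centre-of-pressure
(COP) time series. COP coordinates follow the package convention:

* ``cop_y`` — antero-posterior, normalized by insole length, 0 at the heel
  end and 1 at the toe end;
* ``cop_x`` — lateral, right-positive, with each insole's lateral midline at
  0 and the left foot mirrored about its midline (so a laterally symmetric
  gait has left/right markers at opposite ``cop_x``).

COP coordinates are undefined while the foot is airborne; invalid samples
are stored as NaN. The canonical file dialect is a long-form CSV with
columns ``t, fL, xL, yL, fR, xR, yR``; per-sensor pressure frames plus a
sensor-layout table can be reduced to force + COP with
:func:`pressure_to_force_cop`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, InputError, ParseError

#: Relative force below which the COP is considered undefined (swing phase).
COP_VALIDITY_REL = 1e-9

RECORDING_COLUMNS = ["t", "fL", "xL", "yL", "fR", "xR", "yR"]


@dataclass
class FootTrace:
    """Per-foot time series: vertical force and COP coordinates.

    ``cop_x``/``cop_y`` are NaN wherever the force is below the validity
    threshold (COP undefined in swing).
    """

    f: np.ndarray
    cop_x: np.ndarray
    cop_y: np.ndarray

    def __post_init__(self):
        self.f = np.asarray(self.f, dtype=float)
        self.cop_x = np.asarray(self.cop_x, dtype=float)
        self.cop_y = np.asarray(self.cop_y, dtype=float)
        if not (len(self.f) == len(self.cop_x) == len(self.cop_y)):
            raise InputError("force and COP arrays must have equal length")
        if np.any(self.f < 0):
            raise InputError("vertical force must be non-negative")

    def __len__(self) -> int:
        return len(self.f)

    def valid(self) -> np.ndarray:
        """Boolean mask of samples with a defined COP."""
        fmax = self.f.max(initial=0.0)
        return (self.f > COP_VALIDITY_REL * fmax) & np.isfinite(self.cop_x) & np.isfinite(self.cop_y)


@dataclass
class InsoleRecording:
    """Synchronized left/right insole recording.

    Parameters
    ----------
    t : array
        Sample times in seconds, strictly increasing, uniform ``1/rate``.
    left, right : FootTrace
        Per-foot traces of equal length.
    rate : float
        Sampling frequency in Hz.
    insole_length_l, insole_length_r : float or None
        Physical insole lengths in mm; required to normalize raw data.
    normalized : bool
        True when COP coordinates are already insole-length normalized.
    meta : dict
        Free-form metadata (participant id, dataset id, cohort label).
    """

    t: np.ndarray
    left: FootTrace
    right: FootTrace
    rate: float
    insole_length_l: float | None = None
    insole_length_r: float | None = None
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        if self.rate <= 0:
            raise InputError("sampling rate must be positive")
        if len(self.left) != len(self.right) or len(self.t) != len(self.left):
            raise InputError("left/right/t must have equal length")
        if len(self.t) > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise InputError("sample times must be strictly increasing")
            if not np.allclose(dt, 1.0 / self.rate, rtol=1e-6, atol=1e-9):
                raise InputError("sample spacing must equal 1/rate")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class SensorLayout:
    """Positions (mm, insole frame) and areas (mm^2) of pressure sensors."""

    ids: np.ndarray
    positions: np.ndarray  # (n, 2): x lateral, y antero-posterior, mm
    areas: np.ndarray  # (n,) mm^2

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        self.positions = np.asarray(self.positions, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if len(np.unique(self.ids)) != len(self.ids):
            raise InputError("sensor ids must be unique")
        if np.any(self.areas <= 0):
            raise InputError("sensor areas must be positive")
        if self.positions.shape != (len(self.ids), 2):
            raise InputError("positions must be (n_sensors, 2)")

    def index_of(self, ids) -> np.ndarray:
        order = {s: i for i, s in enumerate(self.ids.tolist())}
        try:
            return np.array([order[s] for s in ids], dtype=int)
        except KeyError as exc:
            raise InputError(f"unknown sensor id: {exc.args[0]!r}") from None


def pressure_to_force_cop(frame, layout: SensorLayout, ids=None):
    """Reduce one per-sensor pressure frame to total force and COP.

    ``F = sum(p_i * a_i)`` and ``COP = sum(p_i * a_i * pos_i) / F`` — the
    area-weighted centroid of the pressure field. When the total force is
    below machine tolerance the COP is returned as NaN.

    Parameters
    ----------
    frame : array
        Pressures, one per sensor; same order as ``layout`` unless ``ids``
        gives an explicit sensor-id order.
    layout : SensorLayout
    ids : sequence, optional
        Sensor ids corresponding to ``frame`` entries.

    Returns
    -------
    (F, cop) : float, ndarray shape (2,)
    """
    p = np.asarray(frame, dtype=float)
    if np.any(p < 0):
        raise InputError("pressures must be non-negative")
    if ids is not None:
        idx = layout.index_of(ids)
        pos, area = layout.positions[idx], layout.areas[idx]
    else:
        if len(p) != len(layout.ids):
            raise InputError("frame length does not match layout")
        pos, area = layout.positions, layout.areas
    w = p * area
    f = float(w.sum())
    if f <= COP_VALIDITY_REL * max(w.max(initial=0.0) * len(w), 1e-300):
        return f, np.array([np.nan, np.nan])
    cop = (w[:, None] * pos).sum(axis=0) / f
    return f, cop


def frames_to_trace(frames, layout: SensorLayout, ids=None) -> FootTrace:
    """Vectorize :func:`pressure_to_force_cop` over a (n_samples, n_sensors) array."""
    frames = np.atleast_2d(np.asarray(frames, dtype=float))
    out_f = np.empty(len(frames))
    out_xy = np.empty((len(frames), 2))
    for i, fr in enumerate(frames):
        out_f[i], out_xy[i] = pressure_to_force_cop(fr, layout, ids=ids)
    return FootTrace(out_f, out_xy[:, 0], out_xy[:, 1])


def normalize_recording(rec: InsoleRecording, lateral_offset: float = 0.0) -> InsoleRecording:
    """Normalize COP coordinates to the insole lengths.

    Both coordinates of each foot are divided by that foot's insole length,
    leaving ``cop_y`` in [0, 1] heel→toe. Already-normalized recordings are
    returned unchanged (idempotent). ``lateral_offset`` shifts the two feet
    apart in the shared lateral frame (in normalized units, default 0).
    """
    if rec.normalized:
        return rec
    if not rec.insole_length_l or not rec.insole_length_r:
        raise ConfigError("insole lengths are required to normalize a recording")
    if rec.insole_length_l <= 0 or rec.insole_length_r <= 0:
        raise ConfigError("insole lengths must be positive")

    def _norm(tr: FootTrace, length: float, sign: float) -> FootTrace:
        return FootTrace(
            tr.f,
            sign * tr.cop_x / length + sign * lateral_offset,
            tr.cop_y / length,
        )

    # left foot mirrored about its lateral midline (sign -1)
    return replace(
        rec,
        left=_norm(rec.left, rec.insole_length_l, -1.0),
        right=_norm(rec.right, rec.insole_length_r, +1.0),
        normalized=True,
    )


def recording_to_frame(rec: InsoleRecording) -> pd.DataFrame:
    """Recording as a long-form DataFrame in the canonical column dialect."""
    return pd.DataFrame(
        {
            "t": rec.t,
            "fL": rec.left.f,
            "xL": rec.left.cop_x,
            "yL": rec.left.cop_y,
            "fR": rec.right.f,
            "xR": rec.right.cop_x,
            "yR": rec.right.cop_y,
        }
    )


def write_recording(rec: InsoleRecording, path) -> None:
    recording_to_frame(rec).to_csv(path, index=False, float_format="%.9g")


def read_recording(path, config: dict | None = None) -> InsoleRecording:
    """Read an insole recording from CSV.

    ``config`` may remap column names (``columns: {t: ..., fL: ...}``) and
    supply ``rate``, ``insole_length_l/r``, ``normalized`` and ``meta``.
    The rate defaults to the reciprocal median time step.
    """
    config = dict(config or {})
    colmap = {c: c for c in RECORDING_COLUMNS}
    colmap.update(config.get("columns", {}))
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        line = _parser_error_line(exc)
        raise ParseError(f"malformed CSV in {path}: {exc}", line=line) from exc
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}", line=1)
    t = df[colmap["t"]].to_numpy(dtype=float)
    rate = config.get("rate")
    if rate is None:
        if len(t) < 2:
            raise ParseError(f"{path}: cannot infer sampling rate from <2 samples")
        rate = 1.0 / float(np.median(np.diff(t)))
    return InsoleRecording(
        t=t,
        left=FootTrace(df[colmap["fL"]], df[colmap["xL"]], df[colmap["yL"]]),
        right=FootTrace(df[colmap["fR"]], df[colmap["xR"]], df[colmap["yR"]]),
        rate=float(rate),
        insole_length_l=config.get("insole_length_l"),
        insole_length_r=config.get("insole_length_r"),
        normalized=bool(config.get("normalized", False)),
        meta=dict(config.get("meta", {})),
    )


def _parser_error_line(exc) -> int | None:
    import re

    m = re.search(r"line (\d+)", str(exc))
    return int(m.group(1)) if m else None


def write_parameters(table: pd.DataFrame, path) -> None:
    """Write a parameter table (one row per dataset) as CSV."""
    table.to_csv(path, index=False, float_format="%.9g")


def read_parameters(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ParseError(f"malformed parameter CSV {path}: {exc}", line=_parser_error_line(exc)) from exc


def write_report(report: dict, path) -> None:
    """Write a cohort-comparison (or QC) report as JSON."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return json.loads(o.to_json(orient="records"))
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(report, indent=2, default=_default, allow_nan=True))


def load_config(path) -> dict:
    """Load a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return cfg
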