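"""Gait-event detection: stance intervals, stride assembly, step validation.

Stance is detected from the vertical force with a relative threshold that is
bootstrapped in two passes: a provisional pass at ``threshold_rel * max(F)``
finds candidate stances, and the final threshold is ``threshold_rel`` times
the median per-stance peak force. This makes detection invariant to scaling
the force trace by any positive constant.

Intervals are half-open sample ranges ``[start, stop)``: ``start`` is the
first loaded sample (the heel-strike event) and ``stop`` the first unloaded
sample after it (the toe-off event).

A stride (gait cycle) is anchored on a left stance and spans the cyclogram's
temporal sequence D_L - B_L - C_LR - D_R - B_R - C_RL: it requires the
previous right toe-off and the next right stance inside the left stance, and
the following left heel strike inside that right stance. The double-support
windows are the stance overlaps; single support is the remainder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import StepValidationError

#: Default relative force threshold (fraction of median per-stance peak).
THRESHOLD_REL = 0.05
#: Default minimum stance duration in seconds.
MIN_STANCE_S = 0.2
#: Default relative band for step validation (fraction of the median).
VALIDATION_BAND = 0.3


@dataclass(frozen=True)
class StanceInterval:
    """One foot-loaded interval, half-open in samples: [start, stop)."""

    side: str  # "left" | "right"
    start: int  # heel-strike sample (first loaded)
    stop: int  # toe-off sample (first unloaded)

    def __post_init__(self):
        if self.start >= self.stop:
            raise ValueError("stance interval must satisfy start < stop")

    @property
    def duration(self) -> int:
        return self.stop - self.start

    def overlap(self, other: "StanceInterval") -> tuple[int, int] | None:
        lo, hi = max(self.start, other.start), min(self.stop, other.stop)
        return (lo, hi) if lo < hi else None


@dataclass(frozen=True)
class GaitCycle:
    """One complete stride anchored on a left stance.

    Sample-index events (all half-open interval boundaries):

    * ``hs_l``/``to_l`` — the anchoring left stance,
    * ``to_r_prev`` — toe-off of the preceding right stance (inside it),
    * ``hs_r``/``to_r`` — the right stance starting inside it,
    * ``hs_l_next`` — the following left heel strike (inside that right
      stance).

    Derived windows (half-open): ``ds_rl_prev`` (right-to-left transfer
    opening the stride), ``ss_l``, ``ds_lr`` (left-to-right transfer),
    ``ss_r``, ``ds_rl`` (closing right-to-left transfer).
    """

    hs_l: int
    to_l: int
    to_r_prev: int
    hs_r: int
    to_r: int
    hs_l_next: int

    def __post_init__(self):
        seq = (self.hs_l, self.to_r_prev, self.hs_r, self.to_l, self.hs_l_next, self.to_r)
        if not all(a < b for a, b in zip(seq, seq[1:])):
            raise ValueError(f"gait-cycle events out of temporal order: {seq}")

    @property
    def ds_rl_prev(self) -> tuple[int, int]:
        return (self.hs_l, self.to_r_prev)

    @property
    def ss_l(self) -> tuple[int, int]:
        return (self.to_r_prev, self.hs_r)

    @property
    def ds_lr(self) -> tuple[int, int]:
        return (self.hs_r, self.to_l)

    @property
    def ss_r(self) -> tuple[int, int]:
        return (self.to_l, self.hs_l_next)

    @property
    def ds_rl(self) -> tuple[int, int]:
        return (self.hs_l_next, self.to_r)


def _runs_above(force: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """Maximal half-open runs where force >= threshold."""
    above = force >= threshold
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(edges[~above[edges]] + 1)
    stops = list(edges[above[edges]] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(len(force))
    return list(zip(starts, stops))


def detect_stance_intervals(
    force,
    rate: float,
    side: str = "left",
    threshold_rel: float = THRESHOLD_REL,
    min_stance_s: float = MIN_STANCE_S,
) -> list[StanceInterval]:
    """Detect stance intervals from a vertical-force trace.

    Returns maximal runs of ``F >= threshold`` lasting at least
    ``min_stance_s``, where the threshold is ``threshold_rel`` times the
    median per-stance peak force (bootstrapped from a provisional pass at
    ``threshold_rel * max(F)``). Empty or all-zero traces yield ``[]``.
    """
    force = np.asarray(force, dtype=float)
    if rate <= 0:
        raise ValueError("rate must be positive")
    if force.size == 0 or force.max(initial=0.0) <= 0:
        return []
    min_len = max(1, int(round(min_stance_s * rate)))

    provisional = _runs_above(force, threshold_rel * force.max())
    peaks = [force[a:b].max() for a, b in provisional if b - a >= min_len]
    if not peaks:
        peaks = [force.max()]
    threshold = threshold_rel * float(np.median(peaks))

    return [
        StanceInterval(side, a, b)
        for a, b in _runs_above(force, threshold)
        if b - a >= min_len
    ]


def assemble_gait_cycles(
    left: list[StanceInterval], right: list[StanceInterval]
) -> list[GaitCycle]:
    """Assemble complete strides from per-foot stance intervals.

    A cycle needs genuine double support on both transfers: the previous
    right stance must end strictly inside the anchoring left stance, the
    next right stance must start strictly inside it, and the following left
    heel strike must fall strictly inside that right stance. Inputs with no
    stance overlap anywhere (running-like gait) produce an empty result with
    a warning.
    """
    left = sorted(left, key=lambda s: s.start)
    right = sorted(right, key=lambda s: s.start)
    cycles: list[GaitCycle] = []
    for i, ls in enumerate(left):
        prev_to = [r.stop for r in right if ls.start < r.stop < ls.stop]
        nxt = [r for r in right if ls.start < r.start < ls.stop]
        if not prev_to or not nxt:
            continue
        rs = nxt[0]
        hs_next = [l2.start for l2 in left[i + 1 :] if rs.start < l2.start < rs.stop]
        if not hs_next:
            continue
        cycles.append(
            GaitCycle(
                hs_l=ls.start,
                to_l=ls.stop,
                to_r_prev=prev_to[0],
                hs_r=rs.start,
                to_r=rs.stop,
                hs_l_next=hs_next[0],
            )
        )
    if not cycles and left and right:
        if not any(ls.overlap(rs) for ls in left for rs in right):
            warnings.warn(
                "no double support found between left and right stances "
                "(running-like input); no gait cycles assembled",
                stacklevel=2,
            )
    return cycles


def validate_steps(
    cycles: list[GaitCycle],
    recording,
    band: float = VALIDATION_BAND,
) -> tuple[list[GaitCycle], list[tuple[int, str]]]:
    """Keep cycles whose stance durations and peak forces are regular.

    A cycle is accepted when both stance durations and both stance peak
    forces lie within ``band`` (relative) of the respective per-recording
    medians. Returns ``(accepted, rejections)`` where rejections pair the
    cycle index with a reason string.

    Raises
    ------
    StepValidationError
        If fewer than 3 cycles are supplied, or every cycle is rejected.
    """
    if len(cycles) < 3:
        raise StepValidationError(f"need >= 3 gait cycles to validate, got {len(cycles)}")
    feats = np.array(
        [
            [
                c.to_l - c.hs_l,
                c.to_r - c.hs_r,
                recording.left.f[c.hs_l : c.to_l].max(),
                recording.right.f[c.hs_r : c.to_r].max(),
            ]
            for c in cycles
        ],
        dtype=float,
    )
    med = np.median(feats, axis=0)
    names = ["left stance duration", "right stance duration", "left peak force", "right peak force"]
    accepted, rejections = [], []
    for i, (c, row) in enumerate(zip(cycles, feats)):
        bad = [
            f"{name} {v:.4g} outside +-{band:.0%} of median {m:.4g}"
            for name, v, m in zip(names, row, med)
            if not (m * (1 - band) <= v <= m * (1 + band))
        ]
        if bad:
            rejections.append((i, "; ".join(bad)))
        else:
            accepted.append(c)
    if not accepted:
        raise StepValidationError("step validation rejected every gait cycle")
    return accepted, rejections
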