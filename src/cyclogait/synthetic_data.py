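"""Synthetic two-cohort insole gait data with planted ground truth.

The generator emulates the statistical structure the analysis assumes: each
cohort has a marker-geometry template (mean positions of the ten cyclogram
clusters) and per-cluster Gaussian scatter; participants add random effects
(a whole-cyclogram translation, small per-cluster offsets, and a scatter
scale factor); datasets draw independent stride-level scatter.

Templates are seeded from the study's printed cohort medians: the
antero-posterior marker positions and the distances AB and BC (hence the
ratio Ra) are reproduced exactly, with lateral coordinates solved from
those constraints. The remaining distances follow from the resulting
geometry — the printed marginal medians are not mutually consistent as a
single point set, so they cannot all be matched at once.

Two output levels are provided:

* marker level (fast): clusters of the ten markers per dataset;
* time-series level: full 50 Hz dual-insole recordings with a double-bump
  stance force and a monotone heel-to-toe COP roll, engineered so every
  planted event falls on an exact sample and the double-support transfer
  paths are collinear with the planted diagonals (so the marker pipeline
  can recover the planted geometry exactly).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import GenerationError
from .io_formats import FootTrace, InsoleRecording

#: Printed cohort medians used to seed the default templates:
#: antero-posterior positions of E, D, B, A and C, and distances AB, BC.
_TEMPLATE_MEDIANS = {
    "diabetic": dict(ap_E=0.008, ap_D=0.377, ap_B=0.695, ap_A=0.805, ap_C=0.557, AB=0.126, BC=0.193),
    "healthy": dict(ap_E=0.004, ap_D=0.306, ap_B=0.810, ap_A=0.833, ap_C=0.564, AB=0.027, BC=0.288),
}

#: Printed per-zone Balance-Index component magnitudes (scaled units); they
#: fix the *relative* scatter of the zones (B > D > A > C > E).
_ZONE_MAGNITUDES = {
    "diabetic": dict(A=13.9, B=50.5, C=11.7, D=27.8, E=3.5),
    "healthy": dict(A=8.1, B=14.8, C=6.6, D=10.3, E=0.7),
}

#: Raw-area scale converting the printed zone magnitudes to normalized
#: insole units; chosen so healthy mid-stance clusters scatter with
#: sigma ~ 0.015 insole lengths (typical of repeated natural strides).
_SIGMA_AREA_SCALE = 3e-5

#: Lateral position of the heel-strike marker E (not constrained by the
#: printed medians; a heel lands slightly lateral of the midline).
_E_LAT = 0.02

_ZONE_OF = {
    "A_L": "A", "A_R": "A", "B_L": "B", "B_R": "B", "C_LR": "C", "C_RL": "C",
    "D_L": "D", "D_R": "D", "E_L": "E", "E_R": "E",
}


@dataclass
class CohortTemplate:
    """Marker-geometry template of one cohort.

    ``positions`` holds the right-side mean position (lat, ap) of zones
    A, B, D, E in normalized insole units; the left side is the lateral
    mirror. ``sigmas`` holds the per-cluster scatter (sigma_x, sigma_y) per
    zone. The C position is emergent: the crossing of the two planted
    double-support diagonals B_R-D_L and B_L-D_R.
    """

    name: str
    positions: dict[str, np.ndarray]
    sigmas: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        self.positions = {z: np.asarray(p, dtype=float) for z, p in self.positions.items()}
        missing = {"A", "B", "D", "E"} - set(self.positions)
        if missing:
            raise GenerationError(f"template {self.name}: missing zones {sorted(missing)}")
        ap = {z: self.positions[z][1] for z in "ABDE"}
        if not ap["E"] < ap["D"] < ap["B"] < ap["A"]:
            raise GenerationError(f"template {self.name}: ap ordering E < D < B < A violated")
        for z, s in self.sigmas.items():
            if min(s) < 0:
                raise GenerationError(f"template {self.name}: negative sigma for zone {z}")
        if self.positions["B"][0] <= 0 or self.positions["D"][0] <= 0:
            raise GenerationError(
                f"template {self.name}: B and D must sit lateral of the midline "
                "(positive lat) or the transfer diagonals cannot cross"
            )

    def intersection_point(self) -> np.ndarray:
        """Crossing of the planted diagonals B_R-D_L and B_L-D_R."""
        b, d = self.positions["B"], self.positions["D"]
        c = _cross_segments(b, _mirror(d), _mirror(b), d)
        if c is None:
            raise GenerationError(f"template {self.name}: transfer diagonals do not cross")
        return c

    def cluster_means(self) -> dict[str, np.ndarray]:
        """Mean positions of the ten clusters (left side mirrored)."""
        out = {}
        for z in "ABDE":
            out[f"{z}_R"] = self.positions[z].copy()
            out[f"{z}_L"] = _mirror(self.positions[z])
        c = self.intersection_point()
        out["C_LR"] = c.copy()
        out["C_RL"] = c.copy()
        return out

    def cluster_sigmas(self) -> dict[str, tuple[float, float]]:
        return {lab: self.sigmas.get(_ZONE_OF[lab], (0.0, 0.0)) for lab in _ZONE_OF}

    def scaled(self, sigma_factor: float) -> "CohortTemplate":
        return replace(
            self,
            sigmas={z: (sx * sigma_factor, sy * sigma_factor) for z, (sx, sy) in self.sigmas.items()},
        )


def _mirror(p: np.ndarray) -> np.ndarray:
    return np.array([-p[0], p[1]])


def _cross_segments(p0, p1, q0, q1):
    d1, d2 = p1 - p0, q1 - q0
    denom = d1[0] * d2[1] - d1[1] * d2[0]
    if abs(denom) < 1e-15:
        return None
    w = q0 - p0
    t = (w[0] * d2[1] - w[1] * d2[0]) / denom
    u = (w[0] * d1[1] - w[1] * d1[0]) / denom
    if 0 <= t <= 1 and 0 <= u <= 1:
        return p0 + t * d1
    return None


def _solve_template(name: str, med: dict, mags: dict, sigma_area_scale: float) -> CohortTemplate:
    """Build a geometrically consistent template from printed medians.

    Lateral coordinates are solved so that |B - C| = BC with C on the
    midline at ap_C (fixing lat_B and, through the diagonal crossing,
    lat_D) and |A - B| = AB (fixing lat_A, medial of B as the COP rolls
    toward the big toe).
    """
    bc_ap = med["ap_B"] - med["ap_C"]
    if med["BC"] <= bc_ap:
        raise GenerationError(f"{name}: BC must exceed its ap component")
    lat_b = float(np.sqrt(med["BC"] ** 2 - bc_ap**2))
    frac = bc_ap / (med["ap_B"] - med["ap_D"])  # = lat_b / (lat_b + lat_d)
    if not 0 < frac < 1:
        raise GenerationError(f"{name}: ap_C must lie between ap_D and ap_B")
    lat_d = lat_b * (1 - frac) / frac
    ab_ap = med["ap_A"] - med["ap_B"]
    if med["AB"] <= abs(ab_ap):
        raise GenerationError(f"{name}: AB must exceed its ap component")
    lat_a = lat_b - float(np.sqrt(med["AB"] ** 2 - ab_ap**2))
    sigmas = {
        z: (float(np.sqrt(m * sigma_area_scale / 2)),) * 2 for z, m in mags.items()
    }
    return CohortTemplate(
        name=name,
        positions={
            "A": np.array([lat_a, med["ap_A"]]),
            "B": np.array([lat_b, med["ap_B"]]),
            "D": np.array([lat_d, med["ap_D"]]),
            "E": np.array([_E_LAT, med["ap_E"]]),
        },
        sigmas=sigmas,
    )


def diabetic_template() -> CohortTemplate:
    """Default diabetic-neuropathy cohort template (collapsed BC, long AB)."""
    return _solve_template(
        "diabetic", _TEMPLATE_MEDIANS["diabetic"], _ZONE_MAGNITUDES["diabetic"], _SIGMA_AREA_SCALE
    )


def healthy_template() -> CohortTemplate:
    """Default healthy cohort template (long BC, short AB)."""
    return _solve_template(
        "healthy", _TEMPLATE_MEDIANS["healthy"], _ZONE_MAGNITUDES["healthy"], _SIGMA_AREA_SCALE
    )


@dataclass
class StudySpec:
    """Conditions of a synthetic two-cohort study.

    Defaults mirror the emulated protocol: 56 diabetic and 70 healthy
    datasets (126 total) over 14/15 participants, 12 consecutive steps
    (6 strides) per dataset at 50 Hz.
    """

    n_diabetic: int = 56
    n_healthy: int = 70
    participants_diabetic: int = 14
    participants_healthy: int = 15
    steps_per_dataset: int = 12  # a step is half a stride
    rate: float = 50.0
    stride_period: float = 1.2  # s; 100 steps/min, a comfortable pace
    stance_fraction: float = 2.0 / 3.0  # of the stride period
    force_peak: float = 700.0  # N
    sigma_scale: float = 1.0  # global multiplier on template scatter
    #: participant random effects: whole-cyclogram translation SD (lat, ap),
    #: per-cluster mean jitter SD, and log-normal scatter-factor SD
    participant_translation_sd: tuple[float, float] = (0.02, 0.05)
    participant_cluster_jitter_sd: float = 0.015
    participant_scatter_log_sd: float = 0.25

    def __post_init__(self):
        if min(self.n_diabetic, self.n_healthy, self.participants_diabetic, self.participants_healthy) <= 0:
            raise GenerationError("cohort and participant counts must be positive")
        if self.steps_per_dataset < 4:
            raise GenerationError("need at least 4 steps (2 strides) per dataset")
        if self.rate <= 0 or self.stride_period <= 0:
            raise GenerationError("rate and stride period must be positive")
        ds = self.stance_fraction - 0.5
        if not 0 < ds < 0.5:
            raise GenerationError("stance fraction must lie in (0.5, 1) for walking gait")

    @property
    def n_strides(self) -> int:
        return self.steps_per_dataset // 2


def sample_marker_clusters(
    template: CohortTemplate,
    n_strides: int,
    seed,
    mean_offsets: dict[str, np.ndarray] | None = None,
    sigma_factor: float = 1.0,
) -> dict[str, np.ndarray]:
    """Draw per-stride marker clusters around the template geometry.

    Each cluster's points are Normal(mean, diag(sigma_x^2, sigma_y^2)) with
    the template (plus optional per-cluster ``mean_offsets``) as mean.
    Reproducible for a fixed seed.
    """
    if n_strides < 2:
        raise GenerationError("need >= 2 strides per dataset")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    means = template.cluster_means()
    sigmas = template.cluster_sigmas()
    out = {}
    for lab in sorted(means):
        mu = means[lab] + (mean_offsets or {}).get(lab, 0.0)
        sx, sy = sigmas[lab]
        pts = rng.normal(mu, [sx * sigma_factor, sy * sigma_factor], size=(n_strides, 2))
        out[lab] = pts
    return out


# --- time-series generation -------------------------------------------------


def _stance_force(n_stance: int, peak: float) -> np.ndarray:
    """Double-bump vertical force over one stance (heel and push-off peaks).

    Two Gaussians at 25% and 75% of stance (sigma = stance/8), shifted so
    the force is exactly zero at both stance boundaries.
    """
    i = np.arange(n_stance + 1, dtype=float)
    c1, c2, s = n_stance / 4.0, 3.0 * n_stance / 4.0, n_stance / 8.0
    g = np.exp(-(((i - c1) / s) ** 2) / 2) + np.exp(-(((i - c2) / s) ** 2) / 2)
    g -= g[0]
    return peak * np.clip(g, 0.0, None)


def generate_recording(
    template: CohortTemplate,
    spec: StudySpec | None = None,
    seed=0,
    mean_offsets: dict[str, np.ndarray] | None = None,
    sigma_factor: float | None = None,
    meta: dict | None = None,
):
    """Generate one dual-insole recording plus its ground truth.

    Per stride, each foot's COP rolls monotonically through the planted
    markers E -> D -> B -> A (with short dwells at E, B and A so extrema
    fall on exact samples) while the vertical force traces a double bump
    that is zero outside the stance. Stances overlap by the double-support
    window, during which the combined COP runs along the planted transfer
    diagonal, so the crossings C are exactly the planted diagonal
    intersections.

    Returns ``(recording, truth)`` where ``truth`` carries planted event
    samples (heel strikes/toe-offs per foot) and, per complete interior
    stride, the ten planted marker points.
    """
    spec = spec or StudySpec()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if sigma_factor is None:
        sigma_factor = spec.sigma_scale
    n_strides = spec.n_strides
    per = int(round(spec.rate * spec.stride_period))
    half = per // 2
    stance = int(round(spec.stance_fraction * per))
    ds = stance - half
    if ds < 4 or per % 2:
        raise GenerationError(
            "stride period and stance fraction must give an even stride and >= 4 "
            "double-support samples at this rate"
        )
    n = per * n_strides
    means = template.cluster_means()
    sigmas = template.cluster_sigmas()

    def draw(lab, k):
        mu = means[lab] + (mean_offsets or {}).get(lab, 0.0)
        sx, sy = sigmas[lab]
        return rng.normal(mu, [sx * sigma_factor, sy * sigma_factor])

    # per-stride planted anchors, one set per foot
    anchors = {"L": [], "R": []}
    for k in range(n_strides):
        for side in ("L", "R"):
            anchors[side].append({z: draw(f"{z}_{side}", k) for z in "EDBA"})

    # anchor sample offsets within a stance and the marker planted there;
    # dwells at E, B and A make the extrema insensitive to one-sample
    # detection offsets, and the B dwell keeps the transfer path collinear
    # with the planted diagonal
    d_reach = min(3, ds - 1)
    offs = np.array([0, 1, d_reach, ds, half, stance - 2, stance - 1, stance], dtype=float)
    keys = ["E", "E", "D", "D", "B", "B", "A", "A"]

    def foot_trace(side: str, starts: list[int]) -> FootTrace:
        f = np.zeros(n)
        x = np.full(n, np.nan)
        y = np.full(n, np.nan)
        fprofile = _stance_force(stance, spec.force_peak)
        for k, s0 in enumerate(starts):
            a = anchors[side][k]
            pts = np.array([a[key] for key in keys])
            hi = min(s0 + stance + 1, n)
            rel = np.arange(hi - s0, dtype=float)
            x[s0:hi] = np.interp(rel, offs, pts[:, 0])
            y[s0:hi] = np.interp(rel, offs, pts[:, 1])
            f[s0:hi] = np.maximum(f[s0:hi], fprofile[: hi - s0])
        x[f <= 0] = np.nan
        y[f <= 0] = np.nan
        return FootTrace(f, x, y)

    hs_l = [per * k for k in range(n_strides)]
    hs_r = [per * k + half for k in range(n_strides)]
    rec = InsoleRecording(
        t=np.arange(n) / spec.rate,
        left=foot_trace("L", hs_l),
        right=foot_trace("R", hs_r),
        rate=spec.rate,
        normalized=True,
        meta=dict(meta or {}),
    )

    # ground truth: complete interior cycles k = 1 .. n_strides - 2
    markers = []
    for k in range(1, n_strides - 1):
        al, ar, ar_prev, al_next = anchors["L"][k], anchors["R"][k], anchors["R"][k - 1], anchors["L"][k + 1]
        c_lr = _cross_segments(al["B"], ar["D"], ar_prev["B"], al["D"])
        c_rl = _cross_segments(ar["B"], al_next["D"], al["B"], ar["D"])
        if c_lr is None or c_rl is None:
            raise GenerationError("planted transfer diagonals do not cross; check template geometry")
        markers.append(
            {
                "E_L": al["E"], "A_L": al["A"], "D_L": al["D"], "B_L": al["B"],
                "E_R": ar["E"], "A_R": ar["A"], "D_R": ar["D"], "B_R": ar["B"],
                "C_LR": c_lr, "C_RL": c_rl,
            }
        )
    truth = {
        "hs_l": hs_l,
        "hs_r": hs_r,
        "to_l": [s + stance for s in hs_l],
        "to_r": [s + stance for s in hs_r],
        "markers": markers,
        "template_means": means,
        "stride_samples": per,
        "stance_samples": stance,
    }
    return rec, truth


def _participant_effects(spec: StudySpec, template: CohortTemplate, rng):
    """Draw one participant's random effects: offsets and scatter factor."""
    lat_sd, ap_sd = spec.participant_translation_sd
    translation = rng.normal(0.0, [lat_sd, ap_sd])
    jitter_sd = spec.participant_cluster_jitter_sd
    offsets = {
        lab: translation + rng.normal(0.0, jitter_sd, size=2)
        for lab in template.cluster_means()
    }
    factor = float(np.exp(rng.normal(0.0, spec.participant_scatter_log_sd)))
    return offsets, factor


def _spread(n_datasets: int, n_participants: int) -> list[int]:
    base, extra = divmod(n_datasets, n_participants)
    return [base + (1 if i < extra else 0) for i in range(n_participants)]


def generate_study(
    spec: StudySpec | None = None,
    seed: int = 0,
    mode: str = "markers",
    templates: tuple[CohortTemplate, CohortTemplate] | None = None,
) -> list[dict]:
    """Generate the full labeled two-cohort study.

    Participant random effects are drawn once per participant; each of
    their datasets then draws independent stride-level scatter. ``mode``
    selects the output level: ``"markers"`` (fast; per-dataset
    ``clusters``) or ``"recordings"`` (full time series with ``truth``).

    Returns a list of dataset dicts with keys ``cohort`` ("D"/"H"),
    ``participant``, ``dataset`` and the mode-dependent payload.
    """
    spec = spec or StudySpec()
    if mode not in ("markers", "recordings"):
        raise ValueError(f"unknown mode {mode!r}")
    d_tpl, h_tpl = templates or (diabetic_template(), healthy_template())
    rng = np.random.default_rng(seed)
    datasets = []
    plan = [
        ("D", d_tpl, spec.n_diabetic, spec.participants_diabetic),
        ("H", h_tpl, spec.n_healthy, spec.participants_healthy),
    ]
    for cohort, tpl, n_data, n_part in plan:
        counts = _spread(n_data, n_part)
        ds_id = 0
        for p_idx, n_sets in enumerate(counts):
            offsets, factor = _participant_effects(spec, tpl, rng)
            for _ in range(n_sets):
                entry = {
                    "cohort": cohort,
                    "participant": f"{cohort}{p_idx:02d}",
                    "dataset": f"{cohort}{p_idx:02d}-{ds_id:03d}",
                }
                sf = factor * spec.sigma_scale
                if mode == "markers":
                    entry["clusters"] = sample_marker_clusters(
                        tpl, spec.n_strides, rng, mean_offsets=offsets, sigma_factor=sf
                    )
                else:
                    entry["recording"], entry["truth"] = generate_recording(
                        tpl, spec, rng, mean_offsets=offsets, sigma_factor=sf,
                        meta={"cohort": cohort, "participant": entry["participant"], "dataset": entry["dataset"]},
                    )
                datasets.append(entry)
                ds_id += 1
    return datasets
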