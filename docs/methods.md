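# Methods

This note documents the models, conventions and numerical choices behind
`cyclogait`, and what the synthetic data do and do not establish.

## Coordinate conventions

All COP coordinates are normalized by the insole length of the foot they
belong to. The antero-posterior coordinate `cop_y` runs 0 (heel end) → 1
(toe end); this origin is inferred from the magnitudes of typical marker
positions (heel-strike markers near 0.005, toe-off markers near 0.8). The
lateral coordinate `cop_x` is right-positive with each insole's lateral
midline at 0 and the left foot mirrored about its midline, so a laterally
symmetric gait places left/right markers at opposite `cop_x` and the
transfer diagonals cross near the midline. An optional lateral inter-foot
offset (default 0) can spread the feet apart. COP samples are undefined
(NaN) when the foot's force is below 1e-9 of its trace maximum — the COP
does not exist in swing.

Per-sensor pressure frames reduce to force and COP as the area-weighted
centroid: `F = Σ pᵢaᵢ`, `COP = Σ pᵢaᵢ·posᵢ / F`. The COP of a frame is by
construction a convex combination of active sensor positions.

## Gait events

Stance is `F ≥ θ` with a relative threshold bootstrapped in two passes:
provisional stances at `θ₀ = 0.05·max(F)` yield per-stance peaks, and the
final threshold is 0.05 times the median peak. The data source gives no
threshold; 5 % of peak force is standard practice in vertical-force gait
event detection, and the bootstrap makes detection exactly invariant to
rescaling the force trace. Minimum stance duration is 0.2 s (shorter bursts
are artifacts at walking cadence). Events are at sample resolution — no
sub-sample interpolation, matching the 50 Hz processing the analysis
emulates. Intervals are half-open `[start, stop)`: `start` is the first
loaded sample (heel strike), `stop` the first unloaded sample (toe-off).

A stride is anchored on a left stance and requires genuine double support
at both transfers plus the following left heel strike; the double-support
windows are the stance overlaps. Step validation keeps cycles whose stance
durations and peak forces lie within ±30 % of the per-recording medians —
a quantitative stand-in for the visual regularity screening the protocol
describes — and needs at least 3 cycles; rejections are logged with
reasons.

"12 consecutive steps" is read as 12 half-strides, i.e. 6 full gait
cycles per dataset (configurable). The two edge strides of a recording act
as lead-in/lead-out, so a 6-stride recording yields 4 complete marker sets.

## Marker extraction

E and A are the extremes of the *own-foot* COP's antero-posterior
coordinate over the stance (ties → earliest sample, search restricted to
valid-COP samples). D and B are the extremes of the *combined* COP within
the single-support window bounded by the contralateral toe-off and heel
strike: at those event samples the contralateral force vanishes, so the
extremum reading coincides with "combined COP at the contralateral event"
on clean data, but is robust to the one-sample onset bias every threshold
detector has (at the first loaded sample the just-landed foot already
contributes force and would drag a literal event-sample reading toward its
heel).

Each double-support transfer is a polyline of combined-COP samples. The C
marker of a transfer is its first proper crossing (scanning the transfer's
segments in temporal order) with the temporally preceding opposite
transfer; each transfer therefore yields exactly one C, labeled by the
direction of the later transfer (C_LR for left→right), giving two C
clusters per recording. When the polylines do not cross (pathological
gait), the midpoint of their closest-approach pair is used and flagged in
the QC report; dropping the point instead would unbalance cluster sizes.
Intersections are computed on the raw 50 Hz polylines — no smoothing or
resampling anywhere in the pipeline.

## Parameters

Cluster statistics use sample standard deviations (n−1). Distances are
Euclidean distances between per-side cluster *mean* positions, averaged
over sides; positions are side-averaged cluster means. (Means of positions,
rather than means of per-stride distances, match the cluster-centred
presentation of the marker rectangles; with small scatter the two
definitions agree to first order.) B–C and C–D pair markers by temporal
adjacency on the cyclogram: `B_L↔C_LR`, `C_LR↔D_R` and mirrored — for a
symmetric gait both pairings coincide. `Ra = BC/AB` and `Rp = CD/DE` raise
errors when their denominators vanish.

The Balance Index sums the five zone areas (left + right `σx·σy`; both C
clusters for zone C). Its default scale is 1 (raw units);
`calibrate_bi_scale` computes the convention-matching constant
`100 / THR_raw` from the two cohorts' raw BIs, after which the optimal
threshold is exactly 100. The constant is cohort-dependent by construction
and is reported alongside the results.

Useful invariants (all tested): translation leaves distances and BI
unchanged; global scaling by `k` scales distances by `k`, BI by `k²`, and
leaves `Ra`, `Rp` unchanged; `AB + BD + DE ≠ AE` since the markers are not
collinear.

## Cohort statistics

`U` is the midrank statistic (ties count ½) for the first sample's
orientation; p-values use the normal approximation with tie and continuity
corrections — appropriate at the cohort sizes used here (56/70); an exact
method is available for small tie-free samples. The separation constant
`S = U/(n₁n₂)` is folded to the smaller orientation, giving `r = 1 − 2S`,
`AUC = 1 − S`, and the identity `AUC = (1 + r)/2` that holds on every
comparison row to machine precision. Effect labels: very small `r ≤ 0.1`,
small `≤ 0.3`, medium `≤ 0.37`, large `> 0.37`.

The ROC sweep uses midpoints of consecutive sorted unique pooled scores
plus sentinels; the orientation (whether high or low scores flag the
diabetic class) is chosen so AUC ≥ 0.5. The trapezoid AUC equals the
U-based AUC exactly on tie-free data (tested to 1e-9). The optimal
threshold maximizes `G = √(TPR·TNR)` within the chosen orientation; ties
are broken by larger Youden `J = TPR + TNR − 1`, then by the threshold
closest to the pooled median (the max-G criterion alone does not fix the
threshold on flat stretches). Thresholds and confusion percentages are
reported only for large effects — small-effect parameters do not qualify
as classifiers and their cells stay blank. Confusion percentages are
relative to each cohort's own size, rounded to 2 decimals; medians are
reported to 3.

The statistical unit is the *dataset* (126 of them), not the participant —
repeated datasets per participant pseudo-replicate, which is noted rather
than "fixed"; the generator's participant random effects let a user study
the consequences. No multiple-testing correction is applied across the 15
parameters.

BI correlations regress `log10(BI)` on each geometry parameter by ordinary
least squares (`Ra` itself log-transformed, being a ratio that spans an
order of magnitude); R² and the two-sided slope p-value are reported.

## Synthetic data

Cohort templates are seeded from the reported cohort medians of the study
conditions being emulated: the antero-posterior positions of E, D, B, A
and C are taken as printed, and the lateral coordinates are then *solved*
so that the distances AB and BC (hence Ra) match the printed medians
exactly, with C on the midline. The printed marginal medians are not
mutually consistent as a single point set (for the healthy values,
AB + BD + DE < AE, impossible by the triangle inequality), so no template
can reproduce every median simultaneously; AE, BD, CD, DE are whatever the
solved geometry implies. In particular the solved geometry separates BD
between cohorts far more than the reported medians do — synthetic rankings
of AE/BD/CD/DE classifiers are template artifacts and should not be read
as predictions.

Per-cluster scatter is axis-aligned Gaussian (the BI uses only `σx·σy`,
which ignores covariance), with per-zone magnitudes proportional to the
reported BI component magnitudes (B > D > A > C > E) and an area scale of
3e-5 chosen once so healthy mid-stance clusters scatter with σ ≈ 0.015
insole lengths — typical stride-to-stride repeatability of natural gait.
Participant random effects: a whole-cyclogram translation
(SD 0.02 lateral / 0.05 antero-posterior), independent per-cluster mean
jitter (SD 0.015), and a log-normal scatter factor (log-SD 0.25). The
translation moves marker *positions* across participants without touching
distances — which is why position parameters classify worse than AB/BC/Ra,
reproducing the reported structure of the real study; the jitter SD sets
the noise floor of the distance parameters.

Time-series mode writes 50 Hz recordings on an exact event grid: stride
period 1.2 s (60 samples, cadence 100 steps/min), stance 0.8 s (40
samples), double support 0.2 s per transfer. The stance fraction (67 %) is
at the high end of normal walking; it keeps every planted event on an
integer sample. The vertical force is two Gaussian bumps (25 % and 75 % of
stance, σ = stance/8, equal peaks of 700 N) shifted to zero exactly at the
stance boundaries. The COP path interpolates planted anchors
E(heel-strike) → D(contralateral toe-off) → B(contralateral heel-strike) →
A(toe-off) with short dwells at E, B and A; the B dwell makes the
double-support combined-COP path exactly collinear with the planted
diagonal, so the extracted C equals the planted diagonal crossing to
numerical precision, and the dwells at E/A absorb the one-sample onset
offset of threshold detection. Planted-geometry recovery through the full
pipeline is therefore exact (≤ 1e-9), which the tests exploit.

What the generator does **not** emulate: COP measurement noise and sensor
quantization, stride-time variability, asymmetric gait, correlated marker
scatter, speed-dependent geometry, or any pathological pattern beyond the
planted geometry/scatter contrast. Passing the recovery tests shows the
pipeline is exact on clean, regular gait with planted structure — not that
it is robust to every real-world artifact.

## Degenerate inputs and tie-breaks (summary)

Zero total force → combined COP undefined (skipped, not raised). All-zero
force trace → no stances. No stance overlap → no cycles, with a warning.
Extremum ties → earliest sample. Non-crossing transfers → flagged
closest-approach midpoint. Zero-scatter clusters → BI 0 with NaN percent
contributions (warned). Identical pooled scores → degenerate-ROC error;
BI calibration propagates it as a calibration error. `AB = 0` or `DE = 0`
→ explicit ratio-undefined errors.

## Problem sizes

Default analyses use the full 126-dataset study in marker (fast) mode and
6-stride recordings in time-series mode; Monte-Carlo checks use 10 000
strides and the null calibration 2 000 replicates at n = 25 — sizes at
which every documented tolerance has comfortable margin while the whole
suite runs in seconds.
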