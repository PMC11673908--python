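# cyclogait

Dynamic centre-of-pressure (COP) cyclogram diagnostics for dual-insole gait
recordings, aimed at screening for diabetic peripheral neuropathy (DPN).

People with DPN lose plantar sensation and walk measurably differently from
healthy adults. When both feet are instrumented with pressure-sensitive
insoles, the force-weighted average of the two feet's COPs traces a closed
curve over repeated strides — the *cyclogram* or *butterfly diagram*. This
package extracts the cyclogram's ten marker points per stride, condenses
them into fifteen parameters (including a novel scatter-based Balance
Index), and evaluates every parameter as a binary classifier separating a
diabetic-neuropathy cohort from a healthy cohort. Because comparable raw
recordings are rarely public, a synthetic study generator with planted
ground truth is a first-class part of the package.

## The model

With per-foot vertical forces `F_L, F_R` and COPs `(x_L, y_L), (x_R, y_R)`
(insole-length normalized, `y` antero-posterior heel→toe), the cyclogram is

```
x_C = (F_R·x_R + F_L·x_L) / (F_R + F_L),   y_C likewise.
```

Per stride and side, five markers are taken: **E** rearmost own-foot COP
after heel strike, **A** frontmost before toe-off, **D**/**B** the combined
COP at contralateral toe-off / heel strike (the cyclogram's turning
points), and **C** the crossing of the two double-support transfer
diagonals. Across strides each marker forms a cluster.

The fifteen parameters are: gait line `AE`, single-support line `BD`, the
positions `ap C, lat C, ap A, ap B, ap D, ap E`, the distances
`AB, BC, CD, DE`, the ratios `Ra = BC/AB` and `Rp = CD/DE`, and the
Balance Index

```
BI = Σ_zone (σx·σy)_left + (σx·σy)_right ,   zones A…E,
```

the summed scatter areas of the clusters (sample SDs), optionally rescaled
so its ROC-optimal threshold is 100. Cohorts are compared per parameter
with the Mann–Whitney U test; with `S = U/(n₁n₂)` (smaller orientation),
the rank effect size is `r = 1 − 2S` and `AUC = 1 − S`. Parameters with a
large effect (`r > 0.37`) get an optimal threshold at the maximum of
`√(TPR·TNR)` plus confusion percentages.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (56 diabetic + 70 healthy datasets, 12 steps each at 50 Hz):

```
python analysis/01_simulate_study.py --seed 1
python analysis/02_extract_parameters.py
python analysis/03_compare_cohorts.py
python analysis/04_correlate_balance_index.py
```

With seed 1 the extraction step prints the cohort medians

```
            AB      BC      Ra      BI
cohort
D       0.1264  0.1941  1.5484  0.0032
H       0.0384  0.2862  7.0278  0.0010
```

— the diabetic cyclogram collapses: the forefoot segment `AB` lengthens
(0.126 vs 0.038 insole lengths), the transfer segment `BC` shortens, and
their ratio `Ra` drops from ~7 to ~1.5, while the raw Balance Index
triples. The comparison step then reports, among others,

```
parameter  median_D  median_H      r  effect    AUC      THR  FN_pct  FP_pct
AB            0.126     0.038  1.000  large   1.000    0.080    0.00    0.00
BC            0.194     0.286  1.000  large   1.000    0.244    0.00    0.00
Ra            1.548     7.028  1.000  large   1.000    2.769    0.00    0.00
BI          169.964    55.041  0.893  large   0.947  100.000   14.29   11.43
```

`AB`, `BC` and `Ra` are near-perfect classifiers of the planted contrast;
the BI (rescaled so its optimal threshold is exactly 100) separates well
but not perfectly, because marker scatter estimated from six strides is
itself noisy. The correlation step finds that the geometry parameters share
roughly half their variance with `log10(BI)` (R² ≈ 0.48–0.54 for `AB`,
`BC`).

The same machinery is available as a CLI (`cyclogait simulate / extract /
compare / report`) and as plain library functions (`cyclogait.combine_cop`,
`cyclogait.compare_cohorts`, …).

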