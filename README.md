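# angiopattern

Classification of physiological patterns of coronary artery disease
(CAD) from single-view angiography-derived **virtual pullback** curves.

Interventional cardiologists increasingly characterize CAD not just by
whether a vessel is ischaemic but by *how* the pressure loss is
distributed along it: a **focal** lesion (one abrupt drop within a short
segment) responds well to a stent, while **diffuse** disease (a gradual
vessel-wide decline), **serial** lesions and **mixed** patterns call for
different strategies. The Murray's law-based quantitative flow ratio
(μFR) provides a pressure-ratio trace along the vessel from a single
angiographic view — a virtual pullback — without a pressure wire or
hyperaemia. This package implements the quantitative toolkit for
classifying those traces:

- **Physiology engine** — the pullback pressure gradient index

  PPGi = ( MaxPPG₂₀ₘₘ / ΔμFR_vessel + (1 − L_disease / L_total) ) / 2

  with the validated cut-off 0.78 (focal ≥ 0.78), the local gradient
  dμFR/ds with the 0.025/mm major-gradient cut-off, the ≤ 0.80
  significance rule and the > 0.95 no-disease exclusion — all computed on
  0.35-mm grids after isotonic (non-increasing) projection of the trace.
- **MFPCA** — multivariate functional principal component analysis of the
  (μFR, lumen-diameter) curve pair; the three leading scores summarize
  joint curve shape.
- **Classifiers** — elastic-net penalized logistic regression (λ path from
  λ_max, cross-validated deviance selection) and random forest, over a
  12-feature curve model and a 13-feature model that appends PPGi.
- **Evaluation harness** — stratified repeated 75/25 splits with
  leakage-free per-split MFPCA refits, confusion metrics, binary and
  one-vs-rest ROC/AUC, and 95% CIs over iterations.
- **Synthetic cohort generator** — labelled vessels with
  focal/diffuse/mixed/serial morphology at the reference class
  proportions (160/74/82/27 of 343) and matching covariate marginals,
  plus an eight-rater consensus-labelling emulator, so the whole pipeline
  is testable without clinical data.

## Worked example

```python
from angiopattern import (resample_curve, compute_ppgi, max_local_gradient,
                          classify_by_ppgi_cutoff, has_major_gradient)

# an 80-mm vessel with a 0.30 pressure drop confined to a 7-mm segment
curve = resample_curve([0, 36, 43, 80], [1.00, 1.00, 0.70, 0.70])
comp = compute_ppgi(curve)
grad = max_local_gradient(curve)
print(f"PPGi = {comp.ppgi:.3f}")
print(f"pattern by cut-off: {classify_by_ppgi_cutoff(comp.ppgi)}")
print(f"max dmuFR/ds = {grad:.3f}/mm, major gradient: {has_major_gradient(grad)}")
```

prints

```
PPGi = 0.954
pattern by cut-off: focal
max dmuFR/ds = 0.043/mm, major gradient: True
```

The whole drop sits inside one 20-mm window (first term 1.0) and only
7 of 80 mm are diseased (second term 0.91), so PPGi ≈ 0.95 — clearly
focal, and the 0.043/mm local gradient marks a major gradient. The same
total drop spread uniformly over the vessel
(`resample_curve([0, 80], [1.00, 0.70])`) gives PPGi = 0.125 → diffuse:
the index isolates *distribution*, not severity.

## Command line

```bash
angiopattern simulate --n-vessels 343 --seed 1 --out-dir data/
angiopattern features --curves data/curves.csv --cohort data/cohort.csv \
    --out data/features.csv
angiopattern train --features data/features.csv --algorithm plr \
    --out data/fit.joblib
angiopattern classify --features data/features.csv --model data/fit.joblib \
    --out data/predictions.csv
angiopattern evaluate --curves data/curves.csv --cohort data/cohort.csv \
    --task focal_vs_diffuse --n-iterations 500 --out data/metrics.json
```

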