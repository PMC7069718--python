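# dsgcdend

Quantitative analysis of direction selectivity in the dendrites of
retinal direction-selective ganglion cells (DSGCs).

ON-OFF DSGCs spike for one motion direction because directionally tuned
GABAergic inhibition from starburst amacrine cells (SACs) vetoes
non-directional excitation — an AND-NOT interaction that recent imaging
work places within individual dendritic segments of < 10 µm. `dsgcdend`
provides, as a tested Python library, the machinery needed to measure and
model that claim:

* **Morphology** — SWC dendritic trees, synthetic DSGC-like arbors, ROI
  placement, and exact cable (tree-path) distances.
* **Synthetic imaging data** — seeded ROI × trial × direction × time
  fluorescence stacks with Von Mises direction tuning, speed-dependent
  onset latencies, distance-correlated synaptic noise, null-direction
  "hot spots", and scenario variants (NMDA block, vGAT KO, SAC ablation).
* **Trace features** — ΔF/F, Savitzky–Golay smoothing, 200 ms windowed
  peaks, 50% rise times, and the 3×baseline-SD responsiveness criterion.
* **Tuning statistics** — vector-sum preferred direction and DSI

      R_x = Σᵢ Rᵢ cos θᵢ,  R_y = Σᵢ Rᵢ sin θᵢ,
      R⃗ = √(R_x² + R_y²),  DSI = R⃗ / Σᵢ Rᵢ ∈ [0, 1],

  angular dispersion σ_θ = √(−2 ln R̄), Von Mises fits (width 1/κ),
  Watson–Williams and Angular-Distance tests, Kolmogorov–Smirnov DSI
  comparisons, coefficient of variation.
* **Spatial analyses** — peak noise-residual cross-correlation vs cable
  distance with exponential fit corr(d) = A·e^(−d/λ) + b and shuffle
  control; stimulus-speed estimation from rise-time regression; Gaussian
  FWHM of hot-spot line profiles.
* **Compartmental model** — a stochastic multi-compartment DSGC (Hines
  cable solver, Crank–Nicolson, numba-compiled) with 177 co-located E/I
  synapse pairs, direction-dependent inhibitory release probability, a
  moving-edge stimulus, and per-site tuning of the voltage integrated
  above a threshold.

## Worked example

```python
import numpy as np
from dsgcdend import (SynthConfig, generate_synthetic_morphology, place_rois,
                      generate_imaging_dataset, compute_dff, compute_features,
                      responsive_mask, vector_sum_tuning)

morph = generate_synthetic_morphology(target_field_diameter=220.0,
                                      branch_order=4, seed=1)
rois  = place_rois(morph, spacing=8.0, seed=2)
stack = generate_imaging_dataset(SynthConfig(seed=5), rois, morph)

feats = compute_features(compute_dff(stack))
resp  = responsive_mask(feats)
peaks = feats.pivot_table(index="roi", columns="direction_deg",
                          values="peak_dff", aggfunc="mean")
dsis = [vector_sum_tuning(np.clip(r.to_numpy(), 0, None),
                          stack.directions_deg).dsi
        for roi, r in peaks.iterrows() if resp[roi]]
print(f"{resp.mean():.0%} responsive, DSI = {np.mean(dsis):.2f} "
      f"+/- {np.std(dsis):.2f}")
```

prints

```
100% responsive, DSI = 0.18 +/- 0.06
```

— every site passes the 3×SD responsiveness criterion, and single-site
dendritic tuning is weak (DSI ≈ 0.2 on 8 directions), as expected for
calcium signals measured with sodium channels blocked. The scripts in
`examples/` walk through each capability the same way; for instance
`examples/05_model_thresholds.py` runs the compartmental model and prints

```
 threshold_mv mean_dsi sigma_theta_deg  n_excluded
        -55.0     0.67            10.7           0
        -50.0     0.86            25.2          45
        -48.0     0.92            34.0         437
DSI monotone increasing: True
sigma_theta non-decreasing: True
```

— stricter dendritic thresholds sharpen tuning while single-set preferred
directions disperse, the signature of a threshold nonlinearity acting on
stochastic synaptic release.

A thin CLI wraps the scenario runners: `dsgcdend run-scenario --seed 1
--out-dir out/` and `dsgcdend simulate-model --seed 1`.

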