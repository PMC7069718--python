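"""Noise correlations between dendritic sites decay over cable distance.

Trial-to-trial residual fluctuations of nearby ROIs co-vary; the peak
residual cross-correlation falls off exponentially with the cable
distance between sites.  The fitted space constant measures the spatial
scale of shared synaptic noise (the generator uses 5.3 um).
"""

import numpy as np

from dsgcdend import (
    SynthConfig,
    compute_dff,
    fit_distance_decay,
    generate_imaging_dataset,
    noise_residuals,
    pairwise_peak_correlation,
    place_rois,
)
from dsgcdend.experiments import imaging_cable

morph = imaging_cable(51, 2.0)          # 102 um dendrite
rois = place_rois(morph, 2.0, seed=0)   # 50 ROIs, 2 um apart
D = rois.cable_distance_matrix(morph)

lams, shuffle_ranges = [], []
for seed in range(5):  # pool imaging sessions, like pooling cells
    stack = generate_imaging_dataset(SynthConfig(seed=seed, n_trials=30),
                                     rois, morph)
    dff = compute_dff(stack)
    res = noise_residuals(dff, direction_deg=90.0)  # orthogonal motion
    pairs = pairwise_peak_correlation(res, rois, morph, distances=D)
    fit = fit_distance_decay(pairs)
    lams.append(fit.lambda_um)
    sh = fit_distance_decay(pairwise_peak_correlation(
        res, rois, morph, shuffle=True, seed=seed, distances=D)).binned["mean"]
    shuffle_ranges.append(sh.max() - sh.min())

print(f"{len(pairs)} ROI pairs per session, 5 sessions")
print(f"last session fit: corr(d) = {fit.amplitude:.2f} "
      f"exp(-d/{fit.lambda_um:.1f} um) + {fit.floor:.2f}")
print(f"generator space constant 5.3 um -> fitted lambda "
      f"{np.mean(lams):.1f} +/- {np.std(lams):.1f} um over sessions")
print(f"shuffled-trial control is flat (binned range "
      f"{np.mean(shuffle_ranges):.3f})")
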