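"""Direction tuning of dendritic sites: vector-sum DSI and Von Mises width.

Builds a synthetic ganglion-cell arbor, simulates an 8-direction
moving-spot imaging experiment, and computes each dendritic ROI's
preferred direction (PD) and direction-selectivity index (DSI).
"""

import numpy as np

from dsgcdend import (
    SynthConfig,
    compute_dff,
    compute_features,
    fit_von_mises,
    generate_imaging_dataset,
    generate_synthetic_morphology,
    place_rois,
    responsive_mask,
    vector_sum_tuning,
)

morph = generate_synthetic_morphology(target_field_diameter=220.0,
                                      branch_order=4, seed=1)
rois = place_rois(morph, spacing=8.0, seed=2)
stack = generate_imaging_dataset(SynthConfig(seed=5), rois, morph)

dff = compute_dff(stack)
feats = compute_features(dff)
resp = responsive_mask(feats)

mean_peaks = feats.pivot_table(index="roi", columns="direction_deg",
                               values="peak_dff", aggfunc="mean")
dsis, pds = [], []
for roi, row in mean_peaks.iterrows():
    if not resp[roi]:
        continue
    tr = vector_sum_tuning(np.clip(row.to_numpy(), 0, None),
                           stack.directions_deg)
    dsis.append(tr.dsi)
    pds.append(tr.preferred_angle_deg)

print(f"{len(rois)} ROIs, {resp.mean():.0%} responsive "
      f"(trial-averaged peak > 3x baseline SD)")
print(f"DSI = {np.mean(dsis):.2f} +/- {np.std(dsis):.2f} "
      "(weak single-site tuning, like dendritic calcium signals)")

# Von Mises fit of one well-tuned site: 1/kappa is the tuning width
best = int(np.argsort(dsis)[-1])
roi_id = mean_peaks.index[best]
fit = fit_von_mises(np.clip(mean_peaks.loc[roi_id].to_numpy(), 0, None),
                    stack.directions_deg)
print(f"example ROI {roi_id}: PD {pds[best]:.0f} deg, DSI {dsis[best]:.2f}, "
      f"Von Mises kappa {fit.kappa:.2f} (width 1/kappa = "
      f"{fit.width_1_over_kappa:.2f})")
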