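# Methods

`dsgcdend` re-implements, as a tested pipeline, the quantitative machinery
used to study direction selectivity in the dendrites of ON-OFF
direction-selective ganglion cells (DSGCs): circular statistics on
ROI-based dendritic calcium signals, spatially resolved noise analyses, a
synthetic-data generator that emulates the imaging experiments, and a
stochastic multi-compartment DSGC model with a threshold-based dendritic
tuning readout. This note records the models, the parameters that matter,
and the design choices made where the design was genuinely open.

## Coordinate and stimulus conventions

All geometry is planar (retina flat-mount view), in micrometres. The
0° motion direction points along +x and angles increase counter-clockwise.
A moving stimulus of direction θ and speed v enters the receptive field at
the line `proj = −R_field` (projection onto the motion axis relative to the
field centre) at the nominal stimulus-onset time, so a point at projection
p responds with latency `(p + R_field)/v`. Default spot speed is 500 µm/s
(8 equally spaced directions); the model's edge moves at 1 mm/s.

## Morphology and cable distance

Dendritic trees are SWC node tables (id, label, x, y, z, radius, parent).
Distances between dendritic points are always *cable* (tree-path)
distances: a point is addressed as a node plus an arc offset toward its
parent, and distances sum straight inter-node segment lengths through the
unique tree path (lowest common ancestor on weighted depths). Where ROIs
on different branches are compared the path runs through the branch point
— the natural reading of cable distance, since no other convention
produces a tree metric.

`generate_synthetic_morphology` grows a planar, roughly radially
symmetric binary tree: `n_trunks` primary dendrites (default 5) leave the
soma at even angles and bifurcate `branch_order − 1` times; section
lengths are chosen so root-to-tip path length equals the field radius,
which bounds every node inside the field by construction. Radii taper
from 0.5 µm (trunk) to 0.15 µm (distal) — typical for DSGC dendrites and,
together with the leak density below, what produces electrotonic subunits
of a few tens of µm. Segment lengths are ≤ 5 µm (default 4 µm with
angular jitter). `place_rois` tiles ROIs (nominal 3–4 µm extent) along
the arbor at a fixed arc spacing; because arc position equals weighted
depth, each edge owns the grid points in its depth interval, which makes
the tiling duplicate-free and keeps consecutive ROIs one spacing apart
within a segment length.

## Synthetic imaging data

The generator produces raw fluorescence stacks `F[roi, trial, direction,
time]` with known ground truth, emulating two-photon imaging of OGB-1
filled dendrites during the 8-direction protocol:

* **Tuning.** Each ROI has a Von Mises tuning curve
  `A·exp(κ(cos(θ−PD_roi)−1))` with per-ROI preferred angles scattered
  around the cell PD (angular SD 20°) and κ drawn around 0.4. κ = 0.4 on
  8 directions yields site DSIs of ≈ 0.19 ± 0.06 — the weak single-site
  tuning regime characteristic of dendritic calcium signals (somatic
  spiking is far sharper). Default peak ΔF/F is 1.0 at the preferred
  direction.
* **Kinetics.** Responses are difference-of-exponential indicator
  transients (10 ms rise, 400 ms decay, peak-normalized), onset exactly
  affine in projected position with slope 1/speed. Default sampling is
  50 Hz, 3 s trials, stimulus onset at 0.6 s (the pre-stimulus interval is
  the ΔF/F baseline window). Baseline drift and bleaching are excluded.
* **Trial-to-trial noise.** Synaptic noise is a *temporal process*, not a
  per-trial scalar: unit-variance Gaussian noise traces, smoothed with the
  indicator kernel, multiply the response envelope. The *shared*
  component is mixed across ROIs through a matrix square root of the
  covariance `exp(−d_cable/λ)` (λ default 5.3 µm) and scaled by the
  direction-dependent inhibition level `w(θ) = (1−cos(θ−PD))/2` — so
  preferred motion is the least variable and null motion the most, which
  is what makes the vGAT-knockout contrast meaningful. An independent
  per-ROI component (SD 0.15 vs shared 0.6) and photon noise
  (SD ∝ √F) complete the model. A scalar-amplitude noise model was
  rejected: it makes every residual proportional to one kernel shape, so
  even independent ROI pairs cross-correlate at |1| per trial, which no
  real dendrite does.
* **Hot spots.** On null-direction trials, candidate sites spaced ≥ 20 µm
  apart fire Bernoulli events (p = 0.1 per trial per site, amplitude
  1.0 ΔF/F with ±20% log-normal jitter) whose spatial weight on
  neighbouring ROIs is Gaussian with FWHM 3.0 µm; event locations are
  logged in the stack metadata. Event probability and amplitude are not
  constrained by data and are exposed in the config.
* **Scenarios.** All randomness flows from one seed through named
  substreams, so scenario variants are seed-matched draw for draw:
  `nmda_block` multiplies amplitudes by 0.6; `vgat_ko` multiplies the
  shared (inhibitory) noise SD by 0.25; `sac_ablation` sets κ to 0 inside
  the ablation patches only — sites there respond at full amplitude in
  every direction (large null responses), while outside-patch traces are
  bit-identical to control.

What the generator does *not* emulate: motion artefacts, bleaching,
ROI-segmentation errors, calcium-release events, or any biophysics of the
SAC→DSGC synapse (that lives in the compartmental model). Passing
closed-loop tests therefore shows the analysis chain is correct and
well-conditioned at realistic noise levels, not that it is robust to
every artefact of real recordings.

## Trace features

ΔF/F uses the per-trace baseline-window mean as F0. Traces are smoothed
with a 2nd-order Savitzky–Golay filter (default 11 samples). The peak is
the mean of the raw trace over a 200 ms window centred on the in-stimulus
maximum of the smoothed trace (a pure-max mode exists behind a flag); the
window mean deliberately averages over the transient decay, so it reads a
few percent below the instantaneous amplitude — this cancels in all
ratio-based statistics (DSI, PD, CoV). Savitzky–Golay fits ring at true
discontinuities, so step-like test signals read ~10% low; calcium
transients have no such edges. The 50% rise time is the first
linear-interpolated crossing of half the in-window smoothed peak,
measured from stimulus onset; it is undefined (NaN, not an error) when
the peak is within 3 baseline SDs. Baseline SD is computed on the
*unsmoothed* ΔF/F baseline pooled across trials — smoothing would deflate
the noise floor and loosen the responsiveness criterion. An ROI is
responsive when its best direction's trial-averaged peak exceeds 3× the
baseline SD (the trial-averaged reading of "responded to at least one
direction"); only responsive ROIs enter tuning statistics.

## Circular statistics

Preferred direction and tuning strength come from the vector sum of mean
responses over directions: `R_x = Σ R_i cos θ_i`, `R_y = Σ R_i sin θ_i`,
`R⃗ = √(R_x²+R_y²)`, `DSI = R⃗/Σ R_i ∈ [0, 1]`. Negative mean responses
(possible at pure-noise sites) are floored at zero with a reported count,
preserving the DSI range. The population dispersion of angles is
`σ_θ = √(−2 ln R̄)` with R̄ the *n-normalized* mean resultant length
(R̄ ≤ 1e−12 reports σ_θ = ∞). On an 8-direction grid the vector-sum PD
estimator is consistent to < 0.25° for κ ≤ 4 but acquires a quantization
bias at larger κ (2.4° at κ = 8; in the κ→∞ limit the PD snaps to the
grid) — a property of the estimator worth knowing when tuning is sharp.

Von Mises tuning curves are fitted as `b + A·exp(κ(cos(θ−μ)−1))` by
least squares with multi-start over the direction grid; 1/κ is the width
metric. Flat data drive κ (or A) to the boundary and are flagged
unconstrained with infinite width. Mean angles are compared with the
Watson–Williams test (classical F with the 1 + 3/(8κ̂) correction; a √F
"T" form is also reported, and a warning is raised when pooled R̄ < 0.7);
angular dispersions with the Angular Distance test (Mann–Whitney on
absolute angular distances from each sample's own mean); DSI
distributions with the two-sample Kolmogorov–Smirnov test. The
coefficient of variation uses the population (n-denominator) SD by
default, with a sample-SD flag.

## Spatial analyses

**Noise correlations.** Residuals subtract each ROI's across-trial mean
trace for one direction (a warning is raised below 30 trials). Per-trial
traces are standardized, cross-correlated over lags within ±0.5 s, and
the per-pair statistic is the across-trial mean of the correlogram
maximum (zero-lag Pearson mode behind a flag). The shuffle control pairs
trial i of one ROI with a seeded derangement of the other's trials.
`corr(d) = A·exp(−d/λ) + b` is fitted to the raw pair points (2 µm binned
means are reported for display; a binned-fit and a zero-floor fit are also
available). The max-over-lags statistic has a known positive floor (the
expected maximum of a noise correlogram) and a mild compression bias:
in closed-loop recovery at λ = 5.3 µm the default statistic fits
λ ≈ 4.9 ± 0.9 µm per 50-ROI session while the zero-lag mode is unbiased
(λ ≈ 5.3). The floor term absorbs the bias offset; the residual ~10%
shrinkage is inherent to taking per-trial maxima and is documented rather
than corrected.

**Stimulus speed.** Per-ROI mean 50% rise times are regressed on the ROI
centroid's scalar projection onto the motion axis; speed = 1/slope. A
global latency offset moves only the intercept. A non-positive slope is
flagged invalid rather than returned.

**Hot-spot widths.** Per-trial spatial maps of peak ΔF/F along a finely
sampled dendrite are screened for events (map maximum exceeding the map
median by a threshold, default 0.5 ΔF/F); the profile within ±6 µm cable
distance of the peak is fitted with a Gaussian plus baseline, and
FWHM = 2√(2 ln 2)·σ. Fits are kept only when they describe a localized
event (centre within half the window, width smaller than the window,
amplitude at least half the detection criterion). For estimator-recovery
experiments the profiles are extracted at generator-logged event
locations instead of detections — the width fit stays blind — because at
realistic null-response amplitudes blind detection admits noise events
that contaminate a width *population* statistic, which is a detector
property, not a width-estimator property.

## The compartmental DSGC model

The tree is discretized into cylindrical compartments of ≤ 5 µm arc
length plus a spherical soma (radius 8 µm; omit it to build bare
cylinders for validation). Membrane: C_m = 1 µF/cm², R_a = 100 Ω·cm,
leak reversal −60 mV. Leak density defaults to 0.5 mS/cm²
(R_m = 2 kΩ·cm², τ_m = 2 ms): an in-circuit leakiness (synaptic
background included implicitly) that, with the tapered radii, yields
transient-frequency electrotonic subunits of a few tens of µm — the
subunit scale reported for ganglion-cell dendrites. Region labels follow
branch order: order ≤ 2 is "primary", everything beyond (and terminal
branches) takes terminal densities. Active Hodgkin–Huxley channels
(Na 150/200/30, K rectifier 35/35/25, slow delayed rectifier 0.8/0.8/0.8
mS/cm² for soma/primary/terminal; E_Na = +55, E_K = −80 mV) are included
only when enabled; the gating-rate temperature factor defaults to 5 —
large enough for fast warm-temperature kinetics, small enough that Na_V
inactivation does not outrun spike initiation. Dendritic tuning analyses
run passive ("Na_V blocked"), matching how the dendritic voltages are
meant to be read.

**Integration.** The tree cable equation is solved implicitly with a
θ-method (Crank–Nicolson default, backward Euler selectable) at
dt = 25 µs, using Hines' ordered elimination: compartments are numbered
parent-before-child so the linear solve is exact in O(N) per step with no
fill-in. The kernel is numba-compiled; voltages are recorded at the start
of each 1 ms recording interval so dt-refinement comparisons align
sample-for-sample. Validation: steady-state attenuation along a passive
sealed-end cylinder matches the analytic cosh ratio to < 10⁻⁶ relative
error; halving dt changes recorded voltages by < 0.01 mV; with all
reversal potentials at the leak value, conductance transients cannot move
the voltage (charge conservation); instability (|V| > 150 mV) raises an
error advising a smaller dt.

**Synapses and release.** 177 co-located E/I pairs are placed
quasi-uniformly by arc length with seeded jitter. Conductances are
biexponential (E: 0.5/3 ms, reversal 0 mV; I: 1/10 ms, reversal −60 mV =
E_leak, i.e. pure shunting). Peak conductances are per-site values scaled
inversely with the local input resistance (computed from the passive
conductance matrix), so every site's unitary EPSP is comparable —
the reading adopted for "a single excitatory event depolarizes its site
by ~5 mV" on a tree whose input resistance varies several-fold from trunk
to tip. Defaults g_e = 0.5 nS, g_i = 3.0 nS give unitary site EPSPs of
≈ 7 mV (range ~5–8). This sits slightly above a literal 5 mV on purpose:
with 5 mV events the −48 mV readout threshold falls in the saturated tail
of the supra-threshold response distribution and the σ_θ progression
stalls between −50 and −48 mV, whereas compound dendritic depolarizations
in this regime should reach ≈ −40 to −25 mV, placing the −55/−50/−48 mV
thresholds mid-distribution. Release is stochastic per synapse per sweep:
success iff a standard normal draw falls below the quantile Φ⁻¹(p) —
algebraically a Bernoulli(p) draw, mirroring the Gaussian-limits framing —
with constant p_exc = 0.5 for excitation and
`p_inh(θ) = p_pref + (p_null − p_pref)(1 − cos(θ − θ_pref))/2`
(p_pref = 0.05, p_null = 0.9) for inhibition: minimal for preferred,
maximal for null motion. Onsets follow the edge-crossing time of each
synapse's projected position plus Gaussian jitter (SD 10 ms).

**Threshold tuning readout.** The per-site, per-direction response is
`∫ max(V(t) − V_thr, 0) dt`; tuning then goes through the same vector-sum
code path as the imaging data. Sites with all-zero responses in a set are
excluded and counted. Population summaries per threshold: mean single-set
DSI and σ_θ of pooled single-set PDs (five sets per run by default —
σ_θ needs a few hundred pooled PDs to stabilize). All sites share one
release law, so per-site *average* tuning is common; site-to-site
differences exist only within single sets, driven by release
stochasticity — raising the threshold from −55 to −50 to −48 mV increases
mean DSI (0.67 → 0.86 → 0.92 in a representative run) and disperses
single-set PDs (σ_θ 11° → 25° → 34°), and the package asserts this trend,
not the paper-morphology-specific values, since the original
reconstruction and synaptic parameters are unavailable.

## Problem sizes

The shipped experiments use a 220 µm synthetic arbor (~260 ROIs at 8 µm
spacing) for tuning and speed analyses; a 102 µm cable with 50 ROIs at
2 µm spacing and 30 trials for noise correlations; a 70 µm cable at 1 µm
ROI sampling for hot-spot profiles (≥ 60 pooled events); and 5-set,
8-direction sweeps of the 526-compartment model for the threshold
analysis. These sizes give each estimator a few hundred effective
samples — enough that closed-loop recovery margins are dominated by the
estimators' intrinsic biases rather than sampling noise.

## Known limitations

* ROIs sample the point at their attachment; the 3–4 µm spatial extent is
  metadata, not an integration aperture, so profile widths are not
  broadened by ROI size.
* The max-over-lags correlation statistic is floor-biased by design;
  quantitative λ comparisons across datasets should use a common trial
  count and trace length (or the zero-lag mode).
* The model's synaptic conductances, release probabilities and jitter are
  calibration choices, not measurements; only trends across thresholds
  and scenario contrasts are meaningful, not absolute DSI/σ_θ values.
* The Watson–Williams test assumes concentrated samples; the
  implementation warns (rather than refuses) when pooled R̄ < 0.7.
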