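"""Synthetic two-photon imaging datasets with known ground truth.

Emulates the statistical structure of dendritic calcium imaging in a
direction-selective ganglion cell during an 8-direction moving-spot
protocol:

* per-ROI Von Mises direction tuning around a common cell preferred
  direction (PD), with flat-tuning dendritic κ so site DSIs land near 0.2;
* response onsets that are affine in the ROI's position projected onto the
  motion axis, with slope 1/speed (nominal spot speed 500 µm/s);
* trial-to-trial amplitude fluctuations split into a *shared* Gaussian
  field whose ROI-pair covariance decays as exp(−d_cable/λ) — the
  inhibition-driven noise the correlation analysis estimates — and
  independent per-ROI noise, plus photon (shot-like) noise on the traces;
* the shared component is weighted by the direction-dependent inhibition
  level w(θ) = (1 − cos(θ − PD))/2, so preferred-motion responses are the
  least variable and null-motion the most;
* sparse null-direction "hot spots": rare Bernoulli events confined to
  Gaussian spatial profiles of configurable FWHM (3 µm default);
* scenario variants: ``nmda_block`` (multiplicative amplitude scaling),
  ``vgat_ko`` (reduced inhibitory/shared noise variance), ``sac_ablation``
  (direction modulation removed inside ablation patches only).

All randomness flows from one seed through named substreams, so scenario
variants are seed-matched draw for draw.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .morphology import Morphology, RoiSet

__all__ = ["SynthConfig", "TraceStack", "generate_imaging_dataset", "render_movie"]

_SCENARIOS = ("control", "nmda_block", "vgat_ko", "sac_ablation")


@dataclass
class SynthConfig:
    """Generator parameters; defaults are the emulated study conditions."""

    # stimulus
    n_directions: int = 8
    n_trials: int = 5
    frame_rate: float = 50.0          # Hz
    trial_duration: float = 3.0       # s
    stim_onset_s: float = 0.6         # time the stimulus enters the field
    stimulus_speed: float = 500.0     # µm/s, nominal spot speed
    field_radius: float | None = None  # µm; inferred from the ROI set if None

    # indicator kernel (OGB-1-like dendritic transient)
    kernel_rise_s: float = 0.010
    kernel_decay_s: float = 0.400

    # fluorescence / photon noise
    baseline_f0: float = 100.0
    photon_noise_sd: float = 0.3      # per-sample SD = this * sqrt(F)

    # tuning (dendritic sites are weakly tuned: κ ≈ 0.4 gives DSI ≈ 0.2)
    cell_pd_deg: float = 0.0
    pd_jitter_deg: float = 20.0       # angular SD of per-ROI preferred angles
    kappa_mean: float = 0.4
    kappa_sd: float = 0.1
    amp_mean: float = 1.0             # peak ΔF/F at the preferred direction
    amp_sd: float = 0.15

    # trial-to-trial noise
    lambda_gen_um: float = 5.3        # shared-noise cable space constant
    shared_sd: float = 0.6            # fractional, scaled by w_inh(θ)
    indep_sd: float = 0.15            # fractional, direction-independent

    # null-direction hot spots
    hotspot_rate: float = 0.1         # per trial per candidate site
    hotspot_fwhm_um: float = 3.0
    hotspot_amp: float = 1.0
    hotspot_site_spacing_um: float = 20.0

    # scenario
    scenario: str = "control"
    nmda_block_factor: float = 0.6
    vgat_noise_factor: float = 0.25
    ablation_centers: list | None = None   # [(x, y), ...] µm
    ablation_radius_um: float = 50.0

    seed: int = 0

    def validate(self) -> None:
        if self.n_directions < 2:
            raise ValueError("n_directions must be >= 2")
        for name in ("n_trials", "frame_rate", "trial_duration", "stimulus_speed",
                     "kernel_rise_s", "kernel_decay_s", "baseline_f0",
                     "hotspot_fwhm_um", "lambda_gen_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.kappa_mean < 0:
            raise ValueError("kappa_mean must be >= 0")
        if self.scenario not in _SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; one of {_SCENARIOS}")
        if not (0 < self.nmda_block_factor < 1):
            raise ValueError("nmda_block_factor must be in (0, 1)")
        if not (0 < self.vgat_noise_factor <= 1):
            raise ValueError("vgat_noise_factor must be in (0, 1]")

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class TraceStack:
    """Raw fluorescence, shape ``[roi, trial, direction, time]``."""

    F: np.ndarray
    time: np.ndarray
    directions_deg: np.ndarray
    speed_um_s: float
    stim_onset_s: float
    field_radius: float
    rois: RoiSet | None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.all(np.isfinite(self.F)) or np.any(self.F <= 0):
            raise ValueError("raw fluorescence must be finite and > 0")
        d = np.asarray(self.directions_deg, dtype=float)
        if np.any(np.diff(d) <= 0) or d[0] < 0 or d[-1] >= 360:
            raise ValueError("direction list must be strictly increasing in [0, 360)")
        if self.F.shape[2] != d.size or self.F.shape[3] != self.time.size:
            raise ValueError("axis lengths inconsistent with metadata")

    # -- HDF5 round trip ---------------------------------------------------
    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as h5:
            h5.create_dataset("F", data=self.F, compression="gzip")
            h5.create_dataset("time", data=self.time)
            h5.create_dataset("directions", data=self.directions_deg)
            if self.rois is not None:
                g = h5.create_group("roi_table")
                for k in ("roi_ids", "x", "y", "node_ids", "offsets", "extent_um"):
                    g.create_dataset(k, data=getattr(self.rois, k))
            meta = {k: v for k, v in self.meta.items()
                    if not isinstance(v, np.ndarray)}
            meta.update(speed_um_s=self.speed_um_s, stim_onset_s=self.stim_onset_s,
                        field_radius=self.field_radius)
            h5.attrs["meta"] = json.dumps(meta, default=str)

    @classmethod
    def from_hdf5(cls, path) -> "TraceStack":
        import h5py

        with h5py.File(path, "r") as h5:
            meta = json.loads(h5.attrs["meta"])
            rois = None
            if "roi_table" in h5:
                g = h5["roi_table"]
                rois = RoiSet(g["roi_ids"][...], g["x"][...], g["y"][...],
                              g["node_ids"][...], g["offsets"][...],
                              g["extent_um"][...])
            return cls(
                F=h5["F"][...], time=h5["time"][...],
                directions_deg=h5["directions"][...],
                speed_um_s=float(meta.pop("speed_um_s")),
                stim_onset_s=float(meta.pop("stim_onset_s")),
                field_radius=float(meta.pop("field_radius")),
                rois=rois, meta=meta,
            )


def _kernel(t: np.ndarray, tau_r: float, tau_d: float) -> np.ndarray:
    """Difference-of-exponentials indicator kernel, peak normalized to 1."""
    t_pk = tau_r * tau_d / (tau_d - tau_r) * np.log(tau_d / tau_r)
    peak = np.exp(-t_pk / tau_d) - np.exp(-t_pk / tau_r)
    k = np.where(t >= 0, np.exp(-np.clip(t, 0, None) / tau_d)
                 - np.exp(-np.clip(t, 0, None) / tau_r), 0.0)
    return k / peak


def _shared_noise_transform(D: np.ndarray, lam: float) -> np.ndarray:
    """Matrix square root of the exp(−d/λ) covariance over ROIs."""
    cov = np.exp(-D / lam)
    w, V = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


def _select_hotspot_sites(D: np.ndarray, min_sep: float) -> list[int]:
    """Greedy subset of ROI indices with pairwise cable distance >= min_sep."""
    sites: list[int] = []
    for i in range(D.shape[0]):
        if all(D[i, j] >= min_sep for j in sites):
            sites.append(i)
    return sites


def generate_imaging_dataset(cfg: SynthConfig, rois: RoiSet,
                             morphology: Morphology) -> TraceStack:
    """Generate a seeded raw-fluorescence stack for the configured scenario.

    Ground-truth per-ROI tuning parameters are exposed in
    ``stack.meta["truth"]`` for closed-loop validation.
    """
    cfg.validate()
    rois.validate_against(morphology)
    n_r = len(rois)
    if n_r == 0:
        raise ValueError("empty ROI set")

    ss = np.random.SeedSequence(cfg.seed)
    streams = {name: np.random.default_rng(child) for name, child in zip(
        ("tuning", "shared", "indep", "photon", "hotspot"), ss.spawn(5))}

    # --- per-ROI ground-truth tuning -------------------------------------
    rng = streams["tuning"]
    pd_r = cfg.cell_pd_deg + rng.normal(0.0, cfg.pd_jitter_deg, n_r)
    kappa_r = np.clip(rng.normal(cfg.kappa_mean, cfg.kappa_sd, n_r), 0.0, None)
    amp_r = np.clip(rng.normal(cfg.amp_mean, cfg.amp_sd, n_r), 0.05, None)

    ablated = np.zeros(n_r, dtype=bool)
    if cfg.scenario == "sac_ablation":
        centers = cfg.ablation_centers or [(40.0, 0.0)]
        for cx, cy in centers:
            ablated |= np.hypot(rois.x - cx, rois.y - cy) <= cfg.ablation_radius_um
        kappa_r = np.where(ablated, 0.0, kappa_r)  # DS modulation lost in patch
    if cfg.scenario == "nmda_block":
        amp_r = amp_r * cfg.nmda_block_factor
    shared_sd = cfg.shared_sd
    if cfg.scenario == "vgat_ko":
        shared_sd = cfg.shared_sd * cfg.vgat_noise_factor

    # --- geometry ---------------------------------------------------------
    directions = np.arange(cfg.n_directions) * (360.0 / cfg.n_directions)
    radial = np.hypot(rois.x, rois.y)
    field_radius = cfg.field_radius if cfg.field_radius is not None \
        else float(radial.max() + 10.0)
    th = np.deg2rad(directions)
    proj = np.outer(rois.x, np.cos(th)) + np.outer(rois.y, np.sin(th))  # [r, d]
    t_on = cfg.stim_onset_s + (proj + field_radius) / cfg.stimulus_speed

    # --- mean amplitudes ---------------------------------------------------
    dtheta = np.deg2rad(directions[None, :] - pd_r[:, None])
    vm = np.exp(kappa_r[:, None] * (np.cos(dtheta) - 1.0))      # [r, d]
    mean_amp = amp_r[:, None] * vm
    w_inh = 0.5 * (1.0 - np.cos(np.deg2rad(directions - cfg.cell_pd_deg)))  # [d]

    # --- trial-to-trial synaptic noise -------------------------------------
    # Synaptic noise is a *temporal process*, not a single per-trial scalar:
    # kernel-smoothed Gaussian noise traces, spatially mixed across ROIs so
    # equal-time covariance follows exp(-d_cable/λ), multiply the response
    # envelope.  (A scalar-amplitude noise model would make every residual
    # proportional to the same kernel shape, so even independent ROI pairs
    # would cross-correlate at |1| per trial — unlike real dendritic data.)
    n_s = int(round(cfg.trial_duration * cfg.frame_rate))
    time = np.arange(n_s) / cfg.frame_rate
    D = rois.cable_distance_matrix(morphology)
    L = _shared_noise_transform(D, cfg.lambda_gen_um)

    from scipy.signal import fftconvolve

    w_sm = _kernel(time[: max(int(cfg.kernel_decay_s * cfg.frame_rate * 4), 4)],
                   cfg.kernel_rise_s, cfg.kernel_decay_s)
    w_norm = np.sqrt(np.sum(w_sm ** 2))

    def smoothed(z):
        return fftconvolve(z, w_sm[(None,) * (z.ndim - 1) + (slice(None),)],
                           mode="full", axes=-1)[..., :n_s] / w_norm

    z = streams["shared"].standard_normal(
        (cfg.n_trials, cfg.n_directions, n_s, n_r))
    s_proc = smoothed(np.einsum("ij,tdsj->itds", L, z))          # [r, t, d, s]
    e_proc = smoothed(streams["indep"].standard_normal(
        (n_r, cfg.n_trials, cfg.n_directions, n_s)))
    noise = shared_sd * w_inh[None, None, :, None] * s_proc \
        + cfg.indep_sd * e_proc                                   # [r, t, d, s]

    # --- traces ------------------------------------------------------------
    # k[r, d, s] = kernel(time[s] - t_on[r, d]); the noise process rides on
    # the response envelope (synaptic noise exists only while inputs arrive)
    karr = _kernel(time[None, None, :] - t_on[:, :, None],
                   cfg.kernel_rise_s, cfg.kernel_decay_s)        # [r, d, s]
    dff = mean_amp[:, None, :, None] * karr[:, None, :, :] * (1.0 + noise)

    # --- hot spots on the null direction ------------------------------------
    null_dir_idx = int(np.argmin(np.abs(
        (directions - (cfg.cell_pd_deg + 180.0) + 180.0) % 360.0 - 180.0)))
    sites = _select_hotspot_sites(D, cfg.hotspot_site_spacing_um)
    sigma = cfg.hotspot_fwhm_um / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    hs_rng = streams["hotspot"]
    n_events = 0
    event_log = []
    for t_idx in range(cfg.n_trials):
        for s_idx in sites:
            if hs_rng.uniform() >= cfg.hotspot_rate:
                continue
            a_evt = cfg.hotspot_amp * float(np.exp(hs_rng.normal(0.0, 0.2)))
            t_evt = t_on[s_idx, null_dir_idx] + float(hs_rng.uniform(0.0, 0.15))
            w_sp = np.exp(-D[:, s_idx] ** 2 / (2.0 * sigma ** 2))
            k_evt = _kernel(time - t_evt, cfg.kernel_rise_s, cfg.kernel_decay_s)
            dff[:, t_idx, null_dir_idx, :] += a_evt * w_sp[:, None] * k_evt[None, :]
            n_events += 1
            event_log.append((t_idx, int(s_idx), a_evt))

    # --- raw fluorescence + photon noise ------------------------------------
    F = cfg.baseline_f0 * (1.0 + dff)
    F = F + streams["photon"].normal(0.0, 1.0, F.shape) \
        * cfg.photon_noise_sd * np.sqrt(np.clip(F, 0.0, None))
    F = np.maximum(F, 1e-3)

    meta = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "scenario": cfg.scenario,
        "n_hotspot_events": n_events,
        "hotspot_events": event_log,
        "null_direction_idx": null_dir_idx,
        "truth": {
            "pd_deg": pd_r, "kappa": kappa_r, "amp": amp_r,
            "ablated": ablated, "t_on": t_on, "mean_amp": mean_amp,
        },
    }
    return TraceStack(F=F, time=time, directions_deg=directions,
                      speed_um_s=cfg.stimulus_speed, stim_onset_s=cfg.stim_onset_s,
                      field_radius=field_radius, rois=rois, meta=meta)


def render_movie(stack: TraceStack, rois: RoiSet, pixel_size: float = 0.5,
                 psf_fwhm: float = 1.0, trial: int = 0, direction: int = 0,
                 path=None) -> np.ndarray:
    """Paint each ROI's trace as a Gaussian blob; returns frames [time, H, W].

    Blobs have unit spatial integral scaled by instantaneous F, so summing
    pixels over an ROI mask recovers its trace up to quantization.
    Overlapping ROIs sum.  Optionally writes an (OME-)TIFF via tifffile.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    margin = 4.0 * psf_fwhm + 2.0
    if len(rois):
        x0, x1 = rois.x.min() - margin, rois.x.max() + margin
        y0, y1 = rois.y.min() - margin, rois.y.max() + margin
    else:
        x0, x1, y0, y1 = -margin, margin, -margin, margin
    nx = max(int(np.ceil((x1 - x0) / pixel_size)), 4)
    ny = max(int(np.ceil((y1 - y0) / pixel_size)), 4)
    xs = x0 + (np.arange(nx) + 0.5) * pixel_size
    ys = y0 + (np.arange(ny) + 0.5) * pixel_size
    sigma = max(psf_fwhm, 1e-6) / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    n_t = stack.time.size
    frames = np.zeros((n_t, ny, nx), dtype=np.float32)
    for r in range(len(rois)):
        gx = np.exp(-(xs - rois.x[r]) ** 2 / (2 * sigma ** 2))
        gy = np.exp(-(ys - rois.y[r]) ** 2 / (2 * sigma ** 2))
        blob = np.outer(gy, gx)
        blob /= blob.sum()
        trace = stack.F[r, trial, direction]
        frames += trace[:, None, None].astype(np.float32) * blob[None].astype(np.float32)
    if path is not None:
        import tifffile

        tifffile.imwrite(path, frames)
    return frames
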