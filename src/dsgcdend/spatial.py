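"""Spatially resolved dendritic analyses.

Three analyses that turn per-ROI calcium signals into spatial statements:

* **Noise correlations vs cable distance.**  Trial-mean-subtracted
  residual traces are cross-correlated for every ROI pair; the per-pair
  statistic (mean over trials of the correlogram peak within ±0.5 s) is
  fitted against cable distance with A·exp(−d/λ) + b.  A shuffled-trial
  control (seeded derangement of one ROI's trials) destroys the shared
  component and should be flat.
* **Stimulus-speed regression.**  Per-ROI 50% rise times regressed on the
  ROI position projected onto the motion axis; the inverse slope estimates
  the stimulus speed.
* **Hot-spot line profiles.**  Gaussian + baseline fits to arc-length
  ΔF/F profiles of localized null-direction events; FWHM = 2√(2 ln 2)·σ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .morphology import Morphology, RoiSet
from .traces import DffStack

__all__ = [
    "ResidualStack",
    "DecayFit",
    "SpeedFit",
    "HotspotProfile",
    "noise_residuals",
    "pairwise_peak_correlation",
    "fit_distance_decay",
    "estimate_stimulus_speed",
    "hotspot_fwhm",
    "extract_hotspot_profiles",
]


@dataclass
class ResidualStack:
    """Residual traces ``r[roi, trial, time]`` for one direction."""

    r: np.ndarray
    time: np.ndarray
    direction_deg: float


@dataclass
class DecayFit:
    amplitude: float
    lambda_um: float
    floor: float
    lambda_um_nofloor: float
    converged: bool
    binned: pd.DataFrame  # columns: bin_center_um, mean, sem, n


@dataclass
class SpeedFit:
    speed_um_s: float
    slope_s_per_um: float
    intercept_s: float
    r_squared: float
    n_rois: int
    valid: bool
    table: pd.DataFrame  # per-ROI projected distance and rise time


@dataclass
class HotspotProfile:
    positions_um: np.ndarray
    profile: np.ndarray
    center_um: float
    sigma_um: float
    amplitude: float
    baseline: float
    fwhm_um: float
    converged: bool


def noise_residuals(dff: DffStack, direction_deg: float) -> ResidualStack:
    """Trial-mean-subtracted residual traces for one stimulus direction.

    Subtracting each ROI's across-trial mean trace removes the
    stimulus-driven component, leaving the trial-to-trial "noise" whose
    spatial correlation structure is analyzed downstream.
    """
    d_idx = int(np.argmin(np.abs(dff.directions_deg - direction_deg)))
    x = dff.dff[:, :, d_idx, :]
    if x.shape[1] < 2:
        raise ValueError("need >= 2 trials to form residuals")
    if x.shape[1] < 30:
        warnings.warn("fewer than 30 trials; residual statistics will be noisy",
                      stacklevel=2)
    r = x - x.mean(axis=1, keepdims=True)
    return ResidualStack(r=r, time=dff.time,
                         direction_deg=float(dff.directions_deg[d_idx]))


def _derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random permutation of range(n) with no fixed point."""
    while True:
        p = rng.permutation(n)
        if not np.any(p == np.arange(n)):
            return p


def pairwise_peak_correlation(
    res: ResidualStack,
    rois: RoiSet,
    m: Morphology,
    max_lag_s: float = 0.5,
    shuffle: bool = False,
    seed: int = 0,
    distances: np.ndarray | None = None,
) -> pd.DataFrame:
    """Peak residual cross-correlation for every ROI pair.

    Per-trial traces are standardized to unit variance, cross-correlated
    over lags within ±``max_lag_s``; the per-pair statistic is the mean
    over trials of the maximum over lags.  In shuffle mode trial i of ROI A
    is paired with a seeded derangement of the trials of ROI B.  Returns a
    table with columns ``roi_a, roi_b, distance_um, peak_corr``;
    zero-variance traces cause the pair's affected trials to be dropped
    (and the pair skipped with a warning if none remain).
    """
    r = res.r
    n_roi, n_trials, n_s = r.shape
    if n_roi < 2:
        raise ValueError("need >= 2 ROIs")
    dt = float(res.time[1] - res.time[0])
    max_lag = max(int(round(max_lag_s / dt)), 0)
    rng = np.random.default_rng(seed)

    sd = r.std(axis=2, keepdims=True)
    ok = sd[..., 0] > 0
    z = (r - r.mean(axis=2, keepdims=True)) / np.where(sd > 0, sd, 1.0)
    z[~ok] = 0.0

    if distances is None:
        distances = rois.cable_distance_matrix(m)

    lags = np.arange(-max_lag, max_lag + 1)
    rows = []
    n_skipped = 0
    for i in range(n_roi):
        for j in range(i + 1, n_roi):
            trial_ok = ok[i] & ok[j]
            if not np.any(trial_ok):
                n_skipped += 1
                continue
            perm = _derangement(n_trials, rng) if shuffle and n_trials > 1 \
                else np.arange(n_trials)
            a = z[i]
            b = z[j][perm]
            # corr at lag L over the overlapping window, normalized by n_s
            best = np.full(n_trials, -np.inf)
            for L in lags:
                if L >= 0:
                    c = np.einsum("ts,ts->t", a[:, L:], b[:, : n_s - L])
                else:
                    c = np.einsum("ts,ts->t", a[:, :L], b[:, -L:])
                np.maximum(best, c / n_s, out=best)
            rows.append((
                int(rois.roi_ids[i]), int(rois.roi_ids[j]),
                float(distances[i, j]), float(best[trial_ok].mean()),
            ))
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} pairs with zero-variance residuals",
                      stacklevel=2)
    return pd.DataFrame(rows, columns=["roi_a", "roi_b", "distance_um", "peak_corr"])


def _exp_decay(d, A, lam, b):
    return A * np.exp(-d / lam) + b


def fit_distance_decay(pairs: pd.DataFrame, bin_width_um: float = 2.0,
                       fit_binned: bool = False) -> DecayFit:
    """Exponential distance-decay fit corr(d) = A·exp(−d/λ) + b.

    Fits the raw pairwise points by default (better conditioned than the
    binned means, which are reported for display); a with-floor and a
    zero-floor λ are both returned since either convention is defensible.
    """
    d = pairs["distance_um"].to_numpy(dtype=float)
    c = pairs["peak_corr"].to_numpy(dtype=float)

    bins = np.floor(d / bin_width_um).astype(int)
    g = pd.DataFrame({"bin": bins, "corr": c}).groupby("bin")["corr"]
    binned = pd.DataFrame({
        "bin_center_um": (g.mean().index + 0.5) * bin_width_um,
        "mean": g.mean().to_numpy(),
        "sem": g.sem().to_numpy(),
        "n": g.count().to_numpy(),
    }).reset_index(drop=True)
    if binned.shape[0] < 3:
        raise ValueError("need >= 3 occupied distance bins")

    xd, yc = (binned["bin_center_um"].to_numpy(), binned["mean"].to_numpy()) \
        if fit_binned else (d, c)

    span = max(float(yc.max() - yc.min()), 1e-6)
    p0 = [span, 5.0, float(np.median(yc[xd > np.median(xd)]))]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                _exp_decay, xd, yc, p0=p0,
                bounds=([0.0, 1e-3, -1.0], [2.0, 1e3, 1.0]), maxfev=10000)
        A, lam, b = (float(v) for v in popt)
        converged = True
    except (RuntimeError, ValueError):
        A = lam = b = float("nan")
        converged = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt0, _ = optimize.curve_fit(
                lambda x, A_, l_: _exp_decay(x, A_, l_, 0.0), xd, yc,
                p0=[span, 5.0], bounds=([0.0, 1e-3], [2.0, 1e3]), maxfev=10000)
        lam0 = float(popt0[1])
    except (RuntimeError, ValueError):
        lam0 = float("nan")
    return DecayFit(A, lam, b, lam0, converged, binned)


def estimate_stimulus_speed(
    features: pd.DataFrame,
    rois: RoiSet,
    direction_deg: float,
    field_center: tuple = (0.0, 0.0),
) -> SpeedFit:
    """Stimulus speed from the rise-time vs projected-distance regression.

    ROI centroids are projected onto the motion-direction unit vector
    (lateral distance along the stimulus trajectory); ordinary least
    squares of the per-ROI mean 50% rise time on projected distance gives
    a slope of 1/speed.  A global latency offset only shifts the
    intercept.
    """
    sub = features[np.isclose(features["direction_deg"], direction_deg)]
    rt = sub.groupby("roi")["rise_time_50"].mean()
    rt = rt.dropna()
    if rt.size < 3:
        raise ValueError("need >= 3 ROIs with defined rise times")
    th = np.deg2rad(direction_deg)
    idx = {int(rid): k for k, rid in enumerate(rois.roi_ids)}
    proj = np.array([
        (rois.x[idx[int(r)]] - field_center[0]) * np.cos(th)
        + (rois.y[idx[int(r)]] - field_center[1]) * np.sin(th)
        for r in rt.index
    ])
    fit = stats.linregress(proj, rt.to_numpy())
    valid = fit.slope > 0
    speed = 1.0 / fit.slope if valid else float("nan")
    table = pd.DataFrame({"roi": rt.index, "projected_um": proj,
                          "rise_time_s": rt.to_numpy()})
    return SpeedFit(float(speed), float(fit.slope), float(fit.intercept),
                    float(fit.rvalue ** 2), int(rt.size), bool(valid), table)


def _gauss(x, b, A, mu, sigma):
    return b + A * np.exp(-((x - mu) ** 2) / (2.0 * sigma ** 2))


_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


def hotspot_fwhm(positions_um, profile) -> HotspotProfile:
    """Gaussian + baseline fit to a 1-D arc-length ΔF/F line profile.

    Requires an interior maximum; monotone profiles return a failure flag.
    FWHM = 2√(2 ln 2)·σ.
    """
    x = np.asarray(positions_um, dtype=float)
    y = np.asarray(profile, dtype=float)
    if x.size < 5:
        raise ValueError("profile too short to fit")
    kmax = int(np.argmax(y))
    interior = 0 < kmax < x.size - 1
    monotone = np.all(np.diff(y) >= 0) or np.all(np.diff(y) <= 0)
    if (not interior) or monotone or np.ptp(y) == 0:
        return HotspotProfile(x, y, np.nan, np.nan, np.nan, np.nan, np.nan,
                              converged=False)
    p0 = [float(np.min(y)), float(np.ptp(y)), float(x[kmax]), 1.5]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                _gauss, x, y, p0=p0,
                bounds=([-np.inf, 1e-9, x.min(), 0.05],
                        [np.inf, np.inf, x.max(), (x.max() - x.min())]),
                maxfev=10000)
    except (RuntimeError, ValueError):
        return HotspotProfile(x, y, np.nan, np.nan, np.nan, np.nan, np.nan,
                              converged=False)
    b, A, mu, sigma = (float(v) for v in popt)
    return HotspotProfile(x, y, mu, sigma, A, b, _FWHM_FACTOR * sigma,
                          converged=True)


def extract_hotspot_profiles(
    dff: DffStack,
    rois: RoiSet,
    m: Morphology,
    direction_deg: float,
    detect_threshold: float = 0.5,
    window_um: float = 6.0,
    distances: np.ndarray | None = None,
    events: list | None = None,
) -> list[HotspotProfile]:
    """Detect and fit localized events along the arbor for one direction.

    For every trial, the per-ROI peak ΔF/F (max over the post-onset
    window) forms a spatial map; a trial contains an event when the map's
    maximum exceeds the map median by ``detect_threshold``.  The profile
    within ``window_um`` cable distance of the peak ROI is fitted with
    :func:`hotspot_fwhm`.  Fits are kept only when they describe a
    localized event: converged, centre within half the window of the peak,
    fitted width smaller than the window, and fitted amplitude at least
    half the detection criterion (rejects fits that merely track the
    broad tuned response or noise field).

    When ``events`` is given — a list of ``(trial, roi_index)`` locations,
    e.g. known event sites in a closed-loop recovery experiment — detection
    is skipped and profiles are extracted at those locations; the Gaussian
    fit itself remains blind to the generating width.
    """
    d_idx = int(np.argmin(np.abs(dff.directions_deg - direction_deg)))
    sel = dff.time >= dff.stim_onset_s
    maps = dff.dff[:, :, d_idx, :][:, :, sel].max(axis=2)  # [roi, trial]
    if distances is None:
        distances = rois.cable_distance_matrix(m)
    if events is None:
        candidates = []
        for t in range(maps.shape[1]):
            k = int(np.argmax(maps[:, t]))
            if maps[k, t] - np.median(maps[:, t]) >= detect_threshold:
                candidates.append((t, k))
    else:
        candidates = [(int(t), int(k)) for t, k in events]

    profiles = []
    for t, k in candidates:
        prof_map = maps[:, t]
        near = np.flatnonzero(distances[k] <= window_um)
        if near.size < 5:
            continue
        # signed arc position along the branch through the peak ROI:
        # sign from the projection onto the neighborhood's principal axis
        pos = distances[k, near].copy()
        dxy = np.column_stack([rois.x[near] - rois.x[k], rois.y[near] - rois.y[k]])
        if np.allclose(dxy, 0):
            continue
        _, _, vt = np.linalg.svd(dxy, full_matrices=False)
        side = np.sign(dxy @ vt[0])
        pos = pos * np.where(side == 0, 1.0, side)
        order = np.argsort(pos)
        fit = hotspot_fwhm(pos[order], prof_map[near][order])
        if (fit.converged
                and abs(fit.center_um) <= window_um / 2.0
                and fit.fwhm_um < window_um
                and fit.amplitude >= 0.5 * detect_threshold):
            profiles.append(fit)
    return profiles
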