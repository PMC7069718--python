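"""ΔF/F conversion and per-trial scalar features of dendritic calcium traces.

The downstream direction-tuning and spatial statistics all consume the
scalar features extracted here: the peak ΔF/F measured as the mean over a
brief (200 ms) window centred on the in-stimulus maximum of the smoothed
trace, the 50% rise time, and the per-ROI responsiveness flag (peak of the
trial-averaged response in the best direction exceeding three times the
baseline noise SD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "DffStack",
    "compute_dff",
    "smooth_trace",
    "peak_response",
    "rise_time_50",
    "compute_features",
    "responsive_mask",
]


class TraceError(ValueError):
    pass


@dataclass
class DffStack:
    """ΔF/F traces, shape ``[roi, trial, direction, time]``.

    ``baseline_window`` is the (start, stop) interval in seconds whose mean
    raw fluorescence defined F0 for each trace.
    """

    dff: np.ndarray
    time: np.ndarray
    directions_deg: np.ndarray
    baseline_window: tuple
    stim_onset_s: float
    meta: dict

    @property
    def n_rois(self) -> int:
        return self.dff.shape[0]


def compute_dff(stack, baseline_window: tuple | None = None) -> DffStack:
    """Convert a raw :class:`~dsgcdend.synth.TraceStack` to ΔF/F.

    F0 is the per-trace mean of the baseline window (default: the whole
    pre-stimulus interval).  dff = (F − F0) / F0.
    """
    time = stack.time
    if baseline_window is None:
        baseline_window = (float(time[0]), float(stack.stim_onset_s))
    b0, b1 = baseline_window
    sel = (time >= b0) & (time < b1)
    if not np.any(sel):
        raise TraceError("baseline window contains no samples")
    F = stack.F
    F0 = F[..., sel].mean(axis=-1, keepdims=True)
    if np.any(F0 <= 0):
        r, t, d, _ = np.unravel_index(int(np.argmax(F0 <= 0)), F0.shape)
        raise TraceError(f"non-positive baseline F0 for roi={r}, trial={t}, direction={d}")
    dff = (F - F0) / F0
    return DffStack(
        dff=dff,
        time=time,
        directions_deg=stack.directions_deg,
        baseline_window=(b0, b1),
        stim_onset_s=stack.stim_onset_s,
        meta=dict(stack.meta),
    )


def smooth_trace(x: np.ndarray, polyorder: int = 2, window: int = 11) -> np.ndarray:
    """Savitzky-Golay least-squares polynomial smoothing (length-preserving)."""
    x = np.asarray(x, dtype=float)
    if window % 2 == 0 or window <= polyorder:
        raise TraceError("window must be odd and greater than polyorder")
    if window >= x.shape[-1]:
        raise TraceError("window must be shorter than the trace")
    return savgol_filter(x, window_length=window, polyorder=polyorder, axis=-1)


def peak_response(
    trace: np.ndarray,
    time: np.ndarray,
    stim_window: tuple,
    peak_window_s: float = 0.2,
    polyorder: int = 2,
    smooth_window: int = 11,
    mode: str = "window_mean",
) -> float:
    """Peak ΔF/F of a single trace.

    Locates the maximum of the smoothed trace inside ``stim_window`` and
    returns the mean of the (raw) trace over a ``peak_window_s`` window
    centred there, clipped to the trace bounds.  ``mode='max'`` returns the
    smoothed maximum itself.
    """
    sel = (time >= stim_window[0]) & (time <= stim_window[1])
    if not np.any(sel):
        raise TraceError("empty stimulus window")
    sm = smooth_trace(trace, polyorder, smooth_window)
    idx_in = np.flatnonzero(sel)
    k = idx_in[int(np.argmax(sm[idx_in]))]
    if mode == "max":
        return float(sm[k])
    half = peak_window_s / 2.0
    t_pk = time[k]
    wsel = (time >= t_pk - half) & (time <= t_pk + half)
    return float(np.mean(trace[wsel]))


def rise_time_50(
    trace: np.ndarray,
    time: np.ndarray,
    stim_window: tuple,
    onset_s: float,
    polyorder: int = 2,
    smooth_window: int = 11,
    noise_floor: float = 0.0,
) -> float:
    """50% rise time of a single trace, in seconds from ``onset_s``.

    First time (linear interpolation between samples) at which the smoothed
    trace reaches half of its in-window peak.  Returns NaN when the peak
    does not exceed ``noise_floor`` (undefined rather than an error).
    """
    sel = (time >= stim_window[0]) & (time <= stim_window[1])
    if not np.any(sel):
        raise TraceError("empty stimulus window")
    sm = smooth_trace(trace, polyorder, smooth_window)
    idx_in = np.flatnonzero(sel)
    kpk = idx_in[int(np.argmax(sm[idx_in]))]
    peak = sm[kpk]
    if peak <= noise_floor:
        return float("nan")
    half = 0.5 * peak
    # search from the stimulus-window start up to the peak
    for k in range(idx_in[0], kpk + 1):
        if sm[k] >= half:
            if k == 0 or sm[k - 1] >= half:
                t_cross = time[k]
            else:
                f = (half - sm[k - 1]) / (sm[k] - sm[k - 1])
                t_cross = time[k - 1] + f * (time[k] - time[k - 1])
            return float(t_cross - onset_s)
    return float("nan")


def compute_features(
    dff: DffStack,
    stim_window: tuple | None = None,
    peak_window_s: float = 0.2,
    smooth_window: int = 11,
    rise_noise_floor_sd: float = 3.0,
) -> pd.DataFrame:
    """Per-(roi, trial, direction) feature table.

    Columns: ``roi, trial, direction_deg, peak_dff, rise_time_50,
    baseline_sd``.  ``baseline_sd`` is the per-ROI SD of the *unsmoothed*
    ΔF/F baseline pooled across trials and directions (smoothing would
    deflate the noise floor against which responsiveness is judged).
    Rise times are NaN when the smoothed peak stays within
    ``rise_noise_floor_sd`` baseline SDs.
    """
    time = dff.time
    if stim_window is None:
        stim_window = (dff.stim_onset_s, float(time[-1]))
    b0, b1 = dff.baseline_window
    bsel = (time >= b0) & (time < b1)
    base_sd = dff.dff[..., bsel].std(axis=(1, 2, 3))  # per ROI

    n_r, n_t, n_d, n_s = dff.dff.shape
    sm = smooth_trace(dff.dff, 2, smooth_window)
    idx_in = np.flatnonzero((time >= stim_window[0]) & (time <= stim_window[1]))
    if idx_in.size == 0:
        raise TraceError("empty stimulus window")
    kpk = idx_in[np.argmax(sm[..., idx_in], axis=-1)]  # [r,t,d] sample index

    # peak = mean of the raw trace over a peak_window_s window centred on
    # the smoothed maximum (clipped to the trace), via cumulative sums
    half = peak_window_s / 2.0
    t_pk = time[kpk]
    lo = np.searchsorted(time, t_pk - half, side="left")
    hi = np.searchsorted(time, t_pk + half, side="right")
    csum = np.concatenate(
        [np.zeros(dff.dff.shape[:-1] + (1,)), np.cumsum(dff.dff, axis=-1)], axis=-1
    )
    flat = csum.reshape(-1, n_s + 1)
    lo_f, hi_f = lo.ravel(), hi.ravel()
    rows_idx = np.arange(flat.shape[0])
    peaks = (flat[rows_idx, hi_f] - flat[rows_idx, lo_f]) / (hi_f - lo_f)
    peaks = peaks.reshape(n_r, n_t, n_d)

    # 50% rise time from stimulus onset, linear interpolation
    rise = np.full((n_r, n_t, n_d), np.nan)
    sm_flat = sm.reshape(-1, n_s)
    kpk_flat = kpk.ravel()
    floor = (rise_noise_floor_sd * base_sd)[:, None, None]
    floor_flat = np.broadcast_to(floor, (n_r, n_t, n_d)).ravel()
    k0 = idx_in[0]
    rise_flat = rise.ravel()
    for i in range(sm_flat.shape[0]):
        pk_val = sm_flat[i, kpk_flat[i]]
        if pk_val <= floor_flat[i]:
            continue
        hv = 0.5 * pk_val
        seg = sm_flat[i, k0:kpk_flat[i] + 1]
        above = seg >= hv
        if not above.any():
            continue
        j = int(np.argmax(above)) + k0
        if j == 0 or sm_flat[i, j - 1] >= hv:
            t_cross = time[j]
        else:
            f = (hv - sm_flat[i, j - 1]) / (sm_flat[i, j] - sm_flat[i, j - 1])
            t_cross = time[j - 1] + f * (time[j] - time[j - 1])
        rise_flat[i] = t_cross - dff.stim_onset_s
    rise = rise_flat.reshape(n_r, n_t, n_d)

    r_ix, t_ix, d_ix = np.meshgrid(
        np.arange(n_r), np.arange(n_t), np.arange(n_d), indexing="ij"
    )
    return pd.DataFrame({
        "roi": r_ix.ravel(),
        "trial": t_ix.ravel(),
        "direction_deg": dff.directions_deg[d_ix.ravel()],
        "peak_dff": peaks.ravel(),
        "rise_time_50": rise.ravel(),
        "baseline_sd": base_sd[r_ix.ravel()],
    })


def responsive_mask(features: pd.DataFrame, k_sd: float = 3.0) -> pd.Series:
    """Per-ROI responsiveness flag.

    An ROI is responsive iff the maximum over directions of its
    trial-averaged peak exceeds ``k_sd`` times its baseline noise SD —
    i.e. it responded to at least one direction of motion.
    """
    mean_peaks = (
        features.groupby(["roi", "direction_deg"])["peak_dff"].mean().groupby("roi").max()
    )
    base_sd = features.groupby("roi")["baseline_sd"].first()
    return mean_peaks > k_sd * base_sd
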