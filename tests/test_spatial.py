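import numpy as np
import pandas as pd
import pytest

from dsgcdend.morphology import place_rois
from dsgcdend.spatial import (
    ResidualStack,
    estimate_stimulus_speed,
    extract_hotspot_profiles,
    fit_distance_decay,
    hotspot_fwhm,
    noise_residuals,
    pairwise_peak_correlation,
)
from dsgcdend.synth import SynthConfig, generate_imaging_dataset
from dsgcdend.traces import DffStack, compute_dff, compute_features

from conftest import straight_cable

FWHM_FACTOR = 2 * np.sqrt(2 * np.log(2))


def _dff_from_array(x, frame_rate=20.0, directions=(90.0,), stim_onset=0.0):
    """x: [roi, trial, time] -> single-direction DffStack."""
    x = np.asarray(x, dtype=float)[:, :, None, :]
    return DffStack(dff=x, time=np.arange(x.shape[-1]) / frame_rate,
                    directions_deg=np.asarray(directions),
                    baseline_window=(0.0, 0.0), stim_onset_s=stim_onset,
                    meta={})


class TestNoiseResiduals:
    def test_identical_trials_zero_residuals(self):
        x = np.tile(np.sin(np.linspace(0, 3, 40)), (3, 5, 1))
        res = noise_residuals(_dff_from_array(x), 90.0)
        assert np.allclose(res.r, 0.0)

    def test_mean_of_residuals_is_zero(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((4, 8, 50))
        with pytest.warns(UserWarning, match="30 trials"):
            res = noise_residuals(_dff_from_array(x), 90.0)
        assert np.allclose(res.r.mean(axis=1), 0.0, atol=1e-12)

    def test_known_offsets_recovered(self):
        base = np.sin(np.linspace(0, 3, 30))
        offsets = np.array([0.5, -0.2, 0.1, -0.4])
        x = base[None, None, :] + offsets[None, :, None]
        res = noise_residuals(_dff_from_array(x), 90.0)
        want = offsets - offsets.mean()
        assert np.allclose(res.r[0, :, 0], want, atol=1e-12)

    def test_single_trial_rejected(self):
        x = np.zeros((2, 1, 30))
        with pytest.raises(ValueError):
            noise_residuals(_dff_from_array(x), 90.0)


class TestPairwiseCorrelation:
    def test_identical_rois_correlate_at_one(self):
        rng = np.random.default_rng(1)
        tr = rng.standard_normal((4, 100))
        x = np.stack([tr, tr.copy()])  # two identical ROIs
        x -= x.mean(axis=1, keepdims=True)
        res = ResidualStack(r=x, time=np.arange(100) / 20.0, direction_deg=90.0)
        m = straight_cable(4, step=2.0)
        rois = place_rois(m, 4.0, seed=0)
        pairs = pairwise_peak_correlation(
            res, rois, m, distances=np.zeros((2, 2)))
        assert pairs["peak_corr"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_shared_plus_independent_gives_half(self):
        # residual = shared + independent noise, variance 1:1 ->
        # zero-lag correlation ~ 0.5
        rng = np.random.default_rng(2)
        n_tr, n_s = 60, 400
        shared = rng.standard_normal((n_tr, n_s))
        a = shared + rng.standard_normal((n_tr, n_s))
        b = shared + rng.standard_normal((n_tr, n_s))
        x = np.stack([a, b])
        x -= x.mean(axis=1, keepdims=True)
        res = ResidualStack(r=x, time=np.arange(n_s) / 100.0, direction_deg=90.0)
        m = straight_cable(4, step=2.0)
        rois = place_rois(m, 4.0, seed=0)
        pairs = pairwise_peak_correlation(
            res, rois, m, max_lag_s=0.0, distances=np.zeros((2, 2)))
        assert pairs["peak_corr"].iloc[0] == pytest.approx(0.5, abs=0.05)

    def test_independent_noise_matches_mc_null_bias(self):
        # max-over-lags of white-noise correlograms has a small positive
        # bias; compare implementation against a direct Monte-Carlo oracle
        rng = np.random.default_rng(3)
        n_tr, n_s, max_lag = 30, 200, 10
        x = rng.standard_normal((2, n_tr, n_s))
        x -= x.mean(axis=1, keepdims=True)
        res = ResidualStack(r=x, time=np.arange(n_s) / 20.0, direction_deg=90.0)
        m = straight_cable(4, step=2.0)
        rois = place_rois(m, 4.0, seed=0)
        pairs = pairwise_peak_correlation(
            res, rois, m, max_lag_s=0.5, distances=np.zeros((2, 2)))
        got = pairs["peak_corr"].iloc[0]

        # oracle: same statistic on fresh white noise, many repetitions
        vals = []
        for _ in range(150):
            a = rng.standard_normal(n_s)
            b = rng.standard_normal(n_s)
            a = (a - a.mean()) / a.std()
            b = (b - b.mean()) / b.std()
            cc = [np.dot(a[max(0, L):n_s + min(0, L)],
                         b[max(0, -L):n_s - max(0, L)]) / n_s
                  for L in range(-max_lag, max_lag + 1)]
            vals.append(max(cc))
        mc_mean = np.mean(vals)
        se = np.std(vals) / np.sqrt(n_tr) + np.std(vals) / np.sqrt(len(vals))
        assert abs(got - mc_mean) < 4 * se

    def test_zero_variance_pair_skipped(self):
        x = np.zeros((2, 3, 50))
        x[0] = np.random.default_rng(0).standard_normal((3, 50))
        x -= x.mean(axis=1, keepdims=True)
        res = ResidualStack(r=x, time=np.arange(50) / 20.0, direction_deg=90.0)
        m = straight_cable(4, step=2.0)
        rois = place_rois(m, 4.0, seed=0)
        with pytest.warns(UserWarning, match="zero-variance"):
            pairs = pairwise_peak_correlation(
                res, rois, m, distances=np.zeros((2, 2)))
        assert len(pairs) == 0


class TestDistanceDecayFit:
    def test_noiseless_recovery(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(0, 40, 300)
        c = 0.6 * np.exp(-d / 5.3) + 0.02
        fit = fit_distance_decay(pd.DataFrame({"distance_um": d,
                                               "peak_corr": c}))
        assert fit.converged
        assert fit.amplitude == pytest.approx(0.6, abs=1e-6)
        assert fit.lambda_um == pytest.approx(5.3, abs=1e-6)
        assert fit.floor == pytest.approx(0.02, abs=1e-6)

    def test_binned_curve_shape(self):
        d = np.concatenate([np.full(10, 1.0), np.full(10, 3.0),
                            np.full(10, 5.0)])
        c = np.concatenate([np.full(10, 0.5), np.full(10, 0.3),
                            np.full(10, 0.1)])
        fit = fit_distance_decay(pd.DataFrame({"distance_um": d,
                                               "peak_corr": c}))
        assert len(fit.binned) == 3
        assert np.allclose(fit.binned["mean"], [0.5, 0.3, 0.1])

    def test_too_few_bins_rejected(self):
        df = pd.DataFrame({"distance_um": [1.0, 1.5], "peak_corr": [0.5, 0.4]})
        with pytest.raises(ValueError):
            fit_distance_decay(df)


class TestSpeedEstimation:
    def test_exact_line(self):
        m = straight_cable(30, step=4.0)
        rois = place_rois(m, 8.0, seed=0)
        v = 500.0
        rows = []
        for k, rid in enumerate(rois.roi_ids):
            rt = rois.x[k] / v + 0.3
            rows.append((int(rid), 0, 0.0, 1.0, rt, 0.01))
        feats = pd.DataFrame(rows, columns=["roi", "trial", "direction_deg",
                                            "peak_dff", "rise_time_50",
                                            "baseline_sd"])
        fit = estimate_stimulus_speed(feats, rois, 0.0)
        assert fit.valid
        assert fit.speed_um_s == pytest.approx(500.0, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_latency_offset_invariance(self):
        m = straight_cable(30, step=4.0)
        rois = place_rois(m, 8.0, seed=0)
        speeds = []
        for offset in (0.0, 0.8):
            rows = [(int(rid), 0, 0.0, 1.0, rois.x[k] / 400.0 + offset, 0.01)
                    for k, rid in enumerate(rois.roi_ids)]
            feats = pd.DataFrame(rows, columns=["roi", "trial", "direction_deg",
                                                "peak_dff", "rise_time_50",
                                                "baseline_sd"])
            speeds.append(estimate_stimulus_speed(feats, rois, 0.0).speed_um_s)
        assert speeds[0] == pytest.approx(speeds[1], rel=1e-9)

    def test_closed_loop_recovery_with_noise(self):
        m = straight_cable(60, step=2.0)  # 120 µm span
        rois = place_rois(m, 6.0, seed=0)
        speeds = []
        for seed in range(3):
            cfg = SynthConfig(seed=seed, n_trials=4)
            stack = generate_imaging_dataset(cfg, rois, m)
            dff = compute_dff(stack)
            feats = compute_features(dff)
            fit = estimate_stimulus_speed(feats, rois, 0.0)
            speeds.append(fit.speed_um_s)
        assert np.mean(speeds) == pytest.approx(500.0, rel=0.05)


class TestHotspotFwhm:
    def test_exact_gaussian_closed_form(self):
        x = np.linspace(-6, 6, 25)
        sigma = 3.0 / FWHM_FACTOR
        y = 0.1 + 1.0 * np.exp(-x ** 2 / (2 * sigma ** 2))
        fit = hotspot_fwhm(x, y)
        assert fit.converged
        assert fit.fwhm_um == pytest.approx(3.0, rel=1e-6)
        assert fit.sigma_um == pytest.approx(sigma, rel=1e-6)

    def test_flat_profile_flagged(self):
        x = np.linspace(-5, 5, 21)
        fit = hotspot_fwhm(x, np.full(21, 0.2))
        assert not fit.converged

    def test_monotone_profile_flagged(self):
        x = np.linspace(-5, 5, 21)
        fit = hotspot_fwhm(x, np.linspace(0, 1, 21))
        assert not fit.converged

    def test_closed_loop_width_recovery(self):
        m = straight_cable(70, step=1.0)
        rois = place_rois(m, 1.0, seed=0)
        D = rois.cable_distance_matrix(m)
        widths = []
        for seed in range(6):
            cfg = SynthConfig(seed=seed, n_trials=30)
            stack = generate_imaging_dataset(cfg, rois, m)
            dff = compute_dff(stack)
            nd = stack.meta["null_direction_idx"]
            ev = [(t, k) for t, k, _ in stack.meta["hotspot_events"]]
            profs = extract_hotspot_profiles(
                dff, rois, m, stack.directions_deg[nd], distances=D,
                events=ev)
            widths += [p.fwhm_um for p in profs]
        assert len(widths) >= 30
        assert np.mean(widths) == pytest.approx(3.0, rel=0.15)

    def test_blind_detection_finds_events(self):
        m = straight_cable(70, step=1.0)
        rois = place_rois(m, 1.0, seed=0)
        D = rois.cable_distance_matrix(m)
        cfg = SynthConfig(seed=2, n_trials=20, shared_sd=0.1, indep_sd=0.05)
        stack = generate_imaging_dataset(cfg, rois, m)
        dff = compute_dff(stack)
        nd = stack.meta["null_direction_idx"]
        profs = extract_hotspot_profiles(dff, rois, m,
                                         stack.directions_deg[nd],
                                         distances=D)
        n_true = stack.meta["n_hotspot_events"]
        assert n_true > 0
        assert len(profs) >= 0.5 * n_true
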