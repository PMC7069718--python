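import numpy as np
import pytest
from scipy.stats import binomtest

from dsgcdend.model import (
    ModelSpec,
    build_model,
    draw_release_outcomes,
    simulate_current_injection,
    simulate_direction_sweep,
    threshold_tuning_map,
)

from conftest import straight_cable

EIGHT = np.arange(8) * 45.0


@pytest.fixture(scope="module")
def arbor_model(arbor):
    return build_model(arbor, ModelSpec(), seed=3)


class TestBuildModel:
    def test_cylinder_compartment_count(self):
        m = straight_cable(20, step=5.0)  # single 100 µm cylinder
        model = build_model(m, ModelSpec(soma_radius_um=None))
        assert model.n_comp == 20

    def test_pair_count(self, arbor_model):
        assert arbor_model.syn_comp.size == 177

    def test_segment_length_bound(self, arbor_model):
        dend = arbor_model.region != 0
        assert arbor_model.length_um[dend].max() <= 5.0 + 1e-9

    def test_input_resistance_matches_finite_cable_formula(self):
        # sealed-end cylinder: R_in = (Ra λ / (π r²)) coth(L/λ) within 1%
        spec = ModelSpec(soma_radius_um=None, g_leak_ms_cm2=0.5)
        m = straight_cable(100, step=5.0, radius=1.0)  # L = 500 µm
        model = build_model(m, spec)
        V = simulate_current_injection(model, 0, 0.05, 400.0)
        r_in = (V[0, -1] - spec.e_leak_mv) / 0.05  # mV / nA = MΩ
        r_cm = 1.0e-4
        rm = 1.0 / (spec.g_leak_ms_cm2 * 1e-3)      # Ω·cm²
        lam_cm = np.sqrt(rm * r_cm / (2 * spec.ra_ohm_cm))
        r_inf = spec.ra_ohm_cm * lam_cm / (np.pi * r_cm ** 2)  # Ω
        L_cm = 500.0e-4
        want = r_inf / np.tanh(L_cm / lam_cm) / 1e6  # MΩ
        assert r_in == pytest.approx(want, rel=0.01)


class TestReleaseRule:
    def test_p_inh_endpoints(self):
        spec = ModelSpec(p_pref=0.05, p_null=0.9, theta_pref_deg=0.0)
        assert spec.p_inh(0.0) == pytest.approx(0.05)
        assert spec.p_inh(180.0) == pytest.approx(0.9)
        assert spec.p_inh(90.0) == pytest.approx((0.05 + 0.9) / 2)

    def test_p_one_releases_all(self, arbor):
        model = build_model(arbor, ModelSpec(p_exc=1.0, p_pref=1.0,
                                             p_null=1.0), seed=0)
        exc, inh, _, _ = draw_release_outcomes(model, 90.0, 1)
        assert exc.all() and inh.all()

    def test_p_zero_releases_none(self, arbor):
        model = build_model(arbor, ModelSpec(p_exc=0.0, p_pref=0.0,
                                             p_null=0.0), seed=0)
        exc, inh, _, _ = draw_release_outcomes(model, 90.0, 1)
        assert not exc.any() and not inh.any()

    def test_null_frequency_matches_binomial(self, arbor_model):
        # empirical inhibitory release rate at the null direction over
        # ~10^4 draws stays within 3 binomial SDs of p_null
        rng = np.random.default_rng(7)
        n_draws = 60  # 60 x 177 > 10^4 synapse draws
        hits = total = 0
        for _ in range(n_draws):
            _, inh, _, _ = draw_release_outcomes(arbor_model, 180.0, rng)
            hits += int(inh.sum())
            total += inh.size
        p_null = arbor_model.spec.p_null
        sd = np.sqrt(p_null * (1 - p_null) / total)
        assert abs(hits / total - p_null) < 3 * sd

    def test_release_count_monotone_in_angle(self, arbor_model):
        # inhibitory counts grow toward the null direction; excitatory flat
        rng = np.random.default_rng(8)
        inh_means, exc_means = [], []
        for theta in (0.0, 90.0, 180.0):
            ih, ex = [], []
            for _ in range(40):
                e, i, _, _ = draw_release_outcomes(arbor_model, theta, rng)
                ih.append(i.mean())
                ex.append(e.mean())
            inh_means.append(np.mean(ih))
            exc_means.append(np.mean(ex))
        assert inh_means[0] < inh_means[1] < inh_means[2]
        # excitatory rate direction-independent: binomial test at p_exc
        n = 40 * 177
        res = binomtest(int(np.round(exc_means[0] * n)), n,
                        arbor_model.spec.p_exc)
        assert res.pvalue > 1e-4

    def test_onsets_track_edge_crossing(self, arbor_model):
        spec = arbor_model.spec
        rng = np.random.default_rng(9)
        _, _, t_e, _ = draw_release_outcomes(arbor_model, 0.0, rng)
        proj = arbor_model.xy[arbor_model.syn_comp][:, 0]  # theta=0 -> x
        slope = np.polyfit(proj, t_e, 1)[0]
        assert slope == pytest.approx(1.0 / (spec.speed_um_s / 1000.0),
                                      rel=0.15)


class TestCableSolver:
    def test_passive_equilibrium_no_input(self, arbor_model):
        sim_v = simulate_current_injection(arbor_model, 0, 0.0, 30.0)
        assert np.allclose(sim_v, -60.0, atol=1e-9)

    def test_sealed_cylinder_attenuation_matches_cosh(self):
        spec = ModelSpec(soma_radius_um=None)
        m = straight_cable(100, step=5.0, radius=1.0)
        model = build_model(m, spec)
        V = simulate_current_injection(model, 0, 0.05, 400.0)
        vss = V[:, -1].astype(float) - spec.e_leak_mv
        x = np.arange(model.n_comp) * 5.0 + 2.5
        rm = 1.0 / (spec.g_leak_ms_cm2 * 1e-3)
        lam_um = np.sqrt(rm * 1.0e-4 / (2 * spec.ra_ohm_cm)) * 1e4
        pred = np.cosh((500.0 - x) / lam_um) / np.cosh(500.0 / lam_um)
        assert np.max(np.abs(vss / vss[0] - pred / pred[0])) < 0.01

    def test_dt_halving_convergence(self):
        m = straight_cable(100, step=5.0, radius=1.0)
        v1 = simulate_current_injection(
            build_model(m, ModelSpec(soma_radius_um=None)), 0, 0.05, 400.0)
        v2 = simulate_current_injection(
            build_model(m, ModelSpec(soma_radius_um=None, dt_ms=0.0125)),
            0, 0.05, 400.0)
        assert np.max(np.abs(v1 - v2)) < 0.1

    def test_single_epsp_attenuates_with_distance(self):
        from dsgcdend.model import _run_once

        spec = ModelSpec(soma_radius_um=None)
        m = straight_cable(40, step=5.0, radius=0.3)
        model = build_model(m, spec)
        site = 20
        V = _run_once(model, np.array([site]), np.array([20.0]),
                      np.array([5e-4]), np.array([0.0]), np.array([0.5]),
                      np.array([3.0]), 100.0)
        peaks = V.max(axis=1) + 60.0
        assert np.argmax(peaks) == site
        right = peaks[site:]
        assert np.all(np.diff(right) < 1e-9)

    def test_shunting_inhibition_reduces_epsp(self):
        # co-located, co-timed E+I with E_inh = E_leak: strictly smaller
        # depolarization than E alone (divisive, not subtractive)
        from dsgcdend.model import _run_once

        spec = ModelSpec(soma_radius_um=None)
        m = straight_cable(40, step=5.0, radius=0.3)
        model = build_model(m, spec)
        site = 20
        v_e = _run_once(model, np.array([site]), np.array([20.0]),
                        np.array([5e-4]), np.array([0.0]), np.array([0.5]),
                        np.array([3.0]), 100.0)
        v_ei = _run_once(model, np.array([site, site]),
                         np.array([20.0, 20.0]), np.array([5e-4, 3e-3]),
                         np.array([0.0, -60.0]), np.array([0.5, 1.0]),
                         np.array([3.0, 10.0]), 100.0)
        assert v_ei[site].max() < v_e[site].max() - 0.5
        # shunting never hyperpolarizes below rest
        assert v_ei.min() >= -60.0 - 1e-6

    def test_charge_conservation_all_reversals_at_leak(self, arbor):
        # E_exc = E_inh = E_leak: conductance transients cannot move V
        spec = ModelSpec(e_rev_exc_mv=-60.0, e_rev_inh_mv=-60.0)
        model = build_model(arbor, spec, seed=3)
        sim = simulate_direction_sweep(model, [0.0], n_sets=1, seed=0)
        assert np.allclose(sim.V, -60.0, atol=1e-6)

    def test_active_channels_spike_and_stay_finite(self, arbor):
        spec = ModelSpec(active_enabled=True)
        model = build_model(arbor, spec, seed=3)
        # sodium spike under somatic current drive
        V = simulate_current_injection(model, 0, 1.0, 60.0)
        assert np.all(np.isfinite(V))
        assert V.max() > -20.0
        # synaptically driven sweep stays finite
        sim = simulate_direction_sweep(model, [0.0], n_sets=1,
                                       seed=1)
        assert np.all(np.isfinite(sim.V))


class TestThresholdTuning:
    @pytest.fixture(scope="class")
    def sweep(self, arbor_model):
        return simulate_direction_sweep(arbor_model, EIGHT, n_sets=2, seed=5)

    def test_low_threshold_equals_full_integral(self, sweep):
        tt = threshold_tuning_map(sweep, [-200.0])
        r = tt.responses[0]
        dend = sweep.model.region != 0
        dt_s = sweep.record_dt_ms / 1000.0
        want = (sweep.V[:, :, dend, :].astype(float) + 200.0).sum(axis=3) * dt_s
        assert np.allclose(r, want, rtol=1e-5)

    def test_threshold_above_max_excludes_all(self, sweep):
        tt = threshold_tuning_map(sweep, [50.0])
        n_sites = int((sweep.model.region != 0).sum())
        assert tt.n_excluded[0] == n_sites * sweep.V.shape[0]
        assert np.isnan(tt.mean_dsi[0])

    def test_trend_over_default_thresholds(self, sweep):
        tt = threshold_tuning_map(sweep, [-55.0, -50.0, -48.0])
        assert np.all(np.diff(tt.mean_dsi) > 0)
        assert tt.sigma_theta_deg[1] > tt.sigma_theta_deg[0]

    def test_population_average_tuning_shared(self, arbor_model):
        # all sites share the same release law: per-site PDs of set-mean
        # responses concentrate near the cell's preferred direction
        sim = simulate_direction_sweep(arbor_model, EIGHT, n_sets=4, seed=6)
        tt = threshold_tuning_map(sim, [-55.0])
        pds = tt.site_pd_deg[0]
        pds = pds[np.isfinite(pds)]
        err = (pds - arbor_model.spec.theta_pref_deg + 180) % 360 - 180
        assert np.abs(np.median(err)) < 15.0
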