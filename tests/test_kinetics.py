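import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from dwellkit import (
    CRTD,
    CRTDGlobalModel,
    KineticModel,
    apparent_lifetime,
    compute_crtd,
    crtd_model,
    expected_scanning_distance,
    global_fit,
    linearized_estimate,
    sample_dwell_times,
    select_model,
    simulate_dwell_dataset,
    simulate_observed_frames,
)


def noise_free_crtds(protocol, k_b, components, n_points=60, scale=1000.0):
    """CRTDs evaluated exactly from the survival model (no sampling)."""
    crtds = []
    for ci in range(protocol.n_conditions):
        tl = protocol.tau_tl(ci)
        t = tl * np.arange(1, n_points + 1)
        y = crtd_model(t, protocol.tau_int, tl, k_b, components)
        crtds.append(CRTD(ci, protocol.tau_int, protocol.tau_d(ci), scale * y))
    return crtds


def geometric_mle(frame_counts_by_condition, protocol):
    """Independent maximum-likelihood oracle for a single-component model:
    observed frame counts are geometric with per-frame survival
    p_j = exp(-(k_b tau_int + k_off tau_tl_j))."""

    def nll(theta):
        k_b, k_off = theta
        total = 0.0
        for ci, m in frame_counts_by_condition.items():
            r = k_b * protocol.tau_int + k_off * protocol.tau_tl(ci)
            p = np.exp(-r)
            total -= np.sum((m - 1) * np.log(p) + np.log1p(-p))
        return total

    res = optimize.minimize(nll, x0=[1.0, 0.05], bounds=[(1e-6, 50), (1e-6, 50)],
                            method="L-BFGS-B")
    assert res.success
    return res.x  # (k_b, k_off)


class TestCRTD:
    def test_counting_example(self, protocol):
        tl = protocol.tau_tl(5)  # 1.0 s
        crtd = compute_crtd(np.array([1, 2, 3]) * tl, protocol, 5)
        np.testing.assert_array_equal(crtd.counts, [3, 2, 1])
        np.testing.assert_allclose(crtd.times, [tl, 2 * tl, 3 * tl])
        assert crtd.total_events == 3

    def test_equal_dwells_step_function(self, protocol):
        tl = protocol.tau_tl(0)
        crtd = compute_crtd(np.full(7, 4 * tl), protocol, 0)
        np.testing.assert_array_equal(crtd.counts, [7, 7, 7, 7])

    def test_survival_matches_closed_form(self, protocol):
        # 1e5 simulated single-exponential dwells: normalized CRTD equals
        # exp(-(k_b tau_int + k_off tau_tl)(m-1)) within binomial error
        k_off, k_b, ci = 0.5, 1.0, 4
        tl = protocol.tau_tl(ci)
        d = sample_dwell_times(KineticModel(((1.0, k_off),)), 100_000, seed=30)
        frames = simulate_observed_frames(d, k_b, protocol, ci, seed=31)
        crtd = compute_crtd(frames * tl, protocol, ci)
        y = crtd.normalized()
        m = np.arange(1, y.size + 1)
        expect = np.exp(-(k_b * protocol.tau_int + k_off * tl) * (m - 1))
        se = np.sqrt(expect * (1 - expect) / crtd.total_events) + 1e-9
        assert np.all(np.abs(y[:10] - expect[:10]) < 4 * se[:10])

    def test_frame_count_round_trip(self):
        crtd = CRTD(0, 0.1, 0.0, np.array([10, 6, 6, 1]))
        m = crtd.to_frame_counts()
        back = CRTD.from_frame_counts(m, 0, 0.1, 0.0)
        np.testing.assert_array_equal(back.counts, crtd.counts)

    def test_invalid_crtds_rejected(self, protocol):
        with pytest.raises(ValueError):
            CRTD(0, 0.1, 0.0, np.array([3, 5, 1]))  # increasing
        with pytest.raises(ValueError):
            compute_crtd(np.array([]), protocol, 0)


class TestCrtdModel:
    def test_no_bleaching_limit(self):
        t = np.linspace(0.1, 50, 20)
        for tau_tl in (0.1, 1.0, 10.0):
            out = crtd_model(t, 0.1, tau_tl, 0.0, ((1.0, 0.2),))
            np.testing.assert_allclose(out, np.exp(-0.2 * t))

    def test_continuous_imaging_limit(self):
        # tau_d = 0: effective rate is k_b + k_off
        t = np.array([1.0, 2.0])
        out = crtd_model(t, 0.1, 0.1, 2.0, ((1.0, 0.3),))
        np.testing.assert_allclose(out, np.exp(-2.3 * t))

    def test_effective_rate_arithmetic(self):
        # k_b = 2/s, tau_int = 0.1 s, tau_tl = 10 s, k_off = 0.0072/s
        out = crtd_model(np.array([1.0]), 0.1, 10.0, 2.0, ((1.0, 0.0072),))
        assert out[0] == pytest.approx(np.exp(-0.0272))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            crtd_model(np.array([1.0]), 0.2, 0.1, 1.0, ((1.0, 0.1),))
        with pytest.raises(ValueError):
            crtd_model(np.array([1.0]), 0.1, 1.0, -1.0, ((1.0, 0.1),))


class TestGlobalFit:
    def test_exact_recovery_from_noise_free_crtds(self, protocol):
        k_b, comps = 0.9, ((0.4, 1 / 26.0), (0.6, 1 / 1.1))
        crtds = noise_free_crtds(protocol, k_b, comps)
        res = CRTDGlobalModel(crtds, order=2).fit()
        assert res.success
        assert abs(res.k_b - k_b) / k_b < 1e-6
        np.testing.assert_allclose(res.k_offs, [1 / 26.0, 1 / 1.1], rtol=1e-6)
        np.testing.assert_allclose(res.amplitudes, [0.4, 0.6], atol=1e-6)

    def test_single_component_recovery_from_simulation(self, protocol):
        truth = KineticModel.from_lifetimes(70.0, k_b=1.0)
        dwells = simulate_dwell_dataset(truth, protocol, 2000, seed=40)
        res = CRTDGlobalModel.from_dwell_tables(dwells, protocol).fit()
        assert res.success
        assert res.slow_lifetime == pytest.approx(70.0, rel=0.10)
        assert res.k_b == pytest.approx(1.0, rel=0.10)

    def test_amplitudes_sum_to_one(self, protocol):
        truth = KineticModel.from_lifetimes([26.0, 1.1], [0.32, 0.68], k_b=1.0)
        dwells = simulate_dwell_dataset(truth, protocol, 2000, seed=41)
        res = CRTDGlobalModel.from_dwell_tables(dwells, protocol, order=2).fit()
        assert res.amplitudes.sum() == pytest.approx(1.0, abs=1e-9)
        assert (res.amplitudes > 0).all()

    def test_agrees_with_geometric_mle_oracle(self, protocol):
        # independent-route check: least squares on CRTDs vs maximum
        # likelihood on the raw geometric frame counts
        truth = KineticModel.from_lifetimes(30.0, k_b=1.0)
        rng = np.random.default_rng(42)
        frames = {}
        for ci in range(protocol.n_conditions):
            d = sample_dwell_times(truth, 1000, seed=rng)
            frames[ci] = simulate_observed_frames(d, truth.k_b, protocol, ci, seed=rng)
        dwells = {ci: m * protocol.tau_tl(ci) for ci, m in frames.items()}
        ls = CRTDGlobalModel.from_dwell_tables(dwells, protocol).fit()
        _, k_off_mle = geometric_mle(frames, protocol)
        assert ls.k_offs[0] == pytest.approx(k_off_mle, rel=0.05)

    def test_effective_rate_decreases_with_frame_period(self, protocol):
        # per-condition apparent rate k_eff falls toward k_off as tau_tl grows
        truth = KineticModel.from_lifetimes(20.0, k_b=1.0)
        dwells = simulate_dwell_dataset(truth, protocol, 4000, seed=43)
        model = CRTDGlobalModel.from_dwell_tables(dwells, protocol)
        lin = linearized_estimate(model.crtds)
        assert np.all(np.diff(lin.k_eff) < 0)
        assert lin.k_eff[-1] < 3 * truth.k_offs[0]

    def test_linearization_agrees_with_global_fit(self, protocol):
        # k_eff*tau_tl vs tau_tl is linear with slope k_off and intercept
        # k_b*tau_int; the two estimators must agree within uncertainties
        truth = KineticModel.from_lifetimes(52.0, k_b=1.0)
        dwells = simulate_dwell_dataset(truth, protocol, 3000, seed=44)
        model = CRTDGlobalModel.from_dwell_tables(dwells, protocol)
        res = model.fit()
        lin = linearized_estimate(model.crtds)
        tolerance = max(3 * lin.k_off_stderr, 0.1 * res.k_offs[0])
        assert abs(lin.k_off - res.k_offs[0]) < tolerance
        assert lin.k_b == pytest.approx(1.0, rel=0.2)

    def test_underidentified_input_flagged(self, protocol):
        crtds = noise_free_crtds(protocol, 1.0, ((1.0, 0.05),))[:1]
        with pytest.warns(UserWarning, match="identifiable"):
            CRTDGlobalModel(crtds, order=1)

    def test_convergence_flag_never_silent(self, protocol):
        crtds = noise_free_crtds(protocol, 1.0, ((1.0, 0.05),))
        res = CRTDGlobalModel(crtds, order=1).fit(max_nfev=1)
        assert res.success is False


@pytest.fixture(scope="module")
def fitted_model(protocol):
    truth = KineticModel.from_lifetimes(50.0, k_b=1.0)
    dwells = simulate_dwell_dataset(truth, protocol, 1500, seed=50)
    return CRTDGlobalModel.from_dwell_tables(dwells, protocol)


class TestBootstrap:

    def test_replicate_count_and_subsample_size(self, protocol, fitted_model):
        boot = fitted_model.bootstrap(n_boot=10, fraction=0.8, seed=51)
        assert len(boot.samples) == 10
        assert boot.n_converged == 10
        assert boot.fraction == 0.8
        # each replicate is fit on floor(0.8 * n) events per condition
        for crtd in fitted_model.crtds:
            assert boot.subsample_sizes[crtd.condition_id] == int(
                np.floor(0.8 * crtd.total_events)
            )

    def test_summary_reports_mean_and_sd(self, fitted_model):
        boot = fitted_model.bootstrap(n_boot=10, fraction=0.8, seed=52)
        summ = boot.summary()
        assert {"mean", "sd"} <= set(summ.columns)
        assert summ.loc["lifetime_slow_s", "mean"] == pytest.approx(50.0, rel=0.2)
        assert summ.loc["lifetime_slow_s", "sd"] > 0

    def test_fixed_seed_bit_identical(self, fitted_model):
        a = fitted_model.bootstrap(n_boot=5, fraction=0.8, seed=53)
        b = fitted_model.bootstrap(n_boot=5, fraction=0.8, seed=53)
        pd.testing.assert_frame_equal(a.samples, b.samples)

    def test_bootstrap_sd_shrinks_with_dataset_size(self, protocol):
        # lifetime SD should fall roughly as 1/sqrt(n) when events grow 4x
        truth = KineticModel.from_lifetimes(40.0, k_b=1.0)
        sds = []
        for n_per in (500, 2000):
            dwells = simulate_dwell_dataset(truth, protocol, n_per, seed=54)
            model = CRTDGlobalModel.from_dwell_tables(dwells, protocol)
            boot = model.bootstrap(n_boot=10, fraction=0.8, seed=55)
            sds.append(boot.summary().loc["lifetime_slow_s", "sd"])
        ratio = sds[1] / sds[0]
        assert ratio < 0.9  # must shrink
        assert 0.15 < ratio  # but not collapse


class TestModelSelection:
    def test_single_component_data_selects_order_one(self, protocol):
        truth = KineticModel.from_lifetimes(30.0, k_b=1.0)
        wins = 0
        for seed in range(10):
            dwells = simulate_dwell_dataset(truth, protocol, 500, seed=seed)
            model1 = CRTDGlobalModel.from_dwell_tables(dwells, protocol, order=1)
            fit1 = model1.fit()
            fit2 = CRTDGlobalModel(model1.crtds, order=2).fit()
            wins += select_model(fit1, fit2).order == 1
        assert wins >= 9

    def test_well_separated_mixture_selects_order_two(self, protocol):
        truth = KineticModel.from_lifetimes([100.0, 1.0], [0.5, 0.5], k_b=1.0)
        wins = 0
        for seed in range(10):
            dwells = simulate_dwell_dataset(truth, protocol, 500, seed=100 + seed)
            model1 = CRTDGlobalModel.from_dwell_tables(dwells, protocol, order=1)
            fit1 = model1.fit()
            fit2 = CRTDGlobalModel(model1.crtds, order=2).fit()
            wins += select_model(fit1, fit2).order == 2
        assert wins >= 9

    def test_parsimony_when_components_collapse(self, protocol):
        # exact single-exponential data: order 2 collapses to equal rates
        # and cannot beat order 1 on BIC
        crtds = noise_free_crtds(protocol, 1.0, ((1.0, 0.1),))
        fit1 = CRTDGlobalModel(crtds, order=1).fit()
        fit2 = CRTDGlobalModel(crtds, order=2).fit()
        assert select_model(fit1, fit2).order == 1

    def test_mismatched_inputs_rejected(self, protocol):
        crtds_a = noise_free_crtds(protocol, 1.0, ((1.0, 0.1),))
        crtds_b = noise_free_crtds(protocol, 1.0, ((1.0, 0.2),))
        fit1 = CRTDGlobalModel(crtds_a, order=1).fit()
        fit2 = CRTDGlobalModel(crtds_b, order=2).fit()
        with pytest.raises(ValueError):
            select_model(fit1, fit2)


class TestDerivedQuantities:
    def test_apparent_lifetime_limits(self):
        assert apparent_lifetime(0.0, 0.1, 1.0, 0.25) == pytest.approx(4.0)
        assert apparent_lifetime(2.0, 0.1, 0.1, 0.0) == pytest.approx(0.5)
        assert apparent_lifetime(2.0, 0.1, 10.0, 0.0072) == pytest.approx(1 / 0.0272)
        with pytest.raises(ValueError):
            apparent_lifetime(0.0, 0.1, 1.0, 0.0)
        with pytest.raises(ValueError):
            apparent_lifetime(1.0, 0.1, 0.05, 0.1)

    def test_scanning_distance(self):
        # 4 nt/s over a 29-s residence time -> 116 nucleotides
        assert expected_scanning_distance(4.0, 29.0) == 116
        assert expected_scanning_distance(0.0, 29.0) == 0
        assert expected_scanning_distance(4.0, 18.0) == 72
        with pytest.raises(ValueError):
            expected_scanning_distance(-1.0, 5.0)


class TestResultsObject:
    def test_summary_and_serialisation(self, protocol):
        crtds = noise_free_crtds(protocol, 0.8, ((1.0, 0.05),))
        res = global_fit(crtds, order=1)
        text = res.summary()
        assert "lifetime" in text and "k_b" in text
        d = res.to_dict()
        assert d["order"] == 1 and d["success"]
        assert d["lifetimes_s"][0] == pytest.approx(20.0, rel=1e-4)

    def test_predict_matches_data_on_exact_input(self, protocol):
        crtds = noise_free_crtds(protocol, 0.8, ((1.0, 0.05),))
        res = global_fit(crtds, order=1)
        for crtd in crtds:
            np.testing.assert_allclose(
                res.predict(crtd.condition_id), crtd.normalized(), atol=1e-6
            )
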