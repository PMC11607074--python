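"""Dwell distributions, exponential CDF fits, bootstrap, weighted rates."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from rotafret.dwell_kinetics import (
    DwellDistribution,
    ExpFit,
    RateEstimate,
    bootstrap_rates,
    choose_fit,
    fit_dwell_cdf,
    rate_error,
    scale_by_cluster_weight,
    weighted_rate,
    with_bootstrap_errors,
)


def dist_from(dwells, pair=(0, 1)):
    return DwellDistribution(pair=pair, dwells=np.asarray(dwells, dtype=float))


class TestCollectAndDistribution:
    def test_cdf_steps(self):
        d = dist_from([0.3, 0.1, 0.2])
        np.testing.assert_allclose(d.dwells, [0.1, 0.2, 0.3])
        np.testing.assert_allclose(d.cdf, [1 / 3, 2 / 3, 1.0])

    def test_exponential_sample_consistent_with_truth(self, rng):
        """Simulated dwells at k=1 are indistinguishable from Exp(1) (KS)."""
        dwells = rng.exponential(1.0, 1000)
        _, p = stats.kstest(dwells, "expon")
        assert p > 0.01

    def test_insufficient_flagged(self):
        d = dist_from([0.1, 0.2])
        assert d.insufficient

    def test_truncated_records_excluded(self):
        from rotafret.dwell_kinetics import collect_dwells
        from rotafret.transition_analysis import TransitionRecord, fit_tdp_mixture

        rng = np.random.default_rng(0)
        recs = [
            TransitionRecord(
                "t",
                rng.normal([0.2, 0.8][i], 0.02),
                rng.normal([0.2, 0.8][1 - i], 0.02),
                dwell_before=1.0,
                truncated_left=(n < 10),
            )
            for n in range(60)
            for i in (0, 1)
        ]
        model = fit_tdp_mixture(recs, 2, n_init=5, seed=0)
        dwells = collect_dwells(recs, model.assign(recs), model)
        assert sum(d.n for d in dwells.values()) == 100  # 20 censored dropped


class TestFitDwellCdf:
    def test_mono_self_consistency(self):
        """Fitting an exactly exponential ECDF recovers k to high precision."""
        t = np.sort(stats.expon(scale=0.5).ppf(np.linspace(0.004, 0.996, 100)))
        fit = fit_dwell_cdf(dist_from(t), 1)
        assert fit.n_components == 1
        assert abs(fit.k1 - 2.0) < 0.05

    def test_biexponential_mixture_recovery(self, rng):
        """Components of a 0.5·Exp(1)+0.5·Exp(10) mixture recovered within 15%."""
        n = 5000
        fast = rng.exponential(0.1, n // 2)
        slow = rng.exponential(1.0, n // 2)
        fit = fit_dwell_cdf(dist_from(np.concatenate([fast, slow])), 2)
        assert abs(fit.k1 - 10) / 10 < 0.15
        assert abs(fit.k2 - 1) / 1 < 0.15
        assert abs(fit.a1 - 0.5) < 0.1
        assert np.isclose(fit.a1 + fit.a2, 1.0)

    def test_mono_data_bi_fit_degenerates_and_bic_prefers_mono(self, rng):
        dwells = rng.exponential(0.5, 800)
        chosen, mono, bi = choose_fit(dist_from(dwells))
        assert chosen.n_components == 1
        # nested-model degeneracy: either a vanishing component or equal rates
        assert bi.a2 < 0.1 or abs(bi.k1 - bi.k2) / bi.k1 < 0.25

    def test_too_few_dwells_raises(self):
        from rotafret.dwell_kinetics import FitError

        with pytest.raises(FitError, match="fewer than 5"):
            fit_dwell_cdf(dist_from([0.1, 0.2, 0.3]), 1)


class TestWeightedRate:
    @pytest.mark.parametrize(
        "a1,k1,a2,k2,expected",
        [
            (1.0, 2.5, 0.0, None, 2.5),
            (0.5, 2.0, 0.5, 2.0, 2.0),
            (0.5, 1.0, 0.5, 3.0, 1.5),  # 1/(0.5 + 1/6)
        ],
    )
    def test_known_values(self, a1, k1, a2, k2, expected):
        assert np.isclose(weighted_rate(a1, k1, a2, k2), expected)

    @given(
        a1=st.floats(min_value=0.05, max_value=0.95),
        k1=st.floats(min_value=0.1, max_value=50),
        k2=st.floats(min_value=0.1, max_value=50),
    )
    def test_symmetric_under_component_exchange(self, a1, k1, k2):
        assert np.isclose(
            weighted_rate(a1, k1, 1 - a1, k2), weighted_rate(1 - a1, k2, a1, k1)
        )

    def test_amplitudes_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            weighted_rate(0.6, 1.0, 0.6, 2.0)


class TestRateError:
    def test_all_zero_deltas(self):
        assert rate_error(0.5, 1.0, 0.5, 2.0, 0, 0, 0, 0) == 0.0

    def test_single_component_reduction(self):
        # A1=1, A2=0: Delta k_av = ΔM = (1/k1)·(Δk1/k1)
        dk = rate_error(1.0, 2.0, 0.0, None, 0.0, 0.1)
        assert np.isclose(dk, (1 / 2.0) * (0.1 / 2.0))

    def test_against_symbolic_oracle(self):
        """The published ΔM/ΔN/Δk_av formulas evaluated independently with
        sympy agree with the implementation on several parameter sets."""
        import sympy as sp

        A1, k1, A2, k2, dA1, dk1, dA2, dk2 = sp.symbols(
            "A1 k1 A2 k2 dA1 dk1 dA2 dk2", positive=True
        )
        M = A1 / k1
        N = A2 / k2
        dM = M * sp.sqrt((dA1 / A1) ** 2 + (dk1 / k1) ** 2)
        dN = N * sp.sqrt((dA2 / A2) ** 2 + (dk2 / k2) ** 2)
        dkav = sp.sqrt(dM**2 + dN**2)
        cases = [
            (0.5, 1.0, 0.5, 1.0, 0.1, 0.1, 0.1, 0.1),
            (0.3, 2.0, 0.7, 0.5, 0.05, 0.2, 0.02, 0.04),
            (0.9, 10.0, 0.1, 0.1, 0.01, 1.0, 0.01, 0.01),
            (0.6, 0.86, 0.4, 0.05, 0.03, 0.09, 0.03, 0.005),
            (0.5, 5.0, 0.5, 0.2, 0.2, 0.5, 0.2, 0.02),
        ]
        for vals in cases:
            subs = dict(zip((A1, k1, A2, k2, dA1, dk1, dA2, dk2), vals))
            expected = float(dkav.subs(subs))
            got = rate_error(*vals, mode="printed")
            assert np.isclose(got, expected, rtol=1e-12)
            # dimensionally consistent mode = k_av^2 × printed combination
            kav = weighted_rate(vals[0], vals[1], vals[2], vals[3])
            assert np.isclose(rate_error(*vals, mode="propagated"), kav**2 * expected)


class TestClusterWeightScaling:
    def test_weight_one_passthrough(self):
        fit = ExpFit(n_components=1, a1=1.0, k1=2.0)
        est = scale_by_cluster_weight(fit, 1.0)
        assert np.isclose(est.k_av, 2.0)

    def test_competing_exits_sum_to_total_exit_rate(self, rng):
        """Branching simulation: state with exits k_a=0.6, k_b=1.4; dwell fits
        scaled by the observed branching weights re-sum to k_a+k_b."""
        k_a, k_b = 0.6, 1.4
        total = k_a + k_b
        n = 4000
        dwells = rng.exponential(1 / total, n)
        which_a = rng.random(n) < k_a / total
        fit_a = fit_dwell_cdf(dist_from(dwells[which_a]), 1)
        fit_b = fit_dwell_cdf(dist_from(dwells[~which_a]), 1)
        w_a = which_a.mean()
        est_a = scale_by_cluster_weight(fit_a, w_a)
        est_b = scale_by_cluster_weight(fit_b, 1 - w_a)
        assert np.isclose(est_a.k_av + est_b.k_av, total, rtol=0.05)
        assert np.isclose(est_a.k_av, k_a, rtol=0.15)

    def test_weight_out_of_range_rejected(self):
        fit = ExpFit(n_components=1, a1=1.0, k1=1.0)
        with pytest.raises(ValueError):
            scale_by_cluster_weight(fit, 1.5)


class TestBootstrap:
    def test_reproducible_given_seed(self, rng):
        d = dist_from(rng.exponential(0.5, 200))
        b1 = bootstrap_rates(d, 1, n_boot=100, seed=9)
        b2 = bootstrap_rates(d, 1, n_boot=100, seed=9)
        assert b1.sd_k1 == b2.sd_k1
        assert b1.n_boot == 100

    def test_degenerate_equal_dwells_near_zero_sd(self):
        d = dist_from(np.full(50, 0.2))
        b = bootstrap_rates(d, 1, n_boot=30, seed=0)
        assert b.sd_k1 < 1e-6

    def test_sd_close_to_asymptotic_k_over_sqrt_n(self, rng):
        """For Exp(k) the MLE SD is k/sqrt(n); the CDF-fit bootstrap SD agrees
        within a factor of 3."""
        n = 500
        d = dist_from(rng.exponential(1.0, n))
        b = bootstrap_rates(d, 1, n_boot=100, seed=4)
        analytic = 1.0 / np.sqrt(n)
        assert b.sd_k1 < 3 * analytic
        assert b.sd_k1 > analytic / 3

    def test_errors_attach_and_propagate(self, rng):
        d = dist_from(rng.exponential(0.5, 300))
        fit = fit_dwell_cdf(d, 1)
        boot = bootstrap_rates(d, 1, n_boot=50, seed=2)
        fit = with_bootstrap_errors(fit, boot)
        est = RateEstimate.from_fit(fit, weight=0.5)
        assert est.k_av > 0 and est.d_k_av > 0
        assert np.isclose(est.k_av, 0.5 / (fit.a1 / fit.k1))
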