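"""Transition records, TDP grids, and constrained mixture clustering."""

import numpy as np
import pytest

from rotafret.hmm_segmentation import IdealizedPath
from rotafret.transition_analysis import (
    ClusteringError,
    TransitionRecord,
    branching_weights,
    build_tdp,
    cluster_tdp,
    extract_transitions,
    fit_tdp_mixture,
    transition_counts,
)


def path_from_states(states, levels, exposure=0.05, trace_id="p0"):
    states = np.asarray(states)
    return IdealizedPath(
        trace_id=trace_id,
        states=states,
        levels=np.asarray(levels)[states],
        exposure=exposure,
    )


def synthetic_records(rng, levels, pairs, n_per_pair, sd=0.02, dwell_rate=1.0):
    recs = []
    for i, j in pairs:
        for _ in range(n_per_pair):
            recs.append(
                TransitionRecord(
                    trace_id="r",
                    e_before=rng.normal(levels[i], sd),
                    e_after=rng.normal(levels[j], sd),
                    dwell_before=rng.exponential(1 / dwell_rate) + 0.05,
                )
            )
    return recs


class TestExtractTransitions:
    def test_hand_counted_example(self):
        path = path_from_states([0] * 10 + [1] * 5 + [0] * 5, [0.2, 0.8])
        recs = extract_transitions([path])
        assert len(recs) == 2
        first, second = recs
        assert (first.e_before, first.e_after) == (0.2, 0.8)
        assert np.isclose(first.dwell_before, 0.5)
        assert first.truncated_left and not first.truncated_right
        assert (second.e_before, second.e_after) == (0.8, 0.2)
        assert np.isclose(second.dwell_before, 0.25)
        assert second.truncated_right and not second.truncated_left

    def test_constant_path_contributes_nothing(self):
        assert extract_transitions([path_from_states([1] * 20, [0.2, 0.8])]) == []

    def test_min_delta_e_merges_flicker_runs(self):
        # levels 0.50 and 0.52 flicker; 0.8 is a genuine excursion
        path = path_from_states([0] * 10 + [1] * 4 + [0] * 6 + [2] * 5, [0.50, 0.52, 0.8])
        recs = extract_transitions([path], min_delta_e=0.05)
        assert len(recs) == 1
        rec = recs[0]
        assert np.isclose(rec.dwell_before, 20 * 0.05)  # merged dwell
        assert abs(rec.e_before - 0.504) < 0.01  # duration-weighted level

    def test_branching_ratio_matches_rates(self, small_sin_dataset, sin_scheme):
        """Departures from cnr split between cr and lnr in proportion to
        k_rec : k_lig (competing exponential clocks)."""
        counts = {}
        for path in small_sin_dataset.paths:
            states = [s for s, _, _ in path.segments]
            for a, b in zip(states, states[1:]):
                counts[(a, b)] = counts.get((a, b), 0) + 1
        n_cr = counts[("cnr", "cr")]
        n_lnr = counts[("cnr", "lnr")]
        p_hat = n_cr / (n_cr + n_lnr)
        p_true = sin_scheme.k_rec / (sin_scheme.k_rec + sin_scheme.k_lig_nr)
        se = np.sqrt(p_true * (1 - p_true) / (n_cr + n_lnr))
        assert abs(p_hat - p_true) < 3 * se


class TestBuildTdp:
    def test_single_record_peaks_at_its_bin(self):
        rec = TransitionRecord("t", 0.3, 0.5, 1.0)
        grid = build_tdp([rec], n_bins=50, bandwidth=0.02)
        i, j = np.unravel_index(np.argmax(grid.density), grid.density.shape)
        assert abs(grid.edges[i] - 0.3) < 0.05 and abs(grid.edges[j] - 0.5) < 0.05

    def test_zero_bandwidth_is_raw_histogram(self):
        recs = [TransitionRecord("t", 0.3, 0.5, 1.0)] * 7
        grid = build_tdp(recs, n_bins=20, bandwidth=0.0)
        assert grid.density.sum() == 7
        assert (grid.density > 0).sum() == 1

    def test_symmetric_data_symmetric_grid(self, rng):
        recs = synthetic_records(rng, [0.3, 0.7], [(0, 1), (1, 0)], 400)
        grid = build_tdp(recs, n_bins=40, bandwidth=0.03)
        asym = np.abs(grid.density - grid.density.T).sum() / grid.density.sum()
        assert asym < 0.15  # equal up to counting noise

    def test_empty_records_warn(self):
        with pytest.warns(UserWarning, match="no transition records"):
            grid = build_tdp([], n_bins=20)
        assert grid.density.sum() == 0


class TestClusterTdp:
    def test_two_state_recovery(self, rng):
        recs = synthetic_records(rng, [0.2, 0.8], [(0, 1), (1, 0)], 300)
        model = cluster_tdp(recs, k_range=(1, 4), n_init=10, seed=0)
        assert model.k == 2
        np.testing.assert_allclose(model.levels, [0.2, 0.8], atol=0.02)

    def test_weights_sum_to_one_and_assignment_deterministic(self, rng):
        recs = synthetic_records(rng, [0.2, 0.5, 0.8], [(0, 1), (1, 0), (1, 2), (2, 1)], 150)
        model = fit_tdp_mixture(recs, 3, n_init=10, seed=1)
        assert np.isclose(model.weights.sum(), 1.0)
        a1 = model.assign(recs)
        a2 = model.assign(recs)
        np.testing.assert_array_equal(a1, a2)

    def test_parameter_recovery_from_own_model(self, rng):
        """EM recovers levels and weights of data drawn from the constrained
        mixture itself (within 3 SE)."""
        levels = np.array([0.25, 0.55, 0.85])
        pairs = [(0, 1), (1, 0), (1, 2), (2, 1), (0, 2), (2, 0)]
        w_true = np.array([0.3, 0.3, 0.15, 0.15, 0.05, 0.05])
        sd = 0.03
        n = 3000
        counts = rng.multinomial(n, w_true)
        recs = []
        for (i, j), m in zip(pairs, counts):
            for _ in range(m):
                recs.append(
                    TransitionRecord(
                        "t", rng.normal(levels[i], sd), rng.normal(levels[j], sd), 1.0
                    )
                )
        model = fit_tdp_mixture(recs, 3, n_init=10, seed=3)
        np.testing.assert_allclose(model.levels, levels, atol=3 * sd / np.sqrt(n / 6))
        order = {p: c for c, p in enumerate(model.pairs)}
        w_fit = np.array([model.weights[order[p]] for p in pairs])
        se = np.sqrt(w_true * (1 - w_true) / n)
        assert np.all(np.abs(w_fit - w_true) < 3 * se + 0.01)

    def test_bic_selects_true_k_in_most_replicates(self):
        """BIC picks K=3 in >=90% of seeded replicates of a well-separated
        3-state simulation."""
        hits = 0
        n_rep = 10
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            recs = synthetic_records(
                rng, [0.2, 0.5, 0.8], [(0, 1), (1, 0), (1, 2), (2, 1)], 120
            )
            model = cluster_tdp(recs, k_range=(1, 6), n_init=10, seed=rep)
            hits += model.k == 3
        assert hits >= 0.9 * n_rep

    def test_too_few_records_raises(self):
        with pytest.raises(ClusteringError, match=">= 10"):
            cluster_tdp([TransitionRecord("t", 0.2, 0.8, 1.0)] * 5)


class TestTransitionCounts:
    def test_single_cluster_gets_all(self, rng):
        recs = synthetic_records(rng, [0.2, 0.8], [(0, 1)], 100)
        model = fit_tdp_mixture(recs, 2, n_init=5, seed=0)
        fracs = transition_counts(model, recs)
        assert np.isclose(fracs[(0, 1)], 1.0)
        assert np.isclose(sum(fracs.values()), 1.0)

    def test_reversible_stationary_fractions_balance(self, rng):
        recs = synthetic_records(rng, [0.3, 0.7], [(0, 1), (1, 0)], 500)
        model = fit_tdp_mixture(recs, 2, n_init=5, seed=0)
        fracs = transition_counts(model, recs)
        # flux balance: forward and reverse counts equal up to sampling error
        assert abs(fracs[(0, 1)] - fracs[(1, 0)]) < 3 * np.sqrt(0.25 / 1000) * 2

    def test_branching_weights_normalize_per_state(self, rng):
        recs = synthetic_records(
            rng, [0.2, 0.5, 0.8], [(0, 1), (1, 0), (1, 2), (2, 1)], 200
        )
        model = fit_tdp_mixture(recs, 3, n_init=5, seed=0)
        bw = branching_weights(model)
        for i in range(3):
            outgoing = sum(w for (a, _), w in bw.items() if a == i)
            assert np.isclose(outgoing, 1.0)
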