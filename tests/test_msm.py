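import numpy as np
import pytest

from conformpath.featurize import FeatureTrajectory
from conformpath.msm import (
    UNDEFINED_TIMESCALE,
    MacrostateModel,
    TransitionMatrix,
    ck_test,
    cluster_microstates,
    count_transitions,
    estimate_T,
    implied_timescales,
    pcca,
    representative_conformation,
    similarity_matrix,
    timescales_from_T,
)

T_REF = np.array([[0.9, 0.1], [0.2, 0.8]])


def sample_chain(T, n_steps, seed, start=0):
    rng = np.random.default_rng(seed)
    cdf = np.cumsum(T, axis=1)
    u = rng.random(n_steps)
    out = np.empty(n_steps + 1, dtype=int)
    out[0] = start
    for t in range(n_steps):
        out[t + 1] = np.searchsorted(cdf[out[t]], u[t])
    return out


class TestClusterMicrostates:
    def _clouds(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((300, 2)) * 0.1 + [0.0, 0.0]
        b = rng.standard_normal((300, 2)) * 0.1 + [5.0, 5.0]
        return FeatureTrajectory(np.vstack([a, b])), a.mean(axis=0), b.mean(axis=0)

    def test_two_clouds_recovered(self):
        traj, mean_a, mean_b = self._clouds()
        model = cluster_microstates(traj, k=2, seed=1)
        centers = sorted(model.centers.tolist())
        assert np.allclose(centers[0], mean_a, atol=0.05)
        assert np.allclose(centers[1], mean_b, atol=0.05)

    def test_k1_center_is_global_mean(self):
        traj, *_ = self._clouds()
        model = cluster_microstates(traj, k=1, seed=0)
        assert np.allclose(model.centers[0], traj.values.mean(axis=0), atol=1e-8)

    def test_fixed_seed_deterministic(self):
        traj, *_ = self._clouds()
        m1 = cluster_microstates(traj, k=5, seed=42)
        m2 = cluster_microstates(traj, k=5, seed=42)
        assert np.array_equal(m1.dtrajs[0], m2.dtrajs[0])

    def test_k_exceeding_distinct_frames_rejected(self):
        traj = FeatureTrajectory(np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]]))
        with pytest.raises(ValueError, match="distinct"):
            cluster_microstates(traj, k=3)


class TestCountTransitions:
    def test_hand_count(self):
        c = count_transitions([np.array([0, 0, 1, 1, 0])], lag=1)
        assert np.array_equal(c, [[1.0, 1.0], [1.0, 1.0]])

    def test_lag_beyond_length_warns_zero(self):
        with pytest.warns(UserWarning, match="zero count"):
            c = count_transitions([np.array([0, 1, 0])], lag=5)
        assert not c.any()

    def test_concatenation_adds_boundary_counts(self):
        d1, d2 = np.array([0, 1, 0]), np.array([1, 1, 0])
        separate = count_transitions([d1, d2], lag=1)
        concat = count_transitions([np.concatenate([d1, d2])], lag=1)
        # brute-force enumeration of the separate counting
        expected = np.zeros((2, 2))
        for d in (d1, d2):
            for a, b in zip(d[:-1], d[1:]):
                expected[a, b] += 1
        assert np.array_equal(separate, expected)
        assert concat.sum() == separate.sum() + 1  # the 0->1 junction pair

    def test_sliding_window_oracle(self):
        rng = np.random.default_rng(3)
        d = rng.integers(0, 4, size=200)
        lag = 7
        c = count_transitions([d], lag=lag)
        expected = np.zeros((4, 4))
        for t in range(len(d) - lag):
            expected[d[t], d[t + lag]] += 1
        assert np.array_equal(c, expected)


class TestCountProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.lists(st.integers(min_value=0, max_value=3), min_size=2, max_size=60),
           st.integers(min_value=1, max_value=5))
    @settings(max_examples=60, deadline=None)
    def test_total_counts_match_window_count(self, dtraj, lag):
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            c = count_transitions([np.array(dtraj)], lag=lag, n_states=4)
        assert c.sum() == max(len(dtraj) - lag, 0)
        assert (c >= 0).all()


class TestEstimateT:
    def test_analytic_two_state(self):
        tm = estimate_T(np.array([[9.0, 1.0], [2.0, 8.0]]), mode="nonreversible")
        assert np.allclose(tm.T, T_REF, atol=1e-14)
        assert np.allclose(tm.pi, [2.0 / 3.0, 1.0 / 3.0], atol=1e-10)

    def test_symmetric_counts_reversible_equals_nonreversible(self):
        c = np.array([[10.0, 3.0, 1.0], [3.0, 8.0, 2.0], [1.0, 2.0, 6.0]])
        t_rev = estimate_T(c, mode="reversible")
        t_non = estimate_T(c, mode="nonreversible")
        assert np.allclose(t_rev.T, t_non.T, atol=1e-8)

    def test_reversible_detailed_balance_residual(self):
        rng = np.random.default_rng(4)
        c = rng.integers(1, 50, size=(5, 5)).astype(float)
        tm = estimate_T(c, mode="reversible")
        flux = tm.pi[:, None] * tm.T
        assert np.abs(flux - flux.T).max() < 1e-8

    def test_largest_scc_restriction(self):
        # state 2 only receives counts, never returns -> outside the SCC
        c = np.array([[5.0, 5.0, 1.0], [5.0, 5.0, 0.0], [0.0, 0.0, 0.0]])
        tm = estimate_T(c)
        assert tm.n_states == 2
        assert np.array_equal(tm.active_set, [0, 1])

    def test_row_stochastic_and_stationary_invariants(self):
        rng = np.random.default_rng(5)
        c = rng.integers(1, 30, size=(6, 6)).astype(float)
        for mode in ("nonreversible", "reversible"):
            tm = estimate_T(c, mode=mode)
            assert np.allclose(tm.T.sum(axis=1), 1.0, atol=1e-12)
            assert np.allclose(tm.pi @ tm.T, tm.pi, atol=1e-8)


class TestImpliedTimescales:
    def test_closed_form_from_exact_matrix(self):
        ts = timescales_from_T(T_REF, lag_time=1.0, n_its=1)
        assert ts[0] == pytest.approx(-1.0 / np.log(0.7), abs=1e-12)

    def test_sampled_chain_recovers_timescale(self):
        d = sample_chain(T_REF, 1_000_000, seed=6)
        ts = implied_timescales([d], lags=[1], n_its=1)
        assert ts[0, 0] == pytest.approx(-1.0 / np.log(0.7), rel=0.05)

    def test_markovian_flatness_across_lags(self):
        d = sample_chain(T_REF, 1_000_000, seed=7)
        ts = implied_timescales([d], lags=[1, 2], n_its=1)
        assert ts[1, 0] == pytest.approx(ts[0, 0], rel=0.05)

    def test_nonpositive_eigenvalue_sentinel(self):
        t_osc = np.array([[0.1, 0.9], [0.9, 0.1]])  # second eigenvalue -0.8
        ts = timescales_from_T(t_osc, lag_time=1.0, n_its=1)
        assert ts[0] == UNDEFINED_TIMESCALE

    def test_lags_must_ascend(self):
        with pytest.raises(ValueError):
            implied_timescales([np.array([0, 1, 0, 1])], lags=[4, 2])


def _tm_from_T(T, pi=None):
    from conformpath.msm import _stationary_distribution

    pi = _stationary_distribution(T) if pi is None else pi
    return TransitionMatrix(
        T=T, lag=1, lag_time=1.0, counts=T, reversible=False, pi=pi,
        active_set=np.arange(T.shape[0]),
    )


class TestPCCA:
    def test_block_diagonal_recovery(self):
        eps = 1e-6
        T = np.array(
            [
                [0.9, 0.1 - eps, eps, 0.0],
                [0.2, 0.8 - eps, 0.0, eps],
                [eps, 0.0, 0.7, 0.3 - eps],
                [0.0, eps, 0.4, 0.6 - eps],
            ]
        )
        T /= T.sum(axis=1, keepdims=True)
        macro = pcca(_tm_from_T(T), 2)
        assert macro.crisp[0] == macro.crisp[1]
        assert macro.crisp[2] == macro.crisp[3]
        assert macro.crisp[0] != macro.crisp[2]

    def test_m_equals_k_limit(self):
        rng = np.random.default_rng(8)
        c = rng.integers(1, 20, size=(4, 4)).astype(float)
        tm = estimate_T(c, mode="reversible")
        macro = pcca(tm, 4)
        assert sorted(macro.crisp.tolist()) == [0, 1, 2, 3]
        assert np.allclose(sorted(macro.probabilities), sorted(tm.pi), atol=1e-6)

    def test_degenerate_eigenvalues_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            pcca(_tm_from_T(np.eye(3)), 2)

    def test_memberships_are_stochastic(self):
        rng = np.random.default_rng(9)
        c = rng.integers(1, 40, size=(8, 8)).astype(float)
        tm = estimate_T(c, mode="reversible")
        macro = pcca(tm, 3)
        assert np.all(macro.memberships >= 0)
        assert np.all(macro.memberships <= 1)
        assert np.allclose(macro.memberships.sum(axis=1), 1.0, atol=1e-12)
        assert macro.probabilities.sum() == pytest.approx(1.0, abs=1e-12)


def _identity_macro(m):
    return MacrostateModel(
        memberships=np.eye(m), crisp=np.arange(m), probabilities=np.full(m, 1.0 / m)
    )


class TestCKTest:
    T3 = np.array(
        [
            [0.97, 0.02, 0.01],
            [0.03, 0.95, 0.02],
            [0.01, 0.03, 0.96],
        ]
    )

    def test_exact_markov_chain_passes(self):
        d = sample_chain(self.T3, 200_000, seed=10)
        result = ck_test([d], lag=1, macro=_identity_macro(3), active_set=np.arange(3))
        assert result.passes()

    def test_factor_one_identity(self):
        d = sample_chain(self.T3, 50_000, seed=11)
        result = ck_test(
            [d], lag=2, macro=_identity_macro(3), active_set=np.arange(3), factors=[1]
        )
        assert np.allclose(result.predicted, result.estimated, atol=1e-12)

    def test_hidden_memory_chain_fails(self):
        # hidden cyclic 3-state chain observed through a 2-state projection:
        # strongly non-Markovian observed dynamics
        t_hidden = np.array([[0.05, 0.95, 0.0], [0.0, 0.05, 0.95], [0.95, 0.0, 0.05]])
        hidden = sample_chain(t_hidden, 300_000, seed=12)
        observed = np.where(hidden == 2, 1, 0)
        result = ck_test(
            [observed], lag=1, macro=_identity_macro(2), active_set=np.arange(2)
        )
        assert not result.passes()


class TestRepresentativeConformation:
    def test_identical_frames_tie_rule(self):
        d = np.zeros((4, 4))
        winner, sim = representative_conformation(d)
        assert winner == 0
        assert np.allclose(sim.scores, 1.0)

    def test_pair_at_d_scale_gives_exp_minus_one(self):
        # distances {1, 1, y} with y chosen so the population std equals 1
        y = 1.0 + 3.0 / np.sqrt(2.0)
        d = np.array([[0.0, 1.0, 1.0], [1.0, 0.0, y], [1.0, y, 0.0]])
        sim = similarity_matrix(d)
        assert sim.d_scale == pytest.approx(1.0, abs=1e-12)
        assert sim.scores[0, 1] == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_hand_evaluated_three_frame_example(self):
        d = np.array([[0.0, 1.0, 4.0], [1.0, 0.0, 4.0], [4.0, 4.0, 0.0]])
        # by hand: off-diagonal distances {1, 4, 4}, population std = sqrt(2);
        # S01 = e^(-1/sqrt(2)) = 0.4930687..., S02 = S12 = e^(-4/sqrt(2)) = 0.0591063...
        winner, sim = representative_conformation(d)
        assert sim.d_scale == pytest.approx(np.sqrt(2.0), abs=1e-12)
        assert sim.scores[0, 1] == pytest.approx(np.exp(-1.0 / np.sqrt(2.0)), abs=1e-12)
        assert sim.scores[0, 2] == pytest.approx(np.exp(-4.0 / np.sqrt(2.0)), abs=1e-12)
        # frames 0 and 1 tie with mean score (1 + 0.493069 + 0.059106)/3;
        # the tie resolves to the lowest index
        assert winner == 0

    def test_coordinate_stack_with_rigid_motion(self):
        rng = np.random.default_rng(13)
        base = rng.standard_normal((5, 3))
        outlier = base + rng.standard_normal((5, 3)) * 2.0
        from conftest import random_rotation

        frames = np.stack([base, base @ random_rotation(rng).T + 3.0, outlier])
        winner, sim = representative_conformation(frames)
        assert sim.distances[0, 1] == pytest.approx(0.0, abs=1e-9)
        assert winner in (0, 1)

    def test_needs_two_frames(self):
        with pytest.raises(ValueError):
            representative_conformation(np.zeros((1, 1)))
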