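"""Aggregate-CN HMM: emissions, transitions, inference vs brute force."""

import itertools

import numpy as np
import pytest
from scipy import stats
from scipy.special import logsumexp

from paracn import hmm, simulate
from paracn.hmm import (
    HmmParams,
    HmmStateSpace,
    forward_backward,
    initial_params,
    log_emission,
    run_multi_sample,
    run_single_sample,
    select_states,
    transition_matrix,
    update_scale,
    viterbi,
)


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------


def brute_force_posteriors(logb, log_pi, log_trans):
    """Path-sum over all K^W state sequences."""
    W, K = logb.shape
    lls = []
    paths = list(itertools.product(range(K), repeat=W))
    for path in paths:
        ll = log_pi[path[0]] + logb[0, path[0]]
        for w in range(1, W):
            ll += log_trans[w - 1][path[w - 1], path[w]] + logb[w, path[w]]
        lls.append(ll)
    lls = np.array(lls)
    total = logsumexp(lls)
    gamma = np.zeros((W, K))
    for path, ll in zip(paths, lls):
        for w, s in enumerate(path):
            gamma[w, s] += np.exp(ll - total)
    best = paths[int(np.argmax(lls))]
    return gamma, np.array(best), total


def random_instance(rng, K, W):
    logb = np.log(rng.uniform(0.05, 1.0, size=(W, K)))
    pi = rng.dirichlet(np.ones(K))
    log_trans = np.empty((W - 1, K, K))
    for w in range(W - 1):
        A = rng.dirichlet(np.ones(K), size=K)
        log_trans[w] = np.log(A)
    return logb, np.log(pi), log_trans


class TestInferenceOracle:
    @pytest.mark.parametrize("K,W", [(3, 5), (2, 9), (4, 4), (2, 2), (6, 3)])
    def test_fb_and_viterbi_match_enumeration(self, K, W):
        rng = np.random.default_rng(K * 100 + W)
        for _ in range(10):
            logb, log_pi, log_trans = random_instance(rng, K, W)
            gamma, xi, ll = forward_backward(logb, log_pi, log_trans)
            bg, bpath, bll = brute_force_posteriors(logb, log_pi, log_trans)
            assert np.max(np.abs(gamma - bg)) < 1e-8
            assert ll == pytest.approx(bll, abs=1e-8)
            path, _ = viterbi(logb, log_pi, log_trans)
            assert np.array_equal(path, bpath)

    def test_single_window_closed_form(self):
        rng = np.random.default_rng(0)
        logb = np.log(rng.uniform(0.1, 1, size=(1, 4)))
        log_pi = np.log(rng.dirichlet(np.ones(4)))
        gamma, xi, ll = forward_backward(logb, log_pi, np.empty((0, 4, 4)))
        expect = np.exp(log_pi + logb[0])
        expect /= expect.sum()
        assert np.allclose(gamma[0], expect)

    def test_uniform_emissions_give_chain_marginals(self):
        """With flat emissions the posteriors are the prior chain marginals
        pi @ A1 @ A2 ... (matrix-power oracle)."""
        rng = np.random.default_rng(1)
        K, W = 3, 6
        logb = np.zeros((W, K))
        pi = rng.dirichlet(np.ones(K))
        log_trans = np.empty((W - 1, K, K))
        marg = [pi]
        for w in range(W - 1):
            A = rng.dirichlet(np.ones(K), size=K)
            log_trans[w] = np.log(A)
            marg.append(marg[-1] @ A)
        gamma, _, _ = forward_backward(logb, np.log(pi), log_trans)
        assert np.allclose(gamma, np.stack(marg), atol=1e-10)

    def test_gamma_rows_sum_to_one(self):
        rng = np.random.default_rng(2)
        logb, log_pi, log_trans = random_instance(rng, 5, 7)
        gamma, xi, _ = forward_backward(logb, log_pi, log_trans)
        assert np.allclose(gamma.sum(axis=1), 1.0)
        assert np.allclose(xi.sum(axis=(1, 2)), 1.0)


class TestTransitionMatrix:
    def test_zero_jumps_identity(self):
        assert np.array_equal(transition_matrix(0.0, 0.0, 4), np.eye(4))

    def test_printed_formula(self):
        A = transition_matrix(1e-2, 1e-2, 3)  # states {3,4,5}
        assert A[1, 2] == pytest.approx(1e-2)   # 4 -> 5
        assert A[0, 2] == pytest.approx(1e-4)   # 3 -> 5
        assert A[1, 1] == pytest.approx(1 - 2e-2)
        assert np.allclose(A.sum(axis=1), 1.0)
        assert (A >= 0).all()

    def test_first_iteration_default(self):
        p = initial_params(HmmStateSpace((3, 4, 5), 4), 100, 10)
        assert np.all(p.a_up == 1e-5) and np.all(p.a_down == 1e-5)

    def test_initial_distribution_normalized(self):
        p = initial_params(HmmStateSpace((2, 3, 4, 5, 6), 4), 100, 5)
        assert p.pi.sum() == pytest.approx(1.0)
        assert p.pi[2] == pytest.approx(1 - 4 / 100)
        assert p.pi[0] == pytest.approx(1 / 100)

    def test_row_sums_for_many_parameters(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            A = transition_matrix(rng.uniform(0, 0.1), rng.uniform(0, 0.1),
                                  int(rng.integers(1, 8)))
            assert np.allclose(A.sum(axis=1), 1.0)
            assert (A >= 0).all()


class TestEmissions:
    def test_cn2_identity_with_background(self):
        o = np.arange(50)
        n, p = np.full(50, 8.0), np.full(50, 0.4)
        got = log_emission(o, n, p, 2, np.ones(50))
        expect = stats.nbinom.logpmf(o, 8.0, 0.4)
        assert np.array_equal(got, expect)  # bit-identical

    def test_cn4_doubles_mean(self):
        n, p = np.array([8.0]), np.array([0.4])
        mean2 = 8.0 * 0.6 / 0.4
        o = np.arange(200)
        lb = log_emission(o, np.full(200, 8.0), np.full(200, 0.4), 4, np.ones(200))
        mean4 = np.sum(o * np.exp(lb))
        assert mean4 == pytest.approx(2 * mean2, rel=1e-6)

    @pytest.mark.parametrize("c", [0, 1, 2, 4, 7])
    def test_pmf_normalizes(self, c):
        o = np.arange(3000)
        lb = log_emission(o, np.full(3000, 8.0), np.full(3000, 0.4), c,
                          np.full(3000, 1.3))
        assert np.exp(logsumexp(lb)) == pytest.approx(1.0, abs=1e-9)

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            log_emission(np.array([-1]), np.array([8.0]), np.array([0.4]), 2,
                         np.array([1.0]))


class TestSelectStates:
    def test_flat_depth_ref_pm_one(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(20, size=(50, 40))
        means = np.full((50, 40), 10.0)
        st = select_states(4, counts, means)
        assert st.copy_numbers == (3, 4, 5)

    def test_deletion_sample_widens_range(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(20, size=(50, 40))
        counts[0] = rng.poisson(10, size=40)
        st = select_states(4, counts, np.full((50, 40), 10.0))
        assert 2 in st.copy_numbers and 4 in st.copy_numbers

    def test_always_contains_ref(self):
        counts = np.full((1, 1), 100)
        st = select_states(4, counts, np.full((1, 1), 10.0))
        assert 4 in st.copy_numbers
        assert max(st.copy_numbers) <= 10  # ref_cn + 6


class TestScaleUpdate:
    def test_recovers_unit_scale(self):
        cfg = simulate.SimConfig(seed=6, n_samples=100)
        sim = simulate.deletion_cohort(cfg, n_carriers=0)
        S, W = sim.counts.shape
        states = HmmStateSpace((3, 4, 5), 4)
        gammas = np.zeros((S, W, states.K))
        gammas[:, :, 1] = 1.0  # truth: everyone CN 4
        m = update_scale(gammas, sim.counts, sim.nb_n, sim.nb_p, states,
                         np.ones(W))
        # per-window ML noise at 100 samples is ~2%; allow 4 sigma
        assert np.all(np.abs(m - 1) < 0.09)
        assert np.mean(np.abs(m - 1) < 0.05) >= 0.9
        assert np.mean(m) == pytest.approx(1.0, abs=0.01)

    def test_recovers_inflated_window(self):
        cfg = simulate.SimConfig(seed=7, n_samples=100)
        m_w = np.ones(60)
        m_w[30] = 1.5
        cn = np.full((100, 60), 4)
        sim = simulate.sim_depth(cfg, cn, m_w=m_w)
        states = HmmStateSpace((3, 4, 5), 4)
        gammas = np.zeros((100, 60, 3))
        gammas[:, :, 1] = 1.0
        m = update_scale(gammas, sim.counts, sim.nb_n, sim.nb_p, states,
                         np.ones(60))
        assert m[30] == pytest.approx(1.5, abs=0.12)
        assert np.median(m) == pytest.approx(1.0, abs=0.05)

    def test_single_term_calculus_oracle(self):
        """Degenerate gamma at c: optimum matches the one-term ML value
        (2 o) / (c n (1-p)/p) up to pmf discreteness."""
        states = HmmStateSpace((4,), 4)
        gammas = np.ones((1, 1, 1))
        counts = np.array([[30]])
        nb_n, nb_p = np.array([[8.0]]), np.array([[0.4]])
        m = update_scale(gammas, counts, nb_n, nb_p, states, np.ones(1))
        expect = (2 * 30) / (4 * 8.0 * 0.6 / 0.4)
        assert m[0] == pytest.approx(expect, abs=0.05)


class TestMultiSample:
    def test_shared_deletion_recovered(self):
        """100 samples at ref CN 4, 10 carrying a 20-window one-copy
        deletion at ~30x: carriers recovered within +-1 window, no false
        Q>=20 segments in non-carriers (Fig-1b-style geometry)."""
        cfg = simulate.SimConfig(seed=8, n_samples=100)
        sim = simulate.deletion_cohort(cfg, n_carriers=10)
        profiles, params, trace = run_multi_sample(
            sim.counts, sim.nb_n, sim.nb_p, ref_cn=4
        )
        hits = 0
        for s in range(10):
            path = np.array(profiles[s].path())
            del_windows = np.where(path == 3)[0]
            if del_windows.size and abs(del_windows[0] - 20) <= 1 \
                    and abs(del_windows[-1] - 39) <= 1 \
                    and np.all(np.diff(del_windows) == 1):
                hits += 1
        assert hits >= 9
        false_calls = 0
        for s in range(10, 100):
            bad = [seg for seg in profiles[s].segments
                   if seg.agg_cn != 4 and seg.quality >= 20]
            false_calls += bool(bad)
        assert false_calls <= 5

    def test_shared_event_raises_boundary_transitions(self):
        """Posterior mass for a deletion shared by half the samples raises
        a_down specifically at the boundary where the event starts."""
        from paracn.hmm import update_transitions_initial

        S, W, K = 6, 12, 3
        states = HmmStateSpace((3, 4, 5), 4)
        gammas = np.zeros((S, W, K))
        gammas[:, :, 1] = 1.0
        xis = np.zeros((S, W - 1, K, K))
        xis[:, :, 1, 1] = 1.0
        # 3 of 6 samples: deletion starting after window 5
        for s in range(3):
            gammas[s, 6:, :] = [[1.0, 0.0, 0.0]] * (W - 6)
            xis[s, 5] = 0.0
            xis[s, 5, 1, 0] = 1.0  # down jump 4 -> 3 at boundary 5
            xis[s, 6:, :, :] = 0.0
            xis[s, 6:, 0, 0] = 1.0
        pi, a_up, a_down = update_transitions_initial(gammas, xis, states)
        others = np.delete(a_down, 5)
        assert a_down[5] > 10 * np.max(others)
        assert pi.sum() == pytest.approx(1.0)

    def test_end_to_end_boundary_spikes_after_fit(self):
        """After a full fit, the fitted jump parameters spike at the true
        boundaries of a 20-window deletion carried by 10% of the cohort."""
        cfg = simulate.SimConfig(seed=9, n_samples=100)
        sim = simulate.deletion_cohort(cfg, n_carriers=10)
        _, params, _ = run_multi_sample(sim.counts, sim.nb_n, sim.nb_p, 4)
        others = np.delete(params.a_down, 19)
        assert params.a_down[19] > 10 * np.median(others)
        others_up = np.delete(params.a_up, 39)
        assert params.a_up[39] > 10 * np.median(others_up)

    def test_loglik_improves_and_stays_stable(self):
        """The monitored total log-likelihood rises overall; clamped and
        robustified updates may cause small dips but never collapses."""
        cfg = simulate.SimConfig(seed=10, n_samples=30)
        sim = simulate.deletion_cohort(cfg, n_carriers=5, n_windows=30)
        _, _, trace = run_multi_sample(sim.counts, sim.nb_n, sim.nb_p, 4)
        assert trace[-1] > trace[0]
        assert np.all(np.diff(trace) > -1.0)

    def test_single_state_constant_profile(self):
        cfg = simulate.SimConfig(seed=11, n_samples=5)
        sim = simulate.deletion_cohort(cfg, n_carriers=0, n_windows=10)
        profiles, params, _ = run_multi_sample(
            sim.counts, sim.nb_n, sim.nb_p, 4,
            states=HmmStateSpace((4,), 4),
        )
        for p in profiles:
            assert len(p.segments) == 1
            assert p.segments[0].agg_cn == 4
            assert p.segments[0].quality == hmm.QUALITY_CAP

    def test_constant_cn_decoded_exactly(self):
        """Samples simulated at constant CN c decode to c in >=99% of
        windows at ~30x depth."""
        cfg = simulate.SimConfig(seed=12, n_samples=40)
        cn = np.full((40, 50), 4)
        cn[:10] = 2
        cn[10:20] = 6
        sim = simulate.sim_depth(cfg, cn)
        profiles, _, _ = run_multi_sample(sim.counts, sim.nb_n, sim.nb_p, 4)
        paths = np.array([p.path() for p in profiles])
        assert (paths == cn).mean() >= 0.99


class TestSingleSample:
    def test_frozen_params_reproduce_training_paths(self):
        cfg = simulate.SimConfig(seed=13, n_samples=50)
        sim = simulate.deletion_cohort(cfg, n_carriers=5, n_windows=40)
        profiles, params, _ = run_multi_sample(sim.counts, sim.nb_n, sim.nb_p, 4)
        for s in range(50):
            solo = run_single_sample(sim.counts[s], sim.nb_n[s], sim.nb_p[s],
                                     params, f"s{s}")
            assert solo.path() == profiles[s].path()

    def test_new_deletion_sample_detected(self):
        cfg = simulate.SimConfig(seed=14, n_samples=100)
        sim = simulate.deletion_cohort(cfg, n_carriers=10)
        _, params, _ = run_multi_sample(sim.counts, sim.nb_n, sim.nb_p, 4)
        cfg2 = simulate.SimConfig(seed=1400, n_samples=1)
        cn = np.full((1, 60), 4)
        cn[0, 20:40] = 3
        sim2 = simulate.sim_depth(cfg2, cn, gc=sim.gc)
        solo = run_single_sample(sim2.counts[0], sim2.nb_n[0], sim2.nb_p[0],
                                 params)
        assert 3 in [seg.agg_cn for seg in solo.segments]

    def test_layout_mismatch_and_empty_params_error(self):
        cfg = simulate.SimConfig(seed=15, n_samples=5)
        sim = simulate.deletion_cohort(cfg, n_carriers=0, n_windows=20)
        _, params, _ = run_multi_sample(sim.counts, sim.nb_n, sim.nb_p, 4)
        with pytest.raises(ValueError, match="layout"):
            run_single_sample(sim.counts[0][:10], sim.nb_n[0][:10],
                              sim.nb_p[0][:10], params)
        with pytest.raises(ValueError, match="empty"):
            HmmParams.from_json({})
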