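"""HMM fitting, Viterbi decoding and dwell extraction."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from smkinetics import REFERENCE_CONFIGS, fit_hmm, simulate_dataset, viterbi_path
from smkinetics.hmm import DwellRecord, extract_dwells, merge_short_runs
from smkinetics.trace_io import detect_photobleach


def brute_force_viterbi(x, means, sds, transmat, startprob):
    """Exhaustive maximization of the joint log-probability over all paths."""
    T, K = len(x), len(means)
    best_lp, best_path = -np.inf, None
    for path in itertools.product(range(K), repeat=T):
        lp = np.log(startprob[path[0]])
        for t in range(T):
            z = (x[t] - means[path[t]]) / sds[path[t]]
            lp += -0.5 * z * z - np.log(sds[path[t]]) - 0.5 * np.log(2 * np.pi)
            if t:
                lp += np.log(transmat[path[t - 1], path[t]])
        if lp > best_lp:
            best_lp, best_path = lp, path
    return np.array(best_path), best_lp


def _fit_from_params(means, sds, transmat, startprob):
    from smkinetics.hmm import HmmFit
    return HmmFit(
        means=np.asarray(means, float),
        sds=np.asarray(sds, float),
        transmat=np.asarray(transmat, float),
        startprob=np.asarray(startprob, float),
        loglik=0.0, converged=True, n_iter=1,
    )


class TestFit:
    def test_noiseless_alternating_trace_exact(self):
        x = np.tile([1.0, 2.0], 15)
        fit = fit_hmm(x, k_max=2, seed=0)
        assert fit.means == pytest.approx([1.0, 2.0], abs=1e-9)
        # strict alternation: off-diagonal transition probabilities ~ 1
        assert fit.transmat[0, 1] > 0.9
        assert fit.transmat[1, 0] > 0.9

    def test_single_level_trace_pruned_to_one_state(self, rng):
        x = 1.0 + rng.normal(0, 0.15, 200)
        fit = fit_hmm(x, k_max=3, seed=0)
        assert fit.n_states == 1
        assert fit.means[0] == pytest.approx(1.0, abs=0.05)

    def test_emission_mean_recovery_across_dataset(self):
        ts = simulate_dataset(REFERENCE_CONFIGS["cfg_apo_wt"], seed=5,
                              n_traces=60)
        means = []
        for t in ts:
            res = detect_photobleach(t)
            if res.censored or res.frame - 1 < 20:
                continue
            fit = fit_hmm(t.intensities[: res.frame - 1], seed=0)
            if fit.n_states == 2:
                means.append(fit.means)
        pooled = np.mean(means, axis=0)
        assert pooled == pytest.approx([1.0, 2.0], abs=0.05)

    def test_loglik_monotone_every_iteration(self, rng):
        x = np.concatenate([rng.normal(1, 0.15, 100), rng.normal(2, 0.15, 100)])
        fit = fit_hmm(x, k_max=2, seed=0)
        diffs = np.diff(fit.loglik_history)
        assert (diffs > -1e-8).all()

    def test_transition_rows_sum_to_one(self, rng):
        x = np.concatenate([rng.normal(1, 0.15, 60), rng.normal(2, 0.15, 60)])
        fit = fit_hmm(x, seed=0)
        assert np.allclose(fit.transmat.sum(axis=1), 1.0, atol=1e-9)
        assert (fit.sds > 0).all()

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            fit_hmm(np.ones(10), seed=0)

    def test_matches_hmmlearn_likelihood(self, rng):
        """Independent cross-check: our best fit scores as well as hmmlearn's
        on the same trace (same model family, both EM maximizers)."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        x = np.concatenate([
            rng.normal(1, 0.15, 150), rng.normal(2, 0.15, 100),
            rng.normal(1, 0.15, 120),
        ])
        ours = fit_hmm(x, k_max=2, seed=0)
        ref = hmmlearn.GaussianHMM(n_components=2, covariance_type="diag",
                                   n_iter=500, tol=1e-6, random_state=0)
        ref.fit(x.reshape(-1, 1))
        ref_ll = ref.score(x.reshape(-1, 1))
        assert ours.loglik >= ref_ll - 1.0
        assert np.sort(ref.means_.ravel()) == pytest.approx(ours.means, abs=0.02)


class TestViterbi:
    def test_zero_noise_recovers_rendered_path(self):
        x = np.repeat([1.0, 2.0, 1.0], [10, 7, 13]).astype(float)
        fit = _fit_from_params([1.0, 2.0], [0.05, 0.05],
                               [[0.95, 0.05], [0.05, 0.95]], [0.5, 0.5])
        ideal = viterbi_path(fit, x)
        assert np.array_equal(fit.means[ideal.states], x)

    def test_six_frame_instance_equals_enumeration(self, rng):
        x = rng.normal([1, 1, 2, 2, 1, 2], 0.3)
        means, sds = np.array([1.0, 2.0]), np.array([0.3, 0.25])
        transmat = np.array([[0.8, 0.2], [0.3, 0.7]])
        startprob = np.array([0.6, 0.4])
        fit = _fit_from_params(means, sds, transmat, startprob)
        ideal = viterbi_path(fit, x)
        bf_path, bf_lp = brute_force_viterbi(x, means, sds, transmat, startprob)
        assert np.array_equal(ideal.states, bf_path)
        assert ideal.log_joint == pytest.approx(bf_lp, abs=1e-9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        n_states=st.integers(2, 3),
        n_frames=st.integers(2, 8),
        seed=st.integers(0, 10_000),
    )
    def test_matches_enumeration_for_random_instances(self, n_states, n_frames,
                                                      seed):
        rng = np.random.default_rng(seed)
        means = np.sort(rng.uniform(0.5, 3.5, n_states))
        sds = rng.uniform(0.1, 0.5, n_states)
        transmat = rng.dirichlet(np.ones(n_states), size=n_states)
        startprob = rng.dirichlet(np.ones(n_states))
        x = rng.normal(means[rng.integers(n_states, size=n_frames)], 0.3)
        fit = _fit_from_params(means, sds, transmat, startprob)
        ideal = viterbi_path(fit, x)
        bf_path, bf_lp = brute_force_viterbi(x, means, sds, transmat, startprob)
        assert ideal.log_joint == pytest.approx(bf_lp, abs=1e-9)
        assert np.array_equal(ideal.states, bf_path)

    def test_framewise_accuracy_on_three_state_simulation(self):
        ts = simulate_dataset(REFERENCE_CONFIGS["cfg_neca_wt"], seed=5,
                              n_traces=60)
        correct = total = 0
        for t in ts:
            if t.meta["true_static"]:
                continue
            res = detect_photobleach(t)
            if res.censored or res.frame - 1 < 20:
                continue
            x = t.intensities[: res.frame - 1]
            truth = t.meta["true_frame_states"][: res.frame - 1]
            fit = fit_hmm(x, seed=0)
            ideal = viterbi_path(fit, x)
            labels = np.clip(np.round(fit.means[ideal.states]), 1, 3)
            correct += (labels == truth).sum()
            total += len(truth)
        assert correct / total >= 0.97


class TestDwellExtraction:
    def test_interior_dwell_kept_ends_censored(self):
        labels = np.array([1, 1, 2, 2, 2, 1, 1])
        dwells, _ = extract_dwells(labels, frame_interval=0.1,
                                   min_dwell_frames=2)
        assert len(dwells) == 1
        d = dwells[0]
        assert (d.state, d.exit_state) == (2, 1)
        assert d.duration_s == pytest.approx(0.3)

    def test_single_frame_blip_removed(self):
        labels = np.array([1, 1, 2, 1, 1])
        dwells, filtered = extract_dwells(labels, min_dwell_frames=2)
        assert dwells == []
        assert np.array_equal(filtered, np.ones(5))

    def test_short_run_absorbed_into_longer_neighbor(self):
        labels = np.array([1, 1, 1, 2, 3, 3])
        filtered = merge_short_runs(labels, min_dwell_frames=2)
        assert np.array_equal(filtered, [1, 1, 1, 1, 3, 3])

    def test_completed_state1_dwells_equal_12_transitions(self):
        """Bookkeeping identity on an apo-like dataset: every completed
        state-1 dwell exits via exactly one 1->2 event."""
        ts = simulate_dataset(REFERENCE_CONFIGS["cfg_apo_wt"], seed=7,
                              n_traces=50)
        n_dwell1 = n_events12 = 0
        for t in ts:
            truth = t.meta["true_frame_states"]
            end = np.argmax(truth == 0) if (truth == 0).any() else len(truth)
            if end < 3:
                continue
            dwells, _ = extract_dwells(truth[:end], frame_interval=0.1)
            n_dwell1 += sum(d.state == 1 for d in dwells)
            n_events12 += sum(
                d.state == 1 and d.exit_state == 2 for d in dwells
            )
        assert n_dwell1 > 0
        assert n_dwell1 == n_events12

    def test_durations_respect_minimum(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(1, 3, size=200)
        dwells, filtered = extract_dwells(labels, frame_interval=0.1,
                                          min_dwell_frames=2)
        for d in dwells:
            assert d.duration_s >= 0.2 - 1e-12
            assert d.exit_state != d.state

    def test_transition_count_symmetry_under_detailed_balance(self):
        """count(1->2) ~ count(2->1) for a reversible two-state chain."""
        ts = simulate_dataset(REFERENCE_CONFIGS["cfg_apo_wt"], seed=9,
                              n_traces=150)
        c12 = c21 = 0
        for t in ts:
            truth = t.meta["true_frame_states"]
            end = np.argmax(truth == 0) if (truth == 0).any() else len(truth)
            if end < 3:
                continue
            dwells, _ = extract_dwells(truth[:end], frame_interval=0.1)
            for d in dwells:
                if (d.state, d.exit_state) == (1, 2):
                    c12 += 1
                elif (d.state, d.exit_state) == (2, 1):
                    c21 += 1
        assert abs(c12 - c21) <= 3 * np.sqrt(c12 + c21)
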