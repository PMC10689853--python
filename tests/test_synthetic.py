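"""Simulator correctness: generator algebra, dwell statistics, determinism."""

import numpy as np
import pytest
from scipy import stats
from scipy.linalg import null_space

from smkinetics import REFERENCE_CONFIGS, build_generator, simulate_dataset
from smkinetics.synthetic import (
    KineticModel,
    ModelValidationError,
    n_static,
    render_trace,
    simple_model,
    simulate_hidden_path,
    stationary_distribution,
)


def oracle_stationary(model):
    """Independent null-space oracle for pi Q = 0 on the bleach-free chain."""
    R = model.rate_matrix().copy()
    np.fill_diagonal(R, 0.0)
    Q = R.copy()
    np.fill_diagonal(Q, -R.sum(axis=1))
    v = null_space(Q.T)[:, 0]
    v = v / v.sum()
    out = np.zeros(model.n_coarse)
    for s, c in enumerate(model.substate_coarse):
        out[c - 1] += v[s]
    return out


class TestGenerator:
    def test_rows_sum_to_zero_and_offdiagonals_are_rates(self):
        m = simple_model({(1, 2): 0.345, (2, 1): 0.587}, (1.0, 2.0))
        Q = build_generator(m)
        assert Q[0, 1] == pytest.approx(0.345)
        assert Q[1, 0] == pytest.approx(0.587)
        assert np.allclose(Q[:-1].sum(axis=1), 0.0, atol=1e-12)

    def test_bleach_column_appended(self):
        m = simple_model({(1, 2): 1.0, (2, 1): 1.0}, (1.0, 2.0), bleach_rate=0.2)
        Q = build_generator(m)
        assert np.allclose(Q[:-1, -1], 0.2)
        assert np.allclose(Q[:-1].sum(axis=1), 0.0, atol=1e-12)

    def test_negative_rate_rejected_naming_pair(self):
        with pytest.raises(ModelValidationError, match=r"\(0,1\)"):
            KineticModel(
                emission_means=(1.0, 2.0),
                emission_sigma=0.15,
                substate_coarse=(1, 2),
                rates=((0.0, -0.1), (0.5, 0.0)),
            )

    @pytest.mark.parametrize(
        "name, expected",
        [
            ("cfg_apo_wt", (0.63, 0.37)),
            ("cfg_neca_wt", (0.49, 0.37, 0.14)),
            ("cfg_neca_wt_minigs", (0.42, 0.37, 0.21)),
        ],
    )
    def test_reference_config_stationary_occupancies(self, name, expected):
        model = REFERENCE_CONFIGS[name].model
        pi = stationary_distribution(model)
        assert np.allclose(pi, oracle_stationary(model), atol=1e-9)
        assert np.allclose(pi, expected, atol=0.005)


class TestHiddenPath:
    def test_zero_rates_single_dwell(self):
        m = simple_model({}, (1.0, 2.0), bleach_rate=0.0)
        Q = build_generator(m)
        p = simulate_hidden_path(Q, 10.0, 5, np.array([1.0, 0.0]))
        assert len(p.segments) == 1
        assert p.segments[0] == (0, 10.0)
        assert p.bleach_time is None

    def test_dwell_durations_cover_observed_window(self, rng):
        model = REFERENCE_CONFIGS["cfg_apo_wt"].model
        Q = build_generator(model)
        for _ in range(50):
            p = simulate_hidden_path(Q, 120.0, rng, model.start_distribution())
            total = sum(d for _, d in p.segments)
            assert total == pytest.approx(p.observed_duration(), abs=1e-9)
            for (a, _), (b, _) in zip(p.segments, p.segments[1:]):
                assert a != b

    def test_state1_mean_dwell_matches_exit_rate(self):
        # bleach-free variant: completed dwells are then pure Exp(exit rate)
        model = simple_model({(1, 2): 0.345, (2, 1): 0.587}, (1.0, 2.0),
                             bleach_rate=0.0)
        Q = build_generator(model)
        rng = np.random.default_rng(77)
        dwells = []
        while len(dwells) < 10_000:
            p = simulate_hidden_path(Q, 600.0, rng, model.start_distribution())
            dwells += [d for s, d in p.segments[:-1] if s == 0]
        dwells = np.asarray(dwells[:10_000])
        expected = 1.0 / 0.345  # exponential-mean oracle
        sem = dwells.std() / np.sqrt(len(dwells))
        assert abs(dwells.mean() - expected) < 3 * sem

    def test_occupancy_matches_stationary_distribution(self):
        model = REFERENCE_CONFIGS["cfg_apo_wt"].model
        Q = build_generator(model)
        rng = np.random.default_rng(11)
        occ = np.zeros(2)
        t_total = 0.0
        while t_total < 5000.0:
            p = simulate_hidden_path(Q, 500.0, rng, model.start_distribution())
            for s, d in p.segments:
                occ[s] += d
            t_total += p.observed_duration()
        frac = occ / occ.sum()
        assert abs(frac[0] - 0.63) < 0.02

    def test_bleach_times_exponential(self):
        model = simple_model(
            {(1, 2): 0.345, (2, 1): 0.587}, (1.0, 2.0),
            bleach_rate=1.0 / 30.0, max_duration=600.0,
        )
        Q = build_generator(model)
        rng = np.random.default_rng(5)
        times = []
        for _ in range(1000):
            p = simulate_hidden_path(Q, 600.0, rng, model.start_distribution())
            if p.bleach_time is not None:
                times.append(p.bleach_time)
        assert abs(np.mean(times) - 30.0) / 30.0 < 0.10

    def test_substate_dwells_follow_two_component_mixture(self):
        """Pooled coarse-state-1 dwells from the hidden substate expansion
        agree with the analytic 50/50 Exp(1.0)/Exp(0.2) mixture (KS test)."""
        model = REFERENCE_CONFIGS["cfg_substates"].model
        nobleach = KineticModel(
            emission_means=model.emission_means,
            emission_sigma=model.emission_sigma,
            substate_coarse=model.substate_coarse,
            rates=model.rates,
            bleach_rate=0.0,
        )
        Q = build_generator(nobleach)
        cdf = lambda t: 1.0 - 0.5 * np.exp(-1.0 * t) - 0.5 * np.exp(-0.2 * t)
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            dwells = []
            while len(dwells) < 5000:
                p = simulate_hidden_path(Q, 2000.0, rng,
                                         nobleach.start_distribution())
                dwells += [
                    d for (s, d) in p.segments[1:-1]
                    if nobleach.substate_coarse[s] == 1
                ]
            res = stats.kstest(np.asarray(dwells[:5000]), cdf)
            assert res.pvalue > 0.01


class TestRenderTrace:
    def _constant_path(self, model, state, t_end):
        from smkinetics.synthetic import HiddenPath
        return HiddenPath(segments=[(state, t_end)], total_duration=t_end,
                          bleach_time=None)

    def test_noiseless_constant_state(self):
        m = simple_model({}, (1.0, 2.0), emission_sigma=0.0)
        tr = render_trace(self._constant_path(m, 1, 5.0), m, 0)
        assert np.allclose(tr.intensities, 2.0)

    def test_subframe_occupancy_weighting(self):
        from smkinetics.synthetic import HiddenPath
        m = simple_model({}, (1.0, 2.0, 3.0), emission_sigma=0.0)
        path = HiddenPath(
            segments=[(2, 0.05), (1, 0.05), (1, 0.1)], total_duration=0.2,
            bleach_time=None,
        )
        tr = render_trace(path, m, 0)
        # first frame: 0.05 s in state 3, 0.05 s in state 2
        assert tr.intensities[0] == pytest.approx(2.5)
        assert tr.intensities[1] == pytest.approx(2.0)

    def test_noise_sd_recovered(self):
        m = simple_model({}, (1.0, 2.0), emission_sigma=0.15,
                         max_duration=600.0)
        tr = render_trace(self._constant_path(m, 0, 600.0), m, 42)
        assert np.std(tr.intensities) == pytest.approx(0.15, abs=0.01)

    def test_post_bleach_frames_are_dark(self):
        from smkinetics.synthetic import HiddenPath
        m = simple_model({}, (1.0, 2.0), emission_sigma=0.0)
        path = HiddenPath(segments=[(1, 3.0)], total_duration=10.0,
                          bleach_time=3.0)
        tr = render_trace(path, m, 0)
        assert np.allclose(tr.intensities[31:], 0.0)
        assert np.allclose(tr.intensities[:30], 2.0)


class TestDataset:
    def test_static_count_deterministic_rounding(self):
        assert n_static(100, 0.55) == 55
        assert n_static(101, 0.55) == 56  # floor(55.55 + 0.5)
        cfg = REFERENCE_CONFIGS["cfg_apo_wt"]
        ts = simulate_dataset(cfg, seed=9, n_traces=100)
        n_true_static = sum(t.meta["true_static"] for t in ts)
        assert n_true_static == 55

    def test_same_seed_bit_identical(self):
        cfg = REFERENCE_CONFIGS["cfg_apo_wt"]
        a = simulate_dataset(cfg, seed=4, n_traces=20)
        b = simulate_dataset(cfg, seed=4, n_traces=20)
        for ta, tb in zip(a, b):
            assert ta.molecule_id == tb.molecule_id
            assert np.array_equal(ta.intensities, tb.intensities)

    def test_static_traces_do_not_switch_states(self):
        cfg = REFERENCE_CONFIGS["cfg_neca_wt"]
        ts = simulate_dataset(cfg, seed=2, n_traces=40)
        for t in ts:
            if t.meta["true_static"]:
                labels = t.meta["true_frame_states"]
                pre = labels[labels > 0]  # before bleach
                assert len(np.unique(pre)) == 1
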