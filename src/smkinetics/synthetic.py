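"""Continuous-time Markov simulation of single-molecule fluorescence traces.

A labeled receptor tethered under TIRF illumination emits at a conformation-
dependent intensity level.  The emitting molecule is modeled as a
continuous-time Markov chain over a small number of coarse conformational
states (inactive, intermediate, active-like), optionally expanded into hidden
kinetic substates that share one emission level but differ in exit rate --
the feature that produces bi-exponential dwell-time distributions.  An
absorbing "bleached" state models irreversible single-step photobleaching.

Traces are rendered at a fixed camera frame interval with exact frame
integration: a frame's noiseless value is the occupancy-time-weighted mean of
the emission levels visited during that frame, so sub-frame transits produce
intermediate intensities exactly as finite integration time does on an EMCCD.
Gaussian read noise is added per frame.

The module ships a set of read-only reference configurations whose rate
constants are chosen so that the analytic stationary occupancies and mean
dwell times reproduce typical receptor behavior under different ligation
conditions (see :data:`REFERENCE_CONFIGS`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .trace_io import Trace, TraceSet

__all__ = [
    "KineticModel",
    "ReferenceConfig",
    "HiddenPath",
    "build_generator",
    "stationary_distribution",
    "simulate_hidden_path",
    "render_trace",
    "simulate_dataset",
    "REFERENCE_CONFIGS",
]


class ModelValidationError(ValueError):
    """Raised when a kinetic model violates its structural invariants."""


@dataclass(frozen=True)
class KineticModel:
    """A coarse-state conformational model with optional hidden substates.

    Parameters
    ----------
    emission_means:
        Normalized emission level per coarse state, strictly increasing
        (nominally 1.0 / 2.0 / 3.0, i.e. levels ~one normalized unit apart).
    emission_sigma:
        Per-frame Gaussian noise SD in normalized units.
    substate_coarse:
        Coarse-state index (1-based) of each hidden substate.  Simple models
        use one substate per coarse state.
    rates:
        ``(S, S)`` array of transition rate constants (1/s) between
        substates; diagonal ignored/zero.
    bleach_rate:
        Rate (1/s) of irreversible photobleaching, applied from every
        substate.
    frame_interval:
        Camera integration time in seconds.
    static_fraction:
        Fraction of simulated traces rendered transition-free (all
        inter-state rates zeroed; bleaching retained), emulating the
        immobile/contaminant population seen in real datasets.
    initial_distribution:
        Probability per substate at t=0.  ``None`` means the stationary
        distribution of the bleach-free chain.
    max_duration:
        Hard cap on trace length in seconds (movie length).
    """

    emission_means: tuple[float, ...]
    substate_coarse: tuple[int, ...]
    rates: tuple[tuple[float, ...], ...]
    emission_sigma: float = 0.15
    bleach_rate: float = 0.0
    frame_interval: float = 0.1
    static_fraction: float = 0.55
    initial_distribution: tuple[float, ...] | None = None
    max_duration: float = 120.0

    def __post_init__(self) -> None:
        means = np.asarray(self.emission_means, dtype=float)
        if means.ndim != 1 or len(means) < 1:
            raise ModelValidationError("emission_means must be a 1-D sequence")
        if len(means) > 1 and not np.all(np.diff(means) > 0):
            raise ModelValidationError(
                "emission means must be strictly increasing with coarse state"
            )
        coarse = np.asarray(self.substate_coarse, dtype=int)
        if coarse.min() < 1 or coarse.max() > len(means):
            raise ModelValidationError("substate_coarse indexes outside coarse states")
        R = np.asarray(self.rates, dtype=float)
        S = len(coarse)
        if R.shape != (S, S):
            raise ModelValidationError(f"rates must be ({S},{S}), got {R.shape}")
        for i in range(S):
            for j in range(S):
                if i != j and R[i, j] < 0:
                    raise ModelValidationError(
                        f"negative rate for substate pair ({i},{j}): {R[i, j]}"
                    )
        if self.bleach_rate < 0:
            raise ModelValidationError("bleach_rate must be >= 0")
        if self.emission_sigma < 0:
            raise ModelValidationError("emission_sigma must be >= 0")
        if not (0.0 <= self.static_fraction <= 1.0):
            raise ModelValidationError("static_fraction must lie in [0, 1]")
        if self.frame_interval <= 0:
            raise ModelValidationError("frame_interval must be > 0")
        if self.initial_distribution is not None:
            p = np.asarray(self.initial_distribution, dtype=float)
            if p.shape != (S,):
                raise ModelValidationError("initial_distribution length mismatch")
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ModelValidationError("initial_distribution must sum to 1")

    # -- derived views -------------------------------------------------

    @property
    def n_coarse(self) -> int:
        return len(self.emission_means)

    @property
    def n_substates(self) -> int:
        return len(self.substate_coarse)

    def rate_matrix(self) -> np.ndarray:
        return np.asarray(self.rates, dtype=float)

    def substate_means(self) -> np.ndarray:
        """Emission mean per substate (substates share their coarse mean)."""
        means = np.asarray(self.emission_means, dtype=float)
        return means[np.asarray(self.substate_coarse, dtype=int) - 1]

    def start_distribution(self) -> np.ndarray:
        if self.initial_distribution is not None:
            return np.asarray(self.initial_distribution, dtype=float)
        return stationary_distribution(self, coarse=False)

    def static_variant(self) -> "KineticModel":
        """Zero all inter-substate rates; bleaching is retained."""
        S = self.n_substates
        zero = tuple(tuple(0.0 for _ in range(S)) for _ in range(S))
        # a static molecule sits wherever it started
        return replace(self, rates=zero)


def simple_model(
    rate_pairs: dict[tuple[int, int], float],
    emission_means: Sequence[float],
    **kwargs,
) -> KineticModel:
    """Build a model with one substate per coarse state from 1-based rate pairs."""
    K = len(emission_means)
    R = np.zeros((K, K))
    for (i, j), k in rate_pairs.items():
        R[i - 1, j - 1] = k
    return KineticModel(
        emission_means=tuple(float(m) for m in emission_means),
        substate_coarse=tuple(range(1, K + 1)),
        rates=tuple(map(tuple, R)),
        **kwargs,
    )


@dataclass(frozen=True)
class ReferenceConfig:
    """A named, versioned simulation condition (model + dataset size + seed)."""

    name: str
    model: KineticModel
    n_traces: int = 300
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_traces < 1:
            raise ModelValidationError("n_traces must be >= 1")


@dataclass
class HiddenPath:
    """Ground-truth state trajectory of one molecule.

    ``segments`` is a list of ``(substate_index, dwell_seconds)`` covering
    ``min(total_duration, bleach_time)``; ``bleach_time`` is ``None`` when the
    molecule survives the full observation window (censored).
    """

    segments: list[tuple[int, float]]
    total_duration: float
    bleach_time: float | None

    def observed_duration(self) -> float:
        return self.total_duration if self.bleach_time is None else min(
            self.total_duration, self.bleach_time
        )


def build_generator(model: KineticModel) -> np.ndarray:
    """Continuous-time generator over substates plus an absorbing bleach row.

    Off-diagonal entries are the transition rate constants; each diagonal is
    the negative row sum, so every row sums to zero.  The last row/column is
    the absorbing bleached state, entered at ``bleach_rate`` from every
    substate.
    """
    S = model.n_substates
    Q = np.zeros((S + 1, S + 1))
    R = model.rate_matrix()
    Q[:S, :S] = R - np.diag(np.diag(R))
    Q[:S, S] = model.bleach_rate
    Q[np.arange(S), np.arange(S)] = 0.0
    Q[np.arange(S), np.arange(S)] = -Q[:S].sum(axis=1)
    return Q


def stationary_distribution(model: KineticModel, coarse: bool = True) -> np.ndarray:
    """Stationary distribution of the bleach-free chain (pi Q = 0, sum pi = 1)."""
    R = model.rate_matrix().copy()
    np.fill_diagonal(R, 0.0)
    S = model.n_substates
    if np.allclose(R, 0.0):
        pi = np.full(S, 1.0 / S)
    else:
        Q = R.copy()
        np.fill_diagonal(Q, -R.sum(axis=1))
        # replace one balance equation with the normalization constraint
        A = np.vstack([Q.T[:-1], np.ones(S)])
        b = np.zeros(S)
        b[-1] = 1.0
        pi = np.linalg.lstsq(A, b, rcond=None)[0]
    if coarse:
        out = np.zeros(model.n_coarse)
        for s, c in enumerate(model.substate_coarse):
            out[c - 1] += pi[s]
        return out
    return pi


def simulate_hidden_path(
    generator: np.ndarray,
    t_end: float,
    rng: np.random.Generator | int,
    start_distribution: np.ndarray | None = None,
) -> HiddenPath:
    """Exact (Gillespie) simulation of the substate chain until bleach or t_end."""
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    S = generator.shape[0] - 1  # last index is the absorbing bleached state
    if start_distribution is None:
        start_distribution = np.full(S, 1.0 / S)
    state = int(rng.choice(S, p=start_distribution))
    t = 0.0
    segments: list[tuple[int, float]] = []
    bleach_time: float | None = None
    while t < t_end:
        exit_rate = -generator[state, state]
        if exit_rate <= 0:
            segments.append((state, t_end - t))
            t = t_end
            break
        dwell = rng.exponential(1.0 / exit_rate)
        if t + dwell >= t_end:
            segments.append((state, t_end - t))
            t = t_end
            break
        segments.append((state, dwell))
        t += dwell
        probs = generator[state].copy()
        probs[state] = 0.0
        probs = probs / exit_rate
        nxt = int(rng.choice(S + 1, p=probs))
        if nxt == S:  # bleached
            bleach_time = t
            break
        state = nxt
    return HiddenPath(segments=segments, total_duration=t_end, bleach_time=bleach_time)


def _frame_state_occupancy(
    path: HiddenPath, frame_interval: float, n_frames: int, n_substates: int
) -> np.ndarray:
    """Occupancy time of each substate within each frame, shape (n_frames, S)."""
    occ = np.zeros((n_frames, n_substates))
    t = 0.0
    edges = np.arange(n_frames + 1) * frame_interval
    for state, dwell in path.segments:
        t0, t1 = t, t + dwell
        i0 = int(np.searchsorted(edges, t0, side="right") - 1)
        i1 = min(int(np.searchsorted(edges, t1, side="left")), n_frames)
        for f in range(max(i0, 0), i1):
            lo = max(t0, edges[f])
            hi = min(t1, edges[f + 1])
            if hi > lo:
                occ[f, state] += hi - lo
        t = t1
    return occ


def render_trace(
    path: HiddenPath,
    model: KineticModel,
    rng: np.random.Generator | int,
    molecule_id: str = "mol_0",
    condition: dict | None = None,
) -> Trace:
    """Render a hidden path into a framewise intensity trace.

    Each frame's noiseless value is the occupancy-weighted mean of substate
    emission levels over that frame; time after photobleaching contributes
    zero signal.  i.i.d. Gaussian noise (``emission_sigma``) is added to every
    frame, including fully bleached ones.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    dt = model.frame_interval
    n_frames = int(round(path.total_duration / dt))
    occ = _frame_state_occupancy(path, dt, n_frames, model.n_substates)
    signal = occ @ model.substate_means() / dt  # bleached time contributes 0
    noise = rng.normal(0.0, model.emission_sigma, size=n_frames)
    times = np.arange(n_frames) * dt
    # majority-occupancy coarse label per frame (0 = mostly bleached), kept as
    # ground truth for recovery tests
    coarse_occ = np.zeros((n_frames, model.n_coarse + 1))
    coarse_occ[:, 0] = dt - occ.sum(axis=1)
    for s, c in enumerate(model.substate_coarse):
        coarse_occ[:, c] += occ[:, s]
    true_frame_states = coarse_occ.argmax(axis=1)
    meta = {
        "true_path": path,
        "true_frame_states": true_frame_states,
        "true_bleach_time": path.bleach_time,
    }
    return Trace(
        molecule_id=molecule_id,
        times=times,
        intensities=signal + noise,
        condition=dict(condition or {}),
        normalized=False,
        meta=meta,
    )


def n_static(n_traces: int, static_fraction: float) -> int:
    """Deterministic count of static traces: floor(n * fraction + 0.5)."""
    return int(np.floor(n_traces * static_fraction + 0.5))


def simulate_dataset(
    config: ReferenceConfig,
    seed: int | None = None,
    n_traces: int | None = None,
) -> TraceSet:
    """Simulate a full trace dataset for one condition.

    Exactly ``floor(n * static_fraction + 0.5)`` traces are static
    (transition-free, random initial state, bleaching retained); the rest are
    dynamic.  Deterministic under a fixed seed.  Ground truth (hidden path,
    framewise labels, static flag) is attached to each trace's ``meta``.
    """
    model = config.model
    n = int(n_traces if n_traces is not None else config.n_traces)
    root = np.random.SeedSequence(seed if seed is not None else config.seed)
    assign_rng = np.random.default_rng(root.spawn(1)[0])
    k_static = n_static(n, model.static_fraction)
    static_mask = np.zeros(n, dtype=bool)
    static_mask[assign_rng.permutation(n)[:k_static]] = True

    Q_dyn = build_generator(model)
    static = model.static_variant()
    Q_sta = build_generator(static)
    start = model.start_distribution()

    traces = []
    children = root.spawn(n)
    for i in range(n):
        rng = np.random.default_rng(children[i])
        Q = Q_sta if static_mask[i] else Q_dyn
        path = simulate_hidden_path(Q, model.max_duration, rng, start)
        tr = render_trace(
            path,
            model,
            rng,
            molecule_id=f"{config.name}_{i:04d}",
            condition={"config": config.name},
        )
        tr.meta["true_static"] = bool(static_mask[i])
        traces.append(tr)
    return TraceSet(
        traces=traces,
        provenance={
            "source": f"simulated:{config.name}",
            "seed": int(seed if seed is not None else config.seed),
            "n_traces": n,
            "n_static_true": int(k_static),
        },
    )


def _cfg(name: str, rate_pairs, means, n_states_hint=None, **kw) -> ReferenceConfig:
    model = simple_model(
        rate_pairs,
        means,
        emission_sigma=0.15,
        bleach_rate=1.0 / 30.0,
        frame_interval=0.1,
        static_fraction=0.55,
        max_duration=120.0,
        **kw,
    )
    return ReferenceConfig(name=name, model=model, n_traces=300, seed=42)


def _substate_config() -> ReferenceConfig:
    """Two-state emission model whose state 1 hides fast/slow substates.

    Substates 1a/1b share emission level 1.0 with exit rates 1.0 and 0.2 1/s;
    state 2 returns to them with equal probability, so pooled state-1 dwells
    follow a 50/50 two-component exponential mixture (bi-exponential).
    """
    R = np.zeros((3, 3))
    R[0, 2] = 1.0   # 1a -> 2 (fast)
    R[1, 2] = 0.2   # 1b -> 2 (slow)
    R[2, 0] = 0.2935  # 2 -> 1a
    R[2, 1] = 0.2935  # 2 -> 1b
    model = KineticModel(
        emission_means=(1.0, 2.0),
        emission_sigma=0.15,
        substate_coarse=(1, 1, 2),
        rates=tuple(map(tuple, R)),
        bleach_rate=1.0 / 30.0,
        frame_interval=0.1,
        static_fraction=0.55,
        max_duration=120.0,
    )
    return ReferenceConfig(name="cfg_substates", model=model, n_traces=300, seed=42)


REFERENCE_CONFIGS: dict[str, ReferenceConfig] = {
    # two-state, apo-like: pi = (0.63, 0.37), mean state-1 dwell 2.9 s
    "cfg_apo_wt": _cfg("cfg_apo_wt", {(1, 2): 0.345, (2, 1): 0.587}, (1.0, 2.0)),
    # three-state, agonist-like: pi = (0.49, 0.37, 0.14); strictly sequential
    "cfg_neca_wt": _cfg(
        "cfg_neca_wt",
        {(1, 2): 0.345, (2, 1): 0.457, (2, 3): 0.227, (3, 2): 0.600},
        (1.0, 2.0, 3.0),
    ),
    # ternary-complex-like: pi = (0.42, 0.37, 0.21)
    "cfg_neca_wt_minigs": _cfg(
        "cfg_neca_wt_minigs",
        {(1, 2): 0.556, (2, 1): 0.631, (2, 3): 0.341, (3, 2): 0.600},
        (1.0, 2.0, 3.0),
    ),
    # two-state with forward/backward rate ratio 2.4
    "cfg_keq24": _cfg("cfg_keq24", {(1, 2): 0.550, (2, 1): 0.229}, (1.0, 2.0)),
    # CAM-like: faster exit from state 1 (mean dwell 1.5 s), three states
    "cfg_cam": _cfg(
        "cfg_cam",
        {(1, 2): 0.667, (2, 1): 0.533, (2, 3): 0.267, (3, 2): 0.533},
        (1.0, 2.0, 3.0),
    ),
    "cfg_substates": _substate_config(),
}
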