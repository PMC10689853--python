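"""Maximum-likelihood HMM idealization of intensity traces.

Each trace is fit with a Gaussian-emission hidden Markov model by Baum-Welch
EM from multiple seeded restarts; the Viterbi algorithm then yields the
globally most probable state path.  States whose average occupancy falls
below 1% are pruned and the model refit.  Consecutive runs shorter than a
minimum dwell are merged into the flanking state before dwell statistics are
collected, and the first and last dwell of each trace are censored (a trace
begins and ends mid-dwell, so those durations are right/left truncated).

The forward-backward and Viterbi recursions are JIT-compiled with numba;
everything else is plain numpy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "HmmFit",
    "IdealizedTrace",
    "DwellRecord",
    "fit_hmm",
    "viterbi_path",
    "extract_dwells",
    "merge_short_runs",
]


# --------------------------------------------------------------------------
# numba kernels
# --------------------------------------------------------------------------

@njit(cache=True)
def _forward_backward(b, transmat, startprob):
    """Scaled forward-backward.

    b: (T, K) emission likelihoods, already rescaled per frame (any positive
    per-frame constant cancels in gamma/xi; the caller tracks the log shift).
    Returns (loglik_shifted, gamma, xi_sum).
    """
    T, K = b.shape
    alpha = np.empty((T, K))
    c = np.empty(T)
    # forward
    c0 = 0.0
    for j in range(K):
        alpha[0, j] = startprob[j] * b[0, j]
        c0 += alpha[0, j]
    if c0 <= 0:
        c0 = 1e-300
    for j in range(K):
        alpha[0, j] /= c0
    c[0] = c0
    for t in range(1, T):
        ct = 0.0
        for j in range(K):
            s = 0.0
            for i in range(K):
                s += alpha[t - 1, i] * transmat[i, j]
            v = s * b[t, j]
            alpha[t, j] = v
            ct += v
        if ct <= 0:
            ct = 1e-300
        for j in range(K):
            alpha[t, j] /= ct
        c[t] = ct
    # backward + accumulators
    beta = np.ones(K)
    newbeta = np.empty(K)
    gamma = np.empty((T, K))
    xi_sum = np.zeros((K, K))
    gl = 0.0
    for j in range(K):
        gamma[T - 1, j] = alpha[T - 1, j]
        gl += gamma[T - 1, j]
    for t in range(T - 2, -1, -1):
        cn = c[t + 1]
        for i in range(K):
            s = 0.0
            for j in range(K):
                w = transmat[i, j] * b[t + 1, j] * beta[j]
                s += w
                xi_sum[i, j] += alpha[t, i] * w / cn
            newbeta[i] = s / cn
        gs = 0.0
        for i in range(K):
            beta[i] = newbeta[i]
            gamma[t, i] = alpha[t, i] * beta[i]
            gs += gamma[t, i]
        if gs > 0:
            for i in range(K):
                gamma[t, i] /= gs
    if gl > 0:
        for j in range(K):
            gamma[T - 1, j] /= gl
    loglik = 0.0
    for t in range(T):
        loglik += np.log(c[t])
    return loglik, gamma, xi_sum


@njit(cache=True)
def _em_loop(x, means0, sd0, tol, max_iter, sd_floor):
    """Full Baum-Welch EM loop (emissions, scaled FB, M-step) in one kernel.

    Returns (means, sds, transmat, startprob, occupancy, history, n_iter,
    converged_flag).
    """
    T = x.shape[0]
    K = means0.shape[0]
    means = means0.copy()
    sds = np.full(K, max(sd0, sd_floor))
    transmat = np.full((K, K), 0.1 / max(K - 1, 1))
    for i in range(K):
        transmat[i, i] = 0.9
    startprob = np.full(K, 1.0 / K)
    history = np.empty(max_iter)
    prev = -1e308
    converged = False
    n_iter = 0
    log2pi_half = 0.5 * np.log(2 * np.pi)
    b = np.empty((T, K))
    gamma = np.empty((T, K))
    occupancy = np.full(K, 1.0 / K)
    for it in range(max_iter):
        n_iter = it + 1
        # emission likelihoods, rescaled per frame for stability
        shift = 0.0
        for t in range(T):
            rowmax = -1e308
            for j in range(K):
                z = (x[t] - means[j]) / sds[j]
                b[t, j] = -0.5 * z * z - np.log(sds[j])
                if b[t, j] > rowmax:
                    rowmax = b[t, j]
            shift += rowmax
            for j in range(K):
                b[t, j] = np.exp(b[t, j] - rowmax)
        ll, gamma_, xi_sum = _forward_backward(b, transmat, startprob)
        gamma = gamma_
        ll += shift - T * log2pi_half
        history[it] = ll
        if prev > -1e307 and abs(ll - prev) < tol * (1.0 + abs(ll)):
            converged = True
            break
        prev = ll
        # M-step
        for j in range(K):
            w = 0.0
            mj = 0.0
            for t in range(T):
                w += gamma[t, j]
                mj += gamma[t, j] * x[t]
            if w > 1e-12:
                mj /= w
                vj = 0.0
                for t in range(T):
                    d = x[t] - mj
                    vj += gamma[t, j] * d * d
                vj /= w
                means[j] = mj
                sj = np.sqrt(vj) if vj > 0 else 0.0
                sds[j] = sj if sj > sd_floor else sd_floor
        for i in range(K):
            rs = 0.0
            for j in range(K):
                rs += xi_sum[i, j]
            if rs > 1e-300:
                for j in range(K):
                    transmat[i, j] = xi_sum[i, j] / rs
            else:
                for j in range(K):
                    transmat[i, j] = 1.0 / K
        ssum = 0.0
        for j in range(K):
            startprob[j] = gamma[0, j] if gamma[0, j] > 1e-12 else 1e-12
            ssum += startprob[j]
        for j in range(K):
            startprob[j] /= ssum
    for j in range(K):
        s = 0.0
        for t in range(T):
            s += gamma[t, j]
        occupancy[j] = s / T
    return means, sds, transmat, startprob, occupancy, history[:n_iter], n_iter, converged


@njit(cache=True)
def _viterbi(logb, log_transmat, log_startprob):
    T, K = logb.shape
    delta = log_startprob + logb[0]
    back = np.zeros((T, K), dtype=np.int64)
    for t in range(1, T):
        newdelta = np.empty(K)
        for j in range(K):
            best = -1e300
            arg = 0
            for i in range(K):
                v = delta[i] + log_transmat[i, j]
                if v > best:
                    best = v
                    arg = i
            newdelta[j] = best + logb[t, j]
            back[t, j] = arg
        delta = newdelta
    path = np.empty(T, dtype=np.int64)
    best = -1e300
    arg = 0
    for j in range(K):
        if delta[j] > best:
            best = delta[j]
            arg = j
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path, best


# --------------------------------------------------------------------------
# results
# --------------------------------------------------------------------------

@dataclass
class HmmFit:
    means: np.ndarray          # (K,) emission means, ascending
    sds: np.ndarray            # (K,) emission SDs
    transmat: np.ndarray       # (K, K) per-frame transition probabilities
    startprob: np.ndarray      # (K,)
    loglik: float
    converged: bool
    n_iter: int
    loglik_history: np.ndarray = field(default_factory=lambda: np.empty(0))
    occupancy: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_states(self) -> int:
        return len(self.means)

    def rescaled(self, scale: float) -> "HmmFit":
        """Fit parameters after dividing the data by ``scale`` (normalization)."""
        return HmmFit(
            means=self.means / scale,
            sds=self.sds / scale,
            transmat=self.transmat.copy(),
            startprob=self.startprob.copy(),
            loglik=self.loglik,
            converged=self.converged,
            n_iter=self.n_iter,
            loglik_history=self.loglik_history.copy(),
            occupancy=self.occupancy.copy(),
        )


@dataclass
class IdealizedTrace:
    molecule_id: str
    states: np.ndarray         # per-frame state index into fit.means (0-based)
    levels: np.ndarray         # per-frame fitted emission level
    log_joint: float
    fit: HmmFit
    frame_interval: float
    coarse_states: np.ndarray | None = None  # 1-based consensus labels


@dataclass
class DwellRecord:
    molecule_id: str
    state: int                 # 1-based state label
    duration_s: float
    exit_state: int            # 1-based; the state entered at the end
    intensity_before: float    # mean fitted level during the dwell
    intensity_after: float     # mean fitted level of the following run


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

def _kmeans1d(x: np.ndarray, k: int, init: np.ndarray, n_iter: int = 25) -> np.ndarray:
    c = init.astype(float).copy()
    for _ in range(n_iter):
        lab = np.abs(x[:, None] - c[None, :]).argmin(axis=1)
        new = c.copy()
        for j in range(k):
            sel = lab == j
            if sel.any():
                new[j] = x[sel].mean()
        if np.allclose(new, c):
            break
        c = new
    return np.sort(c)


def _em(
    x: np.ndarray,
    means0: np.ndarray,
    sd0: float,
    tol: float,
    max_iter: int,
    sd_floor: float,
) -> HmmFit:
    means, sds, transmat, startprob, occ, history, n_iter, converged = _em_loop(
        np.ascontiguousarray(x, dtype=np.float64),
        np.ascontiguousarray(means0, dtype=np.float64),
        float(sd0), float(tol), int(max_iter), float(sd_floor),
    )
    order = np.argsort(means)
    return HmmFit(
        means=means[order],
        sds=sds[order],
        transmat=transmat[np.ix_(order, order)],
        startprob=startprob[order],
        loglik=float(history[-1]),
        converged=bool(converged),
        n_iter=int(n_iter),
        loglik_history=np.asarray(history),
        occupancy=occ[order],
    )


def fit_hmm(
    values: np.ndarray,
    k_max: int = 3,
    n_restarts: int = 5,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int | np.random.Generator = 0,
    prune_occupancy: float = 0.01,
    merge_factor: float = 3.0,
) -> HmmFit:
    """Fit a Gaussian-emission HMM by EM with seeded restarts and pruning.

    The best-likelihood fit over ``n_restarts`` k-means-initialized restarts
    is kept.  Two reductions then guard against overfitting a short trace:
    states whose mean posterior occupancy is below ``prune_occupancy`` are
    removed, and adjacent states whose emission means are closer than
    ``merge_factor`` times the per-frame noise SD (estimated robustly from
    first differences) are merged -- they describe one emission level, not
    two resolvable states.  After either reduction the model is refit; the
    loop runs until stable.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 20:
        raise ValueError("need at least 20 frames to fit an HMM")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spread = float(np.ptp(x))
    scale = max(spread, float(np.std(x)), 1e-12)
    sd_floor = 1e-6 * scale
    d = np.diff(x)
    mad = np.median(np.abs(d - np.median(d)))
    sd0 = float(1.4826 * mad / np.sqrt(2.0)) or max(float(np.std(x)) * 0.2, sd_floor)

    k = int(k_max)
    init_means = None
    short_iter = min(60, max_iter)
    while True:
        best: HmmFit | None = None
        if init_means is None:
            quantiles = np.percentile(x, 100 * (np.arange(k) + 0.5) / k)
            base = _kmeans1d(x, k, np.asarray(quantiles, dtype=float))
        else:
            base = np.sort(init_means)
        # short EM runs from each restart, then polish the best to convergence
        for r in range(n_restarts):
            m0 = base if r == 0 else np.sort(
                base + rng.normal(0.0, 0.05 * scale, size=k)
            )
            fit = _em(x, m0, sd0, tol, short_iter, sd_floor)
            if best is None or fit.loglik > best.loglik:
                best = fit
        assert best is not None
        if not best.converged:
            best = _em(x, best.means, sd0, tol, max_iter, sd_floor)
        if k == 1:
            return best
        # prune states too rare to be real (below the occupancy floor or
        # supported by fewer than ~2 frames)
        keep = (best.occupancy >= prune_occupancy) & (best.occupancy * len(x) >= 2.0)
        if not keep.any():
            return best
        if keep.all():
            # merge unresolvable adjacent levels (same emission state split
            # in two); the noise SD, not the fitted state SD, defines
            # resolvability -- fitted SDs inflate when a state spans levels
            gaps = np.diff(best.means)
            close = gaps < merge_factor * sd0
            if not close.any():
                return best
            i = int(np.argmin(gaps))
            w = best.occupancy[[i, i + 1]]
            merged = float(np.average(best.means[[i, i + 1]], weights=w))
            init_means = np.concatenate(
                [best.means[:i], [merged], best.means[i + 2:]]
            )
            k -= 1
        else:
            k = int(keep.sum())
            init_means = best.means[keep]


def viterbi_path(fit: HmmFit, values: np.ndarray, molecule_id: str = "",
                 frame_interval: float = 0.1) -> IdealizedTrace:
    """Globally most probable state path under the fitted model."""
    x = np.asarray(values, dtype=float)
    logb = (
        -0.5 * ((x[:, None] - fit.means[None, :]) / fit.sds[None, :]) ** 2
        - np.log(fit.sds[None, :])
        - 0.5 * np.log(2 * np.pi)
    )
    path, logp = _viterbi(
        logb,
        np.log(np.maximum(fit.transmat, 1e-300)),
        np.log(np.maximum(fit.startprob, 1e-300)),
    )
    return IdealizedTrace(
        molecule_id=molecule_id,
        states=path,
        levels=fit.means[path],
        log_joint=float(logp),
        fit=fit,
        frame_interval=frame_interval,
    )


# --------------------------------------------------------------------------
# dwell extraction
# --------------------------------------------------------------------------

def _rle(labels: np.ndarray) -> list[list]:
    """Run-length encode to [label, length] pairs."""
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append([int(labels[start]), i - start])
            start = i
    return runs


def merge_short_runs(labels: np.ndarray, min_dwell_frames: int = 2) -> np.ndarray:
    """Absorb runs shorter than the minimum dwell into the longer flanking run.

    Single-frame blips between identical states vanish entirely; a short run
    between two different states is assigned to whichever neighbor is longer
    (ties go to the earlier run).  Applied iteratively, shortest runs first,
    until every surviving run meets the minimum.
    """
    labels = np.asarray(labels).copy()
    if min_dwell_frames <= 1:
        return labels
    runs = _rle(labels)
    while len(runs) > 1:
        lengths = [r[1] for r in runs]
        shortest = min(lengths)
        if shortest >= min_dwell_frames:
            break
        idx = lengths.index(shortest)
        if idx == 0:
            runs[0][0] = runs[1][0]
        elif idx == len(runs) - 1:
            runs[idx][0] = runs[idx - 1][0]
        else:
            left, right = runs[idx - 1], runs[idx + 1]
            runs[idx][0] = left[0] if left[1] >= right[1] else right[0]
        # merge now-adjacent equal-label runs
        merged = [runs[0]]
        for lab, ln in runs[1:]:
            if lab == merged[-1][0]:
                merged[-1][1] += ln
            else:
                merged.append([lab, ln])
        runs = merged
    out = np.empty(len(labels), dtype=labels.dtype)
    pos = 0
    for lab, ln in runs:
        out[pos:pos + ln] = lab
        pos += ln
    return out


def extract_dwells(
    labels: np.ndarray,
    levels: np.ndarray | None = None,
    frame_interval: float = 0.1,
    min_dwell_frames: int = 2,
    molecule_id: str = "",
) -> tuple[list[DwellRecord], np.ndarray]:
    """Completed dwells (and their exit transitions) from an idealized path.

    Runs shorter than ``min_dwell_frames`` are first merged into the flanking
    state.  The first and last dwell of the trace are censored: the molecule
    was already in its first state when observation began and still in its
    last when it bleached, so neither duration is complete.  Each returned
    record is one completed dwell together with the transition that ends it
    (mean fitted intensity before/after, for transition-density plotting).

    Returns ``(dwells, filtered_labels)``.
    """
    labels = np.asarray(labels)
    filtered = merge_short_runs(labels, min_dwell_frames)
    if levels is None:
        levels = filtered.astype(float)
    runs = _rle(filtered)
    dwells: list[DwellRecord] = []
    if len(runs) >= 3:
        # frame offsets of each run
        starts = np.cumsum([0] + [ln for _, ln in runs[:-1]])
        for i in range(1, len(runs) - 1):
            lab, ln = runs[i]
            nxt_lab, nxt_ln = runs[i + 1]
            s = starts[i]
            before = float(np.mean(levels[s:s + ln]))
            after = float(np.mean(levels[starts[i + 1]:starts[i + 1] + nxt_ln]))
            dwells.append(
                DwellRecord(
                    molecule_id=molecule_id,
                    state=int(lab),
                    duration_s=ln * frame_interval,
                    exit_state=int(nxt_lab),
                    intensity_before=before,
                    intensity_after=after,
                )
            )
    return dwells, filtered
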