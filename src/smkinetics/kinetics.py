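"""Dwell-time kinetics: exponential mixture fits, rates and occupancy times.

Completed dwells are partitioned by transition class (state i exited to state
j), binned with the Freedman-Diaconis rule, and fit with both a
mono-exponential ``A exp(-k x)`` and a bi-exponential
``A1 exp(-k1 x) + A2 exp(-k2 x)`` by weighted least squares with Poisson bin
errors.  Reduced chi-squared selects the model (bi-exponential must improve
by a margin and be non-degenerate).  When the bi-exponential wins, the two
rates are amplitude-averaged via ``1/k = a1/k1 + a2/k2`` with a1 + a2 = 1.
Equilibrium rate-constant ratios ``k_eq(i,j) = k(i->j)/k(j->i)`` carry
first-order propagated SDs; mean occupancy times are arithmetic means of
completed dwells pooled over exit classes, with SEM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import chi2

__all__ = [
    "DwellSet",
    "ExpFitResult",
    "RateSummary",
    "fd_bin_width",
    "fit_exponentials",
    "select_model",
    "weighted_rate",
    "keq_ratio",
    "mean_occupancy",
    "analyze_dwell_classes",
]


class DwellDataError(ValueError):
    pass


@dataclass
class DwellSet:
    """Dwell durations for one transition class (state -> exit_state)."""

    state: int
    exit_state: int
    durations: np.ndarray

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, dtype=float)
        if np.any(self.durations <= 0):
            raise DwellDataError("dwell durations must be > 0")

    @property
    def n(self) -> int:
        return len(self.durations)

    @property
    def iqr(self) -> float:
        q1, q3 = np.percentile(self.durations, [25, 75])
        return float(q3 - q1)


@dataclass
class _SingleFit:
    params: np.ndarray        # mono: (A, k); bi: (A1, k1, A2, k2), k1 >= k2
    covariance: np.ndarray
    reduced_chisq: float
    dof: int
    degenerate: bool = False

    @property
    def chisq(self) -> float:
        return self.reduced_chisq * self.dof


@dataclass
class ExpFitResult:
    mono: _SingleFit
    bi: _SingleFit | None     # None when too few dwells / unfittable
    n: int
    bin_width: float
    chosen: str = "mono"      # set by select_model

    @property
    def amplitude_fractions(self) -> np.ndarray | None:
        """Normalized bi-exponential amplitudes (a1 + a2 = 1)."""
        if self.bi is None:
            return None
        A1, _, A2, _ = self.bi.params
        tot = A1 + A2
        return np.array([A1 / tot, A2 / tot])


def fd_bin_width(durations: np.ndarray) -> float:
    """Freedman-Diaconis bin width, 2*IQR/n^(1/3).

    Quartiles use linear interpolation between order statistics.  When the
    IQR is zero (all durations equal up to ties), the fallback width is
    ``range/sqrt(n)``; if the range is also zero the width defaults to one
    representative duration so a single-bin histogram remains well defined.
    """
    x = np.asarray(durations, dtype=float)
    n = len(x)
    if n < 4:
        raise DwellDataError("need >= 4 dwells for a binned fit; pool classes")
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    if iqr > 0:
        return float(2.0 * iqr / n ** (1.0 / 3.0))
    rng = float(np.ptp(x))
    if rng > 0:
        return float(rng / np.sqrt(n))
    return float(x[0])


def _bin_dwells(x: np.ndarray, width: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    lo = x.min()
    n_bins = max(int(np.ceil((x.max() - lo) / width)), 1) + 1
    edges = lo + np.arange(n_bins + 1) * width
    counts, _ = np.histogram(x, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    sigma = np.sqrt(np.maximum(counts, 1.0))
    return centers, counts.astype(float), sigma


def _mono(x, A, k):
    return A * np.exp(-k * x)


def _bi(x, A1, k1, A2, k2):
    return A1 * np.exp(-k1 * x) + A2 * np.exp(-k2 * x)


def fit_exponentials(
    dwells: DwellSet,
    min_mono: int = 10,
    min_bi: int = 25,
    degenerate_rate_tol: float = 0.05,
    degenerate_amp_tol: float = 0.02,
) -> ExpFitResult:
    """Fit mono- and bi-exponential decays to the binned dwell histogram.

    Bins are Freedman-Diaconis; weights are Poisson (sqrt of the count, with
    empty bins given unit error).  The bi-exponential is attempted only with
    at least ``min_bi`` dwells and is declared degenerate when its two rates
    agree within ``degenerate_rate_tol`` (relative) or either normalized
    amplitude falls below ``degenerate_amp_tol``.
    """
    x = dwells.durations
    if dwells.n < min_mono:
        raise DwellDataError(f"need >= {min_mono} dwells, got {dwells.n}")
    width = fd_bin_width(x)
    centers, counts, sigma = _bin_dwells(x, width)
    if len(centers) < 3:
        # resolution floor: split into enough bins for a 2-parameter fit
        width = float(np.ptp(x)) / 4 if np.ptp(x) > 0 else width
        centers, counts, sigma = _bin_dwells(x, max(width, 1e-9))

    k0 = 1.0 / max(float(np.mean(x) - x.min()), 1e-9)
    A0 = float(counts.max())

    popt, pcov = curve_fit(
        _mono, centers, counts, p0=[A0, k0], sigma=sigma, absolute_sigma=True,
        bounds=([0.0, 1e-9], [np.inf, 1e6]), maxfev=20000,
    )
    dof_m = max(len(centers) - 2, 1)
    red_m = float((((counts - _mono(centers, *popt)) / sigma) ** 2).sum() / dof_m)
    mono = _SingleFit(params=popt, covariance=pcov, reduced_chisq=red_m, dof=dof_m)

    bi: _SingleFit | None = None
    if dwells.n >= min_bi and len(centers) >= 5:
        try:
            p0 = [0.7 * A0, 3.0 * k0, 0.3 * A0, 0.3 * k0]
            popt2, pcov2 = curve_fit(
                _bi, centers, counts, p0=p0, sigma=sigma, absolute_sigma=True,
                bounds=([0.0, 1e-9, 0.0, 1e-9], [np.inf, 1e6, np.inf, 1e6]),
                maxfev=40000,
            )
            if popt2[1] < popt2[3]:  # enforce k1 >= k2 (fast component first)
                popt2 = np.array([popt2[2], popt2[3], popt2[0], popt2[1]])
                perm = [2, 3, 0, 1]
                pcov2 = pcov2[np.ix_(perm, perm)]
            dof_b = max(len(centers) - 4, 1)
            red_b = float((((counts - _bi(centers, *popt2)) / sigma) ** 2).sum() / dof_b)
            A1, k1, A2, k2 = popt2
            amp_frac = min(A1, A2) / max(A1 + A2, 1e-300)
            degenerate = (
                abs(k1 - k2) / max(k1, 1e-300) < degenerate_rate_tol
                or amp_frac < degenerate_amp_tol
            )
            bi = _SingleFit(params=popt2, covariance=pcov2, reduced_chisq=red_b,
                            dof=dof_b, degenerate=degenerate)
        except RuntimeError:
            bi = None
    return ExpFitResult(mono=mono, bi=bi, n=dwells.n, bin_width=width)


def select_model(result: ExpFitResult, improvement: float = 0.10,
                 significance: float = 0.01) -> str:
    """Parsimonious reduced-chi-squared model selection.

    The bi-exponential is chosen only when it is available, non-degenerate,
    lowers the reduced chi-squared by more than ``improvement`` relative to
    the mono-exponential, and its absolute chi-squared drop is significant
    for the 2 extra parameters (nested-model test at ``significance``);
    ties and everything else go to mono.  The significance guard keeps small
    head/tail distortions of a genuinely single-exponential dwell histogram
    from promoting a 4-parameter model.
    """
    result.chosen = "mono"
    if result.bi is not None and not result.bi.degenerate:
        m, b = result.mono.reduced_chisq, result.bi.reduced_chisq
        dchi = result.mono.chisq - result.bi.chisq
        crit = chi2.ppf(1.0 - significance, 2)
        if m > 0 and (m - b) / m > improvement and dchi > crit:
            result.chosen = "bi"
    return result.chosen


def weighted_rate(result: ExpFitResult) -> tuple[float, float]:
    """Amplitude-weighted rate constant of the chosen model, with SD.

    Mono: k directly.  Bi: 1/k = a1/k1 + a2/k2 with a_i the normalized
    amplitude fractions (a1 + a2 = 1); the SD comes from first-order
    propagation of the fit covariance through that reduction.
    """
    if result.chosen == "mono" or result.bi is None:
        k = float(result.mono.params[1])
        sd = float(np.sqrt(max(result.mono.covariance[1, 1], 0.0)))
        return k, sd
    A1, k1, A2, k2 = result.bi.params

    def kbar(p):
        a1 = p[0] / (p[0] + p[2])
        a2 = p[2] / (p[0] + p[2])
        return 1.0 / (a1 / p[1] + a2 / p[3])

    p = np.array([A1, k1, A2, k2])
    k = float(kbar(p))
    grad = np.empty(4)
    for i in range(4):
        h = max(1e-7 * abs(p[i]), 1e-10)
        pp, pm = p.copy(), p.copy()
        pp[i] += h
        pm[i] -= h
        grad[i] = (kbar(pp) - kbar(pm)) / (2 * h)
    var = float(grad @ result.bi.covariance @ grad)
    return k, float(np.sqrt(max(var, 0.0)))


def keq_ratio(
    k_ij: float, sd_ij: float, k_ji: float, sd_ji: float
) -> tuple[float, float]:
    """k_eq(i,j) = k(i->j)/k(j->i) with first-order propagated SD."""
    if k_ij <= 0 or k_ji <= 0:
        raise DwellDataError("rate constants must be > 0")
    r = k_ij / k_ji
    sd = r * np.sqrt((sd_ij / k_ij) ** 2 + (sd_ji / k_ji) ** 2)
    return float(r), float(sd)


def mean_occupancy(durations: np.ndarray) -> tuple[float, float | None]:
    """Arithmetic mean of completed dwells in a state, with SEM.

    SEM is ``None`` when only one dwell is available.
    """
    x = np.asarray(durations, dtype=float)
    if len(x) == 0:
        raise DwellDataError("no completed dwells in state")
    mean = float(np.mean(x))
    if len(x) < 2:
        return mean, None
    sem = float(np.std(x, ddof=1) / np.sqrt(len(x)))
    return mean, sem


@dataclass
class RateSummary:
    """Per-class rates, equilibrium ratios and per-state occupancy times."""

    classes: dict[tuple[int, int], dict]          # (i, j) -> fit summary
    keq: dict[tuple[int, int], tuple[float, float]]
    occupancy: dict[int, tuple[float, float | None]]


def analyze_dwell_classes(
    dwell_table,
    n_states: int,
    min_mono: int = 10,
    min_bi: int = 25,
    improvement: float = 0.10,
) -> RateSummary:
    """Full dwell-kinetics stage on a dwell table.

    ``dwell_table`` is a pandas DataFrame with columns ``state``,
    ``exit_state``, ``duration_s`` (1-based states).  Rates are fit per
    ordered class; k_eq is computed for consecutive state pairs; mean
    occupancy pools a state's dwells over all exit classes.
    """
    classes: dict[tuple[int, int], dict] = {}
    rates: dict[tuple[int, int], tuple[float, float]] = {}
    for (i, j), grp in dwell_table.groupby(["state", "exit_state"]):
        dur = grp["duration_s"].to_numpy()
        entry: dict = {"n": len(dur)}
        if len(dur) >= min_mono:
            ds = DwellSet(state=int(i), exit_state=int(j), durations=dur)
            res = fit_exponentials(ds, min_mono=min_mono, min_bi=min_bi)
            select_model(res, improvement=improvement)
            k, sd = weighted_rate(res)
            entry.update(
                model=res.chosen,
                k=k,
                k_sd=sd,
                reduced_chisq_mono=res.mono.reduced_chisq,
                reduced_chisq_bi=res.bi.reduced_chisq if res.bi else None,
                amplitude_fractions=(
                    res.amplitude_fractions.tolist() if res.bi is not None else None
                ),
                bi_rates=(res.bi.params[[1, 3]].tolist() if res.bi is not None else None),
            )
            rates[(int(i), int(j))] = (k, sd)
        else:
            entry.update(model=None, k=None, k_sd=None)
        classes[(int(i), int(j))] = entry

    keq: dict[tuple[int, int], tuple[float, float]] = {}
    for i in range(1, n_states):
        fwd, rev = (i, i + 1), (i + 1, i)
        if fwd in rates and rev in rates:
            keq[fwd] = keq_ratio(*rates[fwd], *rates[rev])

    occupancy: dict[int, tuple[float, float | None]] = {}
    for s, grp in dwell_table.groupby("state"):
        occupancy[int(s)] = mean_occupancy(grp["duration_s"].to_numpy())

    return RateSummary(classes=classes, keq=keq, occupancy=occupancy)
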