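"""Population histograms of normalized intensity and multipeak Gaussian fits.

All pre-bleach frames of the dynamic traces are pooled into one histogram.
The histogram is fit with a sum of Gaussian peaks plus a flat baseline,

    y(x) = y0 + sum_i A_i * exp(-((x - mu_i) / sigma_i)^2),

with peak centers initialized at the TDP consensus levels and allowed to move
only within a small window, while amplitudes, widths and the baseline are
free.  Note the exponent has no factor 2, so the analytic area of peak i is
``A_i * sigma_i * sqrt(pi)``; fractional areas estimate the fractional state
populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "PopulationHistogram",
    "GaussianPeakFit",
    "compile_histogram",
    "fit_multipeak",
    "peak_areas",
    "gaussian_area",
]


class FitError(RuntimeError):
    pass


@dataclass
class PopulationHistogram:
    edges: np.ndarray
    counts: np.ndarray
    se: np.ndarray            # per-bin standard error on the count
    n_frames: int
    n_molecules: int

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    def fractions(self) -> np.ndarray:
        return self.counts / self.counts.sum()


@dataclass
class GaussianPeakFit:
    y0: float
    amplitudes: np.ndarray
    centers: np.ndarray
    widths: np.ndarray
    reduced_chisq: float
    covariance: np.ndarray
    n_bins: int

    @property
    def n_peaks(self) -> int:
        return len(self.amplitudes)

    def model(self, x: np.ndarray) -> np.ndarray:
        return _multipeak(x, self.y0, *np.ravel(
            np.column_stack([self.amplitudes, self.centers, self.widths])
        ))


def compile_histogram(
    values_per_molecule: list[np.ndarray],
    bin_width: float = 0.05,
    bounds: tuple[float, float] | None = None,
    se_method: str = "bootstrap",
    n_boot: int = 200,
    seed: int = 0,
) -> PopulationHistogram:
    """Pool frames across molecules into a binned intensity histogram.

    Per-bin standard errors come from a molecule-level bootstrap by default
    (frames within one molecule are strongly autocorrelated, so resampling
    molecules, not frames, is the honest error model).  ``se_method=
    "multinomial"`` gives the naive frame-level SE
    ``sqrt(N p_b (1 - p_b))`` instead, which is a lower bound.
    """
    arrays = [np.asarray(v, dtype=float) for v in values_per_molecule if len(v)]
    if not arrays:
        raise ValueError("no frames to histogram")
    pooled = np.concatenate(arrays)
    if bounds is None:
        lo = np.floor(pooled.min() / bin_width) * bin_width
        hi = np.ceil(pooled.max() / bin_width) * bin_width
    else:
        lo, hi = bounds
    n_bins = max(int(round((hi - lo) / bin_width)), 1)
    edges = lo + np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(pooled, bins=edges)
    N = counts.sum()
    if se_method == "bootstrap" and len(arrays) < 2:
        se_method = "multinomial"  # bootstrap needs molecules to resample
    if se_method == "multinomial":
        p = counts / N
        se = np.sqrt(N * p * (1.0 - p))
    elif se_method == "bootstrap":
        per_mol = np.stack([np.histogram(v, bins=edges)[0] for v in arrays])
        rng = np.random.default_rng(seed)
        M = len(arrays)
        reps = np.empty((n_boot, n_bins))
        for b in range(n_boot):
            idx = rng.integers(0, M, size=M)
            reps[b] = per_mol[idx].sum(axis=0)
        se = reps.std(axis=0, ddof=1)
    else:
        raise ValueError(f"unknown se_method: {se_method}")
    return PopulationHistogram(
        edges=edges,
        counts=counts.astype(float),
        se=se,
        n_frames=int(N),
        n_molecules=len(arrays),
    )


def _multipeak(x, y0, *params):
    y = np.full_like(np.asarray(x, dtype=float), float(y0))
    for i in range(0, len(params), 3):
        A, mu, sig = params[i], params[i + 1], params[i + 2]
        y = y + A * np.exp(-(((x - mu) / sig) ** 2))
    return y


def fit_multipeak(
    hist: PopulationHistogram,
    centers: np.ndarray,
    center_window: float = 0.15,
    sigma_bounds: tuple[float, float] = (0.05, 0.5),
) -> GaussianPeakFit:
    """Weighted least-squares multipeak Gaussian fit with anchored centers.

    Peak centers start at the TDP consensus levels and may vary within
    ``+/- center_window``; amplitudes are non-negative, widths bounded to
    avoid peak-swallowing degeneracies, and the baseline is free.  Bins are
    weighted by 1/SE^2 (zero-SE bins get the median positive SE).  The
    reduced chi-squared uses ``n_bins - (3 n_peaks + 1)`` degrees of freedom.
    """
    centers = np.sort(np.asarray(centers, dtype=float))
    n_peaks = len(centers)
    x = hist.centers
    y = hist.counts
    se = hist.se.copy()
    pos = se[se > 0]
    if pos.size == 0:
        raise FitError("all-zero histogram")
    se[se <= 0] = np.median(pos)

    p0 = [0.0]
    lower = [-np.inf]
    upper = [np.inf]
    for mu in centers:
        a0 = max(float(np.interp(mu, x, y)), 1.0)
        p0 += [a0, mu, 0.15]
        lower += [0.0, mu - center_window, sigma_bounds[0]]
        upper += [np.inf, mu + center_window, sigma_bounds[1]]
    try:
        popt, pcov = curve_fit(
            _multipeak, x, y, p0=p0, sigma=se, absolute_sigma=True,
            bounds=(lower, upper), maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"multipeak fit did not converge: {exc}") from exc
    resid = (y - _multipeak(x, *popt)) / se
    dof = max(len(x) - len(popt), 1)
    redchi = float((resid**2).sum() / dof)
    A = popt[1::3]
    mu = popt[2::3]
    sig = popt[3::3]
    order = np.argsort(mu)
    # reorder covariance blocks along with the peaks
    idx = np.concatenate([[0], np.concatenate([[1 + 3 * o + k for k in range(3)]
                                               for o in order])]).astype(int)
    return GaussianPeakFit(
        y0=float(popt[0]),
        amplitudes=A[order],
        centers=mu[order],
        widths=sig[order],
        reduced_chisq=redchi,
        covariance=pcov[np.ix_(idx, idx)],
        n_bins=len(x),
    )


def gaussian_area(amplitude: float, width: float) -> float:
    """Analytic area of one peak of the form A*exp(-((x-mu)/sigma)^2)."""
    return float(amplitude * width * np.sqrt(np.pi))


def peak_areas(fit: GaussianPeakFit) -> tuple[np.ndarray, np.ndarray]:
    """Fractional peak areas and their first-order-propagated SDs.

    area_i = A_i * sigma_i * sqrt(pi); fraction_i = area_i / sum_j area_j.
    Uncertainties use the delta method on the fit covariance of
    (A_1, sigma_1, ..., A_n, sigma_n).
    """
    A = fit.amplitudes
    S = fit.widths
    areas = A * S * np.sqrt(np.pi)
    total = areas.sum()
    fractions = areas / total
    # gradient of fraction_i wrt (A_j, sigma_j)
    n = fit.n_peaks
    params = np.empty(2 * n)
    grad = np.zeros((n, 2 * n))
    for i in range(n):
        for j in range(n):
            d_area_j = (np.eye(n)[i, j] * total - areas[i]) / total**2
            grad[i, 2 * j] = d_area_j * S[j] * np.sqrt(np.pi)
            grad[i, 2 * j + 1] = d_area_j * A[j] * np.sqrt(np.pi)
    # covariance of (A_j, sigma_j) pairs pulled from the full fit covariance
    idx = []
    for j in range(n):
        idx += [1 + 3 * j, 1 + 3 * j + 2]
    sub = fit.covariance[np.ix_(idx, idx)]
    var = np.einsum("ip,pq,iq->i", grad, sub, grad)
    sds = np.sqrt(np.maximum(var, 0.0))
    return fractions, sds
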