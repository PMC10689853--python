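"""Transition density plots (TDPs) and consensus state assignment.

A TDP is the 2-D kernel density of (intensity before, intensity after) over
all detected transitions, pooled across molecules.  Off-diagonal clusters
identify exchanging state pairs; the marginal positions of paired maxima give
consensus emission levels, which in turn define the intensity cutoffs used to
classify transitions and to anchor the population-histogram fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "TdpDensity",
    "StateCutoffs",
    "build_tdp",
    "find_peak_centers",
    "define_cutoffs",
    "assign_state",
    "classify_transitions",
]


class EmptyTdpError(ValueError):
    """No transition events: a TDP cannot be built."""


class PeakCountError(ValueError):
    """Fewer density clusters than requested states."""


@dataclass
class TdpDensity:
    grid: np.ndarray          # 1-D grid shared by both axes
    density: np.ndarray       # (G, G), rows = initial intensity, cols = final
    bandwidth: float
    n_transitions: int
    diagonal_halfwidth: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.density, index=self.grid, columns=self.grid)


@dataclass
class StateCutoffs:
    centers: np.ndarray       # consensus emission level per state, ascending
    boundaries: np.ndarray    # midpoints between adjacent centers

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        if len(self.centers) > 1 and not np.all(np.diff(self.centers) > 0):
            raise ValueError("centers must be strictly increasing")
        for b, lo, hi in zip(self.boundaries, self.centers[:-1], self.centers[1:]):
            if not (lo < b < hi):
                raise ValueError("each boundary must lie between adjacent centers")

    @property
    def n_states(self) -> int:
        return len(self.centers)


def build_tdp(
    initial: np.ndarray,
    final: np.ndarray,
    grid_step: float = 0.02,
    bandwidth: float = 0.08,
    bounds: tuple[float, float] = (0.5, 3.5),
    diagonal_halfwidth: float = 0.2,
) -> TdpDensity:
    """Gaussian-kernel density of transition events on a fixed grid.

    The near-diagonal band (|initial - final| < ``diagonal_halfwidth``) is
    zeroed: self-transitions do not exist after idealization, so any mass
    there is kernel leakage from genuine off-diagonal events.  The density
    integrates to 1 over the grid.
    """
    initial = np.asarray(initial, dtype=float)
    final = np.asarray(final, dtype=float)
    if initial.size == 0:
        raise EmptyTdpError("no transition events")
    if initial.shape != final.shape:
        raise ValueError("initial/final length mismatch")
    lo, hi = bounds
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    # separable kernels: density = sum_e gx(e) outer gy(e)
    gx = np.exp(-0.5 * ((grid[None, :] - initial[:, None]) / bandwidth) ** 2)
    gy = np.exp(-0.5 * ((grid[None, :] - final[:, None]) / bandwidth) ** 2)
    density = gx.T @ gy
    xx, yy = np.meshgrid(grid, grid, indexing="ij")
    density[np.abs(xx - yy) < diagonal_halfwidth] = 0.0
    total = density.sum() * grid_step**2
    if total <= 0:
        raise EmptyTdpError("all transition density fell in the excluded band")
    density /= total
    return TdpDensity(
        grid=grid,
        density=density,
        bandwidth=bandwidth,
        n_transitions=int(initial.size),
        diagonal_halfwidth=diagonal_halfwidth,
    )


def find_peak_centers(
    tdp: TdpDensity,
    n_states: int,
    rel_threshold: float = 0.05,
    gap: float = 0.4,
) -> np.ndarray:
    """Consensus emission levels from the TDP's local maxima.

    Local density maxima above ``rel_threshold`` of the global maximum are
    located; their x and y coordinates are pooled (a transition i->j and its
    reverse j->i contribute the same pair of levels) and clustered in 1-D by
    splitting at gaps wider than ``gap`` normalized units.  The
    density-weighted mean of each of the ``n_states`` heaviest clusters is a
    state center; centers are returned ascending.
    """
    d = tdp.density
    local_max = (d == ndimage.maximum_filter(d, size=5)) & (d > rel_threshold * d.max())
    ix, iy = np.nonzero(local_max)
    if ix.size == 0:
        raise PeakCountError("no density peaks found")
    coords = np.concatenate([tdp.grid[ix], tdp.grid[iy]])
    weights = np.concatenate([d[ix, iy], d[ix, iy]])
    order = np.argsort(coords)
    coords, weights = coords[order], weights[order]
    clusters: list[tuple[float, float]] = []  # (weighted mean, total weight)
    start = 0
    for i in range(1, len(coords) + 1):
        if i == len(coords) or coords[i] - coords[i - 1] > gap:
            w = weights[start:i]
            c = coords[start:i]
            clusters.append((float(np.average(c, weights=w)), float(w.sum())))
            start = i
    if len(clusters) < n_states:
        raise PeakCountError(
            f"found {len(clusters)} state level(s); reduce n_states below {n_states}"
        )
    clusters.sort(key=lambda cw: -cw[1])
    centers = np.sort([c for c, _ in clusters[:n_states]])
    return centers


def define_cutoffs(centers: np.ndarray) -> StateCutoffs:
    """Boundaries between adjacent states at the midpoint of their centers."""
    centers = np.sort(np.asarray(centers, dtype=float))
    if len(centers) < 2:
        raise ValueError("need at least 2 centers to define cutoffs")
    boundaries = 0.5 * (centers[:-1] + centers[1:])
    return StateCutoffs(centers=centers, boundaries=boundaries)


def assign_state(values: np.ndarray, cutoffs: StateCutoffs) -> np.ndarray:
    """1-based state labels by boundary bins; a value ON a boundary goes to
    the lower state (deterministic tie-break)."""
    return np.searchsorted(cutoffs.boundaries, np.asarray(values, dtype=float),
                           side="left") + 1


def classify_transitions(
    initial: np.ndarray, final: np.ndarray, cutoffs: StateCutoffs
) -> pd.DataFrame:
    """Per-class transition counts and fractions.

    Each event is assigned a (from, to) class by which side of each boundary
    its initial/final intensities fall.  Returns one row per ordered class
    with columns ``from_state, to_state, count, fraction``; fractions sum to 1
    exactly.  The direct 1<->3 share is ``one_three_fraction``.
    """
    initial = np.asarray(initial, dtype=float)
    final = np.asarray(final, dtype=float)
    if initial.size == 0:
        raise EmptyTdpError("no transition events to classify")
    fr = assign_state(initial, cutoffs)
    to = assign_state(final, cutoffs)
    n = cutoffs.n_states
    rows = []
    total = len(fr)
    for i in range(1, n + 1):
        for j in range(1, n + 1):
            if i == j:
                continue
            count = int(((fr == i) & (to == j)).sum())
            rows.append({"from_state": i, "to_state": j, "count": count,
                         "fraction": count / total})
    same = int((fr == to).sum())
    if same:
        rows.append({"from_state": 0, "to_state": 0, "count": same,
                     "fraction": same / total})
    return pd.DataFrame(rows)


def one_three_fraction(classes: pd.DataFrame) -> float:
    """Share of events classified as direct transitions between states 1 and 3."""
    sel = classes[
        ((classes.from_state == 1) & (classes.to_state == 3))
        | ((classes.from_state == 3) & (classes.to_state == 1))
    ]
    return float(sel["fraction"].sum())
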