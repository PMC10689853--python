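"""Trace containers, tabular I/O, photobleach detection and normalization.

Traces are stored in long-form delimited text (CSV or TSV, auto-detected)
with columns ``molecule_id``, ``time_s``, ``intensity`` plus optional
condition columns.  Analysis operates on the pre-bleach segment of each trace
after normalizing intensities so that the lowest-intensity emission state
sits at 1.0.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "Trace",
    "TraceSet",
    "BleachResult",
    "read_traces",
    "write_traces",
    "detect_photobleach",
    "normalize_trace",
    "estimate_state1_mean",
    "classify_dynamic",
]

SPACING_TOL = 1e-6  # allowed jitter in frame spacing, seconds


class TraceFormatError(ValueError):
    pass


@dataclass
class Trace:
    """One molecule's framewise intensity series."""

    molecule_id: str
    times: np.ndarray
    intensities: np.ndarray
    condition: dict = field(default_factory=dict)
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.times) != len(self.intensities):
            raise TraceFormatError("times and intensities length mismatch")
        if len(self.times) < 2:
            raise TraceFormatError("a trace needs at least 2 frames")
        dts = np.diff(self.times)
        if np.ptp(dts) > SPACING_TOL:
            raise TraceFormatError(
                f"non-uniform frame spacing for {self.molecule_id}"
            )

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def frame_interval(self) -> float:
        return float(np.median(np.diff(self.times)))


@dataclass
class TraceSet:
    traces: list[Trace] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)
    selection_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [t.molecule_id for t in self.traces]
        if len(set(ids)) != len(ids):
            raise TraceFormatError("molecule_ids must be unique")

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)

    def log(self, molecule_id: str, accepted: bool, reason: str) -> None:
        self.selection_log.append(
            {"molecule_id": molecule_id, "accepted": accepted, "reason": reason}
        )

    def selection_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.selection_log, columns=["molecule_id", "accepted", "reason"]
        )


REQUIRED_COLUMNS = ("molecule_id", "time_s", "intensity")


def read_traces(path: str | os.PathLike, sep: str | None = None) -> TraceSet:
    """Read a long-form trace table, grouping rows by molecule.

    Malformed traces (non-numeric values, non-uniform spacing, fewer than two
    frames) are rejected individually and recorded in the selection log with
    a reason code; well-formed traces are returned time-sorted.
    """
    path = os.fspath(path)
    if sep is None:
        sep = "\t" if path.endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"missing required column(s): {missing}")
    extra = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    ts = TraceSet(provenance={"source": path})
    for mol, grp in df.groupby("molecule_id", sort=True):
        grp = grp.sort_values("time_s")
        times = pd.to_numeric(grp["time_s"], errors="coerce").to_numpy()
        vals = pd.to_numeric(grp["intensity"], errors="coerce").to_numpy()
        if np.isnan(times).any() or np.isnan(vals).any():
            ts.log(str(mol), False, "non_numeric_value")
            continue
        condition = {}
        for c in extra:
            u = grp[c].unique()
            condition[c] = u[0] if len(u) == 1 else list(u)
        try:
            tr = Trace(str(mol), times, vals, condition=condition)
        except TraceFormatError as exc:
            reason = "non_uniform_spacing" if "spacing" in str(exc) else "too_short"
            ts.log(str(mol), False, reason)
            continue
        ts.traces.append(tr)
        ts.log(str(mol), True, "ok")
    return ts


def write_traces(traces: TraceSet, path: str | os.PathLike, sep: str | None = None) -> None:
    path = os.fspath(path)
    if sep is None:
        sep = "\t" if path.endswith((".tsv", ".tab")) else ","
    frames = []
    for tr in traces:
        d = {"molecule_id": tr.molecule_id, "time_s": tr.times, "intensity": tr.intensities}
        for k, v in tr.condition.items():
            d[k] = v
        frames.append(pd.DataFrame(d))
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)


@dataclass
class BleachResult:
    frame: int | None  # first fully-bleached frame; None = censored
    multistep: bool = False

    @property
    def censored(self) -> bool:
        return self.frame is None


def _noise_sd(values: np.ndarray) -> float:
    """Robust per-frame noise SD from first differences (level changes are sparse)."""
    d = np.diff(values)
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0)) or float(np.std(d) / np.sqrt(2.0)) or 1e-12


def detect_photobleach(
    trace: Trace, baseline_sd_mult: float = 3.0, window: int = 5, min_tail: int = 5
) -> BleachResult:
    """Locate a terminal single-step drop to the dark baseline.

    A running median must fall below ``tail_level + mult * noise_sd`` for the
    remainder of the trace, and the implied baseline must sit clearly below
    the typical pre-drop signal (guarding against a final dwell in the lowest
    emission state masquerading as a bleach).  Traces showing an additional
    sustained low plateau before the terminal drop are flagged as multi-step.
    """
    x = trace.intensities
    if len(x) < 10:
        return BleachResult(None)
    smooth = ndimage.median_filter(x, size=window, mode="nearest")
    sigma = _noise_sd(x)
    tail_level = float(np.median(smooth[-max(min_tail, 10):]))
    # single-step photobleaching means the molecule goes dark: the terminal
    # level must be consistent with the (background-subtracted) zero baseline,
    # or a final dwell in the lowest emission state would look like a bleach
    if abs(tail_level) > baseline_sd_mult * sigma:
        return BleachResult(None)
    threshold = tail_level + baseline_sd_mult * sigma
    above = smooth > threshold
    if not above.any():
        return BleachResult(None)  # never clearly above baseline: unusable
    last_above = int(np.nonzero(above)[0][-1])
    bleach_frame = last_above + 1
    if len(x) - bleach_frame < min_tail:
        return BleachResult(None)  # no sustained dark tail: censored
    pre = smooth[:bleach_frame]
    q25 = float(np.percentile(pre, 25))
    if threshold >= q25:
        # the "baseline" is not clearly below the signal levels
        return BleachResult(None)
    # multi-step guard: a sustained pre-drop plateau below the lowest
    # emission level (approximated by the 5th percentile; genuine state
    # dwells never sit below it) indicates an extra bleach step
    p05 = float(np.percentile(pre, 5))
    low = pre < p05 - 4.0 * sigma
    multistep = False
    if low.any():
        run = 0
        for flag in low:
            run = run + 1 if flag else 0
            if run >= 10:
                multistep = True
                break
    return BleachResult(int(bleach_frame), multistep)


def estimate_state1_mean(values: np.ndarray) -> float:
    """Lower of two 1-D k-means centers: fallback estimate of the state-1 level."""
    x = np.asarray(values, dtype=float)
    lo, hi = np.percentile(x, [10, 90])
    c = np.array([lo, hi], dtype=float)
    for _ in range(30):
        lab = np.abs(x[:, None] - c[None, :]).argmin(axis=1)
        newc = np.array([x[lab == k].mean() if (lab == k).any() else c[k] for k in range(2)])
        if np.allclose(newc, c):
            break
        c = newc
    return float(c.min())


def normalize_trace(
    trace: Trace, state1_mean: float, bleach_frame: int | None = None
) -> Trace:
    """Divide intensities by the state-1 emission level.

    Only pre-bleach frames are retained (``bleach_frame`` falls back to the
    value stored in ``trace.meta``).  Idempotent when ``state1_mean`` is 1.
    """
    if state1_mean <= 0:
        raise ValueError("state1_mean must be > 0")
    if bleach_frame is None:
        bleach_frame = trace.meta.get("bleach_frame")
    end = int(bleach_frame) if bleach_frame is not None else trace.n_frames
    end = max(end, 2)
    meta = dict(trace.meta)
    meta["state1_mean"] = float(state1_mean)
    meta["bleach_frame"] = bleach_frame
    truth = meta.get("true_frame_states")
    if truth is not None:
        meta["true_frame_states"] = truth[:end]
    return Trace(
        molecule_id=trace.molecule_id,
        times=trace.times[:end],
        intensities=trace.intensities[:end] / float(state1_mean),
        condition=dict(trace.condition),
        normalized=True,
        meta=meta,
    )


def classify_dynamic(labels: np.ndarray) -> bool:
    """A trace is dynamic iff its (minimum-dwell filtered) path still switches state."""
    labels = np.asarray(labels)
    return bool((labels[1:] != labels[:-1]).any())
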