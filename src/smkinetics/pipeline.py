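"""End-to-end orchestration: simulate/load -> select -> idealize -> TDP ->
histogram -> dwell kinetics, with a machine-readable run report.

The stages mirror how single-channel TIRF intensity data are analyzed in
practice: traces showing clean single-step photobleaching are kept, each is
normalized to its lowest emission level, a per-trace HMM idealizes it, pooled
transitions build a TDP whose peak centers define consensus states, the
pooled intensity histogram is fit with center-anchored Gaussians for state
populations, and dwell times per transition class yield rate constants,
equilibrium ratios and mean occupancy times.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .hmm import extract_dwells, fit_hmm, viterbi_path
from .histogram import compile_histogram, fit_multipeak, peak_areas
from .kinetics import analyze_dwell_classes
from .synthetic import REFERENCE_CONFIGS, simulate_dataset
from .tdp import (
    EmptyTdpError,
    StateCutoffs,
    assign_state,
    build_tdp,
    classify_transitions,
    define_cutoffs,
    find_peak_centers,
    one_three_fraction,
)
from .trace_io import (
    Trace,
    TraceSet,
    classify_dynamic,
    detect_photobleach,
    normalize_trace,
    read_traces,
)

__all__ = ["RunConfig", "run_pipeline", "compare_conditions"]

_KNOWN_KEYS = {
    "source", "n_states", "seed", "condition", "out_dir", "n_traces",
    "k_max", "n_restarts", "min_dwell_frames", "baseline_sd_mult",
    "bin_width", "grid_step", "bandwidth", "min_prebleach_frames",
    "improvement", "write_artifacts",
}


@dataclass
class RunConfig:
    """One analysis run: an input source plus analysis parameters.

    ``source`` is either a reference-configuration name (simulated input) or
    a path to a trace table.  ``n_states`` is the number of consensus states
    expected for the condition (2 or 3), as set per experiment.
    """

    source: str
    n_states: int = 2
    seed: int = 42
    condition: str = ""
    out_dir: str | None = None
    n_traces: int | None = None
    k_max: int = 3
    n_restarts: int = 5
    min_dwell_frames: int = 2
    baseline_sd_mult: float = 3.0
    bin_width: float = 0.05
    grid_step: float = 0.02
    bandwidth: float = 0.08
    min_prebleach_frames: int = 20
    improvement: float = 0.10
    write_artifacts: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _acquire(config: RunConfig) -> TraceSet:
    if config.source in REFERENCE_CONFIGS:
        ref = REFERENCE_CONFIGS[config.source]
        return simulate_dataset(ref, seed=config.seed, n_traces=config.n_traces)
    return read_traces(config.source)


def _select_and_idealize(
    traces: TraceSet, config: RunConfig, rng: np.random.Generator
) -> tuple[list[dict], TraceSet]:
    """Bleach-select, normalize and HMM-idealize each trace."""
    per_trace: list[dict] = []
    for tr in traces:
        bleach = detect_photobleach(tr, baseline_sd_mult=config.baseline_sd_mult)
        if bleach.multistep:
            traces.log(tr.molecule_id, False, "multi_step_bleach")
            continue
        if bleach.censored:
            traces.log(tr.molecule_id, False, "no_single_step_bleach")
            continue
        # drop the frame containing the bleach step itself: it integrates a
        # partial dwell and the dark state, giving a spurious low level
        end = bleach.frame - 1
        if end < config.min_prebleach_frames:
            traces.log(tr.molecule_id, False, "too_short_prebleach")
            continue
        pre = tr.intensities[:end]
        fit = fit_hmm(
            pre,
            k_max=config.k_max,
            n_restarts=config.n_restarts,
            seed=np.random.default_rng(rng.integers(2**31)),
        )
        state1_mean = float(fit.means.min())
        if state1_mean <= 0:
            traces.log(tr.molecule_id, False, "nonpositive_state1_level")
            continue
        norm = normalize_trace(tr, state1_mean, bleach_frame=end)
        nfit = fit.rescaled(state1_mean)
        ideal = viterbi_path(
            nfit, norm.intensities, molecule_id=tr.molecule_id,
            frame_interval=tr.frame_interval,
        )
        traces.log(tr.molecule_id, True, "ok")
        per_trace.append({"trace": norm, "fit": nfit, "ideal": ideal})
    return per_trace, traces


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns (and optionally writes) the run report."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xA11CE]))
    traces = _acquire(config)
    n_total = len(traces)
    per_trace, traces = _select_and_idealize(traces, config, rng)

    report: dict[str, Any] = {
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "condition": config.condition or config.source,
        "status": "ok",
    }

    # --- pooled transition events from per-trace idealizations ------------
    ev_initial, ev_final = [], []
    for item in per_trace:
        ideal = item["ideal"]
        dwells, _ = extract_dwells(
            ideal.states, levels=ideal.levels,
            frame_interval=ideal.frame_interval,
            min_dwell_frames=config.min_dwell_frames,
            molecule_id=ideal.molecule_id,
        )
        for d in dwells:
            ev_initial.append(d.intensity_before)
            ev_final.append(d.intensity_after)

    try:
        tdp = build_tdp(
            np.asarray(ev_initial), np.asarray(ev_final),
            grid_step=config.grid_step, bandwidth=config.bandwidth,
        )
        centers = find_peak_centers(tdp, n_states=config.n_states)
        cutoffs = define_cutoffs(centers)
    except (EmptyTdpError, ValueError) as exc:
        report.update(status="failed", failed_stage="tdp", error=str(exc))
        return report

    # --- consensus mapping and final dwell extraction ---------------------
    dwell_rows = []
    dynamic_values: list[np.ndarray] = []
    n_dynamic = n_static = 0
    coarse_event_init, coarse_event_final = [], []
    for item in per_trace:
        ideal = item["ideal"]
        coarse = assign_state(ideal.levels, cutoffs)
        dwells, filtered = extract_dwells(
            coarse, levels=ideal.levels,
            frame_interval=ideal.frame_interval,
            min_dwell_frames=config.min_dwell_frames,
            molecule_id=ideal.molecule_id,
        )
        ideal.coarse_states = filtered
        if classify_dynamic(filtered):
            n_dynamic += 1
            dynamic_values.append(item["trace"].intensities)
            for d in dwells:
                dwell_rows.append(
                    {
                        "molecule_id": d.molecule_id,
                        "state": d.state,
                        "duration_s": d.duration_s,
                        "exit_state": d.exit_state,
                        "intensity_before": d.intensity_before,
                        "intensity_after": d.intensity_after,
                    }
                )
                coarse_event_init.append(d.intensity_before)
                coarse_event_final.append(d.intensity_after)
        else:
            n_static += 1

    log = traces.selection_table()
    n_rejected = int((~log["accepted"]).sum()) if len(log) else 0
    report["selection"] = {
        "total": n_total,
        "accepted": len(per_trace),
        "rejected": n_rejected,
        "dynamic": n_dynamic,
        "static": n_static,
        # fraction of analyzed trajectories showing transitions (the
        # dynamic/static split refers to selected molecules)
        "dynamic_fraction": (
            n_dynamic / (n_dynamic + n_static) if (n_dynamic + n_static) else 0.0
        ),
    }
    report["states"] = {
        "centers": centers.tolist(),
        "boundaries": cutoffs.boundaries.tolist(),
        "n_tdp_transitions": tdp.n_transitions,
    }

    if not dynamic_values:
        report.update(status="failed", failed_stage="selection",
                      error="no dynamic traces")
        return report

    # --- transition-class accounting --------------------------------------
    classes = classify_transitions(
        np.asarray(coarse_event_init), np.asarray(coarse_event_final), cutoffs
    )
    report["transitions"] = {
        "n_events": int(classes["count"].sum()),
        "classes": classes.to_dict(orient="records"),
        "one_three_fraction": one_three_fraction(classes),
    }

    # --- population histogram ---------------------------------------------
    hist = compile_histogram(
        dynamic_values, bin_width=config.bin_width, seed=config.seed
    )
    try:
        peak_fit = fit_multipeak(hist, centers)
        fractions, frac_sd = peak_areas(peak_fit)
        report["populations"] = {
            "fractional_areas": fractions.tolist(),
            "fractional_area_sds": frac_sd.tolist(),
            "peak_centers": peak_fit.centers.tolist(),
            "peak_widths": peak_fit.widths.tolist(),
            "peak_amplitudes": peak_fit.amplitudes.tolist(),
            "baseline": peak_fit.y0,
            "reduced_chisq": peak_fit.reduced_chisq,
            "n_frames": hist.n_frames,
            "n_molecules": hist.n_molecules,
        }
    except Exception as exc:  # keep partial report on fit failure
        report.update(status="failed", failed_stage="histogram_fit", error=str(exc))
        return report

    # --- dwell kinetics -----------------------------------------------------
    dwell_table = pd.DataFrame(
        dwell_rows,
        columns=["molecule_id", "state", "duration_s", "exit_state",
                 "intensity_before", "intensity_after"],
    )
    summary = analyze_dwell_classes(
        dwell_table, n_states=config.n_states, improvement=config.improvement
    )
    report["kinetics"] = {
        "classes": {
            f"{i}->{j}": v for (i, j), v in summary.classes.items()
        },
        "keq": {f"{i},{j}": list(v) for (i, j), v in summary.keq.items()},
        "mean_occupancy_s": {
            str(s): [m, sem] for s, (m, sem) in summary.occupancy.items()
        },
    }

    if config.out_dir and config.write_artifacts:
        _write_artifacts(config.out_dir, report, log, dwell_table, tdp, hist)
    return report


def _write_artifacts(out_dir, report, selection_log, dwell_table, tdp, hist) -> None:
    os.makedirs(out_dir, exist_ok=True)
    selection_log.to_csv(os.path.join(out_dir, "selection_log.tsv"),
                         sep="\t", index=False)
    dwell_table.to_csv(os.path.join(out_dir, "dwells.tsv"), sep="\t", index=False)
    tdp.as_frame().to_csv(os.path.join(out_dir, "tdp_grid.tsv"), sep="\t")
    pd.DataFrame(
        {"bin_center": hist.centers, "count": hist.counts, "se": hist.se}
    ).to_csv(os.path.join(out_dir, "histogram.tsv"), sep="\t", index=False)
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=float)


def compare_conditions(reports: list[dict]) -> pd.DataFrame:
    """Side-by-side comparison of run reports.

    Reports with fewer fitted states than others are compared on the shared
    states only.  Returns one row per condition with state areas, k_eq values
    and mean occupancy times; deltas relative to the first report are
    included for quick reading of equilibrium shifts.
    """
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    rows = []
    for rep in reports:
        if rep.get("status") != "ok":
            raise ValueError(f"report for {rep.get('condition')} is not ok")
        areas = rep["populations"]["fractional_areas"]
        keq = rep["kinetics"]["keq"]
        occ = rep["kinetics"]["mean_occupancy_s"]
        row = {"condition": rep.get("condition", "?")}
        for i, a in enumerate(areas, start=1):
            row[f"area_state{i}"] = a
        row["keq_12"] = keq.get("1,2", [np.nan, np.nan])[0]
        row["keq_23"] = keq.get("2,3", [np.nan, np.nan])[0]
        for s, (m, _sem) in occ.items():
            row[f"occupancy_state{s}_s"] = m
        rows.append(row)
    df = pd.DataFrame(rows).set_index("condition")
    base = df.iloc[0]
    for col in ["keq_12", "keq_23"]:
        if col in df:
            df[f"delta_{col}"] = df[col] - base[col]
    return df
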