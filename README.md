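# smkinetics

Analysis of single-molecule fluorescence intensity trajectories for
conformational kinetics, built for single-channel TIRF experiments on
membrane receptors (e.g. a Cy3-labeled GPCR in a surface-tethered nanodisc).
A labeled receptor switches among a small number of conformations — inactive
(state 1), intermediate (state 2) and active-like (state 3) — each with its
own emission level, until the fluorophore photobleaches in a single step.
`smkinetics` turns a collection of such traces into state populations and
exchange kinetics, and ships a matched simulator so every stage can be tested
against ground truth.

## What it computes

Given per-molecule intensity time series `I(t)` (100 ms frames typical):

1. **Selection & normalization** — keep traces with clean single-step
   photobleaching, drop the rest with logged reasons, and normalize each
   trace by its lowest-intensity emission state so states sit near 1, 2, 3.
2. **Idealization** — per-trace maximum-likelihood hidden Markov model with
   Gaussian emissions (Baum–Welch EM, multiple restarts, numba-accelerated),
   then Viterbi decoding to a discrete state path. Runs shorter than a
   minimum dwell (default 2 frames) are absorbed into the flanking state.
3. **Transition density plot (TDP)** — 2-D kernel density of
   (intensity before, intensity after) over all transitions; its off-diagonal
   peaks define consensus state centers and midpoint cutoffs.
4. **Populations** — pooled intensity histogram of the dynamic traces fit
   with `y(x) = y0 + Σᵢ Aᵢ·exp(−((x−μᵢ)/σᵢ)²)`, centers anchored at the TDP
   values; fractional populations are the peak areas `Aᵢσᵢ√π` normalized to
   their sum.
5. **Dwell kinetics** — dwell times per transition class `i→j`, binned by the
   Freedman–Diaconis rule (`2·IQR/n^{1/3}`), fit with mono- and bi-exponential
   decays; reduced-χ² model selection; amplitude-weighted rate
   `1/k̄ = a₁/k₁ + a₂/k₂`; equilibrium rate-constant ratios
   `k_eq(i,j) = k_{i→j}/k_{j→i}` with propagated SD; and per-state mean
   occupancy times (± SEM).

The simulator (`smkinetics.synthetic`) generates the matching data: a
continuous-time Markov chain over coarse states (optionally expanded into
hidden kinetic substates sharing one emission level, which makes dwell
distributions bi-exponential), exact frame integration at 100 ms, Gaussian
noise of 0.15 normalized units, single-step photobleaching (mean 30 s) and a
55% contamination of static traces. Named reference configurations
(`REFERENCE_CONFIGS`) encode conditions with known stationary occupancies and
rates.

## Worked example

```python
from smkinetics import RunConfig, run_pipeline

report = run_pipeline(RunConfig(source="cfg_apo_wt", n_states=2, seed=1))
sel = report["selection"]
print(f"dynamic fraction: {sel['dynamic_fraction']:.2f}")
print("areas:", [round(100 * a, 1) for a in report["populations"]["fractional_areas"]])
print("k_eq(1,2):", round(report["kinetics"]["keq"]["1,2"][0], 2))
print("mean occupancy state 1 (s):", round(report["kinetics"]["mean_occupancy_s"]["1"][0], 2))
```

prints (seed 1):

```
dynamic fraction: 0.45
areas: [61.9, 38.1]
k_eq(1,2): 0.65
mean occupancy state 1 (s): 2.93
```

Read: 45% of the selected trajectories show transitions; the receptor spends
~62% of its time in the inactive state and ~38% in the intermediate; the
forward/backward rate ratio k(1→2)/k(2→1) ≈ 0.65 favors state 1; and an
average visit to state 1 lasts ~2.9 s. The generating truth for this
configuration is π = (0.63, 0.37), k(1→2)/k(2→1) = 0.345/0.587 = 0.59 and a
2.9 s state-1 dwell, so each stage recovers its target.

The same pipeline is available from the shell:

```bash
smkinetics simulate --config cfg_neca_wt --out traces.tsv
smkinetics analyze --traces traces.tsv --out run/ --n-states 3
smkinetics compare run_a/report.json run_b/report.json
```

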