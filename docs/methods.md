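# Methods

## Model

A single fluorophore-labeled receptor is modeled as a continuous-time Markov
chain over K ∈ {2, 3} coarse conformational states with strictly increasing
emission levels (normalized to 1.0, 2.0, 3.0 after dividing by the lowest
state's level). Transitions are first-order with rate constants k(i→j); in
the sequential topology used by all shipped reference configurations the
direct 1↔3 rates are zero, so the active-like state is reached only through
the intermediate. Photobleaching is an absorbing dark state entered at a
single rate from every conformation — the generator matrix has the bleach
rate appended as an extra column, and rows sum to zero.

Coarse states may be expanded into *hidden kinetic substates*: multiple
chain states that share one emission level but differ in exit rate. A
two-substate expansion with entry split a₁/a₂ makes the pooled dwell-time
density of that coarse state the mixture a₁k₁e^{−k₁t} + a₂k₂e^{−k₂t}, i.e.
bi-exponential, while remaining invisible to any emission-based fit. This is
the mechanism the dwell-kinetics stage is designed to detect.

### Reference configurations

Rates were fixed once, by algebra, from target stationary occupancies and
mean dwells (stationary distribution of a reversible chain:
π_i k(i→j) = π_j k(j→i)):

| name | states | rates (s⁻¹) | implied π | note |
|---|---|---|---|---|
| cfg_apo_wt | 2 | 0.345 / 0.587 | 0.63, 0.37 | state-1 mean dwell 2.9 s |
| cfg_neca_wt | 3 | 0.345, 0.457, 0.227, 0.600 | 0.49, 0.37, 0.14 | sequential |
| cfg_neca_wt_minigs | 3 | 0.556, 0.631, 0.341, 0.600 | 0.42, 0.37, 0.21 | state-3 gain |
| cfg_keq24 | 2 | 0.550 / 0.229 | 0.29, 0.71 | k_eq(1,2) = 2.40 |
| cfg_cam | 3 | 0.667, 0.533, 0.267, 0.533 | 0.35, 0.43, 0.22 | state-1 dwell 1.5 s |
| cfg_substates | 2 | state 1 → {1.0, 0.2}, 50/50 entry | — | bi-exponential dwells |

Common defaults (each is a study condition, not a tuning knob): frame
interval 0.1 s with **exact frame integration** (a frame's noiseless value is
the occupancy-time-weighted mean of the levels visited during it, so
sub-frame transits yield intermediate intensities); i.i.d. Gaussian noise,
σ = 0.15 normalized units (levels sit ~6.7σ apart); bleach rate 1/30 s⁻¹;
trace cap 120 s; 55% static traces (all inter-state rates zeroed, bleaching
retained); 300 traces per dataset. Dynamic traces start from the stationary
distribution. Static-trace count is the deterministic `floor(0.55·n + 0.5)`.

What the simulator does **not** emulate: EMCCD noise physics, background
drift, blinking/photophysics, partial or multi-step bleaching, baseline
offsets. Passing recovery tests therefore demonstrates correctness of the
analysis under idealized noise, not robustness to every real-data pathology;
the multi-step-bleach exclusion path, for example, is exercised only by unit
tests, not by the simulator.

## Analysis stages and estimation choices

**Photobleach detection.** Running-median (window 5) smoothing; per-frame
noise SD from the median absolute first difference (robust to level
switches). The bleach frame is the first index after which the smoothed
trace stays below `tail_level + 3σ`. Two guards: the terminal level must be
consistent with the zero background (|tail| ≤ 3σ — traces are assumed
background-subtracted; a final dwell in state 1 otherwise mimics a bleach),
and the threshold must lie below the 25th percentile of the pre-drop signal.
A sustained (≥10 frame) pre-drop plateau below the 5th percentile − 4σ flags
a multi-step bleach and excludes the trace. The frame containing the bleach
step itself is dropped (it integrates a partial dwell and the dark state).
Censored-at-cap traces are excluded, as selection requires an observed
single-step bleach; bleach-rate estimates over a dataset should use the
censored-exponential MLE (events / total exposure).

**HMM idealization.** Per-trace Gaussian-emission HMM fit by Baum–Welch EM
(scaled forward–backward in numba), k_max = 3, five restarts from jittered
1-D k-means initializations (restarts are 60-iteration short runs; the best
is polished to convergence, tol 1e-6 relative, max 500 iterations;
log-likelihood is monotone by construction and asserted in tests). Two
post-fit reductions repair overfitting on short traces: states with mean
posterior occupancy < 1% (or supported by < 2 expected frames) are pruned,
and adjacent states whose means are closer than 3× the per-frame noise SD
are merged — levels closer than ~3σ are not resolvable as distinct states
when true levels sit ~6σ apart. The model is refit after each reduction.
Normalization divides the trace and fit by the lowest fitted mean. Viterbi
decoding gives the idealized path. hmmlearn's GaussianHMM serves as an
independent oracle in tests (equal-or-better likelihood, matching means);
the substates of one emission level are intentionally *not* distinguishable
by the HMM — they surface only in dwell statistics.

**Dwell extraction.** Runs shorter than `min_dwell_frames` (default 2, i.e.
200 ms — a noise-blip suppressor) are absorbed into the longer flanking run,
iteratively, shortest first. The first and last dwell of every trace are
censored (incomplete by construction). Each completed dwell carries its exit
state and the mean fitted intensity before/after; transition events for the
TDP and for classification are exactly the exits of completed dwells, which
makes the bookkeeping identity (#completed state-1 dwells = #1→2 events)
exact.

**TDP and consensus states.** Gaussian KDE (bandwidth 0.08 ≈ σ/2, fixed for
reproducibility) of (before, after) pairs on a 0.02 grid over [0.5, 3.5]²;
the near-diagonal band (|x−y| < 0.2) is zeroed — no self-transitions exist
after idealization, so mass there is kernel leakage — and the density is
renormalized to integrate to 1. Local maxima above 5% of the peak are pooled
over both axes and clustered by splitting at gaps > 0.4; the
density-weighted cluster means, sorted, are the consensus centers. Cutoffs
are midpoints between adjacent centers (the symmetric, assumption-free
choice); a value exactly on a boundary classifies to the lower state.
Per-trace fitted levels are mapped to the nearest center, which also merges
any residual per-trace overfit states.

**Population histogram.** All pre-bleach frames of dynamic traces pooled
(bin width 0.05). Per-bin SE by molecule-level bootstrap (200 resamples):
frames within one molecule are strongly autocorrelated, so resampling
molecules is the honest error model; the naive multinomial SE is available
as an option and is a lower bound. Weighted least squares of
y0 + Σ Aᵢ·exp(−((x−μᵢ)/σᵢ)²) with μᵢ initialized at the TDP centers and
bounded to ±0.15, Aᵢ ≥ 0, σᵢ ∈ [0.05, 0.5] (prevents peak-swallowing), y0
free. Note the peak form has no factor 2 in the exponent, so the area is
Aσ√π and the fitted σ of a Gaussian population with SD s is s√2. Fractional
areas are normalized peak areas with delta-method SDs from the fit
covariance.

**Dwell kinetics.** Per class i→j: Freedman–Diaconis bins
(linear-interpolation quartiles; IQR = 0 falls back to range/√n, then to a
single bin), weighted least squares on binned counts with Poisson errors
√max(count, 1). Mono fit always (n ≥ 10); bi fit at n ≥ 25 and ≥ 5 bins. A
bi fit is degenerate when its rates agree within 5% or a normalized
amplitude falls below 2%. Model selection: bi wins only if non-degenerate,
its reduced χ² beats mono's by > 10% relative, *and* the absolute χ² drop
exceeds the 99% point of χ²₂ (≈ 9.21) — the nested-model significance guard.
The guard exists because with ~30 bins and reduced χ² < 1, two extra free
parameters routinely buy a ~10% relative improvement by chance; without it
the selector promoted bi on dwell data generated from a single-exponential
process. Calibration under the full rule: mono chosen 100/100 on direct
exponential draws, bi chosen ≥ 80/100 on hidden-substate mixtures.
Rates: k̄ = k (mono) or 1/k̄ = a₁/k₁ + a₂/k₂ (bi, amplitude fractions
a₁+a₂ = 1), SD by first-order propagation; k_eq(i,j) = k̄(i→j)/k̄(j→i) with
SD(r)/r = √((SD₁/k₁)² + (SD₂/k₂)²); mean occupancy is the arithmetic mean of
a state's completed dwells pooled over exit classes, ± SEM. Note that for a
multi-exit state the i→j class's fitted decay reflects the *total* exit rate
(all exits truncate the dwell); reporting it as k(i→j) mirrors standard
dwell-histogram practice rather than correcting it.

## Known biases and limitations

**Finite time resolution biases dwell statistics upward.** With 100 ms
frames and the 2-frame minimum dwell, sub-frame and single-frame visits are
unresolvable: short dwells are truncated away and a removed blip joins its
two flanking dwells into one. Measured on ground-truth paths (no HMM
involved), the state-1 mean occupancy of cfg_cam comes out at ~1.71 s versus
the generating 1.50 s (+14%), while cfg_apo_wt lands at ~3.0 s versus 2.9 s —
the relative bias grows with k·Δt, so only fast kinetics are materially
affected. Bleaching adds a small opposite bias (completed dwells are
Exp(k + k_bleach) distributed, ~−4% here). The exponential *fits* are less
affected (a truncated exponential keeps its decay constant), which is why
k_eq recovery stays within a few percent even where the mean occupancy does
not.

**Apparent direct 1↔3 transitions.** In a strictly sequential chain, a
passage through state 2 shorter than ~1.5 frames is assigned to the flanking
states by Viterbi or removed by the minimum-dwell filter, creating an
apparent direct 1↔3 event. At these rates that produces ~1–3% of classified
transitions (larger for faster intermediate-exit rates); it is a resolution
artifact, not a pathway violation, and scales down with the frame interval.

**Other limitations.** Rates are per-class fits, not a global likelihood
over the chain; censoring is handled by discarding first/last dwells rather
than by survival-corrected fitting; the TDP uses pooled transition weighting
(molecules with more transitions contribute more); per-trace HMM fitting
assumes each trace alone carries enough frames (≥ 20 pre-bleach) to estimate
its levels. Problem sizes in tests and in the acceptance script (300 traces,
10 seeds, ~100-replicate calibrations) were chosen as the smallest sets at
which the recovery tolerances are comfortably resolved.
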