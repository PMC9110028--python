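# Methods

## Model and assumptions

Transmitter release is described by depletion of a single readily
releasable pool (RRP) with normalized occupancy *n* and a fixed release
probability *P*ᵥ per action potential, with activity-dependent
replenishment: between spikes

    dn/dt  = (1 − n) / τᵣ(t),        dτᵣ/dt = (τ_b − τᵣ) / τ_d,

and at each spike time the EPSC is read from the pre-spike occupancy
(EPSC ∝ n·Pᵥ), the pool is depleted (n ← n(1 − Pᵥ)) and the
replenishment time constant is reset to the fast value (τᵣ ← τ_h); the
reset applies to every spike, including the first. The model assumes an
infinite reserve pool, no facilitation of Pᵥ, no calcium dynamics, no
postsynaptic receptor desensitisation, and only normalized amplitudes
(the absolute EPSC scale is "proportional to n·Pᵥ" and never fitted;
amplitudes are handled as positive magnitudes, so inward-current
conventions must be negated on input).

## Exact event-driven integration

Because τᵣ relaxes exponentially between spikes
(τᵣ(Δ) = τ_b + c·e^(−Δ/τ_d), c = τᵣ(0) − τ_b), the depletion deficit
has the closed form

    1 − n(Δ) = (1 − n)·e^(−I),
    I = Δ/τ_b + (τ_d/τ_b)·ln[(τ_b + c·e^(−Δ/τ_d)) / (τ_b + c)],

which reduces to I = Δ/τ_b when c = 0. The default engine iterates this
update spike-to-spike, so traces carry no discretisation error. A
forward-Euler integrator (default dt = 0.01 ms; each inter-spike
interval split into uniform sub-steps ≤ dt so spikes land exactly on
step boundaries) is retained as the reference method; the test suite
requires agreement ≤ 1e−4 in every normalized amplitude at dt = 1e−3 ms
and ≤ 1e−6 in n against a dt = 1e−4 ms oracle for a single interval.

Initial conditions: n₀ = 1 (full pool) and τᵣ = τ_b (terminal at rest)
at protocol start, both overridable. Spikes are indexed from 1
(EPSC₁ = first response); regular trains at f Hz for D ms contain
⌊f·D/1000⌋ spikes starting at t = 0.

## Parameters, units and defaults

| parameter | meaning | unit | canonical WT | canonical KO |
|---|---|---|---|---|
| Pᵥ | release probability per spike | – | 0.13 | 0.266 |
| τ_h | post-spike (fast) replenishment time constant | ms | 66.9 | 52.2 |
| τ_b | background replenishment time constant | ms | 5000 | 5000 |
| τ_d | relaxation of τᵣ back to τ_b | ms | 500 | 500 |

Pᵥ and τ_h are the published fitted values for the two conditions. τ_b
and τ_d are package defaults chosen once from the measured recovery
kinetics at this synapse — a slow recovery component of ≈5 s (pinning
τ_b) and a fast component of ≈0.45 s attributable to the
activity-dependent phase (pinning τ_d ≈ 0.5 s) — and they reproduce the
measured depression scale (e.g. 100 Hz wild-type PPR ≈ 0.88 within the
0.90 ± 0.04 band, steady state ≈ 0.43 vs 0.4 ± 0.1; knockout steady
state ≈ 0.30 vs 0.3 ± 0.08). They are configuration values, not
constants.

## Summary statistics

- Paired-pulse ratio EPSC₂/EPSC₁ and late ratio EPSC₈₀/EPSC₁ (reported
  missing, not an error, for trains shorter than 80 stimuli).
- Depression time course: least-squares fit of
  A(t) = ss + (A₀ − ss)·e^(−t/τ) over the 800 ms train, all three
  parameters free. Leaving A₀ free (rather than pinning it to 1) keeps
  the fit robust to noisy first responses. Note the model's depression
  is not exactly single-exponential (τᵣ is state-dependent), so the
  fitted τ is a summary statistic, not a model parameter.
- Recovery: bi-exponential approach to full recovery,
  A(t) = 1 − D·[f·e^(−t/τ_f) + (1−f)·e^(−t/τ_s)], with the depth D
  fixed at 1 − A_end from the measured end-of-train amplitude and the
  fast/slow ordering enforced by relabelling after the fit; f is the
  fast fraction of the recovery deficit. Time origin is the last
  conditioning stimulus; intervals are in seconds.

Both fits use lmfit with a handful of seeded log-spaced restarts.
Degenerate inputs (flat amplitudes, zero depth) return flagged results
(`converged=False` with a message) instead of raising, so batch
pipelines continue. Fits are invariant to uniform amplitude rescaling
once inputs are renormalized.

## Parameter estimation

The canonical design fits normalized amplitudes from 800 ms trains at
100, 200 and 600 Hz plus the 100 Hz recovery curve simultaneously
(400 Hz data, when generated, is held out for validation). Trains
identify Pᵥ and τ_h; the recovery probes out to 30 s identify τ_b and
τ_d — configurations that leave the slow constants free without
recovery data are fitted but flagged with an identifiability warning.

The objective is the unweighted sum of squared residuals on normalized
amplitudes (inverse-SEM weighting available, since experimental points
are means ± SEM). Optimization is bounded least squares
(scipy `least_squares`, trust-region reflective, ftol=xtol=gtol=1e−14)
with time constants transformed to log₁₀ space — plausible values span
two decades and the transform conditions the problem. Default bounds:
Pᵥ ∈ [0.01, 0.9], τ_h ∈ [1, 1000] ms, τ_b ∈ [100, 60000] ms,
τ_d ∈ [10, 30000] ms, bracketing the physiological range and the 30 s
recovery horizon. Multi-start (default 20 starts: the bound midpoint
plus seeded uniform draws in the transformed space) guards against
local minima; the best start's solution is reported together with every
start's objective. Results are deterministic given the seed.

The knockout "delta" fit frees only Pᵥ and τ_h with τ_b and τ_d fixed
at the wild-type values — the minimal-change comparison that attributes
a condition difference to release probability and activity-dependent
replenishment.

Recovery probes are modelled sequentially within one sweep by default
(each probe itself releases and resets τᵣ, perturbing later probes, as
in a single-trace protocol); an independent mode (each probe a fresh
sweep from the post-train state) is available.

## Synthetic data generator

`generate_dataset` emulates the study conditions: per cell, the four
model parameters are jittered lognormally (unit-mean, CV
`cell_param_cv`, default 0.1); each sweep's amplitudes are multiplied
by (1 + ε), ε ~ N(0, `amp_cv`) (default 0.1), truncated at zero (counted
in a quality log) and renormalized to the sweep's first EPSC; repeats
(default 3) are averaged within cells and cells (default 10) into means
± SEM. Defaults resemble the experimental group sizes (8–21 neurons,
3 repeats per train) without claiming their exact variance structure —
the trial-to-trial variance of the real recordings is not known, so
`amp_cv` is a free knob. Noise is multiplicative because EPSC variance
scales with amplitude at this synapse; an additive floor is not
modelled, nor are membrane currents, stimulus artefacts or recording
noise spectra. Per-sweep renormalization introduces a small upward bias
of order amp_cv² in normalized means (dividing by a noisy first
amplitude), visible only in tight Monte-Carlo comparisons.

Consequently, passing tests demonstrate correctness of the simulator,
statistics and estimator under the model's own data-generating process
(including realistic amplitude noise), not that the model captures every
feature of recorded EPSCs (quantal variability, facilitation,
desensitisation, electrode artefacts are all absent).

## Numerical choices and degenerate inputs

- Exact engine is the default; Euler exists for cross-validation and
  rejects dt ≥ the smallest inter-spike interval.
- Protocols must be strictly increasing and non-empty (constructor
  errors, not flags).
- Pᵥ = 0 is outside the parameter space (0 < Pᵥ ≤ 1); the no-depletion
  limit is exercised with Pᵥ → 0.
- The depression fit flags τ as unidentified when it runs to its search
  bounds; the recovery fit flags zero-depth input.
- Problem sizes: the canonical fit uses 730 amplitude points (80 + 160
  + 480 train points, 10 probes); the noise-robustness study refits 20
  seeded datasets (10 cells × 3 repeats) with 4 starts each.

## Known limitations

- Single homogeneous pool: no reluctant/fast vesicle subpools, so the
  bi-exponential recovery emerges only from the τᵣ relaxation.
- The fitted τ_b/τ_d defaults are calibrated to recovery kinetics, not
  transcribed from the original fit; analyses that depend on their
  absolute values should treat them as configurable.
- Mean-curve fitting is assumed (fits to the across-cell mean, as the
  published comparison plots mean ± SEM); per-cell fitting is possible
  by passing single-cell datasets but is not the canonical path.
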