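# Methods

## Model and assumptions

The walker is a point mass `m = 80 kg` at the hip on rigid massless legs
(`L = 1 m`) with feet of length `l = 0.2 m`, moving in the sagittal plane
under gravity `g = 9.81 m/s²`.  The swing leg is repositioned
instantaneously and for free (massless), the inter-leg angle is reset to
`2θ₀` at every heel strike, and scuffing is ignored.  The hip is a
frictionless pivot; all actuation is a torsional spring at the trailing
ankle, `T = k(μ − ψ)` with maximal plantar flexion `μ = 2.576 rad`,
pre-loaded and released at double-stance onset.  Double stance ends exactly
when `ψ = μ` (the massless trailing foot can push only while the torque is
positive), after which the model is an inverted pendulum about the leading
ankle until the hip angle reaches `−θ₀`.

**Sign convention.**  `θ` is the stance-leg angle from the vertical through
the stance ankle, positive when the hip is *behind* it.  A step runs from
`θ = +θ₀` (just after the collision) to `θ = −θ₀` (the next collision); the
collision itself multiplies the stance-leg angular speed by `cos 2θ₀`.

**Four-bar geometry.**  During double stance the closed chain is:
trailing-foot ground pivot → trailing ankle (`l`) → hip (`L`) → leading
ankle (`L`), with the ground link fixed.  We place the trailing-foot pivot
a distance `l` behind the ankle along the ground.  With the leading ankle
`2L sin θ₀` ahead of the trailing ankle at heel strike, the interior ankle
angle is then closed-form,

    cos ψ(θ) = (l² − c₁² + 2 L c₁ sin θ) / (2 l L),  c₁ = 2L sin θ₀ + l,

with `ψ₀ = π/2 + θ₀` at onset and `dψ/dθ = −c₁ cos θ / (l sin ψ)`.  This
orientation is the one under which the printed `μ = 2.576 rad` yields a
valid hybrid gait at *both* study leg angles: the `ψ = μ` release lands at
`θ = +5.49°` for `θ₀ = π/12` and `+26.27°` for `π/6`, strictly inside the
step and before the linkage singularity (`ψ → π`).  With the pivot forward
of the ankle instead, the release at `θ₀ = π/12` would fall at `θ = −25.8°`
— beyond the heel-strike angle — and no consistent double→single-stance
sequence would exist.  All contracted structure (linear torque law,
collision factor, affine return map, slope `cos² 2θ₀`) is independent of
this choice.

Because the hip rotates about the fixed leading ankle in *both* phases, the
whole step reduces to one scalar ODE:

    double stance:  m L² θ̈ = m g L sin θ + k (μ − ψ(θ)) dψ/dθ
    single stance:        θ̈ = (g/L) sin θ

Both phases are conservative, which gives the affine return map in
`x = Ω²` quoted in the README, a unique monotonically attracting fixed
point `x* = cos²2θ₀ · k₀ C / (1 − cos²2θ₀)` with
`C = (μ − ψ₀)²/(mL²)`, and the single Floquet multiplier `cos² 2θ₀`.

## Numerical integration

Classical RK4 on a fixed grid `h = 1e-4 s` (configurable).  Events are
localized by bisecting the length of a single partial RK4 step across the
detected sign change until the event time is bracketed to 1e-10 s; the
double-stance event `ψ = μ` is equivalent to the closed-form angle
`θ_release`, so both events are monotone crossings of `θ`.  Halving or
dividing `h` by ten moves step durations by well under 1e-6 s (asserted in
the tests, with an independent energy-quadrature oracle agreeing to 1e-8 s).
Falling backward (`θ̇ → 0` before heel strike) aborts the run with the
completed strides attached as a flagged partial series.  The inner loops
are numba-compiled; results are bitwise reproducible for a given seed
(`numpy.random.default_rng`).

Noise: `k` is redrawn once per *step* (a stride consumes two draws), iid
`N(k₀, σ²)`; non-positive draws are rejected and resampled, which at the
calibrated σ (≈ 14% of k₀ at π/12) has probability ~1e-12 per draw.  Every
run starts exactly on the deterministic fixed point; no burn-in strides are
discarded by default (`discard` is available).

## Calibration

Two constants are free per leg angle and both are pinned to published human
values:

* `k₀` — Brent root-finding on the deterministic limit-cycle speed
  (`4L sin θ₀` per stride over the stride period) against 1.35 m/s,
  tolerance 1e-3 m/s.  Result: `k₀ ≈ 86.5 N·m/rad` (π/12),
  `≈ 1028.8` (π/6).
* `σ` — Brent root-finding on the *mean* stride-interval COV of noisy
  500-stride walks over a fixed 5-seed calibration set against 3%,
  tolerance 0.1 percentage points.  COV is computed on stride intervals by
  default; a cadence-based variant sits behind `cov_of="cadence"`.
* rolling disk — the same COV procedure on 500-cycle durations fixes the
  stochastic-force SD (≈ 2.6 N).

## Analysis battery

* **DFA**: integrate mean-subtracted intervals; windows partition the
  profile from the series start (trailing remainder discarded — the
  simplest faithful reading of the windowed-RMS definition); one OLS line
  per window; `F(n)` is the RMS residual over covered samples; `α` is the
  unweighted OLS slope of `log₁₀F` on `log₁₀n` over windows
  `n = round(10^x)`, `x = log₁₀4 … log₁₀(N/2)` step 0.1.  For long walks an
  additional fit over `n ≥ 1000` probes the large-window regime.
* **Spectrum**: squared DFT amplitudes of the mean-subtracted series (no
  taper), `f = j/N` per stride; `β = −slope` of `log₁₀S` on `log₁₀f` over
  the length-specific ranges `[0.01, 0.3]` (N=500), `[1/600, 0.3]`
  (N=3,000), `[2e-5, 0.3]` plus a `[2e-5, 0.01]` diagnostic (N=100,000);
  other lengths use `[5/N, 0.3]`, the rule the 500 and 3,000 ranges follow.
  Fits use all Fourier frequencies in range (no log-binning).
* **Surrogates**: uniformly random permutations (value multiset preserved
  bitwise).
* **Tests**: two-sided t-tests at the 5% level — one-sample against the
  white-noise constants (0.5, 0), paired against per-run surrogates.  The
  test family is an interpretive choice; the source method states only the
  significance level.

## Experiment design and problem sizes

The replication matrix runs 20 simulations per cell (run seed =
`base_seed + index`; shuffle and calibration seeds at documented fixed
offsets so all streams are disjoint and reproducible).  The default
replication profile works at 500 and 3,000 strides; 100,000-stride runs are
supported but long-running, and the package's standing check of the
large-window regime uses a 20,000-stride walk, on which the `n ≥ 1000` DFA
fit visibly drops toward 0.5 while the standard fit stays above it — the
same qualitative crossover reported for 100,000 strides.

## What the generators do and do not emulate

The synthetic white benchmark (mean 1.23 s, SD 0.0369 s) reproduces the
published human mean stride interval and 3% COV; the Brownian benchmark
uses increment SD 0.004 s so a 500-sample path also has ≈3% COV.  The
walker itself emulates only sagittal point-mass mechanics with a single
noise source in ankle actuation: no swing-leg dynamics, no lateral
stability or feedback control, no neural oscillator, no multi-source
physiological noise.  Passing tests therefore demonstrate that *this
mechanism suffices* to generate human-like stride-interval scaling — not
that human walking is mechanistically identical.

## Known limitations and measured deviations

* The step-to-step memory is an exact AR(1) with coefficient `cos² 2θ₀`.
  At `θ₀ = π/6` (coefficient 0.25) this leaves an irreducible low-frequency
  spectral boost of `((1+φ)/(1−φ))² ≈ 2.8`, i.e. β ≈ 0.13 over the
  3,000-stride fit range, and DFA carries the well-known small-window
  positive bias (~+0.02 on iid noise, measured here).  With run-to-run SDs
  of ≈0.02 at 3,000 strides, one-sample t-tests against exactly 0.5 and 0
  therefore *reject* — the corresponding acceptance test states the
  published claim verbatim and is left failing rather than weakened.
  Comparisons against the equally biased white-noise ensemble, or the
  paired surrogate tests, behave as published.
* The four-bar pivot orientation is a reconstruction (see above); it is the
  unique orientation consistent with the printed `μ` for both leg angles.
* `empirical_step_map` and the Floquet finite difference use central
  differences with relative offset 1e-2 (configurable); the map is affine,
  so the estimate is exact to integration error (~1e-8).
* Brownian benchmark paths of ≥10⁵ samples can wander non-positive at the
  default increment SD; the container enforces positive intervals, so very
  long Brownian benchmarks need a smaller `sd`.
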