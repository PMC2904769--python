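# Methods

This note documents the models and procedures implemented in `gaitgem`, the
parameter choices that matter, and the places where the design was
genuinely open.

## Stride series and the treadmill task

A trial is a sequence of stride times *T<sub>n</sub>* (s) and stride
lengths *L<sub>n</sub>* (m) at fixed belt speed *v* (m/s) — the walker
observed at its stride-to-stride Poincaré section.  Stride speed
*S<sub>n</sub>* = *L<sub>n</sub>*/*T<sub>n</sub>* is always derived, never
stored.  Per-trial mean speed is the mean over *S<sub>n</sub>*, which
differs in general from (ΣL)/(ΣT); the test suite carries a two-stride
counterexample.

The task's only hard requirement is staying on the belt.  With forward
taken positive, the net displacement after stride *n* relative to the belt
center is d<sub>net</sub>(n) = Σ<sub>i≤n</sub>(L<sub>i</sub> −
v·T<sub>i</sub>), d<sub>net</sub>(0) = 0, and the requirement is
|d<sub>net</sub>| ≤ d<sub>max</sub> with d<sub>max</sub> = 0.864 m (half
the belt length) throughout.

## GEM decomposition

Both series are normalized to unit variance by their own sample SDs
(ddof = 1); the decomposition is therefore trial-local.  The operating
point is the sample mean of (T, L) by default; a projected variant
(L\* = v·T\*) is provided because the two differ only by an additive
constant in δ<sub>P</sub>, leaving SD(δ<sub>P</sub>) and α(δ<sub>P</sub>)
exactly invariant (asserted to 1e−12/1e−9).  The rotation onto
(ê<sub>T</sub>, ê<sub>P</sub>) preserves normalized dispersion:
Var(δ<sub>T</sub>) + Var(δ<sub>P</sub>) = 2 under unit-variance
normalization.  The sign of ê<sub>P</sub> is chosen so δ<sub>P</sub> > 0
means faster-than-belt; no downstream statistic depends on it.  A
zero-variance series is an error (`DegenerateSeriesError`), not a silent
fallback to unnormalized coordinates; "zero" is judged at a 1e−12 relative
threshold because an arithmetically constant series can carry ~1e−16
rounding noise.

## DFA

Canonical first-order DFA: integrate the mean-removed series, tile the
profile with non-overlapping boxes from the start, remove a linear
least-squares trend per box, pool residuals into the RMS fluctuation
F(n), and fit one α as the unweighted log10-log10 slope over all box
sizes (no crossover segmentation).  Default box layout: ~16 log-uniformly
spaced integer sizes in [4, N/4] (duplicates collapsed, ≥ 6 distinct
sizes required).  The minimum of 4 is the smallest box where a linear fit
leaves two residual degrees of freedom; the maximum of N/4 keeps at least
four boxes at the largest scale.  Forward-only boxing (tail remainder
discarded) is the default; a `boxing="both"` option also tiles from the
end.  At N ≈ 270–500 the two agree within the stochastic tolerances used
everywhere here.

Calibration (N = 500, 100 replicates each, `analysis/04_dfa_calibration.py`):
white noise → mean α 0.524, integrated white noise → 1.480, and the
estimate is monotone in the generator exponent across H ∈ {0.2, 0.5, 0.8,
1.2, 1.5}.  The small upward bias at α = ½ is the familiar small-box bias
of DFA-1 and is well inside the ±0.05–0.1 bands used by the tests.

The synthetic-noise generator is Fourier-filter synthesis: white-noise
rFFT amplitudes shaped by f^(−(2H−1)/2), inverse-transformed and
standardized; for H > 1 the series is the cumulative sum of an H−1 noise.
It is deliberately independent of the DFA implementation so it can serve
as its oracle.

## Surrogates

Three families, each rejection-sampled so every *accepted* surrogate is a
walkable trial (all T, L > 0 and |d<sub>net</sub>| ≤ 0.864 m), with a
capped attempt budget (default 1000 per surrogate) and a generation
report (attempts, rejection causes):

* **independent shuffle** — separate uniform permutations of T and L;
  preserves each marginal exactly, destroys temporal order and T–L
  coupling;
* **phase-randomized** — simple Theiler phase randomization applied to T
  and L separately (fresh phases each; an option shares one phase vector
  across both, off by default).  DC is untouched and the Nyquist bin keeps
  its real value for even N, so the periodogram is preserved to rounding.
  Positivity of the output is part of the same rejection loop, since a
  Gaussian-ized draw can leave the positive orthant;
* **paired shuffle** — one permutation applied to (T, L) jointly;
  preserves the stride point cloud, hence all stride speeds and the
  δ<sub>T</sub>/δ<sub>P</sub> variance ratio exactly.

Surrogate-based dependent measures are averaged over the surrogate set
(default 20 per trial) before any comparison, and each surrogate is
analyzed exactly like a real trial (own GEM frame, full DFA).

## Controllers

State x<sub>n</sub> = (T<sub>n</sub>, L<sub>n</sub>); plant
x<sub>n+1</sub> = x<sub>n</sub> + **G**(I + diag(ν))**u** + **η** with
ν<sub>i</sub> ~ N(0, σ<sub>i</sub>²) multiplicative noise on the control
signal (signal-dependent motor noise), η ~ N(0, diag(σ₃², σ₄²)) additive
state noise, and **G** = diag(g₁, g₂).  With u = 0 and no noise strides
repeat — the discrete skeleton of a limit-cycle walker.

The controller minimizes the expected single-step cost
E[C] = w<sub>e</sub>E[e²] + w<sub>p</sub>E[p²] + w<sub>u1</sub>u₁² +
w<sub>u2</sub>u₂², with the *linear* goal error e = L − vT (proportional
to the perpendicular GEM distance; the linear form is what makes the
expected cost exactly quadratic) and p the distance to the preferred
operating point, **subject to zero expected goal error at the next
stride** under the controller's *internal* model, which always assumes
unit plant gains.  Eliminating the constraint with a Lagrange multiplier
gives, with a = (−v, 1), e₀ = a·x, p₀ = x − x\*, and
A = diag(w<sub>e</sub>a<sub>i</sub>²σ<sub>i</sub>² +
w<sub>p</sub>σ<sub>i</sub>² + w<sub>ui</sub> + w<sub>p</sub>):

    u = −A⁻¹(w_p·p₀ + μ·a),   μ = (e₀ − w_p·a′A⁻¹p₀) / (a′A⁻¹a)

The constrained form was chosen over an unconstrained penalty-only
minimizer after comparing both against the known scaling regimes: with
the printed weights, the penalty-only controller corrects only ~71% of
the goal error per stride and yields α(δ<sub>P</sub>) ≈ 0.61 for MIP and
≈ 0.54 for OVC, inconsistent with the white-noise (≈ ½) and
anti-persistent (< ½) regimes these controllers are defined by.  Under
the constrained form the executed goal-error dynamics are e<sub>n+1</sub>
= (1 − g)e<sub>n</sub> + noise: white for g = 1 (MIP/POP), anti-persistent
for g = 1.24 (OVC), exactly the intended mechanism — the gain mismatch,
not the cost weights, separates optimal from over-correcting control.
The closed form is verified against an independent oracle (Gauss–Hermite
quadrature of the raw cost over all four noise dimensions, minimized
numerically along the constraint line) to 1e−6 on 1000 random states per
preset.

Parameters of the study conditions (all presets): v = 1.21 m/s,
T\* = 1.105 s, L\* = vT\* = 1.337 m, w<sub>e</sub> = w<sub>u1</sub> =
w<sub>u2</sub> = 10, σ₁ = σ₃ = 0.017, σ₂ = σ₄ = 0.010, 20 repetitions of
500 strides, x₀ = (T\*, L\*).  MIP: w<sub>p</sub> = 0, g = 1.  POP:
w<sub>p</sub> = 2.79, g = 1.  OVC: w<sub>p</sub> = 2.79, g₁ = g₂ = 1.24.
Costs and states stay in physical units; w<sub>p</sub> = 2.79 is unitful
(it weights a squared distance mixing s² and m²).

Per-repetition RNG streams derive from (seed, rep, attempt), so runs are
independent and individually reproducible, and every seed fed to numpy
stays below 2³¹.

### Belt compliance of simulated walkers

The controllers regulate *speed*, not position, so d<sub>net</sub> of a
simulated walker is a random walk with per-stride SD ≈ 0.023 m; over 500
strides a raw run stays within the half-belt bound with probability only
≈ 0.75 (MIP), ≈ 0.83 (POP), ≈ 0.93 (OVC).  `run_model_experiment`
therefore regenerates belt-violating repetitions from fresh sub-streams
by default (the count is reported), so that — like the surrogates — every
*analyzed* run is a trial that completed without walking off.  This
conditioning does not measurably bias the α statistics (MIP
α(δ<sub>T</sub>) 1.454 enforced vs 1.458 raw, α(δ<sub>P</sub>) 0.512 vs
0.505); the check can be disabled (`enforce_belt=False`).

### Direction contrasts

SD and α contrasts between δ<sub>T</sub> and δ<sub>P</sub> across the 20
repetitions use a plain two-group one-way F test, df = (1, 2n−2), with
identical-group degeneracy flagged rather than raised.  Across-rep means
carry 95% t-distribution confidence intervals.  p-values are reported but
never used as acceptance surfaces.

## Synthetic data: what it does and does not emulate

The human-like generator *is* the OVC preset (272 strides by default, the
mean analyzed trial length of the motivating experiment).  It reproduces
the statistical signature of human treadmill walking — persistent T and L
(α > ½), anti-persistent S and δ<sub>P</sub> (α < ½), variance elongated
along the GEM, mean speed within 2% of the belt speed — because that is
what the OVC mechanism produces by construction.  It does **not** emulate
within-stride kinematics, speed-dependent changes in means/variability
across walking speeds, between-subject heterogeneity, or equipment noise;
passing tests on these trials demonstrates the *pipeline's* correctness
and the *models'* internal consistency, not agreement with any particular
human dataset.

## Problem sizes

Model experiments run 20 × 500 strides (the study conditions); DFA
calibration uses 100 replicates of N = 500; surrogate sets use 20
surrogates per trial; the controller oracle uses 1000 states per preset.
The full test suite and the reproduction script each complete in well
under two minutes on one CPU.

## Known limitations

* The exact derivation of the published controller (its error definition
  and noise coupling) is not available in the main text we worked from;
  the constrained-optimum reading above is validated only against the
  printed qualitative and quantitative α/variance patterns.  One printed
  value resists it: the POP tangent exponent here is ≈ 0.97–0.99 over
  master seeds, slightly below the published "> 1.0" (the along-GEM
  correction fraction β/(γ+β) ≈ 0.22 implies AR(1) memory whose
  full-range DFA slope at N = 500 is just under 1).
* Printed model F statistics are not matched: their stated df (1, 39)
  cannot be reconciled with 2 × 20 balanced observations (which give
  error df 38); F values are reported with df (1, 38).
* DFA box layout beyond the [4, N/4] log-spaced default (and the exact
  published layout) is unknown; α values quoted here carry the estimator
  bias documented in the calibration table.
* Only the constant-speed GEM in (T, L) is implemented; other goal
  functions (overground, metronome timing) would change the error row
  a and the decomposition but not the architecture.
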