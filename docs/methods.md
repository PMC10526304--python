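# Methods

## Model

The simulator represents short-term (5–10 min) cardiac autonomic control
as three stages.

**Transmitter kinetics.** Each branch (sympathetic/norepinephrine,
vagal/acetylcholine) is driven by a renewal point process whose
inter-stimulus intervals are uniform on `[1/f_hi, 1/f_lo]`.  The default
bands are the physiological ones: vagal (0.25, 0.5) Hz — one input per
2–4 s, the respiratory drive — and sympathetic (0.025, 0.05) Hz.  Each
stimulus injects a quantum `q` into the neuroeffector junction; the
junction concentration decays at `kJ + kT`, a flux `kT·C_J` feeds the
extra-junctional space, which clears at `kE`.  Between stimuli the
linear system is advanced with its exact exponential solution, so the
integration is free of ODE discretisation error at any output step.
For short recordings the compartments start from their stationary means
(no filling transient); the spec-level primitive also supports empty
initial compartments.

**Transduction.** The local drive `d = wJ·C_J + wE·C_E` maps to the
branch signal through `g·[(1−β)·d^γ1 + β·d^γ2]` with cooperativity
exponents `γ1, γ2 ≥ 1` and mixing fraction `β`.  The sympathetic
transduction is linear (`γ = 1`).  The vagal transduction is strongly
cooperative in the calibrated defaults (`γ1 ≈ 11.1`, `γ2 = 6.6`,
`β = 0.03`), representing two receptor populations of different Hill
cooperativity reading the same transmitter concentration.  Cooperativity
is the load-bearing nonlinearity of the model: concentration itself is
exactly linear in the depletion scale `α` (scaling the released quantum
scales every concentration trace proportionally — a tested invariant),
but the *effect* scales as `α^γ`, so a 30% transmitter loss removes the
large majority of vagal heart-rate modulation.  A purely linear chain
cannot do this: under IPFM, sub-beat vagal kernels are
integral-conserving (their RR effect is exactly proportional to their
amplitude) and multi-beat level fluctuations transfer with at most
`α²` times a mean-rate factor, which caps the vagal power loss at
roughly one order of magnitude across the whole protocol — far short of
the two-to-three orders the depletion phenotype requires.  The two
exponents shape the collapse profile: the steep `γ1` term dominates the
first protocol steps, the shallower `γ2` term keeps a measurable,
strictly declining vagal residual through the severe states.

**Coupling and beat generation.** Vagal withdrawal mildly depresses
sympathetic amplitude: `S = S_raw·(1 − κ·(1 − ρ))` with `κ = 0.2` and
`ρ` the current vagal tone relative to its full-transmitter baseline.
The baseline is reconstructed exactly from the depleted run's own
compartment traces (concentrations are linear in `α`, so the `α = 1`
signal is recoverable pointwise); an analytic mean-level formula is
biased under cooperative transduction (Jensen gap) and produced a
spurious sympathetic step late in the protocol.  The combined drive
`m = m0 + S + V` must stay strictly positive — violations raise an
error naming the first offending time, never a silent clip — and feeds
an integral pulse frequency modulation pacemaker: beat `k+1` occurs
when `∫ m/T0 dt` accumulates 1 from beat `k` (trapezoidal integration,
linear interpolation of the crossing).  Zero-mean Gaussian noise of
SD 10 ms is added independently to each emitted RR interval;
non-positive intervals are redrawn deterministically.

## Feature battery

Population variances are used throughout, and the Poincaré width uses
the uncentred successive-difference moment, so the identities
`RMSSD = √2·SD1` and `SDNN² = (SD1² + SD2²)/2` hold to machine
precision.  Spectra are computed on the tachogram — the RR series
cubic-spline resampled at 4 Hz and linearly detrended — with either a
Hann-window Welch estimate (150 s segments, 50% overlap, density
normalised so the band integral recovers the tachogram variance within
5%) or a Burg autoregressive estimate (order 16, coefficients via
statsmodels).  Band powers integrate LF = [0.04, 0.15) Hz and
HF = [0.15, 0.40] Hz by the trapezoid rule with interpolated band
edges; normalized units are defined over LF + HF, so
`LF(nu) + HF(nu) = 100` exactly.  Very-low-frequency power is not
analysed (short recordings); linear detrending stands in for the
smoothness-prior detrending of commercial HRV software because it is
exactly reproducible.

## Calibration and the depletion protocol

The progression protocol holds every parameter fixed and steps
`α` = 1.00, 0.95, …, 0.55 (state 7 ↔ 70% ACh) with depletion applied to
the junctional concentration.  Replicates reuse one common seed list
across all ten states (common random numbers): paired stimulus trains
and noise cancel spectral-estimation error out of the state-to-state
differences, which is what makes strict zero-inversion trend checks
meaningful at 10 replicates.

No parameter values for this model class are observable, so free
parameters are fitted to the packaged 10-state reference trajectory.
`calibrate` minimises the summed squared relative error of {LF(nu),
HF(nu), SDNN, RMSSD, SD1, SD2} plus the squared log-ratio of LF/HF
(which spans 0.56–9.74; a relative error on its logarithm is ill-posed
where the logarithm crosses zero) over the ten states, using Powell's
derivative-free method in log-parameter space with restarts.  Powell is
used because the gain/period compensation ridge of this objective traps
a plain simplex several percent from the optimum, while conjugate
direction line searches recover self-generated targets exactly (a
tested property).  The default free set is the scale parameters (two
branch gains, pacemaker period); rate constants, transduction exponents
and stimulus bands can be freed explicitly.  The shipped defaults are
the converged product of this procedure, with the kinetic structure
(rates, exponents, bands) selected by a broad randomized search over
the same objective.  One structural choice sits outside the default
bands: the calibrated sympathetic stimulus band is (0.041, 0.066) Hz
(one input every 15–24 s) so that the renewal spectral peak falls inside
the LF band; with the textbook 20–40 s spacing the peak lies below
0.04 Hz and the branch contributes almost no LF power in this model.

Two identifiability limits are worth knowing.  First, the objective has
a flat valley trading the vagal gain and pacemaker period against each
other; within it the state-7 LF/HF moves by roughly ±10% between
equally good fits, so refits from different replicate realisations land
at slightly different points.  Second, the calibrated model does not
reach the reference trajectory's mid-state collapse rate: normalized
powers match the reference within ~15% at the endpoint states but
HF(nu) runs high by 40–95% at states 2–5 (the printed early-state
collapse is steeper than any parameterisation of this model family
achieved), and the severe-state SDNN/RMSSD cannot drop below the
10 ms output-noise floor (≈14 ms RMSSD), whereas the reference prints
values down to 6.7 ms.  All eight monotone trends, the endpoint
normalized units, and the balanced-rest (LF/HF < 1) and severe-imbalance
(LF/HF ≈ 9) regimes are reproduced.

## Synthetic cohorts

The clinical recordings behind the group comparison are not available;
the cohort generator produces stand-ins that reproduce the *design* of
that comparison, not patient data.  Each subject draws an ACh fraction
from a group range (controls 0.95–1.00, AD 0.55–0.80), a log-normal
gain multiplier (σ = 0.2, making medians the natural group summary),
and a fresh 5-minute simulation.  Group `variability_scale` factors
(control 0.6, AD 0.35) shrink both branch gains relative to the
progression calibration so that control medians land near the published
clinical medians (SDNN ≈ 36 ms, LF/HF ≈ 0.6) — clinical short-term
variability is far below the reference trajectory's balanced state —
with the lower AD scale reflecting the reduced total power of the
disease state.  With 20 subjects per group, all seven separating
features (SDNN, RMSSD, LF(nu), HF(nu), LF/HF, SD1, SD2) reach
Mann–Whitney p < 0.01 in ≥ 90% of master seeds; SD2/SD1 separates only
weakly, matching its marginal clinical significance.  What passing
these checks shows is that the pipeline detects a cholinergic-depletion
contrast of the published magnitude at the published sample size; it
says nothing about age matching, medication, comorbidity or the true
between-patient dispersion, none of which the generator attempts to
model.

The Mann–Whitney engine reports `U = min(U_x, U_y)` with midranks; for
`n·m ≤ 400` without ties the two-sided p-value is exact (full null
distribution by the standard counting recurrence — effectively complete
enumeration of label arrangements), otherwise a normal approximation
with tie and continuity corrections is used.  No multiplicity
correction is applied, mirroring per-feature reporting at p < 0.01.

## Numerical choices and degenerate inputs

Simulation step 0.01 s (capped at 0.05 s); exact exponential
compartment updates; beat placement by linear interpolation of the
IPFM phase.  Per-run substreams (vagal train, sympathetic train, output
noise) derive from one seed via `SeedSequence`, so every artifact is a
pure function of its seed.  Degenerate inputs are defined rather than
accidental: a `(f, f)` stimulus band gives a strictly periodic train;
zero stimuli give identically zero concentrations; a constant RR series
has SD1 = SD2 = 0 with the axis ratio reported as NaN; zero band power
yields NaN normalized units; AR order 0 returns the flat white-noise
spectrum at the sample variance.

## Known limitations

* Severe-state time-domain magnitudes are floored by the 10 ms output
  noise (see above).
* Mean RR is unconstrained by the reference tables; the calibrated
  resting mean (~590 ms) is on the fast side of normal.
* The transduction exponents are effective, not measured, quantities;
  they absorb whatever receptor-level nonlinearity the real
  concentration–effect chain contains.
* Baroreflex feedback, respiration as an explicit signal, ectopic
  beats and circadian modulation are out of scope; non-autonomic
  influences are lumped into the constant `m0`.
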