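# Methods

## Model and assumptions

The reference system is the Lavrentovich–Hemkin description of spontaneous
astrocytic Ca²⁺ oscillations: a three-variable ODE for cytosolic Ca²⁺ (X),
ER Ca²⁺ (Y) and cytosolic IP₃ (Z), in µM, with Hill-form SERCA uptake,
PLCδ1-mediated IP₃ production, and IP₃-receptor CICR release gated by
activating and inhibiting Ca²⁺ sites.  The ER is the only store; a constant
membrane influx `V_in` is the only external drive.  The exchange fluxes
between cytosol and ER cancel algebraically between the X and Y equations,
giving the identity `dX/dt + dY/dt = V_in − k_out·X`, which the test suite
checks to machine precision on random states for both model forms.

The Hill exponents are used exactly as published (n = 2.02, m = 2.2), not
rounded to 2.

### Dynamical regime at the default parameters

At the published defaults the system has an attracting limit cycle with
period ≈ 183.4 s; cytosolic Ca²⁺ spikes between ≈ 0.024 and 0.65 µM.  Because
the period is on the minutes scale, default runs integrate 2000 s sampled
every 0.5 s, which leaves ≥ 5 full cycles after the 30 % transient discard.

The oscillation exists only in a window of membrane influx.  Linearizing at
the equilibrium `X* = V_in/k_out` gives a leading eigenvalue real part of
+0.17 s⁻¹ at V_in = 0.05 but −0.08 s⁻¹ at V_in = 0.08 and −0.09 s⁻¹ at
V_in = 0.12: above roughly V_in ≈ 0.06–0.07 µM/s the equilibrium is stable
and every trajectory we examined (multiple initial states, 4000 s horizons,
both model forms) converges to it.  Influx-dependence studies therefore use
V_in ∈ {0.04, 0.05, 0.06}, inside the window, where the period decreases
monotonically with influx (224.7 → 183.4 → 171.9 s).  A sweep over
{0.04, 0.08, 0.12} raises a too-few-peaks error at 0.08 by design rather
than reporting a fictitious period.

## Circuit behavioral model

Kirchhoff's current law on three unit capacitors maps the ODEs to node
equations: concentrations are voltages (1 V ≡ 1 µM), fluxes currents
(1 A ≡ 1 µM/s), first-order rates conductances.  The nonlinear blocks are
differential-pair tanh modules with the published shape coefficients:

| block | form | replaces |
|---|---|---|
| SERCA | tanh(5X − 0.065) | v_M2-normalized SERCA Hill term |
| PLC | tanh(1.78X − 0.045) | v_p-normalized PLC Hill term |
| F_X1 | tanh(0.22 − 5.5X) + 1.08 | CICR Ca²⁺ activation gate |
| F_X2 | 4·tanh(3.9X − 0.07) | CICR inhibition-relief gate |
| F_Z | 5·tanh(2.5Z − 0.03) | CICR IP₃ gate |

and `I_CICR = 4·v_M3 · F_X1·F_X2·F_Z · (V_Y − V_X)`, the `(Y − X)` driving
term entering as the leak current divided by its conductance.

**Amplitude bridging.**  The printed tanh coefficients fix shapes only; in
hardware the output scale lives in tail currents and an output resistor,
whose values do not determine it uniquely (the F_X2 and F_Z prefactors 4 and
5 exceed the unit maxima of the gates they approximate).  We therefore expose
one multiplicative gain per block, `(A_serca, A_plc, A_cicr)`, fitted by
closed-form least squares (`A = ⟨f·g⟩/⟨g²⟩`) against the Hill targets on
uniform grids over X ∈ [0, 1.5] µM and Z ∈ [0, 1.0] µM — ranges that cover
the limit-cycle orbit with margin.  At the defaults the calibration gives
A_serca = 14.937 (≈ v_M2), A_plc = 0.04974 (≈ v_p) and A_cicr = 0.04379
(≈ 1/(4·5), undoing the oversized printed prefactors).  The `(Y − X)` factor
is common to both forms and cancels from the CICR fit.  An as-printed mode
(all gains 1) is retained for fidelity tests.

**Exact-plugin seam.**  The five blocks are pluggable callables, so the exact
Hill forms can replace the tanh fits.  In that configuration the circuit
right-hand side is floating-point identical to the reference right-hand side
(identical arithmetic, term by term), and fixed-step trajectories of the two
models are bit-identical — a machine-precision oracle for all the KCL wiring.

**Signed voltages.**  The tanh PLC fit is negative for X < 0.045/1.78 µM, so
the circuit's V_Z genuinely dips a few 10⁻⁵ V negative near the trough of a
V_in = 0.04 cycle.  Node voltages are therefore treated as signed: the
negative-concentration guard applies to the reference model only.

**Behavioral fidelity at the defaults.**  The calibrated circuit oscillates
with period 176.5 s vs 183.4 s for the reference (ratio 1.039, the circuit
slightly fast), with a normalized phase-portrait nearest-neighbor distance
of 0.049.  We document 0.1 as the acceptance threshold for this distance:
orbits further apart than 10 % of their joint range should be treated as a
calibration failure.

## Gliotransmitter release

Glutamate and ATP release gates follow
`τ·dG/dt = [1 + tanh(S(X − h))]·(1 − G) − G/d` with the published constants
(τ = 5 and 3, S = 100 µM⁻¹, h = 0.5 µM, d = 3).  τ values are used literally
as divisors.  With S = 100 the activation is a numerical step: within 10⁻⁸
of its rails 0.1 µM away from threshold.  The sign structure makes [0, 1]
forward-invariant; numerically the solver may undershoot 0 by ~10⁻¹⁷, which
tests tolerate at 10⁻⁹.  Under sustained suprathreshold Ca²⁺ the gate
relaxes to 2d/(2d+1) = 6/7.  The driving trace is held piecewise-linear
between samples; initial release state is (0, 0) (inactive).

## Numerical choices

* **Adaptive solver: LSODA, rtol 1e−8, atol 1e−10.**  The cycle alternates
  slow inter-spike drift with fast relaxation spikes; at equal tolerance
  LSODA needs ~20× fewer right-hand-side evaluations than explicit embedded
  Runge–Kutta here.  Halving the tolerances changes the estimated period by
  far less than 0.1 %.
* **Fixed-step RK4 (step 1 ms)** is available for bit-reproducible runs and
  the exact-plugin identity checks.
* **Guards, never clamps.**  Non-finite states abort the run with the failing
  time; reference-model states below −10⁻⁹ µM do likewise.  Clamping would
  silently change the dynamics.
* **Noise integration** restarts the adaptive solver at every hold boundary,
  so the error control never steps across a discontinuity; with the noise
  disabled the code path is the ordinary single-pass solve, making
  fraction-0 runs bit-identical to clean runs.
* **Period estimation** discards the first 30 % of the run, takes local
  maxima above mid-range + 0.25·(half-range) (plateau ties to the earliest
  sample), and reports the mean and SD of inter-peak intervals; fewer than
  three peaks is an explicit error, distinguishing "no oscillation" from
  "too short to tell".  The estimator is invariant to amplitude scaling and
  time translation, and agrees with an independent mean-crossing estimate
  within 1 % on reference runs.

## Noise model and its scope

Robustness runs add piecewise-constant noise, held for 0.1 s, each draw
uniform on ±(fraction × running max |clean signal|), seeded via independent
child streams per injection point.  The running (causal) maximum is used
rather than the a-priori maximum; for the constant source current the two
coincide.

Two injection modes are provided:

* **Closed-loop (default): the source current I_in**, the oscillator's input
  signal.  At fraction 0.10 the circuit keeps oscillating and its period
  moves by about 0.1 % (176.5 → 176.7 s at seed 11) — the "subtle effects"
  regime.
* **Open-loop: module inputs** (SERCA, PLC, CICR).  Feeding each block its
  clean input waveform plus noise, with no feedback, yields relative RMS
  output deviations of ≈ 0.12 (SERCA), 0.07 (PLC) and 0.15 (CICR) at
  fraction 0.10.  Note the composite CICR block is *not* less affected than
  the single-stage blocks under this metric in the behavioral model.

Module-input injection inside the closed loop is configurable but unstable
at fraction 0.10: the clean Ca²⁺ trough (0.0254 µM) lies within noise reach
of the F_X2 sign change (X ≈ 0.018 µM), below which I_CICR reverses sign
and the unbounded (Y − X) multiplier drives a finite-time escape.  A
physical circuit is stopped by its supply rails; rail saturation is outside
this behavioral model's scope, so the escape is reported loudly rather than
masked.

## What the experiments do and do not show

All experiments run on model-generated trajectories; there is no external
data.  Passing tests certify that the two model forms agree with each other
and with the published parameter structure — saturation points,
half-activations, conservation, limit-cycle period and its influx trend
inside the oscillatory window, release-pulse coupling — not that either
model matches biological astrocyte recordings or transistor-level (SPICE)
waveforms.  Transistor non-idealities, supply rails, device parameters and
power dissipation are out of scope.

## Known limitations

* No oscillation exists above V_in ≈ 0.07 µM/s with the published parameter
  set; influx trends are only meaningful inside the window (see above).
* The behavioral circuit is fragile to closed-loop module-input noise (see
  noise section); use the source-current target for closed-loop robustness.
* No bifurcation-continuation machinery: the influx dependence is explored
  by direct sweeps only.
* `hill` may return exactly 1.0 in floating point when x^p swamps k^p,
  although the mathematical supremum is open.
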