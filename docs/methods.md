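# Methods

## The model

Each Mauthner cell (M-cell) is a single-compartment modified Morris–Lecar
neuron with an additional calcium-dependent potassium current. The membrane
potential of cell *i* obeys

    C dv/dt = −I_Ca − I_K − I_KCa − I_L − I_syn + I_app(t)

with

    I_Ca  = g_Ca · m∞(v) · (v − v_Ca),   m∞(v) = ½(1 + tanh((v − v1)/v2))
    I_K   = g_K · n · (v − v_K)
    I_KCa = g_KCa · [Ca]/([Ca] + k1) · (v − v_K)
    I_L   = g_L · (v − v_L)
    I_syn = g_syn · (v − v_syn) · s_other

where `s_other` is the synaptic variable of the *other* M-cell. The potassium
gate relaxes as dn/dt = φ(n∞(v) − n)/τ_n(v) with
n∞(v) = ½(1 + tanh((v − v3)/v4)) and τ_n(v) = 1/cosh((v − v3)/(2 v4)).
Intracellular calcium follows the balance equation

    d[Ca]/dt = ε(−μ I_Ca − k_Ca [Ca])

and each cell's synaptic output gate follows
ds/dt = α s∞(v)(1 − s) − β s with the logistic s∞(v) = 1/(1+exp(−(v−θ_s)/σ_s)).

The applied current is I_app = I0 + I_i(t) + w_M · E_net, where I_i is the
stimulus pulse train delivered to cell 1 only (I_2 ≡ 0) and E_net is a slow
activity-dependent adaptation variable standing in for the lumped net
pre-synaptic drive (VIIIth-nerve excitation minus feed-forward inhibition):

    dE_net/dt = (ag_max/([Ca] + k2) − E_net) / ρ

Its target decreases reciprocally with calcium; ρ = 8400 ms makes E_net the
slowest variable (≈8.4 s relaxation). `ag_max`, the maximal net excitation, is
the control parameter that stands in for social phenotype: 41.5
(dominant-like), 42.2 (communal-like), 43.5 (subordinate-like).

A note on the adaptation equation: the placement of ρ admits two readings
(rate multiplier vs time constant). We use the time-constant form. It is the
only reading under which (i) the rest state lands where the model's published
operating point sits (E_net ≈ ag_max/([Ca]*+k2) ≈ 0.96–1.01 inside the
analysis band [0.9, 1.2]), and (ii) E_net shows the lagged, non-monotonic
between-spike dynamics (dip then recovery) that drives irregular responding.

## Habituation mechanism

All variables except (v, n) are slow. A stimulus pulse that fires the cell
drives a large calcium influx; elevated calcium both recruits I_KCa and
lowers the E_net target, so repeated firing ratchets the operating point
toward lower excitability. Whether a pulse fires the cell from a given slow
state is summarized by the *jump-up region* of the ([Ca], E_net) plane:
slow states from which a single pulse (fast variables frozen at rest)
produces a spike. Habituation is the slow trajectory exiting this region;
irregular (aperiodic) responding occurs when the trajectory hovers at the
boundary, where firing injects calcium (pushing it out) and skipping lets
calcium decay and E_net recover (pulling it back in).

## Stimulus calibration

The published protocol fixes the pulse amplitude (4.5) and timing (40 pulses
at 1 or 0.2 Hz starting at 20 s) but not the duration of the model's
rectangular current pulse. The duration is not a free detail: the phenotype
separation exists only for pulses *marginally* above the single-pulse firing
threshold, because the slow ratchet shifts the firing margin by only a few
percent of the stimulus. `calibrate_pulse_width` therefore (1) bisects for
the minimal width that fires the subordinate-like cell from rest
(≈1.95 ms at amplitude 4.5), then (2) walks upward in 0.001 ms steps until
the full phenotype contract holds:

- subordinate-like cell fires exactly one action potential per pulse;
- dominant-like cell at 1 Hz responds initially and not at all after
  stimulus 10;
- subordinate-like cell at 1 Hz responds irregularly (firing fraction
  strictly between 0 and 1, no exact period ≤ 10) over the stationary
  100–300 s window;
- both phenotypes answer each of the first five 0.2 Hz stimuli.

The result, **1.963 ms**, is frozen as the package default
(`mauthner.stimulus.DEFAULT_WIDTH`). Below it the response locks onto
periodic skipping (period 4, 5, …); above it onto period 3, then continuous
firing. The contract bracket is ~0.02 ms wide — a direct illustration of how
delicately the circuit sits at its firing boundary.

## Numerics

- Reference integrator: fixed-step classical RK4 at 0.01 ms, compiled with
  numba. Steps are truncated so that pulse edges are exact step boundaries,
  and the full 10-dimensional state is captured exactly at every pulse
  onset (used by the slow-plane projection and the onset-sampled extremes).
  The phraseable alternative — an error-controlled integrator — is
  implemented as a cross-check mode (scipy RK45 integrated piecewise
  between pulse edges, rtol 1e−8) and agrees with the kernel to <1e−3 mV on
  pulse responses; step-halving (0.005 ms) changes the 30 s voltage of the
  dominant-like 1 Hz run by <0.01 mV.
- Trace storage: uniform 0.5 ms sampling (configurable down to the step
  size). Spike detection uses upward crossings of 0 mV — action potentials
  in this regime overshoot 0 mV by tens of mV while subthreshold responses
  stay below ≈ −20 mV — with linear interpolation for latency; 0.5 ms
  sampling localizes crossings well inside the 1 ms requirement.
- Calcium can round off marginally below zero during integration; it is
  clamped to 0 before the saturating terms and the event counted (logged at
  debug level).
- Quasi-steady initialization: 20 s of stimulus-free relaxation from
  (v, n, Ca, s, E_net) = (−30, n∞(−30), 3, s∞(−30), 1); the routine raises
  if the final drift exceeds 1e−3 per ms. Any start in the rest state's
  basin reaches the same state (multi-start test). Note E_net, with its
  8.4 s time constant, is only ≈90 % relaxed after 20 s; this finite
  relaxation is part of the protocol definition, not an error.
- Suprathreshold areas A_i integrate max(v − θ_A, 0) per stimulus window by
  the trapezoidal rule; θ_A defaults to −30 mV, between rest (≈−34.3 mV)
  and spike peak, so subthreshold responses retain small positive areas and
  the log-scale return map is defined. Classifications are robust to
  θ_A ± 2 mV.
- Pattern classification over a stationary window (≥20 stimuli): firing
  fraction f = 0 with converged areas → subthreshold fixed point; f = 1 →
  suprathreshold fixed point; an exactly repeating fired sequence with
  period ≤ 10 → subthreshold (f ≤ ½) or suprathreshold (f > ½) periodic;
  otherwise irregular. Exact repetition is well-defined because the model
  and integrator are deterministic at fixed step size.
- Faithfulness windows: initial 20–30 s and stable 40–70 s (stimulation
  onset 20 s), half-open over pulse onsets.
- Jump-up grid: region [3, 3.2] × [0.9, 1.2], increment 0.01 (tests use
  0.02 for speed; the structure is identical), fast variables frozen at the
  phenotype's rest values, one pulse delivered immediately, spike sought in
  the following 300 ms. The firing indicator must be monotone
  (nonincreasing in [Ca], nondecreasing in E_net); a frontier broken by
  more than one grid cell raises rather than silently mis-mapping.

## Behavioral generator

The synthetic raster generator emulates the shape of the group-level
behavioral findings rather than any individual dataset: per animal and
stimulus k (0-based), an escape response is Bernoulli with probability
plateau + (p0 − plateau)·exp(−k/τ). Defaults (p0 = 1 throughout): at 1 Hz
plateaus 0.05/0.25/0.55 and τ = 3/4/5 stimuli for dominant/communal/
subordinate; at 0.2 Hz plateaus 0.45/0.55/0.70 with the same τ. These
encode the published orderings (subordinates respond most, dominants least;
everyone responds more at 0.2 Hz) with plateau gaps large enough to be
resolved at realistic group sizes. What the generator deliberately omits:
within-animal serial correlation, inter-animal heterogeneity beyond
Bernoulli noise, and any latency–response-probability coupling (latencies
are i.i.d. Gaussian, default 5 ± 1 ms, truncated at 0.5 ms). Tests passing
on generated data therefore validate the estimators and orderings, not
individual-level response dynamics.

Parameter recovery fits the same exponential-plateau curve to per-stimulus
group means by least squares (scipy `curve_fit`, bounded); at 200 animals
per group, p0 and plateau are recovered within ±0.05.

## Problem sizes and known limitations

Long-run analyses use 300 stimuli (320 s of simulated time) to cover the
100–300 s stationary window; Faithfulness scans run each grid cell to 70 s.
The full default scan grids (6 frequencies × 17 ag_max values or 13
amplitudes) complete in a few minutes with the compiled kernel.

Limitations: Faithfulness is a ratio of integer response counts, and the
deterministic response patterns mode-lock onto discrete skipping periods;
as a parameter sweeps across a locking boundary the count can dip by a
single response, so Faithfulness is monotone in ag_max only as a trend,
not exactly cell-by-cell on a fine grid. The two-cell structure is kept as published even though cell 2
never receives stimulus and its rest-state synaptic feedback is nearly
constant; no channel noise, so "irregular" means deterministic aperiodicity
(no chaos certification is attempted); the phenotype phenomenology depends
on the calibrated pulse width as described above, and the width band is
narrow — protocols with substantially stronger or longer pulses produce
uniform full responding instead of habituation; empirical group statistics
(ANOVA families, field-potential latencies) are outside the model's scope.
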