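"""Numerical integration of the circuit and habituation protocol runs.

The reference integrator is a fixed-step classical Runge-Kutta (RK4) scheme at
0.01 ms, compiled with numba. Step boundaries are forced onto every pulse edge
so the rectangular stimulus is resolved exactly, and the full state is captured
at each pulse onset (used by the slow-variable analyses). An error-controlled
mode (scipy RK45, integrated piecewise between pulse edges) is provided as an
independent cross-check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .model import activation_curves, circuit_derivatives
from .params import CellState, CircuitState, ModelParameters, PHENOTYPE_AG_MAX
from .stimulus import DEFAULT_WIDTH, PulseTrain

__all__ = [
    "SimulationTrace",
    "integrate",
    "quasi_steady_state",
    "run_habituation_protocol",
    "calibrate_pulse_width",
]

logger = logging.getLogger(__name__)

DEFAULT_STEP = 0.01          # ms, reference RK4 step
DEFAULT_SAMPLE = 0.5         # ms, trace storage resolution
MAX_STEP = 0.1               # ms, largest permitted fixed step

# indices into the packed parameter array (see params.PARAM_ORDER)
# 0 g_Ca  1 g_K   2 g_KCa 3 g_L   4 v_Ca  5 v_K   6 v_L
# 7 v1    8 v2    9 v3   10 v4   11 k1   12 k2   13 k_Ca
# 14 eps 15 mu   16 C    17 phi  18 alpha 19 beta
# 20 theta_s 21 sigma_s 22 g_syn 23 v_syn 24 I0 25 w_M 26 ag_max 27 rho


@njit(cache=True)
def _rhs(y, p, d1, d2, dy):
    for c in range(2):
        o = 5 * c
        v = y[o]
        n = y[o + 1]
        Ca = y[o + 2]
        if Ca < 0.0:
            Ca = 0.0
        s = y[o + 3]
        E = y[o + 4]
        s_other = y[8 - 5 * c]  # synaptic variable of the other cell
        drive = d1 if c == 0 else d2

        m_inf = 0.5 * (1.0 + np.tanh((v - p[7]) / p[8]))
        n_inf = 0.5 * (1.0 + np.tanh((v - p[9]) / p[10]))
        tau_n = 1.0 / np.cosh((v - p[9]) / (2.0 * p[10]))
        s_inf = 1.0 / (1.0 + np.exp(-(v - p[20]) / p[21]))

        I_Ca = p[0] * m_inf * (v - p[4])
        I_K = p[1] * n * (v - p[5])
        I_KCa = p[2] * (Ca / (Ca + p[11])) * (v - p[5])
        I_L = p[3] * (v - p[6])
        I_syn = p[22] * (v - p[23]) * s_other
        I_app = p[24] + drive + p[25] * E

        dy[o] = (-I_Ca - I_K - I_KCa - I_L - I_syn + I_app) / p[16]
        dy[o + 1] = p[17] * (n_inf - n) / tau_n
        dy[o + 2] = p[14] * (-p[15] * I_Ca - p[13] * Ca)
        dy[o + 3] = p[18] * s_inf * (1.0 - s) - p[19] * s
        dy[o + 4] = (p[26] / (Ca + p[12]) - E) / p[27]


@njit(cache=True)
def _integrate_kernel(y0, p, pulse_times, width, amplitude,
                      t0, t_end, h, sample_interval,
                      t_out, y_out, d_out, onset_states):
    """Fixed-step RK4 with steps truncated at pulse edges.

    Returns (n_samples, status, clamp_count); status 0 = ok, 1 = non-finite
    state encountered.
    """
    n_pulses = pulse_times.shape[0]
    n_edges = 2 * n_pulses
    y = y0.copy()
    k1 = np.empty(10)
    k2 = np.empty(10)
    k3 = np.empty(10)
    k4 = np.empty(10)
    yt = np.empty(10)

    t = t0
    j = 0                      # next pulse-edge index (even = onset, odd = offset)
    ip = 0                     # next pulse-onset capture index
    m = 0                      # samples written
    next_sample = t0
    clamps = 0
    eps_t = 1e-9

    while True:
        # advance past any edges at the current time
        while j < n_edges:
            k = j // 2
            edge = pulse_times[k] + (j % 2) * width
            if edge <= t + eps_t:
                j += 1
            else:
                break
        # capture state exactly at pulse onsets
        while ip < n_pulses and pulse_times[ip] <= t + eps_t:
            if pulse_times[ip] >= t0 - eps_t:
                for q in range(10):
                    onset_states[ip, q] = y[q]
            ip += 1
        inside = (j % 2) == 1
        d1 = amplitude if inside else 0.0

        # store samples due at or before the current time
        if t + eps_t >= next_sample:
            t_out[m] = t
            for q in range(10):
                y_out[m, q] = y[q]
            d_out[m] = d1
            m += 1
            while next_sample <= t + eps_t:
                next_sample += sample_interval

        if t >= t_end - eps_t:
            if m == 0 or t_out[m - 1] < t - eps_t:
                t_out[m] = t
                for q in range(10):
                    y_out[m, q] = y[q]
                d_out[m] = d1
                m += 1
            break

        # choose step: never cross a pulse edge or the horizon
        ht = h
        if j < n_edges:
            k = j // 2
            edge = pulse_times[k] + (j % 2) * width
            if t + ht > edge:
                ht = edge - t
        if t + ht > t_end:
            ht = t_end - t

        _rhs(y, p, d1, 0.0, k1)
        for q in range(10):
            yt[q] = y[q] + 0.5 * ht * k1[q]
        _rhs(yt, p, d1, 0.0, k2)
        for q in range(10):
            yt[q] = y[q] + 0.5 * ht * k2[q]
        _rhs(yt, p, d1, 0.0, k3)
        for q in range(10):
            yt[q] = y[q] + ht * k3[q]
        _rhs(yt, p, d1, 0.0, k4)
        for q in range(10):
            y[q] = y[q] + (ht / 6.0) * (k1[q] + 2.0 * k2[q] + 2.0 * k3[q] + k4[q])
        # integration round-off can push [Ca] slightly negative; clamp
        for c in range(2):
            if y[5 * c + 2] < 0.0:
                y[5 * c + 2] = 0.0
                clamps += 1
        for q in range(10):
            if not np.isfinite(y[q]):
                return m, 1, clamps
        t += ht

    return m, 0, clamps


@dataclass
class SimulationTrace:
    """Sampled trajectory of the circuit under a pulse protocol.

    ``y`` columns are ``[v1, n1, Ca1, s1, E1, v2, n2, Ca2, s2, E2]``;
    ``pulse_onset_states`` holds the exact state at each pulse onset.
    """

    t: np.ndarray
    y: np.ndarray
    drive: np.ndarray
    pulse_onset_states: np.ndarray
    train: PulseTrain
    params: ModelParameters
    step: float
    sample_interval: float

    @property
    def v1(self) -> np.ndarray:
        return self.y[:, 0]

    @property
    def Ca1(self) -> np.ndarray:
        return self.y[:, 2]

    @property
    def E_net1(self) -> np.ndarray:
        return self.y[:, 4]

    def final_state(self) -> CircuitState:
        return CircuitState.from_vector(self.y[-1])

    def to_dataframe(self):
        import pandas as pd

        cols = ["v1", "n1", "Ca1", "s1", "Enet1", "v2", "n2", "Ca2", "s2", "Enet2"]
        df = pd.DataFrame(self.y, columns=cols)
        df.insert(0, "t_ms", self.t)
        df["drive1"] = self.drive
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


_EMPTY_TRAIN_TIMES = np.empty(0, dtype=np.float64)


def integrate(initial: CircuitState, params: ModelParameters, train: PulseTrain | None,
              t_end: float, step: float = DEFAULT_STEP,
              sample_interval: float = DEFAULT_SAMPLE, t0: float = 0.0,
              method: str = "rk4") -> SimulationTrace:
    """Integrate the circuit from ``initial`` over ``[t0, t_end]``.

    Parameters
    ----------
    train : PulseTrain or None
        Stimulus protocol for cell 1 (None = no stimulation).
    step : float
        Fixed RK4 step in ms (<= 0.1; the reference value is 0.01).
    sample_interval : float
        Trace storage resolution in ms (floored at ``step``).
    method : {"rk4", "adaptive"}
        Fixed-step reference kernel, or error-controlled RK45 cross-check.
    """
    if t_end < t0:
        raise ValueError(f"t_end ({t_end}) must be >= t0 ({t0})")
    if step <= 0 or step > MAX_STEP:
        raise ValueError(f"step must lie in (0, {MAX_STEP}] ms, got {step}")
    if train is not None and train.count > 0 and step > train.width:
        raise ValueError(f"step ({step} ms) exceeds pulse width ({train.width} ms)")
    initial.validate()

    sample_interval = max(sample_interval, step)
    if train is None:
        train = PulseTrain(onset=t0, frequency=1.0, count=0)
    pulse_times = train.times().astype(np.float64) if train.count else _EMPTY_TRAIN_TIMES
    y0 = initial.to_vector()
    p = params.to_array()

    if method == "adaptive":
        return _integrate_adaptive(y0, p, params, train, pulse_times, t0, t_end,
                                   step, sample_interval)
    if method != "rk4":
        raise ValueError(f"unknown method {method!r}")

    n_max = int(np.ceil((t_end - t0) / sample_interval)) + 2 * train.count + 8
    t_out = np.empty(n_max)
    y_out = np.empty((n_max, 10))
    d_out = np.empty(n_max)
    onset_states = np.full((train.count, 10), np.nan)

    m, status, clamps = _integrate_kernel(
        y0, p, pulse_times, train.width, train.amplitude,
        float(t0), float(t_end), float(step), float(sample_interval),
        t_out, y_out, d_out, onset_states,
    )
    if status != 0:
        raise FloatingPointError(
            f"non-finite state encountered near t = {t_out[max(m - 1, 0)]:.3f} ms"
        )
    if clamps:
        logger.debug("clamped slightly negative [Ca] on %d integration steps", clamps)

    return SimulationTrace(
        t=t_out[:m].copy(), y=y_out[:m].copy(), drive=d_out[:m].copy(),
        pulse_onset_states=onset_states, train=train, params=params,
        step=step, sample_interval=sample_interval,
    )


def _integrate_adaptive(y0, p, params, train, pulse_times, t0, t_end,
                        step, sample_interval):
    """Error-controlled RK45 integrated piecewise between pulse edges."""
    from scipy.integrate import solve_ivp

    dy = np.empty(10)

    def rhs(t, y, d1):
        _rhs(y, p, d1, 0.0, dy)
        return dy.copy()

    edges = train.edges() if train.count else np.empty(0)
    breakpoints = np.concatenate(([t0], edges[(edges > t0) & (edges < t_end)], [t_end]))
    ts, ys, ds = [], [], []
    onset_states = np.full((train.count, 10), np.nan)
    y = y0.copy()
    if train.count and abs(pulse_times[0] - t0) < 1e-9:
        onset_states[0] = y0
    last = len(breakpoints) - 2
    for seg, (a, b) in enumerate(zip(breakpoints[:-1], breakpoints[1:])):
        d1 = float(train.drive_at(0.5 * (a + b)))
        t_eval = np.concatenate([np.arange(a, b, sample_interval), [b]])
        sol = solve_ivp(rhs, (a, b), y, args=(d1,), method="RK45",
                        rtol=1e-8, atol=1e-10, t_eval=t_eval, max_step=5.0)
        if not sol.success:
            raise FloatingPointError(f"adaptive integration failed on [{a}, {b}]: {sol.message}")
        y = sol.y[:, -1]
        stop = None if seg == last else -1  # drop b: next segment re-emits it
        ts.append(sol.t[:stop])
        ys.append(sol.y.T[:stop])
        ds.append(np.full(sol.t[:stop].size, d1))
        idx = np.searchsorted(pulse_times, b - 1e-9)
        if idx < train.count and abs(pulse_times[idx] - b) < 1e-9:
            onset_states[idx] = y

    return SimulationTrace(
        t=np.concatenate(ts), y=np.vstack(ys), drive=np.concatenate(ds),
        pulse_onset_states=onset_states, train=train, params=params,
        step=step, sample_interval=sample_interval,
    )


def default_initial_guess(params: ModelParameters) -> CircuitState:
    """Generic resting start used for quasi-steady relaxation."""
    v0 = -30.0
    _, n_inf, _, s_inf = activation_curves(v0, params)
    cell = CellState(v=v0, n=n_inf, Ca=3.0, s=s_inf, E_net=1.0)
    return CircuitState.symmetric(cell)


def quasi_steady_state(params: ModelParameters, relax_duration: float = 20000.0,
                       initial: CircuitState | None = None,
                       step: float = DEFAULT_STEP,
                       drift_tol: float = 1e-3) -> CircuitState:
    """Relax the circuit with no stimulus and return the quasi-steady state.

    All protocols start from this state (the model sits at a stable rest
    point without stimulation). Raises ``RuntimeError`` if the state is still
    drifting at the end of the relaxation, which signals a parameter set
    without a reachable rest point.
    """
    if initial is None:
        initial = default_initial_guess(params)
    trace = integrate(initial, params, None, t_end=relax_duration, step=step,
                      sample_interval=max(relax_duration / 200.0, step))
    state = trace.final_state()
    drift = np.max(np.abs(circuit_derivatives(state, params)))
    if drift > drift_tol:
        raise RuntimeError(
            f"state still drifting after {relax_duration} ms relaxation "
            f"(max |dy/dt| = {drift:.3g} > {drift_tol:.3g})"
        )
    return state


def run_habituation_protocol(params: ModelParameters, frequency: float = 1.0,
                             count: int = 40, amplitude: float = 4.5,
                             width: float = DEFAULT_WIDTH, onset: float = 20000.0,
                             t_end: float | None = None,
                             step: float = DEFAULT_STEP,
                             sample_interval: float = DEFAULT_SAMPLE,
                             spike_threshold: float = 0.0,
                             initial: CircuitState | None = None):
    """Quasi-steady initialization followed by a periodic pulse protocol.

    Returns ``(trace, series)`` where ``series`` is the per-stimulus
    :class:`~mauthner.analysis.ResponseSeries` of cell 1. ``initial`` can
    supply a precomputed quasi-steady state to skip the relaxation.
    """
    from .analysis import detect_responses  # local import to avoid a cycle

    train = PulseTrain(onset=onset, frequency=frequency, count=count,
                       amplitude=amplitude, width=width)
    if t_end is None:
        t_end = train.onset + count * train.period
    if initial is None:
        initial = quasi_steady_state(params, relax_duration=min(onset, 20000.0),
                                     step=step)
    trace = integrate(initial, params, train, t_end=t_end, step=step,
                      sample_interval=sample_interval)
    series = detect_responses(trace, train, spike_threshold=spike_threshold)
    return trace, series


def _spike_count_first_pulse(params: ModelParameters, width: float,
                             amplitude: float, step: float,
                             initial: CircuitState) -> int:
    """Spikes of cell 1 within one period of a single pulse from rest."""
    from .analysis import count_upward_crossings

    train = PulseTrain(onset=1000.0, frequency=1.0, count=1,
                       amplitude=amplitude, width=width)
    trace = integrate(initial, params, train, t_end=2000.0, step=step,
                      sample_interval=0.1)
    sel = trace.t >= train.onset
    return count_upward_crossings(trace.v1[sel], 0.0)


def calibrate_pulse_width(bracket: tuple[float, float] = (1.0, 100.0),
                          resolution: float = 0.001,
                          amplitude: float = 4.5,
                          step: float = DEFAULT_STEP,
                          full_contract: bool = True,
                          max_widths: int = 100) -> float:
    """Select the pulse width that reproduces the published response phenotypes.

    The protocol never fixes the duration of the model current pulse, yet the
    response phenotypes live in a narrow band just above the firing threshold:
    a marginally suprathreshold pulse is what lets the slow calcium/adaptation
    drift gate firing. The search proceeds in two stages:

    1. bisect ``bracket`` down to ``resolution`` for the smallest width at
       which the subordinate-like cell (ag_max = 43.5) fires at least one
       action potential to the first pulse from quasi-steady state;
    2. walk upward on a ``resolution`` grid until the phenotype contract holds:

       a. the subordinate-like cell fires exactly one spike to the first pulse;
       b. the dominant-like cell (ag_max = 41.5) at 1 Hz responds to at least
          one of the first 10 stimuli and to none afterwards;
       c. (``full_contract``) the subordinate-like cell at 1 Hz responds
          irregularly over the 100-300 s window (firing fraction strictly
          between 0 and 1, no exact period up to 10), and both phenotypes
          answer every one of the first five 0.2 Hz stimuli.

    Raises ``RuntimeError`` when stage 1 finds no firing width (a model
    configuration error) or the upward walk exhausts ``max_widths`` grid
    points (contract unattainable near threshold).
    """
    params_sub = ModelParameters(ag_max=PHENOTYPE_AG_MAX["subordinate"])
    params_dom = ModelParameters(ag_max=PHENOTYPE_AG_MAX["dominant"])
    qss_sub = quasi_steady_state(params_sub, step=step)
    qss_dom = quasi_steady_state(params_dom, step=step)
    qss_of = {id(params_dom): qss_dom, id(params_sub): qss_sub}

    lo, hi = bracket
    if _spike_count_first_pulse(params_sub, lo, amplitude, step, qss_sub) > 0:
        hi = lo
    elif _spike_count_first_pulse(params_sub, hi, amplitude, step, qss_sub) == 0:
        raise RuntimeError(
            f"no spike to a single pulse even at width {hi} ms; "
            "check the model configuration"
        )
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if _spike_count_first_pulse(params_sub, mid, amplitude, step, qss_sub) > 0:
            hi = mid
        else:
            lo = mid
    threshold_width = np.ceil(hi / resolution) * resolution

    from .analysis import _fired_period, faithfulness

    for k in range(max_widths):
        width = round(threshold_width + k * resolution, 6)
        if _spike_count_first_pulse(params_sub, width, amplitude, step, qss_sub) != 1:
            continue
        _, dom = run_habituation_protocol(params_dom, frequency=1.0, count=40,
                                          amplitude=amplitude, width=width,
                                          step=step, initial=qss_dom)
        if not dom.fired[:10].any() or dom.fired[10:].any():
            continue
        if not full_contract:
            return float(width)
        ok_low = True
        for p in (params_dom, params_sub):
            _, low = run_habituation_protocol(p, frequency=0.2, count=5,
                                              amplitude=amplitude, width=width,
                                              step=step, initial=qss_of[id(p)])
            if not low.fired.all():
                ok_low = False
                break
        if not ok_low:
            continue
        _, sub = run_habituation_protocol(params_sub, frequency=1.0, count=300,
                                          amplitude=amplitude, width=width,
                                          step=step, t_end=320000.0,
                                          initial=qss_sub)
        window = (sub.stimulus_times >= 120000.0) & (sub.stimulus_times < 300000.0)
        fired = sub.fired[window]
        if 0.0 < fired.mean() < 1.0 and _fired_period(fired, 10) is None:
            return float(width)
    raise RuntimeError(
        f"no width within {max_widths} grid points above the firing threshold "
        f"({threshold_width} ms) satisfies the phenotype contract"
    )
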