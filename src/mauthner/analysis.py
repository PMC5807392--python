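"""Per-stimulus response analysis of simulated traces.

Covers spike detection and latency per stimulus, the Faithfulness statistic
(fraction of stimuli in a window that evoke an action potential), suprathreshold
-area return maps with the five-type response classification, the jump-up-region
scan in the slow ([Ca], E_net) plane, slow-variable projections, and
Faithfulness contour scans over stimulus frequency crossed with either the
maximal net excitation ag_max or the pulse amplitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .params import CircuitState, ModelParameters
from .stimulus import DEFAULT_WIDTH, PulseTrain

__all__ = [
    "ResponseSeries",
    "JumpUpGrid",
    "detect_responses",
    "faithfulness",
    "response_areas",
    "return_map",
    "classify_pattern",
    "jump_up_grid",
    "slow_projection",
    "faithfulness_scan",
    "PATTERN_CLASSES",
]

logger = logging.getLogger(__name__)

DEFAULT_SPIKE_THRESHOLD = 0.0    # mV; action potentials overshoot 0 mV
DEFAULT_AREA_THRESHOLD = -30.0   # mV; between rest (~-34 mV) and spike peak

#: Response-pattern classes, in the order traversed as ag_max increases.
PATTERN_CLASSES = (
    "subthreshold_fixed_point",
    "subthreshold_periodic",
    "irregular",
    "suprathreshold_periodic",
    "suprathreshold_fixed_point",
)

# default scan grids (frequency in Hz)
FREQUENCY_GRID = (0.1, 0.2, 0.5, 1.0, 2.0, 5.0)
AG_MAX_GRID = tuple(np.round(np.arange(40.5, 44.5 + 1e-9, 0.25), 4))
AMPLITUDE_GRID = tuple(np.round(np.arange(3.0, 6.0 + 1e-9, 0.25), 4))

#: Faithfulness measurement windows (ms): the initial 20-30 s interval and the
#: stable 40-70 s interval, with stimulation starting at 20 s.
DEFAULT_WINDOWS = {"initial": (20000.0, 30000.0), "stable": (40000.0, 70000.0)}


def count_upward_crossings(v: np.ndarray, threshold: float) -> int:
    """Number of upward threshold crossings in a sampled voltage trace."""
    v = np.asarray(v)
    return int(np.count_nonzero((v[:-1] < threshold) & (v[1:] >= threshold)))


@dataclass
class ResponseSeries:
    """Per-stimulus response summary of cell 1.

    ``latencies`` are ms from pulse onset to the spike-threshold crossing
    (NaN where no spike occurred); ``areas`` holds the suprathreshold areas
    A_i once :func:`response_areas` has been attached.
    """

    stimulus_times: np.ndarray
    fired: np.ndarray
    latencies: np.ndarray
    areas: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.stimulus_times)
        if len(self.fired) != n or len(self.latencies) != n:
            raise ValueError("stimulus_times, fired and latencies must have equal length")
        if self.areas is not None and len(self.areas) != n:
            raise ValueError("areas length must match stimulus count")
        if np.any(np.isfinite(self.latencies) != self.fired):
            raise ValueError("latency must be defined exactly where fired is true")

    def __len__(self) -> int:
        return len(self.stimulus_times)

    def with_areas(self, areas: np.ndarray) -> "ResponseSeries":
        return replace(self, areas=np.asarray(areas, dtype=np.float64))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "stimulus": np.arange(len(self)),
            "t_ms": self.stimulus_times,
            "fired": self.fired.astype(int),
            "latency_ms": self.latencies,
        })
        if self.areas is not None:
            df["area"] = self.areas
        return df


def _window_slices(trace_t: np.ndarray, train: PulseTrain):
    """Sample-index ranges for each per-stimulus window [t_i, t_i + period)."""
    times = train.times()
    starts = np.searchsorted(trace_t, times, side="left")
    ends = np.searchsorted(trace_t, times + train.period, side="left")
    return times, starts, ends


def detect_responses(trace, train: PulseTrain,
                     spike_threshold: float = DEFAULT_SPIKE_THRESHOLD) -> ResponseSeries:
    """Detect action potentials of cell 1 in each per-stimulus window.

    A stimulus counts as answered when the membrane potential crosses
    ``spike_threshold`` upward within ``[times[i], times[i] + period)``;
    the latency is the (linearly interpolated) first-crossing time minus the
    pulse onset.
    """
    if train.count == 0:
        empty = np.empty(0)
        return ResponseSeries(empty, empty.astype(bool), empty)
    if trace.t[-1] < train.times()[-1]:
        raise ValueError("trace does not cover all pulses in the train")
    times, starts, ends = _window_slices(trace.t, train)
    # crossing localization needs sampling finer than ~1 ms inside the protocol
    proto = (trace.t >= train.onset) & (trace.t <= train.end + train.period)
    if proto.sum() > 1 and np.max(np.diff(trace.t[proto])) > 1.0 + 1e-9:
        raise ValueError(
            "trace sampling too coarse to localize spike crossings within 1 ms; "
            "re-run with a finer sample_interval"
        )
    v = trace.v1
    fired = np.zeros(train.count, dtype=bool)
    latencies = np.full(train.count, np.nan)
    for i in range(train.count):
        a, b = starts[i], ends[i]
        if b - a < 2:
            continue
        seg = v[a:b]
        cross = np.nonzero((seg[:-1] < spike_threshold) & (seg[1:] >= spike_threshold))[0]
        if cross.size:
            k = cross[0]
            t_lo, t_hi = trace.t[a + k], trace.t[a + k + 1]
            v_lo, v_hi = seg[k], seg[k + 1]
            t_cross = t_lo + (spike_threshold - v_lo) / (v_hi - v_lo) * (t_hi - t_lo)
            fired[i] = True
            latencies[i] = t_cross - times[i]
    return ResponseSeries(stimulus_times=times, fired=fired, latencies=latencies)


def faithfulness(series: ResponseSeries, window_start: float, window_end: float) -> float:
    """Fraction of stimuli in ``[window_start, window_end)`` that evoked a spike.

    Ranges from 0 (no response) to 1 (full response); higher Faithfulness
    means a lower habituation tendency.
    """
    mask = (series.stimulus_times >= window_start) & (series.stimulus_times < window_end)
    if not mask.any():
        raise ValueError(
            f"window [{window_start}, {window_end}) ms contains no stimuli"
        )
    return float(np.count_nonzero(series.fired[mask])) / int(mask.sum())


def response_areas(trace, train: PulseTrain,
                   area_threshold: float = DEFAULT_AREA_THRESHOLD) -> np.ndarray:
    """Suprathreshold area A_i per stimulus window (mV*ms).

    A_i integrates ``max(v - area_threshold, 0)`` over ``[times[i],
    times[i] + period)`` by the trapezoidal rule on the stored grid. The
    threshold sits between rest and spike peak so that subthreshold responses
    still produce small positive areas (needed for the log-scale return map).
    """
    _, starts, ends = _window_slices(trace.t, train)
    excess = np.maximum(trace.v1 - area_threshold, 0.0)
    areas = np.zeros(train.count)
    for i in range(train.count):
        a, b = starts[i], ends[i]
        if b - a >= 2:
            areas[i] = np.trapezoid(excess[a:b], trace.t[a:b])
    return areas


def return_map(areas: np.ndarray, stimulus_times: np.ndarray,
               window_start: float, window_end: float,
               log: bool = False) -> np.ndarray:
    """Consecutive-area pairs (A_i, A_{i+1}) for stimuli inside a window.

    The analysis window conventionally covers 100-300 s after stimulation
    onset, past the initial transient. With ``log=True`` the pairs are
    log10-transformed (the spread between spike and subthreshold areas spans
    orders of magnitude); zero areas then signal a misconfigured threshold.
    """
    areas = np.asarray(areas, dtype=np.float64)
    stimulus_times = np.asarray(stimulus_times, dtype=np.float64)
    mask = (stimulus_times >= window_start) & (stimulus_times < window_end)
    idx = np.nonzero(mask)[0]
    pair_idx = idx[:-1][np.diff(idx) == 1]
    pairs = np.column_stack([areas[pair_idx], areas[pair_idx + 1]])
    if log:
        if np.any(pairs <= 0):
            raise ValueError(
                "zero suprathreshold area in the analysis window; lower the "
                "area threshold so subthreshold responses remain positive"
            )
        pairs = np.log10(pairs)
    return pairs


def _fired_period(fired: np.ndarray, period_max: int) -> int | None:
    """Smallest exact repetition period p <= period_max of a boolean sequence."""
    n = len(fired)
    for p in range(1, period_max + 1):
        if p >= n:
            break
        if np.array_equal(fired[p:], fired[:-p]):
            return p
    return None


def classify_pattern(series: ResponseSeries, areas: np.ndarray,
                     window_start: float, window_end: float,
                     area_tol: float = 0.05, period_max: int = 10) -> str:
    """Classify the stationary response pattern into one of five types.

    In order of increasing excitability (increasing ag_max):

    1. ``subthreshold_fixed_point`` - no spikes, areas settle to a point;
    2. ``subthreshold_periodic`` - sparse but exactly periodic spiking
       (firing fraction <= 1/2);
    3. ``irregular`` - aperiodic spike sequence (deterministic irregularity);
    4. ``suprathreshold_periodic`` - spikes skipped sparsely but periodically
       (firing fraction > 1/2);
    5. ``suprathreshold_fixed_point`` - a spike for every stimulus.

    ``area_tol`` is the relative area spread below which a non-firing pattern
    counts as converged. The window must exclude the initial transient and
    contain at least 20 stimuli.
    """
    mask = (series.stimulus_times >= window_start) & (series.stimulus_times < window_end)
    if mask.sum() < 20:
        raise ValueError(
            f"analysis window contains only {int(mask.sum())} stimuli; "
            "at least 20 are required for classification"
        )
    fired = series.fired[mask]
    win_areas = np.asarray(areas)[mask]
    f = fired.mean()
    if f == 0.0:
        tail = win_areas[len(win_areas) // 2:]
        spread = np.ptp(tail) / max(np.median(tail), 1e-12)
        return "subthreshold_fixed_point" if spread <= area_tol else "irregular"
    if f == 1.0:
        return "suprathreshold_fixed_point"
    p = _fired_period(fired, period_max)
    if p is not None:
        return "subthreshold_periodic" if f <= 0.5 else "suprathreshold_periodic"
    return "irregular"


@dataclass
class JumpUpGrid:
    """Firing indicator over a grid in the slow ([Ca], E_net) plane.

    ``fired[j, k]`` says whether a single pulse delivered immediately after
    initializing the slow variables at ``(Ca[j], E_net[k])`` (fast variables
    frozen at their quasi-steady values) elicits a spike. ``boundary[j]`` is
    the smallest firing E_net for each Ca (NaN when no E_net in the grid
    fires); the region above/left of the boundary is the jump-up region.
    """

    Ca: np.ndarray
    E_net: np.ndarray
    fired: np.ndarray
    boundary: np.ndarray
    v0: float
    n0: float

    def in_jump_up_region(self, Ca: float, E_net: float) -> bool:
        """Nearest-grid-point membership test."""
        j = int(np.argmin(np.abs(self.Ca - Ca)))
        k = int(np.argmin(np.abs(self.E_net - E_net)))
        return bool(self.fired[j, k])

    def to_dataframe(self) -> pd.DataFrame:
        jj, kk = np.meshgrid(np.arange(len(self.Ca)), np.arange(len(self.E_net)),
                             indexing="ij")
        return pd.DataFrame({
            "Ca": self.Ca[jj.ravel()],
            "E_net": self.E_net[kk.ravel()],
            "fired": self.fired.ravel().astype(int),
        })


def _step_mismatch(seq: np.ndarray) -> int:
    """Distance (in cells) of a boolean sequence from the best step function.

    The ideal frontier profile is False...False True...True; returns the
    minimal number of disagreeing cells over all split points.
    """
    n = len(seq)
    cum_true = np.concatenate([[0], np.cumsum(seq)])
    # split at i: predict False for seq[:i], True for seq[i:]
    mism = [cum_true[i] + (n - i) - (cum_true[n] - cum_true[i]) for i in range(n + 1)]
    return int(min(mism))


def jump_up_grid(params: ModelParameters,
                 region=((3.0, 3.2), (0.9, 1.2)),
                 increment: float = 0.01,
                 v0: float | None = None, n0: float | None = None,
                 amplitude: float = 4.5, width: float = DEFAULT_WIDTH,
                 spike_threshold: float = DEFAULT_SPIKE_THRESHOLD,
                 step: float = 0.01,
                 settle_ms: float = 300.0) -> JumpUpGrid:
    """Map the jump-up region of the slow plane by single-pulse probing.

    For each grid point the slow variables are set to ``(Ca, E_net)``, the
    fast variables to their quasi-steady values ``(v0, n0)`` (computed from
    ``params`` when not given), and a single pulse is delivered immediately;
    ``fired`` records whether cell 1 spikes. The frontier must be monotone:
    firing is easier at low [Ca] (less Ca-dependent K current) and high E_net
    (more tonic drive). A frontier broken by more than one grid cell raises,
    as that indicates a detection problem rather than model behavior.
    """
    from .model import activation_curves
    from .simulate import integrate, quasi_steady_state

    qss = quasi_steady_state(params)
    if v0 is None:
        v0 = qss.cell1.v
    if n0 is None:
        n0 = qss.cell1.n
    _, _, _, s_inf = activation_curves(v0, params)
    s0 = params.alpha * s_inf / (params.alpha * s_inf + params.beta)

    (ca_lo, ca_hi), (e_lo, e_hi) = region
    Ca_grid = np.round(np.arange(ca_lo, ca_hi + increment / 2, increment), 10)
    E_grid = np.round(np.arange(e_lo, e_hi + increment / 2, increment), 10)
    fired = np.zeros((len(Ca_grid), len(E_grid)), dtype=bool)

    train = PulseTrain(onset=0.0, frequency=1.0, count=1,
                       amplitude=amplitude, width=width)
    t_end = width + settle_ms
    base = qss.to_vector()
    for j, ca in enumerate(Ca_grid):
        for k, e in enumerate(E_grid):
            y0 = base.copy()
            y0[0], y0[1], y0[2], y0[3], y0[4] = v0, n0, ca, s0, e
            trace = integrate(CircuitState.from_vector(y0), params, train,
                              t_end=t_end, step=step, sample_interval=0.1)
            fired[j, k] = count_upward_crossings(trace.v1, spike_threshold) > 0

    # frontier structure: nondecreasing in E_net, nonincreasing in Ca
    for j in range(len(Ca_grid)):
        if _step_mismatch(fired[j]) > 1:
            raise RuntimeError(
                f"non-monotone firing frontier along E_net at Ca = {Ca_grid[j]}"
            )
    for k in range(len(E_grid)):
        if _step_mismatch(fired[::-1, k]) > 1:
            raise RuntimeError(
                f"non-monotone firing frontier along Ca at E_net = {E_grid[k]}"
            )

    boundary = np.full(len(Ca_grid), np.nan)
    for j in range(len(Ca_grid)):
        hits = np.nonzero(fired[j])[0]
        if hits.size:
            boundary[j] = E_grid[hits[0]]
    return JumpUpGrid(Ca=Ca_grid, E_net=E_grid, fired=fired, boundary=boundary,
                      v0=float(v0), n0=float(n0))


def slow_projection(trace, train: PulseTrain, series: ResponseSeries) -> pd.DataFrame:
    """([Ca], E_net) of cell 1 at each stimulus onset, tagged with the outcome.

    The projection overlays directly on a :class:`JumpUpGrid` boundary: the
    trajectory sits inside the jump-up region while the cell keeps answering
    stimuli and exits as it habituates.
    """
    states = trace.pulse_onset_states
    if states.shape[0] != train.count:
        raise ValueError("trace was not produced under the given train")
    return pd.DataFrame({
        "stimulus": np.arange(train.count),
        "t_ms": train.times(),
        "Ca": states[:, 2],
        "E_net": states[:, 4],
        "fired": series.fired.astype(bool),
    })


def faithfulness_scan(params: ModelParameters,
                      frequencies=FREQUENCY_GRID,
                      values=AG_MAX_GRID,
                      vary: str = "ag_max",
                      windows: dict | None = None,
                      amplitude: float = 4.5,
                      width: float = DEFAULT_WIDTH,
                      onset: float = 20000.0,
                      step: float = 0.01,
                      spike_threshold: float = DEFAULT_SPIKE_THRESHOLD,
                      progress: bool = False) -> pd.DataFrame:
    """Faithfulness over a (frequency x ag_max) or (frequency x amplitude) grid.

    Each grid cell relaxes its own quasi-steady state (cached per parameter
    set), runs the periodic protocol long enough to cover all measurement
    windows, and records Faithfulness per window. Failures in individual
    cells are recorded as NaN so the scan always completes.

    Returns a tidy frame with columns ``frequency_hz``, the varied quantity,
    ``window``, ``faithfulness`` and ``n_stimuli``.
    """
    from .simulate import integrate, quasi_steady_state

    if vary not in ("ag_max", "amplitude"):
        raise ValueError(f"vary must be 'ag_max' or 'amplitude', got {vary!r}")
    if windows is None:
        windows = DEFAULT_WINDOWS
    t_need = max(end for _, end in windows.values())

    qss_cache: dict[float, CircuitState] = {}

    def state_at_onset(p: ModelParameters) -> CircuitState:
        # protocol semantics: quasi-steady init, then an unstimulated trace
        # segment up to the onset; cache the state reached at the onset
        key = p.ag_max
        if key not in qss_cache:
            state = quasi_steady_state(p, step=step)
            if onset > 0:
                idle = integrate(state, p, None, t_end=onset, step=step,
                                 sample_interval=max(onset / 10.0, step))
                state = idle.final_state()
            qss_cache[key] = state
        return qss_cache[key]

    rows = []
    cells = [(f, v) for f in frequencies for v in values]
    for idx, (freq, val) in enumerate(cells):
        if progress:
            logger.info("faithfulness scan (%s): cell %d/%d", vary, idx + 1, len(cells))
        p = params.with_(ag_max=val) if vary == "ag_max" else params
        amp = amplitude if vary == "ag_max" else val
        period = 1000.0 / freq
        count = int(np.ceil((t_need - onset) / period))
        try:
            train = PulseTrain(onset=onset, frequency=freq, count=count,
                               amplitude=amp, width=min(width, 0.5 * period))
            trace = integrate(state_at_onset(p), p, train, t_end=t_need,
                              step=step, sample_interval=0.5, t0=onset)
            series = detect_responses(trace, train, spike_threshold=spike_threshold)
            for name, (w0, w1) in windows.items():
                mask = (series.stimulus_times >= w0) & (series.stimulus_times < w1)
                rows.append({
                    "frequency_hz": freq, vary: val, "window": name,
                    "faithfulness": faithfulness(series, w0, w1),
                    "n_stimuli": int(mask.sum()),
                })
        except Exception as exc:  # pragma: no cover - defensive per-cell guard
            logger.warning("scan cell (f=%s, %s=%s) failed: %s", freq, vary, val, exc)
            for name in windows:
                rows.append({
                    "frequency_hz": freq, vary: val, "window": name,
                    "faithfulness": np.nan, "n_stimuli": 0,
                })
    return pd.DataFrame(rows)
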