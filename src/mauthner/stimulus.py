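"""Periodic depolarizing-pulse stimulation protocols.

The experimental protocol delivers trains of brief supra-threshold stimuli
(40 pulses at 1 or 0.2 Hz); the model abstracts each as a rectangular current
pulse to cell 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PulseTrain"]

#: Stimulus amplitude of the published protocol (model current units).
DEFAULT_AMPLITUDE = 4.5
#: Default pulse width (ms). The protocol does not dictate a width; this value
#: is the output of :func:`mauthner.simulate.calibrate_pulse_width` with the
#: full phenotype contract (single spike per stimulus, dominant-like
#: extinction at 1 Hz, subordinate-like irregular responding, faithful
#: responses at 0.2 Hz).
DEFAULT_WIDTH = 1.963
#: Default onset (ms): stimulation starts at 20 s, after the quasi-steady
#: relaxation. Trace-reproduction runs use 20300 ms.
DEFAULT_ONSET = 20000.0


@dataclass(frozen=True)
class PulseTrain:
    """A periodic train of rectangular current pulses.

    Parameters
    ----------
    onset : float
        Time of the first pulse (ms).
    frequency : float
        Pulse rate (Hz); the inter-pulse interval is ``1000 / frequency`` ms.
    count : int
        Number of pulses (0 gives an empty protocol).
    amplitude : float
        Pulse current in model units.
    width : float
        Pulse duration (ms); must be shorter than the inter-pulse interval.
    """

    onset: float = DEFAULT_ONSET
    frequency: float = 1.0
    count: int = 40
    amplitude: float = DEFAULT_AMPLITUDE
    width: float = DEFAULT_WIDTH

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError(f"frequency must be positive, got {self.frequency}")
        if self.count < 0 or int(self.count) != self.count:
            raise ValueError(f"count must be a non-negative integer, got {self.count}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be non-negative, got {self.amplitude}")
        if self.count > 0 and not 0 < self.width < self.period:
            raise ValueError(
                f"width must lie in (0, {self.period}) ms at {self.frequency} Hz, got {self.width}"
            )

    @property
    def period(self) -> float:
        """Inter-pulse interval in ms."""
        return 1000.0 / self.frequency

    @property
    def end(self) -> float:
        """Offset time of the last pulse (ms); equals ``onset`` for an empty train."""
        if self.count == 0:
            return self.onset
        return self.onset + (self.count - 1) * self.period + self.width

    def times(self) -> np.ndarray:
        """Ordered pulse-onset times ``onset + k * period`` (ms)."""
        return self.onset + np.arange(self.count) * self.period

    def edges(self) -> np.ndarray:
        """Interleaved pulse on/off times; integration steps never cross these."""
        t = self.times()
        return np.column_stack([t, t + self.width]).ravel()

    def drive_at(self, t) -> np.ndarray | float:
        """Instantaneous stimulus current at time ``t`` (scalar or array).

        Pulse windows are half-open: the amplitude applies on
        ``[times[k], times[k] + width)``.
        """
        t = np.asarray(t, dtype=np.float64)
        if self.count == 0:
            out = np.zeros_like(t)
            return float(out) if t.ndim == 0 else out
        phase = t - self.onset
        k = np.floor(phase / self.period)
        in_pulse = (
            (k >= 0)
            & (k < self.count)
            & (phase - k * self.period >= 0)
            & (phase - k * self.period < self.width)
        )
        out = np.where(in_pulse, self.amplitude, 0.0)
        return float(out) if t.ndim == 0 else out

    def window_of(self, i: int) -> tuple[float, float]:
        """Per-stimulus analysis window ``[times[i], times[i] + period)``."""
        if not 0 <= i < self.count:
            raise IndexError(f"stimulus index {i} out of range for count {self.count}")
        t0 = self.onset + i * self.period
        return t0, t0 + self.period
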