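"""Behavioral response rasters: I/O, binned summaries and a synthetic generator.

A raster records, for each animal, which of the 40 repeated auditory stimuli
evoked an M-cell mediated escape response (binary), with the animal's social
group (communal / dominant / subordinate) and the stimulation frequency.
Summaries mirror the standard presentation: percent response per short
stimulus bin and response rates pooled over 5-stimulus blocks.

The generator draws status-dependent Bernoulli habituation curves: response
probability starts high and decays exponentially to a group- and frequency-
dependent plateau (faster and lower for dominant-like animals, slower and
higher for subordinate-like ones, with higher plateaus at low frequency).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GroupProfile",
    "ResponseRaster",
    "read_raster",
    "write_raster",
    "binned_percent_response",
    "pooled_block_rates",
    "generate_raster",
    "latency_summary",
    "fit_habituation_curve",
    "DEFAULT_PROFILES",
]

GROUPS = ("communal", "dominant", "subordinate")
DEFAULT_N_STIMULI = 40


@dataclass(frozen=True)
class GroupProfile:
    """Habituation-curve parameters of one group.

    Response probability at stimulus k (0-based) is
    ``plateau + (p0 - plateau) * exp(-k / decay_constant)``.
    """

    p0: float
    plateau: float
    decay_constant: float  # stimuli

    def __post_init__(self) -> None:
        if not 0.0 <= self.p0 <= 1.0 or not 0.0 <= self.plateau <= 1.0:
            raise ValueError(f"p0 and plateau must lie in [0, 1]: {self}")
        if self.decay_constant <= 0:
            raise ValueError(f"decay_constant must be positive: {self}")

    def probabilities(self, n_stimuli: int) -> np.ndarray:
        k = np.arange(n_stimuli)
        return self.plateau + (self.p0 - self.plateau) * np.exp(-k / self.decay_constant)


#: Default generator profiles keyed by (group, frequency_hz): high initial
#: response probability decaying to a plateau ordered subordinate > communal >
#: dominant, with higher plateaus at 0.2 Hz than at 1 Hz.
DEFAULT_PROFILES = {
    ("dominant", 1.0): GroupProfile(1.0, 0.05, 3.0),
    ("communal", 1.0): GroupProfile(1.0, 0.25, 4.0),
    ("subordinate", 1.0): GroupProfile(1.0, 0.55, 5.0),
    ("dominant", 0.2): GroupProfile(1.0, 0.45, 3.0),
    ("communal", 0.2): GroupProfile(1.0, 0.55, 4.0),
    ("subordinate", 0.2): GroupProfile(1.0, 0.70, 5.0),
}


@dataclass
class ResponseRaster:
    """Animals x stimuli binary escape responses with group metadata.

    ``responses`` has shape (n_animals, n_stimuli) with entries in {0, 1};
    ``latencies`` (ms), when present, is NaN exactly where no response
    occurred.
    """

    responses: np.ndarray
    groups: np.ndarray          # str per animal
    frequency_hz: float
    animal_ids: np.ndarray | None = None
    latencies: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses)
        if self.responses.ndim != 2:
            raise ValueError("responses must be a 2-D animals x stimuli matrix")
        if not np.isin(self.responses, (0, 1)).all():
            raise ValueError("responses must be binary")
        self.groups = np.asarray(self.groups, dtype=object)
        if len(self.groups) != self.n_animals:
            raise ValueError("one group label per animal required")
        unknown = set(self.groups) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")
        if self.animal_ids is None:
            self.animal_ids = np.array([f"a{i + 1:03d}" for i in range(self.n_animals)],
                                       dtype=object)
        if self.latencies is not None:
            self.latencies = np.asarray(self.latencies, dtype=np.float64)
            if self.latencies.shape != self.responses.shape:
                raise ValueError("latency matrix shape must match responses")
            defined = np.isfinite(self.latencies)
            if np.any(defined != (self.responses == 1)):
                raise ValueError("latency must be present exactly where response = 1")

    @property
    def n_animals(self) -> int:
        return self.responses.shape[0]

    @property
    def n_stimuli(self) -> int:
        return self.responses.shape[1]

    def group_mask(self, group: str) -> np.ndarray:
        return self.groups == group

    def present_groups(self) -> list[str]:
        return [g for g in GROUPS if (self.groups == g).any()]


def _stim_cols(n: int) -> list[str]:
    return [f"s{k + 1:02d}" for k in range(n)]


def _lat_cols(n: int) -> list[str]:
    return [f"lat{k + 1:02d}" for k in range(n)]


def write_raster(raster: ResponseRaster, path) -> None:
    """Write a raster as CSV: animal_id, group, frequency_hz, s01.. (+lat01..)."""
    df = pd.DataFrame({"animal_id": raster.animal_ids, "group": raster.groups})
    df["frequency_hz"] = raster.frequency_hz
    for k, col in enumerate(_stim_cols(raster.n_stimuli)):
        df[col] = raster.responses[:, k]
    if raster.latencies is not None:
        for k, col in enumerate(_lat_cols(raster.n_stimuli)):
            df[col] = raster.latencies[:, k]
    df.to_csv(path, index=False)


def read_raster(path) -> ResponseRaster:
    """Read a raster CSV written by :func:`write_raster`; validates strictly."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty raster file")
    required = {"animal_id", "group", "frequency_hz"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    stim_cols = [c for c in df.columns if c.startswith("s") and c[1:].isdigit()]
    stim_cols.sort(key=lambda c: int(c[1:]))
    if not stim_cols:
        raise ValueError(f"{path}: no stimulus columns (s01..)")
    expected = _stim_cols(len(stim_cols))
    if stim_cols != expected:
        raise ValueError(f"{path}: inconsistent stimulus columns {stim_cols}")

    for row_idx, row in df.iterrows():
        if row["group"] not in GROUPS:
            raise ValueError(f"{path}: row {row_idx + 2}: unknown group {row['group']!r}")
        for col in stim_cols:
            val = row[col]
            if val not in (0, 1):
                raise ValueError(
                    f"{path}: row {row_idx + 2}, column {col}: non-binary value {val!r}"
                )
    freqs = df["frequency_hz"].unique()
    if len(freqs) != 1:
        raise ValueError(f"{path}: mixed stimulation frequencies {freqs}")

    lat_cols = [c for c in df.columns if c.startswith("lat") and c[3:].isdigit()]
    lat = None
    if lat_cols:
        lat_cols.sort(key=lambda c: int(c[3:]))
        if lat_cols != _lat_cols(len(stim_cols)):
            raise ValueError(f"{path}: latency columns do not match stimulus columns")
        lat = df[lat_cols].to_numpy(dtype=np.float64)
    return ResponseRaster(
        responses=df[stim_cols].to_numpy(dtype=np.int64),
        groups=df["group"].to_numpy(dtype=object),
        frequency_hz=float(freqs[0]),
        animal_ids=df["animal_id"].to_numpy(dtype=object),
        latencies=lat,
    )


def _sem(x: np.ndarray) -> float:
    n = len(x)
    if n <= 1:
        return 0.0
    return float(np.std(x, ddof=1) / np.sqrt(n))


def binned_percent_response(raster: ResponseRaster, stimuli_per_bin: int = 2) -> pd.DataFrame:
    """Per-bin percent response (mean over animals +/- SEM) for each group.

    With the published protocols a 2-stimulus bin corresponds to 2 s at 1 Hz
    and 10 s at 0.2 Hz. ``stimuli_per_bin`` must divide the stimulus count.
    """
    n = raster.n_stimuli
    if n % stimuli_per_bin:
        raise ValueError(f"stimuli_per_bin={stimuli_per_bin} does not divide {n} stimuli")
    n_bins = n // stimuli_per_bin
    rows = []
    for group in raster.present_groups():
        sub = raster.responses[raster.group_mask(group)]
        if sub.size == 0:
            raise ValueError(f"group {group!r} has no animals")
        per_animal = sub.reshape(len(sub), n_bins, stimuli_per_bin).mean(axis=2) * 100.0
        for b in range(n_bins):
            rows.append({
                "group": group, "bin": b + 1,
                "mean_percent": float(per_animal[:, b].mean()),
                "sem": _sem(per_animal[:, b]),
                "n": len(sub),
            })
    return pd.DataFrame(rows)


def pooled_block_rates(raster: ResponseRaster, block: int = 5) -> pd.DataFrame:
    """Mean response rate per ``block``-stimulus block (1-5, 6-10, ...) per group."""
    n = raster.n_stimuli
    if n % block:
        raise ValueError(f"block={block} does not divide {n} stimuli")
    n_blocks = n // block
    rows = []
    for group in raster.present_groups():
        sub = raster.responses[raster.group_mask(group)]
        if sub.size == 0:
            raise ValueError(f"group {group!r} has no animals")
        rates = sub.reshape(len(sub), n_blocks, block).mean(axis=2)
        for b in range(n_blocks):
            rows.append({
                "group": group, "block": b + 1,
                "stimuli": f"{b * block + 1}-{(b + 1) * block}",
                "rate": float(rates[:, b].mean()),
                "sem": _sem(rates[:, b]),
                "n": len(sub),
            })
    return pd.DataFrame(rows)


def generate_raster(profiles: dict[str, GroupProfile] | None = None,
                    n_animals: int = 20,
                    n_stimuli: int = DEFAULT_N_STIMULI,
                    frequency_hz: float = 1.0,
                    seed: int = 0,
                    latency_mean: float | None = 5.0,
                    latency_sd: float = 1.0) -> ResponseRaster:
    """Draw a synthetic status-dependent habituation raster.

    ``profiles`` maps group name to :class:`GroupProfile`; by default the
    built-in profiles for ``frequency_hz`` (1 or 0.2) are used. Each animal's
    responses are independent Bernoulli draws from its group's habituation
    curve; identical seeds give identical rasters. When ``latency_mean`` is
    set, responded trials receive Gaussian latencies (ms, truncated at 0.5).
    """
    if profiles is None:
        profiles = {g: DEFAULT_PROFILES[(g, frequency_hz)] for g in GROUPS
                    if (g, frequency_hz) in DEFAULT_PROFILES}
        if not profiles:
            raise ValueError(
                f"no default profiles for frequency {frequency_hz} Hz; pass profiles"
            )
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for group in GROUPS:
        if group not in profiles:
            continue
        p = profiles[group].probabilities(n_stimuli)
        blocks.append((rng.random((n_animals, n_stimuli)) < p).astype(np.int64))
        labels.extend([group] * n_animals)
    responses = np.vstack(blocks)
    lat = None
    if latency_mean is not None:
        lat = np.maximum(rng.normal(latency_mean, latency_sd, responses.shape), 0.5)
        lat[responses == 0] = np.nan
    return ResponseRaster(responses=responses, groups=np.array(labels, dtype=object),
                          frequency_hz=frequency_hz, latencies=lat)


def latency_summary(raster: ResponseRaster) -> pd.DataFrame:
    """Mean +/- SEM response latency per group, pooled over responded trials.

    A group with a single responded trial reports SEM 0 and ``single_trial``
    True rather than NaN.
    """
    if raster.latencies is None:
        raise ValueError("raster has no latency matrix")
    rows = []
    for group in raster.present_groups():
        vals = raster.latencies[raster.group_mask(group)]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"group {group!r} has no responded trials")
        rows.append({
            "group": group,
            "mean_ms": float(vals.mean()),
            "sem_ms": _sem(vals),
            "n_trials": int(vals.size),
            "single_trial": vals.size == 1,
        })
    return pd.DataFrame(rows)


def fit_habituation_curve(raster: ResponseRaster, group: str):
    """Least-squares fit of the exponential-plateau curve to group means.

    Fits ``plateau + (p0 - plateau) * exp(-k / decay_constant)`` to the
    per-stimulus mean response rate of ``group``; returns a fitted
    :class:`GroupProfile`. Used to check that generator parameters are
    recoverable from data of realistic size.
    """
    from scipy.optimize import curve_fit

    sub = raster.responses[raster.group_mask(group)]
    if sub.size == 0:
        raise ValueError(f"group {group!r} has no animals")
    means = sub.mean(axis=0)
    k = np.arange(raster.n_stimuli, dtype=np.float64)

    def curve(k, p0, plateau, tau):
        return plateau + (p0 - plateau) * np.exp(-k / tau)

    popt, _ = curve_fit(curve, k, means, p0=(0.9, 0.3, 4.0),
                        bounds=([0, 0, 0.1], [1, 1, 50]), maxfev=10000)
    return GroupProfile(p0=float(np.clip(popt[0], 0, 1)),
                        plateau=float(np.clip(popt[1], 0, 1)),
                        decay_constant=float(popt[2]))
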