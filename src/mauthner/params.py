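"""Model parameters and state containers for the two-cell M-cell circuit.

The Mauthner cell (M-cell) is modeled as a modified Morris-Lecar neuron with
an additional calcium-dependent potassium current and a slow, calcium-regulated
adaptation variable ``E_net`` that lumps the net pre-synaptic drive to the cell.
Two M-cells are coupled through a voltage-gated synaptic variable; only cell 1
receives the external stimulus current.

Units: time in milliseconds, voltages in mV, currents/conductances/calcium in
dimensionless model units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "ModelParameters",
    "CellState",
    "CircuitState",
    "PHENOTYPE_AG_MAX",
]

#: Canonical ag_max values used throughout: the maximal net excitation acts as
#: a stand-in for social phenotype (low = dominant-like, high = subordinate-like).
PHENOTYPE_AG_MAX = {
    "dominant": 41.5,
    "communal": 42.2,
    "subordinate": 43.5,
}

# Order in which parameters are packed for the numerical kernel.
PARAM_ORDER = (
    "g_Ca", "g_K", "g_KCa", "g_L",
    "v_Ca", "v_K", "v_L",
    "v1", "v2", "v3", "v4",
    "k1", "k2", "k_Ca", "eps", "mu",
    "C", "phi", "alpha", "beta",
    "theta_s", "sigma_s", "g_syn", "v_syn",
    "I0", "w_M", "ag_max", "rho",
)

_POSITIVE = (
    "g_Ca", "g_K", "g_KCa", "g_L", "C", "eps", "rho",
    "k1", "k2", "k_Ca", "alpha", "beta", "phi", "sigma_s",
)


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter set of the circuit equations.

    Defaults are the published operating point of the model; ``ag_max``
    defaults to the dominant-like phenotype and is the main control knob.
    """

    g_Ca: float = 4.0        # maximal Ca conductance
    g_K: float = 8.0         # maximal K conductance
    g_KCa: float = 0.25      # maximal Ca-dependent K conductance
    g_L: float = 2.0         # leak conductance
    v_Ca: float = 120.0      # Ca reversal potential (mV)
    v_K: float = -84.0       # K reversal potential (mV)
    v_L: float = -60.0       # leak reversal potential (mV)
    v1: float = -1.2         # m_inf half-activation (mV)
    v2: float = 18.0         # m_inf slope (mV)
    v3: float = 12.0         # n_inf half-activation (mV)
    v4: float = 17.0         # n_inf slope (mV)
    k1: float = 10.0         # [Ca] half-saturation of I_KCa
    k2: float = 40.0         # [Ca] saturation constant in the E_net target
    k_Ca: float = 1.0        # calcium removal rate
    eps: float = 0.00033     # calcium time-scale factor
    mu: float = 0.2          # calcium influx coupling
    C: float = 1.0           # membrane capacitance
    phi: float = 0.23        # n-gate rate scale
    alpha: float = 10.0      # synaptic opening rate
    beta: float = 0.08       # synaptic closing rate
    theta_s: float = 0.0     # synaptic activation half-voltage (mV)
    sigma_s: float = 4.0     # synaptic activation slope (mV)
    g_syn: float = 0.5       # cross M-cell synaptic conductance
    v_syn: float = -50.0     # synaptic reversal potential (mV)
    I0: float = 40.5         # tonic applied current
    w_M: float = 0.5         # weight of E_net in the applied current
    ag_max: float = 41.5     # maximal net excitation (phenotype parameter)
    rho: float = 8400.0      # E_net time constant (ms)
    s2: float = 0.029        # printed constant with no governing equation; inert

    def __post_init__(self) -> None:
        for name in _POSITIVE:
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"parameter {name} must be strictly positive, got {value}")
        if not np.isfinite(self.ag_max) or self.ag_max <= 0:
            raise ValueError(f"ag_max must be positive and finite, got {self.ag_max}")

    @classmethod
    def for_phenotype(cls, phenotype: str, **overrides) -> "ModelParameters":
        """Parameters with ``ag_max`` set for 'dominant', 'communal' or 'subordinate'."""
        try:
            ag = PHENOTYPE_AG_MAX[phenotype]
        except KeyError:
            raise ValueError(
                f"unknown phenotype {phenotype!r}; expected one of {sorted(PHENOTYPE_AG_MAX)}"
            ) from None
        return cls(ag_max=ag, **overrides)

    def with_(self, **overrides) -> "ModelParameters":
        return replace(self, **overrides)

    def to_array(self) -> np.ndarray:
        """Pack parameters in kernel order (excludes the inert ``s2``)."""
        return np.array([getattr(self, name) for name in PARAM_ORDER], dtype=np.float64)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class CellState:
    """Dynamical variables of one model M-cell."""

    v: float          # membrane potential (mV)
    n: float          # K-gate open fraction
    Ca: float         # intracellular calcium concentration
    s: float          # synaptic activation fraction
    E_net: float      # activity-dependent net excitation

    def validate(self) -> None:
        if not all(np.isfinite([self.v, self.n, self.Ca, self.s, self.E_net])):
            raise ValueError(f"non-finite cell state: {self}")
        if not 0.0 <= self.n <= 1.0:
            raise ValueError(f"gating variable n out of [0,1]: {self.n}")
        if not 0.0 <= self.s <= 1.0:
            raise ValueError(f"synaptic variable s out of [0,1]: {self.s}")
        if self.Ca < 0:
            raise ValueError(f"negative calcium concentration: {self.Ca}")
        if self.E_net <= 0:
            raise ValueError(f"E_net must be positive: {self.E_net}")

    def to_array(self) -> np.ndarray:
        return np.array([self.v, self.n, self.Ca, self.s, self.E_net], dtype=np.float64)

    @classmethod
    def from_array(cls, arr) -> "CellState":
        v, n, Ca, s, E = (float(x) for x in arr)
        return cls(v=v, n=n, Ca=Ca, s=s, E_net=E)


@dataclass
class CircuitState:
    """State of the coupled pair. Cell 1 receives the stimulus; cell 2 does not."""

    cell1: CellState
    cell2: CellState

    def validate(self) -> None:
        self.cell1.validate()
        self.cell2.validate()

    def to_vector(self) -> np.ndarray:
        """Flatten to ``[v1, n1, Ca1, s1, E1, v2, n2, Ca2, s2, E2]``."""
        return np.concatenate([self.cell1.to_array(), self.cell2.to_array()])

    @classmethod
    def from_vector(cls, vec) -> "CircuitState":
        vec = np.asarray(vec, dtype=np.float64)
        if vec.shape != (10,):
            raise ValueError(f"expected a 10-vector, got shape {vec.shape}")
        return cls(cell1=CellState.from_array(vec[:5]), cell2=CellState.from_array(vec[5:]))

    @classmethod
    def symmetric(cls, cell: CellState) -> "CircuitState":
        return cls(cell1=replace(cell), cell2=replace(cell))
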