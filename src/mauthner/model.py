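"""Vector field of the two-cell M-cell circuit.

Each cell obeys a current-balance equation

    C dv/dt = -I_Ca - I_K - I_KCa - I_L - I_syn + I_app(t)

with instantaneous calcium activation m_inf(v), a relaxing potassium gate n,
a calcium balance d[Ca]/dt = eps * (-mu * I_Ca - k_Ca * [Ca]), a first-order
synaptic variable s driven by the membrane potential, and a slow adaptation

    dE_net/dt = (ag_max / ([Ca] + k2) - E_net) / rho

whose target decreases reciprocally with intracellular calcium.  The applied
current is I_app = I0 + I_i(t) + w_M * E_net, where I_i is the stimulus pulse
delivered to cell i (cell 2 receives none) and E_net feeds back the cell's own
adaptation state.  I_syn couples each cell to the *other* cell's synaptic
variable.

These functions are the plain, readable reference implementation; the
integrator in :mod:`mauthner.simulate` uses a compiled kernel that is checked
against them in the test suite.
"""

from __future__ import annotations

import math

import numpy as np

from .params import CellState, CircuitState, ModelParameters

__all__ = [
    "activation_curves",
    "membrane_currents",
    "net_excitation_target",
    "applied_current",
    "cell_derivatives",
    "circuit_derivatives",
    "steady_state_chain",
]


def activation_curves(v, params: ModelParameters):
    """Steady-state gating curves and the n-gate time scale at potential ``v``.

    Returns ``(m_inf, n_inf, tau_n, s_inf)``.  Accepts scalars or arrays.
    """
    v = np.asarray(v, dtype=np.float64)
    m_inf = 0.5 * (1.0 + np.tanh((v - params.v1) / params.v2))
    n_inf = 0.5 * (1.0 + np.tanh((v - params.v3) / params.v4))
    tau_n = 1.0 / np.cosh((v - params.v3) / (2.0 * params.v4))
    s_inf = 1.0 / (1.0 + np.exp(-(v - params.theta_s) / params.sigma_s))
    if v.ndim == 0:
        return float(m_inf), float(n_inf), float(tau_n), float(s_inf)
    return m_inf, n_inf, tau_n, s_inf


def membrane_currents(state: CellState, other_s: float, params: ModelParameters):
    """Ionic and synaptic currents of one cell.

    ``other_s`` is the synaptic variable of the *other* M-cell (the coupling
    is cross-wise).  Returns ``(I_Ca, I_K, I_KCa, I_L, I_syn)``.
    """
    p = params
    v = state.v
    Ca = max(state.Ca, 0.0)  # guard saturating term against round-off
    m_inf = 0.5 * (1.0 + math.tanh((v - p.v1) / p.v2))
    I_Ca = p.g_Ca * m_inf * (v - p.v_Ca)
    I_K = p.g_K * state.n * (v - p.v_K)
    I_KCa = p.g_KCa * (Ca / (Ca + p.k1)) * (v - p.v_K)
    I_L = p.g_L * (v - p.v_L)
    I_syn = p.g_syn * (v - p.v_syn) * other_s
    return I_Ca, I_K, I_KCa, I_L, I_syn


def net_excitation_target(Ca, params: ModelParameters):
    """Quasi-static target of the adaptation variable: ag_max / ([Ca] + k2).

    Strictly decreasing in calcium; equals ag_max / k2 at [Ca] = 0.
    """
    Ca = np.maximum(np.asarray(Ca, dtype=np.float64), 0.0)
    out = params.ag_max / (Ca + params.k2)
    return float(out) if out.ndim == 0 else out


def applied_current(E_net: float, drive: float, params: ModelParameters) -> float:
    """I_app = I0 + stimulus drive + w_M * E_net."""
    return params.I0 + drive + params.w_M * E_net


def cell_derivatives(state: CellState, other_s: float, drive: float,
                     params: ModelParameters) -> np.ndarray:
    """Time derivatives (dv, dn, dCa, ds, dE_net) of one cell."""
    p = params
    I_Ca, I_K, I_KCa, I_L, I_syn = membrane_currents(state, other_s, p)
    _, n_inf, tau_n, s_inf = activation_curves(state.v, p)
    dv = (-I_Ca - I_K - I_KCa - I_L - I_syn + applied_current(state.E_net, drive, p)) / p.C
    dn = p.phi * (n_inf - state.n) / tau_n
    dCa = p.eps * (-p.mu * I_Ca - p.k_Ca * max(state.Ca, 0.0))
    ds = p.alpha * s_inf * (1.0 - state.s) - p.beta * state.s
    dE = (net_excitation_target(state.Ca, p) - state.E_net) / p.rho
    return np.array([dv, dn, dCa, ds, dE])


def circuit_derivatives(state: CircuitState, params: ModelParameters,
                        drive1: float = 0.0, drive2: float = 0.0) -> np.ndarray:
    """Derivatives of the full 10-dimensional circuit state.

    ``drive1``/``drive2`` are the instantaneous stimulus currents delivered to
    the two cells (the standard protocol drives only cell 1).  Raises on an
    invalid (non-finite or out-of-range) state instead of propagating NaNs.
    """
    state.validate()
    d1 = cell_derivatives(state.cell1, state.cell2.s, drive1, params)
    d2 = cell_derivatives(state.cell2, state.cell1.s, drive2, params)
    return np.concatenate([d1, d2])


def steady_state_chain(v_star: float, params: ModelParameters) -> CellState:
    """Closed-form rest state implied by a resting potential ``v_star``.

    With no stimulus the gates and slow variables equilibrate to
    n* = n_inf(v*), [Ca]* = -mu * I_Ca(v*) / k_Ca, E* = ag_max/([Ca]* + k2)
    and s* = alpha s_inf / (alpha s_inf + beta).  The returned state is exact
    for the slow chain; whether the current balance also closes at ``v_star``
    is a property of the parameter set (checked in tests against the
    simulated quasi-steady state).
    """
    p = params
    m_inf, n_inf, _, s_inf = activation_curves(v_star, p)
    I_Ca = p.g_Ca * m_inf * (v_star - p.v_Ca)
    Ca = -p.mu * I_Ca / p.k_Ca
    E = net_excitation_target(Ca, p)
    s = p.alpha * s_inf / (p.alpha * s_inf + p.beta)
    return CellState(v=v_star, n=n_inf, Ca=Ca, s=s, E_net=E)
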