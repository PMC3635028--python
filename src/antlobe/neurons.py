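"""Single-compartment Hodgkin-Huxley dynamics for projection neurons (PNs)
and local neurons (LNs) of the antennal-lobe model.

Each PN carries fast sodium and delayed-rectifier potassium spiking currents
plus a transient (A-type) potassium current; it fires brief (~3 ms) sodium
action potentials.  Each LN carries a transient calcium current, a
calcium-dependent potassium current and a slow delayed rectifier; it fires
broad (~25 ms) calcium spikes that adapt over 100-200 ms.  All currents have
the form ``I_j = g_j * m^M * h^N * (V - E_j)`` with first-order gate
kinetics ``dx/dt = (x_inf(V) - x) / tau_x(V)``.

Units: mV, ms, mS/cm^2, uA/cm^2, uF/cm^2, mM.  The membrane equation is

    C_m dV/dt = -g_L (V - E_L) - sum_j I_j - I_syn + I_input

so a positive ``I_input`` depolarizes.

Kinetic scheme notes
--------------------
PN Na/K gates use Traub-Miles rate functions with per-gate threshold
shifts (Na activation -48, Na inactivation -50, K -58 mV), the scheme used
throughout the antennal-lobe model family this network belongs to.  The LN delayed rectifier is a slow, steep
rectifier (midpoint -10 mV, slope 3 mV, tau 8-28 ms, slowest when
depolarized); together with a bell-shaped calcium-inactivation time
constant (fast recovery at rest, fast inactivation at the peak) it
produces self-terminating ~25 ms calcium spikes and sustained 10-25 Hz
firing (see docs/methods.md for how these kinetics were identified).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

# ---------------------------------------------------------------- constants

CM = 1.0            # uF/cm^2, both cell types

# PN passive + intrinsic
PN_GL, PN_EL = 0.3, -64.0
PN_GNA, PN_ENA = 120.0, 40.0
PN_GK, PN_EK = 3.6, -87.0
PN_GA = 1.43        # A-current reverses at E_K

# LN passive + intrinsic
LN_GL, LN_EL = 0.3, -50.0
LN_GCA, LN_ECA = 5.0, 140.0
LN_GCAK = 0.045
LN_GK, LN_EK = 36.0, -95.0

# intracellular calcium dynamics: d[Ca]/dt = -A*I_Ca - ([Ca]-CA_INF)/TAU_CA
CA_A = 0.0002       # mM cm^2 / (ms uA)
CA_INF = 0.00024    # mM
TAU_CA = 150.0      # ms

# Traub-Miles threshold shifts for the PN spiking currents.  Activation of
# I_Na sits slightly above its inactivation/K counterparts; the K shift is
# deeper, which raises rheobase and softens the onset firing rate so that
# odor-driven PNs are gated by per-cycle inhibition rather than free-running.
V_SHIFT_NA_M = -48.0
V_SHIFT_NA_H = -50.0
V_SHIFT_K = -58.0
PN_KDEACT_SLOW = 20.0   # K deactivation slowdown factor below -55 mV

# LN rectifier (slow, steep; see module docstring)
LN_N_MID, LN_N_SLOPE = -10.0, 3.0
LN_N_TAU_LO, LN_N_TAU_AMP = 8.0, 20.0

# floor keeping tau_m(Ca) positive at strongly hyperpolarized V
TAU_M_CA_FLOOR = 0.1


# --------------------------------------------------- scalar rate functions
# njit scalar kernels; shared by the python API and the simulation engine.

@njit(cache=True)
def _traub_am(V):
    x = 13.0 - V + V_SHIFT_NA_M
    if abs(x) < 1e-9:
        return 0.32 * 4.0
    return 0.32 * x / (math.exp(x / 4.0) - 1.0)


@njit(cache=True)
def _traub_bm(V):
    x = V - V_SHIFT_NA_M - 40.0
    if abs(x) < 1e-9:
        return 0.28 * 5.0
    return 0.28 * x / (math.exp(x / 5.0) - 1.0)


@njit(cache=True)
def _traub_ah(V):
    return 0.128 * math.exp((17.0 - V + V_SHIFT_NA_H) / 18.0)


@njit(cache=True)
def _traub_bh(V):
    return 4.0 / (1.0 + math.exp((40.0 - V + V_SHIFT_NA_H) / 5.0))


@njit(cache=True)
def _traub_an(V):
    x = 15.0 - V + V_SHIFT_K
    if abs(x) < 1e-9:
        return 0.032 * 5.0
    return 0.032 * x / (math.exp(x / 5.0) - 1.0)


@njit(cache=True)
def _traub_bn(V):
    return 0.5 * math.exp((10.0 - V + V_SHIFT_K) / 40.0)


@njit(cache=True)
def na_m_inf(V):
    a, b = _traub_am(V), _traub_bm(V)
    return a / (a + b)


@njit(cache=True)
def na_m_tau(V):
    return 1.0 / (_traub_am(V) + _traub_bm(V))


@njit(cache=True)
def na_h_inf(V):
    a, b = _traub_ah(V), _traub_bh(V)
    return a / (a + b)


@njit(cache=True)
def na_h_tau(V):
    return 1.0 / (_traub_ah(V) + _traub_bh(V))


@njit(cache=True)
def k_n_inf(V):
    a, b = _traub_an(V), _traub_bn(V)
    return a / (a + b)


@njit(cache=True)
def k_n_tau(V):
    # deactivation below ~-55 mV is slowed 20-fold, deepening the
    # after-spike hyperpolarization; this caps repetitive firing near the
    # 10-40 spikes/s range of odor-driven PNs without touching spike shape
    tau = 1.0 / (_traub_an(V) + _traub_bn(V))
    return tau * (1.0 + PN_KDEACT_SLOW / (1.0 + math.exp((V + 55.0) / 3.0)))


@njit(cache=True)
def a_m_inf(V):
    return 1.0 / (1.0 + math.exp(-(V + 60.0) / 8.5))


@njit(cache=True)
def a_m_tau(V):
    return 0.27 / (math.exp((V + 35.8) / 19.7) + math.exp(-(V + 79.7) / 12.7)) + 0.1


@njit(cache=True)
def a_h_inf(V):
    return 1.0 / (1.0 + math.exp((V + 78.0) / 6.0))


@njit(cache=True)
def a_h_tau(V):
    if V > -63.0:
        return 5.1
    return 0.27 / (math.exp((V + 46.0) / 5.0) + math.exp(-(V + 238.0) / 37.5))


@njit(cache=True)
def ca_m_inf(V):
    return 1.0 / (1.0 + math.exp(-(V + 20.0) / 6.5))


@njit(cache=True)
def ca_m_tau(V):
    t = 1.0 + (V + 30.0) * 0.014
    return t if t > TAU_M_CA_FLOOR else TAU_M_CA_FLOOR


@njit(cache=True)
def ca_h_inf(V):
    return 1.0 / (1.0 + math.exp((V + 25.0) / 12.0))


@njit(cache=True)
def ca_h_tau(V):
    # bell around -45 mV: ~50 ms near threshold, ~20 ms recovery at rest and
    # during inhibition, ~6 ms inactivation at the spike plateau
    return 5.0 + 90.0 / (math.exp((V + 45.0) / 10.0) + math.exp(-(V + 45.0) / 14.0))


@njit(cache=True)
def cak_m_inf(ca):
    return ca / (ca + 2.0)


@njit(cache=True)
def cak_m_tau(ca):
    return 100.0 / (ca + 2.0)


@njit(cache=True)
def ln_n_inf(V):
    return 1.0 / (1.0 + math.exp(-(V - LN_N_MID) / LN_N_SLOPE))


@njit(cache=True)
def ln_n_tau(V):
    # slow (~28 ms) above threshold, fast (~8 ms) deactivation below
    return LN_N_TAU_LO + LN_N_TAU_AMP / (1.0 + math.exp(-(V + 35.0) / 5.0))


# ------------------------------------------------------------- label lookup

_GATES = {
    ("Na", "m"): (na_m_inf, na_m_tau, False),
    ("Na", "h"): (na_h_inf, na_h_tau, False),
    ("K", "n"): (k_n_inf, k_n_tau, False),
    ("Kln", "n"): (ln_n_inf, ln_n_tau, False),
    ("A", "m"): (a_m_inf, a_m_tau, False),
    ("A", "h"): (a_h_inf, a_h_tau, False),
    ("Ca", "m"): (ca_m_inf, ca_m_tau, False),
    ("Ca", "h"): (ca_h_inf, ca_h_tau, False),
    ("CaK", "m"): (cak_m_inf, cak_m_tau, True),   # gated by [Ca], not V
}


class ConfigurationError(ValueError):
    """Unknown current/gate label or invalid model configuration."""


def gate_steady_state(current_label: str, gate_label: str, V: float = None,
                      Ca: float = None) -> float:
    """Steady-state value of a gating variable, in [0, 1].

    Voltage-gated gates take ``V`` (mV); the calcium-dependent potassium
    activation takes ``Ca`` (mM, > 0).
    """
    f_inf, _, ca_gated = _lookup(current_label, gate_label)
    x = _gate_arg(current_label, ca_gated, V, Ca)
    return float(f_inf(x))


def gate_time_constant(current_label: str, gate_label: str, V: float = None,
                       Ca: float = None) -> float:
    """Gate relaxation time constant in ms (strictly positive)."""
    _, f_tau, ca_gated = _lookup(current_label, gate_label)
    x = _gate_arg(current_label, ca_gated, V, Ca)
    return float(f_tau(x))


def _lookup(current_label, gate_label):
    try:
        return _GATES[(current_label, gate_label)]
    except KeyError:
        raise ConfigurationError(
            f"unknown gate {gate_label!r} of current {current_label!r}"
        ) from None


def _gate_arg(label, ca_gated, V, Ca):
    if ca_gated:
        if Ca is None or Ca <= 0:
            raise ConfigurationError(f"current {label!r} needs Ca > 0")
        return Ca
    if V is None or not np.isfinite(V):
        raise ConfigurationError(f"current {label!r} needs a finite V")
    return V


# --------------------------------------------------------------- cell state

@dataclass
class NeuronState:
    """Full dynamical state of one model cell.

    ``gates`` maps (current, gate) -> value in [0, 1].  ``Ca`` is the
    intracellular calcium concentration (mM, LN only, PN carries the resting
    value untouched).
    """

    cell_type: str                      # "PN" | "LN"
    V: float
    gates: dict = field(default_factory=dict)
    Ca: float = CA_INF

    @classmethod
    def resting(cls, cell_type: str) -> "NeuronState":
        """State with V at E_L, every gate at steady state, Ca at [Ca]_inf."""
        if cell_type == "PN":
            V = PN_EL
            keys = [("Na", "m"), ("Na", "h"), ("K", "n"), ("A", "m"), ("A", "h")]
        elif cell_type == "LN":
            V = LN_EL
            keys = [("Ca", "m"), ("Ca", "h"), ("CaK", "m"), ("Kln", "n")]
        else:
            raise ConfigurationError(f"unknown cell type {cell_type!r}")
        gates = {k: gate_steady_state(*k, V=V, Ca=CA_INF) for k in keys}
        return cls(cell_type=cell_type, V=V, gates=gates, Ca=CA_INF)


def intrinsic_currents(state: NeuronState) -> dict:
    """Every intrinsic current (uA/cm^2, positive = outward) at ``state``."""
    g, V = state.gates, state.V
    if state.cell_type == "PN":
        return {
            "L": PN_GL * (V - PN_EL),
            "Na": PN_GNA * g[("Na", "m")] ** 3 * g[("Na", "h")] * (V - PN_ENA),
            "K": PN_GK * g[("K", "n")] ** 4 * (V - PN_EK),
            "A": PN_GA * g[("A", "m")] ** 4 * g[("A", "h")] * (V - PN_EK),
        }
    return {
        "L": LN_GL * (V - LN_EL),
        "Ca": LN_GCA * g[("Ca", "m")] ** 2 * g[("Ca", "h")] * (V - LN_ECA),
        "CaK": LN_GCAK * g[("CaK", "m")] * (V - LN_EK),
        "K": LN_GK * g[("Kln", "n")] ** 4 * (V - LN_EK),
    }


def membrane_rhs(state: NeuronState, I_syn: float = 0.0,
                 I_input: float = 0.0) -> dict:
    """Time derivatives of all state fields.

    ``I_syn`` is the total synaptic current (positive = outward, as it
    enters the membrane equation with a minus sign); ``I_input`` is
    depolarizing stimulus/background current.  Returns a dict with keys
    ``"V"``, ``"Ca"`` and one entry per gate.
    """
    if not (np.isfinite(state.V) and np.isfinite(state.Ca)
            and np.isfinite(I_syn) and np.isfinite(I_input)):
        raise FloatingPointError("non-finite input to membrane_rhs")
    cur = intrinsic_currents(state)
    dV = (-sum(cur.values()) - I_syn + I_input) / CM
    out = {"V": dV}
    for key, x in state.gates.items():
        arg = {"Ca": state.Ca} if key[0] == "CaK" else {"V": state.V}
        out[key] = (gate_steady_state(*key, **arg) - x) / gate_time_constant(*key, **arg)
    if state.cell_type == "LN":
        out["Ca"] = -CA_A * cur["Ca"] - (state.Ca - CA_INF) / TAU_CA
    else:
        out["Ca"] = 0.0
    return out


def step_neuron(state: NeuronState, dt: float, I_syn: float = 0.0,
                I_input: float = 0.0) -> NeuronState:
    """One forward-Euler step (reference stepper; the engine has its own)."""
    d = membrane_rhs(state, I_syn, I_input)
    gates = {k: v + dt * d[k] for k, v in state.gates.items()}
    return NeuronState(state.cell_type, state.V + dt * d["V"], gates,
                       state.Ca + dt * d["Ca"])


def resting_potential(cell_type: str) -> float:
    """Quiescent membrane potential with all gates at steady state.

    Found by root-finding on the steady-state current-voltage relation.
    """
    from scipy.optimize import brentq

    def iss(V):
        s = NeuronState.resting(cell_type)
        s.V = V
        for k in list(s.gates):
            arg = {"Ca": s.Ca} if k[0] == "CaK" else {"V": V}
            s.gates[k] = gate_steady_state(*k, **arg)
        return sum(intrinsic_currents(s).values())

    lo, hi = -90.0, -40.0
    return float(brentq(iss, lo, hi, xtol=1e-10))
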