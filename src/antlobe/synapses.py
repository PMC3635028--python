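"""The three synaptic current schemes of the antennal-lobe model.

* Fast GABA (LN -> LN, LN -> PN): continuous transmitter release, a sigmoid
  of presynaptic voltage, driving first-order open-channel kinetics.
* Nicotinic ACh (PN -> PN, PN -> LN): a 0.3 ms transmitter pulse triggered
  each time the presynaptic PN crosses 0 mV from below.
* Slow inhibition (LN -> PN): G-protein-coupled; the same 0.3 ms pulse
  activates receptors R which produce G protein, and the current gates on
  a quartic Hill function of summed G.  Activation needs a volley of a few
  LN spikes, giving the ~150-200 ms "slow" timescale.

Channel state depends only on the presynaptic neuron, so one state per
presynaptic cell serves all of its efferent synapses; postsynaptic sums run
over afferents given by the wiring diagram.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from numba import njit

# transmitter sigmoid (GABA, continuous release)
T_V0, T_SIGMA = -20.0, 1.5

# event pulse (nACh and slow receptors)
T_PULSE = 0.5        # transmitter concentration during the pulse (mM)
T_MAX = 0.3          # pulse duration, ms
EVENT_THRESHOLD = 0.0    # presynaptic upward crossing triggers a pulse, mV
EVENT_REFRACTORY = 2.0   # ms; no re-trigger inside this window

# open-channel rate constants, 1/ms
GABA_ALPHA, GABA_BETA = 10.0, 0.16
NACH_ALPHA, NACH_BETA = 10.0, 0.2

# slow (G-protein) scheme
R1, R2, R3, R4 = 0.5, 0.0013, 0.1, 0.033   # mM^-1 ms^-1 and ms^-1
HILL_K = 100.0                             # uM^4

# reversal potentials, mV
E_GABA = -70.0
E_NACH = 0.0
E_K_SLOW = -95.0

# maximal conductances, mS/cm^2
G_GABA_LN_LN = 0.3
G_GABA_LN_PN = 0.36
G_SLOW_LN_PN = 0.36
G_NACH_PN_LN = 0.045
G_NACH_PN_PN = 0.009


@njit(cache=True)
def gaba_transmitter(V_pre: float) -> float:
    """Continuous GABA release as a sigmoid of presynaptic voltage."""
    return 1.0 / (1.0 + math.exp(-(V_pre - T_V0) / T_SIGMA))


@njit(cache=True)
def pulse_transmitter(t: float, t0: float) -> float:
    """Event-triggered transmitter: T_PULSE inside [t0, t0 + T_MAX], else 0."""
    if t0 <= t <= t0 + T_MAX:
        return T_PULSE
    return 0.0


# alias matching the receptor it feeds
nach_transmitter = pulse_transmitter


@dataclass
class SynapseState:
    """Kinetic state of one presynaptic cell's release machinery.

    O: open-channel fraction (GABA or nACh), in [0, 1].
    R, G: activated-receptor fraction and G-protein concentration of the
    slow scheme (LN only).  t0: time of the last presynaptic event (ms).
    """

    O: float = 0.0
    R: float = 0.0
    G: float = 0.0
    t0: float = -1.0e9


def channel_step(state: SynapseState, T: float, alpha: float, beta: float,
                 dt: float) -> SynapseState:
    """Forward-Euler update of the open-channel fraction.

    dO/dt = alpha (1 - O) T - beta O.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    O = state.O + dt * (alpha * (1.0 - state.O) * T - beta * state.O)
    return SynapseState(O=O, R=state.R, G=state.G, t0=state.t0)


def slow_step(state: SynapseState, T: float, dt: float) -> SynapseState:
    """Forward-Euler update of the G-protein cascade (R then G)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    R = state.R + dt * (R1 * (1.0 - state.R) * T - R2 * state.R)
    G = state.G + dt * (R3 * state.R - R4 * state.G)
    return SynapseState(O=state.O, R=R, G=G, t0=state.t0)


@njit(cache=True)
def hill_activation(G_total: float) -> float:
    """Quartic Hill factor G^4 / (G^4 + K) of the slow current, in [0, 1)."""
    g4 = G_total ** 4
    return g4 / (g4 + HILL_K)


def slow_current(G_total: float, V: float) -> float:
    """Slow inhibitory current density for summed G over afferent LNs."""
    return G_SLOW_LN_PN * hill_activation(G_total) * (V - E_K_SLOW)


def gaba_current(O_total: float, V: float, g_max: float = G_GABA_LN_PN) -> float:
    """Fast GABA current for the summed open fraction over afferent LNs."""
    return g_max * O_total * (V - E_GABA)


def nach_current(O_total: float, V: float, g_max: float = G_NACH_PN_PN) -> float:
    """Nicotinic current for the summed open fraction over afferent PNs."""
    return g_max * O_total * (V - E_NACH)
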