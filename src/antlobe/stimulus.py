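"""Background and odor input to the antennal lobe.

Every PN receives an independent background Poisson train (3500 events/s,
strength 0.0654 uA).  An odor stimulates 36 of the 90 PNs and 12 of the 30
LNs; each stimulated cell receives the superposition of 200 independent
35 events/s Poisson trains (7000 events/s aggregate) whose rate is modulated
by a rise/plateau/decay envelope: Gaussian-shaped rise over 400 ms, plateau
from t_o + s to t_d, root-exponential decay afterwards.

Each input event injects a rectangular current pulse of the per-event
strength, lasting TAU_IN, scaled by a single global INPUT_GAIN.  The (gain,
TAU_IN) pair is the calibration that pins the under-determined input kernel
to the model's rate contracts (background PNs 2-4 spikes/s, stimulated
active PNs 10-40 spikes/s); see docs/methods.md.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

# trial protocol, ms
T_ONSET = 1000.0
T_OFFSET = 3500.0
RISE_TIME = 400.0
C1 = 100000.0            # ms^2
C2 = math.sqrt(1000.0)   # ms^(1/2)

# input rates (events per second) and per-event strengths (uA)
BG_RATE = 3500.0
BG_STRENGTH = 0.0654
N_ORN_TRAINS = 200
ORN_TRAIN_RATE = 35.0
STIM_RATE = N_ORN_TRAINS * ORN_TRAIN_RATE      # aggregate, 7000/s
STIM_STRENGTH_PN = 0.01743
STIM_STRENGTH_LN = 0.01667

# input kernel calibration (frozen; see module docstring)
TAU_IN = 1.0             # ms, rectangular pulse per event
INPUT_GAIN = 20.4        # global gain (dimensionally ~ 1/membrane area)

N_STIM_PN = 36
N_STIM_LN = 12


@njit(cache=True)
def envelope(t: float, t_o: float = T_ONSET, t_d: float = T_OFFSET,
             s: float = RISE_TIME, c1: float = C1, c2: float = C2) -> float:
    """Odor input rate multiplier R(t)/r_m in [0, 1]."""
    if t < t_o:
        return 0.0
    if t < t_o + s:
        d = t - (t_o + s)
        return math.exp(-(d * d) / c1)
    if t <= t_d:
        return 1.0
    return math.exp(-math.sqrt(t - t_d) / c2)


def odor_envelope(t, stim: "OdorStimulus" = None):
    """Vectorized envelope evaluation for an odor's protocol parameters."""
    t_o = stim.t_onset if stim is not None else T_ONSET
    t_d = stim.t_offset if stim is not None else T_OFFSET
    t = np.asarray(t, dtype=float)
    if t.ndim == 0:
        return envelope(float(t), t_o, t_d)
    return np.array([envelope(float(x), t_o, t_d) for x in t])


@dataclass
class OdorStimulus:
    """An odor: the stimulated PN/LN index subsets plus envelope timing."""

    pn_indices: np.ndarray
    ln_indices: np.ndarray
    t_onset: float = T_ONSET
    t_offset: float = T_OFFSET
    seed: int = 0
    name: str = "odor"

    def __post_init__(self):
        self.pn_indices = np.asarray(sorted(set(int(i) for i in self.pn_indices)), dtype=np.int64)
        self.ln_indices = np.asarray(sorted(set(int(i) for i in self.ln_indices)), dtype=np.int64)

    def pn_mask(self, n_pn: int = 90) -> np.ndarray:
        m = np.zeros(n_pn)
        m[self.pn_indices] = 1.0
        return m

    def ln_mask(self, n_ln: int = 30) -> np.ndarray:
        m = np.zeros(n_ln)
        m[self.ln_indices] = 1.0
        return m


def make_odor(seed: int, n_pn: int = 90, n_ln: int = 30,
              name: str = "odor") -> OdorStimulus:
    """Draw a random odor: 36 stimulated PNs and 12 stimulated LNs."""
    rng = np.random.default_rng(seed)
    pn = rng.choice(n_pn, size=N_STIM_PN, replace=False)
    ln = rng.choice(n_ln, size=N_STIM_LN, replace=False)
    return OdorStimulus(pn, ln, seed=seed, name=name)


def make_odor_pair(overlap_pn: float, overlap_ln: float, seed: int,
                   n_pn: int = 90, n_ln: int = 30):
    """Two odors sharing a controlled fraction of stimulated cells.

    The pair shares exactly round(36 * overlap_pn) PNs and
    round(12 * overlap_ln) LNs; the remaining members are drawn disjointly.
    """
    if not (0 <= overlap_pn <= 1 and 0 <= overlap_ln <= 1):
        raise ValueError("overlap fractions must lie in [0, 1]")
    n_shared_pn = round(N_STIM_PN * overlap_pn)
    n_shared_ln = round(N_STIM_LN * overlap_ln)
    need_pn = 2 * N_STIM_PN - n_shared_pn
    need_ln = 2 * N_STIM_LN - n_shared_ln
    if need_pn > n_pn or need_ln > n_ln:
        raise ValueError("overlap infeasible: not enough neurons for "
                         "disjoint remainders")
    rng = np.random.default_rng(seed)
    pool_pn = rng.permutation(n_pn)[:need_pn]
    pool_ln = rng.permutation(n_ln)[:need_ln]
    shared_pn, rest_pn = pool_pn[:n_shared_pn], pool_pn[n_shared_pn:]
    shared_ln, rest_ln = pool_ln[:n_shared_ln], pool_ln[n_shared_ln:]
    k_pn = N_STIM_PN - n_shared_pn
    k_ln = N_STIM_LN - n_shared_ln
    o1 = OdorStimulus(np.concatenate([shared_pn, rest_pn[:k_pn]]),
                      np.concatenate([shared_ln, rest_ln[:k_ln]]),
                      seed=seed, name="odor1")
    o2 = OdorStimulus(np.concatenate([shared_pn, rest_pn[k_pn:]]),
                      np.concatenate([shared_ln, rest_ln[k_ln:]]),
                      seed=seed, name="odor2")
    return o1, o2


def sample_input_train(rate_fn, duration: float, seed: int,
                       strength: float = 1.0, gain: float = 1.0):
    """Sample one inhomogeneous Poisson event train by thinning.

    ``rate_fn(t)`` is the instantaneous rate in events/s over t in ms.
    Returns (event_times_ms, amplitudes); amplitudes are
    ``strength * gain`` per event.  Used for fixture-level checks; the
    simulation engine draws the same statistics step-by-step inline.
    """
    rng = np.random.default_rng(seed)
    rmax = max(float(rate_fn(t)) for t in np.arange(0.0, duration, 1.0))
    if rmax <= 0:
        return np.empty(0), np.empty(0)
    lam = rmax / 1000.0   # events per ms
    t, out = 0.0, []
    while True:
        t += rng.exponential(1.0 / lam)
        if t >= duration:
            break
        if rng.random() < float(rate_fn(t)) / rmax:
            out.append(t)
    times = np.array(out)
    return times, np.full(times.size, strength * gain)


# ----------------------------------------------------------- serialization

def odor_to_dict(odor: OdorStimulus) -> dict:
    return {
        "name": odor.name,
        "pn_indices": [int(i) for i in odor.pn_indices],
        "ln_indices": [int(i) for i in odor.ln_indices],
        "t_onset": float(odor.t_onset),
        "t_offset": float(odor.t_offset),
        "seed": int(odor.seed),
    }


def odor_from_dict(d: dict) -> OdorStimulus:
    return OdorStimulus(np.asarray(d["pn_indices"]), np.asarray(d["ln_indices"]),
                        t_onset=d.get("t_onset", T_ONSET),
                        t_offset=d.get("t_offset", T_OFFSET),
                        seed=d.get("seed", 0), name=d.get("name", "odor"))
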