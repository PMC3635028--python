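"""Forward-Euler integration of the full antennal-lobe network.

The whole network state advances synchronously at dt = 0.01 ms in a single
numba kernel: membrane and gate dynamics for every PN and LN, continuous
GABA release, event-triggered nicotinic and slow-receptor pulses, Poisson
background and envelope-modulated odor input, spike detection (upward 0 mV
crossings; 2 ms re-arm for PNs, 10 ms for the broad LN calcium spikes),
and a decimated LFP proxy (mean PN membrane potential).

Trials are deterministic given (master seed, trial index); the wiring seed
is separate so network variants share one diagram while trials vary.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from . import network as net
from . import stimulus as stim
from . import synapses as syn
from .neurons import (CM, PN_GL, PN_EL, PN_GNA, PN_ENA, PN_GK, PN_EK, PN_GA,
                      LN_GL, LN_EL, LN_GCA, LN_ECA, LN_GCAK, LN_GK, LN_EK,
                      CA_A, CA_INF, TAU_CA,
                      na_m_inf, na_m_tau, na_h_inf, na_h_tau,
                      k_n_inf, k_n_tau, a_m_inf, a_m_tau, a_h_inf, a_h_tau,
                      ca_m_inf, ca_m_tau, ca_h_inf, ca_h_tau,
                      cak_m_inf, cak_m_tau, ln_n_inf, ln_n_tau)
from .spikedata import SpikeData
from .stimulus import envelope
from .synapses import hill_activation

SPIKE_THRESHOLD = 0.0     # mV, upward crossing
SPIKE_REARM_PN = 2.0      # ms
SPIKE_REARM_LN = 10.0     # ms; one broad calcium spike = one event
V_BLOWUP = 200.0          # |V| beyond this aborts the trial

STATUS_OK = 0
STATUS_OVERFLOW = 1
STATUS_DIVERGED = 2


class SimulationDivergedError(RuntimeError):
    pass


@njit(cache=True)
def _poisson(L):
    """Poisson sample by Knuth's product method; L = exp(-lambda)."""
    k = 0
    p = np.random.random()
    while p > L:
        k += 1
        p *= np.random.random()
    return k


@njit(cache=True)
def _run_network(n_steps, dt, seed, n_pn, n_ln,
                 w_gaba_pn, w_gaba_ln, w_nach_pp, w_nach_pl,
                 slow_adj, g_slow,
                 stim_pn, stim_ln, const_pn, const_ln,
                 bg_on, gain, tau_in_steps,
                 t_onset, t_offset, rise, c1, c2,
                 lfp_every, lfp_out,
                 rec_every, v_pn_out, v_ln_out,
                 spk_t_pn, spk_c_pn, spk_t_ln, spk_c_ln):
    np.random.seed(seed)

    # --- state -----------------------------------------------------------
    Vp = np.full(n_pn, PN_EL)
    m_na = np.empty(n_pn); h_na = np.empty(n_pn); n_k = np.empty(n_pn)
    m_a = np.empty(n_pn); h_a = np.empty(n_pn)
    for p in range(n_pn):
        m_na[p] = na_m_inf(PN_EL); h_na[p] = na_h_inf(PN_EL)
        n_k[p] = k_n_inf(PN_EL)
        m_a[p] = a_m_inf(PN_EL); h_a[p] = a_h_inf(PN_EL)

    Vl = np.full(n_ln, LN_EL)
    m_ca = np.empty(n_ln); h_ca = np.empty(n_ln)
    m_ck = np.empty(n_ln); n_kl = np.empty(n_ln)
    Ca = np.full(n_ln, CA_INF)
    for q in range(n_ln):
        m_ca[q] = ca_m_inf(LN_EL); h_ca[q] = ca_h_inf(LN_EL)
        m_ck[q] = cak_m_inf(CA_INF); n_kl[q] = ln_n_inf(LN_EL)

    O_gaba = np.zeros(n_ln)
    O_nach = np.zeros(n_pn)
    R_slow = np.zeros(n_ln)
    G_slow = np.zeros(n_ln)
    t0_pn = np.full(n_pn, -1.0e9)
    t0_ln = np.full(n_ln, -1.0e9)
    last_pn = np.full(n_pn, -1.0e9)
    last_ln = np.full(n_ln, -1.0e9)

    # input event buffers: injected current contribution per step, rolling
    buf_pn = np.zeros((n_pn, tau_in_steps))
    buf_ln = np.zeros((n_ln, tau_in_steps))
    acc_pn = np.zeros(n_pn)
    acc_ln = np.zeros(n_ln)
    bi = 0

    lam_bg = stim.BG_RATE / 1000.0 * dt
    L_bg = math.exp(-lam_bg)
    lam_st_max = stim.STIM_RATE / 1000.0 * dt

    cap_pn = spk_t_pn.shape[1] if n_pn > 0 else 0
    cap_ln = spk_t_ln.shape[1] if n_ln > 0 else 0

    for i in range(n_steps):
        t = i * dt

        # ---- inputs -----------------------------------------------------
        env = envelope(t, t_onset, t_offset, rise, c1, c2)
        L_st = math.exp(-lam_st_max * env)
        for p in range(n_pn):
            a = 0.0
            if bg_on:
                a += stim.BG_STRENGTH * _poisson(L_bg)
            if stim_pn[p] > 0.0 and env > 0.0:
                a += stim.STIM_STRENGTH_PN * _poisson(L_st)
            a *= gain
            acc_pn[p] += a - buf_pn[p, bi]
            buf_pn[p, bi] = a
        for q in range(n_ln):
            a = 0.0
            if stim_ln[q] > 0.0 and env > 0.0:
                a += stim.STIM_STRENGTH_LN * _poisson(L_st)
            a *= gain
            acc_ln[q] += a - buf_ln[q, bi]
            buf_ln[q, bi] = a
        bi = (bi + 1) % tau_in_steps

        # ---- presynaptic channel kinetics -------------------------------
        for q in range(n_ln):
            Tg = 1.0 / (1.0 + math.exp(-(Vl[q] - syn.T_V0) / syn.T_SIGMA))
            O_gaba[q] += dt * (syn.GABA_ALPHA * (1.0 - O_gaba[q]) * Tg
                               - syn.GABA_BETA * O_gaba[q])
            Ts = syn.T_PULSE if (t - t0_ln[q]) <= syn.T_MAX else 0.0
            R_slow[q] += dt * (syn.R1 * (1.0 - R_slow[q]) * Ts
                               - syn.R2 * R_slow[q])
            G_slow[q] += dt * (syn.R3 * R_slow[q] - syn.R4 * G_slow[q])
        for p in range(n_pn):
            Tn = syn.T_PULSE if (t - t0_pn[p]) <= syn.T_MAX else 0.0
            O_nach[p] += dt * (syn.NACH_ALPHA * (1.0 - O_nach[p]) * Tn
                               - syn.NACH_BETA * O_nach[p])

        # ---- postsynaptic conductance sums ------------------------------
        g_gaba_on_pn = np.dot(w_gaba_pn, O_gaba) if n_ln > 0 else np.zeros(n_pn)
        g_gaba_on_ln = np.dot(w_gaba_ln, O_gaba) if n_ln > 0 else np.zeros(n_ln)
        g_nach_on_pn = np.dot(w_nach_pp, O_nach)
        g_nach_on_ln = np.dot(w_nach_pl, O_nach) if n_ln > 0 else np.zeros(n_ln)
        G_tot = np.dot(slow_adj, G_slow) if n_ln > 0 else np.zeros(n_pn)

        # ---- membrane update: PNs ---------------------------------------
        for p in range(n_pn):
            V = Vp[p]
            i_int = (PN_GL * (V - PN_EL)
                     + PN_GNA * m_na[p] ** 3 * h_na[p] * (V - PN_ENA)
                     + PN_GK * n_k[p] ** 4 * (V - PN_EK)
                     + PN_GA * m_a[p] ** 4 * h_a[p] * (V - PN_EK))
            i_syn = (g_gaba_on_pn[p] * (V - syn.E_GABA)
                     + g_nach_on_pn[p] * (V - syn.E_NACH)
                     + g_slow * hill_activation(G_tot[p]) * (V - syn.E_K_SLOW))
            Vnew = V + dt * (-i_int - i_syn + acc_pn[p] + const_pn[p]) / CM
            m_na[p] += dt * (na_m_inf(V) - m_na[p]) / na_m_tau(V)
            h_na[p] += dt * (na_h_inf(V) - h_na[p]) / na_h_tau(V)
            n_k[p] += dt * (k_n_inf(V) - n_k[p]) / k_n_tau(V)
            m_a[p] += dt * (a_m_inf(V) - m_a[p]) / a_m_tau(V)
            h_a[p] += dt * (a_h_inf(V) - h_a[p]) / a_h_tau(V)
            if Vnew > V_BLOWUP or Vnew < -V_BLOWUP:
                return STATUS_DIVERGED, i
            tnew = t + dt
            if V < SPIKE_THRESHOLD <= Vnew and tnew - last_pn[p] >= SPIKE_REARM_PN:
                if spk_c_pn[p] >= cap_pn:
                    return STATUS_OVERFLOW, i
                spk_t_pn[p, spk_c_pn[p]] = tnew
                spk_c_pn[p] += 1
                last_pn[p] = tnew
                t0_pn[p] = tnew
            Vp[p] = Vnew

        # ---- membrane update: LNs ---------------------------------------
        for q in range(n_ln):
            V = Vl[q]
            i_ca = LN_GCA * m_ca[q] ** 2 * h_ca[q] * (V - LN_ECA)
            i_int = (LN_GL * (V - LN_EL)
                     + i_ca
                     + LN_GCAK * m_ck[q] * (V - LN_EK)
                     + LN_GK * n_kl[q] ** 4 * (V - LN_EK))
            i_syn = (g_gaba_on_ln[q] * (V - syn.E_GABA)
                     + g_nach_on_ln[q] * (V - syn.E_NACH))
            Vnew = V + dt * (-i_int - i_syn + acc_ln[q] + const_ln[q]) / CM
            m_ca[q] += dt * (ca_m_inf(V) - m_ca[q]) / ca_m_tau(V)
            h_ca[q] += dt * (ca_h_inf(V) - h_ca[q]) / ca_h_tau(V)
            m_ck[q] += dt * (cak_m_inf(Ca[q]) - m_ck[q]) / cak_m_tau(Ca[q])
            n_kl[q] += dt * (ln_n_inf(V) - n_kl[q]) / ln_n_tau(V)
            Ca[q] += dt * (-CA_A * i_ca - (Ca[q] - CA_INF) / TAU_CA)
            if Vnew > V_BLOWUP or Vnew < -V_BLOWUP:
                return STATUS_DIVERGED, i
            tnew = t + dt
            if V < SPIKE_THRESHOLD <= Vnew and tnew - last_ln[q] >= SPIKE_REARM_LN:
                if spk_c_ln[q] >= cap_ln:
                    return STATUS_OVERFLOW, i
                spk_t_ln[q, spk_c_ln[q]] = tnew
                spk_c_ln[q] += 1
                last_ln[q] = tnew
                t0_ln[q] = tnew
            Vl[q] = Vnew

        # ---- recording --------------------------------------------------
        if lfp_every > 0 and i % lfp_every == 0:
            s = 0.0
            for p in range(n_pn):
                s += Vp[p]
            lfp_out[i // lfp_every] = s / max(n_pn, 1)
        if rec_every > 0 and i % rec_every == 0:
            j = i // rec_every
            for p in range(n_pn):
                v_pn_out[j, p] = Vp[p]
            for q in range(n_ln):
                v_ln_out[j, q] = Vl[q]

    return STATUS_OK, n_steps


# --------------------------------------------------------------- sim config

@dataclass
class SimConfig:
    """Everything that defines a simulation run."""

    variant: str = "I"
    wiring_seed: int = 7
    master_seed: int = 0
    n_trials: int = 80
    duration: float = 10000.0      # ms
    dt: float = 0.01               # ms
    odor: object = None            # OdorStimulus or None
    background: bool = True
    input_gain: float = stim.INPUT_GAIN
    tau_in: float = stim.TAU_IN
    scale_ln_ln_gaba: bool = False
    lfp_every: int = 10            # record mean PN V every N steps (0 = off)
    record_v: bool = False
    rec_every: int = 10

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_trials < 0:
            raise ValueError("n_trials must be non-negative")
        if self.odor is not None and self.duration < self.odor.t_onset:
            raise ValueError("trial shorter than stimulus onset")
        net.get_variant(self.variant)   # validates the label


def trial_seed(master_seed: int, trial_index: int) -> int:
    """Counter-based derivation of a per-trial substream seed (< 2^31)."""
    ss = np.random.SeedSequence((int(master_seed), int(trial_index)))
    return int(ss.generate_state(1)[0] % 2147483647)


@dataclass
class TrialResult:
    spikes: SpikeData
    lfp: np.ndarray = None
    v_pn: np.ndarray = None
    v_ln: np.ndarray = None
    status: int = STATUS_OK


def run_trial(config: SimConfig, trial_index: int = 0,
              wiring: net.WiringDiagram = None) -> TrialResult:
    """Simulate one trial; deterministic in (master seed, trial index)."""
    if wiring is None:
        wiring = net.build_wiring(config.wiring_seed)
    conds = net.apply_variant(wiring, config.variant,
                              scale_ln_ln_gaba=config.scale_ln_ln_gaba)
    n_pn, n_ln = net.N_PN, net.N_LN
    return _run_one(config, trial_index, conds, n_pn, n_ln)


def _run_one(config, trial_index, conds, n_pn, n_ln,
             const_pn=None, const_ln=None):
    dt = config.dt
    n_steps = int(round(config.duration / dt))
    seed = trial_seed(config.master_seed, trial_index)

    odor = config.odor
    stim_pn = odor.pn_mask(n_pn) if odor is not None else np.zeros(n_pn)
    stim_ln = odor.ln_mask(n_ln) if odor is not None else np.zeros(n_ln)
    t_on = odor.t_onset if odor is not None else 1.0e12
    t_off = odor.t_offset if odor is not None else 1.0e12

    if const_pn is None:
        const_pn = np.zeros(n_pn)
    if const_ln is None:
        const_ln = np.zeros(n_ln)

    tau_in_steps = max(1, int(round(config.tau_in / dt)))
    n_lfp = (n_steps + config.lfp_every - 1) // config.lfp_every \
        if config.lfp_every > 0 else 0
    lfp_out = np.zeros(max(n_lfp, 1))
    if config.record_v:
        n_rec = (n_steps + config.rec_every - 1) // config.rec_every
        v_pn = np.zeros((n_rec, n_pn))
        v_ln = np.zeros((n_rec, max(n_ln, 1)))
        rec_every = config.rec_every
    else:
        v_pn = np.zeros((1, n_pn))
        v_ln = np.zeros((1, max(n_ln, 1)))
        rec_every = 0

    cap = max(64, int(0.15 * config.duration))   # headroom: 150 spikes/s
    spk_t_pn = np.zeros((max(n_pn, 1), cap))
    spk_c_pn = np.zeros(max(n_pn, 1), np.int64)
    spk_t_ln = np.zeros((max(n_ln, 1), cap))
    spk_c_ln = np.zeros(max(n_ln, 1), np.int64)

    status, where = _run_network(
        n_steps, dt, seed, n_pn, n_ln,
        conds["w_gaba_ln_pn"], conds["w_gaba_ln_ln"],
        conds["w_nach_pn_pn"], conds["w_nach_pn_ln"],
        conds["slow_adjacency"], conds["g_slow"],
        stim_pn, stim_ln, const_pn, const_ln,
        config.background, config.input_gain, tau_in_steps,
        t_on, t_off, stim.RISE_TIME, stim.C1, stim.C2,
        config.lfp_every, lfp_out,
        rec_every, v_pn, v_ln,
        spk_t_pn, spk_c_pn, spk_t_ln, spk_c_ln)

    if status == STATUS_DIVERGED:
        raise SimulationDivergedError(
            f"|V| exceeded {V_BLOWUP} mV at step {where} "
            f"(t = {where * dt:.2f} ms)")
    if status == STATUS_OVERFLOW:
        raise SimulationDivergedError(f"spike buffer overflow at step {where}")

    trial = [spk_t_pn[p, :spk_c_pn[p]].copy() for p in range(n_pn)]
    trial += [spk_t_ln[q, :spk_c_ln[q]].copy() for q in range(n_ln)]
    sd = SpikeData(n_pn, n_ln, config.duration, trials=[trial],
                   meta=_meta(config, [trial_index]))
    return TrialResult(
        spikes=sd,
        lfp=lfp_out[:n_lfp] if n_lfp else None,
        v_pn=v_pn if config.record_v else None,
        v_ln=v_ln if config.record_v else None,
        status=status)


def run_experiment(config: SimConfig, wiring: net.WiringDiagram = None,
                   trial_indices=None):
    """Run all trials of a stimulus; returns (SpikeData, list of LFP traces).

    Trials are independent given their derived substream seeds, so a subset
    of trial indices can be (re)run without duplicating any other index.
    """
    if wiring is None:
        wiring = net.build_wiring(config.wiring_seed)
    conds = net.apply_variant(wiring, config.variant,
                              scale_ln_ln_gaba=config.scale_ln_ln_gaba)
    if trial_indices is None:
        trial_indices = list(range(config.n_trials))
    if len(set(trial_indices)) != len(trial_indices):
        raise ValueError("duplicate trial indices")
    all_spikes = SpikeData(net.N_PN, net.N_LN, config.duration,
                           meta=_meta(config, trial_indices))
    lfps = []
    for k in trial_indices:
        res = _run_one(config, k, conds, net.N_PN, net.N_LN)
        all_spikes.trials.append(res.spikes.trials[0])
        lfps.append(res.lfp)
    return all_spikes, lfps


def _meta(config, trial_indices):
    m = {
        "variant": config.variant,
        "wiring_seed": config.wiring_seed,
        "master_seed": config.master_seed,
        "dt": config.dt,
        "input_gain": config.input_gain,
        "tau_in": config.tau_in,
        "trial_indices": ",".join(str(i) for i in trial_indices),
    }
    if config.odor is not None:
        m["odor"] = config.odor.name
        m["t_onset"] = config.odor.t_onset
        m["t_offset"] = config.odor.t_offset
        m["odor_seed"] = config.odor.seed
    return m


# ------------------------------------------------------- single-cell runs

def run_single_cell(cell_type: str, I_const: float, duration: float = 500.0,
                    dt: float = 0.01, record_v: bool = True,
                    background: bool = False, gain: float = None,
                    seed: int = 0):
    """Simulate one isolated cell (all synapses absent) under constant
    and/or background drive.  Returns a TrialResult with the voltage trace
    recorded at full resolution."""
    n_pn = 1 if cell_type == "PN" else 0
    n_ln = 1 if cell_type == "LN" else 0
    cfg = SimConfig(variant="I", n_trials=1, duration=duration, dt=dt,
                    odor=None, background=background,
                    record_v=record_v, rec_every=1, lfp_every=0,
                    master_seed=seed)
    if gain is not None:
        cfg.input_gain = gain
    conds = {
        "w_gaba_ln_pn": np.zeros((n_pn, n_ln)),
        "w_gaba_ln_ln": np.zeros((n_ln, n_ln)),
        "w_nach_pn_pn": np.zeros((n_pn, n_pn)),
        "w_nach_pn_ln": np.zeros((n_ln, n_pn)),
        "slow_adjacency": np.zeros((n_pn, n_ln)),
        "g_slow": 0.0,
    }
    const_pn = np.full(n_pn, I_const, float)
    const_ln = np.full(n_ln, I_const, float)
    return _run_one(cfg, 0, conds, n_pn, n_ln, const_pn, const_ln)


def run_uncoupled_pns(n_pn: int, duration: float, master_seed: int = 0,
                      dt: float = 0.01, gain: float = None) -> SpikeData:
    """N independent PNs receiving only the background Poisson drive."""
    cfg = SimConfig(variant="I", n_trials=1, duration=duration, dt=dt,
                    odor=None, background=True, lfp_every=0,
                    master_seed=master_seed)
    if gain is not None:
        cfg.input_gain = gain
    conds = {
        "w_gaba_ln_pn": np.zeros((n_pn, 0)),
        "w_gaba_ln_ln": np.zeros((0, 0)),
        "w_nach_pn_pn": np.zeros((n_pn, n_pn)),
        "w_nach_pn_ln": np.zeros((0, n_pn)),
        "slow_adjacency": np.zeros((n_pn, 0)),
        "g_slow": 0.0,
    }
    res = _run_one(cfg, 0, conds, n_pn, 0)
    return res.spikes


# ------------------------------------------------------------- LFP analysis

def lfp_spectrum(lfp: np.ndarray, dt_ms: float, t_start: float, t_stop: float):
    """Periodogram of a mean-subtracted LFP window.  Returns (f_Hz, power)."""
    from scipy.signal import periodogram

    i0, i1 = int(round(t_start / dt_ms)), int(round(t_stop / dt_ms))
    if i0 < 0 or i1 > lfp.size or i1 <= i0:
        raise ValueError("window outside the recorded trace")
    seg = lfp[i0:i1] - np.mean(lfp[i0:i1])
    f, p = periodogram(seg, fs=1000.0 / dt_ms)
    return f, p


def lfp_peak_frequency(lfps, dt_ms: float, t_start: float, t_stop: float,
                       f_lo: float = 5.0, f_hi: float = 40.0):
    """Trial-averaged spectral peak in a band.  Returns (f_peak, spectrum)."""
    acc = None
    for lfp in lfps:
        f, p = lfp_spectrum(lfp, dt_ms, t_start, t_stop)
        acc = p if acc is None else acc + p
    acc = acc / len(lfps)
    band = (f >= f_lo) & (f <= f_hi)
    fb, pb = f[band], acc[band]
    return float(fb[np.argmax(pb)]), (f, acc)


def band_power(lfps, dt_ms, t_start, t_stop, f_lo=15.0, f_hi=25.0):
    """Mean power in a frequency band of the trial-averaged spectrum."""
    _, (f, p) = lfp_peak_frequency(lfps, dt_ms, t_start, t_stop)
    sel = (f >= f_lo) & (f <= f_hi)
    return float(np.mean(p[sel]))


def spike_width(v: np.ndarray, dt: float, threshold: float):
    """Widths (ms) between successive upward and downward crossings of a
    sub-peak threshold, one value per detected spike."""
    v = np.asarray(v).ravel()
    up = np.nonzero((v[:-1] < threshold) & (v[1:] >= threshold))[0]
    dn = np.nonzero((v[:-1] >= threshold) & (v[1:] < threshold))[0]
    widths = []
    for u in up:
        later = dn[dn > u]
        if later.size:
            widths.append((later[0] - u) * dt)
    return np.asarray(widths)
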