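"""Downstream analyses of temporally bound PN subsets: overlap distance
between odor-specific subsets (SDR), disinhibited-PN classification,
synchronous-event counting, subset pooling, a hypothetical Kenyon-cell
coincidence detector, and the spike-scrambling surrogate control.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .metrics import Epoch, JointTables, extract_subsets


# ------------------------------------------------------------------- SDR

def sdr(A, B) -> float:
    """Symmetric difference ratio between two PN subsets.

    With n = |larger|, k = |smaller|, s = |shared|:  SDR = 2(k - s)/(n + k).
    0 for identical sets, -> 1 for disjoint sets of equal size; the
    cardinality difference does not contribute.
    """
    A, B = set(A), set(B)
    if not A or not B:
        raise ValueError("SDR undefined for empty subsets")
    n, k = max(len(A), len(B)), min(len(A), len(B))
    s = len(A & B)
    return 2.0 * (k - s) / (n + k)


# ------------------------------------------------------- disinhibited PNs

def classify_disinhibited(rates_intact: np.ndarray,
                          rates_noslow: np.ndarray) -> np.ndarray:
    """PN ids whose odor-evoked rate at least doubled without slow synapses.

    Both rate vectors must come from the same wiring, odor and epoch
    (trial-averaged, 1 s from onset).  A silent-in-intact cell that becomes
    active counts as disinhibited (any positive rate at least doubles zero).
    """
    rates_intact = np.asarray(rates_intact, float)
    rates_noslow = np.asarray(rates_noslow, float)
    if rates_intact.shape != rates_noslow.shape:
        raise ValueError("rate vectors of different length")
    mask = (rates_noslow >= 2.0 * rates_intact) & (rates_noslow > 0)
    return np.nonzero(mask)[0]


def disinhibited_fraction_curve(records_by_threshold: dict,
                                disinhibited) -> dict:
    """Fraction of triplet-member PNs classified as disinhibited, per
    BI threshold.

    ``records_by_threshold`` maps threshold -> list of TupleRecord.
    Thresholds whose record list is empty are omitted (undefined point).
    """
    dset = set(int(i) for i in disinhibited)
    out = {}
    for thr, recs in records_by_threshold.items():
        members = set()
        for r in recs:
            members.update(r.ids)
        if not members:
            continue
        out[thr] = len(members & dset) / len(members)
    return out


# ------------------------------------------------------- event counting

def count_triplet_events(spikes, triplet, window: float = 10.0,
                         epoch: Epoch = None, trial: int = None) -> int:
    """Disjoint synchronous firing events of a PN tuple.

    Scanning forward in time, an event is scored whenever every member has
    a spike within a span <= window; the spikes of a scored event are
    consumed, so one burst cannot be counted twice.  Summed over trials
    unless a single ``trial`` index is given.
    """
    if epoch is None:
        epoch = Epoch.stimulus_second(spikes)
    trials = [spikes.trials[trial]] if trial is not None else spikes.trials
    total = 0
    for tr in trials:
        series = []
        for m in triplet:
            t = tr[m]
            series.append(t[(t >= epoch.t_start) & (t < epoch.t_stop)])
        total += _greedy_events(series, window)
    return total


def _greedy_events(series, window: float) -> int:
    ptr = [0] * len(series)
    count = 0
    while all(p < len(s) for p, s in zip(ptr, series)):
        heads = [s[p] for p, s in zip(ptr, series)]
        t_max = max(heads)
        moved = False
        for m, s in enumerate(series):
            while ptr[m] < len(s) and s[ptr[m]] < t_max - window:
                ptr[m] += 1
                moved = True
        if any(p >= len(s) for p, s in zip(ptr, series)):
            break
        if not moved:
            # all heads within [t_max - window, t_max]: one event, consume
            count += 1
            ptr = [p + 1 for p in ptr]
    return count


# ------------------------------------------------------------- pooling

@dataclass
class SubsetRecord:
    """A pooled temporally-bound PN subset with its provenance."""

    ids: frozenset
    odor: str = ""
    variant: str = ""
    threshold: float = float("nan")
    window: float = float("nan")
    n_triplets: int = 0


def pooled_subset(records, odor: str = "", variant: str = "") -> SubsetRecord:
    """Union of the member ids of a list of tuple records."""
    ids = set()
    thr = float("nan")
    win = float("nan")
    for r in records:
        ids.update(r.ids)
        win = r.window
    if records:
        thr = min(r.value for r in records)
    return SubsetRecord(frozenset(ids), odor=odor, variant=variant,
                        threshold=thr, window=win, n_triplets=len(records))


def tune_threshold_for_size(tables: JointTables, target_size: int,
                            start: float = 0.65, measure: str = "BI3",
                            tol: int = 0, max_iter: int = 25):
    """Find a BI threshold whose pooled triplet subset has ~target_size PNs.

    Bisection from ``start``; pooled size is non-increasing in the
    threshold.  Returns (threshold, records).  If the target is not exactly
    attainable the threshold with the closest pooled size (preferring the
    smaller subset on ties) is returned.
    """
    def size_at(thr):
        recs = extract_subsets(measure=measure, threshold=thr, tables=tables)
        return len(pooled_subset(recs).ids), recs

    lo, hi = 0.05, 0.999
    thr = start
    best = None
    for _ in range(max_iter):
        n, recs = size_at(thr)
        cand = (abs(n - target_size), n, thr, recs)
        if best is None or cand[:2] < best[:2]:
            best = cand
        if abs(n - target_size) <= tol:
            return thr, recs
        if n > target_size:
            lo = thr
        else:
            hi = thr
        thr = 0.5 * (lo + hi)
    return best[2], best[3]


# -------------------------------------------------------------- KC readout

@dataclass
class KCDetector:
    """Coincidence detector: fires when >= m_required of its PN subset
    spike inside a sliding window; a dead time of one window follows each
    response."""

    subset: tuple
    m_required: int = 9
    window: float = 10.0
    dead_time: float = None

    def __post_init__(self):
        self.subset = tuple(sorted(set(int(i) for i in self.subset)))
        if self.m_required > len(self.subset):
            raise ValueError("m_required exceeds subset size")
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.dead_time is None:
            self.dead_time = self.window


def kc_response(spikes, detector: KCDetector, epoch: Epoch = None) -> list:
    """KC spike times per trial.

    A KC spike is placed at the first time the trailing window holds spikes
    from at least ``m_required`` distinct subset members.
    """
    if epoch is None:
        epoch = Epoch.stimulus_second(spikes)
    out = []
    for tr in spikes.trials:
        times, whos = [], []
        for m in detector.subset:
            t = tr[m]
            t = t[(t >= epoch.t_start) & (t < epoch.t_stop)]
            times.append(t)
            whos.append(np.full(t.size, m))
        if times:
            t_all = np.concatenate(times)
            w_all = np.concatenate(whos)
            order = np.argsort(t_all, kind="stable")
            t_all, w_all = t_all[order], w_all[order]
        else:
            t_all = np.empty(0)
            w_all = np.empty(0, int)
        kc = []
        left = 0
        counts = {}
        distinct = 0
        last_fire = -np.inf
        for r in range(t_all.size):
            w = int(w_all[r])
            counts[w] = counts.get(w, 0) + 1
            if counts[w] == 1:
                distinct += 1
            while t_all[left] < t_all[r] - detector.window:
                wl = int(w_all[left])
                counts[wl] -= 1
                if counts[wl] == 0:
                    distinct -= 1
                left += 1
            if distinct >= detector.m_required and \
                    t_all[r] - last_fire >= detector.dead_time:
                kc.append(float(t_all[r]))
                last_fire = t_all[r]
        out.append(np.asarray(kc))
    return out


def kc_response_fraction(spikes, detector: KCDetector,
                         epoch: Epoch = None) -> float:
    """Fraction of trials on which the detector fires at least once."""
    resp = kc_response(spikes, detector, epoch)
    return float(np.mean([r.size > 0 for r in resp]))


# --------------------------------------------------------- scrambling null

def scramble_spikes(spikes, subset, epoch: Epoch = None, seed: int = 0):
    """Surrogate data: uniformly redistribute each subset member's spikes
    within the epoch, per trial, preserving the per-(trial, neuron) spike
    count.  Everything outside the epoch or the subset is untouched.
    """
    if epoch is None:
        t_on = float(spikes.meta.get("t_onset", 1000.0))
        epoch = Epoch(t_on, t_on + 500.0)
    rng = np.random.default_rng(seed)
    out = copy.deepcopy(spikes)
    for tr in out.trials:
        for m in subset:
            t = tr[m]
            inside = (t >= epoch.t_start) & (t < epoch.t_stop)
            n_in = int(inside.sum())
            if n_in == 0:
                continue
            new = np.sort(rng.uniform(epoch.t_start, epoch.t_stop, n_in))
            tr[m] = np.sort(np.concatenate([t[~inside], new]))
    out.meta = dict(out.meta)
    out.meta["scrambled"] = f"{epoch.t_start}-{epoch.t_stop}"
    return out
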