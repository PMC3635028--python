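"""Multi-neuron spike-timing statistics: windowed conditional co-firing
probabilities, the synchrony ratio (SR) and the binding index (BI).

All statistics are built from one primitive: for a conditioning neuron i,
look in a w-ms window centered at every spike of i inside the analysis
epoch (pooled over trials) and ask which other neurons fired at least once
inside that window.  P_{S|i} is the fraction of i's spikes whose window
contains spikes of every member of the set S.

The SR of an ordered triplet (i; j, k) is P_{j,k|i} / (P_{j|i} P_{k|i}) - 1:
zero under conditional independence, positive for genuine 3-point
correlation, and bounded in (-1, 1) because P_{j,k|i} <= min(P_{j|i},
P_{k|i}).  Ordered triplets are only considered when both pairwise
conditionals exceed 0.5.  The BI of an unordered tuple is the minimum over
each member's conditional probability that all other members co-fire --
a direct synchrony measure in [0, 1] that is also high for uncorrelated
firing at high rate.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

DEFAULT_WINDOW = 20.0     # ms, centered
PAIR_FILTER = 0.5         # ordered triplets need both P(.|i) above this


@dataclass
class Epoch:
    """Analysis window within each trial, ms."""

    t_start: float
    t_stop: float

    @classmethod
    def stimulus_second(cls, spikes, length: float = 1000.0) -> "Epoch":
        """The first `length` ms of the response after stimulus onset."""
        t_on = float(spikes.meta.get("t_onset", 1000.0))
        return cls(t_on, t_on + length)


@dataclass
class ConditionalProb:
    i: int
    targets: tuple
    window: float
    epoch: Epoch
    numerator: int
    denominator: int

    @property
    def value(self):
        if self.denominator == 0:
            return None            # conditioning neuron silent: undefined
        return self.numerator / self.denominator


@dataclass
class TupleRecord:
    """An extracted PN tuple with its measure value and provenance."""

    ids: tuple
    measure: str
    value: float
    window: float
    epoch: tuple
    n_trials: int
    counts: tuple = ()


# ----------------------------------------------------------- window tables

def window_hit_table(spikes, i: int, window: float, epoch: Epoch,
                     neurons=None) -> tuple:
    """Boolean table W of shape (n_windows, n_neurons): W[s, j] is True iff
    neuron j spiked inside the w-window centered at the s-th epoch spike of
    the conditioning neuron i (windows clipped at trial boundaries, pooled
    over trials)."""
    if neurons is None:
        neurons = range(spikes.n_neurons)
    neurons = list(neurons)
    half = window / 2.0
    rows = []
    for tr in spikes.trials:
        ti = tr[i]
        ti = ti[(ti >= epoch.t_start) & (ti < epoch.t_stop)]
        if ti.size == 0:
            continue
        lo = np.maximum(ti - half, 0.0)
        hi = np.minimum(ti + half, spikes.duration)
        block = np.empty((ti.size, len(neurons)), dtype=bool)
        for c, j in enumerate(neurons):
            tj = tr[j]
            block[:, c] = np.searchsorted(tj, hi, "right") > np.searchsorted(tj, lo, "left")
        rows.append(block)
    if not rows:
        return np.zeros((0, len(neurons)), dtype=bool), neurons
    return np.concatenate(rows, axis=0), neurons


def conditional_joint_prob(spikes, i: int, S, window: float = DEFAULT_WINDOW,
                           epoch: Epoch = None) -> ConditionalProb:
    """P_{S|i}: probability that every neuron in S fires within the window
    centered at a spike of i.  S = empty set gives 1 by convention."""
    S = tuple(S)
    if i in S:
        raise ValueError("conditioning neuron cannot be in the target set")
    if window <= 0:
        raise ValueError("window must be positive")
    if epoch is None:
        epoch = Epoch.stimulus_second(spikes)
    W, _ = window_hit_table(spikes, i, window, epoch, neurons=S)
    denom = W.shape[0]
    num = int(np.all(W, axis=1).sum()) if S else denom
    return ConditionalProb(i, S, window, epoch, num, denom)


# ----------------------------------------------------- all-pairs machinery

class JointTables:
    """Per-conditioning-neuron tables of pairwise joint conditionals.

    For each PN i, ``J[i][j, k]`` = P_{j,k|i} (diagonal: P_{j|i}) over the
    given window/epoch.  ``n[i]`` is the number of conditioning windows
    (spikes of i in the epoch over all trials).
    """

    def __init__(self, spikes, pns=None, window: float = DEFAULT_WINDOW,
                 epoch: Epoch = None):
        if epoch is None:
            epoch = Epoch.stimulus_second(spikes)
        if pns is None:
            pns = list(range(spikes.n_pn))
        self.pns = list(pns)
        self.window = window
        self.epoch = epoch
        self.n_trials = spikes.n_trials
        m = len(self.pns)
        self.J = np.full((m, m, m), np.nan)
        self.n = np.zeros(m, dtype=int)
        self._tables = {}
        for a, i in enumerate(self.pns):
            W, _ = window_hit_table(spikes, i, window, epoch, neurons=self.pns)
            self.n[a] = W.shape[0]
            self._tables[i] = W
            if W.shape[0]:
                Wf = W.astype(np.float64)
                self.J[a] = (Wf.T @ Wf) / W.shape[0]

    def pair_cond(self, a: int, b: int) -> float:
        """P_{b|a} by position in ``pns``."""
        return self.J[a, b, b]

    def higher_joint(self, a: int, others) -> float:
        """P_{others|a} for an arbitrary target set (positions)."""
        W = self._tables[self.pns[a]]
        if W.shape[0] == 0:
            return np.nan
        hit = np.all(W[:, list(others)], axis=1)
        return hit.mean()


def synchrony_ratio(spikes=None, i=None, j=None, k=None,
                    window: float = DEFAULT_WINDOW, epoch: Epoch = None,
                    tables: JointTables = None):
    """SR of the ordered triplet (i; j, k), or None if filtered out.

    The triplet is filtered out when either pairwise conditional is <= 0.5
    or the conditioning neuron never fires in the epoch.
    """
    if tables is None:
        tables = JointTables(spikes, pns=[i, j, k], window=window, epoch=epoch)
        a, b, c = 0, 1, 2
    else:
        a, b, c = (tables.pns.index(x) for x in (i, j, k))
    if tables.n[a] == 0:
        return None
    pj, pk = tables.pair_cond(a, b), tables.pair_cond(a, c)
    if not (pj > PAIR_FILTER and pk > PAIR_FILTER):
        return None
    return float(tables.J[a, b, c] / (pj * pk) - 1.0)


def binding_index(spikes=None, ids=None, window: float = DEFAULT_WINDOW,
                  epoch: Epoch = None, tables: JointTables = None) -> float:
    """BI of an unordered tuple of 3 or 4 PNs.

    min over members m of P_{rest|m}.  If a member never spikes in the
    epoch the BI is 0 by convention (an inactive member cannot be bound).
    """
    ids = tuple(ids)
    if len(ids) not in (3, 4):
        raise ValueError("binding index is defined for triplets/quadruplets")
    if tables is None:
        tables = JointTables(spikes, pns=list(ids), window=window, epoch=epoch)
    pos = [tables.pns.index(x) for x in ids]
    vals = []
    for a in pos:
        others = [b for b in pos if b != a]
        if tables.n[a] == 0:
            return 0.0
        if len(others) == 2:
            vals.append(tables.J[a, others[0], others[1]])
        else:
            vals.append(tables.higher_joint(a, others))
    return float(min(vals))


# ----------------------------------------------------------- bulk extraction

def all_binding_indices(tables: JointTables) -> np.ndarray:
    """Dense BI over all unordered PN triplets (positions in tables.pns).

    Returns a (m, m, m) array; entry [a, b, c] with a<b<c is the BI, other
    entries are NaN-free mirrors (the array is built symmetric).  Members
    with zero epoch spikes force BI = 0.
    """
    J = np.where(np.isnan(tables.J), 0.0, tables.J)
    B1 = J                                  # P_{b,c|a}
    B2 = np.transpose(J, (1, 0, 2))         # P_{a,c|b}
    B3 = np.transpose(J, (2, 1, 0))         # P_{b,a|c} == P_{a,b|c}
    return np.minimum(np.minimum(B1, B2), B3)


def extract_subsets(spikes=None, measure: str = "BI3", threshold: float = 0.5,
                    window: float = DEFAULT_WINDOW, epoch: Epoch = None,
                    tables: JointTables = None, ordered_policy: str = "any"):
    """Exhaustive thresholded extraction of correlated PN tuples.

    measure: "SR" (ordered triplets, reported as unordered sets whose best
    ordering passes per ``ordered_policy``: "any" or "all"), "BI3" or "BI4".
    Returns a list of TupleRecord sorted by decreasing value.
    """
    if tables is None:
        tables = JointTables(spikes, window=window, epoch=epoch)
    m = len(tables.pns)
    ep = (tables.epoch.t_start, tables.epoch.t_stop)
    recs = []

    if measure == "SR":
        J = tables.J
        diag = np.einsum("abb->ab", J)      # P_{b|a}
        for a in range(m):
            if tables.n[a] == 0:
                continue
            good = np.nonzero(diag[a] > PAIR_FILTER)[0]
            good = good[good != a]
            for x in range(len(good)):
                for y in range(x + 1, len(good)):
                    b, c = good[x], good[y]
                    sr = J[a, b, c] / (diag[a, b] * diag[a, c]) - 1.0
                    if sr >= threshold:
                        recs.append(TupleRecord(
                            (tables.pns[a], tables.pns[b], tables.pns[c]),
                            "SR", float(sr), tables.window, ep,
                            tables.n_trials, (int(tables.n[a]),)))
        if ordered_policy not in ("any", "all"):
            raise ValueError("ordered_policy must be 'any' or 'all'")
        best = {}
        cnt = {}
        for r in recs:
            key = tuple(sorted(r.ids))
            cnt[key] = cnt.get(key, 0) + 1
            if key not in best or r.value > best[key].value:
                best[key] = r
        if ordered_policy == "any":
            out = list(best.values())
        else:
            out = [r for key, r in best.items() if cnt[key] == 3]
        return sorted(out, key=lambda r: -r.value)

    if measure == "BI3":
        B = all_binding_indices(tables)
        for a, b, c in combinations(range(m), 3):
            v = B[a, b, c]
            if v >= threshold:
                recs.append(TupleRecord(
                    (tables.pns[a], tables.pns[b], tables.pns[c]),
                    "BI3", float(v), tables.window, ep, tables.n_trials))
        return sorted(recs, key=lambda r: -r.value)

    if measure == "BI4":
        # a quadruplet's BI is bounded by each component triplet's BI, so
        # only quadruplets whose four triplets all pass are candidates
        B = all_binding_indices(tables)
        good3 = [t for t in combinations(range(m), 3) if B[t] >= threshold]
        from collections import defaultdict
        by_pair = defaultdict(set)
        for t in good3:
            s = set(t)
            for pair in combinations(t, 2):
                by_pair[pair].update(s - set(pair))
        seen = set()
        for a, b, c in good3:
            cands = (by_pair[(a, b)] & by_pair[(a, c)] & by_pair[(b, c)])
            for d in cands:
                if d <= c:
                    continue
                quad = tuple(sorted((a, b, c, d)))
                if quad in seen:
                    continue
                seen.add(quad)
                if all(B[t] >= threshold for t in combinations(quad, 3)):
                    ids = tuple(tables.pns[x] for x in quad)
                    v = binding_index(ids=ids, tables=tables)
                    if v >= threshold:
                        recs.append(TupleRecord(ids, "BI4", float(v),
                                                tables.window, ep,
                                                tables.n_trials))
        return sorted(recs, key=lambda r: -r.value)

    raise ValueError(f"unknown measure {measure!r}")


def records_to_table(records) -> str:
    """Tab-separated text, one record per row."""
    lines = ["ids\tmeasure\tvalue\twindow\tepoch\tn_trials"]
    for r in records:
        ids = ",".join(str(i) for i in r.ids)
        lines.append(f"{ids}\t{r.measure}\t{r.value:.4f}\t{r.window}"
                     f"\t{r.epoch[0]}-{r.epoch[1]}\t{r.n_trials}")
    return "\n".join(lines) + "\n"
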