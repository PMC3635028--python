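"""Random wiring of the 90-PN / 30-LN antennal-lobe network and the seven
conductance-scaling variants derived from one fixed wiring diagram.

Connection probabilities are cell-type specific: PN->PN and PN->LN 0.1,
LN->LN 0.25, LN->PN 0.15.  Slow inhibitory synapses share the LN->PN
adjacency exactly, so each PN receives proportional amounts of fast and
slow inhibition.  Variants rescale GABA and/or slow conductances without
touching the wiring, so neuron k is identically wired in every variant.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import numpy as np

from . import synapses as syn

N_PN = 90
N_LN = 30

P_PN_PN = 0.1
P_PN_LN = 0.1
P_LN_LN = 0.25
P_LN_PN = 0.15


@dataclass
class NetworkVariant:
    """A functional state of the network: conductance scale factors."""

    label: str
    gaba_scale: float
    slow_scale: float


#: The seven functional states studied: intact (I), no GABA (NG), doubled and
#: tripled GABA, no slow inhibition (NS), and NS with doubled/tripled GABA.
VARIANTS = {
    "I": NetworkVariant("I", 1.0, 1.0),
    "NG": NetworkVariant("NG", 0.0, 1.0),
    "2X": NetworkVariant("2X", 2.0, 1.0),
    "3X": NetworkVariant("3X", 3.0, 1.0),
    "NS": NetworkVariant("NS", 1.0, 0.0),
    "NS-2X": NetworkVariant("NS-2X", 2.0, 0.0),
    "NS-3X": NetworkVariant("NS-3X", 3.0, 0.0),
}


def get_variant(label: str) -> NetworkVariant:
    try:
        return VARIANTS[label]
    except KeyError:
        raise ValueError(f"unknown network variant {label!r}; "
                         f"choose from {sorted(VARIANTS)}") from None


@dataclass
class WiringDiagram:
    """Four directed adjacency matrices plus provenance.

    ``A[post, pre]`` is 1 if presynaptic neuron ``pre`` synapses onto
    postsynaptic neuron ``post``.  The slow-inhibition adjacency is the
    LN->PN matrix itself (shared object by construction).
    """

    seed: int
    pn_pn: np.ndarray = field(repr=False)   # (N_PN, N_PN)
    pn_ln: np.ndarray = field(repr=False)   # (N_LN, N_PN)
    ln_ln: np.ndarray = field(repr=False)   # (N_LN, N_LN)
    ln_pn: np.ndarray = field(repr=False)   # (N_PN, N_LN)

    @property
    def slow_ln_pn(self) -> np.ndarray:
        """Slow synapses are distributed identically to fast GABA LN->PN."""
        return self.ln_pn

    def edge_counts(self) -> dict:
        return {
            "pn_pn": int(self.pn_pn.sum()),
            "pn_ln": int(self.pn_ln.sum()),
            "ln_ln": int(self.ln_ln.sum()),
            "ln_pn": int(self.ln_pn.sum()),
        }


def build_wiring(seed: int) -> WiringDiagram:
    """Draw the random wiring diagram for a given seed.

    Each ordered (pre, post) pair is an independent Bernoulli draw at the
    cell-type-specific probability.  Self-connections are excluded for
    PN->PN and LN->LN.  The same seed always reproduces the same diagram.
    """
    rng = np.random.default_rng(seed)
    pn_pn = (rng.random((N_PN, N_PN)) < P_PN_PN).astype(np.float64)
    np.fill_diagonal(pn_pn, 0.0)
    pn_ln = (rng.random((N_LN, N_PN)) < P_PN_LN).astype(np.float64)
    ln_ln = (rng.random((N_LN, N_LN)) < P_LN_LN).astype(np.float64)
    np.fill_diagonal(ln_ln, 0.0)
    ln_pn = (rng.random((N_PN, N_LN)) < P_LN_PN).astype(np.float64)
    return WiringDiagram(seed=seed, pn_pn=pn_pn, pn_ln=pn_ln,
                         ln_ln=ln_ln, ln_pn=ln_pn)


def apply_variant(diagram: WiringDiagram, variant,
                  scale_ln_ln_gaba: bool = False) -> dict:
    """Effective conductance matrices for one variant of a fixed wiring.

    Returns per-connection-type matrices already multiplied by the maximal
    conductance and the variant's scale factor, plus the binary slow
    adjacency and the effective slow conductance.  ``scale_ln_ln_gaba``
    controls whether GABA scaling also applies to LN->LN synapses; by
    default only LN->PN GABA is scaled (rescaling inter-LN inhibition
    changes LN firing itself, which re-routes the manipulation through the
    slow pathway and can mask the direct effect on PNs).
    """
    if isinstance(variant, str):
        variant = get_variant(variant)
    gs_ll = variant.gaba_scale if scale_ln_ln_gaba else 1.0
    return {
        "variant": variant,
        "w_gaba_ln_pn": syn.G_GABA_LN_PN * variant.gaba_scale * diagram.ln_pn,
        "w_gaba_ln_ln": syn.G_GABA_LN_LN * gs_ll * diagram.ln_ln,
        "w_nach_pn_pn": syn.G_NACH_PN_PN * diagram.pn_pn,
        "w_nach_pn_ln": syn.G_NACH_PN_LN * diagram.pn_ln,
        "slow_adjacency": diagram.slow_ln_pn,
        "g_slow": syn.G_SLOW_LN_PN * variant.slow_scale,
    }


# ------------------------------------------------------------ edge-list i/o

_BLOCKS = [("PN", "PN", "pn_pn"), ("PN", "LN", "pn_ln"),
           ("LN", "LN", "ln_ln"), ("LN", "PN", "ln_pn")]


def wiring_to_text(diagram: WiringDiagram) -> str:
    """Serialize as an edge list: one ``pre_type pre_i post_type post_i``
    line per directed edge, after a header carrying seed and probabilities."""
    out = StringIO()
    out.write(f"# wiring seed={diagram.seed} n_pn={N_PN} n_ln={N_LN}\n")
    out.write(f"# p pn_pn={P_PN_PN} pn_ln={P_PN_LN} "
              f"ln_ln={P_LN_LN} ln_pn={P_LN_PN}\n")
    for pre_t, post_t, attr in _BLOCKS:
        A = getattr(diagram, attr)
        post_idx, pre_idx = np.nonzero(A)
        for post, pre in zip(post_idx, pre_idx):
            out.write(f"{pre_t} {pre} {post_t} {post}\n")
    return out.getvalue()


def wiring_from_text(text: str) -> WiringDiagram:
    seed = 0
    mats = {"pn_pn": np.zeros((N_PN, N_PN)), "pn_ln": np.zeros((N_LN, N_PN)),
            "ln_ln": np.zeros((N_LN, N_LN)), "ln_pn": np.zeros((N_PN, N_LN))}
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            for tok in line[1:].split():
                if tok.startswith("seed="):
                    seed = int(tok[5:])
            continue
        pre_t, pre, post_t, post = line.split()
        mats[f"{pre_t.lower()}_{post_t.lower()}"][int(post), int(pre)] = 1.0
    return WiringDiagram(seed=seed, **mats)


def save_wiring(diagram: WiringDiagram, path) -> None:
    Path(path).write_text(wiring_to_text(diagram))


def load_wiring(path) -> WiringDiagram:
    return wiring_from_text(Path(path).read_text())
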