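"""Spike-train container shared by the simulator, the fixture generators and
the analysis layer, with HDF5 and plain-text round-trip."""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class SpikeData:
    """Per-trial, per-neuron spike times with trial metadata.

    ``trials[k]`` is a list of 1-D float arrays, one per neuron, of strictly
    increasing spike times in ms within [0, duration].  PNs come first
    (indices 0..n_pn-1), then LNs.  Metadata carries everything needed to
    regenerate the run.
    """

    n_pn: int
    n_ln: int
    duration: float
    trials: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_neurons(self) -> int:
        return self.n_pn + self.n_ln

    def pn_spikes(self, trial: int, pn: int) -> np.ndarray:
        return self.trials[trial][pn]

    def ln_spikes(self, trial: int, ln: int) -> np.ndarray:
        return self.trials[trial][self.n_pn + ln]

    def validate(self) -> None:
        for k, tr in enumerate(self.trials):
            if len(tr) != self.n_neurons:
                raise ValueError(f"trial {k}: {len(tr)} neurons, "
                                 f"expected {self.n_neurons}")
            for arr in tr:
                if arr.size and (arr.min() < 0
                                 or arr.max() > self.duration + 1e-6):
                    raise ValueError(f"trial {k}: spike time out of range")
                if np.any(np.diff(arr) <= 0):
                    raise ValueError(f"trial {k}: times not strictly increasing")

    def rates(self, t_start: float, t_stop: float, neurons=None) -> np.ndarray:
        """Trial-averaged firing rate (spikes/s) of each neuron in a window."""
        if neurons is None:
            neurons = range(self.n_neurons)
        neurons = list(neurons)
        counts = np.zeros(len(neurons))
        for tr in self.trials:
            for j, n in enumerate(neurons):
                a = tr[n]
                counts[j] += np.count_nonzero((a >= t_start) & (a < t_stop))
        dur_s = (t_stop - t_start) / 1000.0
        return counts / max(self.n_trials, 1) / dur_s

    # ------------------------------------------------------------- storage

    def save_h5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["n_pn"] = self.n_pn
            f.attrs["n_ln"] = self.n_ln
            f.attrs["duration"] = self.duration
            for key, val in self.meta.items():
                f.attrs[f"meta_{key}"] = _attr(val)
            for k, tr in enumerate(self.trials):
                g = f.create_group(f"trial_{k:04d}")
                for n, arr in enumerate(tr):
                    g.create_dataset(f"n{n:03d}", data=np.asarray(arr, float))

    @classmethod
    def load_h5(cls, path) -> "SpikeData":
        import h5py

        with h5py.File(path, "r") as f:
            meta = {k[5:]: _unattr(v) for k, v in f.attrs.items()
                    if k.startswith("meta_")}
            out = cls(int(f.attrs["n_pn"]), int(f.attrs["n_ln"]),
                      float(f.attrs["duration"]), meta=meta)
            for tk in sorted(k for k in f.keys() if k.startswith("trial_")):
                g = f[tk]
                out.trials.append([np.asarray(g[nk]) for nk in sorted(g.keys())])
        return out

    # two-column text export: neuron_id time_ms, trials separated by headers
    def to_text(self) -> str:
        lines = [f"# spikedata n_pn={self.n_pn} n_ln={self.n_ln} "
                 f"duration={self.duration} n_trials={self.n_trials}"]
        for k, tr in enumerate(self.trials):
            lines.append(f"# trial {k}")
            for n, arr in enumerate(tr):
                for t in arr:
                    lines.append(f"{n} {t:.6f}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "SpikeData":
        header = None
        trials, cur = [], None
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("# spikedata"):
                header = dict(tok.split("=") for tok in line.split()[2:])
            elif line.startswith("# trial"):
                if cur is not None:
                    trials.append(cur)
                cur = {}
            else:
                n, t = line.split()
                cur.setdefault(int(n), []).append(float(t))
        if cur is not None:
            trials.append(cur)
        n_pn, n_ln = int(header["n_pn"]), int(header["n_ln"])
        out = cls(n_pn, n_ln, float(header["duration"]))
        for tr in trials:
            out.trials.append([np.asarray(sorted(tr.get(n, [])), float)
                               for n in range(n_pn + n_ln)])
        return out

    def save_text(self, path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def load_text(cls, path) -> "SpikeData":
        return cls.from_text(Path(path).read_text())


def _attr(v):
    if isinstance(v, (str, int, float, np.integer, np.floating)):
        return v
    return repr(v)


def _unattr(v):
    if isinstance(v, bytes):
        return v.decode()
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v
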