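"""Deterministic spike-train generators with known correlation structure.

These fixtures make every statistic testable without the biophysical
simulator, and reproduce the three raster regimes that separate the
synchrony ratio from the binding index:

* ``independent``: homogeneous Poisson per neuron.  SR ~ 0 at any rate;
  BI grows with rate (window-occupancy probability 1 - exp(-r w)).
* ``pairwise-only``: a master event train at which every member fires
  independently with probability p (plus optional jitter).  Conditioned on
  one member firing, the others fire with high but *independent*
  probability, so 2-point correlations are strong while SR stays near 0.
* ``triplet-correlated``: all-or-none master events (the whole tuple
  participates with probability p) on top of a low independent background.
  Background spikes dilute the pairwise conditionals below 1 while joint
  co-firing survives, so SR is high; BI is high as well.

A ``cycle-locked`` mode emulates stimulus-locked 20 Hz-modulated firing:
each neuron independently fires on each oscillation cycle with probability
p, jittered around the cycle peak.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spikedata import SpikeData

MODES = ("independent", "pairwise-only", "triplet-correlated", "cycle-locked")


@dataclass
class FixtureSpec:
    n_neurons: int = 3
    rate: float = 2.0              # spikes/s; background rate in correlated modes
    mode: str = "independent"
    master_rate: float = 5.0       # events/s for the correlated modes
    p: float = 0.9                 # participation probability
    jitter: float = 3.0            # ms, s.d. of (truncated) Gaussian jitter
    jitter_cap: float = 10.0       # ms, |jitter| bound (half default window)
    cycle_hz: float = 20.0         # for cycle-locked mode
    duration: float = 10000.0      # ms
    epoch: tuple = (0.0, None)     # spikes generated inside this span
    n_trials: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown fixture mode {self.mode!r}")
        if self.rate < 0 or self.master_rate < 0 or self.jitter < 0:
            raise ValueError("rates and jitter must be non-negative")


def generate_fixture(spec: FixtureSpec) -> SpikeData:
    rng = np.random.default_rng(spec.seed)
    t0, t1 = spec.epoch
    if t1 is None:
        t1 = spec.duration
    data = SpikeData(spec.n_neurons, 0, spec.duration,
                     meta={"fixture_mode": spec.mode, "seed": spec.seed,
                           "t_onset": t0})
    for _ in range(spec.n_trials):
        trial = [_poisson_times(rng, spec.rate, t0, t1)
                 for _ in range(spec.n_neurons)]
        if spec.mode in ("pairwise-only", "triplet-correlated"):
            events = _poisson_times(rng, spec.master_rate, t0, t1)
            for ev in events:
                if spec.mode == "triplet-correlated":
                    members = (range(spec.n_neurons)
                               if rng.random() < spec.p else ())
                else:
                    members = [m for m in range(spec.n_neurons)
                               if rng.random() < spec.p]
                for m in members:
                    trial[m] = np.append(trial[m],
                                         _jittered(rng, ev, spec, t0, t1))
        elif spec.mode == "cycle-locked":
            period = 1000.0 / spec.cycle_hz
            peaks = np.arange(t0 + period / 2.0, t1, period)
            for m in range(spec.n_neurons):
                hit = peaks[rng.random(peaks.size) < spec.p]
                for ev in hit:
                    trial[m] = np.append(trial[m],
                                         _jittered(rng, ev, spec, t0, t1))
        trial = [np.unique(a) for a in trial]
        data.trials.append(trial)
    return data


def _poisson_times(rng, rate_hz, t0, t1):
    span = t1 - t0
    n = rng.poisson(rate_hz * span / 1000.0)
    return np.sort(rng.uniform(t0, t1, n))


def _jittered(rng, ev, spec: FixtureSpec, t0, t1):
    """One spike time near an event, jitter truncated to +-jitter_cap so a
    correlated event stays detectable in the default analysis window."""
    if spec.jitter == 0:
        return min(max(ev, t0), t1 - 1e-6)
    while True:
        d = rng.normal(0.0, spec.jitter)
        if abs(d) <= spec.jitter_cap:
            break
    return min(max(ev + d, t0), t1 - 1e-6)
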