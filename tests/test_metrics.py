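"""Conditional co-firing probabilities, SR and BI against brute-force
oracles on hand-built spike sets, plus their statistical properties on
synthetic trains."""
from itertools import combinations

import numpy as np
import pytest

from antlobe import fixtures as F
from antlobe import metrics as M
from antlobe.spikedata import SpikeData


def hand_built(spike_lists, duration=1000.0):
    sd = SpikeData(len(spike_lists), 0, duration, meta={"t_onset": 0.0})
    sd.trials.append([np.asarray(s, float) for s in spike_lists])
    return sd


def brute_force_cond(sd, i, S, w, epoch):
    """Naive re-computation: loop over every spike and every window."""
    num = den = 0
    half = w / 2.0
    for tr in sd.trials:
        for t in tr[i]:
            if not (epoch.t_start <= t < epoch.t_stop):
                continue
            den += 1
            lo, hi = max(t - half, 0.0), min(t + half, sd.duration)
            if all(np.any((tr[j] >= lo) & (tr[j] <= hi)) for j in S):
                num += 1
    return num, den


class TestConditionalProb:
    def test_manual_enumeration_example(self):
        # windows of i at 100 and 200; j and k both present only at t=100
        sd = hand_built([[100.0, 200.0], [105.0, 300.0], [95.0, 205.0]])
        ep = M.Epoch(0.0, 1000.0)
        p = M.conditional_joint_prob(sd, 0, (1, 2), window=20.0, epoch=ep)
        assert p.value == pytest.approx(0.5)
        assert (p.numerator, p.denominator) == (1, 2)

    def test_empty_target_set_is_vacuous(self):
        sd = hand_built([[10.0, 20.0], [15.0]])
        p = M.conditional_joint_prob(sd, 0, (), epoch=M.Epoch(0, 1000))
        assert p.value == 1.0

    def test_silent_target_gives_zero(self):
        sd = hand_built([[10.0, 20.0], []])
        p = M.conditional_joint_prob(sd, 0, (1,), epoch=M.Epoch(0, 1000))
        assert p.value == 0.0

    def test_silent_conditioning_neuron_is_undefined(self):
        sd = hand_built([[], [10.0]])
        p = M.conditional_joint_prob(sd, 0, (1,), epoch=M.Epoch(0, 1000))
        assert p.value is None

    def test_conditioning_neuron_cannot_be_target(self):
        sd = hand_built([[10.0], [20.0]])
        with pytest.raises(ValueError):
            M.conditional_joint_prob(sd, 0, (0, 1), epoch=M.Epoch(0, 1000))

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(0)
        sd = SpikeData(6, 0, 2000.0, meta={"t_onset": 0.0})
        for _ in range(3):   # three trials
            sd.trials.append([np.sort(rng.uniform(0, 2000, rng.integers(0, 40)))
                              for _ in range(6)])
        ep = M.Epoch(100.0, 1900.0)
        for i in range(6):
            for S in [(j,) for j in range(6) if j != i] + \
                     [tuple(s) for s in combinations([j for j in range(6)
                                                      if j != i], 2)]:
                p = M.conditional_joint_prob(sd, i, S, window=20.0, epoch=ep)
                num, den = brute_force_cond(sd, i, S, 20.0, ep)
                assert (p.numerator, p.denominator) == (num, den), (i, S)


class TestSynchronyRatio:
    def test_independence_null_from_constructed_probabilities(self):
        # conditionally independent co-firing: every window of i contains j
        # with p=0.8 and k with p=0.8 independently
        rng = np.random.default_rng(1)
        ti = np.arange(50.0, 19950.0, 40.0)
        tj = ti[rng.random(ti.size) < 0.8] + 1.0
        tk = ti[rng.random(ti.size) < 0.8] + 2.0
        sd = hand_built([ti, tj, tk], duration=20000.0)
        sr = M.synchrony_ratio(sd, 0, 1, 2, window=20.0,
                               epoch=M.Epoch(0, 20000))
        assert abs(sr) < 0.08

    def test_perfect_cofiring_arithmetic(self):
        # j,k fire together on exactly 80% of i's windows -> SR = 1/0.8 - 1
        ti = np.arange(50.0, 10000.0, 50.0)
        mask = np.arange(ti.size) % 5 != 0       # 4 of 5 windows
        tj, tk = ti[mask] + 2.0, ti[mask] - 2.0
        sd = hand_built([ti, tj, tk], duration=10000.0)
        sr = M.synchrony_ratio(sd, 0, 1, 2, window=20.0,
                               epoch=M.Epoch(0, 10000))
        p = mask.sum() / ti.size
        assert sr == pytest.approx(1 / p - 1, abs=1e-9)

    def test_pair_filter_rejects_weak_conditionals(self):
        ti = np.arange(50.0, 10000.0, 50.0)
        mask = np.arange(ti.size) % 5 < 2        # P = 0.4 <= 0.5
        tj = ti[mask] + 2.0
        tk = ti + 1.0
        sd = hand_built([ti, tj, tk], duration=10000.0)
        assert M.synchrony_ratio(sd, 0, 1, 2, window=20.0,
                                 epoch=M.Epoch(0, 10000)) is None

    def test_sr_bounded_on_simulated_fixtures(self):
        for seed in range(5):
            spec = F.FixtureSpec(rate=20.0, mode="independent", seed=seed,
                                 duration=10000.0, n_trials=2)
            sd = F.generate_fixture(spec)
            for i, j, k in [(0, 1, 2), (1, 0, 2), (2, 0, 1)]:
                sr = M.synchrony_ratio(sd, i, j, k, window=20.0,
                                       epoch=M.Epoch(0, 10000))
                if sr is not None:
                    assert -1.0 < sr < 1.0

    def test_independent_poisson_sr_concentrates_near_zero(self):
        """Across many seeds, the mean SR of a rate-matched independent
        triplet stays within 0.05 of zero."""
        vals = []
        for seed in range(200):
            spec = F.FixtureSpec(rate=40.0, mode="independent", seed=seed,
                                 duration=5000.0, n_trials=1)
            sd = F.generate_fixture(spec)
            sr = M.synchrony_ratio(sd, 0, 1, 2, window=20.0,
                                   epoch=M.Epoch(0, 5000))
            if sr is not None:
                vals.append(sr)
        assert len(vals) > 100
        assert abs(np.mean(vals)) < 0.05


class TestBindingIndex:
    def test_always_cofiring_triplet_has_bi_one(self):
        t = np.arange(50.0, 5000.0, 100.0)
        sd = hand_built([t, t + 3.0, t - 3.0], duration=5000.0)
        assert M.binding_index(sd, (0, 1, 2),
                               epoch=M.Epoch(0, 5000)) == pytest.approx(1.0)

    def test_never_cofiring_triplet_has_bi_zero(self):
        sd = hand_built([[100.0], [500.0], [900.0]])
        assert M.binding_index(sd, (0, 1, 2), epoch=M.Epoch(0, 1000)) == 0.0

    def test_silent_member_forces_zero(self):
        t = np.arange(50.0, 5000.0, 100.0)
        sd = hand_built([t, t + 1.0, []], duration=5000.0)
        assert M.binding_index(sd, (0, 1, 2), epoch=M.Epoch(0, 5000)) == 0.0

    def test_quadruplet_bounded_by_component_triplets(self):
        spec = F.FixtureSpec(n_neurons=4, rate=1.0, mode="triplet-correlated",
                             master_rate=6.0, p=0.9, seed=3,
                             duration=20000.0, n_trials=2)
        sd = F.generate_fixture(spec)
        ep = M.Epoch(0, 20000)
        bi4 = M.binding_index(sd, (0, 1, 2, 3), epoch=ep)
        for tri in combinations(range(4), 3):
            assert bi4 <= M.binding_index(sd, tri, epoch=ep) + 1e-12

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        sd = SpikeData(5, 0, 3000.0, meta={"t_onset": 0.0})
        sd.trials.append([np.sort(rng.uniform(0, 3000, 30)) for _ in range(5)])
        ep = M.Epoch(0.0, 3000.0)
        for ids in combinations(range(5), 3):
            bi = M.binding_index(sd, ids, epoch=ep)
            expected = []
            for m in ids:
                S = tuple(x for x in ids if x != m)
                num, den = brute_force_cond(sd, m, S, 20.0, ep)
                expected.append(num / den)
            assert bi == pytest.approx(min(expected))


@pytest.fixture(scope="module")
def tables():
    spec = F.FixtureSpec(n_neurons=8, rate=2.0, mode="triplet-correlated",
                         master_rate=5.0, p=0.85, seed=9,
                         duration=20000.0, n_trials=2)
    sd = F.generate_fixture(spec)
    return M.JointTables(sd, window=20.0, epoch=M.Epoch(0, 20000))


class TestExtraction:

    def test_threshold_monotonicity(self, tables):
        counts = [len(M.extract_subsets(measure="BI3", threshold=th,
                                        tables=tables))
                  for th in (0.0, 0.2, 0.4, 0.6, 0.8)]
        assert counts == sorted(counts, reverse=True)

    def test_zero_threshold_returns_all_active_triplets(self, tables):
        recs = M.extract_subsets(measure="BI3", threshold=0.0, tables=tables)
        from math import comb
        assert len(recs) == comb(8, 3)

    def test_above_max_threshold_empty(self, tables):
        assert M.extract_subsets(measure="BI3", threshold=1.01,
                                 tables=tables) == []

    def test_sr_extraction_matches_direct_computation(self, tables):
        recs = M.extract_subsets(measure="SR", threshold=0.1, tables=tables)
        for r in recs[:10]:
            i, j, k = r.ids
            direct = M.synchrony_ratio(i=i, j=j, k=k, tables=tables)
            assert direct == pytest.approx(r.value)
            assert direct >= 0.1

    def test_bi4_respects_threshold(self, tables):
        recs = M.extract_subsets(measure="BI4", threshold=0.3, tables=tables)
        for r in recs:
            assert len(r.ids) == 4
            assert r.value >= 0.3
            assert r.value == pytest.approx(
                M.binding_index(ids=r.ids, tables=tables))
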