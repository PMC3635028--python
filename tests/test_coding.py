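"""SDR, disinhibition classification, event counting, KC readout and the
scrambling surrogate, on hand-built data."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from antlobe import coding as C
from antlobe.metrics import Epoch, TupleRecord
from antlobe.spikedata import SpikeData


def hand_built(spike_lists, duration=1000.0, n_trials=1):
    sd = SpikeData(len(spike_lists), 0, duration, meta={"t_onset": 0.0})
    for _ in range(n_trials):
        sd.trials.append([np.asarray(s, float) for s in spike_lists])
    return sd


class TestSDR:
    def test_identical_sets(self):
        assert C.sdr({1, 2, 3}, {1, 2, 3}) == 0.0

    def test_disjoint_equal_size(self):
        assert C.sdr(set(range(12)), set(range(20, 32))) == 1.0

    def test_half_shared(self):
        a, b = set(range(12)), set(range(6, 18))
        assert C.sdr(a, b) == pytest.approx(0.5)

    def test_symmetry_and_cardinality_correction(self):
        a, b = set(range(10)), set(range(5, 12))     # n=10, k=7, s=5
        assert C.sdr(a, b) == C.sdr(b, a) == pytest.approx(2 * (7 - 5) / 17)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            C.sdr(set(), {1})

    @given(st.sets(st.integers(0, 30), min_size=1, max_size=15),
           st.sets(st.integers(0, 30), min_size=1, max_size=15))
    @settings(max_examples=200, deadline=None)
    def test_bounded_and_symmetric(self, a, b):
        v = C.sdr(a, b)
        assert 0.0 <= v <= 1.0
        assert v == C.sdr(b, a)


class TestDisinhibited:
    def test_classification_rules(self):
        r_i = np.array([2.0, 4.0, 0.0, 1.0])
        r_ns = np.array([5.0, 6.0, 1.0, 2.0])
        ids = C.classify_disinhibited(r_i, r_ns)
        # doubled: 2->5 yes, 4->6 no, 0->1 yes (zero-rate convention),
        # 1->2 yes (exactly doubled counts)
        assert list(ids) == [0, 2, 3]

    def test_silent_in_both_is_not_disinhibited(self):
        ids = C.classify_disinhibited(np.zeros(3), np.zeros(3))
        assert ids.size == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            C.classify_disinhibited(np.zeros(3), np.zeros(4))

    def test_fraction_curve_extremes(self):
        recs = {0.0: [TupleRecord((1, 2, 3), "BI3", 0.5, 20, (0, 1), 1)],
                0.9: []}
        curve_all = C.disinhibited_fraction_curve(recs, {1, 2, 3})
        assert curve_all == {0.0: 1.0}          # empty threshold omitted
        curve_none = C.disinhibited_fraction_curve(recs, set())
        assert curve_none == {0.0: 0.0}


class TestEventCounting:
    def test_single_event(self):
        sd = hand_built([[10.0], [12.0], [15.0]])
        assert C.count_triplet_events(sd, (0, 1, 2), window=10.0,
                                      epoch=Epoch(0, 1000)) == 1

    def test_silent_member_no_events(self):
        sd = hand_built([[10.0], [], [15.0]])
        assert C.count_triplet_events(sd, (0, 1, 2), window=10.0,
                                      epoch=Epoch(0, 1000)) == 0

    def test_two_separated_episodes(self):
        sd = hand_built([[10.0, 200.0], [12.0, 204.0], [15.0, 199.0]])
        assert C.count_triplet_events(sd, (0, 1, 2), window=10.0,
                                      epoch=Epoch(0, 1000)) == 2

    def test_burst_not_double_counted(self):
        # one member bursts inside a single co-firing episode
        sd = hand_built([[10.0, 11.0, 12.0, 13.0], [12.0], [15.0]])
        assert C.count_triplet_events(sd, (0, 1, 2), window=10.0,
                                      epoch=Epoch(0, 1000)) == 1

    def test_span_wider_than_window_not_an_event(self):
        sd = hand_built([[10.0], [18.0], [25.0]])
        assert C.count_triplet_events(sd, (0, 1, 2), window=10.0,
                                      epoch=Epoch(0, 1000)) == 0

    def test_sums_over_trials(self):
        sd = hand_built([[10.0], [12.0], [15.0]], n_trials=3)
        assert C.count_triplet_events(sd, (0, 1, 2), window=10.0,
                                      epoch=Epoch(0, 1000)) == 3


class TestPooling:
    def _rec(self, ids, v=0.7):
        return TupleRecord(tuple(ids), "BI3", v, 20.0, (0, 1000), 1)

    def test_disjoint_union(self):
        s = C.pooled_subset([self._rec((1, 2, 3)), self._rec((4, 5, 6))])
        assert s.ids == frozenset(range(1, 7))

    def test_overlapping_union(self):
        s = C.pooled_subset([self._rec((1, 2, 3)), self._rec((2, 3, 4))])
        assert s.ids == frozenset({1, 2, 3, 4})

    def test_empty_input(self):
        assert C.pooled_subset([]).ids == frozenset()


class TestKCDetector:
    def _volley(self, n_members, t, jitter=0.3):
        return [[t + k * jitter] for k in range(n_members)]

    def test_fires_on_nine_coincident_members(self):
        spikes = self._volley(9, 500.0) + [[] for _ in range(4)]
        sd = hand_built(spikes)
        det = C.KCDetector(subset=range(13), m_required=9, window=10.0)
        resp = C.kc_response(sd, det, Epoch(0, 1000))
        assert len(resp[0]) == 1

    def test_eight_members_insufficient(self):
        spikes = self._volley(8, 500.0) + [[] for _ in range(5)]
        sd = hand_built(spikes)
        det = C.KCDetector(subset=range(13), m_required=9, window=10.0)
        resp = C.kc_response(sd, det, Epoch(0, 1000))
        assert len(resp[0]) == 0

    def test_dead_time_suppresses_double_counting(self):
        # a sustained 30 ms volley of all 13 members produces few spikes
        spikes = [[500.0 + j for j in range(0, 30, 3)] for _ in range(13)]
        sd = hand_built(spikes)
        det = C.KCDetector(subset=range(13), m_required=9, window=10.0)
        resp = C.kc_response(sd, det, Epoch(0, 1000))
        assert 1 <= len(resp[0]) <= 3

    def test_m_larger_than_subset_rejected(self):
        with pytest.raises(ValueError):
            C.KCDetector(subset=range(5), m_required=9)

    def test_response_fraction(self):
        sd = hand_built(self._volley(9, 500.0) + [[] for _ in range(4)],
                        n_trials=4)
        det = C.KCDetector(subset=range(13), m_required=9)
        assert C.kc_response_fraction(sd, det, Epoch(0, 1000)) == 1.0


class TestScrambling:
    def test_counts_conserved_and_epoch_respected(self):
        rng = np.random.default_rng(2)
        sd = SpikeData(4, 0, 2000.0, meta={"t_onset": 500.0})
        sd.trials.append([np.sort(rng.uniform(0, 2000, 25)) for _ in range(4)])
        ep = Epoch(500.0, 1000.0)
        out = C.scramble_spikes(sd, subset=[0, 1], epoch=ep, seed=1)
        for m in range(4):
            a, b = sd.trials[0][m], out.trials[0][m]
            assert a.size == b.size
            inside_a = (a >= 500) & (a < 1000)
            inside_b = (b >= 500) & (b < 1000)
            assert inside_a.sum() == inside_b.sum()
            if m >= 2:      # non-subset neurons untouched
                assert np.array_equal(a, b)
            else:           # outside-epoch spikes untouched
                assert np.array_equal(a[~inside_a], b[~inside_b])

    def test_zero_spike_member_unchanged(self):
        sd = hand_built([[], [100.0]], duration=1000.0)
        out = C.scramble_spikes(sd, subset=[0], epoch=Epoch(0, 1000), seed=0)
        assert out.trials[0][0].size == 0

    def test_original_not_mutated(self):
        sd = hand_built([[100.0, 200.0]], duration=1000.0)
        before = sd.trials[0][0].copy()
        C.scramble_spikes(sd, subset=[0], epoch=Epoch(0, 1000), seed=3)
        assert np.array_equal(sd.trials[0][0], before)


class TestThresholdTuning:
    def test_reaches_target_size_on_fixture(self):
        from antlobe import fixtures as F
        from antlobe import metrics as M
        spec = F.FixtureSpec(n_neurons=20, rate=2.0,
                             mode="triplet-correlated", master_rate=5.0,
                             p=0.85, seed=4, duration=20000.0, n_trials=2)
        sd = F.generate_fixture(spec)
        tables = M.JointTables(sd, window=20.0, epoch=M.Epoch(0, 20000))
        thr, recs = C.tune_threshold_for_size(tables, 13, start=0.65)
        size = len(C.pooled_subset(recs).ids)
        assert abs(size - 13) <= 7      # closest attainable pooled size
        assert 0.0 < thr < 1.0
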