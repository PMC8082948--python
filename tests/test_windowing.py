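"""Window segmentation, label assignment and temporal splitting."""

from datetime import datetime

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from physiotrack.records import ImuRecording, LabelSpan
from physiotrack.windowing import (ChannelScaler, MotionClassMap, UNLABELED,
                                   assign_labels, segment_windows,
                                   temporal_split, windows_to_arrays)


def _rec(duration_s, rate=50.0, pid="p0", sid="s0",
         start=datetime(2021, 1, 4, 10, 0)):
    n = int(round(duration_s * rate))
    return ImuRecording(pid, sid, "home", start, rate,
                        np.zeros((n, 9)))


class TestSegmentWindows:
    @pytest.mark.parametrize("dur,window,stride,expected", [
        (60.0, 10.0, 5.0, 11),
        (10.0, 10.0, 5.0, 1),
        (9.9, 10.0, 5.0, 0),
        (300.0, 10.0, 10.0, 30),
    ])
    def test_window_counts(self, dur, window, stride, expected):
        wins = segment_windows(_rec(dur), window, stride)
        assert len(wins) == expected
        if wins:
            assert all(w.values.shape == (int(window * 50), 9) for w in wins)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(T=st.integers(1, 3000), L=st.integers(1, 600),
           S=st.integers(1, 400))
    def test_count_matches_closed_form(self, T, L, S):
        """Window count equals floor((T-L)/S)+1 for any sizes (rate 1 Hz)."""
        rec = ImuRecording("p", "s", "home", datetime(2021, 1, 4), 1.0,
                           np.zeros((T, 9)))
        wins = segment_windows(rec, window_s=L, stride_s=S)
        expected = (T - L) // S + 1 if T >= L else 0
        assert len(wins) == expected
        starts = [w.start_s for w in wins]
        assert starts == [i * S for i in range(expected)]

    def test_invalid_stride(self):
        with pytest.raises(ValueError):
            segment_windows(_rec(60), 10.0, 0.0)

    def test_noninteger_window_rejected(self):
        with pytest.raises(ValueError):
            segment_windows(_rec(60), 10.003, 5.0)


class TestAssignLabels:
    cmap = MotionClassMap({3: 2, 1: 1, 101: 101})

    def test_full_containment(self):
        wins = segment_windows(_rec(30), 10, 10)
        spans = [LabelSpan(0.0, 30.0, 3)]
        out = assign_labels(wins, spans, self.cmap)
        assert [w.label for w in out] == [2, 2, 2]

    def test_majority_coverage_wins(self):
        """60% class A / 40% uncovered -> labeled A at threshold 0.5."""
        wins = segment_windows(_rec(10), 10, 10)
        out = assign_labels(wins, [LabelSpan(0.0, 6.0, 1)], self.cmap)
        assert out[0].label == 1

    def test_exact_tie_stays_unlabeled(self):
        """50/50 coverage fails the strict majority rule."""
        wins = segment_windows(_rec(10), 10, 10)
        out = assign_labels(wins, [LabelSpan(0.0, 5.0, 1)], self.cmap)
        assert out[0].label == UNLABELED

    def test_span_order_invariance(self, rng):
        wins = segment_windows(_rec(120), 10, 5)
        spans = [LabelSpan(0, 40, 1), LabelSpan(50, 80, 3),
                 LabelSpan(90, 120, 1)]
        ref = [w.label for w in assign_labels(wins, spans, self.cmap)]
        for _ in range(3):
            perm = list(rng.permutation(len(spans)))
            got = [w.label for w in
                   assign_labels(wins, [spans[i] for i in perm], self.cmap)]
            assert got == ref

    def test_coverage_fraction_oracle(self, rng):
        """Label equals the brute-force per-sample majority computation."""
        wins = segment_windows(_rec(60), 10, 5)
        spans = [LabelSpan(3.0, 27.0, 1), LabelSpan(31.0, 44.0, 3)]
        out = assign_labels(wins, spans, self.cmap)
        for w in out:
            # brute force: fraction of the window covered by each span class
            cover = {}
            for sp in spans:
                ov = max(0.0, min(w.end_s, sp.end_s) - max(w.start_s, sp.start_s))
                if ov:
                    cover[self.cmap(sp.class_id)] = cover.get(
                        self.cmap(sp.class_id), 0) + ov
            expect = UNLABELED
            if cover:
                best = max(cover, key=cover.get)
                if cover[best] > 0.5 * w.length_s:
                    expect = best
            assert w.label == expect

    def test_missing_exercise_id_named(self):
        wins = segment_windows(_rec(10), 10, 10)
        with pytest.raises(KeyError, match="77"):
            assign_labels(wins, [LabelSpan(0, 10, 77)], self.cmap)

    def test_adl_background_class(self):
        wins = segment_windows(_rec(30), 10, 10)
        out = assign_labels(wins, [], self.cmap, background_class=101)
        assert all(w.label == 101 for w in out)

    def test_overlapping_spans_rejected(self):
        wins = segment_windows(_rec(30), 10, 10)
        with pytest.raises(ValueError):
            assign_labels(wins, [LabelSpan(0, 10, 1), LabelSpan(5, 15, 3)],
                          self.cmap)


class TestTemporalSplit:
    def _sessions(self, pid, times):
        return [(pid, f"{pid}_s{i}", t,
                 segment_windows(_rec(20, pid=pid, sid=f"{pid}_s{i}",
                                      start=t), 10, 10))
                for i, t in enumerate(times)]

    def test_last_session_goes_to_test(self):
        times = [datetime(2021, 1, d, 10, 0) for d in (4, 6, 8)]
        train, test = temporal_split(self._sessions("pA", times))
        assert {w.session_id for w in test} == {"pA_s2"}
        assert {w.session_id for w in train} == {"pA_s0", "pA_s1"}

    def test_single_session_patient_tests_only(self):
        train, test = temporal_split(
            self._sessions("pB", [datetime(2021, 1, 4, 10, 0)]))
        assert train == [] and len(test) == 2

    def test_partition_property(self):
        sess = (self._sessions("pA", [datetime(2021, 1, d) for d in (4, 5, 7)])
                + self._sessions("pB", [datetime(2021, 1, d) for d in (4, 9)]))
        train, test = temporal_split(sess)
        all_ids = {(w.session_id, w.start_s) for w in train + test}
        assert len(all_ids) == len(train) + len(test)   # disjoint
        assert len(train) + len(test) == sum(len(s[3]) for s in sess)

    def test_duplicate_timestamp_tiebreak(self, caplog):
        t = datetime(2021, 1, 4, 10, 0)
        sess = self._sessions("pC", [t, t])
        with caplog.at_level("WARNING"):
            train, test = temporal_split(sess)
        # deterministic: larger session_id wins the tie for test
        assert {w.session_id for w in test} == {"pC_s1"}
        assert any("duplicate" in r.message for r in caplog.records)

    def test_adl_routing(self):
        adl = [("vol0", segment_windows(_rec(20, pid="vol0"), 10, 10))]
        sess = self._sessions("pA", [datetime(2021, 1, 4)])
        train, test = temporal_split(sess, adl, adl_to_test=False)
        assert len(train) == 2
        train2, test2 = temporal_split(sess, adl, adl_to_test=True)
        assert len(train2) == 0 and len(test2) == 4


class TestChannelScaler:
    def test_statistics_from_training_only(self, rng):
        wins = segment_windows(
            ImuRecording("p", "s", "home", datetime(2021, 1, 4), 50.0,
                         rng.normal(3.0, 2.0, size=(1000, 9))), 10, 10)
        scaler = ChannelScaler.fit(wins)
        stacked = np.concatenate([w.values for w in wins])
        np.testing.assert_allclose(scaler.mean, stacked.mean(axis=0))
        np.testing.assert_allclose(scaler.std, stacked.std(axis=0))
        z = scaler.transform(stacked)
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-12)

    def test_arrays_drop_unlabeled(self):
        wins = segment_windows(_rec(40), 10, 10)
        for i, w in enumerate(wins):
            w.label = UNLABELED if i % 2 else 5
        X, y = windows_to_arrays(wins)
        assert X.shape[0] == 2 and set(y) == {5}
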