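"""Stimulus schedule, escape criterion, responsiveness and activity metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from zebrahab.assay import (
    PhaseSpec,
    ScheduleConfig,
    StimulusEvent,
    TrackingRecord,
    auc_responsiveness,
    build_schedule,
    classify_escape,
    non_responder_filter,
    spontaneous_activity,
)


class TestSchedule:
    def test_default_protocol_counts(self):
        sched = build_schedule()
        assert len(sched) == 50
        assert len(sched.phase_events("subthreshold")) == 10
        assert len(sched.phase_events("prehabituation")) == 10
        assert len(sched.phase_events("habituation")) == 30

    def test_phase3_onsets_spaced_one_second(self):
        onsets = [e.onset_s for e in build_schedule().phase_events("habituation")]
        assert np.allclose(np.diff(onsets), 1.0)

    def test_intensities_and_pulse(self):
        sched = build_schedule()
        sub = sched.phase_events("subthreshold")[0]
        hab = sched.phase_events("habituation")[0]
        assert sub.intensity_db == 20.0 and hab.intensity_db == 108.0
        assert all(e.duration_s == 0.5 and e.frequency_hz == 300.0
                   for e in sched.events)

    def test_dropping_phase_one_is_additive(self):
        cfg = ScheduleConfig(
            phases=(
                PhaseSpec("subthreshold", 0, 60.0, 20.0),
                PhaseSpec("prehabituation", 10, 60.0, 108.0),
                PhaseSpec("habituation", 30, 1.0, 108.0),
            )
        )
        assert len(build_schedule(cfg)) == 40

    def test_deterministic(self):
        assert build_schedule().to_frame().equals(build_schedule().to_frame())

    def test_two_break_windows_of_300s(self):
        sched = build_schedule()
        assert len(sched.break_windows) == 2
        assert all(b1 - b0 == 300.0 for b0, b1 in sched.break_windows)

    def test_invalid_phase_refused(self):
        with pytest.raises(ValueError):
            PhaseSpec("habituation", 30, -1.0, 108.0)


def _record(large=0.0, mid=0.0, n_bins=3, start=0.0):
    return TrackingRecord(
        larva_id="l1",
        bins=pd.DataFrame(
            {
                "bin_start_s": start + np.arange(n_bins, dtype=float),
                "dist_small_mm": np.zeros(n_bins),
                "dist_mid_mm": np.full(n_bins, mid),
                "dist_large_mm": np.full(n_bins, large),
            }
        ),
    )


_EVENT = StimulusEvent("habituation", 1, 1.0, 0.5, 300.0, 108.0)


class TestEscapeCriterion:
    def test_fast_movement_during_stimulus_is_escape(self):
        responded, dist = classify_escape(_record(large=12.0), _EVENT)
        assert responded is True and dist == 12.0

    def test_slow_movement_is_not_escape(self):
        responded, dist = classify_escape(_record(mid=8.0), _EVENT)
        assert responded is False and dist == 0.0

    def test_missing_bin_is_missing_not_zero(self):
        ev = StimulusEvent("habituation", 1, 99.0, 0.5, 300.0, 108.0)
        responded, dist = classify_escape(_record(large=5.0), ev)
        assert responded is None and np.isnan(dist)


class TestAUC:
    def test_constant_five(self):
        assert auc_responsiveness(np.full(10, 5.0)) == pytest.approx(45.0)

    def test_zeros(self):
        assert auc_responsiveness(np.zeros(10)) == 0.0

    def test_single_spike_triangle(self):
        assert auc_responsiveness([10, 0, 0, 0, 0, 0, 0, 0, 0, 0]) == pytest.approx(5.0)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="10 stimuli"):
            auc_responsiveness(np.ones(9))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        y1=st.lists(st.floats(0, 50), min_size=10, max_size=10),
        y2=st.lists(st.floats(0, 50), min_size=10, max_size=10),
        lam=st.floats(0, 10),
    )
    def test_linearity(self, y1, y2, lam):
        y1, y2 = np.array(y1), np.array(y2)
        assert auc_responsiveness(lam * y1) == pytest.approx(
            lam * auc_responsiveness(y1), rel=1e-9, abs=1e-9
        )
        assert auc_responsiveness(y1 + y2) == pytest.approx(
            auc_responsiveness(y1) + auc_responsiveness(y2), rel=1e-9, abs=1e-9
        )


def _prehab_table(hits_by_larva):
    rows = []
    for lid, n_hits in hits_by_larva.items():
        for i in range(10):
            rows.append(
                {"larva_id": lid, "phase": "prehabituation",
                 "stimulus_index": i + 1, "responded": i < n_hits}
            )
    return pd.DataFrame(rows)


class TestNonResponderFilter:
    def test_three_of_ten_excluded_four_retained(self):
        table = _prehab_table({"a": 3, "b": 4, "c": 10})
        retained, log = non_responder_filter(table)
        assert set(retained["larva_id"]) == {"b", "c"}
        assert list(log["larva_id"]) == ["a"]
        assert log["prehab_response_rate"].iloc[0] == pytest.approx(0.3)

    def test_empty_cohort(self):
        retained, log = non_responder_filter(pd.DataFrame())
        assert retained.empty and log.empty

    def test_adding_a_response_never_excludes(self):
        for base in range(10):
            t1 = _prehab_table({"a": base})
            t2 = _prehab_table({"a": min(base + 1, 10)})
            kept1 = not non_responder_filter(t1)[0].empty
            kept2 = not non_responder_filter(t2)[0].empty
            assert kept2 >= kept1


class TestSpontaneousActivity:
    BREAKS = [(0.0, 300.0), (400.0, 700.0)]

    def _record_covering(self, per_bin):
        n = 700
        small, mid, large = per_bin
        return TrackingRecord(
            larva_id="l1",
            bins=pd.DataFrame(
                {
                    "bin_start_s": np.arange(n, dtype=float),
                    "dist_small_mm": np.full(n, small),
                    "dist_mid_mm": np.full(n, mid),
                    "dist_large_mm": np.full(n, large),
                }
            ),
        )

    def test_zero_movement(self):
        assert spontaneous_activity(self._record_covering((0, 0, 0)),
                                    self.BREAKS) == 0.0

    def test_single_category(self):
        rec = self._record_covering((0, 1.0, 0))
        assert spontaneous_activity(rec, self.BREAKS) == pytest.approx(600.0)

    def test_mixed_categories(self):
        rec = self._record_covering((0.2, 0.5, 0.1))
        assert spontaneous_activity(rec, self.BREAKS) == pytest.approx(480.0)

    def test_partial_coverage_is_missing(self):
        rec = _record(n_bins=10)
        with pytest.warns(UserWarning, match="missing"):
            out = spontaneous_activity(rec, self.BREAKS)
        assert np.isnan(out)


class TestTrackingRecord:
    def test_non_contiguous_bins_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            TrackingRecord(
                larva_id="l1",
                bins=pd.DataFrame(
                    {
                        "bin_start_s": [0.0, 2.0, 3.0],
                        "dist_small_mm": [0, 0, 0],
                        "dist_mid_mm": [0, 0, 0],
                        "dist_large_mm": [0, 0, 0],
                    }
                ),
            )

    def test_negative_distances_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            _record(large=-1.0)
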