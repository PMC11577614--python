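"""Synthetic cohort generation, round-tripping and structural invariants."""

import numpy as np
import pandas as pd
import pytest

from zebrahab.assay import build_schedule, read_tracking_csv, responses_from_tracking
from zebrahab.cohort import (
    GroupEffectProfile,
    TIMEPOINTS,
    default_profiles,
    emit_tracking_files,
    generate_cohort,
    load_profiles,
    save_profiles,
)
from zebrahab.decay import fit_single_exponential
from zebrahab.model import ModelGains


def _single_group(n=1, sigma=0.0, cv=0.0, **overrides):
    base = GroupEffectProfile(
        name="control",
        n_baseline=n,
        gains_by_timepoint={tp: ModelGains.normal_habituation()
                            for tp in TIMEPOINTS},
        attrition={tp: 0.0 for tp in TIMEPOINTS},
        sigma_mm=sigma,
        gain_cv=cv,
        non_responder_fraction=0.0,
        **overrides,
    )
    return [base]


def test_same_seed_identical_datasets():
    a = generate_cohort(seed=9, n_per_group={"control": 3, "low_impact": 2,
                                             "high_impact": 2})
    b = generate_cohort(seed=9, n_per_group={"control": 3, "low_impact": 2,
                                             "high_impact": 2})
    pd.testing.assert_frame_equal(a.observations, b.observations)
    pd.testing.assert_frame_equal(a.truth, b.truth)


def test_noiseless_larva_recovers_true_decay_constant():
    ds = generate_cohort(_single_group(n=1), seed=1)
    y = ds.observations.query(
        "timepoint == 'pre' and phase == 'habituation'"
    ).sort_values("stimulus_index")["distance_mm"].to_numpy()
    res = fit_single_exponential(y)
    assert res.decay_constant == pytest.approx(1.3, abs=1e-3)


def test_control_subthreshold_response_rate_about_twenty_percent():
    profiles = [p for p in default_profiles() if p.name == "control"]
    ds = generate_cohort(profiles, seed=21)
    sub = ds.observations.query("timepoint == 'pre' and phase == 'subthreshold'")
    assert 0.1 <= sub["responded"].mean() <= 0.3


def test_prehab_response_rate_supra_threshold():
    profiles = [p for p in default_profiles() if p.name == "control"]
    ds = generate_cohort(profiles, seed=22,
                         n_per_group={"control": 60})
    pre = ds.observations.query("timepoint == 'pre' and phase == 'prehabituation'")
    # responders dominate; rate sits near the 85% supra-threshold probability
    assert pre["responded"].mean() > 0.7


def test_attrition_non_increasing_survival(small_cohort):
    surv = small_cohort.survival
    for (_, lid), sub in surv.groupby(["group", "larva_id"]):
        ordered = sub.set_index("timepoint").loc[list(TIMEPOINTS), "alive"]
        alive = ordered.to_numpy().astype(int)
        assert np.all(np.diff(alive) <= 0)


def test_truth_separate_from_observables(small_cohort):
    assert "h2" in small_cohort.truth.columns
    assert "h2" not in small_cohort.observations.columns


class TestTrackingRoundTrip:
    def test_emit_read_classify_reproduces_responses(self, tmp_path):
        ds = generate_cohort(_single_group(n=2, sigma=2.0, cv=0.05), seed=5)
        manifest = emit_tracking_files(ds, tmp_path)
        schedule = build_schedule()
        records = read_tracking_csv(manifest["files"]["pre"])
        rebuilt = responses_from_tracking(records, schedule)
        orig = ds.observations.query("timepoint == 'pre'")
        merged = orig.merge(
            rebuilt, on=["larva_id", "phase", "stimulus_index"],
            suffixes=("_gen", "_read"),
        )
        assert len(merged) == len(orig)
        assert (merged["responded_gen"] == merged["responded_read"]).all()
        assert np.allclose(merged["distance_mm_gen"],
                           merged["distance_mm_read"])

    def test_one_larva_yields_thirty_habituation_rows(self, tmp_path):
        ds = generate_cohort(_single_group(n=1), seed=2)
        manifest = emit_tracking_files(ds, tmp_path)
        records = read_tracking_csv(manifest["files"]["pre"])
        rebuilt = responses_from_tracking(records, build_schedule())
        assert (rebuilt["phase"] == "habituation").sum() == 30

    def test_empty_cohort_header_only_files(self, tmp_path):
        ds = generate_cohort(seed=1, n_per_group={"control": 0,
                                                  "low_impact": 0,
                                                  "high_impact": 0})
        manifest = emit_tracking_files(ds, tmp_path)
        df = pd.read_csv(manifest["files"]["pre"])
        assert df.empty and "dist_large_mm" in df.columns

    def test_spontaneous_total_round_trips(self, tmp_path):
        from zebrahab.assay import spontaneous_activity

        ds = generate_cohort(_single_group(n=1), seed=8)
        manifest = emit_tracking_files(ds, tmp_path)
        schedule = build_schedule()
        rec = list(read_tracking_csv(manifest["files"]["pre"]).values())[0]
        total = spontaneous_activity(rec, schedule.break_windows)
        truth = ds.spontaneous.query("timepoint == 'pre'")["spontaneous_mm"]
        assert total == pytest.approx(float(truth.iloc[0]), rel=1e-9)


class TestProfiles:
    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "profiles.yaml"
        save_profiles(default_profiles(), path)
        loaded = load_profiles(path)
        assert [p.name for p in loaded] == ["control", "low_impact",
                                            "high_impact"]
        assert loaded[0].gains_by_timepoint["pre"] == \
            ModelGains.normal_habituation()

    def test_bundled_profiles_match_defaults(self):
        from importlib.resources import files

        bundled = files("zebrahab").joinpath("data/default_profiles.yaml")
        loaded = load_profiles(str(bundled))
        for got, want in zip(loaded, default_profiles()):
            assert got.to_dict() == want.to_dict()

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError, match="probability"):
            GroupEffectProfile(
                name="x", n_baseline=1,
                gains_by_timepoint={tp: ModelGains() for tp in TIMEPOINTS},
                attrition={tp: 0.0 for tp in TIMEPOINTS},
                p_sub=1.5,
            )
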