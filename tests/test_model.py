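"""Closed-form habituation/fatigue stages and their iterative realisation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from zebrahab.model import (
    GainValidationError,
    ModelGains,
    StimulusTrain,
    combined_response,
    fatigue_magnitude,
    fatigue_transmission,
    habituation_response,
    simulate_block_diagram,
)
from zebrahab.decay import HabituationDecay


class TestHabituationStage:
    @pytest.mark.parametrize(
        "n, gains, expected, tol",
        [
            (1, dict(h1=1, h2=1 / 1.3, h3=0.2), 1.0, 1e-12),
            (30, dict(h1=1, h2=1 / 1.3, h3=0.2), 0.2, 1e-9),
            (2, dict(h1=1, h2=np.log(2), h3=0.0), 0.5, 1e-12),
        ],
    )
    def test_closed_form_values(self, n, gains, expected, tol):
        assert habituation_response(n, ModelGains(**gains)) == pytest.approx(
            expected, abs=tol
        )

    def test_first_response_is_input_gain(self):
        g = ModelGains(h1=0.7, h2=0.5, h3=0.1)
        assert habituation_response(1, g) == pytest.approx(0.7)

    def test_invalid_gain_names_bound(self):
        with pytest.raises(GainValidationError, match="h3"):
            ModelGains(h1=1.0, h3=1.5)
        with pytest.raises(GainValidationError, match="h1"):
            ModelGains(h1=0.0)
        with pytest.raises(GainValidationError, match="f3"):
            ModelGains(f3=0.0)


class TestFatigueStage:
    def test_absent_fatigue_is_zero_everywhere(self):
        g = ModelGains(f1=0, f2=0, f3=1)
        n = np.arange(1, 31)
        assert np.all(fatigue_magnitude(n, g) == 0.0)
        assert np.all(fatigue_transmission(n, g) == 1.0)

    def test_asymptote_is_one_minus_f3(self):
        g = ModelGains(f1=0.5, f2=0.8, f3=0.4)
        assert fatigue_magnitude(50, g) == pytest.approx(0.6, abs=1e-9)
        assert fatigue_transmission(50, g) == pytest.approx(0.4, abs=1e-9)

    def test_initial_fatigue_and_transmission(self):
        g = ModelGains(f1=0.5, f2=0.8, f3=0.4)
        assert fatigue_magnitude(1, g) == pytest.approx(0.1)
        assert fatigue_transmission(1, g) == pytest.approx(0.9)

    def test_fatigue_clipped_at_zero_when_f1_exceeds_offset(self):
        g = ModelGains(f1=0.9, f2=0.5, f3=0.8)  # (1-f3)=0.2 < f1
        assert fatigue_magnitude(1, g) == 0.0
        assert fatigue_magnitude(50, g) == pytest.approx(0.2, abs=1e-9)


class TestCombinedOutput:
    def test_identity_without_fatigue_bit_for_bit(self):
        g = ModelGains.normal_habituation()
        n = np.arange(1, 31)
        assert np.array_equal(combined_response(n, g), habituation_response(n, g))

    def test_first_stimulus_value(self):
        g = ModelGains(h1=1, h2=0.25, h3=0.2, f1=0.5, f2=0.8, f3=0.4)
        assert combined_response(1, g) == pytest.approx(0.9)

    def test_limit_and_rectification(self):
        g = ModelGains.impaired_with_fatigue()
        assert combined_response(500, g) == pytest.approx(-0.4, abs=1e-9)
        assert combined_response(500, g, rectify=True) == 0.0

    def test_monotone_non_increasing_when_unclipped(self):
        g = ModelGains(h1=1, h2=0.3, h3=0.1, f1=0.4, f2=0.6, f3=0.5)
        s = combined_response(np.arange(1, 31), g)
        assert np.all(np.diff(s) <= 1e-12)


class TestIterativeSimulator:
    def test_defaults_reproduce_normal_habituation(self):
        tr = simulate_block_diagram(
            StimulusTrain(30, 1.0, 0.5), ModelGains.normal_habituation()
        )
        assert tr.habituation_output[0] == pytest.approx(1.0)
        assert tr.habituation_output[-1] == pytest.approx(0.2, abs=1e-6)
        assert np.array_equal(tr.combined_output, tr.habituation_output)

    def test_no_habituation_gives_constant_trace(self):
        g = ModelGains(h1=1.0, h2=0.0, h3=0.2)
        tr = simulate_block_diagram(StimulusTrain(10, 1.0, 0.5), g)
        assert np.allclose(tr.combined_output, 1.0)

    def test_coarse_step_refused_with_bound(self):
        with pytest.raises(ValueError, match="isi/100"):
            simulate_block_diagram(
                StimulusTrain(10, 1.0, 0.5), ModelGains(), dt=0.5
            )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        h1=st.floats(0.2, 2.0),
        h2=st.floats(0.0, 2.0),
        h3_frac=st.floats(0.0, 1.0),
        f1=st.floats(0.0, 1.0),
        f2=st.floats(0.0, 2.0),
        f3=st.floats(0.05, 1.0),
    )
    def test_matches_closed_form(self, h1, h2, h3_frac, f1, f2, f3):
        g = ModelGains(h1=h1, h2=h2, h3=h3_frac * h1, f1=f1, f2=f2, f3=f3)
        tr = simulate_block_diagram(StimulusTrain(30, 1.0, 0.5), g, dt=1e-2)
        n = np.arange(1, 31)
        assert np.abs(
            tr.combined_output - combined_response(n, g)
        ).max() < 1e-6


class TestTwoRateStructure:
    def test_double_exponential_fit_recovers_both_rates(self):
        g = ModelGains.impaired_with_fatigue()  # h2=0.25, f2=0.8
        y = combined_response(np.arange(1, 31), g)
        res = HabituationDecay(y, allow_negative_offset=True).fit_double()
        p = res["params"]
        assert p["b1"] == pytest.approx(0.25, abs=1e-3)
        assert p["b2"] == pytest.approx(0.8, abs=1e-3)

    def test_fatigue_shortens_fitted_decay_and_lowers_amplitude_offset(self):
        n = np.arange(1, 31)
        fit_imp = HabituationDecay(
            combined_response(n, ModelGains.impaired_habituation()),
            allow_negative_offset=True,
        ).fit()
        fit_fat = HabituationDecay(
            combined_response(n, ModelGains.impaired_with_fatigue()),
            allow_negative_offset=True,
        ).fit()
        assert fit_fat.decay_constant < fit_imp.decay_constant
        assert fit_fat.amplitude < fit_imp.amplitude
        assert fit_fat.offset < fit_imp.offset


class TestTraceExport:
    def test_csv_round_trip(self, tmp_path):
        import pandas as pd

        tr = simulate_block_diagram(StimulusTrain(10, 1.0, 0.5), ModelGains())
        path = tmp_path / "trace.csv"
        tr.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == [
            "stimulus_index", "habituation_output",
            "fatigue_magnitude", "combined_output",
        ]
        assert np.allclose(df["combined_output"], tr.combined_output)

    def test_gains_json_round_trip(self, tmp_path):
        g = ModelGains.impaired_with_fatigue()
        path = tmp_path / "gains.json"
        g.to_json(path)
        assert ModelGains.from_json(path) == g
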