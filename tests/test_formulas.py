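"""Unit and property tests for the five QTc corrections and ECG-paper conversions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qtckit import (
    DomainError,
    IntervalRecord,
    ValidationError,
    classify_prolonged,
    correct_all,
    hr_from_rr_squares,
    qt_ms_from_squares,
    qtc_bazett,
    qtc_framingham,
    qtc_fridericia,
    qtc_hodges,
    qtc_simple,
    simple_hodges_difference,
)

qt_strategy = st.floats(min_value=200.0, max_value=600.0)
hr_strategy = st.floats(min_value=40.0, max_value=150.0)


class TestPaperConversions:
    @pytest.mark.parametrize(
        "squares, hr",
        [(25, 60.0), (15, 100.0), (9.5, 1500 / 9.5), (10, 150.0)],
    )
    def test_hr_from_rr_squares(self, squares, hr):
        assert hr_from_rr_squares(squares) == pytest.approx(hr)

    @pytest.mark.parametrize("squares, ms", [(10, 400.0), (9.5, 380.0), (11.25, 450.0)])
    def test_qt_from_squares(self, squares, ms):
        assert qt_ms_from_squares(squares) == ms

    @pytest.mark.parametrize("fn", [hr_from_rr_squares, qt_ms_from_squares])
    @pytest.mark.parametrize("bad", [0, -1, float("nan")])
    def test_nonpositive_rejected(self, fn, bad):
        with pytest.raises(DomainError):
            fn(bad)


class TestFormulaValues:
    """Worked examples, including the published bedside-rule illustrations."""

    @pytest.mark.parametrize(
        "qt, hr, expected",
        [
            (400, 60, 400.0),
            (402, 56, 394.0),  # bradycardia example: correction is negative
            (382, 96, 444.0),  # tachycardia example: HR > 90 branch
            (400, 90, 460.0),  # boundary belongs to the no-subtraction branch
            (400, 90.1, 450.2),  # the 10 ms step just past 90 bpm
        ],
    )
    def test_simple_rule(self, qt, hr, expected):
        assert qtc_simple(qt, hr) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "qt, hr, expected", [(400, 60, 400.0), (402, 56, 395.0), (382, 96, 445.0)]
    )
    def test_hodges(self, qt, hr, expected):
        assert qtc_hodges(qt, hr) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "fn, qt, rr, expected",
        [
            (qtc_bazett, 400, 1.0, 400.0),
            (qtc_bazett, 400, 0.25, 800.0),
            (qtc_bazett, 350, 0.64, 437.5),
            (qtc_fridericia, 400, 1.0, 400.0),
            (qtc_fridericia, 400, 0.512, 500.0),
            (qtc_fridericia, 432, 1.728, 360.0),
            (qtc_framingham, 400, 1.0, 400.0),
            (qtc_framingham, 400, 0.5, 477.0),
            (qtc_framingham, 400, 1.5, 323.0),
        ],
    )
    def test_rr_based_formulas(self, fn, qt, rr, expected):
        assert fn(qt, rr) == pytest.approx(expected)

    def test_bazett_fridericia_brute_force_cross_check(self):
        """Power-law formulas agree with direct QT * RR**(-p) on random pairs."""
        rng = np.random.default_rng(5)
        qt = rng.uniform(250, 550, 1000)
        rr = rng.uniform(0.4, 1.5, 1000)
        assert np.allclose(qtc_bazett(qt, rr), qt * rr ** (-0.5))
        assert np.allclose(qtc_fridericia(qt, rr), qt * rr ** (-1.0 / 3.0))


class TestFormulaProperties:
    @given(qt=qt_strategy)
    def test_normal_rate_fixed_point(self, qt):
        """At 60 bpm (RR = 1 s) every correction leaves QT unchanged."""
        for value in (
            qtc_bazett(qt, 1.0),
            qtc_fridericia(qt, 1.0),
            qtc_framingham(qt, 1.0),
            qtc_hodges(qt, 60.0),
            qtc_simple(qt, 60.0),
        ):
            assert value == pytest.approx(qt, abs=1e-9)

    @given(qt=qt_strategy, delta=st.floats(min_value=1.0, max_value=50.0), hr=hr_strategy)
    def test_strictly_increasing_in_qt(self, qt, delta, hr):
        rr = 60.0 / hr
        for fn, rate in [
            (qtc_bazett, rr),
            (qtc_fridericia, rr),
            (qtc_framingham, rr),
            (qtc_hodges, hr),
            (qtc_simple, hr),
        ]:
            assert fn(qt + delta, rate) > fn(qt, rate)

    @given(
        qt_squares=st.floats(min_value=5.0, max_value=13.0),
        rr_squares=st.floats(min_value=11.0, max_value=35.0),
    )
    @settings(max_examples=50)
    def test_unit_coherence(self, qt_squares, rr_squares):
        """Entering paper squares or ms/seconds directly gives the same QTc."""
        qt_ms = qt_ms_from_squares(qt_squares)
        hr = hr_from_rr_squares(rr_squares)
        if qt_ms >= (60.0 / hr) * 1000.0:
            return  # unphysiological combination, rejected by validation anyway
        via_squares = correct_all(
            IntervalRecord("p", 1, "male", qt_ms=qt_ms, hr_bpm=hr)
        )
        via_si = correct_all(
            IntervalRecord("p", 1, "male", qt_ms=qt_ms, rr_s=60.0 / hr)
        )
        for method in ("bazett", "fridericia", "framingham", "hodges", "simple"):
            assert via_squares.qtc(method) == pytest.approx(via_si.qtc(method), rel=1e-9)


class TestSimpleHodgesDifference:
    @pytest.mark.parametrize("hr, expected", [(60, 0.0), (140, 10.0), (1500 / 9.5, 14.47)])
    def test_closed_form(self, hr, expected):
        assert simple_hodges_difference(hr) == pytest.approx(expected, abs=0.005)

    def test_difference_is_qt_independent(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            qt = rng.uniform(250, 550)
            hr = rng.uniform(40, 160)
            assert qtc_simple(qt, hr) - qtc_hodges(qt, hr) == pytest.approx(
                simple_hodges_difference(hr), abs=1e-9
            )

    def test_error_envelope(self):
        """|simple - Hodges| stays within 7.5 ms over 40-130 bpm, 10 ms to 140."""
        grid = np.linspace(40.0, 130.0, 9001)
        assert np.max(np.abs(simple_hodges_difference(grid))) <= 7.5 + 1e-9
        wide = np.linspace(40.0, 140.0, 10001)
        assert np.max(np.abs(simple_hodges_difference(wide))) <= 10.0 + 1e-9


class TestClassifyProlonged:
    @pytest.mark.parametrize(
        "qtc, sex, expected",
        [
            (451, "male", True),
            (450, "male", False),  # "up to 450" is still normal
            (455, "female", False),
            (461, "female", True),
        ],
    )
    def test_thresholds(self, qtc, sex, expected):
        assert classify_prolonged(qtc, sex) is expected

    def test_unknown_sex(self):
        with pytest.raises(ValidationError):
            classify_prolonged(450, "unknown")


class TestIntervalRecordValidation:
    def test_correct_all_populates_all_methods(self):
        rec = IntervalRecord("p1", 1, "female", qt_ms=400.0, rr_s=1.0)
        corr = correct_all(rec)
        for method in ("bazett", "fridericia", "framingham", "hodges", "simple"):
            assert corr.qtc(method) == pytest.approx(400.0)

    def test_paper_examples_via_record(self):
        corr = correct_all(IntervalRecord("p2", 1, "male", qt_ms=382.0, hr_bpm=96.0))
        assert corr.qtc_simple == pytest.approx(444.0)
        assert corr.qtc_hodges == pytest.approx(445.0)
        corr = correct_all(IntervalRecord("p3", 1, "male", qt_ms=402.0, hr_bpm=56.0))
        assert corr.qtc_simple == pytest.approx(394.0)
        assert corr.qtc_hodges == pytest.approx(395.0)

    def test_rr_wins_over_hr(self):
        """When both are given and consistent, HR is recomputed from RR."""
        rec = IntervalRecord("p", 1, "male", qt_ms=400.0, rr_s=0.75, hr_bpm=80.4)
        assert rec.resolved_hr_bpm == pytest.approx(80.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(qt_ms=400.0),  # no rate at all
            dict(qt_ms=400.0, rr_s=1.0, hr_bpm=75.0),  # RR/HR mismatch > 1 bpm
            dict(qt_ms=1100.0, rr_s=1.0),  # QT not shorter than the cycle
            dict(qt_ms=-5.0, rr_s=1.0),
            dict(qt_ms=300.0, hr_bpm=400.0),  # implausible rate
            dict(qt_ms=100.0, rr_s=4.0),  # 15 bpm, outside plausible window
        ],
    )
    def test_invalid_records_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            IntervalRecord("p", 1, "male", **kwargs)
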