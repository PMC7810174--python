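"""Heart-rate correction of the QT interval.

Five corrections are implemented, all returning QTc in milliseconds:

======================  ===========================================
Bazett                  QTc = QT / sqrt(RR)          (RR in seconds)
Fridericia              QTc = QT / RR^(1/3)
Framingham              QTc = QT + 154 (1 - RR)
Hodges                  QTc = QT + 1.75 (HR - 60)    (HR in bpm)
simple (bedside rule)   QTc = QT + 2 (HR - 60),  minus 10 if HR > 90
======================  ===========================================

The simple rule is a piecewise mental-arithmetic approximation to Hodges:
double the HR excess over 60 instead of multiplying by 1.75, and knock off
10 ms above 90 bpm to compensate. Its error relative to Hodges is
0.25 (HR - 60) - 10 [HR > 90], independent of QT, and stays within
+/- 7.5 ms for heart rates between 40 and 130 bpm.

Canonical internal units are QT in ms, RR in seconds, HR in bpm.
Conversions from standard 25 mm/s ECG paper (1 small square = 1 mm =
40 ms; HR = 1500 / RR-in-squares) are explicit functions, never implicit.

All formula functions accept scalars or numpy arrays and never round;
rounding is a reporting concern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import DomainError, ValidationError

__all__ = [
    "METHODS",
    "IntervalRecord",
    "CorrectedRecord",
    "hr_from_rr_squares",
    "qt_ms_from_squares",
    "qtc_bazett",
    "qtc_fridericia",
    "qtc_framingham",
    "qtc_hodges",
    "qtc_simple",
    "correct_all",
    "classify_prolonged",
    "simple_hodges_difference",
]

#: Canonical method names, in the order reports use.
METHODS = ("bazett", "fridericia", "framingham", "hodges", "simple")

#: Milliseconds per 1-mm small square at the standard 25 mm/s paper speed.
MS_PER_SQUARE = 40.0

#: Upper limit of normal QTc (ms) by sex; values above are "prolonged".
PROLONGED_THRESHOLD_MS = {"male": 450.0, "female": 460.0}

#: Physiological heart-rate window accepted by record validation (bpm).
HR_PLAUSIBLE = (20.0, 300.0)


def _require_positive(name: str, value) -> None:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise DomainError(f"{name} must be positive and finite, got {value!r}")


def hr_from_rr_squares(rr_squares):
    """Heart rate in bpm from an RR interval counted in small squares.

    At 25 mm/s one minute spans 1500 small squares, so HR = 1500 / RR.
    """
    _require_positive("rr_squares", rr_squares)
    return 1500.0 / np.asarray(rr_squares, dtype=float)[()]


def qt_ms_from_squares(qt_squares):
    """QT in ms from a QT interval counted in small squares (40 ms each)."""
    _require_positive("qt_squares", qt_squares)
    return MS_PER_SQUARE * np.asarray(qt_squares, dtype=float)[()]


def qtc_bazett(qt_ms, rr_s):
    """Bazett correction, QT / sqrt(RR)."""
    _require_positive("qt_ms", qt_ms)
    _require_positive("rr_s", rr_s)
    return (np.asarray(qt_ms, dtype=float) / np.sqrt(np.asarray(rr_s, dtype=float)))[()]


def qtc_fridericia(qt_ms, rr_s):
    """Fridericia correction, QT / RR^(1/3)."""
    _require_positive("qt_ms", qt_ms)
    _require_positive("rr_s", rr_s)
    return (np.asarray(qt_ms, dtype=float) / np.cbrt(np.asarray(rr_s, dtype=float)))[()]


def qtc_framingham(qt_ms, rr_s):
    """Framingham (linear) correction, QT + 154 (1 - RR)."""
    _require_positive("qt_ms", qt_ms)
    _require_positive("rr_s", rr_s)
    return (np.asarray(qt_ms, dtype=float) + 154.0 * (1.0 - np.asarray(rr_s, dtype=float)))[()]


def qtc_hodges(qt_ms, hr_bpm):
    """Hodges (linear) correction, QT + 1.75 (HR - 60)."""
    _require_positive("qt_ms", qt_ms)
    _require_positive("hr_bpm", hr_bpm)
    return (np.asarray(qt_ms, dtype=float) + 1.75 * (np.asarray(hr_bpm, dtype=float) - 60.0))[()]


def qtc_simple(qt_ms, hr_bpm):
    """Piecewise bedside rule: QT + 2 (HR - 60), minus a further 10 ms when HR > 90.

    The boundary HR = 90 bpm belongs to the no-subtraction branch.
    """
    _require_positive("qt_ms", qt_ms)
    _require_positive("hr_bpm", hr_bpm)
    qt = np.asarray(qt_ms, dtype=float)
    hr = np.asarray(hr_bpm, dtype=float)
    return (qt + 2.0 * (hr - 60.0) - np.where(hr > 90.0, 10.0, 0.0))[()]


def simple_hodges_difference(hr_bpm):
    """QTc(simple) - QTc(Hodges) at a given heart rate; the QT term cancels.

    Closed form: 0.25 (HR - 60) - 10 [HR > 90].  Peaks at 7.5 ms inside the
    40-130 bpm band and reaches 10 ms only at 140 bpm.
    """
    _require_positive("hr_bpm", hr_bpm)
    hr = np.asarray(hr_bpm, dtype=float)
    return (0.25 * (hr - 60.0) - np.where(hr > 90.0, 10.0, 0.0))[()]


Sex = Literal["male", "female"]


def classify_prolonged(qtc_ms, sex: Sex) -> bool:
    """True when QTc exceeds the sex-specific upper limit of normal.

    Normal ranges run *up to* 450 ms in men and 460 ms in women, boundary
    inclusive: QTc = 450 ms in a man is still normal.
    """
    _require_positive("qtc_ms", qtc_ms)
    try:
        threshold = PROLONGED_THRESHOLD_MS[sex]
    except (KeyError, TypeError):
        raise ValidationError(f"unknown sex {sex!r}; expected 'male' or 'female'") from None
    return bool(np.asarray(qtc_ms, dtype=float)[()] > threshold)


@dataclass(frozen=True)
class IntervalRecord:
    """One ECG's measured intervals plus subject metadata.

    At least one of ``rr_s`` / ``hr_bpm`` must be given.  When both are
    present they must agree to within 1 bpm; RR is treated as the measured
    quantity and HR is recomputed from it for all downstream arithmetic.
    """

    patient_id: str
    ecg_index: int
    sex: Sex
    qt_ms: float
    rr_s: float | None = None
    hr_bpm: float | None = None

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise ValidationError(
                f"record {self.patient_id!r}: unknown sex {self.sex!r}"
            )
        if self.ecg_index not in (1, 2):
            raise ValidationError(
                f"record {self.patient_id!r}: ecg_index must be 1 or 2, got {self.ecg_index!r}"
            )
        if not (self.qt_ms and self.qt_ms > 0):
            raise ValidationError(f"record {self.patient_id!r}: qt_ms must be > 0")
        if self.rr_s is None and self.hr_bpm is None:
            raise ValidationError(
                f"record {self.patient_id!r}: need at least one of rr_s / hr_bpm"
            )
        if self.rr_s is not None and self.rr_s <= 0:
            raise ValidationError(f"record {self.patient_id!r}: rr_s must be > 0")
        if self.hr_bpm is not None and self.hr_bpm <= 0:
            raise ValidationError(f"record {self.patient_id!r}: hr_bpm must be > 0")
        if self.rr_s is not None and self.hr_bpm is not None:
            if abs(self.hr_bpm - 60.0 / self.rr_s) > 1.0:
                raise ValidationError(
                    f"record {self.patient_id!r}: rr_s={self.rr_s} implies "
                    f"{60.0 / self.rr_s:.1f} bpm but hr_bpm={self.hr_bpm}"
                )
        hr = self.resolved_hr_bpm
        lo, hi = HR_PLAUSIBLE
        if not (lo <= hr <= hi):
            raise ValidationError(
                f"record {self.patient_id!r}: heart rate {hr:.1f} bpm outside "
                f"plausible range [{lo:.0f}, {hi:.0f}]"
            )
        if self.qt_ms >= self.resolved_rr_s * 1000.0:
            raise ValidationError(
                f"record {self.patient_id!r}: QT {self.qt_ms} ms is not shorter than "
                f"the cycle length {self.resolved_rr_s * 1000.0:.0f} ms"
            )

    @property
    def resolved_rr_s(self) -> float:
        """RR in seconds; derived from HR only when RR was not supplied."""
        return self.rr_s if self.rr_s is not None else 60.0 / self.hr_bpm

    @property
    def resolved_hr_bpm(self) -> float:
        """HR in bpm; recomputed from RR whenever RR is present (RR wins)."""
        return 60.0 / self.rr_s if self.rr_s is not None else self.hr_bpm


@dataclass(frozen=True)
class CorrectedRecord:
    """An interval record with the QTc under each of the five methods."""

    base: IntervalRecord
    qtc_bazett: float
    qtc_fridericia: float
    qtc_framingham: float
    qtc_hodges: float
    qtc_simple: float

    def qtc(self, method: str) -> float:
        if method not in METHODS:
            raise ValidationError(f"unknown method {method!r}; expected one of {METHODS}")
        return getattr(self, f"qtc_{method}")

    def prolonged(self, method: str) -> bool:
        return classify_prolonged(self.qtc(method), self.base.sex)


def correct_all(record: IntervalRecord) -> CorrectedRecord:
    """Apply all five corrections to one record.

    RR and HR are reconciled first (RR measured on paper wins; HR is
    recomputed from it), so the rate-based and cycle-length-based formulas
    see a single consistent rate.
    """
    rr = record.resolved_rr_s
    hr = record.resolved_hr_bpm
    qt = record.qt_ms
    return CorrectedRecord(
        base=record,
        qtc_bazett=qtc_bazett(qt, rr),
        qtc_fridericia=qtc_fridericia(qt, rr),
        qtc_framingham=qtc_framingham(qt, rr),
        qtc_hodges=qtc_hodges(qt, hr),
        qtc_simple=qtc_simple(qt, hr),
    )
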