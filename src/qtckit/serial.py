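"""Serial QTc change (delta-QTc) between a patient's first and second ECG.

Patients contribute at most two tracings, labelled by an explicit
``ecg_index`` column (1 = admission, 2 = next day); the change is always
QTc(ECG 2) - QTc(ECG 1).  For the two linear corrections (Hodges and the
simple rule) the QT terms cancel, so their delta difference depends only
on the pair of heart rates:

    d(simple) - d(Hodges) = 0.25 (HR2 - HR1) - 10 ([HR2 > 90] - [HR1 > 90])
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .agreement import BlandAltmanResult, bland_altman
from .errors import ValidationError
from .formulas import METHODS

__all__ = ["DeltaRecord", "pair_ecgs", "delta_qtc", "delta_agreement"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DeltaRecord:
    """Change in QTc (ms) between ECG 2 and ECG 1 for one patient and method."""

    patient_id: str
    method: str
    delta_qtc: float


def pair_ecgs(corrected: pd.DataFrame) -> pd.DataFrame:
    """Match each patient's ECG 1 with their ECG 2.

    Returns a wide table indexed by patient with ``<col>_1`` / ``<col>_2``
    columns for every QTc column plus HR, keeping only patients who have
    both tracings.  Patients with a single ECG are dropped (and logged);
    a duplicated (patient, ecg_index) is an error.
    """
    required = {"patient_id", "ecg_index"}
    if not required.issubset(corrected.columns):
        raise ValidationError(f"table must have columns {sorted(required)}")
    bad_index = ~corrected["ecg_index"].isin([1, 2])
    if bad_index.any():
        raise ValidationError(
            f"ecg_index must be 1 or 2; offending rows: {corrected.index[bad_index].tolist()}"
        )
    dup = corrected.duplicated(subset=["patient_id", "ecg_index"], keep=False)
    if dup.any():
        dupes = corrected.loc[dup, ["patient_id", "ecg_index"]].drop_duplicates()
        raise ValidationError(
            "duplicate (patient, ecg_index) rows: "
            + ", ".join(f"{p}/{i}" for p, i in dupes.itertuples(index=False))
        )

    value_cols = [c for c in corrected.columns if c.startswith("qtc_") or c == "hr_bpm"]
    wide = corrected.pivot(index="patient_id", columns="ecg_index", values=value_cols)
    # force both ECG slots to exist even when nobody has a second tracing
    wide = wide.reindex(columns=pd.MultiIndex.from_product([value_cols, [1, 2]]))
    wide.columns = [f"{col}_{idx}" for col, idx in wide.columns]
    has_both = wide.notna().all(axis=1)
    unpaired = wide.index[~has_both].tolist()
    if unpaired:
        log.info("%d patients lack a second ECG and are excluded from serial analysis: %s",
                 len(unpaired), unpaired)
    paired = wide.loc[has_both]
    log.info("paired %d patients with both ECG 1 and ECG 2", len(paired))
    return paired


def delta_qtc(pairs: pd.DataFrame, method: str) -> pd.Series:
    """Per-patient QTc change under one method, QTc(ECG 2) - QTc(ECG 1)."""
    if method not in METHODS:
        raise ValidationError(f"unknown method {method!r}; expected one of {METHODS}")
    if len(pairs) == 0:
        raise ValidationError("no paired patients")
    col = f"qtc_{method}"
    delta = pairs[f"{col}_2"] - pairs[f"{col}_1"]
    delta.name = f"delta_{col}"
    return delta


def delta_agreement(deltas_a: pd.Series, deltas_b: pd.Series,
                    method_a: str = "a", method_b: str = "b") -> BlandAltmanResult:
    """Bland-Altman agreement between two methods' per-patient QTc changes."""
    if not deltas_a.index.equals(deltas_b.index):
        raise ValidationError("delta series cover different patients")
    return bland_altman(deltas_a.to_numpy(), deltas_b.to_numpy(),
                        method_a=method_a, method_b=method_b)
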