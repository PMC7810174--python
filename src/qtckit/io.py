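"""CSV readers and writers for the interval / correction pipeline.

CSV is the single interchange format.  Units are declared by column name
— ``qt_ms`` or ``qt_squares``, ``rr_s`` or ``rr_squares`` — never guessed
from the values.  Human-readable agreement reports round to 2 decimals
and format limits of agreement as "lower to upper"; a machine-readable
companion file keeps full precision and round-trips exactly.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .agreement import BlandAltmanResult
from .errors import SchemaError, ValidationError
from .formulas import (
    METHODS,
    IntervalRecord,
    correct_all,
    hr_from_rr_squares,
    qt_ms_from_squares,
)

__all__ = [
    "read_intervals",
    "records_from_table",
    "correct_table",
    "write_corrected",
    "write_agreement_report",
    "read_agreement_report",
]

CANONICAL_COLUMNS = ["patient_id", "ecg_index", "sex", "qt_ms", "rr_s", "hr_bpm"]


def read_intervals(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-ECG interval CSV into canonical columns.

    Accepts QT as ``qt_ms`` or ``qt_squares`` and the rate as ``rr_s``,
    ``rr_squares`` and/or ``hr_bpm``; square counts are converted on read.
    Every row is validated (positivity, RR/HR consistency within 1 bpm,
    QT shorter than the cycle length, plausible rate); failures raise a
    ValidationError naming the offending rows.
    """
    path = Path(path)
    df = pd.read_csv(path)
    cols = set(df.columns)
    for required in ("patient_id", "ecg_index", "sex"):
        if required not in cols:
            raise SchemaError(f"{path}: missing required column {required!r}")
    if "qt_ms" not in cols and "qt_squares" not in cols:
        raise SchemaError(f"{path}: need a qt_ms or qt_squares column")
    if not cols & {"rr_s", "rr_squares", "hr_bpm"}:
        raise SchemaError(f"{path}: need at least one of rr_s, rr_squares, hr_bpm")

    out = pd.DataFrame()
    out["patient_id"] = df["patient_id"].astype(str)
    out["ecg_index"] = df["ecg_index"]
    out["sex"] = df["sex"].astype(str).str.strip().str.lower()
    out["qt_ms"] = (
        df["qt_ms"] if "qt_ms" in cols else df["qt_squares"].map(qt_ms_from_squares)
    )
    if "rr_s" in cols:
        out["rr_s"] = df["rr_s"]
    elif "rr_squares" in cols:
        out["rr_s"] = df["rr_squares"].map(lambda x: 60.0 / hr_from_rr_squares(x))
    else:
        out["rr_s"] = np.nan
    out["hr_bpm"] = df["hr_bpm"] if "hr_bpm" in cols else np.nan

    errors = []
    for i, row in out.iterrows():
        if pd.isna(row["qt_ms"]) and pd.isna(row["rr_s"]) and pd.isna(row["hr_bpm"]):
            continue  # flagged-only row (e.g. excluded patient): no intervals to check
        try:
            _record_from_row(row)
        except ValidationError as exc:
            errors.append(f"row {i + 2}: {exc}")  # +2: header line and 1-based count
    if errors:
        raise ValidationError(f"{path}: {len(errors)} invalid rows\n" + "\n".join(errors))
    return out


def _record_from_row(row: pd.Series) -> IntervalRecord:
    return IntervalRecord(
        patient_id=str(row["patient_id"]),
        ecg_index=int(row["ecg_index"]),
        sex=row["sex"],
        qt_ms=float(row["qt_ms"]),
        rr_s=None if pd.isna(row.get("rr_s")) else float(row["rr_s"]),
        hr_bpm=None if pd.isna(row.get("hr_bpm")) else float(row["hr_bpm"]),
    )


def records_from_table(table: pd.DataFrame) -> list[IntervalRecord]:
    """Materialise validated IntervalRecords from a canonical table."""
    return [_record_from_row(row) for _, row in table.iterrows()]


def correct_table(table: pd.DataFrame) -> pd.DataFrame:
    """Append the five QTc columns and prolonged flags to an interval table.

    Rows lacking usable intervals (e.g. excluded patients in a synthetic
    cohort) are dropped; RR/HR are reconciled per record (RR wins).
    """
    usable = table.dropna(subset=["qt_ms"]).copy() if "qt_ms" in table.columns else table
    if len(usable) == 0:
        raise ValidationError("no usable rows to correct")
    out_rows = []
    for _, row in usable.iterrows():
        rec = _record_from_row(row)
        corr = correct_all(rec)
        d = {
            "patient_id": rec.patient_id,
            "ecg_index": rec.ecg_index,
            "sex": rec.sex,
            "qt_ms": rec.qt_ms,
            "rr_s": rec.resolved_rr_s,
            "hr_bpm": rec.resolved_hr_bpm,
        }
        for m in METHODS:
            d[f"qtc_{m}"] = corr.qtc(m)
        for m in METHODS:
            d[f"prolonged_{m}"] = corr.prolonged(m)
        out_rows.append(d)
    return pd.DataFrame(out_rows)


def write_corrected(corrected: pd.DataFrame, path: str | Path) -> None:
    """Write a corrected table to CSV at full precision."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    corrected.to_csv(path, index=False)


def write_agreement_report(
    results: Sequence[BlandAltmanResult],
    path: str | Path,
    precision: int = 2,
) -> tuple[Path, Path]:
    """Write Bland-Altman results as a human table plus a machine CSV.

    ``<path>`` gets the rounded report (pair, bias, SD, "lower to upper"
    LOA string); ``<stem>.machine.csv`` beside it keeps full precision and
    is exactly recoverable with :func:`read_agreement_report`.  Computed
    values are written as computed — the writer never massages arithmetic
    to match an external table.
    """
    if len(results) == 0:
        raise ValidationError("no results to report")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    human = pd.DataFrame(
        {
            "comparison": [r.pair for r in results],
            "n": [r.n for r in results],
            "bias_ms": [round(r.bias, precision) for r in results],
            "sd_ms": [round(r.sd, precision) for r in results],
            "loa_95": [
                f"{r.loa_lower:.{precision}f} to {r.loa_upper:.{precision}f}"
                for r in results
            ],
        }
    )
    human.to_csv(path, index=False)
    machine_path = path.with_suffix(".machine.csv")
    machine = pd.DataFrame([dataclasses.asdict(r) for r in results])
    machine.to_csv(machine_path, index=False)  # default float repr round-trips exactly
    return path, machine_path


def read_agreement_report(machine_path: str | Path) -> list[BlandAltmanResult]:
    """Recover Bland-Altman results from the machine-readable CSV."""
    df = pd.read_csv(machine_path, float_precision="round_trip")
    return [
        BlandAltmanResult(
            method_a=row.method_a,
            method_b=row.method_b,
            n=int(row.n),
            bias=float(row.bias),
            sd=float(row.sd),
            loa_lower=float(row.loa_lower),
            loa_upper=float(row.loa_upper),
        )
        for row in df.itertuples()
    ]
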