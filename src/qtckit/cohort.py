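"""Synthetic emergency-unit cohort generator.

Emulates the bookkeeping and rate distribution of a single-centre acute
pulmonary oedema cohort: 150 admitted patients, 9 with tracings too poor
to measure, 37 excluded for wide QRS or irregular rhythm (26 left bundle
branch block — one of whom also had atrial fibrillation — 7 atrial
fibrillation/atrial tachycardia, 4 right bundle branch block), leaving
104 included patients of whom 86 contribute a second ECG at least 24 h
later: 190 usable tracings in all.  Heart rate is drawn from a normal
(92, 23) bpm truncated to the observed 44-150 bpm range.

The generative truth model is deliberately Hodges-consistent: each
patient gets a latent rate-free QTc0 ~ N(420, 30) ms, and the measured
QT is QTc0 - 1.75 (HR - 60) plus N(0, 8) ms measurement noise, quantised
to 20 ms (half a small square, caliper reading precision).  Correcting
this data with Hodges therefore recovers a rate-flat QTc by
construction, while Bazett re-introduces a rate trend — the qualitative
behaviour the comparison statistics are meant to detect.

Stream discipline: every patient has an independent child RNG spawned
from the single seed, so enlarging the cohort never perturbs earlier
patients' draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["CohortConfig", "CohortSummary", "generate_cohort", "summarize_cohort"]

#: Exclusion reasons; af_lbbb patients are counted inside the lbbb total.
EXCLUSION_REASONS = ("lbbb", "af_at", "rbbb", "af_lbbb")


@dataclass(frozen=True)
class CohortConfig:
    """All parameters of the synthetic cohort generator.

    Counts mirror the study flow; ``exclusions['af_lbbb']`` is the number
    of patients with *both* atrial fibrillation and left bundle branch
    block, already included in ``exclusions['lbbb']`` (so distinct
    excluded patients = lbbb + af_at + rbbb).  The truth-model parameters
    (``truth_qtc_*``, ``noise_sd``, ``quantum_ms``) are generator
    inventions, not measured study quantities.
    """

    n_admitted: int = 150
    n_inadequate: int = 9
    exclusions: Mapping[str, int] = field(
        default_factory=lambda: {"lbbb": 26, "af_at": 7, "rbbb": 4, "af_lbbb": 1}
    )
    n_second_ecg: int = 86
    hr_mean: float = 92.0
    hr_sd: float = 23.0
    hr_min: float = 44.0
    hr_max: float = 150.0
    hr_correlation: float = 0.0  # within-patient HR correlation across the two ECGs
    male_fraction: float = 0.36
    truth_qtc_mean: float = 420.0
    truth_qtc_sd: float = 30.0
    noise_sd: float = 8.0
    quantum_ms: float = 20.0
    seed: int = 0

    @property
    def n_excluded(self) -> int:
        """Distinct excluded patients (the af_lbbb overlap counted once)."""
        e = self.exclusions
        return e["lbbb"] + e["af_at"] + e["rbbb"]

    @property
    def n_included(self) -> int:
        return self.n_admitted - self.n_inadequate - self.n_excluded

    def validate(self) -> None:
        e = dict(self.exclusions)
        if set(e) != set(EXCLUSION_REASONS):
            raise ValidationError(f"exclusions must have keys {EXCLUSION_REASONS}, got {sorted(e)}")
        if any(v < 0 for v in e.values()):
            raise ValidationError("exclusion counts must be non-negative")
        if e["af_lbbb"] > e["lbbb"]:
            raise ValidationError("af_lbbb patients are a subset of lbbb; count cannot exceed it")
        if self.n_included <= 0:
            raise ValidationError(
                f"infeasible counts: {self.n_admitted} admitted - {self.n_inadequate} inadequate "
                f"- {self.n_excluded} excluded leaves {self.n_included} included"
            )
        if not (0 <= self.n_second_ecg <= self.n_included):
            raise ValidationError(
                f"n_second_ecg={self.n_second_ecg} exceeds included patients ({self.n_included})"
            )
        if not (self.hr_min < self.hr_mean < self.hr_max):
            raise ValidationError("require hr_min < hr_mean < hr_max")
        for name in ("hr_sd", "truth_qtc_sd", "noise_sd", "quantum_ms"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not (-1.0 < self.hr_correlation < 1.0):
            raise ValidationError("hr_correlation must lie in (-1, 1)")
        if not (0.0 <= self.male_fraction <= 1.0):
            raise ValidationError("male_fraction must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["exclusions"] = dict(self.exclusions)
        return d


@dataclass(frozen=True)
class CohortSummary:
    """Descriptive statistics of a generated cohort table."""

    n_patients: int
    n_usable_ecgs: int
    n_inadequate: int
    exclusion_counts: dict
    hr_mean: float
    hr_sd: float
    hr_min: float
    hr_max: float
    male_fraction: float


def _draw_hr_pair(rng: np.random.Generator, cfg: CohortConfig) -> tuple[float, float]:
    """Two heart rates for one patient, truncated to [hr_min, hr_max].

    Exact truncation by rejection; with a nonzero correlation the latent
    bivariate-normal pair is redrawn whole until both land in range.
    """
    rho = cfg.hr_correlation
    for _ in range(10_000):
        z1 = rng.standard_normal()
        z2 = rho * z1 + np.sqrt(1.0 - rho**2) * rng.standard_normal()
        hr1 = cfg.hr_mean + cfg.hr_sd * z1
        hr2 = cfg.hr_mean + cfg.hr_sd * z2
        if cfg.hr_min <= hr1 <= cfg.hr_max and cfg.hr_min <= hr2 <= cfg.hr_max:
            return hr1, hr2
    raise RuntimeError("truncated-normal rejection sampling failed to converge")


def _draw_qt(rng: np.random.Generator, cfg: CohortConfig, qtc0: float, hr: float) -> float:
    """Quantised QT (ms) consistent with the Hodges truth model at this HR.

    Redraws the noise (and, if a patient's latent QTc0 is hopeless at this
    rate, the latent value too) until 0 < QT < RR.
    """
    rr_ms = 60_000.0 / hr
    for attempt in range(10_000):
        qt = qtc0 - 1.75 * (hr - 60.0) + rng.normal(0.0, cfg.noise_sd)
        qt = np.round(qt / cfg.quantum_ms) * cfg.quantum_ms
        if 0.0 < qt < rr_ms:
            return float(qt)
        if attempt % 100 == 99:  # pathological latent value for this rate
            qtc0 = rng.normal(cfg.truth_qtc_mean, cfg.truth_qtc_sd)
    raise RuntimeError("QT sampling failed to converge")


def generate_cohort(config: CohortConfig | None = None) -> pd.DataFrame:
    """Generate the per-ECG interval table for one synthetic cohort.

    One row per ECG.  Inadequate and excluded patients appear with their
    status flag and no usable intervals; included patients carry QT/RR/HR
    measurements, and a random subset of ``n_second_ecg`` of them gets a
    second row with ``ecg_index`` 2.  Fully determined by ``config.seed``.
    """
    cfg = config if config is not None else CohortConfig()
    cfg.validate()

    root = np.random.SeedSequence(cfg.seed)
    # child 0 drives cohort-level choices; children 1..n are per-patient
    streams = root.spawn(cfg.n_admitted + 1)
    rng_cohort = np.random.default_rng(streams[0])

    # deterministic status layout: inadequate first, then exclusions by
    # reason (af_lbbb carved out of the lbbb block), then included
    statuses: list[tuple[str, str | None]] = []
    statuses += [("inadequate", None)] * cfg.n_inadequate
    e = cfg.exclusions
    statuses += [("excluded", "af_lbbb")] * e["af_lbbb"]
    statuses += [("excluded", "lbbb")] * (e["lbbb"] - e["af_lbbb"])
    statuses += [("excluded", "af_at")] * e["af_at"]
    statuses += [("excluded", "rbbb")] * e["rbbb"]
    statuses += [("included", None)] * cfg.n_included

    included_ids = [i for i, (s, _) in enumerate(statuses) if s == "included"]
    second_ecg_ids = set(
        rng_cohort.choice(included_ids, size=cfg.n_second_ecg, replace=False).tolist()
    )

    rows = []
    width = len(str(cfg.n_admitted))
    for i, (status, reason) in enumerate(statuses):
        rng = np.random.default_rng(streams[i + 1])
        pid = f"P{i + 1:0{width}d}"
        sex = "male" if rng.random() < cfg.male_fraction else "female"
        if status != "included":
            rows.append(dict(patient_id=pid, ecg_index=1, sex=sex,
                             qt_ms=np.nan, rr_s=np.nan, hr_bpm=np.nan,
                             status=status, exclusion_reason=reason))
            continue
        qtc0 = rng.normal(cfg.truth_qtc_mean, cfg.truth_qtc_sd)
        hr1, hr2 = _draw_hr_pair(rng, cfg)
        for ecg_index, hr in ((1, hr1), (2, hr2)):
            if ecg_index == 2 and i not in second_ecg_ids:
                continue
            qt = _draw_qt(rng, cfg, qtc0, hr)
            rows.append(dict(patient_id=pid, ecg_index=ecg_index, sex=sex,
                             qt_ms=qt, rr_s=60.0 / hr, hr_bpm=hr,
                             status="included", exclusion_reason=None))
    return pd.DataFrame(rows)


def summarize_cohort(table: pd.DataFrame) -> CohortSummary:
    """Descriptive statistics for validating generator output against its config."""
    if len(table) == 0:
        raise ValidationError("empty cohort table")
    usable = table[table["status"] == "included"]
    hr = usable["hr_bpm"].to_numpy()
    excl = table[table["status"] == "excluded"]
    return CohortSummary(
        n_patients=int(table["patient_id"].nunique()),
        n_usable_ecgs=int(len(usable)),
        n_inadequate=int((table["status"] == "inadequate").sum()),
        exclusion_counts=excl["exclusion_reason"].value_counts().to_dict(),
        hr_mean=float(np.mean(hr)) if len(usable) else float("nan"),
        hr_sd=float(np.std(hr, ddof=1)) if len(usable) > 1 else float("nan"),
        hr_min=float(np.min(hr)) if len(usable) else float("nan"),
        hr_max=float(np.max(hr)) if len(usable) else float("nan"),
        male_fraction=float((usable.drop_duplicates("patient_id")["sex"] == "male").mean())
        if len(usable) else float("nan"),
    )
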