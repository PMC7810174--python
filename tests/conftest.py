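import numpy as np
import pandas as pd
import pytest

from qtckit import CohortConfig, correct_table, generate_cohort
from qtckit.formulas import (
    qtc_bazett,
    qtc_framingham,
    qtc_fridericia,
    qtc_hodges,
    qtc_simple,
)


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """Synthetic cohort with the study-default structure (190 usable ECGs)."""
    return generate_cohort(CohortConfig(seed=20260929))


@pytest.fixture(scope="session")
def corrected_cohort(default_cohort) -> pd.DataFrame:
    return correct_table(default_cohort)


def fast_correct(table: pd.DataFrame) -> pd.DataFrame:
    """Vectorised QTc columns for large synthetic tables (no per-row validation)."""
    usable = table.dropna(subset=["qt_ms"]).copy()
    qt = usable["qt_ms"].to_numpy()
    rr = usable["rr_s"].to_numpy()
    hr = usable["hr_bpm"].to_numpy()
    usable["qtc_bazett"] = qtc_bazett(qt, rr)
    usable["qtc_fridericia"] = qtc_fridericia(qt, rr)
    usable["qtc_framingham"] = qtc_framingham(qt, rr)
    usable["qtc_hodges"] = qtc_hodges(qt, hr)
    usable["qtc_simple"] = qtc_simple(qt, hr)
    return usable


@pytest.fixture(scope="session")
def flat_cohort_config() -> CohortConfig:
    """A large single-ECG cohort with no exclusions, for distributional checks."""
    return CohortConfig(
        seed=8675309,
        n_admitted=20_000,
        n_inadequate=0,
        exclusions={"lbbb": 0, "af_at": 0, "rbbb": 0, "af_lbbb": 0},
        n_second_ecg=0,
    )


@pytest.fixture(scope="session")
def large_corrected(flat_cohort_config) -> pd.DataFrame:
    return fast_correct(generate_cohort(flat_cohort_config))
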