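"""Method-comparison statistics for paired QTc series.

Agreement between two correction methods is summarised the Bland-Altman
way: the mean of the paired differences (bias), their sample standard
deviation, and the 95% limits of agreement bias +/- 1.96 SD, the interval
expected to contain 95% of between-method differences.  Lin's concordance
correlation coefficient complements it with a single scaled index that
penalises both imprecision and systematic shift.

Rate dependence of a correction is measured by the ordinary
least-squares slope of QTc on HR: an ideal correction leaves no residual
rate trend (slope ~ 0 ms/bpm).  Slopes across methods are compared with an
F-test of the method x HR interaction in a stacked linear model, i.e. a
test of slope homogeneity.  Prolonged-QTc prevalences under two methods
are compared with a two-proportion chi-square test (no continuity
correction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.proportion import proportions_chisquare

from .errors import ValidationError
from .formulas import METHODS, classify_prolonged

__all__ = [
    "BlandAltmanResult",
    "RegressionResult",
    "SlopeComparisonResult",
    "PrevalenceComparison",
    "bland_altman",
    "lin_ccc",
    "qtc_hr_regression",
    "compare_slopes",
    "prolonged_prevalence",
    "compare_prevalences",
]

LOA_MULTIPLIER = 1.96  # 95% limits of agreement


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias and 95% limits of agreement between two paired series (ms).

    The difference orientation is ``method_a - method_b``: "A x B" in a
    report means A minus B.
    """

    method_a: str
    method_b: str
    n: int
    bias: float
    sd: float
    loa_lower: float
    loa_upper: float

    @property
    def pair(self) -> str:
        return f"{self.method_a} x {self.method_b}"


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of QTc (ms) on HR (bpm) for one correction method."""

    method: str
    slope: float
    intercept: float
    r2: float
    n: int


@dataclass(frozen=True)
class SlopeComparisonResult:
    """F-test of slope homogeneity across methods (method x HR interaction).

    ``note`` records that the stacked-interaction formulation is one
    specific reading of an otherwise unspecified between-method ANOVA.
    """

    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    note: str = "slope homogeneity tested as the method:HR interaction in a stacked OLS model"


@dataclass(frozen=True)
class PrevalenceComparison:
    """Two-proportion chi-square comparison of prolonged-QTc prevalence."""

    method_a: str
    method_b: str
    prop_a: float
    prop_b: float
    n: int
    statistic: float
    p_value: float


def _paired(values_a, values_b, min_n: int = 2) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError(
            f"paired series must be 1-d and equal length, got {a.shape} and {b.shape}"
        )
    if a.size < min_n:
        raise ValidationError(f"need at least {min_n} pairs, got {a.size}")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValidationError("paired series contain missing values")
    return a, b


def bland_altman(values_a, values_b, method_a: str = "a", method_b: str = "b") -> BlandAltmanResult:
    """Bland-Altman agreement of two paired series.

    bias = mean(a - b); sd uses the n-1 (sample) denominator; limits of
    agreement are bias +/- 1.96 sd.
    """
    a, b = _paired(values_a, values_b)
    d = a - b
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltmanResult(
        method_a=method_a,
        method_b=method_b,
        n=int(d.size),
        bias=bias,
        sd=sd,
        loa_lower=bias - LOA_MULTIPLIER * sd,
        loa_upper=bias + LOA_MULTIPLIER * sd,
    )


def lin_ccc(values_a, values_b) -> float:
    """Lin's concordance correlation coefficient.

    CCC = 2 cov(a, b) / (var(a) + var(b) + (mean(a) - mean(b))^2), with
    1/n moment estimators (Lin's original form).  Undefined when both
    series are constant.
    """
    a, b = _paired(values_a, values_b)
    var_a = float(np.var(a))  # 1/n moments throughout
    var_b = float(np.var(b))
    shift = float(np.mean(a) - np.mean(b))
    denom = var_a + var_b + shift**2
    if denom == 0.0:
        raise ValidationError("CCC undefined: both series are constant and equal")
    cov = float(np.mean((a - np.mean(a)) * (b - np.mean(b))))
    return 2.0 * cov / denom


def qtc_hr_regression(qtc, hr, method: str = "") -> RegressionResult:
    """OLS regression of QTc on HR; slope in ms/bpm, plus intercept and R^2."""
    qtc_arr, hr_arr = _paired(qtc, hr, min_n=3)
    if np.ptp(hr_arr) == 0:
        raise ValidationError("HR is constant; slope is undefined")
    if np.ptp(qtc_arr) == 0:  # flat response: no rate trend, nothing explained
        return RegressionResult(method=method, slope=0.0,
                                intercept=float(qtc_arr[0]), r2=0.0, n=int(qtc_arr.size))
    fit = stats.linregress(hr_arr, qtc_arr)
    return RegressionResult(
        method=method,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        n=int(qtc_arr.size),
    )


def compare_slopes(datasets: Mapping[str, tuple[Sequence[float], Sequence[float]]]) -> SlopeComparisonResult:
    """Test whether the QTc/HR slope is the same across methods.

    ``datasets`` maps a method name to its (qtc, hr) series.  The series
    are stacked into one table and QTc is modelled as
    ``qtc ~ hr * method``; the F-statistic of the ``hr:method``
    interaction is the slope-homogeneity test.
    """
    if len(datasets) < 2:
        raise ValidationError("need at least two methods to compare slopes")
    frames = []
    for name, (qtc, hr) in datasets.items():
        q, h = _paired(qtc, hr, min_n=3)
        frames.append(pd.DataFrame({"qtc": q, "hr": h, "method": name}))
    stacked = pd.concat(frames, ignore_index=True)
    try:
        model = smf.ols("qtc ~ hr * C(method)", data=stacked).fit()
        table = sm.stats.anova_lm(model, typ=2)
    except Exception as exc:  # singular design etc.
        raise ValidationError(f"degenerate design for slope comparison: {exc}") from exc
    row = table.loc["hr:C(method)"]
    f = float(row["F"])
    df_den = int(table.loc["Residual", "df"])
    if not np.isfinite(f):  # identical copies: zero interaction SS and zero residual SS
        f = 0.0
    return SlopeComparisonResult(
        f_statistic=f,
        df_num=int(row["df"]),
        df_den=df_den,
        p_value=float(row["PR(>F)"]) if np.isfinite(row["PR(>F)"]) else 1.0,
    )


def prolonged_prevalence(corrected: pd.DataFrame, method: str) -> float:
    """Fraction of ECGs whose QTc under ``method`` exceeds the sex limit.

    ``corrected`` needs ``sex`` and ``qtc_<method>`` columns (one row per
    ECG, as written by the correction pipeline).
    """
    if method not in METHODS:
        raise ValidationError(f"unknown method {method!r}; expected one of {METHODS}")
    if len(corrected) == 0:
        raise ValidationError("no records")
    col = f"qtc_{method}"
    if col not in corrected.columns or "sex" not in corrected.columns:
        raise ValidationError(f"table must have 'sex' and {col!r} columns")
    flags = [
        classify_prolonged(q, s)
        for q, s in zip(corrected[col].to_numpy(), corrected["sex"].to_numpy())
    ]
    return float(np.mean(flags))


def compare_prevalences(
    count_a: int, count_b: int, n: int, method_a: str = "a", method_b: str = "b"
) -> PrevalenceComparison:
    """Two-proportion chi-square test (no continuity correction).

    Compares ``count_a`` of ``n`` flagged ECGs under method A against
    ``count_b`` of ``n`` under method B.  The pairing of ECGs across
    methods is ignored (unpaired test).
    """
    if n <= 0:
        raise ValidationError("n must be positive")
    if not (0 <= count_a <= n and 0 <= count_b <= n):
        raise ValidationError("counts must lie in [0, n]")
    if count_a == count_b:
        statistic, p = 0.0, 1.0
    else:
        statistic, p, _ = proportions_chisquare([count_a, count_b], [n, n])
    return PrevalenceComparison(
        method_a=method_a,
        method_b=method_b,
        prop_a=count_a / n,
        prop_b=count_b / n,
        n=n,
        statistic=float(statistic),
        p_value=float(p),
    )
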