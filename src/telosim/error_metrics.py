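"""Statistics used to characterise measurement error.

Consistency intraclass correlation (two-way ANOVA, ICC(C,1)), D'Agostino
skewness and Anscombe-Glynn kurtosis tests, error SDs scaled by the SD of
the ideal quantity, and coefficient-of-variation utilities (provided mainly
to demonstrate why CVs on the raw Cq scale understate assay error).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DomainError, UndefinedStatisticError

__all__ = [
    "RepeatedMeasures",
    "ICCResult",
    "MomentTestResult",
    "CVReport",
    "icc_consistency",
    "skewness_test",
    "kurtosis_test",
    "scaled_error_sd",
    "cv_report",
]


@dataclass(frozen=True)
class RepeatedMeasures:
    """n individuals x k repeated measurements of one quantity."""

    values: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise DomainError(f"values must be 2-D (n x k), got ndim={values.ndim}")
        n, k = values.shape
        if n < 2 or k < 2:
            raise DomainError(f"need at least 2 individuals and 2 occasions, got {n} x {k}")
        if not np.all(np.isfinite(values)):
            raise DomainError("values contain non-finite cells")
        object.__setattr__(self, "values", values)
        if self.labels is not None:
            labels = np.asarray(self.labels)
            if labels.shape != (n,):
                raise DomainError("labels must have one entry per individual")
            object.__setattr__(self, "labels", labels)


@dataclass(frozen=True)
class ICCResult:
    """Consistency intraclass correlation with its ANOVA mean squares."""

    icc: float
    ms_rows: float
    ms_error: float
    n: int
    k: int


@dataclass(frozen=True)
class MomentTestResult:
    """A sample moment estimate with its z-test against normality."""

    estimate: float
    statistic: float
    p_value: float


@dataclass(frozen=True)
class CVReport:
    cv_on_cq: float
    cv_on_linear: float


def icc_consistency(data: RepeatedMeasures | np.ndarray) -> ICCResult:
    """Consistency ICC, ICC(C,1), from a two-way decomposition.

    Rows are individuals and columns are measurement occasions; the occasion
    (column) effect is removed from the error term, so a constant shift of
    one occasion — e.g. a plate or run effect — does not reduce the ICC:

        icc = (MS_rows - MS_error) / (MS_rows + (k - 1) * MS_error)
    """
    if not isinstance(data, RepeatedMeasures):
        data = RepeatedMeasures(np.asarray(data, dtype=float))
    x = data.values
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = float(((x - grand) ** 2).sum())
    ss_rows = float(k * ((row_means - grand) ** 2).sum())
    ss_cols = float(n * ((col_means - grand) ** 2).sum())
    ss_error = ss_total - ss_rows - ss_cols
    if ss_total == 0.0:
        raise UndefinedStatisticError("ICC undefined: zero total variance")
    ms_rows = ss_rows / (n - 1)
    ms_error = max(ss_error, 0.0) / ((n - 1) * (k - 1))
    icc = (ms_rows - ms_error) / (ms_rows + (k - 1) * ms_error)
    return ICCResult(icc=float(icc), ms_rows=ms_rows, ms_error=ms_error, n=n, k=k)


def _check_vector(x: np.ndarray, min_length: int, what: str) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < min_length:
        raise DomainError(f"{what} requires at least {min_length} observations, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise DomainError(f"{what} input contains non-finite values")
    if np.ptp(x) == 0.0:
        raise DomainError(f"{what} undefined for a zero-variance sample")
    return x


def skewness_test(x: np.ndarray) -> MomentTestResult:
    """Sample skewness (g1) with the D'Agostino z-test of symmetry.

    The estimate is the third standardised sample moment; the test statistic
    is D'Agostino's transformation of sqrt(b1) to an approximate standard
    normal, two-sided p-value.
    """
    x = _check_vector(x, 9, "skewness test")
    estimate = float(stats.skew(x, bias=True))
    statistic, p_value = stats.skewtest(x)
    return MomentTestResult(estimate=estimate, statistic=float(statistic), p_value=float(p_value))


def kurtosis_test(x: np.ndarray) -> MomentTestResult:
    """Sample excess kurtosis (g2) with the Anscombe-Glynn z-test."""
    x = _check_vector(x, 20, "kurtosis test")
    estimate = float(stats.kurtosis(x, fisher=True, bias=True))
    statistic, p_value = stats.kurtosistest(x)
    return MomentTestResult(estimate=estimate, statistic=float(statistic), p_value=float(p_value))


def scaled_error_sd(measured: np.ndarray, ideal: np.ndarray) -> float:
    """SD of (measured - ideal) scaled by the SD of the ideal quantity.

    On this scale +/-1 means mismeasuring by one standard deviation of the
    true between-individual variation, making error magnitudes comparable
    across quantities measured in different units.
    """
    measured = np.asarray(measured, dtype=float)
    ideal = np.asarray(ideal, dtype=float)
    if measured.shape != ideal.shape:
        raise DomainError("measured and ideal must have equal length")
    if measured.size < 2:
        raise DomainError("need at least 2 observations")
    sd_ideal = float(np.std(ideal, ddof=1))
    if sd_ideal == 0.0:
        raise DomainError("scaled error SD undefined: ideal values have zero variance")
    return float(np.std(measured - ideal, ddof=1)) / sd_ideal


def cv_report(cq: np.ndarray) -> CVReport:
    """Coefficient of variation of a Cq vector, on two scales.

    Returns the CV (SD/mean) on the raw Cq scale and on the linear 2**-Cq
    scale.  The raw-Cq CV is misleadingly small because Cq means are large
    (~15-25 cycles) while their SDs are fractions of a cycle; the linear
    scale is roughly ln(2) * SD(Cq), an order of magnitude larger.
    """
    cq = np.asarray(cq, dtype=float).ravel()
    if cq.size < 2:
        raise DomainError("need at least 2 observations")
    linear = np.exp2(-cq)
    report = []
    for name, values in (("Cq", cq), ("2^-Cq", linear)):
        mean = float(np.mean(values))
        if mean <= 0:
            raise DomainError(f"CV undefined: non-positive mean on the {name} scale")
        report.append(float(np.std(values, ddof=1)) / mean)
    return CVReport(cv_on_cq=report[0], cv_on_linear=report[1])
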