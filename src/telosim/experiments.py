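"""Seeded simulation experiments over the generative model.

Each experiment simulates one or more cohorts, applies the error metrics and
returns a tidy result object.  The repeated-sampling design underlying the
repeatability and longitudinal experiments holds each individual's true
telomere length fixed and redraws the DNA sample and measurement errors,
i.e. it represents re-assaying the same individuals with no true change.
Every experiment is bit-reproducible given (params, seed, grid).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import sim_core
from .error_metrics import MomentTestResult, icc_consistency, kurtosis_test, scaled_error_sd, skewness_test
from .exceptions import DomainError, ParameterError
from .params import SimParams
from .sim_core import simulate_dataset

__all__ = [
    "DistributionStudyResult",
    "ErrorVsTlResult",
    "SweepResult",
    "CrossoverResult",
    "LongitudinalResult",
    "distribution_study",
    "error_vs_tl",
    "repeatability_surface",
    "ts_vs_rawcq_crossover",
    "longitudinal_null",
    "null_curve",
    "correlated_error_sweep",
]

#: Error sigmas outside this range are outside the examined design space.
SIGMA_RANGE = (0.0, 0.3)


def _rng_for(params: SimParams, rng: np.random.Generator | None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(params.seed)


def _check_grid(grid: np.ndarray, lo: float, hi: float, name: str) -> np.ndarray:
    grid = np.asarray(grid, dtype=float).ravel()
    if grid.size == 0:
        raise ParameterError(f"{name} grid is empty")
    if grid.min() < lo or grid.max() > hi:
        raise ParameterError(f"{name} grid must lie within [{lo}, {hi}]")
    return grid


def _paired_sampling(
    params: SimParams, rng: np.random.Generator
) -> tuple[sim_core.CohortDataset, sim_core.CohortDataset]:
    """Two samplings of the same cohort: tl fixed, DNA and errors redrawn.

    Each sampling is normalised by its own cohort-mean reference Cqs, as a
    separate assay run would be; consistency ICC and Pearson correlations
    are invariant to that per-occasion rescaling.
    """
    d1 = simulate_dataset(params, rng)
    d2 = simulate_dataset(params, rng, tl=d1.tl)
    return d1, d2


# ---------------------------------------------------------------------------
# Error distributions (cross-sectional)
# ---------------------------------------------------------------------------

@dataclass
class DistributionStudyResult:
    """Scaled error SDs and moment tests for the three error vectors."""

    scaled_sd: dict[str, float]
    skewness: dict[str, MomentTestResult | None]
    kurtosis: dict[str, MomentTestResult | None]
    degenerate: bool
    n: int

    def to_records(self) -> list[dict]:
        rows = []
        for key in ("cq_t", "cq_s", "ts"):
            skew, kurt = self.skewness[key], self.kurtosis[key]
            rows.append(
                {
                    "quantity": key,
                    "scaled_sd": self.scaled_sd[key],
                    "skewness": None if skew is None else skew.estimate,
                    "skewness_p": None if skew is None else skew.p_value,
                    "kurtosis": None if kurt is None else kurt.estimate,
                    "kurtosis_p": None if kurt is None else kurt.p_value,
                }
            )
        return rows


def distribution_study(
    params: SimParams, rng: np.random.Generator | None = None
) -> DistributionStudyResult:
    """Characterise the error distributions of one simulated dataset.

    Computes measured-minus-ideal error vectors for the telomere Cq, the
    single-copy Cq and the TS ratio, scales each by the SD of the
    corresponding ideal quantity, and runs the skewness and kurtosis tests
    on each.  The Cq errors are normal by construction; the TS error is a
    normal-log-normal mixture and comes out positively skewed and
    leptokurtic.
    """
    rng = _rng_for(params, rng)
    data = simulate_dataset(params, rng)
    errors = {
        "cq_t": data.mcq_t - data.icq_t,
        "cq_s": data.mcq_s - data.icq_s,
        "ts": data.mts - data.its,
    }
    ideals = {"cq_t": data.icq_t, "cq_s": data.icq_s, "ts": data.its}
    degenerate = params.sigma_eps_t == 0.0 and params.sigma_eps_s == 0.0
    scaled_sd, skew, kurt = {}, {}, {}
    for key, err in errors.items():
        scaled_sd[key] = scaled_error_sd(ideals[key] + err, ideals[key])
        if np.ptp(err) == 0.0:
            skew[key] = None
            kurt[key] = None
        else:
            skew[key] = skewness_test(err)
            kurt[key] = kurtosis_test(err)
    return DistributionStudyResult(
        scaled_sd=scaled_sd, skewness=skew, kurtosis=kurt, degenerate=degenerate, n=params.n
    )


# ---------------------------------------------------------------------------
# Error magnitude vs true telomere length
# ---------------------------------------------------------------------------

@dataclass
class ErrorVsTlResult:
    table: pd.DataFrame  # columns tl, its, mts, abs_error
    slope: float
    slope_se: float

    @property
    def slope_z(self) -> float:
        return self.slope / self.slope_se if self.slope_se > 0 else np.nan


def error_vs_tl(params: SimParams, rng: np.random.Generator | None = None) -> ErrorVsTlResult:
    """Regress the absolute TS error on true telomere length (OLS).

    The expected error magnitude is proportional to tl, so the slope is
    positive whenever there is any measurement error.
    """
    rng = _rng_for(params, rng)
    data = simulate_dataset(params, rng)
    abs_error = np.abs(data.mts - data.its)
    table = pd.DataFrame({"tl": data.tl, "its": data.its, "mts": data.mts, "abs_error": abs_error})
    if np.ptp(abs_error) == 0.0:
        return ErrorVsTlResult(table=table, slope=0.0, slope_se=0.0)
    fit = stats.linregress(data.tl, abs_error)
    return ErrorVsTlResult(table=table, slope=float(fit.slope), slope_se=float(fit.stderr))


# ---------------------------------------------------------------------------
# Repeatability sweeps
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    """Tidy grid of repeatability (ICC) estimates with Monte-Carlo errors."""

    table: pd.DataFrame
    mc_replicates: int


def _icc_of_pairs(a: np.ndarray, b: np.ndarray) -> float:
    return icc_consistency(np.column_stack([a, b])).icc


def repeatability_surface(
    params: SimParams,
    grid_sigma_t: np.ndarray,
    grid_sigma_s: np.ndarray,
    mc_replicates: int = 10,
    rng: np.random.Generator | None = None,
) -> SweepResult:
    """Repeatability of the TS ratio over a grid of the two error sigmas.

    For each grid point, draws ``mc_replicates`` paired samplings of the
    same cohort and averages the consistency ICC of the measured TS pairs.
    Also records the ICC of the raw telomere Cq pairs, for which redrawn
    DNA amounts act as within-individual noise.
    """
    grid_sigma_t = _check_grid(grid_sigma_t, *SIGMA_RANGE, name="sigma_eps_t")
    grid_sigma_s = _check_grid(grid_sigma_s, *SIGMA_RANGE, name="sigma_eps_s")
    rng = _rng_for(params, rng)
    rows = []
    for st in grid_sigma_t:
        for ss in grid_sigma_s:
            p = params.replace(sigma_eps_t=float(st), sigma_eps_s=float(ss))
            icc_ts, icc_cqt = [], []
            for _ in range(mc_replicates):
                d1, d2 = _paired_sampling(p, rng)
                icc_ts.append(_icc_of_pairs(d1.mts, d2.mts))
                icc_cqt.append(_icc_of_pairs(d1.mcq_t, d2.mcq_t))
            rows.append(
                {
                    "sigma_eps_t": float(st),
                    "sigma_eps_s": float(ss),
                    "icc_mts": float(np.mean(icc_ts)),
                    "icc_mts_se": float(np.std(icc_ts, ddof=1) / np.sqrt(mc_replicates))
                    if mc_replicates > 1
                    else np.nan,
                    "icc_mcq_t": float(np.mean(icc_cqt)),
                    "mc_replicates": mc_replicates,
                }
            )
    return SweepResult(table=pd.DataFrame(rows), mc_replicates=mc_replicates)


@dataclass
class CrossoverResult:
    table: pd.DataFrame
    crossover_sigma: float  # NaN when the curves do not cross on the grid
    sigma_eps_t: float


def ts_vs_rawcq_crossover(
    params: SimParams,
    grid_sigma_s: np.ndarray,
    sigma_eps_t: float = 0.05,
    mc_replicates: int = 10,
    rng: np.random.Generator | None = None,
) -> CrossoverResult:
    """Where does the TS ratio stop beating the raw telomere Cq?

    Normalising by the single-copy gene removes sample-to-sample DNA
    variation but adds that assay's measurement error.  With the telomere
    error sigma fixed, this sweeps the single-copy error sigma and reports
    both repeatability curves and the crossover sigma: the first grid point
    where ICC(mTS) <= ICC(mCq_t), refined by linear interpolation between
    the bracketing grid points.
    """
    sweep = repeatability_surface(
        params,
        np.asarray([sigma_eps_t]),
        grid_sigma_s,
        mc_replicates=mc_replicates,
        rng=rng,
    )
    table = sweep.table.sort_values("sigma_eps_s").reset_index(drop=True)
    diff = table["icc_mts"].to_numpy() - table["icc_mcq_t"].to_numpy()
    crossover = np.nan
    below = np.nonzero(diff <= 0)[0]
    if below.size:
        i = int(below[0])
        if i == 0:
            crossover = float(table["sigma_eps_s"].iloc[0])
        else:
            x0, x1 = table["sigma_eps_s"].iloc[i - 1], table["sigma_eps_s"].iloc[i]
            y0, y1 = diff[i - 1], diff[i]
            crossover = float(x0 + (x1 - x0) * y0 / (y0 - y1))
    return CrossoverResult(table=table, crossover_sigma=crossover, sigma_eps_t=sigma_eps_t)


# ---------------------------------------------------------------------------
# Longitudinal null patterns
# ---------------------------------------------------------------------------

@dataclass
class LongitudinalResult:
    """Two samplings of the same cohort treated as time 1 / time 2 measures.

    Under the no-change null, any departure of r12 from 1 and any negative
    correlation of change with baseline is produced by measurement error
    alone (regression to the mean).
    """

    mts_t1: np.ndarray
    mts_t2: np.ndarray
    r12: float
    r_change_baseline: float
    slope_t2_on_t1: float
    degenerate: bool = False

    summary_fields: tuple[str, ...] = field(
        default=("r12", "r_change_baseline", "slope_t2_on_t1", "degenerate"), repr=False
    )


def longitudinal_null(
    params: SimParams, rng: np.random.Generator | None = None
) -> LongitudinalResult:
    """Simulate a longitudinal pair with no true telomere change."""
    rng = _rng_for(params, rng)
    d1, d2 = _paired_sampling(params, rng)
    t1, t2 = d1.mts, d2.mts
    delta = t2 - t1
    r12 = float(np.corrcoef(t1, t2)[0, 1])
    slope = float(np.cov(t1, t2)[0, 1] / np.var(t1, ddof=1))
    if np.ptp(delta) <= 1e-9 * max(np.ptp(t1), 1e-300):
        # No measurement error: both samplings reproduce the ideal TS (the
        # redrawn DNA amounts cancel up to floating-point rounding).
        return LongitudinalResult(
            mts_t1=t1, mts_t2=t2, r12=r12, r_change_baseline=np.nan,
            slope_t2_on_t1=slope, degenerate=True,
        )
    r_change = float(np.corrcoef(delta, t1)[0, 1])
    return LongitudinalResult(
        mts_t1=t1, mts_t2=t2, r12=r12, r_change_baseline=r_change, slope_t2_on_t1=slope
    )


def null_curve(
    params: SimParams,
    sigma_grid: np.ndarray,
    mc_replicates: int = 10,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """The no-change null locus of (r12, corr(change, baseline)) vs error sigma.

    Sets both error sigmas equal to each grid value.  Empirical cohort
    estimates can be overlaid on this curve to judge whether their
    longitudinal pattern is compatible with measurement error alone.
    """
    sigma_grid = _check_grid(sigma_grid, 0.0, 0.2, name="sigma")
    rng = _rng_for(params, rng)
    rows = []
    for sigma in sigma_grid:
        p = params.replace(sigma_eps_t=float(sigma), sigma_eps_s=float(sigma))
        r12s, rchs = [], []
        for _ in range(mc_replicates):
            res = longitudinal_null(p, rng)
            r12s.append(res.r12)
            if not res.degenerate:
                rchs.append(res.r_change_baseline)
        rows.append(
            {
                "sigma": float(sigma),
                "r12": float(np.mean(r12s)),
                "r_change_baseline": float(np.mean(rchs)) if rchs else np.nan,
                "mc_replicates": mc_replicates,
            }
        )
    return pd.DataFrame(rows)


def correlated_error_sweep(
    params: SimParams,
    rho_grid: np.ndarray,
    mc_replicates: int = 10,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Repeatability of the TS ratio as the two Cq errors become correlated.

    Positive correlation between eps_t and eps_s partially cancels in the
    difference that enters the TS exponent, so ICC is non-decreasing in rho
    and reaches exactly 1 at rho = 1 with equal sigmas; modest correlations
    have only a small mitigating effect.
    """
    rho_grid = np.asarray(rho_grid, dtype=float).ravel()
    if rho_grid.size == 0 or np.any(np.abs(rho_grid) > 1):
        raise ParameterError("rho grid must be non-empty and lie within [-1, 1]")
    rng = _rng_for(params, rng)
    rows = []
    for rho in rho_grid:
        p = params.replace(rho_err=float(rho))
        iccs = []
        for _ in range(mc_replicates):
            d1, d2 = _paired_sampling(p, rng)
            iccs.append(_icc_of_pairs(d1.mts, d2.mts))
        rows.append(
            {"rho": float(rho), "icc_mts": float(np.mean(iccs)), "mc_replicates": mc_replicates}
        )
    return pd.DataFrame(rows)
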