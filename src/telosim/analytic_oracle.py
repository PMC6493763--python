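"""Closed-form companions to the simulator, used as independent oracles.

The measured TS ratio factorises as ``mts = its * L`` with
``L = 2**-(eps_t - eps_s)`` (up to the constant reference rescaling).  With
normal Cq errors, ``D = eps_t - eps_s`` is normal with
``sigma_D**2 = sigma_eps_t**2 + sigma_eps_s**2 - 2*rho*sigma_eps_t*sigma_eps_s``,
so ``L`` is lognormal with log-SD ``sigma_L = ln(2) * sigma_D``.  The TS
error ``its * (L - 1)`` is therefore a normal-log-normal mixture: positively
skewed, leptokurtic, and with magnitude proportional to the true telomere
length.  Everything below follows from the first two moments of that
lognormal factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import DomainError
from .params import SimParams

__all__ = [
    "TheoryParams",
    "LognormalFactorMoments",
    "lognormal_factor_moments",
    "expected_icc",
    "expected_abs_error_given_tl",
    "rtm_correlation",
    "replicate_sd_reduction",
]

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class TheoryParams:
    """The subset of simulation parameters the closed forms depend on."""

    sigma_t: float = 0.1
    sigma_eps_t: float = 0.0
    sigma_eps_s: float = 0.0
    rho_err: float = 0.0
    mu_s: float = 10.0
    sigma_s: float = 1.0

    @classmethod
    def from_sim_params(cls, params: SimParams) -> "TheoryParams":
        # Closed forms apply to the *effective* error sigma after averaging
        # the k technical replicates.
        k = math.sqrt(params.k_reps)
        return cls(
            sigma_t=params.sigma_t,
            sigma_eps_t=params.sigma_eps_t / k,
            sigma_eps_s=params.sigma_eps_s / k,
            rho_err=params.rho_err,
            mu_s=params.mu_s,
            sigma_s=params.sigma_s,
        )


@dataclass(frozen=True)
class LognormalFactorMoments:
    mean: float
    variance: float
    skewness: float
    sigma_d: float
    sigma_l: float


def _as_theory(params: TheoryParams | SimParams) -> TheoryParams:
    if isinstance(params, SimParams):
        return TheoryParams.from_sim_params(params)
    return params


def _sigma_d(sigma_eps_t: float, sigma_eps_s: float, rho_err: float) -> float:
    if sigma_eps_t < 0 or sigma_eps_s < 0:
        raise DomainError("error sigmas must be >= 0")
    if abs(rho_err) > 1:
        raise DomainError("rho_err must lie in [-1, 1]")
    var = sigma_eps_t**2 + sigma_eps_s**2 - 2.0 * rho_err * sigma_eps_t * sigma_eps_s
    return math.sqrt(max(var, 0.0))


def lognormal_factor_moments(
    sigma_eps_t: float, sigma_eps_s: float, rho_err: float = 0.0
) -> LognormalFactorMoments:
    """Moments of the multiplicative TS error factor ``L = 2**-(eps_t - eps_s)``.

    With ``w = exp(sigma_L**2)``: mean ``sqrt(w)``, variance ``(w - 1) * w``,
    skewness ``(w + 2) * sqrt(w - 1)`` — the standard lognormal moments.
    Positive correlation between the two errors shrinks sigma_D, and with
    rho = 1 and equal sigmas the errors cancel exactly (L degenerate at 1).
    """
    sigma_d = _sigma_d(sigma_eps_t, sigma_eps_s, rho_err)
    sigma_l = _LN2 * sigma_d
    w = math.exp(sigma_l**2)
    return LognormalFactorMoments(
        mean=math.sqrt(w),
        variance=(w - 1.0) * w,
        skewness=(w + 2.0) * math.sqrt(w - 1.0),
        sigma_d=sigma_d,
        sigma_l=sigma_l,
    )


def expected_icc(params: TheoryParams | SimParams) -> float:
    """Population consistency ICC of paired TS measurements, no true change.

    Writing mts = iTS * L with iTS proportional to tl (scaled to unit mean)
    and L the lognormal error factor with raw moments m1, m2:

        between-subject variance v_b = Var(iTS) * m1**2
        within-subject variance  v_w = E[iTS**2] * (m2 - m1**2)

    and the repeatability is v_b / (v_b + v_w).  E[iTS**2] uses the exact
    normal second moment 1 + sigma_t**2.
    """
    p = _as_theory(params)
    if not p.sigma_t > 0:
        raise DomainError("expected_icc requires sigma_t > 0")
    mom = lognormal_factor_moments(p.sigma_eps_t, p.sigma_eps_s, p.rho_err)
    m1_sq = mom.mean**2
    m2_minus_m1_sq = mom.variance
    v_between = (p.sigma_t**2) * m1_sq
    v_within = (1.0 + p.sigma_t**2) * m2_minus_m1_sq
    return v_between / (v_between + v_within)


def expected_abs_error_given_tl(tl: float, params: TheoryParams | SimParams) -> float:
    """Expected |mts - its| conditional on true telomere length.

    Equals ``c * tl`` with ``c = E|L - 1|``; for a lognormal with log-mean 0
    and log-SD s the folded moment has the closed form

        E|L - 1| = exp(s**2 / 2) * (Phi(s) - Phi(-s))

    so the error magnitude is exactly proportional to tl — individuals with
    longer telomeres are measured with larger absolute error.
    """
    if not tl > 0:
        raise DomainError("tl must be > 0")
    p = _as_theory(params)
    s = lognormal_factor_moments(p.sigma_eps_t, p.sigma_eps_s, p.rho_err).sigma_l
    if s == 0.0:
        return 0.0
    phi = 0.5 * (1.0 + math.erf(s / math.sqrt(2.0)))
    c = math.exp(s**2 / 2.0) * (2.0 * phi - 1.0)
    return c * tl


def rtm_correlation(r12: float, sd1: float, sd2: float) -> float:
    """Correlation between change (X2 - X1) and baseline X1 (regression to the mean).

    Blomquist-type closed form:

        (r12 * sd2 - sd1) / sqrt(sd1**2 + sd2**2 - 2 * r12 * sd1 * sd2)

    Under equal SDs this reduces to -sqrt((1 - r12) / 2): even with no true
    change, noisy repeated measures show an apparent negative dependence of
    change on baseline.  Returns NaN when the change has zero variance
    (r12 = 1 with sd1 = sd2).
    """
    if abs(r12) > 1:
        raise DomainError("r12 must lie in [-1, 1]")
    if sd1 <= 0 or sd2 <= 0:
        raise DomainError("sd1 and sd2 must be > 0")
    denom_sq = sd1**2 + sd2**2 - 2.0 * r12 * sd1 * sd2
    if denom_sq <= 0.0:
        return math.nan
    return (r12 * sd2 - sd1) / math.sqrt(denom_sq)


def replicate_sd_reduction(sigma: float, k: int) -> float:
    """Effective error sigma after averaging k independent technical replicates."""
    if sigma < 0:
        raise DomainError("sigma must be >= 0")
    if k < 1:
        raise DomainError("k must be >= 1")
    return sigma / math.sqrt(k)
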