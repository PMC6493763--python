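"""Simulation parameters for the qPCR telomere measurement-error model.

The generative model assigns each individual a true relative telomere length
``tl ~ Normal(1, sigma_t)`` and each DNA sample a single-copy-gene amount
``dna_s ~ Normal(mu_s, sigma_s)``.  Telomeric DNA is ``a * tl * dna_s`` where
``a`` is the fold-abundance of the telomeric sequence relative to the
single-copy gene.  Quantification cycles follow ``Cq = f - log2(DNA)`` and
measurement error is additive normal noise on the Cq scale with standard
deviations ``sigma_eps_t`` / ``sigma_eps_s`` (the "error sigmas"), optionally
correlated across the two reactions (``rho_err``) and averaged over
``k_reps`` technical replicates.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Any

from .exceptions import ParameterError

__all__ = ["SimParams"]


@dataclass(frozen=True)
class SimParams:
    """Parameter set of the generative simulation.

    Defaults are the study conditions used throughout: a cohort of 10 000
    individuals, single-copy DNA amount 10 +/- 1 (arbitrary units), telomeric
    sequence 1000-fold more abundant than the single-copy gene, true relative
    telomere length with 10% between-individual SD, and a fluorescence
    threshold constant of 28 cycles.  The error sigmas default to 0 (no
    measurement error) and are the quantities experiments vary, over the
    examined range 0 to 0.3 cycles.

    Parameters
    ----------
    n : int
        Number of individuals in the cohort (>= 2).
    mu_s, sigma_s : float
        Mean and SD of the true single-copy DNA amount per sample.
    a : float
        Telomere-to-single-copy abundance fold (> 1).
    sigma_t : float
        SD of true relative telomere length across individuals (mean fixed
        at 1).
    f : float
        Fluorescence-threshold constant, in cycles.
    sigma_eps_t, sigma_eps_s : float
        Error sigmas: SD of the additive normal measurement error on the
        telomere and single-copy Cq, in cycles.  Interpreted as the
        *effective* (post replicate-averaging) sigma when ``k_reps == 1``.
    rho_err : float
        Correlation between the telomere and single-copy errors of the same
        sample, in [-1, 1].  Default 0 (independent errors).
    k_reps : int
        Technical replicates per reaction; replicate Cqs are averaged, so the
        effective error SD is ``sigma / sqrt(k_reps)``.
    seed : int or None
        Seed for the random stream when no generator is supplied explicitly.
    """

    n: int = 10_000
    mu_s: float = 10.0
    sigma_s: float = 1.0
    a: float = 1000.0
    sigma_t: float = 0.1
    f: float = 28.0
    sigma_eps_t: float = 0.0
    sigma_eps_s: float = 0.0
    rho_err: float = 0.0
    k_reps: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Raise :class:`ParameterError` naming the first offending field."""
        if not isinstance(self.n, (int,)) or isinstance(self.n, bool):
            raise ParameterError(f"n must be an integer, got {self.n!r}")
        if self.n < 2:
            raise ParameterError(f"n must be >= 2, got {self.n}")
        if not self.mu_s > 0:
            raise ParameterError(f"mu_s must be > 0, got {self.mu_s}")
        if not self.a > 1:
            raise ParameterError(f"a must be > 1, got {self.a}")
        for name in ("sigma_s", "sigma_t", "sigma_eps_t", "sigma_eps_s"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value >= 0):
                raise ParameterError(f"{name} must be >= 0 and finite, got {value}")
        if not math.isfinite(self.f):
            raise ParameterError(f"f must be finite, got {self.f}")
        if not abs(self.rho_err) <= 1:
            raise ParameterError(f"rho_err must lie in [-1, 1], got {self.rho_err}")
        if not isinstance(self.k_reps, int) or isinstance(self.k_reps, bool) or self.k_reps < 1:
            raise ParameterError(f"k_reps must be an integer >= 1, got {self.k_reps!r}")
        if self.seed is not None and (not isinstance(self.seed, int) or self.seed < 0):
            raise ParameterError(f"seed must be a non-negative integer or None, got {self.seed!r}")

    def replace(self, **changes: Any) -> "SimParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, mapping: dict[str, Any]) -> "SimParams":
        """Build from a mapping; unknown keys are an error (anti-typo contract)."""
        known = {field.name for field in dataclasses.fields(cls)}
        unknown = sorted(set(mapping) - known)
        if unknown:
            raise ParameterError(f"unknown simulation parameter(s): {', '.join(unknown)}")
        return cls(**mapping)
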