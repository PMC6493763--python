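"""Generative model: true biology -> DNA sample -> Cq values -> TS ratios.

The chain of quantities per individual is

* ``tl``     true relative telomere length, Normal(1, sigma_t)
* ``dna_s``  single-copy DNA amount in the sample, Normal(mu_s, sigma_s)
* ``dna_t``  telomeric DNA amount, exactly ``a * tl * dna_s``
* ``icq``    ideal (error-free) quantification cycle, ``f - log2(DNA)``
* ``eps``    realised measurement error on the Cq scale (after averaging
  ``k_reps`` technical replicates)
* ``mcq``    measured Cq, ``icq + eps``
* ``its``/``mts``  ideal / measured TS ratio, ``2**-(cq_t - rcq_t - cq_s + rcq_s)``
  with reference Cqs ``rcq`` taken (by default) as the cohort means.

Draw order is fixed and documented — tl, then dna_s, then errors — so that
runs are bit-reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DomainError, FormatError
from .params import SimParams

__all__ = [
    "NormalizationReference",
    "CohortDataset",
    "generate_cohort",
    "ideal_cqs",
    "apply_measurement_error",
    "ts_ratio",
    "simulate_dataset",
]

#: Column order of the serialised per-individual table.
CSV_COLUMNS = [
    "individual_id",
    "tl",
    "dna_s",
    "dna_t",
    "icq_t",
    "icq_s",
    "mcq_t",
    "mcq_s",
    "its",
    "mts",
]


class ReferenceSource(str, Enum):
    COHORT_MEAN = "cohort_mean"
    FIXED_VALUES = "fixed_values"


@dataclass(frozen=True)
class NormalizationReference:
    """Reference Cqs used to normalise TS ratios.

    Reference values rescale every TS ratio by one common factor; they set
    the scale of the ratio (cohort-mean references make the mean TS roughly
    1) but have no effect on correlations or repeatability.
    """

    rcq_t: float
    rcq_s: float
    source: ReferenceSource = ReferenceSource.FIXED_VALUES

    def __post_init__(self) -> None:
        if not (np.isfinite(self.rcq_t) and np.isfinite(self.rcq_s)):
            raise DomainError("reference Cqs must be finite")

    @classmethod
    def cohort_mean(cls, cq_t: np.ndarray, cq_s: np.ndarray) -> "NormalizationReference":
        """Reference taken as the mean Cq of each assay over the whole cohort."""
        return cls(float(np.mean(cq_t)), float(np.mean(cq_s)), ReferenceSource.COHORT_MEAN)


def _positive_normal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal draws with non-positive values rejection-resampled.

    At the default parameterisation (e.g. Normal(1, 0.1)) the rejection
    probability is far below 1e-15, so the distribution is unaffected; the
    resampling guards the subsequent log2 for user-supplied extreme sigmas.
    """
    x = mean + sd * rng.standard_normal(size)
    bad = x <= 0
    while bad.any():
        x[bad] = mean + sd * rng.standard_normal(int(bad.sum()))
        bad = x <= 0
    return x


def generate_cohort(
    params: SimParams,
    rng: np.random.Generator,
    tl: np.ndarray | None = None,
) -> pd.DataFrame:
    """Draw the true per-individual quantities (tl, dna_s, dna_t).

    Parameters
    ----------
    params : SimParams
    rng : numpy Generator
    tl : array, optional
        Pre-existing true telomere lengths.  Supplying them redraws only the
        DNA sample, which is how repeated sampling of the same individuals
        (repeatability and longitudinal designs) is simulated.
    """
    params.validate()
    if tl is None:
        tl = _positive_normal(rng, 1.0, params.sigma_t, params.n)
    else:
        tl = np.asarray(tl, dtype=float)
        if tl.shape != (params.n,):
            raise DomainError(f"tl has shape {tl.shape}, expected ({params.n},)")
        if np.any(tl <= 0):
            raise DomainError("tl must be positive")
    dna_s = _positive_normal(rng, params.mu_s, params.sigma_s, params.n)
    dna_t = params.a * tl * dna_s
    return pd.DataFrame({"tl": tl, "dna_s": dna_s, "dna_t": dna_t})


def ideal_cqs(
    dna_t: np.ndarray, dna_s: np.ndarray, f: float
) -> tuple[np.ndarray, np.ndarray]:
    """Ideal (error-free) Cqs: ``icq = f - log2(dna)`` for each assay."""
    dna_t = np.asarray(dna_t, dtype=float)
    dna_s = np.asarray(dna_s, dtype=float)
    if np.any(dna_t <= 0) or np.any(dna_s <= 0):
        raise DomainError("DNA amounts must be strictly positive")
    return f - np.log2(dna_t), f - np.log2(dna_s)


def apply_measurement_error(
    icq_t: np.ndarray,
    icq_s: np.ndarray,
    params: SimParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Add replicate-averaged bivariate-normal noise to the ideal Cqs.

    Per technical replicate the error pair (eps_t, eps_s) is bivariate normal
    with SDs (sigma_eps_t, sigma_eps_s) and correlation rho_err; the k_reps
    replicate Cqs are averaged, so the effective error SD is sigma/sqrt(k).

    Returns ``(mcq_t, mcq_s, eps_t, eps_s)`` where the eps are the
    post-averaging realised errors.
    """
    params.validate()
    icq_t = np.asarray(icq_t, dtype=float)
    icq_s = np.asarray(icq_s, dtype=float)
    n, k = icq_t.shape[0], params.k_reps
    rho = params.rho_err
    z1 = rng.standard_normal((n, k))
    z2 = rng.standard_normal((n, k))
    eps_t_rep = params.sigma_eps_t * z1
    eps_s_rep = params.sigma_eps_s * (rho * z1 + np.sqrt(1.0 - rho * rho) * z2)
    eps_t = eps_t_rep.mean(axis=1)
    eps_s = eps_s_rep.mean(axis=1)
    return icq_t + eps_t, icq_s + eps_s, eps_t, eps_s


def ts_ratio(
    cq_t: np.ndarray, cq_s: np.ndarray, ref: NormalizationReference
) -> np.ndarray:
    """TS ratio from a pair of Cqs: ``2**-(cq_t - rcq_t - cq_s + rcq_s)``."""
    cq_t = np.asarray(cq_t, dtype=float)
    cq_s = np.asarray(cq_s, dtype=float)
    if not (np.all(np.isfinite(cq_t)) and np.all(np.isfinite(cq_s))):
        raise DomainError("Cq values must be finite")
    return np.exp2(-(cq_t - ref.rcq_t - cq_s + ref.rcq_s))


@dataclass
class CohortDataset:
    """A fully simulated cohort: true values, Cqs and TS ratios per individual.

    Attributes
    ----------
    frame : DataFrame
        Per-individual table with columns tl, dna_s, dna_t, icq_t, icq_s,
        eps_t, eps_s, mcq_t, mcq_s, its, mts.
    params : SimParams or None
    reference_ideal, reference_measured : NormalizationReference
        Cohort-mean references used for the ideal and measured TS ratios.
    """

    frame: pd.DataFrame
    params: SimParams | None = None
    reference_ideal: NormalizationReference | None = None
    reference_measured: NormalizationReference | None = None

    def __len__(self) -> int:
        return len(self.frame)

    def __getattr__(self, name: str):
        # Column access convenience: dataset.mts is frame["mts"].to_numpy().
        frame = self.__dict__.get("frame")
        if frame is not None and name in frame.columns:
            return frame[name].to_numpy()
        raise AttributeError(name)

    def to_csv(self, path: str | Path) -> None:
        """Serialise the per-individual table (full float precision)."""
        out = self.frame.copy()
        out.insert(0, "individual_id", np.arange(len(out)))
        out[CSV_COLUMNS].to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortDataset":
        frame = pd.read_csv(path)
        missing = [c for c in CSV_COLUMNS if c not in frame.columns]
        if missing:
            raise FormatError(f"cohort CSV missing column(s): {', '.join(missing)}")
        frame = frame[CSV_COLUMNS].drop(columns="individual_id")
        frame["eps_t"] = frame["mcq_t"] - frame["icq_t"]
        frame["eps_s"] = frame["mcq_s"] - frame["icq_s"]
        return cls(frame=frame)


def simulate_dataset(
    params: SimParams,
    rng: np.random.Generator | None = None,
    tl: np.ndarray | None = None,
    reference: NormalizationReference | None = None,
) -> CohortDataset:
    """Run the full generative chain and return a :class:`CohortDataset`.

    The ideal TS ratio uses the ideal-Cq cohort means as its reference, so it
    is error-free by construction; the measured TS ratio uses the measured-Cq
    cohort means (or ``reference`` if supplied, which only rescales it).
    Supplying ``tl`` holds the true telomere lengths fixed while redrawing
    the DNA sample and the measurement errors.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    cohort = generate_cohort(params, rng, tl=tl)
    icq_t, icq_s = ideal_cqs(cohort["dna_t"].to_numpy(), cohort["dna_s"].to_numpy(), params.f)
    mcq_t, mcq_s, eps_t, eps_s = apply_measurement_error(icq_t, icq_s, params, rng)
    ref_ideal = NormalizationReference.cohort_mean(icq_t, icq_s)
    ref_measured = reference or NormalizationReference.cohort_mean(mcq_t, mcq_s)
    its = ts_ratio(icq_t, icq_s, ref_ideal)
    mts = ts_ratio(mcq_t, mcq_s, ref_measured)
    frame = cohort.assign(
        icq_t=icq_t, icq_s=icq_s, eps_t=eps_t, eps_s=eps_s,
        mcq_t=mcq_t, mcq_s=mcq_s, its=its, mts=mts,
    )
    return CohortDataset(
        frame=frame,
        params=params,
        reference_ideal=ref_ideal,
        reference_measured=ref_measured,
    )
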