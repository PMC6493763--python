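"""Quality control from technical-replicate Cq tables.

Estimates the error sigma of each assay from replicate runs of the same
biological sample(s) — the quantity the simulator treats as an input — plus
the SD of replicate-group means and duplicate-run repeatability.  A fixture
generator produces synthetic tables in the same long format (one biological
sample run many times for the telomere and single-copy assays, optionally
with per-plate mean shifts).

The headline QC metric here is the within-sample Cq standard deviation, not
a coefficient of variation: CVs on the raw Cq scale are dominated by the
large Cq mean and make assays look far more precise than they are.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .error_metrics import ICCResult, cv_report, icc_consistency
from .exceptions import DomainError, FormatError, ParameterError

__all__ = [
    "TARGETS",
    "ErrorSigmaEstimate",
    "TriplicateMeanResult",
    "DuplicateIccResult",
    "read_replicate_table",
    "write_replicate_table",
    "validate_replicate_table",
    "estimate_error_sigma",
    "triplicate_mean_sd",
    "duplicate_ts_icc",
    "generate_fixture",
]

TARGETS = ("T", "S")
REQUIRED_COLUMNS = ["sample_id", "plate_id", "well_id", "target", "cq"]
_TARGET_ALIASES = {
    "T": "T",
    "S": "S",
    "TELOMERE": "T",
    "TEL": "T",
    "SINGLE-COPY": "S",
    "SINGLE_COPY": "S",
    "SCG": "S",
}

#: Repeatability benchmark commonly applied to duplicate-run ICCs.
ICC_BENCHMARK = 0.75


@dataclass(frozen=True)
class ErrorSigmaEstimate:
    """Error-sigma estimates for one target from replicate Cqs.

    ``sigma_pooled`` pools the within-sample variances with their
    (replicates - 1) degrees of freedom; ``sigma_pairwise`` is the RMS of
    all within-sample pairwise Cq differences divided by sqrt(2) — the
    pairs-of-replicates computation often quoted in reporting guidelines.
    The two coincide exactly for balanced data.
    """

    target: str
    sigma_pooled: float
    sigma_pairwise: float
    sigma_per_plate: dict[str, float]
    n_replicates: int


@dataclass(frozen=True)
class TriplicateMeanResult:
    target: str
    group_size: int
    n_groups: int
    group_mean_sd: float
    reduction_factor: float  # raw sigma estimate / group-mean SD; sqrt(k) if independent


@dataclass(frozen=True)
class DuplicateIccResult:
    icc_result: ICCResult
    below_benchmark: bool
    benchmark: float = ICC_BENCHMARK


def validate_replicate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a long-format replicate table."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"replicate table missing column(s): {', '.join(missing)}")
    table = table[REQUIRED_COLUMNS].copy()
    target = table["target"].astype(str).str.strip().str.upper().map(_TARGET_ALIASES)
    bad = table.index[target.isna()]
    if len(bad):
        row = int(bad[0])
        raise FormatError(
            f"row {row}: unrecognised target {table.loc[row, 'target']!r} "
            f"(expected one of T, S, telomere, single-copy)"
        )
    table["target"] = target
    cq = pd.to_numeric(table["cq"], errors="coerce")
    bad = table.index[~np.isfinite(cq) | (cq <= 0)]
    if len(bad):
        row = int(bad[0])
        raise FormatError(f"row {row}: cq must be a finite positive number, got {table.loc[row, 'cq']!r}")
    table["cq"] = cq.astype(float)
    dup = table.duplicated(subset=["plate_id", "well_id"])
    if dup.any():
        row = int(table.index[dup][0])
        raise FormatError(
            f"row {row}: duplicate (plate_id, well_id) = "
            f"({table.loc[row, 'plate_id']!r}, {table.loc[row, 'well_id']!r})"
        )
    return table


def read_replicate_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a replicate-Cq CSV (header required)."""
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if table.empty:
        raise FormatError(f"{path}: no data rows")
    return validate_replicate_table(table)


def write_replicate_table(table: pd.DataFrame, path: str | Path) -> None:
    table[REQUIRED_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def _within_sample_groups(table: pd.DataFrame, target: str) -> list[np.ndarray]:
    sub = table[table["target"] == target]
    groups = [g["cq"].to_numpy() for _, g in sub.groupby("sample_id", sort=True)]
    short = [
        str(sid)
        for (sid, g) in sub.groupby("sample_id", sort=True)
        if len(g) < 2
    ]
    if short:
        raise DomainError(
            f"target {target}: sample(s) with fewer than 2 replicates: {', '.join(short)}"
        )
    return groups


def _pooled_sd(groups: list[np.ndarray]) -> float:
    num = sum((len(g) - 1) * np.var(g, ddof=1) for g in groups)
    den = sum(len(g) - 1 for g in groups)
    return float(np.sqrt(num / den))


def _pairwise_sd(groups: list[np.ndarray]) -> float:
    # RMS over all within-sample pairs of (cq_i - cq_j) / sqrt(2); for one
    # group, sum over pairs of squared differences equals n*(n-1)*s^2.
    num = sum(len(g) * (len(g) - 1) * np.var(g, ddof=1) for g in groups)
    den = sum(len(g) * (len(g) - 1) for g in groups)
    return float(np.sqrt(num / den))


def estimate_error_sigma(table: pd.DataFrame) -> dict[str, ErrorSigmaEstimate]:
    """Estimate the per-target error sigma from a replicate table.

    Returns an :class:`ErrorSigmaEstimate` per target present, including
    per-plate estimates obtained by restricting to each plate.
    """
    table = validate_replicate_table(table)
    out: dict[str, ErrorSigmaEstimate] = {}
    for target in TARGETS:
        sub = table[table["target"] == target]
        if sub.empty:
            continue
        groups = _within_sample_groups(table, target)
        per_plate: dict[str, float] = {}
        for plate, plate_sub in sub.groupby("plate_id", sort=True):
            plate_groups = [
                g["cq"].to_numpy()
                for _, g in plate_sub.groupby("sample_id", sort=True)
                if len(g) >= 2
            ]
            if plate_groups:
                per_plate[str(plate)] = _pooled_sd(plate_groups)
        out[target] = ErrorSigmaEstimate(
            target=target,
            sigma_pooled=_pooled_sd(groups),
            sigma_pairwise=_pairwise_sd(groups),
            sigma_per_plate=per_plate,
            n_replicates=int(len(sub)),
        )
    if not out:
        raise DomainError("replicate table contains no rows for either target")
    return out


def triplicate_mean_sd(
    table: pd.DataFrame, group_size: int = 3
) -> dict[str, TriplicateMeanResult]:
    """SD of replicate-group means, grouping by well order within plate.

    Groups consecutive wells (input order within each plate and sample) into
    sets of ``group_size`` and reports the SD of the group means, together
    with the implied reduction factor relative to the raw sigma estimate.
    For independent replicates the factor approaches sqrt(group_size);
    plate-level mean shifts make replicates non-independent and pull the
    factor below that.
    """
    if group_size < 1:
        raise ParameterError(f"group_size must be >= 1, got {group_size}")
    table = validate_replicate_table(table)
    sigmas = estimate_error_sigma(table)
    out: dict[str, TriplicateMeanResult] = {}
    for target in TARGETS:
        sub = table[table["target"] == target]
        if sub.empty:
            continue
        means = []
        for (_, _), g in sub.groupby(["sample_id", "plate_id"], sort=True):
            cq = g["cq"].to_numpy()
            if len(cq) % group_size:
                raise DomainError(
                    f"target {target}: {len(cq)} replicates not divisible into groups of {group_size}"
                )
            means.append(cq.reshape(-1, group_size).mean(axis=1))
        means = np.concatenate(means)
        if means.size < 2:
            raise DomainError(f"target {target}: need at least 2 replicate groups")
        group_sd = float(np.std(means, ddof=1))
        raw = sigmas[target].sigma_pooled
        out[target] = TriplicateMeanResult(
            target=target,
            group_size=group_size,
            n_groups=int(means.size),
            group_mean_sd=group_sd,
            reduction_factor=raw / group_sd if group_sd > 0 else np.inf,
        )
    return out


def duplicate_ts_icc(ts_run1: np.ndarray, ts_run2: np.ndarray) -> DuplicateIccResult:
    """Consistency ICC between two duplicate runs of the same samples.

    Flags the result when the ICC falls below the conventional 0.75
    repeatability benchmark.
    """
    ts_run1 = np.asarray(ts_run1, dtype=float).ravel()
    ts_run2 = np.asarray(ts_run2, dtype=float).ravel()
    if ts_run1.shape != ts_run2.shape:
        raise DomainError("the two runs must have equal length")
    result = icc_consistency(np.column_stack([ts_run1, ts_run2]))
    return DuplicateIccResult(icc_result=result, below_benchmark=result.icc < ICC_BENCHMARK)


def default_plate_means(n_plates: int = 2, shift_s: float = 0.0) -> dict[str, dict[str, float]]:
    """Per-plate central Cqs mirroring a typical telomere/single-copy run.

    Central values follow the simulator's defaults (telomere Cq ~ 14.7,
    single-copy Cq ~ 24.7).  ``shift_s`` offsets the single-copy mean of
    successive plates, emulating the plate-to-plate shift (bimodality) seen
    in real replicate data.
    """
    return {
        f"plate{i + 1}": {"T": 14.71, "S": 24.68 + i * shift_s} for i in range(n_plates)
    }


def generate_fixture(
    n_replicates: int = 576,
    sigma_t_assay: float = 0.053,
    sigma_s_assay: float = 0.095,
    plate_means: dict[str, dict[str, float]] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Synthetic replicate table: one biological sample run many times.

    Emulates a large replicate study: ``n_replicates`` wells per target,
    split evenly over the plates, with ``cq = plate_mean[target] + Normal(0,
    sigma_target)``.  The default sigmas (0.053 telomere, 0.095 single-copy)
    are the within-sample Cq SDs typical of careful human qPCR replicate
    data.  Deterministic given the seed.
    """
    if n_replicates < 2:
        raise ParameterError(f"n_replicates must be >= 2, got {n_replicates}")
    if sigma_t_assay < 0 or sigma_s_assay < 0:
        raise ParameterError("assay sigmas must be >= 0")
    if plate_means is None:
        plate_means = default_plate_means()
    for plate, means in plate_means.items():
        if set(means) != set(TARGETS):
            raise ParameterError(f"plate {plate!r} must give central Cqs for both targets T and S")
    rng = np.random.default_rng(seed)
    plates = sorted(plate_means)
    counts = np.full(len(plates), n_replicates // len(plates))
    counts[: n_replicates % len(plates)] += 1
    sigma = {"T": sigma_t_assay, "S": sigma_s_assay}
    rows = []
    for plate, count in zip(plates, counts):
        well = 0
        for target in TARGETS:
            centre = plate_means[plate][target]
            cqs = centre + sigma[target] * rng.standard_normal(int(count))
            for cq in cqs:
                well += 1
                rows.append(
                    {
                        "sample_id": "sample1",
                        "plate_id": plate,
                        "well_id": f"W{well:04d}",
                        "target": target,
                        "cq": float(cq),
                    }
                )
    return pd.DataFrame(rows, columns=REQUIRED_COLUMNS)


def qc_report(table: pd.DataFrame, include_cv: bool = False) -> dict:
    """Flat QC summary (JSON-ready) for a replicate table.

    Reports per-target sigma estimates; CVs are included only on request
    because raw-Cq CVs systematically understate measurement error.
    """
    table = validate_replicate_table(table)
    sigmas = estimate_error_sigma(table)
    report: dict = {"targets": {}}
    for target, est in sigmas.items():
        entry = {
            "sigma_pooled": est.sigma_pooled,
            "sigma_pairwise": est.sigma_pairwise,
            "sigma_per_plate": est.sigma_per_plate,
            "n_replicates": est.n_replicates,
        }
        if include_cv:
            cv = cv_report(table.loc[table["target"] == target, "cq"].to_numpy())
            entry["cv_on_cq"] = cv.cv_on_cq
            entry["cv_on_linear"] = cv.cv_on_linear
            entry["cv_warning"] = (
                "CVs on the raw Cq scale understate measurement error; "
                "prefer the Cq standard deviations above."
            )
        report["targets"][target] = entry
    return report
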