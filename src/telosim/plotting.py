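"""Optional matplotlib views of the experiment results.

Plots are conveniences for inspection; all quantitative results come from
the experiment tables themselves.
"""

from __future__ import annotations

import numpy as np

from .experiments import CrossoverResult, DistributionStudyResult, LongitudinalResult, SweepResult

__all__ = [
    "plot_error_distributions",
    "plot_repeatability_surface",
    "plot_crossover",
    "plot_longitudinal_pair",
]

_LABELS = {"cq_t": "telomere Cq error", "cq_s": "single-copy Cq error", "ts": "TS ratio error"}


def plot_error_distributions(data, result: DistributionStudyResult, axes=None):
    """Histograms of the three scaled error vectors (one panel each)."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(1, 3, figsize=(10, 3), sharey=True)
    errors = {
        "cq_t": (data.mcq_t - data.icq_t) / np.std(data.icq_t, ddof=1),
        "cq_s": (data.mcq_s - data.icq_s) / np.std(data.icq_s, ddof=1),
        "ts": (data.mts - data.its) / np.std(data.its, ddof=1),
    }
    for ax, (key, err) in zip(axes, errors.items()):
        ax.hist(err, bins=60, color="0.4")
        ax.set_xlabel(f"{_LABELS[key]} (ideal SDs)")
        ax.set_title(f"scaled SD = {result.scaled_sd[key]:.2f}")
    return axes


def plot_repeatability_surface(sweep: SweepResult, ax=None):
    """Heatmap of ICC(mTS) over the (sigma_eps_t, sigma_eps_s) grid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pivot = sweep.table.pivot(index="sigma_eps_t", columns="sigma_eps_s", values="icc_mts")
    mesh = ax.pcolormesh(pivot.columns, pivot.index, pivot.to_numpy(), vmin=0, vmax=1)
    ax.figure.colorbar(mesh, ax=ax, label="ICC of measured TS")
    ax.set_xlabel(r"$\sigma_{\epsilon s}$")
    ax.set_ylabel(r"$\sigma_{\epsilon t}$")
    return ax


def plot_crossover(result: CrossoverResult, ax=None):
    """ICC of the TS ratio and of the raw telomere Cq vs single-copy error."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = result.table
    ax.plot(t["sigma_eps_s"], t["icc_mts"], "o-", color="black", label="measured TS")
    ax.plot(t["sigma_eps_s"], t["icc_mcq_t"], "o-", color="tab:red", label="raw telomere Cq")
    if np.isfinite(result.crossover_sigma):
        ax.axvline(result.crossover_sigma, ls=":", color="0.5")
    ax.set_xlabel(r"$\sigma_{\epsilon s}$")
    ax.set_ylabel("ICC")
    ax.legend()
    return ax


def plot_longitudinal_pair(result: LongitudinalResult, ax=None):
    """Time-2 vs time-1 measured TS under the no-change null, with y = x."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(result.mts_t1, result.mts_t2, ".", ms=2, alpha=0.4)
    lims = [min(result.mts_t1.min(), result.mts_t2.min()), max(result.mts_t1.max(), result.mts_t2.max())]
    ax.plot(lims, lims, "k--", lw=1, label="y = x")
    ax.set_xlabel("measured TS, time 1")
    ax.set_ylabel("measured TS, time 2")
    ax.set_title(f"r12 = {result.r12:.2f}")
    ax.legend()
    return ax
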