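"""Publication-style plots for longitudinal cohort summaries.

Matplotlib figure builders; callers save or show the returned figure.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_cohort_timecourse", "plot_lndlf_vs_vvd"]


def plot_cohort_timecourse(summary: pd.DataFrame, metric_label: str,
                           ax=None):
    """Mean ± SD of a normalized metric versus time, one line per dose
    cohort (the standard dose–response time-course layout).

    ``summary`` is the output of
    :func:`svoct.longitudinal.cohort_summary`.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for dose, grp in summary.groupby("dose_Gy"):
        grp = grp.sort_values("day")
        ax.errorbar(grp["day"], grp["mean"], yerr=grp["sd"],
                    marker="o", capsize=3, label=f"{dose:g} Gy")
    ax.set_xlabel("time post-irradiation (days)")
    ax.set_ylabel(metric_label)
    ax.legend(title="dose")
    return ax.figure


def plot_lndlf_vs_vvd(df: pd.DataFrame, r_c: float = 15.0,
                      threshold: float = 150.0, ax=None):
    """Scatter of ln DLF versus VVD with the Poisson parallel-cylinder
    reference line ln DLF = −(Λ/r_c)²·VVD.

    ``df`` needs columns ``VVD`` and ``DLF`` (one row per
    tumour/timepoint).  Departures from the line indicate architectural
    inhomogeneity beyond a random cylinder array.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(df["VVD"], np.log(df["DLF"]), s=25)
    x = np.linspace(0, float(df["VVD"].max()) * 1.05, 50)
    ax.plot(x, -((threshold / r_c) ** 2) * x, "k--",
            label=rf"Poisson cylinders, $r_c$={r_c:g} μm")
    ax.set_xlabel("VVD")
    ax.set_ylabel(rf"ln DLF$_{{{threshold:g}}}$")
    ax.legend()
    return ax.figure
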