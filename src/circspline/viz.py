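"""Optional matplotlib helpers (install the ``plot`` extra).

Each function returns the Axes so callers can restyle or save; nothing here
is needed for fitting or diagnostics tables.
"""

from __future__ import annotations

import numpy as np

from . import lmm, models
from .profiles import average_curve


def _clock_ticks(ax):
    ticks = np.arange(0, 49, 8)
    ax.set_xticks(ticks)
    ax.set_xticklabels([f"{int((12 + t / 2) % 24):02d}:00" for t in ticks])
    ax.set_xlabel("clock time")


def plot_average_curve(profiles, bin_width=1.0, ax=None):
    """Cohort mean BP by time bin — the knot-exploration plot."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    curve = average_curve(profiles, bin_width)
    ax.plot(curve["midpoint"], curve["mean"], "o-", ms=3)
    ax.set_ylabel("mean BP (mmHg)")
    _clock_ticks(ax)
    return ax


def plot_population(cfit: models.CircadianFit, groups=(0,), group_name=None, ax=None,
                    wake=40.0, sleep=22.0):
    """Population trajectory with 95% CI at display knots, per group level."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for g in groups:
        covs = {group_name: g} if group_name else None
        traj = models.predict_population(cfit, wake=wake, sleep=sleep, covariate_values=covs)
        label = f"{group_name}={g}" if group_name else "population"
        (line,) = ax.plot(traj["t"], traj["mean"], label=label)
        ax.fill_between(traj["t"], traj["lo"], traj["hi"], alpha=0.2, color=line.get_color())
    ax.set_ylabel("BP (mmHg)")
    ax.legend()
    _clock_ticks(ax)
    return ax


def plot_subjects(cfit: models.CircadianFit, subject_ids, ax=None):
    """Spaghetti plot: observed readings + EBLUP trajectories per subject."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for sid in subject_ids:
        block = next(b for b in cfit.data.blocks if b.subject_id == sid)
        traj = models.predict_subject(cfit, sid)
        ax.plot(block.slots, block.y, ".", alpha=0.4)
        ax.plot(traj["t"], traj["value"], label=sid)
    ax.set_ylabel("BP (mmHg)")
    ax.legend(fontsize="small")
    _clock_ticks(ax)
    return ax


def plot_acf(cfit: models.CircadianFit, max_lag=10, ax=None):
    """ACF of pre-whitened residuals with an approximate white-noise band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    table = lmm.residual_acf(cfit.fitted, cfit.data, max_lag)
    ax.stem(table["lag"], table["acf"])
    n = cfit.data.n_obs
    band = 1.96 / np.sqrt(n)
    ax.axhspan(-band, band, alpha=0.15)
    ax.set_xlabel("lag (30-min slots)")
    ax.set_ylabel("ACF")
    return ax


def plot_vpc(cfit: models.CircadianFit, nsim=200, seed=0, ax=None):
    """Visual predictive check: simulated band vs observed quantiles."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    table = lmm.vpc(cfit.fitted, cfit.data, nsim=nsim, seed=seed)
    ax.plot(table["slot"], table["sim_mean"], label="simulated mean")
    ax.fill_between(table["slot"], table["sim_lo"], table["sim_hi"], alpha=0.2,
                    label="simulated 5-95%")
    ax.plot(table["slot"], table["obs_lo"], "k--", lw=1, label="observed 5/95%")
    ax.plot(table["slot"], table["obs_hi"], "k--", lw=1)
    ax.set_ylabel("BP (mmHg)")
    ax.legend(fontsize="small")
    _clock_ticks(ax)
    return ax
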