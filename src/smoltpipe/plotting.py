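"""Optional matplotlib renderings of the headline figures."""

from __future__ import annotations

import pandas as pd


def plot_probability_curves(curves: pd.DataFrame, ax=None):
    """Predicted probability of smoltification vs weight per genotype,
    with shaded 95% credible bands.

    ``curves`` is the output of :func:`smoltpipe.model.predict_probability`
    concatenated over genotypes (columns genotype, weight, prob, lo, hi).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for genotype, sub in curves.groupby("genotype", sort=True):
        (line,) = ax.plot(sub["weight"], sub["prob"], label=genotype)
        ax.fill_between(sub["weight"], sub["lo"], sub["hi"], alpha=0.2, color=line.get_color())
    ax.set_xlabel("weight at smoltification (g)")
    ax.set_ylabel("P(smoltification)")
    ax.set_ylim(0, 1)
    ax.legend(title="genotype")
    return ax


def plot_expression_bars(rq: pd.DataFrame, ax=None):
    """Mean relative expression (RQ) per strain x timepoint with SEM bars."""
    import matplotlib.pyplot as plt
    import numpy as np

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    grouped = rq.groupby(["strain", "timepoint"])["rq"]
    means = grouped.mean()
    sems = grouped.sem()
    labels = [f"{s}\n{t}" for s, t in means.index]
    ax.bar(np.arange(len(means)), means.values, yerr=sems.values, capsize=3)
    ax.set_xticks(np.arange(len(means)), labels)
    ax.set_ylabel("relative expression (2$^{-\\Delta\\Delta Ct}$)")
    return ax
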