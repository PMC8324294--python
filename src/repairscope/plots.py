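"""Small plotting helpers for the three analyses (matplotlib)."""

from __future__ import annotations

import numpy as np


def plot_d_app_histogram(d_values, ax=None, bins=None):
    """Log-spaced histogram of apparent diffusion coefficients with the
    immobile/slow/fast class boundaries marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    d = np.asarray(d_values, dtype=float)
    if bins is None:
        bins = np.logspace(-4, 1, 51)
    ax.hist(d, bins=bins, color="0.6")
    for edge in (0.01, 0.1):
        ax.axvline(edge, color="k", ls="--", lw=0.8)
    ax.set_xscale("log")
    ax.set_xlabel(r"apparent D ($\mu m^2/s$)")
    ax.set_ylabel("tracklets")
    return ax


def plot_solidity_histogram(solidities, ax=None):
    """Solidity distribution with the standard 0.05-wide bins."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.hist(np.asarray(solidities, dtype=float), bins=np.arange(0, 1.0001, 0.05), color="0.6")
    ax.set_xlabel("solidity")
    ax.set_ylabel("particles")
    return ax


def plot_foci_counts(counts_by_condition: dict, ax=None):
    """Box plot of foci per nucleus for each condition."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    names = list(counts_by_condition)
    ax.boxplot([np.asarray(counts_by_condition[k]) for k in names], tick_labels=names)
    ax.set_ylabel("foci per nucleus")
    return ax
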