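"""Minimal plotting helpers for experiment error tables."""

from __future__ import annotations

import pandas as pd


def plot_error_curves(table: pd.DataFrame, offset_value=None, ax=None):
    """Expected-error-vs-n curves per classifier and kappa, one offset at a time.

    Returns the matplotlib axis. The plug-in Bayes error appears as a dashed
    reference line.
    """
    import matplotlib.pyplot as plt

    if offset_value is None:
        offset_value = table["offset_value"].iloc[0]
    sub = table[table["offset_value"] == offset_value]
    if ax is None:
        _, ax = plt.subplots()
    for (kind, kappa), grp in sub.groupby(["classifier", "kappa"]):
        grp = grp.sort_values("n")
        ax.errorbar(
            grp["n"], grp["mean_error"], yerr=grp["mc_se"],
            marker="o", capsize=2, label=f"{kind}, kappa={kappa:.0f}",
        )
    bayes = sub.sort_values("n").groupby("n")["bayes_error"].mean()
    ax.plot(bayes.index, bayes.values, "k--", label="Bayes (plug-in)")
    name = sub["offset_name"].iloc[0]
    ax.set_xlabel("training paths per class (n)")
    ax.set_ylabel("expected true error")
    ax.set_title(f"{name} = {offset_value}")
    ax.legend(fontsize=8)
    return ax
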