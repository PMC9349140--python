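"""Minimal plots: tornado diagram and CEAC/CEAF curves."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_tornado(owsa: "pd.DataFrame", top: int = 10, ax=None):
    """Horizontal tornado bars of % departure from the base-case ICUR."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 0.5 * top + 1))
    df = owsa.head(top).iloc[::-1]
    y = np.arange(len(df))
    ax.barh(y, df["pct_departure_high"], color="#c44e52", label="upper limit")
    ax.barh(y, df["pct_departure_low"], color="#4c72b0", label="lower limit")
    ax.set_yticks(y)
    ax.set_yticklabels(df["parameter"])
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("% departure from base-case ICUR")
    ax.legend(loc="lower right", fontsize=8)
    return ax


def plot_ceac(ceac_df, ceaf_df=None, ax=None):
    """CEAC per strategy, with the frontier overlaid when given."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    wtp = ceac_df["wtp"]
    for col in ceac_df.columns:
        if col == "wtp":
            continue
        ax.plot(wtp, ceac_df[col], label=f"CEAC {col}")
    if ceaf_df is not None:
        ax.plot(ceaf_df["wtp"], ceaf_df["probability"], "k--", lw=1.2,
                label="CEAF")
    ax.set_xlabel("willingness to pay (€ per QALY)")
    ax.set_ylabel("probability cost-effective")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    return ax
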