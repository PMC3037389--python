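"""Convenience plots (no test weight): cytometry-style scatters and the
cyclin limit cycle.  Requires matplotlib (``pip install hybridcycle[plot]``)."""

from __future__ import annotations

import numpy as np
import pandas as pd

_STATE_COLORS = {
    1: "#999999", 2: "#1f77b4", 3: "#17becf", 4: "#2ca02c",
    5: "#bcbd22", 6: "#ff7f0e", 7: "#d62728", 8: "#9467bd", 9: "#8c564b",
}


def scatter_dna_vs_cyclin(events: pd.DataFrame, cyclin: str = "A", ax=None,
                          dna_gain: float = 190.0):
    """DNA content vs measured total cyclin, colored by model state.

    ``dna_gain`` rescales the 1..2 DNA axis to an instrument-like axis
    (190 -> G1, 380 -> G2/M); presentation only, never used in statistics.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    colors = events["state"].map(_STATE_COLORS)
    ax.scatter(events["dna_meas"] * dna_gain, events[f"cyc{cyclin}_meas"],
               s=1, c=colors, alpha=0.4, linewidths=0)
    ax.set_xlabel("DNA content (a.u.)")
    ax.set_ylabel(f"total cyclin {cyclin} (a.u.)")
    return ax


def cyclin_loop(events: pd.DataFrame, ax=None, bins: int = 100):
    """Cyclin B vs cyclin A scatter with binned-mean loop over the cycle."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(events["cycA_meas"], events["cycB_meas"], s=1,
               c=events["state"].map(_STATE_COLORS), alpha=0.3, linewidths=0)
    grp = events.groupby(np.minimum((events["phi"] * bins).astype(int), bins - 1))
    ax.plot(grp["cycA_true"].mean(), grp["cycB_true"].mean(),
            "o-", color="goldenrod", ms=3, lw=1)
    ax.set_xlabel("total cyclin A (a.u.)")
    ax.set_ylabel("total cyclin B (a.u.)")
    return ax
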