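"""Plots: per-chromosome association profiles and state-wise survival curves."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_scan_profile", "plot_km"]


def plot_scan_profile(scan, profiles, threshold=2.0, ax=None):
    """-log10 p per marker (dots) with the fused-lasso smooth (line).

    ``scan`` is a MarkerScanResult, ``profiles`` a list of SmoothedProfile.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    y = scan.neglog10p
    ax.plot(scan.pos_bp, y, ".", ms=2, color="black", alpha=0.5,
            label="marker")
    for prof in profiles:
        idx = prof.marker_idx
        ax.plot(scan.pos_bp[idx], prof.f, "-", color="crimson", lw=1.5)
    ax.axhline(threshold, color="grey", ls="--", lw=0.8)
    ax.set_xlabel("position (bp)")
    ax.set_ylabel(r"$-\log_{10} p$")
    return ax


def plot_km(curves, ax=None, labels={-1: "loss", 0: "normal", 1: "gain"}):
    """Step plot of delayed-entry Kaplan-Meier curves per copy state."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for state, (t, s) in curves.items():
        tt = np.concatenate([[0.0], t])
        ss = np.concatenate([[1.0], s])
        ax.step(tt, ss, where="post", label=labels.get(state, str(state)))
    ax.set_xlabel("days from diagnosis")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    return ax
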