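"""Quick-look figures for traces and event tables."""

from __future__ import annotations

import numpy as np

from cuproforce.polymer import PolymerModel, wlc_force

__all__ = ["plot_trace"]


def plot_trace(trace, table=None, ax=None, fit_persistence_length: float = 0.4):
    """Force-extension sawtooth with optional detected events and WLC fits.

    Parameters
    ----------
    trace : ForceExtensionTrace
    table : EventTable, optional
        Detected events; peaks are marked and each fitted contour length is
        drawn as a WLC curve through its rising edge.
    ax : matplotlib Axes, optional

    Returns
    -------
    matplotlib Axes
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.5))
    ax.plot(trace.extension, trace.force, lw=0.5, color="0.4")
    if table is not None:
        for ev in table.events:
            ax.plot(ev.extension, ev.rupture_force, "v", color="C3", ms=5)
            if ev.contour_length:
                model = PolymerModel(ev.contour_length, fit_persistence_length)
                xs = np.linspace(0.2 * ev.contour_length,
                                 min(ev.extension, 0.99 * ev.contour_length), 80)
                ax.plot(xs, wlc_force(xs, model), "--", lw=0.8, color="C0")
    ax.set_xlabel("extension (nm)")
    ax.set_ylabel("force (pN)")
    ax.set_ylim(bottom=min(0.0, float(np.min(trace.force))))
    return ax
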