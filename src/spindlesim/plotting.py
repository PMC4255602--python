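"""Minimal figures for experiment results (length, rates, rasters)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .experiments import ExperimentResult

__all__ = ["plot_experiment"]


def plot_experiment(result: ExperimentResult):
    """Stacked panels: stretch waveform, Ia/II rate traces, spike rasters."""
    n_rasters = len(result.rasters)
    fig, axes = plt.subplots(2 + n_rasters, 1, figsize=(8, 6 + 1.5 * n_rasters),
                             sharex=True)
    t = result.time_ms / 1000.0
    axes[0].plot(t, result.waveform.samples, "k")
    axes[0].set_ylabel("length (L0)")
    axes[0].set_title(result.label)
    axes[1].plot(t, result.ia_rate, label="Ia")
    axes[1].plot(t, result.ii_rate, label="II")
    axes[1].set_ylabel("rate (Hz)")
    axes[1].legend(loc="upper right", frameon=False)
    for ax, (group, raster) in zip(axes[2:], result.rasters.items()):
        ax.plot(raster.times_ms / 1000.0, raster.neuron_ids, ".", ms=1)
        ax.set_ylabel(f"{group} neuron")
    axes[-1].set_xlabel("time (s)")
    fig.tight_layout()
    return fig
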