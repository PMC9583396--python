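"""Rendering of time-frequency coherence maps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .coherence import CoherenceResult


def plot_coherence_map(
    result: CoherenceResult,
    path=None,
    significant_only: bool = True,
    band: tuple[float, float] | None = None,
):
    """Plot the MSC map (optionally masked to significant cells) against time
    relative to peak velocity; returns the matplotlib figure."""
    msc = result.msc
    values = np.where(result.mask.values, msc.values, 0.0) if significant_only else msc.values
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.pcolormesh(msc.times, msc.freqs, values, shading="auto", cmap="magma", vmin=0)
    if band:
        for f in band:
            ax.axhline(f, color="w", ls="--", lw=0.8)
    ax.axvline(0.0, color="c", lw=0.8)
    ax.set_xlabel("time relative to peak velocity (s)")
    ax.set_ylabel("frequency (Hz)")
    ax.set_title(f"wavelet MSC {result.pair} (K={msc.n_trials})")
    fig.colorbar(im, ax=ax, label="coherence")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
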