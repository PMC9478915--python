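"""Plotting helper for visual inspection of tracking results."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .spectral import SpectrogramStack, to_decibel
from .tracker import IdentityTrace


def plot_traces(traces: list[IdentityTrace],
                stack: SpectrogramStack | None = None,
                freq_range: tuple[float, float] | None = None,
                path: str | None = None):
    """Render identity traces, optionally over the summed log spectrogram.

    Returns the matplotlib figure; saves to ``path`` when given.
    """
    fig, ax = plt.subplots(figsize=(10, 5))
    if stack is not None:
        level = to_decibel(stack.summed_psd)
        ax.pcolormesh(stack.time_axis, stack.freq_axis, level,
                      shading="nearest", cmap="viridis", rasterized=True)
    for tr in traces:
        times = [d.time for d in tr.detections]
        freqs = [d.eodf for d in tr.detections]
        ax.plot(times, freqs, ".-", ms=3, lw=1, label=f"id {tr.identity_id}")
    if freq_range is not None:
        ax.set_ylim(*freq_range)
    elif traces:
        freqs = np.concatenate([[d.eodf for d in tr.detections] for tr in traces])
        ax.set_ylim(freqs.min() - 5, freqs.max() + 5)
    ax.set_xlabel("time [s]")
    ax.set_ylabel("EOD frequency [Hz]")
    if len(traces) <= 12:
        ax.legend(fontsize="small")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
    return fig
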