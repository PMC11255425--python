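"""Pseudocolor rendering of voltammogram streams.

The standard FSCV display: time on the x axis, applied potential on the y
axis (unfolded scan sample index), current as color.  Dopamine transients
appear as a band at the oxidation potential with a mirrored reduction band
on the falling limb.
"""

from __future__ import annotations

import numpy as np

from .raw_io import ScanStream

__all__ = ["pseudocolor_plot"]


def pseudocolor_plot(
    stream: ScanStream,
    ax=None,
    cmap: str = "viridis",
    clim_percentile: float = 99.0,
    stim_window: "tuple[float, float] | None" = None,
):
    """Render one channel's (preprocessed) stream as a pseudocolor plot.

    ``stim_window`` draws a box marking stimulation onset and end.  Returns
    the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    lim = np.percentile(np.abs(stream.scans), clim_percentile)
    extent = (
        float(stream.scan_times[0]),
        float(stream.scan_times[-1]),
        0,
        stream.waveform.samples_per_scan,
    )
    im = ax.imshow(
        stream.scans.T,
        aspect="auto",
        origin="lower",
        extent=extent,
        cmap=cmap,
        vmin=-lim,
        vmax=lim,
    )
    if stim_window is not None:
        from matplotlib.patches import Rectangle

        ax.add_patch(
            Rectangle(
                (stim_window[0], 0),
                stim_window[1] - stim_window[0],
                stream.waveform.samples_per_scan,
                fill=False,
                edgecolor="red",
                linewidth=1.5,
            )
        )
    ax.set_xlabel("time (s)")
    ax.set_ylabel("scan sample (potential step)")
    ax.set_title(f"channel {stream.channel_id}")
    ax.figure.colorbar(im, ax=ax, label="current (nA)")
    return ax
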