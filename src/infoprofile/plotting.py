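"""Static profile figures: whole-sequence panel plus optional zooms.

Kept separate from the engine so the core library never imports
matplotlib.  The Agg backend is forced, making figure generation
deterministic and headless-safe.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .engine import ProfileSamples

__all__ = ["plot_profile"]


def _axis_scale(max_pos: int) -> tuple[float, str]:
    if max_pos >= 2_000_000:
        return 1e6, "position (Mb)"
    if max_pos >= 2_000:
        return 1e3, "position (kb)"
    return 1.0, "position (bp)"


def _draw(ax, samples: ProfileSamples, lo: int, hi: int, color="C0", label=None):
    sel = (samples.positions >= lo) & (samples.positions <= hi)
    pos = samples.positions[sel]
    val = samples.values[sel]
    scale, xlabel = _axis_scale(hi)
    ax.plot(pos / scale, val, lw=0.6, color=color, label=label)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("information (bits)")
    ax.set_xlim(lo / scale, hi / scale)


def plot_profile(
    samples: ProfileSamples | Sequence[ProfileSamples],
    out_path,
    zooms: Sequence[tuple[int, int]] = (),
    title: str | None = None,
    labels: Sequence[str] | None = None,
    dpi: int = 150,
) -> None:
    """Render a profile (or overlay of profiles) to an image file.

    ``zooms`` are 1-based inclusive (start, end) base ranges; each adds a
    panel below the whole-sequence one.  Ranges beyond the sequence are
    clipped with a warning.  Output format follows the file extension
    (PNG, SVG, PDF).
    """
    tracks = [samples] if isinstance(samples, ProfileSamples) else list(samples)
    if not tracks or any(t.positions.size == 0 for t in tracks):
        raise ValueError("cannot plot an empty profile")
    length = max(
        int(t.sequence_length) or int(t.positions[-1]) for t in tracks
    )
    panels = []
    for lo, hi in zooms:
        if lo > length or hi < 1 or lo > hi:
            warnings.warn(f"zoom range ({lo}, {hi}) outside sequence; skipped")
            continue
        clipped = (max(1, lo), min(length, hi))
        if clipped != (lo, hi):
            warnings.warn(f"zoom range ({lo}, {hi}) clipped to {clipped}")
        panels.append(clipped)

    n_panels = 1 + len(panels)
    fig, axes = plt.subplots(
        n_panels, 1, figsize=(10, 2.6 * n_panels), squeeze=False
    )
    for i, (lo, hi) in enumerate([(1, length)] + panels):
        ax = axes[i][0]
        for j, track in enumerate(tracks):
            label = labels[j] if labels else None
            _draw(ax, track, lo, hi, color=f"C{j}", label=label)
        if i > 0:
            ax.set_title(f"zoom {lo:,}-{hi:,} bp", fontsize=9)
    if labels:
        axes[0][0].legend(loc="upper right", fontsize=8)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=dpi)
    plt.close(fig)
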