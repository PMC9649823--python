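"""Minimal probability-overlay export.

Renders one axial slice of a CT volume in grayscale with the per-voxel
foreground probability overlaid as a transparent heat map — the quick-look
artifact for inspecting where the segmentation is confident. Plumbing only;
no styling options beyond the essentials.
"""
from __future__ import annotations

import numpy as np

from .errors import ParameterError
from .imaging import CTVolume
from .nn.infer import ProbabilityMap

__all__ = ["export_probability_overlay"]


def export_probability_overlay(vol: CTVolume, prob: ProbabilityMap, path,
                               slice_index: int | None = None,
                               channels=None, alpha: float = 0.5) -> int:
    """Write a PNG of one axial slice with the foreground probability overlay.

    ``channels`` selects which probability channels form the overlay
    (default: all foreground channels, summed). ``slice_index`` defaults to
    the slice with the highest total foreground probability. Returns the
    slice index rendered.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if vol.shape != prob.probs.shape[1:]:
        raise ParameterError("volume and probability map grids differ")
    channels = list(range(1, prob.probs.shape[0])) if channels is None else list(channels)
    fg = prob.probs[channels].sum(axis=0)
    if slice_index is None:
        slice_index = int(np.argmax(fg.sum(axis=(1, 2))))
    if not (0 <= slice_index < vol.shape[0]):
        raise ParameterError(f"slice index {slice_index} outside the volume")

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(vol.voxels[slice_index], cmap="gray", interpolation="nearest")
    overlay = np.ma.masked_less(fg[slice_index], 0.05)
    im = ax.imshow(overlay, cmap="jet", vmin=0.0, vmax=1.0, alpha=alpha,
                   interpolation="nearest")
    fig.colorbar(im, ax=ax, fraction=0.046, label="foreground probability")
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)
    return slice_index
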