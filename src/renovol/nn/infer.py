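"""Sliding-window inference and probability decoding."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ParameterError
from ..imaging import ClassScheme, LabelMap
from .autograd import Tensor, no_grad

__all__ = ["ProbabilityMap", "sliding_window_probabilities", "predict_probabilities", "probabilities_to_labels"]


@dataclass(frozen=True)
class ProbabilityMap:
    """Per-class soft prediction grid; channel axis first, values in [0, 1]."""

    probs: np.ndarray  # (C, nz, ny, nx)
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        p = np.asarray(self.probs)
        if p.ndim != 4:
            raise ParameterError("probability map must be (C, z, y, x)")
        object.__setattr__(self, "probs", p)


def _window_starts(size, patch, stride):
    if size <= patch:
        return [0]
    starts = list(range(0, size - patch + 1, stride))
    if starts[-1] != size - patch:
        starts.append(size - patch)
    return starts


def sliding_window_probabilities(net, volume: np.ndarray, overlap: float = 0.5) -> np.ndarray:
    """Run the network over a (z, y, x) grid with overlapping windows.

    Windows are the network's input patch, shifted by ``patch * (1-overlap)``
    (default 50% overlap); overlapping softmax outputs are averaged
    uniformly. Volumes smaller than the patch are zero-padded at the caudal/
    right/ventral end and the padding is cropped from the result. Per-voxel
    class probabilities sum to 1.
    """
    cfg = net.cfg
    patch = tuple(cfg.patch_size)
    orig_shape = volume.shape
    pad = [max(0, p - s) for p, s in zip(patch, orig_shape)]
    if any(pad):
        volume = np.pad(volume, [(0, p) for p in pad])
    shape = volume.shape
    stride = [max(1, int(round(p * (1.0 - overlap)))) for p in patch]

    probs = np.zeros((cfg.out_channels, *shape), dtype=np.float64)
    counts = np.zeros(shape, dtype=np.float64)
    net.eval()
    with no_grad():
        for z0 in _window_starts(shape[0], patch[0], stride[0]):
            for y0 in _window_starts(shape[1], patch[1], stride[1]):
                for x0 in _window_starts(shape[2], patch[2], stride[2]):
                    sl = (slice(z0, z0 + patch[0]), slice(y0, y0 + patch[1]), slice(x0, x0 + patch[2]))
                    win = volume[sl].astype(np.float32)[None]
                    logits = net(Tensor(win)).data.astype(np.float64)
                    e = np.exp(logits - logits.max(axis=0, keepdims=True))
                    sm = e / e.sum(axis=0, keepdims=True)
                    probs[(slice(None),) + sl] += sm
                    counts[sl] += 1.0
    probs /= counts[None]
    if any(pad):
        probs = probs[:, : orig_shape[0], : orig_shape[1], : orig_shape[2]]
    return probs


def predict_probabilities(checkpoint, vol, overlap: float = 0.5) -> ProbabilityMap:
    """Sliding-window inference from a checkpoint on a preprocessed volume.

    ``vol`` must already be resampled and normalized to [0, 1].
    """
    from .train import restore_network  # local import to avoid a cycle

    v = vol.voxels
    if v.min() < -1e-6 or v.max() > 1.0 + 1e-6:
        raise ParameterError("volume must be normalized to [0, 1] before inference")
    net = restore_network(checkpoint)
    probs = sliding_window_probabilities(net, v, overlap=overlap)
    return ProbabilityMap(probs, vol.spacing, vol.origin)


def probabilities_to_labels(prob: ProbabilityMap, scheme: ClassScheme | None = None) -> LabelMap:
    """Per-voxel argmax decoding; ties break toward the lowest class id."""
    scheme = scheme or ClassScheme.model_output()
    if prob.probs.shape[0] != len(scheme.class_ids):
        raise ParameterError(
            f"probability map has {prob.probs.shape[0]} channels but the scheme "
            f"declares {len(scheme.class_ids)} classes"
        )
    labels = np.argmax(prob.probs, axis=0).astype(np.uint8)
    return LabelMap(labels, prob.spacing, scheme, prob.origin)
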