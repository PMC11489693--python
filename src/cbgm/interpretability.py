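"""1-D Grad-CAM saliency and attention heatmaps.

Grad-CAM localizes the waveform regions driving a class score: the
gradient of the pre-softmax logit for the target class is taken with
respect to a convolutional stage's activations, averaged over time to give
one weight per channel, and the rectified channel-weighted sum of the
activations — linearly upsampled to the 300-sample input grid and
max-normalized — is the saliency map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigError
from .model import CBGMModel
from .signal_io import CLASSES, Segment

logger = logging.getLogger("cbgm")

__all__ = ["SaliencyMap", "grad_cam", "attention_maps"]


@dataclass
class SaliencyMap:
    """Per-sample relevance in [0, 1], aligned to the 300-sample input."""

    values: np.ndarray
    target_class: str
    target_layer: str
    all_zero: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    @property
    def argmax(self) -> int:
        return int(self.values.argmax())


def _conv_layer_index(model: CBGMModel, target_layer: str) -> int:
    names = [f"conv{i + 1}" for i in range(len(model.convs))]
    if target_layer not in names:
        raise ConfigError(
            f"target_layer must be a convolutional stage {names}, "
            f"got {target_layer!r}"
        )
    return names.index(target_layer)


def grad_cam(
    model: CBGMModel,
    segment,
    target_class: str,
    target_layer: str = "conv3",
) -> SaliencyMap:
    """Gradient-weighted class activation map for one pulse."""
    if target_class not in CLASSES:
        raise ConfigError(f"unknown class {target_class!r}")
    layer_idx = _conv_layer_index(model, target_layer)
    x = segment.values if isinstance(segment, Segment) else np.asarray(segment)
    logits = model.forward_tensor(x[None, :], train=False)
    score = logits[0, CLASSES.index(target_class)]
    score.backward(retain_all=True)
    act = model.conv_activations[layer_idx]
    grads = act.grad  # (1, T', C)
    weights = grads.mean(axis=1)  # (1, C): time-averaged channel importance
    cam = np.maximum((weights[:, None, :] * act.data).sum(axis=-1), 0.0)[0]
    # upsample T' -> input length on aligned grids
    n = model.config.input_length
    if cam.size > 1:
        pos = np.linspace(0, cam.size - 1, n)
        cam_full = np.interp(pos, np.arange(cam.size), cam)
    else:
        cam_full = np.full(n, float(cam[0]))
    peak = cam_full.max()
    if peak <= 0:
        logger.warning("Grad-CAM map is all zero (no positive class evidence)")
        return SaliencyMap(np.zeros(n), target_class, target_layer, all_zero=True)
    return SaliencyMap(cam_full / peak, target_class, target_layer)


def attention_maps(model: CBGMModel, segment) -> list:
    """Per-head T x T row-stochastic attention matrices for one pulse."""
    if model.attention is None:
        raise ConfigError("model was built without an attention stage")
    x = segment.values if isinstance(segment, Segment) else np.asarray(segment)
    model.forward(x[None, :])
    return [w[0] for w in model.last_attention]
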