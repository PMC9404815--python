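"""Off-the-shelf deep features from an AlexNet-architecture network.

Spiral images are not used to train anything: a fixed convolutional
network acts as a feature extractor, and activations tapped at different
depths become descriptors for a separate SVM. Six tap points are exposed —
Conv1..Conv5 and fc7 — each taken after the layer's ReLU, and after the
max-pooling stage for Conv1, Conv2 and Conv5 (the conventional
"off-the-shelf" read-out, which also bounds descriptor dimension).

The architecture is the classic 5-conv/3-fc AlexNet:

    Conv(3->64,  11x11, stride 4, pad 2) + ReLU + MaxPool(3, stride 2)
    Conv(64->192, 5x5,  pad 2)           + ReLU + MaxPool(3, stride 2)
    Conv(192->384, 3x3, pad 1)           + ReLU
    Conv(384->256, 3x3, pad 1)           + ReLU
    Conv(256->256, 3x3, pad 1)           + ReLU + MaxPool(3, stride 2)
    flatten -> fc6(9216->4096) + ReLU -> fc7(4096->4096) + ReLU

The forward pass is implemented here directly on numpy (im2col + GEMM).
Two weight modes exist: ``pretrained`` requires an ImageNet-trained
parameter set, which this package does not ship — requesting it raises an
error pointing at the fallback; ``random_seeded`` draws He-initialized
weights from a seeded generator, giving a deterministic random-projection
feature extractor that preserves gross image structure and keeps the whole
pipeline runnable and testable anywhere.

Feature vectors are flattened channel-major (channel, then row, then
column), and their dimension depends only on (layer, input_px).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .hybrid_image import GrayImage

logger = logging.getLogger("spiralad")

#: The six tap points, shallow to deep.
LAYER_TAGS = ("Conv1", "Conv2", "Conv3", "Conv4", "Conv5", "fc7")

#: ImageNet channel statistics, the standard input normalization for
#: networks of this family.
IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)

_CONV_SPECS = (
    # (out_channels, kernel, stride, pad, pool_after)
    (64, 11, 4, 2, True),
    (192, 5, 1, 2, True),
    (384, 3, 1, 1, False),
    (256, 3, 1, 1, False),
    (256, 3, 1, 1, True),
)


class PretrainedWeightsUnavailable(RuntimeError):
    """Raised when pretrained weights are requested but not installed."""


def _check_layer(layer: str) -> None:
    if layer not in LAYER_TAGS:
        raise ValueError(f"layer must be one of {LAYER_TAGS}, got {layer!r}")


@dataclass(frozen=True)
class ExtractorConfig:
    """Feature-extractor settings.

    input_px: network input side (224 default; 227 is the other common
    dialect). weights_mode: "pretrained" or "random_seeded" (the latter
    requires a seed). channel_norm: per-channel (mean, std) applied after
    scaling pixel values to [0, 1].
    """

    input_px: int = 224
    weights_mode: str = "random_seeded"
    seed: int | None = 0
    channel_norm: tuple[tuple[float, ...], tuple[float, ...]] = (IMAGENET_MEAN, IMAGENET_STD)

    def __post_init__(self) -> None:
        if self.weights_mode not in ("pretrained", "random_seeded"):
            raise ValueError(f"unknown weights_mode {self.weights_mode!r}")
        if self.weights_mode == "random_seeded" and self.seed is None:
            raise ValueError("random_seeded weights require a seed")

    def cache_key(self) -> tuple:
        return (self.input_px, self.weights_mode, self.seed)

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "input_px": self.input_px,
                "weights_mode": self.weights_mode,
                "seed": self.seed,
                "channel_norm": self.channel_norm,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class FeatureVector:
    """Flattened activation of one tap point for one image."""

    layer: str
    values: np.ndarray
    subject_id: str = ""
    view: str = ""

    def __post_init__(self) -> None:
        _check_layer(self.layer)
        self.values = np.asarray(self.values, dtype=np.float32).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite entries")

    @property
    def dim(self) -> int:
        return int(self.values.shape[0])


# ---------------------------------------------------------------------------
# Network primitives (im2col convolution, max pooling)
# ---------------------------------------------------------------------------

def _conv2d(x: np.ndarray, weight: np.ndarray, bias: np.ndarray, stride: int, pad: int) -> np.ndarray:
    """2-D convolution, x (C,H,W), weight (O,C,k,k) -> (O,H',W')."""
    c, h, w = x.shape
    o, _, k, _ = weight.shape
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    windows = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
    windows = windows[:, ::stride, ::stride]  # (C, H', W', k, k)
    _, hh, ww, _, _ = windows.shape
    cols = windows.transpose(1, 2, 0, 3, 4).reshape(hh * ww, c * k * k)
    out = cols @ weight.reshape(o, -1).T + bias
    return out.T.reshape(o, hh, ww)


def _maxpool(x: np.ndarray, k: int = 3, stride: int = 2) -> np.ndarray:
    windows = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
    return windows[:, ::stride, ::stride].max(axis=(3, 4))


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class _AlexNetWeights:
    """He-initialized random parameter set for the AlexNet layout."""

    def __init__(self, seed: int):
        rng = np.random.default_rng(seed)
        self.conv: list[tuple[np.ndarray, np.ndarray]] = []
        in_ch = 3
        for out_ch, k, _, _, _ in _CONV_SPECS:
            fan_in = in_ch * k * k
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, k, k))
            self.conv.append((w.astype(np.float32), np.zeros(out_ch, dtype=np.float32)))
            in_ch = out_ch
        self.fc: list[tuple[np.ndarray, np.ndarray]] = []
        # fc dims depend on input_px only through conv5's pooled grid, which
        # is 6x6 for both 224 and 227; frozen here.
        for n_in, n_out in ((256 * 6 * 6, 4096), (4096, 4096)):
            w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in))
            self.fc.append((w.astype(np.float32), np.zeros(n_out, dtype=np.float32)))


_WEIGHT_CACHE: dict[tuple, _AlexNetWeights] = {}


def _get_weights(config: ExtractorConfig) -> _AlexNetWeights:
    if config.weights_mode == "pretrained":
        raise PretrainedWeightsUnavailable(
            "no pretrained ImageNet parameter set is installed with this package; "
            "use weights_mode='random_seeded' (deterministic seeded random projections)"
        )
    key = config.cache_key()
    if key not in _WEIGHT_CACHE:
        _WEIGHT_CACHE[key] = _AlexNetWeights(int(config.seed))
    return _WEIGHT_CACHE[key]


# ---------------------------------------------------------------------------
# Preprocessing and extraction
# ---------------------------------------------------------------------------

def preprocess(image, config: ExtractorConfig = ExtractorConfig()) -> np.ndarray:
    """Turn an image into the (3, input_px, input_px) float32 network input.

    Accepts a GrayImage, a 2-D uint8 array (replicated onto 3 identical
    channels), or an (H, W, 3) uint8 array (one hybrid view per channel).
    The image is resized with bilinear interpolation, scaled to [0, 1], and
    channel-normalized.
    """
    if isinstance(image, GrayImage):
        arr = image.pixels
    else:
        arr = np.asarray(image)
    if arr.ndim == 2:
        pil = Image.fromarray(arr.astype(np.uint8), mode="L")
        pil = pil.resize((config.input_px, config.input_px), Image.BILINEAR)
        chan = np.asarray(pil, dtype=np.float32) / 255.0
        x = np.stack([chan, chan, chan])
    elif arr.ndim == 3 and arr.shape[2] == 3:
        pil = Image.fromarray(arr.astype(np.uint8), mode="RGB")
        pil = pil.resize((config.input_px, config.input_px), Image.BILINEAR)
        x = (np.asarray(pil, dtype=np.float32) / 255.0).transpose(2, 0, 1)
    else:
        raise ValueError("image must be 2-D grayscale or (H, W, 3)")
    mean, std = config.channel_norm
    mean_a = np.asarray(mean, dtype=np.float32)[:, None, None]
    std_a = np.asarray(std, dtype=np.float32)[:, None, None]
    return (x - mean_a) / std_a


def forward_taps(
    x: np.ndarray,
    config: ExtractorConfig = ExtractorConfig(),
    stop_at: str | None = None,
) -> dict[str, np.ndarray]:
    """Run the forward pass, collecting the activation at every tap point.

    ``stop_at`` truncates the pass after that tap. Returns a dict mapping
    layer tags to (C, H, W) conv activations or 1-D fc activations.
    """
    weights = _get_weights(config)
    taps: dict[str, np.ndarray] = {}
    h = np.asarray(x, dtype=np.float32)
    for i, (out_ch, k, stride, pad, pool) in enumerate(_CONV_SPECS):
        w, b = weights.conv[i]
        h = _relu(_conv2d(h, w, b, stride, pad))
        if pool:
            h = _maxpool(h)
        tag = f"Conv{i + 1}"
        taps[tag] = h
        if stop_at == tag:
            return taps
    flat = h.reshape(-1)
    w6, b6 = weights.fc[0]
    h = _relu(w6 @ flat + b6)
    w7, b7 = weights.fc[1]
    taps["fc7"] = _relu(w7 @ h + b7)
    return taps


def extract_features(
    image,
    layer: str,
    config: ExtractorConfig = ExtractorConfig(),
    subject_id: str = "",
    view: str = "",
) -> FeatureVector:
    """Extract the flattened activation at one tap for one image.

    ``image`` may be raw/hybrid (GrayImage or 2-D array), a 3-channel
    composite, or an already-preprocessed (3, input_px, input_px) float
    array. Flattening is channel-major.
    """
    _check_layer(layer)
    arr = image.pixels if isinstance(image, GrayImage) else np.asarray(image)
    if arr.ndim == 3 and arr.shape[0] == 3 and np.issubdtype(arr.dtype, np.floating):
        x = arr
    else:
        x = preprocess(image, config)
    if isinstance(image, GrayImage):
        subject_id = subject_id or image.subject_id
        view = view or image.view
    taps = forward_taps(x, config, stop_at=layer)
    return FeatureVector(layer, taps[layer].ravel(), subject_id=subject_id, view=view)


def feature_dim(layer: str, input_px: int = 224) -> int:
    """Descriptor dimension for a tap point, by shape arithmetic."""
    _check_layer(layer)
    if layer == "fc7":
        return 4096
    side = input_px
    for i, (out_ch, k, stride, pad, pool) in enumerate(_CONV_SPECS):
        side = (side + 2 * pad - k) // stride + 1
        if pool:
            side = (side - 3) // 2 + 1
        if layer == f"Conv{i + 1}":
            return out_ch * side * side


# ---------------------------------------------------------------------------
# Multi-view channel composition (low-level fusion input)
# ---------------------------------------------------------------------------

DEFAULT_CHANNEL_ORDER = ("pressure", "altitude", "velocity")


def compose_channels(
    images: Sequence[GrayImage],
    order: Sequence[str] = DEFAULT_CHANNEL_ORDER,
) -> np.ndarray:
    """Stack three hybrid views of one subject into an (H, W, 3) image.

    Channel c carries the view named by ``order[c]`` (default pressure,
    altitude, velocity). All three must share subject and canvas size. No
    channel replication happens here: each channel is a different view.
    """
    if len(images) != 3 or len(order) != 3:
        raise ValueError("compose_channels takes exactly 3 images and 3 view names")
    by_view = {img.view: img for img in images}
    if set(by_view) != set(order):
        raise ValueError(f"views {sorted(by_view)} do not match requested order {list(order)}")
    subjects = {img.subject_id for img in images}
    if len(subjects) != 1:
        raise ValueError(f"images belong to different subjects: {sorted(subjects)}")
    shapes = {img.pixels.shape for img in images}
    if len(shapes) != 1:
        raise ValueError(f"mismatched canvas sizes: {sorted(shapes)}")
    return np.stack([by_view[v].pixels for v in order], axis=-1)


def decompose_channels(
    composite: np.ndarray,
    order: Sequence[str] = DEFAULT_CHANNEL_ORDER,
    subject_id: str = "",
) -> list[GrayImage]:
    """Inverse of :func:`compose_channels`."""
    composite = np.asarray(composite)
    if composite.ndim != 3 or composite.shape[2] != 3:
        raise ValueError("composite must be (H, W, 3)")
    return [
        GrayImage(composite[:, :, c], order[c], subject_id) for c in range(3)
    ]


# ---------------------------------------------------------------------------
# Persistence: one array container per (view, layer) plus a JSON manifest
# ---------------------------------------------------------------------------

def save_feature_set(
    vectors: Sequence[FeatureVector],
    path,
    config: ExtractorConfig,
) -> None:
    """Persist one (view, layer) feature set as .npz + sidecar manifest."""
    if not vectors:
        raise ValueError("empty feature set")
    layers = {v.layer for v in vectors}
    views = {v.view for v in vectors}
    if len(layers) != 1 or len(views) != 1:
        raise ValueError("a feature set holds exactly one (view, layer)")
    path = Path(path)
    subject_ids = [v.subject_id for v in vectors]
    matrix = np.stack([v.values for v in vectors])
    np.savez_compressed(path, features=matrix)
    manifest = {
        "subject_ids": subject_ids,
        "layer": vectors[0].layer,
        "view": vectors[0].view,
        "dim": int(matrix.shape[1]),
        "config_hash": config.config_hash(),
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=1))


def load_feature_set(path) -> list[FeatureVector]:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    matrix = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))["features"]
    return [
        FeatureVector(manifest["layer"], row, subject_id=sid, view=manifest["view"])
        for sid, row in zip(manifest["subject_ids"], matrix)
    ]
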