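"""Fused CNN feature extraction: three reduced-scale backbone families.

Three convolutional families echo the standard transfer-learning trio used in
dermoscopy pipelines:

* ``mobilenet_v2_style`` — inverted residual blocks built from depthwise-
  separable convolutions (1x1 expand, 3x3 depthwise, 1x1 project) with a
  shortcut addition whenever the stride is 1 and channel counts match;
* ``inception_style`` — inception blocks running 1x1, 3x3 and 5x5 convolution
  branches plus a pooled 1x1 branch in parallel and concatenating along the
  channel axis;
* ``alexnet_style`` — a wide first receptive field (7x7 at this input scale)
  followed by progressively smaller kernels, the canonical
  5-convolution + fully-connected shape.

All use ReLU.  The "features" of a backbone are its global-average-pooled
penultimate activations.  Backbones are deterministic given (spec, seed) and
are used as fixed random-projection extractors (He-initialized); externally
trained weights can be substituted via ``set_weights``.  Random convolutional
features preserve class-discriminative colour/shape statistics well enough
for a downstream classifier at desk scale.

Fusion concatenates the per-backbone vectors in declared order; an optional
:class:`FeatureScaler` standardizes each feature using statistics fitted on
training data only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .image import RasterImage, resize_to

FAMILIES = ("mobilenet_v2_style", "inception_style", "alexnet_style")


# ------------------------------------------------------------------ primitives
def _pad_same(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    ph, pw = kh // 2, kw // 2
    return np.pad(x, ((ph, kh - 1 - ph), (pw, kw - 1 - pw), (0, 0)))


def conv2d(x: np.ndarray, w: np.ndarray, stride: int = 1, same: bool = True) -> np.ndarray:
    """Standard convolution; ``x`` is HWC, ``w`` is (kh, kw, c_in, c_out)."""
    kh, kw = w.shape[:2]
    if same:
        x = _pad_same(x, kh, kw)
    win = sliding_window_view(x, (kh, kw), axis=(0, 1))[::stride, ::stride]
    return np.einsum("hwcij,ijco->hwo", win, w, optimize=True)


def depthwise_conv2d(x: np.ndarray, w: np.ndarray, stride: int = 1) -> np.ndarray:
    """Depthwise convolution; ``w`` is (kh, kw, c)."""
    kh, kw = w.shape[:2]
    x = _pad_same(x, kh, kw)
    win = sliding_window_view(x, (kh, kw), axis=(0, 1))[::stride, ::stride]
    return np.einsum("hwcij,ijc->hwc", win, w, optimize=True)


def maxpool2d(x: np.ndarray, k: int = 2, stride: int | None = None) -> np.ndarray:
    stride = stride or k
    win = sliding_window_view(x, (k, k), axis=(0, 1))[::stride, ::stride]
    return win.max(axis=(-2, -1))


def global_avg_pool(x: np.ndarray) -> np.ndarray:
    return x.mean(axis=(0, 1))


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


# ------------------------------------------------------------------- backbones
@dataclass
class BackboneSpec:
    """Architecture recipe: family, width multiplier, stage depth, input size."""

    family: str
    width_mult: float = 1.0
    depth: int = 2
    input_size: int = 64

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown backbone family: {self.family!r} (choose from {FAMILIES})")
        if self.width_mult <= 0 or self.depth < 1 or self.input_size < 8:
            raise ValueError("width multiplier, depth and input size must be positive")

    def _w(self, base: int) -> int:
        return max(1, int(round(base * self.width_mult)))


@dataclass
class FeatureVector:
    values: np.ndarray
    source: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite entries")

    def __len__(self) -> int:
        return len(self.values)


class Backbone:
    """A forward-only convolutional feature extractor.

    ``weights`` maps layer names to arrays; :meth:`set_weights` accepts
    externally supplied (e.g. trained) parameters with matching shapes.
    """

    def __init__(self, spec: BackboneSpec, seed: int):
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(np.random.SeedSequence([seed, FAMILIES.index(spec.family)]))
        self.weights: dict[str, np.ndarray] = {}
        self._build(rng)
        self.output_dim = len(self.extract_array(np.zeros((spec.input_size, spec.input_size, 3))))

    def _he(self, rng, *shape) -> np.ndarray:
        fan_in = int(np.prod(shape[:-1])) or 1
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

    def _build(self, rng) -> None:
        s, w = self.spec, self.weights
        if s.family == "mobilenet_v2_style":
            c = s._w(8)
            w["stem"] = self._he(rng, 3, 3, 3, c)
            cin = c
            for i in range(s.depth):
                stride_block_out = s._w(8 * (i + 2)) if i % 2 else cin
                exp = cin * 3
                w[f"ir{i}_expand"] = self._he(rng, 1, 1, cin, exp)
                w[f"ir{i}_dw"] = self._he(rng, 3, 3, exp)
                w[f"ir{i}_project"] = self._he(rng, 1, 1, exp, stride_block_out)
                cin = stride_block_out
        elif s.family == "inception_style":
            c = s._w(8)
            w["stem"] = self._he(rng, 3, 3, 3, c)
            cin = c
            for i in range(s.depth):
                b1, b3, b5, bp = s._w(4), s._w(8), s._w(4), s._w(4)
                w[f"inc{i}_1x1"] = self._he(rng, 1, 1, cin, b1)
                w[f"inc{i}_3x3"] = self._he(rng, 3, 3, cin, b3)
                w[f"inc{i}_5x5"] = self._he(rng, 5, 5, cin, b5)
                w[f"inc{i}_pool"] = self._he(rng, 1, 1, cin, bp)
                cin = b1 + b3 + b5 + bp
        else:  # alexnet_style
            chans = [s._w(12), s._w(16), s._w(24), s._w(24), s._w(16)]
            kernels = [7, 5, 3, 3, 3]
            cin = 3
            for i, (cout, k) in enumerate(zip(chans, kernels)):
                w[f"conv{i}"] = self._he(rng, k, k, cin, cout)
                cin = cout

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for name, arr in weights.items():
            if name not in self.weights:
                raise KeyError(f"unknown layer {name!r}")
            if arr.shape != self.weights[name].shape:
                raise ValueError(
                    f"shape mismatch for {name}: {arr.shape} vs {self.weights[name].shape}"
                )
            self.weights[name] = np.asarray(arr, dtype=float)

    # forward pass ----------------------------------------------------------
    def _forward(self, x: np.ndarray) -> np.ndarray:
        s, w = self.spec, self.weights
        if s.family == "mobilenet_v2_style":
            x = _relu(conv2d(x, w["stem"], stride=2))
            for i in range(s.depth):
                stride = 2 if i % 2 else 1
                h = _relu(conv2d(x, w[f"ir{i}_expand"]))
                h = _relu(depthwise_conv2d(h, w[f"ir{i}_dw"], stride=stride))
                h = conv2d(h, w[f"ir{i}_project"])
                if stride == 1 and h.shape[2] == x.shape[2]:
                    h = h + x  # residual shortcut
                x = h
        elif s.family == "inception_style":
            x = _relu(conv2d(x, w["stem"], stride=2))
            x = maxpool2d(x, 2)
            for i in range(s.depth):
                branches = [
                    _relu(conv2d(x, w[f"inc{i}_1x1"])),
                    _relu(conv2d(x, w[f"inc{i}_3x3"])),
                    _relu(conv2d(x, w[f"inc{i}_5x5"])),
                    _relu(conv2d(maxpool2d(x, 3, stride=1) if min(x.shape[:2]) >= 3 else x,
                                 w[f"inc{i}_pool"])),
                ]
                hmin = min(b.shape[0] for b in branches)
                wmin = min(b.shape[1] for b in branches)
                x = np.concatenate([b[:hmin, :wmin] for b in branches], axis=2)
        else:  # alexnet_style
            x = _relu(conv2d(x, w["conv0"], stride=2))
            x = maxpool2d(x, 2)
            x = _relu(conv2d(x, w["conv1"]))
            x = maxpool2d(x, 2)
            for i in range(2, 5):
                x = _relu(conv2d(x, w[f"conv{i}"]))
        return x

    def extract_array(self, pixels01: np.ndarray) -> np.ndarray:
        """Features from an already-resized float image in [0, 1]."""
        if pixels01.shape[:2] != (self.spec.input_size, self.spec.input_size):
            raise ValueError(
                f"expected {self.spec.input_size}x{self.spec.input_size} input, "
                f"got {pixels01.shape[:2]}"
            )
        return global_avg_pool(self._forward(np.asarray(pixels01, dtype=float)))

    def extract(self, img: RasterImage | np.ndarray) -> FeatureVector:
        """Resize/normalize an 8-bit image and extract its feature vector."""
        pixels = img.pixels if isinstance(img, RasterImage) else np.asarray(img)
        x = resize_to(pixels, self.spec.input_size)
        return FeatureVector(self.extract_array(x), self.spec.family)


def build_backbone(spec: BackboneSpec, seed: int) -> Backbone:
    """Construct a deterministic feature extractor for the given spec."""
    return Backbone(spec, seed)


def default_backbones(seed: int, *, input_size: int = 64, width_mult: float = 1.0) -> list[Backbone]:
    """The standard fused trio in declared order."""
    return [
        build_backbone(BackboneSpec(fam, width_mult=width_mult, input_size=input_size), seed)
        for fam in FAMILIES
    ]


# ---------------------------------------------------------------------- fusion
def fuse(vectors: list[FeatureVector]) -> FeatureVector:
    """Concatenate backbone outputs in declared order."""
    if not vectors:
        raise ValueError("cannot fuse an empty list of feature vectors")
    return FeatureVector(np.concatenate([v.values for v in vectors]), "fused")


@dataclass
class FeatureScaler:
    """Per-feature z-scoring with statistics fitted on training data only."""

    mean: np.ndarray | None = None
    std: np.ndarray | None = None
    eps: float = 1e-8

    def fit(self, features: np.ndarray) -> "FeatureScaler":
        arr = np.asarray(features, dtype=float)
        self.mean = arr.mean(axis=0)
        self.std = arr.std(axis=0)
        return self

    def transform(self, features: np.ndarray) -> np.ndarray:
        if self.mean is None:
            raise RuntimeError("scaler must be fitted before transforming")
        return (np.asarray(features, dtype=float) - self.mean) / (self.std + self.eps)

    def fit_transform(self, features: np.ndarray) -> np.ndarray:
        return self.fit(features).transform(features)


def extract_fused(
    backbones: list[Backbone], images: list[RasterImage | np.ndarray]
) -> np.ndarray:
    """Fused feature matrix (n_images x total_dim) for a list of images."""
    rows = [fuse([bb.extract(img) for bb in backbones]).values for img in images]
    return np.vstack(rows)
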