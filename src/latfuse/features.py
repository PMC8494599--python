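"""Weight maps for low-rank fusion from deep convolutional feature maps.

The terminal low-rank parts of the two sources are fed through a
convolutional feature extractor producing 512 rectified feature maps at
1/16 of the input resolution.  The per-cell l1 norm across channels is
the activity level C_k; the pair of activity maps is normalized into a
convex pair of weight maps, which are block-replicated (16x16) back to
full resolution and applied to the low-rank parts as Hadamard weights.

Extractors are pluggable behind a small contract (``FeatureExtractor``):

* :class:`Vgg19Extractor` — pretrained VGG-19, first convolutional layer
  of block 5, post-ReLU (512 channels at 1/16 resolution).  Default for
  real use; requires the optional ``torch``/``torchvision`` extra.
* :class:`RandomConvExtractor` — seeded, bias-free random 16x16 stride-16
  convolution bank with ReLU.  Honors the same contract deterministically
  with no pretrained weights; used throughout the test suite.

Inputs whose sides are not multiples of 16 are reflect-padded up to the
next multiple before extraction and the weight map is cropped back, so
the block replication stays exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np

from .errors import ContractError, DimensionError
from .image_io import ImageMatrix, as_gray_array

__all__ = [
    "BLOCK",
    "N_MAPS",
    "FeatureStack",
    "FeatureExtractor",
    "RandomConvExtractor",
    "Vgg19Extractor",
    "get_extractor",
    "extract_feature_maps",
    "activity_map",
    "weight_pair",
    "upsample_weight",
]

#: Spatial reduction factor of the extractor (four 2x2 poolings in VGG-19).
BLOCK = 16
#: Channel count of the extracted layer.
N_MAPS = 512
#: Minimum input side for feature extraction.
_MIN_SIDE = 32


class FeatureExtractor(Protocol):
    """Contract: map an (H, W) image, H and W multiples of 16, to a
    nonnegative (512, H/16, W/16) array, deterministically."""

    def __call__(self, image: np.ndarray) -> np.ndarray: ...


@dataclass(frozen=True)
class FeatureStack:
    """512 rectified feature maps of one source's terminal low-rank part.

    ``original_shape`` is the pre-padding image shape; ``maps`` cover the
    reflect-padded image at 1/16 resolution.
    """

    maps: np.ndarray  # (512, ceil(H/16), ceil(W/16))
    source_id: int
    original_shape: tuple[int, int]

    def __post_init__(self) -> None:
        if self.maps.ndim != 3 or self.maps.shape[0] != N_MAPS:
            raise ContractError(
                f"FeatureStack needs {N_MAPS} maps of one shape, got array {self.maps.shape}"
            )


class RandomConvExtractor:
    """Seeded fixed-random-filter extractor honoring the feature contract.

    A single bias-free bank of 512 random 16x16 filters applied at
    stride 16 with ReLU.  Zero input maps to zero output; two instances
    with the same seed are bitwise identical.
    """

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.seed = seed
        # (block*block, 512), unit-ish scale per filter
        self._filters = rng.standard_normal((BLOCK * BLOCK, N_MAPS)) / BLOCK

    def __call__(self, image: np.ndarray) -> np.ndarray:
        h, w = image.shape
        if h % BLOCK or w % BLOCK:
            raise ContractError("extractor input sides must be multiples of 16")
        hb, wb = h // BLOCK, w // BLOCK
        blocks = (
            image.reshape(hb, BLOCK, wb, BLOCK)
            .transpose(0, 2, 1, 3)
            .reshape(hb, wb, BLOCK * BLOCK)
        )
        out = np.maximum(blocks @ self._filters, 0.0)  # (hb, wb, 512)
        return np.ascontiguousarray(out.transpose(2, 0, 1))


class Vgg19Extractor:
    """Pretrained VGG-19 features, block-5 conv-1 post-ReLU.

    Grayscale input is replicated to three channels, scaled to [0, 255]
    and the standard per-channel training means are subtracted.  Requires
    the optional torch/torchvision dependency; CPU inference suffices.
    """

    _MEANS = (123.68, 116.779, 103.939)

    def __init__(self) -> None:
        try:
            import torch
            from torchvision.models import VGG19_Weights, vgg19
        except ImportError as exc:  # pragma: no cover - torch is optional
            raise ImportError(
                "the pretrained feature extractor needs the optional "
                "'vgg' extra (pip install latfuse[vgg])"
            ) from exc
        self._torch = torch
        model = vgg19(weights=VGG19_Weights.IMAGENET1K_V1)
        # features[:30] ends just after relu5_1: 512 channels, 1/16 resolution
        self._net = model.features[:30].eval()
        for p in self._net.parameters():
            p.requires_grad_(False)

    def __call__(self, image: np.ndarray) -> np.ndarray:  # pragma: no cover
        torch = self._torch
        rgb = np.stack([image * 255.0 - m for m in self._MEANS], axis=0)
        with torch.no_grad():
            out = self._net(torch.from_numpy(rgb[None]).float())
        return np.maximum(out[0].numpy().astype(np.float64), 0.0)


def get_extractor(mode: str, seed: int = 0) -> FeatureExtractor:
    """Build an extractor from a mode name: ``pretrained`` or ``mock``."""
    if mode == "pretrained":
        return Vgg19Extractor()
    if mode == "mock":
        return RandomConvExtractor(seed=seed)
    raise ValueError(f"unknown feature mode {mode!r}; choose 'pretrained' or 'mock'")


def _pad_to_block(image: np.ndarray) -> np.ndarray:
    h, w = image.shape
    ph = (-h) % BLOCK
    pw = (-w) % BLOCK
    if ph == 0 and pw == 0:
        return image
    return np.pad(image, ((0, ph), (0, pw)), mode="reflect")


def extract_feature_maps(
    lowrank: "ImageMatrix | np.ndarray",
    extractor: FeatureExtractor,
    source_id: int = 1,
) -> FeatureStack:
    """Run the extractor on a (reflect-padded) low-rank part.

    The returned maps have shape ``(512, ceil(H/16), ceil(W/16))``.
    """
    img = as_gray_array(lowrank)
    h, w = img.shape
    if h < _MIN_SIDE or w < _MIN_SIDE:
        raise DimensionError(f"feature extraction needs at least 32x32 input, got {img.shape}")
    padded = _pad_to_block(img)
    maps = np.asarray(extractor(padded), dtype=np.float64)
    expect = (N_MAPS, padded.shape[0] // BLOCK, padded.shape[1] // BLOCK)
    if maps.shape != expect:
        raise ContractError(f"extractor returned shape {maps.shape}, expected {expect}")
    if maps.min() < 0:
        raise ContractError("extractor output must be rectified (nonnegative)")
    return FeatureStack(maps=maps, source_id=source_id, original_shape=(h, w))


def activity_map(fs: "FeatureStack | np.ndarray") -> np.ndarray:
    """Per-cell l1 norm across channels: C(x, y) = sum_m |phi_m(x, y)|."""
    maps = fs.maps if isinstance(fs, FeatureStack) else np.asarray(fs, dtype=np.float64)
    if maps.ndim != 3:
        raise ContractError(f"need a (channels, h, w) stack, got shape {maps.shape}")
    return np.abs(maps).sum(axis=0)


def weight_pair(C1: np.ndarray, C2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalize two activity maps into a convex weight pair.

    ``W_k = C_k / (C_1 + C_2)`` with the 0/0 cells set to 0.5/0.5 (the
    only symmetric convex tie-break).  The pair satisfies
    ``W_1 + W_2 == 1`` exactly at every cell and is bitwise
    swap-symmetric: the smaller quotient is computed by division and its
    partner as ``1 - w`` (exact in round-to-nearest for w <= 0.5).
    """
    C1 = np.asarray(C1, dtype=np.float64)
    C2 = np.asarray(C2, dtype=np.float64)
    if C1.shape != C2.shape:
        raise DimensionError(f"activity maps differ in shape: {C1.shape} vs {C2.shape}")
    if C1.min() < 0 or C2.min() < 0:
        raise ContractError("activity maps must be nonnegative")
    total = C1 + C2
    safe = np.where(total > 0, total, 1.0)
    wmin = np.where(total > 0, np.minimum(C1, C2) / safe, 0.5)
    wmax = 1.0 - wmin
    first_smaller = C1 <= C2
    w1 = np.where(first_smaller, wmin, wmax)
    w2 = np.where(first_smaller, wmax, wmin)
    return w1, w2


def upsample_weight(w_hat: np.ndarray, target_h: int, target_w: int) -> np.ndarray:
    """Block-replicate a low-resolution weight map to pixel resolution.

    Each cell expands to a constant 16x16 block; the result is cropped to
    the original (pre-padding) size.  Replication preserves the pointwise
    sum of a convex pair exactly.
    """
    w_hat = np.asarray(w_hat, dtype=np.float64)
    if w_hat.ndim != 2:
        raise DimensionError(f"weight map must be 2-D, got shape {w_hat.shape}")
    hb, wb = w_hat.shape
    if not (0 < target_h <= hb * BLOCK and 0 < target_w <= wb * BLOCK):
        raise DimensionError(
            f"target {(target_h, target_w)} inconsistent with 16x expansion of {w_hat.shape}"
        )
    if (target_h + BLOCK - 1) // BLOCK != hb or (target_w + BLOCK - 1) // BLOCK != wb:
        raise DimensionError(
            f"target {(target_h, target_w)} inconsistent with 16x expansion of {w_hat.shape}"
        )
    full = np.kron(w_hat, np.ones((BLOCK, BLOCK)))
    return full[:target_h, :target_w]


def weight_maps_for_pair(
    lowrank1: np.ndarray,
    lowrank2: np.ndarray,
    extractor: FeatureExtractor,
) -> tuple[np.ndarray, np.ndarray]:
    """End-to-end weight-map construction for two terminal low-rank parts."""
    fs1 = extract_feature_maps(lowrank1, extractor, source_id=1)
    fs2 = extract_feature_maps(lowrank2, extractor, source_id=2)
    w1_hat, w2_hat = weight_pair(activity_map(fs1), activity_map(fs2))
    h, w = fs1.original_shape
    return upsample_weight(w1_hat, h, w), upsample_weight(w2_hat, h, w)
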