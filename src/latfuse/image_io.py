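"""Reading, validating and writing source images.

Everything downstream assumes a pair of pre-registered, equal-size images:
one grayscale anatomical image (CT/MRI-like) and one grayscale or RGB
functional image (PET/SPECT-like).  This module enforces that contract at
the boundary: intensities are rescaled to [0, 1] floats on read, pairs are
shape-checked, and writing quantizes back to 8- or 16-bit integers.

Registration itself is out of scope; only equal dimensions are verified.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import ContractError, DimensionError, FormatError

__all__ = [
    "ImageMatrix",
    "ColorImageMatrix",
    "read_image",
    "write_image",
    "validate_pair",
    "as_gray_array",
]

#: Minimum side length; the deep-feature stage needs at least one feature
#: cell after its 16x downsampling plus padding headroom.
MIN_SIDE = 32


@dataclass(frozen=True)
class ImageMatrix:
    """Single-channel intensity matrix with values in [0, 1].

    Parameters
    ----------
    pixels : ndarray of shape (H, W), float64
        Intensities in [0, 1].
    bit_depth_origin : int
        Bit depth of the file the image was read from (8 or 16).
        Provenance only; never used in computation.
    """

    pixels: np.ndarray
    bit_depth_origin: int = 8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2:
            raise FormatError(f"ImageMatrix requires a 2-D array, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ContractError("ImageMatrix contains non-finite values")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ContractError("ImageMatrix values must lie in [0, 1]")
        if px.shape[0] < MIN_SIDE or px.shape[1] < MIN_SIDE:
            raise DimensionError(
                f"images must be at least {MIN_SIDE}x{MIN_SIDE}, got {px.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class ColorImageMatrix:
    """RGB image with values in [0, 1], shape (H, W, 3)."""

    pixels: np.ndarray
    bit_depth_origin: int = 8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 3 or px.shape[2] != 3:
            raise FormatError(f"ColorImageMatrix requires shape (H, W, 3), got {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ContractError("ColorImageMatrix contains non-finite values")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ContractError("ColorImageMatrix values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]  # type: ignore[return-value]


def as_gray_array(img: "ImageMatrix | np.ndarray") -> np.ndarray:
    """Accept either an ImageMatrix or a bare 2-D float array."""
    if isinstance(img, ImageMatrix):
        return img.pixels
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise FormatError(f"expected a single-channel image, got shape {arr.shape}")
    return arr


def _bit_depth_of(arr: np.ndarray) -> int:
    if arr.dtype == np.uint8:
        return 8
    if arr.dtype == np.uint16:
        return 16
    raise FormatError(f"unsupported pixel dtype {arr.dtype}; only 8- and 16-bit integer images")


def read_image(path: "str | Path") -> "ImageMatrix | ColorImageMatrix":
    """Read a PNG/TIFF/JPEG image and rescale intensities to [0, 1].

    Grayscale files return an :class:`ImageMatrix`; RGB files return a
    :class:`ColorImageMatrix` unless all three channels are identical, in
    which case the image collapses to a single channel (Atlas-style CT/MRI
    slices are frequently RGB-encoded grayscale).  RGBA is accepted only
    with a fully opaque alpha channel, which is dropped.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # imageio wraps codec errors in various types
        raise IOError(f"cannot read image file {path}: {exc}") from exc

    raw = np.asarray(raw)
    depth = _bit_depth_of(raw)
    scale = float(2**depth - 1)

    if raw.ndim == 2:
        return ImageMatrix(raw.astype(np.float64) / scale, bit_depth_origin=depth)
    if raw.ndim == 3 and raw.shape[2] == 4:
        if not np.all(raw[..., 3] == np.iinfo(raw.dtype).max):
            raise FormatError(f"{path}: RGBA with non-opaque alpha is not supported")
        raw = raw[..., :3]
    if raw.ndim == 3 and raw.shape[2] == 3:
        px = raw.astype(np.float64) / scale
        if np.array_equal(raw[..., 0], raw[..., 1]) and np.array_equal(raw[..., 0], raw[..., 2]):
            return ImageMatrix(px[..., 0], bit_depth_origin=depth)
        return ColorImageMatrix(px, bit_depth_origin=depth)
    raise FormatError(f"{path}: unsupported channel layout with shape {raw.shape}")


def write_image(
    img: "ImageMatrix | ColorImageMatrix | np.ndarray",
    path: "str | Path",
    bit_depth: int = 8,
) -> Path:
    """Quantize to ``bit_depth`` (round-half-up) and write to disk.

    Values must already lie in [0, 1]; out-of-range input raises
    :class:`ContractError` rather than being clipped silently, because a
    caller that forgot to clip has usually also skipped the documented
    reconstruction step.
    """
    if bit_depth not in (8, 16):
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    px = img.pixels if isinstance(img, (ImageMatrix, ColorImageMatrix)) else np.asarray(img, np.float64)
    if not np.all(np.isfinite(px)):
        raise ContractError("cannot write non-finite pixel values")
    if px.min() < 0.0 or px.max() > 1.0:
        raise ContractError(
            "pixel values outside [0, 1]; clip explicitly before writing"
        )
    scale = 2**bit_depth - 1
    # floor(x+0.5) = round-half-up; np.round would round half to even
    quant = np.floor(px * scale + 0.5).astype(np.uint8 if bit_depth == 8 else np.uint16)
    path = Path(path)
    iio.imwrite(path, quant)
    return path


def validate_pair(
    a: "ImageMatrix | ColorImageMatrix",
    b: "ImageMatrix | ColorImageMatrix",
) -> tuple["ImageMatrix | ColorImageMatrix", "ImageMatrix | ColorImageMatrix", str]:
    """Check that two source images can be fused; return them with a mode tag.

    Returns ``(a, b, "gray-gray")`` when both are single-channel and
    ``(a, b, "gray-color")`` when exactly one is RGB.  Fusing two color
    images is unsupported: the color path exists so that a functional
    pseudo-color image keeps its chrominance while its luminance is fused
    with the anatomical grayscale image.
    """
    if a.shape != b.shape:
        raise DimensionError(f"source images differ in size: {a.shape} vs {b.shape}")
    a_color = isinstance(a, ColorImageMatrix)
    b_color = isinstance(b, ColorImageMatrix)
    if a_color and b_color:
        raise FormatError("fusion of two color images is not supported")
    mode = "gray-gray" if not (a_color or b_color) else "gray-color"
    return a, b, mode
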