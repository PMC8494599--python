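"""Deterministic synthetic phantoms for testing and demos.

Real multimodal pairs (e.g. registered MRI/CT and PET/SPECT brain slices)
are external data; these generators produce structurally plausible
stand-ins with known ground truth so every pipeline stage is testable
offline.  Phantoms are geometric rather than anatomically realistic: the
properties under test are algorithmic (energy conservation, sparse
recovery, metric monotonicity), not clinical fidelity.

One seed drives both modalities so a structural/functional pair shares
the identical head mask, emulating registered acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError

__all__ = [
    "PhantomSpec",
    "make_structural_phantom",
    "make_functional_phantom",
    "make_lowrank_sparse",
    "head_mask",
]

_COLORMAPS = ("gray", "hot", "cool")


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a registered phantom pair.

    Parameters
    ----------
    size : (int, int)
        Height and width; at least 64x64 for full-pipeline use.
    seed : int
        Drives every random draw; equal specs give bitwise-equal phantoms.
    n_structures : int
        Number of sharp-edged interior regions in the structural phantom
        and of metabolic blobs in the functional phantom.
    lesion : (row, col, radius, intensity) or None
        Optional disk drawn last (pre-noise) in the structural phantom.
    noise_sd : float
        Standard deviation of additive Gaussian noise, in intensity units.
    """

    size: tuple[int, int] = (128, 128)
    seed: int = 0
    n_structures: int = 4
    lesion: tuple[int, int, int, float] | None = None
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        h, w = self.size
        if h < 8 or w < 8:
            raise ValueError(f"phantom size too small: {self.size}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_structures < 0:
            raise ValueError("n_structures must be nonnegative")


def head_mask(size: tuple[int, int]) -> np.ndarray:
    """Elliptical 'head' mask, centered, semi-axes 0.45 of each side."""
    h, w = size
    rr, cc = np.mgrid[0:h, 0:w]
    return ((rr - (h - 1) / 2) / (0.45 * h)) ** 2 + (
        (cc - (w - 1) / 2) / (0.45 * w)
    ) ** 2 <= 1.0


def _disk(size: tuple[int, int], row: float, col: float, radius: float) -> np.ndarray:
    rr, cc = np.mgrid[0 : size[0], 0 : size[1]]
    return (rr - row) ** 2 + (cc - col) ** 2 <= radius**2


def make_structural_phantom(spec: PhantomSpec) -> np.ndarray:
    """Piecewise-constant 'anatomy' image in [0, 1].

    An elliptical head mask at a base intensity; when ``n_structures >= 1``
    a bright rim (skull analog), nested elliptical regions with distinct
    intensities and thin high-contrast ridge lines (sulci analog); an
    optional lesion disk; additive Gaussian noise; clipped to [0, 1].
    With ``n_structures = 0`` and ``noise_sd = 0`` the output is the bare
    binary mask (exactly two intensity values).
    """
    h, w = spec.size
    rng = np.random.default_rng(spec.seed)
    mask = head_mask(spec.size)
    img = np.zeros((h, w))
    img[mask] = 0.35

    if spec.n_structures >= 1:
        inner = head_mask(spec.size) & ~(
            ((np.mgrid[0:h, 0:w][0] - (h - 1) / 2) / (0.42 * h)) ** 2
            + ((np.mgrid[0:h, 0:w][1] - (w - 1) / 2) / (0.42 * w)) ** 2
            > 1.0
        )
        rim = mask & ~inner
        img[rim] = 0.95
        for _ in range(spec.n_structures):
            cy = rng.uniform(0.3 * h, 0.7 * h)
            cx = rng.uniform(0.3 * w, 0.7 * w)
            ry = rng.uniform(0.05, 0.18) * h
            rx = rng.uniform(0.05, 0.18) * w
            level = rng.uniform(0.2, 0.9)
            rr, cc = np.mgrid[0:h, 0:w]
            region = ((rr - cy) / ry) ** 2 + ((cc - cx) / rx) ** 2 <= 1.0
            img[region & mask] = level
        for _ in range(min(spec.n_structures, 3)):
            # thin bright ridge line across the head (bone/sulci analog)
            r0 = rng.uniform(0.25 * h, 0.75 * h)
            slope = rng.uniform(-0.5, 0.5)
            rr, cc = np.mgrid[0:h, 0:w]
            line = np.abs(rr - (r0 + slope * (cc - w / 2))) <= 1.0
            img[line & mask] = 0.95

    if spec.lesion is not None:
        row, col, radius, intensity = spec.lesion
        disk = _disk(spec.size, row, col, radius)
        if np.any(disk & ~mask):
            raise ContractError("lesion disk extends outside the head mask")
        img[disk] = intensity

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def _apply_colormap(v: np.ndarray, colormap: str) -> np.ndarray:
    if colormap == "gray":
        return np.stack([v, v, v], axis=-1)
    if colormap == "hot":
        r = np.clip(3.0 * v, 0, 1)
        g = np.clip(3.0 * v - 1.0, 0, 1)
        b = np.clip(3.0 * v - 2.0, 0, 1)
        return np.stack([r, g, b], axis=-1)
    if colormap == "cool":
        # classic cyan->magenta ramp, scaled by intensity so zero stays black
        return np.stack([v * v, (1.0 - v) * v, v], axis=-1)
    raise ValueError(f"unknown colormap {colormap!r}; choose from {_COLORMAPS}")


def make_functional_phantom(spec: PhantomSpec, colormap: str = "hot") -> np.ndarray:
    """Smooth pseudo-colored 'metabolism' image, (H, W, 3) in [0, 1].

    A sum of seeded Gaussian blobs inside the head mask, normalized to
    [0, 1] and pushed through a fixed pseudo-color lookup.  Uses the same
    head mask as :func:`make_structural_phantom` for the same spec, so the
    pair is 'registered' by construction.  ``n_structures = 0`` yields an
    all-black image.
    """
    if colormap not in _COLORMAPS:
        raise ValueError(f"unknown colormap {colormap!r}; choose from {_COLORMAPS}")
    h, w = spec.size
    # independent stream so structural/functional draws do not interact
    rng = np.random.default_rng([spec.seed, 1])
    mask = head_mask(spec.size)
    field = np.zeros((h, w))
    rr, cc = np.mgrid[0:h, 0:w]
    for _ in range(spec.n_structures):
        while True:
            cy = rng.uniform(0, h)
            cx = rng.uniform(0, w)
            if mask[int(cy), int(cx)]:
                break
        sigma = rng.uniform(h / 12, h / 6)
        amp = rng.uniform(0.5, 1.0)
        field += amp * np.exp(-((rr - cy) ** 2 + (cc - cx) ** 2) / (2 * sigma**2))
    if spec.noise_sd > 0:
        field = field + rng.normal(0.0, spec.noise_sd, size=field.shape)
    field[~mask] = 0.0
    field = np.clip(field, 0.0, None)
    if field.max() > 0:
        field = field / field.max()
    return np.clip(_apply_colormap(field, colormap), 0.0, 1.0)


def make_lowrank_sparse(
    n: int, rank: int, sparse_frac: float, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Low-rank + sparse test matrix with known ground truth.

    Returns ``(X, G, S)`` where ``G`` is an exactly rank-``rank`` matrix
    with entries spanning [0, 1], ``S`` is zero except for
    ``round(sparse_frac * n^2)`` entries at +/-0.5 in seeded positions,
    and ``X = clip(G + S, 0, 1)``.

    The left factor's first column is pinned to ones so the affine
    rescale of the random factor product into [0, 1] stays inside the
    rank-``rank`` span (a generic rescale would add a rank-one offset).
    """
    if not 0 <= sparse_frac < 0.5:
        raise ValueError("sparse_frac must lie in [0, 0.5)")
    if rank >= n or rank < 1:
        raise ValueError("require 1 <= rank < n")
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((n, rank))
    B = rng.standard_normal((rank, n))
    A[:, 0] = 1.0
    G = A @ B
    G = (G - G.min()) / (G.max() - G.min())

    k = round(sparse_frac * n * n)
    S = np.zeros(n * n)
    idx = rng.choice(n * n, size=k, replace=False)
    S[idx] = rng.choice([-0.5, 0.5], size=k)
    S = S.reshape(n, n)
    X = np.clip(G + S, 0.0, 1.0)
    return X, G, S
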