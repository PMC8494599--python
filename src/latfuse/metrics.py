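"""No-reference fusion quality metrics: Q_TE, Q_G, Q_C, Q_CB.

Each metric scores how well a fused image F preserves information from
two source images A and B, without a ground-truth reference:

* ``q_te``  — Tsallis-entropy information transfer: Tsallis-divergence
  mutual information between each source and the fused image, computed
  from 256-bin joint histograms and normalized by marginal Tsallis
  entropies.  Larger means more source information transferred.
* ``q_g``   — Xydeas-Petrovic gradient preservation: Sobel edge strength
  and orientation preservation pushed through sigmoid models, combined
  per pixel and weighted by source edge strength.  In [0, 1].
* ``q_c``   — Cvejic windowed structural preservation: a covariance-
  weighted mixture of windowed SSIM values against each source.
* ``q_cb``  — Chen-Blum perceptual contrast quality: contrast-sensitivity
  filtering, Peli local band contrast, masked-contrast preservation
  ratios (clamped at 1), saliency-weighted global quality map, reported
  as its mean.

All metrics quantize intensities to 256 levels on entry (values are
clamped into the 8-bit range first, so an unclipped fused matrix can be
scored without clip-induced histogram artifacts elsewhere) and are
invariant under swapping the two sources.  Every constant used is
recorded in :class:`MetricReport.params` so results are auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .errors import DimensionError
from .image_io import as_gray_array

__all__ = ["MetricReport", "q_te", "q_g", "q_c", "q_cb", "evaluate_all"]

# -- Xydeas-Petrovic sigmoid constants (canonical formulation) --------------
_QG_PARAMS = dict(gamma_g=0.9994, kappa_g=-15.0, sigma_g=0.5,
                  gamma_a=0.9879, kappa_a=-22.0, sigma_a=0.8)

# -- SSIM stabilizers on the 0..255 scale -----------------------------------
_SSIM_C1 = (0.01 * 255) ** 2
_SSIM_C2 = (0.03 * 255) ** 2

# -- Chen-Blum constants ----------------------------------------------------
_QCB_PARAMS = dict(
    f0=15.3870, f1=1.3456, a=0.7622,  # difference-of-Gaussians CSF
    sigma1=2.0, sigma2=4.0,           # Peli band-pass pair
    p=3.0, q=2.0, Z=1e-4,             # contrast masking exponents
    pixels_per_degree=32.0,           # viewing geometry for the CSF grid
)


@dataclass(frozen=True)
class MetricReport:
    """The four quality scores plus every constant used to compute them."""

    q_te: float
    q_g: float
    q_c: float
    q_cb: float
    params: dict

    def as_dict(self) -> dict:
        return {"q_te": self.q_te, "q_g": self.q_g, "q_c": self.q_c, "q_cb": self.q_cb}


def _quantize(img) -> np.ndarray:
    """Clamp into the 8-bit range and quantize to 256 integer levels."""
    arr = np.asarray(img.pixels if hasattr(img, "pixels") else img, dtype=np.float64)
    if arr.ndim != 2:
        raise DimensionError(f"metrics take single-channel images, got shape {arr.shape}")
    return np.clip(np.floor(arr * 255.0 + 0.5), 0.0, 255.0)


def _check_triple(a, b, f) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    qa, qb, qf = _quantize(a), _quantize(b), _quantize(f)
    if not (qa.shape == qb.shape == qf.shape):
        raise DimensionError("source and fused images must share one shape")
    return qa, qb, qf


# ---------------------------------------------------------------------------
# Q_TE — Tsallis-entropy information transfer
# ---------------------------------------------------------------------------

def _tsallis_entropy(p: np.ndarray, q: float) -> float:
    return float((1.0 - np.sum(p**q)) / (q - 1.0))


def _tsallis_mi(joint: np.ndarray, q: float) -> float:
    """Tsallis-divergence mutual information of a normalized joint histogram."""
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    denom = np.outer(px, py)[nz] ** (q - 1.0)
    total = np.sum(joint[nz] ** q / denom)
    return float((total - 1.0) / (q - 1.0))


def q_te(a, b, f, q: float = 1.85) -> float:
    """Tsallis mutual-information transfer from both sources to the fusion.

    Implements ``I_q(A;F)/(H_q(A)+H_q(F)) + I_q(B;F)/(H_q(B)+H_q(F))``
    with ``I_q`` the Tsallis-divergence mutual information over the
    256x256 joint intensity histogram and ``H_q`` the marginal Tsallis
    entropy.  Degenerate (constant) images have zero marginal entropy;
    the metric then falls back to 0 with a warning.
    """
    if q <= 0 or q == 1.0:
        raise ValueError("Tsallis order q must be positive and different from 1")
    qa, qb, qf = _check_triple(a, b, f)
    n = qa.size
    bins = np.arange(257)
    h_a = _tsallis_entropy(np.histogram(qa, bins=bins)[0] / n, q)
    h_b = _tsallis_entropy(np.histogram(qb, bins=bins)[0] / n, q)
    h_f = _tsallis_entropy(np.histogram(qf, bins=bins)[0] / n, q)
    if min(h_a, h_b, h_f) <= 1e-12:
        warnings.warn("degenerate (constant) image in q_te; returning 0", stacklevel=2)
        return 0.0
    j_af = np.histogram2d(qa.ravel(), qf.ravel(), bins=(bins, bins))[0] / n
    j_bf = np.histogram2d(qb.ravel(), qf.ravel(), bins=(bins, bins))[0] / n
    return _tsallis_mi(j_af, q) / (h_a + h_f) + _tsallis_mi(j_bf, q) / (h_b + h_f)


# ---------------------------------------------------------------------------
# Q_G — Xydeas-Petrovic gradient-based edge preservation
# ---------------------------------------------------------------------------

def _sobel_polar(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sx = ndimage.sobel(img, axis=1, mode="reflect")
    sy = ndimage.sobel(img, axis=0, mode="reflect")
    g = np.hypot(sx, sy)
    ratio = np.divide(sy, sx, out=np.zeros_like(sy), where=sx != 0)
    alpha = np.where(
        sx == 0, np.sign(sy) * (np.pi / 2), np.arctan(ratio)
    )
    return g, alpha


def _edge_preservation(ga, aa, gf, af) -> np.ndarray:
    p = _QG_PARAMS
    gmax = np.maximum(ga, gf)
    G = np.divide(np.minimum(ga, gf), gmax, out=np.zeros_like(ga), where=gmax > 0)
    A = 1.0 - np.abs(aa - af) / (np.pi / 2)
    qg = p["gamma_g"] / (1.0 + np.exp(p["kappa_g"] * (G - p["sigma_g"])))
    qa = p["gamma_a"] / (1.0 + np.exp(p["kappa_a"] * (A - p["sigma_a"])))
    return qg * qa


def q_g(a, b, f) -> float:
    """Gradient-based edge preservation (Sobel strength + orientation).

    Per pixel, the relative edge-strength and orientation preservation
    of F versus each source are mapped through sigmoid perceptual models
    and combined; the pixel scores are averaged with the source edge
    strengths as weights.  All-flat sources (no gradient anywhere) give
    a defined fallback of 0 with a warning.
    """
    qa, qb, qf = _check_triple(a, b, f)
    ga, aa = _sobel_polar(qa)
    gb, ab = _sobel_polar(qb)
    gf, af = _sobel_polar(qf)
    q_af = _edge_preservation(ga, aa, gf, af)
    q_bf = _edge_preservation(gb, ab, gf, af)
    wa, wb = ga, gb
    denom = np.sum(wa + wb)
    if denom == 0:
        warnings.warn("all-flat images in q_g; returning 0", stacklevel=2)
        return 0.0
    return float(np.sum(q_af * wa + q_bf * wb) / denom)


def q_g_max() -> float:
    """The model's maximum attainable value, reached when F = A = B."""
    p = _QG_PARAMS
    return (
        p["gamma_g"] / (1.0 + np.exp(p["kappa_g"] * (1.0 - p["sigma_g"])))
        * p["gamma_a"] / (1.0 + np.exp(p["kappa_a"] * (1.0 - p["sigma_a"])))
    )


# ---------------------------------------------------------------------------
# Q_C — Cvejic windowed structural preservation
# ---------------------------------------------------------------------------

def _window_stats(win_x: np.ndarray, win_y: np.ndarray):
    """Means, variances and covariance per sliding window (unbiased, N-1)."""
    n = win_x.shape[-1] * win_x.shape[-2]
    mx = win_x.mean(axis=(-2, -1))
    my = win_y.mean(axis=(-2, -1))
    vx = ((win_x - mx[..., None, None]) ** 2).sum(axis=(-2, -1)) / (n - 1)
    vy = ((win_y - my[..., None, None]) ** 2).sum(axis=(-2, -1)) / (n - 1)
    cxy = ((win_x - mx[..., None, None]) * (win_y - my[..., None, None])).sum(
        axis=(-2, -1)
    ) / (n - 1)
    return mx, my, vx, vy, cxy


def _ssim_map(win_x, win_y):
    mx, my, vx, vy, cxy = _window_stats(win_x, win_y)
    return ((2 * mx * my + _SSIM_C1) * (2 * cxy + _SSIM_C2)) / (
        (mx**2 + my**2 + _SSIM_C1) * (vx + vy + _SSIM_C2)
    ), cxy


def q_c(a, b, f, window: int = 8) -> float:
    """Covariance-weighted windowed SSIM against both sources.

    Per sliding window the weight ``mu = sigma_AF / (sigma_AF + sigma_BF)``
    (clipped to [0, 1]; 0.5 when both covariances vanish) mixes the
    windowed SSIM of (A, F) and (B, F); the scores are averaged over all
    windows and the mean clipped to [0, 1].
    """
    qa, qb, qf = _check_triple(a, b, f)
    if qa.shape[0] < window or qa.shape[1] < window:
        raise DimensionError(f"images smaller than the {window}x{window} analysis window")
    win_a = sliding_window_view(qa, (window, window))
    win_b = sliding_window_view(qb, (window, window))
    win_f = sliding_window_view(qf, (window, window))
    ssim_af, cov_af = _ssim_map(win_a, win_f)
    ssim_bf, cov_bf = _ssim_map(win_b, win_f)
    total = cov_af + cov_bf
    mu = np.where(total != 0, np.divide(cov_af, np.where(total != 0, total, 1.0)), 0.5)
    mu = np.clip(mu, 0.0, 1.0)
    score = mu * ssim_af + (1.0 - mu) * ssim_bf
    return float(np.clip(score.mean(), 0.0, 1.0))


# ---------------------------------------------------------------------------
# Q_CB — Chen-Blum perceptual contrast quality
# ---------------------------------------------------------------------------

def _csf_filter(img: np.ndarray) -> np.ndarray:
    """Frequency-domain contrast-sensitivity filtering (difference of Gaussians)."""
    p = _QCB_PARAMS
    h, w = img.shape
    fy = np.fft.fftfreq(h)[:, None] * p["pixels_per_degree"]  # cycles/degree
    fx = np.fft.fftfreq(w)[None, :] * p["pixels_per_degree"]
    r = np.hypot(fy, fx)
    csf = np.exp(-((r / p["f0"]) ** 2)) - p["a"] * np.exp(-((r / p["f1"]) ** 2))
    return np.real(np.fft.ifft2(np.fft.fft2(img) * csf))


def _peli_contrast(img: np.ndarray) -> np.ndarray:
    """Local band-limited contrast: ratio of two Gaussian scales minus one."""
    p = _QCB_PARAMS
    g1 = ndimage.gaussian_filter(img, p["sigma1"], mode="reflect")
    g2 = ndimage.gaussian_filter(img, p["sigma2"], mode="reflect")
    ok = g2 != 0
    return np.divide(g1, np.where(ok, g2, 1.0)) * ok - ok.astype(np.float64)


def _masked_contrast(c: np.ndarray) -> np.ndarray:
    p = _QCB_PARAMS
    ac = np.abs(c)
    return ac ** p["p"] / (ac ** p["q"] + p["Z"])


def q_cb(a, b, f) -> float:
    """Chen-Blum perceptual index in five stages.

    CSF filtering -> Peli local contrast -> contrast masking -> per-pixel
    preservation ratio against each source (clamped at 1) -> saliency
    weights ``lambda_A = C_A^2 / (C_A^2 + C_B^2)`` mixing the two ratio
    maps; the mean of the global quality map is reported.
    """
    qa, qb, qf = _check_triple(a, b, f)
    ca = _masked_contrast(_peli_contrast(_csf_filter(qa)))
    cb = _masked_contrast(_peli_contrast(_csf_filter(qb)))
    cf = _masked_contrast(_peli_contrast(_csf_filter(qf)))

    def ratio(cs, cf):
        hi = np.maximum(cs, cf)
        lo = np.minimum(cs, cf)
        return np.where(hi > 0, np.divide(lo, np.where(hi > 0, hi, 1.0)), 1.0)

    q_af = ratio(ca, cf)
    q_bf = ratio(cb, cf)
    sal = ca**2 + cb**2
    lam_a = np.where(sal > 0, np.divide(ca**2, np.where(sal > 0, sal, 1.0)), 0.5)
    gqm = lam_a * q_af + (1.0 - lam_a) * q_bf
    return float(gqm.mean())


def evaluate_all(a, b, f, q: float = 1.85) -> MetricReport:
    """Compute all four metrics for a (source A, source B, fused F) triple."""
    params = {
        "tsallis_q": q,
        "histogram_bins": 256,
        "q_te_normalization": "I_q(A;F)/(H_q(A)+H_q(F)) + I_q(B;F)/(H_q(B)+H_q(F))",
        "q_g": dict(_QG_PARAMS),
        "ssim_C1": _SSIM_C1,
        "ssim_C2": _SSIM_C2,
        "q_c_window": 8,
        "q_cb": dict(_QCB_PARAMS),
    }
    return MetricReport(
        q_te=q_te(a, b, f, q=q),
        q_g=q_g(a, b, f),
        q_c=q_c(a, b, f),
        q_cb=q_cb(a, b, f),
        params=params,
    )
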