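"""Latent low-rank representation (LatLRR) and its multi-layer iteration.

A grayscale image ``X`` (rows x columns, intensities in [0, 1]) is split as

    X = X Z + L X + E,
    min ||Z||_* + ||L||_* + lambda ||E||_1  s.t.  X = XZ + LX + E,

where ``XZ`` is the low-rank part (global structure and brightness),
``LX`` is the saliency part (edges and local structure) and ``E`` is a
sparse residual.  The problem is solved with an inexact augmented
Lagrange multiplier (ALM) scheme using the auxiliary splitting
``J = Z``, ``S = L`` so that both nuclear-norm proximal steps reduce to
singular value thresholding.

The multi-layer decomposition re-decomposes the low-rank part: at layer
``i`` the solver runs on ``X_{i-1}``, the saliency part ``L_i X_{i-1}``
is stored, and the next input is ``X_i = X_{i-1} Z_i + E_i``.  The sparse
residual is folded forward (and into the terminal low-rank part) rather
than discarded, since fine texture in medical images can carry diagnostic
information; this also makes the telescoping identity

    sum_i saliency_i + terminal_lowrank = X

hold up to the per-layer solver residuals.

The whole image matrix is decomposed at once; there is no patch or
sliding-window sampling.  The solver is fully deterministic: identical
input and configuration give bitwise-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, ConvergenceWarning

__all__ = [
    "SolverConfig",
    "LatLRRComponents",
    "DecompositionStack",
    "soft_threshold",
    "svt",
    "solve_latlrr",
    "decompose_multi",
]


@dataclass(frozen=True)
class SolverConfig:
    """Inexact-ALM schedule for the LatLRR problem.

    Parameters
    ----------
    lam : float
        Balance coefficient ``lambda`` on the l1 term; trades sparsity of
        the residual against the nuclear norms.  0.8 is the customary
        value for LatLRR-based fusion on [0, 1] intensities.
    mu0, rho, mu_max : float
        Initial penalty, growth factor and cap of the ALM penalty
        ``mu``; standard inexact-ALM settings for LRR-family problems.
    tol : float
        Convergence tolerance on the max-norm of the constraint residual
        and both splitting gaps.
    max_iter : int
        Iteration cap; hitting it raises a ConvergenceWarning, not an
        error (a slightly unconverged decomposition is still usable and
        the residual is always reported).
    """

    lam: float = 0.8
    mu0: float = 1e-6
    rho: float = 1.1
    mu_max: float = 1e10
    tol: float = 1e-7
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if self.mu0 <= 0 or self.mu_max <= 0 or self.mu0 >= self.mu_max:
            raise ValueError("require 0 < mu0 < mu_max")
        if self.rho <= 1:
            raise ValueError("rho must exceed 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")


@dataclass(frozen=True)
class LatLRRComponents:
    """One decomposition level: coefficients, parts and solver diagnostics.

    ``lowrank_part + saliency_part + E`` reproduces the input within the
    reported residual (relative Frobenius norm of the constraint gap).
    """

    Z: np.ndarray  # (n, n), n = image columns
    L: np.ndarray  # (m, m), m = image rows
    E: np.ndarray  # (m, n)
    lowrank_part: np.ndarray  # X @ Z
    saliency_part: np.ndarray  # L @ X
    residual: float
    iterations: int
    converged: bool


@dataclass(frozen=True)
class DecompositionStack:
    """Multi-layer decomposition: N saliency parts and one terminal low-rank part.

    The terminal part includes the last layer's sparse residual so that
    the saliency parts and the terminal part sum back to the original
    image (telescoping conservation).
    """

    saliency_parts: list[np.ndarray]
    lowrank_terminal: np.ndarray
    components: list[LatLRRComponents] = field(repr=False, default_factory=list)

    @property
    def layers(self) -> int:
        return len(self.saliency_parts)

    def reconstruct(self) -> np.ndarray:
        """Sum of all saliency parts plus the terminal low-rank part."""
        return sum(self.saliency_parts) + self.lowrank_terminal


def soft_threshold(M: np.ndarray, tau: float) -> np.ndarray:
    """Elementwise shrinkage ``sign(m) * max(|m| - tau, 0)``.

    The proximal operator of ``tau * ||.||_1``.
    """
    if tau < 0:
        raise ValueError(f"tau must be nonnegative, got {tau}")
    M = np.asarray(M, dtype=np.float64)
    return np.sign(M) * np.maximum(np.abs(M) - tau, 0.0)


def svt(M: np.ndarray, tau: float) -> np.ndarray:
    """Singular value thresholding: soft-threshold the spectrum of ``M``.

    The proximal operator of ``tau * ||.||_*`` (nuclear norm): singular
    values are shrunk by ``tau`` and those below ``tau`` vanish.
    """
    if tau < 0:
        raise ValueError(f"tau must be nonnegative, got {tau}")
    M = np.asarray(M, dtype=np.float64)
    if not np.all(np.isfinite(M)):
        raise ContractError("svt input contains non-finite entries")
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    s = np.maximum(s - tau, 0.0)
    return (U * s) @ Vt


def solve_latlrr(X: np.ndarray, cfg: SolverConfig | None = None) -> LatLRRComponents:
    """Solve ``min ||Z||_* + ||L||_* + lam ||E||_1  s.t.  X = XZ + LX + E``.

    Inexact ALM with splitting ``J = Z``, ``S = L``.  Per iteration, in
    this frozen order (the landscape is nonconvex in the splitting, so
    the order is part of the reproducibility contract):

    1. ``J  <- svt(Z + Y2/mu, 1/mu)``
    2. ``S  <- svt(L + Y3/mu, 1/mu)``
    3. ``Z  <- (I + X'X)^-1 (X'(X - LX - E) + J + (X'Y1 - Y2)/mu)``
    4. ``L  <- ((X - XZ - E)X' + S + (Y1 X' - Y3)/mu)(I + XX')^-1``
    5. ``E  <- soft_threshold(X - XZ - LX + Y1/mu, lam/mu)``
    6. multiplier ascent on Y1, Y2, Y3; then ``mu <- min(rho mu, mu_max)``

    Stops when ``max(||X-XZ-LX-E||_inf, ||Z-J||_inf, ||L-S||_inf) < tol``.
    Both normal-equation matrices are symmetric positive definite, so the
    inverses always exist and are precomputed once.
    """
    if cfg is None:
        cfg = SolverConfig()
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError(f"X must be a matrix of at least 2x2, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ContractError("X contains non-finite entries")

    m, n = X.shape
    Xt = X.T
    inv_n = np.linalg.inv(np.eye(n) + Xt @ X)
    inv_m = np.linalg.inv(np.eye(m) + X @ Xt)

    Z = np.zeros((n, n))
    L = np.zeros((m, m))
    E = np.zeros((m, n))
    Y1 = np.zeros((m, n))
    Y2 = np.zeros((n, n))
    Y3 = np.zeros((m, m))
    mu = cfg.mu0

    converged = False
    iterations = 0
    R = X.copy()
    for iterations in range(1, cfg.max_iter + 1):
        J = svt(Z + Y2 / mu, 1.0 / mu)
        S = svt(L + Y3 / mu, 1.0 / mu)
        LX = L @ X
        Z = inv_n @ (Xt @ (X - LX - E) + J + (Xt @ Y1 - Y2) / mu)
        XZ = X @ Z
        L = ((X - XZ - E) @ Xt + S + (Y1 @ Xt - Y3) / mu) @ inv_m
        LX = L @ X
        E = soft_threshold(X - XZ - LX + Y1 / mu, cfg.lam / mu)
        R = X - XZ - LX - E
        Y1 = Y1 + mu * R
        Y2 = Y2 + mu * (Z - J)
        Y3 = Y3 + mu * (L - S)
        mu = min(cfg.rho * mu, cfg.mu_max)
        gap = max(
            np.abs(R).max(initial=0.0),
            np.abs(Z - J).max(initial=0.0),
            np.abs(L - S).max(initial=0.0),
        )
        if gap < cfg.tol:
            converged = True
            break

    residual = float(np.linalg.norm(R) / max(1.0, np.linalg.norm(X)))
    if not converged and residual > 100 * cfg.tol:
        warnings.warn(
            f"LatLRR solver hit max_iter={cfg.max_iter} with relative residual "
            f"{residual:.3e} (> 100*tol)",
            ConvergenceWarning,
            stacklevel=2,
        )
    return LatLRRComponents(
        Z=Z,
        L=L,
        E=E,
        lowrank_part=X @ Z,
        saliency_part=L @ X,
        residual=residual,
        iterations=iterations,
        converged=converged,
    )


def decompose_multi(
    X: np.ndarray, n_layers: int, cfg: SolverConfig | None = None
) -> DecompositionStack:
    """Repeatedly decompose the low-rank part into N saliency layers.

    Layer ``i`` solves LatLRR on ``X_{i-1}`` (with ``X_0 = X``), stores
    the saliency part ``L_i X_{i-1}`` and continues with
    ``X_i = X_{i-1} Z_i + E_i``.  The terminal low-rank part is ``X_N``,
    i.e. the last low-rank part with its sparse residual superimposed.
    """
    if n_layers < 1:
        raise ValueError(f"n_layers must be at least 1, got {n_layers}")
    Xi = np.asarray(X, dtype=np.float64)
    saliency_parts: list[np.ndarray] = []
    components: list[LatLRRComponents] = []
    for _ in range(n_layers):
        comp = solve_latlrr(Xi, cfg)
        saliency_parts.append(comp.saliency_part)
        components.append(comp)
        Xi = comp.lowrank_part + comp.E
    return DecompositionStack(
        saliency_parts=saliency_parts,
        lowrank_terminal=Xi,
        components=components,
    )
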