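"""Essential dynamics: covariance, PCA, cosine-content screening and
free-energy landscapes over principal components.

The covariance matrix of Cartesian node fluctuations,
``M = ⟨(r − ⟨r⟩)(r − ⟨r⟩)ᵀ⟩`` (population divisor F, no mass weighting), is
built after iterative rigid superposition of every frame onto the ensemble
mean.  Its eigenvectors are the principal components; the projection of the
centered trajectory on PC k has variance equal to eigenvalue k.

Sampling convergence of each PC is screened by its cosine content — the
squared overlap of the projection with a half-period cosine; values near 1
are the signature of random-diffusion-like, unconverged sampling, and only
components with cosine content ≤ 0.1 are used for landscapes.

The free-energy landscape over two components is the histogram estimate
``G = −kT ln(P / P_max)`` with the occupied-bin minimum at exactly 0 and
empty bins masked (not zero).  Energies default to kT units (kT = 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import numpy.ma as ma
import scipy.linalg

from .io import Ensemble
from .metrics import iterative_superpose, superpose_frames

__all__ = [
    "CovarianceMatrix",
    "PCAResult",
    "FELGrid",
    "covariance",
    "pca",
    "cosine_content",
    "select_pcs",
    "free_energy_landscape",
]


@dataclass
class CovarianceMatrix:
    """3N×3N Cartesian covariance (Å²) with its mean structure."""

    matrix: np.ndarray
    mean_structure: np.ndarray
    n_frames: int

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=float)
        if not np.allclose(M, M.T, rtol=1e-9, atol=1e-12):
            raise ValueError("covariance matrix must be symmetric")
        self.matrix = 0.5 * (M + M.T)

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0] // 3

    def node_block(self, i: int, j: int) -> np.ndarray:
        """3×3 covariance block between nodes i and j."""
        return self.matrix[3 * i : 3 * i + 3, 3 * j : 3 * j + 3]


def covariance(
    ensemble: Ensemble,
    fit: bool = True,
    reference: np.ndarray | None = None,
) -> CovarianceMatrix:
    """Cartesian covariance of node fluctuations over the frames.

    ``fit=True`` (default) iteratively superposes every frame onto the mean
    before accumulating; this is skipped automatically for fewer than 3
    nodes, where a rigid fit is undefined.  ``reference`` anchors the fit
    orientation (e.g. to the starting structure), making the matrix
    invariant under a global rigid transform of the trajectory.
    """
    if ensemble.n_frames < 2:
        raise ValueError("covariance needs at least 2 frames")
    if fit and ensemble.n_nodes >= 3:
        frames, mean = iterative_superpose(ensemble.coords, reference=reference)
    else:
        frames = ensemble.coords
        mean = frames.mean(axis=0)
    F = frames.shape[0]
    X = frames.reshape(F, -1) - mean.ravel()
    M = (X.T @ X) / F
    return CovarianceMatrix(matrix=M, mean_structure=mean, n_frames=F)


@dataclass
class PCAResult:
    """Eigen-decomposition of a covariance matrix plus frame projections.

    ``eigenvalues`` descending (Å²); ``eigenvectors[:, k]`` the unit PC k with
    the sign convention that its largest-magnitude component is positive.
    ``cosine_contents`` covers the first up-to-20 PCs (NaN when no trajectory
    was supplied).
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    variance_fractions: np.ndarray
    cosine_contents: np.ndarray
    projections: np.ndarray | None

    @property
    def cumulative_variance(self) -> np.ndarray:
        return np.cumsum(self.variance_fractions)


def pca(
    cov: CovarianceMatrix,
    ensemble: Ensemble | None = None,
    n_keep: int | None = None,
) -> PCAResult:
    """Dense symmetric eigendecomposition of the covariance.

    When ``ensemble`` is given, frames are superposed onto the covariance's
    mean structure, centered, and projected on the first ``n_keep``
    eigenvectors (default: all).
    """
    dim = cov.matrix.shape[0]
    if n_keep is None:
        n_keep = dim
    if n_keep > dim:
        raise ValueError("n_keep exceeds 3N")
    lam, vec = scipy.linalg.eigh(cov.matrix)
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    vec = vec[:, order]
    # reproducible sign: largest-magnitude component positive
    flip = np.sign(vec[np.abs(vec).argmax(axis=0), np.arange(dim)])
    flip[flip == 0] = 1.0
    vec = vec * flip

    total = lam.sum()
    fractions = lam / total if total > 0 else np.zeros_like(lam)

    projections = None
    cosines = np.full(min(20, dim), np.nan)
    if ensemble is not None:
        frames = ensemble.coords
        if ensemble.n_nodes >= 3:
            fitted = superpose_frames(frames, cov.mean_structure)
        else:
            fitted = frames
        X = fitted.reshape(frames.shape[0], -1) - cov.mean_structure.ravel()
        projections = X @ vec[:, :n_keep]
        for k in range(min(cosines.size, n_keep)):
            cosines[k] = cosine_content(projections[:, k])
    return PCAResult(
        eigenvalues=lam,
        eigenvectors=vec,
        variance_fractions=fractions,
        cosine_contents=cosines,
        projections=projections,
    )


def cosine_content(projection: np.ndarray) -> float:
    """Cosine content of a PC projection: squared overlap with the first
    half-period cosine, ``c = (2/F) (Σ_t p_t cos(πt/F))² / Σ_t p_t²``.

    c near 1 marks diffusion-like, unconverged sampling; an all-zero series
    is defined as 0 with a warning.
    """
    p = np.asarray(projection, dtype=float)
    F = p.size
    if F < 4:
        raise ValueError("cosine content needs at least 4 frames")
    denom = np.sum(p * p)
    if denom == 0:
        warnings.warn("all-zero projection; cosine content defined as 0",
                      stacklevel=2)
        return 0.0
    t = np.arange(F)
    num = np.sum(p * np.cos(np.pi * t / F)) ** 2
    return float(2.0 / F * num / denom)


def select_pcs(
    result: PCAResult, threshold: float = 0.1, n_screen: int = 20
) -> tuple[int, int]:
    """The two highest-variance PCs (among the first ``n_screen``) whose
    cosine content passes ``≤ threshold``, in variance order.

    Raises if fewer than two pass — the standard remedy is longer sampling.
    """
    cos = result.cosine_contents[:n_screen]
    passing = [k for k in range(cos.size) if np.isfinite(cos[k]) and cos[k] <= threshold]
    if len(passing) < 2:
        raise ValueError(
            "fewer than two principal components pass the cosine-content "
            f"threshold {threshold}; sampling is not converged — extend the "
            "trajectory"
        )
    return passing[0], passing[1]


@dataclass
class FELGrid:
    """Free-energy landscape over two PC projections (kT units).

    ``free_energy`` is a masked 2-D array; empty bins are masked, occupied
    bins have minimum exactly 0.
    """

    edges_a: np.ndarray
    edges_b: np.ndarray
    free_energy: ma.MaskedArray
    temperature_kT: float

    @property
    def mask(self) -> np.ndarray:
        return ma.getmaskarray(self.free_energy)


def free_energy_landscape(
    proj_a: np.ndarray,
    proj_b: np.ndarray,
    n_bins: int = 32,
    temperature_kT: float = 1.0,
) -> FELGrid:
    """Histogram free-energy surface ``G = −kT ln(P / P_max)`` over two
    projection series of equal length."""
    a = np.asarray(proj_a, dtype=float)
    b = np.asarray(proj_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("projections must be equal-length 1-D series")
    if a.size < n_bins:
        raise ValueError("need at least n_bins frames")
    counts, edges_a, edges_b = np.histogram2d(a, b, bins=n_bins)
    occupied = counts > 0
    G = np.full_like(counts, np.nan)
    pmax = counts.max()
    G[occupied] = -temperature_kT * np.log(counts[occupied] / pmax)
    return FELGrid(
        edges_a=edges_a,
        edges_b=edges_b,
        free_energy=ma.masked_invalid(G),
        temperature_kT=temperature_kT,
    )
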