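"""Linear-mutual-information (LMI) cross-correlation maps.

The generalized correlation between two 3-D node fluctuation vectors r_i and
r_j is built from their mutual information under a Gaussian model:

    I_ij = H_i + H_j − H_ij,          H = ½ ln[(2πe)^k det Σ]
    C_ij = (1 − e^{−2 I_ij / d})^{1/2},   d = 3,

with Σ the 3×3 marginal (k = 3) or 6×6 joint (k = 6) covariance block of the
superposed trajectory.  The Gaussian (sample-covariance) plug-in estimator is
what makes the measure *linear*; unlike the Pearson cross-correlation map it
does not miss correlated motion in orthogonal directions.  C is 0 for fully
uncorrelated motion and 1 for fully correlated motion; for an isotropic
per-axis correlation ρ it equals |ρ| exactly.

Degenerate geometry (one node an exact linear copy of another) makes the
joint block singular, the mutual information infinite, and C exactly 1; the
singularity is detected on the unregularized block so the limit is exact.
Entropies are in nats; block diagonals are regularized by ε·trace(M)/3N with
ε = 1e-8 before determinants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Ensemble
from .pca import CovarianceMatrix, covariance

__all__ = [
    "LMICorrelationMatrix",
    "CorrelationDifferenceMap",
    "NonPositiveDefiniteError",
    "gaussian_entropy_terms",
    "lmi",
    "lmi_to_correlation",
    "lmi_matrix",
    "lmi_matrix_from_covariance",
    "difference_map",
]

#: default regularization ε for covariance block diagonals
DEFAULT_REGULARIZATION = 1e-8
#: relative determinant ratio below which a joint block is treated as
#: singular (fully correlated pair)
DEGENERACY_TOL = 1e-12

_LOG_2PIE = np.log(2.0 * np.pi * np.e)


class NonPositiveDefiniteError(ValueError):
    """A covariance block is not positive definite after regularization."""


def _as_matrix(cov: CovarianceMatrix | np.ndarray) -> np.ndarray:
    return cov.matrix if isinstance(cov, CovarianceMatrix) else np.asarray(cov, float)


def _epsilon(matrix: np.ndarray, regularization: float) -> float:
    return regularization * np.trace(matrix) / matrix.shape[0]


def _blocks(matrix: np.ndarray) -> np.ndarray:
    """(N, N, 3, 3) view of the 3N×3N covariance."""
    N = matrix.shape[0] // 3
    return matrix.reshape(N, 3, N, 3).transpose(0, 2, 1, 3)


def _joint_block(matrix: np.ndarray, i: int, j: int) -> np.ndarray:
    b = _blocks(matrix)
    top = np.hstack([b[i, i], b[i, j]])
    bot = np.hstack([b[j, i], b[j, j]])
    return np.vstack([top, bot])


def _entropy(sigma: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        raise NonPositiveDefiniteError(
            "covariance block not positive definite after regularization"
        )
    k = sigma.shape[0]
    return 0.5 * (k * _LOG_2PIE + logdet)


def gaussian_entropy_terms(
    cov: CovarianceMatrix | np.ndarray,
    i: int,
    j: int,
    regularization: float = DEFAULT_REGULARIZATION,
) -> tuple[float, float, float]:
    """Gaussian differential entropies (nats) of nodes i, j and their joint.

    ``H = ½ ln[(2πe)^k det Σ]`` with k = 3 (marginal) or 6 (joint); Σ is the
    corresponding block of the sample covariance (Å²), diagonally regularized.
    """
    M = _as_matrix(cov)
    eps = _epsilon(M, regularization)
    b = _blocks(M)
    H_i = _entropy(b[i, i] + eps * np.eye(3))
    H_j = _entropy(b[j, j] + eps * np.eye(3))
    H_ij = _entropy(_joint_block(M, i, j) + eps * np.eye(6))
    return H_i, H_j, H_ij


def lmi(
    cov: CovarianceMatrix | np.ndarray,
    i: int,
    j: int,
    regularization: float = DEFAULT_REGULARIZATION,
) -> float:
    """Linear mutual information I_ij = H_i + H_j − H_ij in nats (≥ 0).

    Returns ``inf`` when the joint block is singular relative to the
    marginals (exact-copy degeneracy, including i == j).
    """
    M = _as_matrix(cov)
    joint_raw = _joint_block(M, i, j)
    b = _blocks(M)
    eps = _epsilon(M, regularization)
    det_i = np.linalg.det(b[i, i] + eps * np.eye(3))
    det_j = np.linalg.det(b[j, j] + eps * np.eye(3))
    if np.linalg.det(joint_raw) <= DEGENERACY_TOL * det_i * det_j:
        return float("inf")
    H_i, H_j, H_ij = gaussian_entropy_terms(cov, i, j, regularization)
    return max(0.0, H_i + H_j - H_ij)


def lmi_to_correlation(I: float, d: int = 3) -> float:
    """Map mutual information to the generalized correlation in [0, 1]:
    ``C = (1 − e^{−2I/d})^{1/2}``; the infinite sentinel maps to exactly 1."""
    if np.isinf(I):
        return 1.0
    if I < 0:
        raise ValueError("mutual information must be non-negative")
    return float(np.sqrt(1.0 - np.exp(-2.0 * I / d)))


@dataclass
class LMICorrelationMatrix:
    """All-pairs generalized correlation C ∈ [0, 1] and the underlying LMI
    values I (nats; ``inf`` marks degenerate fully-correlated pairs)."""

    C: np.ndarray
    I: np.ndarray
    d_param: int = 3
    node_labels: list[str] | None = None

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        if not np.allclose(C, C.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if C.min() < 0 or C.max() > 1:
            raise ValueError("correlations must lie in [0, 1]")
        self.C = C

    @property
    def n_nodes(self) -> int:
        return self.C.shape[0]


def lmi_matrix_from_covariance(
    cov: CovarianceMatrix | np.ndarray,
    regularization: float = DEFAULT_REGULARIZATION,
    node_labels: list[str] | None = None,
    d: int = 3,
) -> LMICorrelationMatrix:
    """Closed-form LMI correlation matrix from a 3N×3N covariance.

    Because the (2πe)^k factors cancel, ``I_ij = ½ ln(det Σ_i det Σ_j /
    det Σ_ij)`` with regularized blocks; the determinant ratio of the
    unregularized joint block flags degenerate (C = 1) pairs.
    """
    M = _as_matrix(cov)
    N = M.shape[0] // 3
    b = _blocks(M)
    eps = _epsilon(M, regularization)

    eye3 = eps * np.eye(3)
    marg = b[np.arange(N), np.arange(N)] + eye3  # (N, 3, 3)
    det_marg = np.linalg.det(marg)
    if np.any(det_marg <= 0):
        raise NonPositiveDefiniteError("a marginal block is not positive definite")

    # assemble all joint 6×6 blocks
    joint = np.empty((N, N, 6, 6))
    joint[:, :, :3, :3] = b[np.arange(N), np.arange(N)][:, None]
    joint[:, :, 3:, 3:] = b[np.arange(N), np.arange(N)][None, :]
    joint[:, :, :3, 3:] = b
    joint[:, :, 3:, :3] = np.swapaxes(b, 2, 3)
    det_joint_raw = np.linalg.det(joint)
    joint_reg = joint + eps * np.eye(6)
    det_joint = np.linalg.det(joint_reg)

    degenerate = det_joint_raw <= DEGENERACY_TOL * det_marg[:, None] * det_marg[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        I = 0.5 * (
            np.log(det_marg)[:, None] + np.log(det_marg)[None, :] - np.log(det_joint)
        )
    I = np.clip(I, 0.0, None)
    I[degenerate] = np.inf
    np.fill_diagonal(I, np.inf)

    C = np.sqrt(1.0 - np.exp(-2.0 * np.where(np.isinf(I), 0.0, I) / d))
    C[np.isinf(I)] = 1.0
    C = 0.5 * (C + C.T)
    np.fill_diagonal(C, 1.0)
    return LMICorrelationMatrix(C=C, I=I, d_param=d, node_labels=node_labels)


def lmi_matrix(
    ensemble: Ensemble,
    regularization: float = DEFAULT_REGULARIZATION,
    fit: bool = True,
) -> LMICorrelationMatrix:
    """All-pairs LMI correlation of an ensemble (superposed by default)."""
    cov = covariance(ensemble, fit=fit)
    labels = ensemble.selection.labels if ensemble.selection is not None else None
    return lmi_matrix_from_covariance(
        cov, regularization=regularization, node_labels=labels
    )


@dataclass
class CorrelationDifferenceMap:
    """Elementwise ΔC = C_state − C_reference."""

    delta: np.ndarray
    state_label: str
    reference_label: str
    node_labels: list[str] | None = None


def difference_map(
    state: LMICorrelationMatrix,
    reference: LMICorrelationMatrix,
    state_label: str = "state",
    reference_label: str = "reference",
) -> CorrelationDifferenceMap:
    """Difference of two correlation maps (state minus reference)."""
    if state.C.shape != reference.C.shape:
        raise ValueError("correlation matrices differ in size")
    if (
        state.node_labels is not None
        and reference.node_labels is not None
        and state.node_labels != reference.node_labels
    ):
        raise ValueError("node labels differ between state and reference")
    return CorrelationDifferenceMap(
        delta=state.C - reference.C,
        state_label=state_label,
        reference_label=reference_label,
        node_labels=state.node_labels,
    )
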