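"""Anisotropic network model (ANM) and perturbation response scanning (PRS).

The ANM represents a structure as nodes (Cα / P) joined by identical harmonic
springs whenever two nodes lie within a distance cutoff (default 12 Å).  Its
3N×3N Hessian H has exactly six zero eigenvalues for a connected network
(rigid-body translations and rotations); the remaining modes approximate the
collective near-native dynamics, with mode variance proportional to 1/λ.

PRS applies a force of fixed magnitude at each node in turn and reads the
network response through linear response theory, ΔR = H⁻¹ F, where H⁻¹ is the
covariance built from the slowest non-zero modes (default 20).  Averaging the
squared displacement of node j over isotropically distributed unit forces at
node i gives the PRS map; its row means (influence exerted) are the effector
profile and its column means (sensitivity) the sensor profile.

The spring constant γ = 1 by default; all reported normalized quantities are
independent of γ and of the force magnitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse.csgraph

from .io import Ensemble

__all__ = [
    "ANMModel",
    "PRSMap",
    "DisconnectedNetworkError",
    "build_anm",
    "anm_covariance",
    "prs_scan",
    "effector_sensor",
    "averaged_prs",
]

#: eigenvalues below this fraction of the largest are treated as rigid-body
#: zero modes
ZERO_MODE_TOL = 1e-8


class DisconnectedNetworkError(ValueError):
    """The spring network is not connected (more than the rigid-body number of
    near-zero modes)."""


@dataclass
class ANMModel:
    """An assembled ANM: Hessian plus its full eigendecomposition.

    ``eigenvalues`` are ascending; ``eigenvectors[:, k]`` is the unit mode k.
    """

    reference_coords: np.ndarray
    cutoff: float
    gamma: float
    hessian: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    adjacency: np.ndarray = field(repr=False, default=None)

    @property
    def n_nodes(self) -> int:
        return self.reference_coords.shape[0]

    @property
    def n_zero_modes(self) -> int:
        lam_max = self.eigenvalues[-1]
        return int(np.sum(self.eigenvalues <= ZERO_MODE_TOL * lam_max))

    def nonzero_modes(self) -> tuple[np.ndarray, np.ndarray]:
        """(eigenvalues, eigenvectors) of the internal (non-rigid) modes."""
        k = self.n_zero_modes
        return self.eigenvalues[k:], self.eigenvectors[:, k:]


def _is_connected(adjacency: np.ndarray) -> bool:
    n_comp, _ = scipy.sparse.csgraph.connected_components(
        scipy.sparse.csr_matrix(adjacency), directed=False
    )
    return n_comp == 1


def build_anm(
    coords: np.ndarray,
    cutoff: float = 12.0,
    gamma: float = 1.0,
    spring_scale: dict[tuple[int, int], float] | None = None,
) -> ANMModel:
    """Assemble the ANM Hessian for node coordinates (N, 3) in Å.

    The 3×3 super-element for a contacting pair (i, j) is
    ``-γ_ij / |d_ij|² · d_ij d_ijᵀ``; diagonal blocks are minus the row sums,
    so block row sums vanish (translation invariance).  ``spring_scale`` maps
    unordered node pairs to multiplicative stiffness factors, used to model
    local perturbations.

    Raises :class:`DisconnectedNetworkError` when the network has more
    near-zero modes than the rigid-body count.
    """
    coords = np.asarray(coords, dtype=float)
    N = coords.shape[0]
    if N < 2:
        raise ValueError("ANM requires at least 2 nodes")
    diff = coords[:, None, :] - coords[None, :, :]  # (N, N, 3), row i minus j
    dist2 = np.einsum("ijk,ijk->ij", diff, diff)
    with np.errstate(invalid="ignore"):
        contact = (dist2 <= cutoff**2) & ~np.eye(N, dtype=bool)
    if np.any(dist2[contact] < 1e-12):
        raise ValueError("coincident nodes in ANM network")

    gmat = np.where(contact, gamma, 0.0)
    if spring_scale:
        for (i, j), factor in spring_scale.items():
            gmat[i, j] *= factor
            gmat[j, i] *= factor

    with np.errstate(divide="ignore", invalid="ignore"):
        coeff = np.where(contact, gmat / dist2, 0.0)
    blocks = -coeff[:, :, None, None] * diff[:, :, :, None] * diff[:, :, None, :]
    # translation invariance: diagonal block = -sum of off-diagonal row blocks
    idx = np.arange(N)
    blocks[idx, idx] = -blocks.sum(axis=1)
    hessian = blocks.transpose(0, 2, 1, 3).reshape(3 * N, 3 * N)
    hessian = 0.5 * (hessian + hessian.T)  # symmetrize round-off

    eigenvalues, eigenvectors = scipy.linalg.eigh(hessian)
    model = ANMModel(
        reference_coords=coords,
        cutoff=float(cutoff),
        gamma=float(gamma),
        hessian=hessian,
        eigenvalues=eigenvalues,
        eigenvectors=eigenvectors,
        adjacency=contact,
    )
    if not _is_connected(contact):
        raise DisconnectedNetworkError(
            f"spring network at cutoff {cutoff} Å is disconnected "
            f"(more than the rigid-body number of near-zero modes)"
        )
    return model


def anm_covariance(model: ANMModel, n_modes: int | None = 20) -> np.ndarray:
    """Truncated pseudo-inverse covariance over the slowest non-zero modes.

    ``Σ_k (1/λ_k) v_k v_kᵀ`` over the ``n_modes`` smallest non-zero
    eigenvalues; ``n_modes=None`` uses all internal modes, recovering the
    Moore-Penrose pseudo-inverse of the Hessian.
    """
    lam, vec = model.nonzero_modes()
    if n_modes is None:
        n_modes = lam.size
    if n_modes > lam.size:
        raise ValueError(
            f"requested {n_modes} modes but only {lam.size} non-zero modes exist"
        )
    lam = lam[:n_modes]
    vec = vec[:, :n_modes]
    return (vec / lam) @ vec.T


@dataclass
class PRSMap:
    """Perturbation-response map and derived profiles.

    ``raw_response[i, j]`` is the mean squared displacement of node j under a
    unit force at node i, averaged over isotropic force directions.
    ``normalized`` divides each row by its diagonal (self-response), making
    the map independent of γ and force magnitude.
    """

    raw_response: np.ndarray
    normalized: np.ndarray
    effector_profile: np.ndarray
    sensor_profile: np.ndarray
    n_modes_used: int
    metadata: dict = field(default_factory=dict)


def _response_blocks(cov: np.ndarray, n_nodes: int) -> np.ndarray:
    """(N, N, 3, 3) array of covariance blocks C_ij."""
    return cov.reshape(n_nodes, 3, n_nodes, 3).transpose(0, 2, 1, 3)


def effector_sensor(
    prs: "PRSMap | np.ndarray", exclude_self: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Row-mean (effector) and column-mean (sensor) profiles of a normalized
    PRS map, excluding the self-response by default."""
    mat = prs.normalized if isinstance(prs, PRSMap) else np.asarray(prs, dtype=float)
    if exclude_self:
        return effector_sensor_matrix(mat)
    return mat.mean(axis=1), mat.mean(axis=0)


def prs_scan(
    model: ANMModel,
    n_modes: int | None = 20,
    n_force_directions: int | None = None,
    seed: int | None = None,
) -> PRSMap:
    """Scan unit-force perturbations over every node.

    By default the isotropic average over force directions is evaluated in
    closed form: for a unit force uniformly distributed on the sphere,
    ⟨|C_ji f|²⟩ = (1/3)‖C_ji‖_F².  Passing ``n_force_directions`` switches to
    Monte-Carlo direction sampling (kept for validation).
    """
    N = model.n_nodes
    cov = anm_covariance(model, n_modes)
    blocks = _response_blocks(cov, N)  # blocks[i, j] = C_ij
    if n_force_directions is None:
        # raw[i, j] = (1/3) * ||C_ji||_F^2 ; C symmetric => C_ji = C_ij^T
        raw = np.einsum("ijab,ijab->ij", blocks, blocks) / 3.0
        raw = raw.T
    else:
        rng = np.random.default_rng(seed)
        dirs = rng.normal(size=(n_force_directions, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        raw = np.empty((N, N))
        for i in range(N):
            # response of every node j to forces applied at i
            resp = np.einsum("jab,db->jda", blocks[:, i], dirs)
            raw[i] = np.einsum("jda,jda->j", resp, resp) / n_force_directions
    diag = np.diag(raw).copy()
    if np.any(diag <= 0):
        raise ValueError("non-positive self-response; degenerate covariance")
    normalized = raw / diag[:, None]
    lam, _ = model.nonzero_modes()
    used = lam.size if n_modes is None else n_modes
    eff, sen = effector_sensor_matrix(normalized)
    return PRSMap(
        raw_response=raw,
        normalized=normalized,
        effector_profile=eff,
        sensor_profile=sen,
        n_modes_used=used,
        metadata={
            "scalarization": "mean squared displacement, isotropic unit force",
            "normalization": "row / self-response",
        },
    )


def effector_sensor_matrix(normalized: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    N = normalized.shape[0]
    off = ~np.eye(N, dtype=bool)
    effector = (normalized * off).sum(axis=1) / (N - 1)
    sensor = (normalized * off).sum(axis=0) / (N - 1)
    return effector, sensor


def averaged_prs(
    ensemble: Ensemble,
    n_representatives: int = 100,
    cutoff: float = 12.0,
    n_modes: int | None = 20,
) -> PRSMap:
    """PRS averaged over representative frames of an ensemble.

    Evenly spaced representative structures (default 100, or every frame when
    fewer exist) each get their own ANM and normalized PRS map; the result is
    the elementwise mean map with profiles recomputed from it.  Frames whose
    network is disconnected at the cutoff are skipped with a warning.
    """
    F = ensemble.n_frames
    n_rep = min(n_representatives, F)
    frame_ids = np.unique(np.linspace(0, F - 1, n_rep).round().astype(int))
    maps, raws = [], []
    used_modes = None
    for f in frame_ids:
        try:
            model = build_anm(ensemble.coords[f], cutoff=cutoff)
            pmap = prs_scan(model, n_modes=n_modes)
        except DisconnectedNetworkError:
            warnings.warn(
                f"frame {f}: disconnected ANM network at cutoff {cutoff} Å; skipped",
                stacklevel=2,
            )
            continue
        maps.append(pmap.normalized)
        raws.append(pmap.raw_response)
        used_modes = pmap.n_modes_used
    if not maps:
        raise DisconnectedNetworkError("every representative frame was disconnected")
    normalized = np.mean(maps, axis=0)
    raw = np.mean(raws, axis=0)
    eff, sen = effector_sensor_matrix(normalized)
    return PRSMap(
        raw_response=raw,
        normalized=normalized,
        effector_profile=eff,
        sensor_profile=sen,
        n_modes_used=used_modes,
        metadata={"n_representatives": len(maps), "frames": frame_ids.tolist()},
    )
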