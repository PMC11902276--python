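"""Independent reference implementations used only as test oracles.

These deliberately avoid the code paths of the package under test: the
rotation search does a coarse grid plus local refinement over rotation
vectors, the quaternion Kabsch uses the Davenport q-method rather than SVD,
the determinant is a recursive Laplace expansion, and betweenness is an
exhaustive all-simple-paths enumeration.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import scipy.optimize
from scipy.spatial.transform import Rotation


def rmsd_after(mobile: np.ndarray, reference: np.ndarray, R: np.ndarray) -> float:
    """RMSD of rotated, optimally translated mobile vs reference."""
    mob = (mobile - mobile.mean(axis=0)) @ R.T
    ref = reference - reference.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((mob - ref) ** 2, axis=1))))


def grid_search_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Minimal RMSD by coarse rotation-vector grid search plus local
    refinement; independent of any closed-form superposition."""
    best = (np.inf, np.zeros(3))
    for axis in itertools.product([-1.0, 0.0, 1.0], repeat=3):
        a = np.array(axis)
        norm = np.linalg.norm(a)
        if norm == 0:
            candidates = [np.zeros(3)]
        else:
            candidates = [
                a / norm * ang for ang in np.linspace(0.1, np.pi, 16)
            ]
        for rv in candidates:
            val = rmsd_after(mobile, reference, Rotation.from_rotvec(rv).as_matrix())
            if val < best[0]:
                best = (val, rv)
    res = scipy.optimize.minimize(
        lambda rv: rmsd_after(mobile, reference,
                              Rotation.from_rotvec(rv).as_matrix()),
        best[1],
        method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000},
    )
    return float(res.fun)


def quaternion_superpose(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Minimal RMSD via the Davenport q-method (largest eigenvalue of the
    4×4 key matrix), an algorithm independent of SVD-based Kabsch."""
    P = mobile - mobile.mean(axis=0)
    Q = reference - reference.mean(axis=0)
    S = P.T @ Q
    K = np.array(
        [
            [S[0, 0] + S[1, 1] + S[2, 2], S[1, 2] - S[2, 1],
             S[2, 0] - S[0, 2], S[0, 1] - S[1, 0]],
            [S[1, 2] - S[2, 1], S[0, 0] - S[1, 1] - S[2, 2],
             S[0, 1] + S[1, 0], S[0, 2] + S[2, 0]],
            [S[2, 0] - S[0, 2], S[0, 1] + S[1, 0],
             -S[0, 0] + S[1, 1] - S[2, 2], S[1, 2] + S[2, 1]],
            [S[0, 1] - S[1, 0], S[0, 2] + S[2, 0],
             S[1, 2] + S[2, 1], -S[0, 0] - S[1, 1] + S[2, 2]],
        ]
    )
    lam_max = np.linalg.eigvalsh(K)[-1]
    msd = (np.sum(P**2) + np.sum(Q**2) - 2.0 * lam_max) / P.shape[0]
    return float(np.sqrt(max(msd, 0.0)))


def laplace_det(M: np.ndarray) -> float:
    """Determinant by recursive cofactor (Laplace) expansion."""
    M = np.asarray(M, dtype=float)
    n = M.shape[0]
    if n == 1:
        return float(M[0, 0])
    total = 0.0
    rest = M[1:]
    for j in range(n):
        minor = np.delete(rest, j, axis=1)
        total += (-1.0) ** j * M[0, j] * laplace_det(minor)
    return total


def brute_betweenness(G: nx.Graph, rel_tol: float = 1e-9) -> np.ndarray:
    """Raw betweenness by exhaustive all-simple-paths enumeration with
    fractional splitting over equal-weight shortest paths."""
    nodes = sorted(G.nodes())
    bc = {v: 0.0 for v in nodes}
    for ai, a in enumerate(nodes):
        for b in nodes[ai + 1:]:
            scored = []
            for p in nx.all_simple_paths(G, a, b):
                w = sum(G[u][v].get("weight", 1.0) for u, v in zip(p, p[1:]))
                scored.append((w, p))
            if not scored:
                continue
            wmin = min(w for w, _ in scored)
            best = [p for w, p in scored if w <= wmin * (1.0 + rel_tol)]
            for p in best:
                for v in p[1:-1]:
                    bc[v] += 1.0 / len(best)
    return np.array([bc[v] for v in nodes])
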