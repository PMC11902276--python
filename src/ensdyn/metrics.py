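"""Structural metrics over coordinate ensembles.

RMSD/RMSF/radius-of-gyration/centre-of-mass distances plus geometric
hydrogen-bond and salt-bridge detection with per-frame occupancy counting.

Conventions
-----------
* All thresholds are inclusive (≤ / ≥).
* H-bond criterion: donor-acceptor distance ≤ 3.5 Å and, when a hydrogen
  position is supplied, the hydrogen-donor-acceptor angle (deviation from
  linearity measured at the donor) ≤ 30°.  This is the gmx hbond convention;
  with no hydrogen the distance criterion alone decides.
* Salt bridge: minimum distance between listed side-chain N (Arg/Lys) and
  O (Glu/Asp) atoms ≤ 4.0 Å, the conventional definition.
* Occupancies are exact integer counts n_true / n_frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .io import Ensemble, StructureModel

__all__ = [
    "DegenerateGeometryError",
    "HBondCriteria",
    "SaltBridgeCriteria",
    "OccupancyReport",
    "SaltBridge",
    "superpose",
    "superpose_frames",
    "apply_transform",
    "iterative_superpose",
    "rmsd_series",
    "rmsf",
    "radius_of_gyration",
    "com_distance_series",
    "detect_hbond",
    "hbond_occupancy",
    "detect_salt_bridges",
    "salt_bridge_occupancy",
    "mean_sd_string",
    "format_percent",
]


class DegenerateGeometryError(ValueError):
    """Superposition attempted on collinear or coincident points."""


def mean_sd_string(values: np.ndarray, decimals: int = 2) -> str:
    """Render a series as ``"mean (sd)"``, e.g. ``"1.78 (0.29)"``."""
    values = np.asarray(values, dtype=float)
    return f"{values.mean():.{decimals}f} ({values.std():.{decimals}f})"


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares (Kabsch) rigid superposition of ``mobile`` onto
    ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference`` in the
    weighted least-squares sense; the rotation is proper (det +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be (N, 3)")
    N = mobile.shape[0]
    if N < 3:
        raise DegenerateGeometryError("superposition requires at least 3 nodes")
    if weights is None:
        w = np.full(N, 1.0 / N)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (N,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()

    mob_c = mobile - w @ mobile
    ref_c = reference - w @ reference
    if (
        np.linalg.matrix_rank(ref_c, tol=1e-9) < 2
        or np.linalg.matrix_rank(mob_c, tol=1e-9) < 2
    ):
        raise DegenerateGeometryError("collinear or coincident configuration")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # align_vectors warns on near-planar sets
        rot, _ = Rotation.align_vectors(ref_c, mob_c, weights=w)
    R = rot.as_matrix()
    translation = (w @ reference) - (w @ mobile) @ R.T
    fitted = mobile @ R.T + translation
    rmsd = float(np.sqrt(np.sum(w * np.sum((fitted - reference) ** 2, axis=1))))
    return R, translation, rmsd


def apply_transform(
    coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray
) -> np.ndarray:
    return coords @ rotation.T + translation


def _kabsch_batch(
    frames: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Batched unit-weight Kabsch: rotations (F, 3, 3) and translations
    (F, 3) fitting each frame onto the reference."""
    frames = np.asarray(frames, dtype=float)
    reference = np.asarray(reference, dtype=float)
    ref_centroid = reference.mean(axis=0)
    ref_c = reference - ref_centroid
    centroids = frames.mean(axis=1)
    mob_c = frames - centroids[:, None, :]
    H = np.einsum("fni,nj->fij", mob_c, ref_c)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(np.einsum("fji,fkj->fik", Vt, U)))
    Vt = Vt.copy()
    Vt[:, -1, :] *= d[:, None]
    R = np.einsum("fji,fkj->fik", Vt, U)  # R_f = V_f diag(1,1,d) U_f^T
    t = ref_centroid - np.einsum("fij,fj->fi", R, centroids)
    return R, t


def superpose_frames(frames: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Kabsch-fit every frame of an (F, N, 3) stack onto one reference.

    Vectorized over frames (batched 3×3 SVD with the proper-rotation sign
    correction); equivalent to calling :func:`superpose` per frame with unit
    weights.
    """
    R, t = _kabsch_batch(frames, reference)
    return np.einsum("fni,fji->fnj", np.asarray(frames, float), R) + t[:, None, :]


def iterative_superpose(
    coords: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 100,
    reference: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Superpose every frame onto the ensemble mean, iterating mean and fit
    until the mean structure moves by less than ``tol`` Å.

    ``reference`` anchors the orientation of the converged frame set: the
    first fit targets it instead of the raw-frame mean, which makes the
    result invariant under a global rigid transform of the input trajectory.
    Returns ``(fitted_frames, mean_structure)``.
    """
    frames = np.array(coords, dtype=float, copy=True)
    mean = frames.mean(axis=0) if reference is None else np.asarray(reference,
                                                                    float)
    for _ in range(max_iter):
        frames = superpose_frames(frames, mean)
        new_mean = frames.mean(axis=0)
        if np.max(np.abs(new_mean - mean)) < tol:
            mean = new_mean
            break
        mean = new_mean
    return frames, mean


# ---------------------------------------------------------------------------
# RMSD / RMSF / Rg / COM
# ---------------------------------------------------------------------------

def _as_index(sel, n: int) -> np.ndarray:
    if sel is None:
        return np.arange(n)
    idx = np.asarray(sel, dtype=int)
    if idx.size == 0:
        raise ValueError("empty node selection")
    return idx


def rmsd_series(
    ensemble: Ensemble,
    reference: np.ndarray,
    fit_selection: Sequence[int] | None = None,
    measure_selection: Sequence[int] | None = None,
) -> np.ndarray:
    """Per-frame RMSD (Å) to a reference after rigid fitting.

    Each frame is superposed on ``fit_selection`` (default: the measured
    selection, matching gmx rms with a single group) and the RMSD is measured
    over ``measure_selection`` (default: all nodes).
    """
    N = ensemble.n_nodes
    measure = _as_index(measure_selection, N)
    fit = _as_index(fit_selection, N) if fit_selection is not None else measure
    ref = np.asarray(reference, dtype=float)
    if fit.size < 3:
        raise DegenerateGeometryError("fit selection needs at least 3 nodes")
    R, t = _kabsch_batch(ensemble.coords[:, fit], ref[fit])
    fitted = (
        np.einsum("fni,fji->fnj", ensemble.coords[:, measure], R)
        + t[:, None, :]
    )
    d = fitted - ref[measure]
    return np.sqrt(np.mean(np.sum(d * d, axis=2), axis=1))


def rmsf(
    ensemble: Ensemble, fit: bool = True, reference: np.ndarray | None = None
) -> np.ndarray:
    """Per-node root-mean-square fluctuation about the ensemble mean (Å).

    With ``fit=True`` every frame is first superposed onto the (iteratively
    converged) mean structure, removing rigid-body motion.
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    if fit and ensemble.n_nodes >= 3:
        frames, mean = iterative_superpose(ensemble.coords, reference=reference)
    else:
        frames = ensemble.coords
        mean = frames.mean(axis=0)
    d = frames - mean
    return np.sqrt(np.mean(np.sum(d * d, axis=2), axis=0))


def radius_of_gyration(frame: np.ndarray, masses: np.ndarray | None = None) -> float:
    """Radius of gyration (Å); unit masses by default."""
    frame = np.asarray(frame, dtype=float)
    if masses is None:
        m = np.ones(frame.shape[0])
    else:
        m = np.asarray(masses, dtype=float)
    com = (m[:, None] * frame).sum(axis=0) / m.sum()
    d2 = np.sum((frame - com) ** 2, axis=1)
    return float(np.sqrt((m * d2).sum() / m.sum()))


def com_distance_series(
    ensemble: Ensemble,
    group_a: Sequence[int],
    group_b: Sequence[int],
    masses: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame distance between group centroids (geometric by default)."""
    a = _as_index(group_a, ensemble.n_nodes)
    b = _as_index(group_b, ensemble.n_nodes)
    if set(a.tolist()) & set(b.tolist()):
        raise ValueError("groups must be disjoint")
    if masses is None:
        ca = ensemble.coords[:, a].mean(axis=1)
        cb = ensemble.coords[:, b].mean(axis=1)
    else:
        m = np.asarray(masses, dtype=float)
        ca = (m[a][None, :, None] * ensemble.coords[:, a]).sum(axis=1) / m[a].sum()
        cb = (m[b][None, :, None] * ensemble.coords[:, b]).sum(axis=1) / m[b].sum()
    return np.linalg.norm(ca - cb, axis=1)


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HBondCriteria:
    """Geometric H-bond criterion: d(D···A) ≤ 3.5 Å, ∠(H-D-A) ≤ 30°."""

    max_donor_acceptor_distance: float = 3.5
    angle_cutoff: float = 30.0

    def __post_init__(self) -> None:
        if self.max_donor_acceptor_distance <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0 < self.angle_cutoff < 180:
            raise ValueError("angle cutoff must lie in (0, 180) degrees")


def detect_hbond(
    donor: np.ndarray,
    acceptor: np.ndarray,
    hydrogen: np.ndarray | None = None,
    criteria: HBondCriteria = HBondCriteria(),
) -> bool:
    """True iff the donor-acceptor pair satisfies the H-bond criterion.

    Both thresholds are inclusive; without a hydrogen position the angle test
    is skipped (donor-acceptor geometry only).
    """
    donor = np.asarray(donor, dtype=float)
    acceptor = np.asarray(acceptor, dtype=float)
    if np.linalg.norm(acceptor - donor) > criteria.max_donor_acceptor_distance:
        return False
    if hydrogen is None:
        return True
    dh = np.asarray(hydrogen, dtype=float) - donor
    da = acceptor - donor
    denom = np.linalg.norm(dh) * np.linalg.norm(da)
    if denom == 0:
        return True
    cosang = np.clip(np.dot(dh, da) / denom, -1.0, 1.0)
    return bool(np.degrees(np.arccos(cosang)) <= criteria.angle_cutoff)


@dataclass(frozen=True)
class OccupancyReport:
    """Exact occupancy of a per-frame binary interaction."""

    label: str
    n_frames: int
    n_true: int

    @property
    def occupancy(self) -> float:
        return self.n_true / self.n_frames

    @property
    def percent(self) -> float:
        return 100.0 * self.n_true / self.n_frames

    def __str__(self) -> str:
        return f"{self.label} ({format_percent(self.percent)})"


def format_percent(pct: float) -> str:
    """Percent rounded to 2 decimals with trailing zeros trimmed, keeping at
    least one decimal: 73/100 → "73.0", 73.04 → "73.04"."""
    s = f"{pct:.2f}".rstrip("0")
    return s + "0" if s.endswith(".") else s


def hbond_occupancy(
    donor: np.ndarray,
    acceptor: np.ndarray,
    hydrogen: np.ndarray | None = None,
    criteria: HBondCriteria = HBondCriteria(),
    label: str = "hbond",
) -> OccupancyReport:
    """Apply the H-bond criterion per frame; exact integer counting.

    ``donor``/``acceptor`` (and optional ``hydrogen``) are (F, 3) coordinate
    series of the monitored atoms.
    """
    donor = np.atleast_2d(np.asarray(donor, dtype=float))
    acceptor = np.atleast_2d(np.asarray(acceptor, dtype=float))
    if donor.shape != acceptor.shape:
        raise ValueError("donor and acceptor series must have equal shape")
    F = donor.shape[0]
    n_true = sum(
        detect_hbond(
            donor[f],
            acceptor[f],
            None if hydrogen is None else np.asarray(hydrogen)[f],
            criteria,
        )
        for f in range(F)
    )
    return OccupancyReport(label=label, n_frames=F, n_true=int(n_true))


# ---------------------------------------------------------------------------
# Salt bridges
# ---------------------------------------------------------------------------

_ONE_LETTER = {"ARG": "R", "LYS": "K", "GLU": "E", "ASP": "D", "HIS": "H"}


def _short_label(resname: str, resid: int) -> str:
    return f"{_ONE_LETTER.get(resname, resname)}{resid}"


@dataclass(frozen=True)
class SaltBridgeCriteria:
    """Salt-bridge criterion: min side-chain N···O distance ≤ 4.0 Å."""

    max_ON_distance: float = 4.0
    basic_atoms: dict = field(
        default_factory=lambda: {"ARG": ("NH1", "NH2", "NE"), "LYS": ("NZ",)}
    )
    acidic_atoms: dict = field(
        default_factory=lambda: {"GLU": ("OE1", "OE2"), "ASP": ("OD1", "OD2")}
    )

    def __post_init__(self) -> None:
        if self.max_ON_distance <= 0:
            raise ValueError("distance cutoff must be positive")


@dataclass(frozen=True)
class SaltBridge:
    basic_chain: str
    basic_resid: int
    basic_resname: str
    acidic_chain: str
    acidic_resid: int
    acidic_resname: str
    min_distance: float

    @property
    def label(self) -> str:
        return (
            f"{_short_label(self.basic_resname, self.basic_resid)}-"
            f"{_short_label(self.acidic_resname, self.acidic_resid)}"
        )


def _charged_residues(model: StructureModel, atom_table: dict) -> dict:
    """Map (chain, resid, resname) → list of coordinates of listed atoms."""
    out: dict[tuple[str, int, str], list[np.ndarray]] = {}
    wanted: dict[tuple[str, int, str], set[str]] = {}
    for a in model.atoms:
        if a.resname in atom_table and a.name in atom_table[a.resname]:
            out.setdefault((a.chain, a.resid, a.resname), []).append(a.coords)
            wanted.setdefault((a.chain, a.resid, a.resname), set()).add(a.name)
    for key, names in wanted.items():
        expected = set(atom_table[key[2]])
        if names != expected:
            warnings.warn(
                f"residue {key[0]}:{key[1]} ({key[2]}) missing side-chain atoms "
                f"{sorted(expected - names)}; using the atoms present",
                stacklevel=3,
            )
    return out


def detect_salt_bridges(
    model: StructureModel, criteria: SaltBridgeCriteria = SaltBridgeCriteria()
) -> list[SaltBridge]:
    """Salt bridges present in one frame: basic/acidic residue pairs whose
    minimum listed N···O distance is within the cutoff (inclusive)."""
    basics = _charged_residues(model, criteria.basic_atoms)
    acidics = _charged_residues(model, criteria.acidic_atoms)
    bridges = []
    for (bch, bres, bname), bcoords in basics.items():
        for (ach, ares, aname), acoords in acidics.items():
            d = min(
                float(np.linalg.norm(bc - ac)) for bc in bcoords for ac in acoords
            )
            if d <= criteria.max_ON_distance:
                bridges.append(
                    SaltBridge(bch, bres, bname, ach, ares, aname, min_distance=d)
                )
    return sorted(bridges, key=lambda b: (b.basic_chain, b.basic_resid,
                                          b.acidic_chain, b.acidic_resid))


def salt_bridge_occupancy(
    frames: Sequence[StructureModel],
    criteria: SaltBridgeCriteria = SaltBridgeCriteria(),
) -> pd.DataFrame:
    """Per-pair salt-bridge occupancy over a sequence of frames.

    Returns a tidy table with columns label, n_frames, n_bridged,
    occupancy_percent and formatted (the conventional "R83-E86 (73.04)"
    rendering).
    """
    counts: dict[str, int] = {}
    for model in frames:
        for bridge in detect_salt_bridges(model, criteria):
            counts[bridge.label] = counts.get(bridge.label, 0) + 1
    F = len(frames)
    rows = [
        {
            "label": label,
            "n_frames": F,
            "n_bridged": n,
            "occupancy_percent": 100.0 * n / F,
            "formatted": f"{label} ({format_percent(100.0 * n / F)})",
        }
        for label, n in sorted(counts.items())
    ]
    return pd.DataFrame(
        rows,
        columns=["label", "n_frames", "n_bridged", "occupancy_percent", "formatted"],
    )
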