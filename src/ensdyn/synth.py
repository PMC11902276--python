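"""Synthetic coordinate ensembles with known ground truth.

Real microsecond protein-DNA trajectories are neither small nor analytically
characterized, so every downstream stage here is validated against
constructed inputs instead:

* a clash-free toy protein-DNA complex — one Cα pseudo-atom per protein
  residue on a helical trace, one P pseudo-atom per nucleotide on a straight
  backbone trace offset from the helix;
* Gaussian ensembles drawn from the covariance implied by the toy complex's
  own anisotropic network model (ANM), so the true 3N×3N covariance, true
  LMI correlation matrix and true per-node fluctuations are all known in
  closed form;
* designed binary interaction series whose H-bond / salt-bridge occupancies
  are exact by construction.

Frames are sampled in the internal (non-rigid) mode space, so generated
ensembles carry no rigid-body drift; downstream superposition is still
applied by default, which keeps the Kabsch machinery exercised without
confounding the covariance comparisons.  Every stochastic operation takes an
explicit integer seed; there is no global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .anm import build_anm
from .io import Atom, DomainAnnotation, Ensemble, NodeSelection, StructureModel
from .lmi import lmi_matrix_from_covariance

__all__ = [
    "ToyComplexSpec",
    "GroundTruth",
    "EventSeries",
    "GeometryError",
    "build_toy_complex",
    "toy_selection",
    "sample_anm_ensemble",
    "make_event_series",
    "make_correlated_pair",
    "write_ground_truth",
    "read_ground_truth",
]


class GeometryError(ValueError):
    """Generated geometry produced clashing nodes (< 1 Å apart)."""


@dataclass(frozen=True)
class ToyComplexSpec:
    """Geometry of a scaled-down protein-DNA node complex.

    ``rise`` is the consecutive Cα-Cα spacing (Å) along the helical protein
    trace (default 3.8 Å, the canonical value); ``helix_pitch`` is the axial
    advance per turn and ``helix_radius`` the trace radius — the per-residue
    turn angle is solved from the three so consecutive spacing equals the
    rise exactly.  DNA P nodes lie on a straight line parallel to the helix
    axis at ``dna_axis_distance`` Å with ``dna_rise`` Å spacing (~7 Å, the
    B-DNA P-P step).
    """

    n_protein_nodes: int = 60
    n_dna_nodes: int = 8
    rise: float = 3.8
    helix_pitch: float = 5.5
    helix_radius: float = 2.3
    dna_rise: float = 7.0
    dna_axis_distance: float = 9.5
    domain_ranges: DomainAnnotation | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_protein_nodes < 4:
            raise ValueError("need at least 4 protein nodes")
        if self.n_dna_nodes < 0:
            raise ValueError("n_dna_nodes must be non-negative")


def _turn_angle(spec: ToyComplexSpec) -> float:
    """Per-residue turn angle making consecutive node spacing equal the rise."""

    def gap(theta: float) -> float:
        chord = 2.0 * spec.helix_radius * np.sin(theta / 2.0)
        axial = spec.helix_pitch * theta / (2.0 * np.pi)
        return chord**2 + axial**2 - spec.rise**2

    if gap(np.pi) < 0:
        raise GeometryError("helix radius/pitch too small for the requested rise")
    return float(scipy.optimize.brentq(gap, 1e-9, np.pi))


def build_toy_complex(spec: ToyComplexSpec) -> StructureModel:
    """Deterministic node-level structure for a spec: protein chain A
    (residues 1..n, one CA each), DNA chain B (one P per nucleotide)."""
    theta = _turn_angle(spec)
    axial = spec.helix_pitch * theta / (2.0 * np.pi)
    n = spec.n_protein_nodes
    k = np.arange(n)
    protein = np.column_stack(
        [
            spec.helix_radius * np.cos(k * theta),
            spec.helix_radius * np.sin(k * theta),
            k * axial,
        ]
    )
    atoms = [
        Atom(
            serial=i + 1,
            name="CA",
            resname="ALA",
            resid=i + 1,
            chain="A",
            coords=protein[i],
            element="C",
        )
        for i in range(n)
    ]
    if spec.n_dna_nodes:
        m = spec.n_dna_nodes
        z0 = protein[:, 2].mean() - spec.dna_rise * (m - 1) / 2.0
        dna = np.column_stack(
            [
                np.full(m, spec.dna_axis_distance),
                np.zeros(m),
                z0 + np.arange(m) * spec.dna_rise,
            ]
        )
        atoms += [
            Atom(
                serial=n + i + 1,
                name="P",
                resname="DT",
                resid=i + 1,
                chain="B",
                coords=dna[i],
                element="P",
            )
            for i in range(m)
        ]
    model = StructureModel(atoms=atoms, title="toy protein-DNA complex")
    coords = model.coordinates
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
    np.fill_diagonal(d, np.inf)
    if d.min() < 1.0:
        raise GeometryError(f"inter-node clash: min distance {d.min():.3f} Å")
    return model


def toy_selection(spec: ToyComplexSpec) -> NodeSelection:
    """Node selection matching :func:`build_toy_complex` output order."""
    nodes = [("A", i + 1, "CA") for i in range(spec.n_protein_nodes)]
    nodes += [("B", i + 1, "P") for i in range(spec.n_dna_nodes)]
    return NodeSelection(
        nodes=tuple(nodes),
        n_protein=spec.n_protein_nodes,
        n_dna=spec.n_dna_nodes,
    )


@dataclass
class GroundTruth:
    """Analytic truth for a generated ensemble."""

    true_covariance: np.ndarray
    true_lmi_correlation: np.ndarray
    designed_occupancies: dict[str, float] = field(default_factory=dict)

    def node_variance_trace(self, i: int) -> float:
        """Trace of node i's 3×3 covariance block (analytic RMSF²)."""
        return float(np.trace(self.true_covariance[3 * i : 3 * i + 3,
                                                   3 * i : 3 * i + 3]))


def sample_anm_ensemble(
    model: StructureModel,
    cutoff: float = 12.0,
    n_frames: int = 1000,
    temperature_scale: float = 1.0,
    seed: int = 0,
    selection: NodeSelection | None = None,
    spring_scale: dict[tuple[int, int], float] | None = None,
) -> tuple[Ensemble, GroundTruth]:
    """Draw i.i.d. frames from the Gaussian implied by the model's ANM.

    The covariance is ``temperature_scale ×`` the pseudo-inverse of the ANM
    Hessian (all internal modes); sampling happens in mode space, so the six
    rigid-body modes carry exactly zero variance.  ``spring_scale`` perturbs
    selected spring stiffnesses, emulating a local modification.  Returns the
    ensemble and the matching :class:`GroundTruth` (true covariance and the
    closed-form LMI correlation computed from it).
    """
    if n_frames < 2:
        raise ValueError("n_frames must be at least 2")
    coords = model.coordinates
    anm = build_anm(coords, cutoff=cutoff, spring_scale=spring_scale)
    lam, vec = anm.nonzero_modes()
    cov_true = temperature_scale * (vec / lam) @ vec.T
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(size=(n_frames, lam.size))
    disp = (z * np.sqrt(temperature_scale / lam)) @ vec.T
    frames = coords[None, :, :] + disp.reshape(n_frames, coords.shape[0], 3)
    ensemble = Ensemble(
        coords=frames,
        selection=selection,
        provenance=(
            f"ANM Gaussian ensemble: cutoff={cutoff} Å, "
            f"scale={temperature_scale} Å², seed={seed}"
        ),
    )
    if temperature_scale > 0:
        true_lmi = lmi_matrix_from_covariance(cov_true).C
    else:
        # motionless limit: correlation undefined, identity by convention
        true_lmi = np.eye(coords.shape[0])
    truth = GroundTruth(true_covariance=cov_true, true_lmi_correlation=true_lmi)
    return ensemble, truth


@dataclass
class EventSeries:
    """Designed per-frame interaction geometry with a known occupancy.

    ``donor``/``acceptor`` (and ``hydrogen`` for H-bonds) are (F, 3) series;
    for salt bridges read them as the basic-N and acidic-O positions.  The
    bound geometry places the pair at ``bound_distance`` with a linear
    hydrogen; unbound frames sit at ``unbound_distance``.
    """

    series: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    hydrogen: np.ndarray | None
    designed_occupancy: float

    @property
    def realized_occupancy(self) -> float:
        return float(self.series.mean())

    @property
    def n_true(self) -> int:
        return int(self.series.sum())


def make_event_series(
    n_frames: int,
    occupancy: float,
    seed: int = 0,
    pattern: str = "block",
    kind: str = "hbond",
    bound_distance: float = 2.9,
    unbound_distance: float = 5.0,
) -> EventSeries:
    """Binary interaction series with a prescribed occupancy.

    ``pattern="block"`` packs exactly ``round(occupancy × n_frames)``
    satisfying frames first; ``"bernoulli"`` draws i.i.d. with the occupancy
    as probability and reports the realized fraction.
    """
    if not 0.0 <= occupancy <= 1.0:
        raise ValueError("occupancy must lie in [0, 1]")
    if pattern == "block":
        k = int(round(occupancy * n_frames))
        series = np.zeros(n_frames, dtype=bool)
        series[:k] = True
    elif pattern == "bernoulli":
        rng = np.random.default_rng(seed)
        series = rng.random(n_frames) < occupancy
    else:
        raise ValueError(f"unknown pattern {pattern!r}")

    donor = np.zeros((n_frames, 3))
    dist = np.where(series, bound_distance, unbound_distance)
    acceptor = np.zeros((n_frames, 3))
    acceptor[:, 0] = dist
    hydrogen = None
    if kind == "hbond":
        hydrogen = np.zeros((n_frames, 3))
        hydrogen[:, 0] = 1.0  # linear D-H···A, zero deviation angle
    elif kind != "saltbridge":
        raise ValueError(f"unknown kind {kind!r}")
    return EventSeries(
        series=series,
        donor=donor,
        acceptor=acceptor,
        hydrogen=hydrogen,
        designed_occupancy=occupancy,
    )


def make_correlated_pair(
    n_frames: int, rho: float, seed: int = 0, offset: float = 10.0
) -> Ensemble:
    """Two 3-D nodes whose per-axis coordinates are bivariate Gaussian with
    correlation ``rho`` (axes independent, unit variance).

    ``rho = 1`` makes node 2 an exact copy of node 1 plus a fixed offset; the
    closed-form LMI correlation of this construction is exactly |rho|.
    """
    if abs(rho) > 1:
        raise ValueError("|rho| must be at most 1")
    rng = np.random.default_rng(seed)
    x1 = rng.standard_normal(size=(n_frames, 3))
    if abs(rho) == 1.0:
        x2 = np.sign(rho) * x1
    else:
        x2 = rho * x1 + np.sqrt(1.0 - rho**2) * rng.standard_normal(
            size=(n_frames, 3)
        )
    coords = np.stack([x1, x2 + np.array([offset, 0.0, 0.0])], axis=1)
    return Ensemble(
        coords=coords,
        provenance=f"correlated pair rho={rho}, seed={seed}",
    )


# ---------------------------------------------------------------------------
# Ground-truth sidecar files
# ---------------------------------------------------------------------------

def write_ground_truth(path_prefix: str, truth: GroundTruth) -> list[str]:
    """Write ground-truth matrices as documented plain-text files.

    ``<prefix>.cov.txt`` holds the 3N×3N covariance (Å²) and
    ``<prefix>.lmi.txt`` the N×N LMI correlation; both headers name N and
    units.  Returns the paths written.
    """
    n = truth.true_lmi_correlation.shape[0]
    cov_path = f"{path_prefix}.cov.txt"
    lmi_path = f"{path_prefix}.lmi.txt"
    np.savetxt(
        cov_path,
        truth.true_covariance,
        header=f"true covariance, N={n} nodes, shape 3Nx3N, units angstrom^2",
    )
    np.savetxt(
        lmi_path,
        truth.true_lmi_correlation,
        header=f"true LMI correlation, N={n} nodes, dimensionless in [0,1]",
    )
    return [cov_path, lmi_path]


def read_ground_truth(path_prefix: str) -> GroundTruth:
    cov = np.loadtxt(f"{path_prefix}.cov.txt")
    corr = np.loadtxt(f"{path_prefix}.lmi.txt")
    return GroundTruth(true_covariance=cov, true_lmi_correlation=corr)
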