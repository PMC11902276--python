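"""Structure and ensemble I/O for node-level dynamics analysis.

All coordinates are in ångströms, the native PDB unit; any nm input must be
converted at the boundary before entering this package.  Residue numbers are
1-based as printed in PDB files; node indices are 0-based internally.

Analysis nodes are one Cα pseudo-atom per protein residue and one phosphorus
(P) atom per nucleotide, the standard coarse selection for protein-DNA
essential-dynamics and network analyses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "StructureModel",
    "NodeSelection",
    "DomainAnnotation",
    "Ensemble",
    "POLB_DOMAINS",
    "ModelIOError",
    "MalformedStructureError",
    "ModelIndexError",
    "MissingNodeError",
    "read_structure",
    "write_structure",
    "read_ensemble",
    "write_ensemble",
    "read_frame_table",
    "write_frame_table",
    "select_nodes",
]


class ModelIOError(Exception):
    """Base class for structure/ensemble I/O failures."""


class MalformedStructureError(ModelIOError):
    """A PDB record could not be parsed (e.g. a bad coordinate field)."""


class ModelIndexError(ModelIOError, IndexError):
    """Requested MODEL index does not exist in the file."""


class MissingNodeError(ModelIOError, KeyError):
    """A selected node is absent from a frame of an ensemble."""


@dataclass(frozen=True)
class Atom:
    """A single atom record.

    ``coords`` is a length-3 float array in Å.  ``resid`` is the 1-based
    residue number as printed in the PDB file.
    """

    serial: int
    name: str
    resname: str
    resid: int
    chain: str
    coords: np.ndarray
    element: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom {self.serial}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", coords)
        if self.resid < 1:
            raise ValueError(f"atom {self.serial}: resid must be >= 1")
        if not self.name:
            raise ValueError(f"atom {self.serial}: empty atom name")


@dataclass
class StructureModel:
    """An ordered collection of atoms from one model of a structure file."""

    atoms: list[Atom]
    title: str = ""

    def __post_init__(self) -> None:
        keys = [(a.chain, a.resid, a.name) for a in self.atoms]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chain, resid, name) in model")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Å."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def atom_map(self) -> dict[tuple[str, int, str], Atom]:
        return {(a.chain, a.resid, a.name): a for a in self.atoms}

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain, None)
        return list(seen)


@dataclass(frozen=True)
class NodeSelection:
    """Ordered analysis nodes: protein Cα nodes first, then DNA P nodes.

    ``nodes[k]`` is ``(chain, resid, kind)`` with ``kind`` in {"CA", "P"}.
    """

    nodes: tuple[tuple[str, int, str], ...]
    n_protein: int
    n_dna: int

    def __post_init__(self) -> None:
        if self.n_protein + self.n_dna != len(self.nodes):
            raise ValueError("n_protein + n_dna must equal the node count")
        for _, _, kind in self.nodes:
            if kind not in ("CA", "P"):
                raise ValueError(f"unknown node kind {kind!r}")

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def labels(self) -> list[str]:
        return [f"{chain}:{resid}:{kind}" for chain, resid, kind in self.nodes]

    def resids(self) -> np.ndarray:
        return np.array([resid for _, resid, _ in self.nodes], dtype=int)


#: Domain layout of DNA polymerase β used throughout the analyses: the
#: 8 kDa Lyase domain and the D (thumb), C (palm) and N (fingers) subdomains
#: of the 31 kDa polymerase domain.
POLB_DOMAINS: list[tuple[str, int, int]] = [
    ("Lyase", 10, 87),
    ("D", 90, 150),
    ("C", 151, 260),
    ("N", 261, 335),
]


@dataclass
class DomainAnnotation:
    """Inclusive residue ranges labelling structural domains."""

    ranges: list[tuple[str, int, int]] = field(
        default_factory=lambda: list(POLB_DOMAINS)
    )

    def __post_init__(self) -> None:
        spans = sorted((start, end, label) for label, start, end in self.ranges)
        for (s1, e1, l1), (s2, e2, l2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping domain ranges {l1!r} and {l2!r}")

    def label_of(self, resid: int) -> str | None:
        for label, start, end in self.ranges:
            if start <= resid <= end:
                return label
        return None


@dataclass
class Ensemble:
    """A stack of frames over a fixed node selection.

    ``coords`` has shape (F, N, 3) in Å.  ``frame_spacing`` is informational
    (time units between stored frames).
    """

    coords: np.ndarray
    selection: NodeSelection | None = None
    frame_spacing: float = 1.0
    provenance: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coords must have shape (F, N, 3)")
        if coords.shape[0] < 1:
            raise ValueError("ensemble must contain at least one frame")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates in ensemble")
        if self.selection is not None and len(self.selection) != coords.shape[1]:
            raise ValueError("selection size does not match coordinate array")
        self.coords = coords

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[1]


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

_PARSER = PDBParser(PERMISSIVE=True, QUIET=True)


def _parse_models(path: str | Path):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"structure file not found: {path}")
    try:
        structure = _PARSER.get_structure(path.stem, str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise MalformedStructureError(f"{path}: {exc}") from exc
    return list(structure)


def _model_to_structure(model, title: str) -> StructureModel:
    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            for atom in residue:
                # altlocs beyond the first are not handled; Bio.PDB's selected
                # child is taken.
                atoms.append(
                    Atom(
                        serial=int(atom.serial_number),
                        name=atom.get_name(),
                        resname=residue.get_resname().strip(),
                        resid=int(residue.id[1]),
                        chain=str(chain.id),
                        coords=np.asarray(atom.coord, dtype=float),
                        element=(atom.element or "").strip(),
                    )
                )
    return StructureModel(atoms=atoms, title=title)


def read_structure(path: str | Path, model_index: int = 0) -> StructureModel:
    """Read one model of a (possibly multi-model) PDB file.

    ``model_index`` is 0-based over MODEL records; single-model files have
    index 0.
    """
    models = _parse_models(path)
    if not models:
        raise MalformedStructureError(f"{path}: no models found")
    if not 0 <= model_index < len(models):
        raise ModelIndexError(
            f"{path}: model_index {model_index} out of range (file has {len(models)})"
        )
    return _model_to_structure(models[model_index], title=Path(path).stem)


def _format_atom_line(atom: Atom) -> str:
    name = atom.name
    # PDB column convention: short names start in column 14
    if len(name) < 4:
        name = f" {name:<3s}"
    element = atom.element or atom.name[0]
    x, y, z = atom.coords
    return (
        f"ATOM  {atom.serial % 100000:5d} {name:4s} {atom.resname:>3s} "
        f"{atom.chain:1s}{atom.resid:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
    )


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a StructureModel as a single-model PDB file."""
    lines = [f"TITLE     {model.title}"] if model.title else []
    lines += [_format_atom_line(a) for a in model.atoms]
    lines += ["TER", "END", ""]
    Path(path).write_text("\n".join(lines))


def write_ensemble(
    path: str | Path, ensemble: Ensemble, template: StructureModel
) -> None:
    """Write an ensemble as a multi-model PDB using ``template`` for atom
    identities.  ``template`` must contain exactly one atom per node, in node
    order."""
    if len(template) != ensemble.n_nodes:
        raise ValueError("template atom count does not match ensemble nodes")
    lines: list[str] = []
    if template.title:
        lines.append(f"TITLE     {template.title}")
    for f in range(ensemble.n_frames):
        lines.append(f"MODEL     {f + 1:4d}")
        for atom, xyz in zip(template.atoms, ensemble.coords[f]):
            moved = Atom(
                serial=atom.serial,
                name=atom.name,
                resname=atom.resname,
                resid=atom.resid,
                chain=atom.chain,
                coords=xyz,
                element=atom.element,
            )
            lines.append(_format_atom_line(moved))
        lines.append("ENDMDL")
    lines += ["END", ""]
    Path(path).write_text("\n".join(lines))


def read_ensemble(path: str | Path, selection: NodeSelection) -> Ensemble:
    """Read a multi-model PDB into an (F, N, 3) ensemble over ``selection``.

    Every model must contain every selected node; a missing node raises
    :class:`MissingNodeError` naming the frame and node.
    """
    models = _parse_models(path)
    if not models:
        raise MalformedStructureError(f"{path}: zero frames")
    frames = np.empty((len(models), len(selection), 3), dtype=float)
    for f, model in enumerate(models):
        structure = _model_to_structure(model, title="")
        amap = structure.atom_map()
        for k, (chain, resid, kind) in enumerate(selection.nodes):
            key = (chain, resid, kind)
            if key not in amap:
                raise MissingNodeError(
                    f"{path}: frame {f} is missing node {chain}:{resid}:{kind}"
                )
            frames[f, k] = amap[key].coords
    return Ensemble(coords=frames, selection=selection, provenance=str(path))


# ---------------------------------------------------------------------------
# Plain-text frame table
# ---------------------------------------------------------------------------

def write_frame_table(path: str | Path, ensemble: Ensemble) -> None:
    """Write an ensemble as a whitespace table: frame node x y z (Å)."""
    F, N, _ = ensemble.coords.shape
    frame_idx = np.repeat(np.arange(F), N)
    node_idx = np.tile(np.arange(N), F)
    flat = ensemble.coords.reshape(F * N, 3)
    table = np.column_stack([frame_idx, node_idx, flat])
    np.savetxt(
        path,
        table,
        fmt=["%d", "%d", "%.6f", "%.6f", "%.6f"],
        header="frame node x y z (angstrom)",
    )


def read_frame_table(path: str | Path) -> Ensemble:
    """Read a whitespace frame table (frame, node, x, y, z) into an Ensemble."""
    raw = np.loadtxt(path, ndmin=2)
    if raw.shape[1] != 5:
        raise MalformedStructureError(f"{path}: expected 5 columns, got {raw.shape[1]}")
    frames = raw[:, 0].astype(int)
    nodes = raw[:, 1].astype(int)
    F, N = frames.max() + 1, nodes.max() + 1
    if raw.shape[0] != F * N:
        raise MalformedStructureError(f"{path}: incomplete frame table")
    coords = np.empty((F, N, 3), dtype=float)
    coords[frames, nodes] = raw[:, 2:]
    return Ensemble(coords=coords, provenance=str(path))


# ---------------------------------------------------------------------------
# Node selection
# ---------------------------------------------------------------------------

def select_nodes(
    model: StructureModel,
    protein_chains: Iterable[str],
    dna_chains: Iterable[str] = (),
) -> NodeSelection:
    """Select one Cα node per protein residue and one P node per nucleotide.

    Residues lacking the expected node atom (e.g. a 5'-terminal nucleotide
    without a phosphate) are skipped with a logged warning, mirroring the
    convention that only residues carrying the node atom enter the analysis.
    """
    protein_chains = set(protein_chains)
    dna_chains = set(dna_chains)
    present = set(model.chains())
    missing = (protein_chains | dna_chains) - present
    if missing:
        raise ValueError(f"chains not present in model: {sorted(missing)}")

    by_residue: dict[tuple[str, int], dict[str, Atom]] = {}
    for a in model.atoms:
        by_residue.setdefault((a.chain, a.resid), {})[a.name] = a

    def pick(chains: set[str], kind: str) -> list[tuple[str, int, str]]:
        out = []
        for chain, resid in sorted(k for k in by_residue if k[0] in chains):
            if kind in by_residue[(chain, resid)]:
                out.append((chain, resid, kind))
            else:
                logger.warning(
                    "residue %s:%d has no %s atom; skipped from selection",
                    chain, resid, kind,
                )
        return out

    protein_nodes = pick(protein_chains, "CA")
    dna_nodes = pick(dna_chains, "P")
    return NodeSelection(
        nodes=tuple(protein_nodes + dna_nodes),
        n_protein=len(protein_nodes),
        n_dna=len(dna_nodes),
    )
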