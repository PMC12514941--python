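"""Core domain types and ensemble I/O.

A :class:`StructureEnsemble` is the shared in-memory container for one
variant: a bonded topology plus an ordered stack of coordinate frames
(angstrom), possibly concatenated from several independently seeded
replicate trajectories.  All metric modules consume this container and
never touch files themselves.

Coordinates are in Å throughout.  Topology residue numbering is
authoritative; no re-indexing is performed.  Inputs are assumed to be
whole molecules — **no periodic-boundary imaging is applied**, so
trajectories must be unwrapped before loading.  Hydrogens must be present
on protonated donors; no protonation engine is included.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from functools import cached_property
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "AtomRecord",
    "Mutation",
    "Level",
    "SelectionLevel",
    "StructureEnsemble",
    "load_ensemble",
    "write_ensemble",
    "select_atoms",
    "frame_average",
    "AA_3TO1",
    "AA_1TO3",
]

#: standard amino acids, 3-letter -> 1-letter
AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}

WATER_RESNAMES = {"HOH", "WAT", "SOL", "TIP", "TIP3", "T3P", "SPC", "H2O"}

#: heavy backbone atom names; attached hydrogens are also backbone
BACKBONE_HEAVY = {"N", "CA", "C", "O", "OXT"}


class FormatError(ValueError):
    """Raised when an input file violates the ensemble format contract."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the topology (coordinates live in the frames array)."""

    element: str
    name: str
    residue_number: int
    residue_name: str
    chain_id: str
    is_backbone: bool = False
    is_water: bool = False


_MUTATION_RE = re.compile(r"^(?P<chain>[A-Za-z0-9]+):(?P<wt>[A-Z])(?P<pos>\d+)(?P<mut>[A-Z])$")


@dataclass(frozen=True)
class Mutation:
    """A point mutation, e.g. ``Mutation("A", 92, "N", "K")`` == ``A:N92K``."""

    chain_id: str
    position: int
    wt_residue: str
    mut_residue: str

    def __post_init__(self):
        if self.wt_residue == self.mut_residue:
            raise ValueError(f"silent mutation {self}: wild-type equals mutant residue")
        for aa in (self.wt_residue, self.mut_residue):
            if aa not in AA_1TO3:
                raise ValueError(f"unknown amino acid {aa!r} in mutation {self}")

    @classmethod
    def from_string(cls, text: str) -> "Mutation":
        """Parse the ``CHAIN:WposM`` text format (e.g. ``A:N92K``)."""
        m = _MUTATION_RE.match(text.strip())
        if m is None:
            raise ValueError(f"cannot parse mutation {text!r}; expected CHAIN:WposM, e.g. A:N92K")
        return cls(m["chain"], int(m["pos"]), m["wt"], m["mut"])

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.wt_residue}{self.position}{self.mut_residue}"


class Level(str, Enum):
    """Granularity at which a metric is evaluated."""

    RESIDUE = "residue"
    SURROUNDING = "surrounding"
    WHOLE_PROTEIN = "whole_protein"


@dataclass(frozen=True)
class SelectionLevel:
    """A granularity level plus its parameters (8 Å default local radius)."""

    level: Level
    surrounding_radius: float = 8.0

    def __post_init__(self):
        if self.surrounding_radius <= 0:
            raise ValueError("surrounding_radius must be positive")


@dataclass
class StructureEnsemble:
    """Topology + aligned coordinate frames for one variant.

    ``replicate_boundaries`` holds the frame indices at which each
    replicate after the first starts, e.g. ``[10]`` for two replicates of
    ten frames.
    """

    atoms: list[AtomRecord]
    bonds: np.ndarray  # (n_bonds, 2) int atom indices
    frames: np.ndarray  # (n_frames, n_atoms, 3) float, Å
    replicate_boundaries: list[int] = field(default_factory=list)
    variant_id: str = ""

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("ensemble needs at least one frame")
        if self.frames.shape[1] != len(self.atoms):
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} != topology atom count {len(self.atoms)}"
            )
        self.bonds = np.asarray(self.bonds, dtype=int).reshape(-1, 2)
        if self.bonds.size and self.bonds.max() >= len(self.atoms):
            raise ValueError("bond index out of range")

    # -- derived views ---------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @cached_property
    def elements(self) -> np.ndarray:
        return np.array([a.element.upper() for a in self.atoms])

    @cached_property
    def names(self) -> np.ndarray:
        return np.array([a.name for a in self.atoms])

    @cached_property
    def resnums(self) -> np.ndarray:
        return np.array([a.residue_number for a in self.atoms])

    @cached_property
    def resnames(self) -> np.ndarray:
        return np.array([a.residue_name for a in self.atoms])

    @cached_property
    def chain_ids(self) -> np.ndarray:
        return np.array([a.chain_id for a in self.atoms])

    @cached_property
    def is_water(self) -> np.ndarray:
        return np.array([a.is_water for a in self.atoms])

    @cached_property
    def is_protein(self) -> np.ndarray:
        return np.array(
            [(not a.is_water) and a.residue_name in AA_3TO1 for a in self.atoms]
        )

    @cached_property
    def is_backbone(self) -> np.ndarray:
        return np.array([a.is_backbone for a in self.atoms])

    @cached_property
    def is_hydrogen(self) -> np.ndarray:
        return self.elements == "H"

    @cached_property
    def residue_keys(self) -> list[tuple[str, int]]:
        """Unique (chain, resnum) keys of protein residues, topology order."""
        seen: dict[tuple[str, int], None] = {}
        for i in np.flatnonzero(self.is_protein):
            seen.setdefault((self.atoms[i].chain_id, self.atoms[i].residue_number), None)
        return list(seen)

    @cached_property
    def residue_atoms(self) -> dict[tuple[str, int], np.ndarray]:
        """Protein residue key -> atom-index array."""
        out: dict[tuple[str, int], list[int]] = {}
        for i in np.flatnonzero(self.is_protein):
            out.setdefault((self.atoms[i].chain_id, self.atoms[i].residue_number), []).append(i)
        return {k: np.asarray(v, dtype=int) for k, v in out.items()}

    @cached_property
    def bonded(self) -> list[list[int]]:
        """Adjacency list over explicit bonds."""
        adj: list[list[int]] = [[] for _ in range(self.n_atoms)]
        for i, j in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        return adj

    def residue_name_at(self, chain_id: str, position: int) -> str:
        for a in self.atoms:
            if a.chain_id == chain_id and a.residue_number == position and not a.is_water:
                return a.residue_name
        raise KeyError(f"residue {chain_id}:{position} not found in topology")

    def validate_mutation_site(self, mutation: Mutation, is_mutant: bool = False) -> None:
        """Check the mutation position exists and carries the expected residue."""
        expected = mutation.mut_residue if is_mutant else mutation.wt_residue
        found = self.residue_name_at(mutation.chain_id, mutation.position)
        if AA_3TO1.get(found) != expected:
            raise ValueError(
                f"residue at {mutation.chain_id}:{mutation.position} is {found}, "
                f"expected {AA_1TO3[expected]} for mutation {mutation}"
            )


# ---------------------------------------------------------------------------
# I/O (delegated to MDAnalysis)
# ---------------------------------------------------------------------------


def _guess_element(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    if stripped[:2].upper() in {"CL", "BR", "NA", "MG", "ZN", "FE", "CA"} and len(name) > 1:
        # only trust two-letter metals when the PDB name is right-justified;
        # protein atom names (CA, CB...) start in column 14, handled upstream
        pass
    return stripped[0].upper()


def _backbone_flags(names: Sequence[str], elements: Sequence[str], adjacency: list[list[int]]) -> np.ndarray:
    heavy_bb = np.array([n in BACKBONE_HEAVY for n in names])
    flags = heavy_bb.copy()
    for i, el in enumerate(elements):
        if el == "H":
            flags[i] = any(heavy_bb[j] for j in adjacency[i])
    return flags


def load_ensemble(
    topology_source,
    trajectory_sources: Sequence | None = None,
    frame_stride: int = 1,
    variant_id: str | None = None,
) -> StructureEnsemble:
    """Load a structure ensemble from files.

    Parameters
    ----------
    topology_source
        A topology carrying atom *and bond* records — multi-model PDB with
        CONECT records is the portable baseline.
    trajectory_sources
        Optional coordinate files (one per replicate; XTC/DCD/PDB...).  When
        omitted, the topology's own models form a single replicate.
    frame_stride
        Keep every ``frame_stride``-th frame of each replicate.
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(topology_source), to_guess=())

    try:
        bonds = np.asarray(u.bonds.to_indices(), dtype=int)
        if bonds.size == 0:
            raise mda.exceptions.NoDataError("empty bonds")
    except (mda.exceptions.NoDataError, AttributeError) as exc:
        raise FormatError(
            f"topology {topology_source!r} carries no bond records; provide a "
            "bond-bearing topology (e.g. PDB with CONECT records or a .tpr)"
        ) from exc

    names = [a.name for a in u.atoms]
    try:
        elements = [e.capitalize() if e else _guess_element(n) for e, n in zip(u.atoms.elements, names)]
    except (mda.exceptions.NoDataError, AttributeError):
        elements = [_guess_element(n) for n in names]
    try:
        chains = list(u.atoms.chainIDs)
    except (mda.exceptions.NoDataError, AttributeError):
        chains = [s or "A" for s in u.atoms.segids]
    chains = [c if c.strip() else "A" for c in chains]
    resnames = [a.resname.strip().upper() for a in u.atoms]
    resnums = [int(a.resid) for a in u.atoms]

    adjacency: list[list[int]] = [[] for _ in range(len(u.atoms))]
    for i, j in bonds:
        adjacency[i].append(j)
        adjacency[j].append(i)
    bb = _backbone_flags(names, elements, adjacency)

    atoms = [
        AtomRecord(
            element=elements[i],
            name=names[i],
            residue_number=resnums[i],
            residue_name=resnames[i],
            chain_id=chains[i],
            is_backbone=bool(bb[i]),
            is_water=resnames[i] in WATER_RESNAMES,
        )
        for i in range(len(u.atoms))
    ]

    frames: list[np.ndarray] = []
    boundaries: list[int] = []
    if trajectory_sources:
        for src in trajectory_sources:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    uu = mda.Universe(str(topology_source), str(src), to_guess=())
            except (ValueError, IOError) as exc:
                raise FormatError(
                    f"trajectory {src!r} does not match topology: number of atoms differs or "
                    f"file is unreadable ({exc})"
                ) from exc
            if uu.atoms.n_atoms != len(atoms):
                raise FormatError(
                    f"trajectory {src!r} has {uu.atoms.n_atoms} atoms, "
                    f"topology has {len(atoms)}"
                )
            if frames:
                boundaries.append(len(frames))
            for ts in uu.trajectory[::frame_stride]:
                frames.append(ts.positions.astype(float).copy())
    else:
        for ts in u.trajectory[::frame_stride]:
            frames.append(ts.positions.astype(float).copy())

    if variant_id is None:
        variant_id = str(topology_source)
    return StructureEnsemble(
        atoms=atoms,
        bonds=bonds,
        frames=np.asarray(frames),
        replicate_boundaries=boundaries,
        variant_id=variant_id,
    )


def write_ensemble(ensemble: StructureEnsemble, path) -> None:
    """Write a multi-model PDB (with CONECT bonds) that round-trips through
    :func:`load_ensemble`."""
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    n = ensemble.n_atoms
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n_atoms=n,
            n_residues=len({(a.chain_id, a.residue_number, a.is_water) for a in ensemble.atoms}),
            atom_resindex=_residue_indices(ensemble),
            trajectory=True,
        )
        u.add_TopologyAttr("ids", list(range(1, n + 1)))
        u.add_TopologyAttr("names", list(ensemble.names))
        u.add_TopologyAttr("elements", list(ensemble.elements))
        u.add_TopologyAttr("chainIDs", list(ensemble.chain_ids))
        res_keys = _ordered_residues(ensemble)
        u.add_TopologyAttr("resnames", [k[2] for k in res_keys])
        u.add_TopologyAttr("resids", [k[1] for k in res_keys])
        u.add_TopologyAttr("segids", sorted({a.chain_id for a in ensemble.atoms}))
        u.add_bonds([tuple(b) for b in ensemble.bonds])
        u.load_new(ensemble.frames.astype(np.float32), format=MemoryReader)
        with mda.Writer(str(path), n_atoms=n, multiframe=True, bonds="all", reindex=False) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


def _ordered_residues(ensemble: StructureEnsemble) -> list[tuple[str, int, str]]:
    seen: dict[tuple[str, int, str], None] = {}
    for a in ensemble.atoms:
        seen.setdefault((a.chain_id, a.residue_number, a.residue_name), None)
    return list(seen)


def _residue_indices(ensemble: StructureEnsemble) -> np.ndarray:
    order = {k: i for i, k in enumerate(_ordered_residues(ensemble))}
    return np.array(
        [order[(a.chain_id, a.residue_number, a.residue_name)] for a in ensemble.atoms]
    )


# ---------------------------------------------------------------------------
# Selections and averaging
# ---------------------------------------------------------------------------


def select_atoms(
    ensemble: StructureEnsemble,
    mutation: Mutation,
    level: SelectionLevel | Level,
    frame_index: int = 0,
) -> np.ndarray:
    """Atom indices of a selection at one granularity for one frame.

    ``residue`` returns the mutated residue's atoms; ``surrounding`` every
    protein residue with at least one atom within the cutoff radius of any
    atom of the mutated residue *in that frame* (mutated residue included);
    ``whole_protein`` all protein atoms.  Waters are never part of a
    selection — they enter the metrics only through water bridges.
    """
    if isinstance(level, Level):
        level = SelectionLevel(level)
    key = (mutation.chain_id, mutation.position)
    if key not in ensemble.residue_atoms:
        raise KeyError(f"residue {mutation.chain_id}:{mutation.position} not in topology")

    if level.level is Level.WHOLE_PROTEIN:
        return np.flatnonzero(ensemble.is_protein)
    site = ensemble.residue_atoms[key]
    if level.level is Level.RESIDUE:
        return site

    coords = ensemble.frames[frame_index]
    protein_idx = np.flatnonzero(ensemble.is_protein)
    tree = cKDTree(coords[protein_idx])
    near = tree.query_ball_point(coords[site], r=level.surrounding_radius)
    hit_atoms = protein_idx[np.unique(np.concatenate([np.asarray(h, dtype=int) for h in near]))]
    hit_res = {(ensemble.atoms[i].chain_id, ensemble.atoms[i].residue_number) for i in hit_atoms}
    out = np.concatenate([ensemble.residue_atoms[r] for r in sorted(hit_res)])
    return np.sort(out)


def selection_residues(ensemble: StructureEnsemble, atom_indices: np.ndarray) -> list[tuple[str, int]]:
    """Residue keys represented in an atom selection, topology order."""
    keys = {(ensemble.atoms[i].chain_id, ensemble.atoms[i].residue_number) for i in atom_indices}
    return [k for k in ensemble.residue_keys if k in keys]


def frame_average(per_frame_values: Iterable[float]) -> float:
    """Arithmetic mean with equal weight per frame across all replicates."""
    values = np.asarray(list(per_frame_values), dtype=float)
    if values.size == 0:
        raise ValueError("frame_average needs at least one value")
    return float(values.mean())
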