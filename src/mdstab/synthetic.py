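"""Synthetic structure generators for testing and benchmarking.

Everything the package needs as input can be generated here with no
downloads: ideal secondary-structure peptides, seeded jitter
"trajectories", minimal hydrogen-bond / salt-bridge toy systems with
exactly prescribed geometry, and synthetic benchmark sample tables.

Backbones are built from ideal internal coordinates (NeRF chain
extension); sidechains beyond C-beta use idealized generic geometry that
preserves the bonded graph and standard PDB atom names.  Fixtures are
geometrically valid for the metrics under test but are not claimed to be
physically relaxed structures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ensemble import (
    AA_1TO3,
    AtomRecord,
    StructureEnsemble,
)

__all__ = [
    "FixtureSpec",
    "build_ideal_peptide",
    "jitter_trajectory",
    "build_hbond_toy",
    "build_bifurcated_toy",
    "build_water_bridge_toy",
    "build_salt_bridge_toy",
    "build_benchmark_samples",
]

HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-139.0, 135.0)


@dataclass
class FixtureSpec:
    """Recipe for a synthetic peptide ensemble."""

    sequence: str
    conformation: str = "helix"  # "helix" | "strand" | "custom"
    #: (phi, psi) for "custom", or one (phi, psi) pair per residue
    dihedrals: tuple[float, float] | list[tuple[float, float]] | None = None
    n_frames: int = 1
    jitter: float | dict[int, float] = 0.0  # per-axis Gaussian sigma, Å
    seed: int = 0

    def __post_init__(self):
        amps = self.jitter.values() if isinstance(self.jitter, dict) else [self.jitter]
        if any(a < 0 for a in amps):
            raise ValueError("jitter amplitudes must be >= 0")


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle: float, dihedral: float) -> np.ndarray:
    """NeRF placement: position d bonded to c with angle(b,c,d) and
    dihedral(a,b,c,d), angles in degrees."""
    ang = math.radians(angle)
    dih = math.radians(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-10:  # colinear references: pick any perpendicular
        helper = np.array([1.0, 0.0, 0.0])
        if abs(bc[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(helper, bc)
        norm = np.linalg.norm(n)
    n /= norm
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(dih),
            bond * math.sin(ang) * math.sin(dih),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# sidechain topology: resname -> list of (atom, parent); parents must be
# defined earlier in the list (or be CB/CA).  Ring closures listed apart.
_SIDECHAINS: dict[str, list[tuple[str, str]]] = {
    "ALA": [],
    "GLY": [],
    "SER": [("OG", "CB"), ("HG", "OG")],
    "CYS": [("SG", "CB"), ("HG", "SG")],
    "THR": [("OG1", "CB"), ("CG2", "CB"), ("HG1", "OG1")],
    "VAL": [("CG1", "CB"), ("CG2", "CB")],
    "LEU": [("CG", "CB"), ("CD1", "CG"), ("CD2", "CG")],
    "ILE": [("CG1", "CB"), ("CG2", "CB"), ("CD1", "CG1")],
    "MET": [("CG", "CB"), ("SD", "CG"), ("CE", "SD")],
    "PRO": [("CG", "CB"), ("CD", "CG")],
    "PHE": [("CG", "CB"), ("CD1", "CG"), ("CD2", "CG"), ("CE1", "CD1"),
            ("CE2", "CD2"), ("CZ", "CE1")],
    "TYR": [("CG", "CB"), ("CD1", "CG"), ("CD2", "CG"), ("CE1", "CD1"),
            ("CE2", "CD2"), ("CZ", "CE1"), ("OH", "CZ"), ("HH", "OH")],
    "TRP": [("CG", "CB"), ("CD1", "CG"), ("CD2", "CG"), ("NE1", "CD1"),
            ("HE1", "NE1"), ("CE2", "CD2"), ("CE3", "CD2"), ("CZ2", "CE2"),
            ("CZ3", "CE3"), ("CH2", "CZ2")],
    "ASP": [("CG", "CB"), ("OD1", "CG"), ("OD2", "CG")],
    "GLU": [("CG", "CB"), ("CD", "CG"), ("OE1", "CD"), ("OE2", "CD")],
    "ASN": [("CG", "CB"), ("OD1", "CG"), ("ND2", "CG"), ("HD21", "ND2"),
            ("HD22", "ND2")],
    "GLN": [("CG", "CB"), ("CD", "CG"), ("OE1", "CD"), ("NE2", "CD"),
            ("HE21", "NE2"), ("HE22", "NE2")],
    "LYS": [("CG", "CB"), ("CD", "CG"), ("CE", "CD"), ("NZ", "CE"),
            ("HZ1", "NZ"), ("HZ2", "NZ"), ("HZ3", "NZ")],
    "ARG": [("CG", "CB"), ("CD", "CG"), ("NE", "CD"), ("HE", "NE"),
            ("CZ", "NE"), ("NH1", "CZ"), ("NH2", "CZ"), ("HH11", "NH1"),
            ("HH12", "NH1"), ("HH21", "NH2"), ("HH22", "NH2")],
    "HIS": [("CG", "CB"), ("ND1", "CG"), ("CD2", "CG"), ("CE1", "ND1"),
            ("NE2", "CD2"), ("HD1", "ND1")],
}

_RING_CLOSURES: dict[str, list[tuple[str, str]]] = {
    "PHE": [("CZ", "CE2")],
    "TYR": [("CZ", "CE2")],
    "TRP": [("NE1", "CE2"), ("CH2", "CZ3")],
    "HIS": [("CE1", "NE2")],
    "PRO": [("CD", "N")],
}

_BOND_LENGTH = {
    ("C", "C"): 1.53, ("C", "N"): 1.47, ("C", "O"): 1.41, ("C", "S"): 1.81,
    ("C", "H"): 1.09, ("N", "H"): 1.01, ("O", "H"): 0.96, ("S", "H"): 1.34,
    ("S", "S"): 2.05,
}


def _element_of(name: str) -> str:
    return name.strip().lstrip("0123456789")[0].upper()


def _bond_length(a: str, b: str) -> float:
    key = tuple(sorted((_element_of(a), _element_of(b))))
    return _BOND_LENGTH.get(key, 1.5)


class _Builder:
    def __init__(self):
        self.names: list[str] = []
        self.elements: list[str] = []
        self.resnums: list[int] = []
        self.resnames: list[str] = []
        self.chains: list[str] = []
        self.coords: list[np.ndarray] = []
        self.bonds: list[tuple[int, int]] = []

    def add(self, name, resnum, resname, chain, xyz, bond_to=None, element=None):
        idx = len(self.names)
        self.names.append(name)
        self.elements.append(element or _element_of(name))
        self.resnums.append(resnum)
        self.resnames.append(resname)
        self.chains.append(chain)
        self.coords.append(np.asarray(xyz, dtype=float))
        if bond_to is not None:
            self.bonds.append((bond_to, idx))
        return idx

    def to_ensemble(self, variant_id="fixture", n_frames=1) -> StructureEnsemble:
        from .ensemble import WATER_RESNAMES, _backbone_flags

        adjacency: list[list[int]] = [[] for _ in self.names]
        for i, j in self.bonds:
            adjacency[i].append(j)
            adjacency[j].append(i)
        bb = _backbone_flags(self.names, self.elements, adjacency)
        atoms = [
            AtomRecord(
                element=self.elements[i],
                name=self.names[i],
                residue_number=self.resnums[i],
                residue_name=self.resnames[i],
                chain_id=self.chains[i],
                is_backbone=bool(bb[i]),
                is_water=self.resnames[i] in WATER_RESNAMES,
            )
            for i in range(len(self.names))
        ]
        frame = np.asarray(self.coords)[None, :, :]
        frames = np.repeat(frame, n_frames, axis=0)
        return StructureEnsemble(
            atoms=atoms,
            bonds=np.asarray(self.bonds, dtype=int).reshape(-1, 2),
            frames=frames,
            variant_id=variant_id,
        )


def build_ideal_peptide(spec: FixtureSpec | str, chain_id: str = "A") -> StructureEnsemble:
    """Build a single-frame peptide with ideal backbone geometry.

    The helix conformation uses phi = -57, psi = -47 degrees; the strand
    conformation an extended beta geometry.  Amide hydrogens are placed in
    the peptide plane trans to the carbonyl oxygen, so the i -> i+4
    backbone hydrogen bonds of a helix come out at realistic geometry.
    """
    if isinstance(spec, str):
        spec = FixtureSpec(sequence=spec)
    n_res = len(spec.sequence)
    if spec.conformation == "helix":
        per_res = [HELIX_PHI_PSI] * n_res
    elif spec.conformation == "strand":
        per_res = [STRAND_PHI_PSI] * n_res
    elif spec.conformation == "custom":
        if spec.dihedrals is None:
            raise ValueError("custom conformation needs dihedrals=(phi, psi)")
        if isinstance(spec.dihedrals, tuple):
            per_res = [spec.dihedrals] * n_res
        else:
            if len(spec.dihedrals) != n_res:
                raise ValueError("need one (phi, psi) pair per residue")
            per_res = list(spec.dihedrals)
    else:
        raise ValueError(f"unknown conformation {spec.conformation!r}")

    seq3 = []
    for aa in spec.sequence:
        if aa not in AA_1TO3:
            raise ValueError(f"unknown residue {aa!r} in sequence")
        seq3.append(AA_1TO3[aa])

    b = _Builder()
    prev = {}  # atom name -> index of previous residue's backbone atoms
    for ri, resname in enumerate(seq3):
        resnum = ri + 1
        phi, psi = per_res[ri]
        psi_prev = per_res[ri - 1][1] if ri else psi
        if ri == 0:
            n_xyz = np.array([0.0, 0.0, 0.0])
            ca_xyz = np.array([1.458, 0.0, 0.0])
            ang = math.radians(111.2)
            c_xyz = ca_xyz + 1.525 * np.array([-math.cos(ang), math.sin(ang), 0.0])
            i_n = b.add("N", resnum, resname, chain_id, n_xyz)
            i_ca = b.add("CA", resnum, resname, chain_id, ca_xyz, bond_to=i_n)
            i_c = b.add("C", resnum, resname, chain_id, c_xyz, bond_to=i_ca)
        else:
            a_ca, a_c, a_n_prev = b.coords[prev["CA"]], b.coords[prev["C"]], b.coords[prev["N"]]
            n_xyz = _place_atom(a_n_prev, a_ca, a_c, 1.329, 116.2, psi_prev)
            ca_xyz = _place_atom(a_ca, a_c, n_xyz, 1.458, 121.7, 180.0)  # omega trans
            c_xyz = _place_atom(a_c, n_xyz, ca_xyz, 1.525, 111.2, phi)
            i_n = b.add("N", resnum, resname, chain_id, n_xyz, bond_to=prev["C"])
            i_ca = b.add("CA", resnum, resname, chain_id, ca_xyz, bond_to=i_n)
            i_c = b.add("C", resnum, resname, chain_id, c_xyz, bond_to=i_ca)

        # carbonyl O anti to the next amide nitrogen
        o_xyz = _place_atom(b.coords[i_n], b.coords[i_ca], b.coords[i_c], 1.231, 120.5, psi + 180.0)
        i_o = b.add("O", resnum, resname, chain_id, o_xyz, bond_to=i_c)

        # amide hydrogen (none for proline)
        if resname != "PRO":
            if ri == 0:
                h_xyz = _place_atom(b.coords[i_c], b.coords[i_ca], b.coords[i_n], 1.01, 109.5, 180.0)
            else:
                h_xyz = _place_atom(b.coords[prev["O"]], b.coords[prev["C"]], b.coords[i_n], 1.01, 119.0, 180.0)
            b.add("H", resnum, resname, chain_id, h_xyz, bond_to=i_n)

        placed = {"N": i_n, "CA": i_ca, "C": i_c}
        # alpha hydrogen(s) and C-beta via improper dihedrals around CA
        if resname == "GLY":
            for hname, dih in (("HA2", 121.0), ("HA3", -121.0)):
                xyz = _place_atom(b.coords[i_n], b.coords[i_c], b.coords[i_ca], 1.09, 109.5, dih)
                b.add(hname, resnum, resname, chain_id, xyz, bond_to=i_ca)
        else:
            cb_xyz = _place_atom(b.coords[i_n], b.coords[i_c], b.coords[i_ca], 1.53, 110.1, 122.6)
            i_cb = b.add("CB", resnum, resname, chain_id, cb_xyz, bond_to=i_ca)
            placed["CB"] = i_cb
            ha_xyz = _place_atom(b.coords[i_n], b.coords[i_c], b.coords[i_ca], 1.09, 109.5, -116.0)
            b.add("HA", resnum, resname, chain_id, ha_xyz, bond_to=i_ca)
            # sidechain beyond CB: generic NeRF extension down the tree
            child_count: dict[str, int] = {}
            for atom_name, parent in _SIDECHAINS[resname]:
                i_parent = placed[parent]
                gp = _parent_of(resname, parent, placed)
                ggp = _parent_of(resname, _name_of(b, gp), placed) if gp is not None else None
                rank = child_count.get(parent, 0)
                child_count[parent] = rank + 1
                dih = (180.0, 60.0, -60.0)[rank % 3]
                a_ref = b.coords[ggp] if ggp is not None else b.coords[placed["N"]]
                xyz = _place_atom(
                    a_ref, b.coords[gp], b.coords[i_parent],
                    _bond_length(atom_name, parent), 111.0, dih,
                )
                placed[atom_name] = b.add(atom_name, resnum, resname, chain_id, xyz, bond_to=i_parent)
            for x, y in _RING_CLOSURES.get(resname, []):
                if x in placed and y in placed:
                    b.bonds.append((placed[x], placed[y]))

        prev = {"N": i_n, "CA": i_ca, "C": i_c, "O": i_o}

    return b.to_ensemble(variant_id=f"peptide:{spec.sequence}:{spec.conformation}")


def _name_of(b: _Builder, idx: int | None) -> str:
    return b.names[idx] if idx is not None else ""


def _parent_of(resname: str, atom_name: str, placed: dict[str, int]) -> int | None:
    if atom_name in ("", None):
        return None
    if atom_name == "CB":
        return placed["CA"]
    if atom_name == "CA":
        return placed["N"]
    if atom_name == "N":
        return placed["C"] if "C" in placed else None
    for child, parent in _SIDECHAINS.get(resname, []):
        if child == atom_name:
            return placed.get(parent)
    return None


def jitter_trajectory(structure: StructureEnsemble, spec: FixtureSpec) -> StructureEnsemble:
    """Expand a single reference frame into a seeded Gaussian-jitter ensemble.

    Each atom of residue *r* is displaced independently per frame by
    isotropic Gaussian noise with per-axis sigma ``amplitude[r]`` (Å), so at
    large frame counts the RMSF about the mean tends to ``amplitude *
    sqrt(3)``.
    """
    rng = np.random.default_rng(spec.seed)
    base = structure.frames[0]
    n = structure.n_atoms
    if isinstance(spec.jitter, dict):
        amp = np.array([spec.jitter.get(a.residue_number, 0.0) for a in structure.atoms])
    else:
        amp = np.full(n, float(spec.jitter))
    frames = base[None, :, :] + rng.standard_normal((spec.n_frames, n, 3)) * amp[None, :, None]
    return StructureEnsemble(
        atoms=list(structure.atoms),
        bonds=structure.bonds.copy(),
        frames=frames,
        replicate_boundaries=[],
        variant_id=structure.variant_id + f":jitter{spec.seed}",
    )


# ---------------------------------------------------------------------------
# toy systems with exact geometry
# ---------------------------------------------------------------------------


def build_hbond_toy(
    dist_HA: float,
    angle_DHA: float,
    angle_HAX: float = 120.0,
    neighbor_is_hydrogen: bool = False,
) -> StructureEnsemble:
    """Minimal donor/acceptor system realizing exactly the requested
    hydrogen-bond geometry (one N-H donor, one carbonyl-like O acceptor
    with a single covalent neighbor X)."""
    if dist_HA <= 0 or not (0 <= angle_DHA <= 180) or not (0 <= angle_HAX <= 180):
        raise ValueError("unrealizable hydrogen-bond geometry")
    h = np.zeros(3)
    a = np.array([dist_HA, 0.0, 0.0])
    th = math.radians(angle_DHA)
    d = 1.01 * np.array([math.cos(th), math.sin(th), 0.0])
    phi = math.radians(angle_HAX)
    r_ax = 0.96 if neighbor_is_hydrogen else 1.23
    x = a + r_ax * np.array([-math.cos(phi), -math.sin(phi), 0.0])

    b = _Builder()
    i_d = b.add("N", 1, "ALA", "A", d)
    b.add("H", 1, "ALA", "A", h, bond_to=i_d)
    i_a = b.add("O", 2, "ALA", "A", a)
    xname = "HX" if neighbor_is_hydrogen else "C"
    b.add(xname, 2, "ALA", "A", x, bond_to=i_a, element="H" if neighbor_is_hydrogen else "C")
    return b.to_ensemble(variant_id="hbond_toy")


def build_bifurcated_toy(angle_DHA: float = 170.0, dist_HA: float = 2.0) -> StructureEnsemble:
    """One donor hydrogen engaged by two acceptors at mirrored geometry.

    With the default parameters both bonds individually have ideal-plateau
    geometry (dist_HA <= 2.1 Å, angle_DHA >= 165 degrees, unhindered
    acceptors), so before capping each is worth the full ideal energy.
    """
    h = np.zeros(3)
    th = math.radians(angle_DHA)
    b = _Builder()
    # donor N-H along +x
    dvec = np.array([1.01, 0.0, 0.0])
    i_d = b.add("N", 1, "ALA", "A", dvec)
    b.add("H", 1, "ALA", "A", h, bond_to=i_d)
    for k, sign in ((2, 1.0), (3, -1.0)):
        avec = dist_HA * np.array([math.cos(th), sign * math.sin(th), 0.0])
        i_a = b.add("O", k, "ALA", "A", avec)
        # neighbor at 120 degrees from H, out of the way
        nb = avec + 1.23 * _rotated_neighbor(avec - h, sign)
        b.add("C", k, "ALA", "A", nb, bond_to=i_a)
    return b.to_ensemble(variant_id="bifurcated_toy")


def _rotated_neighbor(ah: np.ndarray, sign: float) -> np.ndarray:
    """Unit vector making a 120-degree H-A-X angle with the A->H direction."""
    back = -ah / np.linalg.norm(ah)  # A -> H
    perp = np.cross(back, np.array([0.0, 0.0, 1.0]))
    perp /= np.linalg.norm(perp)
    ang = math.radians(120.0)
    return math.cos(ang) * back + math.sin(ang) * perp


def build_water_bridge_toy() -> StructureEnsemble:
    """A water donating two ideal hydrogen bonds to two protein carbonyls."""
    b = _Builder()
    ow = np.zeros(3)
    i_ow = b.add("OW", 1, "HOH", "W", ow, element="O")
    ang = math.radians(104.5)
    dirs = [np.array([1.0, 0.0, 0.0]), np.array([math.cos(ang), math.sin(ang), 0.0])]
    for k, (hname, u) in enumerate(zip(("HW1", "HW2"), dirs), start=2):
        hh = 0.96 * u
        b.add(hname, 1, "HOH", "W", hh, bond_to=i_ow, element="H")
        acc = hh + 2.0 * u  # linear D-H...A, dist_HA = 2.0
        i_a = b.add("O", k, "ALA", "A", acc)
        nb = acc + 1.23 * _rotated_neighbor(acc - hh, 1.0)
        b.add("C", k, "ALA", "A", nb, bond_to=i_a)
    return b.to_ensemble(variant_id="water_bridge_toy")


def build_salt_bridge_toy(distance: float, n_frames: int = 1) -> StructureEnsemble:
    """An Asp/Lys pair with the carboxylate O to amine N distance set exactly.

    All other inter-residue atom distances are kept larger than the
    contact distance so exactly one residue pair can qualify.
    """
    if distance <= 0:
        raise ValueError("distance must be positive")
    b = _Builder()
    # aspartate: backbone stub + carboxylate pointing +x
    i_n = b.add("N", 1, "ASP", "A", [-4.0, 0.0, 0.0])
    i_ca = b.add("CA", 1, "ASP", "A", [-2.9, 0.8, 0.0], bond_to=i_n)
    i_c = b.add("C", 1, "ASP", "A", [-3.3, 2.2, 0.0], bond_to=i_ca)
    b.add("O", 1, "ASP", "A", [-4.5, 2.5, 0.0], bond_to=i_c)
    i_cb = b.add("CB", 1, "ASP", "A", [-1.6, 0.2, 0.0], bond_to=i_ca)
    i_cg = b.add("CG", 1, "ASP", "A", [-0.5, 1.0, 0.0], bond_to=i_cb)
    b.add("OD1", 1, "ASP", "A", [0.0, 0.0, 0.0], bond_to=i_cg)
    b.add("OD2", 1, "ASP", "A", [-0.3, 2.2, 0.6], bond_to=i_cg)

    # lysine approaching along +x; NZ sits `distance` from OD1 (origin)
    nz = np.array([distance, 0.0, 0.0])
    i_n2 = b.add("N", 2, "LYS", "A", nz + [5.6, 1.0, 0.0])
    i_ca2 = b.add("CA", 2, "LYS", "A", nz + [4.6, 0.2, 0.0], bond_to=i_n2)
    i_c2 = b.add("C", 2, "LYS", "A", nz + [5.2, -1.2, 0.0], bond_to=i_ca2)
    b.add("O", 2, "LYS", "A", nz + [6.4, -1.4, 0.0], bond_to=i_c2)
    i_cb2 = b.add("CB", 2, "LYS", "A", nz + [3.4, 0.9, 0.0], bond_to=i_ca2)
    i_cg2 = b.add("CG", 2, "LYS", "A", nz + [2.4, 0.1, 0.5], bond_to=i_cb2)
    i_cd2 = b.add("CD", 2, "LYS", "A", nz + [1.6, 0.8, 1.2], bond_to=i_cg2)
    i_ce2 = b.add("CE", 2, "LYS", "A", nz + [0.9, 0.3, 2.0], bond_to=i_cd2)
    i_nz = b.add("NZ", 2, "LYS", "A", nz, bond_to=i_ce2)
    for k, hxyz in enumerate(([0.4, 0.9, 0.0], [0.4, -0.9, 0.0], [0.0, 0.0, 1.0]), start=1):
        b.add(f"HZ{k}", 2, "LYS", "A", nz + hxyz, bond_to=i_nz)
    return b.to_ensemble(variant_id=f"salt_bridge_toy:{distance}", n_frames=n_frames)


# ---------------------------------------------------------------------------
# benchmark sample tables
# ---------------------------------------------------------------------------


def build_benchmark_samples(
    amino_acids: str | None = None,
    exposure_classes: tuple[str, ...] = ("buried", "partial", "exposed"),
    n_per_category: int = 50,
    seed: int = 0,
    rmsf_sigma: float = 0.4,
    sasa_scale: float = 30.0,
):
    """Draw a synthetic per-residue sample table for benchmark-curve fitting.

    Sidechain RMSF is drawn log-normally with a class-dependent median
    (buried < partial < exposed), hydrophobic SASA log-normally around a
    per-amino-acid scale — the typical right-skewed shapes of the real
    quantities.  Purely a fixture distribution; seeded and reproducible.
    """
    import pandas as pd

    if amino_acids is None:
        amino_acids = "ACDEFGHIKLMNPQRSTVWY"
    if n_per_category < 2:
        raise ValueError("need at least 2 samples per category")
    rng = np.random.default_rng(seed)
    med = {"buried": 0.25, "partial": 0.45, "exposed": 0.8}
    rows = []
    for aa in amino_acids:
        for cls in exposure_classes:
            rmsf = med[cls] * np.exp(rng.normal(0.0, rmsf_sigma, n_per_category))
            sasa = sasa_scale * (1.0 + "ACDEFGHIKLMNPQRSTVWY".index(aa) / 10.0) * np.exp(
                rng.normal(0.0, 0.5, n_per_category)
            )
            for r, s in zip(rmsf, sasa):
                rows.append(
                    {
                        "amino_acid": aa,
                        "exposure_class": cls,
                        "sidechain_rmsf": float(r),
                        "hydrophobic_sasa": float(s),
                        "has_sidechain": True,
                    }
                )
    return pd.DataFrame(rows)
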