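"""Whole-protein structural checks: helices, propensity, capping,
disulfides, salt bridges.

Helices are assigned once, on the first frame, with a Kabsch–Sander
style backbone hydrogen-bond electrostatic energy

    E = 0.084 · 332 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)   kcal/mol

(bond if E < −0.5 kcal/mol); an α-helix is a run of i → i+4 bonded
turns.  These checks do not fluctuate meaningfully over short
trajectories, so they are reported at the whole-protein level only —
except the salt-bridge count, which is averaged per frame.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from .ensemble import AA_1TO3, AA_3TO1, Mutation, StructureEnsemble

__all__ = [
    "HelixSegment",
    "load_propensity_scale",
    "assign_helices",
    "propensity_delta",
    "capping_check",
    "disulfide_count",
    "salt_bridge_count",
    "SALT_BRIDGE_CUTOFF",
    "N_CAP_RESIDUES",
    "C_CAP_RESIDUES",
]

DSSP_COUPLING = 0.084 * 332.0  # kcal·Å/mol
DSSP_CUTOFF = -0.5  # kcal/mol
SALT_BRIDGE_CUTOFF = 4.0  # Å, strict less-than
DISULFIDE_SG_CUTOFF = 2.3  # Å fallback when bonds are silent
CAP_WINDOW = 5  # residues around a helix terminus checked for capping

#: residues able to fill the capping role at a helix terminus
N_CAP_RESIDUES = frozenset("NDSTG")
C_CAP_RESIDUES = frozenset("G")

ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC_ATOMS = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"), "HIS": ("ND1", "NE2")}


@dataclass(frozen=True)
class HelixSegment:
    chain: str
    start_residue: int
    end_residue: int  # inclusive

    def __post_init__(self):
        if self.end_residue - self.start_residue + 1 < 4:
            raise ValueError("helix segments are at least 4 residues long")

    def __contains__(self, item: tuple[str, int]) -> bool:
        chain, pos = item
        return chain == self.chain and self.start_residue <= pos <= self.end_residue


def load_propensity_scale(path=None) -> dict[str, float]:
    """Helix-propensity penalties (kJ/mol, alanine = 0 reference).

    The shipped scale is the widely used experimental helix-propensity
    ladder converted to kJ/mol; proline's penalty is 13.22 kJ/mol.
    """
    if path is None:
        text = resources.files("mdstab.data").joinpath("helix_propensity.csv").read_text().splitlines()
    else:
        with open(path) as fh:
            text = fh.read().splitlines()
    scale = {row["amino_acid"].strip(): float(row["penalty_kj_mol"]) for row in csv.DictReader(text)}
    if scale.get("A") != 0.0:
        raise ValueError("propensity scale must use alanine as its zero reference")
    return scale


def _backbone_atom(ensemble: StructureEnsemble, key: tuple[str, int], name: str) -> int | None:
    for i in ensemble.residue_atoms.get(key, ()):
        if ensemble.atoms[i].name == name:
            return i
    return None


def assign_helices(ensemble: StructureEnsemble) -> list[HelixSegment]:
    """α-helix segments from frame 1 backbone hydrogen bonding."""
    coords = ensemble.frames[0]
    keys = ensemble.residue_keys
    chains: dict[str, list[int]] = {}
    for chain, pos in keys:
        chains.setdefault(chain, []).append(pos)

    segments: list[HelixSegment] = []
    for chain, positions in chains.items():
        positions = sorted(positions)
        # i -> i+4 turn flags indexed by list position
        turn = np.zeros(len(positions), dtype=bool)
        for li, pos in enumerate(positions):
            if li + 4 >= len(positions) or positions[li + 4] != pos + 4:
                continue
            i_c = _backbone_atom(ensemble, (chain, pos), "C")
            i_o = _backbone_atom(ensemble, (chain, pos), "O")
            j_n = _backbone_atom(ensemble, (chain, pos + 4), "N")
            j_h = _backbone_atom(ensemble, (chain, pos + 4), "H")
            if i_c is None or i_o is None:
                raise ValueError(f"residue {chain}:{pos} lacks backbone C/O atoms")
            if j_n is None:
                raise ValueError(f"residue {chain}:{pos + 4} lacks a backbone N atom")
            if j_h is None:
                continue  # proline-like nitrogen: no donor, no turn
            r_on = np.linalg.norm(coords[i_o] - coords[j_n])
            r_ch = np.linalg.norm(coords[i_c] - coords[j_h])
            r_oh = np.linalg.norm(coords[i_o] - coords[j_h])
            r_cn = np.linalg.norm(coords[i_c] - coords[j_n])
            energy = DSSP_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
            turn[li] = energy < DSSP_CUTOFF
        # two consecutive turns at i-1, i make residues i..i+3 helical
        helical = np.zeros(len(positions), dtype=bool)
        for li in range(1, len(positions)):
            if turn[li - 1] and turn[li]:
                helical[li : li + 4] = True
        start = None
        for li, flag in enumerate(list(helical) + [False]):
            contiguous = (
                flag and li < len(positions)
                and (start is None or positions[li] == positions[li - 1] + 1)
            )
            if contiguous and start is None:
                start = li
            elif not contiguous and start is not None:
                if li - start >= 4:
                    segments.append(HelixSegment(chain, positions[start], positions[li - 1]))
                start = li if flag and li < len(positions) else None
    return segments


def propensity_delta(
    mutation: Mutation,
    helices: list[HelixSegment],
    scale: dict[str, float] | None = None,
) -> float:
    """Helix-propensity penalty change (kJ/mol), mutant − wild type.

    Only evaluated when the site lies inside a helix at least five
    positions from both termini; otherwise 0 (capping territory is
    handled separately).
    """
    if scale is None:
        scale = load_propensity_scale()
    for seg in helices:
        if (mutation.chain_id, mutation.position) in seg:
            if (
                mutation.position - seg.start_residue >= 5
                and seg.end_residue - mutation.position >= 5
            ):
                return scale[mutation.mut_residue] - scale[mutation.wt_residue]
    return 0.0


def capping_check(
    mutation: Mutation,
    helices: list[HelixSegment],
    n_cap_residues: frozenset[str] = N_CAP_RESIDUES,
    c_cap_residues: frozenset[str] = C_CAP_RESIDUES,
) -> bool:
    """True when the mutation disrupts a capping-capable residue near a
    helix terminus: the wild-type residue fills the motif role (N-cap:
    Asn/Asp/Ser/Thr/Gly, C-cap: Gly) within five residues of the helix
    start/end and the mutant residue does not preserve it."""
    for seg in helices:
        if mutation.chain_id != seg.chain:
            continue
        near_n = abs(mutation.position - seg.start_residue) <= CAP_WINDOW
        near_c = abs(mutation.position - seg.end_residue) <= CAP_WINDOW
        if near_n and mutation.wt_residue in n_cap_residues and mutation.mut_residue not in n_cap_residues:
            return True
        if near_c and mutation.wt_residue in c_cap_residues and mutation.mut_residue not in c_cap_residues:
            return True
    return False


def disulfide_count(ensemble: StructureEnsemble) -> int:
    """Cys–Cys bridges: explicit SG–SG bond records, or SG pairs closer
    than 2.3 Å in frame 1 when the bond list is silent."""
    sg = [
        i
        for i in range(ensemble.n_atoms)
        if ensemble.atoms[i].residue_name == "CYS" and ensemble.atoms[i].name == "SG"
    ]
    sg_set = set(sg)
    pairs = set()
    for i, j in ensemble.bonds:
        if i in sg_set and j in sg_set:
            pairs.add((min(i, j), max(i, j)))
    if pairs:
        return len(pairs)
    coords = ensemble.frames[0]
    for ii, i in enumerate(sg):
        for j in sg[ii + 1 :]:
            if np.linalg.norm(coords[i] - coords[j]) <= DISULFIDE_SG_CUTOFF:
                pairs.add((i, j))
    return len(pairs)


def _charged_his(ensemble: StructureEnsemble, atoms: np.ndarray) -> bool:
    """His counts as positive only when both ring nitrogens carry a proton."""
    names = {ensemble.atoms[i].name for i in atoms}
    return "HD1" in names and "HE2" in names


def salt_bridge_count(ensemble: StructureEnsemble) -> float:
    """Mean per-frame number of salt-bridged residue pairs (whole protein).

    A bridge is a sidechain carboxylate oxygen of Asp/Glu strictly closer
    than 4 Å to a charged sidechain nitrogen of Arg, Lys, or (doubly
    protonated) His; multiple O–N contacts within one residue pair count
    once.
    """
    acidic: list[tuple[tuple[str, int], int]] = []
    basic: list[tuple[tuple[str, int], int]] = []
    for key, atoms in ensemble.residue_atoms.items():
        resname = ensemble.atoms[atoms[0]].residue_name
        if resname in ACIDIC_ATOMS:
            wanted = ACIDIC_ATOMS[resname]
            acidic.extend((key, i) for i in atoms if ensemble.atoms[i].name in wanted)
        elif resname in BASIC_ATOMS:
            if resname == "HIS" and not _charged_his(ensemble, atoms):
                continue
            wanted = BASIC_ATOMS[resname]
            basic.extend((key, i) for i in atoms if ensemble.atoms[i].name in wanted)
    if not acidic or not basic:
        return 0.0

    a_idx = np.array([i for _, i in acidic])
    b_idx = np.array([i for _, i in basic])
    counts = []
    for f in range(ensemble.n_frames):
        coords = ensemble.frames[f]
        tree = cKDTree(coords[b_idx])
        pairs = set()
        for (a_key, ai), hits in zip(acidic, tree.query_ball_point(coords[a_idx], r=SALT_BRIDGE_CUTOFF)):
            for h in hits:
                b_key, bi = basic[h]
                if np.linalg.norm(coords[ai] - coords[bi]) < SALT_BRIDGE_CUTOFF:
                    pairs.add((a_key, b_key))
        counts.append(len(pairs))
    return float(np.mean(counts))
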