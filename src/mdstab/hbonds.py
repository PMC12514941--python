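"""Hydrogen-bond detection, energy estimation, and bookkeeping.

Candidate bonds are detected with deliberately lenient geometric cutoffs
(donor–acceptor distance <= 3.5 Å, donor–hydrogen–acceptor angle >= 100°)
and then filtered by an approximate bond energy, so no charge information
is needed.  The energy model scales an ideal interaction energy of
25 kJ/mol by three saturated ramp functions:

    E = 25 · S_HA · S_DHA · S_HAX

    S_HA  = clamp((2.6 − max(d_HA, 2.1)) / (2.6 − 2.1))
    S_DHA = clamp((min(θ_DHA, 165) − 100) / (165 − 100))
    S_HAX = min over acceptor neighbours X of
            clamp((min θ_HAX − 85) / (95 − 85))   for heavy X
            clamp((min θ_HAH − 75) / (85 − 75))   for hydrogen X

Bonds at or below 6.25 kJ/mol are discarded; when an atom takes part in
more than one retained bond (bifurcation), every bond after its strongest
is capped at 15 kJ/mol.  Water bridges sum their member-bond energies and
pay a 32.2 kJ/mol entropic penalty for immobilizing the water.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .ensemble import (
    Level,
    Mutation,
    SelectionLevel,
    StructureEnsemble,
    frame_average,
    select_atoms,
)

__all__ = [
    "HBondGeometry",
    "HBond",
    "WaterBridge",
    "E_IDEAL",
    "ENERGY_FLOOR",
    "BIFURCATION_CAP",
    "WATER_ENTROPY_PENALTY",
    "detect_candidate_hbonds",
    "hbond_energy",
    "filter_and_cap",
    "find_water_bridges",
    "unsatisfied_count",
    "hbond_metric_deltas",
    "frame_hbond_state",
]

E_IDEAL = 25.0  # kJ/mol for an ideal interaction
ENERGY_FLOOR = 6.25  # kJ/mol; bonds at or below are discarded
BIFURCATION_CAP = 15.0  # kJ/mol cap on 2nd and further bonds of an atom
WATER_ENTROPY_PENALTY = 32.2  # kJ/mol to remove one water from solution

DA_CUTOFF = 3.5  # Å, donor-acceptor detection distance
DHA_CUTOFF = 100.0  # degrees, minimal donor-hydrogen-acceptor angle

DONOR_ACCEPTOR_ELEMENTS = ("N", "O", "S")


@dataclass(frozen=True)
class HBondGeometry:
    dist_HA: float
    dist_DA: float
    angle_DHA: float
    #: (angle_HAX degrees, neighbour is hydrogen) per acceptor covalent neighbour
    neighbor_angles: tuple[tuple[float, bool], ...] = ()

    def __post_init__(self):
        if self.dist_HA <= 0 or self.dist_DA <= 0:
            raise ValueError("hydrogen-bond distances must be positive")
        if not (0.0 <= self.angle_DHA <= 180.0):
            raise ValueError("angle_DHA must lie in [0, 180]")


@dataclass
class HBond:
    donor: int
    hydrogen: int
    acceptor: int
    geometry: HBondGeometry
    energy: float | None = None
    is_water_mediated: bool = False

    @property
    def atoms(self) -> tuple[int, int, int]:
        return (self.donor, self.hydrogen, self.acceptor)


@dataclass
class WaterBridge:
    water_residue: tuple[str, int]
    member_bonds: list[HBond]
    energy: float

    @property
    def protein_atoms(self) -> set[int]:
        out: set[int] = set()
        for b in self.member_bonds:
            out.update(b.atoms)
        return out


def _clamp01(x: float) -> float:
    return 0.0 if x < 0.0 else (1.0 if x > 1.0 else x)


def hbond_energy(geometry: HBondGeometry) -> float:
    """Approximate hydrogen-bond energy in kJ/mol (0 to 25)."""
    s_ha = _clamp01((2.6 - max(geometry.dist_HA, 2.1)) / (2.6 - 2.1))
    s_dha = _clamp01((min(geometry.angle_DHA, 165.0) - 100.0) / (165.0 - 100.0))
    s_hax = 1.0
    for angle, is_h in geometry.neighbor_angles:
        lo, hi = (75.0, 85.0) if is_h else (85.0, 95.0)
        s_hax = min(s_hax, _clamp01((min(angle, hi) - lo) / (hi - lo)))
    return E_IDEAL * s_ha * s_dha * s_hax


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at b of a-b-c in degrees."""
    u = a - b
    v = c - b
    cosv = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0))))


def detect_candidate_hbonds(
    ensemble: StructureEnsemble,
    frame: int = 0,
    compute_energy: bool = True,
) -> list[HBond]:
    """All (donor, hydrogen, acceptor) candidates in one frame.

    Donors are N/O/S atoms with a covalently bound hydrogen; acceptors any
    N/O/S atom not covalently bound to the donor or its hydrogen.
    """
    coords = ensemble.frames[frame]
    el = ensemble.elements
    polar = np.isin(el, DONOR_ACCEPTOR_ELEMENTS)
    if not ensemble.is_hydrogen.any():
        raise ValueError(
            "topology contains no hydrogens; hydrogen-bond analysis needs an "
            "explicitly protonated input"
        )

    adjacency = ensemble.bonded
    donors = [
        i
        for i in np.flatnonzero(polar)
        if any(el[j] == "H" for j in adjacency[i])
    ]
    acceptors = np.flatnonzero(polar)
    if not donors or acceptors.size == 0:
        return []

    tree = cKDTree(coords[acceptors])
    bonds: list[HBond] = []
    for d in donors:
        near = tree.query_ball_point(coords[d], r=DA_CUTOFF)
        hydrogens = [j for j in adjacency[d] if el[j] == "H"]
        for ai in near:
            a = int(acceptors[ai])
            if a == d or a in adjacency[d]:
                continue
            for h in hydrogens:
                if a in adjacency[h]:
                    continue
                angle_dha = _angle(coords[d], coords[h], coords[a])
                if angle_dha < DHA_CUTOFF:
                    continue
                neighbor_angles = tuple(
                    (_angle(coords[h], coords[a], coords[x]), el[x] == "H")
                    for x in adjacency[a]
                    if x != h
                )
                geom = HBondGeometry(
                    dist_HA=float(np.linalg.norm(coords[h] - coords[a])),
                    dist_DA=float(np.linalg.norm(coords[d] - coords[a])),
                    angle_DHA=angle_dha,
                    neighbor_angles=neighbor_angles,
                )
                bond = HBond(donor=d, hydrogen=h, acceptor=a, geometry=geom)
                if compute_energy:
                    bond.energy = hbond_energy(geom)
                bonds.append(bond)
    return bonds


def filter_and_cap(bonds: list[HBond]) -> list[HBond]:
    """Drop weak bonds, then cap bifurcated ones.

    Bonds with energy <= 6.25 kJ/mol are removed.  Among the retained
    bonds, each atom's strongest bond keeps its energy; every further bond
    sharing a hydrogen or an acceptor atom is capped at 15 kJ/mol.  (A
    donor heavy atom engaging two acceptors through two *different*
    hydrogens — e.g. a bridging water — is not bifurcated and is not
    capped.)  Ties are broken by (donor, hydrogen, acceptor) index order.
    """
    retained = [b for b in bonds if b.energy is not None and b.energy > ENERGY_FLOOR]
    order = sorted(retained, key=lambda b: (-b.energy, b.donor, b.hydrogen, b.acceptor))
    seen: set[int] = set()
    out: list[HBond] = []
    for b in order:
        capped = b
        if b.hydrogen in seen or b.acceptor in seen:
            capped = replace(b, energy=min(b.energy, BIFURCATION_CAP))
        seen.add(b.hydrogen)
        seen.add(b.acceptor)
        out.append(capped)
    out.sort(key=lambda b: b.atoms)
    return out


def find_water_bridges(
    ensemble: StructureEnsemble,
    frame: int,
    retained_protein_water_bonds: list[HBond],
) -> list[WaterBridge]:
    """Group energy-filtered protein-water bonds into first-order bridges.

    A water engaged in two or more protein hydrogen bonds forms one
    bridge; its energy is the member-bond sum minus the 32.2 kJ/mol
    entropic penalty, floored at zero.
    """
    by_water: dict[tuple[str, int], list[HBond]] = {}
    for b in retained_protein_water_bonds:
        for idx in (b.donor, b.acceptor):
            atom = ensemble.atoms[idx]
            if atom.is_water:
                by_water.setdefault((atom.chain_id, atom.residue_number), []).append(b)
                break
    bridges = []
    for water, members in sorted(by_water.items()):
        if len(members) < 2:
            continue
        raw = sum(b.energy for b in members) - WATER_ENTROPY_PENALTY
        members = [replace(b, is_water_mediated=True) for b in members]
        bridges.append(WaterBridge(water, members, max(raw, 0.0)))
    return bridges


@dataclass
class FrameHBondState:
    """Retained bonds of one frame, split by water involvement."""

    protein_bonds: list[HBond] = field(default_factory=list)
    bridges: list[WaterBridge] = field(default_factory=list)

    @property
    def engaged_atoms(self) -> set[int]:
        out: set[int] = set()
        for b in self.protein_bonds:
            out.update(b.atoms)
        for br in self.bridges:
            out.update(br.protein_atoms)
        return out


def frame_hbond_state(ensemble: StructureEnsemble, frame: int) -> FrameHBondState:
    """Run the full per-frame pipeline: detect, score, filter, cap, bridge."""
    candidates = detect_candidate_hbonds(ensemble, frame)
    retained = filter_and_cap(candidates)
    is_w = ensemble.is_water
    protein_bonds, water_bonds = [], []
    for b in retained:
        touches_water = bool(is_w[b.donor] or is_w[b.acceptor])
        both_water = bool(is_w[b.donor] and is_w[b.acceptor])
        if both_water:
            continue  # water-water bonds never contribute
        (water_bonds if touches_water else protein_bonds).append(b)
    bridges = find_water_bridges(ensemble, frame, water_bonds)
    return FrameHBondState(protein_bonds=protein_bonds, bridges=bridges)


def candidate_partner_atoms(
    ensemble: StructureEnsemble, partner_mode: str = "results"
) -> np.ndarray:
    """Protein atoms counted as potential hydrogen-bond partners.

    ``"results"``: all N, O, S atoms plus hydrogens covalently bound to
    them.  ``"methods"``: all oxygens plus nitrogens with no bound
    hydrogen (the narrower alternative definition).
    """
    el = ensemble.elements
    adjacency = ensemble.bonded
    protein = ensemble.is_protein
    out = []
    for i in range(ensemble.n_atoms):
        if not protein[i]:
            continue
        if partner_mode == "results":
            if el[i] in DONOR_ACCEPTOR_ELEMENTS:
                out.append(i)
            elif el[i] == "H" and any(el[j] in DONOR_ACCEPTOR_ELEMENTS for j in adjacency[i]):
                out.append(i)
        elif partner_mode == "methods":
            if el[i] == "O":
                out.append(i)
            elif el[i] == "N" and not any(el[j] == "H" for j in adjacency[i]):
                out.append(i)
        else:
            raise ValueError(f"unknown partner_mode {partner_mode!r}")
    return np.asarray(out, dtype=int)


def unsatisfied_count(
    ensemble: StructureEnsemble,
    frame: int,
    selection: np.ndarray,
    state: FrameHBondState | None = None,
    partner_mode: str = "results",
) -> int:
    """Selection atoms that could hydrogen-bond but are engaged in no
    retained bond (water-mediated membership satisfies an atom)."""
    if state is None:
        state = frame_hbond_state(ensemble, frame)
    partners = set(candidate_partner_atoms(ensemble, partner_mode))
    engaged = state.engaged_atoms
    return sum(1 for i in selection if int(i) in partners and int(i) not in engaged)


def selection_hbond_energy(state: FrameHBondState, selection: np.ndarray) -> float:
    """Total retained bond energy touching the selection, bridges included."""
    sel = set(int(i) for i in selection)
    total = 0.0
    for b in state.protein_bonds:
        if sel.intersection(b.atoms):
            total += b.energy
    for br in state.bridges:
        if sel.intersection(br.protein_atoms):
            total += br.energy
    return total


def hbond_metric_deltas(
    mut_ensemble: StructureEnsemble,
    wt_ensemble: StructureEnsemble,
    mutation: Mutation,
    level: SelectionLevel | Level,
    partner_mode: str = "results",
) -> tuple[float, float]:
    """(ΔE_total kJ/mol, Δ unsatisfied count), mutant minus wild type.

    Per-frame totals are frame-averaged per variant before differencing;
    the surrounding selection is recomputed every frame.
    """
    values = []
    for ens, is_mut in ((mut_ensemble, True), (wt_ensemble, False)):
        energies, unsats = [], []
        for f in range(ens.n_frames):
            state = frame_hbond_state(ens, f)
            sel = select_atoms(ens, mutation, level, frame_index=f)
            energies.append(selection_hbond_energy(state, sel))
            unsats.append(unsatisfied_count(ens, f, sel, state, partner_mode))
        values.append((frame_average(energies), frame_average(unsats)))
    (e_mut, u_mut), (e_wt, u_wt) = values
    return e_mut - e_wt, u_mut - u_wt
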