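"""Solvent-accessible surface area and hydrophobic exposure.

SASA is computed per atom with a Shrake–Rupley style algorithm
(probe radius 1.4 Å, published single-atom van der Waals radii, 100
sphere points per atom by default) on the protein atoms of each frame.
The hydrophobic exposure of a residue is the SASA summed over its apolar
atoms — every atom engaged in a C–C or C–H bond, i.e. carbons and the
hydrogens bound to them — averaged over the trajectory.  The resulting
value is mapped to a [0, 1] score through a per-amino-acid benchmark
curve.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .ensemble import AA_3TO1, StructureEnsemble

__all__ = [
    "SasaAnalysis",
    "hydrophobic_sasa",
    "exposure_score",
    "apolar_atom_mask",
    "PROBE_RADIUS",
    "SASA_POINTS",
]

PROBE_RADIUS = 1.4  # Å
SASA_POINTS = 100  # sphere sample points per atom


def apolar_atom_mask(ensemble: StructureEnsemble) -> np.ndarray:
    """Atoms engaged in a C–C or C–H bond: carbons bound to C or H, and
    hydrogens bound to carbon."""
    if ensemble.bonds.size == 0:
        raise ValueError("hydrophobic SASA needs bond information in the topology")
    el = ensemble.elements
    mask = np.zeros(ensemble.n_atoms, dtype=bool)
    for i, j in ensemble.bonds:
        pair = {el[i], el[j]}
        if pair == {"C"} or pair == {"C", "H"}:
            mask[i] = mask[j] = True
    return mask


class SasaAnalysis:
    """Per-frame per-atom SASA of the protein component, lazily computed."""

    def __init__(
        self,
        ensemble: StructureEnsemble,
        probe_radius: float = PROBE_RADIUS,
        point_number: int = SASA_POINTS,
    ):
        self.ensemble = ensemble
        self.probe_radius = probe_radius
        self.point_number = point_number
        self._protein_idx = np.flatnonzero(ensemble.is_protein)
        self._per_frame: dict[int, np.ndarray] = {}

    def atom_sasa(self, frame: int) -> np.ndarray:
        """Full-length per-atom SASA array (Å²); non-protein atoms are 0."""
        if frame not in self._per_frame:
            self._per_frame[frame] = self._compute(frame)
        return self._per_frame[frame]

    def _compute(self, frame: int) -> np.ndarray:
        import biotite.structure as struc

        ens = self.ensemble
        idx = self._protein_idx
        arr = struc.AtomArray(len(idx))
        arr.coord = ens.frames[frame][idx].astype(np.float32)
        arr.element = ens.elements[idx]
        arr.res_id = ens.resnums[idx]
        arr.res_name = ens.resnames[idx]
        arr.chain_id = ens.chain_ids[idx]
        arr.atom_name = ens.names[idx]
        values = struc.sasa(
            arr,
            probe_radius=self.probe_radius,
            point_number=self.point_number,
            vdw_radii="Single",
        )
        out = np.zeros(ens.n_atoms)
        out[idx] = np.nan_to_num(values, nan=0.0)
        return out

    # -- residue aggregates ---------------------------------------------

    def residue_sasa(self, frame: int) -> dict[tuple[str, int], float]:
        per_atom = self.atom_sasa(frame)
        return {
            key: float(per_atom[atoms].sum())
            for key, atoms in self.ensemble.residue_atoms.items()
        }

    def mean_residue_sasa(self) -> dict[tuple[str, int], float]:
        """Trajectory-mean total SASA per residue (Å²)."""
        totals: dict[tuple[str, int], float] = {}
        for f in range(self.ensemble.n_frames):
            for key, v in self.residue_sasa(f).items():
                totals[key] = totals.get(key, 0.0) + v
        return {k: v / self.ensemble.n_frames for k, v in totals.items()}

    def hydrophobic_residue_sasa(self, frame: int) -> dict[tuple[str, int], float]:
        per_atom = self.atom_sasa(frame)
        apolar = apolar_atom_mask(self.ensemble)
        return {
            key: float(per_atom[atoms[apolar[atoms]]].sum())
            for key, atoms in self.ensemble.residue_atoms.items()
        }

    def mean_hydrophobic_sasa(self) -> dict[tuple[str, int], float]:
        """Trajectory-mean hydrophobic SASA per residue (Å²)."""
        totals: dict[tuple[str, int], float] = {}
        for f in range(self.ensemble.n_frames):
            for key, v in self.hydrophobic_residue_sasa(f).items():
                totals[key] = totals.get(key, 0.0) + v
        return {k: v / self.ensemble.n_frames for k, v in totals.items()}


def hydrophobic_sasa(
    ensemble: StructureEnsemble,
    frame: int,
    residue: tuple[str, int],
    analysis: SasaAnalysis | None = None,
) -> float:
    """Hydrophobic SASA (Å²) of one residue in one frame."""
    if analysis is None:
        analysis = SasaAnalysis(ensemble)
    values = analysis.hydrophobic_residue_sasa(frame)
    if residue not in values:
        raise KeyError(f"residue {residue} not in topology")
    return values[residue]


def exposure_score(sasa: float, amino_acid: str, curve_set) -> float:
    """Map a hydrophobic SASA value to [0, 1] via the amino acid's
    benchmark curve (1 = unremarkable exposure, 0 = extreme)."""
    return curve_set.score(amino_acid, sasa)
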