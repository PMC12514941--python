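"""Backbone and sidechain flexibility metrics.

Backbone flexibility is the per-residue RMSF of the Cα atoms after a
global least-squares superposition of all frames.  Sidechain flexibility
removes backbone motion by locally aligning each residue's ±1 backbone
neighbourhood before computing the RMSF of its non-backbone atoms.  The
sidechain RMSF is normalized into a [0, 1] score through a benchmark
curve selected by amino acid and solvent-exposure class:

* buried: 0 % relative SASA
* partial: (0, 20] %
* exposed: > 20 %

where relative SASA is the trajectory-mean residue SASA divided by a
reference SASA of the free amino acid (a swappable literature table).
"""

from __future__ import annotations

import csv
from enum import Enum
from importlib import resources

import numpy as np
from scipy.spatial.transform import Rotation

from .ensemble import AA_3TO1, StructureEnsemble
from .exposure import SasaAnalysis

__all__ = [
    "ExposureClass",
    "ResidueFlexibility",
    "backbone_rmsf",
    "sidechain_rmsf",
    "exposure_class",
    "sidechain_score",
    "load_reference_sasa",
    "residue_exposure_classes",
]


class ExposureClass(str, Enum):
    BURIED = "buried"
    PARTIAL = "partial"
    EXPOSED = "exposed"


def load_reference_sasa(path=None) -> dict[str, float]:
    """Reference free-residue SASA (Å²) per amino-acid 1-letter code.

    The shipped default is a published theoretical maximum-accessibility
    table; any CSV with columns ``amino_acid,sasa`` covering all 20
    residues may be substituted.
    """
    if path is None:
        source = resources.files("mdstab.data").joinpath("reference_sasa.csv")
        text = source.read_text().splitlines()
    else:
        with open(path) as fh:
            text = fh.read().splitlines()
    table = {}
    for row in csv.DictReader(text):
        table[row["amino_acid"].strip()] = float(row["sasa"])
    missing = set("ACDEFGHIKLMNPQRSTVWY") - set(table)
    if missing:
        raise ValueError(f"reference SASA table missing residues: {sorted(missing)}")
    return table


def _superpose_frames(frames: np.ndarray, fit_idx: np.ndarray) -> np.ndarray:
    """Least-squares superpose every frame onto frame 0 using ``fit_idx``
    atoms; the fitted transform is applied to all atoms."""
    ref = frames[0, fit_idx]
    ref_center = ref.mean(axis=0)
    out = np.empty_like(frames)
    for f in range(frames.shape[0]):
        mob = frames[f, fit_idx]
        mob_center = mob.mean(axis=0)
        if len(fit_idx) < 3:
            rot = Rotation.identity()
        else:
            rot, _ = Rotation.align_vectors(ref - ref_center, mob - mob_center)
        out[f] = rot.apply(frames[f] - mob_center) + ref_center
    return out


def _rmsf(coords: np.ndarray) -> np.ndarray:
    """RMSF per atom: sqrt(mean squared deviation from the mean position)."""
    mean = coords.mean(axis=0)
    return np.sqrt(((coords - mean) ** 2).sum(axis=2).mean(axis=0))


def backbone_rmsf(
    ensemble: StructureEnsemble,
    selection: list[tuple[str, int]] | None = None,
) -> tuple[dict[tuple[str, int], float], float]:
    """Per-residue Cα RMSF (Å) after global Cα superposition, plus the
    mean over the selected residues (all protein residues by default)."""
    if ensemble.n_frames < 2:
        raise ValueError("RMSF is undefined for a single frame")
    ca_idx = np.flatnonzero(
        (ensemble.names == "CA") & ensemble.is_protein
    )
    if ca_idx.size == 0:
        raise ValueError("no C-alpha atoms found")
    fitted = _superpose_frames(ensemble.frames, ca_idx)
    values = _rmsf(fitted[:, ca_idx])
    per_residue = {
        (ensemble.atoms[i].chain_id, ensemble.atoms[i].residue_number): float(v)
        for i, v in zip(ca_idx, values)
    }
    keys = selection if selection is not None else list(per_residue)
    mean = float(np.mean([per_residue[k] for k in keys]))
    return per_residue, mean


def sidechain_rmsf(ensemble: StructureEnsemble, residue: tuple[str, int]) -> float:
    """Sidechain RMSF (Å) after local alignment on the backbone of
    residues i−1..i+1 (truncated at chain ends).  Residues without
    sidechain atoms (glycine) return 0."""
    if ensemble.n_frames < 2:
        raise ValueError("RMSF is undefined for a single frame")
    if residue not in ensemble.residue_atoms:
        raise KeyError(f"residue {residue} not in topology")
    chain, pos = residue
    fit_atoms: list[int] = []
    for neighbor in (pos - 1, pos, pos + 1):
        key = (chain, neighbor)
        if key in ensemble.residue_atoms:
            for i in ensemble.residue_atoms[key]:
                if ensemble.is_backbone[i] and not ensemble.is_hydrogen[i]:
                    fit_atoms.append(i)
    side_atoms = np.array(
        [i for i in ensemble.residue_atoms[residue] if not ensemble.is_backbone[i]],
        dtype=int,
    )
    if side_atoms.size == 0:
        return 0.0
    fitted = _superpose_frames(ensemble.frames, np.asarray(fit_atoms, dtype=int))
    return float(_rmsf(fitted[:, side_atoms]).mean())


def exposure_class(
    residue: tuple[str, int],
    mean_sasa: float,
    residue_name: str,
    reference_sasa: dict[str, float],
) -> ExposureClass:
    """Classify a residue by trajectory-mean relative SASA."""
    aa = AA_3TO1.get(residue_name, residue_name)
    if aa not in reference_sasa:
        raise KeyError(f"no reference SASA for residue type {residue_name!r}")
    fraction = 100.0 * mean_sasa / reference_sasa[aa]
    if fraction <= 0.0:
        return ExposureClass.BURIED
    if fraction <= 20.0:
        return ExposureClass.PARTIAL
    return ExposureClass.EXPOSED


def residue_exposure_classes(
    ensemble: StructureEnsemble,
    analysis: SasaAnalysis | None = None,
    reference_sasa: dict[str, float] | None = None,
) -> dict[tuple[str, int], ExposureClass]:
    """Exposure class for every protein residue of an ensemble."""
    if analysis is None:
        analysis = SasaAnalysis(ensemble)
    if reference_sasa is None:
        reference_sasa = load_reference_sasa()
    mean_sasa = analysis.mean_residue_sasa()
    out = {}
    for key, atoms in ensemble.residue_atoms.items():
        resname = ensemble.atoms[atoms[0]].residue_name
        out[key] = exposure_class(key, mean_sasa[key], resname, reference_sasa)
    return out


def sidechain_score(
    rmsf: float, amino_acid: str, exposure: ExposureClass | str, curve_set
) -> float:
    """Map a sidechain RMSF to [0, 1] via the (amino acid, exposure class)
    benchmark curve; lower RMSF never scores worse."""
    exposure = ExposureClass(exposure)
    return curve_set.score((amino_acid, exposure.value), rmsf)


class ResidueFlexibility:
    """Bundle of flexibility observables for one residue."""

    __slots__ = ("residue", "backbone_rmsf", "sidechain_rmsf", "exposure", "sidechain_score")

    def __init__(self, residue, backbone_rmsf, sidechain_rmsf, exposure, sidechain_score=None):
        if backbone_rmsf < 0 or sidechain_rmsf < 0:
            raise ValueError("RMSF must be non-negative")
        self.residue = residue
        self.backbone_rmsf = backbone_rmsf
        self.sidechain_rmsf = sidechain_rmsf
        self.exposure = exposure
        self.sidechain_score = sidechain_score
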