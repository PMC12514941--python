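"""Per-mutation metric assembly, normalization, and composite ranking.

Every metric is evaluated per variant (frame-averaged over its
trajectory) and reported as the difference mutant − wild type, so 0
always means "no change".  Fluctuating metrics are computed at the
mutated-residue and 8 Å-surrounding levels (whole-protein is opt-in,
since it converges slowly on short trajectories); the salt-bridge count
is always whole-protein; helix and disulfide checks are whole-protein
only.  Each column is divided by its population standard deviation over
the mutation set (no centering — 0 stays the wild-type reference) and
multiplied by a fixed polarity so that positive always means predicted
stabilization.  The composite score is the plain mean of the scaled
columns and drives the ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .benchmark import BenchmarkCurveSet
from .ensemble import (
    AA_3TO1,
    Level,
    Mutation,
    SelectionLevel,
    StructureEnsemble,
    select_atoms,
    selection_residues,
)
from .exposure import SasaAnalysis
from .flexibility import (
    backbone_rmsf,
    load_reference_sasa,
    residue_exposure_classes,
    sidechain_rmsf,
    sidechain_score,
)
from .hbonds import frame_hbond_state, selection_hbond_energy, unsatisfied_count
from .structure import (
    assign_helices,
    capping_check,
    disulfide_count,
    load_propensity_scale,
    propensity_delta,
    salt_bridge_count,
)

__all__ = [
    "METRIC_POLARITY",
    "BINARY_METRICS",
    "ScoringConfig",
    "evaluate_mutation",
    "scale_table",
    "composite_and_rank",
    "score_mutations",
]

logger = logging.getLogger(__name__)

#: +1 if a raw increase is stabilizing, −1 otherwise (fixed ledger)
METRIC_POLARITY: dict[str, int] = {
    "hbond_energy": +1,
    "sidechain_score": +1,
    "exposure_score": +1,
    "salt_bridges": +1,
    "disulfides": +1,
    "unsatisfied": -1,
    "backbone_rmsf": -1,
    "helix_propensity": -1,
    "capping_disruption": -1,
}

#: binary flags enter the composite as 0/−1 and bypass SD normalization
BINARY_METRICS = {"capping_disruption"}


@dataclass
class ScoringConfig:
    surrounding_radius: float = 8.0
    include_whole_protein: bool = False  # opt-in: converges slowly on short MDs
    rmsf_curves: BenchmarkCurveSet | None = None
    sasa_curves: BenchmarkCurveSet | None = None
    reference_sasa: dict[str, float] | None = None
    propensity_scale: dict[str, float] | None = None
    partner_mode: str = "results"
    max_frames: int | None = None  # slice each variant's trajectory

    def levels(self) -> list[SelectionLevel]:
        out = [
            SelectionLevel(Level.RESIDUE, self.surrounding_radius),
            SelectionLevel(Level.SURROUNDING, self.surrounding_radius),
        ]
        if self.include_whole_protein:
            out.append(SelectionLevel(Level.WHOLE_PROTEIN, self.surrounding_radius))
        return out


def _column(metric: str, level: SelectionLevel | None = None) -> str:
    return f"{metric}[{level.level.value}]" if level else f"{metric}[whole_protein]"


class _VariantAnalysis:
    """Caches the expensive per-ensemble intermediates across mutations."""

    def __init__(self, ensemble: StructureEnsemble, config: ScoringConfig):
        if config.max_frames is not None:
            ensemble = StructureEnsemble(
                atoms=ensemble.atoms,
                bonds=ensemble.bonds,
                frames=ensemble.frames[: config.max_frames],
                replicate_boundaries=[
                    b for b in ensemble.replicate_boundaries if b < config.max_frames
                ],
                variant_id=ensemble.variant_id,
            )
        self.ensemble = ensemble
        self.config = config
        self._hbond_states = None
        self._sasa = None
        self._rmsf = None
        self._side_rmsf: dict = {}
        self._exposure = None

    @property
    def hbond_states(self):
        if self._hbond_states is None:
            self._hbond_states = [
                frame_hbond_state(self.ensemble, f) for f in range(self.ensemble.n_frames)
            ]
        return self._hbond_states

    @property
    def sasa(self) -> SasaAnalysis:
        if self._sasa is None:
            self._sasa = SasaAnalysis(self.ensemble)
        return self._sasa

    @property
    def backbone_rmsf(self) -> dict:
        if self._rmsf is None:
            self._rmsf, _ = backbone_rmsf(self.ensemble)
        return self._rmsf

    def sidechain_rmsf(self, residue) -> float:
        if residue not in self._side_rmsf:
            self._side_rmsf[residue] = sidechain_rmsf(self.ensemble, residue)
        return self._side_rmsf[residue]

    @property
    def exposure_classes(self):
        if self._exposure is None:
            reference = self.config.reference_sasa or load_reference_sasa()
            self._exposure = residue_exposure_classes(self.ensemble, self.sasa, reference)
        return self._exposure

    # -- per-level observables -------------------------------------------

    def observables(self, mutation: Mutation) -> dict[str, float]:
        cfg = self.config
        ens = self.ensemble
        out: dict[str, float] = {}
        for level in cfg.levels():
            energies, unsats = [], []
            for f in range(ens.n_frames):
                sel = select_atoms(ens, mutation, level, frame_index=f)
                state = self.hbond_states[f]
                energies.append(selection_hbond_energy(state, sel))
                unsats.append(
                    unsatisfied_count(ens, f, sel, state, cfg.partner_mode)
                )
            out[_column("hbond_energy", level)] = float(np.mean(energies))
            out[_column("unsatisfied", level)] = float(np.mean(unsats))

            if ens.n_frames >= 2:
                sel0 = select_atoms(ens, mutation, level, frame_index=0)
                residues = selection_residues(ens, sel0)
                rmsf = self.backbone_rmsf
                out[_column("backbone_rmsf", level)] = float(
                    np.mean([rmsf[r] for r in residues if r in rmsf])
                )
                if cfg.rmsf_curves is not None:
                    scores = []
                    for r in residues:
                        aa = AA_3TO1[ens.atoms[ens.residue_atoms[r][0]].residue_name]
                        if aa == "G":
                            continue  # no sidechain to score
                        scores.append(
                            sidechain_score(
                                self.sidechain_rmsf(r), aa,
                                self.exposure_classes[r], cfg.rmsf_curves,
                            )
                        )
                    if scores:
                        out[_column("sidechain_score", level)] = float(np.mean(scores))
            if cfg.sasa_curves is not None:
                hydro = self.sasa.mean_hydrophobic_sasa()
                sel0 = select_atoms(ens, mutation, level, frame_index=0)
                residues = selection_residues(ens, sel0)
                scores = []
                for r in residues:
                    aa = AA_3TO1[ens.atoms[ens.residue_atoms[r][0]].residue_name]
                    scores.append(cfg.sasa_curves.score(aa, hydro[r]))
                out[_column("exposure_score", level)] = float(np.mean(scores))
        out["salt_bridges[whole_protein]"] = salt_bridge_count(ens)
        return out


def evaluate_mutation(
    mut_ensemble: StructureEnsemble,
    wt_ensemble: StructureEnsemble | _VariantAnalysis,
    mutation: Mutation,
    config: ScoringConfig | None = None,
) -> dict[str, float]:
    """Raw metric deltas (mutant − wild type) for one mutation."""
    if config is None:
        config = ScoringConfig()
    wt = (
        wt_ensemble
        if isinstance(wt_ensemble, _VariantAnalysis)
        else _VariantAnalysis(wt_ensemble, config)
    )
    wt.ensemble.validate_mutation_site(mutation, is_mutant=False)
    mut_ensemble.validate_mutation_site(mutation, is_mutant=True)
    mut = _VariantAnalysis(mut_ensemble, config)

    wt_obs = wt.observables(mutation)
    mut_obs = mut.observables(mutation)
    row = {}
    for key in wt_obs:
        if key in mut_obs:
            row[key] = mut_obs[key] - wt_obs[key]

    helices = assign_helices(wt.ensemble)
    scale = config.propensity_scale or load_propensity_scale()
    row["helix_propensity[whole_protein]"] = propensity_delta(mutation, helices, scale)
    row["capping_disruption[whole_protein]"] = float(capping_check(mutation, helices))
    row["disulfides[whole_protein]"] = float(
        disulfide_count(mut.ensemble) - disulfide_count(wt.ensemble)
    )
    return row


def scale_table(
    raw: pd.DataFrame,
    polarity: dict[str, int] | None = None,
    predictor_scores: pd.Series | None = None,
    predictor_polarity: int = -1,
) -> pd.DataFrame:
    """SD-normalize and sign-adjust a raw delta table.

    Each column is divided by its population standard deviation across
    the mutation set (zero-SD columns are dropped from the composite with
    a warning) and multiplied by its metric's polarity.  Binary flag
    columns bypass the SD division.  Optional primary-predictor scores
    are normalized the same way (default polarity −1: ΔΔG-style, lower is
    better) and appended as one more column.
    """
    if polarity is None:
        polarity = METRIC_POLARITY
    if len(raw) < 2:
        raise ValueError("scaling needs at least 2 mutations (SD undefined)")
    scaled = {}
    for col in raw.columns:
        metric = col.split("[")[0]
        sign = polarity.get(metric)
        if sign is None:
            raise KeyError(f"no polarity registered for metric {metric!r}")
        values = raw[col].astype(float)
        if metric in BINARY_METRICS:
            scaled[col] = values * sign
            continue
        sd = float(values.std(ddof=0))
        if sd == 0.0:
            logger.warning("column %s has zero SD across the set; dropped from composite", col)
            continue
        scaled[col] = values / sd * sign
    if predictor_scores is not None:
        values = predictor_scores.reindex(raw.index).astype(float)
        if values.isna().any():
            raise ValueError("predictor scores missing for some mutations")
        sd = float(values.std(ddof=0))
        if sd == 0.0:
            logger.warning("predictor column has zero SD; dropped from composite")
        else:
            scaled["predictor"] = values / sd * predictor_polarity
    return pd.DataFrame(scaled, index=raw.index)


def composite_and_rank(scaled: pd.DataFrame) -> pd.DataFrame:
    """Mean of scaled columns, descending sort, lexicographic tie-break."""
    table = scaled.copy()
    table["composite"] = scaled.mean(axis=1)
    # descending composite, ascending mutation id on ties
    order = sorted(table.index, key=lambda m: (-table.at[m, "composite"], str(m)))
    table = table.loc[order]
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def score_mutations(
    wt_ensemble: StructureEnsemble,
    mutant_ensembles: dict[Mutation, StructureEnsemble],
    config: ScoringConfig | None = None,
    predictor_scores: pd.Series | None = None,
) -> pd.DataFrame:
    """Full pipeline: raw deltas → scaled table → composite → ranking.

    Returns one DataFrame indexed by mutation id with ``raw:`` and
    ``scaled:`` column groups plus ``composite`` and ``rank``.
    """
    if config is None:
        config = ScoringConfig()
    wt = _VariantAnalysis(wt_ensemble, config)
    rows = {}
    for mutation, ens in mutant_ensembles.items():
        rows[str(mutation)] = evaluate_mutation(ens, wt, mutation, config)
    raw = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    raw.index.name = "mutation"
    scaled = scale_table(raw, predictor_scores=predictor_scores)
    ranked = composite_and_rank(scaled)
    out = pd.concat(
        [raw.add_prefix("raw:"), ranked.drop(columns=["composite", "rank"]).add_prefix("scaled:")],
        axis=1,
    )
    out["composite"] = ranked["composite"]
    out["rank"] = ranked["rank"]
    return out.sort_values("rank")
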