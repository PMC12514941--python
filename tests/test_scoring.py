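"""Metric assembly, SD normalization, polarity, composite ranking."""

import numpy as np
import pandas as pd
import pytest

from mdstab.ensemble import Mutation
from mdstab.scoring import (
    METRIC_POLARITY,
    ScoringConfig,
    composite_and_rank,
    evaluate_mutation,
    scale_table,
    score_mutations,
)


class TestEvaluateMutation:
    def test_wild_type_versus_itself_is_all_zero(self, scored_variant_pair):
        wt, _ = scored_variant_pair
        # clone the wild type but call it the "mutant" topology of a real site:
        # every metric delta must vanish when ensembles are identical
        from mdstab.ensemble import StructureEnsemble

        m = Mutation("A", 5, "S", "C")
        clone_atoms = [
            a if a.residue_number != 5 else type(a)(
                a.element, a.name, a.residue_number, "CYS", a.chain_id,
                a.is_backbone, a.is_water,
            )
            for a in wt.atoms
        ]
        clone = StructureEnsemble(clone_atoms, wt.bonds, wt.frames, variant_id="clone")
        row = evaluate_mutation(clone, wt, m, ScoringConfig())
        fluctuating = {k: v for k, v in row.items() if not k.startswith("capping")}
        # identical coordinates -> identical frame averages -> zero deltas
        for key, value in fluctuating.items():
            if key.startswith(("hbond", "unsatisfied", "backbone", "salt", "disulf")):
                assert value == pytest.approx(0.0, abs=1e-9), key

    def test_added_salt_bridge_shows_in_delta(self):
        from mdstab.synthetic import build_salt_bridge_toy

        near = build_salt_bridge_toy(3.5, n_frames=2)
        far = build_salt_bridge_toy(5.5, n_frames=2)
        # treat "far" as wild type (site 2 LYS), "near" as its mutant
        from mdstab.structure import salt_bridge_count

        assert salt_bridge_count(near) - salt_bridge_count(far) == 1.0

    def test_whole_protein_columns_are_opt_in(self, scored_variant_pair):
        wt, mutants = scored_variant_pair
        (m, ens), *_ = mutants.items()
        off = evaluate_mutation(ens, wt, m, ScoringConfig(include_whole_protein=False))
        on = evaluate_mutation(ens, wt, m, ScoringConfig(include_whole_protein=True))
        assert "hbond_energy[whole_protein]" not in off
        assert "hbond_energy[whole_protein]" in on
        # salt bridges and helix checks are always whole-protein
        assert "salt_bridges[whole_protein]" in off
        assert "helix_propensity[whole_protein]" in off

    def test_topology_mismatch_raises(self, scored_variant_pair):
        wt, mutants = scored_variant_pair
        (m, ens), *_ = mutants.items()
        wrong = Mutation("A", m.position, m.wt_residue,
                         "W" if m.mut_residue != "W" else "F")
        with pytest.raises(ValueError):
            evaluate_mutation(ens, wt, wrong, ScoringConfig())


class TestScaleTable:
    def _raw(self, **cols):
        base = {"hbond_energy[residue]": [1.0, 3.0]}
        base.update(cols)
        return pd.DataFrame(base, index=["A:A1G", "A:A2G"])

    def test_population_sd_normalization(self):
        scaled = scale_table(self._raw())
        # values {1, 3}: population SD is 1 -> scaled values unchanged
        assert list(scaled["hbond_energy[residue]"]) == [1.0, 3.0]

    def test_zero_sd_column_dropped_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="mdstab.scoring"):
            scaled = scale_table(self._raw(**{"unsatisfied[residue]": [2.0, 2.0]}))
        assert "unsatisfied[residue]" not in scaled.columns
        assert any("zero SD" in r.message for r in caplog.records)

    def test_polarity_flips_destabilizing_metrics(self):
        scaled = scale_table(self._raw(**{"backbone_rmsf[residue]": [0.5, 0.1]}))
        assert scaled["backbone_rmsf[residue]"].iloc[0] < 0  # raw increase -> negative

    def test_binary_capping_bypasses_sd(self):
        scaled = scale_table(self._raw(**{"capping_disruption[whole_protein]": [1.0, 0.0]}))
        assert list(scaled["capping_disruption[whole_protein]"]) == [-1.0, 0.0]

    def test_predictor_appended_with_ddg_polarity(self):
        pred = pd.Series([-2.0, 2.0], index=["A:A1G", "A:A2G"])
        scaled = scale_table(self._raw(), predictor_scores=pred)
        # lower (more negative) ΔΔG is better -> first mutation scores higher
        assert scaled["predictor"].iloc[0] > scaled["predictor"].iloc[1]

    def test_single_mutation_rejected(self):
        with pytest.raises(ValueError, match="2 mutations"):
            scale_table(pd.DataFrame({"hbond_energy[residue]": [1.0]}, index=["A:A1G"]))

    def test_polarity_ledger_is_total(self):
        assert set(METRIC_POLARITY.values()) == {-1, 1}
        for metric in ("hbond_energy", "sidechain_score", "exposure_score",
                       "salt_bridges", "disulfides"):
            assert METRIC_POLARITY[metric] == 1
        for metric in ("unsatisfied", "backbone_rmsf", "helix_propensity",
                       "capping_disruption"):
            assert METRIC_POLARITY[metric] == -1


class TestCompositeAndRank:
    def _scaled(self, values, ids=None):
        ids = ids or [f"A:A{i+1}G" for i in range(len(values))]
        return pd.DataFrame({"m1": values}, index=ids)

    def test_single_mutation_gets_rank_one(self):
        out = composite_and_rank(self._scaled([0.7]))
        assert list(out["rank"]) == [1]

    def test_ties_break_alphabetically(self):
        out = composite_and_rank(self._scaled([0.5, 0.5], ids=["A:B2C", "A:A1G"]))
        assert list(out.index) == ["A:A1G", "A:B2C"]

    def test_sign_flip_reverses_ranking(self):
        scaled = pd.DataFrame(
            {"m1": [0.3, -0.1, 0.8], "m2": [0.1, 0.2, -0.35]},
            index=["A:A1G", "A:A2G", "A:A3G"],
        )
        fwd = composite_and_rank(scaled)
        rev = composite_and_rank(-scaled)
        assert list(fwd.index) == list(rev.index)[::-1]

    def test_composite_is_mean_of_columns(self):
        scaled = pd.DataFrame({"m1": [1.0, 0.0], "m2": [0.0, 1.0]}, index=["a", "b"])
        out = composite_and_rank(scaled)
        assert out["composite"].tolist() == [0.5, 0.5]

    def test_monotone_in_score_bump(self):
        rng = np.random.default_rng(0)
        scaled = pd.DataFrame({"m1": rng.normal(size=6)},
                              index=[f"A:A{i+1}G" for i in range(6)])
        base = composite_and_rank(scaled)
        target = base.index[3]
        bumped = scaled.copy()
        bumped.loc[target, "m1"] += 1.0
        after = composite_and_rank(bumped)
        assert after.loc[target, "rank"] <= base.loc[target, "rank"]


class TestFullPipeline:
    def test_ranked_table_shape_and_columns(self, scored_variant_pair, benchmark_sets):
        wt, mutants = scored_variant_pair
        rmsf_set, sasa_set, _ = benchmark_sets
        cfg = ScoringConfig(rmsf_curves=rmsf_set, sasa_curves=sasa_set)
        table = score_mutations(wt, mutants, cfg)
        assert len(table) == 3
        assert list(table["rank"]) == [1, 2, 3]
        assert any(c.startswith("raw:hbond_energy") for c in table.columns)
        assert any(c.startswith("scaled:") for c in table.columns)
        assert table["composite"].is_monotonic_decreasing

    def test_rescaling_a_raw_column_leaves_ranking_unchanged(self, scored_variant_pair):
        wt, mutants = scored_variant_pair
        cfg = ScoringConfig()
        from mdstab.scoring import _VariantAnalysis

        wt_an = _VariantAnalysis(wt, cfg)
        rows = {
            str(m): evaluate_mutation(ens, wt_an, m, cfg) for m, ens in mutants.items()
        }
        raw = pd.DataFrame.from_dict(rows, orient="index")
        ranked1 = composite_and_rank(scale_table(raw))
        raw2 = raw.copy()
        raw2["hbond_energy[residue]"] *= 37.0  # positive rescale is absorbed by SD
        ranked2 = composite_and_rank(scale_table(raw2))
        assert list(ranked1.index) == list(ranked2.index)
        assert np.allclose(ranked1["composite"], ranked2["composite"])
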