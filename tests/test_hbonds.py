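"""Hydrogen-bond energetics: ramps, filtering, capping, bridges,
unsatisfied counting, and brute-force oracle equivalence."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdstab.ensemble import Level, Mutation
from mdstab.hbonds import (
    BIFURCATION_CAP,
    E_IDEAL,
    ENERGY_FLOOR,
    WATER_ENTROPY_PENALTY,
    HBond,
    HBondGeometry,
    detect_candidate_hbonds,
    filter_and_cap,
    frame_hbond_state,
    hbond_energy,
    hbond_metric_deltas,
    unsatisfied_count,
)
from mdstab.synthetic import (
    build_bifurcated_toy,
    build_hbond_toy,
    build_water_bridge_toy,
)


def geometry(dist_HA=2.0, angle_DHA=180.0, neighbors=((120.0, False),)):
    return HBondGeometry(
        dist_HA=dist_HA, dist_DA=dist_HA + 1.0, angle_DHA=angle_DHA,
        neighbor_angles=tuple(neighbors),
    )


class TestEnergyFunction:
    @pytest.mark.parametrize(
        "dist,angle,neighbors,expected",
        [
            # ideal interaction: full 25 kJ/mol
            (2.0, 180.0, ((120.0, False),), 25.0),
            # each printed ramp at its midpoint: 25 * 0.5^3
            (2.35, 132.5, ((90.0, False),), 3.125),
            # distance ramp endpoint
            (2.6, 180.0, ((120.0, False),), 0.0),
            # plateau: anything at/below 2.1 Å is ideal
            (1.8, 180.0, ((120.0, False),), 25.0),
            # hydrogen-neighbour ramp midpoint (75..85 window)
            (2.0, 180.0, ((80.0, True),), 12.5),
            # heavy neighbour fully blocking
            (2.0, 180.0, ((85.0, False),), 0.0),
            # no acceptor neighbours: no steric scaling
            (2.0, 180.0, (), 25.0),
            # worst neighbour governs
            (2.0, 180.0, ((120.0, False), (90.0, False)), 12.5),
        ],
    )
    def test_ramp_values(self, dist, angle, neighbors, expected):
        assert hbond_energy(geometry(dist, angle, neighbors)) == pytest.approx(expected)

    @settings(max_examples=200, derandomize=True)
    @given(
        d1=st.floats(1.5, 3.4), d2=st.floats(1.5, 3.4),
        a1=st.floats(0.0, 180.0), a2=st.floats(0.0, 180.0),
    )
    def test_monotone_in_distance_and_angle(self, d1, d2, a1, a2):
        """E is non-increasing in dist_HA and non-decreasing in angle_DHA."""
        lo_d, hi_d = sorted((d1, d2))
        lo_a, hi_a = sorted((a1, a2))
        assert hbond_energy(geometry(lo_d, 150.0)) >= hbond_energy(geometry(hi_d, 150.0))
        assert hbond_energy(geometry(2.2, hi_a)) >= hbond_energy(geometry(2.2, lo_a))

    @settings(max_examples=200, derandomize=True)
    @given(
        d=st.floats(0.5, 5.0), a=st.floats(0.0, 180.0),
        nb=st.floats(0.0, 180.0), is_h=st.booleans(),
    )
    def test_energy_bounded(self, d, a, nb, is_h):
        e = hbond_energy(geometry(d, a, ((nb, is_h),)))
        assert 0.0 <= e <= E_IDEAL


class TestDetection:
    def test_toy_geometry_reproduced(self):
        ens = build_hbond_toy(2.0, 160.0, 110.0)
        (bond,) = detect_candidate_hbonds(ens)
        assert bond.geometry.dist_HA == pytest.approx(2.0, abs=1e-9)
        assert bond.geometry.angle_DHA == pytest.approx(160.0, abs=1e-6)
        ((ax, is_h),) = bond.geometry.neighbor_angles
        assert ax == pytest.approx(110.0, abs=1e-6)
        assert not is_h

    @pytest.mark.parametrize(
        "dist_HA,angle,expected_candidates",
        [
            (2.4, 120.0, 1),   # D-A 3.4 Å, angle fine
            (2.49, 180.0, 1),  # D-A 3.5 Å boundary retained
            (2.6, 180.0, 0),   # D-A 3.61 Å: outside distance cutoff
            (2.0, 99.0, 0),    # angle below 100°
            (2.0, 100.0, 1),   # angle boundary retained
        ],
    )
    def test_detection_cutoffs(self, dist_HA, angle, expected_candidates):
        ens = build_hbond_toy(dist_HA, angle)
        assert len(detect_candidate_hbonds(ens)) == expected_candidates

    def test_no_hydrogens_is_explicit_error(self):
        from mdstab.synthetic import build_salt_bridge_toy
        ens = build_salt_bridge_toy(3.5)
        keep = [i for i in range(ens.n_atoms) if ens.elements[i] != "H"]
        import numpy as np
        from mdstab.ensemble import StructureEnsemble
        remap = {old: new for new, old in enumerate(keep)}
        bonds = [
            (remap[i], remap[j]) for i, j in ens.bonds if i in remap and j in remap
        ]
        bare = StructureEnsemble(
            [ens.atoms[i] for i in keep], np.array(bonds), ens.frames[:, keep],
            variant_id="bare",
        )
        with pytest.raises(ValueError, match="hydrogen"):
            detect_candidate_hbonds(bare)


class TestFilterAndCap:
    def _bond(self, energy, donor=0, hydrogen=1, acceptor=2):
        return HBond(donor, hydrogen, acceptor, geometry(), energy=energy)

    def test_floor_is_strict(self):
        bonds = [self._bond(ENERGY_FLOOR), self._bond(ENERGY_FLOOR + 1e-9, acceptor=3)]
        kept = filter_and_cap(bonds)
        assert len(kept) == 1 and kept[0].acceptor == 3

    def test_bifurcated_second_bond_capped(self):
        ens = build_bifurcated_toy()
        kept = filter_and_cap(detect_candidate_hbonds(ens))
        assert sorted(b.energy for b in kept) == [BIFURCATION_CAP, E_IDEAL]

    def test_single_moderate_bond_unchanged(self):
        kept = filter_and_cap([self._bond(7.0)])
        assert kept[0].energy == 7.0

    def test_third_bond_also_capped(self):
        bonds = [self._bond(25.0, acceptor=2), self._bond(20.0, acceptor=3),
                 self._bond(18.0, acceptor=4)]
        kept = filter_and_cap(bonds)
        by_acceptor = {b.acceptor: b.energy for b in kept}
        assert by_acceptor == {2: 25.0, 3: 15.0, 4: 15.0}

    def test_distinct_hydrogens_on_one_donor_not_capped(self):
        bonds = [self._bond(25.0, hydrogen=1, acceptor=3),
                 self._bond(25.0, hydrogen=2, acceptor=4)]
        kept = filter_and_cap(bonds)
        assert [b.energy for b in kept] == [25.0, 25.0]

    def test_equal_energy_tie_broken_by_index_order(self):
        bonds = [self._bond(25.0, acceptor=5), self._bond(25.0, acceptor=3)]
        kept = {b.acceptor: b.energy for b in filter_and_cap(bonds)}
        assert kept == {3: 25.0, 5: 15.0}


class TestWaterBridges:
    def test_bridge_energy_pays_entropic_penalty(self):
        ens = build_water_bridge_toy()
        state = frame_hbond_state(ens, 0)
        (bridge,) = state.bridges
        assert bridge.energy == pytest.approx(2 * E_IDEAL - WATER_ENTROPY_PENALTY)
        assert len(bridge.member_bonds) == 2
        assert not state.protein_bonds

    def test_single_water_bond_is_no_bridge(self):
        ens = build_water_bridge_toy()
        # pull the second acceptor out of range
        coords = ens.frames[0].copy()
        second_acceptor = ens.residue_atoms[("A", 3)]
        coords[second_acceptor] += 40.0
        from mdstab.ensemble import StructureEnsemble
        e = StructureEnsemble(ens.atoms, ens.bonds, coords[None], variant_id="one")
        state = frame_hbond_state(e, 0)
        assert state.bridges == []

    def test_weak_members_floor_at_zero(self):
        from mdstab.hbonds import find_water_bridges
        ens = build_water_bridge_toy()
        weak = [
            HBond(0, 1, 3, geometry(), energy=7.0),
            HBond(0, 2, 5, geometry(), energy=7.0),
        ]
        (bridge,) = find_water_bridges(ens, 0, weak)
        assert bridge.energy == 0.0  # 14 - 32.2 floored


class TestUnsatisfied:
    def test_isolated_carbonyl_counts_once(self):
        ens = build_hbond_toy(3.2, 120.0)  # weak candidate, filtered out
        state = frame_hbond_state(ens, 0)
        sel = np.arange(ens.n_atoms)
        # partners: donor N + its H, acceptor O  (neighbour C is apolar)
        assert unsatisfied_count(ens, 0, sel, state) == 3

    def test_engaged_atoms_not_counted(self):
        ens = build_hbond_toy(2.0, 180.0)
        state = frame_hbond_state(ens, 0)
        sel = np.arange(ens.n_atoms)
        assert unsatisfied_count(ens, 0, sel, state) == 0

    def test_filtering_precedes_counting(self):
        # energy below the floor: detected but not retained -> unsatisfied
        ens = build_hbond_toy(2.5, 120.0)
        state = frame_hbond_state(ens, 0)
        assert [round(b.energy, 3) for b in state.protein_bonds] == []
        sel = np.arange(ens.n_atoms)
        assert unsatisfied_count(ens, 0, sel, state) == 3

    def test_methods_partner_mode_is_narrower(self):
        ens = build_hbond_toy(3.2, 120.0)
        state = frame_hbond_state(ens, 0)
        sel = np.arange(ens.n_atoms)
        # methods mode: O only (N carries a hydrogen; H atoms not partners)
        assert unsatisfied_count(ens, 0, sel, state, partner_mode="methods") == 1


class TestOracleEquivalence:
    """Retained-bond sets match a brute-force enumeration on tiny systems."""

    def brute_force(self, ens, frame=0):
        from mdstab.hbonds import DA_CUTOFF, DHA_CUTOFF, _angle

        coords = ens.frames[frame]
        el = ens.elements
        adj = ens.bonded
        polar = [i for i in range(ens.n_atoms) if el[i] in ("N", "O", "S")]
        out = []
        for d, a in itertools.product(polar, polar):
            if d == a or a in adj[d]:
                continue
            for h in adj[d]:
                if el[h] != "H" or a in adj[h]:
                    continue
                if np.linalg.norm(coords[d] - coords[a]) > DA_CUTOFF:
                    continue
                if _angle(coords[d], coords[h], coords[a]) < DHA_CUTOFF:
                    continue
                out.append((d, h, a))
        return sorted(out)

    @pytest.mark.parametrize("seed", range(6))
    def test_random_small_systems(self, seed):
        from mdstab.ensemble import AtomRecord, StructureEnsemble

        rng = np.random.default_rng(seed)
        n_groups = 5
        atoms, bonds, coords = [], [], []
        for g in range(n_groups):  # N-H fragments and O acceptors
            center = rng.uniform(0, 8, 3)
            if g % 2 == 0:
                atoms.append(AtomRecord("N", "N", g + 1, "ALA", "A"))
                coords.append(center)
                atoms.append(AtomRecord("H", "H", g + 1, "ALA", "A"))
                coords.append(center + rng.normal(0, 0.5, 3))
                bonds.append((len(atoms) - 2, len(atoms) - 1))
            else:
                atoms.append(AtomRecord("O", "O", g + 1, "ALA", "A"))
                coords.append(center)
        ens = StructureEnsemble(atoms, np.array(bonds), np.asarray(coords)[None],
                                variant_id=f"rand{seed}")
        found = sorted(b.atoms for b in detect_candidate_hbonds(ens))
        assert found == self.brute_force(ens)


class TestMetricDeltas:
    def test_self_comparison_is_zero(self):
        ens = build_hbond_toy(2.0, 180.0)
        m = Mutation("A", 1, "A", "G")
        de, du = hbond_metric_deltas(ens, ens, m, Level.WHOLE_PROTEIN)
        assert de == 0.0 and du == 0.0

    def test_gained_permanent_bond_counts_fully(self):
        strong = build_hbond_toy(2.0, 180.0)
        broken = build_hbond_toy(2.0, 110.0)  # weak: filtered out
        m = Mutation("A", 1, "A", "G")
        de, du = hbond_metric_deltas(strong, broken, m, Level.WHOLE_PROTEIN)
        assert de == pytest.approx(E_IDEAL)
        assert du < 0  # donor/H no longer unsatisfied

    def test_half_occupancy_halves_the_delta(self):
        import numpy as np
        from mdstab.ensemble import StructureEnsemble

        strong = build_hbond_toy(2.0, 180.0)
        weak = build_hbond_toy(2.0, 110.0)
        frames = np.concatenate([strong.frames, weak.frames])
        half = StructureEnsemble(strong.atoms, strong.bonds, frames, variant_id="half")
        none = StructureEnsemble(weak.atoms, weak.bonds,
                                 np.repeat(weak.frames, 2, axis=0), variant_id="none")
        m = Mutation("A", 1, "A", "G")
        de, _ = hbond_metric_deltas(half, none, m, Level.WHOLE_PROTEIN)
        assert de == pytest.approx(E_IDEAL / 2)
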