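"""Pseudo-reaction LP, lookup cascade and free-energy arithmetic."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pathranker.errors import ThermodynamicsError
from pathranker.records import (
    GROUP_THERMO_SUBSTITUTED,
    PathwayRecord,
    ReactionRecord,
    Species,
)
from pathranker.synth import FixtureSpec, make_formation_table, make_pathway_set, make_toy_chassis
from pathranker.thermo import (
    TableFormationProvider,
    build_pseudo_reaction,
    lookup_compound,
    pathway_dg,
    pathway_intermediates,
    reaction_dg,
)

IK1 = "LFQSCWFLJHTTHZ-UHFFFAOYSA-N"  # ethanol
IK2 = "OKKJLVBELUTLKV-UHFFFAOYSA-N"  # methanol


def _provider(rows):
    return TableFormationProvider(pd.DataFrame(rows))


class TestPseudoReactionLP:
    def test_three_reaction_system_multipliers(self, worked_example_pathway):
        p, chassis_species = worked_example_pathway
        x, _ = build_pseudo_reaction(p, chassis_species)
        assert x == pytest.approx([3.0, 1.5, 1.0], abs=1e-9)

    def test_three_reaction_system_net_coefficients(self, worked_example_pathway):
        p, chassis_species = worked_example_pathway
        _, net = build_pseudo_reaction(p, chassis_species)
        assert net.reactants["MNXM4"] == pytest.approx(5.5, abs=1e-9)
        assert net.reactants["MNXM6"] == pytest.approx(4.0, abs=1e-9)
        assert net.products["MNXM13"] == pytest.approx(4.0, abs=1e-9)
        assert net.products["MNXM15"] == pytest.approx(3.0, abs=1e-9)
        assert net.products["MNXM5"] == pytest.approx(4.0, abs=1e-9)
        # intermediates cancelled exactly
        assert "CMPD3" not in net.species_ids
        assert "CMPD4" not in net.species_ids

    def test_single_reaction_pathway_is_identity(self):
        r = ReactionRecord(id="r", reactants={"A": 1}, products={"T": 2})
        p = PathwayRecord(
            id="p", reactions=[r], target_id="T",
            species={s: Species(id=s) for s in "AT"},
        )
        x, net = build_pseudo_reaction(p)
        assert x == pytest.approx([1.0])
        assert net.reactants == {"A": 1.0}
        assert net.products == {"T": 2.0}

    def test_unit_chain_eliminates_intermediate(self):
        p = PathwayRecord(
            id="p",
            reactions=[
                ReactionRecord(id="r1", reactants={"A": 1}, products={"B": 1}),
                ReactionRecord(id="r2", reactants={"B": 1}, products={"T": 1}),
            ],
            target_id="T",
            species={s: Species(id=s) for s in "ABT"},
        )
        x, net = build_pseudo_reaction(p)
        assert x == pytest.approx([1.0, 1.0])
        assert net.reactants == {"A": 1.0}
        assert net.products == {"T": 1.0}

    def test_infeasible_cancellation_lists_intermediates(self):
        # B and C force x1 = x2 and x2 = 2*x1 simultaneously: only x = 0,
        # excluded by the multiplier lower bound of 1.
        p = PathwayRecord(
            id="p",
            reactions=[
                ReactionRecord(id="r1", reactants={"A": 1, "C": 2}, products={"B": 1}),
                ReactionRecord(id="r2", reactants={"B": 1}, products={"C": 1, "T": 1}),
            ],
            target_id="T",
            species={s: Species(id=s) for s in "ABCT"},
        )
        with pytest.raises(ThermodynamicsError, match="B"):
            build_pseudo_reaction(p)

    def test_multipliers_componentwise_minimal_on_worked_example(self, worked_example_pathway):
        p, chassis_species = worked_example_pathway
        x, _ = build_pseudo_reaction(p, chassis_species)
        intermediates = pathway_intermediates(p, chassis_species)
        A = np.array(
            [
                [r.net_stoichiometry().get(sid, 0.0) for r in p.reactions]
                for sid in intermediates
            ]
        )
        grid = np.arange(1.0, 3.51, 0.5)
        for y in itertools.product(grid, repeat=3):
            y = np.array(y)
            feasible = np.allclose(A @ y, 0.0, atol=1e-9)
            if feasible and np.all(y <= x + 1e-9) and not np.allclose(y, x):
                pytest.fail(f"found smaller feasible multipliers {y}")

    def test_cancellation_holds_on_generated_pathways(self, toy_chassis):
        spec = FixtureSpec(seed=3, n_pathways=25, positive_fraction=0.3)
        for p, _ in make_pathway_set(spec, toy_chassis):
            chassis_species = set(toy_chassis.species)
            _, net = build_pseudo_reaction(p, chassis_species)
            for sid in pathway_intermediates(p, chassis_species):
                assert sid not in net.species_ids


class TestLookupCascade:
    def test_id_match_stops_cascade(self):
        prov = _provider(
            [
                {"provider_key": "A", "dg_kj_mol": -10.0, "inchikey": IK1},
                {"provider_key": "other", "dg_kj_mol": -20.0, "inchikey": IK2},
            ]
        )
        ref = lookup_compound(Species(id="A", inchikey=IK2), prov)
        assert ref.matched_by == "id"
        assert ref.provider_key == "A"  # inchikey rung (→ other) never tried

    def test_structure_rungs_in_order(self):
        prov = _provider(
            [{"provider_key": "K", "dg_kj_mol": -1.0, "inchikey": IK1,
              "inchi": "InChI=1S/C2H6O/c1-2-3/h3H,2H2,1H3", "smiles": "CCO"}]
        )
        assert lookup_compound(Species(id="zz", inchikey=IK1), prov).matched_by == "inchikey"
        assert lookup_compound(
            Species(id="zz", inchi="InChI=1S/C2H6O/c1-2-3/h3H,2H2,1H3"), prov
        ).matched_by == "inchi"
        assert lookup_compound(Species(id="zz", smiles="CCO"), prov).matched_by == "smiles"

    def test_inchikey_block1_takes_first_of_list(self):
        # two provider compounds share the connectivity block; the first
        # (sorted) key is taken
        ik_a = "LFQSCWFLJHTTHZ-AAAAAAAAAA-N"
        ik_b = "LFQSCWFLJHTTHZ-BBBBBBBBBB-N"
        prov = _provider(
            [
                {"provider_key": "k2", "dg_kj_mol": -2.0, "inchikey": ik_b},
                {"provider_key": "k1", "dg_kj_mol": -1.0, "inchikey": ik_a},
            ]
        )
        ref = lookup_compound(Species(id="zz", inchikey=IK1), prov)
        assert ref.matched_by == "inchikey_block1"
        assert ref.provider_key == "k1"

    def test_substitution_is_last_resort_and_recorded(self):
        prov = _provider([{"provider_key": "SUB", "dg_kj_mol": -5.0}])
        s = Species(id="orphan")
        ref = lookup_compound(s, prov, substitutions={"orphan": "SUB"})
        assert ref.matched_by == "substitution"

        p = PathwayRecord(
            id="p",
            reactions=[ReactionRecord(id="r", reactants={"A": 1}, products={"orphan": 1})],
            target_id="orphan",
            species={"A": Species(id="A"), "orphan": s},
        )
        prov2 = _provider(
            [{"provider_key": "A", "dg_kj_mol": -1.0},
             {"provider_key": "SUB", "dg_kj_mol": -5.0}]
        )
        est = pathway_dg(p, prov2, substitutions={"orphan": "SUB"})
        assert est is not None
        assert p.groups[GROUP_THERMO_SUBSTITUTED] == ["orphan"]

    def test_all_rungs_fail_returns_none(self):
        prov = _provider([{"provider_key": "X", "dg_kj_mol": -1.0}])
        assert lookup_compound(Species(id="zz", inchikey=IK1), prov) is None


class TestFreeEnergies:
    def test_reaction_dg_is_formation_difference(self):
        prov = _provider(
            [
                {"provider_key": "A", "dg_kj_mol": -50.0, "uncertainty": 1.0},
                {"provider_key": "B", "dg_kj_mol": -30.0, "uncertainty": 2.0},
            ]
        )
        r = ReactionRecord(id="r", reactants={"A": 2}, products={"B": 1})
        species = {s: Species(id=s) for s in "AB"}
        est = reaction_dg(r, species, prov)
        assert est.value == pytest.approx(1 * -30.0 - 2 * -50.0)
        assert est.uncertainty == pytest.approx(((2 * 1.0) ** 2 + (1 * 2.0) ** 2) ** 0.5)

    def test_unresolved_species_gives_no_value(self):
        prov = _provider([{"provider_key": "A", "dg_kj_mol": -50.0}])
        r = ReactionRecord(id="r", reactants={"A": 1}, products={"B": 1})
        species = {s: Species(id=s) for s in "AB"}
        assert reaction_dg(r, species, prov) is None

    def test_identity_reaction_has_zero_dg(self):
        prov = _provider([{"provider_key": "A", "dg_kj_mol": -50.0}])
        r = ReactionRecord(id="r", reactants={"A": 1}, products={"A": 1})
        assert reaction_dg(r, {"A": Species(id="A")}, prov).value == pytest.approx(0.0)

    def test_pathway_dg_equals_multiplier_weighted_reaction_sum(self, worked_example_pathway):
        p, chassis_species = worked_example_pathway
        table = make_formation_table(list(p.species.values()), seed=9)
        prov = TableFormationProvider(table)
        x, _ = build_pseudo_reaction(p, chassis_species)
        member = sum(
            xi * reaction_dg(r, p.species, prov).value
            for xi, r in zip(x, p.reactions)
        )
        est = pathway_dg(p, prov, chassis_species=chassis_species)
        assert est.value == pytest.approx(member, abs=1e-6)
        assert p.properties["pathway_dg"] == pytest.approx(est.value)

    def test_unit_multipliers_sum_reaction_dgs(self):
        p = PathwayRecord(
            id="p",
            reactions=[
                ReactionRecord(id="r1", reactants={"A": 1}, products={"B": 1}),
                ReactionRecord(id="r2", reactants={"B": 1}, products={"T": 1}),
            ],
            target_id="T",
            species={s: Species(id=s) for s in "ABT"},
        )
        prov = _provider(
            [
                {"provider_key": "A", "dg_kj_mol": -10.0},
                {"provider_key": "B", "dg_kj_mol": -25.0},
                {"provider_key": "T", "dg_kj_mol": -32.0},
            ]
        )
        total = sum(reaction_dg(r, p.species, prov).value for r in p.reactions)
        assert pathway_dg(p, prov).value == pytest.approx(total)

    def test_provider_swap_changes_values_not_structure(self, worked_example_pathway):
        p, chassis_species = worked_example_pathway

        class ConstantProvider:
            def resolve(self, kind, value):
                return value if kind == "id" else None

            def resolve_block1(self, block):
                return []

            def dg_of(self, key):
                return -7.0, None

        table = make_formation_table(list(p.species.values()), seed=9)
        est_table = pathway_dg(
            p.__class__(**{**p.__dict__, "groups": dict(p.groups), "properties": {}}),
            TableFormationProvider(table),
            chassis_species=chassis_species,
        )
        est_const = pathway_dg(p, ConstantProvider(), chassis_species=chassis_species)
        assert est_table is not None and est_const is not None
        assert est_table.value != pytest.approx(est_const.value)
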