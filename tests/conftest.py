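"""Shared fixtures: all test inputs are generated programmatically."""

from __future__ import annotations

import pytest

from pathranker.records import PathwayRecord, ReactionRecord, Species
from pathranker.synth import make_toy_chassis


@pytest.fixture(scope="session")
def toy_chassis():
    return make_toy_chassis(4, seed=1)


@pytest.fixture()
def worked_example_pathway():
    """The 3-reaction system used to exercise the pseudo-reaction LP:
    chain substrates MNXM*, intermediates CMPD3/CMPD4, product TARGET."""
    rxns = [
        ReactionRecord(
            id="Rxn1",
            reactants={"MNXM188": 1, "MNXM4": 1, "MNXM6": 1, "MNXM1": 3},
            products={"CMPD4": 1, "CMPD3": 1, "MNXM13": 1, "MNXM15": 1, "MNXM5": 1},
        ),
        ReactionRecord(
            id="Rxn2",
            reactants={"MNXM4": 1, "CMPD3": 2},
            products={"MNXM1": 2, "TARGET": 1},
        ),
        ReactionRecord(
            id="Rxn3",
            reactants={"MNXM4": 1, "MNXM6": 1, "CMPD4": 3},
            products={"MNXM13": 1, "MNXM5": 1},
        ),
    ]
    sids = set().union(*(r.species_ids for r in rxns))
    p = PathwayRecord(
        id="worked_example",
        reactions=rxns,
        target_id="TARGET",
        species={s: Species(id=s) for s in sids},
    )
    chassis_species = {s for s in sids if s.startswith("MNXM")}
    return p, chassis_species


@pytest.fixture()
def simple_pathway():
    """Two-step pathway A → B → T with real small-molecule structures."""
    species = {
        "A": Species(id="A", smiles="CCO"),
        "B": Species(id="B", smiles="CCC"),
        "T": Species(id="T", smiles="CCCO"),
        "NADH_s": Species(id="NADH_s", smiles="CC(C)O", name="nadh"),
        "NAD_s": Species(id="NAD_s", smiles="CC(C)C", name="nad"),
    }
    reactions = [
        ReactionRecord(
            id="step1",
            reactants={"A": 1, "NADH_s": 1},
            products={"B": 1, "NAD_s": 1},
            ec_numbers=["1.1.1.1"],
            rule_id="RR1",
            template_reaction_id="T1",
            rule_score=0.8,
        ),
        ReactionRecord(
            id="step2",
            reactants={"B": 1},
            products={"T": 1},
            ec_numbers=["2.3.1.9"],
            rule_id="RR2",
            template_reaction_id="T2",
            rule_score=0.6,
        ),
    ]
    return PathwayRecord(
        id="simple", reactions=reactions, target_id="T", species=species
    )
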