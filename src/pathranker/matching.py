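"""Similarity between a predicted pathway and a literature reference pathway.

A reference pathway is an ordered list of steps, each carrying EC numbers and
main substrates/products (with structures where known). Step similarity
combines identity of main species — compared by InChIKey connectivity block,
falling back to ids — with EC agreement to three levels; cofactors (common
currency metabolites) are excluded from the main sets, so two pathways that
agree on main substrates and products per step score above the 0.5 labelling
threshold even when their cofactor usage differs. Predicted reactions are
assigned to reference steps by an order-preserving dynamic program and the
pathway score is the assignment total over the longer of the two pathways.

A predicted pathway is labelled a literature pathway iff its score is
strictly above 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ArgumentError
from .records import PathwayRecord, ReactionRecord, Species

MATCH_THRESHOLD = 0.5

#: Default cofactor list: common currency metabolites, as MetaNetX ids and
#: plain names (matched case-insensitively against species ids and names).
DEFAULT_COFACTORS = frozenset(
    {
        # MetaNetX ids
        "mnxm1",  # H+
        "mnxm2",  # H2O
        "mnxm3",  # ATP
        "mnxm7",  # ADP
        "mnxm8",  # NAD+
        "mnxm9",  # phosphate
        "mnxm10",  # NADH
        "mnxm5",  # NADP+
        "mnxm6",  # NADPH
        "mnxm13",  # CO2
        "mnxm4",  # O2
        "mnxm11",  # diphosphate
        "mnxm12",  # CoA
        # plain names
        "h+",
        "h2o",
        "water",
        "atp",
        "adp",
        "amp",
        "nad",
        "nad+",
        "nadh",
        "nadp",
        "nadp+",
        "nadph",
        "pi",
        "phosphate",
        "ppi",
        "diphosphate",
        "coa",
        "co2",
        "o2",
    }
)


@dataclass
class ReferenceStep:
    """One literature step: EC numbers plus main substrates and products."""

    ec_numbers: list[str] = field(default_factory=list)
    substrates: list[Species] = field(default_factory=list)
    products: list[Species] = field(default_factory=list)


@dataclass
class ReferencePathway:
    """A literature pathway for one target compound."""

    target: Species
    steps: list[ReferenceStep]

    def __post_init__(self) -> None:
        if not self.steps:
            raise ArgumentError("reference pathway has no steps")


@dataclass
class MatchResult:
    """Similarity in [0,1] and the (injective) predicted→reference step map."""

    score: float
    step_map: dict[str, int] = field(default_factory=dict)


def _is_cofactor(sp: Species, cofactors: frozenset[str]) -> bool:
    return sp.id.lower() in cofactors or (sp.name or "").lower() in cofactors


def _main_keys(species: Iterable[Species], cofactors: frozenset[str]) -> set[str]:
    keys = set()
    for sp in species:
        if _is_cofactor(sp, cofactors):
            continue
        keys.add(sp.inchikey_block1 or sp.id)
    return keys


def _jaccard(a: set[str], b: set[str]) -> float:
    if not a and not b:
        return 1.0
    union = a | b
    return len(a & b) / len(union) if union else 0.0


def _ec_agreement(ecs_a: Sequence[str], ecs_b: Sequence[str]) -> float:
    """Best pairwise EC prefix agreement, counted to three levels (of 3)."""
    best = 0.0
    for ea in ecs_a:
        pa = ea.split(".")[:3]
        for eb in ecs_b:
            pb = eb.split(".")[:3]
            n = 0
            for x, y in zip(pa, pb):
                if x != y or x in ("", "-"):
                    break
                n += 1
            best = max(best, n / 3.0)
    return best


def _step_similarity(
    r: ReactionRecord,
    species: dict[str, Species],
    step: ReferenceStep,
    cofactors: frozenset[str],
) -> float:
    pred_species = [
        species.get(sid, Species(id=sid)) for sid in sorted(r.species_ids)
    ]
    pred_keys = _main_keys(pred_species, cofactors)
    ref_keys = _main_keys(step.substrates + step.products, cofactors)
    structural = _jaccard(pred_keys, ref_keys)
    if not r.ec_numbers and not step.ec_numbers:
        # no EC on either side: structure identity carries full weight
        return structural
    return 0.5 * structural + 0.5 * _ec_agreement(r.ec_numbers, step.ec_numbers)


def match_score(
    p: PathwayRecord,
    ref: ReferencePathway,
    cofactors: frozenset[str] = DEFAULT_COFACTORS,
) -> MatchResult:
    """Best order-preserving assignment of predicted reactions to reference
    steps; pathway score = assignment total / max(#reactions, #steps).

    Raises
    ------
    ArgumentError
        On an empty reference.
    """
    if not ref.steps:
        raise ArgumentError("reference pathway has no steps")
    n, m = len(p.reactions), len(ref.steps)
    sim = np.zeros((n, m))
    for i, r in enumerate(p.reactions):
        for j, step in enumerate(ref.steps):
            sim[i, j] = _step_similarity(r, p.species, step, cofactors)

    # DP over order-preserving injective assignments maximising total similarity
    best = np.zeros((n + 1, m + 1))
    choice = np.zeros((n + 1, m + 1), dtype=np.int8)  # 1 = matched (i,j)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            skip = max(best[i - 1, j], best[i, j - 1])
            take = best[i - 1, j - 1] + sim[i - 1, j - 1]
            if take > skip + 1e-15:
                best[i, j] = take
                choice[i, j] = 1
            else:
                best[i, j] = skip

    step_map: dict[str, int] = {}
    i, j = n, m
    while i > 0 and j > 0:
        if choice[i, j] == 1:
            step_map[p.reactions[i - 1].id] = j - 1
            i, j = i - 1, j - 1
        elif best[i - 1, j] >= best[i, j - 1]:
            i -= 1
        else:
            j -= 1

    score = float(best[n, m]) / max(n, m)
    return MatchResult(score=min(1.0, max(0.0, score)), step_map=step_map)


def as_reference(
    p: PathwayRecord, cofactors: frozenset[str] = DEFAULT_COFACTORS
) -> ReferencePathway:
    """View a predicted pathway as a reference (for self-match and tests)."""
    steps = []
    for r in p.reactions:
        steps.append(
            ReferenceStep(
                ec_numbers=list(r.ec_numbers),
                substrates=[
                    p.species.get(sid, Species(id=sid)) for sid in sorted(r.reactants)
                ],
                products=[
                    p.species.get(sid, Species(id=sid)) for sid in sorted(r.products)
                ],
            )
        )
    target = p.species.get(p.target_id, Species(id=p.target_id))
    return ReferencePathway(target=target, steps=steps)


def label_literature(results: Sequence[MatchResult]) -> list[bool]:
    """True iff the match score is strictly above 0.5."""
    return [r.score > MATCH_THRESHOLD for r in results]
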