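"""Expansion of master pathways into complete reaction pathways.

Retrosynthesis tools emit *master pathways*: ordered chemical transformations
at the reaction-rule level, cofactor-free, where one transformation may
reference several rules and each rule generalises one or more full template
reactions from knowledge databases. Completion forks each transformation over
its rules, then each rule over its templates, re-adding the template's
cofactors; the Cartesian product of per-transformation alternatives gives the
complete pathway set, from which duplicates (identical reaction multisets
under structure-based species identity) are removed.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import LookupError_, ParseError, ValidationError
from .records import PathwayRecord, ReactionRecord, Species, species_key


@dataclass
class Transformation:
    """A rule-level, cofactor-free chemical transformation."""

    id: str
    lhs: dict[str, float]
    rhs: dict[str, float]
    rule_ids: list[str]

    def __post_init__(self) -> None:
        if not self.rule_ids:
            raise ValidationError(f"transformation {self.id!r}: rule_ids is empty")


@dataclass
class MasterPathway:
    """Ordered transformations ending at the target species."""

    id: str
    transformations: list[Transformation]
    target_id: str

    def __post_init__(self) -> None:
        if not self.transformations:
            raise ValidationError(f"master pathway {self.id!r} has no transformations")


@dataclass
class RuleDatabase:
    """rule id -> [(template reaction id, full reaction with cofactors, score)].

    ``species`` optionally carries structure annotations for the species the
    templates mention; bare Species records are synthesised for the rest.
    """

    entries: dict[str, list[tuple[str, ReactionRecord, float]]]
    species: dict[str, Species] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rule_id, templates in self.entries.items():
            if not templates:
                raise ValidationError(f"rule {rule_id!r} has no templates")
            for _, _, score in templates:
                if not 0.0 <= score <= 1.0:
                    raise ValidationError(
                        f"rule {rule_id!r}: rule_score {score} not in [0,1]"
                    )

    def templates(self, rule_id: str) -> list[tuple[str, ReactionRecord, float]]:
        if rule_id not in self.entries:
            raise LookupError_(f"unknown reaction rule {rule_id!r}")
        return self.entries[rule_id]


# ---------------------------------------------------------------------------
# Rule database TSV dialect: rule_id, template_id, equation, direction, rule_score
# Equation grammar: `n id + n id <=> n id + ...` (n optional, default 1).
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(r"^(?:(\d+(?:\.\d+)?)\s+)?(\S+)$")


def _parse_side(side: str, ctx: str) -> dict[str, float]:
    out: dict[str, float] = {}
    side = side.strip()
    if not side:
        return out
    for term in side.split("+"):
        m = _TERM_RE.match(term.strip())
        if not m:
            raise ParseError(f"{ctx}: cannot parse equation term {term.strip()!r}")
        coeff = float(m.group(1)) if m.group(1) else 1.0
        sid = m.group(2)
        out[sid] = out.get(sid, 0.0) + coeff
    return out


def parse_equation(equation: str, ctx: str = "equation") -> tuple[dict, dict]:
    if "<=>" not in equation:
        raise ParseError(f"{ctx}: equation lacks '<=>' separator: {equation!r}")
    lhs, rhs = equation.split("<=>", 1)
    return _parse_side(lhs, ctx), _parse_side(rhs, ctx)


def format_equation(reactants: dict[str, float], products: dict[str, float]) -> str:
    def side(d: dict[str, float]) -> str:
        return " + ".join(
            (f"{v:g} {k}" if v != 1 else k) for k, v in sorted(d.items())
        )

    return f"{side(reactants)} <=> {side(products)}"


def read_rule_database(path: str | Path) -> RuleDatabase:
    """Load the 5-column TSV rule database.

    Columns: ``rule_id``, ``template_id``, ``equation``, ``direction``
    (``forward`` or ``reverse``; reverse swaps the equation sides),
    ``rule_score``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"rule_id": str, "template_id": str})
    required = {"rule_id", "template_id", "equation", "direction", "rule_score"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"rule database missing columns: {sorted(missing)}")
    entries: dict[str, list[tuple[str, ReactionRecord, float]]] = {}
    for row in df.itertuples(index=False):
        lhs, rhs = parse_equation(
            row.equation, ctx=f"rule {row.rule_id}/template {row.template_id}"
        )
        if str(row.direction).strip() == "reverse":
            lhs, rhs = rhs, lhs
        template = ReactionRecord(
            id=str(row.template_id), reactants=lhs, products=rhs
        )
        entries.setdefault(str(row.rule_id), []).append(
            (str(row.template_id), template, float(row.rule_score))
        )
    return RuleDatabase(entries=entries)


def write_rule_database(db: RuleDatabase, path: str | Path) -> None:
    rows = []
    for rule_id in sorted(db.entries):
        for template_id, template, score in db.entries[rule_id]:
            rows.append(
                {
                    "rule_id": rule_id,
                    "template_id": template_id,
                    "equation": format_equation(template.reactants, template.products),
                    "direction": "forward",
                    "rule_score": score,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Completion and enumeration
# ---------------------------------------------------------------------------

def complete_transformation(
    t: Transformation, db: RuleDatabase
) -> list[ReactionRecord]:
    """One completed reaction per (rule, template) pair referenced by ``t``.

    Each completed reaction keeps the transformation's own lhs/rhs species and
    adds the template's cofactors — template participants whose identity key
    matches none of the transformation's species — at template stoichiometry.
    """
    completed: list[ReactionRecord] = []
    own_keys = {
        _key_of(sid, db) for sid in itertools.chain(t.lhs, t.rhs)
    }
    for rule_id in t.rule_ids:
        for template_id, template, score in db.templates(rule_id):
            reactants = dict(t.lhs)
            products = dict(t.rhs)
            for sid, coeff in template.reactants.items():
                if _key_of(sid, db) not in own_keys:
                    reactants[sid] = reactants.get(sid, 0.0) + coeff
            for sid, coeff in template.products.items():
                if _key_of(sid, db) not in own_keys:
                    products[sid] = products.get(sid, 0.0) + coeff
            completed.append(
                ReactionRecord(
                    id=f"{t.id}__{rule_id}__{template_id}",
                    reactants=reactants,
                    products=products,
                    rule_id=rule_id,
                    template_reaction_id=template_id,
                    rule_score=score,
                )
            )
    return completed


def _key_of(sid: str, db: RuleDatabase) -> str:
    sp = db.species.get(sid)
    return species_key(sp) if sp is not None else sid


def _species_for(sids: set[str], db: RuleDatabase) -> dict[str, Species]:
    return {
        sid: db.species.get(sid, Species(id=sid)) for sid in sids
    }


def enumerate_pathways(
    m: MasterPathway, db: RuleDatabase, keep_top: int | None = None
) -> list[PathwayRecord]:
    """Cartesian product of per-transformation completed alternatives.

    Duplicate pathways — identical reaction multisets under InChIKey-else-id
    species identity with stoichiometry compared at 1e-9 — are removed.
    Output order is deterministic: lexicographic by the tuple of reaction ids.
    When ``keep_top`` is given, only the N best pathways by descending mean
    rule score (ties broken by pathway id) are returned.
    """
    alternatives = [complete_transformation(t, db) for t in m.transformations]
    pathways: list[PathwayRecord] = []
    seen: set[frozenset] = set()
    for idx, combo in enumerate(itertools.product(*alternatives)):
        sids = set().union(*(r.species_ids for r in combo))
        species = _species_for(sids, db)
        sigs = [r.signature(species) for r in combo]
        multiset = frozenset((sig, sigs.count(sig)) for sig in sigs)
        if multiset in seen:
            continue
        seen.add(multiset)
        reactions = [
            ReactionRecord(
                id=r.id,
                reactants=dict(r.reactants),
                products=dict(r.products),
                rule_id=r.rule_id,
                template_reaction_id=r.template_reaction_id,
                rule_score=r.rule_score,
            )
            for r in combo
        ]
        pathways.append(
            PathwayRecord(
                id=f"{m.id}__{idx + 1:03d}",
                reactions=reactions,
                target_id=m.target_id,
                species=species,
            )
        )
    pathways.sort(key=lambda p: tuple(r.id for r in p.reactions))
    if keep_top is not None:
        pathways.sort(
            key=lambda p: (
                -_mean_rule_score(p),
                p.id,
            )
        )
        pathways = pathways[:keep_top]
        pathways.sort(key=lambda p: tuple(r.id for r in p.reactions))
    return pathways


def _mean_rule_score(p: PathwayRecord) -> float:
    scores = [r.rule_score for r in p.reactions if r.rule_score is not None]
    return sum(scores) / len(scores) if scores else 0.0
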