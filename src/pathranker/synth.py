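"""Synthetic fixtures: toy chassis models, rule databases, formation-energy
tables and labelled pathway collections, generated with no downloads.

Every generator is a pure function of its arguments and seed. Synthetic
species carry real (small alkane/alcohol) SMILES drawn from a fixed
32-molecule alphabet so fingerprints and InChIKeys are computed by real
chemistry code; species deliberately left structureless get a deterministic
hash-based key in the 14-10-1 InChIKey pattern so identity logic is still
exercised.

The labelled pathway generator emulates the structure of a pathway-scoring
training set — many candidate pathways per (target, chassis) pair with a
small positive fraction — by planting an effect on positives: more negative
pathway ΔG, higher target flux and higher enzyme-availability score, each
shifted by ``effect_size`` noise standard deviations. It does not emulate
real chemistry: fingerprint features carry no label signal, so classifier
performance on these sets reflects the planted pathway-level effect only.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .enumeration import MasterPathway, RuleDatabase, Transformation
from .errors import ArgumentError
from .records import ChassisModel, PathwayRecord, ReactionRecord, Species

#: Fixed 32-molecule alphabet of small alkane/alcohol SMILES.
SMILES_ALPHABET = (
    "C", "CC", "CCC", "CCCC", "CCCCC", "CCCCCC", "CCCCCCC", "CCCCCCCC",
    "CO", "CCO", "CCCO", "CCCCO", "CCCCCO", "CCCCCCO", "CCCCCCCO", "CCCCCCCCO",
    "OCCO", "OCCCO", "OCCCCO", "OCCCCCO",
    "CC(C)C", "CC(C)CC", "CC(C)CCC", "CC(C)(C)C",
    "CC(C)O", "CC(O)CC", "CC(C)(C)O", "OCC(C)C",
    "CCC(C)C", "CC(C)C(C)C", "OCC(C)(C)C", "CCC(C)O",
)

DEFAULT_TAXON = 511145  # E. coli K-12 MG1655


def synthetic_inchikey(text: str) -> str:
    """Deterministic hash of ``text`` into the 14-10-1 InChIKey pattern."""
    digest = hashlib.sha256(text.encode()).hexdigest().upper()
    letters = "".join(chr(ord("A") + int(c, 16) % 26) for c in digest)
    return f"{letters[:14]}-{letters[14:24]}-N"


def _real_inchikey(smiles: str) -> str | None:
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    return Chem.MolToInchiKey(mol) if mol is not None else None


def _species(sid: str, smiles: str | None, name: str = "") -> Species:
    if smiles is not None:
        return Species(
            id=sid, name=name or sid, smiles=smiles, inchikey=_real_inchikey(smiles)
        )
    return Species(id=sid, name=name or sid, inchikey=synthetic_inchikey(sid))


@dataclass
class FixtureSpec:
    """Study conditions for a labelled pathway collection.

    ``positive_fraction`` defaults to the 754/7919 rate of the benchmark
    training set this generator emulates; ``effect_size`` is the planted
    separation between positives and negatives in noise standard deviations.
    """

    seed: int = 0
    n_pathways: int = 200
    n_reactions_range: tuple[int, int] = (2, 5)
    positive_fraction: float = 754 / 7919
    effect_size: float = 3.0
    cofactor_set: Sequence[str] = ("COF_NADH", "COF_NAD")

    def __post_init__(self) -> None:
        lo, hi = self.n_reactions_range
        if not 1 <= lo <= hi:
            raise ArgumentError(f"invalid n_reactions_range {self.n_reactions_range}")
        if not 0.0 < self.positive_fraction < 1.0:
            raise ArgumentError(
                f"positive_fraction {self.positive_fraction} not in (0,1)"
            )
        if self.effect_size < 0:
            raise ArgumentError(f"effect_size {self.effect_size} must be >= 0")


# ---------------------------------------------------------------------------
# Toy chassis
# ---------------------------------------------------------------------------

def make_toy_chassis(n_core: int = 4, seed: int = 0) -> ChassisModel:
    """A feasible linear chassis: uptake → core chain → biomass.

    ``n_core`` core metabolites give n_core+1 reactions (uptake, n_core-1
    conversions, biomass); the biomass optimum equals the uptake bound (10).
    Deterministic for fixed arguments.
    """
    if n_core < 2:
        raise ArgumentError("n_core must be >= 2")
    species = {
        f"core_{i}": _species(f"core_{i}", SMILES_ALPHABET[i % len(SMILES_ALPHABET)])
        for i in range(n_core)
    }
    reactions = [
        ReactionRecord(
            id="EX_core_0", reactants={}, products={"core_0": 1.0},
            lower_bound=0.0, upper_bound=10.0,
        )
    ]
    for i in range(n_core - 1):
        reactions.append(
            ReactionRecord(
                id=f"CONV_{i}",
                reactants={f"core_{i}": 1.0},
                products={f"core_{i + 1}": 1.0},
            )
        )
    reactions.append(
        ReactionRecord(
            id="BIOMASS", reactants={f"core_{n_core - 1}": 1.0}, products={}
        )
    )
    return ChassisModel(
        id=f"toy_chassis_{n_core}_{seed}",
        species=species,
        reactions=reactions,
        biomass_reaction_id="BIOMASS",
        taxon_id=DEFAULT_TAXON,
    )


# ---------------------------------------------------------------------------
# Labelled pathway collections
# ---------------------------------------------------------------------------

#: Noise standard deviations (the "separation unit" of effect_size).
DG_SIGMA = 20.0       # kJ/mol
FLUX_SIGMA = 0.5      # mmol/gDCW/h
AVAIL_SIGMA = 0.1


def make_pathway_set(
    spec: FixtureSpec, chassis: ChassisModel
) -> list[tuple[PathwayRecord, int]]:
    """Labelled synthetic pathways attached to the chassis.

    Each pathway consumes a chassis core metabolite, runs through synthetic
    intermediates (alphabet SMILES) with a cofactor pair on each step, and
    produces its own target. Positives receive the planted effect: pathway
    ΔG shifted down, target flux and availability shifted up, each by
    ``effect_size`` noise standard deviations. The realised positive count
    is ``round(n_pathways * positive_fraction)`` exactly.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pathways
    n_pos = int(round(n * spec.positive_fraction))
    labels = np.zeros(n, dtype=int)
    labels[:n_pos] = 1
    rng.shuffle(labels)

    entry = sorted(chassis.species)[0]
    # disjoint (consumed, produced) pairs: each cofactor stays on one side of
    # the whole pathway, so it is an FBA orphan, never a pseudo-intermediate
    cofs = list(spec.cofactor_set)
    if len(cofs) % 2:
        cofs.append(cofs[0] + "_ox")
    cof_pairs = [(cofs[i], cofs[i + 1]) for i in range(0, len(cofs), 2)]
    cof_species = {
        cid: _species(cid, SMILES_ALPHABET[(7 * k + 3) % len(SMILES_ALPHABET)])
        for k, cid in enumerate(cofs)
    }

    out: list[tuple[PathwayRecord, int]] = []
    lo, hi = spec.n_reactions_range
    for p_idx in range(n):
        label = int(labels[p_idx])
        eff = spec.effect_size if label else 0.0
        length = int(rng.integers(lo, hi + 1))

        chain = [entry] + [f"P{p_idx}_I{j}" for j in range(length - 1)] + [f"P{p_idx}_T"]
        species: dict[str, Species] = {entry: chassis.species[entry]}
        for sid in chain[1:]:
            species[sid] = _species(
                sid, SMILES_ALPHABET[int(rng.integers(len(SMILES_ALPHABET)))]
            )
        for sp in cof_species.values():
            species.setdefault(sp.id, sp)

        avail_mu = min(0.95, 0.5 + eff * AVAIL_SIGMA)
        reactions = []
        for j in range(length):
            red, ox = cof_pairs[j % len(cof_pairs)]
            score = float(np.clip(rng.normal(avail_mu, AVAIL_SIGMA), 0.01, 1.0))
            reactions.append(
                ReactionRecord(
                    id=f"P{p_idx}_R{j}",
                    reactants={chain[j]: 1.0, red: 1.0},
                    products={chain[j + 1]: 1.0, ox: 1.0},
                    rule_id=f"RR_P{p_idx}_{j}",
                    template_reaction_id=f"T_P{p_idx}_{j}",
                    rule_score=score,
                    dg_prime=float(rng.normal(-5.0, 10.0)),
                )
            )

        pathway = PathwayRecord(
            id=f"P{p_idx}",
            reactions=reactions,
            target_id=chain[-1],
            species=species,
        )
        pathway.properties["pathway_dg"] = float(
            rng.normal(-eff * DG_SIGMA, DG_SIGMA)
        )
        pathway.properties["target_flux"] = float(
            np.clip(rng.normal(1.0 + eff * FLUX_SIGMA, FLUX_SIGMA), 0.0, None)
        )
        pathway.properties["chassis_id"] = chassis.id
        out.append((pathway, label))
    return out


# ---------------------------------------------------------------------------
# Rule databases and master pathways
# ---------------------------------------------------------------------------

def make_rule_db(
    n_rules: int = 2,
    templates_per_rule: int | Sequence[int] = 2,
    seed: int = 0,
    shared_template: bool = False,
) -> tuple[RuleDatabase, MasterPathway]:
    """A rule database plus a matching master pathway with predictable counts.

    The master pathway is a chain A_0 → A_1 → ... → A_n of ``n_rules``
    transformations, transformation i referencing rule ``R{i}``. Rule i has
    its stated number of templates, each adding a distinct cofactor pair, so
    transformation i completes into exactly that many alternatives and the
    enumeration count is their product. With ``shared_template`` the first
    transformation references a second rule whose single template duplicates
    the first rule's first template (structurally identical completion), so
    enumeration collapses that planted duplicate.
    """
    if n_rules < 1:
        raise ArgumentError("n_rules must be >= 1")
    if isinstance(templates_per_rule, int):
        per_rule = [templates_per_rule] * n_rules
    else:
        per_rule = list(templates_per_rule)
        if len(per_rule) != n_rules:
            raise ArgumentError("templates_per_rule length must equal n_rules")

    rng = np.random.default_rng(seed)
    species: dict[str, Species] = {}
    for i in range(n_rules + 1):
        sid = f"A{i}"
        species[sid] = _species(
            sid, SMILES_ALPHABET[int(rng.integers(len(SMILES_ALPHABET)))]
        )

    entries: dict[str, list[tuple[str, ReactionRecord, float]]] = {}
    max_templates = max(per_rule)
    for k in range(max_templates):
        for suffix in ("red", "ox"):
            cid = f"COF{k}_{suffix}"
            species[cid] = _species(
                cid, SMILES_ALPHABET[int(rng.integers(len(SMILES_ALPHABET)))]
            )

    for i in range(n_rules):
        templates = []
        for k in range(per_rule[i]):
            tid = f"T{i}_{k}"
            template = ReactionRecord(
                id=tid,
                reactants={f"A{i}": 1.0, f"COF{k}_red": 1.0},
                products={f"A{i + 1}": 1.0, f"COF{k}_ox": 1.0},
            )
            score = round(float(rng.uniform(0.3, 0.95)), 3)
            templates.append((tid, template, score))
        entries[f"R{i}"] = templates

    transformations = [
        Transformation(
            id=f"TR{i}",
            lhs={f"A{i}": 1.0},
            rhs={f"A{i + 1}": 1.0},
            rule_ids=[f"R{i}"],
        )
        for i in range(n_rules)
    ]

    if shared_template:
        # second rule on the first transformation, duplicating R0's first template
        tid, template, score = entries["R0"][0]
        dup = ReactionRecord(
            id=f"{tid}_dup",
            reactants=dict(template.reactants),
            products=dict(template.products),
        )
        entries["R0b"] = [(f"{tid}_dup", dup, score)]
        transformations[0].rule_ids.append("R0b")

    db = RuleDatabase(entries=entries, species=species)
    master = MasterPathway(
        id=f"master_{seed}", transformations=transformations, target_id=f"A{n_rules}"
    )
    return db, master


# ---------------------------------------------------------------------------
# Formation-energy tables
# ---------------------------------------------------------------------------

def make_formation_table(
    species: Sequence[Species],
    seed: int = 0,
    missing_fraction: float = 0.0,
) -> pd.DataFrame:
    """Formation energies for the given species, keyed by species id, with
    InChIKey columns so the lookup cascade is exercisable. With
    ``missing_fraction`` > 0 a deterministic subset of rows is dropped."""
    rng = np.random.default_rng(seed)
    rows = []
    for sp in species:
        rows.append(
            {
                "provider_key": sp.id,
                "dg_kj_mol": round(float(rng.normal(-100.0, 50.0)), 3),
                "uncertainty": round(float(rng.uniform(0.5, 5.0)), 3),
                "inchikey": sp.inchikey or "",
                "inchi": sp.inchi or "",
                "smiles": sp.smiles or "",
            }
        )
    df = pd.DataFrame(rows)
    if missing_fraction > 0:
        keep = rng.random(len(df)) >= missing_fraction
        df = df[keep].reset_index(drop=True)
    return df
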