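"""Core data model: species, reactions, pathways and chassis models.

A heterologous pathway is an ordered list of reactions, substrate side first,
target-producing reaction last, together with the chemical species it touches
and named groups that mark pathway membership and bookkeeping sets (species
ignored during FBA, species substituted for thermodynamics). A chassis model
is the host organism's stoichiometric model with flux bounds and a designated
biomass reaction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import ValidationError

# 14-10-1 block pattern of an InChIKey, e.g. LFQSCWFLJHTTHZ-UHFFFAOYSA-N
INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")

#: Group names with defined semantics in the enriched SBML dialect.
GROUP_PATHWAY = "rp_pathway"
GROUP_FBA_IGNORED = "rp_fba_ignored_species"
GROUP_THERMO_SUBSTITUTED = "rp_thermo_substituted_species"
KNOWN_GROUPS = (GROUP_PATHWAY, GROUP_FBA_IGNORED, GROUP_THERMO_SUBSTITUTED)


@dataclass
class Species:
    """A chemical species, optionally annotated with structure identifiers.

    Parameters
    ----------
    id : str
        Identifier, unique within a pathway or model.
    name : str
        Free-text name.
    inchi, smiles, inchikey : str or None
        Structure identifiers. ``inchikey`` must match the 14-10-1 block
        pattern when present.
    cross_refs : list of str
        MIRIAM-style database-qualified identifiers (``db:id``).
    formation_dg : float or None
        Standard formation energy in kJ/mol, when known.
    """

    id: str
    name: str = ""
    inchi: str | None = None
    smiles: str | None = None
    inchikey: str | None = None
    cross_refs: list[str] = field(default_factory=list)
    formation_dg: float | None = None

    def __post_init__(self) -> None:
        if not (self.id or self.inchi or self.smiles or self.inchikey):
            raise ValidationError("species needs at least one identifier")
        if self.inchikey is not None and not INCHIKEY_RE.match(self.inchikey):
            raise ValidationError(
                f"species {self.id!r}: InChIKey {self.inchikey!r} does not "
                "match the 14-10-1 block pattern"
            )

    @property
    def inchikey_block1(self) -> str | None:
        """First (connectivity) block of the InChIKey, or None."""
        return self.inchikey.split("-")[0] if self.inchikey else None


def species_key(s: Species) -> str:
    """Identity key used for deduplication: InChIKey when present, else id."""
    return s.inchikey if s.inchikey else s.id


@dataclass
class ReactionRecord:
    """A stoichiometric reaction, optionally annotated with rule provenance.

    ``reactants`` and ``products`` map species ids to positive stoichiometric
    coefficients. A species listed on both sides with equal stoichiometry is
    net-zero and is removed from both on construction; unequal occurrences are
    reduced to the net side.
    """

    id: str
    reactants: dict[str, float] = field(default_factory=dict)
    products: dict[str, float] = field(default_factory=dict)
    ec_numbers: list[str] = field(default_factory=list)
    rule_id: str | None = None
    template_reaction_id: str | None = None
    rule_score: float | None = None
    dg_prime: float | None = None
    dg_uncertainty: float | None = None
    lower_bound: float | None = None
    upper_bound: float | None = None

    def __post_init__(self) -> None:
        self._cancel_net_zero()
        if self.rule_score is not None and not 0.0 <= self.rule_score <= 1.0:
            raise ValidationError(
                f"reaction {self.id!r}: rule_score {self.rule_score} not in [0,1]"
            )
        if (
            self.lower_bound is not None
            and self.upper_bound is not None
            and self.lower_bound > self.upper_bound
        ):
            raise ValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        for side_name, side in (("reactants", self.reactants), ("products", self.products)):
            for sid, coeff in side.items():
                if coeff <= 0:
                    raise ValidationError(
                        f"reaction {self.id!r}: non-positive {side_name} "
                        f"stoichiometry for {sid!r}"
                    )

    def _cancel_net_zero(self, tol: float = 1e-9) -> None:
        for sid in sorted(set(self.reactants) & set(self.products)):
            net = self.products[sid] - self.reactants[sid]
            if abs(net) <= tol:
                del self.reactants[sid]
                del self.products[sid]
            elif net > 0:
                del self.reactants[sid]
                self.products[sid] = net
            else:
                del self.products[sid]
                self.reactants[sid] = -net

    def validate(self, allow_boundary: bool = False) -> None:
        """Check side non-emptiness; boundary (exchange) reactions may have one
        empty side in a chassis context."""
        if not allow_boundary and (not self.reactants or not self.products):
            raise ValidationError(
                f"reaction {self.id!r}: reactants and products must be non-empty"
            )
        if not self.reactants and not self.products:
            raise ValidationError(f"reaction {self.id!r}: empty reaction")

    @property
    def species_ids(self) -> set[str]:
        return set(self.reactants) | set(self.products)

    def net_stoichiometry(self) -> dict[str, float]:
        """Signed stoichiometry map: products positive, reactants negative."""
        net: dict[str, float] = {}
        for sid, coeff in self.reactants.items():
            net[sid] = net.get(sid, 0.0) - coeff
        for sid, coeff in self.products.items():
            net[sid] = net.get(sid, 0.0) + coeff
        return net

    def signature(self, species: Mapping[str, Species], tol: float = 1e-9) -> tuple:
        """Structure-based identity of the reaction: sorted signed stoichiometry
        keyed by InChIKey-else-id, coefficients rounded to ``tol``."""
        items = []
        for sid, coeff in self.net_stoichiometry().items():
            sp = species.get(sid)
            key = species_key(sp) if sp is not None else sid
            items.append((key, round(coeff / tol) * tol))
        return tuple(sorted(items))


@dataclass
class PathwayRecord:
    """An ordered heterologous pathway with species, groups and properties.

    ``groups`` maps group names to member id lists; the three named groups of
    the enriched SBML dialect are supported out of the box. ``properties``
    holds computed pathway-level quantities (``pathway_dg``, ``target_flux``,
    ``direct_score``, ``global_score``, ...).
    """

    id: str
    reactions: list[ReactionRecord]
    target_id: str
    species: dict[str, Species] = field(default_factory=dict)
    groups: dict[str, list[str]] = field(default_factory=dict)
    properties: dict[str, float | str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.groups.setdefault(GROUP_PATHWAY, [r.id for r in self.reactions])

    def validate(self) -> None:
        errors: list[str] = []
        if not any(self.target_id in r.products for r in self.reactions):
            errors.append(f"target {self.target_id!r} is produced by no reaction")
        known_ids = set(self.species) | {r.id for r in self.reactions}
        for r in self.reactions:
            try:
                r.validate()
            except ValidationError as e:
                errors.append(str(e))
            for sid in r.species_ids:
                if sid not in self.species:
                    errors.append(f"reaction {r.id!r} references unknown species {sid!r}")
        for gname, members in self.groups.items():
            for m in members:
                if m not in known_ids:
                    errors.append(f"group {gname!r} references unknown id {m!r}")
        if errors:
            raise ValidationError("; ".join(errors))

    def group(self, name: str) -> list[str]:
        return self.groups.setdefault(name, [])

    def reaction(self, rid: str) -> ReactionRecord:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)


@dataclass
class ChassisModel:
    """Host stoichiometric model: species, bounded reactions, biomass, taxon.

    Flux bounds are in mmol·gDCW⁻¹·h⁻¹ by convention. Boundary reactions
    (one empty side) model uptake and secretion.
    """

    id: str
    species: dict[str, Species]
    reactions: list[ReactionRecord]
    biomass_reaction_id: str
    taxon_id: int = 0
    ignored_species: list[str] = field(default_factory=list)

    DEFAULT_BOUND = 1000.0

    def __post_init__(self) -> None:
        if self.biomass_reaction_id not in {r.id for r in self.reactions}:
            raise ValidationError(
                f"biomass reaction {self.biomass_reaction_id!r} not in model"
            )
        for r in self.reactions:
            r.validate(allow_boundary=True)
            if r.lower_bound is None:
                r.lower_bound = 0.0
            if r.upper_bound is None:
                r.upper_bound = self.DEFAULT_BOUND

    def reaction(self, rid: str) -> ReactionRecord:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def copy(self) -> "ChassisModel":
        import copy as _copy

        return _copy.deepcopy(self)

    def to_cobra(self):
        """Build a COBRApy model (objective = biomass) from this record."""
        import cobra

        model = cobra.Model(self.id)
        mets = {
            sid: cobra.Metabolite(sid, name=sp.name or sid, compartment="c")
            for sid, sp in self.species.items()
        }
        rxns = []
        for r in self.reactions:
            rx = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
            rxns.append(rx)
        model.add_reactions(rxns)
        for r, rx in zip(self.reactions, rxns):
            rx.add_metabolites(
                {mets[sid]: coeff for sid, coeff in r.net_stoichiometry().items()}
            )
        model.objective = self.biomass_reaction_id
        return model


def merge_species(target: dict[str, Species], extra: Iterable[Species]) -> None:
    """Add species into ``target`` keeping existing entries on id collision."""
    for sp in extra:
        target.setdefault(sp.id, sp)
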