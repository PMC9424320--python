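"""Reader/writer for the enriched SBML dialect carrying pathway annotations.

Standard SBML Level 3 has no slot for structure identifiers (InChI, SMILES,
InChIKey), reaction-rule provenance (rule id, template reaction id, rule
score) or computed pathway properties. Following the SBML custom-annotation
mechanism, those live in a dedicated XML namespace inside ``<annotation>``
elements, so any standards-compliant reader simply ignores them. Pathway
membership and the two bookkeeping species sets are encoded with the SBML
``groups`` package under the names ``rp_pathway``, ``rp_fba_ignored_species``
and ``rp_thermo_substituted_species``.

The emitted dialect is SBML Level 3 Version 1 + groups; the reader accepts
Version 1 and 2. The annotation schema (one namespace, one element per field)
is defined by this package, not by any external wire format.
"""

from __future__ import annotations

import math
from pathlib import Path
from xml.sax.saxutils import escape, quoteattr

import libsbml

from .errors import ConfigurationError, ParseError, StructuralError, ValidationError
from .records import (
    GROUP_PATHWAY,
    KNOWN_GROUPS,
    ChassisModel,
    PathwayRecord,
    ReactionRecord,
    Species,
)

#: Namespace for custom annotations; configurable via the ``annotation_namespace``
#: config key on the CLI, fixed here as the default.
ANNOTATION_NS = "https://pathranker.dev/ns/annotation/v1"
ANNOTATION_PREFIX = "prk"

_SPECIES_FIELDS = ("inchi", "smiles", "inchikey")
_REACTION_STR_FIELDS = ("rule_id", "template_id", "rule_score", "dg_prime", "dg_uncertainty")


def _fmt(x: float) -> str:
    """Decimal string with up to 6 significant digits (round-trip stable)."""
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return f"{x:.6g}"


def _annotation_xml(elements: list[str]) -> str:
    p = ANNOTATION_PREFIX
    body = "".join(f"<{p}:{e}/>" if e.endswith("/") else e for e in elements)
    return f'<{p}:pathranker xmlns:{p}={quoteattr(ANNOTATION_NS)}>{body}</{p}:pathranker>'


def _elem(_tag: str, **attrs: str) -> str:
    p = ANNOTATION_PREFIX
    a = "".join(f" {k}={quoteattr(str(v))}" for k, v in attrs.items() if v is not None)
    return f"<{p}:{_tag}{a}/>"


def _set_annotation(sbase, elements: list[str]) -> None:
    if elements:
        ok = sbase.setAnnotation(_annotation_xml(elements))
        if ok != libsbml.LIBSBML_OPERATION_SUCCESS:
            raise ValidationError(f"failed to set annotation on {sbase.getId()!r}")


def _read_annotation(sbase) -> dict[str, dict[str, str]]:
    """Return {element_name: {attr: value}} for our namespace; repeated
    elements collect into 'name#i' keys after the first."""
    out: dict[str, dict[str, str]] = {}
    node = sbase.getAnnotation()
    if node is None:
        return out
    for i in range(node.getNumChildren()):
        child = node.getChild(i)
        if child.getURI() != ANNOTATION_NS:
            continue
        for j in range(child.getNumChildren()):
            el = child.getChild(j)
            attrs = {
                el.getAttributes().getName(k): el.getAttributes().getValue(k)
                for k in range(el.getAttributes().getLength())
            }
            name = el.getName()
            key = name
            n = 1
            while key in out:
                key = f"{name}#{n}"
                n += 1
            out[key] = attrs
    return out


def _multi(ann: dict[str, dict[str, str]], name: str) -> list[dict[str, str]]:
    vals = []
    if name in ann:
        vals.append(ann[name])
    n = 1
    while f"{name}#{n}" in ann:
        vals.append(ann[f"{name}#{n}"])
        n += 1
    return vals


def _check_sid(sid: str) -> str:
    if not libsbml.SyntaxChecker.isValidSBMLSId(sid):
        raise ValidationError(f"{sid!r} is not a valid SBML identifier")
    return sid


# ---------------------------------------------------------------------------
# Pathway writer
# ---------------------------------------------------------------------------

def write_pathway(p: PathwayRecord) -> bytes:
    """Serialise a pathway to enriched SBML L3V1 (groups package enabled).

    Raises
    ------
    ValidationError
        If the record violates its invariants (offending ids are listed).
    """
    p.validate()
    ns = libsbml.SBMLNamespaces(3, 1)
    ns.addPackageNamespace("groups", 1)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("groups", False)

    model = doc.createModel()
    model.setId(_check_sid(p.id))
    model.setName(p.id)

    model_elems = [_elem("target", id=p.target_id)]
    for key in sorted(p.properties):
        model_elems.append(_elem("property", name=key, value=str(p.properties[key])))
    _set_annotation(model, model_elems)

    comp = model.createCompartment()
    comp.setId("c")
    comp.setConstant(True)
    comp.setSize(1.0)

    for sid in sorted(p.species):
        sp = p.species[sid]
        s = model.createSpecies()
        s.setId(_check_sid(sp.id))
        s.setName(sp.name or sp.id)
        s.setCompartment("c")
        s.setConstant(False)
        s.setHasOnlySubstanceUnits(False)
        s.setBoundaryCondition(False)
        elems = []
        for fld in _SPECIES_FIELDS:
            val = getattr(sp, fld)
            if val is not None:
                elems.append(_elem(fld, value=val))
        if sp.formation_dg is not None:
            elems.append(_elem("formation_dg", value=_fmt(sp.formation_dg)))
        for xref in sp.cross_refs:
            elems.append(_elem("xref", value=xref))
        _set_annotation(s, elems)

    for r in p.reactions:
        rx = model.createReaction()
        rx.setId(_check_sid(r.id))
        rx.setReversible(False)
        rx.setFast(False)
        for sid in sorted(r.reactants):
            sr = rx.createReactant()
            sr.setSpecies(sid)
            sr.setStoichiometry(float(_fmt(r.reactants[sid])))
            sr.setConstant(True)
        for sid in sorted(r.products):
            sr = rx.createProduct()
            sr.setSpecies(sid)
            sr.setStoichiometry(float(_fmt(r.products[sid])))
            sr.setConstant(True)
        elems = []
        if r.rule_id is not None:
            elems.append(_elem("rule_id", value=r.rule_id))
        if r.template_reaction_id is not None:
            elems.append(_elem("template_id", value=r.template_reaction_id))
        if r.rule_score is not None:
            elems.append(_elem("rule_score", value=_fmt(r.rule_score)))
        if r.dg_prime is not None:
            elems.append(_elem("dg_prime", value=_fmt(r.dg_prime)))
        if r.dg_uncertainty is not None:
            elems.append(_elem("dg_uncertainty", value=_fmt(r.dg_uncertainty)))
        for ec in r.ec_numbers:
            elems.append(_elem("ec", value=ec))
        _set_annotation(rx, elems)

    gplug = model.getPlugin("groups")
    for gname in KNOWN_GROUPS:
        members = p.groups.get(gname, [])
        if not members:
            continue
        g = gplug.createGroup()
        g.setId(gname)
        g.setKind("collection")
        for m in members:
            mem = g.createMember()
            mem.setIdRef(m)
    # any extra user groups, in sorted order for determinism
    for gname in sorted(set(p.groups) - set(KNOWN_GROUPS)):
        members = p.groups[gname]
        if not members:
            continue
        g = gplug.createGroup()
        g.setId(_check_sid(gname))
        g.setKind("collection")
        for m in members:
            mem = g.createMember()
            mem.setIdRef(m)

    return libsbml.writeSBMLToString(doc).encode()


# ---------------------------------------------------------------------------
# Pathway reader
# ---------------------------------------------------------------------------

def _parse_document(document: bytes | str) -> libsbml.SBMLDocument:
    text = document.decode() if isinstance(document, bytes) else document
    doc = libsbml.readSBMLFromString(text)
    n_fatal = sum(
        1
        for i in range(doc.getNumErrors())
        if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
    )
    if n_fatal or doc.getModel() is None:
        msgs = "; ".join(
            doc.getError(i).getMessage().strip()
            for i in range(doc.getNumErrors())
            if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        )
        raise ParseError(f"malformed SBML document: {msgs or 'no model element'}")
    return doc


def _float_or_none(attrs: dict[str, str] | None) -> float | None:
    if attrs is None or "value" not in attrs:
        return None
    return float(attrs["value"])


def read_pathway(document: bytes | str) -> PathwayRecord:
    """Parse an enriched SBML document into a :class:`PathwayRecord`.

    The reactions of the returned record are exactly the members of the
    ``rp_pathway`` group, in group order (substrate side first by convention).

    Raises
    ------
    ParseError
        If the XML is malformed or not SBML.
    StructuralError
        If the ``rp_pathway`` group is absent.
    """
    doc = _parse_document(document)
    model = doc.getModel()

    species: dict[str, Species] = {}
    for i in range(model.getNumSpecies()):
        s = model.getSpecies(i)
        ann = _read_annotation(s)
        species[s.getId()] = Species(
            id=s.getId(),
            name=s.getName() or "",
            inchi=(ann.get("inchi") or {}).get("value"),
            smiles=(ann.get("smiles") or {}).get("value"),
            inchikey=(ann.get("inchikey") or {}).get("value"),
            cross_refs=[a["value"] for a in _multi(ann, "xref")],
            formation_dg=_float_or_none(ann.get("formation_dg")),
        )

    reactions_by_id: dict[str, ReactionRecord] = {}
    for i in range(model.getNumReactions()):
        rx = model.getReaction(i)
        ann = _read_annotation(rx)
        score = ann.get("rule_score")
        reactions_by_id[rx.getId()] = ReactionRecord(
            id=rx.getId(),
            reactants={
                rx.getReactant(j).getSpecies(): rx.getReactant(j).getStoichiometry()
                for j in range(rx.getNumReactants())
            },
            products={
                rx.getProduct(j).getSpecies(): rx.getProduct(j).getStoichiometry()
                for j in range(rx.getNumProducts())
            },
            ec_numbers=[a["value"] for a in _multi(ann, "ec")],
            rule_id=(ann.get("rule_id") or {}).get("value"),
            template_reaction_id=(ann.get("template_id") or {}).get("value"),
            rule_score=_float_or_none(score),
            dg_prime=_float_or_none(ann.get("dg_prime")),
            dg_uncertainty=_float_or_none(ann.get("dg_uncertainty")),
        )

    groups: dict[str, list[str]] = {}
    gplug = model.getPlugin("groups")
    if gplug is not None:
        for i in range(gplug.getNumGroups()):
            g = gplug.getGroup(i)
            groups[g.getId()] = [
                g.getMember(j).getIdRef() for j in range(g.getNumMembers())
            ]
    if GROUP_PATHWAY not in groups:
        raise StructuralError(
            f"document {model.getId()!r} has no group named {GROUP_PATHWAY!r}"
        )

    mann = _read_annotation(model)
    target = (mann.get("target") or {}).get("id")
    properties: dict[str, float | str] = {}
    for attrs in _multi(mann, "property"):
        val = attrs.get("value", "")
        try:
            properties[attrs["name"]] = float(val)
        except ValueError:
            properties[attrs["name"]] = val

    pathway_rids = groups[GROUP_PATHWAY]
    missing = [rid for rid in pathway_rids if rid not in reactions_by_id]
    if missing:
        raise StructuralError(
            f"group {GROUP_PATHWAY!r} references unknown reactions: {missing}"
        )
    reactions = [reactions_by_id[rid] for rid in pathway_rids]

    if target is None:
        # fall back: the last pathway reaction's sole new product
        target = sorted(reactions[-1].products)[0] if reactions else ""

    return PathwayRecord(
        id=model.getId(),
        reactions=reactions,
        target_id=target,
        species=species,
        groups=groups,
        properties=properties,
    )


# ---------------------------------------------------------------------------
# Chassis reader
# ---------------------------------------------------------------------------

def read_chassis(
    document: bytes | str | Path,
    biomass_hint: str | None = None,
    taxon_id: int | None = None,
) -> ChassisModel:
    """Import a genome-scale model (SBML L3 + flux bounds) as a ChassisModel.

    ``document`` may be raw SBML bytes/text or a filesystem path. The biomass
    reaction is taken from ``biomass_hint`` when given, else from the model's
    declared objective.

    Raises
    ------
    ConfigurationError
        If no biomass reaction can be resolved.
    ValidationError
        If any reaction has lower bound > upper bound.
    """
    import cobra.io

    try:
        if isinstance(document, Path) or (
            isinstance(document, str) and not document.lstrip().startswith("<")
        ):
            cmodel = cobra.io.read_sbml_model(str(document))
        else:
            text = document.decode() if isinstance(document, bytes) else document
            cmodel = cobra.io.sbml._sbml_to_model(_parse_document(text))
    except ValueError as exc:  # e.g. lower bound above upper bound
        raise ValidationError(str(exc)) from exc

    species = {}
    for met in cmodel.metabolites:
        ann = met.annotation or {}

        def _first(key):
            v = ann.get(key)
            if isinstance(v, list):
                return v[0] if v else None
            return v

        species[met.id] = Species(
            id=met.id,
            name=met.name or "",
            inchi=_first("inchi"),
            smiles=_first("smiles"),
            inchikey=_first("inchikey"),
        )

    reactions = []
    for rx in cmodel.reactions:
        reactants: dict[str, float] = {}
        products: dict[str, float] = {}
        for met, coeff in rx.metabolites.items():
            if coeff < 0:
                reactants[met.id] = -coeff
            else:
                products[met.id] = coeff
        reactions.append(
            ReactionRecord(
                id=rx.id,
                reactants=reactants,
                products=products,
                lower_bound=rx.lower_bound,
                upper_bound=rx.upper_bound,
            )
        )

    if biomass_hint is not None:
        biomass = biomass_hint
        if biomass not in {r.id for r in reactions}:
            raise ConfigurationError(f"biomass hint {biomass!r} not in model")
    else:
        objective_rxns = [
            rx.id
            for rx in cmodel.reactions
            if rx.objective_coefficient not in (0, 0.0)
        ]
        if not objective_rxns:
            raise ConfigurationError(
                "no biomass reaction: model declares no objective and no hint given"
            )
        biomass = objective_rxns[0]

    if taxon_id is None:
        ann = cmodel.annotation or {}
        tax = ann.get("taxonomy")
        if isinstance(tax, list):
            tax = tax[0] if tax else None
        try:
            taxon_id = int(tax) if tax is not None else 0
        except (TypeError, ValueError):
            taxon_id = 0

    return ChassisModel(
        id=cmodel.id or "chassis",
        species=species,
        reactions=reactions,
        biomass_reaction_id=biomass,
        taxon_id=taxon_id,
    )


def write_chassis(model: ChassisModel) -> bytes:
    """Serialise a chassis model to SBML L3 with flux bounds (via COBRApy)."""
    import tempfile

    import cobra.io

    cmodel = model.to_cobra()
    with tempfile.NamedTemporaryFile(suffix=".xml", delete=False) as fh:
        path = fh.name
    try:
        cobra.io.write_sbml_model(cmodel, path)
        data = Path(path).read_bytes()
    finally:
        Path(path).unlink(missing_ok=True)
    return data
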