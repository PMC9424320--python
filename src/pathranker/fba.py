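"""Fraction-of-reaction flux balance analysis.

Ranks a heterologous pathway by the maximal flux it can push into its target
while the host still grows: biomass flux is first maximised unconstrained,
then pinned (both bounds) to a stated fraction of that optimum, and the
target sink is maximised under that burden. All modified bounds are restored
afterwards, so the call leaves the model bit-for-bit unchanged.

Orphan species — pathway species absent from the chassis that are only ever
consumed, or only ever produced, by the pathway — cannot be balanced by any
chassis flux; they are excluded from mass balance and recorded in the group
``rp_fba_ignored_species``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ArgumentError, MergeError, SolverError
from .records import (
    GROUP_FBA_IGNORED,
    ChassisModel,
    PathwayRecord,
    ReactionRecord,
)

#: Conventional sink reaction bounds: irreversible export, [0, 1000].
SINK_BOUNDS = (0.0, 1000.0)
DEFAULT_FRACTION = 0.75


@dataclass
class FbaResult:
    """Outcome of a fraction-of-reaction FBA run."""

    biomass_optimum: float
    fraction: float
    target_flux: float
    ignored_species: list[str] = field(default_factory=list)


def sink_id(target_id: str) -> str:
    return f"SINK_{target_id}"


def _orphan_species(model: ChassisModel, p: PathwayRecord) -> list[str]:
    consumed: set[str] = set()
    produced: set[str] = set()
    for r in p.reactions:
        consumed.update(r.reactants)
        produced.update(r.products)
    orphans = []
    for sid in sorted(consumed ^ produced):  # one side only across the pathway
        if sid in model.species:
            continue
        if sid == p.target_id:
            continue  # the target gets a sink instead
        orphans.append(sid)
    return orphans


def merge_pathway(model: ChassisModel, p: PathwayRecord) -> ChassisModel:
    """Return a copy of the chassis with the pathway and a target sink added.

    Orphan species are left out of the added reactions' mass balance and
    listed in the returned model's ``ignored_species``. A reaction id already
    present in the chassis is accepted only if its definition is identical.

    Raises
    ------
    MergeError
        On an id collision with a differing definition.
    """
    merged = model.copy()
    ignored = _orphan_species(model, p)
    ignored_set = set(ignored)
    merged.ignored_species = ignored

    existing = {r.id: r for r in merged.reactions}
    for r in p.reactions:
        reactants = {s: c for s, c in r.reactants.items() if s not in ignored_set}
        products = {s: c for s, c in r.products.items() if s not in ignored_set}
        new = ReactionRecord(
            id=r.id,
            reactants=reactants,
            products=products,
            lower_bound=0.0,
            upper_bound=ChassisModel.DEFAULT_BOUND,
        )
        if r.id in existing:
            old = existing[r.id]
            if (
                old.reactants != new.reactants
                or old.products != new.products
            ):
                raise MergeError(
                    f"reaction id {r.id!r} exists in chassis with a different definition"
                )
            continue  # identical: merged once
        merged.reactions.append(new)
        existing[r.id] = new

    for sid, sp in p.species.items():
        if sid not in ignored_set:
            merged.species.setdefault(sid, sp)

    sid_rxn = sink_id(p.target_id)
    if sid_rxn not in existing:
        sink = ReactionRecord(
            id=sid_rxn,
            reactants={p.target_id: 1.0},
            products={},
            lower_bound=SINK_BOUNDS[0],
            upper_bound=SINK_BOUNDS[1],
        )
        merged.reactions.append(sink)
    return merged


def fraction_of_reaction_fba(
    model: ChassisModel,
    p: PathwayRecord,
    fraction: float = DEFAULT_FRACTION,
) -> FbaResult:
    """Maximise target production with biomass pinned to ``fraction`` of its
    unconstrained optimum.

    The result is written into ``p.properties`` (``target_flux``,
    ``biomass_optimum``, ``fba_fraction``) and the orphan list into the
    pathway group ``rp_fba_ignored_species``.

    Raises
    ------
    ArgumentError
        If ``fraction`` is outside (0, 1].
    SolverError
        If the merged model is infeasible.
    """
    if not 0.0 < fraction <= 1.0:
        raise ArgumentError(f"fraction must be in (0, 1], got {fraction}")

    merged = merge_pathway(model, p)
    cmodel = merged.to_cobra()

    original_bounds = {rx.id: rx.bounds for rx in cmodel.reactions}

    biomass = cmodel.reactions.get_by_id(merged.biomass_reaction_id)
    sink = cmodel.reactions.get_by_id(sink_id(p.target_id))
    try:
        cmodel.objective = biomass.id
        biomass_opt = cmodel.slim_optimize(error_value=None)
        if biomass_opt is None:
            raise SolverError("biomass optimisation infeasible")
        biomass.bounds = (fraction * biomass_opt, fraction * biomass_opt)
        cmodel.objective = sink.id
        target_flux = cmodel.slim_optimize(error_value=None)
        if target_flux is None:
            raise SolverError("target optimisation infeasible at pinned biomass")
    finally:
        for rx in cmodel.reactions:
            rx.bounds = original_bounds[rx.id]

    p.properties["biomass_optimum"] = float(biomass_opt)
    p.properties["fba_fraction"] = float(fraction)
    p.properties["target_flux"] = float(target_flux)
    p.groups[GROUP_FBA_IGNORED] = list(merged.ignored_species)

    return FbaResult(
        biomass_optimum=float(biomass_opt),
        fraction=fraction,
        target_flux=float(target_flux),
        ignored_species=list(merged.ignored_species),
    )
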