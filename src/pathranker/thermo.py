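"""Pathway thermodynamics via the global pseudo-reaction.

A pathway's Gibbs free energy is the energy of the net reaction linking
chassis substrates to the target. Building that net reaction means finding
one stoichiometric multiplier per pathway reaction such that every pathway
intermediate cancels exactly:

    minimise  c^T x   subject to  A x = 0,  x >= 1

where A is the intermediates-by-reactions matrix (products positive,
reactants negative) and c places 1 on every target-producing reaction.
Minimisation picks the componentwise-smallest feasible multipliers; the
feasible set is closed under uniform up-scaling, so maximising the same
objective would be unbounded.

Species are resolved against a pluggable formation-energy provider with a
first-hit cascade: species id, InChIKey, InChI, SMILES, then the first
compound listed under the InChIKey's first (connectivity) block, then a
user-supplied substitution. Substituted species are recorded in the pathway
group ``rp_thermo_substituted_species``. A reaction with any unresolved,
unsubstituted species has no thermodynamic value.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Protocol

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .errors import ParseError, ThermodynamicsError
from .records import (
    GROUP_THERMO_SUBSTITUTED,
    PathwayRecord,
    ReactionRecord,
    Species,
)

CANCEL_TOL = 1e-9


@dataclass(frozen=True)
class CompoundRef:
    """A resolved provider compound and the cascade rung that matched it."""

    provider_key: str
    matched_by: str  # id | inchikey | inchi | smiles | inchikey_block1 | substitution


@dataclass(frozen=True)
class DgEstimate:
    """A Gibbs free energy value (kJ/mol) with optional uncertainty."""

    value: float
    uncertainty: float | None = None


class FormationEnergyProvider(Protocol):
    """Minimal provider interface for formation energies."""

    def resolve(self, kind: str, value: str) -> str | None:
        """Return the provider key matching ``value`` of ``kind`` (one of
        id/inchikey/inchi/smiles), or None."""
        ...

    def resolve_block1(self, block: str) -> list[str]:
        """Provider keys whose compound InChIKey starts with ``block``."""
        ...

    def dg_of(self, provider_key: str) -> tuple[float, float | None]:
        """Formation energy (kJ/mol) and optional uncertainty for a key."""
        ...


class TableFormationProvider:
    """TSV-backed provider: columns ``provider_key``, ``dg_kj_mol``,
    ``uncertainty`` (optional), plus optional ``inchikey``/``inchi``/``smiles``
    columns used for structure matching."""

    def __init__(self, table: pd.DataFrame):
        if "provider_key" not in table.columns or "dg_kj_mol" not in table.columns:
            raise ParseError(
                "formation table needs 'provider_key' and 'dg_kj_mol' columns"
            )
        self._table = table.set_index("provider_key", drop=False)
        self._by: dict[str, dict[str, str]] = {"id": {}, "inchikey": {}, "inchi": {}, "smiles": {}}
        for key, row in self._table.iterrows():
            self._by["id"].setdefault(str(key), str(key))
            for kind in ("inchikey", "inchi", "smiles"):
                val = row.get(kind)
                if isinstance(val, str) and val:
                    self._by[kind].setdefault(val, str(key))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TableFormationProvider":
        return cls(pd.read_csv(path, sep="\t", dtype={"provider_key": str}))

    def resolve(self, kind: str, value: str) -> str | None:
        return self._by.get(kind, {}).get(value)

    def resolve_block1(self, block: str) -> list[str]:
        keys = []
        for ik, key in self._by["inchikey"].items():
            if ik.split("-")[0] == block:
                keys.append(key)
        return sorted(keys)

    def dg_of(self, provider_key: str) -> tuple[float, float | None]:
        row = self._table.loc[provider_key]
        unc = row.get("uncertainty")
        return float(row["dg_kj_mol"]), (None if pd.isna(unc) else float(unc))


def lookup_compound(
    s: Species,
    provider: FormationEnergyProvider,
    substitutions: Mapping[str, str] | None = None,
) -> CompoundRef | None:
    """Resolve a species through the first-hit cascade; None when all fail."""
    for kind, value in (
        ("id", s.id),
        ("inchikey", s.inchikey),
        ("inchi", s.inchi),
        ("smiles", s.smiles),
    ):
        if value is None:
            continue
        key = provider.resolve(kind, value)
        if key is not None:
            return CompoundRef(provider_key=key, matched_by=kind)
    if s.inchikey_block1:
        candidates = provider.resolve_block1(s.inchikey_block1)
        if candidates:
            return CompoundRef(provider_key=candidates[0], matched_by="inchikey_block1")
    if substitutions and s.id in substitutions:
        return CompoundRef(provider_key=substitutions[s.id], matched_by="substitution")
    return None


# ---------------------------------------------------------------------------
# Pseudo-reaction LP
# ---------------------------------------------------------------------------

def pathway_intermediates(
    p: PathwayRecord, chassis_species: set[str] | None = None
) -> list[str]:
    """Species produced by one pathway reaction and consumed by another,
    excluding the target and any chassis species."""
    produced: set[str] = set()
    consumed: set[str] = set()
    for r in p.reactions:
        produced.update(r.products)
        consumed.update(r.reactants)
    inter = produced & consumed
    inter.discard(p.target_id)
    if chassis_species:
        inter -= chassis_species
    return sorted(inter)


def build_pseudo_reaction(
    p: PathwayRecord, chassis_species: set[str] | None = None
) -> tuple[np.ndarray, ReactionRecord]:
    """Multipliers and net (global pseudo-) reaction for a pathway.

    Solves ``min c^T x  s.t.  A x = 0, x >= 1`` over the intermediates-by-
    reactions matrix A; the net reaction is the multiplier-weighted sum of
    the pathway reactions with species of net coefficient below 1e-9 dropped.

    Raises
    ------
    ThermodynamicsError
        If the intermediates cannot all cancel (LP infeasible); the message
        lists the non-cancellable intermediates.
    """
    n = len(p.reactions)
    intermediates = pathway_intermediates(p, chassis_species)
    A = np.zeros((len(intermediates), n))
    for j, r in enumerate(p.reactions):
        net = r.net_stoichiometry()
        for i, sid in enumerate(intermediates):
            A[i, j] = net.get(sid, 0.0)
    c = np.array(
        [1.0 if p.target_id in r.products else 0.0 for r in p.reactions]
    )

    if n == 1 or not intermediates:
        x = np.ones(n)
    else:
        res = linprog(
            c,
            A_eq=A,
            b_eq=np.zeros(len(intermediates)),
            bounds=[(1.0, None)] * n,
            method="highs",
        )
        if not res.success:
            bad = [
                intermediates[i]
                for i in range(len(intermediates))
                if np.any(A[i] != 0)
            ]
            raise ThermodynamicsError(
                "intermediate cancellation infeasible; non-cancellable "
                f"intermediates: {bad}"
            )
        x = res.x

    net_total: dict[str, float] = {}
    for mult, r in zip(x, p.reactions):
        for sid, coeff in r.net_stoichiometry().items():
            net_total[sid] = net_total.get(sid, 0.0) + mult * coeff

    reactants = {}
    products = {}
    for sid, coeff in net_total.items():
        if abs(coeff) < CANCEL_TOL:
            continue
        if coeff > 0:
            products[sid] = coeff
        else:
            reactants[sid] = -coeff
    net = ReactionRecord(
        id=f"{p.id}__pseudo", reactants=reactants, products=products
    )
    return x, net


# ---------------------------------------------------------------------------
# Free energies
# ---------------------------------------------------------------------------

def _resolve_all(
    r: ReactionRecord,
    species: Mapping[str, Species],
    provider: FormationEnergyProvider,
    substitutions: Mapping[str, str] | None,
) -> dict[str, CompoundRef] | None:
    refs: dict[str, CompoundRef] = {}
    for sid in sorted(r.species_ids):
        sp = species.get(sid, Species(id=sid))
        ref = lookup_compound(sp, provider, substitutions)
        if ref is None:
            return None
        refs[sid] = ref
    return refs


def reaction_dg(
    r: ReactionRecord,
    species: Mapping[str, Species],
    provider: FormationEnergyProvider,
    substitutions: Mapping[str, str] | None = None,
) -> DgEstimate | None:
    """ΔG′ of one reaction from formation energies, or None when any
    participating species is unresolved and unsubstituted."""
    refs = _resolve_all(r, species, provider, substitutions)
    if refs is None:
        return None
    value = 0.0
    var = 0.0
    any_unc = False
    for sid, coeff in r.net_stoichiometry().items():
        dg, unc = provider.dg_of(refs[sid].provider_key)
        value += coeff * dg
        if unc is not None:
            var += (coeff * unc) ** 2
            any_unc = True
    return DgEstimate(value=value, uncertainty=(var**0.5 if any_unc else None))


def pathway_dg(
    p: PathwayRecord,
    provider: FormationEnergyProvider,
    substitutions: Mapping[str, str] | None = None,
    chassis_species: set[str] | None = None,
) -> DgEstimate | None:
    """ΔG′ of the pathway's global pseudo-reaction; stored in
    ``p.properties['pathway_dg']`` when computable.

    Substituted species occurring in the pathway are recorded in the group
    ``rp_thermo_substituted_species``.
    """
    _, net = build_pseudo_reaction(p, chassis_species)
    if substitutions:
        recorded = p.group(GROUP_THERMO_SUBSTITUTED)
        for sid in sorted(p.species):
            if sid in substitutions:
                ref = lookup_compound(p.species[sid], provider, substitutions)
                if ref is not None and ref.matched_by == "substitution":
                    if sid not in recorded:
                        recorded.append(sid)
    est = reaction_dg(net, p.species, provider, substitutions)
    if est is not None:
        p.properties["pathway_dg"] = est.value
        if est.uncertainty is not None:
            p.properties["pathway_dg_uncertainty"] = est.uncertainty
    return est


def annotate_reaction_dgs(
    p: PathwayRecord,
    provider: FormationEnergyProvider,
    substitutions: Mapping[str, str] | None = None,
) -> None:
    """Fill ``dg_prime``/``dg_uncertainty`` on each resolvable reaction."""
    for r in p.reactions:
        est = reaction_dg(r, p.species, provider, substitutions)
        if est is not None:
            r.dg_prime = est.value
            r.dg_uncertainty = est.uncertainty
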