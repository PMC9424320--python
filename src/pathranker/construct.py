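"""Combinatorial BASIC-style construct design.

A construct places one promoter and an operon of CDS parts — each preceded
by an RBS-carrying UTR linker — into a backbone. Enumerating every choice of
promoter, per-slot linker assignment and (optionally) CDS order gives
|promoters| · |linkers|^G · G! designs for G CDS parts; the registry of the
lycopene study (2 promoters, 2 linkers, 3 CDS, permutation on) yields 96.

Designs serialise to an assembly-plan CSV with the dialect
``design_id,backbone,promoter,slot1_linker,slot1_cds,...`` (one row per
design, stable column order); the exact column names are defined by this
package.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import SerializationError, ValidationError


@dataclass
class PartsRegistry:
    """Available parts: promoters, RBS linkers, CDS list, one backbone."""

    promoters: list[str]
    rbs_linkers: list[str]
    cds: list[str]
    backbone: str

    def __post_init__(self) -> None:
        for name in ("promoters", "rbs_linkers", "cds"):
            vals = getattr(self, name)
            if not vals:
                raise ValidationError(f"registry field {name!r} is empty")
            if len(set(vals)) != len(vals):
                raise ValidationError(f"registry field {name!r} has duplicate ids")
        if not self.backbone:
            raise ValidationError("registry field 'backbone' is empty")

    @classmethod
    def from_csv(cls, path: str | Path) -> "PartsRegistry":
        """Read a registry CSV with columns ``part_id`` and ``role`` (one of
        promoter/rbs_linker/cds/backbone)."""
        df = pd.read_csv(path, dtype=str)
        if not {"part_id", "role"} <= set(df.columns):
            raise ValidationError("parts registry needs 'part_id' and 'role' columns")
        by_role: dict[str, list[str]] = {}
        for row in df.itertuples(index=False):
            by_role.setdefault(str(row.role), []).append(str(row.part_id))
        backbones = by_role.get("backbone", [])
        if len(backbones) != 1:
            raise ValidationError(
                f"registry must declare exactly one backbone, found {len(backbones)}"
            )
        return cls(
            promoters=by_role.get("promoter", []),
            rbs_linkers=by_role.get("rbs_linker", []),
            cds=by_role.get("cds", []),
            backbone=backbones[0],
        )


@dataclass
class ConstructDesign:
    """One construct: promoter + ordered (CDS, linker) slots on a backbone."""

    promoter: str
    slots: list[tuple[str, str]]  # (cds, rbs_linker) per slot
    backbone: str
    design_id: str = field(default="")

    def __post_init__(self) -> None:
        if not self.design_id:
            self.design_id = make_design_id(self.promoter, self.slots)


def make_design_id(promoter: str, slots: Sequence[tuple[str, str]]) -> str:
    """Deterministic readable id, unique under (promoter, slots)."""
    parts = [promoter] + [f"{cds}.{linker}" for cds, linker in slots]
    return "_".join(parts)


def enumerate_constructs(
    reg: PartsRegistry,
    permute: bool = True,
    exclude: Sequence[str] = (),
) -> list[ConstructDesign]:
    """All designs in deterministic lexicographic order.

    With ``permute`` the CDS order varies over all G! permutations, otherwise
    only the registry order is used. ``exclude`` drops designs by id (the
    full theoretical set is emitted by default).
    """
    excluded = set(exclude)
    orders = (
        sorted(itertools.permutations(sorted(reg.cds)))
        if permute
        else [tuple(reg.cds)]
    )
    designs = []
    for promoter in sorted(reg.promoters):
        for order in orders:
            for linkers in itertools.product(
                sorted(reg.rbs_linkers), repeat=len(order)
            ):
                slots = list(zip(order, linkers))
                design = ConstructDesign(
                    promoter=promoter, slots=slots, backbone=reg.backbone
                )
                if design.design_id in excluded:
                    continue
                designs.append(design)
    return designs


def write_assembly_plan(designs: Sequence[ConstructDesign]) -> str:
    """Serialise designs to the assembly-plan CSV dialect.

    Raises
    ------
    SerializationError
        On an empty design list or duplicate design ids.
    """
    if not designs:
        raise SerializationError("no designs to serialise")
    ids = [d.design_id for d in designs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise SerializationError(f"duplicate design ids: {dupes}")
    n_slots = {len(d.slots) for d in designs}
    if len(n_slots) != 1:
        raise SerializationError("designs have differing slot counts")
    g = n_slots.pop()

    columns = ["design_id", "backbone", "promoter"]
    for i in range(1, g + 1):
        columns += [f"slot{i}_linker", f"slot{i}_cds"]
    rows = []
    for d in designs:
        row: dict[str, str] = {
            "design_id": d.design_id,
            "backbone": d.backbone,
            "promoter": d.promoter,
        }
        for i, (cds, linker) in enumerate(d.slots, start=1):
            row[f"slot{i}_linker"] = linker
            row[f"slot{i}_cds"] = cds
        rows.append(row)
    df = pd.DataFrame(rows, columns=columns)
    buf = io.StringIO()
    df.to_csv(buf, index=False, lineterminator="\n")
    return buf.getvalue()


def read_assembly_plan(csv_text: str) -> list[ConstructDesign]:
    """Inverse of :func:`write_assembly_plan`."""
    df = pd.read_csv(io.StringIO(csv_text), dtype=str)
    slot_cols = sorted(
        (c for c in df.columns if c.startswith("slot") and c.endswith("_cds")),
        key=lambda c: int(c[4:-4]),
    )
    designs = []
    for row in df.itertuples(index=False):
        slots = []
        for c in slot_cols:
            i = c[4:-4]
            slots.append((getattr(row, f"slot{i}_cds"), getattr(row, f"slot{i}_linker")))
        designs.append(
            ConstructDesign(
                promoter=row.promoter,
                slots=slots,
                backbone=row.backbone,
                design_id=row.design_id,
            )
        )
    return designs


def lycopene_registry() -> PartsRegistry:
    """The registry of the lycopene study: promoters PJ23105/PJ23116, RBS
    linkers A03/A04, the crtE/crtB/crtI CDSs and the SEVA p15A backbone."""
    return PartsRegistry(
        promoters=["PJ23105", "PJ23116"],
        rbs_linkers=["A03", "A04"],
        cds=["crtE", "crtB", "crtI"],
        backbone="BASIC_SEVA_36_CmR-p15A.1",
    )
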