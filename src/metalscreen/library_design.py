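"""Combinatorial enumeration of triazole ligands and metal-complex assembly.

Ligands arise from an in-situ azide transfer on an amine followed by a
copper-catalyzed cycloaddition with an alkyne; on the composition level this
is exact bookkeeping: product = amine + alkyne + 2N - 2H. Two ligand classes
exist depending on which partner carries the pyridine:

* ``Tz-4-P``  — primary amine x 2-alkynylpyridine
* ``Tz-1-MP`` — 2-picolylamine x aryl alkyne

Assembled complexes are cations: metal fragment + ligand (+ optional axial
ligand), with a fixed class/scaffold compatibility matrix.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import DuplicateIdError, InvalidPairingError, PlateOverflowError
from .formula import ElementalFormula

ROLES = frozenset({"primary-amine", "2-alkynylpyridine", "2-picolylamine", "aryl-alkyne"})
LIGAND_CLASSES = ("Tz-4-P", "Tz-1-MP")

#: (amine role, alkyne role) -> ligand class
_PAIRING = {
    ("primary-amine", "2-alkynylpyridine"): "Tz-4-P",
    ("2-picolylamine", "aryl-alkyne"): "Tz-1-MP",
}

#: azide formation + cycloaddition composition delta relative to amine + alkyne
TRIAZOLE_DELTA: Mapping[str, int] = {"N": 2, "H": -2}


@dataclass(frozen=True)
class BuildingBlock:
    id: str
    role: str
    formula: ElementalFormula
    structure: str | None = None
    display_name: str = ""
    placeholder: bool = False

    def __post_init__(self):
        if self.role not in ROLES:
            raise InvalidPairingError(f"unknown role {self.role!r} for {self.id}")


@dataclass(frozen=True)
class LigandSpec:
    id: str
    ligand_class: str
    formula: ElementalFormula
    parent_ids: tuple[str, str]  # (amine id, alkyne id)


@dataclass(frozen=True)
class ScaffoldSpec:
    """Metal fragment retained in the assembled cation."""

    id: str
    fragment_formula: ElementalFormula
    fragment_charge: int
    compatible_classes: frozenset[str]
    axial_formula: ElementalFormula = field(default_factory=ElementalFormula)
    display_name: str = ""


@dataclass(frozen=True)
class ComplexSpec:
    id: str
    scaffold_id: str
    ligand_id: str
    ligand_class: str
    formula: ElementalFormula  # full cation composition
    charge: int


@dataclass(frozen=True)
class PlateMap:
    plate_id: str
    wells: Mapping[str, str]  # "A1".."H12" -> compound id


def couple_triazole(amine: BuildingBlock, alkyne: BuildingBlock) -> LigandSpec:
    """Couple one amine with one alkyne into a triazole ligand.

    The product composition is amine + alkyne + 2N - 2H; the ligand id is the
    concatenation of the parent ids (amine first).
    """
    cls = _PAIRING.get((amine.role, alkyne.role))
    if cls is None:
        raise InvalidPairingError(
            f"cannot couple {amine.id} ({amine.role}) with {alkyne.id} ({alkyne.role})"
        )
    formula = (amine.formula + alkyne.formula).apply_delta(TRIAZOLE_DELTA)
    return LigandSpec(
        id=f"{amine.id}{alkyne.id}",
        ligand_class=cls,
        formula=formula,
        parent_ids=(amine.id, alkyne.id),
    )


def _check_unique(blocks: Iterable[BuildingBlock], what: str) -> None:
    seen: set[str] = set()
    for b in blocks:
        if b.id in seen:
            raise DuplicateIdError(f"duplicate {what} id {b.id!r}")
        seen.add(b.id)


def enumerate_ligands(
    amines: Sequence[BuildingBlock], alkynes: Sequence[BuildingBlock]
) -> list[LigandSpec]:
    """Full Cartesian cross, amine-major ordering.

    Empty inputs yield an empty list; duplicate ids or heterogeneous roles
    within a list raise.
    """
    for blocks, what in ((amines, "amine"), (alkynes, "alkyne")):
        _check_unique(blocks, what)
        roles = {b.role for b in blocks}
        if len(roles) > 1:
            raise InvalidPairingError(f"mixed {what} roles in registry: {sorted(roles)}")
    return [couple_triazole(am, al) for am in amines for al in alkynes]


def assemble_complexes(
    ligands: Sequence[LigandSpec], scaffolds: Sequence[ScaffoldSpec]
) -> list[ComplexSpec]:
    """One complex per compatible (scaffold, ligand) pair, scaffold-major order.

    Incompatible pairs are skipped silently; the count therefore equals the
    sum over scaffolds of their compatible ligand counts.
    """
    out: list[ComplexSpec] = []
    for sc in scaffolds:
        for lig in ligands:
            if lig.ligand_class not in sc.compatible_classes:
                continue
            out.append(
                ComplexSpec(
                    id=f"{sc.id}({lig.id})",
                    scaffold_id=sc.id,
                    ligand_id=lig.id,
                    ligand_class=lig.ligand_class,
                    formula=sc.fragment_formula + lig.formula + sc.axial_formula,
                    charge=sc.fragment_charge,
                )
            )
    return out


ROW_LABELS = string.ascii_uppercase[:8]  # A..H


def well_name(index: int) -> str:
    """Row-major well coordinate for a 0-based index (0 -> A1, 12 -> B1)."""
    return f"{ROW_LABELS[index // 12]}{index % 12 + 1}"


def assign_plate(compound_ids: Sequence[str], plate_id: str = "plate1") -> PlateMap:
    """Row-major fill A1 -> A12 -> B1 ... of up to 96 compounds."""
    if len(compound_ids) > 96:
        raise PlateOverflowError(f"{len(compound_ids)} compounds exceed 96 wells")
    wells = {well_name(i): cid for i, cid in enumerate(compound_ids)}
    return PlateMap(plate_id=plate_id, wells=wells)
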