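"""Default building-block and scaffold registries, plus tabular I/O.

Only a subset of the building blocks used in the original campaign are
identifiable by name; the rest ship as documented placeholders
(``placeholder=True``) with chemically plausible formulas. Enumeration
counts and all downstream pipeline behaviour are registry-independent, so
users can swap in their own CSV registries at any time.
"""

from __future__ import annotations

import csv
import math
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from .formula import ElementalFormula
from .library_design import BuildingBlock, ScaffoldSpec

# id, role, formula (Hill), name, placeholder?
_AMINES = [
    ("M1", "C3H9N", "propylamine", True),
    ("M2", "C2H6N2O", "2-aminoacetamide (pendant amide)", False),
    ("M3", "C4H11N", "isobutylamine", True),
    ("M4", "C4H11N", "butylamine", True),
    ("M5", "C8H11N", "(S)-1-phenylethylamine", False),
    ("M6", "C6H13N", "cyclohexylamine", True),
    ("M7", "C5H7NO", "furfurylamine", True),
    ("M8", "C7H9N", "benzylamine", True),
    ("M9", "C8H11N", "2-phenylethylamine", True),
    ("M10", "C8H11N", "4-methylbenzylamine", True),
    ("M11", "C9H11NO2", "methyl 4-(aminomethyl)benzoate (phenyl ester)", False),
    ("M12", "C8H11NO", "4-methoxybenzylamine", True),
    ("M13", "C7H8FN", "4-fluorobenzylamine", True),
    ("M14", "C8H11NO", "3-methoxybenzylamine", True),
    ("M15", "C10H12N2O5S", "7-aminocephalosporanic acid", False),
    ("M16", "C16H19N3O4S", "ampicillin", False),
    ("M17", "C7H8ClN", "4-chlorobenzylamine", True),
    ("M18", "C6H8N2", "3-(aminomethyl)pyridine", True),
    ("M19", "C9H13NO2", "2,4-dimethoxybenzylamine", True),
    ("M20", "C5H11NO", "tetrahydrofurfurylamine", True),
    ("M21", "C3H7N", "allylamine", True),
    ("M22", "C7H8FN", "3-fluorobenzylamine", True),
    ("M23", "C13H13N", "4-phenylbenzylamine (biaryl)", False),
    ("M24", "C5H7NS", "2-thiophenemethylamine", True),
]

_PYRIDYL_ALKYNES = [
    ("Y1", "C7H5N", "2-ethynylpyridine", True),
    ("Y2", "C8H7N", "6-methyl-2-ethynylpyridine", False),
    ("Y3", "C8H7NO", "6-methoxy-2-ethynylpyridine", True),
    ("Y4", "C7H4BrN", "5-bromo-2-ethynylpyridine (para-bromo)", False),
]

_PICOLYLAMINES = [
    ("P1", "C6H8N2", "2-picolylamine", True),
    ("P2", "C7H10N2", "6-methyl-2-picolylamine", True),
    ("P3", "C6H7FN2", "5-fluoro-2-picolylamine", True),
    ("P4", "C6H7ClN2", "5-chloro-2-picolylamine", True),
    ("P5", "C6H7BrN2", "5-bromo-2-picolylamine", True),
    ("P6", "C8H12N2", "2-(2-aminopropan-2-yl)pyridine (gem-dimethyl)", False),
    ("P7", "C7H10N2", "4-methyl-2-picolylamine", True),
    ("P8", "C7H10N2O", "6-methoxy-2-picolylamine", True),
]

_ARYL_ALKYNES = [
    ("A1", "C8H6", "phenylacetylene", True),
    ("A2", "C9H8", "4-methylphenylacetylene", True),
    ("A3", "C8H5NO2", "1-ethynyl-4-nitrobenzene (p-nitro)", False),
    ("A4", "C8H5F", "1-ethynyl-4-fluorobenzene", True),
    ("A5", "C8H5Cl", "1-ethynyl-4-chlorobenzene", True),
    ("A6", "C8H5Br", "1-ethynyl-4-bromobenzene", True),
    ("A7", "C9H8O", "1-ethynyl-4-methoxybenzene", True),
    ("A8", "C9H8", "1-ethynyl-3-methylbenzene", True),
    ("A9", "C9H8O", "1-ethynyl-3-methoxybenzene", True),
    ("A10", "C8H5F", "1-ethynyl-2-fluorobenzene", True),
    ("A11", "C10H10", "1-ethynyl-3,5-dimethylbenzene", True),
    ("A12", "C12H14", "1-ethynyl-4-tert-butylbenzene", True),
]


def _blocks(rows, role: str) -> list[BuildingBlock]:
    return [
        BuildingBlock(
            id=i,
            role=role,
            formula=ElementalFormula.from_hill(f),
            display_name=name,
            placeholder=ph,
        )
        for i, f, name, ph in rows
    ]


def default_amines() -> list[BuildingBlock]:
    """24 primary amines (M1-M24) of the pyridine-triazole library."""
    return _blocks(_AMINES, "primary-amine")


def default_pyridyl_alkynes() -> list[BuildingBlock]:
    """4 2-alkynylpyridines (Y1-Y4)."""
    return _blocks(_PYRIDYL_ALKYNES, "2-alkynylpyridine")


def default_picolylamines() -> list[BuildingBlock]:
    """8 2-picolylamines (P1-P8)."""
    return _blocks(_PICOLYLAMINES, "2-picolylamine")


def default_aryl_alkynes() -> list[BuildingBlock]:
    """12 aryl alkynes (A1-A12)."""
    return _blocks(_ARYL_ALKYNES, "aryl-alkyne")


def default_scaffolds() -> list[ScaffoldSpec]:
    """The five metal scaffolds with their cation fragment compositions.

    Tz-4-P ligands coordinate to all five; Tz-1-MP only to IrCp* and RuCy.
    The fac-tricarbonyl scaffolds carry 1-methylbenzimidazole (C8H8N2) as the
    axial ligand.
    """
    both = frozenset({"Tz-4-P", "Tz-1-MP"})
    t4p = frozenset({"Tz-4-P"})
    bemeim = ElementalFormula.from_hill("C8H8N2")
    F = ElementalFormula.from_hill
    return [
        ScaffoldSpec("IrCN", F("C22H16IrN2"), 1, t4p, display_name="[Ir(ppy)2(L)]+"),
        ScaffoldSpec("IrCp*", F("C10H15ClIr"), 1, both, display_name="[Ir(Cp*)Cl(L)]+"),
        ScaffoldSpec("RuCy", F("C10H14ClRu"), 1, both, display_name="[Ru(p-cymene)Cl(L)]+"),
        ScaffoldSpec("Re(CO)3", F("C3O3Re"), 1, t4p, axial_formula=bemeim,
                     display_name="[Re(CO)3(L)(BeMeIm)]+"),
        ScaffoldSpec("Mn(CO)3", F("C3MnO3"), 1, t4p, axial_formula=bemeim,
                     display_name="[Mn(CO)3(L)(BeMeIm)]+"),
    ]


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------


def save_building_blocks(blocks: Sequence[BuildingBlock], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "role", "smiles", "formula", "name", "placeholder"])
        for b in blocks:
            w.writerow([b.id, b.role, b.structure or "", b.formula.to_hill(),
                        b.display_name, int(b.placeholder)])


def load_building_blocks(path: str | Path) -> list[BuildingBlock]:
    """Read a registry CSV (columns id, role, formula; smiles/name optional)."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                BuildingBlock(
                    id=row["id"].strip(),
                    role=row["role"].strip(),
                    formula=ElementalFormula.from_hill(row["formula"]),
                    structure=row.get("smiles") or None,
                    display_name=row.get("name", ""),
                    placeholder=bool(int(row.get("placeholder", 0) or 0)),
                )
            )
    return out


def load_scaffolds(path: str | Path) -> list[ScaffoldSpec]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                ScaffoldSpec(
                    id=row["id"].strip(),
                    fragment_formula=ElementalFormula.from_hill(row["fragment_formula"]),
                    fragment_charge=int(row["fragment_charge"]),
                    compatible_classes=frozenset(row["compatible_classes"].split(";")),
                    axial_formula=ElementalFormula.from_hill(row.get("axial_formula", "") or ""),
                    display_name=row.get("name", ""),
                )
            )
    return out


def save_scaffolds(scaffolds: Sequence[ScaffoldSpec], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "fragment_formula", "fragment_charge", "axial_formula",
                    "compatible_classes", "name"])
        for s in scaffolds:
            w.writerow([s.id, s.fragment_formula.to_hill(), s.fragment_charge,
                        s.axial_formula.to_hill(), ";".join(sorted(s.compatible_classes)),
                        s.display_name])


def load_lead_compounds() -> pd.DataFrame:
    """Shipped screening summary for the six re-synthesized lead complexes.

    Columns: compound_id, cc50_um, hc10_um (may be censored, parsed to +inf),
    mic_lo_um, mic_hi_um.
    """
    with resources.files("metalscreen.data").joinpath("lead_compounds.csv").open() as fh:
        df = pd.read_csv(fh, dtype={"hc10_um": str})
    df["hc10_um"] = [
        math.inf if str(v).strip().startswith(">") else float(v) for v in df["hc10_um"]
    ]
    return df
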