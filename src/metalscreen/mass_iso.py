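"""Monoisotopic masses, isotope-pattern convolution and expected ion species.

The isotope table ships with the package (``data/isotopes.tsv``) and carries
standard IUPAC abundances; several of the metals handled here (Ru, Re, Ir)
and Br/Cl are strongly polyisotopic, so target-ion matching needs full
envelope simulation rather than a single m/z.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Mapping, Sequence

from .errors import FormulaUnderflowError, InputError, UnknownElementError
from .formula import ElementalFormula

ELECTRON_MASS = 0.000548579909  # Da

#: formula delta turning [M]+ into the MeCN adduct dication [M - Cl + C2H3N]2+
MECN_ADDUCT_DELTA: Mapping[str, int] = {"Cl": -1, "C": 2, "H": 3, "N": 1}


@lru_cache(maxsize=1)
def isotope_table() -> dict[str, tuple[tuple[float, float], ...]]:
    """Load the shipped isotope table: element -> ((mass, abundance), ...)."""
    table: dict[str, list[tuple[float, float]]] = {}
    text = resources.files("metalscreen.data").joinpath("isotopes.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        el, mass, ab = line.split("\t")
        table.setdefault(el, []).append((float(mass), float(ab)))
    out: dict[str, tuple[tuple[float, float], ...]] = {}
    for el, isos in table.items():
        isos.sort()
        total = sum(a for _, a in isos)
        if abs(total - 1.0) > 1e-4:
            raise ValueError(f"abundances for {el} sum to {total}")
        out[el] = tuple(isos)
    return out


def _isotopes_of(el: str) -> tuple[tuple[float, float], ...]:
    try:
        return isotope_table()[el]
    except KeyError:
        raise UnknownElementError(f"element {el!r} not in isotope table") from None


def monoisotopic_mass(f: ElementalFormula | Mapping[str, int]) -> float:
    """Mass of the isotopologue built from each element's most abundant isotope."""
    total = 0.0
    for el, n in dict(f).items():
        isos = _isotopes_of(el)
        mass = max(isos, key=lambda p: p[1])[0]
        total += n * mass
    return total


def combine_formula(base: ElementalFormula, delta: Mapping[str, int]) -> ElementalFormula:
    """Element-wise signed sum; underflow raises :class:`FormulaUnderflowError`."""
    return base.apply_delta(delta)


# ---------------------------------------------------------------------------
# isotope-pattern convolution
# ---------------------------------------------------------------------------

Peaks = list[tuple[float, float]]  # (mass Da, probability)


def _merge(peaks: Peaks, width: float) -> Peaks:
    """Centroid-merge peaks closer than ``width`` (abundance-weighted)."""
    if not peaks:
        return []
    peaks = sorted(peaks)
    out: Peaks = []
    cm, cp = peaks[0]
    for m, p in peaks[1:]:
        if m - cm <= width:
            tot = cp + p
            cm = (cm * cp + m * p) / tot
            cp = tot
        else:
            out.append((cm, cp))
            cm, cp = m, p
    out.append((cm, cp))
    return out


def _convolve(a: Peaks, b: Peaks, width: float, floor: float) -> Peaks:
    prod = [(ma + mb, pa * pb) for ma, pa in a for mb, pb in b]
    merged = _merge(prod, width)
    if floor > 0.0 and merged:
        cut = floor * max(p for _, p in merged)
        merged = [(m, p) for m, p in merged if p >= cut]
    return merged


def _element_power(el: str, n: int, width: float, floor: float) -> Peaks:
    """Distribution of n atoms of one element, by binary exponentiation."""
    base: Peaks = list(_isotopes_of(el))
    result: Peaks = [(0.0, 1.0)]
    while n:
        if n & 1:
            result = _convolve(result, base, width, floor)
        n >>= 1
        if n:
            base = _convolve(base, base, width, floor)
    return result


@dataclass(frozen=True)
class IsotopePattern:
    """Centroided isotope envelope; base peak normalized to 100."""

    peaks: tuple[tuple[float, float], ...]  # (m/z, relative abundance)
    charge: int

    @property
    def base_peak_mz(self) -> float:
        return max(self.peaks, key=lambda p: p[1])[0]

    @property
    def mzs(self) -> tuple[float, ...]:
        return tuple(m for m, _ in self.peaks)


def isotope_pattern(
    f: ElementalFormula | Mapping[str, int],
    z: int = 1,
    prune: float = 1e-4,
    merge_width: float = 0.01,
) -> IsotopePattern:
    """Full isotope envelope of a cation of composition ``f`` at charge ``z``.

    Per-element isotopologue distributions are convolved iteratively; peaks
    closer than ``merge_width`` (in Da on the neutral-mass axis) are merged to
    their abundance-weighted centroid, peaks below ``prune`` x base peak are
    dropped and abundances rescaled to a base peak of exactly 100.
    m/z = (mass - z * electron mass) / z.
    """
    if z < 1:
        raise InputError("charge must be >= 1")
    # intermediate floor well below the final prune so pruning error stays
    # negligible; disabled entirely when prune == 0 (oracle-exact mode)
    floor = prune * 1e-3 if prune > 0 else 0.0
    dist: Peaks = [(0.0, 1.0)]
    for el, n in dict(f).items():
        if n:
            dist = _convolve(dist, _element_power(el, n, merge_width, floor), merge_width, floor)
    dist = _merge(dist, merge_width)
    pmax = max(p for _, p in dist)
    if prune > 0:
        dist = [(m, p) for m, p in dist if p >= prune * pmax]
    peaks = tuple(((m - z * ELECTRON_MASS) / z, 100.0 * p / pmax) for m, p in sorted(dist))
    return IsotopePattern(peaks=peaks, charge=z)


# ---------------------------------------------------------------------------
# expected ion species per complex
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IonSpecies:
    """A target ion derived from a complex cation by a signed formula delta."""

    base_complex_id: str
    label: str
    charge: int
    formula_delta: Mapping[str, int] = field(default_factory=dict)

    def formula(self, base: ElementalFormula) -> ElementalFormula:
        return base.apply_delta(self.formula_delta)


def expected_ions(c, adduct_scaffolds: Sequence[str] = ("IrCp*",)) -> list[IonSpecies]:
    """Target ion species for a complex.

    Default policy: every complex yields its parent cation [M]+; complexes on
    scaffolds in ``adduct_scaffolds`` additionally yield the MeCN-adduct
    dication [M - Cl + C2H3N]2+ observed alongside the parent ion.
    """
    species = [IonSpecies(base_complex_id=c.id, label="M+", charge=1)]
    if c.scaffold_id in adduct_scaffolds:
        species.append(
            IonSpecies(
                base_complex_id=c.id,
                label="M2+ (MeCN adduct)",
                charge=2,
                formula_delta=dict(MECN_ADDUCT_DELTA),
            )
        )
    return species


def mz_of(s: IonSpecies, base: ElementalFormula) -> float:
    """Monoisotopic m/z of an ion species applied to a base cation formula."""
    try:
        f = s.formula(base)
    except FormulaUnderflowError:
        raise
    return (monoisotopic_mass(f) - s.charge * ELECTRON_MASS) / s.charge
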