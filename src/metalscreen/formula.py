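"""Integer elemental-composition arithmetic and Hill-notation parsing.

An :class:`ElementalFormula` is an immutable multiset of element symbols.
All composition bookkeeping in the package (ligand coupling, complex
assembly, adduct deltas) is exact integer arithmetic on these objects.
"""

from __future__ import annotations

import re
from collections.abc import Mapping
from typing import Iterator

from .errors import FormulaError, FormulaUnderflowError

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ElementalFormula(Mapping):
    """Immutable map element symbol -> non-negative integer count.

    Supports ``+`` between formulas, ``*`` by a non-negative integer and
    :meth:`apply_delta` for signed adjustments (raising
    :class:`FormulaUnderflowError` when a count would go negative).
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None):
        clean: dict[str, int] = {}
        for el, n in (counts or {}).items():
            n = int(n)
            if n < 0:
                raise FormulaError(f"negative count for {el}: {n}")
            if n:
                clean[el] = n
        self._counts = dict(sorted(clean.items()))

    # -- Mapping protocol -------------------------------------------------
    def __getitem__(self, el: str) -> int:
        return self._counts.get(el, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, el: object) -> bool:
        return el in self._counts

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other: "ElementalFormula | Mapping[str, int]") -> "ElementalFormula":
        out = dict(self._counts)
        for el, n in dict(other).items():
            out[el] = out.get(el, 0) + int(n)
        return ElementalFormula(out)

    def __mul__(self, k: int) -> "ElementalFormula":
        if k < 0:
            raise FormulaError("cannot scale a formula by a negative integer")
        return ElementalFormula({el: n * k for el, n in self._counts.items()})

    __rmul__ = __mul__

    def apply_delta(self, delta: Mapping[str, int]) -> "ElementalFormula":
        """Apply a signed element-count delta; underflow raises."""
        out = dict(self._counts)
        for el, n in delta.items():
            new = out.get(el, 0) + int(n)
            if new < 0:
                raise FormulaUnderflowError(
                    f"delta drives {el} below zero ({out.get(el, 0)} {n:+d})"
                )
            out[el] = new
        return ElementalFormula(out)

    # -- comparison / hashing ---------------------------------------------
    def __eq__(self, other: object) -> bool:
        if isinstance(other, ElementalFormula):
            return self._counts == other._counts
        if isinstance(other, Mapping):
            return self._counts == {k: v for k, v in other.items() if v}
        return NotImplemented

    def __hash__(self) -> int:
        return hash(tuple(self._counts.items()))

    # -- serialization ----------------------------------------------------
    @classmethod
    def from_hill(cls, s: str) -> "ElementalFormula":
        """Parse Hill-notation strings such as ``"C14H12N4"`` or ``"H2O"``."""
        s = s.strip()
        if not s:
            return cls()
        pos = 0
        counts: dict[str, int] = {}
        for m in _TOKEN.finditer(s):
            if m.start() != pos:
                raise FormulaError(f"cannot parse formula {s!r} at position {pos}")
            pos = m.end()
            el, num = m.group(1), m.group(2)
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        if pos != len(s):
            raise FormulaError(f"cannot parse formula {s!r} at position {pos}")
        return cls(counts)

    def to_hill(self) -> str:
        """Hill notation: C first, then H, then remaining symbols sorted."""
        parts = []
        order = []
        if "C" in self._counts:
            order.append("C")
            if "H" in self._counts:
                order.append("H")
            order += sorted(el for el in self._counts if el not in ("C", "H"))
        else:
            order = sorted(self._counts)
        for el in order:
            n = self._counts[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"ElementalFormula({self.to_hill()!r})"
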