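"""Elemental formulas of (derivatized) GC-MS fragment ions.

Metabolites measured by GC-MS are chemically derivatized before injection
(methoximation of ketones, tert-butyldimethylsilylation of active hydrogens),
so the ion actually integrated carries C, H, Si and sometimes N atoms beyond
the metabolite backbone.  Natural heavy isotopes of *all* of these atoms
contribute to the measured mass-isotopomer envelope and must be modeled when
correcting raw distributions, which is why formulas here describe the full
fragment ion, not the bare metabolite.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping

__all__ = ["ChemicalFormula", "FormulaError", "KNOWN_ELEMENTS"]

#: Elements that can occur in MOX/TBDMS-derivatized metabolite fragments.
KNOWN_ELEMENTS = ("C", "H", "N", "O", "P", "S", "Si")

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed or chemically invalid formula strings."""


@dataclass(frozen=True)
class ChemicalFormula:
    """An element → atom-count map, e.g. ``C19H42NO4Si3``.

    Parameters
    ----------
    counts
        Mapping from element symbol to a positive atom count.  Zero counts
        are dropped; at least one element must remain.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned: dict[str, int] = {}
        for element, n in self.counts.items():
            if element not in KNOWN_ELEMENTS:
                raise FormulaError(f"unknown element symbol: {element!r}")
            if not isinstance(n, int) or n < 0:
                raise FormulaError(f"atom count for {element} must be a non-negative integer, got {n!r}")
            if n > 0:
                cleaned[element] = n
        if not cleaned:
            raise FormulaError("formula must contain at least one atom")
        object.__setattr__(self, "counts", cleaned)

    @classmethod
    def parse(cls, text: str) -> "ChemicalFormula":
        """Parse a plain formula string such as ``"C5H8NO4"``.

        An omitted count means one atom.  Unknown element symbols raise
        :class:`FormulaError` naming the offending symbol.
        """
        if not text or not text.strip():
            raise FormulaError("empty formula string")
        text = text.strip()
        counts: dict[str, int] = {}
        pos = 0
        for match in _TOKEN.finditer(text):
            if match.start() != pos:
                raise FormulaError(f"unparseable formula fragment at {text[pos:]!r}")
            symbol, digits = match.groups()
            if symbol not in KNOWN_ELEMENTS:
                raise FormulaError(f"unknown element symbol: {symbol!r}")
            counts[symbol] = counts.get(symbol, 0) + (int(digits) if digits else 1)
            pos = match.end()
        if pos != len(text):
            raise FormulaError(f"unparseable formula fragment at {text[pos:]!r}")
        return cls(counts)

    def __str__(self) -> str:
        # Hill order: C first, H second, remaining elements alphabetically.
        parts = []
        for element in self._hill_order():
            n = self.counts[element]
            parts.append(element if n == 1 else f"{element}{n}")
        return "".join(parts)

    def _hill_order(self) -> Iterator[str]:
        for element in ("C", "H"):
            if element in self.counts:
                yield element
        yield from sorted(e for e in self.counts if e not in ("C", "H"))

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self.counts)

    @property
    def carbons(self) -> int:
        return self.counts.get("C", 0)

    def without_carbons(self, n: int) -> "ChemicalFormula":
        """Return the formula with ``n`` carbon atoms removed.

        Used when building correction matrices: carbons known to carry
        tracer ¹³C are taken out of the natural-abundance pool.
        """
        if n < 0 or n > self.carbons:
            raise FormulaError(f"cannot remove {n} carbons from {self}")
        counts = dict(self.counts)
        if n == self.carbons:
            counts.pop("C", None)
        else:
            counts["C"] = self.carbons - n
        if not counts:
            raise FormulaError(f"removing {n} carbons from {self} leaves no atoms")
        return ChemicalFormula(counts)
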