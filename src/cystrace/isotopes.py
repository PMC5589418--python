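"""Natural isotope abundances per element.

The default table holds IUPAC-style representative terrestrial abundances
expressed as (integer mass shift, fraction) lists per element, which is the
only information the mass-isotopomer arithmetic needs (nominal-mass GC-MS
cannot resolve isotope fine structure, so e.g. ¹⁵N and ¹³C at the same
nominal shift are simply summed by convolution).  The table is versioned and
user-replaceable from a YAML file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = ["IsotopeAbundanceTable", "DEFAULT_ISOTOPES", "IsotopeTableError"]


class IsotopeTableError(ValueError):
    """Raised for invalid or incomplete abundance tables."""


@dataclass(frozen=True)
class IsotopeAbundanceTable:
    """Per-element natural isotope abundance vectors.

    ``abundances[element][k]`` is the fractional abundance of the isotope
    ``k`` integer mass units above the lightest isotope.  Each element's
    vector must sum to 1 within 1e-9.
    """

    abundances: Mapping[str, tuple[float, ...]]
    name: str = "custom"
    version: str = ""

    def __post_init__(self) -> None:
        frozen: dict[str, tuple[float, ...]] = {}
        for element, vec in self.abundances.items():
            arr = tuple(float(x) for x in vec)
            if not arr:
                raise IsotopeTableError(f"element {element}: empty abundance vector")
            if any(x < 0 for x in arr):
                raise IsotopeTableError(f"element {element}: negative abundance")
            if abs(sum(arr) - 1.0) > 1e-9:
                raise IsotopeTableError(
                    f"element {element}: abundances sum to {sum(arr)!r}, expected 1 within 1e-9"
                )
            frozen[element] = arr
        object.__setattr__(self, "abundances", frozen)

    def atom_distribution(self, element: str) -> np.ndarray:
        """Mass-shift distribution of a single atom of ``element``."""
        try:
            return np.asarray(self.abundances[element], dtype=float)
        except KeyError:
            raise IsotopeTableError(
                f"element {element!r} missing from abundance table {self.name!r}"
            ) from None

    def __contains__(self, element: str) -> bool:
        return element in self.abundances

    @classmethod
    def from_yaml(cls, path: str | Path) -> "IsotopeAbundanceTable":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict) or "elements" not in data:
            raise IsotopeTableError(f"{path}: expected a mapping with an 'elements' key")
        return cls(
            abundances={e: tuple(v) for e, v in data["elements"].items()},
            name=str(data.get("name", Path(path).stem)),
            version=str(data.get("version", "")),
        )

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "name": self.name,
            "version": self.version,
            "elements": {e: list(v) for e, v in self.abundances.items()},
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


#: Representative terrestrial abundances (IUPAC CIAAW rounded values).
DEFAULT_ISOTOPES = IsotopeAbundanceTable(
    abundances={
        "C": (0.9893, 0.0107),
        "H": (0.999885, 0.000115),
        "N": (0.99636, 0.00364),
        "O": (0.99757, 0.00038, 0.00205),
        "P": (1.0,),
        "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
        "Si": (0.92223, 0.04685, 0.03092),
    },
    name="iupac-ciaaw",
    version="2013-rounded",
)

#: A table with all abundance at mass shift 0 — useful for tests and as the
#: identity limit of the correction machinery.
def monoisotopic_table(elements: Sequence[str] = ("C", "H", "N", "O", "P", "S", "Si")) -> IsotopeAbundanceTable:
    return IsotopeAbundanceTable(
        abundances={e: (1.0,) for e in elements}, name="monoisotopic"
    )
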