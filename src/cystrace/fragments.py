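"""Default fragment library for MOX/TBDMS-derivatized metabolites.

Formulas are the [M−57]⁺ ions (loss of the tert-butyl radical from a TBDMS
group) of the methoxime/tert-butyldimethylsilyl derivatives routinely used
for ¹³C tracing of amino acids and TCA-cycle intermediates.  Derivatization
chemistry: each TBDMS group replaces an active hydrogen (net +C6H14Si), each
methoximation converts a ketone C=O to C=N−OCH3 (net +CH3N), and [M−57]⁺
loses C4H9.  The resulting compositions match the fragment m/z values in
the standard GC-MS derivatization literature, but the library is explicitly
a configurable default: override it with your own TSV when your method
integrates different ions.

Diagnostic mass shifts follow the oxidative route of [U-¹³C₅]glutamine
carbon: m+5 for the five-carbon pool upstream of decarboxylation
(glutamine, glutamate, α-ketoglutarate) and m+4 for species measured after
one oxidative decarboxylation (fumarate, malate, aspartate, citrate).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .formulas import ChemicalFormula
from .mid import FragmentDefinition

__all__ = [
    "DEFAULT_FRAGMENTS",
    "DIAGNOSTIC_SHIFTS",
    "fragment_library",
    "read_fragment_table",
    "write_fragment_table",
]

_DEFAULT_ROWS = [
    # metabolite, fragment name, formula, backbone carbons
    ("glutamine", "M-57", "C19H43N2O3Si3", 5),
    ("glutamate", "M-57", "C19H42NO4Si3", 5),
    ("alpha-ketoglutarate", "M-57", "C14H28NO5Si2", 5),  # 1 MOX + 2 TBDMS
    ("fumarate", "M-57", "C12H23O4Si2", 4),
    ("malate", "M-57", "C18H39O5Si3", 4),
    ("aspartate", "M-57", "C18H40NO4Si3", 4),
    ("citrate", "M-57", "C26H55O7Si4", 6),
]

DEFAULT_FRAGMENTS: tuple[FragmentDefinition, ...] = tuple(
    FragmentDefinition(
        metabolite=met,
        fragment_name=name,
        fragment_formula=ChemicalFormula.parse(formula),
        n_backbone_carbons=nc,
    )
    for met, name, formula, nc in _DEFAULT_ROWS
)

#: Diagnostic shift per metabolite (m+5 pre-decarboxylation, m+4 after).
DIAGNOSTIC_SHIFTS: dict[str, int] = {
    "glutamine": 5,
    "glutamate": 5,
    "alpha-ketoglutarate": 5,
    "fumarate": 4,
    "malate": 4,
    "aspartate": 4,
    "citrate": 4,
}

_COLUMNS = ["metabolite", "fragment_name", "formula", "n_backbone_carbons", "n_measured_shifts"]


def fragment_library(fragments=DEFAULT_FRAGMENTS) -> dict[str, FragmentDefinition]:
    """Index fragments by metabolite name (one fragment per metabolite)."""
    return {f.metabolite: f for f in fragments}


def read_fragment_table(path: str | Path) -> tuple[FragmentDefinition, ...]:
    """Read a fragment-definition TSV.

    Columns: metabolite, fragment_name, formula, n_backbone_carbons,
    n_measured_shifts (the last may be empty to take the default window of
    n_backbone_carbons + 2).
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: fragment table missing column(s) {missing}")
    out = []
    for row in df.itertuples(index=False):
        window = getattr(row, "n_measured_shifts", None)
        window = -1 if window is None or pd.isna(window) else int(window)
        out.append(
            FragmentDefinition(
                metabolite=str(row.metabolite),
                fragment_name=str(row.fragment_name),
                fragment_formula=ChemicalFormula.parse(str(row.formula)),
                n_backbone_carbons=int(row.n_backbone_carbons),
                n_measured_shifts=window,
            )
        )
    return tuple(out)


def write_fragment_table(fragments, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "metabolite": f.metabolite,
                "fragment_name": f.fragment_name,
                "formula": str(f.fragment_formula),
                "n_backbone_carbons": f.n_backbone_carbons,
                "n_measured_shifts": f.n_measured_shifts,
            }
            for f in fragments
        ],
        columns=_COLUMNS,
    ).to_csv(path, sep="\t", index=False)
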