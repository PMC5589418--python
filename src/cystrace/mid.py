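"""Mass-isotopomer distributions and theoretical isotopologue envelopes.

A mass-isotopomer distribution (MID) is the fractional abundance vector of a
metabolite fragment's isotopologues m+0, m+1, …, m+n, where m+i is i integer
mass units above the monoisotopic species.  With a [U-¹³C₅]glutamine tracer,
m+5 marks intact glutamine carbon skeletons in five-carbon metabolites and
m+4 marks four-carbon species produced after one oxidative decarboxylation.

Two conventions used throughout the package:

* m+0 is index 0 everywhere (0-based mass-shift indexing);
* theoretical envelopes truncated to a measurement window are *not*
  renormalized, so truncation behaves monotonically; fully corrected MIDs
  are normalized and validated strictly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .formulas import ChemicalFormula
from .isotopes import IsotopeAbundanceTable

__all__ = [
    "MassIsotopomerDistribution",
    "FragmentDefinition",
    "convolve",
    "natural_envelope",
    "natural_distribution",
    "MIDError",
]

_SUM_TOL = 1e-6


class MIDError(ValueError):
    """Raised for invalid mass-isotopomer vectors."""


@dataclass(frozen=True)
class MassIsotopomerDistribution:
    """Fractional abundances over m+0 … m+n for one fragment in one sample.

    Fractions are non-negative and sum to at most 1 (sub-normalized vectors
    arise from truncating a theoretical envelope to a finite measurement
    window).  Use :meth:`require_normalized` where a true probability vector
    is required, e.g. for natural-abundance-corrected output.
    """

    metabolite: str
    fragment: str
    fractions: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.fractions, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise MIDError("fractions must be a non-empty 1-D vector")
        if np.any(arr < -1e-12):
            raise MIDError(f"negative fraction in MID for {self.metabolite}/{self.fragment}")
        arr = np.clip(arr, 0.0, None)
        total = float(arr.sum())
        if total > 1.0 + _SUM_TOL:
            raise MIDError(
                f"MID for {self.metabolite}/{self.fragment} sums to {total}, exceeding 1"
            )
        if total <= 0.0:
            raise MIDError(f"MID for {self.metabolite}/{self.fragment} is all zero")
        arr.setflags(write=False)
        object.__setattr__(self, "fractions", arr)

    @property
    def n_shifts(self) -> int:
        return len(self.fractions) - 1

    def fraction_at(self, shift: int) -> float:
        if not 0 <= shift <= self.n_shifts:
            raise MIDError(
                f"mass shift {shift} out of range 0..{self.n_shifts} "
                f"for {self.metabolite}/{self.fragment}"
            )
        return float(self.fractions[shift])

    @property
    def is_normalized(self) -> bool:
        return abs(float(self.fractions.sum()) - 1.0) <= _SUM_TOL

    def require_normalized(self) -> "MassIsotopomerDistribution":
        if not self.is_normalized:
            raise MIDError(
                f"MID for {self.metabolite}/{self.fragment} sums to "
                f"{float(self.fractions.sum())}, expected 1 within {_SUM_TOL}"
            )
        return self


@dataclass(frozen=True)
class FragmentDefinition:
    """A measured GC-MS ion fragment of a metabolite.

    ``n_backbone_carbons`` counts the carbons that can carry tracer ¹³C
    (the metabolite backbone); the remaining carbons of ``fragment_formula``
    come from derivatization and only contribute natural abundance.
    ``n_measured_shifts`` is the width of the recorded m+i window.
    """

    metabolite: str
    fragment_name: str
    fragment_formula: ChemicalFormula
    n_backbone_carbons: int
    n_measured_shifts: int = -1  # -1 → default to n_backbone_carbons + 2

    def __post_init__(self) -> None:
        if self.n_measured_shifts < 0:
            object.__setattr__(self, "n_measured_shifts", self.n_backbone_carbons + 2)
        if self.n_backbone_carbons < 0:
            raise MIDError("n_backbone_carbons must be non-negative")
        if self.n_backbone_carbons > self.fragment_formula.carbons:
            raise MIDError(
                f"{self.metabolite}/{self.fragment_name}: {self.n_backbone_carbons} backbone "
                f"carbons exceed the {self.fragment_formula.carbons} carbons of "
                f"{self.fragment_formula}"
            )
        if self.n_measured_shifts < self.n_backbone_carbons:
            raise MIDError(
                f"{self.metabolite}/{self.fragment_name}: measured window "
                f"({self.n_measured_shifts}) narrower than backbone carbon count "
                f"({self.n_backbone_carbons})"
            )


def convolve(a: Sequence[float] | np.ndarray, b: Sequence[float] | np.ndarray) -> np.ndarray:
    """Discrete convolution of two non-negative mass-shift vectors.

    The result has length ``len(a) + len(b) - 1`` and its sum equals the
    product of the input sums, so convolving probability vectors yields a
    probability vector.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise MIDError("cannot convolve an empty vector")
    if np.any(a < 0) or np.any(b < 0):
        raise MIDError("convolution inputs must be non-negative")
    return np.convolve(a, b)


def natural_envelope(
    formula: ChemicalFormula,
    table: IsotopeAbundanceTable,
    n_shifts: int | None = None,
) -> np.ndarray:
    """Theoretical natural-abundance isotopologue envelope of a formula.

    Convolves the single-atom mass-shift distribution of every atom in
    ``formula``; equivalent to brute-force enumeration over all atom-isotope
    assignments.  With ``n_shifts`` the envelope is truncated (not
    renormalized) to m+0 … m+n_shifts; ``None`` keeps the full envelope.
    """
    envelope = np.ones(1)
    for element in formula:
        atom = table.atom_distribution(element)
        n = formula[element]
        # binary exponentiation of the per-atom distribution
        power = atom
        while n:
            if n & 1:
                envelope = np.convolve(envelope, power)
            n >>= 1
            if n:
                power = np.convolve(power, power)
        if n_shifts is not None and len(envelope) > n_shifts + 1:
            envelope = envelope[: n_shifts + 1]  # higher terms can't re-enter the window
    if n_shifts is not None:
        out = np.zeros(n_shifts + 1)
        out[: len(envelope)] = envelope[: n_shifts + 1]
        return out
    return envelope


def natural_distribution(
    formula: ChemicalFormula,
    table: IsotopeAbundanceTable,
    n_shifts: int,
    metabolite: str = "",
    fragment: str = "",
) -> MassIsotopomerDistribution:
    """Natural envelope of ``formula`` as a (possibly truncated) MID."""
    if n_shifts < 0:
        raise MIDError("n_shifts must be non-negative")
    return MassIsotopomerDistribution(
        metabolite=metabolite or str(formula),
        fragment=fragment or "natural",
        fractions=natural_envelope(formula, table, n_shifts),
    )
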