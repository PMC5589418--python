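"""Natural-abundance correction of raw mass-isotopomer measurements.

Raw GC-MS intensities over m+0 … m+n mix tracer-derived labeling with the
natural heavy-isotope envelope of the whole derivatized fragment (¹³C in
derivatization carbons, ²⁹/³⁰Si from TBDMS groups, ¹⁸O, …).  The forward
model is linear: if x_j is the true fraction of molecules with j tracer
carbons, the expected measurement is M·x where column j of M is the natural
envelope of the fragment with j carbons withdrawn from the natural pool
(those carbons are tracer ¹³C), shifted up j mass units and truncated to the
measured window.  Correction inverts this model by non-negative least
squares and renormalizes, which reproduces the noiseless inverse exactly and
degrades gracefully when noise would otherwise produce negative fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import nnls

from .isotopes import IsotopeAbundanceTable, DEFAULT_ISOTOPES
from .mid import (
    FragmentDefinition,
    MassIsotopomerDistribution,
    MIDError,
    convolve,
    natural_envelope,
)

__all__ = ["CorrectionMatrix", "build_correction_matrix", "correct_mid", "CorrectionError"]


class CorrectionError(ValueError):
    """Raised when a raw vector cannot be corrected."""


@dataclass(frozen=True)
class CorrectionMatrix:
    """Forward model mapping tracer-isotopomer fractions to measured shifts.

    Shape is (n_measured_shifts + 1) × (n_backbone_carbons + 1).  Each column
    sums to at most 1; the deficit is envelope mass falling outside the
    measured window.
    """

    matrix: np.ndarray
    fragment: FragmentDefinition

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        expected = (self.fragment.n_measured_shifts + 1, self.fragment.n_backbone_carbons + 1)
        if m.shape != expected:
            raise CorrectionError(f"correction matrix shape {m.shape}, expected {expected}")
        if np.any(m < 0):
            raise CorrectionError("correction matrix has negative entries")
        m.setflags(write=False)
        object.__setattr__(self, "matrix", m)


def build_correction_matrix(
    fragment: FragmentDefinition,
    table: IsotopeAbundanceTable = DEFAULT_ISOTOPES,
    tracer_purity: float = 1.0,
) -> CorrectionMatrix:
    """Build the natural-abundance forward model for one fragment.

    ``tracer_purity`` is the isotopic purity of the tracer carbon (1.0 means
    every tracer carbon is ¹³C); when below 1 each tracer carbon contributes
    a (1−p, p) two-point distribution instead of a pure one-unit shift.
    """
    if not 0.0 < tracer_purity <= 1.0:
        raise CorrectionError(f"tracer purity must be in (0, 1], got {tracer_purity}")
    rows = fragment.n_measured_shifts + 1
    cols = fragment.n_backbone_carbons + 1
    matrix = np.zeros((rows, cols))
    tracer_atom = np.array([1.0 - tracer_purity, tracer_purity])
    formula = fragment.fragment_formula
    for j in range(cols):
        if j == formula.carbons and set(formula.counts) == {"C"}:
            rest = np.ones(1)  # pure-carbon fragment with every carbon traced
        else:
            rest = natural_envelope(formula.without_carbons(j), table)
        col = rest
        for _ in range(j):
            col = convolve(col, tracer_atom)
        matrix[:, j] = np.pad(col, (0, max(0, rows - len(col))))[:rows]
    return CorrectionMatrix(matrix=matrix, fragment=fragment)


def correct_mid(
    raw: Sequence[float] | np.ndarray,
    matrix: CorrectionMatrix,
) -> MassIsotopomerDistribution:
    """Deconvolve a raw intensity vector into a tracer-only MID.

    Solves ``matrix · x ≈ raw`` under non-negativity and renormalizes x to
    sum to 1.  Raw intensities may be on any scale (areas, counts); only
    their relative sizes matter.
    """
    raw = np.asarray(raw, dtype=float)
    frag = matrix.fragment
    if raw.ndim != 1 or len(raw) != frag.n_measured_shifts + 1:
        raise CorrectionError(
            f"raw vector length {raw.shape} does not match measured window "
            f"{frag.n_measured_shifts + 1} for {frag.metabolite}/{frag.fragment_name}"
        )
    if np.any(raw < 0):
        raise CorrectionError(f"negative raw intensity for {frag.metabolite}/{frag.fragment_name}")
    total = raw.sum()
    if total <= 0:
        raise CorrectionError(f"all-zero raw vector for {frag.metabolite}/{frag.fragment_name}")
    x, _ = nnls(matrix.matrix, raw / total)
    s = x.sum()
    if s <= 0:
        raise CorrectionError(
            f"correction produced an all-zero solution for {frag.metabolite}/{frag.fragment_name}"
        )
    return MassIsotopomerDistribution(
        metabolite=frag.metabolite,
        fragment=frag.fragment_name,
        fractions=x / s,
    ).require_normalized()
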