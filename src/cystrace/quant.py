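"""Isotope-dilution quantification and tracer-spike planning.

Absolute media/plasma concentrations are obtained by single-point isotope
dilution: a fixed volume of sample is mixed with an equal (or known) volume
of a mix of uniformly labeled internal standards, and the analyte
concentration follows from the unlabeled/labeled signal ratio.  Because the
standards are fully mass-shifted there is no spectral cross-talk, and a unit
response factor is assumed unless a per-analyte calibration factor is
supplied.

The same module plans tracer spikes: how much labeled tracer to add to a
medium with a known basal concentration so the pool reaches a target
fractional enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "InternalStandardMix",
    "QuantMeasurement",
    "isotope_dilution_concentration",
    "spike_to_enrichment",
    "realized_enrichment",
    "QuantError",
]


class QuantError(ValueError):
    """Raised for undefined quantification computations."""


@dataclass(frozen=True)
class InternalStandardMix:
    """Labeled-standard concentrations (µM) per analyte in the spike mix."""

    concentrations_um: Mapping[str, float]
    label: str = "internal-standard mix"

    def __post_init__(self) -> None:
        for analyte, conc in self.concentrations_um.items():
            if conc <= 0:
                raise QuantError(f"{self.label}: non-positive concentration for {analyte}")

    def __contains__(self, analyte: str) -> bool:
        return analyte in self.concentrations_um

    def concentration(self, analyte: str) -> float:
        try:
            return float(self.concentrations_um[analyte])
        except KeyError:
            raise QuantError(f"analyte {analyte!r} absent from {self.label}") from None


@dataclass(frozen=True)
class QuantMeasurement:
    """Signal pair for one analyte in one sample (areas, arbitrary units)."""

    sample_id: str
    analyte: str
    analyte_signal: float
    standard_signal: float
    sample_volume_ul: float = 10.0
    mix_volume_ul: float = 10.0

    def __post_init__(self) -> None:
        if self.analyte_signal < 0 or self.standard_signal < 0:
            raise QuantError(f"sample {self.sample_id}: negative signal")
        if self.sample_volume_ul <= 0 or self.mix_volume_ul <= 0:
            raise QuantError(f"sample {self.sample_id}: volumes must be positive")


def isotope_dilution_concentration(
    m: QuantMeasurement,
    mix: InternalStandardMix,
    response_factor: float = 1.0,
) -> float:
    """Analyte concentration (µM) in the original sample.

    (analyte signal / standard signal) · standard concentration ·
    (mix volume / sample volume) / response factor.  Ratio-based, hence
    invariant to rescaling both signals.
    """
    if m.standard_signal <= 0:
        raise QuantError(
            f"sample {m.sample_id}: zero internal-standard signal for {m.analyte}; "
            "no quantification possible"
        )
    if response_factor <= 0:
        raise QuantError("response factor must be positive")
    return (
        (m.analyte_signal / m.standard_signal)
        * mix.concentration(m.analyte)
        * (m.mix_volume_ul / m.sample_volume_ul)
        / response_factor
    )


def spike_to_enrichment(basal_conc_um: float, target_enrichment: float) -> float:
    """Tracer concentration (µM) to add so the pool reaches a target enrichment.

    Solves x/(x + basal) = target, i.e. x = target·basal/(1 − target).
    A target of 1 is unreachable by spiking into an unlabeled pool.
    """
    if basal_conc_um <= 0:
        raise QuantError("basal concentration must be positive")
    if not 0.0 < target_enrichment < 1.0:
        raise QuantError("target enrichment must lie strictly between 0 and 1")
    return target_enrichment * basal_conc_um / (1.0 - target_enrichment)


def realized_enrichment(basal_conc_um: float, spike_conc_um: float) -> float:
    """Fractional enrichment achieved by adding tracer to an unlabeled pool."""
    if basal_conc_um < 0 or spike_conc_um < 0:
        raise QuantError("concentrations must be non-negative")
    total = basal_conc_um + spike_conc_um
    if total <= 0:
        raise QuantError("basal and spike concentrations are both zero")
    return spike_conc_um / total
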