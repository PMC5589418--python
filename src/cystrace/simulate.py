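"""Synthetic tracer-experiment generator with recorded ground truth.

Every pipeline stage has a forward model here that it inverts exactly in
the noiseless limit:

* labeling — a two-parameter mixture per metabolite: the true
  diagnostic-shift fraction at time t is g·e·(1 − exp(−t/τ)), where g is
  the glutamine-derived fraction of the pool, e the tracer enrichment and τ
  the pool turnover time constant; the rest of the pool sits at m+0.  The
  true MID is pushed through the fragment's natural-abundance forward model
  and perturbed with multiplicative intensity noise, yielding raw
  (uncorrected) intensities.  Steady state (t → ∞) gives g·e, so the
  natural-abundance-corrected, enrichment-normalized contribution recovers
  g — the quantity the analysis estimates.
* growth — exponential counts with multiplicative lognormal noise.
* media exchange — concentrations driven by per-cell fluxes integrated over
  the growth curve.
* quantification — signal ratios consistent with true concentrations.

Noise is multiplicative lognormal throughout (biological intensities are
positive and CV-scaled), parameterized so the noise factor has mean 1.
Condition presets are calibrated to the qualitative regime they emulate —
high glutamine-derived fractions under RPMI-like nutrient excess, low under
serum-like conditions, intermediate when only cystine is raised — and are
presets, not flux estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .correction import build_correction_matrix
from .fragments import DEFAULT_FRAGMENTS, fragment_library
from .isotopes import DEFAULT_ISOTOPES, IsotopeAbundanceTable
from .mid import FragmentDefinition

__all__ = [
    "MetaboliteParams",
    "ConditionSpec",
    "GroundTruthRecord",
    "PRESETS",
    "get_preset",
    "simulate_labeling",
    "simulate_growth",
    "simulate_media_exchange",
    "simulate_quant",
    "SimulationError",
]

LN2 = math.log(2.0)


class SimulationError(ValueError):
    """Raised for invalid simulation specifications."""


@dataclass(frozen=True)
class MetaboliteParams:
    """Ground-truth labeling/flux parameters for one metabolite."""

    glutamine_fraction: float      # g in [0, 1]
    diagnostic_shift: int          # 5 pre-decarboxylation, 4 after
    tau_hours: float = 2.0         # pool turnover time constant
    flux_fmol_per_cell_day: float = 0.0  # release positive, consumption negative

    def __post_init__(self) -> None:
        if not 0.0 <= self.glutamine_fraction <= 1.0:
            raise SimulationError("glutamine-derived fraction must lie in [0, 1]")
        if self.tau_hours <= 0:
            raise SimulationError("turnover time constant must be positive")

    def true_fraction(self, enrichment: float, time_hr: float | None = None) -> float:
        """True diagnostic-shift fraction at time t (None → steady state)."""
        g = self.glutamine_fraction * enrichment
        if time_hr is None or math.isinf(time_hr):
            return g
        if time_hr < 0:
            raise SimulationError("time must be non-negative")
        return g * -math.expm1(-time_hr / self.tau_hours)


@dataclass(frozen=True)
class ConditionSpec:
    """Complete ground-truth description of one culture condition."""

    name: str
    tracer_enrichment: float
    metabolites: Mapping[str, MetaboliteParams]
    growth_rate_per_day: float = LN2 / 2.0
    initial_cells: float = 2e5
    intensity_cv: float = 0.05
    count_cv: float = 0.10
    quant_cv: float = 0.03
    media_concentrations_um: Mapping[str, float] = field(default_factory=dict)
    tracer: str = "glutamine"

    def __post_init__(self) -> None:
        if not 0.0 < self.tracer_enrichment < 1.0:
            raise SimulationError("tracer enrichment must lie strictly between 0 and 1")
        if self.initial_cells <= 0:
            raise SimulationError("initial cell count must be positive")
        for cv in (self.intensity_cv, self.count_cv, self.quant_cv):
            if cv < 0:
                raise SimulationError("noise CVs must be non-negative")

    @property
    def doubling_time_hours(self) -> float | None:
        if self.growth_rate_per_day <= 0:
            return None
        return 24.0 * LN2 / self.growth_rate_per_day


@dataclass(frozen=True)
class GroundTruthRecord:
    """Ground truth emitted alongside every synthetic dataset."""

    condition: str
    seed: int
    params: Mapping[str, float | str]
    truth: pd.DataFrame


def _preset_metabolites(
    g: Mapping[str, float], taus: Mapping[str, float], fluxes: Mapping[str, float]
) -> dict[str, MetaboliteParams]:
    shifts = {"glutamine": 5, "glutamate": 5, "alpha-ketoglutarate": 5,
              "fumarate": 4, "malate": 4, "aspartate": 4, "citrate": 4}
    return {
        met: MetaboliteParams(
            glutamine_fraction=g[met],
            diagnostic_shift=shifts[met],
            tau_hours=taus.get(met, 3.0),
            flux_fmol_per_cell_day=fluxes.get(met, 0.0),
        )
        for met in g
    }


_TAUS = {"glutamine": 1.5, "glutamate": 2.0, "alpha-ketoglutarate": 2.5,
         "fumarate": 3.5, "malate": 3.5, "aspartate": 4.5, "citrate": 4.0}

#: Condition presets.  Glutamine-derived fractions anchor to the regimes the
#: generator emulates: nutrient-rich RPMI-like culture (~80% of glutamate
#: glutamine-derived, >60% of TCA intermediates), serum-like culture (~35%
#: glutamate), and serum raised to culture-level cystine (intermediate).
#: The tracer itself always has g = 1 (its labeled fraction IS the
#: enrichment).  Growth: 48 hr doubling in serum, 24 hr in RPMI.  Exchange
#: fluxes (fmol/cell/day, release positive) reflect cystine-stimulated
#: glutamine consumption and glutamate release.
PRESETS: dict[str, ConditionSpec] = {
    "rpmi": ConditionSpec(
        name="rpmi",
        tracer_enrichment=0.33,
        metabolites=_preset_metabolites(
            g={"glutamine": 1.0, "glutamate": 0.80, "alpha-ketoglutarate": 0.70,
               "fumarate": 0.65, "malate": 0.65, "aspartate": 0.62, "citrate": 0.62},
            taus=_TAUS,
            fluxes={"glutamine": -120.0, "glutamate": 80.0},
        ),
        growth_rate_per_day=LN2,
        media_concentrations_um={"glutamine": 1849.0, "glutamate": 122.0, "cystine": 187.0},
    ),
    "serum": ConditionSpec(
        name="serum",
        tracer_enrichment=0.33,
        metabolites=_preset_metabolites(
            g={"glutamine": 1.0, "glutamate": 0.35, "alpha-ketoglutarate": 0.30,
               "fumarate": 0.28, "malate": 0.28, "aspartate": 0.25, "citrate": 0.25},
            taus=_TAUS,
            fluxes={"glutamine": -50.0, "glutamate": 15.0},
        ),
        growth_rate_per_day=LN2 / 2.0,
        media_concentrations_um={"glutamine": 183.0, "glutamate": 192.0, "cystine": 0.3},
    ),
    "serum_cystine": ConditionSpec(
        name="serum_cystine",
        tracer_enrichment=0.33,
        metabolites=_preset_metabolites(
            g={"glutamine": 1.0, "glutamate": 0.65, "alpha-ketoglutarate": 0.55,
               "fumarate": 0.50, "malate": 0.50, "aspartate": 0.48, "citrate": 0.48},
            taus={k: v * 0.6 for k, v in _TAUS.items()},  # faster turnover under cystine
            fluxes={"glutamine": -100.0, "glutamate": 60.0},
        ),
        growth_rate_per_day=LN2 / 2.0,
        media_concentrations_um={"glutamine": 183.0, "glutamate": 192.0, "cystine": 208.3},
    ),
}


def get_preset(name: str, **overrides) -> ConditionSpec:
    """Fetch a preset, optionally overriding spec fields (e.g. CVs)."""
    try:
        spec = PRESETS[name]
    except KeyError:
        raise SimulationError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
    return replace(spec, **overrides) if overrides else spec


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise factors with mean 1 and coefficient of variation cv."""
    if cv <= 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def simulate_labeling(
    spec: ConditionSpec,
    fragments: Sequence[FragmentDefinition] = DEFAULT_FRAGMENTS,
    timepoints_hr: Sequence[float] | None = None,
    n_replicates: int = 3,
    seed: int = 0,
    abundance_table: IsotopeAbundanceTable = DEFAULT_ISOTOPES,
    total_intensity: float = 1e6,
) -> tuple[pd.DataFrame, GroundTruthRecord]:
    """Generate a raw (uncorrected) mass-isotopomer intensity table.

    ``timepoints_hr=None`` simulates isotopic steady state; otherwise each
    time point follows the first-order approach g·e·(1 − exp(−t/τ)).
    Returns the long-format raw table and the ground truth.
    """
    library = fragment_library(fragments)
    missing = [m for m in spec.metabolites if m not in library]
    if missing:
        raise SimulationError(f"no fragment definition for metabolite(s) {missing}")
    rng = np.random.default_rng(seed)
    times: list[float | None] = list(timepoints_hr) if timepoints_hr is not None else [None]
    rows, truth_rows = [], []
    for t_index, t in enumerate(times):
        for rep in range(1, n_replicates + 1):
            tag = f"{spec.name}_r{rep}" if t is None else f"{spec.name}_t{t_index}_r{rep}"
            for met, params in spec.metabolites.items():
                frag = library[met]
                f_true = params.true_fraction(spec.tracer_enrichment, t)
                true_mid = np.zeros(frag.n_backbone_carbons + 1)
                true_mid[0] = 1.0 - f_true
                true_mid[params.diagnostic_shift] += f_true
                matrix = build_correction_matrix(frag, abundance_table)
                expected = matrix.matrix @ true_mid
                raw = expected * total_intensity * _lognormal_factors(
                    rng, spec.intensity_cv, expected.shape
                )
                for shift, value in enumerate(raw):
                    rows.append({
                        "sample_id": tag,
                        "condition": spec.name,
                        "replicate": rep,
                        "time_hr": np.inf if t is None else t,
                        "metabolite": met,
                        "fragment_name": frag.fragment_name,
                        "mass_shift": shift,
                        "value": value,
                    })
                truth_rows.append({
                    "sample_id": tag,
                    "metabolite": met,
                    "time_hr": np.inf if t is None else t,
                    "glutamine_fraction": params.glutamine_fraction,
                    "tracer_enrichment": spec.tracer_enrichment,
                    "diagnostic_shift": params.diagnostic_shift,
                    "true_diagnostic_fraction": f_true,
                })
    truth = GroundTruthRecord(
        condition=spec.name,
        seed=seed,
        params={"tracer_enrichment": spec.tracer_enrichment, "intensity_cv": spec.intensity_cv,
                "n_replicates": n_replicates, "mode": "steady" if timepoints_hr is None else "kinetic"},
        truth=pd.DataFrame(truth_rows),
    )
    return pd.DataFrame(rows), truth


def simulate_growth(
    spec: ConditionSpec,
    days: Sequence[float],
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruthRecord]:
    """Generate noisy exponential growth curves (one culture per replicate)."""
    days = np.asarray(days, dtype=float)
    if days.size < 2 or np.any(np.diff(days) <= 0):
        raise SimulationError("days must be at least two strictly increasing values")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_replicates + 1):
        expected = spec.initial_cells * np.exp(spec.growth_rate_per_day * days)
        counts = expected * _lognormal_factors(rng, spec.count_cv, days.shape)
        for t, c in zip(days, counts):
            rows.append({
                "culture_id": f"{spec.name}_g{rep}",
                "replicate": rep,
                "time_days": t,
                "cell_count": c,
            })
    truth = GroundTruthRecord(
        condition=spec.name,
        seed=seed,
        params={
            "initial_cells": spec.initial_cells,
            "growth_rate_per_day": spec.growth_rate_per_day,
            "doubling_time_hours": spec.doubling_time_hours or float("nan"),
            "count_cv": spec.count_cv,
        },
        truth=pd.DataFrame(rows),
    )
    return pd.DataFrame(rows), truth


def simulate_media_exchange(
    spec: ConditionSpec,
    volume_ml: float = 2.0,
    duration_days: float = 2.0,
    n_replicates: int = 1,
    seed: int = 0,
    measurement_cv: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruthRecord]:
    """Generate spent-media measurements plus the paired two-point growth table.

    Final concentration = initial + flux · (integrated cell·days) / volume,
    floored at zero (a floor signals nutrient exhaustion and is warned
    about).  Returns (exchange table, growth table, ground truth).
    """
    import warnings

    if volume_ml <= 0 or duration_days <= 0:
        raise SimulationError("volume and duration must be positive")
    rng = np.random.default_rng(seed)
    r = spec.growth_rate_per_day
    n0 = spec.initial_cells
    cell_days = n0 * duration_days if r == 0 else n0 * math.expm1(r * duration_days) / r
    exchange_rows, growth_rows, truth_rows = [], [], []
    for rep in range(1, n_replicates + 1):
        culture = f"{spec.name}_x{rep}"
        growth_rows += [
            {"culture_id": culture, "time_days": 0.0, "cell_count": n0},
            {"culture_id": culture, "time_days": duration_days,
             "cell_count": n0 * math.exp(r * duration_days)},
        ]
        for met, params in spec.metabolites.items():
            if params.flux_fmol_per_cell_day == 0.0:
                continue
            initial = spec.media_concentrations_um.get(met)
            if initial is None:
                continue
            delta_um = params.flux_fmol_per_cell_day * cell_days / (volume_ml * 1e6)
            final = initial + delta_um
            if final < 0:
                warnings.warn(
                    f"{culture}/{met}: media depleted (computed {final:.3g} µM); floored at 0",
                    stacklevel=2,
                )
                final = 0.0
            noisy_final = final * float(_lognormal_factors(rng, measurement_cv, ()))
            exchange_rows.append({
                "culture_id": culture,
                "metabolite": met,
                "conc_initial_uM": initial,
                "conc_final_uM": noisy_final,
                "volume_mL": volume_ml,
                "t0_days": 0.0,
                "t1_days": duration_days,
            })
            truth_rows.append({
                "culture_id": culture,
                "metabolite": met,
                "flux_fmol_per_cell_day": params.flux_fmol_per_cell_day,
                "integrated_cell_days": cell_days,
            })
    truth = GroundTruthRecord(
        condition=spec.name,
        seed=seed,
        params={"growth_rate_per_day": r, "initial_cells": n0,
                "volume_ml": volume_ml, "duration_days": duration_days,
                "measurement_cv": measurement_cv},
        truth=pd.DataFrame(truth_rows),
    )
    return pd.DataFrame(exchange_rows), pd.DataFrame(growth_rows), truth


def simulate_quant(
    true_concentrations_um: Mapping[str, float],
    standard_concentrations_um: Mapping[str, float],
    n_samples: int = 3,
    seed: int = 0,
    cv: float = 0.03,
    sample_volume_ul: float = 10.0,
    mix_volume_ul: float = 10.0,
    base_signal: float = 1e5,
) -> tuple[pd.DataFrame, GroundTruthRecord]:
    """Generate single-point isotope-dilution signal pairs.

    The unlabeled/labeled signal ratio encodes the true concentration given
    the stated volumes; both signals carry independent multiplicative noise.
    """
    missing = [a for a in true_concentrations_um if a not in standard_concentrations_um]
    if missing:
        raise SimulationError(f"internal-standard mix does not cover analyte(s) {missing}")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(1, n_samples + 1):
        for analyte, conc in true_concentrations_um.items():
            is_conc = standard_concentrations_um[analyte]
            ratio = (conc / is_conc) * (sample_volume_ul / mix_volume_ul)
            std_signal = base_signal * float(_lognormal_factors(rng, cv, ()))
            ana_signal = base_signal * ratio * float(_lognormal_factors(rng, cv, ()))
            rows.append({
                "sample_id": f"quant_s{i}",
                "analyte": analyte,
                "analyte_signal": ana_signal,
                "standard_signal": std_signal,
                "sample_volume_ul": sample_volume_ul,
                "mix_volume_ul": mix_volume_ul,
            })
    truth = GroundTruthRecord(
        condition="quant",
        seed=seed,
        params={"cv": cv, "n_samples": n_samples},
        truth=pd.DataFrame(
            [{"analyte": a, "true_concentration_uM": c} for a, c in true_concentrations_um.items()]
        ),
    )
    return pd.DataFrame(rows), truth
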