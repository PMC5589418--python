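"""End-to-end orchestration: correct → summarize → compare → rates → quant."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .correction import build_correction_matrix, correct_mid
from .enrichment import (
    ConditionComparison,
    ConditionSummary,
    LabelingSample,
    cystine_induced_increase,
    summarize_condition,
)
from .fragments import DEFAULT_FRAGMENTS, fragment_library, read_fragment_table
from .io import (
    ExperimentConfig,
    SchemaError,
    read_exchange_table,
    read_growth_table,
    read_mid_table,
    read_quant_table,
)
from .isotopes import DEFAULT_ISOTOPES, IsotopeAbundanceTable
from .mid import FragmentDefinition, MassIsotopomerDistribution
from .quant import InternalStandardMix, QuantMeasurement, isotope_dilution_concentration
from .rates import ExchangeExperiment, exchange_rate, fit_exponential_growth, GrowthCurve

__all__ = ["RunReport", "correct_table", "samples_from_corrected", "compute_rates",
           "compute_quant", "run_pipeline"]


@dataclass(frozen=True)
class RunReport:
    """All pipeline outputs plus provenance."""

    summaries: Mapping[str, ConditionSummary]
    comparisons: tuple[ConditionComparison, ...]
    corrected: pd.DataFrame
    rates: pd.DataFrame | None
    quant: pd.DataFrame | None
    provenance: Mapping[str, str]


def correct_table(
    raw: pd.DataFrame,
    fragments: Sequence[FragmentDefinition] = DEFAULT_FRAGMENTS,
    abundance_table: IsotopeAbundanceTable = DEFAULT_ISOTOPES,
) -> pd.DataFrame:
    """Natural-abundance-correct every (sample, fragment) in a raw MID table."""
    library = fragment_library(fragments)
    matrices = {}
    out_rows = []
    keep = [c for c in ("condition", "replicate", "time_hr") if c in raw.columns]
    for (sample, met, frag_name), group in raw.groupby(
        ["sample_id", "metabolite", "fragment_name"], sort=False
    ):
        if met not in library:
            raise SchemaError(f"no fragment definition for metabolite {met!r}")
        frag = library[met]
        if met not in matrices:
            matrices[met] = build_correction_matrix(frag, abundance_table)
        ordered = group.sort_values("mass_shift")
        corrected = correct_mid(ordered["value"].to_numpy(), matrices[met])
        meta = {c: ordered.iloc[0][c] for c in keep}
        for shift, value in enumerate(corrected.fractions):
            out_rows.append({
                "sample_id": sample, **meta, "metabolite": met,
                "fragment_name": frag_name, "mass_shift": shift, "value": value,
            })
    return pd.DataFrame(out_rows)


def samples_from_corrected(
    corrected: pd.DataFrame,
    tracer: str = "glutamine",
    tracer_shift: int = 5,
) -> list[LabelingSample]:
    """Group a corrected MID table into per-sample LabelingSample objects."""
    samples = []
    for sample_id, group in corrected.groupby("sample_id", sort=False):
        mids = {}
        for (met, frag_name), sub in group.groupby(["metabolite", "fragment_name"], sort=False):
            ordered = sub.sort_values("mass_shift")
            mids[met] = MassIsotopomerDistribution(
                metabolite=met, fragment=frag_name,
                fractions=ordered["value"].to_numpy(),
            )
        condition = str(group.iloc[0]["condition"]) if "condition" in group else ""
        replicate = int(group.iloc[0]["replicate"]) if "replicate" in group else 0
        samples.append(LabelingSample(
            sample_id=str(sample_id), condition=condition, replicate=replicate,
            mids=mids, tracer=tracer, tracer_shift=tracer_shift,
        ))
    return samples


def compute_rates(growth: pd.DataFrame, exchange: pd.DataFrame) -> pd.DataFrame:
    """Fit per-culture growth and normalize media changes to cell·days."""
    fits = {}
    for culture_id, group in growth.groupby("culture_id", sort=False):
        ordered = group.sort_values("time_days")
        fits[culture_id] = fit_exponential_growth(GrowthCurve(
            times=ordered["time_days"].to_numpy(),
            counts=ordered["cell_count"].to_numpy(),
            culture_id=str(culture_id),
        ))
    rows = []
    for row in exchange.itertuples(index=False):
        if row.culture_id not in fits:
            raise SchemaError(f"no growth curve for culture {row.culture_id!r}")
        fit = fits[row.culture_id]
        exp = ExchangeExperiment(
            culture_id=str(row.culture_id), metabolite=str(row.metabolite),
            conc_initial_um=float(row.conc_initial_uM), conc_final_um=float(row.conc_final_uM),
            volume_ml=float(row.volume_mL), t0_days=float(row.t0_days), t1_days=float(row.t1_days),
        )
        rows.append({
            "culture_id": exp.culture_id,
            "metabolite": exp.metabolite,
            "rate_fmol_per_cell_day": exchange_rate(exp, fit),
            "growth_rate_per_day": fit.rate,
            "doubling_time_hours": fit.doubling_time_hours,
            "fit_residual_norm": fit.residual_norm,
        })
    return pd.DataFrame(rows)


def compute_quant(signals: pd.DataFrame, mix: InternalStandardMix) -> pd.DataFrame:
    rows = []
    for row in signals.itertuples(index=False):
        m = QuantMeasurement(
            sample_id=str(row.sample_id), analyte=str(row.analyte),
            analyte_signal=float(row.analyte_signal), standard_signal=float(row.standard_signal),
            sample_volume_ul=float(row.sample_volume_ul), mix_volume_ul=float(row.mix_volume_ul),
        )
        rows.append({
            "sample_id": m.sample_id, "analyte": m.analyte,
            "concentration_uM": isotope_dilution_concentration(m, mix),
        })
    return pd.DataFrame(rows)


def run_pipeline(config: ExperimentConfig, out_dir: str | Path | None = None) -> RunReport:
    """Run every configured stage and (optionally) write all outputs.

    Deterministic given its inputs; every output traces to an input file
    through the provenance block (config hash + tool version).
    """
    fragments = (
        read_fragment_table(config.fragments) if config.fragments else DEFAULT_FRAGMENTS
    )
    abundances = (
        IsotopeAbundanceTable.from_yaml(config.abundances)
        if config.abundances else DEFAULT_ISOTOPES
    )
    summaries: dict[str, ConditionSummary] = {}
    comparisons: list[ConditionComparison] = []
    corrected = pd.DataFrame()
    if config.mids is not None:
        raw = read_mid_table(config.mids)
        corrected = correct_table(raw, fragments, abundances)
        samples = samples_from_corrected(corrected, config.tracer, config.tracer_shift)
        by_condition: dict[str, list[LabelingSample]] = {}
        for s in samples:
            by_condition.setdefault(s.condition, []).append(s)
        summaries = {c: summarize_condition(ss) for c, ss in by_condition.items()}
        for comp in config.comparisons:
            high, low = str(comp["high"]), str(comp["low"])
            metabolite = str(comp.get("metabolite", "alpha-ketoglutarate"))
            for name in (high, low):
                if name not in summaries:
                    raise SchemaError(f"comparison references unknown condition {name!r}")
            comparisons.append(cystine_induced_increase(
                summaries[high], summaries[low], metabolite, equal_var=config.equal_var,
            ))
    rates = None
    if config.growth is not None and config.exchange is not None:
        rates = compute_rates(read_growth_table(config.growth), read_exchange_table(config.exchange))
    quant = None
    if config.quant_signals is not None:
        if not config.standard_mix_um:
            raise SchemaError("quant signals configured without an internal-standard mix")
        quant = compute_quant(
            read_quant_table(config.quant_signals),
            InternalStandardMix(concentrations_um=config.standard_mix_um),
        )
    report = RunReport(
        summaries=summaries,
        comparisons=tuple(comparisons),
        corrected=corrected,
        rates=rates,
        quant=quant,
        provenance={"config_hash": config.config_hash, "version": __version__},
    )
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def _summary_frame(summaries: Mapping[str, ConditionSummary]) -> pd.DataFrame:
    rows = []
    for cond, s in summaries.items():
        for met in s.mean_labeling:
            contributions = s.contributions.get(met, ())
            rows.append({
                "condition": cond, "metabolite": met, "n": s.n,
                "mean_labeling": s.mean_labeling[met], "sd_labeling": s.sd_labeling[met],
                "mean_enrichment": s.mean_enrichment,
                "mean_contribution": float(np.mean(contributions)) if contributions else np.nan,
            })
    return pd.DataFrame(rows)


def _comparison_frame(comparisons: Sequence[ConditionComparison]) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        rows.append({
            "high_condition": c.high.condition, "low_condition": c.low.condition,
            "metabolite": c.metabolite, "statistic": c.statistic,
            "high_contributions": ";".join(f"{v:.6g}" for v in c.high_contributions),
            "low_contributions": ";".join(f"{v:.6g}" for v in c.low_contributions),
            "t": c.ttest.t if c.ttest else np.nan,
            "df": c.ttest.df if c.ttest else np.nan,
            "p_raw": c.ttest.p if c.ttest else np.nan,  # unadjusted p-values
        })
    return pd.DataFrame(rows)


def write_report(report: RunReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not report.corrected.empty:
        report.corrected.to_csv(out / "corrected_mids.csv", index=False)
        _summary_frame(report.summaries).to_csv(out / "condition_summary.csv", index=False)
    if report.comparisons:
        _comparison_frame(report.comparisons).to_csv(out / "comparisons.csv", index=False)
    if report.rates is not None:
        report.rates.to_csv(out / "rates.csv", index=False)
    if report.quant is not None:
        report.quant.to_csv(out / "quant.csv", index=False)
    payload = {
        "provenance": dict(report.provenance),
        "conditions": {
            c: {"n": s.n, "mean_enrichment": s.mean_enrichment,
                "mean_contribution": {m: float(np.mean(v)) for m, v in s.contributions.items()}}
            for c, s in report.summaries.items()
        },
        "comparisons": [
            {"high": c.high.condition, "low": c.low.condition, "metabolite": c.metabolite,
             "statistic": c.statistic, "p_raw": (c.ttest.p if c.ttest else None)}
            for c in report.comparisons
        ],
    }
    (out / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    lines = [f"cystrace report (version {report.provenance.get('version', '?')}, "
             f"config {report.provenance.get('config_hash', '-')})", ""]
    for c, s in report.summaries.items():
        lines.append(f"condition {c}: n={s.n}, tracer enrichment {s.mean_enrichment:.3f}")
        for met, vals in s.contributions.items():
            lines.append(f"  {met}: normalized contribution {np.mean(vals):.3f}")
    for c in report.comparisons:
        p = f", p={c.ttest.p:.3g}" if c.ttest else ""
        lines.append(
            f"increase of glutamine contribution to {c.metabolite} "
            f"({c.high.condition} - {c.low.condition}): {c.statistic:.3f}{p}"
        )
    (out / "report.txt").write_text("\n".join(lines) + "\n")
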