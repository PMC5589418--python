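"""CSV/TSV readers and writers plus the experiment-layout configuration.

All tables are long-format, comma-separated, UTF-8, '.'-decimal, with a
header row.  Readers validate loudly: a missing column, a duplicate record
or a gap in the mass-shift ladder is an error naming the offender, never a
silent coercion.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "MID_COLUMNS",
    "SchemaError",
    "read_mid_table",
    "write_mid_table",
    "read_growth_table",
    "read_exchange_table",
    "read_quant_table",
    "ExperimentConfig",
    "load_config",
]

MID_COLUMNS = ["sample_id", "condition", "metabolite", "fragment_name", "mass_shift", "value"]
GROWTH_COLUMNS = ["culture_id", "time_days", "cell_count"]
EXCHANGE_COLUMNS = ["culture_id", "metabolite", "conc_initial_uM", "conc_final_uM",
                    "volume_mL", "t0_days", "t1_days"]
QUANT_COLUMNS = ["sample_id", "analyte", "analyte_signal", "standard_signal",
                 "sample_volume_ul", "mix_volume_ul"]


class SchemaError(ValueError):
    """Raised when an input table violates its schema."""


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_mid_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format raw/corrected MID table.

    Requires columns sample_id, condition, metabolite, fragment_name,
    mass_shift, value; per (sample_id, metabolite, fragment_name) the mass
    shifts must be consecutive integers starting at 0 and unique.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, MID_COLUMNS, path)
    df["mass_shift"] = df["mass_shift"].astype(int)
    keys = ["sample_id", "metabolite", "fragment_name"]
    dupes = df.duplicated(subset=keys + ["mass_shift"])
    if dupes.any():
        offender = df.loc[dupes.idxmax(), keys + ["mass_shift"]].to_dict()
        raise SchemaError(f"{path}: duplicate record {offender}")
    for group_key, group in df.groupby(keys, sort=False):
        shifts = sorted(group["mass_shift"])
        expected = list(range(len(shifts)))
        if shifts != expected:
            gap = next((s for s in expected if s not in shifts), shifts[0])
            raise SchemaError(
                f"{path}: mass shifts for {dict(zip(keys, group_key))} are {shifts}; "
                f"missing shift {gap}"
            )
    return df


def write_mid_table(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in df.columns if c in MID_COLUMNS or c in ("replicate", "time_hr")]
    df.to_csv(path, index=False, columns=cols or None)


def read_growth_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, GROWTH_COLUMNS, path)
    if (df["cell_count"] <= 0).any():
        raise SchemaError(f"{path}: non-positive cell_count")
    return df


def read_exchange_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, EXCHANGE_COLUMNS, path)
    return df


def read_quant_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, QUANT_COLUMNS, path)
    return df


@dataclass(frozen=True)
class ExperimentConfig:
    """Parsed experiment-layout configuration.

    Paths are resolved relative to the config file's directory.  ``None``
    for fragment/abundance paths selects the shipped defaults.
    """

    mids: Path | None = None
    fragments: Path | None = None
    abundances: Path | None = None
    growth: Path | None = None
    exchange: Path | None = None
    quant_signals: Path | None = None
    standard_mix_um: Mapping[str, float] = field(default_factory=dict)
    tracer: str = "glutamine"
    tracer_shift: int = 5
    comparisons: tuple[Mapping[str, str], ...] = ()
    equal_var: bool = True
    steady_rel_tol: float = 0.05
    raw_text: str = ""

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.raw_text.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> ExperimentConfig:
    """Load a YAML experiment configuration."""
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: config must be a mapping")

    def resolve(key: str) -> Path | None:
        value = data.get(key)
        return (path.parent / value) if value else None

    tracer = data.get("tracer", {}) or {}
    comparisons = tuple(data.get("comparisons", []) or [])
    for comp in comparisons:
        for k in ("high", "low"):
            if k not in comp:
                raise SchemaError(f"{path}: comparison entry missing key {k!r}: {comp}")
    quant = data.get("quant", {}) or {}
    options = data.get("options", {}) or {}
    return ExperimentConfig(
        mids=resolve("mids"),
        fragments=resolve("fragments"),
        abundances=resolve("abundances"),
        growth=resolve("growth"),
        exchange=resolve("exchange"),
        quant_signals=(path.parent / quant["signals"]) if quant.get("signals") else None,
        standard_mix_um=dict(quant.get("mix", {}) or {}),
        tracer=str(tracer.get("metabolite", "glutamine")),
        tracer_shift=int(tracer.get("shift", 5)),
        comparisons=comparisons,
        equal_var=bool(options.get("equal_var", True)),
        steady_rel_tol=float(options.get("steady_rel_tol", 0.05)),
        raw_text=text,
    )
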