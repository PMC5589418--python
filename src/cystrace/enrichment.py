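"""Enrichment statistics for glutamine-anaplerosis tracing experiments.

The central quantity is the *normalized contribution*: a metabolite's
diagnostic-shift fraction (m+5 or m+4) divided by the tracer enrichment
(glutamine m+5 in the same sample by default).  Because the medium glutamine
pool is only partially labeled (~33% in the experimental design this package
emulates), raw fractional labeling understates how much of a metabolite pool
is glutamine-derived; dividing by the enrichment recovers the
glutamine-derived fraction under a well-mixed precursor model.

The headline comparison statistic is the cystine-induced increase of
glutamine contribution to α-ketoglutarate: the difference in normalized αKG
contribution between a high-cystine and a low-cystine condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .fragments import DIAGNOSTIC_SHIFTS
from .mid import MassIsotopomerDistribution

__all__ = [
    "LabelingSample",
    "ConditionSummary",
    "ConditionComparison",
    "TTestResult",
    "fractional_labeling",
    "normalized_contribution",
    "summarize_condition",
    "cystine_induced_increase",
    "steady_state_check",
    "unpaired_t_test",
    "EnrichmentError",
]


class EnrichmentError(ValueError):
    """Raised for undefined or ill-posed enrichment computations."""


@dataclass(frozen=True)
class LabelingSample:
    """One biological replicate: corrected MIDs for every measured metabolite."""

    sample_id: str
    condition: str
    replicate: int
    mids: Mapping[str, MassIsotopomerDistribution]
    tracer: str = "glutamine"
    tracer_shift: int = 5

    def __post_init__(self) -> None:
        if self.tracer not in self.mids:
            raise EnrichmentError(
                f"sample {self.sample_id}: tracer metabolite {self.tracer!r} not measured"
            )

    @property
    def tracer_enrichment(self) -> float:
        return fractional_labeling(self.mids[self.tracer], self.tracer_shift)


@dataclass(frozen=True)
class ConditionSummary:
    """Per-metabolite labeling summary for one condition."""

    condition: str
    n: int
    mean_labeling: Mapping[str, float]      # diagnostic-shift fraction, mean over replicates
    sd_labeling: Mapping[str, float]
    mean_enrichment: float                  # tracer m+5, mean over replicates
    contributions: Mapping[str, tuple[float, ...]]  # per-replicate normalized contributions


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class ConditionComparison:
    """High- vs low-condition normalized contributions for one metabolite."""

    high: ConditionSummary
    low: ConditionSummary
    metabolite: str
    statistic: float
    high_contributions: tuple[float, ...]
    low_contributions: tuple[float, ...]
    ttest: TTestResult | None = None


def fractional_labeling(mid: MassIsotopomerDistribution, shift: int) -> float:
    """Fraction of the pool at a given mass shift (e.g. m+5)."""
    return mid.fraction_at(shift)


def normalized_contribution(
    metabolite_mid: MassIsotopomerDistribution,
    metabolite_shift: int,
    tracer_mid: MassIsotopomerDistribution,
    tracer_shift: int = 5,
) -> float:
    """Fraction of the metabolite pool derived from the tracer.

    Divides the metabolite's diagnostic-shift fraction by the tracer
    enrichment.  Undefined (raises) when the tracer is unlabeled.
    """
    enrichment = fractional_labeling(tracer_mid, tracer_shift)
    if enrichment <= 0:
        raise EnrichmentError(
            f"tracer {tracer_mid.metabolite} has zero m+{tracer_shift} enrichment; "
            "normalized contribution is undefined"
        )
    return fractional_labeling(metabolite_mid, metabolite_shift) / enrichment


def _diagnostic_shift(metabolite: str, shifts: Mapping[str, int] | None) -> int:
    table = DIAGNOSTIC_SHIFTS if shifts is None else shifts
    try:
        return table[metabolite]
    except KeyError:
        raise EnrichmentError(f"no diagnostic mass shift configured for {metabolite!r}") from None


def summarize_condition(
    samples: Sequence[LabelingSample],
    diagnostic_shifts: Mapping[str, int] | None = None,
) -> ConditionSummary:
    """Summarize replicate samples of one condition.

    Means and SDs of diagnostic-shift fractional labeling per metabolite,
    plus per-replicate normalized contributions (each replicate's labeling
    divided by that same replicate's tracer enrichment).
    """
    if not samples:
        raise EnrichmentError("no samples to summarize")
    conditions = {s.condition for s in samples}
    if len(conditions) != 1:
        raise EnrichmentError(f"samples span multiple conditions: {sorted(conditions)}")
    metabolites = sorted(set().union(*(s.mids.keys() for s in samples)))
    mean_lab: dict[str, float] = {}
    sd_lab: dict[str, float] = {}
    contributions: dict[str, tuple[float, ...]] = {}
    for met in metabolites:
        shift = _diagnostic_shift(met, diagnostic_shifts)
        labs = [fractional_labeling(s.mids[met], shift) for s in samples if met in s.mids]
        mean_lab[met] = float(np.mean(labs))
        sd_lab[met] = float(np.std(labs, ddof=1)) if len(labs) > 1 else 0.0
        contributions[met] = tuple(
            normalized_contribution(s.mids[met], shift, s.mids[s.tracer], s.tracer_shift)
            for s in samples
            if met in s.mids
        )
    enrichments = [s.tracer_enrichment for s in samples]
    return ConditionSummary(
        condition=samples[0].condition,
        n=len(samples),
        mean_labeling=mean_lab,
        sd_labeling=sd_lab,
        mean_enrichment=float(np.mean(enrichments)),
        contributions=contributions,
    )


def cystine_induced_increase(
    high: ConditionSummary,
    low: ConditionSummary,
    metabolite: str = "alpha-ketoglutarate",
    run_ttest: bool = True,
    equal_var: bool = True,
) -> ConditionComparison:
    """Cystine-induced increase of glutamine contribution to a metabolite.

    Mean normalized contribution in the high(-cystine) condition minus the
    mean in the low condition; per-replicate values are retained so the
    difference can be tested.  Antisymmetric in its two conditions.
    """
    for summary in (high, low):
        if metabolite not in summary.contributions:
            raise EnrichmentError(
                f"metabolite {metabolite!r} missing from condition {summary.condition!r}"
            )
    hi = high.contributions[metabolite]
    lo = low.contributions[metabolite]
    statistic = float(np.mean(hi) - np.mean(lo))
    ttest = None
    if run_ttest and len(hi) >= 2 and len(lo) >= 2:
        ttest = unpaired_t_test(hi, lo, equal_var=equal_var)
    return ConditionComparison(
        high=high,
        low=low,
        metabolite=metabolite,
        statistic=statistic,
        high_contributions=tuple(hi),
        low_contributions=tuple(lo),
        ttest=ttest,
    )


def steady_state_check(
    times: Sequence[float],
    values: Sequence[float],
    rel_tol: float = 0.05,
) -> tuple[bool, float | None]:
    """Decide whether a labeling time course has reached isotopic steady state.

    Steady state is declared at the endpoint of the first successive change
    from which every later successive relative change is within ``rel_tol``;
    a perfectly constant series is steady from its first point.  Returns
    ``(attained, time_of_attainment)`` with time ``None`` when never steady.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size != values.size:
        raise EnrichmentError("times and values must have the same length")
    if times.size < 2:
        raise EnrichmentError("steady-state check needs at least two time points")
    if np.any(np.diff(times) <= 0):
        raise EnrichmentError("times must be strictly increasing")
    if np.all(values == values[0]):
        return True, float(times[0])
    denom = np.maximum(np.abs(values[:-1]), np.finfo(float).tiny)
    changes = np.abs(np.diff(values)) / denom
    ok = changes <= rel_tol
    # last index where a change violated the tolerance; steady just after it
    bad = np.nonzero(~ok)[0]
    first_steady = (bad[-1] + 2) if bad.size else 1
    if first_steady >= times.size:
        return False, None
    return True, float(times[first_steady])


def unpaired_t_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_var: bool = True,
) -> TTestResult:
    """Two-tailed unpaired t-test (Student's by default, Welch optional)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise EnrichmentError("t-test needs at least two observations per group")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        df = float(a.size + b.size - 2)
        if a.mean() == b.mean():
            return TTestResult(t=0.0, df=df, p=1.0)
        return TTestResult(t=math.copysign(math.inf, a.mean() - b.mean()), df=df, p=0.0)
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))
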