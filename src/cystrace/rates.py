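"""Proliferation, exponential-growth fitting, and media exchange rates.

Consumption/release rates are computed the way tracing studies normalize
spent-media measurements: the change in a metabolite's media concentration
over the culture interval is divided by the number of cell·days the media
was conditioned, obtained by integrating an exponential growth curve fitted
to the cell counts.  Sign convention: release positive, consumption
negative.  Rates are reported in fmol/cell/day (concentrations enter in µM,
volumes in mL).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "GrowthCurve",
    "GrowthFit",
    "ExchangeExperiment",
    "proliferation_rate",
    "fit_exponential_growth",
    "two_point_growth_fit",
    "integrated_cell_days",
    "exchange_rate",
    "RateError",
]

# below |rate|·span of this size the closed form is replaced by its series limit
_RATE_EPS = 1e-12


class RateError(ValueError):
    """Raised for ill-posed growth or exchange computations."""


@dataclass(frozen=True)
class GrowthCurve:
    """Cell counts over time for one culture."""

    times: np.ndarray  # days, strictly increasing
    counts: np.ndarray  # cells, positive
    culture_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.counts, dtype=float)
        if t.ndim != 1 or t.size != c.size:
            raise RateError("times and counts must be 1-D vectors of equal length")
        if t.size < 2:
            raise RateError("growth curve needs at least two points")
        if np.any(np.diff(t) <= 0):
            raise RateError(f"culture {self.culture_id!r}: times must be strictly increasing")
        if np.any(c <= 0):
            raise RateError(f"culture {self.culture_id!r}: cell counts must be positive")
        t.setflags(write=False)
        c.setflags(write=False)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "counts", c)


@dataclass(frozen=True)
class GrowthFit:
    """Parameters of N(t) = N0·exp(rate·t)."""

    n0: float          # cells at t = 0
    rate: float        # per day, natural-log scale; ≤ 0 for dying cultures
    residual_norm: float = 0.0

    @property
    def doubling_time_hours(self) -> float | None:
        """24·ln2/rate; undefined (None) for non-growing cultures."""
        if self.rate <= 1e-12:  # numerically zero growth
            return None
        return 24.0 * math.log(2.0) / self.rate

    def predict(self, t: np.ndarray | float) -> np.ndarray | float:
        return self.n0 * np.exp(self.rate * np.asarray(t, dtype=float))


@dataclass(frozen=True)
class ExchangeExperiment:
    """One spent-media measurement for one metabolite in one culture."""

    culture_id: str
    metabolite: str
    conc_initial_um: float
    conc_final_um: float
    volume_ml: float
    t0_days: float
    t1_days: float

    def __post_init__(self) -> None:
        if self.volume_ml <= 0:
            raise RateError(f"culture {self.culture_id!r}: volume must be positive")
        if self.t1_days <= self.t0_days:
            raise RateError(f"culture {self.culture_id!r}: end time must exceed start time")


def proliferation_rate(initial_count: float, final_count: float, elapsed_days: float) -> float:
    """Doublings per day: log2(final/initial)/elapsed.  Negative for net death."""
    if initial_count <= 0 or final_count <= 0:
        raise RateError("cell counts must be positive")
    if elapsed_days <= 0:
        raise RateError("elapsed time must be positive")
    return math.log2(final_count / initial_count) / elapsed_days


def two_point_growth_fit(
    t0: float, count0: float, t1: float, count1: float
) -> GrowthFit:
    """Exact exponential through two (time, count) points."""
    if count0 <= 0 or count1 <= 0:
        raise RateError("cell counts must be positive")
    if t1 <= t0:
        raise RateError("second time point must be later than the first")
    rate = math.log(count1 / count0) / (t1 - t0)
    n0 = count0 * math.exp(-rate * t0)
    return GrowthFit(n0=n0, rate=rate, residual_norm=0.0)


def fit_exponential_growth(curve: GrowthCurve, relative_residuals: bool = True) -> GrowthFit:
    """Nonlinear least-squares fit of N(t) = N0·exp(rate·t) to cell counts.

    By default residuals are weighted by the observed counts (relative-error
    objective), which matches the multiplicative error structure of cell
    counting and keeps late, large-count time points from dominating the
    fit; ``relative_residuals=False`` selects unweighted residuals on the
    count scale.  Two-point curves degrade to the exact solution.  Starting
    values come from a log-linear regression, which already solves the
    noiseless case.
    """
    t, c = curve.times, curve.counts
    if t.size == 2:
        return two_point_growth_fit(t[0], c[0], t[1], c[1])
    slope, intercept = np.polyfit(t, np.log(c), 1)
    try:
        popt, _ = curve_fit(
            lambda tt, n0, r: n0 * np.exp(r * tt),
            t,
            c,
            p0=[math.exp(intercept), slope],
            sigma=c if relative_residuals else None,
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological inputs
        raise RateError(f"exponential fit failed for culture {curve.culture_id!r}: {exc}") from exc
    n0, rate = float(popt[0]), float(popt[1])
    residuals = c - n0 * np.exp(rate * t)
    return GrowthFit(n0=n0, rate=rate, residual_norm=float(np.linalg.norm(residuals)))


def integrated_cell_days(fit: GrowthFit, t0: float, t1: float) -> float:
    """∫ N(t) dt over [t0, t1] in cell·days.

    Closed form N0·(e^(r·t1) − e^(r·t0))/r, with the continuous r → 0 limit
    N0·(t1 − t0) used when |r·(t1 − t0)| is numerically negligible.
    """
    if t1 <= t0:
        raise RateError("integration interval must have t1 > t0")
    span = t1 - t0
    if abs(fit.rate * span) < _RATE_EPS:
        return fit.n0 * span
    return fit.n0 * math.exp(fit.rate * t0) * math.expm1(fit.rate * span) / fit.rate


def exchange_rate(exp: ExchangeExperiment, fit: GrowthFit) -> float:
    """Consumption/release rate in fmol/cell/day (release positive).

    (ΔC · volume) / integrated cell·days, with ΔC = final − initial media
    concentration.  µM · mL = 10⁻⁹ mol·10⁻³ = picomole·mL/µL… concretely:
    1 µM over 1 mL is 10⁻⁹ mol = 10⁶ fmol.
    """
    cell_days = integrated_cell_days(fit, exp.t0_days, exp.t1_days)
    if cell_days <= 0:
        raise RateError(f"culture {exp.culture_id!r}: non-positive integrated cell·days")
    delta_fmol = (exp.conc_final_um - exp.conc_initial_um) * exp.volume_ml * 1e6
    return delta_fmol / cell_days
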