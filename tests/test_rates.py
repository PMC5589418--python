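"""Growth fitting, integrated cell-days, and exchange rates."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from cystrace import (
    ExchangeExperiment,
    GrowthCurve,
    GrowthFit,
    exchange_rate,
    fit_exponential_growth,
    get_preset,
    integrated_cell_days,
    proliferation_rate,
    simulate_growth,
    simulate_media_exchange,
    two_point_growth_fit,
)
from cystrace.pipeline import compute_rates
from cystrace.rates import RateError


class TestProliferationRate:
    def test_two_doublings_in_four_days(self):
        assert proliferation_rate(20000, 80000, 4) == pytest.approx(0.5)

    def test_no_net_growth(self):
        assert proliferation_rate(50000, 50000, 4) == 0.0

    def test_death_is_negative(self):
        assert proliferation_rate(50000, 25000, 2) == pytest.approx(-0.5)

    def test_half_doubling_per_day_means_48h_doubling(self):
        # 0.5 doublings/day corresponds to a 48 hr doubling time
        rate = proliferation_rate(1e5, 1e5 * 2 ** 2, 4)
        assert 24 / rate == pytest.approx(48.0)

    def test_invalid_counts(self):
        with pytest.raises(RateError):
            proliferation_rate(0, 100, 1)


class TestExponentialFit:
    def test_exact_doubling_curve(self):
        curve = GrowthCurve(np.array([0, 2, 4, 6.0]), np.array([1e5, 2e5, 4e5, 8e5]))
        fit = fit_exponential_growth(curve)
        assert fit.rate == pytest.approx(math.log(2) / 2, rel=1e-9)
        assert fit.doubling_time_hours == pytest.approx(48.0, rel=1e-9)
        assert fit.n0 == pytest.approx(1e5, rel=1e-6)

    def test_constant_counts(self):
        curve = GrowthCurve(np.array([0, 1, 2.0]), np.array([5e4, 5e4, 5e4]))
        fit = fit_exponential_growth(curve)
        assert fit.rate == pytest.approx(0.0, abs=1e-9)
        assert fit.doubling_time_hours is None

    def test_two_point_agreement_with_proliferation_rate(self):
        fit = two_point_growth_fit(0.0, 1e5, 2.0, 3e5)
        assert fit.rate / math.log(2) == pytest.approx(proliferation_rate(1e5, 3e5, 2.0))

    def test_noiseless_recovery_to_high_precision(self):
        t = np.linspace(0, 8, 9)
        truth = GrowthFit(n0=2e5, rate=0.31)
        fit = fit_exponential_growth(GrowthCurve(t, np.asarray(truth.predict(t))))
        assert fit.rate == pytest.approx(truth.rate, rel=1e-9)

    def test_non_increasing_times_rejected(self):
        with pytest.raises(RateError):
            GrowthCurve(np.array([0, 1, 1.0]), np.array([1e5, 2e5, 3e5]))

    def test_noisy_recovery_simulation_study(self):
        # 10% count noise, 9 daily samples, triplicate counts per time point
        # (the design the generator emulates): doubling time within 10%
        spec = get_preset("serum")
        truth_hours = spec.doubling_time_hours
        ok = 0
        n_sim = 200
        for seed in range(n_sim):
            df, _ = simulate_growth(spec, days=np.arange(9.0), n_replicates=3, seed=seed)
            mean = df.groupby("time_days")["cell_count"].mean()
            fit = fit_exponential_growth(
                GrowthCurve(mean.index.to_numpy(dtype=float), mean.to_numpy())
            )
            if abs(fit.doubling_time_hours - truth_hours) / truth_hours < 0.10:
                ok += 1
        assert ok / n_sim >= 0.95


class TestIntegratedCellDays:
    def test_constant_population(self):
        assert integrated_cell_days(GrowthFit(1e5, 0.0), 0, 2) == pytest.approx(2e5)

    def test_matches_numerical_quadrature(self):
        fit = GrowthFit(n0=1e5, rate=math.log(2) / 2)
        expected, _ = quad(lambda t: fit.predict(t), 0, 2)
        got = integrated_cell_days(fit, 0, 2)
        assert got == pytest.approx(expected, rel=1e-9)
        assert got == pytest.approx(2.885e5, rel=1e-3)

    def test_linearity_in_n0(self):
        a = integrated_cell_days(GrowthFit(1e5, 0.4), 0, 3)
        b = integrated_cell_days(GrowthFit(2e5, 0.4), 0, 3)
        assert b == pytest.approx(2 * a)

    def test_additive_over_adjacent_intervals(self):
        fit = GrowthFit(1.3e5, 0.27)
        whole = integrated_cell_days(fit, 0, 4)
        parts = integrated_cell_days(fit, 0, 1.7) + integrated_cell_days(fit, 1.7, 4)
        assert whole == pytest.approx(parts, rel=1e-12)

    def test_continuous_at_zero_rate(self):
        lim = integrated_cell_days(GrowthFit(1e5, 0.0), 0, 2)
        near = integrated_cell_days(GrowthFit(1e5, 1e-14), 0, 2)
        assert near == pytest.approx(lim, rel=1e-9)


class TestExchangeRate:
    def test_hand_unit_calculation(self):
        # -100 uM over 2 mL is -0.2 umol = -2e8 fmol; over 2e5 cell-days
        # that is -1000 fmol/cell/day (consumption)
        exp = ExchangeExperiment("c", "glutamine", 100.0, 0.0, 2.0, 0.0, 2.0)
        fit = GrowthFit(n0=1e5, rate=0.0)  # 2e5 cell-days over 2 days
        assert exchange_rate(exp, fit) == pytest.approx(-1000.0)

    def test_zero_delta_gives_zero_rate(self):
        exp = ExchangeExperiment("c", "glutamine", 100.0, 100.0, 2.0, 0.0, 2.0)
        assert exchange_rate(exp, GrowthFit(1e5, 0.3)) == 0.0

    def test_consumption_is_negative_release_positive(self):
        fit = GrowthFit(1e5, 0.2)
        eat = ExchangeExperiment("c", "glutamine", 183.0, 150.0, 2.0, 0.0, 2.0)
        spit = ExchangeExperiment("c", "glutamate", 192.0, 210.0, 2.0, 0.0, 2.0)
        assert exchange_rate(eat, fit) < 0 < exchange_rate(spit, fit)

    def test_round_trip_with_simulator(self):
        spec = get_preset("serum")
        exchange, growth, truth = simulate_media_exchange(spec, seed=0)
        rates = compute_rates(growth, exchange)
        merged = rates.merge(truth.truth, on=["culture_id", "metabolite"])
        assert len(merged) == len(truth.truth) > 0
        assert merged["rate_fmol_per_cell_day"].to_numpy() == pytest.approx(
            merged["flux_fmol_per_cell_day"].to_numpy(), rel=1e-9
        )
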