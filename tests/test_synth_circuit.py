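"""Circuit simulator: fixed point, noise layers, measurement rendering."""

import numpy as np
import pytest

from duotune import (
    CircuitParams,
    MeasurementParams,
    deterministic_reporter,
    lac_like,
    simulate_control_sample,
    simulate_flow_sample,
    simulate_population,
    tet_like,
)
from duotune.synth_circuit import active_fraction, promoter_activity


def bisect_fixed_point(params: CircuitParams, inducer: float, n: float, tol: float = 1e-12):
    """Independent bisection oracle for G = N*alpha*a(r_ratio*G*rho)."""
    rho = active_fraction(inducer, params)

    def rhs(g):
        return n * params.alpha * promoter_activity(params.r_ratio * g * rho, params)

    lo, hi = 0.0, n * params.alpha
    if hi == 0:
        return 0.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if rhs(mid) > mid:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(1.0, hi):
            break
    return 0.5 * (lo + hi)


class TestDeterministicSkeleton:
    def test_no_production_gives_zero_reporter(self):
        params = CircuitParams(mode="constitutive_repressor", alpha=0.0, burst=0.0)
        pop = simulate_population(params, inducer=10.0, n_cells=500, seed=0)
        assert np.all(pop.reporter == 0.0)

    def test_constitutive_strong_repression_closed_form(self):
        # R0*rho >> K_R with basal 0.1: activity = 0.1 + 0.9/(1+(R0*rho/K_R)^h)
        params = CircuitParams(
            mode="constitutive_repressor",
            alpha=1000.0,
            basal=0.1,
            K_R=10.0,
            hill_R=1.0,
            R0=1e6,
            N_mean=5,
            N_disp=2.0,
            burst=0.0,
            size_cv2=0.0,
        )
        rho = 1.0  # zero inducer
        expected_activity = 0.1 + 0.9 / (1.0 + (1e6 * rho / 10.0) ** 1.0)
        pop = simulate_population(params, inducer=0.0, n_cells=2000, seed=3)
        expected = pop.copy_number * 1000.0 * expected_activity
        np.testing.assert_allclose(pop.reporter, expected, rtol=1e-12)

    def test_autoregulated_sqrt_scaling_in_copy_number(self):
        # strong repression, basal=0, hill_R=1: G ~ sqrt(N*alpha*K_R/(r*rho))
        params = CircuitParams(
            mode="autoregulated", alpha=1e4, basal=0.0, K_R=5.0, hill_R=1.0, r_ratio=2.0
        )
        g4 = deterministic_reporter(params, 0.0, 4)
        g16 = deterministic_reporter(params, 0.0, 16)
        elasticity = np.log(g16 / g4) / np.log(16 / 4)
        assert elasticity == pytest.approx(0.5, abs=0.01)
        approx = np.sqrt(4 * 1e4 * 5.0 / 2.0)
        assert g4 == pytest.approx(approx, rel=0.02)

    def test_fixed_point_matches_bisection_oracle_across_sweep(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            params = CircuitParams(
                mode="autoregulated",
                alpha=float(rng.uniform(10, 1e5)),
                basal=float(rng.uniform(0, 0.3)),
                K_R=float(rng.uniform(0.5, 100)),
                hill_R=float(rng.uniform(1, 4)),
                Kd_I=float(rng.uniform(1, 100)),
                hill_I=float(rng.uniform(1, 4)),
                r_ratio=float(rng.uniform(0.1, 5)),
            )
            inducer = float(rng.uniform(0, 200))
            n = int(rng.integers(1, 40))
            got = deterministic_reporter(params, inducer, n)
            want = bisect_fixed_point(params, inducer, n)
            assert got == pytest.approx(want, rel=1e-8)

    def test_dosage_compensation_elasticity(self):
        auto = CircuitParams(mode="autoregulated", alpha=1e4, basal=0.0, K_R=5.0, hill_R=1.0)
        const = CircuitParams(mode="constitutive_repressor", alpha=1e4, R0=100.0, K_R=5.0)
        eps = 1e-4
        for params, bound in [(auto, "lt"), (const, "eq")]:
            g1 = deterministic_reporter(params, 0.0, 10.0)
            g2 = deterministic_reporter(params, 0.0, 10.0 * (1 + eps))
            elasticity = np.log(g2 / g1) / np.log(1 + eps)
            if bound == "lt":
                assert elasticity < 1.0
            else:
                assert elasticity == pytest.approx(1.0, abs=1e-6)

    def test_halving_copy_number_drops_less_with_feedback(self):
        auto = CircuitParams(mode="autoregulated", alpha=1e4, basal=0.0, K_R=5.0, hill_R=1.0)
        const = CircuitParams(mode="constitutive_repressor", alpha=1e4, R0=100.0)
        drop_auto = 1 - deterministic_reporter(auto, 0.0, 5) / deterministic_reporter(auto, 0.0, 10)
        drop_const = 1 - deterministic_reporter(const, 0.0, 5) / deterministic_reporter(const, 0.0, 10)
        assert drop_auto < drop_const

    def test_monotone_dose_response_deterministic_limit(self):
        ladder = [0.0, 2.0, 4.5, 10.0, 22.4, 50.0, 111.8, 250.0, 559.0, 1250.0]
        for params in (lac_like(), CircuitParams(mode="constitutive_repressor", R0=50.0, Kd_I=40.0)):
            g = [deterministic_reporter(params, i, 10) for i in ladder]
            assert np.all(np.diff(g) >= 0)

    def test_inducer_affinity_gap_exceeds_three_orders(self):
        # ATc-like Kd in nM vs IPTG-like Kd in uM
        atc_nM = tet_like().Kd_I
        iptg_nM = lac_like().Kd_I * 1000.0
        assert iptg_nM / atc_nM > 1000.0


class TestPopulationStochastics:
    def test_identical_seed_reproduces_population(self):
        a = simulate_population(lac_like(), 50.0, 5000, seed=7)
        b = simulate_population(lac_like(), 50.0, 5000, seed=7)
        np.testing.assert_array_equal(a.reporter, b.reporter)
        np.testing.assert_array_equal(a.copy_number, b.copy_number)
        np.testing.assert_array_equal(a.cell_size, b.cell_size)

    def test_population_mean_converges_to_deterministic_value(self):
        params = lac_like(burst=0.0, size_cv2=0.0, N_disp=0.0)
        pop = simulate_population(params, 100.0, 1000, seed=1)
        g_det = deterministic_reporter(params, 100.0, round(params.N_mean))
        np.testing.assert_allclose(pop.reporter, g_det, rtol=1e-10)

    def test_invalid_params_name_violated_invariant(self):
        with pytest.raises(ValueError, match="basal"):
            CircuitParams(basal=1.5)
        with pytest.raises(ValueError, match="Hill"):
            CircuitParams(hill_R=0.5)
        with pytest.raises(ValueError, match="N_mean"):
            CircuitParams(N_mean=0.0)
        with pytest.raises(ValueError, match="mode"):
            CircuitParams(mode="oscillator")

    def test_size_factor_mean_and_cv2(self):
        pop = simulate_population(lac_like(size_cv2=0.1), 0.0, 200_000, seed=5)
        s = pop.cell_size
        assert s.mean() == pytest.approx(1.0, abs=0.01)
        assert s.var() / s.mean() ** 2 == pytest.approx(0.1, rel=0.05)


class TestFlowSample:
    def test_default_event_count_is_30000(self, measurement):
        pop = simulate_population(lac_like(), 50.0, 30_000, seed=0)
        table = simulate_flow_sample(pop, measurement, seed=1)
        assert table.n_events == 30_000

    def test_noise_free_measurement_is_identity(self):
        meas = MeasurementParams(
            autofluorescence=0.0,
            instrument_cv=0.0,
            maturation_fl1=1.0,
            debris_fraction=0.0,
        )
        pop = simulate_population(lac_like(), 50.0, 5000, seed=2)
        table = simulate_flow_sample(pop, meas, n_events=5000, seed=3)
        np.testing.assert_array_equal(table.column("fl1_area"), pop.reporter)

    def test_debris_count_is_binomial(self):
        meas = MeasurementParams(debris_fraction=0.05)
        pop = simulate_population(lac_like(), 50.0, 2000, seed=0)
        n_events, n_seeds = 30_000, 100
        counts = [
            simulate_flow_sample(pop, meas, n_events=n_events, seed=s).is_debris.sum()
            for s in range(n_seeds)
        ]
        expected = n_events * 0.05
        se = np.sqrt(n_events * 0.05 * 0.95 / n_seeds)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_resampling_when_events_exceed_cells(self, measurement):
        pop = simulate_population(lac_like(), 50.0, 100, seed=0)
        table = simulate_flow_sample(pop, measurement, n_events=1000, seed=1)
        assert table.n_events == 1000


class TestControlSample:
    def test_zero_autofluorescence_gives_zero_fl1(self):
        meas = MeasurementParams(autofluorescence=0.0, instrument_cv=0.0, debris_fraction=0.0)
        table = simulate_control_sample(meas, n_events=500, seed=0)
        np.testing.assert_array_equal(table.column("fl1_area"), 0.0)

    def test_mean_tracks_autofluorescence_per_size(self):
        meas = MeasurementParams(autofluorescence=50.0, debris_fraction=0.0)
        means = [
            simulate_control_sample(meas, n_events=10_000, seed=s, size_cv2=0.05)
            .column("fl1_area")
            .mean()
            for s in range(5)
        ]
        # E[fl1] = autofluorescence * E[s] = 50; SE over the pooled draws
        se = 50.0 * np.sqrt(0.05) / np.sqrt(5 * 10_000)
        assert abs(np.mean(means) - 50.0) < 3 * se + 0.05

    def test_control_flag_set(self, measurement):
        table = simulate_control_sample(measurement, n_events=200, seed=0)
        assert table.is_control
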