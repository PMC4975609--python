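"""Sensitivity functional, plateau time, grid search and noise thresholds."""

import math

import numpy as np
import pytest

from axonsens import (
    NoiseModel,
    ParameterGrid,
    Scenario,
    SequenceParams,
    TissueModel,
    a0_limit,
    contrast,
    delta0_plateau,
    diameter_derivative,
    noise_sigma,
    optimize_sensitivity,
    resolvable_range,
    sensitivity_full,
    sensitivity_map,
    sensitivity_restricted,
    signals_vs_diameter,
)

P_STRONG = SequenceParams(G=0.3, delta=0.036, Delta=0.046, N=1)
PERP = Scenario()
NO_T2 = Scenario(include_T2=False)


class TestDerivative:
    def test_linear_function_exact(self):
        f = lambda a: 3.0 + 2e5 * a
        assert diameter_derivative(f, 5e-6, h=1e-8) == pytest.approx(2e5, rel=1e-9)

    def test_quadratic_function_exact_central(self):
        f = lambda a: (a * 1e6) ** 2
        # central difference has no error for quadratics
        assert diameter_derivative(f, 3e-6, h=0.01e-6) == pytest.approx(6e6, rel=1e-9)

    def test_one_sided_at_origin(self, basis, tissue):
        fn = lambda a: float(
            signals_vs_diameter(P_STRONG, tissue, NO_T2, basis, np.array([a]))[0]
        )
        d0 = diameter_derivative(fn, 0.0)
        assert d0 == pytest.approx(0.0, abs=1e3)  # < 0.001 per um

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            diameter_derivative(lambda a: a, -1e-6)
        with pytest.raises(ValueError):
            diameter_derivative(lambda a: float("nan"), 1e-6)


class TestNoise:
    def test_sigma_values_at_reference_settings(self):
        assert round(noise_sigma(10, 0.120, 0.070), 3) == 0.018
        assert round(noise_sigma(20, 0.120, 0.070), 3) == 0.009
        assert round(noise_sigma(50, 0.120, 0.070), 4) == 0.0036

    def test_zero_te0(self):
        assert noise_sigma(20, 0.0, 0.070) == pytest.approx(1 / 20)

    def test_model_validation(self):
        with pytest.raises(ValueError):
            NoiseModel(SNR=0)


class TestSensitivity:
    def test_t2_weighting_is_multiplicative(self, basis, tissue):
        full = sensitivity_full(P_STRONG, tissue, basis, PERP, a=2e-6)
        bare = sensitivity_full(P_STRONG, tissue, basis, NO_T2, a=2e-6)
        assert full == pytest.approx(bare * math.exp(-P_STRONG.te / tissue.T2), rel=1e-12)

    def test_full_equals_f_times_restricted_without_t2(self, basis, tissue):
        bare = sensitivity_full(P_STRONG, tissue, basis, NO_T2, a=4e-6)
        restr = sensitivity_restricted(P_STRONG, tissue, basis, a=4e-6)
        assert bare == pytest.approx(tissue.f * restr, rel=1e-12)

    def test_zero_diameter_zero_sensitivity(self, basis, tissue):
        assert sensitivity_restricted(P_STRONG, tissue, basis, a=0.0) < 1.0  # 1/m scale

    def test_sensitivity_drops_off_perpendicular(self, basis, tissue):
        perp = sensitivity_full(P_STRONG, tissue, basis, Scenario(theta_deg=0.0), a=2e-6)
        tilted = sensitivity_full(P_STRONG, tissue, basis, Scenario(theta_deg=10.0), a=2e-6)
        assert tilted < perp

    def test_oscillating_loses_less_when_tilted(self, basis, tissue):
        """Low-frequency oscillating sequences retain sensitivity off-axis."""
        p2 = SequenceParams(G=0.3, delta=0.038, Delta=0.048, N=2)
        loss1 = (
            sensitivity_full(P_STRONG, tissue, basis, Scenario(theta_deg=10.0), a=2e-6)
            / sensitivity_full(P_STRONG, tissue, basis, PERP, a=2e-6)
        )
        loss2 = (
            sensitivity_full(p2, tissue, basis, Scenario(theta_deg=10.0), a=2e-6)
            / sensitivity_full(p2, tissue, basis, PERP, a=2e-6)
        )
        assert loss2 > loss1


class TestPlateau:
    def test_small_diameter_flattens_immediately(self, basis):
        tis = TissueModel(a=1e-6)
        for (G, d, N) in [(0.3, 0.010, 1), (0.1, 0.040, 2)]:
            d0, met = delta0_plateau(G, d, N, tis, basis)
            assert met and d0 == 0.0

    def test_infeasible_combination_rejected(self, basis):
        with pytest.raises(ValueError):
            delta0_plateau(0.3, 0.002, 1, TissueModel(a=5e-6), basis)

    def test_larger_pores_need_longer_separation(self, basis):
        d0_small, _ = delta0_plateau(0.3, 0.010, 1, TissueModel(a=4e-6), basis)
        d0_large, _ = delta0_plateau(0.3, 0.010, 1, TissueModel(a=9e-6), basis)
        assert d0_large > d0_small


class TestGridSearch:
    def test_map_optimum_dominates_all_entries(self, basis, tissue):
        grid = ParameterGrid.regular(G_step=0.05, delta_step=0.01, N_values=(1, 2))
        m = sensitivity_map(grid, 4e-6, tissue, PERP, basis)
        assert (m.table["sensitivity_per_um"] >= 0).all()
        assert m.optimum.value_per_um >= m.table["sensitivity_per_um"].max()

    def test_empty_grid_raises(self, basis, tissue):
        grid = ParameterGrid(G_values=(), delta_values=(), N_values=(1,))
        with pytest.raises(ValueError):
            optimize_sensitivity(grid, 4e-6, tissue, PERP, basis)

    def test_ties_break_to_smaller_sequence(self, basis, tissue):
        # G = 0 rows all have zero sensitivity: the first enumerated wins
        grid = ParameterGrid(G_values=(0.0,), delta_values=(0.01, 0.02), N_values=(1, 2))
        best = optimize_sensitivity(grid, 4e-6, tissue, PERP, basis)
        assert (best.params.N, best.params.delta) == (1, 0.01)


class TestNoiseThresholds:
    def test_contrast_zero_epsilon(self, basis, tissue):
        assert contrast(4e-6, 0.0, P_STRONG, tissue, PERP, basis) == 0.0

    def test_contrast_epsilon_equals_a_is_a0_quantity(self, basis, tissue):
        c = contrast(4e-6, 4e-6, P_STRONG, tissue, PERP, basis)
        s = signals_vs_diameter(P_STRONG, tissue, PERP, basis, np.array([0.0, 4e-6]))
        assert c == pytest.approx(abs(s[1] - s[0]), rel=1e-12)

    def test_contrast_invalid_epsilon(self, basis, tissue):
        with pytest.raises(ValueError):
            contrast(1e-6, 2e-6, P_STRONG, tissue, PERP, basis)

    def test_a0_monotone_in_noise(self, basis, tissue):
        lo = a0_limit(NoiseModel(SNR=10), P_STRONG, tissue, PERP, basis)
        hi = a0_limit(NoiseModel(SNR=50), P_STRONG, tissue, PERP, basis)
        assert hi <= lo

    def test_a0_sentinel_when_threshold_unreachable(self, basis, tissue):
        huge = NoiseModel(SNR=1e-3)
        assert a0_limit(huge, P_STRONG, tissue, PERP, basis) is None

    def test_range_vanishing_noise_covers_contrasted_region(self, basis, tissue):
        tiny = NoiseModel(SNR=1e9)
        iv = resolvable_range(1e-6, tiny, P_STRONG, tissue, PERP, basis)
        lo = min(x[0] for x in iv)
        hi = max(x[1] for x in iv)
        assert lo == pytest.approx(1e-6)
        assert hi == pytest.approx(10e-6)

    def test_range_empty_under_huge_noise(self, basis, tissue):
        iv = resolvable_range(1e-6, NoiseModel(SNR=1e-3), P_STRONG, tissue, PERP, basis)
        assert iv == []
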