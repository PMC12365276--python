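"""Fractional Tchebichef polynomial family: closed form, recurrences, weight."""

import math

import numpy as np
import pytest

from frtm import (BasisConfig, DomainError, SampleGrid, SingularityError,
                  analytic_frt, build_basis, frt_recurrence,
                  normalized_initials, normalized_recurrence, weight)
from frtm.basis import frt_coefficients, norm_constants, sqrt_weight


class TestAnalyticForm:
    def test_degree_zero_is_one(self):
        assert analytic_frt(0, 0.7, 0.3) == 1.0

    def test_degree_one_is_one_minus_2t_alpha(self):
        assert analytic_frt(1, 1.0, 0.5) == pytest.approx(0.0, abs=1e-15)
        assert analytic_frt(1, 2.0, 0.6) == pytest.approx(1 - 2 * 0.36)

    def test_degree_two_coefficients_and_value(self):
        # beta_{2,k} expand to (1, -8, 8): 1 - 8 t^a + 8 t^{2a}
        assert frt_coefficients(2) == [1, -8, 8]
        assert analytic_frt(2, 1.0, 0.5) == pytest.approx(-1.0)

    @pytest.mark.parametrize("n", range(1, 9))
    def test_matches_shifted_chebyshev_at_alpha_one(self, n):
        t = np.linspace(0.02, 0.98, 25)
        expected = np.cos(n * np.arccos(1 - 2 * t))
        assert np.max(np.abs(analytic_frt(n, 1.0, t) - expected)) < 1e-10

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            analytic_frt(2, -1.0, 0.5)
        with pytest.raises(DomainError):
            analytic_frt(2, 1.0, 1.5)
        with pytest.raises(DomainError):
            analytic_frt(31, 1.0, 0.5)  # beyond the exact-coefficient cap


class TestRecurrence:
    def test_row_zero_all_ones(self):
        grid = SampleGrid.midpoint(17)
        assert np.all(frt_recurrence(0, 0.9, grid)[0] == 1.0)

    def test_row_two_value(self):
        grid = SampleGrid(t_values=np.array([0.25, 0.5]))
        assert frt_recurrence(2, 1.0, grid)[2, 1] == pytest.approx(-1.0)

    @pytest.mark.parametrize("alpha", [0.5, 0.8, 1.0, 1.5, 2.0])
    def test_matches_analytic_oracle(self, alpha):
        grid = SampleGrid.midpoint(33)
        rows = frt_recurrence(8, alpha, grid)
        worst = max(
            np.max(np.abs(rows[n] - analytic_frt(n, alpha, grid.t_values)))
            for n in range(9)
        )
        assert worst < 1e-9


class TestWeight:
    def test_hand_values(self):
        assert weight(0.6, 2.0) == pytest.approx(1.25)
        assert weight(0.5, 2.0) == pytest.approx(1 / math.sqrt(0.75))

    def test_singularity_and_domain(self):
        with pytest.raises(SingularityError):
            weight(1.0, 1.0)
        with pytest.raises(DomainError):
            weight(-0.2, 1.0)
        with pytest.raises(DomainError):
            weight(0.5, 0.0)

    def test_sqrt_weight_squares_to_weight(self):
        t = np.linspace(0.05, 0.95, 19)
        for alpha in (0.5, 1.0, 2.5):
            assert np.allclose(sqrt_weight(t, alpha) ** 2, weight(t, alpha))


class TestNormalizedFamily:
    def test_initials_hand_values(self):
        grid = SampleGrid(t_values=np.array([0.6]))
        row0, row1 = normalized_initials(grid, 2.0)
        assert row0[0] == pytest.approx(math.sqrt(1.25) / math.sqrt(2))  # 0.790569...
        assert row1[0] == pytest.approx(math.sqrt(1.25) * (1 - 2 * 0.36))  # 0.313050...

    def test_initial_ratio_cancels_weight(self):
        grid = SampleGrid.midpoint(11)
        row0, row1 = normalized_initials(grid, 1.3)
        expect = math.sqrt(2) * (1 - 2 * grid.t_values**1.3)
        assert np.allclose(row1 / row0, expect)

    def test_recurrence_step_oracle(self):
        # sqrt(w(0.6)) * FrT_2(alpha=2, 0.6) with the sqrt(2) carried by c_0
        grid = SampleGrid(t_values=np.array([0.6]))
        rows = np.vstack(normalized_initials(grid, 2.0))
        row2 = normalized_recurrence(rows, 1, grid, 2.0)
        oracle = math.sqrt(1.25) * analytic_frt(2, 2.0, 0.6)
        assert row2[0] == pytest.approx(oracle, abs=1e-12)

    @pytest.mark.parametrize("alpha", [0.5, 1.0, 2.0])
    def test_whole_matrix_equals_weighted_analytic(self, alpha):
        cfg = BasisConfig(alpha=alpha, signal_length=33, max_order=8)
        bm = build_basis(cfg)
        sw = sqrt_weight(bm.grid.t_values, alpha)
        c = norm_constants(8)
        worst = max(
            np.max(np.abs(bm.values[n]
                          - sw * analytic_frt(n, alpha, bm.grid.t_values)
                          / math.sqrt(c[n])))
            for n in range(9)
        )
        assert worst < 1e-9

    def test_requires_two_seed_rows(self):
        grid = SampleGrid.midpoint(5)
        with pytest.raises(DomainError):
            normalized_recurrence(np.ones((1, 5)), 0, grid, 1.0)


class TestBuildBasis:
    def test_row_zero_proportional_to_weight_root(self):
        bm = build_basis(BasisConfig(alpha=1.0, signal_length=8, max_order=7))
        sw = sqrt_weight(bm.grid.t_values, 1.0)
        ratio = bm.values[0] / sw
        assert np.allclose(ratio, ratio[0])
        assert np.all(np.isfinite(bm.values))

    def test_deterministic(self):
        cfg = BasisConfig(alpha=0.8, signal_length=32, max_order=31)
        a, b = build_basis(cfg), build_basis(cfg)
        assert np.array_equal(a.values, b.values)

    @pytest.mark.parametrize("alpha", [0.1, 0.5, 1.0, 2.0, 4.0])
    def test_finite_for_alpha_in_working_range(self, alpha):
        bm = build_basis(BasisConfig(alpha=alpha, signal_length=64, max_order=63))
        assert np.all(np.isfinite(bm.values))

    def test_moderate_order_matrix_has_full_rank(self):
        # beyond roughly order N/2 the tabulated rows alias and the numeric
        # rank drops; at moderate order the rank oracle is clean
        bm = build_basis(BasisConfig(alpha=0.8, signal_length=64, max_order=31))
        assert np.linalg.matrix_rank(bm.values) == 32

    def test_dc_only_basis_allowed(self):
        bm = build_basis(BasisConfig(alpha=1.0, signal_length=16, max_order=0))
        assert bm.shape == (1, 16)

    def test_config_validation(self):
        with pytest.raises(DomainError):
            BasisConfig(alpha=0.0, signal_length=8, max_order=7)
        with pytest.raises(DomainError):
            BasisConfig(alpha=1.0, signal_length=8, max_order=8)
        with pytest.raises(DomainError):
            BasisConfig(alpha=1.0, signal_length=8, max_order=7, grid_epsilon=0.7)

    def test_midpoint_grid_strictly_interior(self):
        grid = SampleGrid.midpoint(100, grid_epsilon=1e-6)
        assert np.all(grid.t_values > 0) and np.all(grid.t_values < 1)
        assert np.all(np.diff(grid.t_values) > 0)
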