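"""Tissue covariance pooling, per-cell covariance, bivariate surfaces."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isoforage import (
    CalibrationSample,
    GridSpec,
    IsotopeSample,
    Raster,
    TissueCov,
    Variogram,
    assignment_surface,
    assignment_surfaces,
    bivariate_density,
    build_cov_field,
    pooled_tissue_covariance,
    validate_calibration,
)
from isoforage.assignment import CovField
from isoforage.errors import ValidationError
from isoforage.isoscape import Isoscape


def cal(area, d13c, d15n, i=0, lon=-75.0, lat=30.0):
    return CalibrationSample(
        id=f"{area}-{i}", year=2007, tissue="epidermis",
        d13C=d13c, d15N=d15n, lon=lon, lat=lat, area=area,
    )


def make_isoscapes(grid, mu_c, mu_n, se_c=0.0, se_n=0.0):
    vario = Variogram("exponential", 0.0, 1.0, 1.0)
    return (
        Isoscape("C", Raster(grid, np.asarray(mu_c, float)),
                 Raster(grid, np.full(grid.shape, se_c)), vario),
        Isoscape("N", Raster(grid, np.asarray(mu_n, float)),
                 Raster(grid, np.full(grid.shape, se_n)), vario),
    )


class TestPooledTissueCovariance:
    def test_identical_groups_average_to_themselves(self, rng):
        base_c = np.array([-18.0, -17.0, -16.5, -17.5])
        base_n = np.array([7.0, 8.0, 8.5, 7.7])
        samples = []
        for area in ("CAN", "MAB", "SAB", "SNWA", "FLKeys", "SWFL"):
            offs = {"CAN": 0.0, "MAB": 1.0, "SAB": 2.0, "SNWA": 3.0,
                    "FLKeys": 4.0, "SWFL": 5.0}[area]
            for i in range(4):
                samples.append(cal(area, base_c[i] + offs, base_n[i] - offs, i))
        tc = pooled_tissue_covariance(samples)
        assert tc.var_c == pytest.approx(base_c.var(ddof=1))
        assert tc.var_n == pytest.approx(base_n.var(ddof=1))
        assert tc.corr == pytest.approx(np.corrcoef(base_c, base_n)[0, 1])

    def test_two_area_toy_matches_hand_computed_means(self):
        g1_c, g1_n = [-18.0, -17.0, -16.0, -15.0], [7.0, 7.5, 9.0, 8.5]
        g2_c, g2_n = [-12.0, -12.5, -11.0, -13.5], [10.0, 11.0, 10.5, 12.0]
        samples = [cal("CAN", c, n, i) for i, (c, n) in enumerate(zip(g1_c, g1_n))]
        samples += [cal("MAB", c, n, i) for i, (c, n) in enumerate(zip(g2_c, g2_n))]
        tc = pooled_tissue_covariance(samples)
        # independent arithmetic, group by group
        v1c, v2c = np.var(g1_c, ddof=1), np.var(g2_c, ddof=1)
        v1n, v2n = np.var(g1_n, ddof=1), np.var(g2_n, ddof=1)
        r1 = np.corrcoef(g1_c, g1_n)[0, 1]
        r2 = np.corrcoef(g2_c, g2_n)[0, 1]
        assert tc.var_c == pytest.approx((v1c + v2c) / 2)
        assert tc.var_n == pytest.approx((v1n + v2n) / 2)
        assert tc.corr == pytest.approx((r1 + r2) / 2)
        assert tc.cov == pytest.approx(tc.corr * np.sqrt(tc.var_c * tc.var_n))

    def test_small_group_named_in_error(self):
        samples = [cal("CAN", -18 + i, 7 + i, i) for i in range(4)]
        samples += [cal("MAB", -15.0, 9.0, 0), cal("MAB", -15.5, 9.5, 1)]
        with pytest.raises(ValidationError, match="MAB"):
            pooled_tissue_covariance(samples)

    def test_implied_matrix_is_psd(self, rng):
        samples = []
        for j, area in enumerate(("CAN", "MAB", "SAB")):
            c = rng.normal(-16 + j, 1.0, 8)
            n = rng.normal(8 + j, 0.8, 8)
            samples += [cal(area, ci, ni, i) for i, (ci, ni) in enumerate(zip(c, n))]
        tc = pooled_tissue_covariance(samples)
        assert np.all(np.linalg.eigvalsh(tc.matrix) >= -1e-12)


class TestCovField:
    GRID = GridSpec(0.0, 3.0, 0.0, 1.0, 1.0)  # 1 x 3 cells

    def test_zero_kriging_error_returns_tissue_matrix(self):
        tc = TissueCov(0.5, 0.4, 0.25)
        iso_c, iso_n = make_isoscapes(self.GRID, np.zeros((1, 3)), np.zeros((1, 3)))
        cf = build_cov_field(tc, iso_c, iso_n)
        np.testing.assert_allclose(cf.vc, 0.5)
        np.testing.assert_allclose(cf.vn, 0.4)
        assert cf.cov == pytest.approx(tc.cov)

    def test_variances_add_per_cell(self):
        tc = TissueCov(0.5, 0.4, 0.1 / np.sqrt(0.5 * 0.4))  # cov exactly 0.1
        iso_c, iso_n = make_isoscapes(
            self.GRID, np.zeros((1, 3)), np.zeros((1, 3)), se_c=0.3, se_n=0.2
        )
        cf = build_cov_field(tc, iso_c, iso_n)
        np.testing.assert_allclose(cf.vc, 0.59)
        np.testing.assert_allclose(cf.vn, 0.44)
        assert cf.cov == pytest.approx(0.1)

    def test_every_cell_positive_definite_on_random_fixture(self, rng):
        grid = GridSpec(0.0, 10.0, 0.0, 10.0, 1.0)
        tc = TissueCov(0.5, 0.4, 0.9)
        iso_c, iso_n = make_isoscapes(
            grid,
            rng.normal(-15, 2, grid.shape),
            rng.normal(8, 2, grid.shape),
        )
        # random non-negative se fields
        object.__setattr__(iso_c.se, "values", np.abs(rng.normal(0, 1, grid.shape)))
        object.__setattr__(iso_n.se, "values", np.abs(rng.normal(0, 1, grid.shape)))
        cf = build_cov_field(tc, iso_c, iso_n)
        assert np.all(cf.det()[grid.mask] > 0)


class TestBivariateDensity:
    def test_mode_of_standard_normal(self):
        val = bivariate_density((0.0, 0.0), (0.0, 0.0), np.eye(2))
        assert val == pytest.approx(1.0 / (2 * np.pi), rel=1e-12)

    def test_symmetry_about_the_mean(self):
        sigma = np.array([[2.0, 0.5], [0.5, 1.0]])
        mu = (1.0, -1.0)
        d = (0.7, 0.3)
        up = bivariate_density((mu[0] + d[0], mu[1] + d[1]), mu, sigma)
        dn = bivariate_density((mu[0] - d[0], mu[1] - d[1]), mu, sigma)
        assert up == pytest.approx(dn, rel=1e-12)

    def test_hand_computed_quadratic_form(self):
        # sigma = [[2, .5], [.5, 1]]: det = 1.75,
        # inv = [[1, -.5], [-.5, 2]] / 1.75; x = (1, 0) gives quad = 1/1.75
        sigma = np.array([[2.0, 0.5], [0.5, 1.0]])
        expected = np.exp(-0.5 * (1.0 / 1.75)) / (2 * np.pi * np.sqrt(1.75))
        assert bivariate_density((1.0, 0.0), (0.0, 0.0), sigma) == pytest.approx(
            expected, rel=1e-12
        )

    def test_singular_sigma_rejected(self):
        with pytest.raises(ValidationError):
            bivariate_density((0, 0), (0, 0), np.array([[1.0, 1.0], [1.0, 1.0]]))


def three_cell_setup():
    grid = GridSpec(0.0, 3.0, 0.0, 1.0, 1.0)
    mu_c = np.array([[-18.0, -14.0, -10.0]])
    mu_n = np.array([[6.0, 10.0, 14.0]])
    iso_c, iso_n = make_isoscapes(grid, mu_c, mu_n)
    cov = CovField(grid, np.ones(grid.shape), np.ones(grid.shape), 0.0)
    return grid, iso_c, iso_n, cov


class TestAssignmentSurface:
    def test_three_cell_toy_density_ratios(self):
        _, iso_c, iso_n, cov = three_cell_setup()
        s = IsotopeSample("t", 2007, "epidermis", -14.0, 10.0)
        surf = assignment_surface(s, iso_c, iso_n, cov)
        np.testing.assert_allclose(
            surf.raster.values, [[np.exp(-16.0), 1.0, np.exp(-16.0)]], rtol=1e-12
        )

    def test_mode_at_matching_mean(self):
        _, iso_c, iso_n, cov = three_cell_setup()
        s = IsotopeSample("t", 2007, "epidermis", -18.0, 6.0)
        surf = assignment_surface(s, iso_c, iso_n, cov)
        assert surf.raster.values[0, 0] == 1.0

    def test_normalization_bounds(self, rng):
        grid = GridSpec(0.0, 8.0, 0.0, 8.0, 1.0)
        iso_c, iso_n = make_isoscapes(
            grid, rng.normal(-15, 2, grid.shape), rng.normal(8, 2, grid.shape),
            se_c=0.2, se_n=0.2,
        )
        cov = build_cov_field(TissueCov(0.4, 0.3, 0.1), iso_c, iso_n)
        samples = [
            IsotopeSample(f"t{i}", 2007, "epidermis",
                          rng.normal(-15, 2), rng.normal(8, 2))
            for i in range(20)
        ]
        for surf in assignment_surfaces(samples, iso_c, iso_n, cov):
            v = surf.raster.masked_values()
            assert v.max() == 1.0
            assert v.min() >= 0.0

    def test_monotone_in_mahalanobis_distance_with_constant_cov(self):
        _, iso_c, iso_n, cov = three_cell_setup()
        s = IsotopeSample("t", 2007, "epidermis", -17.0, 7.0)
        surf = assignment_surface(s, iso_c, iso_n, cov).raster.values[0]
        d2 = (np.array([-18.0, -14.0, -10.0]) + 17.0) ** 2 + (
            np.array([6.0, 10.0, 14.0]) - 7.0
        ) ** 2
        order = np.argsort(d2)
        assert np.all(np.diff(surf[order]) <= 1e-15)

    @given(scale=st.floats(1e-6, 1e6))
    @settings(max_examples=30, derandomize=True)
    def test_scale_invariance_of_normalization(self, scale):
        # multiplying every density by a constant cannot change the surface:
        # normalization divides by the max, so the ratio is unchanged
        logd = np.array([[-3.0, -1.0, -40.0]])
        a = np.exp(logd - logd.max())
        b = scale * np.exp(logd)
        b = b / b.max()
        np.testing.assert_allclose(a, b, rtol=1e-9)


class TestValidateCalibration:
    def test_animal_at_argmax_scores_one(self):
        grid, iso_c, iso_n, cov = three_cell_setup()
        animal = CalibrationSample(
            id="t", year=2007, tissue="epidermis", d13C=-14.0, d15N=10.0,
            lon=1.5, lat=0.5, area="SAB",
        )
        surf = assignment_surfaces([animal], iso_c, iso_n, cov)
        out = validate_calibration(surf, [animal])
        assert out.values["t"] == 1.0
        assert out.median == 1.0

    def test_location_on_masked_cell_snaps_to_neighbor(self):
        mask = np.array([[True, False, True]])
        grid = GridSpec(0.0, 3.0, 0.0, 1.0, 1.0, mask=mask)
        mu_c = np.array([[-18.0, -14.0, -10.0]])
        mu_n = np.array([[6.0, 10.0, 14.0]])
        iso_c, iso_n = make_isoscapes(grid, mu_c, mu_n)
        cov = CovField(grid, np.ones(grid.shape), np.ones(grid.shape), 0.0)
        animal = CalibrationSample(
            id="t", year=2007, tissue="epidermis", d13C=-18.0, d15N=6.0,
            lon=1.5, lat=0.5, area="SAB",  # falls on the masked middle cell
        )
        surf = assignment_surfaces([animal], iso_c, iso_n, cov)
        out = validate_calibration(surf, [animal])
        assert out.values["t"] == pytest.approx(1.0)  # snaps west to the mode
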