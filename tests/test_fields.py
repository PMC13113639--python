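"""Clean-field generators: grids, Gaussian/wave/step modalities, normalization."""

import numpy as np
import pytest

import pgrecon as pg
from pgrecon.fields import MIN_GRID_SIDE


class TestMakeGrid:
    def test_endpoints_and_evenness(self):
        spec = pg.GridSpec(9, 9)
        x, y = pg.make_grid(spec)
        assert x[0] == -1.0 and x[-1] == 1.0
        assert np.allclose(np.diff(x), 0.25)
        assert np.allclose(x, y)

    def test_spacing_closed_form(self):
        spec = pg.GridSpec(64, 64)
        assert spec.spacing[0] == pytest.approx(2.0 / 63)
        x, _ = pg.make_grid(spec)
        assert len(x) == 64

    def test_rejects_too_coarse_grid(self):
        with pytest.raises(ValueError):
            pg.GridSpec(MIN_GRID_SIDE - 1, 64)


class TestGaussianField:
    def test_peak_value_at_center_node(self, grid64):
        # center placed exactly on a grid node -> exp(0) = 1 before scaling
        x, _ = pg.make_grid(grid64)
        f = pg.gaussian_field(grid64, center=(x[20], x[40]), alpha=9.0,
                              normalization="none")
        assert f.values[20, 40] == pytest.approx(1.0)
        assert f.values.argmax() == 20 * 64 + 40

    def test_closed_form_half_value(self, grid64):
        # at squared distance ln2 from the center, exp(-1*ln2) = 1/2
        x, _ = pg.make_grid(grid64)
        cx = x[10]
        f = pg.gaussian_field(grid64, center=(cx, 0.0), alpha=1.0,
                              normalization="none")
        d = np.sqrt(np.log(2.0))
        val = np.exp(-1.0 * ((cx + d - cx) ** 2))
        assert val == pytest.approx(0.5)
        # verify the sampled field against the closed form at every node
        X, Y = np.meshgrid(x, x, indexing="ij")
        expected = np.exp(-((X - cx) ** 2 + Y**2))
        np.testing.assert_allclose(f.values, expected, atol=1e-12)

    def test_support_shrinks_with_alpha(self, grid64):
        wide = pg.gaussian_field(grid64, alpha=4.0)
        tight = pg.gaussian_field(grid64, alpha=400.0)
        assert (tight.values > 0.5).sum() < (wide.values > 0.5).sum()

    def test_radial_symmetry_at_equidistant_nodes(self, grid64):
        f = pg.gaussian_field(grid64, center=(0.0, 0.0), alpha=10.0,
                              normalization="none")
        # nodes mirrored through the center are equidistant
        assert abs(f.values[10, 20] - f.values[-11, -21]) < 1e-12

    def test_rejects_nonpositive_alpha(self, grid64):
        with pytest.raises(ValueError):
            pg.gaussian_field(grid64, alpha=0.0)


class TestWaveField:
    def test_unit_value_where_phase_hits_peak(self, grid64):
        # f.x = 0 along x=0 with fy=0; phase pi/2 -> sin = 1
        f = pg.wave_field(grid64, freq=(1.0, 0.0), phase=np.pi / 2)
        x, _ = pg.make_grid(grid64)
        j0 = np.argmin(np.abs(x))  # x=0 is not a node at n=64; use n=65 grid
        g65 = pg.GridSpec(65, 65)
        f65 = pg.wave_field(g65, freq=(1.0, 0.0), phase=np.pi / 2)
        assert f65.values[32, 5] == pytest.approx(1.0)

    def test_constant_along_orthogonal_axis(self, grid64):
        f = pg.wave_field(grid64, freq=(1.0, 0.0))
        assert np.ptp(f.values, axis=1).max() == 0.0

    def test_spatial_mean_half_over_whole_periods(self, grid64):
        f = pg.wave_field(grid64, freq=(1.0, 0.0), phase=0.0)
        assert f.values.mean() == pytest.approx(0.5, abs=0.02)

    def test_rejects_degenerate_constant(self, grid64):
        with pytest.raises(ValueError):
            pg.wave_field(grid64, freq=(0.0, 0.0))


class TestStepField:
    def test_binarization_at_two_levels(self, grid64):
        f = pg.step_field(grid64, "gaussian", levels=2)
        assert set(np.unique(f.values)) == {0.0, 1.0}

    def test_five_levels_on_uniform_lattice(self, grid64):
        f = pg.step_field(grid64, "square", levels=5)
        uniq = np.unique(f.values)
        assert len(uniq) <= 5
        assert np.all(np.isin(uniq, [0.0, 0.25, 0.5, 0.75, 1.0]))

    def test_quantization_idempotent(self, grid64):
        f = pg.step_field(grid64, "gaussian", levels=4)
        again = pg.step_field(grid64, levels=4, base=f)
        np.testing.assert_array_equal(f.values, again.values)

    def test_rejects_single_level(self, grid64):
        with pytest.raises(ValueError):
            pg.step_field(grid64, levels=1)


class TestNormalizeUnitRange:
    def test_two_point_rescale(self, grid16):
        v = np.full(grid16.shape, 2.0)
        v[0, 0] = 4.0
        f = pg.Field(v, grid16)
        out = pg.normalize_unit_range(f)
        assert out.values.min() == 0.0 and out.values.max() == 1.0

    def test_identity_when_already_unit_range(self, grid16, rng):
        v = rng.uniform(size=grid16.shape)
        v.flat[0], v.flat[-1] = 0.0, 1.0
        f = pg.Field(v, grid16)
        np.testing.assert_array_equal(pg.normalize_unit_range(f).values, v)

    def test_affine_formula(self, grid16):
        v = np.zeros(grid16.shape)
        v[0, 0], v[0, 1], v[0, 2] = -1.0, 0.0, 3.0
        out = pg.normalize_unit_range(pg.Field(v, grid16)).values
        assert out[0, 0] == 0.0
        assert out[0, 1] == pytest.approx(0.25)
        assert out[0, 2] == 1.0

    def test_rejects_constant_field(self, grid16):
        with pytest.raises(ValueError):
            pg.normalize_unit_range(pg.Field(np.ones(grid16.shape), grid16))


def test_all_generators_finite_and_unit_span(grid64):
    fields = [
        pg.gaussian_field(grid64, alpha=20.0),
        pg.step_field(grid64, "gaussian", 5),
        pg.step_field(grid64, "square", 3),
    ]
    for f in fields:
        assert np.all(np.isfinite(f.values))
        assert f.values.min() == pytest.approx(0.0, abs=1e-9)
        assert f.values.max() == pytest.approx(1.0, abs=1e-9)


def test_field_spec_round_trip(grid64):
    f = pg.gaussian_field(grid64, center=(0.2, -0.1), alpha=30.0)
    again = pg.evaluate_field_spec(grid64, f.spec)
    np.testing.assert_array_equal(f.values, again.values)
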