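"""Phantom rasterization, forward dipole physics and echo simulation."""

import numpy as np
import pytest

from qsmfid.core import GridMeta, wrap_phase
from qsmfid.phantom import (
    DEFAULT_TES_S,
    InclusionSpec,
    PhantomSpec,
    default_phantom,
    dephasing_map,
    forward_field,
    rasterize_chi_highres,
    rasterize_phantom,
    simulate_echoes,
)
from .conftest import make_body_phantom


def _grid(n=32, vox=(1.0, 1.0, 2.0)):
    return GridMeta.centered((n, n, n // 2), vox)


class TestRasterize:
    def test_no_inclusions_gives_uniform_background(self):
        grid = _grid()
        spec = make_body_phantom(grid, [], body_semi=(14, 14, 14))
        spec = spec.replace(background_chi=1.5)
        chi, m0, r2s, truth = rasterize_phantom(spec.replace(
            body=spec.body.__class__("ellipsoid", (0, 0, 0), (14, 14, 14),
                                     chi=1.5, m0=0.0, label="tissue"),
            prostate=spec.prostate.__class__("ellipsoid", (0, 0, 0), (5, 5, 5),
                                             chi=1.5, m0=0.0, label="tissue"),
        ))
        assert np.allclose(chi, 1.5)

    def test_subvoxel_sphere_partial_volume_matches_closed_form(self):
        # 0.15 mm gold sphere centered in a 1 x 1 x 2 mm voxel: the voxel
        # chi is the analytic volume fraction times the material value
        grid = _grid(16)
        sphere = InclusionSpec("sphere", (0.5, 0.5, -1.0), (0.15,),
                               chi=-36.0, m0=0.0, label="gold")
        spec = make_body_phantom(grid, [], body_semi=(7, 7, 7),
                                 prostate_semi=(4, 4, 5))
        spec = spec.replace(inclusions=[sphere], oversample=8)
        # place prostate around the marker so validation passes
        spec = spec.replace(prostate=InclusionSpec(
            "ellipsoid", (0.5, 0.5, -1.0), (4, 4, 5), m0=1.0, label="tissue"))
        chi, _, _, truth = rasterize_phantom(spec)
        idx = tuple(np.round(grid.world_to_voxel((0.5, 0.5, -1.0))).astype(int))
        expected = -36.0 * (4.0 / 3.0 * np.pi * 0.15**3) / 2.0
        # oversample-8 sampling resolves the fraction to a few percent
        assert chi[idx] == pytest.approx(expected, rel=0.15)
        assert truth.marker_positions.shape == (1, 3)

    def test_integrated_chi_conserved_for_resolved_sphere(self):
        grid = _grid(32, (1.0, 1.0, 1.0))
        sphere = InclusionSpec("sphere", (0.0, 0.0, 0.0), (2.0,),
                               chi=-36.0, m0=0.0, label="gold")
        spec = make_body_phantom(grid, [], body_semi=(14, 14, 7),
                                 prostate_semi=(5, 5, 5))
        spec = spec.replace(inclusions=[sphere], oversample=4)
        chi, _, _, _ = rasterize_phantom(spec)
        vox_vol = np.prod(grid.voxel_size)
        total = chi.sum() * vox_vol
        expected = -36.0 * 4.0 / 3.0 * np.pi * 2.0**3
        assert total == pytest.approx(expected, rel=0.01)

    def test_inclusion_outside_grid_raises_with_name(self):
        grid = _grid(16)
        far = InclusionSpec("sphere", (200.0, 0.0, 0.0), (1.0,), label="other")
        spec = make_body_phantom(grid, [], body_semi=(7, 7, 7),
                                 prostate_semi=(4, 4, 5))
        spec = spec.replace(inclusions=[far])
        with pytest.raises(ValueError, match="inclusion_0"):
            rasterize_phantom(spec)

    def test_gold_outside_prostate_rejected(self):
        grid = _grid(32)
        stray = InclusionSpec("sphere", (0.0, 13.0, 0.0), (1.0,),
                              chi=-36.0, m0=0.0, label="gold")
        with pytest.raises(ValueError, match="prostate"):
            make_body_phantom(grid, [stray], body_semi=(14, 14, 14))


class TestForwardField:
    def test_uniform_chi_gives_zero_field(self, small_grid):
        # D(0) = 0: the mean field of a periodic uniform distribution
        # vanishes, so the unpadded (periodic) convolution returns zero
        chi = np.full(small_grid.shape, 3.0)
        field = forward_field(chi, small_grid, pad_factor=1.0)
        assert np.allclose(field, 0.0, atol=1e-10)

    def test_sphere_matches_analytic_dipole(self):
        # external field of a uniformly susceptible sphere:
        # (chi/3) (a/r)^3 (3 cos^2 t - 1), Lorentz convention
        n, a = 96, 4.0
        grid = GridMeta.centered((n, n, n), (1.0, 1.0, 1.0))
        sphere = InclusionSpec("sphere", (0, 0, 0), (a,), chi=1.0, label="other")
        spec = make_body_phantom(grid, [], body_semi=(45, 45, 45))
        spec = spec.replace(inclusions=[sphere], oversample=4)
        chi, _, _, _ = rasterize_phantom(spec)
        field = forward_field(chi, grid)
        x = grid.axis_coords(0)
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        r = np.sqrt(X**2 + Y**2 + Z**2)
        with np.errstate(divide="ignore", invalid="ignore"):
            cos2 = np.where(r > 0, (Z / np.maximum(r, 1e-9)) ** 2, 0.0)
            analytic = (1.0 / 3.0) * (a / np.maximum(r, 1e-9)) ** 3 * (3 * cos2 - 1)
        sel = (r >= 3 * a) & (r <= n / 2 - 8)
        scale = np.abs(analytic[sel]).max()
        err = np.abs(field[sel] - analytic[sel]) / scale
        assert err.max() < 0.05
        # interior field vanishes in the Lorentz convention (threshold
        # relative to the unit susceptibility contrast)
        assert np.abs(field[r < 0.5 * a]).max() < 0.005

    def test_mirror_symmetry(self, small_grid):
        rng = np.random.default_rng(0)
        chi = np.zeros(small_grid.shape)
        chi[20:28, 24:30, 30:34] = rng.normal(size=(8, 6, 4))
        chi_m = chi[::-1, ::-1, ::-1]
        f = forward_field(chi, small_grid)
        f_m = forward_field(chi_m, small_grid)
        # index reversal mirrors the field exactly (even kernel); the
        # small tolerance absorbs residual pad wrap-around
        assert np.allclose(f[::-1, ::-1, ::-1], f_m, atol=5e-6)

    def test_linearity(self, small_grid):
        rng = np.random.default_rng(1)
        a = rng.normal(size=small_grid.shape)
        b = rng.normal(size=small_grid.shape)
        fa = forward_field(a, small_grid)
        fb = forward_field(b, small_grid)
        fab = forward_field(2.0 * a - 0.5 * b, small_grid)
        assert np.allclose(fab, 2.0 * fa - 0.5 * fb, atol=1e-9)


class TestDephasing:
    def test_uniform_field_no_dephasing(self):
        grid = _grid(16)
        o = 2
        chi_hi = np.zeros(tuple(n * o for n in grid.shape))
        r2p = dephasing_map(chi_hi, grid, oversample=o)
        assert np.allclose(r2p, 0.0)

    def test_marker_neighborhood_dephases_more_than_far_voxels(self):
        spec = default_phantom(noise_sigma=0.0)
        spec = spec.replace(grid=GridMeta.centered((64, 64, 24), (1, 1, 2)),
                            inclusions=[spec.inclusions[0]],
                            body=InclusionSpec("ellipsoid", (0, 0, 0),
                                               (28, 28, 22), m0=1, r2star=30,
                                               label="tissue"))
        chi_hi, fine = rasterize_chi_highres(spec)
        r2p = dephasing_map(chi_hi, spec.grid, spec.oversample)
        center = np.round(spec.grid.world_to_voxel(spec.inclusions[0].center)).astype(int)
        near = r2p[center[0] - 2:center[0] + 3,
                   center[1] - 2:center[1] + 3,
                   center[2] - 1:center[2] + 2].max()
        far = r2p[center[0] + 8:center[0] + 12,
                  center[1] + 8:center[1] + 12, center[2]].max()
        assert near > 10 * far

    def test_r2prime_linear_in_b0(self):
        grid = _grid(16)
        rng = np.random.default_rng(2)
        o = 2
        chi_hi = np.zeros(tuple(n * o for n in grid.shape))
        chi_hi[10:14, 10:14, 8:10] = rng.normal(size=(4, 4, 2))
        r1 = dephasing_map(chi_hi, grid, o)
        grid2 = GridMeta(grid.shape, grid.voxel_size, grid.origin,
                         grid.b0_axis, b0=3.0)
        r2 = dephasing_map(chi_hi, grid2, o)
        assert np.allclose(r2, 2.0 * r1, rtol=1e-6)

    def test_oversample_one_rejected(self):
        grid = _grid(8)
        with pytest.raises(ValueError):
            dephasing_map(np.zeros(grid.shape), grid, oversample=1)


class TestSimulateEchoes:
    def test_zero_field_magnitude_decay_and_phase(self):
        grid = _grid(8)
        m0 = np.full(grid.shape, 2.0)
        r2s = np.full(grid.shape, 40.0)
        field = np.zeros(grid.shape)
        gre = simulate_echoes(m0, r2s, field, grid, noise_sigma=0.0)
        tes = np.asarray(DEFAULT_TES_S)
        for j, te in enumerate(tes):
            assert np.allclose(np.abs(gre.data[j]), 2.0 * np.exp(-40.0 * te))
            assert np.allclose(np.angle(gre.data[j]), 0.0)

    def test_phase_equals_wrapped_larmor_phase(self):
        grid = _grid(8)
        f_hz = 10.0
        field = np.full(grid.shape, f_hz / grid.hz_per_ppm)
        gre = simulate_echoes(np.ones(grid.shape), np.zeros(grid.shape),
                              field, grid, noise_sigma=0.0)
        for j, te in enumerate(gre.tes):
            expected = wrap_phase(np.array(2 * np.pi * f_hz * te))
            assert np.allclose(np.angle(gre.data[j]), expected, atol=1e-10)

    def test_noise_deterministic_in_seed(self):
        grid = _grid(8)
        args = (np.ones(grid.shape), np.zeros(grid.shape),
                np.zeros(grid.shape), grid)
        a = simulate_echoes(*args, noise_sigma=0.05, seed=7)
        b = simulate_echoes(*args, noise_sigma=0.05, seed=7)
        c = simulate_echoes(*args, noise_sigma=0.05, seed=8)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_nonincreasing_tes_rejected(self):
        grid = _grid(8)
        with pytest.raises(ValueError):
            simulate_echoes(np.ones(grid.shape), np.zeros(grid.shape),
                            np.zeros(grid.shape), grid,
                            tes=[0.003, 0.002])


def test_inclusion_order_permutation_invariance():
    """Non-overlapping inclusions rasterize identically in any order."""
    grid = _grid(32)
    a = InclusionSpec("sphere", (3.0, 2.0, -2.0), (1.0,), chi=-36.0,
                      m0=0.0, label="gold")
    b = InclusionSpec("sphere", (-4.0, -3.0, 3.0), (1.5,), chi=-21.0,
                      m0=0.3, label="calcification")
    spec1 = make_body_phantom(grid, [a, b], body_semi=(14, 14, 14))
    spec2 = make_body_phantom(grid, [b, a], body_semi=(14, 14, 14))
    chi1, m01, r1, _ = rasterize_phantom(spec1)
    chi2, m02, r2, _ = rasterize_phantom(spec2)
    assert np.array_equal(chi1, chi2)
    assert np.array_equal(m01, m02)
    assert np.array_equal(r1, r2)


def test_default_phantom_structure():
    spec = default_phantom()
    labels = [i.label for i in spec.inclusions]
    assert labels.count("gold") == 3
    assert "calcification" in labels and "air" in labels
    assert spec.grid.shape == (160, 160, 48)
    assert spec.grid.voxel_size == (1.0, 1.0, 2.0)
    assert np.isclose(spec.grid.b0, 1.5)
    tes = np.asarray(DEFAULT_TES_S)
    assert tes.size == 6
    assert np.isclose(tes[0], 0.0031)
    assert np.isclose(tes[-1], 0.0246)
    assert np.allclose(np.diff(tes), 0.0043)
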