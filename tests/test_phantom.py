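"""Phantom generator: geometry, ground-truth fibers, tensors, DWI/LGE simulation."""

import numpy as np
import pytest
from scipy.optimize import brentq

from myodti.dti import fractional_anisotropy, mean_diffusivity
from myodti.phantom import (
    PhantomParams,
    assemble_tensors,
    build_geometry,
    generate_phantom,
    ground_truth_fibers,
    make_gradient_scheme,
    prolate_eigenvalues,
    simulate_dwi,
    simulate_lge,
)

from conftest import SMALL_KW


def ray_cast_thickness(lv_mask, voxel_mm, theta_deg, dr=0.05, fan_deg=3):
    """Independent thickness oracle: in-wall length of radial rays from the axis.

    Averages a small fan of rays around theta to suppress the jaggedness of a
    single nearest-voxel-sampled ray against the voxelized wall boundary.
    """
    nx, ny, nz = lv_mask.shape
    cx, cy = (nx - 1) / 2 * voxel_mm, (ny - 1) / 2 * voxel_mm
    wall2d = lv_mask[:, :, nz // 2]
    radii = np.arange(dr / 2, nx * voxel_mm / 2, dr)
    lengths = []
    for theta in np.arange(theta_deg - fan_deg, theta_deg + fan_deg + 1):
        xi = np.rint((np.cos(np.deg2rad(theta)) * radii + cx) / voxel_mm).astype(int)
        yi = np.rint((np.sin(np.deg2rad(theta)) * radii + cy) / voxel_mm).astype(int)
        ok = (xi >= 0) & (xi < nx) & (yi >= 0) & (yi < ny)
        lengths.append(wall2d[xi[ok], yi[ok]].sum() * dr)
    return float(np.mean(lengths))


class TestGeometry:
    def test_no_scar_uniform_thickness(self):
        p = PhantomParams(**SMALL_KW).control()
        lv, blood, scar = build_geometry(p)
        assert scar.sum() == 0
        expected = p.epi_radius_mm - p.endo_radius_mm
        for theta in (0, 45, 100, 237):
            t = ray_cast_thickness(lv, 0.5, theta)
            assert t == pytest.approx(expected, abs=0.3)

    def test_sector_thinning(self):
        p = PhantomParams(**SMALL_KW)  # thinning 5.1/7.0 in (60, 120) degrees
        lv, blood, scar = build_geometry(p)
        in_sector = np.mean([ray_cast_thickness(lv, 0.5, th) for th in (70, 90, 110)])
        outside = np.mean([ray_cast_thickness(lv, 0.5, th) for th in (0, 180, 270)])
        assert in_sector == pytest.approx(7.0 * 5.1 / 7.0, abs=0.3)
        assert outside == pytest.approx(7.0, abs=0.3)

    def test_scar_occupies_endocardial_half(self):
        p = PhantomParams(**SMALL_KW)
        lv, blood, scar = build_geometry(p)
        x, y, _ = np.meshgrid(
            *[(np.arange(n) - (n - 1) / 2) * 0.5 for n in p.grid_shape], indexing="ij"
        )
        theta = np.degrees(np.arctan2(y, x)) % 360
        sector_wall = lv & (theta >= 60) & (theta < 120)
        frac = scar.sum() / sector_wall.sum()
        # endocardial half of an annulus holds slightly less than half the voxels
        # (voxel density grows with radius): analytic fraction for this geometry
        epi_s = p.endo_radius_mm + 7.0 * p.scar_thinning_factor
        w = epi_s - p.endo_radius_mm
        area = lambda d0, d1: (epi_s * (d1 - d0) - w * (d1**2 - d0**2) / 2)
        expected = area(0.5, 1.0) / area(0.0, 1.0)
        assert frac == pytest.approx(expected, abs=0.03)
        assert not np.any(scar & ~lv)

    def test_grid_too_small_raises(self):
        with pytest.raises(ValueError, match="grid too small"):
            PhantomParams(grid_shape=(32, 32, 16), endo_radius_mm=8.0, epi_radius_mm=15.0)

    def test_invalid_params_raise(self):
        with pytest.raises(ValueError):
            PhantomParams(endo_radius_mm=15.0, epi_radius_mm=8.0)
        with pytest.raises(ValueError):
            PhantomParams(fa_normal=1.2)
        with pytest.raises(ValueError):
            PhantomParams(scar_thinning_factor=0.0)
        with pytest.raises(ValueError):
            PhantomParams(alpha_epi_deg=-95.0)


class TestGroundTruthFibers:
    def test_linear_profile_outside_sector(self, small_noiseless_infarcted):
        b = small_noiseless_infarcted
        p = b.params
        x, y, _ = np.meshgrid(
            *[(np.arange(n) - (n - 1) / 2) * 0.5 for n in p.grid_shape], indexing="ij"
        )
        theta = np.degrees(np.arctan2(y, x)) % 360
        outside = b.lv_mask & ((theta < 60) | (theta >= 120))
        expected = p.alpha_epi_deg + p.alpha_range_deg * b.true_depth_norm[outside]
        np.testing.assert_allclose(b.true_inclination[outside], expected, atol=1e-9)
        # angles stay within the configured epi/endo endpoints
        a = b.true_inclination[outside]
        assert a.min() >= -60.0 - 1e-9 and a.max() <= 52.5 + 1e-9

    def test_midpoint_angle(self):
        p = PhantomParams(**SMALL_KW).control()
        lv, _, _ = build_geometry(p)
        _, alpha, _ = ground_truth_fibers(lv, p)
        x, y, _ = np.meshgrid(
            *[(np.arange(n) - (n - 1) / 2) * 0.5 for n in p.grid_shape], indexing="ij"
        )
        d = (p.epi_radius_mm - np.hypot(x, y)) / 7.0  # analytic normalized depth
        mid = lv & (np.abs(d - 0.5) < 0.01)
        assert mid.any()
        # midpoint of (-60, 52.5) is -3.75; the +-0.01 depth window allows +-1.125 deg
        assert np.allclose(alpha[mid], -3.75, atol=1.2)

    def test_fibers_tangential(self, small_noiseless_infarcted):
        b = small_noiseless_infarcted
        x, y, _ = np.meshgrid(
            *[(np.arange(n) - (n - 1) / 2) * 0.5 for n in b.params.grid_shape], indexing="ij"
        )
        r = np.hypot(x, y)
        radial = np.stack([x / r, y / r, np.zeros_like(r)], axis=-1)
        dot = np.abs(np.sum(b.true_fibers * radial, axis=-1))[b.lv_mask]
        assert dot.max() < 1e-9  # imbrication 0 by construction

    def test_injected_imbrication_tilt(self):
        p = PhantomParams(imbrication_deg=5.0, **SMALL_KW).control()
        lv, _, _ = build_geometry(p)
        fibers, _, phi = ground_truth_fibers(lv, p)
        assert np.allclose(phi[lv], 5.0)

    def test_empty_mask_raises(self):
        p = PhantomParams(**SMALL_KW)
        with pytest.raises(ValueError):
            ground_truth_fibers(np.zeros(p.grid_shape, bool), p)


class TestProlateTensors:
    def test_isotropic_limit(self):
        lam = prolate_eigenvalues(6.33e-4, 0.0)
        assert lam == pytest.approx((6.33e-4,) * 3)

    @pytest.mark.parametrize("md,fa", [(6.33e-4, 0.37), (9.08e-4, 0.24), (1e-3, 0.9)])
    def test_md_fa_round_trip(self, md, fa):
        lam = np.array(prolate_eigenvalues(md, fa))
        assert mean_diffusivity(lam) == pytest.approx(md, abs=1e-10)
        assert fractional_anisotropy(lam) == pytest.approx(fa, abs=1e-10)

    def test_against_root_search_oracle(self):
        md, fa = 9.08e-4, 0.24

        def fa_of_lam1(lam1):
            lam23 = (3 * md - lam1) / 2
            return fractional_anisotropy(np.array([lam1, lam23, lam23])) - fa

        lam1_oracle = brentq(fa_of_lam1, md * (1 + 1e-9), 3 * md * (1 - 1e-9))
        assert prolate_eigenvalues(md, fa)[0] == pytest.approx(lam1_oracle, rel=1e-9)

    def test_assemble_fa_zero_gives_isotropic(self):
        mask = np.ones((2, 2, 2), bool)
        fibers = np.zeros((2, 2, 2, 3))
        fibers[..., 0] = 1.0
        field = assemble_tensors(fibers, 6.33e-4, 0.0, mask)
        expected = np.broadcast_to(6.33e-4 * np.eye(3), (8, 3, 3))
        np.testing.assert_allclose(field.tensors[mask], expected, atol=1e-18)

    def test_assemble_primary_eigenvector_is_fiber(self):
        rng = np.random.default_rng(3)
        mask = np.ones((3, 3, 3), bool)
        fibers = rng.normal(size=(3, 3, 3, 3))
        fibers /= np.linalg.norm(fibers, axis=-1, keepdims=True)
        field = assemble_tensors(fibers, 6.33e-4, 0.37, mask)
        dots = np.abs(np.sum(field.v1 * fibers, axis=-1))
        np.testing.assert_allclose(dots[mask], 1.0, atol=1e-10)

    def test_invalid_inputs_raise(self):
        mask = np.ones((1, 1, 1), bool)
        fibers = np.zeros((1, 1, 1, 3))
        fibers[..., 0] = 1.0
        with pytest.raises(ValueError):
            assemble_tensors(fibers, -1e-4, 0.3, mask)
        with pytest.raises(ValueError):
            assemble_tensors(fibers, 1e-3, 1.0, mask)


class TestGradientScheme:
    def test_counts_and_b0(self):
        scheme = make_gradient_scheme(15, seed=1)
        assert len(scheme) == 16
        assert (scheme.b_values == 0).sum() == 1
        assert np.allclose(np.linalg.norm(scheme.directions, axis=1), 1.0, atol=1e-9)

    def test_octahedral_preset_solvable(self):
        scheme = make_gradient_scheme(6)
        from myodti.dti import design_matrix

        d = design_matrix(scheme.directions[scheme.dwi_index], scheme.b_values[scheme.dwi_index])
        assert np.isfinite(np.linalg.cond(d))
        assert np.linalg.matrix_rank(d) == 6

    def test_determinism(self):
        a = make_gradient_scheme(15, seed=7)
        b = make_gradient_scheme(15, seed=7)
        np.testing.assert_array_equal(a.directions, b.directions)

    def test_too_few_directions(self):
        with pytest.raises(ValueError):
            make_gradient_scheme(5)

    def test_condition_number_bound(self):
        for seed in range(3):
            make_gradient_scheme(15, seed=seed, max_condition=10.0)  # raises if violated


class TestSimulateDWI:
    def test_noiseless_b0_equals_s0(self, small_noiseless_infarcted):
        b = small_noiseless_infarcted
        b0 = b.dwi.signals[..., b.dwi.scheme.b0_index[0]]
        np.testing.assert_allclose(b0[b.lv_mask], b.params.s0, rtol=1e-12)

    def test_isotropic_attenuation(self):
        mask = np.ones((2, 2, 2), bool)
        fibers = np.zeros((2, 2, 2, 3))
        fibers[..., 0] = 1.0
        field = assemble_tensors(fibers, 9.08e-4, 0.0, mask)
        scheme = make_gradient_scheme(15, b_value=800.0, seed=0)
        dwi = simulate_dwi(field, scheme, s0=100.0, snr=np.inf)
        att = dwi.signals[0, 0, 0, scheme.dwi_index] / 100.0
        np.testing.assert_allclose(att, np.exp(-0.7264), atol=1e-6)

    def test_attenuation_monotone_in_alignment(self):
        mask = np.ones((1, 1, 1), bool)
        fibers = np.zeros((1, 1, 1, 3))
        fibers[..., 0] = 1.0
        field = assemble_tensors(fibers, 9.08e-4, 0.24, mask)
        lam1 = prolate_eigenvalues(9.08e-4, 0.24)[0]
        scheme = make_gradient_scheme(15, b_value=800.0, seed=2)
        dwi = simulate_dwi(field, scheme, s0=100.0, snr=np.inf)
        sig = dwi.signals[0, 0, 0, scheme.dwi_index]
        align = np.abs(scheme.directions[scheme.dwi_index][:, 0])
        order = np.argsort(align)
        assert np.all(np.diff(sig[order]) <= 1e-12)  # more aligned -> more attenuated
        assert sig.min() >= 100.0 * np.exp(-800 * lam1) - 1e-9

    def test_seed_reproducibility(self, small_noisy_infarcted):
        b = small_noisy_infarcted
        again = generate_phantom(b.params)
        np.testing.assert_array_equal(b.dwi.signals, again.dwi.signals)
        np.testing.assert_array_equal(b.lge, again.lge)

    def test_bad_s0_raises(self, small_noiseless_infarcted):
        b = small_noiseless_infarcted
        with pytest.raises(ValueError):
            simulate_dwi(b.true_tensors, b.dwi.scheme, s0=0.0, snr=120.0)


class TestSimulateLGE:
    def test_sigma_zero_two_levels(self, small_noiseless_infarcted):
        b = small_noiseless_infarcted
        lge = simulate_lge(b.lv_mask, b.scar_mask, sigma=0.0)
        assert set(np.unique(lge[b.lv_mask])) == {100.0, 200.0}

    def test_empty_scar_unimodal(self, small_noiseless_control):
        b = small_noiseless_control
        lge = simulate_lge(b.lv_mask, b.scar_mask, sigma=0.0)
        assert set(np.unique(lge[b.lv_mask])) == {100.0}

    def test_invalid_args_raise(self, small_noiseless_infarcted):
        b = small_noiseless_infarcted
        with pytest.raises(ValueError):
            simulate_lge(b.lv_mask, b.scar_mask, mu_fibrotic=90.0, mu_normal=100.0)
        with pytest.raises(ValueError):
            simulate_lge(b.lv_mask, b.scar_mask, sigma=-1.0)
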