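"""Tensor-field autocorrelation: dyadics, spectral ACF, profiles, ξ fits."""

import numpy as np
import pytest

from fiberarch import (
    BlockGrid,
    BlockODF,
    accumulate_odf,
    acf3d,
    block_frame,
    dyadic_field,
    fit_correlation_length,
    fit_frame_correlation_lengths,
    max_autocorrelation_length,
    patchwork_orientation_field,
    radial_profiles,
)
from fiberarch.acf import ACFVolume, CorrelationFit


def random_axial_field(shape, seed, valid_fraction=1.0):
    rng = np.random.default_rng(seed)
    v = rng.normal(size=shape + (3,))
    v /= np.linalg.norm(v, axis=-1, keepdims=True)
    valid = rng.uniform(size=shape) < valid_fraction
    from fiberarch import OrientationField

    ones = np.ones(shape, dtype=np.float32)
    return OrientationField(
        axis=v.astype(np.float32), coherence=ones.copy(), energy=ones.copy(),
        valid=valid, voxel_size=np.ones(3),
    )


def direct_acf(T, valid):
    """Brute-force masked autocorrelation over every lag (independent oracle)."""
    s = np.array(T.shape[:3])
    Tm = T[valid].mean(axis=0)
    Tc = (T - Tm) * valid[..., None, None]
    out = np.full(tuple(2 * s - 1), np.nan)
    pairs = np.zeros(tuple(2 * s - 1), dtype=int)
    m = valid.astype(float)
    for dz in range(-(s[0] - 1), s[0]):
        for dy in range(-(s[1] - 1), s[1]):
            for dx in range(-(s[2] - 1), s[2]):
                sl_a = tuple(slice(max(0, d), min(n, n + d)) for d, n in zip((dz, dy, dx), s))
                sl_b = tuple(slice(max(0, -d), min(n, n - d)) for d, n in zip((dz, dy, dx), s))
                npair = (m[sl_a] * m[sl_b]).sum()
                idx = (dz + s[0] - 1, dy + s[1] - 1, dx + s[2] - 1)
                pairs[idx] = int(round(npair))
                if npair > 0:
                    # full 3x3 contraction counts off-diagonals twice (Frobenius)
                    out[idx] = float((Tc[sl_a] * Tc[sl_b]).sum()) / npair
    var0 = out[tuple(s - 1)]
    return np.clip(out / var0, -1.0, 1.0), pairs


class TestDyadic:
    def test_ez_dyadic_matrix(self):
        f = random_axial_field((2, 2, 2), 0)
        f.axis[:] = np.array([1.0, 0, 0], dtype=np.float32)  # e_z in (z,y,x) order
        d = dyadic_field(f)
        np.testing.assert_allclose(d.tensors[0, 0, 0], np.diag([2 / 3, -1 / 3, -1 / 3]), atol=1e-7)

    def test_sign_invariance(self):
        f = random_axial_field((4, 4, 4), 1)
        g = random_axial_field((4, 4, 4), 1)
        g.axis *= -1
        np.testing.assert_allclose(dyadic_field(f).tensors, dyadic_field(g).tensors, atol=1e-12)

    def test_traceless_and_fixed_frobenius_norm(self):
        d = dyadic_field(random_axial_field((5, 5, 5), 2))
        T = d.tensors
        np.testing.assert_allclose(np.trace(T, axis1=-2, axis2=-1), 0.0, atol=1e-12)
        np.testing.assert_allclose(np.einsum("...ab,...ab->...", T, T), 2.0 / 3.0, atol=1e-12)

    def test_invalid_voxels_zeroed(self):
        f = random_axial_field((4, 4, 4), 3, valid_fraction=0.5)
        d = dyadic_field(f)
        np.testing.assert_allclose(d.tensors[~f.valid], 0.0)


class TestACF3D:
    def test_spectral_equals_direct_summation(self):
        """FFT path against the brute-force masked oracle, all lags, ≤1e-8."""
        for shape, vf, seed in (((12, 12, 12), 1.0, 0), ((9, 10, 11), 0.7, 1), ((16, 16, 16), 0.5, 2)):
            f = random_axial_field(shape, seed, valid_fraction=vf)
            d = dyadic_field(f)
            acfv = acf3d(d, min_pairs=1, min_side=8)
            expect, pairs = direct_acf(d.tensors, d.valid)
            np.testing.assert_array_equal(acfv.n_pairs, pairs)
            both = pairs > 0
            np.testing.assert_allclose(acfv.C[both], expect[both], atol=1e-8)

    def test_zero_lag_unity_and_even_symmetry(self, meshwork80_field):
        acfv = acf3d(dyadic_field(meshwork80_field), region=tuple([slice(8, 72)] * 3))
        assert acfv.C[acfv.center] == 1.0
        flipped = acfv.C[::-1, ::-1, ::-1]
        both = np.isfinite(acfv.C) & np.isfinite(flipped)
        np.testing.assert_allclose(acfv.C[both], flipped[both], atol=1e-9)

    def test_constant_field_flagged_homogeneous(self):
        f = random_axial_field((40, 40, 40), 4)
        f.axis[:] = np.array([0, 1, 0], dtype=np.float32)
        acfv = acf3d(dyadic_field(f))
        assert acfv.homogeneous

    def test_sparse_region_flagged_insufficient(self):
        f = random_axial_field((40, 40, 40), 5, valid_fraction=0.02)
        assert acf3d(dyadic_field(f)).insufficient

    def test_small_region_rejected(self):
        f = random_axial_field((16, 16, 16), 6)
        with pytest.raises(ValueError, match="32"):
            acf3d(dyadic_field(f), region=tuple([slice(0, 16)] * 3))

    def test_mean_subtraction_kills_far_correlations(self, meshwork80_field):
        acfv = acf3d(dyadic_field(meshwork80_field), region=tuple([slice(8, 72)] * 3))
        cen = np.array(acfv.center)
        grids = np.meshgrid(*[np.arange(n) - c for n, c in zip(acfv.C.shape, cen)], indexing="ij")
        rr = np.sqrt(sum(g * g for g in grids))
        far = (rr > 15) & np.isfinite(acfv.C)
        assert abs(np.nanmean(acfv.C[far])) < 0.05


class TestBlockFrame:
    def _odf_with_peaks(self, axes):
        b = BlockODF(psi=np.ones(4) / 4, gfa=0.5, n_valid=10, block_index=(0, 0, 0), center_um=np.zeros(3))
        b.peaks = [(np.asarray(a, dtype=float), 1.0 - 0.1 * i) for i, a in enumerate(axes)]
        return b

    def test_two_peak_frame_follows_peaks(self):
        fr = block_frame(self._odf_with_peaks([(1.0, 0, 0), (0, 0, 1.0)]))
        np.testing.assert_allclose(fr[0], [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(fr[1], [0, 0, 1], atol=1e-12)
        assert abs(abs(fr[2][1]) - 1.0) < 1e-12

    def test_single_peak_frame_deterministic_and_orthonormal(self):
        fr1 = block_frame(self._odf_with_peaks([(0.0, 0, 1.0)]))
        fr2 = block_frame(self._odf_with_peaks([(0.0, 0, 1.0)]))
        np.testing.assert_array_equal(fr1, fr2)
        np.testing.assert_allclose(fr1 @ fr1.T, np.eye(3), atol=1e-12)

    def test_random_odf_frames_orthonormal(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a = rng.normal(size=3)
            a /= np.linalg.norm(a)
            b = rng.normal(size=3)
            b -= (b @ a) * a
            b /= np.linalg.norm(b)
            fr = block_frame(self._odf_with_peaks([a, b]))
            assert abs(abs(np.linalg.det(fr)) - 1.0) < 1e-9

    def test_empty_odf_rejected(self):
        with pytest.raises(ValueError):
            block_frame(self._odf_with_peaks([]))


class TestProfilesAndFits:
    def _isotropic_acf(self, s=41, xi0=8.0):
        g = np.arange(-(s - 1), s)
        zz, yy, xx = np.meshgrid(g, g, g, indexing="ij")
        C = np.exp(-np.sqrt(zz**2 + yy**2 + xx**2) / xi0)
        return ACFVolume(C=C, lag_spacing=1.0, n_pairs=np.full(C.shape, 1000), variance0=1.0)

    def test_isotropic_acf_profiles_all_match_exponential(self):
        acfv = self._isotropic_acf()
        prof = radial_profiles(acfv, np.eye(3))
        expect = np.exp(-prof.r / 8.0)
        for p in (*prof.axial, prof.fiber_plane_radial, prof.transverse_radial):
            assert p[0] == pytest.approx(1.0, abs=1e-9)
            np.testing.assert_allclose(p, expect, atol=0.02)

    def test_r_grid_truncated_to_available_lags(self):
        acfv = self._isotropic_acf(s=21)
        prof = radial_profiles(acfv, np.eye(3), r_max_um=500.0)
        assert prof.r[-1] <= 20.0

    def test_exponential_profile_recovered_within_1_percent(self):
        r = np.arange(0.0, 51.0)
        xi, r2, capped, failed = fit_correlation_length(r, np.exp(-r / 20.0))
        assert not capped and not failed
        assert xi == pytest.approx(20.0, rel=0.01)
        assert r2 > 0.999

    def test_constant_profile_capped_with_flag(self):
        r = np.arange(0.0, 51.0)
        xi, _, capped, failed = fit_correlation_length(r, np.ones_like(r))
        assert capped and not failed
        assert xi == pytest.approx(50.0)

    def test_oscillating_profile_detected_as_misfit(self):
        r = np.arange(0.0, 51.0)
        c = np.cos(2 * np.pi * r / 40.0) * np.exp(-r / 30.0)
        xi, r2, capped, failed = fit_correlation_length(r, c)
        assert not failed
        assert r2 < 0.9

    def test_too_few_points_flagged_failed(self):
        r = np.arange(0.0, 6.0)
        c = np.array([1.0, 0.04, 0.01, 0.005, 0.001, 0.0001])
        xi, r2, capped, failed = fit_correlation_length(r, c)
        assert failed and np.isnan(xi)

    def test_xi_max_is_max_over_axes(self):
        fit = CorrelationFit(
            xi=np.array([20.0, 8.0, 8.0]), r2=np.ones(3),
            capped=np.zeros(3, bool), failed=np.zeros(3, bool), fit_range=(1.0, 50.0),
        )
        assert max_autocorrelation_length(fit) == 20.0

    def test_all_failed_gives_nan(self):
        fit = CorrelationFit(
            xi=np.full(3, np.nan), r2=np.full(3, np.nan),
            capped=np.zeros(3, bool), failed=np.ones(3, bool), fit_range=(1.0, 50.0),
        )
        assert np.isnan(max_autocorrelation_length(fit))


class TestParameterRecovery:
    def _xi_max_of_patchwork(self, patch_um, sphere):
        field = patchwork_orientation_field((96, 96, 96), patch_um, seed=3)
        acfv = acf3d(dyadic_field(field))
        (block,) = accumulate_odf(field, BlockGrid(block_size=96), sphere)
        prof = radial_profiles(acfv, block_frame(block))
        return fit_frame_correlation_lengths(prof).xi_max

    def test_xi_max_monotone_in_patch_size(self, sphere_small):
        xis = [self._xi_max_of_patchwork(s, sphere_small) for s in (10.0, 20.0, 40.0)]
        assert xis[0] < xis[1] < xis[2]

    def test_xi_stable_under_default_noise(self, sphere_small):
        from fiberarch import PhantomSpec, compute_structure_tensor, generate_phantom, principal_orientation

        xis = []
        for noise_sd in (0.0, 0.05):
            spec = PhantomSpec(motif="bundled", shape=(80, 80, 80), seed=9, noise_sd=noise_sd)
            ph = generate_phantom(spec)
            f = principal_orientation(compute_structure_tensor(ph.volume, 1.0), 1.0)
            (block,) = accumulate_odf(f, BlockGrid(block_size=64, origin=(8, 8, 8)), sphere_small)
            acfv = acf3d(dyadic_field(f), region=tuple([slice(8, 72)] * 3))
            prof = radial_profiles(acfv, block_frame(block))
            xis.append(fit_frame_correlation_lengths(prof).xi_max)
        assert abs(xis[1] - xis[0]) / xis[0] < 0.25

    def test_bundled_longer_range_than_meshwork(self, bundled80_field, meshwork80_field, sphere_small):
        out = {}
        for name, f in (("bundled", bundled80_field), ("meshwork", meshwork80_field)):
            (block,) = accumulate_odf(f, BlockGrid(block_size=64, origin=(8, 8, 8)), sphere_small)
            acfv = acf3d(dyadic_field(f), region=tuple([slice(8, 72)] * 3))
            prof = radial_profiles(acfv, block_frame(block))
            out[name] = fit_frame_correlation_lengths(prof).xi_max
        assert out["bundled"] > out["meshwork"]
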