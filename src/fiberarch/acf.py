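"""Spatial autocorrelation of the local orientation tensor field.

Axial directions are lifted to traceless dyadic tensors T(x) = v vᵀ − I/3
(invariant under v → −v). Within an analysis region the mean tensor over valid
voxels is subtracted and the normalized autocorrelation

    C(Δ) = ⟨ (T(x) − T̄) : (T(x+Δ) − T̄) ⟩ / ⟨ ‖T − T̄‖² ⟩

is computed with a zero-padded FFT per tensor component; masked (invalid)
voxels are excluded through pair-count normalization rather than zero-filling.
C is resampled into a fiber-aligned frame (e1 = dominant ODF peak) to give
axial profiles and radially averaged in-plane profiles, and correlation
lengths ξ are obtained by fitting an exponential decay exp(−r/ξ) to each axial
profile. All lags are in μm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft
from scipy import ndimage

from .odf import BlockODF
from .orientation import OrientationField, canonicalize

# Frobenius component weights for a symmetric 3x3 tensor stored as
# (zz, yy, xx, zy, zx, yx): off-diagonals count twice.
_COMP = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
_WEIGHT = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])


@dataclass
class DyadicField:
    """Traceless orientation dyadic per voxel; zero tensor where invalid."""

    tensors: np.ndarray  # (*shape, 3, 3) float
    valid: np.ndarray
    voxel_size: np.ndarray


@dataclass
class ACFVolume:
    """Centered, normalized 3D autocorrelation over integer lag offsets.

    C has shape (2s_z−1, 2s_y−1, 2s_x−1) with zero lag at the center index;
    C(0) = 1 when the region is not homogeneous; C(Δ) = C(−Δ). Lags with
    fewer than ``min_pairs`` contributing voxel pairs are NaN.
    """

    C: np.ndarray
    lag_spacing: float
    n_pairs: np.ndarray
    variance0: float
    homogeneous: bool = False
    insufficient: bool = False

    @property
    def center(self):
        return tuple(s // 2 for s in self.C.shape)


@dataclass
class CorrelationFit:
    """Exponential-decay fits along the three frame axes.

    xi : (3,) correlation lengths, μm (capped at the window half-length when
    the profile never decays below 1/e); r2 : goodness on the log scale;
    capped / failed : per-axis flags. xi_max = max over successful axes.
    """

    xi: np.ndarray
    r2: np.ndarray
    capped: np.ndarray
    failed: np.ndarray
    fit_range: tuple

    @property
    def xi_max(self) -> float:
        ok = ~self.failed
        if not ok.any():
            return float("nan")
        return float(np.max(self.xi[ok]))

    @property
    def all_capped(self) -> bool:
        ok = ~self.failed
        return bool(ok.any() and self.capped[ok].all())


@dataclass
class ACFProfiles:
    """Fiber-frame resamplings of an ACFVolume (all profiles start at C=1)."""

    frame: np.ndarray  # rows e1, e2, e3 (z, y, x components)
    r: np.ndarray  # μm, strictly increasing from 0
    axial: np.ndarray  # (3, len(r)) profiles along e1, e2, e3
    fiber_plane_radial: np.ndarray  # azimuthal average in span(e1, e2)
    transverse_radial: np.ndarray  # azimuthal average in span(e2, e3)
    transverse_2d: np.ndarray  # (2m+1, 2m+1) slice of C in span(e2, e3)


def dyadic_field(field: OrientationField) -> DyadicField:
    """Lift an orientation field to traceless dyadics v vᵀ − I/3 (zero where invalid)."""
    v = field.axis.astype(np.float64)
    nrm = np.linalg.norm(v, axis=-1, keepdims=True)
    np.divide(v, nrm, out=v, where=nrm > 0)  # exact unit norm in double precision
    T = v[..., :, None] * v[..., None, :]
    T -= np.eye(3) / 3.0
    T[~field.valid] = 0.0
    return DyadicField(tensors=T, valid=field.valid.copy(), voxel_size=field.voxel_size)


def _centered(corr: np.ndarray, shape) -> np.ndarray:
    """Extract lags −(s−1)…(s−1) per axis from a zero-padded circular correlation."""
    out = corr
    for ax, s in enumerate(shape):
        n = out.shape[ax]
        idx = np.concatenate([np.arange(n - (s - 1), n), np.arange(s)])
        out = np.take(out, idx, axis=ax)
    return out


def acf3d(
    dyadic: DyadicField,
    region: tuple | None = None,
    min_valid_fraction: float = 0.10,
    min_pairs: int = 8,
    variance_floor: float = 1e-10,
    min_side: int = 32,
) -> ACFVolume:
    """Masked, mean-subtracted 3D autocorrelation of the dyadic field.

    ``region`` is an optional tuple of slices selecting an analysis block
    (default: the whole field). Requires >= ``min_side`` voxels per side (32
    by default; lower only for small verification fixtures) and a valid
    fraction >= ``min_valid_fraction`` (otherwise flagged insufficient);
    a near-zero zero-lag variance flags the region homogeneous.
    """
    sl = region if region is not None else tuple(slice(0, s) for s in dyadic.valid.shape)
    valid = dyadic.valid[sl]
    shape = valid.shape
    if min(shape) < min_side:
        raise ValueError(f"ACF region must be at least {min_side} voxels per side")
    vs = np.asarray(dyadic.voxel_size, dtype=float)
    if not np.allclose(vs, vs[0]):
        raise ValueError("ACF analysis requires isotropic voxels")
    lag = float(vs[0])
    n_valid = int(valid.sum())
    frac = n_valid / valid.size
    empty = ACFVolume(
        C=np.zeros([2 * s - 1 for s in shape]),
        lag_spacing=lag,
        n_pairs=np.zeros([2 * s - 1 for s in shape]),
        variance0=0.0,
    )
    if frac < min_valid_fraction:
        empty.insufficient = True
        return empty

    T = dyadic.tensors[sl]
    Tm = T[valid].mean(axis=0)
    padded = [sfft.next_fast_len(2 * s - 1) for s in shape]
    m = valid.astype(np.float64)
    Mf = sfft.rfftn(m, padded)
    n_pairs = _centered(sfft.irfftn(Mf * np.conj(Mf), padded), shape)
    n_pairs = np.round(n_pairs).astype(np.int64)

    num = np.zeros([2 * s - 1 for s in shape])
    for (a, b), w in zip(_COMP, _WEIGHT):
        comp = (T[..., a, b] - Tm[a, b]) * m
        F = sfft.rfftn(comp, padded)
        num += w * _centered(sfft.irfftn(F * np.conj(F), padded), shape)

    center = tuple(s - 1 for s in shape)
    if n_pairs[center] <= 0:
        empty.insufficient = True
        return empty
    variance0 = num[center] / n_pairs[center]
    if variance0 < variance_floor:
        return ACFVolume(
            C=np.zeros_like(num), lag_spacing=lag, n_pairs=n_pairs, variance0=float(variance0), homogeneous=True
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        C = num / n_pairs / variance0
    C[n_pairs < min_pairs] = np.nan
    np.clip(C, -1.0, 1.0, out=C)
    C[center] = 1.0
    return ACFVolume(C=C, lag_spacing=lag, n_pairs=n_pairs, variance0=float(variance0))


def _perpendicular(v: np.ndarray) -> np.ndarray:
    ref = np.zeros(3)
    ref[int(np.argmin(np.abs(v)))] = 1.0
    p = np.cross(v, ref)
    return p / np.linalg.norm(p)


def block_frame(odf: BlockODF) -> np.ndarray:
    """Orthonormal frame (rows e1, e2, e3) aligned to the block's ODF peaks.

    e1 = dominant peak axis; e2 = second peak orthogonalized against e1 when
    two or more peaks exist, otherwise a deterministic perpendicular (the
    coordinate axis least aligned with e1, orthogonalized); e3 = e1 × e2.
    """
    if not odf.peaks:
        raise ValueError("block_frame requires an ODF with at least one peak")
    e1 = np.asarray(odf.peaks[0][0], dtype=float)
    e1 /= np.linalg.norm(e1)
    if len(odf.peaks) >= 2:
        p2 = np.asarray(odf.peaks[1][0], dtype=float)
        e2 = p2 - (p2 @ e1) * e1
        nrm = np.linalg.norm(e2)
        e2 = e2 / nrm if nrm > 1e-9 else _perpendicular(e1)
    else:
        e2 = _perpendicular(e1)
    e2 = canonicalize(e2)
    e3 = np.cross(e1, e2)
    e3 /= np.linalg.norm(e3)
    return np.stack([e1, e2, e3])


def _sample_c(acfv: ACFVolume, points_um: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of C at physical lag offsets (μm), NaNs as 0."""
    center = np.asarray(acfv.center, dtype=float)
    coords = (points_um / acfv.lag_spacing + center).T
    Cf = np.nan_to_num(acfv.C, nan=0.0)
    return ndimage.map_coordinates(Cf, coords, order=1, mode="nearest")


def radial_profiles(
    acfv: ACFVolume, frame: np.ndarray, r_max_um: float | None = None, n_azimuth: int = 72
) -> ACFProfiles:
    """Resample an ACF volume into fiber-frame axial and radial profiles.

    The r grid runs from 0 in steps of the lag spacing up to the window
    half-length (or ``r_max_um`` if smaller; larger requests are truncated).
    In-plane profiles average C over ``n_azimuth`` azimuths in each plane.
    """
    if acfv.homogeneous or acfv.insufficient:
        raise ValueError("radial profiles undefined for a degenerate ACF volume")
    max_lag = (min(acfv.C.shape) // 2) * acfv.lag_spacing  # lags actually available
    window_half = ((min(acfv.C.shape) + 1) // 2) * acfv.lag_spacing / 2.0
    r_max = window_half if r_max_um is None else min(r_max_um, max_lag)
    r = np.arange(0.0, r_max + 1e-9, acfv.lag_spacing)
    e1, e2, e3 = frame
    axial = np.stack([_sample_c(acfv, np.outer(r, e)) for e in (e1, e2, e3)])
    theta = np.linspace(0.0, 2.0 * np.pi, n_azimuth, endpoint=False)

    def plane_avg(u, v):
        dirs = np.cos(theta)[:, None] * u + np.sin(theta)[:, None] * v  # (A, 3)
        pts = r[:, None, None] * dirs[None, :, :]
        vals = _sample_c(acfv, pts.reshape(-1, 3)).reshape(len(r), n_azimuth)
        return vals.mean(axis=1)

    fiber_plane = plane_avg(e1, e2)
    transverse = plane_avg(e2, e3)
    m = len(r) - 1
    grid = np.arange(-m, m + 1) * acfv.lag_spacing
    A, B = np.meshgrid(grid, grid, indexing="ij")
    pts2d = A[..., None] * e2 + B[..., None] * e3
    t2d = _sample_c(acfv, pts2d.reshape(-1, 3)).reshape(2 * m + 1, 2 * m + 1)
    return ACFProfiles(
        frame=frame, r=r, axial=axial, fiber_plane_radial=fiber_plane, transverse_radial=transverse, transverse_2d=t2d
    )


def fit_correlation_length(
    r: np.ndarray, profile: np.ndarray, fit_floor: float = 0.05, min_points: int = 5
):
    """Fit C(r) = exp(−r/ξ) on the log scale over r ∈ [Δr, first C < fit_floor].

    Returns (xi, r2, capped, failed). The single-parameter least-squares
    solution is 1/ξ = Σ r·(−ln C) / Σ r²; R² is computed on ln C against the
    fitted line. If the profile never drops below 1/e inside the window (or the
    fitted ξ exceeds it), ξ is capped at the window half-length and flagged.
    Fewer than ``min_points`` usable points flags the fit failed.
    """
    r = np.asarray(r, dtype=float)
    c = np.asarray(profile, dtype=float)
    half = r[-1]
    usable = np.ones(len(r), dtype=bool)
    usable[0] = False  # r = 0 carries no information for a through-origin fit
    below = np.where(c < fit_floor)[0]
    if below.size:
        usable[below[0]:] = False
    usable &= np.isfinite(c) & (c > fit_floor)
    n_use = int(usable.sum())
    if n_use < min_points:
        return float("nan"), float("nan"), False, True
    ru, cu = r[usable], c[usable]
    y = np.log(cu)
    denom = float(np.sum(ru * (-y)))
    if denom <= 0:
        return float(half), 0.0, True, False
    inv_xi = denom / float(np.sum(ru * ru))
    xi = 1.0 / inv_xi
    yhat = -ru * inv_xi
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res < 1e-20 else 0.0)
    capped = False
    if xi > half or np.nanmin(c) > np.exp(-1.0):
        xi = float(half)
        capped = True
    return float(xi), float(r2), capped, False


def fit_frame_correlation_lengths(profiles: ACFProfiles, fit_floor: float = 0.05) -> CorrelationFit:
    """Correlation lengths along the three frame axes of an ACFProfiles."""
    xi = np.empty(3)
    r2 = np.empty(3)
    capped = np.zeros(3, dtype=bool)
    failed = np.zeros(3, dtype=bool)
    for i in range(3):
        xi[i], r2[i], capped[i], failed[i] = fit_correlation_length(profiles.r, profiles.axial[i], fit_floor)
    return CorrelationFit(xi=xi, r2=r2, capped=capped, failed=failed, fit_range=(float(profiles.r[1]) if len(profiles.r) > 1 else 0.0, float(profiles.r[-1])))


def max_autocorrelation_length(fits: CorrelationFit) -> float:
    """Maximum correlation length over the three frame axes (NaN if all fits failed)."""
    return fits.xi_max
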