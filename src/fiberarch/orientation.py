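"""Per-voxel fiber orientation from 3D structure tensors.

The local structure tensor is the Gaussian-windowed second moment of the image
intensity gradient, T = G_w * (∇I ∇Iᵀ), with gradients taken as
derivative-of-Gaussian filters at a smaller scale. For a bright tubular
structure the intensity varies least along the fiber, so the fiber axis is the
eigenvector of the smallest eigenvalue of T.

Orientations are axial: v and -v are identified, and every stored vector is
sign-canonicalized (largest-magnitude component positive, ties broken in
z, y, x order). Vector components are in (z, y, x) order matching array axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu


@dataclass
class StructureTensorParams:
    """Scales of the structure-tensor computation, in μm.

    sigma_gradient is the derivative-of-Gaussian scale (≈ fiber radius);
    sigma_window is the tensor-smoothing window (≈ 3× fiber radius). Both are
    converted to per-axis voxel units via the voxel size, so anisotropic voxel
    grids are handled transparently.
    """

    sigma_gradient: float = 1.0
    sigma_window: float = 3.0

    def __post_init__(self):
        if not (0 < self.sigma_gradient <= self.sigma_window):
            raise ValueError("require 0 < sigma_gradient <= sigma_window")


@dataclass
class OrientationField:
    """Per-voxel axial fiber direction with coherence and validity.

    axis : (*shape, 3) float32, unit vectors (z, y, x) where valid, 0 elsewhere.
    coherence : (*shape,) float32 in [0, 1].
    energy : (*shape,) float32, structure-tensor trace (local gradient energy).
    valid : (*shape,) bool.
    voxel_size : (3,) float, μm per voxel along (z, y, x).
    """

    axis: np.ndarray
    coherence: np.ndarray
    energy: np.ndarray
    valid: np.ndarray
    voxel_size: np.ndarray

    @property
    def shape(self):
        return self.valid.shape


def _as_voxel_size(voxel_size) -> np.ndarray:
    vs = np.asarray(voxel_size, dtype=float)
    if vs.ndim == 0:
        vs = np.full(3, float(vs))
    if vs.shape != (3,) or np.any(vs <= 0):
        raise ValueError("voxel_size must be a positive scalar or length-3 (z, y, x)")
    return vs


def canonicalize(v: np.ndarray) -> np.ndarray:
    """Flip axial vectors so the largest-|component| is positive.

    Ties are broken by component order (z, y, x); zero vectors pass through.
    Idempotent, and maps v and -v to the same representative.
    """
    v = np.asarray(v, dtype=float)
    single = v.ndim == 1
    v2 = np.atleast_2d(v).copy()
    lead = np.argmax(np.abs(v2), axis=-1)
    sign = np.sign(np.take_along_axis(v2, lead[..., None], axis=-1))[..., 0]
    v2[sign < 0] *= -1.0
    return v2[0] if single else v2.reshape(v.shape)


def compute_structure_tensor(
    volume: np.ndarray, voxel_size, params: StructureTensorParams | None = None
) -> np.ndarray:
    """Structure tensor field T(x), shape (*volume.shape, 3, 3), float32.

    Gradients are derivative-of-Gaussian at ``params.sigma_gradient`` (μm) and
    the gradient outer products are smoothed with a Gaussian window at
    ``params.sigma_window`` (μm); both sigmas are converted to voxels per axis.
    T is symmetric positive semidefinite at every voxel.
    """
    params = params or StructureTensorParams()
    vs = _as_voxel_size(voxel_size)
    vol = np.asarray(volume, dtype=np.float32)
    if vol.ndim != 3:
        raise ValueError("volume must be 3D")
    sig_g = params.sigma_gradient / vs
    sig_w = params.sigma_window / vs
    if np.any(np.array(vol.shape) < 2 * params.sigma_window / vs.min()):
        raise ValueError("volume too small for the requested window scale")

    grads = []
    for ax in range(3):
        order = [0, 0, 0]
        order[ax] = 1
        grads.append(ndimage.gaussian_filter(vol, sigma=sig_g, order=order, mode="nearest"))

    T = np.empty(vol.shape + (3, 3), dtype=np.float32)
    for a in range(3):
        for b in range(a, 3):
            comp = ndimage.gaussian_filter(grads[a] * grads[b], sigma=sig_w, mode="nearest")
            T[..., a, b] = comp
            if a != b:
                T[..., b, a] = comp
    return T


def _border_mask(shape, margin_vox: np.ndarray) -> np.ndarray:
    """True inside the filter-supported interior, False within the border margin."""
    ok = np.ones(shape, dtype=bool)
    for ax, m in enumerate(margin_vox):
        m = int(m)
        if m <= 0:
            continue
        sl = [slice(None)] * 3
        sl[ax] = slice(0, m)
        ok[tuple(sl)] = False
        sl[ax] = slice(shape[ax] - m, shape[ax])
        ok[tuple(sl)] = False
    return ok


def energy_validity_mask(energy: np.ndarray, method: str = "otsu", rel_floor: float = 1e-3) -> np.ndarray:
    """Voxels whose gradient energy plausibly comes from labeled structure.

    "otsu" (default) thresholds log-energy, separating the noise-gradient mode of
    the background from the fiber-gradient mode. "median" applies a floor of
    ``rel_floor`` × the volume-median energy.
    """
    if method == "median":
        return energy > rel_floor * np.median(energy)
    if method != "otsu":
        raise ValueError(f"unknown validity method {method!r}")
    pos = energy > 0
    if not pos.any():
        return np.zeros_like(energy, dtype=bool)
    loge = np.log(energy[pos].astype(np.float64))
    if loge.max() - loge.min() < 1e-6:
        return pos
    thr = threshold_otsu(loge, nbins=256)
    out = np.zeros_like(energy, dtype=bool)
    out[pos] = loge > thr
    return out


def principal_orientation(
    tensor: np.ndarray,
    voxel_size,
    params: StructureTensorParams | None = None,
    mask_method: str = "otsu",
    energy_rel_floor: float = 1e-3,
) -> OrientationField:
    """Fiber axis, coherence and validity from a structure-tensor field.

    Axis = eigenvector of the smallest eigenvalue (intensity varies least along
    a bright tube). With eigenvalues λ1 ≤ λ2 ≤ λ3, coherence = (λ2-λ1)/(λ1+λ2+λ3)
    clipped to [0, 1]; 0 for an isotropic tensor, where the axis falls back to
    e_z by convention. Voxels fail validity when their energy falls below the
    structure threshold (see energy_validity_mask) or when they lie within
    ceil(3·sigma_window) voxels of the volume edge, where the filter support is
    truncated.
    """
    params = params or StructureTensorParams()
    vs = _as_voxel_size(voxel_size)
    if tensor.ndim != 5 or tensor.shape[-2:] != (3, 3):
        raise ValueError("tensor field must have shape (*vol, 3, 3)")
    if not np.isfinite(tensor).all():
        raise ValueError("tensor field contains non-finite values")
    shape = tensor.shape[:3]
    energy = (tensor[..., 0, 0] + tensor[..., 1, 1] + tensor[..., 2, 2]).astype(np.float32)

    valid = energy_validity_mask(energy, method=mask_method, rel_floor=energy_rel_floor)
    margin = np.ceil(3.0 * params.sigma_window / vs).astype(int)
    valid &= _border_mask(shape, margin)

    axis = np.zeros(shape + (3,), dtype=np.float32)
    coherence = np.zeros(shape, dtype=np.float32)
    if valid.any():
        Tv = tensor[valid].astype(np.float32)
        w, V = np.linalg.eigh(Tv)  # ascending eigenvalues
        tr = w.sum(axis=1)
        tr_safe = np.where(tr > 0, tr, 1.0)
        coh = np.clip((w[:, 1] - w[:, 0]) / tr_safe, 0.0, 1.0)
        ax = V[:, :, 0]
        # isotropic / degenerate tensors: coherence 0, axis e_z by convention
        degen = (w[:, 1] - w[:, 0]) <= 1e-7 * np.maximum(tr, 1e-30)
        ax[degen] = np.array([1.0, 0.0, 0.0], dtype=np.float32)
        coh[degen] = 0.0
        axis[valid] = canonicalize(ax).astype(np.float32)
        coherence[valid] = coh.astype(np.float32)
    return OrientationField(axis=axis, coherence=coherence, energy=energy, valid=valid, voxel_size=vs)


def orientation_to_rgb(field: OrientationField, scale_by: str = "coherence", intensity: np.ndarray | None = None) -> np.ndarray:
    """Direction-coded RGB volume: R = |v·e_ML|, G = |v·e_DV|, B = |v·e_AP|.

    The anatomical mapping follows the default (ML, DV, AP) = (x, y, z), i.e.
    red codes medio-lateral, green dorso-ventral, blue antero-posterior.
    Channels are scaled by coherence (default) or by a supplied intensity
    volume normalized to its maximum; invalid voxels are black.
    """
    v = field.axis
    # axis components stored (z, y, x); RGB wants (|v_x|, |v_y|, |v_z|)
    rgb = np.abs(v[..., ::-1]).astype(np.float32)
    if scale_by == "coherence":
        w = field.coherence
    elif scale_by == "intensity":
        if intensity is None:
            raise ValueError("scale_by='intensity' requires an intensity volume")
        mx = float(intensity.max()) or 1.0
        w = (intensity / mx).astype(np.float32)
    else:
        raise ValueError(f"unknown scale_by {scale_by!r}")
    rgb *= w[..., None]
    rgb[~field.valid] = 0.0
    return rgb
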