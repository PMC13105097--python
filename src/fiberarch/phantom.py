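"""Synthetic axon phantoms with voxel-level ground truth.

Emulates volumes of brightly labeled large-caliber axons on a dark background,
in the three architectural motifs observed in human white matter:

* ``meshwork`` — low-density fibers with uniformly random 3D directions
  (the multi-orientation motif of superficial white matter),
* ``laminar`` — stacked slabs of thickness λ/2 along a layer normal, fibers in
  alternate slabs parallel to one of two near-orthogonal in-plane axes
  (the laminar/orthogonal motif), and
* ``bundled`` — high-density fibers near-parallel to a single bundle axis
  (the coherent-tract motif).

Fibers are straight tubes with a radial Gaussian intensity profile (peak 1,
scale = radius); overlapping tubes combine by maximum (label saturation).
The rendered volume is then blurred (PSF), offset by a background level, and
degraded with additive Gaussian noise — a minimal model of lightsheet imaging.
Voxel-level ground truth records each fiber's own axial direction wherever a
tube interior (distance ≤ radius) covers a voxel, and is NaN on background.

All positions are in μm; arrays and vectors are in (z, y, x) order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .orientation import OrientationField, canonicalize

MOTIFS = ("meshwork", "laminar", "bundled")
MOTIF_CODES = {"background": 0, "meshwork": 1, "laminar": 2, "bundled": 3}

_DEFAULT_FILL = {"meshwork": 0.03, "laminar": 0.12, "bundled": 0.30}


class PhantomGenerationError(RuntimeError):
    pass


def _unit(v, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (3,) or abs(np.linalg.norm(v) - 1.0) > 1e-9:
        raise ValueError(f"{name} must be a unit 3-vector (|norm-1| <= 1e-9)")
    return v


@dataclass
class PhantomSpec:
    """Full description of a synthetic axon volume.

    Defaults are the desk-scale study conditions: 1 μm isotropic voxels,
    1 μm fiber radius (large-caliber axons at tissue scale), per-motif volume
    fill targets increasing meshwork < laminar < bundled, 40 μm laminar period,
    5° angular jitter, ~1 μm PSF, and mild additive noise.
    """

    motif: str = "meshwork"
    shape: tuple = (192, 192, 192)
    voxel_size: float = 1.0
    fiber_radius: float = 1.0
    fiber_count: int | None = None
    volume_fill_target: float | None = None
    laminar_period: float = 40.0
    layer_normal: tuple = (1.0, 0.0, 0.0)  # +z
    layer_axes: tuple = ((0.0, 0.0, 1.0), (0.0, 1.0, 0.0))  # x, y
    bundle_axis: tuple = (1.0, 0.0, 0.0)  # z
    angular_jitter_deg: float = 5.0
    psf_sigma: tuple = (1.0, 1.0, 1.0)
    noise_sd: float = 0.05
    background_level: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.motif not in MOTIFS:
            raise ValueError(f"motif must be one of {MOTIFS}")
        if self.volume_fill_target is None and self.fiber_count is None:
            self.volume_fill_target = _DEFAULT_FILL[self.motif]
        if self.angular_jitter_deg < 0:
            raise ValueError("angular_jitter_deg must be >= 0")
        if self.fiber_radius < self.voxel_size / 2:
            raise ValueError("fiber_radius must be >= voxel_size/2 (unresolvable tube)")
        if self.motif == "laminar":
            if self.laminar_period <= 0:
                raise ValueError("laminar_period must be > 0")
            n = _unit(self.layer_normal, "layer_normal")
            a0 = _unit(self.layer_axes[0], "layer_axes[0]")
            a1 = _unit(self.layer_axes[1], "layer_axes[1]")
            if abs(np.dot(a0, a1)) > 0.5:  # axial separation >= 60°
                raise ValueError("layer_axes must be separated by at least 60°")
            for a in (a0, a1):
                if abs(np.dot(a, n)) > 0.35:  # within ~20° of perpendicular
                    raise ValueError("layer_axes must be near-perpendicular to layer_normal")
        if self.motif == "bundled":
            _unit(self.bundle_axis, "bundle_axis")

    @property
    def extent_um(self) -> np.ndarray:
        return np.asarray(self.shape, dtype=float) * self.voxel_size


@dataclass
class Phantom:
    """Rendered volume plus voxel-level ground truth.

    truth_orientation is NaN where no fiber interior covers the voxel (an
    explicit undefined sentinel, never a zero vector); truth_valid marks the
    defined voxels. truth_motif holds MOTIF_CODES per voxel.
    """

    volume: np.ndarray
    truth_orientation: np.ndarray
    truth_valid: np.ndarray
    truth_motif: np.ndarray
    spec: object = None

    @property
    def foreground_fraction(self) -> float:
        return float(self.truth_valid.mean())


def _ray_box(p: np.ndarray, d: np.ndarray, extent: np.ndarray):
    """Intersect the line p + t·d with the box [0, extent]^3; return (t0, t1) or None."""
    t0, t1 = -np.inf, np.inf
    for ax in range(3):
        if abs(d[ax]) < 1e-12:
            if p[ax] < 0 or p[ax] > extent[ax]:
                return None
            continue
        ta = (0.0 - p[ax]) / d[ax]
        tb = (extent[ax] - p[ax]) / d[ax]
        t0 = max(t0, min(ta, tb))
        t1 = min(t1, max(ta, tb))
    if not (t1 > t0):
        return None
    return t0, t1


def _splat_segment(canvas, a, b, radius, voxel_size, direction=None, truth=None, truth_g=None, truth_label=None, motif_code=0):
    """Max-combine one tube segment into the canvas; optionally record ground truth."""
    vs = voxel_size
    shape = np.asarray(canvas.shape)
    pad = 5.5 * radius  # Gaussian tail < 3e-7 at the box boundary
    lo = np.maximum(np.floor((np.minimum(a, b) - pad) / vs).astype(int), 0)
    hi = np.minimum(np.ceil((np.maximum(a, b) + pad) / vs).astype(int) + 1, shape)
    if np.any(hi <= lo):
        return
    grids = np.meshgrid(*[(np.arange(lo[i], hi[i]) + 0.5) * vs for i in range(3)], indexing="ij")
    pts = np.stack(grids, axis=-1)
    ab = b - a
    seg_len2 = float(ab @ ab)
    rel = pts - a
    if seg_len2 < 1e-24:
        dist2 = np.einsum("...i,...i->...", rel, rel)
    else:
        t = np.clip(np.einsum("...i,i->...", rel, ab) / seg_len2, 0.0, 1.0)
        diff = rel - t[..., None] * ab
        dist2 = np.einsum("...i,...i->...", diff, diff)
    g = np.exp(-0.5 * dist2 / (radius * radius)).astype(np.float32)
    sl = tuple(slice(lo[i], hi[i]) for i in range(3))
    sub = canvas[sl]
    np.maximum(sub, g, out=sub)
    if truth is not None:
        interior = dist2 <= radius * radius
        tg = truth_g[sl]
        better = interior & (g > tg)
        if better.any():
            tg[better] = g[better]
            truth[sl][better] = direction.astype(np.float32)
            truth_label[sl][better] = motif_code


def render_fibers(paths, radius: float, canvas: np.ndarray, voxel_size: float = 1.0) -> np.ndarray:
    """Render fiber polylines (μm coordinates) as Gaussian-profile tubes.

    Each fiber contributes peak amplitude 1 on its axis with radial Gaussian
    scale = radius; overlapping fibers combine by maximum. Segments outside the
    canvas are clipped. Modifies and returns ``canvas``.
    """
    if radius < voxel_size / 2:
        raise ValueError("radius must be >= voxel_size/2 (unresolvable tube)")
    max_seg = max(8.0, 4.0 * radius)
    for path in paths:
        path = np.asarray(path, dtype=float)
        for a, b in zip(path[:-1], path[1:]):
            n_sub = max(1, int(np.ceil(np.linalg.norm(b - a) / max_seg)))
            for k in range(n_sub):
                _splat_segment(
                    canvas,
                    a + (b - a) * (k / n_sub),
                    a + (b - a) * ((k + 1) / n_sub),
                    radius,
                    voxel_size,
                )
    return canvas


def add_imaging_noise(volume, psf_sigma, noise_sd, background_level, seed, voxel_size=1.0) -> np.ndarray:
    """Blur with a per-axis Gaussian PSF (μm), add background, add Gaussian noise, clip at 0."""
    psf = np.asarray(psf_sigma, dtype=float)
    if psf.ndim == 0:
        psf = np.full(3, float(psf))
    if np.any(psf < 0) or noise_sd < 0:
        raise ValueError("psf_sigma and noise_sd must be >= 0")
    out = np.asarray(volume, dtype=np.float32)
    if not np.isfinite(out).all():
        raise ValueError("volume contains non-finite values")
    if np.any(psf > 0):
        out = ndimage.gaussian_filter(out, sigma=psf / voxel_size, mode="nearest")
    out = out + np.float32(background_level)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, noise_sd, size=out.shape).astype(np.float32)
    return np.clip(out, 0.0, None)


def _jitter_axis(axis: np.ndarray, sigma_deg: float, rng) -> np.ndarray:
    """Tilt an axis by a half-normal(σ) angle toward a uniformly random azimuth."""
    if sigma_deg <= 0:
        return axis.copy()
    ang = abs(rng.normal(0.0, np.radians(sigma_deg)))
    # orthonormal pair perpendicular to axis
    ref = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    v = np.cos(ang) * axis + np.sin(ang) * (np.cos(phi) * e1 + np.sin(phi) * e2)
    return v / np.linalg.norm(v)


def _inplane_jitter(axis: np.ndarray, normal: np.ndarray, sigma_deg: float, rng) -> np.ndarray:
    """Rotate an in-plane axis about the layer normal by a signed normal(σ) angle.

    Laminar jitter is restricted to the layer plane so fibers stay inside their
    slab over their full length; free 3D jitter would let them drift across
    slabs and destroy the alternation the generator defines.
    """
    if sigma_deg <= 0:
        return axis.copy()
    ang = rng.normal(0.0, np.radians(sigma_deg))
    perp = np.cross(normal, axis)
    v = np.cos(ang) * axis + np.sin(ang) * perp
    v -= np.dot(v, normal) * normal
    return v / np.linalg.norm(v)


def _sample_fiber(spec: PhantomSpec, rng):
    """Draw one fiber: (endpoint a, endpoint b, axial direction), μm coordinates."""
    extent = spec.extent_um
    p = rng.uniform(0.0, 1.0, size=3) * extent
    if spec.motif == "meshwork":
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
    elif spec.motif == "bundled":
        d = _jitter_axis(np.asarray(spec.bundle_axis, dtype=float), spec.angular_jitter_deg, rng)
    else:  # laminar
        n = np.asarray(spec.layer_normal, dtype=float)
        slab = int(np.floor((p @ n) / (spec.laminar_period / 2.0)))
        base = np.asarray(spec.layer_axes[slab % 2], dtype=float)
        d = _inplane_jitter(base, n, spec.angular_jitter_deg, rng)
    hit = _ray_box(p, d, extent)
    if hit is None:
        return None
    t0, t1 = hit
    return p + t0 * d, p + t1 * d, d


def generate_phantom(spec: PhantomSpec, max_fibers: int | None = None) -> Phantom:
    """Generate a synthetic axon volume with ground truth from a PhantomSpec.

    Fibers are added until ``volume_fill_target`` (fraction of voxels covered by
    a tube interior) is reached, or exactly ``fiber_count`` fibers are drawn if
    given. ``max_fibers`` overrides the iteration cap of the fill loop; an
    unreachable fill target raises PhantomGenerationError naming the achieved
    density. Identical specs (including seed) produce bit-identical phantoms.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.shape)
    canvas = np.zeros(shape, dtype=np.float32)
    truth = np.full(shape + (3,), np.nan, dtype=np.float32)
    truth_g = np.zeros(shape, dtype=np.float32)
    truth_label = np.zeros(shape, dtype=np.uint8)
    vs = spec.voxel_size
    motif_code = MOTIF_CODES[spec.motif]
    max_seg = max(8.0, 4.0 * spec.fiber_radius)

    def add_fiber():
        f = _sample_fiber(spec, rng)
        if f is None:
            return
        a, b, d = f
        n_sub = max(1, int(np.ceil(np.linalg.norm(b - a) / max_seg)))
        dcan = canonicalize(d)
        for k in range(n_sub):
            _splat_segment(
                canvas,
                a + (b - a) * (k / n_sub),
                a + (b - a) * ((k + 1) / n_sub),
                spec.fiber_radius,
                vs,
                direction=dcan,
                truth=truth,
                truth_g=truth_g,
                truth_label=truth_label,
                motif_code=motif_code,
            )

    if spec.fiber_count is not None:
        for _ in range(int(spec.fiber_count)):
            add_fiber()
    else:
        target = float(spec.volume_fill_target)
        vol_um3 = float(np.prod(spec.extent_um))
        mean_len = 0.7 * float(max(spec.extent_um))
        k_expected = max(1, int(target * vol_um3 / (np.pi * spec.fiber_radius**2 * mean_len)))
        cap = 6 * k_expected + 200 if max_fibers is None else int(max_fibers)
        batch = max(1, min(max(16, k_expected // 8), cap))
        drawn = 0
        while True:
            frac = float((truth_g > 0).mean())
            if frac >= target:
                break
            if drawn >= cap:
                raise PhantomGenerationError(
                    f"fill target {target:.3f} unreachable within iteration cap; achieved density {frac:.4f} after {drawn} fibers"
                )
            for _ in range(batch):
                add_fiber()
            drawn += batch

    noise_seed = int(rng.integers(0, 2**31 - 1))
    volume = add_imaging_noise(
        canvas, spec.psf_sigma, spec.noise_sd, spec.background_level, noise_seed, voxel_size=vs
    )
    valid = truth_g > 0
    return Phantom(volume=volume, truth_orientation=truth, truth_valid=valid, truth_motif=truth_label, spec=spec)


def generate_composite(specs, axis: int = 2) -> Phantom:
    """Concatenate phantoms generated from ``specs`` along one array axis.

    All specs must share voxel size and shape on the non-concatenated axes.
    Per-voxel motif labels record which region each voxel came from, giving the
    ground truth for motif-classification maps across region boundaries.
    """
    phantoms = [generate_phantom(s) for s in specs]
    vs = {s.voxel_size for s in specs}
    if len(vs) != 1:
        raise ValueError("composite phantoms require a common voxel size")
    return Phantom(
        volume=np.concatenate([p.volume for p in phantoms], axis=axis),
        truth_orientation=np.concatenate([p.truth_orientation for p in phantoms], axis=axis),
        truth_valid=np.concatenate([p.truth_valid for p in phantoms], axis=axis),
        truth_motif=np.concatenate([p.truth_motif for p in phantoms], axis=axis),
        spec=tuple(specs),
    )


def patchwork_orientation_field(shape, patch_um: float, voxel_size: float = 1.0, seed: int = 0) -> OrientationField:
    """Orientation field that is constant on cubic patches of side ``patch_um``.

    Each patch receives an independent uniformly random axial direction. Used
    to probe correlation-length recovery: the tensor-field autocorrelation of
    this field decays on the scale of the patch size.
    """
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in shape)
    n_patch = np.ceil(np.asarray(shape) * voxel_size / patch_um).astype(int)
    dirs = rng.normal(size=(*n_patch, 3))
    dirs /= np.linalg.norm(dirs, axis=-1, keepdims=True)
    dirs = canonicalize(dirs.reshape(-1, 3)).reshape(*n_patch, 3).astype(np.float32)
    idx = [np.minimum((np.arange(shape[i]) * voxel_size / patch_um).astype(int), n_patch[i] - 1) for i in range(3)]
    axis = dirs[np.ix_(idx[0], idx[1], idx[2])]
    ones = np.ones(shape, dtype=np.float32)
    return OrientationField(
        axis=axis,
        coherence=ones.copy(),
        energy=ones.copy(),
        valid=np.ones(shape, dtype=bool),
        voxel_size=np.full(3, float(voxel_size)),
    )
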