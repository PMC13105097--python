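"""Block-wise discrete orientation distribution functions.

The orientation field is partitioned into non-overlapping analysis cubes
(default 100³ voxels, the tissue-scale analysis unit). Within each cube, every
valid voxel's axial direction contributes half its weight to the sphere bin
nearest +v and half to the bin nearest -v, producing a normalized discrete ODF
ψ over the sphere sampling (default 6,500 directions). Each ODF is summarized
by its generalized fractional anisotropy and by its peaks, with peak pairs
separated by at least 45°.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .orientation import OrientationField, canonicalize
from .sphere import SphereSampling


@dataclass
class BlockGrid:
    """Non-overlapping cube partition of the voxel grid.

    Blocks are anchored at ``origin`` (voxels); partial blocks at the volume
    edge are dropped. Intervals are half-open in (z, y, x) voxel indices.
    """

    block_size: int = 100
    origin: tuple = (0, 0, 0)
    stride: int | None = None

    def __post_init__(self):
        if self.block_size < 16:
            raise ValueError("block_size must be >= 16")
        if self.stride is None:
            self.stride = self.block_size
        if self.stride < 1:
            raise ValueError("stride must be >= 1")

    def blocks(self, shape):
        """Yield (index_tuple, slices) for every block fully inside ``shape``."""
        counts = [
            max(0, (shape[ax] - self.origin[ax] - self.block_size) // self.stride + 1)
            for ax in range(3)
        ]
        for i in range(counts[0]):
            for j in range(counts[1]):
                for k in range(counts[2]):
                    starts = [self.origin[ax] + idx * self.stride for ax, idx in enumerate((i, j, k))]
                    yield (i, j, k), tuple(slice(s, s + self.block_size) for s in starts)

    def grid_shape(self, shape):
        return tuple(
            max(0, (shape[ax] - self.origin[ax] - self.block_size) // self.stride + 1) for ax in range(3)
        )

    def center_um(self, index, voxel_size):
        vs = np.asarray(voxel_size, dtype=float)
        starts = np.array([self.origin[ax] + index[ax] * self.stride for ax in range(3)], dtype=float)
        return (starts + self.block_size / 2.0) * vs


@dataclass
class BlockODF:
    """Discrete ODF of one analysis cube.

    psi : (N,) nonnegative weights summing to 1 (antipodally symmetric);
    gfa : generalized fractional anisotropy of psi;
    peaks : list of (axis, amplitude), amplitude-descending, axes the
        sign-canonical member of each antipodal pair, pairwise >= 45° apart;
    n_valid : number of contributing voxels; empty when n_valid == 0.
    """

    psi: np.ndarray
    gfa: float
    n_valid: int
    block_index: tuple
    center_um: np.ndarray
    peaks: list = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return self.n_valid == 0

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


def gfa(psi: np.ndarray) -> float:
    """Generalized fractional anisotropy of a discrete ODF.

    GFA = sqrt( n·Σ(ψ_i − ψ̄)² / ((n−1)·Σψ_i²) ), the standard dMRI
    normalized-dispersion statistic: 0 when every direction carries equal
    weight, 1 when all weight sits on a single direction.
    """
    psi = np.asarray(psi, dtype=np.float64)
    s2 = float(np.sum(psi * psi))
    if s2 <= 0.0 or float(np.sum(psi)) <= 0.0:
        raise ValueError("GFA undefined for an all-zero ODF")
    if psi.max() == psi.min():  # exactly uniform: zero dispersion by definition
        return 0.0
    n = psi.size
    mean = psi.mean()
    num = n * float(np.sum((psi - mean) ** 2))
    return float(np.sqrt(num / ((n - 1) * s2)))


def smooth_odf(psi: np.ndarray, sphere: SphereSampling) -> np.ndarray:
    """One step of neighbor-graph averaging (kernel width ≈ the bin spacing, ~5°)."""
    out = psi.astype(np.float64).copy()
    for i, nb in enumerate(sphere.neighbors):
        out[i] = 0.5 * psi[i] + 0.5 * psi[nb].mean()
    s = out.sum()
    return out / s if s > 0 else out


def find_odf_peaks(
    odf,
    sphere: SphereSampling,
    min_separation_deg: float = 45.0,
    rel_amplitude: float = 0.3,
    smooth: bool = True,
):
    """ODF peaks: smoothed local maxima, antipodally merged, >= 45° apart.

    Candidates are local maxima of the (optionally neighbor-smoothed) ψ on the
    sphere graph with amplitude >= rel_amplitude × max(ψ); each antipodal pair
    is reported once as its sign-canonical axis; peaks are then selected
    greedily by amplitude subject to pairwise axial separation
    >= min_separation_deg. Returns a list of (axis, amplitude).
    """
    psi = odf.psi if isinstance(odf, BlockODF) else np.asarray(odf, dtype=np.float64)
    if psi.sum() <= 0:
        return []
    p = smooth_odf(psi, sphere) if smooth else psi / psi.sum()
    pmax = p.max()
    if pmax <= 0:
        return []
    cand = [
        i
        for i in range(sphere.n)
        if p[i] >= rel_amplitude * pmax and all(p[i] >= p[j] for j in sphere.neighbors[i])
    ]
    # merge antipodal duplicates: keep one member per ± pair
    seen = set()
    merged = []
    for i in cand:
        a = int(sphere.antipode_index[i])
        if a in seen:
            continue
        seen.add(i)
        merged.append(i)
    merged.sort(key=lambda i: -p[i])
    min_dot = np.cos(np.radians(min_separation_deg))
    peaks = []
    for i in merged:
        d = sphere.directions[i]
        if all(abs(float(d @ q)) < min_dot + 1e-12 for q, _ in peaks):
            peaks.append((canonicalize(d), float(p[i])))
    return peaks


def accumulate_odf(
    ofield: OrientationField,
    grid: BlockGrid,
    sphere: SphereSampling,
    weighting: str = "count",
    min_separation_deg: float = 45.0,
    rel_amplitude: float = 0.3,
):
    """Accumulate per-block discrete ODFs and their GFA and peaks.

    weighting "count" gives every valid voxel unit weight; "coherence" weights
    by the structure-tensor coherence. Each voxel's weight is split half/half
    between the bins nearest +v and -v (the exact antipodes of each other in
    this sampling), so ψ is antipodally symmetric by construction. Blocks with
    no valid voxels are flagged empty.
    """
    if weighting not in ("count", "coherence"):
        raise ValueError("weighting must be 'count' or 'coherence'")
    out = []
    for index, sl in grid.blocks(ofield.shape):
        v = ofield.valid[sl]
        n_valid = int(v.sum())
        center = grid.center_um(index, ofield.voxel_size)
        psi = np.zeros(sphere.n, dtype=np.float64)
        if n_valid:
            axes = ofield.axis[sl][v]
            w = np.ones(n_valid) if weighting == "count" else ofield.coherence[sl][v].astype(np.float64)
            idx = sphere.nearest(axes)
            np.add.at(psi, idx, w / 2.0)
            np.add.at(psi, sphere.antipode_index[idx], w / 2.0)
            tot = psi.sum()
            if tot > 0:
                psi /= tot
            else:
                n_valid = 0
        block = BlockODF(
            psi=psi,
            gfa=gfa(psi) if n_valid else float("nan"),
            n_valid=n_valid,
            block_index=index,
            center_um=center,
        )
        if n_valid:
            block.peaks = find_odf_peaks(block, sphere, min_separation_deg, rel_amplitude)
        out.append(block)
    return out
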