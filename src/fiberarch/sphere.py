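"""Discrete sphere samplings used as ODF supports.

Fiber orientations are axial (v and -v are the same physical direction), so the
sampling is built to be exactly centrally symmetric: an equal-area spiral is laid
out on one hemisphere and mirrored through the origin. The antipode map is then
an exact involution, and a discrete ODF accumulated by splitting each axial
observation between the bins nearest +v and -v is antipodally symmetric to
machine precision.

All direction vectors use (z, y, x) component order, matching array axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))

# octahedral fixture layout, (z, y, x) components
_OCTAHEDRON = np.array(
    [
        [1.0, 0.0, 0.0],
        [-1.0, 0.0, 0.0],
        [0.0, 1.0, 0.0],
        [0.0, -1.0, 0.0],
        [0.0, 0.0, 1.0],
        [0.0, 0.0, -1.0],
    ]
)


@dataclass
class SphereSampling:
    """N unit directions with a symmetric neighbor graph and exact antipodes.

    Attributes
    ----------
    directions : (N, 3) float array of unit vectors, (z, y, x) order.
    neighbors : list of int arrays, symmetric k-nearest-neighbor adjacency.
    antipode_index : (N,) int array; ``directions[antipode_index[i]] == -directions[i]``.
    """

    directions: np.ndarray
    neighbors: list
    antipode_index: np.ndarray
    _tree: cKDTree = field(default=None, repr=False, compare=False)

    @property
    def n(self) -> int:
        return self.directions.shape[0]

    @property
    def tree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.directions)
        return self._tree

    def nearest(self, vectors: np.ndarray) -> np.ndarray:
        """Index of the sampling direction nearest each unit vector."""
        _, idx = self.tree.query(np.atleast_2d(vectors), k=1)
        return idx


def _hemisphere_spiral(m: int) -> np.ndarray:
    i = np.arange(m)
    z = (i + 0.5) / m  # z in (0, 1): strictly one hemisphere
    rho = np.sqrt(1.0 - z * z)
    phi = i * _GOLDEN_ANGLE
    return np.stack([z, rho * np.sin(phi), rho * np.cos(phi)], axis=1)


def _neighbor_graph(directions: np.ndarray, k: int) -> list:
    tree = cKDTree(directions)
    _, idx = tree.query(directions, k=k + 1)
    adj = [set() for _ in range(len(directions))]
    for i, row in enumerate(idx):
        for j in row[1:]:
            adj[i].add(int(j))
            adj[int(j)].add(i)
    return [np.array(sorted(s), dtype=np.intp) for s in adj]


def build_sphere(n_points: int = 6500, layout: str = "spiral", k_neighbors: int = 6) -> SphereSampling:
    """Build a centrally symmetric sampling of the unit sphere.

    Parameters
    ----------
    n_points : even number of directions (default 6500, the ODF resolution used
        throughout the analysis).
    layout : "spiral" (equal-area hemisphere spiral + antipodes) or "octahedral"
        (n_points must be 6; the ±x, ±y, ±z fixture used in tests).
    k_neighbors : nearest-neighbor count for the adjacency graph (symmetrized).
    """
    if n_points < 12 and layout == "spiral":
        raise ValueError("spiral sphere sampling requires n_points >= 12")
    if layout == "octahedral":
        if n_points != 6:
            raise ValueError("octahedral layout is defined for n_points == 6")
        directions = _OCTAHEDRON.copy()
        antipode = np.array([1, 0, 3, 2, 5, 4])
        neighbors = _neighbor_graph(directions, 4)
        return SphereSampling(directions, neighbors, antipode)
    if layout != "spiral":
        raise ValueError(f"unknown sphere layout {layout!r}")
    if n_points % 2:
        raise ValueError("n_points must be even for an antipodally symmetric sampling")
    m = n_points // 2
    north = _hemisphere_spiral(m)
    directions = np.concatenate([north, -north], axis=0)
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    antipode = np.concatenate([np.arange(m) + m, np.arange(m)])
    neighbors = _neighbor_graph(directions, k_neighbors)
    return SphereSampling(directions, neighbors, antipode.astype(np.intp))


def mean_nearest_neighbor_angle(sphere: SphereSampling) -> float:
    """Mean angular spacing (radians) between each direction and its nearest neighbor."""
    d, _ = sphere.tree.query(sphere.directions, k=2)
    chord = d[:, 1]
    return float(np.mean(2.0 * np.arcsin(np.clip(chord / 2.0, 0.0, 1.0))))


def min_pairwise_angle(sphere: SphereSampling) -> float:
    """Minimum angular spacing (radians) over all direction pairs."""
    d, _ = sphere.tree.query(sphere.directions, k=2)
    chord = d[:, 1].min()
    return float(2.0 * np.arcsin(np.clip(chord / 2.0, 0.0, 1.0)))
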