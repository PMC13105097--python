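"""Volume I/O: TIFF stacks and chunked multiresolution array stores.

Volumes are (z, y, x) arrays with voxel-size metadata in μm. The chunked
store is a zarr group whose arrays "0", "1", … form a factor-2 image pyramid
(level L voxels are 2^L times the base voxel size); TIFF stacks carry the
voxel size in ImageJ-style metadata. Reading a pyramid level absent from a
store falls back to 2× mean-downsampling of the finest available level, with
a warning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
import zarr


@dataclass
class PyramidMeta:
    """Voxel-size bookkeeping for expansion imaging and the MIP pyramid.

    ``physical_voxel_um`` is the voxel pitch in the expanded gel;
    ``expansion_factor`` converts back to the original tissue scale, giving
    ``base_voxel_um = physical_voxel_um / expansion_factor`` at pyramid level
    0; level L voxels are ``base_voxel_um × 2**L``.
    """

    base_voxel_um: float
    expansion_factor: float = 1.0
    level: int = 0

    @classmethod
    def from_physical(cls, physical_voxel_um: float, expansion_factor: float, level: int = 0) -> "PyramidMeta":
        return cls(base_voxel_um=physical_voxel_um / expansion_factor, expansion_factor=expansion_factor, level=level)

    @property
    def physical_voxel_um(self) -> float:
        return self.base_voxel_um * self.expansion_factor

    @property
    def voxel_um(self) -> float:
        """Tissue-scale voxel size at this pyramid level."""
        return mip_voxel_size(self, self.level)


def mip_voxel_size(meta: PyramidMeta, level: int) -> float:
    """Tissue-scale voxel size (μm) at pyramid level ``level``: base × 2^level."""
    if level < 0:
        raise ValueError("pyramid level must be >= 0")
    return meta.base_voxel_um * 2.0**level


def downsample2x(volume: np.ndarray) -> np.ndarray:
    """2× mean-downsampling per axis (trailing odd voxels dropped)."""
    s = [(d // 2) * 2 for d in volume.shape]
    v = volume[: s[0], : s[1], : s[2]].astype(np.float32)
    return v.reshape(s[0] // 2, 2, s[1] // 2, 2, s[2] // 2, 2).mean(axis=(1, 3, 5))


def write_volume(path, volume: np.ndarray, voxel_um: float, meta: PyramidMeta | None = None, levels: int = 1):
    """Write a volume as a TIFF stack (.tif) or a multiresolution zarr store.

    ``voxel_um`` is the (isotropic) voxel size of the level written; for zarr,
    ``levels`` additional pyramid levels are generated by 2× mean-downsampling.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        vol = np.asarray(volume, dtype=np.float32)
        axes = "ZYXS" if vol.ndim == 4 else "ZYX"
        tifffile.imwrite(
            path,
            vol,
            imagej=True,
            resolution=(1.0 / voxel_um, 1.0 / voxel_um),
            metadata={"spacing": voxel_um, "unit": "um", "axes": axes},
        )
        return
    root = zarr.open_group(str(path), mode="w")
    lvl = np.asarray(volume, dtype=np.float32)
    for L in range(levels):
        arr = root.create_array(str(L), shape=lvl.shape, dtype="float32", chunks=tuple(min(64, s) for s in lvl.shape))
        arr[:] = lvl
        if L + 1 < levels:
            lvl = downsample2x(lvl)
    root.attrs["voxel_size_um"] = float(voxel_um)
    root.attrs["axes"] = "zyx"
    if meta is not None:
        root.attrs["expansion_factor"] = float(meta.expansion_factor)
        root.attrs["base_voxel_um"] = float(meta.base_voxel_um)


def read_volume(path, level: int = 0, voxel_um: float | None = None):
    """Read a volume and its metadata; returns (array, PyramidMeta).

    For TIFF, the voxel size comes from the ImageJ metadata or, failing that,
    the explicit ``voxel_um`` argument (an error if neither is available).
    For zarr stores, a missing pyramid level is computed by repeated 2× mean-
    downsampling of the finest stored level, with a warning.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            vol = tf.asarray()
            vs = None
            if tf.imagej_metadata and "spacing" in tf.imagej_metadata:
                vs = float(tf.imagej_metadata["spacing"])
        if vs is None:
            vs = voxel_um
        if vs is None:
            raise ValueError("TIFF lacks voxel-size metadata; pass an explicit voxel size (--voxel-um)")
        if level != 0:
            raise ValueError("TIFF stacks are single-level; request level 0")
        return np.asarray(vol, dtype=np.float32), PyramidMeta(base_voxel_um=vs, level=0)
    root = zarr.open_group(str(path), mode="r")
    base_vs = root.attrs.get("voxel_size_um", voxel_um)
    if base_vs is None:
        raise ValueError("store lacks voxel-size metadata; pass an explicit voxel size (--voxel-um)")
    expansion = float(root.attrs.get("expansion_factor", 1.0))
    available = sorted((k for k in root.array_keys()), key=int)
    meta = PyramidMeta(base_voxel_um=float(base_vs), expansion_factor=expansion, level=level)
    if str(level) in available:
        return np.asarray(root[str(level)][:], dtype=np.float32), meta
    finer = [int(a) for a in available if int(a) < level]
    if not finer:
        raise ValueError(f"level {level} finer than stored levels {available}")
    src = max(finer)
    warnings.warn(f"pyramid level {level} absent; computing by 2x mean-downsampling from level {src}")
    vol = np.asarray(root[str(src)][:], dtype=np.float32)
    for _ in range(level - src):
        vol = downsample2x(vol)
    return vol, meta


def write_maps(out_dir, maps: dict, table=None):
    """Write block maps as CSV grids (one z-slab per section) plus an index JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    index = {}
    for name, grid in maps.items():
        fn = out_dir / f"{name}.csv"
        flat = grid.reshape(grid.shape[0], -1)
        header = f"# axis order (z,y,x); grid shape {grid.shape}; rows = z, columns = y*x flattened"
        np.savetxt(fn, flat, delimiter=",", header=header)
        index[name] = {"file": fn.name, "shape": list(grid.shape)}
    (out_dir / "maps.json").write_text(json.dumps(index, indent=2))
    if table is not None:
        table.to_csv(out_dir / "architecture_table.csv", index=False)


def read_map(out_dir, name: str) -> np.ndarray:
    out_dir = Path(out_dir)
    index = json.loads((out_dir / "maps.json").read_text())
    info = index[name]
    flat = np.loadtxt(out_dir / info["file"], delimiter=",", ndmin=2)
    return flat.reshape(info["shape"])
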