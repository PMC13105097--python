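"""Block-table masking and spatial-map assembly.

The per-block results (GFA, peaks, correlation lengths, laminar calls, motif)
are collected into an architecture table (one pandas row per analysis cube).
Blocks with low fractional anisotropy or at the border are omitted from all
spatial maps; maps are grids with one value per block cell, NaN where masked.
Cell ordering is z-major, 0-based, half-open block intervals in (z, y, x).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .odf import BlockGrid

MOTIF_MAP_CODES = {"masked": -1, "meshwork": 1, "multi_orientation": 1, "laminar": 2, "bundled": 3}

TABLE_COLUMNS = [
    "i", "j", "k", "center_z_um", "center_y_um", "center_x_um", "n_valid", "valid_fraction",
    "gfa", "n_peaks", "peak1", "peak2", "xi_e1_um", "xi_e2_um", "xi_e3_um",
    "r2_e1", "r2_e2", "r2_e3", "xi_max_um", "xi_capped",
    "is_laminar", "period_um", "snr1", "snr2", "reasons", "motif", "masked", "mask_reason",
]


def _fmt_axis(v) -> str:
    if v is None:
        return ""
    return "/".join(f"{float(x):.4f}" for x in v)


def build_table(blocks, fits, calls, motifs, block_size: int) -> pd.DataFrame:
    """Assemble the architecture table from per-block results.

    ``blocks`` are BlockODFs; ``fits``/``calls``/``motifs`` are parallel lists
    (entries may be None for empty blocks).
    """
    rows = []
    for odf, fit, call, motif in zip(blocks, fits, calls, motifs):
        i, j, k = odf.block_index
        row = {
            "i": i, "j": j, "k": k,
            "center_z_um": odf.center_um[0], "center_y_um": odf.center_um[1], "center_x_um": odf.center_um[2],
            "n_valid": odf.n_valid,
            "valid_fraction": odf.n_valid / block_size**3,
            "gfa": odf.gfa,
            "n_peaks": odf.n_peaks,
            "peak1": _fmt_axis(odf.peaks[0][0]) if odf.n_peaks >= 1 else "",
            "peak2": _fmt_axis(odf.peaks[1][0]) if odf.n_peaks >= 2 else "",
            "xi_e1_um": fit.xi[0] if fit else np.nan,
            "xi_e2_um": fit.xi[1] if fit else np.nan,
            "xi_e3_um": fit.xi[2] if fit else np.nan,
            "r2_e1": fit.r2[0] if fit else np.nan,
            "r2_e2": fit.r2[1] if fit else np.nan,
            "r2_e3": fit.r2[2] if fit else np.nan,
            "xi_max_um": fit.xi_max if fit else np.nan,
            "xi_capped": bool(fit.all_capped) if fit else False,
            "is_laminar": bool(call.is_laminar and odf.n_peaks >= 2) if call else False,
            "period_um": call.period_um if call else np.nan,
            "snr1": call.snr1 if call else np.nan,
            "snr2": call.snr2 if call else np.nan,
            "reasons": ";".join(sorted(call.reasons)) if call else "",
            "motif": motif if motif else "masked",
            "masked": odf.empty,
            "mask_reason": "empty" if odf.empty else "",
        }
        rows.append(row)
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def mask_blocks(
    table: pd.DataFrame,
    grid: BlockGrid,
    volume_shape,
    gfa_floor: float = 0.4,
    border_margin_blocks: int = 0,
    min_valid_fraction: float = 0.05,
) -> pd.DataFrame:
    """Apply the map-level omission rules; returns a copy with masked/mask_reason set.

    A block is masked when its GFA falls below ``gfa_floor`` ("low_fa"), when
    its voxel span comes within ``border_margin_blocks`` block-widths of a
    volume face — margin 0 masks only blocks flush with a face — ("border"),
    or when its valid-voxel fraction is below ``min_valid_fraction``, the
    proxy for lying outside labeled tissue ("tissue"). Raising ``gfa_floor``
    can only mask more blocks, never fewer.
    """
    out = table.copy()
    reasons = []
    masked = []
    shape = np.asarray(volume_shape)
    thr = border_margin_blocks * grid.block_size
    for _, row in out.iterrows():
        why = [] if not row["masked"] else [row["mask_reason"]]
        starts = np.array(
            [grid.origin[ax] + int(row[c]) * grid.stride for ax, c in enumerate(("i", "j", "k"))]
        )
        dist = int(np.minimum(starts, shape - (starts + grid.block_size)).min())
        if dist <= thr:
            why.append("border")
        if not np.isnan(row["gfa"]) and row["gfa"] < gfa_floor:
            why.append("low_fa")
        if row["valid_fraction"] < min_valid_fraction:
            why.append("tissue")
        masked.append(bool(why))
        reasons.append(";".join(sorted(set(w for w in why if w))))
    out["masked"] = masked
    out["mask_reason"] = reasons
    out.loc[out["masked"], "motif"] = "masked"
    return out


def assemble_maps(table: pd.DataFrame, grid_shape) -> dict:
    """Per-block-cell grids {gfa_map, xi_map, laminar_map, motif_map}.

    Masked cells are NaN (−1 in the integer motif map). Cells are indexed
    (i, j, k) in z-major order matching the block grid.
    """
    gfa_map = np.full(grid_shape, np.nan)
    xi_map = np.full(grid_shape, np.nan)
    lam_map = np.full(grid_shape, -1, dtype=np.int8)
    motif_map = np.full(grid_shape, -1, dtype=np.int8)
    for _, row in table.iterrows():
        idx = (int(row["i"]), int(row["j"]), int(row["k"]))
        if row["masked"]:
            continue
        gfa_map[idx] = row["gfa"]
        xi_map[idx] = row["xi_max_um"]
        lam_map[idx] = 1 if row["is_laminar"] else 0
        motif_map[idx] = MOTIF_MAP_CODES.get(row["motif"], -1)
    return {"gfa_map": gfa_map, "xi_map": xi_map, "laminar_map": lam_map, "motif_map": motif_map}


def render_map_png(grid: np.ndarray, path, vmin=None, vmax=None, cmap: str = "viridis", z: int | None = None):
    """Render one z-slab of a block map to PNG with a fixed color scale.

    GFA maps conventionally use vmin=0.4, vmax=1.0; masked (NaN / negative
    integer) cells render blank. ``z`` defaults to the middle slab.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = np.asarray(grid, dtype=float)
    if np.issubdtype(grid.dtype, np.integer):
        data[grid < 0] = np.nan
    z = grid.shape[0] // 2 if z is None else z
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(data[z], vmin=vmin, vmax=vmax, cmap=cmap, origin="upper", interpolation="nearest")
    ax.set_xlabel("x block")
    ax.set_ylabel("y block")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def audit_geometry(table: pd.DataFrame, grid: BlockGrid, volume_shape, voxel_size) -> bool:
    """Check that every block center maps back inside the input volume bounds."""
    vs = np.asarray(voxel_size, dtype=float)
    extent = np.asarray(volume_shape) * vs
    centers = table[["center_z_um", "center_y_um", "center_x_um"]].to_numpy()
    return bool(np.all((centers >= 0) & (centers <= extent)))
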