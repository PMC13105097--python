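"""End-to-end fiber-architecture analysis: orient → ODF → ACF → laminar → maps.

``run_pipeline`` takes a configuration (a PipelineConfig or an equivalent
mapping, e.g. parsed from YAML), executes every stage deterministically, and
returns the architecture table, the block maps, and a provenance record
listing every parameter. The input is either a volume on disk or a phantom
specification; analysis cubes default to 100³ voxels.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field as dfield

import numpy as np

from . import __version__
from .acf import acf3d, block_frame, dyadic_field, fit_frame_correlation_lengths, radial_profiles
from .io import read_volume, write_maps
from .laminar import LaminarCall, PeriodicityCriteria, classify_block, detect_periodicity
from .maps import assemble_maps, build_table, mask_blocks
from .odf import BlockGrid, accumulate_odf
from .orientation import StructureTensorParams, compute_structure_tensor, principal_orientation
from .phantom import PhantomSpec, generate_phantom
from .sphere import build_sphere

log = logging.getLogger("fiberarch")


@dataclass
class PipelineConfig:
    """All knobs of the analysis, with the package defaults."""

    input_path: str | None = None
    pyramid_level: int = 0
    voxel_um: float | None = None
    phantom: PhantomSpec | None = None
    sigma_gradient_um: float = 1.0
    sigma_window_um: float = 3.0
    mask_method: str = "otsu"
    block_size: int = 100
    block_origin: tuple = (0, 0, 0)
    n_sphere: int = 6500
    odf_weighting: str = "count"
    min_peak_separation_deg: float = 45.0
    peak_rel_amplitude: float = 0.3
    fit_floor: float = 0.05
    criteria: PeriodicityCriteria = dfield(default_factory=PeriodicityCriteria)
    gfa_bundled_floor: float = 0.5
    gfa_mask_floor: float = 0.4
    border_margin_blocks: int = 0
    min_valid_fraction: float = 0.05


@dataclass
class PipelineResult:
    table: object
    maps: dict
    grid: BlockGrid
    ofield: object
    blocks: list
    calls: list
    provenance: dict


def _to_plain(obj):
    """Recursively convert tuples/arrays to lists so the record is YAML-safe."""
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _provenance(cfg: PipelineConfig, volume_shape, voxel_um) -> dict:
    rec = {"fiberarch_version": __version__, "volume_shape": list(volume_shape), "voxel_um": float(voxel_um)}
    d = asdict(cfg)
    d["phantom"] = asdict(cfg.phantom) if cfg.phantom is not None else None
    rec["config"] = _to_plain(d)
    return rec


def analyze_volume(volume: np.ndarray, voxel_um: float, cfg: PipelineConfig) -> PipelineResult:
    """Run the analysis stages on an in-memory volume."""
    st_params = StructureTensorParams(cfg.sigma_gradient_um, cfg.sigma_window_um)
    log.info("structure tensor: shape=%s voxel=%.3f um", volume.shape, voxel_um)
    T = compute_structure_tensor(volume, voxel_um, st_params)
    ofield = principal_orientation(T, voxel_um, st_params, mask_method=cfg.mask_method)
    del T

    sphere = build_sphere(cfg.n_sphere)
    grid = BlockGrid(block_size=cfg.block_size, origin=tuple(cfg.block_origin))
    blocks = accumulate_odf(
        ofield, grid, sphere, weighting=cfg.odf_weighting,
        min_separation_deg=cfg.min_peak_separation_deg, rel_amplitude=cfg.peak_rel_amplitude,
    )
    log.info("accumulated %d block ODFs", len(blocks))

    dy = dyadic_field(ofield)
    fits, calls, motifs = [], [], []
    for odf, (_, sl) in zip(blocks, grid.blocks(ofield.shape)):
        if odf.empty or not odf.peaks:
            fits.append(None)
            calls.append(None)
            motifs.append("masked" if odf.empty else "multi_orientation")
            continue
        acfv = acf3d(dy, region=sl)
        if acfv.insufficient or acfv.homogeneous:
            fits.append(None)
            call = LaminarCall(reasons={"degenerate_acf"})
            call.n_peaks = odf.n_peaks
            calls.append(call)
            motifs.append(classify_block(odf, call, cfg.gfa_bundled_floor))
            continue
        frame = block_frame(odf)
        profiles = radial_profiles(acfv, frame)
        fit = fit_frame_correlation_lengths(profiles, fit_floor=cfg.fit_floor)
        call = detect_periodicity(profiles, cfg.criteria)
        motif = classify_block(odf, call, cfg.gfa_bundled_floor)
        fits.append(fit)
        calls.append(call)
        motifs.append(motif)

    table = build_table(blocks, fits, calls, motifs, cfg.block_size)
    table = mask_blocks(
        table, grid, volume.shape,
        gfa_floor=cfg.gfa_mask_floor,
        border_margin_blocks=cfg.border_margin_blocks,
        min_valid_fraction=cfg.min_valid_fraction,
    )
    maps = assemble_maps(table, grid.grid_shape(ofield.shape))
    prov = _provenance(cfg, volume.shape, voxel_um)
    return PipelineResult(table=table, maps=maps, grid=grid, ofield=ofield, blocks=blocks, calls=calls, provenance=prov)


def run_pipeline(cfg: PipelineConfig, out_dir=None) -> PipelineResult:
    """Execute the full pipeline from a config; optionally write outputs.

    The input is ``cfg.phantom`` (generated on the fly) or ``cfg.input_path``
    (read at ``cfg.pyramid_level``). Deterministic for a fixed config.
    """
    if cfg.phantom is not None:
        ph = generate_phantom(cfg.phantom)
        volume, voxel_um = ph.volume, cfg.phantom.voxel_size
    elif cfg.input_path is not None:
        volume, meta = read_volume(cfg.input_path, level=cfg.pyramid_level, voxel_um=cfg.voxel_um)
        voxel_um = meta.voxel_um
    else:
        raise ValueError("config must provide either a phantom spec or an input path")
    result = analyze_volume(volume, voxel_um, cfg)
    if out_dir is not None:
        from pathlib import Path

        import yaml

        from .maps import render_map_png

        write_maps(out_dir, result.maps, table=result.table)
        render_map_png(result.maps["gfa_map"], Path(out_dir, "gfa_map.png"), vmin=0.4, vmax=1.0)
        render_map_png(result.maps["xi_map"], Path(out_dir, "xi_map.png"))
        render_map_png(result.maps["laminar_map"], Path(out_dir, "laminar_map.png"), vmin=0.0, vmax=1.0, cmap="Oranges")
        Path(out_dir, "provenance.yaml").write_text(yaml.safe_dump(result.provenance, sort_keys=True))
    return result


def config_from_dict(d: dict) -> PipelineConfig:
    """Build a PipelineConfig from a plain mapping (e.g. parsed YAML)."""
    d = dict(d)
    if d.get("phantom"):
        d["phantom"] = PhantomSpec(**{k: tuple(v) if isinstance(v, list) else v for k, v in d["phantom"].items()})
    if d.get("criteria"):
        c = dict(d["criteria"])
        if isinstance(c.get("period_band"), list):
            c["period_band"] = tuple(c["period_band"])
        d["criteria"] = PeriodicityCriteria(**c)
    if isinstance(d.get("block_origin"), list):
        d["block_origin"] = tuple(d["block_origin"])
    return PipelineConfig(**d)
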