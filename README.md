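# fiberarch

Quantification of 3D white-matter fiber architecture from axon-scale image
volumes.

Single-axon-resolution volumes of human white matter (e.g. from expansion
lightsheet microscopy of NFH-labeled projection axons) reveal distinct
organizational motifs: loosely packed **multi-orientation meshworks**,
**laminar/orthogonal** stacks of near-perpendicular fiber layers, and tightly
packed **bundles**. `fiberarch` turns a 3D grayscale volume of bright tubular
axons into quantitative maps of that architecture:

1. **Orientation field** — per-voxel structure tensors
   T = G_σw ∗ (∇I ∇Iᵀ), with derivative-of-Gaussian gradients at scale σg.
   The fiber axis v is the eigenvector of the smallest eigenvalue (intensity
   varies least along a bright tube); coherence = (λ₂−λ₁)/(λ₁+λ₂+λ₃).
   Orientations are axial (v ≡ −v) and sign-canonicalized.
2. **Block ODFs** — the volume is partitioned into analysis cubes (default
   100³ voxels) and each cube's valid orientations are binned on a
   6,500-direction equal-area sphere sampling into a discrete orientation
   distribution function ψ. Each ODF is summarized by its **generalized
   fractional anisotropy**
   GFA = √( n·Σᵢ(ψᵢ−ψ̄)² / ((n−1)·Σᵢψᵢ²) ) ∈ [0, 1]
   (0 = all orientations equally represented, 1 = a single dominant
   orientation) and by its peaks, enforcing ≥ 45° pairwise peak separation.
3. **Tensor-field autocorrelation** — axial directions are lifted to traceless
   dyadics T(x) = v vᵀ − I/3 and the masked, mean-subtracted 3D
   autocorrelation C(Δ) is computed spectrally per cube. Axial profiles in a
   fiber-aligned frame are fit with C(r) = exp(−r/ξ) to give correlation
   lengths; ξ_max maps the spatial scale of organization.
4. **Laminar periodicity** — transverse-plane ACF profiles are screened for
   spatial oscillations: ≥ 1.5 full cycles in the window, spectral peak SNR
   thresholds in both the 1D and 2D Fourier domains, and a negative-swing
   criterion. A cube is called laminar only when the screen passes *and* its
   ODF has ≥ 2 peaks; cubes with low GFA or at the tissue border are omitted
   from all maps.

A bundled synthetic-phantom generator (`fiberarch.phantom`) renders the three
motifs as Gaussian-profile tubes with voxel-level ground-truth orientations,
blur and noise, and is used to validate the pipeline end to end.

## Worked example

Analyze a laminar phantom (120³ voxels at 1 μm, layer period λ = 30 μm, one
100³ analysis cube):

```python
from fiberarch import PhantomSpec
from fiberarch.pipeline import PipelineConfig, run_pipeline

spec = PhantomSpec(motif="laminar", shape=(120, 120, 120), seed=2,
                   laminar_period=30.0)
cfg = PipelineConfig(phantom=spec, block_size=100, block_origin=(10, 10, 10))
res = run_pipeline(cfg)
row = res.table.iloc[0]
print(f"GFA        : {row.gfa:.3f}")
print(f"ODF peaks  : {row.n_peaks}")
print(f"xi_max um  : {row.xi_max_um:.1f}")
print(f"laminar    : {row.is_laminar}, period = {row.period_um:.1f} um")
print(f"motif      : {row.motif}")
```

prints

```
GFA        : 0.994
ODF peaks  : 2
xi_max um  : 50.0
laminar    : True, period = 30.0 um
motif      : laminar
```

The two ODF peaks are the two alternating layer axes; the in-layer
correlation lengths rail at the window half-length (50 μm, flagged capped)
because orientation is coherent across the whole cube in-plane, while along
the layer normal the oscillating profile decorrelates within ~3 μm; the
spectral screen recovers the 30 μm period exactly and the cube is classified
laminar.

The same pipeline is available from the shell:

```bash
fiberarch simulate --out sim --motif laminar --period-um 30 --seed 2 --size 120
fiberarch run cfg.yaml --out results_dir
```

with per-stage subcommands `orient`, `odf`, `acf`, `laminar` operating on a
working directory. Outputs are an architecture table (CSV, one row per cube:
GFA, peak axes, ξ per frame axis, ξ_max, laminar call with period and SNRs,
motif, mask reason), block-grid maps (CSV + JSON index) and a provenance
record listing every parameter.

## Conventions

Arrays are (z, y, x), 0-based, half-open block intervals; all direction
vectors use (z, y, x) component order; physical units are μm at tissue scale
(multiresolution pyramid metadata converts expanded-gel voxel pitch to tissue
scale, e.g. 0.75 μm physical at 3× expansion = 0.25 μm at level 0, doubling
per level). Orientation-coded RGB uses red = medio-lateral (x), green =
dorso-ventral (y), blue = antero-posterior (z).
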