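# Methods

This note documents the models, parameters, numerical choices and known
limitations of `fiberarch`. Everything quantitative stated here is computed by
the test suite or by `scripts/acceptance.py`; nothing is quoted from external
measurements.

## Orientation estimation

The local structure tensor is T(x) = G_σw ∗ (∇I ∇Iᵀ) with
derivative-of-Gaussian gradients at scale σg. Defaults σg = 1 μm and
σw = 3 μm correspond to one and three fiber radii at the default phantom
scale: the gradient scale matches the tube cross-section (maximal response),
and the window pools enough gradient directions around a tube to make the
eigenstructure stable without mixing unrelated fibers. Both scales are
specified in μm and converted per axis by the voxel size, so anisotropic
voxel grids are handled by construction.

A bright tube varies least along its axis, so the fiber axis is the
eigenvector of the smallest eigenvalue λ₁ (ascending order). Coherence
(λ₂−λ₁)/(λ₁+λ₂+λ₃) is 0 for isotropic and planar neighborhoods and reaches
1/2 for an ideal tube. Degenerate tensors (λ₂−λ₁ ≤ 10⁻⁷·trace) receive
coherence 0 and the conventional axis e_z. Orientations are axial; every
stored vector is sign-canonicalized (largest-|component| positive, ties
broken z, y, x), an idempotent rule applied everywhere downstream.

**Validity mask.** Voxels are excluded when their gradient energy (tensor
trace) is indistinguishable from the noise floor, or when they lie within
ceil(3σw) voxels of the volume edge (truncated filter support). The default
energy rule thresholds log-energy with Otsu's method: on labeled-axon
volumes the energy histogram has a noise-gradient mode (background) and a
fiber-gradient mode 10–100× higher, and the Otsu split lands between them.
A fixed relative floor (energy > 10⁻³ × volume median) is available as
`mask_method="median"`, but on sparse volumes the median *is* the background
energy, so that rule admits nearly every background voxel and dilutes the
block ODFs with noise orientations — the reason Otsu is the default.

## Block ODFs, GFA and peaks

Analysis cubes default to 100³ voxels, non-overlapping, anchored at a
configurable origin; partial edge cubes are dropped. The ODF support is an
equal-area spiral on one hemisphere plus its exact antipodes (N = 6500), so
the antipode map is an exact involution; each valid voxel adds half its
weight to the bin nearest +v and half to the bin nearest −v, making ψ
antipodally symmetric to machine precision. Voxels are weighted by count
(default) or coherence.

GFA uses the standard normalized-dispersion form
√(n·Σ(ψᵢ−ψ̄)²/((n−1)·Σψᵢ²)); an exactly uniform ψ returns exactly 0.
Note that GFA of a *discrete* ODF depends on the bin count relative to the
number of distinct fiber directions present: a few hundred straight fibers
on 6,500 bins produce a sparse ψ and hence a higher GFA than the same
architecture binned coarsely. Cross-motif *orderings* (bundled > laminar >
meshwork) are therefore the meaningful statistic at desk scale, and they are
what the tests assert.

Peaks are local maxima of ψ on the bin-adjacency graph after one step of
neighbor averaging (kernel ≈ the 2.5° bin spacing, suppressing single-bin
noise), thresholded at 0.3 × max, merged over antipodal pairs, and selected
greedily by amplitude subject to ≥ 45° pairwise axial separation. The 0.3
relative amplitude and the one-step smoothing are free choices; the 45°
separation is part of the method definition.

## Tensor-field autocorrelation and correlation lengths

Axial orientations are lifted to traceless dyadics T = v vᵀ − I/3 (invariant
under v → −v; renormalized in double precision so trace vanishes to 1e-12).
Per cube, the mean tensor over valid voxels is subtracted — without mean
subtraction the laminar oscillation rides on a large constant and is
invisible — and the autocorrelation is computed component-wise with
zero-padded FFTs. Invalid voxels are excluded by pair-count normalization
(correlation of gappy fields), not zero-filled; lags with < 8 pairs are NaN;
estimates are clipped to [−1, 1] (the estimator is unbiased per lag but not
variance-bounded at extreme lags). Zero-lag variance < 10⁻¹⁰ flags a region
homogeneous; valid fraction < 10 % flags it insufficient. The spectral path
is verified against a brute-force masked summation at every lag (≤ 1e-8).

Profiles are resampled by trilinear interpolation in a fiber-aligned frame:
e1 = dominant ODF peak, e2 = second peak orthogonalized (or a deterministic
perpendicular if only one peak), e3 = e1 × e2. Axial profiles along each
frame axis, azimuthally averaged radial profiles in the fiber (e1,e2) and
transverse (e2,e3) planes, and a 2D transverse slice are produced on an
r-grid at the lag spacing up to the window half-length (50 μm for 100³
cubes at 1 μm).

Correlation lengths come from a single-parameter log-scale least-squares fit
of C(r) = exp(−r/ξ) over r ∈ [Δr, first r with C < 0.05]; 1/ξ = Σr(−ln C)/Σr².
Fits with < 5 usable points fail (block masked in ξ maps); profiles that
never drop below 1/e cap ξ at the window half-length with a flag.
ξ_max = max over the three frame axes — "maximum autocorrelation length" is
interpreted as a maximum over frame axes, the natural finite set once a
fiber frame is fixed.

## Laminar periodicity screen

Laminar architecture oscillates in the transverse ACF at the layer period λ.
The screen works on the radially averaged transverse profile, detrended by
*subtracting* a fitted exponential envelope (dividing the envelope out
amplifies estimator noise at large lags where the envelope → 0). Since the
ACF is even in lag, spectra are computed on the even extension C(−R)…C(R):
the usable window is twice the maximum lag (100 μm for 100³ cubes), which is
what the ≥ 1.5-cycle rule is measured against.

Criteria (all must pass; failures are recorded by name):

* **snr_1d** — the in-band spectral candidate must be a local maximum at the
  independent-resolution scale (rejecting the monotone leakage ridge of
  envelope misfit), its SNR against the median off-peak power ≥ 3, and the
  candidate sinusoid's amplitude on the detrended profile ≥ 0.05. The
  amplitude floor guards the SNR ratio, which is a ratio of near-zero powers
  on smooth profiles.
* **cycles** — window × frequency ≥ 1.5. The searched period band
  [10 μm, window/1.5] enforces this a priori; the explicit check is a
  backstop against refinement drift, so on smooth profiles the failure
  normally surfaces as snr_1d rather than cycles.
* **snr_2d** — the 2D transverse power spectrum must show a ring maximum at
  the matching radial frequency with SNR ≥ 3 against the ring-median at
  other radii.
* **oscillation** — the transverse profile must dip below −0.05 and rebound
  by ≥ 0.05: a decaying profile never swings negative-and-back, a laminar
  one does by a large margin. This spatial-domain criterion is what makes
  specificity on bundled/meshwork volumes robust; their spectra can contain
  incidental band-edge power, but their profiles never oscillate.

The period is estimated from the transverse profile but refined on the
detrended axial profile along e3 (the layer normal when two peaks exist):
azimuthal averaging turns a planar cosine into a Bessel-like waveform whose
spectral edge biases the peak by ~10 %, while the e3 profile carries the
unsmeared oscillation (observed recovery error ≤ ~1.5 % for λ = 20–40 μm in
100-μm windows). SNR thresholds default to 3.0 — a conventional
"robust" spectral detection level; both are configurable.

**Classification.** laminar ⇔ screen passed ∧ ODF has ≥ 2 peaks; else
bundled ⇔ exactly 1 peak ∧ GFA ≥ 0.5; else multi-orientation. Map-level
masking omits cubes with GFA < 0.4, cubes flush with the volume border
(margin configurable in block widths), and cubes whose valid-voxel fraction
is < 0.05. The valid-fraction floor is deliberately low: with an
energy-based validity mask the fraction tracks stain density, not tissue
presence, and sparse meshwork still deserves classification.

## Synthetic phantoms

The generator emulates NFH-labeled axon volumes as the three motifs. Fibers
are straight tubes with a radial Gaussian intensity profile (peak 1, scale =
radius), max-combined (label saturation, not additive stain); imaging is
modeled as Gaussian PSF blur, constant background, additive Gaussian noise,
clipped at zero. Ground truth records each fiber's own axial direction where
a tube interior (distance ≤ radius) covers a voxel, NaN elsewhere.

Defaults define the study conditions: 1 μm isotropic voxels, 1 μm fiber
radius (large-caliber projection axons at tissue scale), λ = 40 μm laminar
period, 5° angular jitter, 1 μm PSF, noise SD 0.05, background 0.02, and
volume-fill targets 0.03 (meshwork) < 0.12 (laminar) < 0.30 (bundled),
reproducing the qualitative density progression of the motifs. No published
per-motif density or caliber distributions exist to calibrate against, so
these are free parameters chosen once at plausible values.

Laminar jitter is restricted to rotations within the layer plane so a fiber
stays inside its λ/2 slab over its whole length; free 3D jitter at 5° would
walk a ~200 μm fiber across several 10–20 μm slabs and destroy the very
alternation the motif defines. A patchwork generator (orientation constant
on cubic patches) provides a direct probe of correlation-length recovery
without rendering.

**What the phantoms do not emulate:** fiber curvature and fasciculation,
caliber distributions, expansion artifacts, anisotropic PSF, depth-dependent
attenuation, multi-channel labeling. Passing tests therefore demonstrate
correctness of the measurement chain on geometrically ideal fibers, not
biological fidelity of absolute GFA/ξ values on tissue.

## Problem sizes and determinism

Validation volumes are 56³–144×144×576 voxels with 40³–100³ analysis cubes —
large enough that every cube carries ≥ 10⁵ valid voxels while the full suite
and the acceptance script each run in minutes on one CPU. All randomness
flows through seeded `numpy` generators; identical specs and configs produce
bit-identical phantoms and output tables. The pipeline writes a provenance
record containing every parameter and the package version.

## Known limitations

* One orientation per voxel: crossing fibers inside a window blend into the
  eigenstructure rather than resolving into separate compartments.
* GFA magnitudes are bin-count dependent (see above); compare within a fixed
  sampling only.
* The laminar screen assumes a single dominant period; multi-period or
  wavelet analysis is out of scope.
* ξ fits assume exponential decay; oscillating or railed profiles are
  flagged (low R², capped) rather than modeled.
* Contiguity of laminar domains across cubes is not analyzed; the map is
  per-cube.
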