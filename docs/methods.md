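# Methods

`situtomo` implements the quantitative analysis pipeline for time-resolved
phase-contrast micro-tomography of articular cartilage (AC) and meniscus
(MM) under in situ compression: image-quality metrics, depth-resolved
chondrocyte density, 3D collagen fiber orientation, mechanical-property
derivation, radiation-dose estimation, and repeat-scan variability. Since
no tomographic data ship with the package, every stage is validated on
synthetic phantoms with known ground truth; this note records the models,
the parameter choices that matter, and what phantom-based validation does
and does not demonstrate.

## Conventions

Volumes are `(z, y, x)` arrays with `z` the loading/depth axis, 0-based
indices and half-open ranges. The default voxel size is 2.75 µm
(isotropic), the acquisition pixel size of the targeted synchrotron
setup; physical sizes convert to voxels by nearest-integer rounding
(500 µm → 182 voxels), recorded in output metadata. Compression strains
and stresses are reported as positive magnitudes; strain is referenced
to the post-preload sample height.

## Image quality (`situtomo.quality`)

**Resolution.** The rotationally averaged 3D power spectral density
(mean removed, 64 radial bins to Nyquist) of a resolved image falls to a
flat noise baseline at a cutoff frequency `f_c`; resolution is `1/f_c`
voxels. Operationalization: baseline = mean power over the top decile of
frequency bins; `f_c` = lowest frequency beyond which power stays below
`1.1 × baseline` for all higher bins. Two numerical safeguards: (i)
convergence is judged on a 3-bin forward moving average, because single
noise bins fluctuate by a few percent (≈2.4 σ exceeds the 1.1 factor
often enough to matter) while the reported cutoff keeps single-bin
resolution; (ii) a spectrum whose sub-cutoff power never exceeds
5 × baseline is flagged degenerate (pure noise has no resolved band) and
the resolution is reported as the largest measurable scale. Both factors
are exposed as arguments. On band-limited phantoms with a hard 0.2
cyc/px cutoff the estimator recovers the cutoff within one bin.

**SNR and CNR.** SNR = mean(foreground)/sd(background); CNR(A, B) =
(I_A − I_B)/√((σ_A² + σ_B²)/2), with sds computed with the unbiased
(n−1) estimator over user-supplied ROI masks (the package does not
choose ROIs). Both are invariant to positive rescaling; CNR is also
offset-invariant, SNR is not — intensity normalization on read is
therefore explicit and recorded.

## Chondrocyte density (`situtomo.cartilage`)

Chondrocytes appear as small ellipsoidal inclusions contrasting with the
extracellular matrix (dark, lacuna-like, by default). The segmenter is a
deterministic classical pipeline — Gaussian smoothing, polarity
normalization, Otsu (or manual) threshold inside the tissue mask,
radius-1 morphological opening, connected-component size filter — chosen
over a trained pixel classifier for exact reproducibility without a
model file.

Parameter choices:

* `smooth_sigma_px = 0.75`. Cells are only 2–4 voxels in radius at
  2.75 µm; smoothing at σ comparable to the radius erases their
  intensity plateau, which drags the Otsu threshold toward the matrix
  mode and inflates segmented volume by ≈20 %. σ = 0.75 suppresses noise
  while keeping the plateau (phantom Dice ≈ 0.93, per-layer density
  error < 1 percentage point).
* `size_range_um = (8, 40)` spherical-equivalent diameter, converted to
  voxel-volume bounds; removes noise specks and fused artefacts.
* A bimodality guard rejects degenerate thresholds: splitting unimodal
  noise yields a class separation of ≈2.7 pooled sds regardless of
  scale, genuine cell/matrix contrast is far larger, so a separation
  below 3 returns an empty mask with a warning.

Density is the **volume percentage** of cell voxels among tissue voxels
in each of 10 equal-thickness depth layers (layer 1 at the articular
surface, 0 % depth); individual cells are never counted, since columnar
cell stacks are not separable at this contrast. Layering is exact:
summing layer fractions times layer tissue volumes reproduces the total
segmented volume. For multi-time-point series, each of the (default 5)
subvolumes is layered separately and layer-wise mean ± sd across
subvolumes is tabulated.

## Fiber orientation (`situtomo.meniscus`)

The structure gradient tensor: smooth with Gaussian σ = 1 voxel, take
the 3D Sobel gradient g, form g gᵀ, smooth each of the six unique
components with Gaussian σ = 4 voxels (both stages mirror-padded), and
eigendecompose the symmetric 3×3 tensor per voxel. With eigenvalues
λ1 ≥ λ2 ≥ λ3, the eigenvector of λ3 is the fiber direction — intensity
varies least along the fiber. Coherence = (λ1 − λ3)/(λ1 + λ2 + λ3);
voxels with coherence < 0.01 (configurable) or within 2 σ_tensor = 8
voxels of the volume edge are invalid.

**Angle convention.** Azimuth ϕ ∈ [0, 180)° is the in-plane angle from
+x in the cross-sectional x–y plane; elevation θ ∈ [−90, 90]° is the
angle from that plane toward +z (the loading axis). Orientations are
axial — a fiber and its reverse are identical — so each eigenvector is
folded into the y ≥ 0 hemisphere (ties toward x ≥ 0, then z > 0) before
angles are read. This hemisphere is exactly the set parameterized by
(ϕ ∈ [0, 180), θ ∈ [−90, 90]), so antipodal vectors map to identical
stored angles, which a z-sign fold with subsequent ϕ-folding would not
guarantee. Near-vertical fibers (|θ| > 85°) have geometrically
meaningless azimuths and are excluded from azimuth histograms via a
dedicated mask.

Histograms use 1° bins, are normalized to sum to 1, and are averaged
across subvolumes as the mean of per-subvolume normalized histograms.
Peak tracking across time points reports the maximum bin and its height,
breaking ties toward the smallest |angle| with a logged flag.

Validation on straight-fiber phantoms (radius 3 voxels, SNR 5): modal
recovered angles within 3° of truth across random directions (elevation
restricted to |θ| ≤ 60° for the azimuth check, since ϕ is ill-defined
near the pole), modal azimuth shift of 45° ± 2° under in-plane volume
rotation, and a cos θ elevation density for isotropic fiber draws.

## Mechanics (`situtomo.mechanics`)

Protocols: continuous loading (CL; 0.03 %/s ramp to 15 % or 30 % strain,
7 equidistant scans) and stress-relaxation (StR; two 15 % steps at
1 %/s, holds of 600 and 900 s, scans at each peak and at offsets 20, 40,
60, 100, 300, 600 s). The nominal StR plan therefore yields 14 triggers
(2 steps × 7 offsets counting the peak), or 16 with the optional
end-of-relaxation trigger; coinciding triggers (a 600 s offset meeting
the end of a 600 s hold) are kept as distinct scheduled scans rather
than silently merged.

Stress assumes a constant 4-mm-diameter circular cross-section
(12.566 mm²); strain is displacement over the post-preload height taken
from the static tomogram. Derived quantities:

* **E_i** — least-squares stress–strain slope over the final 2 % strain
  (configurable) of the ramp before each peak.
* **E_qeq** — equilibrium stress per step is the mean over the last 10 s
  (configurable) of its hold; E_qeq is the slope between the relaxed
  stresses at 15 % and 30 % strain. "Quasi"-equilibrium: meniscus can
  need far longer than the holds to relax fully.
* **Relaxation ratio** — equilibrium/peak stress per step. For a
  standard linear solid this equals E∞/E₀ for the first step; the second
  step relaxes from a pre-strained state and its closed form is
  2E∞/(E∞ + E₀).
* **ν_s** — lateral/axial strain magnitude. Lateral strain is the
  relative change of the sample diameter measured from 1D edge profiles
  (mean intensity projections with sub-voxel half-maximum crossings);
  because it is a relative change, the chord-averaging bias of the
  projected profile cancels.
* **H_A** = (1 − ν) E_qeq / ((1 + ν)(1 − 2ν)); diverges as ν → 0.5 and
  reduces to E_qeq at ν = 0.

**Absorbed dose.** The sample is a homogeneous soft-tissue cylinder
(µ/ρ = 0.7786 cm² g⁻¹ at 21 keV; density 1.06 g cm⁻³ as this package's
configurable default, a standard soft-tissue value) uniformly covered by
a parallel beam while rotating, so deposition averages azimuthally:

    D = Ψ ∫₋R^R (1 − exp(−2µ√(R² − x²))) dx / (ρ π R²),   µ = (µ/ρ)·ρ

evaluated by adaptive quadrature. Since 1 − e⁻ˣ ≤ min(x, 1), the dose is
bounded above by both the optically thin limit Ψ·µ/ρ and the opaque
limit 2Ψ/(ρπR), approaching each asymptotically. The beamline photon
fluence is an input; the package does not assume one.

## Synthetic data (`situtomo.synthetic`)

The generators define the validation conditions; analysis code never
reads their ground truth.

* **Fiber phantoms** — straight cylinders rasterized as anti-aliased
  distance fields (the wall weight ramps linearly over one voxel, which
  avoids stair-step orientation bias), default radius 3 voxels
  (8.25 µm), unit fiber/zero matrix intensity, additive Gaussian noise
  (sd 0.2 → SNR 5 in validation). Orientation distributions: delta,
  axial von Mises, or uniform; "uniform" elevation samples sin θ
  uniformly so jointly-uniform specs give isotropic directions with the
  cos θ area element.
* **Cartilage phantoms** — non-overlapping ellipsoidal cells placed
  layer by layer until each of 10 target layer densities is met (random
  sequential placement; realized truth-mask density lands within ≈1
  percentage point of target for targets ≤ 30 %). Cell semi-axes
  interpolate with depth from flattened discoidal at the surface
  (4 × 10 × 10 µm) to rounder at depth (9 × 7 × 7 µm); default contrast
  0.3 (cells) vs 0.7 (matrix) with noise sd 0.05 — contrast and noise
  are free parameters of the phantom, not measured tissue values.
* **Loading curves** — the standard linear solid (SLS), the simplest
  viscoelastic model with distinct instantaneous (E₀) and equilibrium
  (E∞) moduli, so recovery is analytic: a step ε₀ relaxes as
  ε₀[E∞ + (E₀−E∞)e^(−t/τ)]; piecewise-linear strain histories are
  evaluated exactly by ramp superposition (verified against ODE
  integration to 10⁻⁶ MPa). Forces come from the 4-mm cross-section
  plus optional Gaussian noise.
* **Repeat pairs** — one clean volume plus two independent noise
  realizations, the second rigidly shifted (periodic boundary for
  integer shifts).

All generators are bit-reproducible under a fixed seed.

What the phantoms do **not** model: phase-contrast edge enhancement and
its noise texture, reconstruction artefacts (rings, motion blur), curved
or bundled fibers, cell-shape irregularity, and partial-volume gradients
at tissue boundaries. Passing validation therefore demonstrates
correctness of the numerics and the stated recovery properties under
idealized contrast — not segmentation or orientation accuracy on real
tissue, which depends on contrast and artefact levels the phantoms do
not reproduce.

## Repeatability (`situtomo.repeatability`)

Translation-only registration by phase correlation (plain
cross-correlation normalization, which is more robust than spectral
whitening at moderate SNR), with optional sub-voxel upsampling; rotation
is assumed negligible for remove-and-rescan experiments. Alignment is
flagged failed below a normalized correlation of 0.2 or beyond a 50-voxel
shift bound. Matched subvolumes default to a centred 300³-voxel box
(0.825 mm side at 2.75 µm); full-depth variants are available for
meniscus. Differences are reported per density layer (absolute
percentage points) and per histogram (maximum and mean absolute bin
difference); the comparison is symmetric and identically zero for
identical inputs. Noise-free constructed shifts are recovered exactly;
at SNR 5 within one voxel.

## Problem sizes used in validation

Orientation recovery runs on eight 128³ phantoms plus two 96³ phantoms
(rotation and isotropy checks); the density pipeline on one
120 × 96 × 96 phantom; resolution recovery on twenty 64³ phantoms; the
Monte-Carlo dose cross-check on 4 × 10⁶ rays; registration on 48³
volumes over 10 noise seeds. These sizes put every recovery criterion
comfortably in its asymptotic regime while keeping the full validation
suite around a minute of compute.

## Known limitations

* No biphasic/poroelastic modelling, permeability fitting, or digital
  volume correlation; no deformable registration.
* Density is volume fraction only — no instance counting or tracking.
* The resolution criterion's baseline/threshold constants are an
  operationalization (the underlying Fourier criterion admits variants);
  comparisons across datasets should hold them fixed.
* Subvolume placement is seed-fixed uniform rejection sampling; there is
  no content-aware artefact avoidance.
* The SLS is a single-relaxation-time stand-in: real cartilage/meniscus
  relaxation is multi-exponential, so recovered E₀/E∞/τ from real data
  are effective, not constitutive, parameters.
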