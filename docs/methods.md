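# Methods

## Problem and model

Digital breast tomosynthesis (DBT) reconstructs a quasi-3D attenuation
volume from a small number of low-dose projection views acquired over a
narrow arc (here 15 views over 15°). Because each view contributes a share
of the total dose, dropping half of the views halves the dose — at the cost
of image quality. This package simulates that trade-off end to end: a
digital breast phantom is projected, Poisson quantum noise is added, a
half-dose acquisition is produced by *thinning* the acquired views (never by
re-simulation), both arms are reconstructed with four algorithms, and the
loss of resolution and contrast is quantified.

### Acquisition model

The scanner is partial-isocentric: a stationary flat-panel detector in the
`z = 0` plane, the breast support at `z = source_to_detector −
source_to_support`, and the source swinging on an arc of radius
`source_to_support` about a pivot on the support plane. Defaults
(`source_to_detector = 700` mm, `source_to_support = 660` mm, detector pitch
0.14 mm) are representative of commercial DBT and are config-overridable;
they are declared, not measured. The physics is monoenergetic Beer–Lambert:
a detector pixel sees the line integral `p = ∫ μ dl` (the projector), and a
noisy acquisition draws detected counts `N ~ Poisson(Φ·e^(−p))` per pixel at
incident fluence `Φ` photons/pixel/view, floors them at one photon, and
converts back with `p̃ = −ln(N/Φ)`. Upward count fluctuations are not
clipped, so `p̃` may be slightly negative; the floor bounds it above by
`ln Φ`.

The default fluence is `Φ = 5·10⁴` photons per 0.14-mm pixel per view. At a
~20 keV effective energy, an automatic-exposure-control DBT pass (average
glandular dose ≈ 1.5 mGy over 15 views) delivers on the order of
10⁴–5·10⁴ incident photons per binned pixel per view; behind a 40-mm slab
(transmission ≈ 0.1) the default yields ≈ 5·10³ detected counts, i.e. a
per-pixel line-integral noise of σ ≈ 0.014. No electronic noise, scatter,
detector blur or polyenergetic effects are modelled.

### Projectors

Two ray models share one geometry:

* **Joseph (default)** — voxel-driven interpolating ray tracing: each ray is
  sampled once per slice, the slice bilinearly interpolated at the
  intersection and weighted by the slant path through the slice. Compiled
  kernels (numba); the backprojector scatters with exactly the weights the
  projector gathers, so the pair is an exact adjoint and rays missing the
  grid contribute exactly zero.
* **Siddon** — exact ray/voxel intersection lengths assembled into a cached
  sparse matrix per view. Slow (per-ray Python loop) and intended for small
  grids, where it serves as an independently checkable reference; the test
  suite validates it against a brute-force per-voxel slab-intersection
  matrix built by entirely separate code.

Coordinates: right-handed, origin at the detector centre, `x` along tube
motion (detector columns), `y` along detector rows, `z` perpendicular to the
detector (slice axis); 0-based indices with pixel/voxel centres at
half-integer multiples of the pitch from the centred origin.

## Phantom

The synthetic phantom emulates a heterogeneous 50% glandular / 50% adipose
slab with embedded targets:

* background: a Gaussian random field, smoothed to a 2 mm correlation
  length, thresholded at the quantile matching the glandular fraction into a
  two-phase medium, then lightly smoothed — values therefore stay within
  [μ_adipose, μ_glandular] = [0.046, 0.080] mm⁻¹ (nominal ~20 keV values;
  the physical swirled phantom this emulates has feature scales of a few
  mm, which 2 mm represents);
* microcalcifications: spheres of 0.29 and 0.40 mm diameter at 0.50 mm⁻¹
  (CaCO₃-like), rendered by partial-volume-weighted rasterisation (8³
  midpoint subsamples per voxel) so that sub-voxel inserts still deposit
  the correct fractional attenuation;
* masses: spheres of 3.9 and 4.7 mm diameter adding a +0.015 mm⁻¹ contrast
  offset to the *local* background (near-tissue-equivalent lesions).

The default grid is 32 × 128 × 128 voxels at 1 × 0.14 × 0.14 mm — an
18 × 18 mm in-plane crop around the insert cluster at full detector pitch,
with the four inserts placed one per quadrant in the mid-plane slice. This
desk-scale field of view preserves the pixel-unit ROI conventions (21 × 21
px for the 3.9-mm mass, 33 × 25 px for the 4.7-mm) while keeping a full
ten-seed comparison in minutes on one CPU. Identical (spec, seed) gives a
bit-identical phantom.

### Thinning rule

From an odd number of views `n ≥ 3`, the half acquisition keeps the odd
0-based indices 1, 3, …, n−2 — exactly `(n−1)/2` views, symmetric about the
central angle, each bit-identical to its source view. This is the only
symmetric equal-stride selection mapping 15 views onto 7; it drops both
endpoint views.

## Reconstruction algorithms

All four are deterministic in (projections, geometry, parameters); SART,
MLEM and ASD-POCS outputs are nonnegative.

* **FBP** — each projection is zero-padded to the next power of two,
  multiplied in the frequency domain by a ramp `|f|` or Shepp–Logan
  `|f|·sinc(f/2f_N)` kernel, scaled by the detector pitch, backprojected and
  divided by the view count. The default applies the kernel to the **2D**
  Fourier transform of each projection (radially symmetric response), which
  restores the impulse shape in both detector directions — this is what
  gives FBP its resolution advantage on profiles drawn perpendicular to the
  sweep. A classical 1D row filter along the tube-motion axis is available
  (`filter_mode="1d"`).
* **SART** — per view `v` (ascending angle): `x ← x + λ·A_vᵀ[(b_v − A_v x) /
  (A_v·1)] / (A_vᵀ·1)` with positivity after each view; one iteration = one
  sweep over all views; λ = 1 and 5 iterations by default. Normalisation
  weights below 10⁻¹² are treated as zero (no division by zero, rays/voxels
  outside the coverage are left untouched).
* **MLEM** — `x ← x · Aᵀ(b/(Ax + ε)) / Aᵀ1` on the line-integral data
  treated as a nonnegative Poisson sinogram, from a uniform positive start
  `mean(b)/mean(Aᵀ1)`; 2 iterations by default. MLEM's statistical
  derivation assumes counts; applying it to log-converted data follows the
  common DBT practice this pipeline replicates.
* **ASD-POCS** — per outer iteration: one SART sweep at relaxation β with
  positivity (POCS step, image change `dp`), then `ng` steepest-descent
  substeps of size `dtvg = α·dp` along the unit-normalised gradient of the
  smoothed isotropic TV `Σ√(‖∇x‖² + δ²)` (δ = 10⁻⁸), then adaptation
  `β ← β·β_red`, and `α ← α·α_red` when the TV excursion exceeds
  `γ_max·dp` while the data residual exceeds ε. Defaults: 5 iterations,
  β = 1, β_red = 0.995, α = 0.002, α_red = 0.95, γ_max = 0.95, ng = 25,
  ε = 0 (the residual gate disabled, so α stays eligible to shrink).
  `ng = 0` reduces the method exactly to the POCS-only (SART + positivity)
  trajectory, and α → 0 recovers SART under the same β schedule — both are
  tested identities.

Iteration counts (5/5/2) follow the convergence-selection convention the
convergence study reproduces: RMSE and the universal quality index (QI)
between consecutive iterates flatten by those counts.

## Metrics

* **FWHM** (mm): three parallel single-pixel profiles along `y`
  (perpendicular to the sweep) through a microcalcification's registered
  centre and its ±1-pixel neighbours along `x`. Per profile: background =
  mean of the outer 20% of samples at each end; half-maximum = background +
  (peak − background)/2; crossings by linear interpolation. The reported
  value is the mean over lines that yield a peak (the side lines graze
  sub-voxel inserts and may legitimately fail); a measurement with no valid
  line raises a flagged failure, never a silent zero. FWHM is invariant to
  intensity scaling and offsets by construction.
* **CNR**: `(μ_Feature − μ_BG)/σ_BG` on the in-focus slice, feature ROI of
  the study shape centred on the mass, background ROI of the same shape
  displaced 4.5 mm along `y` into lesion-free texture (adjacent placement
  keeps the two ROIs in the same structural neighbourhood); σ_BG is the
  sample standard deviation (ddof = 1). σ_BG = 0 is a flagged failure.
* **SSIM/MSSIM**: per-window luminance, contrast and structure terms with
  stabilisers C1 = (0.01·L)², C2 = (0.03·L)², C3 = C2/2, exponents
  α = β = γ = 1, 11 × 11 Gaussian window (σ = 1.5 px), L = max − min of the
  reference image; the map covers every fully interior window and MSSIM is
  its arithmetic mean. The 15-view reconstruction is always the reference
  and the 7-view the objective, both on the in-focus plane.
* **QI**: the zero-stabiliser specialisation of SSIM over an 8 × 8 uniform
  sliding window; degenerate windows (zero combined variance or mean
  energy) are skipped with a recorded count. QI equals the C1 = C2 = 0
  limit of SSIM on non-degenerate windows, which the tests assert to 10⁻¹⁰.
* **RMSE**: `√mean((a−b)²)`.
* **Rate of change**: `100·(value₇ − value₁₅)/value₁₅`, flagged when the
  reference is zero.

The in-focus plane is the slice containing the registered insert centres.

## Experiment designs and problem sizes

* *Parameter sweep*: ASD-POCS over an (α, ng) grid; per cell and seed it
  records FWHM per microcalcification, CNR per mass and the background-ROI
  standard deviation. Failures are flagged per cell and the sweep continues.
* *Convergence study*: SART, MLEM, ASD-POCS on the 15-view acquisition;
  RMSE and QI between consecutive iterates at every iteration.
* *Projection comparison*: per seed, one noisy 15-view acquisition, a
  thinned 7-view arm (per-view SHA-256 hashes kept so subset purity is
  checkable), five reconstruction variants (FBP-ramp, FBP-SL, SART, MLEM,
  ASD-POCS) at both view counts, and the full metric panel with per-seed
  rate-of-change columns plus across-seed means and standard errors.

The original measurements used one physical phantom; this pipeline
replicates the design over ten phantom seeds and reports mean ± standard
error, so the across-seed variance includes texture realisation, not just
photon noise. Stochastic property tests (the α-monotonicity of background
noise) run on a reduced 16 × 64 × 64 phantom with an 80 × 160 detector —
same composition and insert sizes, quarter-scale grid — chosen as the
smallest grid on which the 3.9-mm mass and both microcalcifications fit
with their ROIs.

## Numerical choices

* SART/MLEM weight floor 10⁻¹²; MLEM division guard ε = 10⁻¹⁰.
* TV smoothing δ = 10⁻⁸ inside the gradient-norm square root.
* FBP zero-padding to the next power of two ≥ 2n per filtered axis.
* View sweep order: ascending angle (fixed for bit-reproducibility).
* All volumes start from zero except MLEM (uniform positive).
* Phantom and photon noise use `numpy.random.default_rng`; the experiment
  layer derives the photon seed as `phantom_seed + 100003` so the two
  streams never coincide.

## Known limitations

* The mass contrast (+0.015 mm⁻¹) is comparable to the two-phase texture's
  ROI-mean differences, so single-seed mass CNR can take either sign; CNR
  is only meaningful here through paired (15 vs 7 view) comparisons, and
  per-seed CNR rates are heavy-tailed when the 15-view reference is near
  zero. A physical phantom has one fixed texture realisation and does not
  show this across-replicate instability.
* Under view thinning of the *same* acquired data, FBP — linear and
  view-count-normalised — produces 7- and 15-view slices that are nearly
  identical (interior correlation ≈ 0.995 at the default dose), while the
  SART-based methods land at different convergence states (a sweep performs
  one sub-update per view). MSSIM between arms therefore ranks FBP above
  the iterative methods on this smooth synthetic phantom. Clinical anatomy,
  electronic noise and scatter — all outside this model — push FBP the
  other way; passing or failing that ordering here says nothing about
  clinical images.
* The 2-iteration MLEM reconstruction leaves sub-voxel microcalcifications
  barely above the textured background; its FWHM cells are frequently
  flagged as unmeasurable. This is the expected behaviour of early-stopped
  MLEM, which favours low-contrast detectability over resolution.
* No detector blur, lag, scatter, beam hardening or polyenergetic spectra;
  dosimetry (average glandular dose) is carried as metadata only.
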