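# dbtsim

Simulation and limited-angle reconstruction pipeline for **projection-reduced
digital breast tomosynthesis (DBT)**.

DBT acquires a handful of low-dose x-ray projections over a narrow arc
(15 views over 15° here) and reconstructs a quasi-3D volume. Since each view
carries a share of the patient dose, *thinning* the acquired stack to every
other view halves the dose — if a reconstruction algorithm can preserve
image quality from 7 views, the dose reduction is free. This package builds
the whole evaluation loop for that question, fully synthetically:

1. **Phantom** — a heterogeneous 50% glandular / 50% adipose slab texture
   (attenuation 0.046–0.080 mm⁻¹) with CaCO₃-like microcalcifications
   (0.29 / 0.40 mm ⌀) and low-contrast spheroidal masses (3.9 / 4.7 mm ⌀,
   +0.015 mm⁻¹ above local background), on a 32 × 128 × 128 grid at
   1 × 0.14 × 0.14 mm.
2. **Acquisition** — partial-isocentric geometry, monoenergetic
   Beer–Lambert line integrals, Poisson quantum mottle
   (`N ~ Poisson(Φ·e^(−p))`, `p̃ = −ln(N/Φ)`), and the half-dose arm by pure
   view selection (odd indices of 15 → exactly 7, symmetric about 0°).
3. **Reconstruction** — FBP (Ramp / Shepp–Logan kernels), SART, MLEM, and
   ASD-POCS (adaptive steepest descent – projection onto convex sets),
   which alternates a SART data-consistency sweep with `ng` steepest-descent
   substeps along the normalised total-variation gradient
   (TV(x) = Σ‖∇x‖₂; defaults α = 0.002, ng = 25, 5 outer iterations).
4. **Metrics** — FWHM of profiles through the microcalcifications
   (resolution), CNR = (μ_F − μ_BG)/σ_BG of the masses (low-contrast
   detectability), SSIM/MSSIM between the 7-view and 15-view
   reconstructions (contrast preservation), RMSE and the universal quality
   index QI between iterates (convergence), and the 15→7 rate of change.

Intended users: medical-imaging researchers prototyping limited-angle
reconstruction or dose-reduction studies who want a deterministic, fully
inspectable desk-scale testbed rather than scanner data.

## Worked example

```python
import dbtsim as d
from dbtsim import metrics as mx

cfg = d.ExperimentConfig()                      # default study conditions
op15 = cfg.operator()
phantom = d.build_phantom(cfg.phantom)          # seed-0 digital breast phantom

full = d.simulate_acquisition(phantom, op15, cfg.fluence_per_view, seed=100003)
half = d.thin_projections(full)                 # 15 views -> 7, pure selection
op7 = d.SystemOperator(half.geometry, op15.volume_shape, op15.voxel_size)

mc = phantom.find_insert("microcalcification", 0.29)
for algo in ("fbp", "asd_pocs"):
    r15 = d.reconstruct(algo, full, op15)
    r7 = d.reconstruct(algo, half, op7)
    w15 = mx.fwhm_of_insert(r15.data, mc.center_voxel, 1.5, phantom.voxel_size)
    w7 = mx.fwhm_of_insert(r7.data, mc.center_voxel, 1.5, phantom.voxel_size)
    m = mx.mssim(r15.data[15], r7.data[15])
    print(f"{algo:9s} FWHM(0.29mm MC) 15v={w15:.3f} mm  7v={w7:.3f} mm  "
          f"rate={mx.rate_of_change(w15, w7):+.1f}%  MSSIM(7v|15v)={m:.3f}")
```

prints

```
fbp       FWHM(0.29mm MC) 15v=0.213 mm  7v=0.200 mm  rate=-5.8%  MSSIM(7v|15v)=0.951
asd_pocs  FWHM(0.29mm MC) 15v=0.246 mm  7v=0.256 mm  rate=+4.3%  MSSIM(7v|15v)=0.854
```

Reading it: FBP resolves the 0.29-mm microcalcification most sharply
(FWHM ≈ 0.21 mm vs 0.25 mm for ASD-POCS — the TV prior trades a little
resolution for noise suppression), and on this phantom seed its 7-view
reconstruction is structurally very close to its 15-view one
(MSSIM 0.95). The rate column is the percent change of the half-dose arm
relative to the normal arm.

## Command line

The same pipeline is scriptable through a thin CLI:

```bash
dbtsim phantom   --seed 0 --out out/phantom
dbtsim simulate  --seed 0 --thin --out out/proj
dbtsim reconstruct --algo asd_pocs --projections out/proj/projections.h5 --out out/rec
dbtsim compare   --config myconfig.yaml --out out/report
dbtsim sweep     --alpha 0.0005 --alpha 0.002 --alpha 0.01 --out out/sweep
dbtsim converge  --max-iterations 8 --out out/converge
```

`compare` writes the full normal-vs-half report: tidy per-measurement CSV,
a wide per-(seed, algorithm, views) table with rate-of-change columns, and
an across-seed mean ± standard-error summary.

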