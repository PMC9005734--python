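# svoct

Quantification of 3D tumour microvascular heterogeneity from
speckle-variance optical coherence tomography (svOCT) angiography.

Tumour response to high-dose-per-fraction radiotherapy is thought to be
driven in part by ablation of the microvasculature. A single vascular
volume density (VVD) number averages away the spatial structure of the
vessel network, so this package computes distance-resolved metrics of the
vascular architecture from label-free 3D angiography, for longitudinal
(pre-/post-irradiation) small-animal imaging studies:

- **Speckle-variance angiography.** Flowing blood decorrelates OCT
  speckle between M repeated same-position B-scans while static tissue
  does not; the per-pixel population variance

  `sv(z, x) = (1/M) Σ_t (Ī(z,x) − I_t(z,x))²`

  lights up vessels.
- **Vessel segmentation.** Morphological denoising, a Beer–Lambert
  depth-decaying threshold, a step-down exponential filter for sub-vessel
  decorrelation "shadow" tails, multiscale Frangi vesselness (scales in
  μm, converted per axis for anisotropic grids), binarization and
  small-artifact removal, VOI masking, and nearest-neighbour resampling
  to an isotropic (2.5 μm)³ grid.
- **DNV metrics.** The exact 3D Euclidean distance transform gives each
  tissue voxel its distance δ to the nearest vessel (DNV). From the
  unit-normalized DNV histogram n(δ) (2.5 μm bins):
  - the **diffusion-limited fraction** `DLF_Λ = Σ_{δ≥Λ} n(δ)`, with
    Λ = 150 μm ≈ 2√(D/M), the oxygen diffusion–consumption distance
    (D = 2000 μm²/s, M = 15 mmHg/s ÷ 40 mmHg = 0.375 s⁻¹) — a proxy for
    poorly oxygenated tissue;
  - the **convexity index** λ, the power-law exponent of n(δ) ~ δ^λ
    fitted over δ ≤ 60 μm — positive for efficiently spaced vessels,
    near zero/negative for aggregated ones;
  - **VVD**, and the Poisson parallel-cylinder null model
    `ln DLF_Λ ≈ −(Λ/r_c)²·VVD` (plus its exact form
    `−ρπ(Λ+r_c)²`), departures from which flag architectural
    inhomogeneity beyond simple randomness.
- **Longitudinal statistics.** Per-subject normalizations
  `DLF_150(t)/DLF_150(0)` and `Δλ(t) = λ(t) − λ(0)`, cohort summaries,
  one-way ANOVA across dose groups followed by Welch t-tests against
  unirradiated controls, and time-to-peak extraction.
- **Synthetic phantoms.** Poisson parallel-cylinder fields (with the
  closed-form DLF oracle `exp(−ρπ(Λ+r_c)²)`), random branching vessel
  trees, and a repeated-B-scan speckle simulator (frozen tissue speckle,
  per-frame vessel redraws, Beer–Lambert depth attenuation, sub-vessel
  shadow tails) so the entire pipeline is testable against known ground
  truth without animal data.

## Worked example

Simulate a cylinder phantom, run angiography + segmentation, and compute
the heterogeneity metrics:

```python
import numpy as np
from svoct import (CylinderFieldSpec, SpeckleSimSpec, SegmentationConfig,
                   generate_parallel_cylinders, simulate_bscan_stack,
                   speckle_variance_volume, segment_volume, compute_metrics,
                   poisson_dlf_exact)

spec = CylinderFieldSpec(box_size=(400.0, 1000.0, 500.0), r_c=20.0,
                         line_density=1.5e-5, axis="y", seed=11)
field = generate_parallel_cylinders(spec, voxel_spacing=(4.0, 5.0, 5.0))
stack = simulate_bscan_stack(field.mask, SpeckleSimSpec(seed=11))
angio = speckle_variance_volume(stack)
mask, log = segment_volume(angio, SegmentationConfig())
record, hist = compute_metrics(mask, thresholds=(150.0,))

print(f"ground-truth VVD : {field.mask.vessel_fraction():.4f}")
print(f"segmented VVD    : {record.vvd:.4f}")
print(f"DLF_150          : {record.dlf[150.0]:.4f}")
print(f"lambda           : {record.convexity.exponent:.3f} "
      f"(stderr {record.convexity.stderr:.3f}, R^2 {record.convexity.r_squared:.3f})")
null = np.exp(poisson_dlf_exact(record.vvd, r_c=20.0))
print(f"Poisson-null DLF_150 at the segmented VVD: {null:.4f}")
```

prints

```
ground-truth VVD : 0.0094
segmented VVD    : 0.0108
DLF_150          : 0.5208
lambda           : 0.342 (stderr 0.025, R^2 0.899)
Poisson-null DLF_150 at the segmented VVD: 0.4547
```

The segmentation recovers the phantom's vascular volume density within
~15%. Half of the tissue lies beyond 150 μm of a vessel (this particular
realization is sparse), somewhat above the Poisson-cylinder expectation
at the same VVD — the kind of departure that, on real tumours, signals
vessel aggregation. λ ≈ 0.34 reflects a histogram that still rises at
short distances but far less steeply than the λ = 1 of an isolated
vessel.

## Command line

```sh
svoct simulate --out-dir phantom --r-c 20 --vvd 0.02 --seed 3
svoct angio    --in phantom/bscan_stack.tif --out angio.tif
svoct segment  --in angio.tif --out mask.tif
svoct metrics  --mask mask.tif --out metrics.csv --histogram hist.csv
svoct cohort   --table cohort.csv --metric DLF_150 --day 17 --out summary.csv
svoct run      --config pipeline.yaml
```

`svoct run` executes the full configured pipeline (validated YAML,
unknown keys rejected) and writes a manifest with the config hash and
per-stage voxel counts.

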