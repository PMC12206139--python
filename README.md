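# hepatovasc

3D liver microvascular analysis for optical-resolution photoacoustic
microscopy (OR-PAM). The package separates the two compartments of the
hepatic blood supply that share one hemoglobin-contrast image — wall-bearing
vessels (portal/central branches, tens of µm) and the hepatic sinusoid mesh
(3–5 µm capillaries) — and quantifies each in physical units, for
researchers tracking microvascular remodelling in fatty-liver disease
models (NASH) or any longitudinal liver imaging study.

## What it computes

Given an intensity stack `I(z, y, x)` with voxel spacing in µm
(z = depth), the chain runs:

1. **Depth compensation** — per-slice percentile profiling (I1, I99);
   histogram matching of every slice to the widest-range reference layer.
2. **Vessel isolation** — grayscale erosion with a spherical element whose
   radius balances two sweep metrics,
   `MID(r) = |mean(I_r) − mean(I)|` and `IR(r) = ΣI_r / ΣI`
   (their min–max-normalized curves cross near the sinusoid radius,
   ≈ 4 µm); then local-mean adaptive thresholding and a median-volume
   component filter.
3. **Sinusoid recovery** — subtraction of the scaled vessel mask, negative
   clipping, multiscale Frangi (Hessian) tubular filtering, adaptive
   segmentation; masks are disjoint by construction.
4. **Morphometry** — 3D thinning to a skeleton graph; length, volume,
   cylinder-model radius `r = √(V/(πL))`, tortuosity (chord/path ∈ (0, 1]),
   density `D = V_S / (V − V_L)`, vessel counts.
5. **Branch analysis** — dead-end / crossing / complex classification and
   per-class box-counting fractal dimension
   `FD = −lim log N(L) / log L`.
6. **Coverage** — per-vessel sinusoidal canopy rate
   `R_i = Σ[V_i ∧ S′] / ΣV_i` with high/low-coverage classification at 50 %.
7. **GLCM quality scores** for comparing imaging configurations.

Because no public datasets exist for this modality, the `phantom` module
generates synthetic liver-like volumes (basal vessel trunks, an
anastomosing sinusoid mesh, exponential depth attenuation, detector noise)
with voxel-level ground truth, so the whole chain is testable end to end.
See `docs/methods.md` for the model details and design rationale.

## Worked example

```python
from hepatovasc import PhantomSpec, PipelineConfig, generate_phantom, run_pipeline
from hepatovasc.phantom import evaluate_separation

ph = generate_phantom(PhantomSpec(shape=(96, 160, 160), seed=1))
result = run_pipeline(ph.intensity, PipelineConfig())

print(f"erosion radius: {result.erosion_radius_um:.1f} um")
print(f"vessel count:   {result.vessel_count}")
print(f"density D:      {result.density:.4f}  (truth {ph.realized['sinusoid_density']:.4f})")
print(f"radius:         {result.metrics.radius_um:.2f} um")
print(f"tortuosity:     {result.metrics.tortuosity:.3f}")
scores = evaluate_separation(result.vessel_mask, result.sinusoid_mask,
                             ph.vessel_truth, ph.sinusoid_truth)
print(f"vessel Dice {scores['vessel_dice']:.3f}, sinusoid Dice {scores['sinusoid_dice']:.3f}")
```

prints

```
erosion radius: 4.0 um
vessel count:   6
density D:      0.0965  (truth 0.0846)
radius:         2.75 um
tortuosity:     0.784
vessel Dice 0.951, sinusoid Dice 0.823
```

i.e. on a phantom degraded with 10 % noise and 2 mm⁻¹ attenuation, the
chain recovers the sinusoid compartment at Dice 0.82 and its density within
~15 %, with a cylinder-model radius of 2.75 µm against a generative mean of
2 µm (segmentation at the partial-volume boundary widens thin tubes
slightly; on a noise-free phantom the error drops to ~0.3 µm).

The same chain is available from the shell:

```bash
hepatovasc phantom --stage early --seed 1 --out-dir ph/
hepatovasc run ph/intensity.tif --spacing 1,1,1 --out-dir results/
hepatovasc coverage results/vessel_mask.tif results/sinusoid_mask.tif --out cov.csv
```

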