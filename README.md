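# myelotrace

Quantification of hemispheric asymmetry in intracortical myelin
orientation and columnar cell-body organisation from 3D cleared-tissue
light-sheet volumes of mouse auditory cortex.

Cleared-brain light-sheet imaging resolves myelinated fibres and neuronal
somata across entire cortical regions, but at a resolution (0.54 × 0.54 ×
4 µm voxels) that does not allow tracing single fibres.  `myelotrace`
implements a pixel-level pipeline that nevertheless extracts quantitative
structure from such data:

1. **Cell-centre annotation** — the somata channel is convolved (FFT) with
   the real part of a complex 3D *Gabor spherical-shell* kernel

   K(x, y, z) = 1/(2πσr₀) · e^(−π((r′−r₀)/σ)²) · e^(i(2πf₀(r′−r₀)+φ)),

   a radially offset Gaussian envelope modulated by a radial plane wave
   (z compressed to match the anisotropic voxels); local maxima of the
   response mark cell centres.
2. **Neighbourhood statistics** — per reference cell, a 54 µm cube of the
   surrounding centres gives a local density field p = c/d³; averaged over
   every 5th cell and normalised by the voxel count at each radius, the
   radial distance distribution exposes microcolumns (peaks at ~6 and
   ~12 µm along the pia–white-matter axis).
3. **Orientation analysis** — per 2D plane, the myelin channel is median-
   and Sato-filtered, and the structure tensor J (windowed covariance of
   image gradients) is evaluated in 24 × 24 px windows:
   φ = ½·atan2(2J₁₂, J₂₂−J₁₁), E = tr J, C = (λmax−λmin)/(λmax+λmin).
   Windows with E·C below a gate are rejected; angles are corrected for
   cortical curvature via a quadratic surface fit to the autofluorescence
   channel (distance-transform gradient → local tangent) and assigned to
   cortical layers by depth (L6 excluded).
4. **Circular regression** — corrected axial angles θ ∈ [0°, 180°) are
   doubled onto the circle and fitted with Bayesian projected-normal
   circular GLMs (latent y ~ N₂(Bx, I), Gibbs sampler) with hemisphere
   side, and optionally cortical layer, as covariates; reported are
   circular posterior means, 95% HPD intervals, DIC model comparison, and
   a 25× stratified bootstrap for datasets too large to fit at once.

Because raw microscopy volumes are tens of gigabytes, the package ships a
first-class synthetic-data module (`myelotrace.synth`) that renders
microcolumnar somata, layered fibre fields beneath curved surfaces and
projected-normal orientation samples with exported ground truth, so every
stage is testable end to end on a desk.

## Worked example

```python
from myelotrace import synth, circglm
from myelotrace.circular import axial_diff_deg

# synthetic axial orientations at the study's pooled group means
df = synth.gen_orientation_samples(
    synth.side_only_design(n_per_side=10_000, seed=1))

fit = circglm.fit_pn_glm(df, formula=("side",),
                         iters=1500, burnin=300, seed=3)
print(fit.table[["side", "mean_deg", "hpd_lower", "hpd_upper"]])
print("L - R difference:",
      round(axial_diff_deg(fit.mean_deg(side="L"), fit.mean_deg(side="R")), 3))
```

prints

```
  side   mean_deg  hpd_lower  hpd_upper
0    L  90.933304  90.879277  90.990032
1    R  90.240521  90.178483  90.295082
L - R difference: 0.693
```

i.e. the regression recovers the injected left (90.9°) and right (90.2°)
hemisphere mean orientations — fibres predominantly radial, slightly
rotated — and their ~0.7° hemispheric difference, with tight 95% HPD
intervals at n = 10,000 angles per side.

A full synthetic cohort (render → detect/orient → regress) runs through
`myelotrace.pipeline.run_cohort(RunConfig(...))` or the CLI:

```sh
myelotrace simulate --kind cells --out cells.tif --seed 1
myelotrace detect-cells cells.tif --out centres.csv --r0 8 --sigma 3 --phase 0
myelotrace neighborhood cells.truth.csv --out profile.csv --d 54 --stride 5
myelotrace report --out report.json --seed 1
```

## Layout

- `src/myelotrace/volume.py` — stacks, voxel metadata, TIFF IO
- `src/myelotrace/synth.py` — synthetic volumes, designs, ground truth
- `src/myelotrace/detect.py` — shell kernel, detection, scoring
- `src/myelotrace/neighborhood.py` — density fields, radial profiles
- `src/myelotrace/orientation.py` — structure tensor, surface, layers
- `src/myelotrace/circglm.py` — projected-normal GLM, HPD, DIC, bootstrap
- `src/myelotrace/pipeline.py` — cohort orchestration and provenance
- `docs/methods.md` — model descriptions, defaults and limitations
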