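# vesselcut

Retinal blood-vessel extraction from fundus images by a four-stage
pipeline, together with a synthetic fundus-phantom generator that makes
every stage testable offline with pixel-exact ground truth.

Segmenting the retinal vasculature is a core step in the diagnosis of
glaucoma, diabetic retinopathy and hypertensive changes, and in
feature-based retinal image registration. The package is aimed at image
analysts who need a rule-based (training-free) vessel segmenter with fully
inspectable intermediate stages, and at method developers who want each
stage unit-testable against ground truth.

## Method

Given a gray fundus image *I* (green channel by default), the pipeline
computes:

1. **Multiscale Hessian enhancement.** At each scale *s*, the eigenvalues
   λ₁, λ₂ (|λ₁| ≤ |λ₂|) of the scale-normalized Hessian score tubularity
   through

   V(s) = |λ₁|²·e^{|c − |λ₁|/√(λ₁²+λ₂²)|} + |λ₂|²·e^{||λ₂|/√(λ₁²+λ₂²) − c|},

   with c = √2/2. The enhanced image is VL(X) = max over the scale list of
   V(s), and s(p), the argmax scale, tracks local vessel half-width.

2. **Nonlocal-means filtering.** NL(i) = Σ_j w(i,j)·VL(j) over a search
   window, with patch-similarity weights
   w(i,j) ∝ exp(−‖v(N_i) − v(N_j)‖²/h²) normalized to sum to 1; noise in
   the likeness map is averaged out while vessel ridges survive.

3. **Radial gradient symmetry transform.** Each pixel votes along its unit
   gradient direction out to radius 2·s(p) with linearly decaying weight,
   producing an accumulator A; the directional likeness is
   VL_G = NL·(A/M_n)^q. A two-sided symmetry flag keeps only pixels lying
   between two stronger, anti-parallel gradients within ±2·s(p), giving
   VL_Sym = VL_G·Flag. Thresholding, erosion and small-component removal
   yield a coarse vasculature; blob-like structures (the optic disk) whose
   radius exceeds the vote reach are suppressed.

4. **Seeded graph cut.** The skeleton of the coarse vasculature is definite
   foreground F_d; VL_Sym thresholds T_h/T_l define candidate foreground
   F_c, candidate background B_c, and definite background B_d. With
   D_F(p) = d_f(p)/(d_f(p)+d_b(p)) the normalized distance to the seed
   sets, t-links are w₁·VL_Sym/D_F toward the preferred terminal and
   w₂·VL_Sym/D_F toward the other (w₁ > 1 > w₂ > 0); n-links cost
   k/(|I(p)−I(q)|+η) on the 8-neighbor system. An exact max-flow/min-cut
   minimizes E(L) = E_d(L) + k·E_s(L).

Segmentations are scored inside the field of view by sensitivity,
specificity and accuracy: SE = N_correct_vessel/N_vessel,
SP = N_correct_nonvessel/N_nonvessel, AC = N_correct_total/N_total.

## Worked example

```python
import numpy as np
from vesselcut import (fundus_phantom_spec, generate_phantom, segment,
                       confusion, metrics)

spec = fundus_phantom_spec(image_size=(200, 200), noise_sigma=0.03, rng_seed=7)
phantom = generate_phantom(spec)           # image + exact ground truth
result = segment(phantom.image)            # full four-stage pipeline
se, sp, ac = metrics(confusion(result.mask, phantom.truth_mask))
print(f"vessel pixels found: {int(result.mask.sum())}")
print(f"energy of the cut:   {result.energy:.2f}")
print(f"SE={se:.4f}  SP={sp:.4f}  AC={ac:.4f}")
```

prints

```
vessel pixels found: 1176
energy of the cut:   12465.30
SE=0.2941  SP=1.0000  AC=0.9294
```

The phantom contains three vessels (half-widths 2/4/6 px), a bright
optic-disk analogue and speckles on a 0.8 background with noise σ = 0.03.
The pipeline finds the vessel cores with no false positives (SP = 1):
accuracy is high while sensitivity is conservative, because the symmetry
gate only fires on the inner part of each vessel profile and the erosion
step further narrows the coarse map — see `docs/methods.md` for why masks
under-cover vessel width and what that implies on real data.

Command-line equivalents:

```bash
vesselcut segment --input img.png --out vessels.png [--fov fov.png] \
    [--config params.yaml] [--filter-first] [--save-debug dbg/]
vesselcut eval --pred vessels.png --truth manual.png [--fov fov.png]
```

The DRIVE-style layout (`images/`, `mask/`, `1st_manual/`) can be driven
with these two commands; no external data is needed for any test.

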