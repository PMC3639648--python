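# Methods

This note documents the models and numerical choices behind `vesselcut`,
what the synthetic phantoms do and do not emulate, and the known
limitations of the pipeline.

## Pipeline model and assumptions

The pipeline assumes a 2D gray image in [0, 1] in which vessels are
*dark, locally straight, tubular* structures of half-width roughly 1–6
pixels on a brighter, slowly varying background. All stages operate on the
(row, col), 0-based pixel grid; convolutions use reflective boundaries.

**Hessian enhancement.** Second derivatives are Gaussian-derivative
convolutions at standard deviation *s*, multiplied by *s*^γ (γ = 2, the
standard scale-space normalization) so responses are comparable across
scales; the image mean is subtracted before differentiation because the
sampled derivative kernels do not annihilate constants exactly (kernel
sums are ~1e−4 off zero) and demeaning removes that bias at its source.
The likeness function is evaluated exactly in its two-term exponential
form with c = √2/2; it carries **no sign test on λ₂** and no Gaussian
(negative-exponent) penalties, so it also responds to bright ridges and
does not strongly suppress blobs — both properties are inherited by
design, and a `dark_only` flag restricting the response to λ₂ > 0 (dark
ridges) is provided but off by default. The degenerate flat case is defined
as V = 0 and applied whenever √(λ₁²+λ₂²) ≤ 1e−12, the double-precision
noise floor for unit-range images. Ties in the scale maximum go to the
smallest scale, stabilizing the optimal-scale map on plateaus.

Default scale list: {1, 1.5, 2, 3, 4, 5, 6} px, covering the phantom (and
typical fundus) vessel half-widths.

**Nonlocal means.** Patch distance is the plain (unweighted) sum of
squared differences; the center pixel is included in the average with
unnormalized weight 1. Defaults: search radius 7 px, patch radius 2 px,
and strength h = 10× the noise standard deviation of the map being
filtered, estimated by the median absolute deviation of the diagonal
Laplacian pseudo-residual (insensitive to smooth structure). The
implementation accumulates one shifted box-filtered SSD map per window
offset and is exactly equivalent to the quadruple-loop definition (tested
to 1e−10). No fast approximations (integral images, PCA patches) are
used: exactness over speed at these image sizes.

Before filtering, the pipeline rescales the enhanced map by its maximum so
that VL, NL and VL_Sym live on a common [0, 1] footing; the adaptive h,
the coarse threshold and the graph-cut weights are all calibrated on that
scale. The filter may be applied to the raw image instead (before
enhancement) via `filter_first`; the default order is enhance-then-filter.

**Radial symmetry transform.** Sobel gradients (scaled to unit-step
derivative estimates) define the voting direction. Votes are cast along
+g(p) only: in the enhanced/filtered map, vessels are *bright* ridges, so
flank gradients point uphill into the vessel and one-sided voting lands on
centerlines. Vote radii run r = 0, Δr, …, 2·s(p) (Δr = 1 px); the target
cell is rounded to the grid and the increment is (2s − ‖c−p‖)/(2s) with
the **rounded** offset norm, so the r = 0 self-vote is exactly 1 and the
endpoint vote is exactly 0. Rounding can push a diagonal target marginally
beyond 2s; such increments are clipped at zero so the accumulator remains
a nonnegative vote count. Out-of-bounds targets are skipped. The
normalization M_n defaults to max(A), and the radial strictness q to 2.

The symmetry flag samples both rays at unit steps t ≤ 2·s(p) and requires
two samples (one per ray) with gradient magnitude ≥ ‖G(p)‖ and unit
gradients anti-parallel within 15° (a cosine test, not componentwise).
Zero-gradient pixels carry no search direction and are flagged false; on
real data the centerline always carries a small residual gradient, so this
convention only affects exactly symmetric synthetic profiles.

**Coarse threshold.** T_h defaults to the 80th percentile of the positive
VL_Sym values. The positive values are heavy-tailed (a thin vessel core
carries large values over a sea of tiny gated responses); histogram-shape
rules such as Otsu's method are erratic on such tails — on 100–120 px
phantoms they regularly return a threshold above essentially every pixel,
leaving an empty mask — while a fixed upper quantile tracks the core
stably across image sizes with perfect on-vessel precision in our
phantoms. An explicit `t_h` overrides the rule. Erosion uses a disk of
radius 1; 8-connected components under T_num = 30 px are then removed
(the mask is eroded before counting, not the accumulator).

**Graph cut.** Seeds: skeleton → F_d (priority), VL_Sym > T_h → F_c,
VL_Sym < T_l → B_d, rest B_c, with T_l = 0.5·T_h by default. Distances to
the seed sets use the exact Euclidean distance transform; an
intensity-weighted geodesic variant (costs 1 + 100·|∇I| integrated along
8-connected paths) is available as an option. The t-link rows for *both*
candidate classes divide by D_F, exactly as the energy model defines them;
D_B is computed and exposed, and a `use_db_for_bc` switch substitutes it
in the B_c rows for users who prefer the symmetric variant. Defaults
w₁ = 2, w₂ = 0.5, k = 1, η = 0.01. n-link intensity comes from the
filtered map NL (the most denoised surface available); configurable to
the raw gray channel.

The min-cut is solved exactly on fixed-point integer capacities. The
solver works in 32-bit units, so the scale is chosen from an a-priori
bound on the achievable flow (the cheaper of the two all-seed cuts) such
that the flow stays below 2³⁰; seed "infinity" t-links get the constant
2³¹−1, which no minimum cut can then afford to sever — the hard seed
constraints are structural, not probabilistic. In integer units the
max-flow equals the min-cut capacity *exactly*; the reported float energy
re-evaluates the returned labeling with the original capacities (the
fixed-point resolution, relative ~1e−6 or finer, is the only gap between
the two). Pixels reachable from the source in the residual graph become
foreground. If either definite seed set is empty (no structure anywhere),
the graph problem is degenerate and the coarse mask is returned with a
warning.

## Synthetic phantoms: what they emulate, what they do not

`fundus_phantom_spec` renders dark vessels (flat-bottomed dips, contrast
0.25 on a 0.8 background, half-widths 2/4/6 px) along jittered polylines,
one bright disk of radius 0.09·min(H, W) (the optic-disk analogue), and
six small speckles of alternating polarity; the clean image is blurred by
a 1-px Gaussian so the vessel flanks carry the opposing gradients the
symmetry stage needs, then Gaussian noise (σ = 0.03 by default) is added
and the result clipped to [0, 1]. Ground truth marks exactly the pixels
within a half-width of a centerline; distractors are excluded.

Not emulated: vessel branching and tortuosity beyond polylines, caliber
variation along a vessel, the central light reflex, illumination/shading
fields, the circular FOV rim, and pathology (hemorrhages, exudates).
Passing the synthetic suite therefore demonstrates the *mechanics* of each
stage — enhancement, denoising, suppression, seeded cutting — under
controlled contrast and noise; it does not certify accuracy on clinical
images, where contrast is lower, illumination varies, and annotation is
itself uncertain.

Benchmark problem sizes (the package's own choices): the end-to-end suite
uses ten 200×200 phantoms at σ = 0.03; scale-recovery trials use two
straight vessels (half-widths 2 and 6) on 128×128; suppression trials use
one primary vessel (half-width 5) plus an equal-contrast disk of radius
16 px on 128×128, with the disk polarity alternating between trials. The
disk radius is deliberately *larger than the vote reach* 2·s_max = 12 px:
that is the geometry of a real optic disc (several vessel widths across),
and it is the regime in which the transform's suppression mechanism —
votes cannot reach the blob center, and the rim fails the two-sided
magnitude test — operates. A disk comparable in size to the scale range
is structurally a thick vessel and is *not* suppressed.

## Known limitations

* **Masks are conservative in width.** The two-sided symmetry gate fires
  only where the local gradient is weaker than both flank maxima — the
  inner part of each vessel profile. Pixels on the outer flanks get
  VL_Sym = 0, fall below T_l, and are hard-labeled definite background,
  which the cut must respect. Sensitivity on the phantom suite is
  therefore ~0.3 at specificity 1.0; accuracy stays above 0.92 because
  background dominates. Loosening T_l cannot recover the flanks (their
  VL_Sym is exactly zero).
* **Thin vessels vs. erosion.** A vessel of half-width ≤ 3 px leaves a
  symmetry band 1–2 px wide; the disk-radius-1 erosion can erase it
  entirely, after which the component filter discards the fragments. Wide
  vessels are robust; the thinnest are fragile — visible in the suite's
  per-phantom sensitivities.
* **Blob suppression depends on the scale range.** Bright/dark blobs are
  suppressed only when their radius exceeds 2·s_max; enlarging the scale
  list extends vessel coverage but weakens suppression of mid-sized blobs.
* **The likeness function is unsigned.** Without `dark_only` it enhances
  bright ridges and edges as well; downstream stages, not the enhancement,
  carry the burden of rejecting them.
* **Otsu-style thresholds are unreliable here** (see Coarse threshold
  above); the quantile default assumes vessels occupy a roughly stable
  fraction of the gated response, which holds for fundus-like content but
  not for arbitrary scenes.
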