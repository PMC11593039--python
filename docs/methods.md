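# Methods

## The measurement model

A vertebral body is reduced to a binary sagittal mask with pixel spacing in
mm. Heights are taken at three column bands along the anterior–posterior
(AP) extent, centered by default at 15%, 50% and 85% of the extent with a
half-width of 5% of the extent. The height at a band is the vertical
foreground extent (max − min + 1 rows) within the band, times the row
spacing — the digital analogue of caliper placement on the endplates, and
deliberately robust to endplate concavity (a concave band reports the
rim-to-rim extent, as a caliper would). Band placement is configurable; the
defaults put each band comfortably inside the anterior/posterior thirds
while avoiding the rounded cortical corners.

The height loss ratio is `HLR = max(0, 1 − min(Ha, Hm)/Hp)`, graded
normal/mild/moderate/severe at 0.20/0.25/0.40 with inclusive lower bounds.
The worst (smaller) of the anterior and middle columns governs, matching
how wedge and biconcave deformities are read. The binary "HLR positive"
call defaults to the 0.25 diagnostic threshold; 0.20 (where grading starts
calling a body abnormal) ships as the obvious alternative preset, since
reasonable readers use either.

### Alignment

Masks are first resampled to isotropic pixels (nearest-neighbour, to the
finer spacing) when row/column spacings differ, because rotation mixes the
two axes. Tilt is then removed in two stages:

1. **Gross orientation** — if the body is clearly elongated
   (major/minor axis ratio > 1.3) and its principal axis is more than 20°
   from horizontal, a principal-component rotation levels it first.
2. **Endplate leveling** — the residual tilt is the least-squares slope of
   the inferior (bottom) foreground boundary over the central 70% of the AP
   extent, and the mask is rotated by that angle when it exceeds 0.5°.

The two-stage design exists because a principal-axis fit alone is *biased
by the deformity itself*: a wedged body is a trapezoid whose principal axis
tilts several degrees even when the vertebra is perfectly level, and
"correcting" that tilt corrupts all three heights. The inferior endplate is
the surface compression deformities leave fixed, so its slope isolates true
rotation. It is reliable for tilts up to roughly ±30°; beyond that the
gross PCA stage engages first.

Rotation uses bilinear interpolation thresholded at 0.5; measured heights
on rotated copies agree with the unrotated measurement to within about
1.5 px.

## The phantom

Each vertebral body is a rounded rectangle (default 35 mm wide, 25 mm
posterior height, 6 mm disc gaps, 1 mm isotropic pixels) whose superior
endplate profile is remapped per deformity while the inferior endplate
stays fixed:

- **wedge** — anterior plateau at `(1 − t)·Hp`, cosine ramp to a posterior
  plateau at `Hp`;
- **biconcave** — `Hp` plateaus over the anterior and posterior bands with
  a cosine dip to `(1 − t)·Hp` across the middle band;
- **crush** — the whole profile scaled by `(1 − t)`.

Profiles are flat across every measurement band (band half-width plus a 2%
guard), so band-extent measurement recovers the designed heights up to
pixel rounding; at 25 mm / 1 mm spacing the HLR recovery error is ~0.01
MAE. The truth table stores the exact pre-rasterization heights and the
Genant HLR they imply — which is 0 for crush bodies even though they are
labelled fractured: the ratio's blind spot is a *feature* of the truth
model, not an error. Corner rounding (default 8% of the body size, capped
at 9% of the width) never reaches the measurement bands. 3-D output is a
thin stack of the same profile; morphometry reduces 3-D input to the
largest-area sagittal slice per vertebra.

The raster reserves one vertical slot per vertebra sized by its undeformed
posterior height, so bounding boxes never overlap along the spine axis and
a deformity only shrinks the body within its slot.

### Cohort composition

`cohort_spec` builds study-population-style cohorts (the
`paper_scale_cohort_spec` preset: 99 fractured, 882 normal, 981 total).
Chosen once to emulate a chronic-VCF reading population and not tuned
afterwards:

- fractured vertebrae: 90% wedge/biconcave with HLR uniform in
  [0.25, 0.60); 5% sub-threshold (HLR in [0.15, 0.25), the
  absolute-loss-on-a-tall-body failure mode); 5% crush (ratio-blind);
- normal vertebrae: benign degenerative height loss, half-normal with
  scale 0.15 truncated at 0.45, rendered as shallow wedging/biconcavity
  but labelled non-fractured — so a ratio-only reader produces realistic
  false positives (~9–12% at the 0.25 threshold);
- posterior heights N(25, 2.5) mm clipped to [15, 35].

Under these conditions HLR-only reading operates near 88% sensitivity /
88% specificity.

### What the phantom does not emulate

No CT appearance (noise, partial volume, kernel variation), no spinal
curvature or inter-patient pose variation, no segmentation errors feeding
morphometry, and — importantly — **no correlation between the two error
processes**. In clinical data the detector's false positives concentrate on
the same degenerated vertebrae the ratio flags, so fusing adds few new
false positives; in the phantom the mock detector errs independently of
the benign-height-loss process, so Method 3's false-positive union is
larger, and the detector-only AUROC can exceed the fused AUROCs. Passing
tests therefore demonstrate the correctness and the ordering guarantees of
the pipeline (Method 3 never loses sensitivity over Method 1, Method 4
never loses specificity), not clinical operating points.

## The mock detector

Confidence scores are logit-normal: `conf = expit(μ + z)`, `z ~ N(0, 1)`,
with `μ = Φ⁻¹(p)` so that `P(conf ≥ 0.5) = p` exactly — `p` being the
sensitivity target for fractured vertebrae and one minus the specificity
target for normals. Unit logit scale keeps the distributions unimodal and
overlapping (AUC ≈ Φ((μ₊ − μ₋)/√2) ≈ 0.98 at the 0.83/0.96 defaults).
Degenerate targets (0 or 1) truncate `z` to the matching half-line so the
guarantee holds per-sample. A box — the truth box jittered by 5% of its
size — is emitted only when the confidence clears a floor (default 0.05),
so weak normals produce no box at all, which is what Method 4's default
negation criterion ("any box exists", implemented as confidence ≥ 1e-6)
keys on. Setting the negation threshold to exactly 0 disables negation and
Method 4 degenerates to Method 1.

## Fusion scores and ROC

Each method defines a fused score whose thresholding at the method's
operating point reproduces its binary call: HLR (Method 1), confidence
(Method 2), `max(1{HLR≥τ}, conf)` (Method 3), `conf · 1{HLR≥τ}` pinned to 0
below τ (Method 4). ROC curves sweep the detector axis with τ fixed.
Ties at any threshold resolve as "≥", consistent with the closed lower
bounds of the grade intervals.

Two detector thresholds exist deliberately: the positive-override point
θ_pos and a weaker negation point θ_neg ≤ θ_pos. A single shared threshold
cannot express a fusion in which the negative override removes fewer true
positives than the detector-only method misses, which is the regime these
strategies target.

## Metrics and intervals

Segmentation overlap uses the Dice decomposition
(`DSC = 2TP/(2TP+FP+FN)`, `FND = 2FN/...`, `FPD = 2FP/...`), satisfying
`DSC = F1 = 1 − (FND+FPD)/2` and `IoU = DSC/(2−DSC)` exactly; two empty
masks raise rather than silently scoring 1. Classification metrics carry
exact Clopper–Pearson 95% intervals (each metric as a binomial over its own
denominator; accuracy over the full cohort) — exact rather than
Wilson/Wald because the interval is honest at the small positive counts
(n ≈ 100) these studies report. A metric with a zero denominator is
flagged NaN instead of failing the whole report. AUROC is the trapezoidal
area under the empirical ROC (all score thresholds retained), equal to the
tie-aware Mann–Whitney statistic; percentages are reported to two decimals
with round-half-even.

## Numerical choices and degenerate inputs

- Masks are reduced to their largest connected component before
  measurement; an empty mask or column band raises a named error.
- Label maps are cropped per label before per-vertebra work, keeping the
  981-vertebra cohort (a ~31000 × 45 px raster) measurable in a few
  seconds.
- Box-to-vertebra matching assigns each detection to the single truth box
  with maximal IoU at a permissive default threshold (0.25): attribution is
  per vertebra, localization tightness is not scored. Per-vertebra
  confidence is the max over assigned boxes; across sagittal slices, the
  max over slices.
- Problem sizes used by the test suite and the acceptance script — the
  981-vertebra evaluation cohort, a 200-vertebra recovery phantom, 50
  seeds × 1000 vertebrae for the ordering properties, 100 seeds × ≤200
  scores for the AUROC oracle — were chosen to give stable statistics
  (binomial SE ≲ 0.04 everywhere a rate is asserted).

## Known limitations

- Endplate leveling assumes the inferior endplate is intact; fractures of
  the inferior endplate (rare in chronic VCF screening but possible) would
  bias the tilt estimate.
- The HU texture operation is a uniform random decrement of the eroded
  interior — a stand-in for trabecular rarefaction sufficient for testing
  mask/rim bookkeeping, not a radiological model.
- Vertebra naming (C/T/L levels) is out of scope; vertebrae are identified
  by label id.
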