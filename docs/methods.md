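# Methods

This document records the scientific model behind `filletbend`, the
parameter choices, and the numerical decisions that shape its results.

## 1. Physical premise

The wooden breast condition stiffens broiler breast fillets. On a conveyor,
a fillet crossing the discharge-roller edge behaves like a cantilever: the
overhanging part of a normal fillet droops and wraps around the edge, while
a wooden-breast fillet stays nearly straight until it tips off. A sideview
camera aimed at the discharge edge therefore sees a clear, mechanically
grounded difference between the classes — no spectral or texture information
is needed.

## 2. Scene model and simulator

All coordinates are image pixels, row 0 at the top. The default geometry is
the study condition used throughout the tests:

| parameter | value | meaning |
| --- | --- | --- |
| `image_w × image_h` | 960 × 696 | frame size |
| `belt_row` | 320 | belt surface row |
| `edge_col` | 620 | discharge edge column |
| `roller_radius` R | 49 | axle sits R below the belt at the edge |
| `arrival_col` | 420 | vertical trigger line |
| `departure_row` | 600 | horizontal trigger line |
| `line_speed` | 6 px/frame | 50 FPM tag at 200 frames/s (10/100 FPM ⇒ 3/12) |

A fillet is a tapered half-elliptical thickness profile (tail-first, thinner
leading end; lengths ≈ 320 px, thickness 73–85 px depending on class) lying
on the belt. Once a column overhangs the edge by `x` pixels it sags by the
cantilever-like law

```
δ(x) = x² / (2 · rigidity),   capped at 180 px,
```

so `rigidity` (px) is the single mechanical parameter separating classes.
When the centroid passes the edge column the fillet detaches: its
deformation freezes and it falls with constant downward acceleration
(3 px/frame²) plus a forward velocity gained at detachment (6 px/frame).
The forward "tipping kick" is a deliberate extension of a straight-down
fall: without it every falling centroid converges on the axle and the
class separation the distance descriptor relies on disappears; physically,
rotating over the edge does accelerate the center of mass forward before
release.

Frames are 8-bit grayscale, background 10, fillet 200, additive Gaussian
noise σ = 4. The simulator returns exact per-frame ground-truth masks and
the true arrival/departure trigger frames.

**Rigidity calibration.** The class presets (normal 40, moderate 160,
severe 240 px, each drawn log-normally with 15 % spread per fillet) were
calibrated — before any test was frozen — so that simulated NMDM group
means land near previously reported values for graded fillets
(≈ 0.41 / 0.63 / 0.66). A 45-pass cohort at master seed 42 gives NMDM
0.443 / 0.649 / 0.670, MDM 40.8 / 61.4 / 64.2 px and MBE 21.9 / 10.5 / 8.5.
The simulator reproduces the *orderings* and rough magnitudes of the real
measurements; it makes no claim to reproduce their variances, the absolute
MBE scale, or classifier scores on real video.

## 3. Motion sensing

Two single-pixel trigger lines delimit each pass in software: a vertical
line at `arrival_col` and a horizontal line at `departure_row`. A line fires
when ≥ 5 of its pixels exceed intensity 60, debounced over 2 consecutive
frames. The tracking window runs from the debounced arrival to the debounced
departure (or the last frame with content if the fillet leaves sideways).
On simulated cohorts the detected window start is within ±2 frames of the
ground-truth arrival.

## 4. Segmentation

Five fixed stages: global threshold (60) → hole filling (4-connected) →
median filter (3×3) → morphological opening (disk radius 2) → size filter
(≥ 500 px, 8-connected); the largest surviving component is the fillet.
The post-threshold stages are local operators, so they run on a padded crop
around the thresholded foreground and are embedded back — identical output,
several times faster. On noise-free simulated frames the result overlaps
ground truth with IoU ≥ 0.95 throughout the pass (flat, bent and falling
phases); the opening trims at most a few thin tail columns.

Region properties use a pixel-as-unit-square convention: a component
spanning rows `r0..r1` has height `h = r1 − r0 + 1`, with box edges half a
pixel outside the extreme pixel centers, so the centroid split satisfies
`h = ht + hb` exactly and a symmetric mask gives `ht = hb`.

**Perimeter.** The Crofton 4-direction estimator is used. It is nearly
unbiased on smooth shapes (0.4 % error on a digitized disk of radius 50,
comfortably within the 5 % the bending-energy normalization needs), at the
cost of sitting ~5 % below the true perimeter of axis-aligned rectangles;
an 8-connected boundary walk has the opposite (worse, ~+5 %) bias on disks.

## 5. Bending energy

For each windowed frame:

1. rotate the segmented mask about its centroid so the second-moment major
   axis is horizontal (nearest-neighbor inverse mapping on a tight canvas);
2. take the medial-axis skeleton of the rotated mask;
3. collapse the skeleton to one row per column (the median — robust to
   branch spurs), drop the outermost 5 % of columns at each end (where
   medial axes of blunt shapes grow diagonal spurs), and fit a quadratic
   `y = a x² + b x + c` by least squares;
4. sample the analytic curvature `C(x) = |2a| / (1 + (2ax + b)²)^{3/2}` at
   the integer columns spanned by the full skeleton (`L` of them), and score

```
BE = (P² / L) · Σ C(x)².
```

For a curve of constant curvature κ₀, `Σ C² ≈ L κ₀²`, so `BE ≈ P² κ₀²` —
dimensionless and scale-invariant since `P κ₀` is a pure shape number.
Validated properties (phantom oracles, frozen before the tests):

* straight rectangle: BE ≈ 2·10⁻³² (flat fit);
* quadratic band scaled ×0.5 / ×1.5 / ×2.0: BE ratio 1.014 / 1.035 / 1.006;
* constant-curvature arc (κ₀ = 1/1000): BE / (P²κ₀²) = 0.983;
* coefficient recovery: fitted `a` within 10 % of a phantom's true value.

**Orientation sensitivity.** Re-rotating a rasterized arc by 20–135° before
the analysis changes BE by up to ~12 %. The residual comes from
nearest-neighbor resampling of the boundary (stair-casing) and the skeleton
jitter it induces, not from the fit; the tests assert ±15 %. MBE, the
per-pass maximum, is unaffected in practice because consecutive frames give
near-identical orientations.

## 6. Distance metric

`d_i = ‖centroid_i − axle‖` with the axle at `(belt_row + R, edge_col)`.
The pass minimum is MDM; dividing by the per-fillet scale factor
`H = ht + R` (first flat frame) gives NMDM, with the identity
`NMDM · H = MDM` holding to 10⁻⁹. The alternative factors `HTR = ht + R`
and `HBR = hb + R` are exported as features in their own right. Missing
frames are skipped, never interpolated; ties in the minimum resolve to the
first occurrence (same for the MBE maximum).

## 7. Features and evaluation

Eleven columns per fillet: `NMDM, MDM, MBE` (pass descriptors),
`MAXH, AVGH, MAXL, AREA, PERIM, HTR, HBR` (first-frame sizes), `label`
(0/1/2). Group statistics: per-feature one-way ANOVA, Tukey HSD letters
(maximal cliques of the non-significance graph, lettered by descending
group mean), and Spearman ρ against the ordinal label.

Classification is deliberately 1-D: each feature alone, normal (0) vs
wooden breast (1 ∪ 2), with LDA, QDA, a depth-3 decision tree, an RBF SVM
(C = 1, standardized input) and 5-NN. Evaluation is 10-repeated stratified
5-fold cross-validation; metrics (OACC, BACC, F1, MCC) are computed from
each repeat's pooled out-of-fold predictions and averaged over repeats
(fold-level averaging is available behind a flag). Zero-denominator MCC/F1
are defined as 0. A fold whose training split lost a class triggers a
re-stratification, never a silent skip.

Score-grid aggregation (row / column / block-subtotal / grand means)
reports three decimals with half-up rounding applied only at rendering;
values are snapped to nine decimals first so decimal ties computed in
binary floating point still round as their decimal arithmetic would.
The bundled reference tables reproduce previously published marginals,
with one exception: the published grand mean cell (0.814) disagrees with
its own constituent cells, which average to 0.810; the package reports the
arithmetic 0.810.

## 8. Problem sizes and runtime (single CPU)

* one pass: ~190 frames of 960×696; simulation ≈ 1.5 s, full feature
  extraction ≈ 2.5–3 s;
* 45-pass cohort: ≈ 2.5–3 min end to end;
* full test suite: ≈ 10–12 min; acceptance script: ≈ 4 min.

## 9. Known limitations

* The simulator's fall and sag laws are kinematic sketches, not mechanics;
  only the class orderings they induce are treated as meaningful.
* Bending energy is orientation-stable only to ~±15 % under arbitrary
  pre-rotation (Section 5); within a conveyor pass this is immaterial.
* No motion blur is modeled at high line speeds; the line-speed tag only
  scales the per-frame translation.
* Three-tier severity classification is out of scope; all classification is
  binary normal vs wooden breast.
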