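# Methods

## The measurement model

A plant is imaged from three directions (two side views at 90°, one top
view, RGB) plus one top-view steady-state fluorescence image. The
analysis treats every image as an 8-bit colour raster and proceeds in
four stages.

**1-NN colour classification.** Each pixel is assigned the class of its
nearest labelled reference colour under Euclidean distance in raw RGB.
Distances are compared as exact integer squared distances, so ties are
well defined; an exact tie between classes is resolved by a fixed
priority list (background first by default). We deliberately use raw RGB
and k = 1: it is the simplest classifier consistent with
"nearest-neighbour colour classification", it is exactly checkable
against a brute-force oracle, and the colour space/neighbour count are
the obvious knobs to expose if real imagery demands more.

**Noise removal.** The plant class is opened (erosion then dilation,
disk structuring element, default radius 1; pixels outside the image
count as background) and 8-connected plant components smaller than
`min_size` (default 50 px) are dropped. Radius 0 plus `min_size` 0 is
the identity. With dilation ≤ erosion the operation is anti-extensive on
the plant class — cleanup never invents plant pixels.

**Composition.** All surviving plant components are treated as a single
object: pixel count, union bounding box, height = bounding-box row span.
An image without plant pixels yields a flagged empty object, not an
error.

**Traits.** Projected shoot area (PSA) is the sum of the three per-view
pixel counts and serves as the biomass surrogate; its calibration
against fresh weight is an ordinary least-squares regression.
Senescence is quantified on the fluorescence image only: senescent % =
100 · senescent / (healthy + senescent), i.e. the denominator is the
top-view shoot area of that image, not the RGB PSA. For the fluorescence
mask, noise removal is applied to the shoot *union* (healthy ∪
senescent) and the surviving pixels keep their tissue label. This
follows the processing order "separate object from background, remove
noise, then classify tissue"; opening each tissue class separately would
erode the internal healthy/senescent boundary and bias the fraction by
up to a few percentage points on small plants.

## Growth-phase analysis

Per-plant relative growth rate over an interval is
RGR = (ln A_end − ln A_start)/Δt. The osmotic index is
mean(RGR_treated)/mean(RGR_control) over day 0 → breakpoint (default
day 10); the ionic index is the same ratio over breakpoint → last day.
Confidence intervals are bootstrap over replicate plants (treated and
control resampled independently). We use the normal-interval bootstrap
(estimate ± z·SD of bootstrap replicates) rather than percentile
intervals: at n = 7 per group the percentile interval of a ratio of
means undercovers noticeably, while the normal interval stays close to
nominal 95% coverage in the package's own Monte-Carlo calibration.

Percent growth reduction, 100·(1 − treated/control), is computed on
replicate means at a given day and dose. In the zero-noise limit it
equals 1 − exp((r_eff − r)·(d − lag)) of the growth generator, which the
tests assert.

## Ion bookkeeping and statistics

* K⁺/Na⁺ is computed **per replicate and then averaged**. The
  alternative (ratio of group means) is demonstrably a different
  statistic — the worked two-replicate example gives 145.0 vs 144.4 —
  and only the mean-of-ratios convention is internally consistent with
  the reported group ratios this design mirrors.
* Tissue ion concentration from a digest: amount (µmol) =
  digest concentration (mM) × digest volume (mL); tissue water (mL) =
  fresh − dry weight (1 g ≡ 1 mL); concentration = amount / tissue
  water. Expressing leaf ion content in tissue water is the only reading
  that yields mM from dried, digested tissue; it is an interpretation and
  flagged as such.
* Tissue tolerance score = senescent % / leaf Na⁺ (mM); lower = more
  tolerant. No standard numeric definition of tissue tolerance exists
  for this assay — the published argument is qualitative (high Na⁺ with
  low senescence) — so the score is this package's declared
  operationalisation; its group SE uses first-order error propagation of
  the two group means.
* Two-way ANOVA is the standard fixed-effects cultivar × salt model
  (statsmodels OLS + type-II ANOVA), with stars at p < 0.05 / p < 0.01.
  LSD = t(1−α/2, df_error)·√(2·MSE/n); letters are assigned by the
  sorted-sweep insert-and-absorb convention (maximal runs of pairwise
  non-significant means over the descending sort). The tested contract
  is the pairwise relation — means ≥ LSD apart never share a letter,
  means < LSD apart always share one — not the letter strings, which are
  convention-dependent. The pooled LSD requires equal replication and
  the code refuses unequal group sizes.

## The synthetic-data generator

The generator emulates the study's data, not its optics.

* **RGB scenes.** Shoots are arching polyline strokes (default width
  3 px) in plant green over a background of blue pellet, white pot and
  grey frame regions — the pellet/pot palette mimics a soil surface
  covered with blue plastic pellets chosen as a favourable segmentation
  background. The second side view is the mirrored stroke set and the
  top view the transposed set on a transposed canvas; all three views of
  one spec therefore have identical ground-truth pixel counts, a known
  simplification of real 3-D plants. Strokes keep a 6 px border margin
  and width-3 strokes are unions of unit-disk dilations, hence exactly
  invariant under the default radius-1 opening — noiseless pipeline area
  equals ground truth exactly by construction, which is what makes the
  exact-recovery tests meaningful.
* **Noise.** Truncated per-channel Gaussian (default sd 8, clipped to
  [0, 255]). The palette stays separable at this noise level but
  individual pixels do get misclassified; the cleanup stage is what
  keeps the measured area within tolerance.
* **Fluorescence.** Healthy tissue is rendered red, senescent yellow, on
  a near-black background. The senescent fraction is allocated as
  contiguous patches grown best-first from the most distal plant pixels
  (leaf tips senesce first); the pixel target is the rounded fraction of
  plant pixels and the remainder stays healthy, so the realised fraction
  is within one pixel of the requested one.
* **Growth.** A(t) = A0·exp(r·t) with r = r_control up to `lag_days`
  (default 10 — no early growth penalty, matching the observed lack of
  an osmotic response in these cultivars) and
  r_control·(1 − penalty_per_mM·dose) afterwards. The default penalty
  0.0037 /mM yields a ≈31% reduction at 100 mM by day 20, inside the
  30–37% range the design targets. Observation noise is multiplicative
  mean-one log-normal (default CV 0.1), so areas stay positive.
  Validation rejects parameter combinations that would drive RGR
  negative.
* **Ion tables.** Leaf Na⁺ rises linearly with dose with a per-cultivar
  slope; K⁺ rises mildly; senescence accrues above a dose threshold.
  The two default cultivar profiles reproduce the contrast the assay is
  meant to detect: a "tolerant" profile with high Na⁺ uptake but ~4%
  senescence at 200 mM, and a "sensitive" profile with lower Na⁺ but
  ~23% senescence. Replicate noise is Gaussian, truncated at small
  positive concentrations.

What passing tests on this generator do **not** show: robustness to
specular highlights, shadows, overlapping leaves, camera calibration
drift, or fluorescence bleed-through — none of which the renderer
models. The generator's role is to make the arithmetic of the chain
falsifiable, not to certify performance on instrument imagery.

## Problem sizes and numerics

Default synthetic images are 150×200 px with plants of roughly 1–3
thousand pixels — scaled-down scenes with the same relative structure as
instrument images. The calibration studies use the design's replication
(n = 7), 200 simulated experiments for phase-index coverage, 500–1000
bootstrap resamples, and 1000 null simulations for the ANOVA type-I
check. All generators and analyses are bit-reproducible given a seed;
seeds are threaded explicitly (numpy `SeedSequence` children, kept below
2³¹).

## Known limitations

* The colour palettes are calibrated for class separability, not for any
  specific camera; no pixel-level colour statistics of a real rig were
  available.
* Height is reported in pixel rows; no mm calibration is attempted.
* The two side views are symmetric transforms of one stroke set, so
  view-to-view area variation of real plants is not represented.
* ANOVA is per-experiment fixed-effects only; no repeated-measures or
  mixed models.
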