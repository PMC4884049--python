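# phenosalt

Non-destructive, image-based phenotyping of salinity-tolerance traits in
rice (*Oryza sativa*). Salinity limits rice growth in two phases: an
early, shoot-ion-independent **osmotic** phase, and a later **ionic**
phase in which Na⁺ accumulating in the shoot causes premature leaf
senescence. Because classical biomass and injury scoring are destructive
or subjective, screening programmes increasingly rely on repeated imaging
of the same plants. This package implements that analysis chain for a
controlled pot experiment — two rice cultivars × several NaCl levels ×
replicates, imaged at 0, 10 and 20 days after salt application — together
with a synthetic-data generator that provides images and growth tables
with exact ground truth, so every stage is testable without instrument
data.

## What it computes

* **Segmentation.** Each pixel is labelled by 1-nearest-neighbour colour
  classification against labelled reference colours (Euclidean distance
  in RGB, deterministic tie-breaking), noise is removed by a
  morphological opening and a connected-component size filter, and all
  surviving plant components are composed into one object whose pixel
  count and bounding-box height are measured.
* **Projected shoot area.** PSA = A_side1 + A_side2 + A_top (two side
  views at 90° plus one top view), a linear surrogate for shoot fresh
  biomass; the calibration is an OLS regression of fresh weight on PSA.
* **Senescence.** Top-view steady-state fluorescence images are split
  into healthy (red chlorophyll fluorescence) and senescent (yellow)
  tissue; senescence % = 100 · senescent / (healthy + senescent) pixels
  of that image.
* **Phase analysis.** Relative growth rate RGR = Δln(PSA)/Δt per
  interval; osmotic index = mean treated RGR / mean control RGR over
  days 0–10, ionic index likewise over days 10–20, with bootstrap 95%
  CIs; percent growth reduction = 100·(1 − treated/control) on replicate
  means.
* **Ion reporting.** Leaf Na⁺/K⁺ summaries where K⁺/Na⁺ is the mean of
  per-replicate ratios; tissue ion concentration from digests expressed
  in tissue water (fresh − dry weight); a tissue-tolerance score
  (senescent % per mM leaf Na⁺ — lower is more tolerant).
* **Experiment support.** Stepwise salt dosing (50 mM increments every
  12 h) with CaCl₂ supplementation at a 30:1 Na⁺:Ca²⁺ molar ratio,
  watering-to-weight, two-way ANOVA (cultivar × salt) with significance
  stars, and LSD(0.05) letter groupings.

## Worked example

```python
import phenosalt as ps
from phenosalt.cli import default_rgb_reference, default_fluor_reference

spec = ps.random_plant_spec(geometry_seed=21, noise_sd=8.0,
                            senescent_fraction=0.25, seed=3)
images, truth_masks = ps.render_rgb_views(spec)
clf = ps.train_color_classifier(default_rgb_reference(spec))
areas = {}
for view, img in images.items():
    mask = ps.clean_mask(ps.classify_pixels(img, clf))
    areas[view] = ps.compose_plant_object(mask).pixel_count
psa = ps.projected_shoot_area(areas["side1"], areas["side2"], areas["top"])
print("projected shoot area:", psa)

fimg, _, _ = ps.render_fluor_image(spec)
fclf = ps.train_color_classifier(default_fluor_reference(spec))
res = ps.senescence_fraction(ps.classify_fluor(fimg, fclf))
print(f"senescent area: {res.senescent_percent:.1f}% of {res.plant_px} px")

params = ps.SyntheticGrowthParams(lag_days=10, penalty_per_mM=0.0037,
                                  noise_cv=0.1, seed=0)
df = ps.simulate_growth(params, [0, 100], [0, 10, 20], 7)
idx = ps.phase_indices(df[df.dose_mM == 100], df[df.dose_mM == 0], rng=0)
print(f"osmotic {idx.osmotic_index:.3f}, ionic {idx.ionic_index:.3f}")
```

prints

```
projected shoot area: 3354
senescent area: 25.0% of 1118 px
osmotic 0.911, ionic 0.710
```

The segmented area equals the generator's ground truth (3354 px) despite
pixel noise of sd 8; the recovered senescent fraction matches the 25%
programmed into the fluorescence image; the osmotic index is consistent
with 1 (no early growth penalty — its 95% CI, 0.81–1.02, covers 1.0),
while the ionic index ≈ 0.71 reflects the programmed post-lag growth-rate
penalty at 100 mM NaCl (true value 0.63 under observation noise).

## Command line

```
phenosalt simulate --seed 1 --outdir run/          # synthetic fixture
phenosalt report --fixture run/ --outdir run/out   # full pipeline
phenosalt schedule --target 200                    # salt dosing plan
```

`simulate` writes images (`<plantID>_day<D>_<view>.png`), ground-truth
masks and CSVs plus colour-reference files; `report` runs segmentation →
senescence → traits → statistics and emits per-stage CSVs plus
`summary.json`.

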