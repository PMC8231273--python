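# lungmsi

Spatial analysis of drug distribution in lung tissue sections imaged by
MALDI mass-spectrometry imaging (MSI).

## The problem

When a drug such as budesonide is instilled into the lungs — alone in
saline, or mixed with an exogenous surfactant that spreads it along the
air–liquid interface — the question is *where it ends up*: clustered in a
few dense patches near the central airways, or distributed evenly out to the
lobe periphery. MSI answers this label-free: each 400 µm pixel of a tissue
section carries a centroid mass spectrum, and the drug's ion intensity can
be mapped across the section. `lungmsi` implements the quantitative analysis
of such maps for treatment-group comparisons, and ships a seeded synthetic
cohort generator so the entire analysis is testable end to end without
animal data.

## The method

For each section (grid of centroid spectra, `imzML` processed mode):

1. **Ion maps** — per-pixel intensity is the sum of centroids within a
   tolerance window around each registered target: drug (GirP-derivatized
   budesonide, *m/z* 564.308 ± 0.005), internal standard (derivatized
   triamcinolone, 568.283 ± 0.005), heme (616.176 ± 0.005) and porcine SP-C
   (4188 ± 1).
2. **Normalization** — the drug map is divided pixel-wise by the internal
   standard map.
3. **Tissue mask** — heme ionizes only where tissue is present; the mask is
   the largest connected component of heme-positive pixels.
4. **Detection threshold** — a high quantile (default 0.99) of the pooled
   on-tissue normalized intensities of drug-free control sections.
5. **Quartile statistics** — each section's on-tissue signal is scaled and
   mean-centered, then rank-binned into quartiles Q1–Q4. Adjacent
   (8-neighbor) Q4 pixels form *clumps*; the clump count and median clump
   size (pixels) summarize how aggregated the drug is.
6. **Border distance** — the tissue border is the alpha hull (α = 1.2 mm) of
   the on-tissue pixel centers; each Q4 pixel's Euclidean distance to the
   border is binned in 3 mm bands.
7. **Group statistics** — per-animal clump counts, median sizes and per-band
   pixel fractions are compared between groups with an exact two-sided
   Wilcoxon rank-sum test, W = Σ ranks of group A, p = min(1, 2·min(P(W ≤ w),
   P(W ≥ w))) by full enumeration of all C(n_A+n_B, n_A) assignments.
   Animal-characteristics tables (mean ± SD per group) are checked with a
   one-way ANOVA computed from summary statistics.

The synthetic generator emulates four treatment-like patterns on an
irregular, non-convex lobe mask: `clumpy` (few large separated central
foci — drug in saline), `dispersed` (many small border-biased foci — drug
spread by surfactant), `cleared` (the dispersed field scaled by 1 − 0.93,
the ~93% two-hour lung clearance) and `control` (no drug).

## Worked example

```python
from lungmsi import PipelineConfig, run_full_pipeline

cfg = PipelineConfig(n_per_group=5, seed=20210612, output_dir="demo_run")
summary = run_full_pipeline(cfg)
print(round(summary["threshold"], 4))
for c in summary["comparisons"]:
    print(f"{c['statistic']:34s} p = {c['p_two_sided']:.5g} ({c['method']})")
```

prints

```
0.1292
clump_count                        p = 0.0079365 (exact)
clump_median_size_px               p = 0.0079365 (exact)
distance_0-3mm_fractions           p = 0.0079365 (exact)
distance_3-6mm_fractions           p = 0.015873 (exact)
distance_6-9mm_fractions           p = 0.30952 (exact)
distance_9-12mm_fractions          p = 1 (exact)
```

The detection threshold (0.1292, normalized intensity units) is the 99th
percentile of the two control sections' pooled signal. The surfactant-like
group has more clumps per section (23–28 vs 8–12) that are smaller (median
17–29 px vs 80–112 px) than the saline-like group — complete separation of
two groups of five gives the smallest attainable two-sided exact p,
2/252 ≈ 0.0079. The distance profile shows the surfactant-like group
enriched within 3 mm of the tissue border but indistinguishable far from
it. `demo_run/` receives per-section rasters, clump tables, border
polylines, distance profiles, a group-comparison table and a checksummed
run manifest; `lungmsi render demo_run` draws the intensity, Q2/Q4 and
border overlay maps.

The same pipeline is scriptable from the shell:

```
lungmsi generate --seed 1 --out cohort      # write the cohort as imzML
lungmsi run --seed 1 --out results          # full analysis
lungmsi render results                      # figures
```

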