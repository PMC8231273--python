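# Methods

## Scope and data model

`lungmsi` analyzes centroided MSI rasters: one peak list per pixel on a
regular grid (400 µm pitch by default, matching low-duty-cycle acquisitions
of large lamb-lung sections of roughly 50 × 20 mm). Only imzML "processed"
mode is supported — centroided acquisitions store a separate m/z array per
pixel — and continuous (profile-layout) files are rejected rather than
silently converted. Coordinates are 1-based in files (the imzML convention)
and 0-based in memory. m/z is held in 64-bit floats because the extraction
windows are ±0.005 Da; intensities in 32-bit floats. imzML has no standard
slot for pixel pitch, declared m/z range or section/group labels, so these
travel in the cohort manifest table; the reader accepts them as overrides.
Files are serialized with a content-derived UUID so identical datasets give
byte-identical file pairs.

## Ion maps, normalization, masking, thresholding

A pixel's value for an ion target is the **sum** of centroid intensities
within `target ± tolerance`. The original description says only that
intensity is "plotted"; the sum is robust when a peak is split across
neighboring centroids, and a max option would change nothing downstream
because the statistics are rank-based. Off-tissue and dropped pixels are
*missing* (NaN), never zero, so every statistic runs over tissue pixels
only.

Normalization is the pixel-wise ratio to the internal-standard image
(derivatized triamcinolone, 568.283 m/z); pixels with non-positive
reference become missing and are tallied. Normalization precedes
thresholding.

The tissue mask keeps pixels whose heme intensity exceeds
`min_fraction` (default 0.05) of the median positive heme intensity, then
retains the largest 8-connected component. The 0.05 default is a weak cut
— heme is either present (tissue) or essentially absent — and on noiseless
synthetic sections the mask recovers the generator's ground truth exactly.

The detection threshold is a quantile (default 0.99,
linear-interpolation convention) of the pooled on-tissue normalized
intensities of the drug-free control sections. The source analysis states
only that controls set the threshold, not the rule; a pooled high quantile
is the natural formalization and is monotone in the quantile by
construction.

## Spatial statistics

Per-section standardization is the z-score over on-tissue pixels (sample
SD). Quartile binning is rank-based: pixels ranked ascending, rank *r* of
*n* mapped to label ⌈4r/n⌉, ties broken by row-major pixel order so the
result is deterministic; class sizes differ by at most one. Because only
ranks matter, the quartile map is invariant under any strictly monotone
transform — z-scoring first changes nothing, which the tests exercise.
Quartiles are computed over **all** on-tissue pixels (not only
above-threshold ones), since the whole section's signal is standardized.

Clumps are connected components of Q4 pixels, 8-neighbor by default
(4-neighbor available); singletons are clumps of size 1. The implementation
is `scipy.ndimage.label`; an independent pure-Python flood fill serves as
the test oracle, exhaustively on all 4×4 binary grids and on random 50×50
grids.

The tissue border is the alpha shape of the on-tissue pixel centers in
physical mm: Delaunay triangles with circumradius ≤ α, unioned, with
collinear ring vertices simplified away (so the large-α limit equals the
convex hull exactly, vertex for vertex). The default α = 1.2 mm (3× pixel
pitch) is the smallest value that reliably keeps synthetic lobe masks
single-ringed. Q4-pixel distances to the border are Euclidean
point-to-polyline distances, binned into half-open 3 mm bands
[0,3), [3,6), [6,9), [9,12); pixels outside every ring (possible with a
very small α) get distance 0 and a warning tally. Colocalization between
two channels (drug and SP-C in consecutive sections, which share gross
geometry at this raster) is the Spearman rank correlation over shared
tissue pixels.

## Group statistics

The experimental unit is the animal (one section per animal). The exact
two-sided Wilcoxon rank-sum test enumerates all C(n_A+n_B, n_A) assignments
of the pooled mid-ranks, conditioning on the observed tie pattern;
p = min(1, 2·min(P(W ≤ w), P(W ≥ w))). The doubled smaller tail is the
dominant convention for exact rank tests. Above a combined n of 20 the
test switches to a tie-corrected, continuity-corrected normal
approximation. Per-band distance comparisons use per-animal bin fractions
(counts optional) with no multiplicity adjustment, matching per-band
reporting. The one-way ANOVA from summary statistics uses
SSB = Σ nᵢ(x̄ᵢ − x̄)², SSW = Σ (nᵢ−1)sᵢ², F = (SSB/(k−1))/(SSW/(N−k)), and
is algebraically identical to the raw-data ANOVA (tested by
reconstruction). A Tukey HSD from summary statistics is provided as the
post hoc test; the original analysis does not name its post hoc method, so
this is a conventional stand-in.

## Synthetic cohorts: what they emulate, and what they do not

No raw acquisitions are publicly deposited for studies of this kind, so the
generator produces sections with the *structure* the analysis assumes. All
randomness flows from a single integer seed through independent
sub-streams (mask, fields, per-dataset assembly), so a section is
bit-reproducible and the drug dataset is unchanged whether or not the SP-C
companion is generated.

- **Lobe mask**: a star-shaped region — an ellipse (~44 × 80% of the grid)
  whose radius is modulated by random low-order harmonics plus one
  guaranteed wedge notch — covering 30–80% of the grid, connected by
  construction, always with at least one concavity.
- **Drug field**: a sum of isotropic super-Gaussian (quartic) foci,
  `a·exp(−(r²/2σ²)²)` — plateaus with steep edges, like discrete
  instilled-bolus patches. Steep edges matter: with plain Gaussian foci the
  quartile cut falls on wide shallow-gradient shoulders where pixel noise
  detaches speckle singletons, distorting clump counts and medians in a way
  real patchy deposits do not. Pattern defaults: `clumpy` = 8 foci of
  σ = 2.0 mm, centrally placed with a 3σ minimum separation (boluses are
  spatially distinct); `dispersed` = 60 foci of σ = 0.8 mm with 70% of
  centers border-biased (weight ∝ exp(−d/2 mm)); `cleared` = the
  seed-matched dispersed field × (1 − 0.93); `control` = no drug. Focus
  amplitudes are U(0.8, 1.2) × base intensity.
- **Noise**: multiplicative log-normal pixel noise, CV 0.15 for analyte
  channels (0.3× that for the uniformly sprayed internal standard, 1.2×
  for heme); sparse broadband chemical-noise centroids (~2 per pixel at
  0.1% of base intensity) everywhere including off-tissue; and an
  in-window chemical baseline on 3% of tissue pixels, log-normal with
  median 0.10× base and σ_log = 0.7. The baseline is what a control
  section's intensity distribution shows and what the control threshold is
  estimated from; its scale was chosen so that the 99th-percentile
  threshold sits above the 93%-cleared signal — the regime the 120-minute
  sections are in — while its tail stays too light to contaminate the top
  quartile. `noise_cv=0` switches every noise source off (used by
  ground-truth tests).
- **SP-C companion**: same geometry, m/z 2000–5000, a 4188 m/z peak whose
  field is `c·drug + (1−c)·independent` for coupling `c` (default 0.8),
  at 0.3× the drug amplitude (SP-C is a minor surfactant component).

What the generator does **not** model: derivatization chemistry, matrix
crystallization, mass-accuracy drift, isotope envelopes, spatial noise
correlation, partial-volume effects at the tissue edge, or genuine
consecutive-section misregistration (the SP-C channel shares the drug
channel's mask exactly). Passing tests therefore demonstrate that the
pipeline recovers planted spatial structure under realistic intensity
statistics — not that it is robust to every artifact of real acquisitions.

Cohort layout follows the study design: n per treatment arm (saline-like
clumpy, surfactant-like dispersed at 1 min, cleared at 120 min) plus two
drug-free controls, each section with a distinct seed derived from the
cohort seed.

## Numerical and design choices

- Windowed extraction is edge-inclusive (|Δm/z| ≤ tolerance).
- Rare duplicate centroids in synthetic spectra are merged by summing, so
  m/z stays strictly ascending.
- Quartile tie-break is row-major and documented; an all-tied section bins
  deterministically.
- The exact-test enumeration limit (combined n = 20, ≈184k assignments)
  keeps the exact path well under a second at the study's group sizes.
- Zero-variance inputs (constant sections, zero within-group variance) are
  errors, not silent NaNs.
- Empty clump sets yield count 0 with an undefined median, excluded from
  median-size comparisons.
- The pipeline writes a manifest with a config hash (excluding the output
  path), the seed, the package version and SHA-256 checksums of every
  output file; rerunning a config reproduces byte-identical summaries.

## Problem sizes used in the test suite

Unit tests run on small grids (≤ 20×40) for I/O and geometry; the
cohort-level checks run the full default study conditions — 50×125 pixel
sections (≈ 50 × 20 mm at 400 µm), five sections per arm — including a
20-cohort parameter-recovery sweep for the clump-statistic ordering and a
full-cohort pipeline run for the group-comparison checks.

## Known limitations

- The alpha parameter, adjacency rule and quartile domain of the original
  analysis are unstated; the defaults here (1.2 mm, 8-neighbor, all tissue
  pixels) are documented choices, not recovered facts.
- Whether thresholding operated on normalized or raw intensities is
  likewise unstated; this implementation thresholds normalized values.
- The exact test enumerates combinations in pure Python; for combined
  n > 20 it approximates. Group sizes beyond ~10 per arm were not the
  design target.
- The SP-C target (4188 m/z) is stored as an opaque registry entry; no
  isotopic interpretation is attached to it.
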