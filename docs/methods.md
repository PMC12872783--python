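# Methods

This note documents the models, conventions and defaults behind `endosig`,
and what the synthetic-data tests do and do not demonstrate about real data.

## Nuclear translocation quantification

**Model.** A field is a pair of single-channel rasters: a nuclear stain
(DAPI) and a marker whose nuclear/cytoplasmic partitioning is the readout.
Per cell, the statistic is

    N/C = (mean marker over nuclear mask − mode) / (mean marker over ring − mode)

where `mode` is the modal intensity of the whole marker field. The mode is
used (rather than mean/median of a background region) because in a sparse
field most pixels are background, making the histogram peak a robust
background estimate; it is computed per field, which tolerates illumination
drift between fields. Using a ratio of background-corrected means makes the
statistic invariant to detector gain (multiplying the image by c > 0) and
offset (adding a constant), which the test suite asserts.

**Segmentation.** Median filter (radius 2, symmetric-reflection borders;
the kernel size is a convention — filtering is standard, the radius choice
is ours) → Otsu threshold → binarize (`value > t`) → fill holes (nucleoli
are artifacts for this purpose) → 8-connected components → area gate →
optionally drop border-touching components (their rings are truncated
asymmetrically) → relabel 1..K. The Otsu threshold is computed by exact
integer arithmetic over all candidate thresholds for integer images, with
ties broken toward the lowest threshold, so it provably equals an
exhaustive between-class-variance search. A blank (single-valued) field
yields zero nuclei rather than an error.

The default area gate is 100 µm² (in pixels via the pixel size, else
200 px) to 10× that. Note this default is deliberately conservative and is
narrower than nuclei rendered from the default synthetic area distribution;
analyses of the synthetic scenes pass explicit bounds (800–30 000 px at
0.65 µm/px) appropriate to the rendered geometry. The bounds are ordinary
configurable parameters of `segment_nuclei` and of the pipeline config.

**Perinuclear ring.** "Dilation by r" means the Euclidean-distance
threshold d ≤ r from the nucleus (identical to dilation by a disk
structuring element). Ring k is `gap < d ≤ gap + ring_width` around nucleus
k, minus all nuclear masks. Defaults gap 1 px, width 4 px — a narrow band
that stays inside the cytoplasm of the cells being modeled; the gap buffers
against ≤ 1 px segmentation erosion at the nuclear rim. Pixels claimed by
two candidate rings are excluded from both (conservative against
cross-cell contamination); nearest-nucleus assignment is available via
`contested="nearest"` (lower label wins exact distance ties). Rings may be
truncated at the image border or empty; downstream QC flags this.

**QC.** An automated surrogate for manual review, not a reconstruction of
any reviewer's criteria: area bounds, minimum ring pixel count (default
10), solidity floor (default 0.90 — touching nuclei fail this rather than
being watershed-split). Cells with a ring mean at/below the mode get
`nonpositive_cytoplasm` and no ratio; a negative corrected nuclear mean
over a positive ring yields a (negative) ratio flagged `negative_nuclear`.
Flags annotate; nothing is deleted.

**Statistics.** Two groups: two-tailed unpaired Student's t (pooled
variance; Welch behind a flag). Three or more: one-way ANOVA with Tukey HSD
(studentized-range distribution). Normality screening by the
D'Agostino–Pearson omnibus test, returned as "not applicable" below n = 20.
Summaries report mean ± sample SD and median/quartiles
(linear-interpolation convention). Tests can be run per cell (pooled) or
per experiment (means of experiment replicates); the unit used is recorded
in every output row, since pooling cells across experiments treats cells as
independent — a deliberate, visible choice.

## SILAC differential analysis

**Inputs.** Tab-delimited MaxQuant-dialect tables. The generator emits one
unified phosphosite-dialect table per replicate (carrying "Unique
peptides"); the parser equally accepts the real MaxQuant split, joining
peptide counts from a proteinGroups table by protein ID. "+" marks in
"Reverse"/"Potential contaminant" become booleans; unparseable ratios
become missing with a warning, never zero.

**Filtering** (per replicate, first-violated-rule bookkeeping so kept +
dropped = input): reverse-database decoys, potential contaminants, proteins
with < 2 unique peptides, and sites with localization probability < 0.75.
The peptide threshold is standard; the localization cutoff of 0.75 is a
field convention (class I sites) and configurable.

**Merging.** Duplicates sharing (gene name, protein ID, site) collapse to
one record; ratios merge as the median on the log2 scale (geometric median
of ratios), robust to one bad quantification. Distinct site annotations
under one protein are kept separate with a warning.

**Normalization and orientation.** log2(H/L), then orientation: the caller
must state which channel carries the mutant in the forward experiment
(`mutant_channel_forward`, no default — it is experiment metadata); the
reverse replicate's sign is flipped first, then each replicate is centered
by subtracting its median (mean behind a flag). After this, positive always
means higher in mutant.

**Significance.** Combined value = mean of the available oriented
replicates; sites in one replicate only are flagged `single_replicate`;
sites whose replicates disagree in sign with each beyond 2 replicate-SDs
are `discordant` and excluded from calling. Significance = outside
mean ± 2·SD of the usable combined values. Under normality this flags
2(1−Φ(2)) ≈ 4.55 % — often loosely described as "the top 5 %"; the two
phrasings differ slightly and this package implements the ± 2 SD rule.
Thresholds are computed per table pair (phosphosite and protein tables get
their own SD).

**Imputation.** Missing combined values become min(observed) − 0.1 log2
units ("minimum minus a small constant"), flagged `imputed`, for
visualization only: imputed entries never enter SD estimation or
significance.

**Over-representation.** One-sided hypergeometric upper-tail p per gene set
(equivalent to one-sided Fisher's exact), sets intersected with the
user-supplied background first, BH-adjusted across sets, with the sample
odds ratio. This is a generic stand-in for commercial pathway tools: no
curated knowledge base, no activation z-scores.

## Synthetic data: what it emulates, and what it does not

**Scenes.** Non-overlapping axis-aligned ellipses (aspect ratio uniform in
[1.0, 1.6]) on a flat background; nuclear areas drawn from measured
endothelial cell-size distributions (wild-type-like 1661.078 ± 416.71 µm²,
mutant-like 3004.675 ± 254.55 µm²; strictly positive by resampling); a
cytoplasmic annulus (default 8 px) at `background + cyto_level`; nuclear
marker at `background + ratio × cyto_level`, so truth-mask measurement
recovers the true ratio exactly up to 16-bit rounding. Placement is
rejection sampling with a minimum centroid distance of the two semi-major
axes + annulus + 2 px (a "crowded" mode drops the annulus term to exercise
the contested-ring policy, keeping nuclei disjoint) and a retry cap that
raises a density error. Noise models: none, additive Gaussian truncated at
zero, or Poisson on the expected intensity; defaults at background 50,
cytoplasmic excess 100, so "5 % noise" is Gaussian σ = 5. Images are 16-bit
unsigned, clipped with a warning.

Not emulated: PSF blur, chromatic shift, uneven illumination, autofluorescence,
touching/overlapping nuclei, out-of-focus light, marker texture. Passing
the recovery tests therefore shows the measurement chain is correct and
well-calibrated under its own model — not that segmentation would be as
accurate on real micrographs, where the manual-review surrogate (QC flags)
matters far more.

**Tables.** n sites (default 5000) with an exact count
`round(fraction_shifted × n)` truly shifted by ± shift_magnitude log2 units
(default 0.9 = 3 noise-SDs at the default per-replicate log2 noise SD of
0.3); the forward table carries the shift with mutant-heavy orientation and
the reverse table its negation; independent per-replicate noise and
missingness (default 10 %); decoy/contaminant/low-peptide rows in stated
counts. Not emulated: intensity-dependent ratio variance, shared-peptide
ambiguity, protein-level/site-level dependence, batch structure.

## Numerical and design choices

- Otsu: exact rational comparisons for integer images; float images use
  256 equal-width bins with bin-edge thresholds.
- Background mode: integer images use one bin per intensity; real-valued
  images use width-`bin_width` bins anchored at a multiple of the width
  below the minimum; ties break toward the lowest bin.
- Median-filter borders: symmetric reflection.
- Connectivity: 8-connected components.
- Degenerate inputs: single-valued image → "no nuclei" result (error only
  when `otsu_threshold` is called directly); zero-spread significance input
  → no flags plus a warning; all-missing imputation input → error.
- Determinism: every generator/pipeline takes one integer seed;
  per-task seeds are derived via `numpy.random.SeedSequence`. Identical
  config + seed reproduces outputs byte-for-byte.
- Problem sizes in the verification suite: 100 cells per condition
  (5 fields × 20 cells, 1024² px), 5000-site tables, 10 000-value null
  calibration — sizes at which the measured quantities are stable to well
  within their tolerances.

## Known limitations

- No watershed splitting of touching nuclei (flagged by solidity instead),
  no 3-D stacks, no deconvolution, no marker-channel segmentation.
- The QC rules are surrogates for manual review and should be re-tuned per
  dataset; pixel size and magnification defaults are conventions.
- The over-representation stage tests membership only; it has no notion of
  direction or pathway topology.
- Per-cell pooling across experiments understates between-experiment
  variance; use `unit="experiment"` when experiments are the replication
  unit.
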