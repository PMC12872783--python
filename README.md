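# endosig

Quantitative analysis pipelines for studies of endothelial signaling driven
by constitutively active Gαq (GNAQ p.R183Q, the capillary-malformation /
Sturge–Weber mutation), where the two key desk-side readouts are:

1. **Nuclear translocation imaging** — per-cell nuclear-to-cytoplasmic (N/C)
   ratios of a transcription factor (e.g. NFAT1/2) from two-channel
   fluorescence micrographs. Nuclei are segmented from the nuclear-stain
   channel (median filter → Otsu threshold → hole filling → connected
   components with area gates), the cytoplasm is proxied by a narrow
   perinuclear ring built by morphological dilation, and

   N/C = (mean nuclear marker − mode) / (mean ring marker − mode),

   with the field's modal intensity as the background estimate. Automated QC
   flags (area bounds, ring size, solidity) replace manual review; nothing
   is deleted, flagged cells are just excluded from summaries.

2. **SILAC phosphoproteomics post-processing** — MaxQuant-dialect ratio
   tables from a forward/reverse label-swap pair are filtered (decoys,
   contaminants, < 2 unique peptides, localization probability), duplicate
   entries merged (log-scale median), H/L ratios log2-transformed,
   median-centered and oriented so positive always means "higher in
   mutant", replicates combined, sites outside mean ± 2 SD flagged
   significant (≈ the top 5 % under normality), missing values imputed for
   display only, and gene-set over-representation tested with one-sided
   Fisher / hypergeometric p-values plus Benjamini–Hochberg adjustment.

A third component, `endosig.synth`, generates both kinds of input with known
ground truth (image scenes with controllable true N/C ratio; label-swap
table pairs with a stated fraction of truly shifted sites), so every stage
is testable end-to-end without external data. A group-statistics layer
(D'Agostino–Pearson screen, Student's t, one-way ANOVA + Tukey HSD) mirrors
the comparisons such studies report.

## Worked example

```python
import numpy as np
from endosig.synth import SceneSpec, generate_scene
from endosig import imaging
from endosig.stats import t_test_unpaired, significance_tier

# wild-type-like scene: true N/C ratio ~ N(2.0, 0.2), 5% Gaussian noise
dapi, marker, truth = generate_scene(
    SceneSpec(n_cells=20, nc_ratio=(2.0, 0.2),
              noise="gaussian", noise_sigma=5.0, seed=1))

nuclei = imaging.segment_nuclei(dapi, min_area=800, max_area=30000)
rings = imaging.build_rings(nuclei, gap=1, ring_width=4)
mode = imaging.estimate_background_mode(marker)
records = imaging.qc_filter(
    imaging.measure_cells(marker, nuclei, rings, mode),
    imaging.QCRules(min_area_px=800, max_area_px=30000))
ratios = np.array([r.nc_ratio for r in records if r.ok])
print(nuclei.n_labels, mode, np.median(ratios))
```

prints `20 50 1.995...`: all 20 nuclei are found, the background mode is the
rendered background level (50 counts), and the median measured N/C ratio is
1.995 against a true mean of 2.0. Repeating with a "retained" condition
(true ratio 0.5, seed 2) and comparing:

```python
res = t_test_unpaired(ratios, mut_ratios)
print(f"t = {res.t:.2f}, df = {res.df:.0f}, p = {res.p:.2e}",
      significance_tier(res.p))
```

gives `t = 39.46, df = 38, p = 1.89e-32 ****` — the translocated group sits
far above the retained one, the direction such an experiment is designed to
detect.

For the SILAC side, `generate_silac_tables(TableSpec(n_sites=2000, seed=3))`
plus `differential_analysis(..., mutant_channel_forward="heavy")` reports
dropping exactly the 25 decoy, 25 contaminant and 50 low-peptide rows, a
combined-replicate SD of 0.304 log2 units, and 113/2000 sites flagged beyond
± 2 SD (5 % of sites are truly shifted by 3 noise-SDs in this spec).

Each stage is also runnable from the shell via the `endosig` CLI
(`simulate`, `imaging`, `silac`, `stats` subcommands) from a YAML config;
the resolved config, a run log and all CSV outputs land in `--outdir`.

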