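# transcortex

Imaging transcriptomics asks what is anatomically special — in terms of gene
expression and cell-type composition — about brain regions identified by an
fMRI contrast. `transcortex` implements that analysis for atlas-style
microarray data as a tested, reusable Python pipeline:

1. **Probe selection** — keep probes detected above background in ≥ 50 % of
   all samples, then collapse to one probe per gene by maximum Spearman
   correlation with companion RNAseq data on matched samples, dropping genes
   that RNAseq cannot confirm (ρ < 0.2 or absent).
2. **Spatial mapping** — samples carry MNI world coordinates (mm); a
   thresholded statistical map (NIfTI) is interpolated trilinearly at each
   (optionally x-mirrored) coordinate, labelling left-cortical samples
   *affected* (value ≥ 0.5 in any mask) or *control*.
3. **Normalization** — per-gene removal of additive donor (batch) terms by
   OLS with sum-to-zero contrasts, then two passes of scaled robust sigmoid
   normalization, x_y = 1/(1 + exp(−(x_i − ⟨x⟩)/(IQR/1.35))) rescaled to
   [0, 1] — first per gene across samples, then within each sample across
   genes.
4. **Moderated differential expression** — per-gene GLS under a
   block-exchangeable intra-donor correlation (a consensus ρ estimated across
   genes by a trimmed Fisher-z pooled moment estimator), empirical-Bayes
   variance shrinkage s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g) with the scaled-F
   prior fitted by digamma/trigamma moment matching, moderated t on d_g + d₀
   df, and Benjamini–Hochberg FDR control.
5. **Differential stability** — per gene, the mean over donor pairs of the
   Pearson correlation between structure-averaged expression profiles;
   DE vs other genes compared by a two-sided Mann–Whitney U test.
6. **Enrichment** — upper-tail hypergeometric tests of the DE gene set in
   GMT collections with fold enrichment (k/n)/(K/N); BH for term sets,
   Bonferroni for cell-type marker sets (markers gated at ≥ 5 genes per
   type); disease-signature set construction (q ≤ 0.05, |logFC| > 0.1) and
   trimmed-mean cell-type expression summaries (middle 50 % of log2(x+1)).

A synthetic-atlas generator (`transcortex.synthetic_data`) produces
seed-deterministic donor bundles, masks, marker sets and ground truth with
the statistical structure the pipeline assumes, so the full analysis runs
and is validated without any external download.

## Worked example

```bash
transcortex simulate --outdir demo/atlas --seed 11 \
    --n-donors 4 --samples-per-donor 80 --n-genes 500 \
    --n-planted-de 25 --mask-fraction 0.08

transcortex run --outdir demo/out \
    --bundle demo/atlas/donor_D1 --bundle demo/atlas/donor_D2 \
    --bundle demo/atlas/donor_D3 --bundle demo/atlas/donor_D4 \
    --mask demo/atlas/mask_left.nii --rnaseq demo/atlas/rnaseq.csv \
    --cortical-labels demo/atlas/cortical_labels.txt \
    --markers demo/atlas/markers.gmt
```

prints

```
transcortex 0.1.0 run (config 03cfce34e3cd)
  donors: 4
  samples_loaded: 352
  probes_loaded: 1095
  genes_kept: 448
  probes_dropped: 632
  samples_affected: 26
  samples_control: 294
  samples_excluded: 32
  consensus_rho: -0.0123
  ebayes_d0: None
  ebayes_s0_sq: 0.070462
  de_higher: 18
  de_lower: 7
  ds_median_de: -0.0274
  ds_median_other: -0.0197
  ds_mannwhitney_p: 0.9942921028971835
  enriched_markers: 3
  enriched_set_names: ['celltype_01', 'celltype_02', 'celltype_03']
```

Reading the report: of 500 simulated genes, 448 survive probe selection
(the rest fail detection, lack RNAseq support, or track it too poorly);
26 of 320 cortical samples fall inside the mask; the generator planted 25
differentially expressed genes and the moderated test calls 18 higher plus
7 lower at q < 0.05; the three marker sets built to overlap the planted
genes — and only those — reach Bonferroni significance. `ebayes_d0: None`
means the fitted prior df is infinite (after sigmoid normalization the
per-gene variances show no excess scatter, so complete pooling is the
correct limit), and the consensus intra-donor correlation is ≈ 0 because
donor demeaning precedes it. Per-stage TSV tables (probe selection report,
sample assignment, DE table, DS table, enrichment records) and
`report.json` land in `demo/out/`.

Per-stage subcommands (`select-probes`, `map-samples`, `normalize`, `de`,
`stability`, `enrich`) expose the same machinery on individual files; the
library API mirrors them one module per stage.

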