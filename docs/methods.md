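# Methods

## The analysis model

The pipeline characterizes an fMRI-defined cortical region by contrasting
microarray gene expression of atlas samples inside the region ("affected")
against the remaining left-cortical samples ("control"), while accounting
for the two donor-driven phenomena that dominate multi-donor atlas data:

* **additive donor offsets** — gene-specific shifts of a whole donor's
  measurements (tissue handling, array batch, genuine inter-individual
  level differences). These are removable by a linear model and are handled
  in the normalization stage;
* **residual intra-donor correlation** — after offsets are removed, samples
  from one brain remain more alike than samples from different brains. This
  cannot be subtracted; it is modelled in the DE stage as an exchangeable
  within-donor correlation shared across genes.

### Probe selection

Detection (present/absent) calls are pooled across all loaded samples of
all donors; a probe survives at mean detection ≥ `min_fraction` (default
0.5, inclusive — "at least half"). Per gene, each surviving probe is ranked
by Spearman correlation (average ranks, Pearson on ranks) against the
gene's RNAseq profile on the sample intersection; the maximum wins, with
ties broken to the lexicographically smallest probe id for determinism. A
gene is dropped entirely when it is absent from the RNAseq rows, all-zero
there (operationalizing "not detected by RNAseq"; no threshold is defined
beyond zero), or its best correlation is < `rho_min` (default 0.2, strict).
Fewer than 3 matched samples makes the correlation meaningless and is fatal.

### Spatial mapping

Sample coordinates are world-space MNI millimetres; masks are NIfTI volumes
whose affine maps voxel indices to the same space. The mask value at a
sample is the trilinear blend of the 8 surrounding voxels
(`scipy.ndimage.map_coordinates`, order 1); coordinates outside the index
bounding box yield 0. A left-cortical sample (structure label in the
configured cortical list, hemisphere left) is affected when the maximum
over masks is ≥ `threshold`, default 0.5 — the rule that reproduces
nearest-neighbour membership on binary masks while staying continuous; the
boundary value counts as inside. Mirroring a right-hemisphere mask is
implemented exactly, by negating the sample x before lookup, never by
resampling the volume. Multiple masks combine as a union (max).

### Normalization

Batch removal fits, per gene, expression ~ intercept + sum-to-zero donor
contrasts by OLS and subtracts the donor terms (the intercept is kept), the
same operation as limma's `removeBatchEffect` with one batch factor. No
covariates are fitted — none are defined for this design. Scaled robust
sigmoid normalization then maps each vector through a sigmoid centered at
the median with scale IQR/1.35 and min–max rescales the result to [0, 1].
Quartiles are linear-interpolation (type-7); 1.35 is kept verbatim as the
normal-consistency constant. Degenerate scales fall back in order IQR →
1.349·MAD → SD; an all-constant vector (or a rescale with zero range) maps
to 0.5 everywhere, keeping the transform total and rank-preserving wherever
ranks are defined. The gene-wise pass (across samples) always precedes the
within-sample pass (across genes); the stage tag enforces the order. The
analysis subset (affected + control samples) is what gets normalized.

### Moderated differential expression

Design: intercept + affected indicator. The consensus intra-donor
correlation is estimated from OLS residuals: per gene, a one-way ANOVA on
the donor grouping gives the between-donor variance component
(MSB − MSW)/n₀ with the standard unbalanced-design constant n₀; its share
of total variance is that gene's correlation estimate. Estimates are pooled
by a 15 %-trimmed mean on the Fisher-z (atanh) scale and transformed back.
The ANOVA form is used instead of raw pairwise residual products because
the intercept has already absorbed the grand mean; the naive pairwise
estimator is biased low by roughly ρ/k for k donors, which at k = 6 is
large enough to matter. All-singleton blocks return 0 with a warning.

Each gene is then fitted by GLS under the block-exchangeable correlation,
implemented by an exact whitening transform (within a block of size m the
mean direction is scaled by (1+(m−1)ρ)^−½ and its orthocomplement by
(1−ρ)^−½), so ρ = 0 reduces to OLS identically. Residual variances s²_g on
d df are shrunk toward a scaled-F prior (d₀, s₀²) fitted by matching the
mean and variance of log s² through digamma/trigamma equations, with the
trigamma inverse solved by Newton iteration; the posterior variance is
s̃²_g = (d₀s₀² + d s²_g)/(d₀ + d) and the moderated t uses d + d₀ df
(normal when d₀ = ∞). This is the same moment procedure as limma's
`fitFDist`/`squeezeVar`, and the test suite cross-checks it against
Bioconductor limma via Rscript. One deliberate divergence: when the
observed log-variances show no excess scatter (the d₀ = ∞ branch), the
pooled location is the plain geometric mean exp(mean log s²), so identical
input variances are returned unchanged rather than inflated by the
digamma sampling-bias correction — the coherent choice when there is no
scatter to debias. Zero-variance genes are assigned the prior variance and
flagged. BH adjustment is the classical step-up with a cumulative minimum;
calls use strict q < α and direction = sign of the coefficient.

### Differential stability

DS of a gene is the mean over donor pairs of the Pearson correlation
between the two donors' per-structure mean expression vectors, restricted
to structures both donors sampled (pairs sharing < 3 structures contribute
nothing; genes with no usable pair are excluded and logged). DS is
invariant to per-donor affine rescaling. The DE-vs-other comparison uses a
two-sided Mann–Whitney U (U of the first group, sum-rank convention): exact
enumeration when both groups are ≤ 20 without ties, otherwise the
tie-corrected normal approximation without continuity correction (so
identical groups give p = 1 exactly). An externally computed gene→DS table
can be supplied instead of recomputing, reproducing the cross-referencing
mode of published DS values.

### Enrichment

Hypergeometric upper tail P(X ≥ k) with the analysis gene universe as
background; gene sets are intersected with the background first, and sets
that vanish are skipped. Fold enrichment is (k/n)/(K/N); when K = 0 or
n = 0 the ratio is undefined and the record is skipped. Term collections
use BH with the rule fold > 1.0 and q < 0.05; cell-type marker collections
use Bonferroni p < 0.05 after removing marker sets with fewer than 5 genes.
An EASE-style conservative variant (testing k − 1) is available behind a
flag. Whether the original web-service tests were one-tailed is not
documented; the one-tailed upper tail is assumed and recorded in output
metadata. Disease signature sets take genes at q ≤ 0.05 (inclusive) with
logFC strictly above 0.1 (higher) or below −0.1 (lower); empty sets are
retained as warnings since stricter gates are known to empty them.
Trimmed-mean cell-type expression is the mean of the middle 50 % of
log2(x+1) values per (gene, cell type) — floor(n/4) dropped from each end —
with types under 4 cells excluded; log2(x+1) is a declared choice, since
the upstream transform of such reference tables is not printed.

## The synthetic-data generator

`generate_atlas` emulates exactly the structure the analysis assumes:
gene baselines ~ U(3, 10) (log-intensity scale); additive donor offsets
~ N(0, donor_batch_sd²) per (donor, gene); residuals with exchangeable
intra-donor correlation ρ (a shared per-(donor, gene) component plus
independent noise, total sd `residual_sd`); a planted mean shift of
`de_effect_size`·`residual_sd` inside the mask for `n_planted_de` genes
(70 % higher, 30 % lower by default); probes nested in genes with one
designated high-fidelity probe (noise sd 0.1) competing against noisier,
biased siblings, plus per-probe Bernoulli detection rates; left-cortical
sample coordinates placed so exactly round(mask_fraction × cortical
samples) fall inside an axis-aligned box mask in a 40×48×40 grid with 2 mm
affine (plus a mirrored right-hemisphere twin); companion RNAseq for the
first `rnaseq_donors` donors sharing the donor-level biological signal with
independent noise sd `rnaseq_noise_sd`; and marker sets with controlled
overlap with the planted genes. A small set of deliberately low-fidelity
genes (probe noise sd 8) exercises the RNAseq-correlation exclusion path,
and a fraction of genes is withheld from the RNAseq rows to exercise the
absent-gene path.

Defaults are the reference conditions: 6 donors × 200 cortical samples,
2000 genes, 2 RNAseq donors, mask fraction 0.05 (→ 60 affected vs 1140
control), donor_batch_sd 0.8, residual_sd 0.4, ρ = 0.3, effect 1.0 sd —
the shape of a six-donor atlas analysis at a scale that runs the whole
pipeline in well under two minutes. Structural layout (which probe and
gene ids exist, which genes lack RNAseq) is a function of the configuration
alone, so changing the seed changes values but never shapes or
identifiers; all value randomness flows from the single seeded generator.

What the generator does **not** emulate: realistic cortical geometry or
structure ontologies (parcels are assigned at random, so differential
stability on synthetic data hovers near 0 and the DS group comparison is
null — the DS tests therefore validate the estimator against constructed
fixtures, not a planted regional-profile effect), RNA-degradation
covariates, intensity-dependent detection, or probe cross-hybridization.
Passing tests demonstrate the statistics recover what the generative model
plants; they do not certify performance on real atlas data, whose
reannotation, parcellation and covariate structure are inputs here.

## Numerical choices and scales

* Reported checks run at the sizes the estimators need: 2000 genes for
  correlation recovery, 5000 for the variance-prior fit and the type-I
  rate, 20-gene fixtures for dense-oracle equivalence at 1e-8.
* Trigamma-inverse Newton iteration converges to 1e-8 relative; the prior
  fit falls back to d₀ = ∞ (complete pooling) when the moment variance is
  non-positive, the documented limit of the reference method.
* Correlation estimates are clipped to |ρ| ≤ 0.999 before atanh pooling.
* The whitening transform refuses non-positive-definite block structures
  (ρ ≤ −1/(m−1)).
* Tie-breaks (probe collapse) and label orders are deterministic; pipeline
  reports embed the config hash and seed.

## Known limitations

* The consensus-correlation estimator is the specified moment/trimmed-z
  procedure, not REML; on 6-donor data it sits ~0.02–0.03 below the true ρ
  (within the ±0.05 recovery target). Its purpose is to protect the DE
  standard errors, for which the pipeline's type-I calibration is the
  operative check.
* Batch removal by donor demeaning also absorbs the donor-shared residual
  component, so the consensus ρ estimated *after* normalization is ≈ 0 by
  construction; the estimator proves itself on un-demeaned data, and the
  dual safeguard (demeaning + GLS) is retained because real designs may be
  unbalanced enough to leave residual correlation.
* Only intercept + indicator designs are fitted (a covariate hook exists at
  the design-matrix level); no quantile normalization, precision weights,
  or surrogate-variable adjustment.
* Gene identifiers are case-sensitive symbols with no alias resolution.
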