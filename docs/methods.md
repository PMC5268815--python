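# Methods

`elementdm` implements a two-level differential-methylation (DM) analysis
for fractional-methylation (beta) matrices of the kind produced by 450K
methylation arrays, together with the downstream integration steps a
case/control epigenomics study needs: chromatin-state enrichment of DM,
methylation–expression correlation, clone-based bisulfite / oxidative-
bisulfite 5hmC decomposition, and delta-Ct qPCR summaries.  This note
describes the models, the thresholds and their defaults, the numerical
choices, and what the synthetic-data tests do and do not demonstrate.

## Probe quality control

Beta values whose detection p-value exceeds 0.05 are set missing (strict
`>`).  Probes are then removed, in order: (1) probes on chrX/chrY; (2)
probes missing in more than 20% of samples (computed after detection
masking, since masking is the first cleaning step); (3) probes querying a
common SNP with minor allele frequency above 0.01.  A probe is attributed
to the first rule that removes it, so the per-rule counts in the
`FilterReport` always sum to the number removed; this attribution order is
a convention chosen for deterministic reporting.  Probes with no SNP
annotation are treated as MAF 0.

## Element-level segmentation

Chromatin-state intervals (promoter active/weak/poised, enhancer
active/poised, insulator) from all available cell lines are collapsed into
a non-cell-specific union per element class: a position belongs to a class
if any queried cell line annotates it with any sub-state of that class.
All intervals are handled as 0-based half-open internally; manifest
positions are declared 1-based and converted exactly once at read time.

Within one merged element, retained CpGs are clustered wherever
consecutive CpGs are less than 500 bp apart (strict `<`, measured between
successive coordinates).  Then:

* a multi-CpG cluster spanning ≤ 500 bp becomes one *grouped* segment;
* a lone CpG gets a 500 bp window centred on it (`[pos−250, pos+250)`;
  centring is symmetric and convention-free);
* a wider cluster is tiled with 500 bp windows over the cluster extended
  by 100 bp flanks on both sides, stepping 400 bp (100 bp overlap between
  tiles), plus a final tile right-anchored at the extended end so the
  cluster tail is always covered.  Duplicate tiles are deduplicated and
  tiles containing no retained CpG are dropped, so the segment universe
  counts probe-bearing segments only.

A CpG overlapping elements of two classes is segmented independently per
class, and may belong to two overlapping tiles.  Segment methylation is
the arithmetic mean of the non-missing member betas per sample, with the
contributing CpG count recorded; a segment with no informative member in a
sample is missing for that sample.

## DM testing and classification

Each unit (CpG or segment) is tested with a two-sided two-sample
Student's t-test with pooled variance (Welch available via
`equal_var=False`); units with fewer than 3 non-missing values in either
group are reported untested.  Units where both groups are numerically
constant get t = 0, p = 1 when the means agree and are flagged degenerate
otherwise (tolerance 1e-12 absorbs float error).

P-values are adjusted with the Benjamini–Hochberg step-up procedure
separately per level, with m equal to the number of evaluable units at
that level.  Classifications:

* **stringent** — CpG: q < 0.05 and |DFM| > 0.15; segment: q < 0.05 and
  |DFM| > 0.10, or |DFM| > 0.15 for single-CpG segments.  DFM is the
  case-minus-control difference in mean fractional methylation.  All
  inequalities are strict.
* **lenient (per gene)** — at least 2 units annotated to the gene with
  nominal p < 0.05 and |DFM| above the level-appropriate threshold.  The
  effect-size clause is read as a difference (|DFM|), consistent with the
  stringent criteria.  Direction agreement between qualifying units is not
  required by default; `require_same_sign=True` provides the stricter
  reading.  Segments inherit the union of their member CpGs' genes.

Heat-map standardisation z-scores each unit across samples using the
population SD (divide by n); constant units become zero rows and are
flagged.

## Chromatin-state enrichment

Enrichment of DM units in a state is estimated by a univariate logistic
regression of the DM indicator on the state-membership indicator; the
odds ratio is exp(slope) and the p-value is the slope's Wald test.  For
any 2×2 table with all cells positive this OR equals the cross-product
ratio exactly (the model is saturated); Fisher's exact test is available
as a cross-check.  Tables with a zero margin or a zero cell (infinite
MLE) are flagged degenerate with OR missing rather than reporting an
arbitrary finite value.  The enrichment universe is the retained, tested
probe set, not genome-wide positions.  Methylation-level summaries
classify mean betas as low (< 0.3), intermediate, or high (> 0.7); the
boundaries are configuration-exposed conventions.

## Methylation–expression integration

Genes with mean FPKM < 1 in both groups are excluded (≥ 1 in at least one
group retains).  A unit maps to a gene when it lies within the gene span
or within 1,500 bp upstream of the TSS, strand-aware; units may map to
several genes.  For each mapped (gene, unit) pair the raw FPKM values are
correlated with fractional methylation across all samples pooled,
independent of case/control status.  "rho" is the Pearson coefficient by
default — the significance criterion rho > 0.7 corresponds to R² > 0.5
under Pearson — with Spearman available.  A pair is significant when
p < 0.005 and |rho| > 0.7, enforced conjunctively.  Pairs with fewer than
4 informative samples or constant values are skipped and counted.
Gene-level DM lists are overlapped with correlated genes over the
universe of genes both expressed (post-filter) and represented on the
array, and the enrichment over random expectation reuses the 2×2
machinery.  A stringency sweep recomputes the overlap at increasing DM
thresholds.

## 5hmC inference from paired bisulfite chemistries

Standard bisulfite conversion scores 5mC + 5hmC; oxidative bisulfite
scores 5mC only.  Fractions are computed per chemistry independently
(clone numbers need not match or pair).  Per CpG: 5mC = oxBS fraction;
5hmC = max(BS − oxBS, 0).  Negative raw differences arise only from clone
sampling noise, so they are clamped at zero and flagged, preserving the
information.  A Wald two-proportion interval on the difference conveys
the clone-sampling uncertainty.  Group comparisons pool clones within
group and apply a two-sided Fisher exact test per CpG.  With 10 clones per
chemistry the estimator's RMSE at (5mC 0.4, 5hmC 0.3) is ≈ 0.20 — exact
binomial enumeration over the 11×11 outcome grid gives the reference
value the tests check against — so single-CpG calls at this depth are
semi-quantitative by design.

## qPCR

Replicate Cts above the 40-cycle cap are dropped as undetermined; mean
target Ct above 32 sets a low-abundance warning (both configurable).
ΔCt = mean(Ct_target) − mean(Ct_housekeeping); relative expression is
2^−ΔCt.  Group folds use 2^(mean ΔCt_b − mean ΔCt_a) (the ΔΔCt
convention) with a t-test on the ΔCt values; per-sample fold averaging
is a distinct aggregation and is not applied implicitly.  Dose–response
tables normalise every (gene, group, dose) stratum mean to the untreated
control-group stratum, which is therefore 1 by construction.

## Synthetic data: what it emulates, and what passing tests show

The generator lays genes on one synthetic chromosome with promoters at
the TSS, enhancers in gene bodies (a configurable fraction wide enough to
force tiling), intergenic insulators, intergenic background CpGs,
sex-chromosome probes and SNP-flagged probes, plus two cell-line tracks
with jittered, partially overlapping state calls.  Defaults mirror a
5-case vs 5-control array study.

Numerical choices that matter:

* **Baselines** come from a low (Beta(2,18), mean ≈ 0.1) / high
  (Beta(18,2), mean ≈ 0.9) mixture, drawn once per element: contiguous
  CpGs of one element share their regime, which is the biological premise
  of element-level analysis and lets an element-wide spike of Δbeta = 0.3
  be realised without clipping at the [0,1] boundary.
* **Within-group noise** is additive normal on the beta scale
  (SD 0.05, truncated to [0.001, 0.999]).  A logit-scale noise model was
  considered and rejected: its skew at low baselines makes the pooled
  t-test measurably conservative (type-I ≈ 0.040 at n = 5+5 versus 0.052
  for the truncated-normal model), which would misrepresent the test's
  calibration, and it does not hold the stated beta-scale SD.
* **DM spikes** act at element granularity — every member CpG shifts by
  Δbeta = 0.3 toward the valid range — matching the premise that the
  methylation of contiguous CpGs moves together.  SNP flags are placed
  only on non-element probes so a planted element is never silently
  truncated by QC.
* **Expression coupling**: for half of the DM genes whose spiked element
  is position-linked to the gene (intergenic insulators cannot produce an
  observable link under the span + 1.5 kb mapping rule), log2(FPKM) is
  linear in the realised beta of one member CpG, negative-signed at
  promoters and positive elsewhere.  The log2 amplitude is 1.0 per
  methylation SD with target log-scale correlation 0.95, which realises
  raw-FPKM |rho| ≈ 0.92–0.93 at n = 10 — the magnitude reported for
  strongly coupled DM/DE genes in stromal-cell studies — because the
  exponential transform attenuates Pearson correlation on the raw scale.
* **Clones and qPCR** follow their declared generative models directly:
  Bernoulli(5mC+5hmC) / Bernoulli(5mC) clone calls, and Cts from a true
  ΔCt with −1 cycle per µM dose effect (2-fold per µM) and 0.15-cycle
  replicate noise.

Problem sizes were chosen so every property is measurable in seconds:
60 genes (≈ 650 probes, ≈ 240 segments) per study for recovery runs,
300 genes (≈ 3,100 retained probes) for null calibration, 20 seeds for
the recovery aggregate, and 10,000 simulated CpGs for estimator accuracy.

What passing does **not** show: the generator has no probe-chemistry
(type I/II) effects, no batch structure, no cell-composition
heterogeneity, no spatial correlation of noise beyond the shared element
mode, and uses idealised genome coordinates.  Recovery results therefore
demonstrate correctness of the machinery under its stated model, not
performance on real array data, where effect sizes are smaller and noise
is structured.

## Known limitations

* The t-test assumes approximately normal within-group variation of beta
  values; heavily bimodal within-group distributions would call for a
  rank or beta-regression test that the package does not provide.
* Enrichment treats probes as exchangeable units; spatial correlation
  between nearby probes inflates the nominal precision of the Wald test.
* The 5hmC subtraction estimator is unbiased only up to clamping; at
  true 5hmC near 0 the clamped estimator is upward-biased by
  construction.
* Correlation p-values at n = 10 rely on the bivariate-normal null; raw
  FPKM is right-skewed, so the uncoupled false-flag rate runs slightly
  above nominal (observed ≈ 0.005–0.006).
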