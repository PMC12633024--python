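# Methods

This note documents the models, conventions and numerical choices behind
`hrdscape`: an exome-scale pipeline that classifies tumors as homologous-
recombination deficient (HRD) or proficient (HRP), scores their inflammation
state from bulk expression, profiles allele-specific copy number in 100-kb
bins, and tests the associations between the two layers.  Everything runs on
synthetic cohorts with ground truth; the sections below state what each
stage computes and what the synthetic data do and do not establish.

## Coordinates and formats

All in-memory intervals are 0-based half-open, so `length == end - start`;
the TSV interchange files (MAF dialect, segment tables, gene tables) are
1-based inclusive and converted only in `hrdscape.io`.  Mutation positions
are kept 1-based (MAF convention) because no interval arithmetic touches
them.  Chromosome names are normalized by stripping a leading `chr` and
mapping `23`/`24` to `X`/`Y`.  Unknown consequence tokens are preserved as
`other` so that filters, not the parser, decide relevance.

## SBS96 catalogs and the spectrum panel

Single-base substitutions are tallied on the pyrimidine strand into the
standard 96 trinucleotide channels (substitution type major, 5' then 3'
flank alphabetical).  SNVs whose context cannot be resolved from the inline
context column or a genome accessor are excluded and counted.

The packaged spectrum panel is synthetic: six COSMIC-*shaped* probability
vectors (flat SBS5-like background, SBS1-like CpG clock, near-flat SBS3-like
HRD signature, SBS6-like mismatch-repair, SBS10-like POLE, SBS45-like
8-oxo-G artifact), constructed from parametric channel weights and versioned
with the package.  They are deterministic, mutually linearly independent
(pairwise cosine < 0.97), and substitutable by real COSMIC spectra anywhere
a panel is accepted.  Using a packaged synthetic panel keeps the whole
pipeline runnable and testable with no downloads.

## Signature-3 features

Three features summarize HRD-signature evidence per sample:

* **Likelihood** — the two-class posterior
  `prior·L(c|pos) / [prior·L(c|pos) + (1−prior)·L(c|neg)]` with multinomial
  log-likelihoods of the catalog under packaged HRD-positive and
  HRD-negative mixture spectra.  Spectra get a `1e-9` pseudocount before the
  log so a zero-probability channel cannot annihilate the product; a
  zero-count catalog returns the prior (no evidence).  The prior defaults to
  0.5.
* **Cosine** similarity of the raw catalog with the SBS3-like spectrum
  (NaN for an empty catalog, which has no direction).
* **NNLS exposure** — non-negative least squares decomposition of the
  catalog over the panel (`scipy.optimize.nnls`), reported in mutation units
  and as a fraction of total exposure.

## Microhomology deletions

Deletions of ≥ 5 bp are split by flanking microhomology: the MH length is
the maximum of the longest prefix of the deleted sequence matching the start
of the 3' flank and the longest suffix matching the end of the 5' flank,
capped below the deletion length (a full-length match is a tandem-repeat
unit, not microhomology).  MH ≥ 2 bp routes a deletion to the MMEJ-linked
(ID6-like) count, otherwise to the NHEJ-linked (ID8-like) count; shorter
deletions count toward neither.  Flanks come from inline context columns or
a genome accessor; deletions without resolvable flanks are excluded with a
logged count.

## TMB, pathogenicity, triage, artifact filter

* **TMB** = nonsynonymous SNVs + indels (truncating ∪ nonsynonymous
  consequence sets) per megabase.  The exome footprint defaults to 38 Mb and
  is configurable.
* **Pathogenic somatic variant**: truncating consequence; or nonsynonymous
  with SIFT `deleterious` *and* PolyPhen `probably_damaging`; or ClinVar
  `pathogenic`/`likely_pathogenic` — with a ClinVar `Benign` label vetoing
  every route.
* **Hypermutation triage** assigns MMRD when the MSIsensor-style score is
  ≥ 3.5 or the MMR-like exposure fraction ≥ 0.3 at TMB ≥ 10/Mb; otherwise
  POLE when the POLE-like fraction ≥ 0.3 at TMB ≥ 100/Mb; otherwise MMRP.
  A missing MSI score degrades to the signature-only branch with a logged
  note.  MMRD/POLE samples are never HRD-classified; their class is the
  final label.
* **Artifact filter**: samples whose SBS45-like exposure fraction is ≥ 0.2
  are excluded from all downstream stages; the exclusion count and rate are
  reported.  The threshold encodes "presence" of the artifact signature and
  is configurable.

## Copy-number analyses

**Baselines.**  Per chromosome, segment-length-weighted mean major/minor
copy number over segments > 100 kb; the sample baseline aggregates
chromosomes weighted by qualifying coverage (equivalently, a genome-wide
weighted mean).  Samples with no qualifying segment are dropped with a
logged reason.

**Scar scores.**  Following the conventions of the original scar
publications: HRD-LOH counts contiguous LOH runs (minor < 1) longer than
15 Mb that cover < 99% of their chromosome; TAI counts allelic-imbalance
segments (major ≠ minor) that are the first or last segment of a chromosome
and do not span the centromere; LST counts, per chromosome arm, junctions
between ≥ 10 Mb states after discarding pieces < 3 Mb and fusing equal
neighbors, with junction gaps ≤ 3 Mb.  GIS is their sum.  Abutting segments
with equal allele-specific state are merged first, which makes all three
scores invariant under value-preserving segment splits (property-tested and
checked against a brute-force definitional oracle on 200 random genomes).

**Bin profiles.**  100-kb bins carry overlap-length-weighted minor/major
values; LOH is weighted minor < 1, amplification deviation is weighted major
minus the sample baseline major (keeping amplification largely independent
of LOH load).  Bins without segment coverage are missing (NaN), never zero.
The Y chromosome is always dropped; X is profiled only for female samples.

**Gene calls.**  A gene takes the segment containing its midpoint
(midpoint assignment is documented and configurable): relative amplification
= total CN ≥ baseline total + 2 ("gains of 2 or 3" read as inclusive of
larger gains); focal amplification additionally requires
log10(segment length) < 6.5; LOH = minor < 1; deep deletion = total
CN < 0.5 (the deep-deletion cutoff is a package choice, configurable).

**Region statistics.**  Per region and sample: LOH fraction over
non-missing bins and mean amplification deviation; group summaries carry
95% one-sample-t confidence intervals; between-group comparisons use
Welch t-tests on both variables.  Differential regions are maximal runs of
≥ `min_span_bins` (default 10, i.e. 1 Mb) bins significant after
Benjamini–Hochberg at α = 0.05, bridged across gaps of ≤ 2 quiet bins, with
the direction (which group is higher) attached.  BH per comparison is a
package choice; the correction is not otherwise pinned down.

**Co-occurrence** of two boolean statuses uses the sample odds ratio
ad/bc (Haldane 0.5 correction when a cell is empty, flagged) with a
two-sided Fisher exact p (verified against exhaustive hypergeometric
enumeration for n ≤ 40).

## The HRD classifier

Features per sample: signature-3 likelihood, cosine, exposure and exposure
fraction; GIS; MH and non-MH deletion counts.

Training is weakly supervised, in two steps per scope:

1. **Seeds** — samples with biallelic BRCA1/2 loss.  Biallelic loss
   requires a deep deletion alone, two hits among {pathogenic somatic,
   pathogenic germline, promoter silencing, deep deletion}, or one such hit
   plus locus LOH.  LOH alone is *intact* (the retained allele is
   unaffected).  Each seed recruits its 3 most similar BRCA-wildtype
   samples by cosine similarity in z-scored feature space (duplicates kept
   once); everything else starts negative.  Cosine on z-scores is a package
   choice where only "similarity in the feature space" is pinned down.
2. **Two-step fit** — a gradient-boosted tree classifier
   (`sklearn.GradientBoostingClassifier`) with hyperparameters chosen by
   stratified 5-fold cross-validated AUC over the grid trees ∈ {100, 300},
   depth ∈ {2, 3}, learning rate ∈ {0.05, 0.1}.  Out-of-fold scores from
   step 1 revise the labels (negatives ≥ 0.5 become positive, positives
   < 0.5 become negative) and step 2 re-runs the full optimization on the
   revised labels.

Scopes: one pan-cancer model on all eligible samples; a type-specific model
for each tumor type with > 10 seeds and ≥ 30 samples; one pooled model for
the remaining types.  Final labels combine pan and type-level scores at
0.5/0.5 thresholds: high/high = HRD, low/low = HRP, discordant = HRD-low.
Biallelic BRCA1/2 samples labeled HRD-low/HRP are overridden to HRD with a
flag, and the summary reports the overridden share of all HRD labels.

**Out-of-fold scoring.**  For the training cohort, the stored per-sample
scores are out-of-fold predictions at the winning hyperparameters, not
in-sample predictions of the final fit.  This matters for honest cohort
evaluation: the seed-neighbor protocol couples folds for the seed samples
themselves (a held-out seed's recruited neighbors sit in the training folds
labeled positive), so in-sample or even out-of-fold scores of *seeds* are
optimistically tied to the labels.  Consequently the zero-effect null
calibration is evaluated on BRCA-wildtype samples — the samples whose
status the classifier actually has to infer; seeds enter with their status
observed.  On that population the null AUC is centred on 0.5, and the
label fraction under the null stays at seed prevalence.  New samples
(outside the training cohort) are scored by the fitted models directly.

## Inflammation score

ssGSEA follows the single-sample ranked-walk formulation: genes are ranked
by expression descending; the score integrates the difference between the
|rank statistic|^τ-weighted step CDF of in-set genes and the uniform step
CDF of out-of-set genes, with τ = 0.25 and cohort range normalization as
the community defaults (both configurable; `normalize="none"` gives raw
integrals).  Ties break by gene order under a stable sort, so the statistic
is exactly rank-based; a strictly monotone transform of a sample's
expression leaves its score unchanged (tested), and the implementation is
checked against an independently coded literal walk on random matrices to
1e-6.

The Inflammation Score (IS) is the plain mean of the four signature scores
(a z-then-average mode is available as an option).  Hot / intermediate /
cold status uses within-tumor-type IS tertiles computed on eligible samples
(non-viral, non-MMRD, non-POLE) via linearly interpolated empirical
quantiles, then applied to *all* samples of the type; boundary samples take
the lower status (cold at T1, intermediate at T2); types with < 3 eligible
samples or degenerate thresholds are flagged.  `z_is` standardizes the IS
within tumor type using the eligible samples' moments.

Comparisons use Welch t-tests with t > 0 ⇔ HRD higher.  The regressions are
ordinary least squares with intercept: IS ~ HRD + TMB (per group or pooled)
and, within HRD samples, IS ~ per-region LOH fraction + oncogene-
amplification indicator (default oncogene panel: BCL11A, BCL6, CCND1, CDK6,
EGFR, FGFR1, KRAS, TERT).  Rank-deficient designs raise an error naming the
collinear columns; constant covariates are dropped with a log message.

## Association and TME analyses

A gene is "dysfunctional" when it has a pathogenic somatic or germline
variant, a deep deletion, or promoter silencing (OR-combination; a package
choice).  DDR enrichment tests dysfunction × {HRD, HRP} per gene by Fisher,
BH across genes, optionally restricted to BRCA-wildtype backgrounds.
Pair epistasis tests "both genes dysfunctional" against HRD the same way,
with a convenience sweep over (gene, TP53) pairs.  ORA is the upper
hypergeometric tail over user-supplied gene sets with BH across sets; list
genes outside the universe are an error.

Cell fractions are z-scored within tumor type; ΔZ is the difference of
group means with a Welch t per (type, cell type).  Cell types are clustered
by agglomerative clustering (Euclidean, average linkage — configurable;
the number of clusters defaults to 5) on their column vectors across the
stacked comparisons, with cluster ids relabeled in order of first
appearance so the partition is column-order invariant.  Pairwise Pearson
correlations come with two-sided p-values and a p < 0.05 mask; constant
columns are masked.

## The synthetic cohort generator

The generator defines the study conditions; its defaults are the packaged
cohort every recovery experiment uses (600 samples, seed 1): three tumor
types of 200 — two dHpC-group (HRD prevalence 0.35 and 0.25, one all-female)
and one dCpH-group (prevalence 0.25, 20% viral-positive).  Per sample:

* **Condition** — MMRD (4%), POLE (2%), else HRD at the type prevalence,
  else HRP; 1% of samples are artifact-dominated (SBS45-like weight 0.6).
* **SNVs** — multinomial draws from condition-specific mixtures over the
  packaged panel (HRD: SBS3-like weight 0.57 vs 0.05 in HRP) at log-normal
  burdens (medians 150/120 SNVs for HRD/HRP, 900 for MMRD, 8000 for POLE —
  exome-scale counts that put hypermutators beyond the triage TMB gates).
  Consequences, positions and gene attributions are random; targeted
  pathogenic hits draw their channel from the sample's own mixture so they
  do not distort catalog shape.
* **Indels** — Poisson counts of ≥ 5 bp deletions with constructed flanks:
  MH deletions carry an embedded 2–6 bp flank match, non-MH deletions have
  both flank matches broken; rates 12/6 (MH/non-MH) in HRD vs 1/2 in HRP,
  plus uncounted short deletions.
* **Segments** — per chromosome, Poisson breakpoints (mean 4 HRD / 1.2 HRP)
  with per-segment LOH probability 0.35/0.06 and amplification 0.12/0.04;
  whole-chromosome LOH as a distinct event class (5%/1%); biallelic BRCA
  samples get targeted LOH (or deep-deletion) windows at the BRCA locus;
  dCpH-HRD samples get focal oncogene amplifications (p = 0.45 vs 0.08);
  two region effects plant group-conditional LOH enrichment (chr4:60–65 Mb,
  0.8 in dCpH-HRD vs 0.2; chr3:80–86 Mb, 0.6 in dHpC-HRD vs 0.15).  Males
  are hemizygous X.
* **Inflammation** — a latent level: N(0,1) + HRD effect (+1.2 in dHpC,
  −1.2 in dCpH) − 0.8 per planted-region LOH − 0.5 for oncogene
  amplification.  Expression = per-gene baseline N(7,1) + 2.0 × latent on
  the 100 members of the four packaged immune sets + N(0,1) noise
  (amplitude ≫ noise, the regime where IS recovery is claimed).
* **Cell fractions** — Dirichlet draws with concentration tilted by the
  latent level: +0.8 on the tumor-reactive types (exhausted CD8, Treg,
  B cell), +0.3 on the myeloid group, −0.3 on CAFs.

The zero-effect null configuration equalizes every HRD-conditional
parameter (mixtures, burdens, indel rates, scar geometry, region and
oncogene effects, inflammation effects, DDR/TP53 alteration rates) and
realizes biallelic BRCA through mutation + silencing rather than locus LOH,
so the ground-truth flag leaves no footprint in any feature.

All randomness flows from one `numpy` generator seeded by the config;
fixed config ⇒ byte-identical outputs.

**What the generator does not emulate**: clonal structure and subclonal
copy number, purity/ploidy distortion, expression–copy-number coupling,
realistic gene lengths or linkage, sequencing depth effects, and real
signature spectra.  Passing recovery tests therefore demonstrates that the
pipeline's inference is correct *when its modeling assumptions hold*, not
that TCGA-scale effect sizes are reproduced.

## Problem sizes and experiment design

Experiments use cohort sizes chosen to give stable statistics at desk
scale: the packaged 600-sample cohort for recovery (AUC, balanced accuracy,
IS correlation), 300-sample null cohorts over 20 seeds for the zero-effect
calibration (single-point hyperparameter grid, pan-cancer scope only — null
behavior does not depend on the grid search), 100 samples per arm for
region detection with 50-sample arms over 20 seeds for its null rate, and
100 expression-layer simulations at 100 per arm for the IS sign-recovery
rate.  The two accounting percentages (label overrides, artifact exclusion)
are computed by running the actual bookkeeping code at the cohort sizes
where such figures are conventionally quoted (1,066 HRD labels; 10,308
samples).

## Known limitations

* The per-tumor-type behavior of signature-3 scoring in real data depends
  on WGS-trained reference spectra; the packaged mixtures stand in for
  them, and users analyzing real cohorts should substitute refitted spectra
  and recalibrate the triage thresholds.
* Differential-region boundaries are bin-resolution objects; sub-bin
  precision is not attempted.
* The classifier's HRD-low band depends directly on the 0.5/0.5 score
  thresholds; no claim is made that its share matches any particular
  cohort.
* Fisher-based enrichment is conservative at small counts (the null
  rejection rate sits below α), which is inherited by the BH-adjusted
  sweeps.
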