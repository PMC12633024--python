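# hrdscape

Exome-scale analysis of homologous-recombination deficiency (HRD) and its
immune correlates.

Tumors that cannot repair double-strand breaks by homologous recombination
(most famously through biallelic *BRCA1*/*BRCA2* loss) accumulate
characteristic genomic damage — a near-flat single-base-substitution
signature (SBS3), deletions at microhomologies, and large allele-specific
copy-number scars — and respond differently to PARP inhibition and immune
checkpoint blockade.  `hrdscape` implements the computational pipeline for
studying this state at whole-exome scale, for cancer-genomics analysts who
have somatic mutation calls (MAF), allele-specific copy-number segments
(ASCAT-like) and bulk expression, but no whole-genome sequencing:

* **Mutational features** — SBS96 catalogs; SBS3 evidence by a two-class
  multinomial likelihood, cosine similarity and non-negative least squares
  (NNLS) exposures over a spectrum panel; counts of ≥ 5 bp deletions with
  and without ≥ 2 bp flanking microhomology; tumor mutational burden (TMB);
  MMRD/POLE hypermutation triage; an SBS45 sequencing-artifact filter.
* **Copy-number scars** — sample baselines; the genomic instability score
  GIS = HRD-LOH + TAI + LST; 100-kb LOH/amplification genome profiles;
  gene-level amplification/LOH/deep-deletion calls; differential-region
  detection and co-occurrence statistics.
* **HRD classifier** — a weakly supervised, two-step gradient-boosted
  classifier seeded on biallelic *BRCA1/2* samples (plus their nearest
  feature-space neighbors), trained pan-cancer and per tumor type with
  5-fold cross-validated hyperparameters, yielding HRD / HRD-low / HRP
  labels with a biallelic override.
* **Inflammation score (IS)** — the mean of four single-sample GSEA
  (ssGSEA) scores over immune signatures (type-I IFN, chemokine T-cell
  recruitment, IFN-γ, cytotoxic CD8), hot/intermediate/cold tertile status
  per tumor type, and regressions of IS on HRD + TMB and on regional LOH +
  oncogene amplification.
* **Associations** — DDR-gene and gene-pair enrichment (Fisher +
  Benjamini–Hochberg), hypergeometric over-representation analysis, and
  tumor-microenvironment cell-fraction analyses (within-type z-scores, ΔZ
  between groups, hierarchical clustering of cell types, correlation
  matrices).
* **Synthetic cohorts** — a generator that emulates the statistical
  structure of all these inputs with ground-truth labels, so every stage is
  testable end to end without downloads.

## Worked example

The numbered scripts under `analysis/` run the full study on the packaged
600-sample synthetic cohort (three tumor types; ground truth known) and
write tables under `results/`.  For example:

```bash
python analysis/01_simulate_cohort.py
python analysis/04_hrd_classifier.py
```

prints

```
wrote results/hrd_labels.tsv (600 samples)
label counts: {'HRP': 399, 'HRD': 165, 'MMRD': 22, 'POLE': 8, 'excluded': 4, 'HRD_low': 2}
pan-score AUC vs ground truth: 0.997
HRD-vs-HRP balanced accuracy:  1.000
```

The 22 MMRD and 8 POLE hypermutators were triaged out before HRD scoring
and keep their class as the final label; 4 artifact-dominated samples were
excluded; the remaining samples score AUC 0.997 against the generator's
true HRD flags.  `analysis/05_inflammation.py` then recovers the planted
tumor-type-specific inflammation structure:

```
corr(IS, latent inflammation) = 0.958
  dCpH: HRD-vs-HRP t = -9.59 (p = 2.6e-17)
  dHpC: HRD-vs-HRP t = +6.40 (p = 1.1e-09)
```

i.e. HRD tumors are hotter than HRP in the dHpC-group types and colder in
the dCpH-group types, and (per `analysis/03_copy_number_scars.py` and the
genomic regression in script 05) the planted chr4 LOH region is detected
with exact bin boundaries and is the strongest negative predictor of IS
among HRD samples.

The same stages work on real data: read your MAF with
`hrdscape.io.read_maf`, segments with `read_segments`, gene sets with
`read_gmt`, and substitute refitted signature spectra for the packaged
panel where you have them.

## Layout

```
src/hrdscape/      library: io, spectra, signatures, scars, classifier,
                   inflammation, associations, simulate, pipeline, experiments
analysis/          numbered drivers reproducing the study on synthetic data
scripts/           acceptance.py (headline numbers as JSON)
tests/             pytest suite incl. brute-force oracle checks
docs/methods.md    models, conventions, numerical choices, limitations
```
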