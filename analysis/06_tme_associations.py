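#!/usr/bin/env python
"""DDR-gene enrichment, gene-pair epistasis, over-representation, and the
tumor-microenvironment cell-fraction analyses (delta-Z, clustering,
correlation).

Writes results/ddr_enrichment.tsv, results/tme_delta.tsv and
results/celltype_clusters.tsv.
"""

from pathlib import Path

import pandas as pd

from hrdscape.associations import (
    alteration_matrix,
    cluster_celltypes,
    correlate_celltypes,
    ddr_enrichment,
    ora,
    pair_epistasis_sweep,
    stack_delta_tables,
    tme_delta,
    zscore_within_type,
)
from hrdscape.classifier import biallelic_brca_samples, call_biallelic
from hrdscape.datatypes import GeneSet
from hrdscape.inflammation import inflammation_score, tertile_status
from hrdscape.scars import compute_baselines, gene_calls_cohort
from hrdscape.signatures import is_pathogenic
from hrdscape.simulate import DDR_GENES, default_config, simulate_cohort

OUT = Path("results")


def main() -> None:
    cohort = simulate_cohort(default_config(seed=1))
    truth = cohort.truth.set_index("sample_id")
    ann = cohort.annotations.set_index("sample_id")
    samples = list(truth.index)
    hrd = truth["hrd_status"]

    # ---- dysfunction matrix from somatic / germline / CNA / silencing ----
    baselines = compute_baselines(cohort.segments)
    gene_cna = gene_calls_cohort(cohort.segments, cohort.gene_coords, baselines)
    genes = DDR_GENES + ["TP53"]
    somatic = [
        (r.sample_id, r.gene) for r in cohort.mutations if r.gene in genes and is_pathogenic(r)
    ]
    deep = gene_cna[gene_cna["deep_deletion"] & gene_cna["gene"].isin(genes)]
    alterations = alteration_matrix(
        {
            "somatic": somatic,
            "germline": zip(cohort.germline["sample_id"], cohort.germline["gene"]),
            "silencing": zip(cohort.silencing["sample_id"], cohort.silencing["gene"]),
            "deep_deletion": zip(deep["sample_id"], deep["gene"]),
        },
        samples=samples,
        genes=genes,
    )

    # enrichment in BRCA-wildtype HRD vs HRP
    biallelic = call_biallelic(
        cohort.mutations, cohort.germline, gene_cna, cohort.silencing, ["BRCA1", "BRCA2"], samples
    )
    brca = set(biallelic_brca_samples(biallelic))
    mask = pd.Series([s not in brca for s in samples], index=samples)
    enr = ddr_enrichment(alterations, hrd, genes=[g for g in DDR_GENES if g not in ("BRCA1", "BRCA2")],
                         background_mask=mask)
    OUT.mkdir(exist_ok=True)
    enr.to_csv(OUT / "ddr_enrichment.tsv", sep="\t", index=False)
    n_sig = int((enr["q"] < 0.05).sum())
    print(f"wrote {OUT / 'ddr_enrichment.tsv'}: {n_sig}/{len(enr)} DDR genes enriched "
          "in BRCA-WT HRD at q < 0.05")

    pairs = pair_epistasis_sweep(alterations, DDR_GENES[2:8], "TP53", hrd)
    print("gene-pair (x TP53) epistasis, top rows:")
    print(pairs.sort_values("p").head(3).round(4).to_string(index=False))

    # generic ORA demo over the packaged immune sets
    universe = list(cohort.expression.index)
    hit_list = sorted(cohort.gene_sets[0].genes)[:15] + universe[-5:]
    oraout = ora(hit_list, universe, cohort.gene_sets)
    print("ORA of a type-I-IFN-loaded gene list over the four immune sets:")
    print(oraout.round(6).to_string(index=False))

    # ---- TME delta-Z / clustering / correlation ----
    scores = inflammation_score(cohort.expression, cohort.gene_sets)
    excluded = set(truth.index[truth["hypermutation_class"] != "MMRP"]) | set(
        ann.index[ann["viral_status"] == "positive"]
    )
    tert = tertile_status(scores["IS"], cohort.annotations, excluded=excluded)
    hot = tert.status == "hot"
    cold = tert.status == "cold"

    comparisons = {
        "hrd_vs_hrp": tme_delta(cohort.cell_fractions, cohort.annotations, hrd, ~hrd),
        "hotHRD_vs_coldHRD": tme_delta(cohort.cell_fractions, cohort.annotations, hrd & hot, hrd & cold),
        "hotHRP_vs_coldHRP": tme_delta(cohort.cell_fractions, cohort.annotations, ~hrd & hot, ~hrd & cold),
    }
    stacked = stack_delta_tables(comparisons)
    comparisons["hrd_vs_hrp"].to_csv(OUT / "tme_delta.tsv", sep="\t", index=False)
    clusters = cluster_celltypes(stacked, k=5)
    clusters.to_frame().to_csv(OUT / "celltype_clusters.tsv", sep="\t")
    print(f"wrote {OUT / 'tme_delta.tsv'} and {OUT / 'celltype_clusters.tsv'}")
    print("cell-type clusters (k=5):")
    for c in sorted(clusters.unique()):
        print(f"  cluster {c}: {', '.join(clusters.index[clusters == c])}")

    z = zscore_within_type(cohort.cell_fractions, ann["tumor_type"])
    r, p, sig = correlate_celltypes(z.loc[hrd[hrd].index])
    pair = ("CD8_cytotoxic_exhausted", "B_cell")
    print(f"corr({pair[0]}, {pair[1]}) in HRD samples: r = {r.loc[pair]:.2f} "
          f"(significant: {bool(sig.loc[pair])})")


if __name__ == "__main__":
    main()
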