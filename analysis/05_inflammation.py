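#!/usr/bin/env python
"""Inflammation scoring and its genomic correlates.

Computes ssGSEA scores for the four packaged immune signatures, averages
them into the Inflammation Score (IS), assigns hot/intermediate/cold status
from within-tumor-type tertiles (excluding viral-positive and hypermutated
samples from the thresholds), compares z-scored IS between HRD and HRP per
group, and fits the two regressions: IS ~ HRD + TMB, and (in HRD samples)
IS ~ regional LOH + oncogene amplification.

Writes results/inflammation.tsv.
"""

from pathlib import Path

import pandas as pd

from hrdscape.experiments import is_recovery_experiment
from hrdscape.inflammation import inflammation_score, regress_is, regress_is_on_genomics, tertile_status
from hrdscape.pipeline import extract_features
from hrdscape.scars import cohort_bin_profiles, compute_baselines, region_sample_summaries
from hrdscape.simulate import default_config, simulate_cohort

OUT = Path("results")


def main() -> None:
    cohort = simulate_cohort(default_config(seed=1))
    truth = cohort.truth.set_index("sample_id")
    ann = cohort.annotations.set_index("sample_id")

    scores = inflammation_score(cohort.expression, cohort.gene_sets)
    excluded = set(truth.index[truth["hypermutation_class"] != "MMRP"]) | set(
        ann.index[ann["viral_status"] == "positive"]
    )
    tert = tertile_status(scores["IS"], cohort.annotations, excluded=excluded)
    out = scores.copy()
    out["status"] = tert.status
    out["z_is"] = tert.z_is
    OUT.mkdir(exist_ok=True)
    out.to_csv(OUT / "inflammation.tsv", sep="\t")
    print(f"wrote {OUT / 'inflammation.tsv'}")
    print("status counts:", dict(tert.status.value_counts()))

    res = is_recovery_experiment(cohort)
    print(f"corr(IS, latent inflammation) = {res.correlation:.3f}")
    for group, cmp in res.compare_by_group.items():
        print(f"  {group}: HRD-vs-HRP t = {cmp.t:+.2f} (p = {cmp.p:.2g})")

    # IS ~ HRD + TMB, per group, on eligible samples
    feats = extract_features(cohort.mutations, cohort.segments, cohort.annotations, cohort.genome)
    groups = {tt.name: tt.group for tt in cohort.config.tumor_types}
    for group in ("dHpC", "dCpH"):
        members = [
            s for s in tert.z_is.dropna().index
            if s not in excluded and groups[ann.loc[s, "tumor_type"]] == group
        ]
        fit = regress_is(
            tert.z_is.loc[members], truth.loc[members, "hrd_status"], feats.features.loc[members, "tmb"]
        )
        print(f"IS ~ HRD + TMB in {group}: HRD t = {fit.loc['hrd', 't']:+.2f} "
              f"(p = {fit.loc['hrd', 'p']:.2g}), TMB t = {fit.loc['tmb', 't']:+.2f}")

    # IS ~ region LOH + oncogene amplification among HRD samples
    baselines = compute_baselines(cohort.segments)
    profiles = cohort_bin_profiles(
        cohort.segments, cohort.genome, baselines, sex_by_sample=ann["sex"].to_dict()
    )
    hrd_samples = [s for s in truth.index[truth["hrd_status"]] if s in profiles.samples]
    loh = pd.DataFrame(index=pd.Index(profiles.samples, name="sample_id"))
    for eff in cohort.config.region_effects:
        summ = region_sample_summaries(profiles, eff.chrom, eff.start, eff.end)
        loh[f"loh_{eff.chrom}:{eff.start // 10**6}Mb"] = summ["loh_fraction"]
    fit = regress_is_on_genomics(
        tert.z_is.loc[hrd_samples], loh.loc[hrd_samples], truth.loc[hrd_samples, "og_amp"]
    )
    print("IS ~ regional LOH + OG amplification (HRD samples):")
    print(fit.round(3).to_string())


if __name__ == "__main__":
    main()
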