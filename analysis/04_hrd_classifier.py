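#!/usr/bin/env python
"""Train the two-step HRD classifier and write final labels.

Runs the complete protocol — hypermutation triage, artifact exclusion,
biallelic BRCA1/2 seed calling, neighbor augmentation, two-step gradient-
boosted training (pan-cancer + per-type + pooled), score combination and the
biallelic override — and reports recovery against the generator's ground
truth.

Writes results/hrd_labels.tsv.
"""

from pathlib import Path

from hrdscape.experiments import hrd_recovery_experiment

OUT = Path("results")


def main() -> None:
    rec = hrd_recovery_experiment(seed=1)
    OUT.mkdir(exist_ok=True)
    rec.pipeline.labels.to_csv(OUT / "hrd_labels.tsv", sep="\t", index=False)
    print(f"wrote {OUT / 'hrd_labels.tsv'} ({rec.n_samples} samples)")
    print(f"label counts: {rec.label_counts}")
    print(f"pan-score AUC vs ground truth: {rec.auc:.3f}")
    print(f"HRD-vs-HRP balanced accuracy:  {rec.balanced_accuracy:.3f}")
    print(f"HRD-low fraction: {100 * rec.hrd_low_fraction:.1f}%")
    print(f"biallelic overrides: {rec.pipeline.finalize_summary}")
    meta = rec.pipeline.bundle.metadata
    print(f"type-specific models: {meta['type_models']}; pooled: {meta['pooled_types']}")


if __name__ == "__main__":
    main()
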