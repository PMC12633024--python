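"""End-to-end orchestration: cohort inputs -> features -> HRD labels.

The stages are:

1. SBS96 catalogs and NNLS exposures over the packaged spectrum panel;
   signature-3 likelihood (against packaged HRD-positive / negative mixture
   spectra), cosine and exposure features.
2. Microhomology-deletion counts and TMB.
3. Hypermutation triage (MMRD / POLE) and artifact-sample removal.
4. Copy-number baselines, scar scores (GIS) and gene-level calls.
5. Biallelic BRCA1/2 calls, two-step classifier training, final labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from hrdscape.classifier import (
    BRCA_GENES,
    ClassifierConfig,
    FinalizeSummary,
    HrdClassifierBundle,
    call_biallelic,
    classify,
    finalize_labels,
    train_hrd_classifier,
)
from hrdscape.datatypes import GenomeBuild, MutationRecord
from hrdscape.scars import (
    compute_baselines,
    compute_scars_cohort,
    gene_calls_cohort,
)
from hrdscape.signatures import (
    Catalog96,
    NnlsResult,
    TriageThresholds,
    build_catalog,
    compute_tmb,
    cosine_to,
    count_microhomology_deletions,
    filter_artifact_samples,
    nnls_exposures,
    sig3_likelihood,
    triage_hypermutation,
)
from hrdscape.spectra import Spectrum96, default_panel, mix_spectra

logger = logging.getLogger(__name__)

#: Mixture weights of the packaged HRD-positive and HRD-negative expected
#: spectra used by the signature-3 likelihood (stand-ins for WGS-derived
#: average spectra of signature-3-positive / negative tumors).
SIG3_POS_WEIGHTS = {"sig3": 0.6, "background": 0.25, "clock": 0.15}
SIG3_NEG_WEIGHTS = {"background": 0.55, "clock": 0.40, "sig3": 0.05}


@dataclass
class FeatureTable:
    """Per-sample features plus triage / filter bookkeeping."""

    features: pd.DataFrame  # indexed by sample_id, classifier feature columns + tmb
    hypermutation: pd.Series  # MMRP / MMRD / POLE
    artifact_excluded: frozenset
    catalogs: Dict[str, Catalog96]
    exposures: Dict[str, NnlsResult]


def extract_features(
    mutations: Sequence[MutationRecord],
    segments: pd.DataFrame,
    annotations: pd.DataFrame,
    genome: GenomeBuild,
    panel: Optional[Sequence[Spectrum96]] = None,
    triage_thresholds: TriageThresholds = TriageThresholds(),
    sbs45_threshold: float = 0.2,
    footprint_mb: float = 38.0,
) -> FeatureTable:
    """Compute the classifier feature vector for every sample."""
    panel = list(panel) if panel is not None else default_panel()
    pos = mix_spectra(panel, SIG3_POS_WEIGHTS, "sig3_positive")
    neg = mix_spectra(panel, SIG3_NEG_WEIGHTS, "sig3_negative")
    sig3 = next(s for s in panel if s.name == "sig3")

    ann = annotations.set_index("sample_id")
    samples = list(ann.index)
    catalogs = build_catalog(mutations, genome, samples=samples)
    exposures = {s: nnls_exposures(catalogs[s], panel) for s in samples}
    indels = count_microhomology_deletions(mutations, genome, samples=samples)
    tmb = compute_tmb(mutations, footprint_mb, samples=samples)
    scars = compute_scars_cohort(segments, genome)

    rows = []
    hyper = {}
    for s in samples:
        cat, exp = catalogs[s], exposures[s]
        msi = ann.loc[s, "msi_score"]
        msi = None if pd.isna(msi) else float(msi)
        hyper[s] = triage_hypermutation(cat, exp, msi, tmb[s], triage_thresholds).cls
        total = cat.total
        rows.append(
            {
                "sample_id": s,
                "sig3_likelihood": sig3_likelihood(cat, pos, neg),
                "sig3_cosine": cosine_to(cat, sig3) if total else 0.0,
                "sig3_exposure": exp.exposures.get("sig3", 0.0),
                "sig3_exposure_fraction": exp.fraction("sig3") if "sig3" in exp.exposures else 0.0,
                "gis": scars["gis"].get(s, 0),
                "n_del_mh": indels[s].n_del_mh,
                "n_del_no_mh": indels[s].n_del_no_mh,
                "tmb": tmb[s],
            }
        )
    features = pd.DataFrame(rows).set_index("sample_id")
    artifact = filter_artifact_samples(exposures, sbs45_threshold)
    return FeatureTable(
        features=features,
        hypermutation=pd.Series(hyper, name="hypermutation"),
        artifact_excluded=artifact.excluded,
        catalogs=catalogs,
        exposures=exposures,
    )


@dataclass
class PipelineResult:
    features: FeatureTable
    biallelic: pd.DataFrame
    gene_cna: pd.DataFrame
    bundle: HrdClassifierBundle
    labels: pd.DataFrame  # sample_id, label (incl. MMRD/POLE/excluded), scores
    finalize_summary: FinalizeSummary


def run_hrd_pipeline(
    mutations: Sequence[MutationRecord],
    segments: pd.DataFrame,
    annotations: pd.DataFrame,
    genome: GenomeBuild,
    gene_coords: pd.DataFrame,
    germline: Optional[pd.DataFrame] = None,
    silencing: Optional[pd.DataFrame] = None,
    ddr_genes: Sequence[str] = BRCA_GENES,
    classifier_config: ClassifierConfig = ClassifierConfig(),
    panel: Optional[Sequence[Spectrum96]] = None,
) -> PipelineResult:
    """Run triage, feature extraction, biallelic calling, training and
    labeling on a full cohort.

    Hypermutated samples keep their MMRD / POLE class as the final label;
    artifact samples are labeled ``excluded``.
    """
    empty = pd.DataFrame(columns=["sample_id", "gene"])
    germline = germline if germline is not None else empty
    silencing = silencing if silencing is not None else empty

    feats = extract_features(mutations, segments, annotations, genome, panel=panel)
    ann = annotations.set_index("sample_id")
    samples = list(ann.index)

    baselines = compute_baselines(segments)
    gene_cna = gene_calls_cohort(segments, gene_coords, baselines)
    biallelic = call_biallelic(mutations, germline, silencing=silencing, gene_cna=gene_cna, genes=list(ddr_genes), samples=samples)

    eligible = [
        s
        for s in samples
        if feats.hypermutation[s] == "MMRP" and s not in feats.artifact_excluded
    ]
    bundle = train_hrd_classifier(
        feats.features.loc[eligible], annotations, biallelic, classifier_config
    )
    labels = classify(feats.features.loc[eligible], annotations, bundle)
    labels, summary = finalize_labels(labels, biallelic)

    passthrough = []
    for s in samples:
        if s in eligible:
            continue
        label = "excluded" if s in feats.artifact_excluded else feats.hypermutation[s]
        passthrough.append(
            {"sample_id": s, "label": label, "pan_score": np.nan, "type_score": np.nan, "override": False}
        )
    if passthrough:
        labels = pd.concat([labels, pd.DataFrame(passthrough)], ignore_index=True)
    labels = labels.set_index("sample_id").loc[samples].reset_index()

    return PipelineResult(
        features=feats,
        biallelic=biallelic,
        gene_cna=gene_cna,
        bundle=bundle,
        labels=labels,
        finalize_summary=summary,
    )
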