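"""Two-step gradient-boosted HRD classification.

The training protocol is weakly supervised: samples with biallelic BRCA1/2
loss seed the positive class, each seed recruits its three most similar
BRCA-wildtype samples (cosine similarity in z-scored feature space), a first
gradient-boosted model is fit with 5-fold cross-validated hyperparameter
selection, labels are revised from its out-of-fold scores (high-scoring
negatives become positive and vice versa), and a second model is fit the same
way.  A pan-cancer model is trained on all eligible samples; tumor types with
enough seed positives get their own model and the rest share a pooled model.
Final labels combine the pan-cancer and type-level scores: high on both =
HRD, low on both = HRP, discordant = HRD-low, and biallelic BRCA1/2 samples
are overridden to HRD regardless of score.

Hypermutated (MMRD / POLE) and artifact-flagged samples must be excluded
before training; their labels pass through untouched.

Out-of-fold scores (not in-sample predictions of the final fit) are stored
for the training cohort, so that cohort-level evaluation is not inflated by
memorization of the seed labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from hrdscape.datatypes import MutationRecord
from hrdscape.signatures import is_pathogenic

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = [
    "sig3_likelihood",
    "sig3_cosine",
    "sig3_exposure",
    "sig3_exposure_fraction",
    "gis",
    "n_del_mh",
    "n_del_no_mh",
]

BRCA_GENES = ("BRCA1", "BRCA2")


# --------------------------------------------------------------------------
# biallelic calls
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class BiallelicCall:
    sample_id: str
    gene: str
    status: str  # biallelic_loss / monoallelic / intact
    hits: Tuple[str, ...]


def call_biallelic(
    mutations: Iterable[MutationRecord],
    germline: pd.DataFrame,
    gene_cna: pd.DataFrame,
    silencing: pd.DataFrame,
    genes: Sequence[str],
    samples: Sequence[str],
) -> pd.DataFrame:
    """Biallelic-loss calls per (sample, gene).

    Hit classes: pathogenic somatic variant, pathogenic germline variant,
    promoter silencing, deep deletion, locus LOH.  Biallelic loss requires a
    deep deletion alone, two hits of the non-LOH classes, or one such hit
    plus LOH (the second allele lost with the region).  A single non-LOH hit
    is monoallelic; LOH alone is intact (the retained allele is unaffected).

    ``germline`` and ``silencing`` are tables with ``sample_id`` and ``gene``
    columns (one row per pathogenic call / silencing event); ``gene_cna`` is
    the cohort gene-call table from :func:`hrdscape.scars.gene_calls_cohort`.
    """
    genes = list(genes)
    somatic_hits = set()
    for rec in mutations:
        if rec.gene in genes and is_pathogenic(rec):
            somatic_hits.add((rec.sample_id, rec.gene))
    germline_hits = (
        set(zip(germline["sample_id"], germline["gene"])) if len(germline) else set()
    )
    silencing_hits = (
        set(zip(silencing["sample_id"], silencing["gene"])) if len(silencing) else set()
    )
    cna = gene_cna[gene_cna["gene"].isin(genes)]
    loh_hits = set(zip(cna.loc[cna["loh"], "sample_id"], cna.loc[cna["loh"], "gene"]))
    deep_hits = set(
        zip(cna.loc[cna["deep_deletion"], "sample_id"], cna.loc[cna["deep_deletion"], "gene"])
    )
    rows = []
    for sample in samples:
        for gene in genes:
            key = (sample, gene)
            hits = []
            if key in somatic_hits:
                hits.append("pathogenic_somatic")
            if key in germline_hits:
                hits.append("pathogenic_germline")
            if key in silencing_hits:
                hits.append("promoter_silencing")
            if key in deep_hits:
                hits.append("deep_deletion")
            has_loh = key in loh_hits
            if has_loh:
                hits.append("loh")
            n_core = len(hits) - (1 if has_loh else 0)
            if key in deep_hits or n_core >= 2 or (n_core >= 1 and has_loh):
                status = "biallelic_loss"
            elif n_core == 1:
                status = "monoallelic"
            else:
                status = "intact"
            rows.append(
                {"sample_id": sample, "gene": gene, "status": status, "hits": ",".join(hits)}
            )
    return pd.DataFrame(rows)


def biallelic_brca_samples(calls: pd.DataFrame) -> pd.Index:
    mask = calls["gene"].isin(BRCA_GENES) & (calls["status"] == "biallelic_loss")
    return pd.Index(calls.loc[mask, "sample_id"].unique())


# --------------------------------------------------------------------------
# seed labeling
# --------------------------------------------------------------------------


class TrainingError(RuntimeError):
    pass


def seed_labels(
    features: pd.DataFrame,
    seeds: Sequence[str],
    n_neighbors: int = 3,
) -> pd.Series:
    """Initial labels: seed samples positive, each augmented with its
    ``n_neighbors`` most similar non-seed samples; the rest negative.

    Similarity is cosine in z-scored feature space.  A non-seed sample
    recruited by several seeds is kept once.  Raises
    :class:`TrainingError` with fewer than two seeds.
    """
    seeds = [s for s in seeds if s in features.index]
    if len(seeds) < 2:
        raise TrainingError(
            f"need >= 2 seed (biallelic BRCA1/2) samples to train, got {len(seeds)}"
        )
    X = features[FEATURE_COLUMNS].to_numpy(float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    norms = np.linalg.norm(Z, axis=1)
    norms[norms == 0] = 1.0
    U = Z / norms[:, None]
    is_seed = features.index.isin(seeds)
    sims = U[is_seed] @ U[~is_seed].T  # seeds x candidates
    candidates = features.index[~is_seed]
    positives = set(seeds)
    k = min(n_neighbors, sims.shape[1])
    for row in sims:
        top = np.argsort(row, kind="stable")[::-1][:k]
        positives.update(candidates[top])
    labels = pd.Series(0, index=features.index, dtype=int)
    labels.loc[list(positives)] = 1
    return labels


# --------------------------------------------------------------------------
# model fitting
# --------------------------------------------------------------------------

DEFAULT_GRID = tuple(
    {"n_estimators": n, "max_depth": d, "learning_rate": lr}
    for n in (100, 300)
    for d in (2, 3)
    for lr in (0.05, 0.1)
)

#: Single-point grid for experiments where hyperparameter search is not the
#: object of study (e.g. permutation nulls).
FAST_GRID = ({"n_estimators": 100, "max_depth": 2, "learning_rate": 0.1},)


@dataclass
class FittedStep:
    model: GradientBoostingClassifier
    best_params: dict
    cv_auc: float
    oof_scores: pd.Series


def train_step(
    features: pd.DataFrame,
    labels: pd.Series,
    cv_folds: int = 5,
    grid: Sequence[dict] = DEFAULT_GRID,
    seed: int = 0,
) -> FittedStep:
    """Fit a gradient-boosted classifier with CV hyperparameter selection.

    Returns the refit model, the winning grid point, its mean cross-
    validated AUC, and out-of-fold scores for every training sample.
    Deterministic given ``seed``.
    """
    y = labels.loc[features.index].to_numpy(int)
    if len(np.unique(y)) < 2:
        raise TrainingError("training labels contain a single class")
    X = features[FEATURE_COLUMNS].to_numpy(float)
    n_folds = min(cv_folds, int(np.bincount(y).min()))
    if n_folds < 2:
        raise TrainingError("minority class too small for cross-validation")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    best: Optional[Tuple[float, dict, np.ndarray]] = None
    for params in grid:
        oof = np.zeros(len(y))
        aucs = []
        for tr, te in splits:
            model = GradientBoostingClassifier(random_state=seed, **params)
            model.fit(X[tr], y[tr])
            scores = model.predict_proba(X[te])[:, 1]
            oof[te] = scores
            if len(np.unique(y[te])) == 2:
                aucs.append(roc_auc_score(y[te], scores))
        mean_auc = float(np.mean(aucs)) if aucs else 0.5
        if best is None or mean_auc > best[0]:
            best = (mean_auc, dict(params), oof)
    cv_auc, best_params, oof = best
    model = GradientBoostingClassifier(random_state=seed, **best_params)
    model.fit(X, y)
    return FittedStep(
        model=model,
        best_params=best_params,
        cv_auc=cv_auc,
        oof_scores=pd.Series(oof, index=features.index),
    )


def relabel(
    scores: pd.Series,
    labels: pd.Series,
    theta_hi: float = 0.5,
    theta_lo: float = 0.5,
) -> Tuple[pd.Series, Dict[str, int]]:
    """Revise labels from step-1 scores: negatives scoring >= ``theta_hi``
    become positive, positives scoring < ``theta_lo`` become negative."""
    new = labels.copy()
    up = (labels == 0) & (scores >= theta_hi)
    down = (labels == 1) & (scores < theta_lo)
    new[up] = 1
    new[down] = 0
    flips = {"to_positive": int(up.sum()), "to_negative": int(down.sum())}
    logger.info("relabeling: %(to_positive)d -> HRD, %(to_negative)d -> HRP", flips)
    return new, flips


# --------------------------------------------------------------------------
# full training protocol
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassifierConfig:
    n_neighbors: int = 3
    cv_folds: int = 5
    grid: Sequence[dict] = DEFAULT_GRID
    theta_hi: float = 0.5
    theta_lo: float = 0.5
    #: decision thresholds on the pan-cancer and type-level scores
    theta_pan: float = 0.5
    theta_type: float = 0.5
    #: minimum seed-HRD samples for a tumor-type-specific model
    min_type_seeds: int = 11
    #: minimum total samples for a tumor-type-specific model
    min_type_samples: int = 30
    seed: int = 0


@dataclass
class ScopeModel:
    """One trained scope (pan-cancer, a tumor type, or the pooled rest)."""

    name: str
    step1: FittedStep
    step2: FittedStep
    flips: Dict[str, int]

    @property
    def oof_scores(self) -> pd.Series:
        return self.step2.oof_scores

    def score(self, features: pd.DataFrame) -> pd.Series:
        X = features[FEATURE_COLUMNS].to_numpy(float)
        return pd.Series(self.step2.model.predict_proba(X)[:, 1], index=features.index)


@dataclass
class HrdClassifierBundle:
    pan: ScopeModel
    by_type: Dict[str, ScopeModel]
    pooled: Optional[ScopeModel]
    config: ClassifierConfig
    #: out-of-fold pan and type-level scores for the training cohort
    cohort_scores: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def type_model_for(self, tumor_type: str) -> Optional[ScopeModel]:
        if tumor_type in self.by_type:
            return self.by_type[tumor_type]
        return self.pooled


def _two_step(
    features: pd.DataFrame,
    seeds: Sequence[str],
    config: ClassifierConfig,
    name: str,
) -> ScopeModel:
    labels0 = seed_labels(features, seeds, n_neighbors=config.n_neighbors)
    step1 = train_step(features, labels0, config.cv_folds, config.grid, config.seed)
    labels1, flips = relabel(step1.oof_scores, labels0, config.theta_hi, config.theta_lo)
    if labels1.nunique() < 2:
        logger.warning("scope %s: relabeling collapsed to one class; keeping step-1 labels", name)
        labels1 = labels0
    step2 = train_step(features, labels1, config.cv_folds, config.grid, config.seed)
    return ScopeModel(name=name, step1=step1, step2=step2, flips=flips)


def train_hrd_classifier(
    features: pd.DataFrame,
    annotations: pd.DataFrame,
    biallelic: pd.DataFrame,
    config: ClassifierConfig = ClassifierConfig(),
) -> HrdClassifierBundle:
    """Run the two-step protocol for the pan-cancer scope, each qualifying
    tumor type, and a pooled scope for the remaining types.

    ``features`` is indexed by sample id with :data:`FEATURE_COLUMNS`;
    hypermutated and artifact samples must already be excluded.  A type
    qualifies for its own model with more than 10 seed-HRD samples and at
    least ``config.min_type_samples`` samples; otherwise it is served by the
    pooled model.
    """
    ann = annotations.set_index("sample_id") if "sample_id" in annotations.columns else annotations
    types = ann.loc[features.index, "tumor_type"]
    seeds = [s for s in biallelic_brca_samples(biallelic) if s in features.index]

    pan = _two_step(features, seeds, config, "pan-cancer")

    by_type: Dict[str, ScopeModel] = {}
    pooled_types: List[str] = []
    for tumor_type in types.unique():
        members = features.index[types == tumor_type]
        type_seeds = [s for s in seeds if s in members]
        if len(type_seeds) >= config.min_type_seeds and len(members) >= config.min_type_samples:
            try:
                by_type[tumor_type] = _two_step(
                    features.loc[members], type_seeds, config, tumor_type
                )
                continue
            except TrainingError as exc:
                logger.warning("type %s falls back to pooled model: %s", tumor_type, exc)
        pooled_types.append(tumor_type)

    pooled = None
    if pooled_types:
        members = features.index[types.isin(pooled_types)]
        pooled_seeds = [s for s in seeds if s in members]
        try:
            pooled = _two_step(features.loc[members], pooled_seeds, config, "pooled")
        except TrainingError as exc:
            logger.warning("pooled scope not trainable (%s); pan-cancer scores will serve", exc)

    type_scores = pd.Series(np.nan, index=features.index)
    for scope in list(by_type.values()) + ([pooled] if pooled else []):
        type_scores.loc[scope.oof_scores.index] = scope.oof_scores
    type_scores = type_scores.fillna(pan.oof_scores)
    cohort_scores = pd.DataFrame(
        {"pan_score": pan.oof_scores, "type_score": type_scores}, index=features.index
    )
    metadata = {
        "n_samples": len(features),
        "n_seeds": len(seeds),
        "type_models": sorted(by_type),
        "pooled_types": sorted(pooled_types),
        "seed": config.seed,
        "pan_best_params": pan.step2.best_params,
        "pan_cv_auc": pan.step2.cv_auc,
    }
    return HrdClassifierBundle(
        pan=pan,
        by_type=by_type,
        pooled=pooled,
        config=config,
        cohort_scores=cohort_scores,
        metadata=metadata,
    )


# --------------------------------------------------------------------------
# labeling
# --------------------------------------------------------------------------

LABEL_COLUMNS = ["sample_id", "label", "pan_score", "type_score", "override"]


def combine_scores(pan: float, typ: float, theta_pan: float = 0.5, theta_type: float = 0.5) -> str:
    """Final label from the pan-cancer and type-level scores: high on both
    = HRD, low on both = HRP, discordant = HRD-low."""
    if pan >= theta_pan and typ >= theta_type:
        return "HRD"
    if pan < theta_pan and typ < theta_type:
        return "HRP"
    return "HRD_low"


def classify(
    features: pd.DataFrame,
    annotations: pd.DataFrame,
    bundle: HrdClassifierBundle,
    use_cohort_scores: bool = True,
) -> pd.DataFrame:
    """Assign HRD / HRD-low / HRP labels from pan + type-level scores.

    Samples present in the training cohort reuse their stored out-of-fold
    scores when ``use_cohort_scores`` (recommended for cohort-level
    analysis); unseen samples are scored by the fitted models, with unknown
    tumor types served by the pooled (or pan-cancer) model.
    """
    ann = annotations.set_index("sample_id") if "sample_id" in annotations.columns else annotations
    types = ann.loc[features.index, "tumor_type"]
    pan_scores = pd.Series(np.nan, index=features.index)
    type_scores = pd.Series(np.nan, index=features.index)
    if use_cohort_scores:
        known = features.index.intersection(bundle.cohort_scores.index)
        pan_scores.loc[known] = bundle.cohort_scores.loc[known, "pan_score"]
        type_scores.loc[known] = bundle.cohort_scores.loc[known, "type_score"]
    todo = features.index[pan_scores.isna()]
    if len(todo):
        pan_scores.loc[todo] = bundle.pan.score(features.loc[todo])
        for tumor_type, members in features.loc[todo].groupby(types.loc[todo]).groups.items():
            scope = bundle.type_model_for(tumor_type) or bundle.pan
            type_scores.loc[members] = scope.score(features.loc[members])
    cfg = bundle.config
    labels = [
        combine_scores(p, t, cfg.theta_pan, cfg.theta_type)
        for p, t in zip(pan_scores, type_scores)
    ]
    return pd.DataFrame(
        {
            "sample_id": features.index,
            "label": labels,
            "pan_score": pan_scores.to_numpy(),
            "type_score": type_scores.to_numpy(),
            "override": False,
        }
    )


@dataclass(frozen=True)
class FinalizeSummary:
    n_overridden: int
    n_hrd_total: int

    @property
    def override_pct(self) -> float:
        return 100.0 * self.n_overridden / self.n_hrd_total if self.n_hrd_total else 0.0

    def __str__(self) -> str:
        return (
            f"{self.n_overridden} out of {self.n_hrd_total}; "
            f"{self.override_pct:.1f}% of all HRD-labeled cases were overridden "
            "from their classifier label by biallelic BRCA1/2 status"
        )


def finalize_labels(
    labels: pd.DataFrame, biallelic: pd.DataFrame
) -> Tuple[pd.DataFrame, FinalizeSummary]:
    """Override HRD-low / HRP labels of biallelic BRCA1/2 samples to HRD.

    Returns the revised table plus a summary reporting the overridden
    fraction of all final HRD labels.  MMRD / POLE labels are never touched.
    """
    out = labels.copy()
    brca = set(biallelic_brca_samples(biallelic))
    flip = out["sample_id"].isin(brca) & out["label"].isin(["HRD_low", "HRP"])
    out.loc[flip, "label"] = "HRD"
    out.loc[flip, "override"] = True
    summary = FinalizeSummary(
        n_overridden=int(flip.sum()), n_hrd_total=int((out["label"] == "HRD").sum())
    )
    logger.info("%s", summary)
    return out, summary
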