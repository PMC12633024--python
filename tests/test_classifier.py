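"""Biallelic calling, seed labeling, two-step training and labeling."""

import numpy as np
import pandas as pd
import pytest

from hrdscape.classifier import (
    FAST_GRID,
    ClassifierConfig,
    FEATURE_COLUMNS,
    TrainingError,
    call_biallelic,
    combine_scores,
    finalize_labels,
    relabel,
    seed_labels,
    train_hrd_classifier,
    train_step,
)
from hrdscape.datatypes import MutationRecord, VariantClass


# --------------------------------------------------------------------------
# biallelic calls
# --------------------------------------------------------------------------


def _gene_cna(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "gene", "total_cn", "relative_amp", "focal_amp", "loh", "deep_deletion"]
    )


def _pathogenic_somatic(sample, gene):
    return MutationRecord(
        sample, "1", 100, "C", "T", VariantClass.SNV,
        consequence="Nonsense_Mutation", gene=gene,
    )


def test_biallelic_status_rules():
    empty = pd.DataFrame(columns=["sample_id", "gene"])
    cna = _gene_cna(
        [
            ("s1", "BRCA1", 2.0, False, False, True, False),   # somatic + LOH
            ("s2", "BRCA1", 3.0, False, False, False, False),  # somatic only
            ("s3", "BRCA1", 0.0, False, False, True, True),    # deep deletion alone
            ("s4", "BRCA1", 2.0, False, False, True, False),   # LOH alone
        ]
    )
    muts = [_pathogenic_somatic("s1", "BRCA1"), _pathogenic_somatic("s2", "BRCA1")]
    calls = call_biallelic(muts, empty, cna, empty, ["BRCA1"], ["s1", "s2", "s3", "s4"])
    status = calls.set_index("sample_id")["status"]
    assert status["s1"] == "biallelic_loss"
    assert status["s2"] == "monoallelic"
    assert status["s3"] == "biallelic_loss"
    assert status["s4"] == "intact"  # LOH alone leaves the retained allele intact


def test_biallelic_two_non_cna_hits():
    empty = pd.DataFrame(columns=["sample_id", "gene"])
    germline = pd.DataFrame([("s1", "BRCA2")], columns=["sample_id", "gene"])
    silencing = pd.DataFrame([("s1", "BRCA2")], columns=["sample_id", "gene"])
    calls = call_biallelic([], germline, _gene_cna([]), silencing, ["BRCA2"], ["s1"])
    assert calls.iloc[0]["status"] == "biallelic_loss"


def test_benign_somatic_is_not_a_hit():
    empty = pd.DataFrame(columns=["sample_id", "gene"])
    rec = MutationRecord(
        "s1", "1", 100, "C", "T", VariantClass.SNV,
        consequence="Nonsense_Mutation", gene="BRCA1", clinvar="benign",
    )
    cna = _gene_cna([("s1", "BRCA1", 2.0, False, False, True, False)])
    calls = call_biallelic([rec], empty, cna, empty, ["BRCA1"], ["s1"])
    assert calls.iloc[0]["status"] == "intact"


# --------------------------------------------------------------------------
# seed labeling
# --------------------------------------------------------------------------


def _features(X, names=None):
    names = names or [f"s{i}" for i in range(len(X))]
    return pd.DataFrame(X, index=names, columns=FEATURE_COLUMNS)


def test_seed_labels_counts_and_dedup():
    rng = np.random.default_rng(0)
    # 10 well-separated seed clusters, each seed near 3 dedicated WT samples
    blocks = []
    names = []
    for k in range(10):
        center = rng.normal(0, 5, size=7)
        blocks.append(center)  # the seed itself
        names.append(f"seed{k}")
        for j in range(3):
            blocks.append(center + rng.normal(0, 1e-3, size=7))
            names.append(f"wt{k}_{j}")
    feats = _features(np.array(blocks), names)
    labels = seed_labels(feats, [f"seed{k}" for k in range(10)])
    assert labels.sum() == 40  # 10 seeds + 30 distinct neighbors

    # two identical seeds share their neighborhood: shared picks counted once
    X = np.zeros((6, 7))
    X[0] = X[1] = [1, 0, 0, 0, 0, 0, 0]
    X[2] = [1, 1e-6, 0, 0, 0, 0, 0]
    X[3] = [1, 0, 1e-6, 0, 0, 0, 0]
    X[4] = [1, 0, 0, 1e-6, 0, 0, 0]
    X[5] = [-1, 5, 5, 5, 5, 5, 5]
    feats = _features(X, ["a", "b", "w1", "w2", "w3", "far"])
    labels = seed_labels(feats, ["a", "b"])
    assert labels.sum() == 5  # 2 seeds + the 3 shared neighbors, not 8


def test_seed_identical_to_wt_sample_is_top_neighbor():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(20, 7))
    X[7] = X[0]  # WT sample 7 identical to seed 0
    feats = _features(X)
    labels = seed_labels(feats, ["s0", "s1"], n_neighbors=1)
    assert labels["s7"] == 1


def test_too_few_seeds_aborts():
    with pytest.raises(TrainingError):
        seed_labels(_features(np.zeros((5, 7))), ["s0"])


# --------------------------------------------------------------------------
# training steps
# --------------------------------------------------------------------------


def _separable(n=120, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, 7))
    X[:, 0] += 8 * y  # feature 0 fully separates the classes
    return _features(X), pd.Series(y, index=[f"s{i}" for i in range(n)])


def test_train_step_separable_and_deterministic():
    feats, y = _separable()
    fit1 = train_step(feats, y, grid=FAST_GRID, seed=3)
    assert fit1.cv_auc >= 0.99
    fit2 = train_step(feats, y, grid=FAST_GRID, seed=3)
    pd.testing.assert_series_equal(fit1.oof_scores, fit2.oof_scores)
    assert fit1.best_params == fit2.best_params


def test_train_step_shuffled_labels_auc_is_chance():
    """Permutation null: out-of-fold AUC ~ 0.5 averaged over 20 shuffles."""
    from sklearn.metrics import roc_auc_score

    feats, y = _separable(n=150)
    aucs = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        y_perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        fit = train_step(feats, y_perm, grid=FAST_GRID, seed=seed)
        aucs.append(roc_auc_score(y_perm, fit.oof_scores))
    assert abs(np.mean(aucs) - 0.5) < 0.05


def test_train_step_single_class_errors():
    feats, y = _separable()
    with pytest.raises(TrainingError):
        train_step(feats, pd.Series(1, index=feats.index), grid=FAST_GRID)


def test_relabel_rules_and_boundaries():
    scores = pd.Series([0.95, 0.05, 0.6], index=["neg_hi", "pos_lo", "stay"])
    labels = pd.Series([0, 1, 1], index=scores.index)
    new, flips = relabel(scores, labels, theta_hi=0.5, theta_lo=0.5)
    assert new["neg_hi"] == 1 and new["pos_lo"] == 0 and new["stay"] == 1
    assert flips == {"to_positive": 1, "to_negative": 1}
    new, flips = relabel(scores, labels, theta_hi=1.0 + 1e-9, theta_lo=0.0)
    assert flips["to_positive"] == 0  # threshold above 1: no upward flips


# --------------------------------------------------------------------------
# full protocol
# --------------------------------------------------------------------------


def _cohort_frames(seed=0, n_per_type=(80, 80, 20)):
    """Synthetic feature cohort: 3 types; the last is too small for its own
    model (4 seeds)."""
    rng = np.random.default_rng(seed)
    rows, names, ann, seeds = [], [], [], []
    for t, n in enumerate(n_per_type):
        hrd = rng.random(n) < 0.3
        X = rng.normal(size=(n, 7))
        X[:, 0] += 3 * hrd
        X[:, 4] += 4 * hrd
        for i in range(n):
            name = f"t{t}_{i}"
            names.append(name)
            rows.append(X[i])
            ann.append({"sample_id": name, "tumor_type": f"TYPE{t}"})
            if hrd[i] and (t < 2 or len([s for s in seeds if s.startswith("t2")]) < 4):
                seeds.append(name)
    feats = _features(np.array(rows), names)
    biallelic = pd.DataFrame(
        [{"sample_id": s, "gene": "BRCA1", "status": "biallelic_loss", "hits": "x,y"} for s in seeds]
    )
    return feats, pd.DataFrame(ann), biallelic


def test_small_type_falls_back_to_pooled_model():
    feats, ann, biallelic = _cohort_frames()
    cfg = ClassifierConfig(grid=FAST_GRID, seed=5)
    bundle = train_hrd_classifier(feats, ann, biallelic, cfg)
    assert "TYPE0" in bundle.by_type and "TYPE1" in bundle.by_type
    assert "TYPE2" not in bundle.by_type  # only 4 seeds -> pooled
    assert bundle.pooled is not None
    assert bundle.metadata["pooled_types"] == ["TYPE2"]
    # every cohort sample has both scores
    assert bundle.cohort_scores.notna().all().all()


@pytest.mark.parametrize(
    "pan, typ, expected",
    [(0.9, 0.8, "HRD"), (0.9, 0.2, "HRD_low"), (0.2, 0.9, "HRD_low"), (0.1, 0.1, "HRP")],
)
def test_score_combination_rule(pan, typ, expected):
    assert combine_scores(pan, typ, 0.5, 0.5) == expected


def test_finalize_override_and_accounting():
    labels = pd.DataFrame(
        {
            "sample_id": ["brca_hrp", "wt_hrp", "brca_hrd"],
            "label": ["HRP", "HRP", "HRD"],
            "pan_score": [0.1, 0.1, 0.9],
            "type_score": [0.2, 0.1, 0.9],
            "override": False,
        }
    )
    biallelic = pd.DataFrame(
        [
            {"sample_id": "brca_hrp", "gene": "BRCA2", "status": "biallelic_loss", "hits": ""},
            {"sample_id": "brca_hrd", "gene": "BRCA1", "status": "biallelic_loss", "hits": ""},
        ]
    )
    out, summary = finalize_labels(labels, biallelic)
    out = out.set_index("sample_id")
    assert out.loc["brca_hrp", "label"] == "HRD" and out.loc["brca_hrp", "override"]
    assert out.loc["wt_hrp", "label"] == "HRP" and not out.loc["wt_hrp", "override"]
    assert not out.loc["brca_hrd", "override"]  # already HRD: no override needed
    assert summary.n_overridden == 1 and summary.n_hrd_total == 2


def test_score_monotone_trend_in_scar_and_indel_features(recovery):
    """Perturbing GIS and MH-deletion counts upward should not decrease the
    pan-cancer score as a statistical trend over 100 samples."""
    bundle = recovery.pipeline.bundle
    feats = recovery.pipeline.features.features
    eligible = bundle.cohort_scores.index
    rng = np.random.default_rng(0)
    pick = rng.choice(len(eligible), size=100, replace=False)
    base = feats.loc[eligible[pick], FEATURE_COLUMNS]
    bumped = base.copy()
    bumped["gis"] += feats["gis"].std()
    bumped["n_del_mh"] += feats["n_del_mh"].std()
    delta = bundle.pan.score(bumped) - bundle.pan.score(base)
    assert delta.mean() >= 0
    # most samples move up or stay put (tiny numerical jitter tolerated)
    assert (delta >= -1e-6).mean() > 0.8
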