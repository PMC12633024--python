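"""Mutational features: catalogs, signature refitting, microhomology
counting, TMB, pathogenicity, triage and the artifact filter."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import likelihood_posterior_bruteforce, microhomology_bruteforce
from hrdscape.datatypes import MutationRecord, VariantClass
from hrdscape.signatures import (
    ArtifactFilterResult,
    Catalog96,
    NnlsResult,
    TriageThresholds,
    build_catalog,
    compute_tmb,
    cosine_to,
    count_microhomology_deletions,
    filter_artifact_samples,
    is_pathogenic,
    microhomology_length,
    nnls_exposures,
    sig3_likelihood,
    triage_hypermutation,
)
from hrdscape.spectra import CHANNELS, Spectrum96, default_panel


def snv(sample, ref, alt, ctx, **kw):
    return MutationRecord(sample, "1", 100, ref, alt, VariantClass.SNV, trinucleotide_context=ctx, **kw)


# --------------------------------------------------------------------------
# catalogs
# --------------------------------------------------------------------------


def test_catalog_strand_collapsing_and_conservation():
    cats = build_catalog([snv("s", "G", "A", "CGT")])
    assert cats["s"].counts[CHANNELS.index("A[C>T]G")] == 1
    assert cats["s"].total == 1


def test_empty_input_gives_zero_catalog():
    cats = build_catalog([], samples=["s"])
    assert cats["s"].total == 0 and cats["s"].counts.shape == (96,)


def test_catalog_sum_conserves_usable_snvs(small_cohort):
    """Every simulated SNV carries inline context, so catalog sums must
    equal per-sample SNV counts exactly (nothing excluded)."""
    cats = build_catalog(small_cohort.mutations)
    n_snv = {}
    for rec in small_cohort.mutations:
        if rec.variant_class is VariantClass.SNV:
            n_snv[rec.sample_id] = n_snv.get(rec.sample_id, 0) + 1
    for s, cat in cats.items():
        assert cat.total + cat.n_excluded == n_snv[s]
        assert cat.n_excluded == 0


def test_unresolvable_context_excluded_with_count():
    rec = MutationRecord("s", "1", 100, "G", "A", VariantClass.SNV)  # no context anywhere
    cats = build_catalog([rec])
    assert cats["s"].total == 0 and cats["s"].n_excluded == 1


# --------------------------------------------------------------------------
# signature-3 likelihood / cosine / NNLS
# --------------------------------------------------------------------------


@pytest.fixture(scope="module")
def pos_neg():
    panel = {s.name: s for s in default_panel()}
    return panel["sig3"], panel["background"]


def test_likelihood_symmetry_and_dominance(pos_neg):
    pos, _ = pos_neg
    counts = np.zeros(96)
    top = np.argsort(pos.probs)[-5:]
    counts[top] = 20
    cat = Catalog96("s", counts)
    assert sig3_likelihood(cat, pos, pos, 0.5) == pytest.approx(0.5)
    neg = Spectrum96.from_weights("flatneg", np.ones(96) + 5 * (np.arange(96) < 16))
    assert sig3_likelihood(cat, pos, neg, 0.5) > 0.5


def test_zero_catalog_returns_prior(pos_neg):
    pos, neg = pos_neg
    assert sig3_likelihood(Catalog96("s", np.zeros(96)), pos, neg, 0.37) == 0.37


def test_likelihood_matches_direct_product_oracle(pos_neg):
    pos, neg = pos_neg
    rng = np.random.default_rng(0)
    for _ in range(25):
        n = int(rng.integers(1, 21))  # small counts keep direct products stable
        counts = rng.multinomial(n, np.ones(96) / 96).astype(float)
        prior = float(rng.uniform(0.05, 0.95))
        got = sig3_likelihood(Catalog96("s", counts), pos, neg, prior)
        want = likelihood_posterior_bruteforce(counts, pos.probs, neg.probs, prior)
        assert got == pytest.approx(want, abs=1e-9)


def test_likelihood_monotone_in_prior(pos_neg):
    pos, neg = pos_neg
    rng = np.random.default_rng(1)
    cat = Catalog96("s", rng.multinomial(60, np.ones(96) / 96).astype(float))
    priors = np.linspace(0.01, 0.99, 25)
    scores = [sig3_likelihood(cat, pos, neg, p) for p in priors]
    assert all(b >= a for a, b in zip(scores, scores[1:]))


def test_cosine_extremes_and_oracle(pos_neg):
    pos, _ = pos_neg
    cat = Catalog96("s", 50 * pos.probs)
    assert cosine_to(cat, pos) == pytest.approx(1.0)
    disjoint = Spectrum96.from_weights("d", (np.arange(96) < 16).astype(float))
    counts = np.zeros(96)
    counts[50] = 10  # channel where the disjoint spectrum is 0
    assert cosine_to(Catalog96("s", counts), disjoint) == pytest.approx(0.0)
    rng = np.random.default_rng(2)
    counts = rng.integers(0, 9, size=96).astype(float)
    got = cosine_to(Catalog96("s", counts), pos)
    want = float(np.dot(counts, pos.probs) / (np.linalg.norm(counts) * np.linalg.norm(pos.probs)))
    assert got == pytest.approx(want)
    assert np.isnan(cosine_to(Catalog96("s", np.zeros(96)), pos))


def test_nnls_recovers_exact_mixture(panel):
    s1, s2 = panel[0], panel[2]
    cat = Catalog96("s", 30 * s1.probs + 70 * s2.probs)
    res = nnls_exposures(cat, panel)
    assert res.exposures[s1.name] == pytest.approx(30, abs=1e-6)
    assert res.exposures[s2.name] == pytest.approx(70, abs=1e-6)
    assert res.residual == pytest.approx(0, abs=1e-6)
    single = nnls_exposures(Catalog96("s", 50 * s1.probs), panel)
    assert single.exposures[s1.name] == pytest.approx(50, abs=1e-6)
    assert sum(v for k, v in single.exposures.items() if k != s1.name) == pytest.approx(0, abs=1e-6)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_nnls_exposure_sum_bounded(seed):
    """Exposures cannot exceed the catalog mass by more than the residual."""
    panel = default_panel()
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 30, size=96).astype(float)
    res = nnls_exposures(Catalog96("s", counts), panel)
    assert res.total <= counts.sum() + 96 * res.residual + 1e-6


# --------------------------------------------------------------------------
# microhomology
# --------------------------------------------------------------------------


def test_microhomology_examples():
    # prefix of the deleted sequence recurs at the start of the 3' flank
    assert microhomology_length("TAGGC", "GGGGGGG", "TAGCAXX".replace("X", "G")) == 3
    assert microhomology_length("AAAAA", "CCCCCCC", "GGGGGGG") == 0
    # a full-length match is a repeat unit: capped below deletion length
    assert microhomology_length("AAAAA", "CCCCCCC", "AAAAAGG") == 4


def test_microhomology_matches_overlap_scan_oracle():
    rng = np.random.default_rng(3)
    bases = "ACGT"
    for _ in range(1000):
        n = int(rng.integers(2, 12))
        deleted = "".join(bases[i] for i in rng.integers(0, 4, n))
        f5 = "".join(bases[i] for i in rng.integers(0, 2, 15))  # AC-rich: frequent overlaps
        f3 = "".join(bases[i] for i in rng.integers(0, 2, 15))
        assert microhomology_length(deleted, f5, f3) == microhomology_bruteforce(deleted, f5, f3)


def deletion(sample, deleted, f5, f3):
    return MutationRecord(
        sample, "1", 100, f5[-1] + deleted, f5[-1], VariantClass.DELETION,
        consequence="Frame_Shift_Del", flank_5p=f5, flank_3p=f3,
    )


def test_deletion_routing_by_size_and_mh():
    recs = [
        deletion("s", "TAGGC", "G" * 20, "TAGCA" + "G" * 15),  # MH 3 -> mh bucket
        deletion("s", "AAAAA", "C" * 20, "G" * 20),  # MH 0 -> no-mh bucket
        deletion("s", "ACGT", "C" * 20, "G" * 20),  # 4 bp: counted by neither
    ]
    feats = count_microhomology_deletions(recs)
    assert feats["s"].n_del_mh == 1
    assert feats["s"].n_del_no_mh == 1


def test_unresolvable_flanks_excluded():
    rec = MutationRecord("s", "1", 100, "GACGTA", "G", VariantClass.DELETION)
    feats = count_microhomology_deletions([rec], samples=["s"])
    assert feats["s"].n_del_mh == 0 and feats["s"].n_del_no_mh == 0


# --------------------------------------------------------------------------
# TMB / pathogenicity / triage / artifact filter
# --------------------------------------------------------------------------


def test_tmb_counts_nonsynonymous_per_mb():
    recs = [snv("s", "C", "T", "ACA", gene=None) for _ in range(50)]
    for r in recs[:38]:
        r.consequence = "Missense_Mutation"
    for r in recs[38:76 - 38]:
        r.consequence = "Nonsense_Mutation"
    for r in recs[76 - 38:]:
        r.consequence = "Silent"
    recs = recs * 2  # 76 nonsynonymous + 48 silent
    assert compute_tmb(recs, footprint_mb=38.0)["s"] == pytest.approx(2.0)
    assert compute_tmb([], footprint_mb=38.0, samples=["s"])["s"] == 0.0
    silent_only = [snv("s", "C", "T", "ACA")]
    silent_only[0].consequence = "Silent"
    assert compute_tmb(silent_only, 38.0)["s"] == 0.0
    with pytest.raises(ValueError):
        compute_tmb([], footprint_mb=0)


@pytest.mark.parametrize(
    "consequence, sift, polyphen, clinvar, expected",
    [
        ("Nonsense_Mutation", None, None, None, True),
        ("Frame_Shift_Del", None, None, None, True),
        ("Missense_Mutation", "deleterious(0)", "benign(0.1)", None, False),
        ("Missense_Mutation", "deleterious(0)", "probably_damaging(0.99)", None, True),
        ("Missense_Mutation", None, None, "likely_pathogenic", True),
        ("Missense_Mutation", None, None, "pathogenic", True),
        ("Frame_Shift_Del", None, None, "benign", False),  # ClinVar Benign vetoes all routes
        ("Missense_Mutation", "deleterious(0)", "probably_damaging(1)", "benign", False),
        ("Silent", None, None, None, False),
    ],
)
def test_pathogenicity_filter(consequence, sift, polyphen, clinvar, expected):
    is_del = "Del" in consequence
    rec = MutationRecord(
        "s", "1", 10,
        "CA" if is_del else "C",
        "C" if is_del else "T",
        VariantClass.DELETION if is_del else VariantClass.SNV,
        consequence=consequence, sift=sift, polyphen=polyphen, clinvar=clinvar,
    )
    assert is_pathogenic(rec) is expected


def _nnls(fractions):
    total = 100.0
    return NnlsResult(exposures={k: v * total for k, v in fractions.items()}, residual=0.0)


def test_triage_rules():
    cat = Catalog96("s", np.ones(96))
    th = TriageThresholds()
    exp = _nnls({"mmr": 0.1, "pole": 0.1, "background": 0.8})
    assert triage_hypermutation(cat, exp, msi_score=5.0, tmb=1.0, thresholds=th).cls == "MMRD"
    exp = _nnls({"mmr": 0.05, "pole": 0.8, "background": 0.15})
    assert triage_hypermutation(cat, exp, msi_score=0.1, tmb=120.0, thresholds=th).cls == "POLE"
    exp = _nnls({"mmr": 0.05, "pole": 0.05, "background": 0.9})
    assert triage_hypermutation(cat, exp, msi_score=0.1, tmb=1.0, thresholds=th).cls == "MMRP"
    # missing MSI degrades to the signature-only branch
    exp = _nnls({"mmr": 0.5, "pole": 0.0, "background": 0.5})
    assert triage_hypermutation(cat, exp, msi_score=None, tmb=20.0, thresholds=th).cls == "MMRD"
    assert triage_hypermutation(cat, exp, msi_score=None, tmb=1.0, thresholds=th).cls == "MMRP"


def test_artifact_filter_threshold_and_accounting():
    exposures = {
        "keep": _nnls({"sbs45": 0.0, "background": 1.0}),
        "drop": _nnls({"sbs45": 0.6, "background": 0.4}),
    }
    res = filter_artifact_samples(exposures, 0.2)
    assert res.excluded == frozenset({"drop"})
    # printed exclusion rate for a 10,308-sample run flagging 94
    big = {f"k{i}": _nnls({"sbs45": 0.6 if i < 94 else 0.0, "background": 1.0}) for i in range(10308)}
    res = filter_artifact_samples(big, 0.2)
    assert res.n_excluded == 94
    assert f"{res.exclusion_rate_pct:.1f}" == "0.9"
    assert "94/10308, 0.9%" in res.summary()
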