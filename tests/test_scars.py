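"""Copy-number baselines, scar scores, bin profiles, gene calls, region
statistics and co-occurrence tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracles import fisher_exact_bruteforce, random_segment_genome, scars_bruteforce
from hrdscape.datatypes import GenomeBuild, default_genome
from hrdscape.scars import (
    GeneCnaParams,
    NoQualifyingSegments,
    ScarParams,
    bh_adjust,
    bin_profile,
    cohort_bin_profiles,
    compute_baseline,
    compute_scars,
    cooccurrence,
    differential_regions,
    gene_calls,
    genome_bins,
    group_region_stats,
)

MB = 1_000_000


def seg_frame(rows, sample="s1"):
    return pd.DataFrame(
        [(sample, c, s, e, ma, mi) for c, s, e, ma, mi in rows],
        columns=["sample_id", "chrom", "start", "end", "major", "minor"],
    )


# --------------------------------------------------------------------------
# baselines
# --------------------------------------------------------------------------


def test_baseline_weighted_means():
    segs = seg_frame([("1", 0, 10 * MB, 2, 1), ("2", 0, 10 * MB, 4, 1)])
    b = compute_baseline(segs)
    assert b.major == pytest.approx(3.0)  # equal qualifying coverage -> midpoint
    assert b.minor == pytest.approx(1.0)
    assert b.total == pytest.approx(4.0)


def test_baseline_single_segment_and_short_filter():
    b = compute_baseline(seg_frame([("1", 0, 5 * MB, 2, 1)]))
    assert (b.major, b.minor, b.total) == (2, 1, 3)
    # a 50-kb-only chromosome contributes nothing
    segs = seg_frame([("1", 0, 5 * MB, 2, 1), ("2", 0, 50_000, 8, 8)])
    b = compute_baseline(segs)
    assert b.major == 2 and "2" not in b.per_chromosome
    with pytest.raises(NoQualifyingSegments):
        compute_baseline(seg_frame([("1", 0, 50_000, 2, 1)]))


def test_flat_genome_baseline_is_exact(genome):
    """A uniformly (2,1) genome has baseline (2,1) and all amp_dev == 0."""
    rows = [(c, 0, genome.lengths[c], 2, 1) for c in genome.autosomes()]
    segs = seg_frame(rows)
    b = compute_baseline(segs)
    assert b.major == pytest.approx(2) and b.minor == pytest.approx(1)
    prof = bin_profile(segs, genome, b, sex="female")
    covered = prof["amp_dev"].notna()
    assert covered.any()
    assert np.allclose(prof.loc[covered, "amp_dev"], 0.0)


# --------------------------------------------------------------------------
# scar scores
# --------------------------------------------------------------------------


@pytest.fixture(scope="module")
def simple_genome():
    return GenomeBuild(lengths={"1": 120 * MB}, centromeres={"1": (55 * MB, 60 * MB)})


def test_interstitial_loh_counts_once(simple_genome):
    segs = seg_frame(
        [("1", 0, 20 * MB, 1, 1), ("1", 20 * MB, 40 * MB, 2, 0), ("1", 40 * MB, 120 * MB, 1, 1)]
    )
    s = compute_scars(segs, simple_genome)
    assert s.n_loh_segments == 1


def test_whole_chromosome_loh_excluded(simple_genome):
    segs = seg_frame([("1", 0, 120 * MB, 2, 0)])
    s = compute_scars(segs, simple_genome)
    assert s.n_loh_segments == 0


def test_lst_breakpoint_between_large_segments(simple_genome):
    # both flanks >= 10 Mb inside the p-arm
    segs = seg_frame(
        [("1", 0, 12 * MB, 1, 1), ("1", 12 * MB, 27 * MB, 2, 1), ("1", 27 * MB, 120 * MB, 1, 1)]
    )
    s = compute_scars(segs, simple_genome)
    assert s.n_lst >= 1


def test_tai_telomeric_imbalance(simple_genome):
    # terminal AI segment on the q side, not crossing the centromere
    segs = seg_frame([("1", 0, 100 * MB, 1, 1), ("1", 100 * MB, 120 * MB, 2, 1)])
    s = compute_scars(segs, simple_genome)
    assert s.n_tai == 1
    # an AI segment spanning the whole chromosome crosses the centromere: no TAI
    s = compute_scars(seg_frame([("1", 0, 120 * MB, 2, 1)]), simple_genome)
    assert s.n_tai == 0


def test_gis_is_sum_of_parts(simple_genome):
    segs = seg_frame(
        [("1", 0, 20 * MB, 2, 0), ("1", 20 * MB, 40 * MB, 1, 1), ("1", 40 * MB, 120 * MB, 2, 1)]
    )
    s = compute_scars(segs, simple_genome)
    assert s.gis == s.n_loh_segments + s.n_tai + s.n_lst


def test_scars_match_bruteforce_oracle_on_random_genomes(genome):
    rng = np.random.default_rng(11)
    params = ScarParams()
    for _ in range(200):
        by_chrom = random_segment_genome(rng, dict(genome.lengths))
        rows = [(c, s, e, ma, mi) for c, segs in by_chrom.items() for s, e, ma, mi in segs]
        got = compute_scars(seg_frame(rows), genome, params)
        want = scars_bruteforce(by_chrom, dict(genome.lengths), dict(genome.centromeres))
        assert (got.n_loh_segments, got.n_tai, got.n_lst) == want


def test_gis_invariant_under_value_preserving_splits(genome):
    rng = np.random.default_rng(12)
    for _ in range(20):
        by_chrom = random_segment_genome(rng, dict(genome.lengths))
        rows = [(c, s, e, ma, mi) for c, segs in by_chrom.items() for s, e, ma, mi in segs]
        base = compute_scars(seg_frame(rows), genome)
        split_rows = []
        for c, s, e, ma, mi in rows:
            if e - s > 2 and rng.random() < 0.5:
                cut = int(rng.integers(s + 1, e))
                split_rows += [(c, s, cut, ma, mi), (c, cut, e, ma, mi)]
            else:
                split_rows.append((c, s, e, ma, mi))
        split = compute_scars(seg_frame(split_rows), genome)
        assert (split.n_loh_segments, split.n_tai, split.n_lst) == (
            base.n_loh_segments, base.n_tai, base.n_lst,
        )


# --------------------------------------------------------------------------
# bin profiles
# --------------------------------------------------------------------------


def test_bin_weighted_minor_and_loh_flag(genome):
    segs = seg_frame(
        [("1", 0, 60_000, 2, 1), ("1", 60_000, 200_000, 2, 0)]
    )
    b = compute_baseline(seg_frame([("1", 0, 200 * MB, 2, 1)]))
    prof = bin_profile(segs, genome, b, sex="female")
    first = prof[(prof["chrom"] == "1") & (prof["start"] == 0)].iloc[0]
    assert first["minor"] == pytest.approx(0.6)  # 60 kb at 1 + 40 kb at 0
    assert first["loh"] == 1.0  # weighted minor < 1
    second = prof[(prof["chrom"] == "1") & (prof["start"] == 100_000)].iloc[0]
    assert second["loh"] == 1.0 and second["minor"] == pytest.approx(0.0)


def test_bin_full_minor_one_is_not_loh(genome):
    segs = seg_frame([("1", 0, 100_000, 2, 1)])
    b = compute_baseline(seg_frame([("1", 0, 200 * MB, 2, 1)]))
    prof = bin_profile(segs, genome, b, sex="female")
    assert prof.iloc[0]["loh"] == 0.0


def test_sex_chromosome_handling(genome):
    rows = [(c, 0, genome.lengths[c], 2, 1) for c in genome.chromosomes if c != "Y"]
    segs = seg_frame(rows)
    b = compute_baseline(segs)
    male = bin_profile(segs, genome, b, sex="male")
    female = bin_profile(segs, genome, b, sex="female")
    assert male.loc[male["chrom"] == "X", "minor"].isna().all()  # X missing in males
    assert female.loc[female["chrom"] == "X", "minor"].notna().all()
    assert "Y" not in set(male["chrom"])  # Y never profiled


def test_uncovered_bins_are_missing_not_zero(genome):
    segs = seg_frame([("1", 0, 10 * MB, 2, 1)])
    b = compute_baseline(segs)
    prof = bin_profile(segs, genome, b, sex="female")
    far = prof[(prof["chrom"] == "1") & (prof["start"] >= 50 * MB)]
    assert far["minor"].isna().all() and far["loh"].isna().all()


def test_bin_loh_fraction_matches_segment_coverage(genome):
    """Chromosome-wide LOH fraction from bins equals the segment-level LOH
    coverage fraction up to bin-edge discretization."""
    segs = seg_frame(
        [("1", 0, 37_300_000, 1, 0), ("1", 37_300_000, 200 * MB, 1, 1)]
    )
    b = compute_baseline(segs)
    prof = bin_profile(segs, genome, b, sex="female")
    sub = prof[prof["chrom"] == "1"]
    frac = np.nanmean(sub["loh"])
    assert frac == pytest.approx(37.3 / 200, abs=100_000 / (200 * MB) + 1e-9)


# --------------------------------------------------------------------------
# gene calls
# --------------------------------------------------------------------------


def test_gene_call_rules():
    genes = pd.DataFrame(
        [("FOCAL", "1", 10 * MB, 10 * MB + 100_000), ("BROAD", "2", 10 * MB, 10 * MB + 100_000),
         ("LOHG", "3", MB, 2 * MB), ("DEEP", "4", MB, 2 * MB), ("NOCOV", "1", 150 * MB, 151 * MB)],
        columns=["gene", "chrom", "start", "end"],
    )
    focal_len = int(10 ** 6.4)
    segs = seg_frame(
        [
            ("1", 10 * MB - focal_len // 2, 10 * MB + focal_len - focal_len // 2, 4, 1),
            ("2", 5 * MB, 5 * MB + 10 ** 7, 4, 1),
            ("3", 0, 5 * MB, 2, 0),
            ("4", 0, 5 * MB, 0.2, 0.1),
        ]
    )
    baseline = compute_baseline(seg_frame([("1", 0, 100 * MB, 2, 1)]))  # total 3
    calls = gene_calls(segs, genes, baseline).set_index("gene")
    assert calls.loc["FOCAL", "relative_amp"] and calls.loc["FOCAL", "focal_amp"]
    assert calls.loc["BROAD", "relative_amp"] and not calls.loc["BROAD", "focal_amp"]
    assert calls.loc["LOHG", "loh"] and not calls.loc["LOHG", "relative_amp"]
    assert calls.loc["DEEP", "deep_deletion"]
    assert "NOCOV" not in calls.index  # no covering segment -> missing call
    # invariant: focal implies relative
    assert not (calls["focal_amp"] & ~calls["relative_amp"]).any()


# --------------------------------------------------------------------------
# region statistics and differential regions
# --------------------------------------------------------------------------


def _profiles_for(loh_rows, genome):
    """Build CohortBinProfiles from an explicit {sample: rows} dict."""
    frames = []
    for sample, rows in loh_rows.items():
        frames.append(seg_frame(rows, sample=sample))
    segs = pd.concat(frames, ignore_index=True)
    from hrdscape.scars import compute_baselines

    baselines = compute_baselines(segs)
    return cohort_bin_profiles(segs, genome, baselines, {s: "female" for s in loh_rows})


def test_group_region_stats_identical_and_separated(genome):
    full = [("1", 0, 200 * MB, 1, 0)]
    none = [("1", 0, 200 * MB, 1, 1)]
    profiles = _profiles_for(
        {"a1": full, "a2": full, "a3": none, "b1": full, "b2": full, "b3": none}, genome
    )
    regions = pd.DataFrame([("1", 0, 50 * MB)], columns=["chrom", "start", "end"])
    out = group_region_stats(profiles, {"A": ["a1", "a2", "a3"], "B": ["b1", "b2", "b3"]}, regions)
    assert out["loh_fraction_t"].iloc[0] == pytest.approx(0.0, abs=1e-9)
    assert out["loh_fraction_p"].iloc[0] == pytest.approx(1.0)

    profiles = _profiles_for(
        {"a1": full, "a2": full, "b1": none, "b2": none}, genome
    )
    out = group_region_stats(profiles, {"A": ["a1", "a2"], "B": ["b1", "b2"]}, regions)
    row = out.iloc[0]
    assert row["loh_fraction_A"] == pytest.approx(1.0)
    assert row["loh_fraction_B"] == pytest.approx(0.0)
    assert row["loh_fraction_degenerate"]  # zero variance in both arms


def test_differential_regions_min_span_larger_than_genome(genome):
    full = [("1", 0, 200 * MB, 1, 0)]
    none = [("1", 0, 200 * MB, 1, 1)]
    profiles = _profiles_for({"a1": full, "a2": full, "b1": none, "b2": none}, genome)
    out = differential_regions(
        profiles, {"A": ["a1", "a2"], "B": ["b1", "b2"]}, min_span_bins=10**6
    )
    assert out.empty


def test_bh_adjust_properties():
    p = np.array([0.01, 0.01, 0.01])
    assert np.allclose(bh_adjust(p), 0.01)  # m equal p-values stay equal
    rng = np.random.default_rng(5)
    p = rng.uniform(size=50)
    q = bh_adjust(p)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)  # monotone in p
    assert q[order][-1] == pytest.approx(p[order][-1])  # max q equals max p
    sm_q = stats.false_discovery_control(p)  # independent reference
    assert np.allclose(q, sm_q)


# --------------------------------------------------------------------------
# co-occurrence
# --------------------------------------------------------------------------


def test_cooccurrence_closed_form_and_independence():
    a = np.repeat([True, True, False, False], [30, 70, 10, 90])
    b = np.repeat([True, False, True, False], [30, 70, 10, 90])
    res = cooccurrence(a, b)
    assert res.odds_ratio == pytest.approx(30 * 90 / (70 * 10))
    a = np.repeat([True, True, False, False], [25, 25, 25, 25])
    b = np.repeat([True, False, True, False], [25, 25, 25, 25])
    res = cooccurrence(a, b)
    assert res.odds_ratio == pytest.approx(1.0)
    assert res.p_value == pytest.approx(1.0)


def test_cooccurrence_degenerate_and_haldane():
    res = cooccurrence([True] * 5, [True, False, True, False, True])
    assert res.degenerate and res.p_value == 1.0 and np.isnan(res.odds_ratio)
    res = cooccurrence([True, True, False, False], [True, True, True, False])
    assert res.haldane_corrected  # one empty cell
    assert np.isfinite(res.odds_ratio)


def test_fisher_p_matches_enumeration_oracle():
    rng = np.random.default_rng(6)
    for _ in range(60):
        n = int(rng.integers(8, 41))
        a = rng.random(n) < rng.uniform(0.2, 0.8)
        b = rng.random(n) < rng.uniform(0.2, 0.8)
        if a.all() or (~a).all() or b.all() or (~b).all():
            continue
        res = cooccurrence(a, b)
        assert res.p_value == pytest.approx(fisher_exact_bruteforce(res.table), rel=1e-9)
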