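"""Copy-number baselines, genomic scar scores, binned LOH/amplification
profiles, gene-level calls and region statistics.

Scar definitions follow the conventions of the original scar publications:

* HRD-LOH — loss-of-heterozygosity regions (weighted minor copy number < 1)
  longer than 15 Mb that do not span a whole chromosome;
* TAI — allelic-imbalance segments (major != minor) that reach a telomere
  (first or last segment of the chromosome) without crossing the centromere;
* LST — breakpoints between adjacent copy-number states each >= 10 Mb after
  removal of segments < 3 Mb, counted per chromosome arm;
* GIS — the sum of the three.

All intervals are 0-based half-open; ``length == end - start``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from hrdscape.datatypes import GenomeBuild

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# baselines
# --------------------------------------------------------------------------

#: Segments at or below this length are ignored when computing baselines.
BASELINE_MIN_SEGMENT_BP = 100_000


@dataclass(frozen=True)
class SampleBaseline:
    """Length-weighted mean allele-specific copy number of one sample.

    ``per_chromosome`` maps chromosome -> (major, minor, qualifying coverage
    in bp); the sample-level values aggregate chromosomes weighted by that
    coverage.  ``total`` is major + minor.
    """

    sample_id: str
    major: float
    minor: float
    per_chromosome: Dict[str, Tuple[float, float, int]]

    @property
    def total(self) -> float:
        return self.major + self.minor


class NoQualifyingSegments(ValueError):
    """Raised when a sample has no segment above the baseline length filter."""


def compute_baseline(
    segments: pd.DataFrame, min_segment_bp: int = BASELINE_MIN_SEGMENT_BP
) -> SampleBaseline:
    """Segment-length-weighted copy-number baseline for one sample.

    Chromosome means use only segments longer than ``min_segment_bp``; the
    sample mean weights chromosomes by their qualifying coverage, so it
    equals the genome-wide length-weighted mean over qualifying segments.
    Chromosomes with no qualifying segment contribute nothing.
    """
    sample_ids = segments["sample_id"].unique()
    if len(sample_ids) != 1:
        raise ValueError("compute_baseline expects the segments of exactly one sample")
    lengths = segments["end"] - segments["start"]
    keep = segments[lengths > min_segment_bp]
    if keep.empty:
        raise NoQualifyingSegments(
            f"sample {sample_ids[0]} has no segment longer than {min_segment_bp} bp"
        )
    per_chrom: Dict[str, Tuple[float, float, int]] = {}
    for chrom, sub in keep.groupby("chrom", sort=False):
        w = (sub["end"] - sub["start"]).to_numpy(float)
        per_chrom[chrom] = (
            float(np.average(sub["major"], weights=w)),
            float(np.average(sub["minor"], weights=w)),
            int(w.sum()),
        )
    cov = np.array([c for _, _, c in per_chrom.values()], dtype=float)
    majors = np.array([m for m, _, _ in per_chrom.values()])
    minors = np.array([m for _, m, _ in per_chrom.values()])
    return SampleBaseline(
        sample_id=str(sample_ids[0]),
        major=float(np.average(majors, weights=cov)),
        minor=float(np.average(minors, weights=cov)),
        per_chromosome=per_chrom,
    )


def compute_baselines(segments: pd.DataFrame) -> Dict[str, SampleBaseline]:
    """Baselines for every sample; samples with no qualifying segment are
    dropped with a logged reason."""
    out: Dict[str, SampleBaseline] = {}
    for sample, sub in segments.groupby("sample_id", sort=False):
        try:
            out[sample] = compute_baseline(sub)
        except NoQualifyingSegments as exc:
            logger.warning("excluding sample from baselines: %s", exc)
    return out


# --------------------------------------------------------------------------
# scar scores
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ScarScores:
    sample_id: str
    n_loh_segments: int
    n_tai: int
    n_lst: int

    @property
    def gis(self) -> int:
        return self.n_loh_segments + self.n_tai + self.n_lst


@dataclass(frozen=True)
class ScarParams:
    loh_min_bp: int = 15_000_000
    lst_min_bp: int = 10_000_000
    lst_smooth_bp: int = 3_000_000
    #: an LOH region covering at least this fraction of its chromosome counts
    #: as whole-chromosome LOH and is excluded from HRD-LOH
    whole_chrom_fraction: float = 0.99


def _merge_runs(rows: List[Tuple[int, int, float, float]]) -> List[Tuple[int, int, float, float]]:
    """Merge abutting segments with identical (major, minor)."""
    merged: List[Tuple[int, int, float, float]] = []
    for start, end, major, minor in rows:
        if merged and merged[-1][1] == start and merged[-1][2:] == (major, minor):
            prev = merged.pop()
            merged.append((prev[0], end, major, minor))
        else:
            merged.append((start, end, major, minor))
    return merged


def compute_scars(
    segments: pd.DataFrame,
    genome: GenomeBuild,
    params: ScarParams = ScarParams(),
) -> ScarScores:
    """HRD-LOH / TAI / LST scar scores for one sample.

    Chromosomes without a centromere interval in the genome build are
    skipped for TAI and LST with a warning (LOH is still counted there).
    """
    sample_ids = segments["sample_id"].unique()
    if len(sample_ids) != 1:
        raise ValueError("compute_scars expects the segments of exactly one sample")
    n_loh = n_tai = n_lst = 0
    for chrom, sub in segments.groupby("chrom", sort=False):
        chrom_len = genome.lengths.get(chrom)
        rows = list(
            zip(
                sub["start"].astype(int),
                sub["end"].astype(int),
                sub["major"].astype(float),
                sub["minor"].astype(float),
            )
        )
        merged = _merge_runs(rows)

        # HRD-LOH: contiguous minor<1 runs > 15 Mb, not a whole chromosome
        loh_runs: List[Tuple[int, int]] = []
        for start, end, _major, minor in merged:
            if minor < 1:
                if loh_runs and loh_runs[-1][1] == start:
                    loh_runs[-1] = (loh_runs[-1][0], end)
                else:
                    loh_runs.append((start, end))
        for start, end in loh_runs:
            if end - start <= params.loh_min_bp:
                continue
            if chrom_len is not None and (end - start) >= params.whole_chrom_fraction * chrom_len:
                continue
            n_loh += 1

        cen = genome.centromeres.get(chrom)
        if cen is None:
            logger.warning("no centromere for chromosome %s; skipping TAI/LST there", chrom)
            continue
        cen_start, cen_end = cen

        # TAI: allelic-imbalance segment at either chromosome end that does
        # not span the centromere
        if merged:
            for start, end, major, minor in {merged[0], merged[-1]}:
                if major == minor:
                    continue
                if start < cen_start and end > cen_end:
                    continue
                n_tai += 1

        # LST: per arm, drop short segments, re-merge identical states, count
        # transitions with >= 10 Mb on both sides and a gap <= the smoothing
        # window
        for arm_start, arm_end in ((0, cen_start), (cen_end, chrom_len or merged[-1][1])):
            arm = []
            for start, end, major, minor in merged:
                s, e = max(start, arm_start), min(end, arm_end)
                if e - s > 0:
                    arm.append((s, e, major, minor))
            arm = [seg for seg in arm if seg[1] - seg[0] >= params.lst_smooth_bp]
            smoothed: List[Tuple[int, int, float, float]] = []
            for seg in arm:
                if smoothed and smoothed[-1][2:] == seg[2:]:
                    prev = smoothed.pop()
                    smoothed.append((prev[0], seg[1], seg[2], seg[3]))
                else:
                    smoothed.append(seg)
            for left, right in zip(smoothed, smoothed[1:]):
                gap = right[0] - left[1]
                if (
                    gap <= params.lst_smooth_bp
                    and left[1] - left[0] >= params.lst_min_bp
                    and right[1] - right[0] >= params.lst_min_bp
                ):
                    n_lst += 1
    return ScarScores(
        sample_id=str(sample_ids[0]), n_loh_segments=n_loh, n_tai=n_tai, n_lst=n_lst
    )


def compute_scars_cohort(
    segments: pd.DataFrame, genome: GenomeBuild, params: ScarParams = ScarParams()
) -> pd.DataFrame:
    rows = []
    for sample, sub in segments.groupby("sample_id", sort=False):
        s = compute_scars(sub, genome, params)
        rows.append((sample, s.n_loh_segments, s.n_tai, s.n_lst, s.gis))
    return pd.DataFrame(
        rows, columns=["sample_id", "n_loh_segments", "n_tai", "n_lst", "gis"]
    ).set_index("sample_id")


# --------------------------------------------------------------------------
# 100-kb bin profiles
# --------------------------------------------------------------------------

BIN_SIZE = 100_000


def genome_bins(genome: GenomeBuild, binsize: int = BIN_SIZE, include_x: bool = True) -> pd.DataFrame:
    """Fixed bin index over the genome (Y always excluded)."""
    rows = []
    for chrom, length in genome.lengths.items():
        if chrom == "Y" or (chrom == "X" and not include_x):
            continue
        nbins = (length + binsize - 1) // binsize
        for b in range(nbins):
            rows.append((chrom, b * binsize, min((b + 1) * binsize, length)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def bin_profile(
    segments: pd.DataFrame,
    genome: GenomeBuild,
    baseline: SampleBaseline,
    sex: str = "unknown",
    binsize: int = BIN_SIZE,
) -> pd.DataFrame:
    """Per-bin weighted minor/major, LOH flag and baseline-corrected
    amplification deviation for one sample.

    Bins with zero segment coverage are missing (NaN), not zero.  The Y
    chromosome is dropped; the X chromosome is profiled only for female
    samples (per-sample LOH on X is not interpretable in males).
    """
    bins = genome_bins(genome, binsize)
    out = {}
    for col in ("minor", "major", "coverage"):
        out[col] = np.full(len(bins), np.nan)
    offsets = {}
    pos = 0
    for chrom, sub in bins.groupby("chrom", sort=False):
        offsets[chrom] = (pos, len(sub))
        pos += len(sub)
    for chrom, sub in segments.groupby("chrom", sort=False):
        if chrom == "Y":
            continue
        if chrom == "X" and sex != "female":
            continue
        if chrom not in offsets:
            continue
        off, nbins = offsets[chrom]
        chrom_len = genome.lengths[chrom]
        cov = np.zeros(nbins)
        minor_sum = np.zeros(nbins)
        major_sum = np.zeros(nbins)
        for start, end, major, minor in zip(
            sub["start"].astype(int), sub["end"].astype(int), sub["major"], sub["minor"]
        ):
            end = min(end, chrom_len)
            b0, b1 = start // binsize, (end - 1) // binsize
            idx = np.arange(b0, b1 + 1)
            bs = idx * binsize
            be = np.minimum(bs + binsize, chrom_len)
            ov = np.minimum(end, be) - np.maximum(start, bs)
            cov[idx] += ov
            minor_sum[idx] += ov * minor
            major_sum[idx] += ov * major
        covered = cov > 0
        sl = slice(off, off + nbins)
        out["coverage"][sl] = cov
        out["minor"][sl][covered] = minor_sum[covered] / cov[covered]
        out["major"][sl][covered] = major_sum[covered] / cov[covered]
    prof = bins.copy()
    prof["minor"] = out["minor"]
    prof["major"] = out["major"]
    width = (prof["end"] - prof["start"]).to_numpy(float)
    prof["coverage_fraction"] = np.where(np.isnan(out["coverage"]), 0.0, out["coverage"]) / width
    minor_arr = prof["minor"].to_numpy(float)
    with np.errstate(invalid="ignore"):
        prof["loh"] = np.where(np.isnan(minor_arr), np.nan, (minor_arr < 1).astype(float))
    prof["amp_dev"] = prof["major"] - baseline.major
    return prof


@dataclass
class CohortBinProfiles:
    """Stacked bin profiles: ``loh`` and ``amp`` are samples x bins float
    matrices (NaN = missing bin), ``bins`` indexes the columns."""

    bins: pd.DataFrame
    samples: List[str]
    loh: np.ndarray
    amp: np.ndarray

    def region_mask(self, chrom: str, start: int, end: int) -> np.ndarray:
        b = self.bins
        return ((b["chrom"] == chrom) & (b["end"] > start) & (b["start"] < end)).to_numpy()


def cohort_bin_profiles(
    segments: pd.DataFrame,
    genome: GenomeBuild,
    baselines: Dict[str, SampleBaseline],
    sex_by_sample: Optional[Dict[str, str]] = None,
    binsize: int = BIN_SIZE,
) -> CohortBinProfiles:
    bins = genome_bins(genome, binsize)
    samples = [s for s in segments["sample_id"].unique() if s in baselines]
    loh = np.full((len(samples), len(bins)), np.nan)
    amp = np.full((len(samples), len(bins)), np.nan)
    sex_by_sample = sex_by_sample or {}
    for i, sample in enumerate(samples):
        prof = bin_profile(
            segments[segments["sample_id"] == sample],
            genome,
            baselines[sample],
            sex=sex_by_sample.get(sample, "unknown"),
            binsize=binsize,
        )
        loh[i] = prof["loh"].to_numpy(float)
        amp[i] = prof["amp_dev"].to_numpy(float)
    return CohortBinProfiles(bins=bins, samples=samples, loh=loh, amp=amp)


# --------------------------------------------------------------------------
# gene-level calls
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneCnaParams:
    #: copies above the sample baseline total that count as amplification
    amp_gain: float = 2.0
    #: log10(segment length) below which an amplification is focal
    focal_log10_length: float = 6.5
    #: total copy number below which a deep (biallelic) deletion is called
    deep_deletion_total: float = 0.5


def gene_calls(
    segments: pd.DataFrame,
    gene_coords: pd.DataFrame,
    baseline: SampleBaseline,
    params: GeneCnaParams = GeneCnaParams(),
) -> pd.DataFrame:
    """Gene-level CNA calls for one sample.

    Each gene takes the values of the segment containing its midpoint; genes
    with no covering segment are omitted (missing call).  Booleans follow
    the relative/focal amplification, LOH (minor < 1) and deep-deletion
    rules.
    """
    rows = []
    by_chrom = {c: sub.sort_values("start") for c, sub in segments.groupby("chrom", sort=False)}
    for gene, chrom, gstart, gend in zip(
        gene_coords["gene"], gene_coords["chrom"], gene_coords["start"], gene_coords["end"]
    ):
        mid = (int(gstart) + int(gend)) // 2
        sub = by_chrom.get(chrom)
        if sub is None:
            continue
        starts = sub["start"].to_numpy()
        k = int(np.searchsorted(starts, mid, side="right")) - 1
        if k < 0 or sub["end"].iloc[k] <= mid:
            continue
        seg = sub.iloc[k]
        total = float(seg["major"] + seg["minor"])
        seg_len = int(seg["end"] - seg["start"])
        relative_amp = total >= baseline.total + params.amp_gain
        focal_amp = relative_amp and np.log10(seg_len) < params.focal_log10_length
        rows.append(
            {
                "gene": gene,
                "total_cn": total,
                "relative_amp": relative_amp,
                "focal_amp": focal_amp,
                "loh": float(seg["minor"]) < 1,
                "deep_deletion": total < params.deep_deletion_total,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene", "total_cn", "relative_amp", "focal_amp", "loh", "deep_deletion"]
    )


def gene_calls_cohort(
    segments: pd.DataFrame,
    gene_coords: pd.DataFrame,
    baselines: Dict[str, SampleBaseline],
    params: GeneCnaParams = GeneCnaParams(),
) -> pd.DataFrame:
    frames = []
    for sample, sub in segments.groupby("sample_id", sort=False):
        if sample not in baselines:
            continue
        calls = gene_calls(sub, gene_coords, baselines[sample], params)
        calls.insert(0, "sample_id", sample)
        frames.append(calls)
    if not frames:
        return pd.DataFrame(
            columns=["sample_id", "gene", "total_cn", "relative_amp", "focal_amp", "loh", "deep_deletion"]
        )
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# region statistics and differential regions
# --------------------------------------------------------------------------


def _t_ci(values: np.ndarray, level: float = 0.95) -> Tuple[float, float, float]:
    """(mean, lo, hi) of a one-sample t confidence interval."""
    values = values[~np.isnan(values)]
    n = len(values)
    mean = float(values.mean()) if n else float("nan")
    if n < 2 or np.std(values, ddof=1) == 0:
        return mean, mean, mean
    se = float(np.std(values, ddof=1) / np.sqrt(n))
    tq = stats.t.ppf(0.5 + level / 2, n - 1)
    return mean, mean - tq * se, mean + tq * se


def region_sample_summaries(
    profiles: CohortBinProfiles, chrom: str, start: int, end: int
) -> pd.DataFrame:
    """Per-sample LOH fraction (over non-missing bins) and mean amplification
    deviation within a region."""
    mask = profiles.region_mask(chrom, start, end)
    if not mask.any():
        raise ValueError(f"region {chrom}:{start}-{end} overlaps no bins")
    with np.errstate(invalid="ignore"):
        loh_frac = np.nanmean(profiles.loh[:, mask], axis=1)
        amp_mean = np.nanmean(profiles.amp[:, mask], axis=1)
    return pd.DataFrame(
        {"sample_id": profiles.samples, "loh_fraction": loh_frac, "amp_dev": amp_mean}
    ).set_index("sample_id")


def _welch(a: np.ndarray, b: np.ndarray) -> Tuple[float, float, bool]:
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        return float("nan"), 1.0, True
    if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
        return 0.0, 1.0, True
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p), False


def group_region_stats(
    profiles: CohortBinProfiles,
    groups: Dict[str, Sequence[str]],
    regions: pd.DataFrame,
) -> pd.DataFrame:
    """Per-region, per-group LOH fraction and amplification with 95% one-
    sample-t confidence intervals, plus between-group Welch t-tests.

    ``groups`` maps two group names to sample-id lists; ``regions`` has
    columns chrom, start, end.
    """
    if len(groups) != 2:
        raise ValueError("group_region_stats expects exactly two groups")
    (name_a, ids_a), (name_b, ids_b) = groups.items()
    idx = {s: i for i, s in enumerate(profiles.samples)}
    ia = [idx[s] for s in ids_a if s in idx]
    ib = [idx[s] for s in ids_b if s in idx]
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError("need >= 2 samples per group")
    rows = []
    for _, reg in regions.iterrows():
        summ = region_sample_summaries(profiles, reg["chrom"], reg["start"], reg["end"])
        row = {"chrom": reg["chrom"], "start": reg["start"], "end": reg["end"]}
        arrays = {}
        for gname, gi in ((name_a, ia), (name_b, ib)):
            for var in ("loh_fraction", "amp_dev"):
                vals = summ[var].to_numpy()[gi]
                mean, lo, hi = _t_ci(vals)
                row[f"{var}_{gname}"] = mean
                row[f"{var}_{gname}_lo"] = lo
                row[f"{var}_{gname}_hi"] = hi
                arrays[(gname, var)] = vals
        for var in ("loh_fraction", "amp_dev"):
            t, p, degenerate = _welch(arrays[(name_a, var)], arrays[(name_b, var)])
            row[f"{var}_t"] = t
            row[f"{var}_p"] = p
            row[f"{var}_degenerate"] = degenerate
        rows.append(row)
    return pd.DataFrame(rows)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (NaN-aware)."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = len(pv)
    if m == 0:
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    q[ok] = adj
    return q


def differential_regions(
    profiles: CohortBinProfiles,
    groups: Dict[str, Sequence[str]],
    alpha: float = 0.05,
    min_span_bins: int = 10,
    gap_bins: int = 2,
    variable: str = "loh",
) -> pd.DataFrame:
    """Detect maximal runs of bins whose between-group difference survives
    Benjamini–Hochberg at ``alpha``.

    Per bin, a Welch t-test compares the two groups' per-sample values
    (LOH indicators or amplification deviations); significant bins are
    merged across gaps of <= ``gap_bins`` non-significant bins and runs
    spanning >= ``min_span_bins`` bins are reported with their direction.
    """
    if len(groups) != 2:
        raise ValueError("differential_regions expects exactly two groups")
    (name_a, ids_a), (name_b, ids_b) = groups.items()
    idx = {s: i for i, s in enumerate(profiles.samples)}
    ia = [idx[s] for s in ids_a if s in idx]
    ib = [idx[s] for s in ids_b if s in idx]
    mat = profiles.loh if variable == "loh" else profiles.amp
    a, b = mat[ia], mat[ib]
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=False, nan_policy="omit")
        mean_diff = np.nanmean(a, axis=0) - np.nanmean(b, axis=0)
    p = np.asarray(p, dtype=float)
    q = bh_adjust(p)
    sig = np.where(np.isnan(q), False, q < alpha)

    bins = profiles.bins
    regions = []
    for chrom in bins["chrom"].unique():
        cmask = (bins["chrom"] == chrom).to_numpy()
        cidx = np.flatnonzero(cmask)
        sig_local = np.flatnonzero(sig[cmask])
        if len(sig_local) == 0:
            continue
        # cluster significant bins, bridging gaps of <= gap_bins quiet bins
        clusters = [[sig_local[0], sig_local[0]]]
        for j in sig_local[1:]:
            if j - clusters[-1][1] - 1 <= gap_bins:
                clusters[-1][1] = j
            else:
                clusters.append([j, j])
        for lo_local, hi_local in clusters:
            span = hi_local - lo_local + 1
            if span < min_span_bins:
                continue
            lo, hi = cidx[lo_local], cidx[hi_local]
            d = float(np.nanmean(mean_diff[lo : hi + 1]))
            regions.append(
                {
                    "chrom": chrom,
                    "start": int(bins["start"].iloc[lo]),
                    "end": int(bins["end"].iloc[hi]),
                    "n_bins": span,
                    "direction": name_a if d > 0 else name_b,
                    "mean_difference": d,
                }
            )
    return pd.DataFrame(
        regions, columns=["chrom", "start", "end", "n_bins", "direction", "mean_difference"]
    )


# --------------------------------------------------------------------------
# co-occurrence
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CooccurrenceResult:
    odds_ratio: float
    p_value: float
    table: Tuple[Tuple[int, int], Tuple[int, int]]
    haldane_corrected: bool = False
    degenerate: bool = False


def cooccurrence(status_a: Sequence[bool], status_b: Sequence[bool]) -> CooccurrenceResult:
    """Sample odds ratio (ad/bc, Haldane 0.5 correction when a cell is zero)
    and two-sided Fisher exact p for two boolean statuses over the same
    samples."""
    a = np.asarray(status_a, dtype=bool)
    b = np.asarray(status_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("status vectors must cover the same samples")
    n11 = int(np.sum(a & b))
    n10 = int(np.sum(a & ~b))
    n01 = int(np.sum(~a & b))
    n00 = int(np.sum(~a & ~b))
    table = ((n11, n10), (n01, n00))
    if a.all() or (~a).all() or b.all() or (~b).all():
        return CooccurrenceResult(
            odds_ratio=float("nan"), p_value=1.0, table=table, degenerate=True
        )
    haldane = 0 in (n11, n10, n01, n00)
    if haldane:
        oratio = (n11 + 0.5) * (n00 + 0.5) / ((n10 + 0.5) * (n01 + 0.5))
    else:
        oratio = n11 * n00 / (n10 * n01)
    _, p = stats.fisher_exact([[n11, n10], [n01, n00]], alternative="two-sided")
    return CooccurrenceResult(
        odds_ratio=float(oratio), p_value=float(p), table=table, haldane_corrected=haldane
    )
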