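"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle re-derives a statistic directly from its definition with naive
code (explicit enumeration, direct products, plain string scans), staying
independent of the package's implementation path.
"""

from __future__ import annotations

import math
from typing import Dict, List, Tuple

import numpy as np


# --------------------------------------------------------------------------
# two-class multinomial posterior by direct (unnormalized) products
# --------------------------------------------------------------------------


def likelihood_posterior_bruteforce(
    counts: np.ndarray, pos: np.ndarray, neg: np.ndarray, prior: float, pseudo: float = 1e-9
) -> float:
    """Direct-product evaluation, feasible for small total counts."""

    def prod_likelihood(p: np.ndarray) -> float:
        q = (p + pseudo) / (p + pseudo).sum()
        out = 1.0
        for c, pi in zip(counts, q):
            out *= pi ** c
        return out

    a = prior * prod_likelihood(pos)
    b = (1 - prior) * prod_likelihood(neg)
    return a / (a + b)


# --------------------------------------------------------------------------
# microhomology by exhaustive overlap scan
# --------------------------------------------------------------------------


def microhomology_bruteforce(deleted: str, flank_5p: str, flank_3p: str) -> int:
    """Largest k < len(deleted) such that the deleted sequence's k-prefix
    matches the start of the 3' flank or its k-suffix matches the end of the
    5' flank, found by scanning every k."""
    n = len(deleted)
    best = 0
    for k in range(1, n):
        if len(flank_3p) >= k and deleted[:k] == flank_3p[:k]:
            best = max(best, k)
        if len(flank_5p) >= k and deleted[n - k :] == flank_5p[len(flank_5p) - k :]:
            best = max(best, k)
    return best


# --------------------------------------------------------------------------
# Fisher exact two-sided p by hypergeometric enumeration
# --------------------------------------------------------------------------


def fisher_exact_bruteforce(table: Tuple[Tuple[int, int], Tuple[int, int]]) -> float:
    """Sum of the probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's (two-sided by the
    probability rule)."""
    (a, b), (c, d) = table
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def table_prob(x: int) -> float:
        # P(X = x) for X hypergeometric: x successes in row1 draws
        return (
            math.comb(col1, x)
            * math.comb(n - col1, row1 - x)
            / math.comb(n, row1)
        )

    p_obs = table_prob(a)
    total = 0.0
    for x in range(max(0, row1 - (n - col1)), min(row1, col1) + 1):
        p = table_prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def hypergeom_upper_tail_bruteforce(hits: int, universe: int, set_size: int, draws: int) -> float:
    """P(X >= hits) by direct summation of the hypergeometric pmf."""
    total = 0.0
    for x in range(hits, min(draws, set_size) + 1):
        total += (
            math.comb(set_size, x)
            * math.comb(universe - set_size, draws - x)
            / math.comb(universe, draws)
        )
    return min(total, 1.0)


# --------------------------------------------------------------------------
# genomic scar scores straight from their definitions
# --------------------------------------------------------------------------

Seg = Tuple[int, int, float, float]  # start, end, major, minor


def _merge_same_state(segs: List[Seg]) -> List[Seg]:
    out: List[Seg] = []
    for seg in sorted(segs):
        if out and out[-1][1] == seg[0] and out[-1][2] == seg[2] and out[-1][3] == seg[3]:
            out[-1] = (out[-1][0], seg[1], seg[2], seg[3])
        else:
            out.append(seg)
    return out


def scars_bruteforce(
    segments_by_chrom: Dict[str, List[Seg]],
    lengths: Dict[str, int],
    centromeres: Dict[str, Tuple[int, int]],
    loh_min: int = 15_000_000,
    lst_min: int = 10_000_000,
    smooth: int = 3_000_000,
    whole_fraction: float = 0.99,
) -> Tuple[int, int, int]:
    """(HRD-LOH, TAI, LST) from the raw definitions.

    HRD-LOH: maximal contiguous stretches with minor < 1, longer than
    ``loh_min`` and covering less than ``whole_fraction`` of the chromosome.
    TAI: first/last same-state run with major != minor not containing the
    centromere interval.  LST: per arm, after discarding sub-``smooth``
    pieces and fusing equal states, junctions with both sides >= ``lst_min``
    and separation <= ``smooth``.
    """
    n_loh = n_tai = n_lst = 0
    for chrom, segs in segments_by_chrom.items():
        merged = _merge_same_state(list(segs))
        chrom_len = lengths[chrom]

        # LOH stretches
        stretches: List[Tuple[int, int]] = []
        for s, e, _ma, mi in merged:
            if mi < 1:
                if stretches and stretches[-1][1] == s:
                    stretches[-1] = (stretches[-1][0], e)
                else:
                    stretches.append((s, e))
        for s, e in stretches:
            if e - s > loh_min and (e - s) < whole_fraction * chrom_len:
                n_loh += 1

        if chrom not in centromeres:
            continue
        cs, ce = centromeres[chrom]

        # TAI
        ends = [merged[0]] if merged else []
        if len(merged) > 1:
            ends.append(merged[-1])
        for s, e, ma, mi in ends:
            if ma != mi and not (s < cs and e > ce):
                n_tai += 1

        # LST per arm
        for a0, a1 in ((0, cs), (ce, chrom_len)):
            clipped = []
            for s, e, ma, mi in merged:
                s2, e2 = max(s, a0), min(e, a1)
                if e2 > s2:
                    clipped.append((s2, e2, ma, mi))
            big = [x for x in clipped if x[1] - x[0] >= smooth]
            fused: List[Seg] = []
            for x in big:
                if fused and fused[-1][2] == x[2] and fused[-1][3] == x[3]:
                    fused[-1] = (fused[-1][0], x[1], x[2], x[3])
                else:
                    fused.append(x)
            for left, right in zip(fused, fused[1:]):
                if (
                    right[0] - left[1] <= smooth
                    and left[1] - left[0] >= lst_min
                    and right[1] - right[0] >= lst_min
                ):
                    n_lst += 1
    return n_loh, n_tai, n_lst


def random_segment_genome(
    rng: np.random.Generator, lengths: Dict[str, int]
) -> Dict[str, List[Seg]]:
    """A random fully-covered segment genome with a scar-prone state mix."""
    out: Dict[str, List[Seg]] = {}
    states = [(1.0, 1.0), (1.0, 0.0), (2.0, 0.0), (2.0, 1.0), (3.0, 1.0), (2.0, 2.0)]
    for chrom, length in lengths.items():
        n_bp = int(rng.poisson(4))
        cuts = sorted(int(x) for x in rng.integers(1, length, size=n_bp))
        bounds = [0] + cuts + [length]
        segs = []
        for s, e in zip(bounds, bounds[1:]):
            if e > s:
                ma, mi = states[rng.integers(0, len(states))]
                segs.append((s, e, ma, mi))
        out[chrom] = segs
    return out


# --------------------------------------------------------------------------
# ssGSEA reference: literal step-CDF walk, one gene at a time
# --------------------------------------------------------------------------


def ssgsea_bruteforce(expr: np.ndarray, genes: List[str], gene_set: set, tau: float) -> float:
    """Literal implementation of the ranked-walk integral for one sample."""
    order = sorted(range(len(genes)), key=lambda i: (-expr[i], i))
    n = len(genes)
    in_flags = [genes[i] in gene_set for i in order]
    weights = []
    for pos, flag in enumerate(in_flags):
        rank_stat = n - pos
        weights.append(abs(rank_stat) ** tau if flag else 0.0)
    denom_in = sum(weights)
    n_out = sum(1 for f in in_flags if not f)
    es = 0.0
    cum_in = 0.0
    cum_out = 0.0
    for w, flag in zip(weights, in_flags):
        cum_in += w / denom_in
        if not flag:
            cum_out += 1.0 / n_out
        es += cum_in - cum_out
    return es
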