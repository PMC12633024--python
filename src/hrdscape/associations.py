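"""Gene-level enrichment statistics and tumor-microenvironment (TME)
cell-fraction analyses.

Covers: per-gene DNA-damage-response (DDR) dysfunction enrichment in HRD vs
HRP, gene-pair ("epistatic") enrichment, generic hypergeometric over-
representation analysis (ORA) over user-supplied gene sets, within-tumor-type
z-scored cell-fraction comparisons (delta-Z), hierarchical clustering of cell
types across comparisons, and pairwise cell-type correlations.  Multiple
testing uses Benjamini-Hochberg throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from hrdscape.datatypes import GeneSet
from hrdscape.scars import bh_adjust, cooccurrence

logger = logging.getLogger(__name__)


def alteration_matrix(
    sources: Dict[str, Iterable[Tuple[str, str]]],
    samples: Sequence[str],
    genes: Sequence[str],
) -> pd.DataFrame:
    """Boolean samples x genes "dysfunctional" matrix from (sample, gene)
    event streams (pathogenic somatic / germline, deep deletion, promoter
    silencing); any event class marks the gene dysfunctional."""
    mat = pd.DataFrame(False, index=pd.Index(samples, name="sample_id"), columns=list(genes))
    for _name, pairs in sources.items():
        for sample, gene in pairs:
            if sample in mat.index and gene in mat.columns:
                mat.loc[sample, gene] = True
    return mat


def ddr_enrichment(
    alterations: pd.DataFrame,
    hrd: pd.Series,
    genes: Optional[Sequence[str]] = None,
    background_mask: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Per-gene Fisher test of dysfunction x {HRD, HRP}, BH-adjusted.

    ``background_mask`` restricts the tested samples (e.g. to exclude
    biallelic BRCA1/2 carriers so enrichment reflects BRCA-wildtype HRD).
    Genes absent from the matrix are skipped with a warning; unaltered genes
    get q = 1 and an undefined odds ratio, flagged.
    """
    if genes is None:
        genes = list(alterations.columns)
    idx = alterations.index
    if background_mask is not None:
        idx = idx[background_mask.loc[idx].astype(bool)]
    hrd_vec = hrd.loc[idx].astype(bool).to_numpy()
    rows = []
    for gene in genes:
        if gene not in alterations.columns:
            logger.warning("gene %s absent from alteration matrix; skipped", gene)
            continue
        alt = alterations.loc[idx, gene].to_numpy(bool)
        res = cooccurrence(alt, hrd_vec)
        rows.append(
            {
                "gene": gene,
                "n_altered": int(alt.sum()),
                "odds_ratio": res.odds_ratio,
                "p": res.p_value,
                "degenerate": res.degenerate,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out.loc[out["degenerate"], "q"] = 1.0
    return out


def pair_epistasis(
    alterations: pd.DataFrame,
    gene_a: str,
    gene_b: str,
    hrd: pd.Series,
) -> pd.DataFrame:
    """Fisher test of "both genes dysfunctional" vs HRD status."""
    for g in (gene_a, gene_b):
        if g not in alterations.columns:
            raise KeyError(f"gene {g!r} absent from alteration matrix")
    both = (alterations[gene_a] & alterations[gene_b]).to_numpy(bool)
    res = cooccurrence(both, hrd.loc[alterations.index].astype(bool).to_numpy())
    return pd.DataFrame(
        [
            {
                "gene_a": gene_a,
                "gene_b": gene_b,
                "n_both": int(both.sum()),
                "odds_ratio": res.odds_ratio,
                "p": res.p_value,
                "degenerate": res.degenerate,
            }
        ]
    )


def pair_epistasis_sweep(
    alterations: pd.DataFrame,
    genes: Sequence[str],
    partner: str,
    hrd: pd.Series,
) -> pd.DataFrame:
    """Convenience sweep of :func:`pair_epistasis` over (gene, partner)
    pairs (typically partner = TP53), BH-adjusted across the sweep."""
    frames = [
        pair_epistasis(alterations, g, partner, hrd)
        for g in genes
        if g != partner and g in alterations.columns
    ]
    out = pd.concat(frames, ignore_index=True)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out.loc[out["degenerate"], "q"] = 1.0
    return out


def ora(
    gene_list: Sequence[str],
    universe: Sequence[str],
    gene_sets: Sequence[GeneSet],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``gene_list`` in each set.

    p is the upper tail P(X >= hits) with population = universe, successes =
    set intersect universe, draws = len(gene_list); BH across sets.  Genes
    outside the universe are an error (they would silently bias the tail).
    """
    universe_set = set(universe)
    offenders = sorted(set(gene_list) - universe_set)
    if offenders:
        raise ValueError(f"gene list members outside the universe: {offenders}")
    list_set = set(gene_list)
    M, n = len(universe_set), len(list_set)
    rows = []
    for gs in gene_sets:
        in_universe = gs.genes & universe_set
        hits = sorted(list_set & in_universe)
        K = len(in_universe)
        p = float(stats.hypergeom.sf(len(hits) - 1, M, K, n)) if K else 1.0
        rows.append(
            {
                "set": gs.name,
                "set_size": K,
                "n_hits": len(hits),
                "p": p,
                "hit_genes": ",".join(hits),
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


# --------------------------------------------------------------------------
# TME cell fractions
# --------------------------------------------------------------------------


def zscore_within_type(
    fractions: pd.DataFrame, tumor_types: pd.Series
) -> pd.DataFrame:
    """Z-score each cell-type column within each tumor type."""
    z = pd.DataFrame(np.nan, index=fractions.index, columns=fractions.columns)
    for _type, members in fractions.groupby(tumor_types.loc[fractions.index]).groups.items():
        sub = fractions.loc[members]
        sd = sub.std(ddof=1).replace(0, np.nan)
        z.loc[members] = (sub - sub.mean()) / sd
    return z


def tme_delta(
    fractions: pd.DataFrame,
    annotations: pd.DataFrame,
    group1: pd.Series,
    group2: pd.Series,
    min_per_arm: int = 2,
) -> pd.DataFrame:
    """Delta-Z table: per (tumor type, cell type), the difference of group
    mean z-scored fractions with a Welch t-test.

    ``group1`` / ``group2`` are boolean sample masks (e.g. HRD vs HRP, or
    hot-HRD vs cold-HRD); z-scores are computed within tumor type over all
    samples of the type.  Types with an arm below ``min_per_arm`` are
    skipped with a warning.
    """
    ann = annotations.set_index("sample_id") if "sample_id" in annotations.columns else annotations
    types = ann.loc[fractions.index, "tumor_type"]
    z = zscore_within_type(fractions, types)
    rows = []
    for tumor_type, members in z.groupby(types).groups.items():
        g1 = [s for s in members if group1.get(s, False)]
        g2 = [s for s in members if group2.get(s, False)]
        if len(g1) < min_per_arm or len(g2) < min_per_arm:
            logger.warning("tumor type %s skipped in delta-Z (arms %d/%d)", tumor_type, len(g1), len(g2))
            continue
        for cell in z.columns:
            a = z.loc[g1, cell].dropna().to_numpy()
            b = z.loc[g2, cell].dropna().to_numpy()
            if len(a) < min_per_arm or len(b) < min_per_arm:
                continue
            dz = float(a.mean() - b.mean())
            if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_ind(a, b, equal_var=False)
            rows.append(
                {
                    "tumor_type": tumor_type,
                    "cell_type": cell,
                    "dz": dz,
                    "t": float(t),
                    "p": float(p),
                    "n1": len(a),
                    "n2": len(b),
                }
            )
    return pd.DataFrame(rows, columns=["tumor_type", "cell_type", "dz", "t", "p", "n1", "n2"])


def stack_delta_tables(tables: Dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Stack delta-Z tables from several comparisons into a
    (comparison, tumor type) x cell-type matrix for clustering."""
    pieces = []
    for name, tab in tables.items():
        wide = tab.pivot(index="tumor_type", columns="cell_type", values="dz")
        wide.index = [f"{name}:{t}" for t in wide.index]
        pieces.append(wide)
    return pd.concat(pieces, axis=0)


def cluster_celltypes(stacked_dz: pd.DataFrame, k: int = 5) -> pd.Series:
    """Agglomerative clustering (Euclidean, average linkage) of cell-type
    column vectors of the stacked delta-Z matrix, cut at ``k`` clusters.

    Rows with missing values are dropped before clustering; cluster ids are
    relabeled 1..k in order of first appearance so the partition is
    invariant to cell-type column order up to renaming.
    """
    if k > stacked_dz.shape[1]:
        raise ValueError(f"k={k} exceeds the {stacked_dz.shape[1]} cell types")
    X = stacked_dz.dropna(axis=0, how="any").to_numpy(float).T  # cell types x comparisons
    Z = linkage(X, method="average", metric="euclidean")
    raw = fcluster(Z, t=k, criterion="maxclust")
    relabel: Dict[int, int] = {}
    assign = []
    for r in raw:
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        assign.append(relabel[r])
    return pd.Series(assign, index=stacked_dz.columns, name="cluster")


def correlate_celltypes(
    z_fractions: pd.DataFrame, alpha: float = 0.05
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlation of z-scored cell fractions.

    Returns (r, p, significant) DataFrames; constant columns give NaN r,
    p = 1 and are never significant.  Requires >= 3 samples.
    """
    if len(z_fractions) < 3:
        raise ValueError("need >= 3 samples for correlation")
    cols = list(z_fractions.columns)
    m = len(cols)
    r = np.full((m, m), np.nan)
    p = np.ones((m, m))
    X = z_fractions.to_numpy(float)
    for i in range(m):
        for j in range(i, m):
            a, b = X[:, i], X[:, j]
            ok = ~np.isnan(a) & ~np.isnan(b)
            if ok.sum() < 3 or np.std(a[ok]) == 0 or np.std(b[ok]) == 0:
                continue
            if i == j:
                r[i, j] = 1.0
                p[i, j] = 0.0
                continue
            rr, pp = stats.pearsonr(a[ok], b[ok])
            r[i, j] = r[j, i] = float(rr)
            p[i, j] = p[j, i] = float(pp)
    r_df = pd.DataFrame(r, index=cols, columns=cols)
    p_df = pd.DataFrame(p, index=cols, columns=cols)
    sig = (p_df < alpha) & r_df.notna()
    return r_df, p_df, sig
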