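"""ssGSEA, the composite Inflammation Score (IS), hot/cold tertile status
and the IS regressions.

The IS is the per-sample mean of four single-sample GSEA scores over curated
immune signatures (type-I interferon response, chemokine-driven T-cell
recruitment, IFN-gamma response, cytotoxic CD8 T-cell activation).  Samples
are called hot / intermediate / cold by the within-tumor-type tertiles of
the IS, computed on samples without viral infection or hypermutation but
applied to every sample of the type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from hrdscape.datatypes import GeneSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SsgseaConfig:
    """Parameters of the single-sample ranked-walk enrichment statistic.

    ``tau`` is the rank-weight exponent (0 gives unweighted step CDFs; the
    community default 0.25 up-weights extreme ranks mildly).  ``normalize``
    rescales the scores by the range across the whole result ("range") or
    leaves raw integrated differences ("none").
    """

    tau: float = 0.25
    normalize: str = "range"  # range / none

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.normalize not in ("range", "none"):
            raise ValueError(f"unknown normalization mode {self.normalize!r}")


def _ssgsea_sample(expr: np.ndarray, in_set: np.ndarray, tau: float) -> float:
    """Ranked-walk enrichment for one sample.

    Genes are ordered by expression, descending; the score integrates the
    difference between the |rank statistic|^tau-weighted step CDF of in-set
    genes and the uniform step CDF of out-of-set genes.  Ties are broken by
    gene order (stable sort), so the statistic is exactly rank-based.
    """
    n = len(expr)
    order = np.argsort(-expr, kind="stable")
    ranked_in = in_set[order]
    # rank statistic: n for the top gene down to 1 for the bottom gene
    r = np.arange(n, 0, -1, dtype=float)
    w = np.where(ranked_in, r**tau, 0.0)
    denom_in = w.sum()
    n_out = n - int(in_set.sum())
    if denom_in == 0 or n_out == 0:
        raise ValueError("gene set must hit the matrix without covering it")
    cdf_in = np.cumsum(w) / denom_in
    cdf_out = np.cumsum(~ranked_in) / n_out
    return float(np.sum(cdf_in - cdf_out))


def ssgsea(
    expr: pd.DataFrame,
    gene_set: GeneSet,
    config: SsgseaConfig = SsgseaConfig(),
) -> pd.Series:
    """ssGSEA scores of one gene set across all samples of a genes x samples
    matrix.  Raises if the set shares no gene with the matrix."""
    scores = ssgsea_matrix(expr, [gene_set], config)
    return scores.loc[gene_set.name]


def ssgsea_matrix(
    expr: pd.DataFrame,
    gene_sets: Sequence[GeneSet],
    config: SsgseaConfig = SsgseaConfig(),
) -> pd.DataFrame:
    """ssGSEA scores (sets x samples).  Range normalization, when on, divides
    all scores by the max-min range over the whole matrix, following the
    common single-sample GSEA convention."""
    genes = pd.Index(expr.index)
    X = expr.to_numpy(float)
    masks = {}
    for gs in gene_sets:
        mask = genes.isin(gs.genes).astype(bool)
        if not mask.any():
            raise ValueError(f"gene set {gs.name!r} shares no genes with the matrix")
        masks[gs.name] = mask
    out = np.empty((len(gene_sets), expr.shape[1]))
    for j in range(expr.shape[1]):
        col = X[:, j]
        for i, gs in enumerate(gene_sets):
            out[i, j] = _ssgsea_sample(col, masks[gs.name], config.tau)
    if config.normalize == "range":
        rng = out.max() - out.min()
        if rng > 0:
            out = out / rng
    return pd.DataFrame(out, index=[gs.name for gs in gene_sets], columns=expr.columns)


def inflammation_score(
    expr: pd.DataFrame,
    gene_sets: Sequence[GeneSet],
    config: SsgseaConfig = SsgseaConfig(),
) -> pd.DataFrame:
    """Per-sample signature scores plus their mean, the Inflammation Score.

    Returns a samples x (signatures..., IS) frame.  All four sets must
    resolve against the matrix.
    """
    if len(gene_sets) != 4:
        raise ValueError(f"the inflammation score averages four signatures, got {len(gene_sets)}")
    scores = ssgsea_matrix(expr, gene_sets, config).T
    scores["IS"] = scores.mean(axis=1)
    scores.index.name = "sample_id"
    return scores


# --------------------------------------------------------------------------
# tertile status
# --------------------------------------------------------------------------


@dataclass
class TertileResult:
    status: pd.Series  # hot / intermediate / cold (NaN for unassignable types)
    thresholds: pd.DataFrame  # tumor_type x (t1, t2, n_eligible, degenerate)
    z_is: pd.Series  # IS z-scored within tumor type on eligible samples


def tertile_status(
    is_scores: pd.Series,
    annotations: pd.DataFrame,
    excluded: Optional[Set[str]] = None,
    min_eligible: int = 3,
) -> TertileResult:
    """Hot/intermediate/cold status from within-tumor-type IS tertiles.

    ``excluded`` samples (viral-positive, MMRD, POLE) do not contribute to
    the tertile thresholds or the z-normalization moments, but still receive
    a status from their type's thresholds.  Boundary samples take the lower
    status (cold at T1, intermediate at T2).  Types with fewer than
    ``min_eligible`` eligible samples are flagged and left unassigned.
    """
    excluded = excluded or set()
    ann = annotations.set_index("sample_id") if "sample_id" in annotations.columns else annotations
    types = ann.loc[is_scores.index, "tumor_type"]
    status = pd.Series(np.nan, index=is_scores.index, dtype=object)
    z_is = pd.Series(np.nan, index=is_scores.index, dtype=float)
    rows = []
    for tumor_type, members in is_scores.groupby(types).groups.items():
        eligible = [s for s in members if s not in excluded]
        vals = is_scores.loc[eligible]
        if len(eligible) < min_eligible:
            logger.warning(
                "tumor type %s has %d eligible samples (< %d); no status assigned",
                tumor_type,
                len(eligible),
                min_eligible,
            )
            rows.append((tumor_type, np.nan, np.nan, len(eligible), True))
            continue
        t1, t2 = np.quantile(vals, [1 / 3, 2 / 3])
        degenerate = not (t1 < t2)
        all_vals = is_scores.loc[members]
        if degenerate:
            status.loc[members] = "intermediate"
        else:
            status.loc[members] = np.select(
                [all_vals > t2, all_vals <= t1], ["hot", "cold"], default="intermediate"
            )
        sd = vals.std(ddof=1)
        if sd > 0:
            z_is.loc[members] = (all_vals - vals.mean()) / sd
        else:
            z_is.loc[members] = 0.0
        rows.append((tumor_type, float(t1), float(t2), len(eligible), degenerate))
    thresholds = pd.DataFrame(
        rows, columns=["tumor_type", "t1", "t2", "n_eligible", "degenerate"]
    ).set_index("tumor_type")
    return TertileResult(status=status, thresholds=thresholds, z_is=z_is)


# --------------------------------------------------------------------------
# comparisons and regressions
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CompareResult:
    t: float
    p: float
    n_hrd: int
    n_hrp: int
    degenerate: bool = False


def compare_is(z_is: pd.Series, hrd: pd.Series) -> CompareResult:
    """Welch two-sample t-test on z-scored IS; t > 0 means HRD higher."""
    hrd = hrd.loc[z_is.index].astype(bool)
    a = z_is[hrd].dropna().to_numpy()
    b = z_is[~hrd].dropna().to_numpy()
    if len(a) < 2 or len(b) < 2:
        return CompareResult(float("nan"), 1.0, len(a), len(b), degenerate=True)
    if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
        return CompareResult(0.0, 1.0, len(a), len(b), degenerate=True)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return CompareResult(float(t), float(p), len(a), len(b))


class CollinearityError(ValueError):
    pass


def _ols(y: np.ndarray, X: pd.DataFrame) -> pd.DataFrame:
    design = sm.add_constant(X.astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        # name offending columns: those whose removal restores full column rank
        offenders = [
            c
            for c in X.columns
            if np.linalg.matrix_rank(design.drop(columns=[c]).to_numpy()) == rank
        ]
        raise CollinearityError(f"design matrix is rank deficient; collinear columns: {offenders}")
    fit = sm.OLS(y, design).fit()
    ci = fit.conf_int()
    return pd.DataFrame(
        {
            "coef": fit.params,
            "t": fit.tvalues,
            "p": fit.pvalues,
            "ci_lo": ci[0],
            "ci_hi": ci[1],
        }
    )


def regress_is(
    z_is: pd.Series,
    hrd: pd.Series,
    tmb: pd.Series,
    extra: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """OLS of z-scored IS on HRD status and TMB (plus optional covariates).

    Returns per-coefficient estimates with t, p and 95% CI; the HRD row
    isolates the inflammation shift attributable to HRD at fixed mutational
    burden.
    """
    X = pd.DataFrame({"hrd": hrd.loc[z_is.index].astype(float), "tmb": tmb.loc[z_is.index]})
    if extra is not None:
        X = pd.concat([X, extra.loc[z_is.index]], axis=1)
    return _ols(z_is.to_numpy(float), X)


def regress_is_on_genomics(
    z_is: pd.Series,
    loh_fractions: pd.DataFrame,
    og_amp: pd.Series,
) -> pd.DataFrame:
    """OLS of z-scored IS on per-region LOH fractions and oncogene-
    amplification status (HRD samples only by construction of the inputs).

    ``loh_fractions`` is samples x regions; column order is preserved in the
    output.  All-zero covariate columns are dropped (intercept-only in the
    degenerate limit); duplicated columns raise a collinearity error.
    """
    X = loh_fractions.loc[z_is.index].copy()
    X["og_amp"] = og_amp.loc[z_is.index].astype(float)
    nonconstant = [c for c in X.columns if X[c].nunique() > 1]
    dropped = [c for c in X.columns if c not in nonconstant]
    if dropped:
        logger.info("dropping constant covariates: %s", dropped)
    X = X[nonconstant]
    if X.shape[1] == 0:
        fit = sm.OLS(z_is.to_numpy(float), np.ones((len(z_is), 1))).fit()
        return pd.DataFrame(
            {
                "coef": [fit.params[0]],
                "t": [fit.tvalues[0]],
                "p": [fit.pvalues[0]],
                "ci_lo": [fit.conf_int()[0][0]],
                "ci_hi": [fit.conf_int()[0][1]],
            },
            index=["const"],
        )
    return _ols(z_is.to_numpy(float), X)
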