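"""Per-sample mutational features: SBS96 catalogs, signature-3 refitting,
microhomology-deletion counts, TMB, hypermutation triage and the artifact
filter.

The signature-3 feature core follows the likelihood / cosine / non-negative
least squares refitting approach used by exome-scale HRD detection: a sample
catalog is compared against an expected HRD-positive spectrum and an
HRD-negative spectrum through a two-class multinomial likelihood ratio, and
decomposed over a spectrum panel by NNLS for exposure estimates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
from scipy.optimize import nnls

from hrdscape.datatypes import (
    GenomeBuild,
    MutationRecord,
    NONSYNONYMOUS_CONSEQUENCES,
    TRUNCATING_CONSEQUENCES,
    VariantClass,
)
from hrdscape.spectra import Spectrum96, channel_of, panel_matrix

logger = logging.getLogger(__name__)

#: Pseudocount added to spectrum channels before taking logs, so that
#: zero-probability channels cannot annihilate a multinomial likelihood.
SPECTRUM_PSEUDOCOUNT = 1e-9


@dataclass
class Catalog96:
    """96-channel SBS counts for one sample; ``n_excluded`` counts SNVs whose
    trinucleotide context could not be resolved."""

    sample_id: str
    counts: np.ndarray
    n_excluded: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.shape != (96,):
            raise ValueError("catalog must have 96 channels")
        if (c < 0).any():
            raise ValueError("negative catalog counts")
        self.counts = c

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class Sig3Features:
    likelihood_score: float
    cosine: float
    exposure: float
    exposure_fraction: float


@dataclass(frozen=True)
class IndelFeatures:
    """Counts of >= 5 bp deletions with (ID6-linked) and without (ID8-linked)
    flanking microhomology of >= 2 bp."""

    n_del_mh: int = 0
    n_del_no_mh: int = 0


@dataclass(frozen=True)
class HypermutationCall:
    sample_id: str
    cls: str  # MMRP / MMRD / POLE
    msi_score: Optional[float]
    mmr_exposure_fraction: float
    pole_exposure_fraction: float
    tmb: float


@dataclass(frozen=True)
class TriageThresholds:
    """Hypermutation triage cutoffs.

    ``msi_threshold`` follows the MSIsensor convention (score >= 3.5 is
    MSI-high); exposure fractions and TMB gates decide signature-driven
    calls when the MSI score is absent or sub-threshold.
    """

    msi_threshold: float = 3.5
    f_mmr: float = 0.3
    f_pole: float = 0.3
    t_hyper: float = 10.0  # mutations / Mb
    t_pole: float = 100.0


def _context_for(record: MutationRecord, genome: Optional[GenomeBuild]) -> Optional[str]:
    if record.trinucleotide_context is not None:
        return record.trinucleotide_context
    if genome is not None and genome.fetch is not None:
        # pos is 1-based; context spans [pos-1, pos+2) in 0-based half-open.
        try:
            return genome.fetch(record.chrom, record.pos - 2, record.pos + 1)
        except Exception:  # noqa: BLE001 - any accessor failure means "unresolvable"
            return None
    return None


def build_catalog(
    mutations: Iterable[MutationRecord],
    genome: Optional[GenomeBuild] = None,
    samples: Optional[Sequence[str]] = None,
) -> Dict[str, Catalog96]:
    """Build per-sample SBS96 catalogs.

    Non-SNVs are ignored; SNVs whose context cannot be resolved (from the
    record's inline context column or the genome accessor) are excluded with
    a logged count.  ``samples`` optionally forces all-zero catalogs for
    samples without usable SNVs.
    """
    counts: Dict[str, np.ndarray] = {}
    excluded: Dict[str, int] = {}
    for s in samples or ():
        counts[s] = np.zeros(96)
        excluded[s] = 0
    for rec in mutations:
        if rec.variant_class is not VariantClass.SNV:
            continue
        counts.setdefault(rec.sample_id, np.zeros(96))
        excluded.setdefault(rec.sample_id, 0)
        ctx = _context_for(rec, genome)
        if ctx is None:
            excluded[rec.sample_id] += 1
            continue
        try:
            k = channel_of(rec.ref, rec.alt, ctx)
        except (KeyError, ValueError):
            excluded[rec.sample_id] += 1
            continue
        counts[rec.sample_id][k] += 1
    total_excluded = sum(excluded.values())
    if total_excluded:
        logger.warning("excluded %d SNVs with unresolvable context", total_excluded)
    return {
        s: Catalog96(sample_id=s, counts=c, n_excluded=excluded[s]) for s, c in counts.items()
    }


def _log_multinomial(counts: np.ndarray, probs: np.ndarray) -> float:
    """Multinomial log-likelihood up to the count-only coefficient (which
    cancels in two-class ratios)."""
    p = probs + SPECTRUM_PSEUDOCOUNT
    p = p / p.sum()
    return float(np.dot(counts, np.log(p)))


def sig3_likelihood(
    catalog: Catalog96,
    pos: Spectrum96,
    neg: Spectrum96,
    prior_pos: float = 0.5,
) -> float:
    """Two-class posterior that the catalog was drawn from the HRD-positive
    spectrum rather than the negative one.

    Computed in log space:
    ``prior*L(c|pos) / [prior*L(c|pos) + (1-prior)*L(c|neg)]``.  A zero-count
    catalog returns ``prior_pos`` (no evidence either way).
    """
    if not 0.0 <= prior_pos <= 1.0:
        raise ValueError("prior_pos must be in [0, 1]")
    if catalog.total == 0:
        return prior_pos
    if prior_pos == 0.0:
        return 0.0
    if prior_pos == 1.0:
        return 1.0
    lp = _log_multinomial(catalog.counts, pos.probs) + math.log(prior_pos)
    ln = _log_multinomial(catalog.counts, neg.probs) + math.log(1.0 - prior_pos)
    m = max(lp, ln)
    num = math.exp(lp - m)
    return num / (num + math.exp(ln - m))


def cosine_to(catalog: Catalog96, spectrum: Spectrum96) -> float:
    """Cosine similarity between the catalog and a spectrum (NaN for an
    empty catalog, which has no direction)."""
    c = catalog.counts
    norm = np.linalg.norm(c) * np.linalg.norm(spectrum.probs)
    if norm == 0:
        return float("nan")
    return float(np.dot(c, spectrum.probs) / norm)


@dataclass(frozen=True)
class NnlsResult:
    exposures: Dict[str, float]
    residual: float

    @property
    def total(self) -> float:
        return sum(self.exposures.values())

    def fraction(self, name: str) -> float:
        t = self.total
        return self.exposures[name] / t if t > 0 else 0.0


def nnls_exposures(catalog: Catalog96, panel: Sequence[Spectrum96]) -> NnlsResult:
    """Non-negative least squares decomposition of the catalog over a panel.

    Exposures are in mutation units (they need not sum exactly to the
    catalog total; the residual captures the rest).
    """
    if not panel:
        raise ValueError("panel must be non-empty")
    A = panel_matrix(panel)
    e, rnorm = nnls(A, catalog.counts)
    return NnlsResult(
        exposures={s.name: float(x) for s, x in zip(panel, e)}, residual=float(rnorm)
    )


def microhomology_length(deleted: str, flank_5p: str, flank_3p: str) -> int:
    """Microhomology of a deletion against its immediate flanks.

    The length is the maximum of (a) the longest prefix of the deleted
    sequence equal to the start of the 3' flank and (b) the longest suffix
    equal to the end of the 5' flank, capped below the deletion length (a
    full-length match is a repeat unit, not microhomology).
    """
    deleted, flank_5p, flank_3p = deleted.upper(), flank_5p.upper(), flank_3p.upper()
    n = len(deleted)
    mh3 = 0
    for i in range(min(n, len(flank_3p))):
        if deleted[i] == flank_3p[i]:
            mh3 += 1
        else:
            break
    mh5 = 0
    for i in range(min(n, len(flank_5p))):
        if deleted[n - 1 - i] == flank_5p[len(flank_5p) - 1 - i]:
            mh5 += 1
        else:
            break
    return min(max(mh3, mh5), n - 1)


def count_microhomology_deletions(
    mutations: Iterable[MutationRecord],
    genome: Optional[GenomeBuild] = None,
    min_deletion_bp: int = 5,
    min_mh_bp: int = 2,
    samples: Optional[Sequence[str]] = None,
) -> Dict[str, IndelFeatures]:
    """Count >= ``min_deletion_bp`` deletions per sample, split by whether a
    microhomology of >= ``min_mh_bp`` flanks the deleted sequence.

    Flanks come from the record's inline ``flank_5p``/``flank_3p`` columns or,
    failing that, the genome accessor; deletions with unresolvable flanks are
    excluded with a logged count.
    """
    mh: Dict[str, int] = {s: 0 for s in samples or ()}
    no_mh: Dict[str, int] = {s: 0 for s in samples or ()}
    n_unresolved = 0
    for rec in mutations:
        if rec.variant_class is not VariantClass.DELETION:
            continue
        mh.setdefault(rec.sample_id, 0)
        no_mh.setdefault(rec.sample_id, 0)
        deleted = rec.deleted_sequence
        if deleted is None or len(deleted) < min_deletion_bp:
            continue
        f5, f3 = rec.flank_5p, rec.flank_3p
        if (f5 is None or f3 is None) and genome is not None and genome.fetch is not None:
            # deleted bases occupy [pos + len(anchor) - 1, ...) 0-based
            anchor = len(rec.ref) - len(deleted)
            del_start = rec.pos - 1 + anchor
            del_end = del_start + len(deleted)
            try:
                f5 = genome.fetch(rec.chrom, max(0, del_start - len(deleted)), del_start)
                f3 = genome.fetch(rec.chrom, del_end, del_end + len(deleted))
            except Exception:  # noqa: BLE001
                f5 = f3 = None
        if f5 is None or f3 is None or len(f5) < len(deleted) or len(f3) < len(deleted):
            n_unresolved += 1
            continue
        if microhomology_length(deleted, f5, f3) >= min_mh_bp:
            mh[rec.sample_id] += 1
        else:
            no_mh[rec.sample_id] += 1
    if n_unresolved:
        logger.warning("excluded %d deletions with unresolvable flanks", n_unresolved)
    return {s: IndelFeatures(n_del_mh=mh[s], n_del_no_mh=no_mh[s]) for s in mh}


def compute_tmb(
    mutations: Iterable[MutationRecord],
    footprint_mb: float = 38.0,
    samples: Optional[Sequence[str]] = None,
) -> Dict[str, float]:
    """Tumor mutational burden: nonsynonymous SNVs + indels per megabase of
    assayed exome (default footprint 38 Mb)."""
    if footprint_mb <= 0:
        raise ValueError("footprint_mb must be positive")
    counted = TRUNCATING_CONSEQUENCES | NONSYNONYMOUS_CONSEQUENCES
    counts: Dict[str, int] = {s: 0 for s in samples or ()}
    for rec in mutations:
        counts.setdefault(rec.sample_id, 0)
        if rec.consequence in counted:
            counts[rec.sample_id] += 1
    return {s: c / footprint_mb for s, c in counts.items()}


def is_pathogenic(record: MutationRecord) -> bool:
    """Pathogenicity filter for somatic variants.

    True when the consequence is truncating, or a nonsynonymous change is
    SIFT-deleterious AND PolyPhen-probably_damaging, or ClinVar calls it
    pathogenic / likely_pathogenic — unless ClinVar labels it Benign, which
    vetoes every route.
    """
    clinvar = (record.clinvar or "").strip().lower()
    if clinvar == "benign":
        return False
    if record.consequence in TRUNCATING_CONSEQUENCES:
        return True
    if record.consequence in NONSYNONYMOUS_CONSEQUENCES:
        sift = (record.sift or "").strip().lower()
        polyphen = (record.polyphen or "").strip().lower()
        if sift.startswith("deleterious") and polyphen.startswith("probably_damaging"):
            return True
        if clinvar in ("pathogenic", "likely_pathogenic"):
            return True
    return False


def triage_hypermutation(
    catalog: Catalog96,
    exposures: NnlsResult,
    msi_score: Optional[float],
    tmb: float,
    thresholds: TriageThresholds = TriageThresholds(),
) -> HypermutationCall:
    """Classify a sample as MMRP, MMRD or POLE before HRD scoring.

    MMRD when the MSI score exceeds its threshold, or the MMR-like exposure
    fraction and TMB both exceed theirs; otherwise POLE when the POLE-like
    exposure fraction is high at ultra-hypermutated TMB; otherwise MMRP.
    A missing MSI score degrades to the signature-only branch.
    """
    f_mmr = exposures.fraction("mmr") if "mmr" in exposures.exposures else 0.0
    f_pole = exposures.fraction("pole") if "pole" in exposures.exposures else 0.0
    if msi_score is None:
        logger.info("sample %s has no MSI score; using signature-only triage", catalog.sample_id)
        msi_branch = False
    else:
        msi_branch = msi_score >= thresholds.msi_threshold
    if msi_branch or (f_mmr >= thresholds.f_mmr and tmb >= thresholds.t_hyper):
        cls = "MMRD"
    elif f_pole >= thresholds.f_pole and tmb >= thresholds.t_pole:
        cls = "POLE"
    else:
        cls = "MMRP"
    return HypermutationCall(
        sample_id=catalog.sample_id,
        cls=cls,
        msi_score=msi_score,
        mmr_exposure_fraction=f_mmr,
        pole_exposure_fraction=f_pole,
        tmb=tmb,
    )


@dataclass(frozen=True)
class ArtifactFilterResult:
    excluded: frozenset
    n_total: int
    threshold: float

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)

    @property
    def exclusion_rate_pct(self) -> float:
        return 100.0 * self.n_excluded / self.n_total if self.n_total else 0.0

    def summary(self) -> str:
        return (
            f"{self.n_excluded}/{self.n_total}, "
            f"{self.exclusion_rate_pct:.1f}% of all samples excluded "
            f"(artifact-signature exposure fraction >= {self.threshold})"
        )


def filter_artifact_samples(
    exposures_by_sample: Dict[str, NnlsResult],
    sbs45_fraction_threshold: float = 0.2,
    signature_name: str = "sbs45",
) -> ArtifactFilterResult:
    """Flag samples dominated by the 8-oxo-guanine sequencing artifact
    signature for removal from all downstream stages."""
    excluded = frozenset(
        s
        for s, res in exposures_by_sample.items()
        if signature_name in res.exposures
        and res.fraction(signature_name) >= sbs45_fraction_threshold
    )
    result = ArtifactFilterResult(
        excluded=excluded, n_total=len(exposures_by_sample), threshold=sbs45_fraction_threshold
    )
    if excluded:
        logger.info(result.summary())
    return result
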