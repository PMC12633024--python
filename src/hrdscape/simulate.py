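"""Synthetic cohort generator with ground truth.

Emulates the statistical structure of the pipeline's inputs so that every
downstream stage is testable without external downloads:

* mutation catalogs are multinomial draws from condition-specific mixtures
  over the packaged spectrum panel at log-normal burdens (hypermutator
  classes get their own mixtures and burdens; a small fraction of samples
  is dominated by the sequencing-artifact spectrum);
* deletions carry explicit ref/alt strings and inline flanking sequence
  constructed to have (or lack) >= 2 bp of microhomology, at HRD-dependent
  Poisson rates;
* allele-specific segments are generated from a per-chromosome Poisson
  breakpoint process with HRD-dependent LOH and amplification state
  probabilities, whole-chromosome LOH as a distinct event class, targeted
  LOH windows at BRCA loci for biallelic samples, focal oncogene
  amplifications, and group-conditional regional LOH enrichment;
* expression is baseline plus a latent inflammation effect on the members
  of four packaged immune gene sets plus Gaussian noise; the latent
  inflammation score responds to HRD with opposite signs in the two
  tumor-type groups (dHpC: HRD hotter; dCpH: HRD colder) and negatively to
  regional LOH and oncogene amplification;
* cell fractions are Dirichlet draws whose concentration is tilted by the
  latent inflammation score for the tumor-reactive cell types.

All randomness flows from one ``numpy`` generator seeded by the config, so
a fixed config gives byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from hrdscape import io as hio
from hrdscape.datatypes import GeneSet, GenomeBuild, MutationRecord, VariantClass, default_genome
from hrdscape.spectra import CHANNELS, Spectrum96, default_panel

logger = logging.getLogger(__name__)

MB = 1_000_000
BASES = "ACGT"


# --------------------------------------------------------------------------
# packaged gene annotation on the synthetic genome
# --------------------------------------------------------------------------

DDR_GENES = [
    "BRCA1",
    "BRCA2",
    "PALB2",
    "RAD51C",
    "RAD51D",
    "BRIP1",
    "BARD1",
    "BLM",
    "FANCA",
    "FANCF",
    "FANCM",
    "FANCD2",
    "ATM",
    "ATR",
    "CHEK2",
    "PRKDC",
    "HERC2",
]

ONCOGENES = ["BCL11A", "BCL6", "CCND1", "CDK6", "EGFR", "FGFR1", "KRAS", "TERT"]

_GENE_PLACEMENT = {
    # gene: (chrom, start in Mb); each gene spans 0.1 Mb
    "TP53": ("1", 10),
    "PALB2": ("1", 40),
    "BCL11A": ("1", 60),
    "ATM": ("1", 120),
    "BCL6": ("1", 140),
    "FANCA": ("1", 150),
    "CHEK2": ("1", 170),
    "PRKDC": ("2", 20),
    "HERC2": ("2", 40),
    "CCND1": ("2", 80),
    "BRCA1": ("2", 110),
    "RAD51C": ("2", 120),
    "BRIP1": ("2", 130),
    "CDK6": ("2", 150),
    "BARD1": ("3", 10),
    "BRCA2": ("3", 30),
    "EGFR": ("3", 60),
    "BLM": ("3", 70),
    "FANCF": ("3", 95),
    "FGFR1": ("3", 110),
    "FANCM": ("4", 10),
    "FANCD2": ("4", 70),
    "KRAS": ("4", 20),
    "ATR": ("4", 50),
    "RAD51D": ("4", 80),
    "TERT": ("4", 90),
}


def default_gene_table() -> pd.DataFrame:
    """Gene intervals (0-based half-open) on the synthetic genome."""
    rows = [
        (gene, chrom, int(mb * MB), int(mb * MB) + 100_000)
        for gene, (chrom, mb) in _GENE_PLACEMENT.items()
    ]
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


def default_inflammation_sets(n_genes_per_set: int = 25) -> List[GeneSet]:
    """Four placeholder immune signatures (synthetic gene symbols).

    Stand-ins for the published type-I IFN / chemokine / IFN-gamma /
    cytotoxic-CD8 signatures, which are not redistributable; real GMTs can
    be substituted anywhere a gene-set list is accepted.
    """
    names = ["IFN_TYPE1", "CHEMOKINE_TCELL", "IFN_GAMMA", "CD8_CYTOTOXIC"]
    return [
        GeneSet(name=name, genes=frozenset(f"{name}_G{i:02d}" for i in range(n_genes_per_set)))
        for name in names
    ]


#: cell types grouped by the co-occurrence module they emulate
CELL_TYPES_CLUSTER1 = ["CD8_cytotoxic_exhausted", "Treg", "B_cell"]
CELL_TYPES_CLUSTER2 = ["macrophage", "mDC", "DC1", "DC2"]
CELL_TYPES_OTHER = ["neutrophil", "pDC", "plasma_cell", "CD4_naive", "CAF", "monocyte"]
CELL_TYPES = CELL_TYPES_CLUSTER1 + CELL_TYPES_CLUSTER2 + CELL_TYPES_OTHER


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TumorTypeConfig:
    name: str
    n_samples: int
    group: str  # dHpC / dCpH
    hrd_prevalence: float
    mmrd_rate: float = 0.04
    pole_rate: float = 0.02
    viral_positive_rate: float = 0.0
    female_fraction: float = 0.5


@dataclass(frozen=True)
class RegionEffect:
    """Group-conditional LOH enrichment of one genomic window."""

    chrom: str
    start: int
    end: int
    group: str  # tumor-type group whose HRD samples are enriched
    p_enriched: float = 0.8
    p_background: float = 0.2


@dataclass(frozen=True)
class ScarModel:
    """Segment-geometry parameters by HRD status."""

    breakpoint_rate_hrd: float = 4.0  # Poisson mean per chromosome
    breakpoint_rate_hrp: float = 1.2
    p_loh_hrd: float = 0.35  # per-segment LOH state probability
    p_loh_hrp: float = 0.06
    p_amp_hrd: float = 0.12
    p_amp_hrp: float = 0.04
    whole_chrom_loh_hrd: float = 0.05
    whole_chrom_loh_hrp: float = 0.01


@dataclass(frozen=True)
class InflammationModel:
    hrd_effect: Dict[str, float] = field(
        default_factory=lambda: {"dHpC": 1.2, "dCpH": -1.2}
    )
    region_is_effect: float = -0.8  # per planted-region LOH event
    og_amp_is_effect: float = -0.5
    amplitude: float = 2.0  # expression shift per latent-IS unit on set genes
    noise_sd: float = 1.0
    n_background_genes: int = 800
    genes_per_set: int = 25


@dataclass(frozen=True)
class CellFractionModel:
    base_alpha: float = 5.0
    tilt_cluster1: float = 0.8
    tilt_cluster2: float = 0.3
    tilt_caf: float = -0.3


@dataclass(frozen=True)
class CohortConfig:
    tumor_types: Tuple[TumorTypeConfig, ...]
    seed: int = 1
    #: signature-mixture weights by condition over the packaged panel
    signature_weights: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {
            "hrp": {"background": 0.55, "clock": 0.34, "sig3": 0.05, "mmr": 0.03, "pole": 0.02, "sbs45": 0.01},
            "hrd": {"background": 0.22, "clock": 0.15, "sig3": 0.57, "mmr": 0.03, "pole": 0.02, "sbs45": 0.01},
            "mmrd": {"background": 0.10, "clock": 0.18, "sig3": 0.02, "mmr": 0.68, "pole": 0.01, "sbs45": 0.01},
            "pole": {"background": 0.10, "clock": 0.05, "sig3": 0.02, "mmr": 0.03, "pole": 0.79, "sbs45": 0.01},
        }
    )
    #: (mu, sigma) of the log-normal SNV burden per condition
    snv_burden: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {
            "hrp": (np.log(120.0), 0.4),
            "hrd": (np.log(150.0), 0.4),
            "mmrd": (np.log(900.0), 0.3),
            "pole": (np.log(8000.0), 0.15),
        }
    )
    artifact_rate: float = 0.01
    artifact_sbs45_weight: float = 0.6
    #: Poisson means of (microhomology, non-microhomology) >= 5 bp deletions
    indel_rates: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {"hrd": (12.0, 6.0), "hrp": (1.0, 2.0)}
    )
    scar_model: ScarModel = ScarModel()
    region_effects: Tuple[RegionEffect, ...] = (
        RegionEffect("4", 60 * MB, 65 * MB, "dCpH", 0.8, 0.2),
        RegionEffect("3", 80 * MB, 86 * MB, "dHpC", 0.6, 0.15),
    )
    og_amp_prob_dcph_hrd: float = 0.45
    og_amp_prob_background: float = 0.08
    biallelic_brca_fraction: float = 0.5
    #: when False, biallelic BRCA loss is realized through mutation +
    #: silencing only (no locus LOH / deep-deletion windows), so the seeds
    #: leave no copy-number footprint — used by zero-effect null cohorts
    biallelic_cna_mechanisms: bool = True
    #: per-gene dysfunction probability of non-BRCA DDR genes
    ddr_alteration_rate_hrd: float = 0.08
    ddr_alteration_rate_hrp: float = 0.015
    tp53_alteration_rate_hrd: float = 0.5
    tp53_alteration_rate_hrp: float = 0.25
    inflammation: InflammationModel = InflammationModel()
    cell_fractions: CellFractionModel = CellFractionModel()

    def __post_init__(self) -> None:
        for tt in self.tumor_types:
            for p in (tt.hrd_prevalence, tt.mmrd_rate, tt.pole_rate, tt.viral_positive_rate):
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"probability out of [0, 1] in tumor type {tt.name}: {p}")
        for cond, weights in self.signature_weights.items():
            total = sum(weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"signature weights for {cond!r} sum to {total}, not 1")
            if any(w < 0 for w in weights.values()):
                raise ValueError(f"negative signature weight in {cond!r}")
        for eff in self.region_effects:
            for p in (eff.p_enriched, eff.p_background):
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"region-effect probability out of [0, 1]: {p}")


def default_config(seed: int = 1) -> CohortConfig:
    """The packaged three-type, 600-sample cohort with strong effects."""
    return CohortConfig(
        tumor_types=(
            TumorTypeConfig("OV-like", 200, "dHpC", 0.35, female_fraction=1.0),
            TumorTypeConfig("BRCA-like", 200, "dHpC", 0.25, female_fraction=0.95),
            TumorTypeConfig("LUSC-like", 200, "dCpH", 0.25, viral_positive_rate=0.2, female_fraction=0.4),
        ),
        seed=seed,
    )


def null_config(seed: int = 1) -> CohortConfig:
    """The same cohort with every HRD-linked effect zeroed.

    HRD samples keep their ground-truth flag (and the biallelic BRCA seeds
    attached to it) but receive the HRP signature mixture, indel rates, scar
    geometry and inflammation model, so features carry no signal about the
    flag.
    """
    cfg = default_config(seed)
    weights = dict(cfg.signature_weights)
    weights["hrd"] = dict(weights["hrp"])
    burden = dict(cfg.snv_burden)
    burden["hrd"] = burden["hrp"]
    return replace(
        cfg,
        signature_weights=weights,
        snv_burden=burden,
        indel_rates={"hrd": cfg.indel_rates["hrp"], "hrp": cfg.indel_rates["hrp"]},
        scar_model=ScarModel(
            breakpoint_rate_hrd=ScarModel().breakpoint_rate_hrp,
            breakpoint_rate_hrp=ScarModel().breakpoint_rate_hrp,
            p_loh_hrd=ScarModel().p_loh_hrp,
            p_loh_hrp=ScarModel().p_loh_hrp,
            p_amp_hrd=ScarModel().p_amp_hrp,
            p_amp_hrp=ScarModel().p_amp_hrp,
            whole_chrom_loh_hrd=ScarModel().whole_chrom_loh_hrp,
            whole_chrom_loh_hrp=ScarModel().whole_chrom_loh_hrp,
        ),
        region_effects=tuple(
            replace(eff, p_enriched=eff.p_background) for eff in cfg.region_effects
        ),
        og_amp_prob_dcph_hrd=cfg.og_amp_prob_background,
        biallelic_cna_mechanisms=False,
        ddr_alteration_rate_hrd=cfg.ddr_alteration_rate_hrp,
        tp53_alteration_rate_hrd=cfg.tp53_alteration_rate_hrp,
        inflammation=replace(
            cfg.inflammation, hrd_effect={"dHpC": 0.0, "dCpH": 0.0}, region_is_effect=0.0, og_amp_is_effect=0.0
        ),
    )


# --------------------------------------------------------------------------
# the generator
# --------------------------------------------------------------------------


@dataclass
class SimulatedCohort:
    mutations: List[MutationRecord]
    segments: pd.DataFrame
    expression: pd.DataFrame  # genes x samples
    cell_fractions: pd.DataFrame  # samples x cell types (rows sum to 1)
    annotations: pd.DataFrame
    germline: pd.DataFrame  # sample_id, gene
    silencing: pd.DataFrame  # sample_id, gene
    truth: pd.DataFrame
    gene_coords: pd.DataFrame
    gene_sets: List[GeneSet]
    genome: GenomeBuild
    config: CohortConfig


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _mutate_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in BASES if b != base]
    return choices[rng.integers(0, 3)]


_CHANNEL_PARTS = []
for _label in CHANNELS:
    _CHANNEL_PARTS.append((_label[0], _label[2], _label[4], _label[6]))  # 5', ref, alt, 3'


_SNV_CONSEQUENCES = ["Missense_Mutation", "Silent", "Nonsense_Mutation", "Splice_Site", "Nonstop_Mutation", "other"]
_SNV_CONSEQUENCE_P = [0.55, 0.25, 0.06, 0.04, 0.01, 0.09]


def _mixture_snv(rng: np.random.Generator, probs: np.ndarray) -> Tuple[str, str, str]:
    """Draw (ref, alt, context) from the sample's own channel mixture so
    targeted pathogenic hits do not distort the catalog shape."""
    k = int(rng.choice(96, p=probs))
    five, ref, alt, three = _CHANNEL_PARTS[k]
    return ref, alt, five + ref + three


def _snv_records(
    rng: np.random.Generator,
    sample_id: str,
    catalog_counts: np.ndarray,
    genome: GenomeBuild,
    gene_pool: Sequence[str],
) -> List[MutationRecord]:
    chroms = list(genome.lengths)
    lens = np.array([genome.lengths[c] for c in chroms], dtype=float)
    n = int(catalog_counts.sum())
    if n == 0:
        return []
    channel_idx = np.repeat(np.arange(96), catalog_counts.astype(int))
    ci = rng.choice(len(chroms), size=n, p=lens / lens.sum())
    pos = 1 + (rng.random(n) * (lens[ci] - 1)).astype(int)
    cons = rng.choice(len(_SNV_CONSEQUENCES), size=n, p=_SNV_CONSEQUENCE_P)
    genes = rng.integers(0, len(gene_pool), size=n)
    records: List[MutationRecord] = []
    for k, c, p, q, g in zip(channel_idx, ci, pos, cons, genes):
        five, ref, alt, three = _CHANNEL_PARTS[k]
        records.append(
            MutationRecord(
                sample_id=sample_id,
                chrom=chroms[c],
                pos=int(p),
                ref=ref,
                alt=alt,
                variant_class=VariantClass.SNV,
                consequence=_SNV_CONSEQUENCES[q],
                gene=gene_pool[g],
                trinucleotide_context=five + ref + three,
            )
        )
    return records


def _deletion_record(
    rng: np.random.Generator,
    sample_id: str,
    genome: GenomeBuild,
    with_mh: bool,
    length: Optional[int] = None,
) -> MutationRecord:
    """A deletion whose inline flanks carry (or avoid) >= 2 bp microhomology."""
    n = int(length if length is not None else rng.integers(5, 16))
    deleted = _random_seq(rng, n)
    flank = 20
    f5 = list(_random_seq(rng, flank))
    f3 = list(_random_seq(rng, flank))
    if with_mh and n >= 3:  # MH >= 2 requires a deletion of >= 3 bp
        m = int(rng.integers(2, min(6, n - 1) + 1))  # MH length in [2, min(6, n-1)]
        f3[:m] = list(deleted[:m])
        if m < flank:
            f3[m] = _mutate_base(rng, deleted[m]) if m < n else f3[m]
        # keep the 5' side below the MH threshold so the intended side defines it
        f5[-1] = _mutate_base(rng, deleted[-1])
    else:
        f3[0] = _mutate_base(rng, deleted[0])
        f5[-1] = _mutate_base(rng, deleted[-1])
    f5 = "".join(f5)
    f3 = "".join(f3)
    anchor = f5[-1]
    chroms = list(genome.lengths)
    chrom = chroms[rng.integers(0, len(chroms))]
    pos = int(rng.integers(1, genome.lengths[chrom] - n - 1))
    return MutationRecord(
        sample_id=sample_id,
        chrom=chrom,
        pos=pos,
        ref=anchor + deleted,
        alt=anchor,
        variant_class=VariantClass.DELETION,
        consequence="Frame_Shift_Del" if n % 3 else "In_Frame_Del",
        flank_5p=f5,
        flank_3p=f3,
    )


def _apply_window(
    segs: List[Tuple[int, int, float, float]],
    ws: int,
    we: int,
    state: Tuple[float, float],
) -> List[Tuple[int, int, float, float]]:
    """Override the copy-number state inside [ws, we), re-clipping segments."""
    out: List[Tuple[int, int, float, float]] = []
    for start, end, major, minor in segs:
        if end <= ws or start >= we:
            out.append((start, end, major, minor))
            continue
        if start < ws:
            out.append((start, ws, major, minor))
        if end > we:
            out.append((we, end, major, minor))
    out.append((ws, we, state[0], state[1]))
    return sorted(out)


def _segment_sample(
    rng: np.random.Generator,
    genome: GenomeBuild,
    hrd: bool,
    sex: str,
    model: ScarModel,
) -> Dict[str, List[Tuple[int, int, float, float]]]:
    bp_rate = model.breakpoint_rate_hrd if hrd else model.breakpoint_rate_hrp
    p_loh = model.p_loh_hrd if hrd else model.p_loh_hrp
    p_amp = model.p_amp_hrd if hrd else model.p_amp_hrp
    p_whole = model.whole_chrom_loh_hrd if hrd else model.whole_chrom_loh_hrp
    result: Dict[str, List[Tuple[int, int, float, float]]] = {}
    for chrom, length in genome.lengths.items():
        if chrom == "Y":
            continue
        if chrom == "X" and sex != "female":
            result[chrom] = [(0, length, 1.0, 0.0)]  # hemizygous X
            continue
        if rng.random() < p_whole:
            result[chrom] = [(0, length, float(rng.integers(1, 3)), 0.0)]
            continue
        n_bp = int(rng.poisson(bp_rate))
        cuts = sorted(int(x) for x in rng.integers(1, length, size=n_bp))
        bounds = [0] + cuts + [length]
        segs = []
        for s, e in zip(bounds, bounds[1:]):
            if e <= s:
                continue
            u = rng.random()
            if u < p_loh:
                state = (float(rng.integers(1, 3)), 0.0)
            elif u < p_loh + p_amp:
                state = (float(rng.integers(3, 5) - 1), 1.0)  # major 2-3
            else:
                state = (1.0, 1.0)
            segs.append((s, e, state[0], state[1]))
        result[chrom] = segs
    return result


def simulate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Generate a full synthetic cohort plus ground-truth labels."""
    rng = np.random.default_rng(config.seed)
    genome = default_genome()
    panel = {s.name: s for s in default_panel()}
    gene_coords = default_gene_table()
    gene_sets = default_inflammation_sets(config.inflammation.genes_per_set)
    gene_window = {
        g: (c, int(s), int(e))
        for g, c, s, e in zip(
            gene_coords["gene"], gene_coords["chrom"], gene_coords["start"], gene_coords["end"]
        )
    }
    background_genes = [f"GENE{i:04d}" for i in range(config.inflammation.n_background_genes)]

    mutations: List[MutationRecord] = []
    seg_rows: List[Tuple[str, str, int, int, float, float]] = []
    ann_rows = []
    truth_rows = []
    germline_rows = []
    silencing_rows = []
    latent_effects = []

    sample_counter = 0
    for tt in config.tumor_types:
        for _ in range(tt.n_samples):
            sample_id = f"S{sample_counter:04d}"
            sample_counter += 1
            sex = "female" if rng.random() < tt.female_fraction else "male"
            viral = "positive" if rng.random() < tt.viral_positive_rate else "negative"

            u = rng.random()
            if u < tt.mmrd_rate:
                condition = "mmrd"
            elif u < tt.mmrd_rate + tt.pole_rate:
                condition = "pole"
            elif u < tt.mmrd_rate + tt.pole_rate + tt.hrd_prevalence:
                condition = "hrd"
            else:
                condition = "hrp"
            hrd = condition == "hrd"
            hyper = {"mmrd": "MMRD", "pole": "POLE"}.get(condition, "MMRP")
            artifact = rng.random() < config.artifact_rate

            # BRCA status among HRD samples
            brca_status = "WT"
            if hrd and rng.random() < config.biallelic_brca_fraction:
                brca_status = "BRCA1-/-" if rng.random() < 0.6 else "BRCA2-/-"

            # ---- SNVs ----
            weights = dict(config.signature_weights[condition])
            if artifact:
                w45 = config.artifact_sbs45_weight
                scale = (1.0 - w45) / (1.0 - weights["sbs45"])
                weights = {k: v * scale for k, v in weights.items() if k != "sbs45"}
                weights["sbs45"] = w45
            probs = np.zeros(96)
            for name, w in weights.items():
                probs += w * panel[name].probs
            probs = probs / probs.sum()
            mu, sigma = config.snv_burden[condition]
            n_snv = max(5, int(rng.lognormal(mu, sigma)))
            catalog = rng.multinomial(n_snv, probs)
            mutations.extend(_snv_records(rng, sample_id, catalog, genome, background_genes))

            # ---- indels ----
            mh_rate, nomh_rate = config.indel_rates["hrd" if hrd else "hrp"]
            for _ in range(int(rng.poisson(mh_rate))):
                mutations.append(_deletion_record(rng, sample_id, genome, with_mh=True))
            for _ in range(int(rng.poisson(nomh_rate))):
                mutations.append(_deletion_record(rng, sample_id, genome, with_mh=False))
            for _ in range(int(rng.poisson(1.5))):  # short deletions, counted by neither class
                mutations.append(
                    _deletion_record(rng, sample_id, genome, with_mh=bool(rng.random() < 0.5), length=int(rng.integers(1, 5)))
                )

            # ---- DDR / TP53 dysfunction ----
            dysfunctional: List[str] = []
            if brca_status != "WT":
                dysfunctional.append("BRCA1" if brca_status == "BRCA1-/-" else "BRCA2")
            p_ddr = config.ddr_alteration_rate_hrd if hrd else config.ddr_alteration_rate_hrp
            for gene in DDR_GENES:
                if gene in ("BRCA1", "BRCA2"):
                    continue
                if rng.random() < p_ddr:
                    dysfunctional.append(gene)
            p_tp53 = config.tp53_alteration_rate_hrd if hrd else config.tp53_alteration_rate_hrp
            if rng.random() < p_tp53:
                dysfunctional.append("TP53")

            # windows forcing targeted copy-number states: (chrom, start, end, major, minor)
            forced_windows: List[Tuple[str, int, int, float, float]] = []
            for gene in dysfunctional:
                mechanism = rng.random()
                if gene in ("BRCA1", "BRCA2"):
                    chrom, gs, ge = gene_window[gene]
                    if not config.biallelic_cna_mechanisms:
                        # two non-CNA hits: pathogenic somatic + silencing
                        ref_b, alt_b, ctx_b = _mixture_snv(rng, probs)
                        mutations.append(
                            MutationRecord(
                                sample_id=sample_id,
                                chrom=chrom,
                                pos=gs + int(rng.integers(1, 100_000)),
                                ref=ref_b,
                                alt=alt_b,
                                variant_class=VariantClass.SNV,
                                consequence="Nonsense_Mutation",
                                gene=gene,
                                trinucleotide_context=ctx_b,
                            )
                        )
                        silencing_rows.append((sample_id, gene))
                        continue
                    pad = int(rng.integers(5, 15)) * MB
                    loh_window = (chrom, max(0, gs - pad), min(genome.lengths[chrom], ge + pad), 1.0, 0.0)
                    if mechanism < 0.10:
                        # homozygous (deep) deletion of the locus
                        forced_windows.append(
                            (chrom, max(0, gs - 200_000), min(genome.lengths[chrom], ge + 200_000), 0.0, 0.0)
                        )
                        continue
                    if mechanism < 0.55 or mechanism >= 0.90:
                        ref_b, alt_b, ctx_b = _mixture_snv(rng, probs)
                        mutations.append(
                            MutationRecord(
                                sample_id=sample_id,
                                chrom=chrom,
                                pos=gs + int(rng.integers(1, 100_000)),
                                ref=ref_b,
                                alt=alt_b,
                                variant_class=VariantClass.SNV,
                                consequence="Nonsense_Mutation",
                                gene=gene,
                                trinucleotide_context=ctx_b,
                            )
                        )
                    elif mechanism < 0.80:
                        germline_rows.append((sample_id, gene))
                    else:
                        silencing_rows.append((sample_id, gene))
                    if mechanism >= 0.90:
                        silencing_rows.append((sample_id, gene))  # second hit without LOH
                    else:
                        forced_windows.append(loh_window)
                else:
                    chrom, gs_, ge_ = gene_window[gene]
                    if mechanism < 0.7:
                        damaging = rng.random() < 0.6
                        ref_d, alt_d, ctx_d = _mixture_snv(rng, probs)
                        mutations.append(
                            MutationRecord(
                                sample_id=sample_id,
                                chrom=chrom,
                                pos=gs_ + int(rng.integers(1, 100_000)),
                                ref=ref_d,
                                alt=alt_d,
                                variant_class=VariantClass.SNV,
                                consequence="Nonsense_Mutation" if damaging else "Missense_Mutation",
                                sift=None if damaging else "deleterious(0.01)",
                                polyphen=None if damaging else "probably_damaging(0.99)",
                                gene=gene,
                                trinucleotide_context=ctx_d,
                            )
                        )
                    elif mechanism < 0.85:
                        germline_rows.append((sample_id, gene))
                    else:
                        silencing_rows.append((sample_id, gene))

            # ---- segments ----
            segs_by_chrom = _segment_sample(rng, genome, hrd, sex, config.scar_model)
            for chrom, ws, we, major, minor in forced_windows:
                segs_by_chrom[chrom] = _apply_window(segs_by_chrom[chrom], ws, we, (major, minor))

            region_loh_flags = {}
            for eff in config.region_effects:
                p = eff.p_enriched if (hrd and tt.group == eff.group) else eff.p_background
                flag = rng.random() < p
                region_loh_flags[f"{eff.chrom}:{eff.start}-{eff.end}"] = flag
                if flag:
                    segs_by_chrom[eff.chrom] = _apply_window(
                        segs_by_chrom[eff.chrom], eff.start, eff.end, (1.0, 0.0)
                    )

            og_p = (
                config.og_amp_prob_dcph_hrd
                if (hrd and tt.group == "dCpH")
                else config.og_amp_prob_background
            )
            og_amp = rng.random() < og_p
            if og_amp:
                n_amps = int(rng.integers(1, 4))
                for gene in rng.choice(ONCOGENES, size=n_amps, replace=False):
                    chrom, gs_, ge_ = gene_window[gene]
                    half = int(rng.integers(4, 12)) * 100_000  # focal: ~0.8-2.4 Mb span
                    ws = max(0, (gs_ + ge_) // 2 - half)
                    we = min(genome.lengths[chrom], (gs_ + ge_) // 2 + half)
                    gain = float(rng.integers(3, 5))  # major 3-4 (>= 2 above diploid baseline)
                    segs_by_chrom[chrom] = _apply_window(segs_by_chrom[chrom], ws, we, (gain, 1.0))

            for chrom, segs in segs_by_chrom.items():
                for s, e, major, minor in segs:
                    seg_rows.append((sample_id, chrom, s, e, major, minor))

            # ---- latent inflammation ----
            latent = float(rng.normal(0.0, 1.0))
            if hrd:
                latent += config.inflammation.hrd_effect.get(tt.group, 0.0)
            latent += config.inflammation.region_is_effect * sum(region_loh_flags.values())
            if og_amp:
                latent += config.inflammation.og_amp_is_effect

            msi = float(rng.uniform(5.0, 25.0)) if condition == "mmrd" else float(rng.uniform(0.0, 3.0))
            ann_rows.append((sample_id, tt.name, sex, viral, None, round(msi, 3)))
            truth_rows.append(
                {
                    "sample_id": sample_id,
                    "hrd_status": hrd,
                    "hypermutation_class": hyper,
                    "brca_status": brca_status,
                    "latent_is": latent,
                    "og_amp": og_amp,
                    "artifact": artifact,
                    **{f"region_loh_{k}": v for k, v in region_loh_flags.items()},
                }
            )
            latent_effects.append(latent)

    if truth_rows:
        truth = pd.DataFrame(truth_rows).set_index("sample_id")
    else:
        cols = [
            "sample_id", "hrd_status", "hypermutation_class", "brca_status",
            "latent_is", "og_amp", "artifact",
        ] + [f"region_loh_{e.chrom}:{e.start}-{e.end}" for e in config.region_effects]
        truth = pd.DataFrame(columns=cols).set_index("sample_id")
    samples = list(truth.index)

    # ---- expression ----
    set_genes = [g for gs in gene_sets for g in sorted(gs.genes)]
    all_genes = set_genes + DDR_GENES + ONCOGENES + ["TP53"] + background_genes
    n_genes = len(all_genes)
    baseline = rng.normal(7.0, 1.0, size=n_genes)
    in_any_set = np.array([g in set(set_genes) for g in all_genes], dtype=float)
    latent = np.array(latent_effects)
    infl = config.inflammation
    expr = (
        baseline[:, None]
        + infl.amplitude * in_any_set[:, None] * latent[None, :]
        + rng.normal(0.0, infl.noise_sd, size=(n_genes, len(samples)))
    )
    expression = pd.DataFrame(expr, index=all_genes, columns=samples)
    expression.index.name = "gene"

    # ---- cell fractions ----
    cf = config.cell_fractions
    tilts = np.array(
        [cf.tilt_cluster1] * len(CELL_TYPES_CLUSTER1)
        + [cf.tilt_cluster2] * len(CELL_TYPES_CLUSTER2)
        + [cf.tilt_caf if ct == "CAF" else 0.0 for ct in CELL_TYPES_OTHER]
    )
    fractions = np.empty((len(samples), len(CELL_TYPES)))
    for i, lat in enumerate(latent):
        alpha = cf.base_alpha * np.exp(tilts * lat)
        fractions[i] = rng.dirichlet(alpha)
    cell_fractions = pd.DataFrame(fractions, index=samples, columns=CELL_TYPES)
    cell_fractions.index.name = "sample_id"

    segments = pd.DataFrame(
        seg_rows, columns=["sample_id", "chrom", "start", "end", "major", "minor"]
    ).sort_values(["sample_id", "chrom", "start"], kind="stable").reset_index(drop=True)
    annotations = pd.DataFrame(ann_rows, columns=hio.ANNOTATION_COLUMNS)
    germline = pd.DataFrame(germline_rows, columns=["sample_id", "gene"]).drop_duplicates()
    silencing = pd.DataFrame(silencing_rows, columns=["sample_id", "gene"]).drop_duplicates()

    return SimulatedCohort(
        mutations=mutations,
        segments=segments,
        expression=expression,
        cell_fractions=cell_fractions,
        annotations=annotations,
        germline=germline,
        silencing=silencing,
        truth=truth.reset_index(),
        gene_coords=gene_coords,
        gene_sets=gene_sets,
        genome=genome,
        config=config,
    )


# --------------------------------------------------------------------------
# output
# --------------------------------------------------------------------------


def emit_truth_tables(truth: pd.DataFrame, outdir) -> None:
    """Write the ground-truth table(s) as TSV; round-trips via pandas."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def write_cohort(cohort: SimulatedCohort, outdir) -> None:
    """Write every pipeline input plus the truth tables under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hio.write_maf(cohort.mutations, outdir / "mutations.maf")
    hio.write_segments(cohort.segments, outdir / "segments.tsv")
    hio.write_matrix(cohort.expression, outdir / "expression.tsv", index_label="gene")
    hio.write_matrix(cohort.cell_fractions, outdir / "cell_fractions.tsv", index_label="sample_id")
    hio.write_annotations(cohort.annotations, outdir / "annotations.tsv")
    cohort.germline.to_csv(outdir / "germline.tsv", sep="\t", index=False)
    cohort.silencing.to_csv(outdir / "silencing.tsv", sep="\t", index=False)
    hio.write_gene_coords(cohort.gene_coords, outdir / "genes.tsv")
    hio.write_gmt(cohort.gene_sets, outdir / "inflammation_sets.gmt")
    emit_truth_tables(cohort.truth, outdir)
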