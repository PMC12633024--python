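"""Core domain types shared by all analysis stages.

Coordinate convention: every interval held in memory (segments, bins, genes,
centromeres) is 0-based half-open, so ``length == end - start``.  The tab-
separated input/output files use the field-standard 1-based inclusive
convention; conversion happens only in :mod:`hrdscape.io`.  Point positions of
mutations are kept 1-based (MAF convention) since no interval arithmetic is
done on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Mapping, Optional


class VariantClass(str, Enum):
    SNV = "SNV"
    INSERTION = "insertion"
    DELETION = "deletion"


#: Consequences treated as truncating (protein-disrupting regardless of
#: in-silico predictions).
TRUNCATING_CONSEQUENCES = frozenset(
    {
        "Nonsense_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "Translation_Start_Site",
        "Splice_Site",
    }
)

#: Non-truncating protein-altering consequences; pathogenicity for these
#: requires supporting SIFT/PolyPhen or ClinVar evidence.
NONSYNONYMOUS_CONSEQUENCES = frozenset(
    {
        "Missense_Mutation",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Nonstop_Mutation",
    }
)

KNOWN_CONSEQUENCES = TRUNCATING_CONSEQUENCES | NONSYNONYMOUS_CONSEQUENCES | {"Silent"}


def normalize_chrom(name: str) -> str:
    """Normalize a chromosome token: strip a leading ``chr``; map 23/24 to X/Y."""
    s = str(name).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s == "23":
        return "X"
    if s == "24":
        return "Y"
    return s


def normalize_consequence(token: str) -> str:
    token = str(token).strip()
    return token if token in KNOWN_CONSEQUENCES else "other"


@dataclass
class MutationRecord:
    """One somatic variant with consequence and pathogenicity annotations.

    ``pos`` is the 1-based position of the first reference base.  For indels
    the alleles follow the anchored style (e.g. ref ``ACGTAA`` / alt ``A`` is
    a 5-bp deletion).  ``flank_5p``/``flank_3p`` optionally carry reference
    sequence immediately surrounding the *changed* bases so microhomology can
    be assessed without a genome FASTA; ``trinucleotide_context`` carries the
    reference-strand 3-mer centered on an SNV.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: VariantClass
    consequence: str = "other"
    sift: Optional[str] = None
    polyphen: Optional[str] = None
    clinvar: Optional[str] = None
    gene: Optional[str] = None
    trinucleotide_context: Optional[str] = None
    flank_5p: Optional[str] = None
    flank_3p: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles are identical")
        if self.variant_class is VariantClass.DELETION and len(self.ref) <= len(self.alt):
            raise ValueError("deletion requires len(ref) > len(alt)")
        ctx = self.trinucleotide_context
        if ctx is not None:
            if len(ctx) != 3:
                raise ValueError(f"trinucleotide context must be a 3-mer, got {ctx!r}")
            if self.variant_class is VariantClass.SNV and ctx[1] != self.ref:
                raise ValueError(
                    f"context {ctx!r} does not have the reference base {self.ref!r} at its center"
                )
        self.chrom = normalize_chrom(self.chrom)

    @property
    def deleted_sequence(self) -> Optional[str]:
        """Bases removed by a deletion, with the shared allele prefix stripped."""
        if self.variant_class is not VariantClass.DELETION:
            return None
        k = 0
        while k < len(self.alt) and k < len(self.ref) and self.ref[k] == self.alt[k]:
            k += 1
        return self.ref[k:]


@dataclass(frozen=True)
class AlleleSpecificSegment:
    """One allele-specific copy-number segment (0-based half-open internally)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    major: float
    minor: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty segment [{self.start}, {self.end})")
        if self.major < self.minor:
            raise ValueError(f"major ({self.major}) < minor ({self.minor})")
        if self.minor < 0:
            raise ValueError("negative copy number")
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SampleAnnotation:
    sample_id: str
    tumor_type: str
    sex: str = "unknown"  # female / male / unknown
    viral_status: str = "unknown"  # negative / positive / unknown
    subtype: Optional[str] = None
    msi_score: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.tumor_type:
            raise ValueError("tumor_type must be non-empty")
        if self.sex not in ("female", "male", "unknown"):
            raise ValueError(f"unknown sex token {self.sex!r}")
        if self.viral_status not in ("negative", "positive", "unknown"):
            raise ValueError(f"unknown viral status {self.viral_status!r}")
        if self.msi_score is not None and self.msi_score < 0:
            raise ValueError("msi_score must be >= 0")


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set needs a name")
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "genes", frozenset(self.genes))

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GenomeBuild:
    """Chromosome lengths, centromere intervals and an optional sequence accessor.

    ``fetch(chrom, start, end)`` (0-based half-open) returns reference bases;
    it is only needed when mutation records do not carry inline context.
    """

    lengths: Mapping[str, int]
    centromeres: Mapping[str, tuple]
    fetch: Optional[Callable[[str, int, int], str]] = None

    def __post_init__(self) -> None:
        self.lengths = {normalize_chrom(c): int(n) for c, n in self.lengths.items()}
        self.centromeres = {
            normalize_chrom(c): (int(a), int(b)) for c, (a, b) in self.centromeres.items()
        }
        for chrom, (a, b) in self.centromeres.items():
            n = self.lengths.get(chrom)
            if n is None:
                raise ValueError(f"centromere given for unknown chromosome {chrom!r}")
            if not (0 <= a < b <= n):
                raise ValueError(f"centromere [{a}, {b}) outside chromosome {chrom} (len {n})")

    @property
    def chromosomes(self) -> list:
        return list(self.lengths)

    def autosomes(self) -> list:
        return [c for c in self.lengths if c not in ("X", "Y")]

    def check_interval(self, chrom: str, start: int, end: int) -> None:
        n = self.lengths.get(normalize_chrom(chrom))
        if n is None:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not (0 <= start < end <= n):
            raise ValueError(f"interval [{start}, {end}) outside {chrom} (len {n})")


def default_genome() -> GenomeBuild:
    """A compact synthetic genome used by the cohort simulator and tests.

    Four autosomes plus X, with centromeres placed off-center so that
    telomere/centromere-dependent scar definitions (TAI, per-arm LST) are
    exercised.  Sizes are in the 100–200 Mb range of real human chromosomes
    while keeping 100-kb binning desk-sized (~7,200 bins).
    """
    mb = 1_000_000
    lengths = {"1": 200 * mb, "2": 160 * mb, "3": 120 * mb, "4": 100 * mb, "X": 140 * mb}
    centromeres = {
        "1": (95 * mb, 100 * mb),
        "2": (60 * mb, 64 * mb),
        "3": (50 * mb, 54 * mb),
        "4": (38 * mb, 42 * mb),
        "X": (58 * mb, 62 * mb),
    }
    return GenomeBuild(lengths=lengths, centromeres=centromeres)
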