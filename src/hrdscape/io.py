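"""Readers and writers for the tab-separated interchange formats.

All files are UTF-8 TSV with a header row.  Genomic intervals are stored
1-based inclusive on disk (the MAF / segment-file convention) and converted
to the internal 0-based half-open convention here, and only here.
"""

from __future__ import annotations

import logging
from typing import Iterable, List, Optional

import pandas as pd

from hrdscape.datatypes import (
    AlleleSpecificSegment,
    GeneSet,
    MutationRecord,
    SampleAnnotation,
    VariantClass,
    normalize_chrom,
    normalize_consequence,
)

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


MAF_REQUIRED = [
    "Tumor_Sample_Barcode",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
]

_MAF_OPTIONAL = {
    "sift": "SIFT",
    "polyphen": "PolyPhen",
    "clinvar": "CLIN_SIG",
    "gene": "Hugo_Symbol",
    "trinucleotide_context": "CONTEXT",
    "flank_5p": "FLANK_5P",
    "flank_3p": "FLANK_3P",
}


def _opt(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    return s if s and s not in (".", "NA", "nan") else None


def _variant_class(ref: str, alt: str) -> VariantClass:
    # MAF sometimes encodes indels with a "-" allele; treat it as empty.
    ref = "" if ref == "-" else ref
    alt = "" if alt == "-" else alt
    if len(ref) == len(alt) == 1:
        return VariantClass.SNV
    if len(alt) > len(ref):
        return VariantClass.INSERTION
    return VariantClass.DELETION


def read_maf(path) -> List[MutationRecord]:
    """Read a MAF-dialect somatic mutation table (MC3-like column names).

    Unknown annotation columns map to absent optionals; unknown consequence
    tokens are preserved as ``"other"`` so downstream filters, not the
    parser, decide relevance.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    for col in MAF_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"MAF file {path} is missing mandatory column {col!r}")
    records: List[MutationRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        row = dict(zip(df.columns, row))
        try:
            pos = int(row["Start_Position"])
        except ValueError as exc:
            raise FormatError(
                f"non-numeric Start_Position {row['Start_Position']!r} at line {i} of {path}"
            ) from exc
        ref = row["Reference_Allele"].strip()
        alt = row["Tumor_Seq_Allele2"].strip()
        opt = {key: _opt(row.get(col)) for key, col in _MAF_OPTIONAL.items()}
        records.append(
            MutationRecord(
                sample_id=row["Tumor_Sample_Barcode"].strip(),
                chrom=row["Chromosome"],
                pos=pos,
                ref=ref,
                alt=alt,
                variant_class=_variant_class(ref, alt),
                consequence=normalize_consequence(row["Variant_Classification"]),
                **opt,
            )
        )
    return records


def write_maf(records: Iterable[MutationRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "Tumor_Sample_Barcode": r.sample_id,
                "Chromosome": r.chrom,
                "Start_Position": r.pos,
                "Reference_Allele": r.ref,
                "Tumor_Seq_Allele2": r.alt,
                "Variant_Classification": r.consequence,
                "SIFT": r.sift or "",
                "PolyPhen": r.polyphen or "",
                "CLIN_SIG": r.clinvar or "",
                "Hugo_Symbol": r.gene or "",
                "CONTEXT": r.trinucleotide_context or "",
                "FLANK_5P": r.flank_5p or "",
                "FLANK_3P": r.flank_3p or "",
            }
        )
    pd.DataFrame(rows, columns=MAF_REQUIRED + list(_MAF_OPTIONAL.values())).to_csv(
        path, sep="\t", index=False
    )


SEGMENT_COLUMNS = ["sample_id", "chrom", "start", "end", "major", "minor"]
_SEG_ALIASES = {
    "sample": "sample_id",
    "nmajor": "major",
    "nminor": "minor",
    "chromosome": "chrom",
}


def segments_frame(segments: Iterable[AlleleSpecificSegment]) -> pd.DataFrame:
    """Internal tabular form of a segment collection (0-based half-open)."""
    df = pd.DataFrame(
        [(s.sample_id, s.chrom, s.start, s.end, s.major, s.minor) for s in segments],
        columns=SEGMENT_COLUMNS,
    )
    return df.sort_values(["sample_id", "chrom", "start"], kind="stable").reset_index(drop=True)


def validate_segments(df: pd.DataFrame) -> pd.DataFrame:
    """Sort and check the segment invariants (no within-sample overlap, major >= minor)."""
    df = df.sort_values(["sample_id", "chrom", "start"], kind="stable").reset_index(drop=True)
    if (df["end"] <= df["start"]).any():
        bad = df[df["end"] <= df["start"]].iloc[0]
        raise FormatError(f"segment with end <= start: {tuple(bad[SEGMENT_COLUMNS])}")
    if (df["major"] < df["minor"]).any():
        bad = df[df["major"] < df["minor"]].iloc[0]
        raise FormatError(f"segment with minor > major: {tuple(bad[SEGMENT_COLUMNS])}")
    for (sample, chrom), sub in df.groupby(["sample_id", "chrom"], sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        overlap = starts[1:] < ends[:-1]
        if overlap.any():
            k = int(overlap.argmax())
            raise FormatError(
                f"overlapping segments for {sample}/{chrom}: "
                f"[{starts[k]}, {ends[k]}) and [{starts[k + 1]}, {ends[k + 1]})"
            )
    return df


def read_segments(path) -> pd.DataFrame:
    """Read an ASCAT-like allele-specific segment TSV.

    Returns a DataFrame with columns ``sample_id, chrom, start, end, major,
    minor`` in internal 0-based half-open coordinates, sorted by
    (sample, chrom, start); within-sample overlaps are rejected.
    """
    df = pd.read_csv(path, sep="\t")
    df.columns = [_SEG_ALIASES.get(str(c).strip().lower(), str(c).strip().lower()) for c in df.columns]
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"segment file {path} is missing column(s) {missing}")
    df = df[SEGMENT_COLUMNS].copy()
    df["chrom"] = df["chrom"].map(normalize_chrom)
    df["sample_id"] = df["sample_id"].astype(str)
    # 1-based inclusive on disk -> 0-based half-open in memory.
    df["start"] = df["start"].astype(int) - 1
    df["end"] = df["end"].astype(int)
    return validate_segments(df)


def write_segments(df: pd.DataFrame, path) -> None:
    out = df[SEGMENT_COLUMNS].copy()
    out["start"] = out["start"].astype(int) + 1  # back to 1-based inclusive
    out = out.rename(columns={"sample_id": "sample"})
    out.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> List[GeneSet]:
    """Read a GMT gene-set file (name, description, genes... per line)."""
    sets: List[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {i} of {path} has fewer than 3 fields")
            name = fields[0]
            genes = frozenset(g for g in fields[2:] if g)
            sets.append(GeneSet(name=name, genes=genes))
    return sets


def write_gmt(sets: Iterable[GeneSet], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.name, "na"] + sorted(s.genes)) + "\n")


ANNOTATION_COLUMNS = ["sample_id", "tumor_type", "sex", "viral_status", "subtype", "msi_score"]


def annotations_frame(annotations: Iterable[SampleAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (a.sample_id, a.tumor_type, a.sex, a.viral_status, a.subtype, a.msi_score)
            for a in annotations
        ],
        columns=ANNOTATION_COLUMNS,
    )


def read_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("sample_id", "tumor_type") if c not in df.columns]
    if missing:
        raise FormatError(f"annotation file {path} is missing column(s) {missing}")
    for col in ANNOTATION_COLUMNS:
        if col not in df.columns:
            df[col] = None
    df = df[ANNOTATION_COLUMNS].copy()
    df["sample_id"] = df["sample_id"].astype(str)
    for col in ("sex", "viral_status"):
        df[col] = df[col].fillna("unknown")
    df["subtype"] = df["subtype"].where(df["subtype"].notna(), None)
    return df


def write_annotations(df: pd.DataFrame, path) -> None:
    df[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_matrix(path) -> pd.DataFrame:
    """Read a numeric matrix TSV with row labels in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


GENE_COLUMNS = ["gene", "chrom", "start", "end"]


def read_gene_coords(path) -> pd.DataFrame:
    """Read gene intervals (TSV: gene, chrom, start, end; 1-based inclusive)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in GENE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"gene coordinate file {path} is missing column(s) {missing}")
    df = df[GENE_COLUMNS].copy()
    df["chrom"] = df["chrom"].map(normalize_chrom)
    df["start"] = df["start"].astype(int) - 1
    df["end"] = df["end"].astype(int)
    return df


def write_gene_coords(df: pd.DataFrame, path) -> None:
    out = df[GENE_COLUMNS].copy()
    out["start"] = out["start"].astype(int) + 1
    out.to_csv(path, sep="\t", index=False)
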