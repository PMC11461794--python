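"""Readers and writers for the on-disk formats.

Native formats are plain TSV (variant tables, depth profiles, alignment
geometry), BED + FASTA for the panel, and COSMIC-style TSV for signature
matrices. A minimal VCF 4.2 subset reader (INFO keys SVLEN/SVTYPE, FORMAT
AD/DP) is provided for interchange; TSV is authoritative.

Panel BED convention: column 4 is the locus name, column 5 the locus
class (``genic``, ``intergenic`` or ``mixed``).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from .model import (
    AlignmentSupport,
    DepthProfile,
    PanelLocus,
    PrimaryAlignment,
    SignatureMatrix,
    SupplementaryAlignment,
    VariantCall,
    VariantType,
)

__all__ = [
    "TableParseError",
    "read_variant_table",
    "write_variant_table",
    "read_depth_profile",
    "write_depth_profile",
    "read_panel_bed",
    "write_panel",
    "read_signature_matrix",
    "read_alignment_geometry",
    "write_alignment_geometry",
    "infer_vtype",
]

PathLike = Union[str, Path]

VARIANT_COLUMNS = [
    "sample",
    "chrom",
    "pos",
    "ref",
    "alt",
    "vtype",
    "alt_count",
    "site_depth",
    "sv_len",
]


class TableParseError(ValueError):
    """A row of an input table failed to parse or validate."""


def infer_vtype(ref: str, alt: str, sv_len: int | None = None) -> VariantType:
    """Infer the variant type from allele strings and the SVLEN field."""
    if alt.startswith("<"):
        if alt == "<INV>":
            return VariantType.INVERSION
        if alt == "<DUP>" or alt == "<INS>":
            return VariantType.INSERTION
        if alt == "<DEL>":
            return VariantType.DELETION
        raise TableParseError(f"unsupported symbolic allele {alt!r}")
    if len(ref) == 1 and len(alt) == 1:
        return VariantType.SNV
    if len(ref) == len(alt):
        return VariantType.MNV
    if len(ref) == 1 and len(alt) > 1 and alt[0] == ref:
        return VariantType.INSERTION
    if len(alt) == 1 and len(ref) > 1 and ref[0] == alt:
        return VariantType.DELETION
    return VariantType.COMPLEX


def read_variant_table(path: PathLike, dialect: str = "tsv") -> list[VariantCall]:
    """Read consensus variant calls from a TSV table or a VCF file.

    Every row is parsed or rejected with its line number. The variant
    type is inferred from ref/alt allele strings and SVLEN when the
    ``vtype`` column is absent or empty.
    """
    if dialect == "vcf":
        return _read_vcf(path)
    if dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}")

    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = {"sample", "chrom", "pos", "ref", "alt", "alt_count", "site_depth"}
        missing = required - set(header)
        if missing:
            raise TableParseError(f"{path}: missing required columns {sorted(missing)}")
        idx = {name: header.index(name) for name in header}
        calls: list[VariantCall] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")

            def get(col: str) -> str | None:
                if col not in idx or idx[col] >= len(fields):
                    return None
                value = fields[idx[col]]
                return None if value in (".", "") else value

            try:
                pos = int(get("pos"))  # type: ignore[arg-type]
            except (TypeError, ValueError):
                raise TableParseError(f"{path}:{lineno}: malformed coordinate {get('pos')!r}")
            sv_raw = get("sv_len")
            sv_len = int(sv_raw) if sv_raw is not None else None
            ref = get("ref") or ""
            alt = get("alt") or ""
            vtype_raw = get("vtype")
            vtype = VariantType(vtype_raw) if vtype_raw else infer_vtype(ref, alt, sv_len)
            try:
                calls.append(
                    VariantCall(
                        sample_id=get("sample") or "",
                        chrom=get("chrom") or "",
                        pos=pos,
                        ref=ref,
                        alt=alt,
                        vtype=vtype,
                        alt_count=int(get("alt_count")),  # type: ignore[arg-type]
                        site_depth=int(get("site_depth")),  # type: ignore[arg-type]
                        sv_len=sv_len,
                    )
                )
            except (TypeError, ValueError) as exc:
                raise TableParseError(f"{path}:{lineno}: {exc}") from exc
    return calls


def write_variant_table(calls: Iterable[VariantCall], path: PathLike) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(VARIANT_COLUMNS) + "\n")
        for c in calls:
            fh.write(
                "\t".join(
                    [
                        c.sample_id,
                        c.chrom,
                        str(c.pos),
                        c.ref,
                        c.alt,
                        c.vtype.value,
                        str(c.alt_count),
                        str(c.site_depth),
                        "." if c.sv_len is None else str(c.sv_len),
                    ]
                )
                + "\n"
            )


def _read_vcf(path: PathLike) -> list[VariantCall]:
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            sv_len = rec.info.get("SVLEN")
            if isinstance(sv_len, (tuple, list)):
                sv_len = sv_len[0]
            for sample_id, sample in rec.samples.items():
                ad = sample.get("AD")
                dp = sample.get("DP")
                if ad is None or dp is None:
                    continue
                alt_count = ad[1]
                if not alt_count:
                    continue
                alt = rec.alts[0]
                vtype = infer_vtype(rec.ref, alt, sv_len)
                calls.append(
                    VariantCall(
                        sample_id=sample_id,
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        vtype=vtype,
                        alt_count=int(alt_count),
                        site_depth=int(dp),
                        sv_len=None if sv_len is None else int(sv_len),
                    )
                )
    return calls


def read_depth_profile(
    path: PathLike, panel: list[PanelLocus], sample_id: str | None = None
) -> DepthProfile:
    """Read a per-position depth TSV (columns: chrom, pos, depth; 1-based).

    Reference-base depth totals (C/G vs T/A) are computed by consulting
    the panel sequence at every covered position.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "pos": int, "depth": int})
    if df.empty:
        raise TableParseError(f"{path}: no depth records")
    by_name = {loc.contig_name: loc for loc in panel}
    bad = df[~df["chrom"].isin(by_name)]
    if not bad.empty:
        raise TableParseError(
            f"{path}: positions outside panel on contigs {sorted(bad['chrom'].unique())}"
        )
    depth: dict[str, np.ndarray] = {
        loc.contig_name: np.zeros(len(loc), dtype=np.int64) for loc in panel
    }
    for chrom, group in df.groupby("chrom", sort=False):
        loc = by_name[str(chrom)]
        offsets = group["pos"].to_numpy() - 1 - loc.start
        if (offsets < 0).any() or (offsets >= len(loc)).any():
            offenders = group["pos"].to_numpy()[(offsets < 0) | (offsets >= len(loc))]
            raise TableParseError(
                f"{path}: positions outside locus {chrom}: {offenders[:10].tolist()}"
            )
        depth[str(chrom)][offsets] = group["depth"].to_numpy()
    return DepthProfile.from_arrays(sample_id or path.stem, depth, panel)


def write_depth_profile(profile: DepthProfile, panel: list[PanelLocus], path: PathLike) -> None:
    by_name = {loc.contig_name: loc for loc in panel}
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tdepth\n")
        for name, arr in profile.depth.items():
            start = by_name[name].start
            for i, d in enumerate(arr):
                fh.write(f"{name}\t{start + i + 1}\t{int(d)}\n")


def read_panel_bed(bed_path: PathLike, fasta_path: PathLike) -> list[PanelLocus]:
    """Read the panel definition and attach reference sequences.

    Overlapping intervals are accepted with a warning; intervals beyond
    the end of their contig are errors.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    loci: list[PanelLocus] = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise TableParseError(
                    f"{bed_path}:{lineno}: expected >= 5 columns (chrom start end name class)"
                )
            chrom, start_s, end_s, name, cls = fields[:5]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise TableParseError(f"{bed_path}:{lineno}: malformed coordinate")
            if chrom not in seqs:
                raise TableParseError(f"{bed_path}:{lineno}: contig {chrom!r} not in FASTA")
            if end > len(seqs[chrom]):
                raise TableParseError(
                    f"{bed_path}:{lineno}: interval end {end} beyond contig length {len(seqs[chrom])}"
                )
            loci.append(
                PanelLocus(
                    contig_name=name,
                    chrom=chrom,
                    start=start,
                    end=end,
                    cls=cls,
                    sequence=seqs[chrom][start:end],
                )
            )
    intervals = sorted((l.chrom, l.start, l.end) for l in loci)
    for (c1, s1, e1), (c2, s2, e2) in zip(intervals, intervals[1:]):
        if c1 == c2 and s2 < e1:
            warnings.warn(f"overlapping panel intervals on {c1}: [{s1},{e1}) and [{s2},{e2})")
            break
    return loci


def write_panel(panel: list[PanelLocus], bed_path: PathLike, fasta_path: PathLike) -> None:
    with open(fasta_path, "w") as fa:
        for loc in panel:
            fa.write(f">{loc.chrom}\n")
            for i in range(0, len(loc.sequence), 70):
                fa.write(loc.sequence[i : i + 70] + "\n")
    with open(bed_path, "w") as bed:
        for loc in panel:
            bed.write(f"{loc.chrom}\t{loc.start}\t{loc.end}\t{loc.contig_name}\t{loc.cls}\n")


def read_signature_matrix(path: PathLike) -> SignatureMatrix:
    """Read a COSMIC-style SBS96 signature TSV (rows "A[C>A]A" ...)."""
    from .spectra import SBS96_LABELS

    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(SBS96_LABELS) - set(df.index)
    if missing:
        raise TableParseError(f"{path}: missing {len(missing)} SBS96 context rows")
    df = df.loc[list(SBS96_LABELS)]
    return SignatureMatrix(names=list(df.columns), matrix=df.to_numpy(dtype=float))


GEOMETRY_COLUMNS = [
    "sample",
    "chrom",
    "pos",
    "allele_len",
    "concordant",
    "insert_size",
    "r1_start",
    "r1_end",
    "r1_strand",
    "r1_clip5",
    "r1_clip3",
    "r2_start",
    "r2_end",
    "r2_strand",
    "r2_clip5",
    "r2_clip3",
    "supp_read",
    "supp_start",
    "supp_end",
    "supp_strand",
]


def write_alignment_geometry(supports: Iterable[AlignmentSupport], path: PathLike) -> None:
    def fmt(x) -> str:
        return "." if x is None else str(x)

    with open(path, "w") as fh:
        fh.write("\t".join(GEOMETRY_COLUMNS) + "\n")
        for s in supports:
            supp_read = "1" if s.read1_supp is not None else ("2" if s.read2_supp is not None else None)
            supp = s.read1_supp or s.read2_supp
            row = [
                s.variant_key[0],
                s.variant_key[1],
                str(s.variant_key[2]),
                str(s.variant_key[3]),
                "1" if s.concordant else "0",
                fmt(s.insert_size),
                str(s.read1.aligned_start),
                str(s.read1.aligned_end),
                s.read1.strand,
                str(s.read1.softclip5),
                str(s.read1.softclip3),
                str(s.read2.aligned_start),
                str(s.read2.aligned_end),
                s.read2.strand,
                str(s.read2.softclip5),
                str(s.read2.softclip3),
                fmt(supp_read),
                fmt(None if supp is None else supp.aligned_start),
                fmt(None if supp is None else supp.aligned_end),
                fmt(None if supp is None else supp.strand),
            ]
            fh.write("\t".join(row) + "\n")


def read_alignment_geometry(path: PathLike) -> list[AlignmentSupport]:
    df = pd.read_csv(path, sep="\t", na_values=["."], dtype={"sample": str, "chrom": str})
    supports: list[AlignmentSupport] = []
    for row in df.itertuples(index=False):
        supp = None
        if isinstance(row.supp_strand, str):
            supp = SupplementaryAlignment(
                aligned_start=int(row.supp_start),
                aligned_end=int(row.supp_end),
                strand=row.supp_strand,
            )
        supports.append(
            AlignmentSupport(
                variant_key=(row.sample, row.chrom, int(row.pos), int(row.allele_len)),
                read1=PrimaryAlignment(
                    int(row.r1_start), int(row.r1_end), row.r1_strand,
                    int(row.r1_clip5), int(row.r1_clip3),
                ),
                read2=PrimaryAlignment(
                    int(row.r2_start), int(row.r2_end), row.r2_strand,
                    int(row.r2_clip5), int(row.r2_clip3),
                ),
                concordant=bool(int(row.concordant)),
                insert_size=None if pd.isna(row.insert_size) else int(row.insert_size),
                read1_supp=supp if row.supp_read == 1 else None,
                read2_supp=supp if row.supp_read == 2 else None,
            )
        )
    return supports
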