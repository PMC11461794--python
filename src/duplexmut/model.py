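"""Core data model for duplex-consensus variant analysis.

The pipeline operates on consensus-level variant calls from duplex
sequencing of a small targeted panel, together with per-position duplex
depth profiles, the panel definition (loci with reference sequence), and
alignment-geometry records used for circular-DNA analysis.

Coordinate conventions
----------------------
Variant positions are 1-based; for indels and structural variants ``pos``
is the anchor base *before* the inserted/deleted sequence (VCF style).
Panel loci are stored 0-based half-open (BED style); the conversion
happens only at the I/O boundary.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "VariantType",
    "VariantCall",
    "PanelLocus",
    "DepthProfile",
    "PrimaryAlignment",
    "SupplementaryAlignment",
    "AlignmentSupport",
    "SupportingFragment",
    "JunctionCall",
    "CircleAnalysisResult",
    "SignatureMatrix",
    "variant_class",
    "net_length",
    "SV_LENGTH_THRESHOLD",
]

#: insertions/deletions with |net length| above this are structural variants
SV_LENGTH_THRESHOLD = 1000


class VariantType(str, enum.Enum):
    SNV = "SNV"
    MNV = "MNV"
    INSERTION = "insertion"
    DELETION = "deletion"
    INVERSION = "inversion"
    COMPLEX = "complex"


@dataclass
class VariantCall:
    """One consensus-level variant record.

    ``alt_count`` is the number of distinct duplex source molecules
    supporting the alternate allele; ``site_depth`` the number of duplex
    molecules covering ``pos``. ``vaf`` is computed once at construction
    and is the single source of truth for every downstream threshold.
    """

    sample_id: str
    chrom: str
    pos: int  # 1-based anchor base
    ref: str
    alt: str
    vtype: VariantType
    alt_count: int
    site_depth: int
    sv_len: Optional[int] = None
    vaf: float = field(init=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.alt_count < 1:
            raise ValueError(f"alt_count must be >= 1, got {self.alt_count}")
        if self.alt_count > self.site_depth:
            raise ValueError(
                f"alt_count {self.alt_count} exceeds site_depth {self.site_depth}"
            )
        if self.vtype is VariantType.SNV and not (
            len(self.ref) == 1 and len(self.alt) == 1
        ):
            raise ValueError(f"SNV must have 1 bp ref and alt: {self.ref}>{self.alt}")
        if self.vtype is VariantType.MNV and not (
            len(self.ref) == len(self.alt) and len(self.ref) > 1
        ):
            raise ValueError(f"MNV must have equal ref/alt length > 1: {self.ref}>{self.alt}")
        self.vaf = self.alt_count / self.site_depth

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity of the mutational event (clonal copies share a key)."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def end(self) -> int:
        """1-based inclusive end of the reference footprint."""
        return self.pos + len(self.ref) - 1


def net_length(call: VariantCall) -> int:
    """Signed net change in allele length.

    For complex substitutions (reference sequence replaced by a different-
    length alternate) the net gain/loss classifies the event as insertion
    or deletion, and its magnitude is the indel length. Inversions use the
    SVLEN-style field when the alt is symbolic.
    """
    if call.sv_len is not None and (call.alt.startswith("<") or call.vtype is VariantType.INVERSION):
        return call.sv_len
    return len(call.alt) - len(call.ref)


def variant_class(call: VariantCall) -> str:
    """Coarse class used for burden reporting: SNV, MNV, indel, or SV.

    Indels are insertions/deletions with |net length| <= 1000 bp;
    larger ones, and all inversions, are structural variants.
    """
    if call.vtype is VariantType.SNV:
        return "SNV"
    if call.vtype is VariantType.MNV:
        return "MNV"
    if call.vtype is VariantType.INVERSION:
        return "SV"
    return "SV" if abs(net_length(call)) > SV_LENGTH_THRESHOLD else "indel"


@dataclass
class PanelLocus:
    """One target region of the capture panel, with attached sequence."""

    contig_name: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    cls: str  # genic | intergenic | mixed
    sequence: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty locus {self.contig_name}: [{self.start}, {self.end})")
        if len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"sequence length {len(self.sequence)} != locus span "
                f"{self.end - self.start} for {self.contig_name}"
            )
        if self.cls not in ("genic", "intergenic", "mixed"):
            raise ValueError(f"unknown locus class {self.cls!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class DepthProfile:
    """Per-position duplex depth over the panel for one sample.

    ``depth`` maps contig name -> int array over the locus span. Totals at
    C/G versus T/A reference positions are the denominators for the
    substitution-subtype rates.
    """

    sample_id: str
    depth: dict[str, np.ndarray]
    total_duplex_bases: int = 0
    depth_at_CG: int = 0
    depth_at_TA: int = 0

    @classmethod
    def from_arrays(
        cls, sample_id: str, depth: dict[str, np.ndarray], panel: list[PanelLocus]
    ) -> "DepthProfile":
        by_name = {loc.contig_name: loc for loc in panel}
        cg = ta = 0
        for name, arr in depth.items():
            loc = by_name[name]
            seq = np.frombuffer(loc.sequence.upper().encode(), dtype="S1")
            is_cg = (seq == b"C") | (seq == b"G")
            cg += int(arr[is_cg].sum())
            ta += int(arr[~is_cg].sum())
        return cls(
            sample_id=sample_id,
            depth=depth,
            total_duplex_bases=cg + ta,
            depth_at_CG=cg,
            depth_at_TA=ta,
        )

    def locus_total(self, contig_name: str) -> int:
        return int(self.depth[contig_name].sum())

    def depth_at(self, contig_name: str, pos: int) -> int:
        """Duplex depth at a 1-based position on a panel contig."""
        return int(self.depth[contig_name][pos - 1])


@dataclass
class PrimaryAlignment:
    """Primary alignment of one consensus read (0-based half-open)."""

    aligned_start: int
    aligned_end: int
    strand: str  # fwd | rev
    softclip5: int = 0
    softclip3: int = 0

    def __post_init__(self) -> None:
        if self.aligned_end < self.aligned_start:
            raise ValueError("aligned_end < aligned_start")
        if self.softclip5 < 0 or self.softclip3 < 0:
            raise ValueError("negative soft-clip length")
        if self.strand not in ("fwd", "rev"):
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass
class SupplementaryAlignment:
    aligned_start: int
    aligned_end: int
    strand: str


@dataclass
class AlignmentSupport:
    """Geometry of one duplex consensus read pair supporting a junction.

    Discordant pairs carry a supplementary alignment on one mate spanning
    the junction; concordant pairs carry a computed insert size.
    """

    variant_key: tuple[str, str, int, int]  # (sample_id, chrom, pos, allele_length)
    read1: PrimaryAlignment
    read2: PrimaryAlignment
    concordant: bool
    insert_size: Optional[int] = None
    read1_supp: Optional[SupplementaryAlignment] = None
    read2_supp: Optional[SupplementaryAlignment] = None

    def __post_init__(self) -> None:
        if self.concordant and self.insert_size is None:
            raise ValueError("concordant support requires insert_size")


@dataclass
class SupportingFragment:
    """One physical DNA fragment inferred from a consensus read pair."""

    fragment_length: int
    contains_duplicated_or_flanking: bool
    geometry: str  # discordant_split | concordant


@dataclass
class JunctionCall:
    """A putative D-A junction event (apparent large insertion).

    The inserted allele ABCD may arise from excision+circularization or
    from a chromosomal tandem duplication; both fuse the end (D) to the
    beginning (A) of the reference allele.
    """

    variant_key: tuple[str, str, int]
    allele_length: int
    has_DA_junction: bool
    vaf: float
    match_position: Optional[int] = None
    supporting_fragments: list[SupportingFragment] = field(default_factory=list)
    classification: str = "ambiguous"  # circle_consistent | tandem_duplication | ambiguous


@dataclass
class CircleAnalysisResult:
    """Cohort- or sample-level summary of the circular-DNA analysis."""

    n_insertions_gt20: int
    n_with_junction: int
    subset_below_median: list[JunctionCall]
    n_fragments_below_median: int
    binomial_p: Optional[float]
    candidate_microdnas: list[JunctionCall]
    candidate_frequency: Optional[float] = None
    candidate_count_vaf_filtered: Optional[int] = None


@dataclass
class SignatureMatrix:
    """COSMIC-style SBS96 signature matrix (columns sum to one)."""

    names: list[str]
    matrix: np.ndarray  # 96 x k

    def __post_init__(self) -> None:
        if self.matrix.shape != (96, len(self.names)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match {len(self.names)} names"
            )
        if np.any(self.matrix < 0):
            raise ValueError("signature matrix has negative entries")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("signature columns must sum to 1")
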