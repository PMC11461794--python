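"""Detection and classification of putative circular DNA (microDNA).

Apparent large insertions whose inserted allele is an exact (or
near-exact) copy of the reference immediately downstream of the variant
position carry a D-A junction: the end (D) of a reference allele ABCD
fused to its beginning (A). Such junctions arise either from excision
and circularization of ABCD, or from a chromosomal tandem duplication
(TD). The two origins are discriminated by the physical fragment
lengths supporting the junction:

* a circle must be cleaved to enter the sequencing library, so every
  supporting fragment is at most the allele length and contains no
  duplicated or flanking sequence;
* a TD sits on ordinary chromosomal DNA, so fragment lengths mirror the
  library insert-size distribution independent of allele length, and
  any fragment longer than its allele necessarily contains duplicated
  ABCD and possibly flanking sequence.

Restricting to junction events with allele length at most the library
median insert size gives the subset where duplicated sequence would be
detectable; under the all-TD null about half of those fragments should
exceed the median, which an exact one-sided binomial test evaluates.
No VAF filter is applied to large insertions.
"""

from __future__ import annotations

import logging
import math
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .model import (
    AlignmentSupport,
    CircleAnalysisResult,
    JunctionCall,
    PanelLocus,
    SupportingFragment,
    VariantCall,
    VariantType,
    net_length,
)

__all__ = [
    "detect_DA_junction",
    "infer_fragment_length",
    "AmbiguousFragmentError",
    "classify_circle_vs_td",
    "binomial_subset_test",
    "call_candidate_microdnas",
    "analyze_circles",
    "median_insert_size",
    "CANDIDATE_MIN_ALLELE",
]

logger = logging.getLogger(__name__)

#: junction-positive events must exceed this allele length (strict) to be
#: called candidate microDNAs
CANDIDATE_MIN_ALLELE = 125


def _hamming_match_positions(
    contig: str, pattern: str, max_mismatch: int
) -> np.ndarray:
    """0-based start offsets where pattern matches contig with at most
    ``max_mismatch`` mismatches (fixed-length, no indels)."""
    c = np.frombuffer(contig.upper().encode(), dtype=np.uint8)
    p = np.frombuffer(pattern.upper().encode(), dtype=np.uint8)
    if len(p) > len(c):
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(c, len(p))
    mismatches = (windows != p).sum(axis=1)
    return np.nonzero(mismatches <= max_mismatch)[0]


def detect_DA_junction(
    call: VariantCall,
    chrom_seq: str,
    mismatch_per_bp: float = 1 / 50,
) -> tuple[bool, Optional[int]]:
    """Test whether an insertion call supports a D-A junction.

    The inserted allele sequence is searched against the call's own
    contig allowing ``floor(allele_length * mismatch_per_bp)``
    mismatches (so alleles shorter than 50 bp allow none). The call is
    junction-positive iff a match starts exactly 1 bp downstream of the
    variant position — with anchor-base insertions this is the unique
    placement making the insert a copy of the downstream reference.

    Returns (junction_positive, 1-based match start or None).
    """
    allele = call.alt[1:] if not call.alt.startswith("<") else ""
    if len(allele) < 20:
        raise ValueError("allele sequence must be >= 20 bp for junction search")
    max_mm = math.floor(len(allele) * mismatch_per_bp)
    hits = _hamming_match_positions(chrom_seq, allele, max_mm)
    # 1-based match start = offset + 1; junction requires start == pos + 1
    positive = bool((hits == call.pos).any())
    if positive:
        return True, call.pos + 1
    return False, int(hits[0]) + 1 if len(hits) else None


class AmbiguousFragmentError(ValueError):
    """Fragment geometry is incomplete or inconsistent."""


def infer_fragment_length(support: AlignmentSupport) -> int:
    """Infer the physical DNA fragment length from read-pair geometry.

    Concordant pairs: the computed insert size plus any 5' soft-clipped
    bases (5' clips at a D-A junction align to the other end of the
    allele, so they extend the physical fragment). Discordant pairs: a
    pseudo-pair is formed from the primary alignment of one read and the
    supplementary alignment of the other; the length is the right-most
    end of the reverse-aligned member minus the left-most start of the
    forward-aligned member, again counting 5' clips that extend beyond
    the aligned span. 3' soft clips are adapter read-through on short
    fragments and never contribute.
    """
    if support.concordant:
        return support.insert_size + support.read1.softclip5 + support.read2.softclip5
    if support.read2_supp is not None:
        primary, supp = support.read1, support.read2_supp
    elif support.read1_supp is not None:
        primary, supp = support.read2, support.read1_supp
    else:
        raise AmbiguousFragmentError("discordant pair lacks a supplementary alignment")
    if primary.strand == supp.strand:
        raise AmbiguousFragmentError("pseudo-pair members on the same strand")
    if primary.strand == "fwd":
        left = primary.aligned_start - primary.softclip5
        right = supp.aligned_end
    else:
        left = supp.aligned_start
        right = primary.aligned_end + primary.softclip5
    if right <= left:
        raise AmbiguousFragmentError("non-positive inferred fragment length")
    return right - left


def classify_circle_vs_td(jc: JunctionCall, median_insert: int) -> str:
    """Classify a junction-positive event as circle-consistent or TD.

    TD iff any supporting fragment contains duplicated/flanking sequence
    (fragment longer than the allele); circle-consistent iff all
    fragments are at most the allele length with no duplicated sequence;
    ambiguous when no usable fragment geometry exists.
    """
    if not jc.supporting_fragments:
        return "ambiguous"
    if any(
        f.contains_duplicated_or_flanking or f.fragment_length > jc.allele_length
        for f in jc.supporting_fragments
    ):
        return "tandem_duplication"
    return "circle_consistent"


def binomial_subset_test(
    subset: Sequence[JunctionCall], median_insert: int
) -> tuple[int, int, Optional[float]]:
    """Exact one-sided binomial test on short-allele junction events.

    ``subset`` holds junction calls with allele length <= the library
    median insert size. Under the all-TD null, fragment length is
    independent of allele length, so each supporting fragment is shorter
    than the median with probability 1/2. Returns (k_below, n,
    P(X >= k_below | n, 0.5)), or (0, 0, None) for an empty subset.
    """
    lengths = [f.fragment_length for jc in subset for f in jc.supporting_fragments]
    n = len(lengths)
    if n == 0:
        return 0, 0, None
    k = sum(length < median_insert for length in lengths)
    p = float(sps.binomtest(k, n, 0.5, alternative="greater").pvalue)
    return k, n, p


def median_insert_size(insert_sizes: Sequence[int]) -> int:
    """Library median insert size from concordant-pair insert sizes."""
    if not insert_sizes:
        raise ValueError("no insert sizes supplied")
    return int(np.median(np.asarray(insert_sizes)))


def call_candidate_microdnas(
    junction_calls: Sequence[JunctionCall],
    duplex_bases: Optional[int] = None,
    vaf_max: Optional[float] = None,
) -> CircleAnalysisResult:
    """Summary-level candidate-microDNA calling (no VAF filter by default).

    Candidates are junction-positive events with allele length strictly
    greater than 125 bp. When ``vaf_max`` is supplied an additional
    count restricted to VAF < vaf_max is reported for consistency with
    the gated burden statistics.
    """
    gt20 = [jc for jc in junction_calls if jc.allele_length > 20]
    positive = [jc for jc in gt20 if jc.has_DA_junction]
    candidates = [jc for jc in positive if jc.allele_length > CANDIDATE_MIN_ALLELE]
    return CircleAnalysisResult(
        n_insertions_gt20=len(gt20),
        n_with_junction=len(positive),
        subset_below_median=[],
        n_fragments_below_median=0,
        binomial_p=None,
        candidate_microdnas=candidates,
        candidate_frequency=(len(candidates) / duplex_bases if duplex_bases else None),
        candidate_count_vaf_filtered=(
            sum(jc.vaf < vaf_max for jc in candidates) if vaf_max is not None else None
        ),
    )


def analyze_circles(
    calls: Sequence[VariantCall],
    panel: Sequence[PanelLocus],
    geometry: Sequence[AlignmentSupport],
    median_insert: int,
    duplex_bases: Optional[int] = None,
    vaf_max: Optional[float] = None,
    mismatch_per_bp: float = 1 / 50,
) -> tuple[list[JunctionCall], CircleAnalysisResult]:
    """Full circular-DNA analysis of one sample or pooled cohort.

    Takes unique (clonally collapsed) calls *before* any VAF gate,
    detects D-A junctions among apparent insertions with allele length
    >= 20 bp, attaches inferred fragment lengths, classifies each
    junction event, and runs the short-allele binomial test.
    """
    by_name = {loc.contig_name: loc for loc in panel}
    frag_by_key: dict[tuple, list[SupportingFragment]] = {}
    for support in geometry:
        try:
            length = infer_fragment_length(support)
        except AmbiguousFragmentError as exc:
            logger.info("skipping fragment for %s: %s", support.variant_key, exc)
            continue
        frag_by_key.setdefault(tuple(support.variant_key), []).append(
            SupportingFragment(
                fragment_length=length,
                contains_duplicated_or_flanking=False,  # set once allele known
                geometry="concordant" if support.concordant else "discordant_split",
            )
        )

    junction_calls: list[JunctionCall] = []
    for c in calls:
        if c.vtype not in (VariantType.INSERTION, VariantType.COMPLEX):
            continue
        allele_len = net_length(c)
        if allele_len < 20 or c.alt.startswith("<"):
            continue
        loc = by_name.get(c.chrom)
        if loc is None:
            continue
        positive, match_pos = detect_DA_junction(c, loc.sequence, mismatch_per_bp)
        frags = frag_by_key.get((c.sample_id, c.chrom, c.pos, allele_len), [])
        for f in frags:
            f.contains_duplicated_or_flanking = f.fragment_length > allele_len
        jc = JunctionCall(
            variant_key=(c.sample_id, c.chrom, c.pos),
            allele_length=allele_len,
            has_DA_junction=positive,
            vaf=c.vaf,
            match_position=match_pos,
            supporting_fragments=frags,
        )
        if positive:
            jc.classification = classify_circle_vs_td(jc, median_insert)
        junction_calls.append(jc)

    result = call_candidate_microdnas(junction_calls, duplex_bases, vaf_max)
    subset = [
        jc
        for jc in junction_calls
        if jc.has_DA_junction and jc.allele_length <= median_insert
    ]
    k, n, p = binomial_subset_test(subset, median_insert)
    result.subset_below_median = subset
    result.n_fragments_below_median = k
    result.binomial_p = p
    return junction_calls, result
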