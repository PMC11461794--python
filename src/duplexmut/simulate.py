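"""Synthetic duplex-sequencing cohort generator with ground truth.

Generates everything the analysis consumes — a targeted panel with
reference sequences, per-sample consensus variant tables, per-position
duplex depth profiles, and alignment-geometry records for junction
events — with every implanted event labeled, so each downstream stage
can be tested for exact recovery.

The generator emulates the statistical structure of deep targeted duplex
data from matched blood and sperm: ~1.2-1.3 Gb of duplex bases per
sample over a 48 kb panel (~27,000x molecular depth), heterozygous
germline variants at VAF ~ 50%, clonally expanded somatic mutations,
Poisson-distributed singleton SNVs/MNVs/indels/SVs at tissue-specific
rates, cross-sample contaminant pairs, realignment-artifact SNVs near
indels and over clonal MNVs, and apparent large insertions carrying D-A
junctions of either circular-DNA or tandem-duplication origin with
self-consistent fragment geometries.

It does not model read-level sequence error (consensus errors are
assumed removed upstream) or alignment noise.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import (
    AlignmentSupport,
    DepthProfile,
    PanelLocus,
    PrimaryAlignment,
    SupplementaryAlignment,
    VariantCall,
    VariantType,
)

__all__ = [
    "GeneratorConfig",
    "CohortTruth",
    "SyntheticSample",
    "SyntheticCohort",
    "generate_panel",
    "generate_sample",
    "generate_cohort",
    "generate_junction_reads",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: consensus read length used for synthetic alignment geometry
READ_LEN = 140


@dataclass
class GeneratorConfig:
    """Study conditions for one tissue.

    Rates are per duplex base; the defaults reproduce deep targeted
    duplex sequencing of blood or sperm from healthy young men
    (use :meth:`blood` / :meth:`sperm`).
    """

    tissue: str = "sperm"
    n_samples: int = 6
    duplex_bases_per_sample: int = 1_250_000_000
    snv_mf: float = 2.5e-8
    mnv_mf: float = 4.0e-10
    indel_mf: float = 3.2e-8  # small (non-junction) indels only
    sv_mf: float = 3.7e-9  # inversions and >1 kb deletions
    sbs6_weights: tuple[float, ...] = (0.08, 0.04, 0.46, 0.11, 0.26, 0.05)
    cpg_ct_fraction: float = 0.36
    germline_het_per_kb: float = 0.8
    clonal_fraction_snv: float = 0.04
    clonal_fraction_non_snv: float = 0.30
    clonal_as_duplicates: bool = False
    circle_count: int = 50
    td_count: int = 1
    random_insertion_count: int = 2
    circle_modes: tuple[float, ...] = (180.0, 370.0, 560.0)
    circle_mode_weights: tuple[float, ...] = (0.5, 0.3, 0.2)
    circle_mode_sd: float = 25.0
    circle_min_length: int = 130
    td_allele_length: int = 75
    median_insert_size: int = 233
    insert_size_sd: float = 45.0
    contaminants_per_sample: int = 1
    mnv_partial_snv_count: int = 1
    indel_proximal_snv_count: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duplex_bases_per_sample <= 0:
            raise ValueError("duplex_bases_per_sample must be > 0")
        for r in (self.snv_mf, self.mnv_mf, self.indel_mf, self.sv_mf):
            if r < 0:
                raise ValueError("rates must be >= 0")
        if abs(sum(self.sbs6_weights) - 1.0) > 1e-9:
            raise ValueError("sbs6_weights must sum to 1")

    @classmethod
    def sperm(cls, **overrides) -> "GeneratorConfig":
        return cls(**{**dict(tissue="sperm"), **overrides})

    @classmethod
    def blood(cls, **overrides) -> "GeneratorConfig":
        defaults = dict(
            tissue="blood",
            snv_mf=1.2e-7,
            mnv_mf=1.3e-9,
            indel_mf=7.6e-9,
            sv_mf=3.8e-10,
            sbs6_weights=(0.14, 0.06, 0.53, 0.07, 0.12, 0.08),
            cpg_ct_fraction=0.35,
            circle_count=0,
            td_count=0,
            random_insertion_count=1,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class CohortTruth:
    """Ground-truth labels for every implanted event."""

    seed: int
    events: list[dict] = field(default_factory=list)

    def count(self, label: str, sample_id: str | None = None) -> int:
        return sum(
            1
            for e in self.events
            if e["label"] == label and (sample_id is None or e["sample_id"] == sample_id)
        )

    def of(self, label: str, sample_id: str | None = None) -> list[dict]:
        return [
            e
            for e in self.events
            if e["label"] == label and (sample_id is None or e["sample_id"] == sample_id)
        ]


@dataclass
class SyntheticSample:
    sample_id: str
    tissue: str
    calls: list[VariantCall]
    depth: DepthProfile
    geometry: list[AlignmentSupport]


@dataclass
class SyntheticCohort:
    panel: list[PanelLocus]
    samples: dict[str, SyntheticSample]
    truth: CohortTruth

    def calls_by_sample(self) -> dict[str, list[VariantCall]]:
        return {sid: s.calls for sid, s in self.samples.items()}


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    # independent, reproducible stream per (seed, sample); crc32 keeps the
    # key stable across runs and below 2**32
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(sample_id.encode())]))


def _random_sequence(rng: np.random.Generator, length: int, gc_fraction: float) -> str:
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    seq = rng.choice(_BASES, size=length, p=p)
    # break homopolymers longer than 8 bp by resampling the offending base
    run = 1
    for i in range(1, length):
        if seq[i] == seq[i - 1]:
            run += 1
            if run > 8:
                others = _BASES[_BASES != seq[i]]
                seq[i] = rng.choice(others)
                run = 1
        else:
            run = 1
    return seq.tobytes().decode()


def generate_panel(
    n_loci: int = 20,
    locus_len: int = 2400,
    gc_fraction: float = 0.41,
    seed: int = 0,
) -> list[PanelLocus]:
    """Generate a synthetic capture panel of independent loci.

    Each locus is its own contig. With the standard 20-locus panel the
    genic/intergenic/mixed labels are assigned 10/6/4; sequences match a
    target GC fraction and avoid homopolymers longer than 8 bp.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if not (0 < gc_fraction < 1):
        raise ValueError(f"gc_fraction must be in (0, 1), got {gc_fraction}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 422]))
    if n_loci == 20:
        classes = ["genic"] * 10 + ["intergenic"] * 6 + ["mixed"] * 4
    else:
        classes = [("genic", "intergenic")[i % 2] for i in range(n_loci)]
    panel = []
    for i in range(n_loci):
        name = f"locus{i + 1:02d}"
        panel.append(
            PanelLocus(
                contig_name=name,
                chrom=name,
                start=0,
                end=locus_len,
                cls=classes[i],
                sequence=_random_sequence(rng, locus_len, gc_fraction),
            )
        )
    return panel


class _PositionPools:
    """Index of panel positions by pyrimidine-collapsed reference base and
    CpG status, used to place substitutions with the desired context mix."""

    def __init__(self, panel: Sequence[PanelLocus]):
        self.panel = list(panel)
        c_pos, t_pos, cpg, non_cpg_c = [], [], [], []
        for li, loc in enumerate(self.panel):
            seq = loc.sequence
            for i in range(1, len(seq) - 1):
                b = seq[i]
                entry = (li, i)
                if b in "CG":
                    c_pos.append(entry)
                    is_cpg = (b == "C" and seq[i + 1] == "G") or (
                        b == "G" and seq[i - 1] == "C"
                    )
                    (cpg if is_cpg else non_cpg_c).append(entry)
                else:
                    t_pos.append(entry)
        self.by_pyr = {"C": c_pos, "T": t_pos}
        self.cpg = cpg
        self.non_cpg_c = non_cpg_c

    def draw(self, rng: np.random.Generator, pool: list[tuple[int, int]]) -> tuple[int, int]:
        return pool[int(rng.integers(len(pool)))]


def _snv_at(
    panel: Sequence[PanelLocus],
    li: int,
    i: int,
    sbs6_class: str,
) -> tuple[str, int, str, str]:
    """Materialize an SNV of the given pyrimidine-collapsed class at a
    panel position, respecting the reference strand."""
    loc = panel[li]
    ref = loc.sequence[i]
    pyr_ref, pyr_alt = sbs6_class[0], sbs6_class[2]
    if ref in "CT":
        alt = pyr_alt
    else:
        alt = _COMPLEMENT[pyr_alt]
    return loc.contig_name, loc.start + i + 1, ref, alt


def _depth_arrays(
    rng: np.random.Generator, config: GeneratorConfig, panel: Sequence[PanelLocus]
) -> dict[str, np.ndarray]:
    panel_len = sum(len(loc) for loc in panel)
    mean_depth = config.duplex_bases_per_sample / panel_len
    depth = {}
    for loc in panel:
        d = int(round(mean_depth * np.exp(rng.normal(0.0, 0.08))))
        depth[loc.contig_name] = np.full(len(loc), max(d, 1), dtype=np.int64)
    return depth


def _circle_length(rng: np.random.Generator, config: GeneratorConfig) -> int:
    """Multimodal circle length (nucleosome-scale periodicity)."""
    while True:
        mode = rng.choice(len(config.circle_modes), p=np.asarray(config.circle_mode_weights))
        length = int(round(rng.normal(config.circle_modes[mode], config.circle_mode_sd)))
        if length >= config.circle_min_length:
            return length


def _insert_size(rng: np.random.Generator, config: GeneratorConfig) -> int:
    return max(100, int(round(rng.normal(config.median_insert_size, config.insert_size_sd))))


def generate_junction_reads(
    rng: np.random.Generator,
    config: GeneratorConfig,
    sample_id: str,
    loc: PanelLocus,
    pos: int,
    allele_length: int,
    origin: str,
    n_fragments: int = 1,
) -> tuple[list[AlignmentSupport], list[int]]:
    """Build read-pair geometries for fragments supporting a D-A junction.

    Circle-origin fragments are bounded by the allele length (a circle
    must be cleaved to enter the library, so no fragment can exceed it);
    tandem-duplication fragments are drawn from the library insert-size
    distribution independent of allele length, and fragments longer than
    the allele physically contain duplicated/flanking sequence.
    """
    if allele_length < 20:
        raise ValueError("allele_length must be >= 20")
    supports: list[AlignmentSupport] = []
    lengths: list[int] = []
    key = (sample_id, loc.contig_name, pos, allele_length)
    for _ in range(n_fragments):
        if origin == "circle":
            f = min(_insert_size(rng, config), allele_length)
        elif origin == "tandem_duplication":
            f = _insert_size(rng, config)
        else:
            raise ValueError(f"unknown junction origin {origin!r}")
        lengths.append(f)
        left = loc.start + pos  # 0-based coordinate of the base after the anchor
        concordant = rng.random() < 0.2 and f > READ_LEN + 10
        if concordant:
            clip5 = int(rng.integers(0, min(31, max(1, f - READ_LEN))))
            supports.append(
                AlignmentSupport(
                    variant_key=key,
                    read1=PrimaryAlignment(
                        left + clip5, left + clip5 + READ_LEN, "fwd", softclip5=clip5
                    ),
                    read2=PrimaryAlignment(
                        max(left, left + f - READ_LEN), left + f, "rev",
                        softclip3=int(rng.integers(0, 20)) if f < 142 else 0,
                    ),
                    concordant=True,
                    insert_size=f - clip5,
                )
            )
        else:
            # pseudo-pair: fwd primary of read1 + rev supplementary of read2
            clip5 = int(rng.integers(0, 31))
            r1_end = min(left + clip5 + READ_LEN, left + f)
            supports.append(
                AlignmentSupport(
                    variant_key=key,
                    read1=PrimaryAlignment(left + clip5, r1_end, "fwd", softclip5=clip5),
                    read2=PrimaryAlignment(
                        max(left, left + f - 80), max(left + 1, left + f - 10), "rev",
                        softclip5=40,
                    ),
                    concordant=False,
                    read2_supp=SupplementaryAlignment(
                        max(left, left + f - READ_LEN), left + f, "rev"
                    ),
                )
            )
    return supports, lengths


def generate_sample(
    config: GeneratorConfig,
    panel: Sequence[PanelLocus],
    sample_id: str,
    pools: _PositionPools | None = None,
) -> tuple[SyntheticSample, list[dict]]:
    """Generate one sample's variant rows, depth profile, and geometry.

    Returns the sample plus its truth-event records. Singleton counts
    per class are Poisson with mean rate x duplex bases.
    """
    if not panel:
        raise ValueError("panel must be non-empty")
    rng = _sample_rng(config.seed, sample_id)
    pools = pools or _PositionPools(panel)
    depth_arrays = _depth_arrays(rng, config, panel)
    profile = DepthProfile.from_arrays(sample_id, depth_arrays, list(panel))
    bases = profile.total_duplex_bases
    by_name = {loc.contig_name: loc for loc in panel}
    panel_list = list(panel)

    calls: list[VariantCall] = []
    truth: list[dict] = []
    geometry: list[AlignmentSupport] = []

    def depth_at(chrom: str, pos: int) -> int:
        return int(depth_arrays[chrom][pos - 1])

    def emit(
        label: str, chrom: str, pos: int, ref: str, alt: str, vtype: VariantType,
        alt_count: int, sv_len: int | None = None, **extra,
    ) -> None:
        d = depth_at(chrom, pos)
        alt_count = min(alt_count, d)
        n_rows = alt_count if (config.clonal_as_duplicates and alt_count > 1) else 1
        per_row = 1 if n_rows > 1 else alt_count
        for _ in range(n_rows):
            calls.append(
                VariantCall(
                    sample_id=sample_id, chrom=chrom, pos=pos, ref=ref, alt=alt,
                    vtype=vtype, alt_count=per_row, site_depth=d, sv_len=sv_len,
                )
            )
        truth.append(
            dict(
                label=label, sample_id=sample_id, chrom=chrom, pos=pos, ref=ref,
                alt=alt, vtype=vtype.value, alt_count=alt_count, **extra,
            )
        )

    # --- germline heterozygous SNVs (VAF ~ 50%) ---
    panel_kb = sum(len(l) for l in panel_list) / 1000
    for _ in range(rng.poisson(config.germline_het_per_kb * panel_kb)):
        li, i = pools.draw(rng, pools.by_pyr["C"] if rng.random() < 0.45 else pools.by_pyr["T"])
        loc = panel_list[li]
        ref = loc.sequence[i]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        d = depth_at(loc.contig_name, loc.start + i + 1)
        emit(
            "germline", loc.contig_name, loc.start + i + 1, ref, str(alt),
            VariantType.SNV, max(1, rng.binomial(d, 0.5)),
        )

    # --- singleton / clonal somatic SNVs ---
    weights = np.asarray(config.sbs6_weights)
    classes = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
    for _ in range(rng.poisson(config.snv_mf * bases)):
        cls = classes[int(rng.choice(6, p=weights))]
        if cls == "C>T" and rng.random() < config.cpg_ct_fraction:
            li, i = pools.draw(rng, pools.cpg)
        elif cls.startswith("C"):
            li, i = pools.draw(rng, pools.non_cpg_c)
        else:
            li, i = pools.draw(rng, pools.by_pyr["T"])
        chrom, pos, ref, alt = _snv_at(panel_list, li, i, cls)
        clonal = rng.random() < config.clonal_fraction_snv
        k = 2 + int(rng.poisson(1.0)) if clonal else 1
        emit("clonal_somatic" if clonal else "singleton_snv", chrom, pos, ref, alt,
             VariantType.SNV, k, sbs6=cls)

    # --- MNVs ---
    for _ in range(rng.poisson(config.mnv_mf * bases)):
        loc = panel_list[int(rng.integers(len(panel_list)))]
        i = int(rng.integers(1, len(loc.sequence) - 3))
        ref = loc.sequence[i : i + 2]
        alt = "".join(str(rng.choice([b for b in "ACGT" if b != r])) for r in ref)
        clonal = rng.random() < config.clonal_fraction_non_snv
        emit("singleton_mnv", loc.contig_name, loc.start + i + 1, ref, alt,
             VariantType.MNV, 2 if clonal else 1)

    # --- small indels ---
    for _ in range(rng.poisson(config.indel_mf * bases)):
        loc = panel_list[int(rng.integers(len(panel_list)))]
        size = int(rng.integers(1, 3)) if rng.random() < 0.6 else int(rng.integers(3, 21))
        i = int(rng.integers(1, len(loc.sequence) - size - 2))
        anchor = loc.sequence[i]
        clonal = rng.random() < config.clonal_fraction_non_snv
        k = 2 if clonal else 1
        if rng.random() < 0.5:  # insertion
            ins = _random_sequence(rng, size, 0.5)
            emit("singleton_indel", loc.contig_name, loc.start + i + 1, anchor,
                 anchor + ins, VariantType.INSERTION, k, net=size)
        else:
            ref = loc.sequence[i : i + size + 1]
            emit("singleton_indel", loc.contig_name, loc.start + i + 1, ref,
                 anchor, VariantType.DELETION, k, net=-size)

    # --- SVs: inversions and >1 kb deletions ---
    for _ in range(rng.poisson(config.sv_mf * bases)):
        loc = panel_list[int(rng.integers(len(panel_list)))]
        if rng.random() < 0.8:
            length = int(rng.integers(100, min(2000, len(loc.sequence) - 2)))
            i = int(rng.integers(1, len(loc.sequence) - length - 1))
            emit("singleton_sv", loc.contig_name, loc.start + i + 1,
                 loc.sequence[i], "<INV>", VariantType.INVERSION, 1, sv_len=length)
        else:
            length = int(rng.integers(1001, min(2200, len(loc.sequence) - 2)))
            i = int(rng.integers(1, len(loc.sequence) - length - 1))
            ref = loc.sequence[i : i + length + 1]
            emit("singleton_sv", loc.contig_name, loc.start + i + 1, ref,
                 loc.sequence[i], VariantType.DELETION, 1, net=-length)

    # --- artifact constructs exercising the manual filters ---
    for _ in range(config.mnv_partial_snv_count):
        loc = panel_list[int(rng.integers(len(panel_list)))]
        i = int(rng.integers(1, len(loc.sequence) - 4))
        ref = loc.sequence[i : i + 3]
        alt = "".join(str(rng.choice([b for b in "ACGT" if b != r])) for r in ref)
        d = depth_at(loc.contig_name, loc.start + i + 1)
        emit("clonal_mnv", loc.contig_name, loc.start + i + 1, ref, alt,
             VariantType.MNV, max(2, int(0.02 * d)))
        emit("mnv_partial_snv", loc.contig_name, loc.start + i + 2,
             loc.sequence[i + 1], alt[1], VariantType.SNV, 1)

    for _ in range(config.indel_proximal_snv_count):
        loc = panel_list[int(rng.integers(len(panel_list)))]
        i = int(rng.integers(1, len(loc.sequence) - 30))
        ref = loc.sequence[i : i + 6]
        emit("singleton_indel", loc.contig_name, loc.start + i + 1, ref,
             loc.sequence[i], VariantType.DELETION, 1, net=-5)
        off = int(rng.integers(1, 11))
        j = i + 5 + off  # within the exclusion window of the right boundary
        snv_ref = loc.sequence[j]
        snv_alt = str(rng.choice([b for b in "ACGT" if b != snv_ref]))
        emit("indel_proximal_snv", loc.contig_name, loc.start + j + 1,
             snv_ref, snv_alt, VariantType.SNV, 1)

    # --- D-A junction events: circles, tandem duplications, and
    #     junction-negative random insertions ---
    for origin, count in (("circle", config.circle_count),
                          ("tandem_duplication", config.td_count)):
        for _ in range(count):
            loc = panel_list[int(rng.integers(len(panel_list)))]
            L = _circle_length(rng, config) if origin == "circle" else config.td_allele_length
            # the inserted allele is an exact copy of the reference starting
            # 1 bp downstream of the anchor, which is what a D-A junction is
            i = int(rng.integers(1, len(loc.sequence) - L - 2))
            pos = loc.start + i + 1
            allele = loc.sequence[i + 1 : i + 1 + L]
            anchor = loc.sequence[i]
            d = depth_at(loc.contig_name, pos)
            high_vaf = rng.random() < 0.06
            k = max(2, int(0.012 * d)) if high_vaf else 1 + int(rng.poisson(0.3))
            n_frag = 1 + int(rng.poisson(0.3))
            supports, lengths = generate_junction_reads(
                rng, config, sample_id, loc, pos, L, origin, n_frag
            )
            geometry.extend(supports)
            emit(origin, loc.contig_name, pos, anchor, anchor + allele,
                 VariantType.INSERTION, max(1, k), allele_length=L,
                 fragment_lengths=lengths)

    for _ in range(config.random_insertion_count):
        loc = panel_list[int(rng.integers(len(panel_list)))]
        L = int(rng.integers(21, 126))
        i = int(rng.integers(1, len(loc.sequence) - 2))
        anchor = loc.sequence[i]
        emit("random_insertion", loc.contig_name, loc.start + i + 1, anchor,
             anchor + _random_sequence(rng, L, 0.5), VariantType.INSERTION, 1,
             allele_length=L)

    sample = SyntheticSample(
        sample_id=sample_id, tissue=config.tissue, calls=calls,
        depth=profile, geometry=geometry,
    )
    return sample, truth


def generate_cohort(
    configs: Sequence[GeneratorConfig],
    panel: Sequence[PanelLocus] | None = None,
    seed: int | None = None,
) -> SyntheticCohort:
    """Generate a multi-sample cohort, then implant cross-sample
    contaminant pairs (a low-VAF copy of another sample's germline
    variant, within the same tissue)."""
    seed = configs[0].seed if seed is None else seed
    panel = list(panel) if panel is not None else generate_panel(seed=seed)
    pools = _PositionPools(panel)
    samples: dict[str, SyntheticSample] = {}
    truth = CohortTruth(seed=seed)
    for config in configs:
        for i in range(config.n_samples):
            sid = f"{config.tissue}{i + 1}"
            sample, events = generate_sample(config, panel, sid, pools)
            samples[sid] = sample
            truth.events.extend(events)

    # contaminant pairs: donor germline -> low-VAF copy in a peer sample
    for config in configs:
        ids = [f"{config.tissue}{i + 1}" for i in range(config.n_samples)]
        if len(ids) < 2 or config.contaminants_per_sample == 0:
            continue
        for sid in ids:
            rng = _sample_rng(config.seed, sid + ":contam")
            donors = [g for g in ids if g != sid]
            germ = [e for e in truth.events
                    if e["label"] == "germline" and e["sample_id"] in donors]
            if not germ:
                continue
            for _ in range(config.contaminants_per_sample):
                src = germ[int(rng.integers(len(germ)))]
                recipient = samples[sid]
                d = recipient.depth.depth_at(src["chrom"], src["pos"])
                k = max(1, int(0.004 * d))
                recipient.calls.append(
                    VariantCall(
                        sample_id=sid, chrom=src["chrom"], pos=src["pos"],
                        ref=src["ref"], alt=src["alt"], vtype=VariantType.SNV,
                        alt_count=k, site_depth=d,
                    )
                )
                truth.events.append(
                    dict(label="contaminant_pair", sample_id=sid, chrom=src["chrom"],
                         pos=src["pos"], ref=src["ref"], alt=src["alt"],
                         vtype="SNV", alt_count=k, donor=src["sample_id"])
                )
    return SyntheticCohort(panel=panel, samples=samples, truth=truth)
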