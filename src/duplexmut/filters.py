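"""Rare-variant filtering ladder.

Raw duplex-consensus calls are converted into the per-sample set of
unique mutations used for every burden and spectrum statistic:

1. clonal collapse — identical mutations seen in more than one molecule
   of the same sample are counted once (clonal expansion);
2. exclusion of SNVs overlapping clonal MNVs (no-calls inside an MNV can
   generate false partial SNV calls);
3. exclusion of SNVs within a window of indel boundaries (realignment
   artifacts cluster there);
4. intra-cohort contamination removal — a low-VAF call that matches
   another sample's likely-germline variant;
5. the VAF gate that removes inherited polymorphisms and early
   developmental mutations.

Contamination matching runs before the VAF gate so the germline copies
it needs to see are still present. The circular-DNA analysis consumes
the pre-gate set (no VAF filter is applied to large insertions).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .model import VariantCall, VariantType, net_length, variant_class

__all__ = [
    "FilterConfig",
    "ClonalityStats",
    "FilterReport",
    "collapse_clonal",
    "apply_vaf_gate",
    "exclude_snv_over_clonal_mnv",
    "exclude_snv_near_indels",
    "indel_boundaries",
    "remove_intra_cohort_contamination",
    "run_filter_ladder",
]


@dataclass
class FilterConfig:
    """Thresholds of the filtering ladder (defaults are the standard analysis)."""

    vaf_max: float = 0.01
    clonal_mnv_vaf_min: float = 0.01
    indel_exclusion_window_bp: int = 10
    contamination_low_vaf: float = 0.01
    contamination_germline_vaf: float = 0.30
    shared_mutation_mode: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.vaf_max <= 1):
            raise ValueError(f"vaf_max must be in (0, 1], got {self.vaf_max}")
        if self.indel_exclusion_window_bp < 0:
            raise ValueError("indel_exclusion_window_bp must be >= 0")


@dataclass
class ClonalityStats:
    n_input_rows: int
    n_unique: int
    single_count_fraction_snv: float | None
    single_count_fraction_non_snv: float | None


@dataclass
class FilterReport:
    """Accounting of the ladder: every input call is retained or removed
    by exactly one (first-triggering) filter."""

    n_input_unique: int = 0
    removed: Counter = field(default_factory=Counter)
    retained_by_sample: dict[str, Counter] = field(default_factory=dict)
    clonality: dict[str, ClonalityStats] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())

    def to_dict(self) -> dict:
        return {
            "n_input_unique": self.n_input_unique,
            "removed": dict(self.removed),
            "retained_by_sample": {s: dict(c) for s, c in self.retained_by_sample.items()},
            "clonality": {
                s: {
                    "n_input_rows": c.n_input_rows,
                    "n_unique": c.n_unique,
                    "single_count_fraction_snv": c.single_count_fraction_snv,
                    "single_count_fraction_non_snv": c.single_count_fraction_non_snv,
                }
                for s, c in self.clonality.items()
            },
        }


def collapse_clonal(calls: list[VariantCall]) -> tuple[list[VariantCall], ClonalityStats]:
    """Merge identical mutations from one sample into one unique record.

    Identity is (chrom, pos, ref, alt); the merged record's alt_count is
    the total number of supporting molecules. Calls must all come from
    the same sample.
    """
    samples = {c.sample_id for c in calls}
    if len(samples) > 1:
        raise ValueError(f"collapse_clonal expects one sample, got {sorted(samples)}")
    merged: dict[tuple, VariantCall] = {}
    for c in calls:
        prev = merged.get(c.key)
        if prev is None:
            merged[c.key] = VariantCall(
                sample_id=c.sample_id,
                chrom=c.chrom,
                pos=c.pos,
                ref=c.ref,
                alt=c.alt,
                vtype=c.vtype,
                alt_count=c.alt_count,
                site_depth=c.site_depth,
                sv_len=c.sv_len,
            )
        else:
            merged[c.key] = VariantCall(
                sample_id=prev.sample_id,
                chrom=prev.chrom,
                pos=prev.pos,
                ref=prev.ref,
                alt=prev.alt,
                vtype=prev.vtype,
                alt_count=prev.alt_count + c.alt_count,
                site_depth=max(prev.site_depth, c.site_depth),
                sv_len=prev.sv_len,
            )
    unique = list(merged.values())
    snv = [c for c in unique if c.vtype is VariantType.SNV]
    non = [c for c in unique if c.vtype is not VariantType.SNV]
    stats = ClonalityStats(
        n_input_rows=len(calls),
        n_unique=len(unique),
        single_count_fraction_snv=(
            sum(c.alt_count == 1 for c in snv) / len(snv) if snv else None
        ),
        single_count_fraction_non_snv=(
            sum(c.alt_count == 1 for c in non) / len(non) if non else None
        ),
    )
    return unique, stats


def apply_vaf_gate(calls: list[VariantCall], vaf_max: float) -> list[VariantCall]:
    """Retain calls with VAF <= vaf_max (inclusive gate)."""
    return [c for c in calls if c.vaf <= vaf_max]


def exclude_snv_over_clonal_mnv(
    snvs: list[VariantCall],
    mnvs: list[VariantCall],
    clonal_mnv_vaf_min: float = 0.01,
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Drop SNVs whose position lies inside a same-sample clonal MNV span.

    An MNV is clonal when its (post-collapse) VAF >= clonal_mnv_vaf_min.
    Returns (retained, removed).
    """
    spans: dict[str, list[tuple[str, int, int]]] = {}
    for m in mnvs:
        if m.vaf >= clonal_mnv_vaf_min:
            spans.setdefault(m.sample_id, []).append((m.chrom, m.pos, m.end))
    retained, removed = [], []
    for s in snvs:
        hit = any(
            chrom == s.chrom and start <= s.pos <= end
            for chrom, start, end in spans.get(s.sample_id, [])
        )
        (removed if hit else retained).append(s)
    return retained, removed


def indel_boundaries(indel: VariantCall) -> tuple[int, int]:
    """Reference coordinates of the two indel boundaries.

    Deletions: {pos, pos + |net length|}; insertions: {pos, pos + 1},
    the anchor base and the base after the insertion point.
    """
    n = net_length(indel)
    if n < 0:
        return (indel.pos, indel.pos + abs(n))
    return (indel.pos, indel.pos + 1)


def exclude_snv_near_indels(
    snvs: list[VariantCall],
    indels: list[VariantCall],
    window_bp: int = 10,
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Drop SNVs within window_bp (inclusive) of a same-sample indel boundary."""
    bounds: dict[str, list[tuple[str, int]]] = {}
    for ind in indels:
        for b in indel_boundaries(ind):
            bounds.setdefault(ind.sample_id, []).append((ind.chrom, b))
    retained, removed = [], []
    for s in snvs:
        hit = any(
            chrom == s.chrom and abs(s.pos - b) <= window_bp
            for chrom, b in bounds.get(s.sample_id, [])
        )
        (removed if hit else retained).append(s)
    return retained, removed


def remove_intra_cohort_contamination(
    cohort: dict[str, list[VariantCall]],
    low_vaf: float = 0.01,
    germline_vaf: float = 0.30,
) -> tuple[dict[str, list[VariantCall]], dict[str, list[VariantCall]]]:
    """Remove likely cross-sample contamination.

    A call is removed iff its VAF < low_vaf in its own sample and the
    identical (chrom, pos, ref, alt) appears with VAF > germline_vaf in
    at least one *other* sample. The germline copy is untouched.
    """
    if len(cohort) < 2:
        import warnings

        warnings.warn("contamination filter needs >= 2 samples; no-op")
        return cohort, {s: [] for s in cohort}
    germline_keys: dict[tuple, set[str]] = {}
    for sample, calls in cohort.items():
        for c in calls:
            if c.vaf > germline_vaf:
                germline_keys.setdefault(c.key, set()).add(sample)
    retained: dict[str, list[VariantCall]] = {}
    removed: dict[str, list[VariantCall]] = {}
    for sample, calls in cohort.items():
        keep, drop = [], []
        for c in calls:
            owners = germline_keys.get(c.key, set())
            if c.vaf < low_vaf and owners - {sample}:
                drop.append(c)
            else:
                keep.append(c)
        retained[sample] = keep
        removed[sample] = drop
    return retained, removed


def remove_shared_mutations(
    tissue_pairs: dict[str, tuple[list[VariantCall], list[VariantCall]]],
) -> dict[str, tuple[list[VariantCall], list[VariantCall]]]:
    """Alternative filter: drop mutations present in both tissues of one
    individual (keyed on (chrom, pos, ref, alt)); both copies removed."""
    out = {}
    for individual, (a, b) in tissue_pairs.items():
        shared = {c.key for c in a} & {c.key for c in b}
        out[individual] = (
            [c for c in a if c.key not in shared],
            [c for c in b if c.key not in shared],
        )
    return out


def run_filter_ladder(
    cohort: dict[str, list[VariantCall]],
    config: FilterConfig | None = None,
) -> tuple[dict[str, list[VariantCall]], FilterReport]:
    """Run the full ladder over a cohort of per-sample call lists.

    Order: clonal collapse -> clonal-MNV overlap -> indel-proximal ->
    contamination -> VAF gate. Returns the per-sample unique mutation
    sets and an accounting report.
    """
    config = config or FilterConfig()
    report = FilterReport()

    collapsed: dict[str, list[VariantCall]] = {}
    for sample, calls in cohort.items():
        unique, stats = collapse_clonal(calls)
        collapsed[sample] = unique
        report.clonality[sample] = stats
        report.n_input_unique += len(unique)

    staged: dict[str, list[VariantCall]] = {}
    for sample, unique in collapsed.items():
        snvs = [c for c in unique if c.vtype is VariantType.SNV]
        mnvs = [c for c in unique if c.vtype is VariantType.MNV]
        others = [c for c in unique if c.vtype not in (VariantType.SNV, VariantType.MNV)]
        indel_like = [
            c
            for c in unique
            if c.vtype in (VariantType.INSERTION, VariantType.DELETION, VariantType.COMPLEX)
        ]
        snvs, over_mnv = exclude_snv_over_clonal_mnv(snvs, mnvs, config.clonal_mnv_vaf_min)
        report.removed["snv_over_clonal_mnv"] += len(over_mnv)
        snvs, near_indel = exclude_snv_near_indels(
            snvs, indel_like, config.indel_exclusion_window_bp
        )
        report.removed["snv_near_indel"] += len(near_indel)
        staged[sample] = snvs + mnvs + others

    staged, contaminated = remove_intra_cohort_contamination(
        staged, config.contamination_low_vaf, config.contamination_germline_vaf
    )
    report.removed["contamination"] += sum(len(v) for v in contaminated.values())

    final: dict[str, list[VariantCall]] = {}
    for sample, calls in staged.items():
        gated = apply_vaf_gate(calls, config.vaf_max)
        report.removed["vaf_gate"] += len(calls) - len(gated)
        final[sample] = gated
        by_class = Counter()
        for c in gated:
            by_class[variant_class(c)] += 1
        report.retained_by_sample[sample] = by_class
    return final, report
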