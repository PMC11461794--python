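"""Mutation-frequency (burden) statistics.

Mutation frequency (MF) is the number of unique mutations divided by the
number of informative duplex bases. Substitution-subtype rates are
depth-normalized by reference base: pyrimidine-collapsed C>N rates use
the summed duplex depth at reference C/G positions, T>N rates the depth
at T/A positions. Tissue-level MF is reported both pooled
(sum of counts / sum of bases) and as the mean of per-sample MFs — the
two differ whenever yields differ across samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .model import DepthProfile, PanelLocus, VariantCall, VariantType, variant_class

__all__ = [
    "BurdenResult",
    "mutation_frequency",
    "format_mf",
    "subtype_rates",
    "pyrimidine_class",
    "cpg_fraction",
    "per_locus_mf",
    "cross_tissue_correlation",
    "sample_burden",
    "SBS6_CLASSES",
]

SBS6_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def mutation_frequency(unique_count: int, duplex_bases: int) -> float:
    """Unique mutations per duplex base."""
    if duplex_bases <= 0:
        raise ValueError(f"duplex_bases must be > 0, got {duplex_bases}")
    if unique_count < 0:
        raise ValueError("unique_count must be >= 0")
    return unique_count / duplex_bases


def format_mf(mf: float) -> str:
    """Format a rate at 2 significant figures in scientific notation,
    e.g. 7.599e-09 -> '7.6E-09'."""
    if mf == 0:
        return "0"
    return f"{mf:.1E}"


def pyrimidine_class(ref: str, alt: str) -> str:
    """Collapse a substitution onto the pyrimidine reference strand.

    Mutations at purine reference bases (A/G) are complemented, so G>A
    is counted as C>T.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref in ("G", "A"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    cls = f"{ref}>{alt}"
    if cls not in SBS6_CLASSES:
        raise ValueError(f"not a substitution: {ref}>{alt}")
    return cls


def subtype_rates(snvs: Sequence[VariantCall], depth: DepthProfile) -> dict[str, float]:
    """Depth-normalized rates of the six substitution classes."""
    counts = {c: 0 for c in SBS6_CLASSES}
    for v in snvs:
        if v.vtype is not VariantType.SNV:
            raise ValueError(f"subtype_rates expects SNVs, got {v.vtype}")
        counts[pyrimidine_class(v.ref, v.alt)] += 1
    rates = {}
    for cls, n in counts.items():
        denom = depth.depth_at_CG if cls.startswith("C") else depth.depth_at_TA
        if denom == 0:
            if n > 0:
                raise ValueError(f"nonzero {cls} count with zero reference-base depth")
            rates[cls] = 0.0
        else:
            rates[cls] = n / denom
    return rates


def _context(panel_by_name: dict[str, PanelLocus], v: VariantCall) -> Optional[str]:
    loc = panel_by_name.get(v.chrom)
    if loc is None:
        return None
    i = v.pos - 1 - loc.start
    if i < 1 or i >= len(loc.sequence) - 1:
        return None
    return loc.sequence[i - 1 : i + 2]


def cpg_fraction(snvs: Sequence[VariantCall], panel: Sequence[PanelLocus]) -> Optional[float]:
    """Fraction of C>T mutations (pyrimidine-collapsed) at CpG sites.

    A CpG site is a reference C immediately followed by G (NCG context);
    mutations at reference G are assessed on the complementary strand.
    Returns None when there are no C>T mutations; variants whose context
    falls off the panel edge are skipped with a warning.
    """
    import warnings

    by_name = {loc.contig_name: loc for loc in panel}
    n_ct = n_cpg = 0
    for v in snvs:
        if v.vtype is not VariantType.SNV or pyrimidine_class(v.ref, v.alt) != "C>T":
            continue
        ctx = _context(by_name, v)
        if ctx is None:
            warnings.warn(f"context off panel edge at {v.chrom}:{v.pos}; variant skipped")
            continue
        n_ct += 1
        if v.ref.upper() == "C":
            n_cpg += ctx[2] == "G"
        else:  # reference G: CpG on the other strand means a C precedes it
            n_cpg += ctx[0] == "C"
    if n_ct == 0:
        return None
    return n_cpg / n_ct


def per_locus_mf(
    calls: Sequence[VariantCall],
    depth: DepthProfile,
    panel: Sequence[PanelLocus],
) -> tuple[dict[str, float], Optional[float]]:
    """Per-locus mutation frequency and the fold-range max/min.

    Loci with zero depth are excluded and flagged; loci with zero counts
    are excluded from the fold-range (but reported with rate 0).
    """
    import warnings

    counts = {loc.contig_name: 0 for loc in panel}
    for c in calls:
        if c.chrom in counts:
            counts[c.chrom] += 1
    rates: dict[str, float] = {}
    for loc in panel:
        total = depth.locus_total(loc.contig_name)
        if total == 0:
            warnings.warn(f"locus {loc.contig_name} has zero depth; excluded")
            continue
        rates[loc.contig_name] = counts[loc.contig_name] / total
    nonzero = [r for r in rates.values() if r > 0]
    fold = (max(nonzero) / min(nonzero)) if len(nonzero) >= 2 else None
    return rates, fold


def cross_tissue_correlation(
    x: Sequence[float], y: Sequence[float]
) -> tuple[Optional[float], Optional[float]]:
    """Pearson product-moment correlation with two-sided p-value.

    Returns (None, None) when either vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None, None
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class BurdenResult:
    """Per-sample burden summary (one Table-style row)."""

    sample_id: str
    tissue: str
    duplex_bases: int
    counts: dict[str, int]
    mf: dict[str, float]
    per_locus: dict[str, float] = field(default_factory=dict)
    locus_fold_range: Optional[float] = None
    subtype_rates: dict[str, float] = field(default_factory=dict)
    cpg_ct_fraction: Optional[float] = None


def sample_burden(
    sample_id: str,
    tissue: str,
    unique_calls: Sequence[VariantCall],
    depth: DepthProfile,
    panel: Sequence[PanelLocus],
) -> BurdenResult:
    """Compute the full burden summary for one sample's unique mutations."""
    counts = {k: 0 for k in ("SNV", "MNV", "indel", "SV")}
    for c in unique_calls:
        counts[variant_class(c)] += 1
    bases = depth.total_duplex_bases
    mf = {k: mutation_frequency(n, bases) for k, n in counts.items()}
    snvs = [c for c in unique_calls if c.vtype is VariantType.SNV]
    rates_by_locus, fold = per_locus_mf(snvs, depth, panel)
    return BurdenResult(
        sample_id=sample_id,
        tissue=tissue,
        duplex_bases=bases,
        counts=counts,
        mf=mf,
        per_locus=rates_by_locus,
        locus_fold_range=fold,
        subtype_rates=subtype_rates(snvs, depth),
        cpg_ct_fraction=cpg_fraction(snvs, panel),
    )


def pooled_mf(results: Sequence[BurdenResult], vclass: str) -> float:
    """Tissue-level MF as sum of counts over sum of duplex bases."""
    return sum(r.counts[vclass] for r in results) / sum(r.duplex_bases for r in results)


def mean_sample_mf(results: Sequence[BurdenResult], vclass: str) -> tuple[float, float]:
    """Tissue-level MF as mean (and SD) of per-sample MFs."""
    vals = np.array([r.mf[vclass] for r in results])
    return float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
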