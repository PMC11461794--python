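"""Mutational spectra and spectrum-comparison statistics.

Single-base substitutions are pyrimidine-collapsed into 6 classes or 96
trinucleotide-context classes (COSMIC ordering, substitution-major:
A[C>A]A, C[C>A]A, ... T[T>G]T after sorting within each substitution by
5' then 3' flank). Spectra are compared with the likelihood-ratio
(G) statistic for multinomial homogeneity of two mutant spectra, with an
asymptotic chi-square p-value and an optional Monte Carlo p-value for
small counts. Cosine similarity relates observed spectra to reference
spectra or COSMIC signature columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .burden import SBS6_CLASSES, pyrimidine_class
from .model import PanelLocus, VariantCall, VariantType, net_length

__all__ = [
    "SBS96_LABELS",
    "SpectrumSBS",
    "IndelMnvSpectrum",
    "build_sbs_spectrum",
    "lr_spectrum_test",
    "lr_null_rejection_rate",
    "cosine_similarity",
    "classify_indels_svs",
]

_BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(s: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(s))


def _make_sbs96_labels() -> tuple[str, ...]:
    labels = []
    for sub in SBS6_CLASSES:
        for five in _BASES:
            for three in _BASES:
                labels.append(f"{five}[{sub}]{three}")
    return tuple(labels)


SBS96_LABELS = _make_sbs96_labels()
_SBS96_INDEX = {lab: i for i, lab in enumerate(SBS96_LABELS)}
_SBS6_INDEX = {c: i for i, c in enumerate(SBS6_CLASSES)}


@dataclass
class SpectrumSBS:
    """A 6- or 96-class substitution count spectrum."""

    kind: str  # sbs6 | sbs96
    counts: np.ndarray

    def __post_init__(self) -> None:
        expected = 6 if self.kind == "sbs6" else 96
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.kind not in ("sbs6", "sbs96"):
            raise ValueError(f"kind must be sbs6 or sbs96, got {self.kind!r}")
        if self.counts.shape != (expected,):
            raise ValueError(f"{self.kind} spectrum needs {expected} counts")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def labels(self) -> tuple[str, ...]:
        return SBS6_CLASSES if self.kind == "sbs6" else SBS96_LABELS

    @property
    def proportions(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / total


def sbs96_class(ref: str, alt: str, context: str) -> str:
    """Map a substitution with its trinucleotide context to an SBS96 label.

    ``context`` is the 3-mer centred on the mutated base on the reference
    strand. Purine-reference mutations are reverse-complemented so every
    class has a pyrimidine (C or T) at the centre.
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if context[1] != ref:
        raise ValueError(f"context {context} does not match ref {ref}")
    if ref in "AG":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        context = _revcomp(context)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def build_sbs_spectrum(
    snvs: Sequence[VariantCall],
    panel: Sequence[PanelLocus],
    kind: str = "sbs96",
) -> SpectrumSBS:
    """Tally SNVs into a pyrimidine-collapsed SBS6 or SBS96 spectrum.

    Trinucleotide contexts come from the panel reference sequence;
    variants whose +/-1 bp context falls off a locus edge are skipped
    with a warning.
    """
    by_name = {loc.contig_name: loc for loc in panel}
    n = 6 if kind == "sbs6" else 96
    counts = np.zeros(n, dtype=np.int64)
    for v in snvs:
        if v.vtype is not VariantType.SNV:
            continue
        if kind == "sbs6":
            counts[_SBS6_INDEX[pyrimidine_class(v.ref, v.alt)]] += 1
            continue
        loc = by_name.get(v.chrom)
        i = None if loc is None else v.pos - 1 - loc.start
        if loc is None or i < 1 or i >= len(loc.sequence) - 1:
            warnings.warn(f"missing context for {v.chrom}:{v.pos}; variant skipped")
            continue
        ctx = loc.sequence[i - 1 : i + 2]
        counts[_SBS96_INDEX[sbs96_class(v.ref, v.alt, ctx)]] += 1
    return SpectrumSBS(kind=kind, counts=counts)


def lr_spectrum_test(
    table_a: Sequence[int],
    table_b: Sequence[int],
    monte_carlo: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[float, int, float, Optional[float]]:
    """Likelihood-ratio test that two mutant spectra share one multinomial.

    The two count vectors are stacked into a 2 x k contingency table;
    G = 2 * sum O * ln(O / E) with expectations from the margins, df =
    k - 1, and the p-value from the chi-square upper tail. Cells with
    O = 0 contribute nothing. With ``monte_carlo`` > 0 an additional
    resampling p-value is computed by drawing both spectra from the
    pooled proportions, which is preferable when class counts are small.

    Returns (G, df, p_asymptotic, p_monte_carlo_or_None).
    """
    a = np.asarray(table_a, dtype=float)
    b = np.asarray(table_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("spectra must be 1-D vectors of equal length")
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("both spectra must have positive totals")

    def g_stat(x: np.ndarray, y: np.ndarray) -> float:
        obs = np.stack([x, y])
        col = obs.sum(axis=0)
        row = obs.sum(axis=1)
        expected = np.outer(row, col) / obs.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
        return float(2.0 * terms.sum())

    g = g_stat(a, b)
    df = len(a) - 1
    p = float(sps.chi2.sf(g, df))
    p_mc = None
    if monte_carlo > 0:
        rng = rng or np.random.default_rng()
        pooled = (a + b) / (a.sum() + b.sum())
        na, nb = int(a.sum()), int(b.sum())
        sim_a = rng.multinomial(na, pooled, size=monte_carlo)
        sim_b = rng.multinomial(nb, pooled, size=monte_carlo)
        hits = sum(g_stat(sa.astype(float), sb.astype(float)) >= g for sa, sb in zip(sim_a, sim_b))
        p_mc = (hits + 1) / (monte_carlo + 1)
    return g, df, p, p_mc


def lr_null_rejection_rate(
    k: int,
    n: int,
    reps: int,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    proportions: Sequence[float] | None = None,
) -> float:
    """Empirical type-I error of the LR spectrum test under the null.

    Draws ``reps`` pairs of spectra from one shared multinomial
    (``proportions`` or uniform over k classes, n mutations each) and
    returns the fraction rejected at level ``alpha`` using the
    asymptotic chi-square p-value.
    """
    rng = rng or np.random.default_rng()
    p = np.full(k, 1.0 / k) if proportions is None else np.asarray(proportions, float)
    a = rng.multinomial(n, p, size=reps).astype(float)
    b = rng.multinomial(n, p, size=reps).astype(float)
    obs = np.stack([a, b], axis=1)  # (reps, 2, k)
    col = obs.sum(axis=1, keepdims=True)
    row = obs.sum(axis=2, keepdims=True)
    expected = row * col / obs.sum(axis=(1, 2), keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
    g = 2.0 * terms.sum(axis=(1, 2))
    crit = sps.chi2.isf(alpha, k - 1)
    return float((g > crit).mean())


def cosine_similarity(u: Sequence[float], v: Sequence[float]) -> float:
    """Cosine similarity u.v / (|u||v|); in [0, 1] for nonnegative vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for zero vector")
    return float(u @ v / (nu * nv))


SMALL_INDEL_BINS = ("Ins 1-2", "Ins 3-20", "Del 1-2", "Del 3-20", "MNV")
LARGE_EVENT_TYPES = ("deletion", "insertion/duplication", "inversion")


@dataclass
class IndelMnvSpectrum:
    """Small indel/MNV bins plus the merged >20 bp indel + SV type table.

    Indel length for complex variants is the net change in allele
    length; events >20 bp are merged across the 1000 bp indel/SV calling
    boundary into type categories.
    """

    small_counts: dict[str, int] = field(default_factory=dict)
    large_counts: dict[str, int] = field(default_factory=dict)
    large_frequencies: dict[str, float] = field(default_factory=dict)
    deletion_lengths_gt20: list[int] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(self.small_counts.values()) + sum(self.large_counts.values())

    def deletion_length_summary(self) -> Optional[dict[str, float]]:
        if not self.deletion_lengths_gt20:
            return None
        arr = np.array(self.deletion_lengths_gt20)
        return {"median": float(np.median(arr)), "max": float(arr.max())}


def classify_indels_svs(
    calls: Sequence[VariantCall], duplex_bases: int | None = None
) -> IndelMnvSpectrum:
    """Tabulate non-SNV unique calls by size and type.

    Small bins: insertions/deletions of 1-2 and 3-20 bp net length, and
    MNVs. Events with |net length| > 20 bp (including all SVs and
    inversions) are grouped by type. Inversions without a usable length
    are counted with length missing.
    """
    spec = IndelMnvSpectrum(
        small_counts={b: 0 for b in SMALL_INDEL_BINS},
        large_counts={t: 0 for t in LARGE_EVENT_TYPES},
    )
    for c in calls:
        if c.vtype is VariantType.SNV:
            raise ValueError("classify_indels_svs expects non-SNV calls")
        if c.vtype is VariantType.MNV:
            spec.small_counts["MNV"] += 1
            continue
        if c.vtype is VariantType.INVERSION:
            spec.large_counts["inversion"] += 1
            continue
        n = net_length(c)
        if n == 0:
            # length-neutral complex substitution; fold into MNV-like bin
            spec.small_counts["MNV"] += 1
            continue
        size = abs(n)
        if size <= 2:
            spec.small_counts["Ins 1-2" if n > 0 else "Del 1-2"] += 1
        elif size <= 20:
            spec.small_counts["Ins 3-20" if n > 0 else "Del 3-20"] += 1
        else:
            if n > 0:
                spec.large_counts["insertion/duplication"] += 1
            else:
                spec.large_counts["deletion"] += 1
                spec.deletion_lengths_gt20.append(size)
    if duplex_bases:
        spec.large_frequencies = {
            t: n / duplex_bases for t, n in spec.large_counts.items()
        }
    return spec
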