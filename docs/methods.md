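# Methods

## Data model and conventions

Variant positions are 1-based; indel and SV positions anchor on the
base *before* the inserted/deleted sequence (VCF convention). Panel
intervals are 0-based half-open (BED convention) and converted only at
the I/O boundary. VAF = supporting duplex molecules / duplex depth at
the site, computed once at parse time and never recomputed downstream,
so every threshold sees the same number.

Variant classes: SNV; MNV (equal-length substitution > 1 bp);
indel (|net length| ≤ 1000 bp); SV (net length > 1000 bp, and all
inversions). For complex substitutions the signed *net change in allele
length* classifies the event as insertion or deletion and defines its
length. The 1000 bp indel/SV boundary is a variant-calling convention,
so the merged > 20 bp size-type table re-pools both classes into
deletion / insertion-duplication / inversion categories.

## Filtering ladder

Order: clonal collapse → SNV-over-clonal-MNV exclusion → indel-proximal
SNV exclusion → intra-cohort contamination removal → VAF gate.
Contamination matching runs *before* the VAF gate deliberately: the
rule needs to see the likely-germline copies (VAF > 30%) that the gate
would discard. Each removed call is attributed to exactly one
(first-triggering) filter, so the report satisfies
input = retained + Σ removals.

Decisions where the procedure was genuinely open:

- **Indel boundaries** are the two reference coordinates
  {pos, pos + |net length|} for deletions and {pos, pos + 1} for
  insertions; distance is in reference bp and "within 10 bp" is
  *inclusive* (an SNV exactly 10 bp away is removed).
- **Clonal-MNV overlap** uses the post-collapse VAF, since clonality is
  a molecule-count property, and removes an SNV only when its position
  lies inside a same-sample MNV span with VAF ≥ 1%.
- The **VAF gate is inclusive** (retain iff VAF ≤ threshold); the
  contamination rule's arms are strict (< low-VAF, > germline-VAF) as
  stated.
- The alternative **shared-mutation filter** (drop mutations present in
  both tissues of one individual) is provided separately and is off by
  default; it is a reporting alternative, not a ladder stage.

The circular-DNA analysis consumes the *pre-gate*, clonally collapsed
calls: large insertions are analyzed at any VAF.

## Burden statistics

MF = unique mutations / duplex bases, displayed at 2 significant
figures in scientific notation. Tissue-level MF is reported both pooled
(Σ counts / Σ bases) and as the mean ± SD of per-sample MFs; the two
differ when yields differ, and both are standard summaries.
Substitution subtype rates divide pyrimidine-collapsed class counts by
the duplex depth summed over reference C/G (for C>N) or T/A (for T>N)
positions. Locus-level MF uses strictly in-locus depth; the fold-range
is max/min over loci with nonzero rates, and zero-depth loci are
excluded with a flag. Pearson correlations use the standard
product-moment statistic with a two-sided t-test p-value and are
reported as missing under zero variance.

## Spectrum comparison

Two spectra are compared with the likelihood-ratio statistic for
multinomial homogeneity: the count vectors form a 2×k table,
G = 2·Σ O ln(O/E) with expectations from the margins, df = k−1, p from
the χ² upper tail; empty cells contribute zero. This equals twice the
difference between the unrestricted and pooled multinomial maximized
log-likelihoods (verified against an independent oracle in the tests).
Because several comparisons of interest involve small sperm counts, a
Monte Carlo p-value (resampling both spectra from the pooled
proportions) is available; at k = 6 and n = 200 the asymptotic test
holds its nominal 5% level within ±0.01 (calibrated by simulation).
SBS96 classes use the COSMIC substitution-major ordering
(A[C>A]A … T[T>G]T) so signature TSVs interoperate directly; purine-
reference mutations are reverse-complemented with their context.
Signature matrices are validated to column sums of 1 ± 1e-9. Cosine
similarity is the plain u·v/(‖u‖‖v‖) on nonnegative vectors.

## Circular-DNA analysis

**Junction detection.** The inserted allele (≥ 20 bp) is scanned
against its own contig with a fixed-length Hamming match allowing
`floor(L/50)` mismatches — the stricter reading of "1 mismatch per
50 bp" (alleles < 50 bp allow none); the rate is configurable. A call
is junction-positive iff a match starts exactly 1 bp downstream of the
variant position; with anchor-base insertions this is the unique
placement that makes the insert a copy of the downstream reference.
Matches elsewhere are reported but do not support a junction.

**Fragment lengths.** Concordant pairs: insert size plus all 5'
soft-clipped bases (at a D-A junction the 5' clip aligns to the other
end of the allele and is physically part of the fragment). Discordant
pairs: a pseudo-pair of one read's primary and the other's
supplementary alignment; length = right-most end of the reverse-aligned
member − left-most start of the forward-aligned member, including 5'
clips extending beyond the primary span (supplementary records carry no
clip fields and contribute their aligned ends). 3' clips are adapter
read-through on fragments < 142 bp and never contribute. Pairs lacking
a usable supplementary, or with both pseudo-members on one strand, are
logged and skipped as ambiguous.

**Classification.** Tandem duplication iff *any* supporting fragment
contains duplicated/flanking sequence (operationally: fragment length
exceeds allele length) — a single informative fragment suffices;
circle-consistent iff all fragments ≤ allele length; ambiguous iff a
junction-positive event has no usable fragment geometry. The boundary
fragment == allele is circle-consistent.

**Binomial test.** Restricted to junction events with allele length ≤
the library median insert size (computed from the supplied insert-size
distribution; 233 bp is the generator default, not a constant), where
duplicated sequence would be detectable. Under the all-TD null each
fragment is below the median with probability ½; the reported p is the
exact one-sided tail P(X ≥ k | n, ½) over supporting fragments.
Candidates = junction-positive events with allele length strictly
> 125 bp; frequency = candidates / duplex bases, with an additional
VAF-gated count for consistency with burden tables.

## Synthetic cohort generator

The generator emulates deep targeted DS of matched blood and sperm from
healthy young men. Defaults (per sample; all configurable):

| parameter | blood | sperm | rationale |
|---|---|---|---|
| duplex bases | 1.25 Gb | 1.25 Gb | 48 kb panel at ~26,000x molecular depth |
| SNV rate /bp | 1.2e-7 | 2.5e-8 | tissue-typical somatic vs germline burden |
| MNV rate /bp | 1.3e-9 | 4.0e-10 | |
| small-indel rate /bp | 7.6e-9 | 3.2e-8 | sperm small indels *excluding* junction events |
| SV rate /bp | 3.8e-10 | 3.7e-9 | inversions (80%) and >1 kb deletions (20%) |
| SBS6 weights | C>T 0.53, C>A 0.14, T>C 0.12, … | C>T 0.46, T>C 0.26, … | dominant C>T with elevated T>C in germline |
| CpG fraction of C>T | 0.35 | 0.36 | deamination at methylated CpG |
| clonal fraction (SNV / non-SNV) | 0.04 / 0.30 | same | ~96% / ~70% single-count unique mutations |
| germline het sites | 0.8 /kb | same | human heterozygosity on a 48 kb panel |
| circles / TDs / random inserts | 0 / 0 / 1 | 50 / 1 / 2 | sperm-specific junction burden; ~96% of >20 bp insertions junction-positive |
| circle lengths | — | Gaussians at 180/370/560 bp (wt 0.5/0.3/0.2, sd 25, min 130) | nucleosome-scale periodic size distribution of microDNA |
| TD allele | — | 75 bp | the informative short-allele TD geometry |
| insert size | N(233, 45), floor 100 | same | library median insert 233 bp |

The sperm indel-class total (small indels + circle-origin insertions
with net length ≤ 1000 bp) then reproduces the ~7.2e-8/bp sperm
indel MF. Samples draw from independent RNG streams keyed by
(seed, sample id), so each sample is reproducible in isolation. Clonal
events are emitted as one row with alt_count = k by default, or as k
duplicate rows to exercise deduplication. Contaminant pairs copy a
random peer germline variant at VAF ~0.4%. Artifact constructs (a
partial SNV over a clonal MNV; an SNV within 10 bp of a deletion
boundary) are implanted one per sample to exercise the manual filters.
Panel sequences hit a target GC fraction (0.41) and avoid homopolymers
longer than 8 bp.

**What the generator does not model** — and hence what passing tests do
not show about real data: read-level sequencing error and consensus
miscalls, alignment/realignment noise (artifact SNVs are implanted, not
emergent), capture bias beyond a mild lognormal per-locus depth factor
(σ = 0.08), mapping ambiguity in repetitive sequence (panel contigs are
independent random sequences), genuine biological clustering of
mutations, and SV breakpoints spanning locus boundaries.

## Problem sizes and numerics

The default test suite and acceptance run use the full study scale
(12 samples × 1.25 Gb duplex bases): because the generator works at the
level of events and per-position depth over a 48 kb panel, full scale
costs only a few seconds. Simulation-based checks use 10³–10⁴
replicates (LR calibration 10⁴; classifier cross-error check 10³
events). Recovery tests accept deviations up to 3 Poisson standard
errors of the expected event count; the indel-proximal exclusion
removes real SNVs that happen to fall near indels (~5% of the panel
lies in exclusion windows in sperm-like samples), a small conservative
bias absorbed by that tolerance.

Degenerate inputs: empty depth files, zero-variance correlation
vectors, zero-count CpG denominators, empty binomial subsets, and
zero-depth loci all return explicit missing values or typed errors
rather than NaNs. Determinism: all randomness flows from
numpy SeedSequence; reruns with one seed are byte-identical.

## Known limitations

- The TSV variant-table schema is this package's own (the upstream
  consensus caller's native format is not public); the VCF subset
  reader covers interchange.
- Junction detection assumes insertions are reported with an anchor
  base and searches only the call's own contig, mirroring the
  per-chromosome search of the original procedure; trans-contig copies
  are out of scope.
- Signature *decomposition* is out of scope; only cosine similarity to
  supplied signature matrices is provided.
- The genic/intergenic MF contrast is reported as group means only (no
  ANOVA machinery).
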