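"""D-A junction detection, fragment-length inference, circle-vs-TD
classification, and the short-allele binomial test."""

import numpy as np
import pytest

from duplexmut.eccdna import (
    AmbiguousFragmentError,
    analyze_circles,
    binomial_subset_test,
    classify_circle_vs_td,
    detect_DA_junction,
    infer_fragment_length,
    median_insert_size,
)
from duplexmut.model import (
    AlignmentSupport,
    JunctionCall,
    PrimaryAlignment,
    SupplementaryAlignment,
    SupportingFragment,
    VariantCall,
    VariantType,
)
from duplexmut.simulate import generate_panel


def _insertion(chrom_seq, pos, allele, sample="s1", depth=20000, alt_count=1):
    """Insertion call at 1-based anchor pos with given inserted sequence."""
    anchor = chrom_seq[pos - 1]
    return VariantCall(sample_id=sample, chrom="locus01", pos=pos,
                       ref=anchor, alt=anchor + allele,
                       vtype=VariantType.INSERTION,
                       alt_count=alt_count, site_depth=depth)


@pytest.fixture(scope="module")
def contig():
    return generate_panel(n_loci=1, locus_len=2400, gc_fraction=0.45, seed=21)[0].sequence


def _mutate(seq, n, rng):
    s = list(seq)
    for i in rng.choice(len(s), size=n, replace=False):
        s[i] = next(b for b in "ACGT" if b != s[i])
    return "".join(s)


class TestDetectJunction:
    def test_exact_downstream_copy_is_positive(self, contig):
        pos = 500
        allele = contig[pos : pos + 180]  # reference starting 1 bp downstream
        call = _insertion(contig, pos, allele)
        positive, match = detect_DA_junction(call, contig)
        assert positive and match == pos + 1

    def test_mismatch_budget_boundary(self, contig):
        """180 bp allows floor(180/50) = 3 mismatches: positive at 3,
        negative at 4."""
        rng = np.random.default_rng(0)
        pos = 500
        allele = contig[pos : pos + 180]
        ok = _insertion(contig, pos, _mutate(allele, 3, rng))
        bad = _insertion(contig, pos, _mutate(allele, 4, rng))
        assert detect_DA_junction(ok, contig)[0] is True
        assert detect_DA_junction(bad, contig)[0] is False

    def test_short_allele_allows_zero_mismatches(self, contig):
        pos = 300
        allele = contig[pos : pos + 40]
        rng = np.random.default_rng(1)
        assert detect_DA_junction(_insertion(contig, pos, allele), contig)[0]
        assert not detect_DA_junction(
            _insertion(contig, pos, _mutate(allele, 1, rng)), contig)[0]

    def test_random_insert_is_negative(self, contig):
        rng = np.random.default_rng(2)
        for _ in range(20):
            allele = "".join(rng.choice(list("ACGT"), size=180))
            call = _insertion(contig, 500, allele)
            assert detect_DA_junction(call, contig)[0] is False

    def test_copy_elsewhere_is_negative(self, contig):
        """A perfect match that is not exactly 1 bp downstream does not
        support a D-A junction."""
        allele = contig[800 : 800 + 150]
        call = _insertion(contig, 500, allele)
        positive, match = detect_DA_junction(call, contig)
        assert positive is False
        assert match == 801  # the off-position match is still reported

    def test_agrees_with_bruteforce_hamming_scan(self, contig):
        """Oracle: pure-python sliding Hamming scan over the contig."""
        rng = np.random.default_rng(3)
        for _ in range(15):
            pos = int(rng.integers(1, 2100))
            L = int(rng.integers(60, 250))
            if pos + L >= len(contig):
                continue
            allele = _mutate(contig[pos : pos + L], int(rng.integers(0, 6)), rng)
            call = _insertion(contig, pos, allele)
            k = L // 50
            hits = [
                off for off in range(len(contig) - L + 1)
                if sum(a != b for a, b in zip(contig[off : off + L], allele)) <= k
            ]
            expected = pos in hits
            assert detect_DA_junction(call, contig)[0] == expected

    def test_too_short_allele_rejected(self, contig):
        with pytest.raises(ValueError, match=">= 20"):
            detect_DA_junction(_insertion(contig, 10, contig[10:25]), contig)


class TestFragmentLength:
    def test_concordant_adds_five_prime_clips(self):
        s = AlignmentSupport(
            variant_key=("s1", "locus01", 100, 180),
            read1=PrimaryAlignment(130, 270, "fwd", softclip5=30),
            read2=PrimaryAlignment(140, 250, "rev"),
            concordant=True, insert_size=150,
        )
        assert infer_fragment_length(s) == 180

    def test_three_prime_clip_ignored(self):
        s = AlignmentSupport(
            variant_key=("s1", "locus01", 100, 120),
            read1=PrimaryAlignment(100, 200, "fwd", softclip5=0, softclip3=25),
            read2=PrimaryAlignment(110, 220, "rev", softclip3=18),
            concordant=True, insert_size=120,
        )
        assert infer_fragment_length(s) == 120

    def test_discordant_pseudo_pair(self):
        # fwd primary starts at 1030 with 30 bp 5' clip; rev supplementary
        # ends at 1370: fragment spans 1000..1370 = 370 bp
        s = AlignmentSupport(
            variant_key=("s1", "locus01", 1000, 370),
            read1=PrimaryAlignment(1030, 1170, "fwd", softclip5=30),
            read2=PrimaryAlignment(1250, 1330, "rev", softclip5=40),
            concordant=False,
            read2_supp=SupplementaryAlignment(1230, 1370, "rev"),
        )
        assert infer_fragment_length(s) == 370

    def test_missing_supplementary_is_ambiguous(self):
        s = AlignmentSupport(
            variant_key=("s1", "locus01", 1000, 370),
            read1=PrimaryAlignment(1030, 1170, "fwd"),
            read2=PrimaryAlignment(1250, 1330, "rev"),
            concordant=False,
        )
        with pytest.raises(AmbiguousFragmentError):
            infer_fragment_length(s)

    def test_generator_geometry_roundtrip(self, study_cohort):
        """Inferred fragment lengths equal the generator's truth."""
        truth = {}
        for e in study_cohort.truth.events:
            if e["label"] in ("circle", "tandem_duplication"):
                key = (e["sample_id"], e["chrom"], e["pos"], e["allele_length"])
                truth[key] = sorted(e["fragment_lengths"])
        checked = 0
        inferred = {}
        for s in study_cohort.samples.values():
            for g in s.geometry:
                inferred.setdefault(tuple(g.variant_key), []).append(
                    infer_fragment_length(g))
        for key, lengths in inferred.items():
            assert sorted(lengths) == truth[key]
            checked += 1
        assert checked > 100


def _jc(allele, frag_lengths, flagged=None):
    frags = [
        SupportingFragment(fragment_length=f,
                           contains_duplicated_or_flanking=(flagged or [False] * len(frag_lengths))[i],
                           geometry="discordant_split")
        for i, f in enumerate(frag_lengths)
    ]
    return JunctionCall(variant_key=("s1", "locus01", 1, allele), allele_length=allele,
                        has_DA_junction=True, vaf=1e-4, supporting_fragments=frags)


class TestClassification:
    def test_td_from_duplicated_flanking_fragment(self):
        jc = _jc(75, [180], flagged=[True])
        assert classify_circle_vs_td(jc, 233) == "tandem_duplication"

    def test_fragment_longer_than_allele_implies_td(self):
        assert classify_circle_vs_td(_jc(75, [180]), 233) == "tandem_duplication"

    def test_circle_when_all_fragments_within_allele(self):
        assert classify_circle_vs_td(_jc(370, [160, 230]), 233) == "circle_consistent"

    def test_boundary_fragment_equal_to_allele_is_circle(self):
        assert classify_circle_vs_td(_jc(233, [233]), 233) == "circle_consistent"

    def test_no_fragments_is_ambiguous(self):
        assert classify_circle_vs_td(_jc(300, []), 233) == "ambiguous"


class TestBinomialSubset:
    def test_three_of_four(self):
        # enumeration over 2^4 equally likely outcomes: P(X >= 3) = 5/16
        k, n, p = binomial_subset_test([_jc(200, [100, 120, 150, 250])], 233)
        assert (k, n) == (3, 4)
        assert p == pytest.approx(0.3125)

    def test_all_below_is_half_power_n(self):
        for n in (1, 5, 10):
            calls = [_jc(200, [100] * n)]
            k, nn, p = binomial_subset_test(calls, 233)
            assert (k, nn) == (n, n)
            assert p == pytest.approx(0.5 ** n)

    def test_empty_subset_missing(self):
        assert binomial_subset_test([], 233) == (0, 0, None)


def test_median_insert_size():
    assert median_insert_size([200, 233, 260]) == 233
    with pytest.raises(ValueError):
        median_insert_size([])


class TestCandidateCalling:
    def test_boundary_125_excluded(self, contig):
        from duplexmut.eccdna import call_candidate_microdnas

        jcs = [_jc(125, [100]), _jc(126, [100]), _jc(300, [200])]
        res = call_candidate_microdnas(jcs, duplex_bases=10**9)
        assert len(res.candidate_microdnas) == 2
        assert res.candidate_frequency == pytest.approx(2e-9)

    def test_junction_negative_never_candidate(self):
        from duplexmut.eccdna import call_candidate_microdnas

        jc = _jc(300, [200])
        jc.has_DA_junction = False
        res = call_candidate_microdnas([jc])
        assert res.candidate_microdnas == []
        assert res.n_insertions_gt20 == 1 and res.n_with_junction == 0


class TestCohortAnalysis:
    def test_implanted_events_classified_without_cross_errors(self, study_cohort):
        """Every implanted circle is junction-positive and never labeled
        TD; every implanted TD whose fragments exceed its allele is
        labeled TD."""
        from duplexmut.filters import collapse_clonal

        truth_circles, truth_tds = {}, {}
        for e in study_cohort.truth.events:
            key = (e["sample_id"], e["chrom"], e["pos"], e.get("allele_length"))
            if e["label"] == "circle":
                truth_circles[key] = e
            elif e["label"] == "tandem_duplication":
                truth_tds[key] = e
        pooled, geom = [], []
        for s in study_cohort.samples.values():
            if s.tissue != "sperm":
                continue
            unique, _ = collapse_clonal(s.calls)
            pooled += unique
            geom += s.geometry
        jcs, res = analyze_circles(pooled, study_cohort.panel, geom, median_insert=233)
        by_key = {(jc.variant_key[0], jc.variant_key[1], jc.variant_key[2],
                   jc.allele_length): jc for jc in jcs}
        assert len(truth_circles) >= 250
        for key in truth_circles:
            jc = by_key[key]
            assert jc.has_DA_junction
            assert jc.classification != "tandem_duplication"
        for key, e in truth_tds.items():
            jc = by_key[key]
            assert jc.has_DA_junction
            if any(f > e["allele_length"] for f in e["fragment_lengths"]):
                assert jc.classification == "tandem_duplication"

    def test_no_junctions_in_blood(self, study_cohort):
        from duplexmut.filters import collapse_clonal

        pooled, geom = [], []
        for s in study_cohort.samples.values():
            if s.tissue != "blood":
                continue
            unique, _ = collapse_clonal(s.calls)
            pooled += unique
            geom += s.geometry
        _, res = analyze_circles(pooled, study_cohort.panel, geom, median_insert=233)
        assert res.candidate_microdnas == []
        assert res.n_with_junction == 0
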