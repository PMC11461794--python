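"""Filtering ladder: unit rules, boundaries, accounting, and a
brute-force O(n^2) oracle for the pairwise rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from duplexmut.filters import (
    FilterConfig,
    apply_vaf_gate,
    collapse_clonal,
    exclude_snv_near_indels,
    exclude_snv_over_clonal_mnv,
    indel_boundaries,
    remove_intra_cohort_contamination,
    run_filter_ladder,
)
from duplexmut.model import VariantCall, VariantType
from tests.conftest import make_snv


def make_del(sample="s1", chrom="locus01", pos=100, size=5, alt_count=1, depth=20000):
    ref = "A" + "C" * size
    return VariantCall(sample_id=sample, chrom=chrom, pos=pos, ref=ref, alt="A",
                       vtype=VariantType.DELETION, alt_count=alt_count, site_depth=depth)


def make_mnv(sample="s1", chrom="locus01", pos=100, length=3, alt_count=1, depth=20000):
    return VariantCall(sample_id=sample, chrom=chrom, pos=pos, ref="A" * length,
                       alt="C" * length, vtype=VariantType.MNV,
                       alt_count=alt_count, site_depth=depth)


class TestCollapseClonal:
    def test_identical_rows_merge_with_summed_support(self):
        rows = [make_snv(alt_count=1) for _ in range(3)]
        unique, stats = collapse_clonal(rows)
        assert len(unique) == 1
        assert unique[0].alt_count == 3
        assert stats.n_input_rows == 3 and stats.n_unique == 1

    def test_single_count_fraction(self):
        rows = [make_snv(pos=p) for p in range(1, 97)]
        rows += [make_snv(pos=p, alt_count=2) for p in range(200, 204)]
        _, stats = collapse_clonal(rows)
        assert stats.single_count_fraction_snv == pytest.approx(0.96)

    def test_same_position_different_alt_kept_separate(self):
        rows = [make_snv(alt="T"), make_snv(alt="G"), make_snv(alt="T")]
        unique, _ = collapse_clonal(rows)
        assert sorted((u.alt, u.alt_count) for u in unique) == [("G", 1), ("T", 2)]

    def test_mixed_samples_rejected(self):
        with pytest.raises(ValueError, match="one sample"):
            collapse_clonal([make_snv(sample="a"), make_snv(sample="b")])


class TestVafGate:
    def test_gate_is_inclusive(self):
        keep = make_snv(alt_count=180, site_depth=20000)  # VAF 0.009
        at = make_snv(pos=2, alt_count=200, site_depth=20000)  # exactly 0.01
        drop = make_snv(pos=3, alt_count=10000, site_depth=20000)  # germline
        out = apply_vaf_gate([keep, at, drop], 0.01)
        assert [c.pos for c in out] == [100, 2]

    @given(st.lists(st.integers(1, 1000), min_size=1, max_size=50))
    @settings(deadline=None, max_examples=25)
    def test_monotone_in_threshold(self, counts):
        calls = [make_snv(pos=i + 1, alt_count=c, site_depth=1000)
                 for i, c in enumerate(counts)]
        low = apply_vaf_gate(calls, 0.01)
        high = apply_vaf_gate(calls, 0.05)
        assert set(id(c) for c in low) <= set(id(c) for c in high)


class TestMnvOverlap:
    def test_snv_inside_clonal_mnv_removed(self):
        mnv = make_mnv(pos=104, length=3, alt_count=400)  # VAF 0.02
        snv = make_snv(pos=105)
        retained, removed = exclude_snv_over_clonal_mnv([snv], [mnv])
        assert retained == [] and removed == [snv]

    def test_low_vaf_mnv_does_not_trigger(self):
        mnv = make_mnv(pos=104, length=3, alt_count=100)  # VAF 0.005
        snv = make_snv(pos=105)
        retained, _ = exclude_snv_over_clonal_mnv([snv], [mnv])
        assert retained == [snv]

    def test_adjacent_snv_retained(self):
        mnv = make_mnv(pos=104, length=3, alt_count=400)  # span 104-106
        for pos, kept in [(103, True), (104, False), (106, False), (107, True)]:
            retained, _ = exclude_snv_over_clonal_mnv([make_snv(pos=pos)], [mnv])
            assert bool(retained) is kept

    def test_other_sample_mnv_ignored(self):
        mnv = make_mnv(sample="s2", pos=104, alt_count=400)
        retained, _ = exclude_snv_over_clonal_mnv([make_snv(pos=105)], [mnv])
        assert len(retained) == 1


class TestIndelProximity:
    def test_boundaries(self):
        assert indel_boundaries(make_del(pos=100, size=5)) == (100, 105)
        ins = VariantCall(sample_id="s1", chrom="c", pos=100, ref="A", alt="ATTT",
                          vtype=VariantType.INSERTION, alt_count=1, site_depth=100)
        assert indel_boundaries(ins) == (100, 101)

    def test_window_is_inclusive_at_10(self):
        indel = make_del(pos=100, size=5)  # boundaries 100, 105
        at10 = make_snv(pos=115)
        at11 = make_snv(pos=116)
        retained, removed = exclude_snv_near_indels([at10, at11], [indel], 10)
        assert removed == [at10] and retained == [at11]

    def test_constructed_cohort_removes_exact_count(self):
        # 33 SNVs placed inside windows, 20 outside
        indels = [make_del(pos=1000 * (i + 1), size=4) for i in range(33)]
        inside = [make_snv(pos=1000 * (i + 1) + 7) for i in range(33)]
        outside = [make_snv(pos=1000 * (i + 1) + 500) for i in range(20)]
        retained, removed = exclude_snv_near_indels(inside + outside, indels, 10)
        assert len(removed) == 33
        assert len(retained) == 20


class TestContamination:
    def test_truth_table(self):
        germ = make_snv(sample="donor", alt_count=10000, site_depth=20000)  # VAF 0.5
        low = make_snv(sample="victim", alt_count=100, site_depth=20000)  # 0.005
        mid = make_snv(sample="other", alt_count=400, site_depth=20000)  # 0.02
        lone = make_snv(sample="victim", pos=999, alt_count=100, site_depth=20000)
        cohort = {"donor": [germ], "victim": [low, lone], "other": [mid]}
        retained, removed = remove_intra_cohort_contamination(cohort)
        assert removed["victim"] == [low]  # matches germline, low VAF
        assert retained["other"] == [mid]  # fails the low-VAF arm
        assert retained["donor"] == [germ]  # germline copy untouched
        assert lone in retained["victim"]  # present nowhere else

    def test_implanted_pairs_all_recovered(self):
        rng = np.random.default_rng(1)
        cohort = {f"s{i}": [] for i in range(6)}
        implanted = 0
        for i in range(6):
            for j in range(16 if i == 0 else 2):
                pos = int(rng.integers(1, 40000))
                donor = f"s{(i + 1) % 6}"
                cohort[donor].append(make_snv(sample=donor, pos=pos,
                                              alt_count=10000, site_depth=20000))
                cohort[f"s{i}"].append(make_snv(sample=f"s{i}", pos=pos,
                                                alt_count=80, site_depth=20000))
                implanted += 1
        assert implanted == 26
        _, removed = remove_intra_cohort_contamination(cohort)
        assert sum(len(v) for v in removed.values()) == 26
        assert len(removed["s0"]) == 16

    def test_single_sample_noop_with_warning(self):
        cohort = {"s1": [make_snv()]}
        with pytest.warns(UserWarning):
            retained, removed = remove_intra_cohort_contamination(cohort)
        assert retained == cohort and removed == {"s1": []}


def _brute_force_ladder(cohort, config):
    """Independent O(n^2) reimplementation of the pairwise rules."""
    collapsed = {}
    for sample, calls in cohort.items():
        seen = {}
        for c in calls:
            if c.key in seen:
                prev = seen[c.key]
                seen[c.key] = VariantCall(
                    sample_id=c.sample_id, chrom=c.chrom, pos=c.pos, ref=c.ref,
                    alt=c.alt, vtype=c.vtype,
                    alt_count=prev.alt_count + c.alt_count,
                    site_depth=max(prev.site_depth, c.site_depth), sv_len=c.sv_len)
            else:
                seen[c.key] = c
        collapsed[sample] = list(seen.values())
    staged = {}
    for sample, calls in collapsed.items():
        out = []
        for c in calls:
            if c.vtype is VariantType.SNV:
                killed = False
                for m in calls:
                    if m.vtype is VariantType.MNV and m.vaf >= config.clonal_mnv_vaf_min \
                            and m.chrom == c.chrom and m.pos <= c.pos <= m.end:
                        killed = True
                for ind in calls:
                    if ind.vtype in (VariantType.INSERTION, VariantType.DELETION,
                                     VariantType.COMPLEX) and ind.chrom == c.chrom:
                        for b in indel_boundaries(ind):
                            if abs(c.pos - b) <= config.indel_exclusion_window_bp:
                                killed = True
                if killed:
                    continue
            out.append(c)
        staged[sample] = out
    final = {}
    for sample, calls in staged.items():
        out = []
        for c in calls:
            contaminated = False
            if c.vaf < config.contamination_low_vaf and len(staged) >= 2:
                for other, ocalls in staged.items():
                    if other == sample:
                        continue
                    for o in ocalls:
                        if o.key == c.key and o.vaf > config.contamination_germline_vaf:
                            contaminated = True
            if not contaminated and c.vaf <= config.vaf_max:
                out.append(c)
        final[sample] = out
    return final


def test_ladder_matches_brute_force_oracle(small_cohort):
    config = FilterConfig()
    cohort = {sid: s.calls[:100] for sid, s in small_cohort.samples.items()}
    assert sum(len(v) for v in cohort.values()) <= 400
    fast, _ = run_filter_ladder(cohort, config)
    slow = _brute_force_ladder(cohort, config)
    for sample in cohort:
        assert sorted(c.key for c in fast[sample]) == sorted(c.key for c in slow[sample])


def test_ladder_accounting_and_idempotence(small_cohort):
    config = FilterConfig()
    cohort = small_cohort.calls_by_sample()
    filtered, report = run_filter_ladder(cohort, config)
    n_retained = sum(len(v) for v in filtered.values())
    assert report.n_input_unique == n_retained + report.n_removed
    twice, report2 = run_filter_ladder(filtered, config)
    assert {s: sorted(c.key for c in v) for s, v in twice.items()} == \
           {s: sorted(c.key for c in v) for s, v in filtered.items()}


def test_ladder_clean_cohort_zero_removals(panel):
    from duplexmut.simulate import GeneratorConfig, generate_cohort

    config = GeneratorConfig.sperm(
        seed=3, n_samples=2, duplex_bases_per_sample=100_000_000,
        snv_mf=2.5e-8, mnv_mf=0, indel_mf=0, sv_mf=0, clonal_fraction_snv=0,
        circle_count=0, td_count=0, random_insertion_count=0,
        contaminants_per_sample=0, mnv_partial_snv_count=0,
        indel_proximal_snv_count=0, germline_het_per_kb=0,
    )
    cohort = generate_cohort([config], panel, seed=3)
    filtered, report = run_filter_ladder(cohort.calls_by_sample())
    assert report.n_removed == 0
    assert sum(len(v) for v in filtered.values()) == report.n_input_unique


def test_ladder_removal_counts_match_truth(small_cohort):
    filtered, report = run_filter_ladder(small_cohort.calls_by_sample())
    truth = small_cohort.truth
    assert report.removed["contamination"] >= truth.count("contaminant_pair")
    assert report.removed["snv_over_clonal_mnv"] >= truth.count("mnv_partial_snv")
    assert report.removed["snv_near_indel"] >= truth.count("indel_proximal_snv")
    # no implanted artifact survives
    surviving = {(c.sample_id, *c.key) for v in filtered.values() for c in v}
    for label in ("contaminant_pair", "mnv_partial_snv", "indel_proximal_snv"):
        for e in truth.events:
            if e["label"] == label:
                assert (e["sample_id"], e["chrom"], e["pos"], e["ref"], e["alt"]) \
                    not in surviving


def test_shared_mutation_mode_removes_cross_tissue_pairs():
    from duplexmut.filters import remove_shared_mutations

    blood = [make_snv(sample="b1", pos=10), make_snv(sample="b1", pos=20)]
    sperm = [make_snv(sample="sp1", pos=10), make_snv(sample="sp1", pos=30)]
    out = remove_shared_mutations({"ind1": (blood, sperm)})
    a, b = out["ind1"]
    assert [c.pos for c in a] == [20] and [c.pos for c in b] == [30]
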