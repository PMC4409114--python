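"""Reciprocal overlap, locus clustering, Jaccard concordance, novelty."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnvpop.intervals import (
    OverlapRule,
    cluster_loci,
    dedup_same_sample,
    flag_novel,
    jaccard_calls,
    reciprocal_overlap,
)
from conftest import make_call, random_calls


def brute_force_loci(calls, rule, type_aware=True):
    """Independent oracle: O(n^2) pairwise links + connected components."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(calls)))
    for i in range(len(calls)):
        for j in range(i + 1, len(calls)):
            if type_aware and calls[i].cnv_type != calls[j].cnv_type:
                continue
            if rule.matches(calls[i], calls[j]):
                g.add_edge(i, j)
    return {frozenset(comp) for comp in nx.connected_components(g)}


class TestReciprocalOverlap:
    def test_worked_arithmetic(self):
        a = make_call(start=100, end=200)
        b = make_call(start=150, end=250)
        # overlap 150..200 = 51 bp, each interval 101 bp
        assert reciprocal_overlap(a, b) == pytest.approx(51 / 101)
        assert OverlapRule(threshold=0.5).matches(a, b)

    def test_identity_and_disjoint(self):
        a = make_call(start=100, end=200)
        assert reciprocal_overlap(a, a) == 1.0
        assert reciprocal_overlap(a, make_call(start=300, end=400)) == 0.0
        assert reciprocal_overlap(a, make_call(chrom="2", start=100, end=200)) == 0.0

    @settings(max_examples=100, deadline=None)
    @given(
        s1=st.integers(1, 10**6), l1=st.integers(1, 10**5),
        s2=st.integers(1, 10**6), l2=st.integers(1, 10**5),
    )
    def test_symmetric_and_bounded(self, s1, l1, s2, l2):
        a = make_call(start=s1, end=s1 + l1 - 1)
        b = make_call(start=s2, end=s2 + l2 - 1)
        assert reciprocal_overlap(a, b) == reciprocal_overlap(b, a)
        assert 0.0 <= reciprocal_overlap(a, b) <= 1.0

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_rule_threshold_range(self, bad):
        with pytest.raises(ValueError):
            OverlapRule(threshold=bad)


class TestClusterLoci:
    def test_three_identical_intervals_one_locus(self):
        calls = [make_call(sample=f"S{i}", pop=f"P{i}") for i in range(3)]
        loci = cluster_loci(calls)
        assert len(loci) == 1
        assert loci[0].populations_present == {"P0", "P1", "P2"}

    def test_disjoint_intervals_two_loci(self):
        calls = [make_call(start=100, end=200), make_call(start=10_000, end=10_100)]
        assert len(cluster_loci(calls)) == 2

    def test_single_linkage_chains(self):
        # a-b and b-c match at >=50% but a-c do not: one locus of three
        a = make_call(start=100, end=200, sample="S1")
        b = make_call(start=150, end=250, sample="S2")
        c = make_call(start=200, end=300, sample="S3")
        rule = OverlapRule(threshold=0.5)
        assert rule.matches(a, b) and rule.matches(b, c) and not rule.matches(a, c)
        loci = cluster_loci([a, b, c], rule)
        assert len(loci) == 1
        assert len(loci[0].member_calls) == 3
        assert (loci[0].start, loci[0].end) == (100, 300)

    def test_strict_all_pairs_splits_chain(self):
        a = make_call(start=100, end=200, sample="S1")
        b = make_call(start=150, end=250, sample="S2")
        c = make_call(start=200, end=300, sample="S3")
        assert len(cluster_loci([a, b, c], strict_all_pairs=True)) == 2

    def test_type_aware_never_merges_dup_del(self):
        dup = make_call(cnv_type="DUP")
        dele = make_call(cnv_type="DEL")
        assert len(cluster_loci([dup, dele])) == 2
        assert len(cluster_loci([dup, dele], type_aware=False)) == 1

    def test_partition_property(self, rng):
        calls = random_calls(rng, 200)
        loci = cluster_loci(calls)
        members = [c for l in loci for c in l.member_calls]
        assert len(members) == len(calls)
        assert sorted(map(id, members)) == sorted(map(id, calls))

    @pytest.mark.parametrize("seed,n", [(0, 60), (1, 120), (2, 250)])
    def test_matches_brute_force_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        calls = random_calls(rng, n)
        rule = OverlapRule(threshold=0.5)
        pos = {id(c): i for i, c in enumerate(calls)}
        got = {
            frozenset(pos[id(c)] for c in l.member_calls)
            for l in cluster_loci(calls, rule)
        }
        assert got == brute_force_loci(calls, rule)

    def test_exact_breakpoint_mode(self):
        a = make_call(start=100, end=10_000)
        b = make_call(start=105, end=10_003, sample="S2")
        loose = OverlapRule(mode="exact_breakpoint", breakpoint_tolerance=10)
        tight = OverlapRule(mode="exact_breakpoint", breakpoint_tolerance=0)
        assert len(cluster_loci([a, b], loose)) == 1
        assert len(cluster_loci([a, b], tight)) == 2

    def test_empty_input(self):
        assert cluster_loci([]) == []


class TestDedup:
    def test_same_sample_overlaps_collapse(self):
        a = make_call(start=100, end=10_000)
        b = make_call(start=120, end=10_050)  # same sample, matches a
        other = make_call(start=100, end=10_000, sample="S2")
        kept = dedup_same_sample([a, b, other])
        assert len(kept) == 2
        assert {c.sample_id for c in kept} == {"S1", "S2"}

    def test_keeps_longest(self):
        short = make_call(start=100, end=10_000)
        longer = make_call(start=90, end=10_050)
        assert dedup_same_sample([short, longer]) == [longer]


class TestJaccard:
    def test_identical_sets(self, rng):
        calls = random_calls(rng, 30)
        assert jaccard_calls(calls, list(calls)) == 1.0

    def test_disjoint_sets(self):
        a = [make_call(start=100, end=200), make_call(start=1000, end=1100)]
        b = [make_call(start=10**6 + s, end=10**6 + s + 100) for s in (0, 500, 1000)]
        assert jaccard_calls(a, b) == 0.0

    def test_subset_worked_example(self):
        x = make_call(start=100, end=10_000)
        y = make_call(start=50_000, end=60_000)
        # A = {x, y}, B = {x}: 1 match / (2 + 1 - 1) = 0.5
        assert jaccard_calls([x, y], [x]) == 0.5

    def test_both_empty_convention(self):
        assert jaccard_calls([], []) == 1.0

    def test_monotone_under_disjoint_additions(self, rng):
        a = random_calls(rng, 20)
        b = list(a)
        prev = jaccard_calls(a, b)
        for k in range(5):
            b.append(make_call(chrom="21", start=10**6 * (k + 1), end=10**6 * (k + 1) + 200_000))
            cur = jaccard_calls(a, b)
            assert cur <= prev
            prev = cur

    def test_types_matched_separately(self):
        dup = make_call(cnv_type="DUP")
        dele = make_call(cnv_type="DEL", cn=1)
        # same interval, opposite types: no match when split by type
        assert jaccard_calls([dup], [dele]) == 0.0
        assert jaccard_calls([dup], [dele], by_type=False) == 1.0


class TestNovelty:
    def test_known_and_novel(self):
        ref = [make_call(start=100, end=10_000, sample="ref", pop="ref")]
        known = make_call(start=100, end=10_000)
        far = make_call(start=10**7, end=10**7 + 10_000)
        flags, summary = flag_novel([known, far], ref)
        assert flags == [False, True]
        assert summary.n_novel == 1

    def test_below_threshold_is_novel(self):
        # reciprocal overlap 0.4 < 0.5 threshold
        ref = [make_call(start=1, end=1000, sample="ref", pop="ref")]
        call = make_call(start=601, end=1600)
        assert reciprocal_overlap(call, ref[0]) == pytest.approx(0.4)
        flags, _ = flag_novel([call], ref)
        assert flags == [True]

    def test_empty_reference_all_novel_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            flags, summary = flag_novel([make_call()], [])
        assert flags == [True]
        assert summary.novel_fraction == 1.0
        assert any("empty reference" in r.message for r in caplog.records)
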