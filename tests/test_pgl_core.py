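"""Paired-genomic-loci algebra against brute-force oracles and examples."""

import numpy as np
import pandas as pd
import pytest

from loopvar.pgl_core import (
    GenomicInterval,
    Loop,
    LoopSet,
    closest,
    coverage,
    find_span,
    gap_distance,
    intersect1d,
    intersect_loops,
    merge_loops,
    read_bedpe,
    write_bedpe,
)

from conftest import brute_components, loops_close, mk_loop, random_loopset


class TestIntervals:
    def test_invalid_intervals_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)

    def test_gap_distance(self):
        a = GenomicInterval("chr1", 0, 10)
        assert gap_distance(a, GenomicInterval("chr1", 5, 15)) == 0
        assert gap_distance(a, GenomicInterval("chr1", 10, 15)) == 0
        assert gap_distance(a, GenomicInterval("chr1", 25, 30)) == 15
        with pytest.raises(ValueError):
            gap_distance(a, GenomicInterval("chr2", 0, 10))

    def test_loop_canonical_anchor_order(self):
        lp = mk_loop("chr1", 500, 600, 100, 200)
        assert (lp.anchorA.start, lp.anchorB.start) == (100, 500)

    def test_interchromosomal_loop_rejected(self):
        with pytest.raises(ValueError):
            Loop(GenomicInterval("chr1", 0, 10), GenomicInterval("chr2", 0, 10))


class TestMerge:
    def test_empty_set_identity(self):
        assert len(merge_loops(LoopSet(), 20_000)) == 0

    def test_two_loop_union_span(self):
        s = LoopSet(
            [
                mk_loop("chr1", 100_000, 110_000, 300_000, 310_000),
                mk_loop("chr1", 115_000, 125_000, 305_000, 315_000),
            ]
        )
        m = merge_loops(s, 20_000, keep_rule="union_span")
        assert len(m) == 1
        lp = m[0]
        assert (lp.anchorA.start, lp.anchorA.end) == (100_000, 125_000)
        assert (lp.anchorB.start, lp.anchorB.end) == (300_000, 315_000)

    def test_zero_slack_no_overlap_is_noop(self, rng):
        s = LoopSet(
            [
                mk_loop("chr1", 0, 10, 100, 110),
                mk_loop("chr1", 50, 60, 200, 210),
                mk_loop("chr2", 0, 10, 100, 110),
            ]
        )
        m = merge_loops(s, 0)
        assert [lp.key for lp in m] == [lp.key for lp in s]

    def test_negative_slack_rejected(self):
        with pytest.raises(ValueError):
            merge_loops(LoopSet(), -1)

    def test_mixed_chromosomes_never_merge(self):
        s = LoopSet(
            [mk_loop("chr1", 0, 10, 100, 110), mk_loop("chr2", 0, 10, 100, 110)]
        )
        assert len(merge_loops(s, 10**9)) == 2

    @pytest.mark.parametrize("keep_rule", ["union_span", "most_significant", "smallest_anchors"])
    def test_idempotent(self, rng, keep_rule):
        for _ in range(20):
            s = random_loopset(rng, int(rng.integers(2, 12)))
            slack = int(rng.integers(0, 100_000))
            once = merge_loops(s, slack, keep_rule=keep_rule)
            twice = merge_loops(once, slack, keep_rule=keep_rule)
            assert [a.key for a in once] == [b.key for b in twice]

    def test_grouping_matches_brute_force_closure(self, rng):
        for _ in range(50):
            s = random_loopset(rng, int(rng.integers(2, 10)))
            slack = int(rng.integers(0, 200_000))
            merged = merge_loops(s, slack, keep_rule="most_significant")
            expected = brute_components(s.loops, slack)
            assert len(merged) == len(expected)

    def test_keep_rules(self):
        s = LoopSet(
            [
                mk_loop("chr1", 0, 10_000, 100_000, 110_000, p=1e-6),
                mk_loop("chr1", 5_000, 8_000, 102_000, 104_000, p=1e-3),
            ]
        )
        assert merge_loops(s, 0, "most_significant")[0].payload["p"] == 1e-6
        assert merge_loops(s, 0, "smallest_anchors")[0].total_anchor_length == 5_000


class TestIntersect:
    def test_self_intersection_reflexive(self, rng):
        s = random_loopset(rng, 8)
        ev = intersect_loops(s, s, slack_bp=0)
        self_pairs = [(a, b) for a, b in ev if a.key == b.key]
        assert len(self_pairs) >= len(s)

    def test_disjoint_chromosomes_empty(self):
        a = LoopSet([mk_loop("chr1", 0, 10, 100, 110)])
        b = LoopSet([mk_loop("chr2", 0, 10, 100, 110)])
        assert intersect_loops(a, b, slack_bp=10**9) == []

    def test_one_vs_two_gives_two_events(self):
        a = LoopSet([mk_loop("chr1", 100, 200, 1_000, 1_100)])
        b = LoopSet(
            [
                mk_loop("chr1", 150, 250, 1_050, 1_150, name="b1"),
                mk_loop("chr1", 90, 120, 990, 1_010, name="b2"),
                mk_loop("chr1", 10_000, 10_100, 20_000, 20_100, name="far"),
            ]
        )
        ev = intersect_loops(a, b, slack_bp=0)
        assert sorted(e[1].payload["name"] for e in ev) == ["b1", "b2"]

    def test_matches_all_pairs_brute_force(self, rng):
        for _ in range(30):
            a = random_loopset(rng, int(rng.integers(1, 8)))
            b = random_loopset(rng, int(rng.integers(1, 8)))
            slack = int(rng.integers(0, 150_000))
            got = {
                (la.key, lb.key) for la, lb in intersect_loops(a, b, slack_bp=slack)
            }
            want = {
                (la.key, lb.key)
                for la in a
                for lb in b
                if loops_close(la, lb, slack)
            }
            assert got == want


class TestIntersect1D:
    def test_feature_between_anchors_not_annotated(self):
        s = LoopSet([mk_loop("chr1", 100, 200, 1_000, 1_100)])
        ann = intersect1d(s, [GenomicInterval("chr1", 500, 600)])
        assert ann[0]["A"] == [] and ann[0]["B"] == []

    def test_feature_equal_to_anchor_annotates_that_anchor(self):
        s = LoopSet([mk_loop("chr1", 100, 200, 1_000, 1_100)])
        ann = intersect1d(s, [GenomicInterval("chr1", 100, 200)])
        assert len(ann[0]["A"]) == 1 and ann[0]["B"] == []

    def test_matches_exhaustive_scan(self, rng):
        s = random_loopset(rng, 50)
        feats = [
            GenomicInterval(
                ["chr1", "chr2"][int(rng.integers(2))],
                int(p := rng.integers(0, 1_000_000)),
                int(p + rng.integers(1, 30_000)),
            )
            for _ in range(200)
        ]
        ann = intersect1d(s, feats)
        for rec in ann:
            lp = rec["loop"]
            for side, anchor in (("A", lp.anchorA), ("B", lp.anchorB)):
                want = sorted(
                    (
                        f
                        for f in feats
                        if f.chrom == anchor.chrom
                        and f.start < anchor.end
                        and anchor.start < f.end
                    ),
                    key=lambda f: (f.start, f.end),
                )
                assert rec[side] == want


class TestCoverage:
    def loops(self):
        return LoopSet(
            [
                mk_loop("chr1", 1_000, 2_000, 10_000, 11_000, name="L1"),
                mk_loop("chr2", 1_000, 2_000, 10_000, 11_000, name="L2"),
            ]
        )

    def test_no_contacts_all_zero(self):
        df = pd.DataFrame(columns=["chrom", "pos1", "pos2", "sample"])
        counts = coverage(self.loops(), df)
        assert (counts.to_numpy() == 0).all()

    def test_membership_counting(self):
        df = pd.DataFrame(
            {
                "chrom": ["chr1"] * 4,
                "pos1": [1_500, 1_200, 10_500, 1_100],
                "pos2": [10_200, 10_900, 1_800, 5_000],  # last: one end outside
                "sample": ["s1"] * 4,
            }
        )
        counts = coverage(self.loops(), df, pad_bp=0)
        assert counts.loc[:, "s1"].tolist() == [3, 0]

    def test_other_chromosome_contact_counts_zero(self):
        df = pd.DataFrame(
            {"chrom": ["chr3"], "pos1": [1_500], "pos2": [10_500], "sample": ["s1"]}
        )
        assert coverage(self.loops(), df)["s1"].sum() == 0

    def test_end_order_invariance(self, rng):
        s = random_loopset(rng, 10)
        n = 300
        df = pd.DataFrame(
            {
                "chrom": rng.choice(["chr1", "chr2"], n),
                "pos1": rng.integers(0, 1_000_000, n),
                "pos2": rng.integers(0, 1_000_000, n),
                "sample": rng.choice(["a", "b"], n),
            }
        )
        swapped = df.rename(columns={"pos1": "pos2", "pos2": "pos1"})
        c1 = coverage(s, df, pad_bp=5_000)
        c2 = coverage(s, swapped, pad_bp=5_000)
        assert (c1.to_numpy() == c2.to_numpy()).all()

    def test_interchromosomal_skipped_with_counter(self):
        df = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "chrom2": ["chr1", "chr2"],
                "pos1": [1_500, 1_500],
                "pos2": [10_500, 10_500],
                "sample": ["s1", "s1"],
            }
        )
        counts = coverage(self.loops(), df)
        assert counts.attrs["skipped"] == 1
        assert counts["s1"].tolist() == [1, 0]


class TestClosest:
    def test_identical_candidate_distance_zero(self):
        q = mk_loop("chr1", 100, 200, 1_000, 1_100)
        cand, d = closest(q, LoopSet([q]))
        assert d == 0

    def test_chebyshev_on_anchor_gaps(self):
        q = mk_loop("chr1", 100_000, 110_000, 500_000, 510_000)
        near = mk_loop("chr1", 115_000, 120_000, 515_000, 520_000, name="n")  # 5k/5k
        far = mk_loop("chr1", 111_000, 112_000, 540_000, 541_000, name="f")  # 1k/30k
        cand, d = closest(q, LoopSet([near, far]))
        assert cand.payload["name"] == "n" and d == 5_000

    def test_empty_candidates_error(self):
        with pytest.raises(ValueError):
            closest(mk_loop("chr1", 0, 1, 10, 11), LoopSet())


class TestSpan:
    def test_definition(self):
        s = LoopSet([mk_loop("chr1", 10, 20, 50, 60)])
        iv = find_span(s)[0]
        assert (iv.start, iv.end) == (10, 60)

    def test_span_covers_anchors(self, rng):
        s = random_loopset(rng, 100)
        for lp, iv in zip(s, find_span(s)):
            assert len(iv) >= len(lp.anchorA) and len(iv) >= len(lp.anchorB)
            assert iv.start == lp.anchorA.start
            assert iv.end == max(lp.anchorA.end, lp.anchorB.end)


class TestBedpeIO:
    def test_round_trip(self, rng, tmp_path):
        s = random_loopset(rng, 25)
        path = tmp_path / "loops.bedpe"
        write_bedpe(s, path)
        back = read_bedpe(path)
        assert [a.key for a in s] == [b.key for b in back]
        assert [a.payload for a in s] == [b.payload for b in back]

    def test_anchor_order_canonicalized_on_read(self, tmp_path):
        path = tmp_path / "swapped.bedpe"
        path.write_text("chr1\t5000\t6000\tchr1\t100\t200\tx\t.\t.\t.\n")
        s = read_bedpe(path)
        assert s[0].anchorA.start == 100 and s[0].anchorB.start == 5_000

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.bedpe"
        path.write_text("")
        assert len(read_bedpe(path)) == 0

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.bedpe"
        path.write_text("chr1\t0\t100\tchr1\t200\t300\n" "chr1\tnope\t100\n")
        with pytest.raises(ValueError, match=":2"):
            read_bedpe(path)
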