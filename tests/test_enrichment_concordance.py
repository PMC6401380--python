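"""Fisher-based enrichments, CNV/direction/concordance statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from loopvar.enrichment_concordance import (
    Contingency2x2,
    cnv_type_binomial,
    containment_enrichment,
    direction_test,
    eqtl_loop_overlap,
    fc_concordance,
    fisher_exact,
    maternal_fc,
    paired_state_network,
    state_enrichment_at_anchors,
    threshold_sweep,
)
from loopvar.pgl_core import GenomicInterval, LoopSet

from conftest import mk_loop


def hypergeom_two_sided(a, b, c, d):
    """Exhaustive point-probability-rule oracle for a 2x2 table."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    probs = {
        x: math.comb(col1, x)
        * math.comb(n - col1, row1 - x)
        / math.comb(n, row1)
        for x in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))


class TestFisherExact:
    def test_flat_table(self):
        orr, p = fisher_exact(Contingency2x2(5, 5, 5, 5))
        assert orr == 1.0 and p == 1.0

    def test_printed_scale_table(self):
        orr, p = fisher_exact(Contingency2x2(12, 102, 708, 25_857))
        assert orr == pytest.approx(4.30, abs=0.01)
        assert p == pytest.approx(hypergeom_two_sided(12, 102, 708, 25_857), rel=1e-9)

    def test_one_sided_not_larger_than_two_sided(self, rng):
        for _ in range(30):
            a, b, c, d = (int(x) for x in rng.integers(0, 20, 4))
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            t = Contingency2x2(a, b, c, d)
            _, p2 = fisher_exact(t)
            _, pg = fisher_exact(t, sided="greater")
            _, pl = fisher_exact(t, sided="less")
            assert min(pg, pl) <= p2 + 1e-12

    def test_zero_cell_continuity_corrected_or(self):
        t = Contingency2x2(5, 0, 3, 7)
        assert t.odds_ratio() == pytest.approx((5.5 * 7.5) / (0.5 * 3.5))

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            Contingency2x2(-1, 0, 0, 0)


def state_bins_frame(n_bins=2_000, n_states=5, rng=None):
    states = (
        rng.integers(1, n_states + 1, n_bins)
        if rng is not None
        else np.ones(n_bins, dtype=int)
    )
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n_bins) * 200,
            "state": states,
        }
    )


class TestStateEnrichment:
    def test_whole_genome_anchors_give_unit_or(self, rng):
        bins = state_bins_frame(rng=rng)
        anchors = [GenomicInterval("chr1", 0, 2_000 * 200)]
        res = state_enrichment_at_anchors(anchors, bins)
        assert np.allclose(res["odds_ratio"], 1.0)

    def test_single_state_anchors(self, rng):
        bins = state_bins_frame(rng=rng)
        s1 = bins.loc[bins["state"] == 1, "start"].to_numpy()[:50]
        anchors = [GenomicInterval("chr1", int(s), int(s) + 200) for s in s1]
        res = state_enrichment_at_anchors(anchors, bins)
        assert res.loc[1, "odds_ratio"] > 100  # continuity-corrected, flagged
        assert (res.drop(index=1)["odds_ratio"] < 1).all()

    def test_twofold_enrichment_recovered(self, rng):
        bins = state_bins_frame(n_bins=20_000, rng=rng)
        # anchors sample state-3 bins at twice the rate of other bins
        is3 = (bins["state"] == 3).to_numpy()
        prob = np.where(is3, 2.0, 1.0)
        prob = prob / prob.sum()
        idx = rng.choice(len(bins), size=3_000, replace=False, p=prob)
        anchors = [
            GenomicInterval("chr1", int(s), int(s) + 200)
            for s in bins["start"].to_numpy()[idx]
        ]
        res = state_enrichment_at_anchors(anchors, bins)
        assert res.loc[3, "odds_ratio"] == pytest.approx(2.0, rel=0.10)
        assert res.loc[3, "significant"]


class TestPairedStateNetwork:
    def loops_with_states(self, pairs, offset=0):
        loops, bins_rows = [], []
        cursor = offset
        for k, (sa, sb) in enumerate(pairs):
            a0 = cursor
            b0 = cursor + 1_000_000
            loops.append(mk_loop("chr1", a0, a0 + 200, b0, b0 + 200, name=f"L{k}"))
            bins_rows.append({"chrom": "chr1", "start": a0, "state": sa})
            bins_rows.append({"chrom": "chr1", "start": b0, "state": sb})
            cursor += 3_000_000
        return LoopSet(loops), pd.DataFrame(bins_rows)

    def test_constructed_pairing_dominates(self):
        test_loops, bins = self.loops_with_states([("A", "B")] * 8)
        bg_loops, bg_bins = self.loops_with_states(
            [("A", "A"), ("B", "B")] * 4, offset=100_000_000
        )
        allbins = pd.concat([bins, bg_bins]).drop_duplicates(["chrom", "start"])
        res = paired_state_network(
            test_loops, allbins, contrast_loops=bg_loops
        )
        row = res.set_index(["state1", "state2"]).loc[("A", "B")]
        assert row["n_loops"] == 8 and row["n_background"] == 0
        assert row["odds_ratio"] > 10

    def test_pair_counts_symmetric(self):
        loops_ab, bins = self.loops_with_states([("A", "B"), ("B", "A")])
        res = paired_state_network(
            loops_ab, bins, contrast_loops=loops_ab
        )
        row = res.set_index(["state1", "state2"]).loc[("A", "B")]
        assert row["n_loops"] == 2  # (A,B) and (B,A) pool together

    def test_random_states_nominal_rate(self, rng):
        pairs = [
            (str(rng.integers(4)), str(rng.integers(4))) for _ in range(60)
        ]
        loops, bins = self.loops_with_states(pairs)
        null_sets = []
        for _ in range(3):
            perm = [
                (str(rng.integers(4)), str(rng.integers(4))) for _ in range(60)
            ]
            # same coordinates, re-labelled states: emulate a null rotation
            nl, nb = self.loops_with_states(perm)
            null_sets.append((nl, nb))
        # use the first null's loops as contrast with merged bins
        res = paired_state_network(
            loops,
            bins,
            contrast_loops=null_sets[0][0].__class__(
                list(null_sets[0][0])
            ),
        )
        assert (res["significant"]).mean() < 0.2


class TestContainment:
    def test_identical_sets_unit_or(self, rng):
        loops = LoopSet(
            [mk_loop("chr1", i * 10**6, i * 10**6 + 10_000, i * 10**6 + 200_000, i * 10**6 + 210_000) for i in range(10)]
        )
        feats = [GenomicInterval("chr1", 100_000, 101_000)]
        res = containment_enrichment(loops, loops, feats)
        assert res["odds_ratio"] == 1.0 and res["p"] == 1.0

    def test_features_only_in_test_spans(self):
        test = LoopSet(
            [mk_loop("chr1", 0, 10_000, 200_000, 210_000, name="t")]
        )
        bg = LoopSet(
            [mk_loop("chr1", 10_000_000, 10_010_000, 10_200_000, 10_210_000, name="b") for _ in range(1)]
        )
        feats = [GenomicInterval("chr1", 50_000, 60_000)]
        res = containment_enrichment(test, bg, feats)
        assert res["table"].a == 1 and res["table"].c == 0
        assert res["odds_ratio"] > 1

    def test_printed_proportions_give_expected_or(self):
        # 12 of 114 vs 708 of 26,679-ish background: OR ~ 4.3
        orr, p = fisher_exact(Contingency2x2(12, 102, 708, 25_857))
        assert orr == pytest.approx(4.3, abs=0.05)


class TestThresholdSweep:
    def make(self, rng, n=60):
        loops, feats = [], []
        ps = {}
        for i in range(n):
            a0 = i * 3_000_000
            loops.append(
                mk_loop("chr1", a0, a0 + 10_000, a0 + 500_000, a0 + 510_000, name=f"L{i}")
            )
            ps[f"L{i}"] = (i + 1) / n
        return LoopSet(loops), pd.Series(ps), feats

    def test_loosest_threshold_or_is_unity(self, rng):
        loops, ps, _ = self.make(rng)
        feats = [GenomicInterval("chr1", 100_000, 110_000)]
        res = threshold_sweep(ps, loops, feats, thresholds=[1.0, 0.5])
        assert res.iloc[0]["odds_ratio"] == 1.0

    def test_feature_concentrated_in_low_p_loops(self, rng):
        loops, ps, _ = self.make(rng)
        # features inside the spans of the 10 lowest-p loops
        feats = [
            GenomicInterval("chr1", i * 3_000_000 + 100_000, i * 3_000_000 + 110_000)
            for i in range(10)
        ]
        res = threshold_sweep(ps, loops, feats, thresholds=[1.0, 0.5, 0.2])
        ors = res["odds_ratio"].to_numpy()
        assert ors[0] == 1.0 and ors[-1] > ors[0]

    def test_exclusion_removes_from_both_sides(self, rng):
        loops, ps, _ = self.make(rng, n=20)
        feats = [GenomicInterval("chr1", 100_000, 110_000)]
        res = threshold_sweep(
            ps, loops, feats, thresholds=[1.0], exclude={"L0"}
        )
        assert res.iloc[0]["n_test"] == 19

    def test_unsorted_thresholds_rejected(self, rng):
        loops, ps, _ = self.make(rng, n=10)
        with pytest.raises(ValueError):
            threshold_sweep(ps, loops, [], thresholds=[0.1, 0.5])


class TestCnvBinomial:
    def test_printed_counts_give_mu(self):
        assert 1_045 / (1_767 + 1_045) == pytest.approx(0.37, abs=0.005)

    def test_observed_at_mu_gives_half(self):
        res = cnv_type_binomial(37, 63, mu=0.37)
        assert res["z"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(0.5)

    def test_against_exact_binomial_tail(self):
        res = cnv_type_binomial(30, 70, mu=0.37)
        exact = stats.binom.sf(29, 100, 0.37)  # P(X >= 30)
        assert res["p"] == pytest.approx(exact, abs=0.05)

    def test_invalid_mu(self):
        with pytest.raises(ValueError):
            cnv_type_binomial(1, 1, mu=1.5)


class TestEqtlOverlap:
    def test_coincident_pair_flagged(self):
        loops = LoopSet([mk_loop("chr1", 100_000, 110_000, 500_000, 510_000, name="L")])
        pairs = LoopSet([mk_loop("chr1", 100_000, 110_000, 500_000, 510_000)])
        flags = eqtl_loop_overlap(pairs, loops)
        assert bool(flags["L"])

    def test_thirty_kb_off_not_flagged(self):
        loops = LoopSet([mk_loop("chr1", 100_000, 110_000, 500_000, 510_000, name="L")])
        pairs = LoopSet([mk_loop("chr1", 140_000, 150_000, 540_000, 550_000)])
        assert not bool(eqtl_loop_overlap(pairs, loops)["L"])

    def test_invariant_to_pair_anchor_order(self):
        loops = LoopSet([mk_loop("chr1", 100_000, 110_000, 500_000, 510_000, name="L")])
        p1 = LoopSet([mk_loop("chr1", 95_000, 96_000, 505_000, 506_000)])
        p2 = LoopSet([mk_loop("chr1", 505_000, 506_000, 95_000, 96_000)])
        assert bool(eqtl_loop_overlap(p1, loops)["L"]) == bool(
            eqtl_loop_overlap(p2, loops)["L"]
        )


class TestDirectionTest:
    def test_identical_groups_p_near_one(self):
        v = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        g = np.array(["x"] * 4 + ["ref"] * 4)
        res = direction_test(v, g, "ref")
        assert res.iloc[0]["p"] > 0.85

    def test_separated_triples_exact_p(self):
        v = np.array([1.0, 2, 3, 4, 5, 6])
        g = np.array(["lo"] * 3 + ["ref"] * 3)
        res = direction_test(v, g, "ref")
        assert res.iloc[0]["U"] == 0.0
        assert res.iloc[0]["p"] == pytest.approx(0.1)

    def test_exact_mode_matches_permutation_enumeration(self, rng):
        x = rng.normal(size=4)
        ref = rng.normal(size=5)
        res = direction_test(
            np.concatenate([x, ref]),
            np.array(["x"] * 4 + ["ref"] * 5),
            "ref",
        )
        pooled = np.concatenate([x, ref])
        u_obs = sum((xi > r) + 0.5 * (xi == r) for xi in x for r in ref)
        count = 0
        total = 0
        for comb in itertools.combinations(range(9), 4):
            xs = pooled[list(comb)]
            rs = pooled[[i for i in range(9) if i not in comb]]
            u = sum((xi > r) + 0.5 * (xi == r) for xi in xs for r in rs)
            total += 1
            if min(u, 20 - u) <= min(u_obs, 20 - u_obs):
                count += 1
        assert res.iloc[0]["p"] == pytest.approx(count / total, rel=1e-9)

    def test_shifted_groups_detected(self):
        r = np.random.default_rng(1234)
        ref = r.normal(0, 1, 500)
        up = r.normal(0.3, 1, 500)
        res = direction_test(
            np.concatenate([up, ref]),
            np.array(["up"] * 500 + ["ref"] * 500),
            "ref",
        )
        assert res.iloc[0]["p"] < 0.01 and res.iloc[0]["shift"] > 0


class TestConcordance:
    def test_identity_gives_r_one(self):
        x = np.linspace(-2, 2, 30)
        res = fc_concordance(x, x)
        assert res["r"] == pytest.approx(1.0)

    def test_matches_closed_form_pearson(self, rng):
        x = rng.normal(size=20)
        y = 0.3 * x + rng.normal(size=20)
        res = fc_concordance(y, x)
        r = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert res["r"] == pytest.approx(r, abs=1e-12)

    def test_coupled_simulation_recovery(self, rng):
        x = rng.normal(0, 2, 500)
        y = 0.1 * x + rng.normal(0, 0.1, 500)
        res = fc_concordance(y, x)
        assert res["p"] < 1e-10 and res["r"] > 0.5
        assert len(res["binned"]) >= 3


class TestMaternalFC:
    def test_balanced_zero(self):
        assert maternal_fc(0.5) == 0.0

    def test_derived_value(self):
        assert maternal_fc(0.7) == pytest.approx(np.log2(0.7 / 0.3))
        assert maternal_fc(0.7) == pytest.approx(1.222, abs=1e-3)

    def test_antisymmetric(self, rng):
        for p in rng.uniform(0.01, 0.99, 30):
            assert maternal_fc(p) == pytest.approx(-maternal_fc(1 - p), rel=1e-9)

    def test_bounds(self):
        with pytest.raises(ValueError):
            maternal_fc(0.0)
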