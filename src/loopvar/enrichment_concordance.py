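"""Enrichment and concordance statistics for loop sets.

Every enrichment here reduces to a Fisher's exact test on a 2x2 table
through one audited code path (:func:`fisher_exact`): chromatin-state
enrichment at anchors, paired-state networks across opposing anchors,
feature containment within loop spans, imbalance-threshold sweeps, and
loop-set overlaps.  Alongside: a one-sided binomial-normal test for CNV
type composition, 2D eQTL-eGene overlap flags, Mann-Whitney direction
tests of fold-change shifts, and Pearson concordance of loop vs molecular
phenotype fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pgl_core import GenomicInterval, Loop, LoopSet, find_span, intersect_loops, intersect1d

__all__ = [
    "Contingency2x2",
    "fisher_exact",
    "state_enrichment_at_anchors",
    "anchor_states",
    "paired_state_network",
    "containment_enrichment",
    "threshold_sweep",
    "cnv_type_binomial",
    "eqtl_loop_overlap",
    "direction_test",
    "fc_concordance",
    "maternal_fc",
]

STATE_BIN_BP = 200


@dataclass(frozen=True)
class Contingency2x2:
    """Counts (a, b) / (c, d); a = feature-positive in the test group."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")

    def odds_ratio(self) -> float:
        """Sample OR with a 0.5 continuity correction when any cell is 0."""
        a, b, c, d = self.a, self.b, self.c, self.d
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return (a * d) / (b * c)


def fisher_exact(
    table: Contingency2x2, sided: str = "two-sided"
) -> tuple[float, float]:
    """Fisher's exact test; returns (sample OR, exact hypergeometric p).

    Two-sided p uses the point-probability rule (sum of all tables as or
    less probable than the observed one).
    """
    t = [[table.a, table.b], [table.c, table.d]]
    alt = {"two-sided": "two-sided", "greater": "greater", "less": "less"}[sided]
    _, p = stats.fisher_exact(t, alternative=alt)
    return table.odds_ratio(), float(p)


# ---------------------------------------------------------------------------
# chromatin states
# ---------------------------------------------------------------------------


def state_enrichment_at_anchors(
    anchors: list[GenomicInterval],
    state_bins: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-state enrichment of 200-bp state bins at loop anchors.

    ``state_bins`` columns: chrom, start, state (bins are the fixed 200-bp
    grid).  For each state the proportion of bins in that state among
    anchor-overlapping bins is compared with the genome-wide background
    proportion (all bins) by Fisher's exact test; significance is
    Bonferroni at alpha / n_states.
    """
    on_anchor = np.zeros(len(state_bins), dtype=bool)
    starts = state_bins["start"].to_numpy()
    chroms = state_bins["chrom"].to_numpy()
    for iv in anchors:
        sel = (
            (chroms == iv.chrom)
            & (starts + STATE_BIN_BP > iv.start)
            & (starts < iv.end)
        )
        on_anchor |= sel
    states = sorted(state_bins["state"].unique())
    n_states = len(states)
    rows = []
    state_arr = state_bins["state"].to_numpy()
    for s in states:
        in_s = state_arr == s
        t = Contingency2x2(
            int((on_anchor & in_s).sum()),
            int((on_anchor & ~in_s).sum()),
            int(in_s.sum()),
            int((~in_s).sum()),
        )
        orr, p = fisher_exact(t)
        rows.append(
            {
                "state": s,
                "a": t.a,
                "b": t.b,
                "c": t.c,
                "d": t.d,
                "odds_ratio": orr,
                "p": p,
                "significant": p < alpha / n_states,
            }
        )
    return pd.DataFrame(rows).set_index("state")


def anchor_states(loops: LoopSet, state_bins: pd.DataFrame) -> list[dict]:
    """States overlapping each anchor of each loop (via intersect1d)."""
    feats = [
        GenomicInterval(r.chrom, int(r.start), int(r.start) + STATE_BIN_BP)
        for r in state_bins.itertuples()
    ]
    states = state_bins["state"].to_list()
    by_iv = {(f.chrom, f.start, f.end): s for f, s in zip(feats, states)}
    ann = intersect1d(loops, feats)
    out = []
    for rec in ann:
        out.append(
            {
                "loop": rec["loop"],
                "A": sorted({by_iv[f.chrom, f.start, f.end] for f in rec["A"]}),
                "B": sorted({by_iv[f.chrom, f.start, f.end] for f in rec["B"]}),
            }
        )
    return out


def _pair_counts(annotations: list[dict], states: list) -> dict[tuple, int]:
    counts = {p: 0 for p in _all_pairs(states)}
    for rec in annotations:
        seen = set()
        for sa in rec["A"]:
            for sb in rec["B"]:
                seen.add(tuple(sorted((sa, sb))))
        for p in seen:
            counts[p] += 1
    return counts


def _all_pairs(states: list) -> list[tuple]:
    out = []
    for i, s1 in enumerate(states):
        for s2 in states[i:]:
            out.append((s1, s2))
    return out


def paired_state_network(
    loops: LoopSet,
    state_bins: pd.DataFrame,
    null_loop_sets: list[LoopSet] | None = None,
    contrast_loops: LoopSet | None = None,
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Enrichment of chromatin-state pairs at opposing loop anchors.

    For every unordered state pair (self-pairs included) the number of
    loops with one state at one anchor and the other state at the opposing
    anchor is compared against an expectation: the mean count over
    ``null_loop_sets`` (permutation mode) or the count in
    ``contrast_loops`` (group-contrast mode, e.g. HTAL vs non-HTAL with
    FDR).  Edge weight is the odds ratio.
    """
    if (null_loop_sets is None) == (contrast_loops is None):
        raise ValueError("provide exactly one of null_loop_sets / contrast_loops")
    states = sorted(state_bins["state"].unique())
    obs = _pair_counts(anchor_states(loops, state_bins), states)
    n_obs = len(loops)
    if null_loop_sets is not None:
        bg_counts = {p: 0.0 for p in _all_pairs(states)}
        n_bg = 0
        for ns in null_loop_sets:
            c = _pair_counts(anchor_states(ns, state_bins), states)
            for p in bg_counts:
                bg_counts[p] += c[p]
            n_bg += len(ns)
        bg = {p: int(round(v)) for p, v in bg_counts.items()}
    else:
        bg = _pair_counts(anchor_states(contrast_loops, state_bins), states)
        n_bg = len(contrast_loops)
    rows = []
    for pair in _all_pairs(states):
        t = Contingency2x2(
            obs[pair], n_obs - obs[pair], bg[pair], max(n_bg - bg[pair], 0)
        )
        orr, p = fisher_exact(t)
        rows.append(
            {
                "state1": pair[0],
                "state2": pair[1],
                "n_loops": obs[pair],
                "n_background": bg[pair],
                "odds_ratio": orr,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    if fdr:
        out["q"] = stats.false_discovery_control(out["p"].to_numpy(), method="bh")
        out["significant"] = out["q"] < alpha
    else:
        out["significant"] = out["p"] < alpha
    return out


# ---------------------------------------------------------------------------
# containment / sweeps / overlaps
# ---------------------------------------------------------------------------


def _contains_feature(
    loops: LoopSet, features: list[GenomicInterval]
) -> np.ndarray:
    spans = find_span(loops)
    flags = np.zeros(len(spans), dtype=bool)
    for i, sp in enumerate(spans):
        flags[i] = any(
            f.chrom == sp.chrom and f.start < sp.end and sp.start < f.end
            for f in features
        )
    return flags


def containment_enrichment(
    test_loops: LoopSet,
    background_loops: LoopSet,
    features: list[GenomicInterval],
) -> dict:
    """Fisher test of the feature-containing proportion, test vs background.

    A loop "contains" a feature when the feature overlaps the region
    between the start of its first anchor and the end of its second.
    """
    ft = _contains_feature(test_loops, features)
    fb = _contains_feature(background_loops, features)
    t = Contingency2x2(
        int(ft.sum()), int((~ft).sum()), int(fb.sum()), int((~fb).sum())
    )
    orr, p = fisher_exact(t)
    return {"table": t, "odds_ratio": orr, "p": p}


def threshold_sweep(
    loop_p: pd.Series,
    loops: LoopSet,
    features: list[GenomicInterval],
    thresholds: list[float],
    exclude: set | None = None,
) -> pd.DataFrame:
    """Containment enrichment as the imbalance-p threshold tightens.

    At each threshold t the test set is loops with p <= t and the
    background the full (union) set; ``exclude`` drops loop ids (e.g.
    imprinted/CNV loops) from both sides.  Bonferroni across thresholds.
    """
    if list(thresholds) != sorted(thresholds, reverse=True):
        raise ValueError("thresholds must be descending")
    ids = [lp.payload.get("name", f"loop_{i}") for i, lp in enumerate(loops)]
    keep = [i for i, lid in enumerate(ids) if not (exclude and lid in exclude)]
    bg = LoopSet([loops[i] for i in keep])
    bg_ids = [ids[i] for i in keep]
    contains = _contains_feature(bg, features)
    pvals = loop_p.reindex(bg_ids).to_numpy()
    rows = []
    for t in thresholds:
        sel = pvals <= t
        tab = Contingency2x2(
            int((sel & contains).sum()),
            int((sel & ~contains).sum()),
            int(contains.sum()),
            int((~contains).sum()),
        )
        orr, p = fisher_exact(tab)
        rows.append(
            {
                "threshold": t,
                "n_test": int(sel.sum()),
                "odds_ratio": orr,
                "p": p,
                "significant": p < 0.05 / len(thresholds),
            }
        )
    return pd.DataFrame(rows)


def cnv_type_binomial(
    n_duplication: int, n_deletion: int, mu: float
) -> dict:
    """One-sided test for duplication excess over the genome-wide rate.

    Among loops containing a single CNV type, Z = (f - mu) /
    sqrt(mu (1 - mu) / n) with f the observed duplication fraction; p is
    the upper normal tail (direction stated by design).
    """
    if not 0.0 < mu < 1.0:
        raise ValueError("mu must be in (0, 1)")
    n = n_duplication + n_deletion
    if n == 0:
        raise ValueError("no single-type CNV loops")
    f = n_duplication / n
    z = (f - mu) / np.sqrt(mu * (1 - mu) / n)
    return {"fraction": f, "z": float(z), "p": float(stats.norm.sf(z)), "n": n}


def eqtl_loop_overlap(
    pairs: LoopSet, loops: LoopSet, slack_bp: int = 20_000
) -> pd.Series:
    """Flag loops within ``slack_bp`` (2D) of any eQTL-eGene pair."""
    flagged = set()
    for la, lb in intersect_loops(loops, pairs, slack_bp=slack_bp):
        flagged.add(la.key)
    return pd.Series(
        [lp.key in flagged for lp in loops],
        index=[lp.payload.get("name", f"loop_{i}") for i, lp in enumerate(loops)],
        name="near_eqtl",
    )


# ---------------------------------------------------------------------------
# direction & concordance
# ---------------------------------------------------------------------------


def direction_test(
    values: np.ndarray,
    groups: np.ndarray,
    reference_group,
) -> pd.DataFrame:
    """Mann-Whitney U of each group's values against a reference group.

    Two-sided; exact enumeration when both samples have <= 8 observations,
    otherwise the normal approximation with tie correction.  Reports the
    median shift per group.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ref = values[groups == reference_group]
    if len(ref) == 0:
        raise ValueError("empty reference group")
    rows = []
    for g in np.unique(groups):
        if g == reference_group:
            continue
        x = values[groups == g]
        if len(x) == 0:
            continue
        method = "exact" if (len(x) <= 8 and len(ref) <= 8) else "asymptotic"
        res = stats.mannwhitneyu(x, ref, alternative="two-sided", method=method)
        rows.append(
            {
                "group": g,
                "n": len(x),
                "shift": float(np.median(x) - np.median(ref)),
                "U": float(res.statistic),
                "p": float(res.pvalue),
            }
        )
    return pd.DataFrame(rows)


def fc_concordance(
    loop_log2fc: np.ndarray,
    phenotype_log2fc: np.ndarray,
    n_bins: int = 5,
) -> dict:
    """Pearson concordance of loop vs phenotype fold changes.

    r and its t-distribution p are computed on the raw pairs; a box
    summary (median/quartiles of loop FC) is reported per phenotype-FC
    bin for display.
    """
    x = np.asarray(phenotype_log2fc, dtype=float)
    y = np.asarray(loop_log2fc, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    r, p = stats.pearsonr(x, y)
    bins = pd.qcut(x, q=n_bins, duplicates="drop")
    summary = (
        pd.DataFrame({"bin": bins, "loop_log2fc": y})
        .groupby("bin", observed=True)["loop_log2fc"]
        .describe()[["count", "25%", "50%", "75%"]]
    )
    return {"r": float(r), "p": float(p), "binned": summary}


def maternal_fc(maternal_allele_frequency: float) -> float:
    """Maternal-over-paternal log2 fold change from an allele frequency."""
    maf = float(maternal_allele_frequency)
    if not 0.0 < maf < 1.0:
        raise ValueError("maternal allele frequency must be in (0, 1)")
    return float(np.log2(maf / (1.0 - maf)))
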