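"""Harmonizing multi-resolution loop-caller output into call sets.

Loop callers are run per resolution and are technically noisy: calls for
the same underlying loop appear at many resolutions with slightly shifted
anchors, and spurious calls appear at random matrix positions far off the
diagonal in only one or two resolutions.  The harmonization pipeline:

1. per-resolution post-processing — neighbourhood pruning for
   Fit-Hi-C-style significance grids (``prune_fithic``), then merging
   within 20 kb and discarding singleton interactions
   (``postprocess_fithic``); resolution-scaled merging for HICCUPS-style
   calls (``merge_hiccups``);
2. ``collapse_resolutions`` — intersect calls across resolutions within
   one caller, keep the finest-resolution call per intersection event, and
   drop loops supported by too few resolutions (< 3 for HICCUPS-style,
   < 7 for Fit-Hi-C-style);
3. ``intersect_callers`` — combine callers, keeping the call with the
   smallest total anchor size at each cross-caller intersection;
4. ``build_union`` — merge the two cell types' call sets into the union
   loop set with the 1/2/3-loop event rules.

"Within 20 kb" always means: gap distance of both anchor pairs <= 20 kb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pgl_core import (
    GenomicInterval,
    Loop,
    LoopSet,
    closest,
    connected_groups,
    loop_distance,
    merge_loops,
    _merge_group,
    _keep_tiebreak,
)

__all__ = [
    "SignificanceGrid",
    "CallerOutput",
    "prune_fithic",
    "postprocess_fithic",
    "merge_hiccups",
    "collapse_resolutions",
    "intersect_callers",
    "build_union",
    "harmonize",
    "DEFAULT_MIN_SUPPORT",
]

DEFAULT_MIN_SUPPORT = {"fithic_like": 7, "hiccups_like": 3}

MERGE_SLACK_BP = 20_000


@dataclass
class SignificanceGrid:
    """Sparse symmetric per-resolution significance matrix.

    ``bins`` maps (i, j) bin-index pairs to (raw_count, q, significant);
    access is symmetric — entries are stored with i <= j.
    """

    chrom: str
    resolution_bp: int
    bins: dict[tuple[int, int], tuple[float, float, bool]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if self.resolution_bp <= 0:
            raise ValueError("resolution must be positive")
        self.bins = {
            (min(i, j), max(i, j)): v for (i, j), v in self.bins.items()
        }

    def set(self, i: int, j: int, count: float, q: float, significant: bool) -> None:
        if not 0.0 <= q <= 1.0:
            raise ValueError("q must be in [0, 1]")
        self.bins[(min(i, j), max(i, j))] = (count, q, significant)

    def significant(self, i: int, j: int) -> bool:
        v = self.bins.get((min(i, j), max(i, j)))
        return bool(v[2]) if v is not None else False


def prune_fithic(grid: SignificanceGrid) -> LoopSet:
    """Keep significant bin pairs supported by their local neighbourhood.

    A significant pair (i, j) survives iff, for each anchor held fixed, at
    least 3 of the 5 bins immediately upstream of the opposing anchor are
    significant, OR at least 3 of the 5 immediately downstream are.
    Out-of-range neighbours count as not significant.
    """
    res = grid.resolution_bp
    kept = []
    for (i, j), (count, q, sig) in sorted(grid.bins.items()):
        if not sig:
            continue

        def side_ok(fixed: int, opposing: int) -> bool:
            up = sum(
                grid.significant(fixed, opposing - k) for k in range(1, 6)
            )
            down = sum(
                grid.significant(fixed, opposing + k) for k in range(1, 6)
            )
            return up >= 3 or down >= 3

        if side_ok(i, j) and side_ok(j, i):
            kept.append(
                Loop(
                    GenomicInterval(grid.chrom, i * res, (i + 1) * res),
                    GenomicInterval(grid.chrom, j * res, (j + 1) * res),
                    {"q": q, "count": count, "caller": "fithic_like", "resolution": res},
                )
            )
    return LoopSet(kept, provenance=f"fithic_pruned@{res}")


def postprocess_fithic(pruned: LoopSet) -> LoopSet:
    """Merge pruned interactions within 20 kb; discard singletons.

    Interactions with no other pre-merge interaction within 20 kb
    (connected components of size 1) are dropped; each remaining component
    keeps its most significant member.
    """
    groups = connected_groups(pruned.loops, MERGE_SLACK_BP)
    merged = [
        _merge_group(g, "most_significant") for g in groups if len(g) >= 2
    ]
    return LoopSet(merged, provenance="fithic_postprocessed")


@dataclass
class CallerOutput:
    """One caller at one resolution."""

    caller: str  # fithic_like | hiccups_like
    resolution_bp: int
    loops: LoopSet


def merge_hiccups(calls: CallerOutput) -> LoopSet:
    """Within-resolution merge for HICCUPS-style calls.

    Slack is 20 kb for resolutions <= 10 kb and twice the anchor size
    (2 x resolution) above that; the most significant call is retained at
    each merge event.
    """
    res = calls.resolution_bp
    slack = MERGE_SLACK_BP if res <= 10_000 else 2 * res
    return merge_loops(calls.loops, slack, keep_rule="most_significant")


def collapse_resolutions(
    outputs: list[CallerOutput], min_support: int
) -> LoopSet:
    """Intersect one caller's calls across resolutions; filter by support.

    Calls from all resolutions are grouped by transitive 20-kb closeness;
    each group keeps the call from the smallest resolution, annotated with
    ``support`` = number of distinct contributing resolutions, and groups
    with support < ``min_support`` are dropped (inclusive threshold).
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    pooled = [lp for out in outputs for lp in out.loops]
    kept = []
    for group in connected_groups(pooled, MERGE_SLACK_BP):
        support = len({lp.payload.get("resolution") for lp in group})
        if support < min_support:
            continue
        rep = min(
            group,
            key=lambda lp: (lp.payload.get("resolution", np.inf), _keep_tiebreak(lp)),
        )
        rep = Loop(rep.anchorA, rep.anchorB, {**rep.payload, "support": support})
        kept.append(rep)
    return LoopSet(kept, provenance=f"collapsed(min_support={min_support})")


def intersect_callers(fithic: LoopSet, hiccups: LoopSet) -> LoopSet:
    """Cross-caller combination keeping the tightest call per intersection.

    The union of both collapsed sets, except that at each cross-set
    intersection event (20-kb closeness, transitive) only the member with
    the smallest total anchor length survives (ties: smaller significance,
    then coordinates); loops unique to one caller pass through unchanged.
    """
    pooled = list(fithic) + list(hiccups)
    kept = []
    for group in connected_groups(pooled, MERGE_SLACK_BP):
        kept.append(
            min(
                group,
                key=lambda lp: (
                    lp.total_anchor_length,
                    lp.significance(),
                    lp.key,
                ),
            )
        )
    return LoopSet(kept, provenance="cross_caller")


def harmonize(
    caller_outputs: dict[str, dict[int, LoopSet]],
    min_support: dict[str, int] | None = None,
) -> dict:
    """Per-resolution call tables -> one cell type's final call set.

    Applies the within-resolution merge (HICCUPS-style sets), collapses
    across resolutions with the caller's support threshold, then
    intersects callers.  Returns per-caller collapsed sets and the final
    cross-caller set.
    """
    min_support = {**DEFAULT_MIN_SUPPORT, **(min_support or {})}
    collapsed: dict[str, LoopSet] = {}
    for caller, by_res in caller_outputs.items():
        outs = []
        for res, ls in sorted(by_res.items()):
            if caller == "hiccups_like":
                ls = merge_hiccups(CallerOutput(caller, res, ls))
            outs.append(CallerOutput(caller, res, ls))
        collapsed[caller] = collapse_resolutions(outs, min_support[caller])
    final = intersect_callers(
        collapsed.get("fithic_like", LoopSet()),
        collapsed.get("hiccups_like", LoopSet()),
    )
    return {"collapsed": collapsed, "final": final}


def _pair_merge(a: Loop, b: Loop) -> Loop:
    return _merge_group([a, b], "union_span")


def build_union(set_a: LoopSet, set_b: LoopSet) -> LoopSet:
    """Union loop set from two cell types' call sets.

    Merge events (20-kb closeness, transitive) are resolved by size:
    1 loop — retained; 2 loops — merged (bounding anchors); 3 loops — the
    closest two (Chebyshev anchor-gap distance) merged, the third retained
    as called; larger events — greedy repeated closest-pair merging
    (merged pairs are finalized, the leftover loop is retained), flagged
    with ``big_event`` in the payload.
    """
    pooled = list(set_a) + list(set_b)
    out = []
    for group in connected_groups(pooled, MERGE_SLACK_BP):
        if len(group) == 1:
            out.append(group[0])
        elif len(group) == 2:
            out.append(_pair_merge(group[0], group[1]))
        else:
            flag = len(group) > 3
            members = sorted(group, key=lambda lp: lp.key)
            while len(members) >= 2:
                best = None
                for i in range(len(members)):
                    for j in range(i + 1, len(members)):
                        d = loop_distance(members[i], members[j])
                        if best is None or d < best[0]:
                            best = (d, i, j)
                _, i, j = best
                merged = _pair_merge(members[i], members[j])
                if flag:
                    merged.payload["big_event"] = True
                out.append(merged)
                members = [m for k, m in enumerate(members) if k not in (i, j)]
            out.extend(members)
    return LoopSet(out, provenance="union")
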