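"""Paired-genomic-loci (PGL) interval algebra.

A chromatin loop is a pair of genomic intervals (anchors) on the same
chromosome together with a free-form payload (caller, resolution,
significance, annotations).  Every downstream analysis — harmonizing caller
output, counting contacts, permutation nulls, enrichment — reduces to a
handful of 2D interval operations implemented here: merge, intersect,
1D feature annotation, contact coverage, closest-pair search and span
extraction, plus BEDPE I/O.

Coordinates are 0-based half-open (BED convention) throughout.  Distances
between intervals are *gap* distances: 0 if the intervals overlap, else the
number of bases separating them.  Two loops are "within s bp" of each other
when BOTH anchor pairs have gap distance <= s.  Loops are unstranded.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "Loop",
    "LoopSet",
    "gap_distance",
    "loop_gap",
    "loop_distance",
    "merge_loops",
    "intersect_loops",
    "intersect1d",
    "coverage",
    "closest",
    "find_span",
    "read_bedpe",
    "write_bedpe",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(f"empty/inverted interval: {self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def gap_distance(a: GenomicInterval, b: GenomicInterval) -> int:
    """Gap distance between two intervals on the same chromosome.

    0 if they overlap or abut base-to-base; otherwise the number of bases
    strictly between them.
    """
    if a.chrom != b.chrom:
        raise ValueError("gap distance undefined across chromosomes")
    return max(a.start - b.end, b.start - a.end, 0)


@dataclass
class Loop:
    """A paired-genomic-loci record: two same-chromosome anchors + payload.

    Anchors are stored in canonical order (anchorA.start <= anchorB.start,
    ties broken by end)."""

    anchorA: GenomicInterval
    anchorB: GenomicInterval
    payload: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.anchorA.chrom != self.anchorB.chrom:
            raise ValueError("loops must be intra-chromosomal")
        a, b = self.anchorA, self.anchorB
        if (a.start, a.end) > (b.start, b.end):
            self.anchorA, self.anchorB = b, a

    @property
    def chrom(self) -> str:
        return self.anchorA.chrom

    @property
    def total_anchor_length(self) -> int:
        return len(self.anchorA) + len(self.anchorB)

    @property
    def key(self) -> tuple:
        return (
            self.chrom,
            self.anchorA.start,
            self.anchorA.end,
            self.anchorB.start,
            self.anchorB.end,
        )

    def significance(self) -> float:
        """p- or q-value from the payload; +inf when absent (least significant)."""
        for k in ("p", "q", "p_value", "q_value"):
            v = self.payload.get(k)
            if v is not None:
                return float(v)
        return float("inf")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Loop({self.chrom}:{self.anchorA.start}-{self.anchorA.end} x "
            f"{self.chrom}:{self.anchorB.start}-{self.anchorB.end})"
        )


def loop_gap(l1: Loop, l2: Loop) -> tuple[int, int]:
    """(gapA, gapB) between the corresponding anchors of two loops."""
    return (
        gap_distance(l1.anchorA, l2.anchorA),
        gap_distance(l1.anchorB, l2.anchorB),
    )


def loop_distance(l1: Loop, l2: Loop) -> int:
    """Chebyshev distance on anchor gaps: max(gapA, gapB)."""
    ga, gb = loop_gap(l1, l2)
    return max(ga, gb)


def loops_within(l1: Loop, l2: Loop, slack_bp: int) -> bool:
    """True iff both anchor gap distances are <= slack_bp (same chromosome)."""
    if l1.chrom != l2.chrom:
        return False
    ga, gb = loop_gap(l1, l2)
    return ga <= slack_bp and gb <= slack_bp


def _payload_key(payload: dict) -> tuple:
    return tuple(sorted((k, repr(v)) for k, v in payload.items()))


class LoopSet:
    """Ordered, duplicate-free collection of canonical loops.

    Loops are sorted by (chrom, startA, endA, startB, endB); exact
    duplicates (identical coordinates and payload) are dropped.
    """

    def __init__(self, loops: Iterable[Loop] = (), provenance: str = ""):
        seen: set[tuple] = set()
        uniq: list[Loop] = []
        for lp in loops:
            k = (lp.key, _payload_key(lp.payload))
            if k not in seen:
                seen.add(k)
                uniq.append(lp)
        uniq.sort(key=lambda lp: lp.key)
        self.loops: list[Loop] = uniq
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self.loops)

    def __iter__(self) -> Iterator[Loop]:
        return iter(self.loops)

    def __getitem__(self, i: int) -> Loop:
        return self.loops[i]

    def chroms(self) -> list[str]:
        return sorted({lp.chrom for lp in self.loops})

    def by_chrom(self) -> dict[str, list[Loop]]:
        out: dict[str, list[Loop]] = {}
        for lp in self.loops:
            out.setdefault(lp.chrom, []).append(lp)
        return out

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"LoopSet({len(self)} loops, provenance={self.provenance!r})"


# ---------------------------------------------------------------------------
# grouping machinery
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _within_pairs(loops: Sequence[Loop], slack_bp: int) -> Iterator[tuple[int, int]]:
    """Yield index pairs (i < j) of same-chromosome loops within slack_bp.

    Vectorized blockwise all-pairs test; loops must share one chromosome.
    """
    n = len(loops)
    if n < 2:
        return
    sa = np.array([lp.anchorA.start for lp in loops])
    ea = np.array([lp.anchorA.end for lp in loops])
    sb = np.array([lp.anchorB.start for lp in loops])
    eb = np.array([lp.anchorB.end for lp in loops])
    block = max(1, int(2e7) // n)
    for lo in range(0, n, block):
        hi = min(lo + block, n)
        ga = np.maximum(
            np.maximum(sa[lo:hi, None] - ea[None, :], sa[None, :] - ea[lo:hi, None]), 0
        )
        gb = np.maximum(
            np.maximum(sb[lo:hi, None] - eb[None, :], sb[None, :] - eb[lo:hi, None]), 0
        )
        ok = (ga <= slack_bp) & (gb <= slack_bp)
        for ii, jj in zip(*np.nonzero(ok)):
            i, j = lo + ii, jj
            if i < j:
                yield i, j


def connected_groups(loops: Sequence[Loop], slack_bp: int) -> list[list[Loop]]:
    """Transitive closure of the "both anchors within slack" relation.

    Returns connected components; loops on different chromosomes never group.
    """
    groups: list[list[Loop]] = []
    by_chrom: dict[str, list[Loop]] = {}
    for lp in loops:
        by_chrom.setdefault(lp.chrom, []).append(lp)
    for _, chrom_loops in sorted(by_chrom.items()):
        uf = _UnionFind(len(chrom_loops))
        for i, j in _within_pairs(chrom_loops, slack_bp):
            uf.union(i, j)
        comp: dict[int, list[Loop]] = {}
        for i, lp in enumerate(chrom_loops):
            comp.setdefault(uf.find(i), []).append(lp)
        groups.extend(comp.values())
    return groups


def _keep_tiebreak(lp: Loop) -> tuple:
    return (lp.significance(), lp.total_anchor_length, lp.key)


def _merge_group(group: list[Loop], keep_rule: str) -> Loop:
    if keep_rule == "union_span":
        chrom = group[0].chrom
        a = GenomicInterval(
            chrom,
            min(lp.anchorA.start for lp in group),
            max(lp.anchorA.end for lp in group),
        )
        b = GenomicInterval(
            chrom,
            min(lp.anchorB.start for lp in group),
            max(lp.anchorB.end for lp in group),
        )
        rep = min(group, key=_keep_tiebreak)
        payload = dict(rep.payload)
        payload["n_merged"] = len(group)
        return Loop(a, b, payload)
    if keep_rule == "most_significant":
        return min(group, key=_keep_tiebreak)
    if keep_rule == "smallest_anchors":
        return min(
            group, key=lambda lp: (lp.total_anchor_length, lp.significance(), lp.key)
        )
    raise ValueError(f"unknown keep_rule: {keep_rule}")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def merge_loops(loops: LoopSet, slack_bp: int, keep_rule: str = "union_span") -> LoopSet:
    """Merge loops whose anchor pairs both lie within ``slack_bp``.

    Grouping is the transitive closure of the pairwise relation (connected
    components), so merging is idempotent.  ``keep_rule`` selects the group
    representative: ``union_span`` (bounding union of each anchor),
    ``most_significant`` (smallest p/q), or ``smallest_anchors``.
    """
    if slack_bp < 0:
        raise ValueError("slack_bp must be non-negative")
    current = list(loops.loops)
    while True:
        groups = connected_groups(current, slack_bp)
        merged = [_merge_group(g, keep_rule) for g in groups]
        # union_span bounding anchors can fall within slack of another
        # group through different member pairs; iterate to the fixpoint so
        # merging is idempotent for every keep rule
        if len(merged) == len(current):
            break
        current = merged
    return LoopSet(merged, provenance=f"merge(slack={slack_bp},{keep_rule})")


def intersect_loops(
    a: LoopSet, b: LoopSet, slack_bp: int = 0
) -> list[tuple[Loop, Loop]]:
    """All pairs (la, lb) with both anchor pairs within ``slack_bp``."""
    if slack_bp < 0:
        raise ValueError("slack_bp must be non-negative")
    events: list[tuple[Loop, Loop]] = []
    b_by_chrom = b.by_chrom()
    for chrom, a_loops in sorted(a.by_chrom().items()):
        b_loops = b_by_chrom.get(chrom, [])
        if not b_loops:
            continue
        combined = list(a_loops) + list(b_loops)
        na = len(a_loops)
        for i, j in _within_pairs(combined, slack_bp):
            if i < na <= j:
                events.append((combined[i], combined[j]))
        # _within_pairs yields i<j only; also check a-vs-b pairs where the
        # b loop sorts before... indices are positional (a block then b
        # block), so i<na<=j covers every cross pair exactly once.
    return events


def intersect1d(
    loops: LoopSet, features: Iterable[GenomicInterval]
) -> list[dict]:
    """Annotate each loop with features overlapping either anchor.

    A feature annotates a loop iff it overlaps (>= 1 bp, half-open
    semantics) anchorA or anchorB; the result records which anchor.

    Returns one dict per loop: ``{"loop": Loop, "A": [features], "B": [...]}``.
    """
    trees: dict[str, IntervalTree] = {}
    for f in features:
        trees.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, f)
    out = []
    for lp in loops:
        tree = trees.get(lp.chrom)
        hits_a = (
            sorted(
                (iv.data for iv in tree.overlap(lp.anchorA.start, lp.anchorA.end)),
                key=lambda f: (f.start, f.end),
            )
            if tree
            else []
        )
        hits_b = (
            sorted(
                (iv.data for iv in tree.overlap(lp.anchorB.start, lp.anchorB.end)),
                key=lambda f: (f.start, f.end),
            )
            if tree
            else []
        )
        out.append({"loop": lp, "A": hits_a, "B": hits_b})
    return out


def coverage(
    loops: LoopSet,
    contacts: pd.DataFrame,
    pad_bp: int = 0,
    sample_col: str | None = "sample",
) -> pd.DataFrame:
    """Count contacts supporting each loop, per sample.

    ``contacts`` must have columns chrom, pos1, pos2 (+ a sample column
    unless ``sample_col`` is None).  A contact increments a loop iff one end
    falls within anchorA padded by ``pad_bp`` and the other within anchorB
    padded likewise, in either end order; one contact may count toward
    several loops.  Inter-chromosomal rows (chrom2 column differing from
    chrom, if present) are skipped and counted in ``result.attrs["skipped"]``.
    """
    if pad_bp < 0:
        raise ValueError("pad_bp must be non-negative")
    df = contacts
    skipped = 0
    if "chrom2" in df.columns:
        inter = df["chrom2"].to_numpy() != df["chrom"].to_numpy()
        skipped = int(inter.sum())
        df = df.loc[~inter]
    if sample_col is None:
        samples = ["count"]
        sample_of = np.zeros(len(df), dtype=int)
    else:
        cats = pd.Categorical(df[sample_col])
        samples = list(cats.categories)
        sample_of = cats.codes
    loop_ids = [f"{lp.key}" for lp in loops]
    counts = np.zeros((len(loops.loops), len(samples)), dtype=int)

    chrom_arr = df["chrom"].to_numpy()
    pos1 = df["pos1"].to_numpy()
    pos2 = df["pos2"].to_numpy()
    order = np.argsort(chrom_arr, kind="stable")
    chrom_sorted = chrom_arr[order]
    bounds = {}
    if len(df):
        uniq, starts = np.unique(chrom_sorted, return_index=True)
        starts = list(starts) + [len(chrom_sorted)]
        bounds = {c: (starts[i], starts[i + 1]) for i, c in enumerate(uniq)}

    for li, lp in enumerate(loops.loops):
        if lp.chrom not in bounds:
            continue
        lo, hi = bounds[lp.chrom]
        idx = order[lo:hi]
        p1, p2 = pos1[idx], pos2[idx]
        a0, a1 = lp.anchorA.start - pad_bp, lp.anchorA.end + pad_bp
        b0, b1 = lp.anchorB.start - pad_bp, lp.anchorB.end + pad_bp
        in_a1 = (p1 >= a0) & (p1 < a1)
        in_b1 = (p1 >= b0) & (p1 < b1)
        in_a2 = (p2 >= a0) & (p2 < a1)
        in_b2 = (p2 >= b0) & (p2 < b1)
        hit = (in_a1 & in_b2) | (in_b1 & in_a2)
        if hit.any():
            np.add.at(counts[li], sample_of[idx[hit]], 1)
    result = pd.DataFrame(counts, index=loop_ids, columns=samples)
    result.attrs["skipped"] = skipped
    return result


def closest(query: Loop, candidates: LoopSet) -> tuple[Loop, int]:
    """Nearest candidate by Chebyshev anchor-gap distance; ties broken by
    canonical coordinate order.  Candidates on other chromosomes are at
    infinite distance."""
    if len(candidates) == 0:
        raise ValueError("closest() requires a non-empty candidate set")
    best: tuple[float, tuple, Loop] | None = None
    for cand in candidates:
        d = (
            float(loop_distance(query, cand))
            if cand.chrom == query.chrom
            else float("inf")
        )
        item = (d, cand.key, cand)
        if best is None or item[:2] < best[:2]:
            best = item
    assert best is not None
    if not np.isfinite(best[0]):
        raise ValueError("no candidate on the query chromosome")
    return best[2], int(best[0])


def find_span(loops: LoopSet) -> list[GenomicInterval]:
    """One interval per loop from the first anchor's start to the second
    anchor's end (the max end when the anchors nest)."""
    return [
        GenomicInterval(
            lp.chrom, lp.anchorA.start, max(lp.anchorA.end, lp.anchorB.end)
        )
        for lp in loops
    ]


# ---------------------------------------------------------------------------
# BEDPE I/O
# ---------------------------------------------------------------------------

_BEDPE_CORE = [
    "chrom1",
    "start1",
    "end1",
    "chrom2",
    "start2",
    "end2",
    "name",
    "score",
    "strand1",
    "strand2",
]


def write_bedpe(loops: LoopSet, path) -> None:
    """Write a 10-column BEDPE with payload keys as extra named columns."""
    extra_keys: list[str] = []
    for lp in loops:
        for k in lp.payload:
            if k not in extra_keys:
                extra_keys.append(k)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_BEDPE_CORE + extra_keys) + "\n")
        for i, lp in enumerate(loops):
            row = [
                lp.chrom,
                str(lp.anchorA.start),
                str(lp.anchorA.end),
                lp.chrom,
                str(lp.anchorB.start),
                str(lp.anchorB.end),
                str(lp.payload.get("name", ".")),
                str(lp.payload.get("score", ".")),
                ".",
                ".",
            ]
            row += [repr(lp.payload.get(k, "")) for k in extra_keys]
            fh.write("\t".join(row) + "\n")


def read_bedpe(path) -> LoopSet:
    """Read BEDPE (10 core columns + optional payload columns).

    Anchors are canonicalized on read; malformed lines raise with their
    line number.  Payload columns written by :func:`write_bedpe` round-trip
    losslessly (values are stored with ``repr``).
    """
    loops = []
    extra_keys: list[str] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                cols = line.lstrip("#").split("\t")
                if cols[: len(_BEDPE_CORE)] == _BEDPE_CORE:
                    extra_keys = cols[len(_BEDPE_CORE):]
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{ln}: expected >= 6 BEDPE columns")
            try:
                a = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
                b = GenomicInterval(parts[3], int(parts[4]), int(parts[5]))
            except (ValueError, IndexError) as e:
                raise ValueError(f"{path}:{ln}: malformed BEDPE line: {e}") from e
            payload: dict = {}
            if len(parts) >= 7 and parts[6] != ".":
                payload["name"] = parts[6]
            if len(parts) >= 8 and parts[7] != ".":
                payload["score"] = parts[7]
            for k, raw in zip(extra_keys, parts[10:]):
                if raw != "" and raw != "''":
                    try:
                        payload[k] = eval(raw, {"__builtins__": {}}, {"inf": float("inf"), "nan": float("nan")})
                    except Exception:
                        payload[k] = raw
            loops.append(Loop(a, b, payload))
    return LoopSet(loops, provenance=str(path))
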