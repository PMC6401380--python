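"""Rotation-based null loop sets on the gap-removed genome.

Chromatin loops and genome annotations are both highly structured along
the chromosome, so enrichment tests need a null that preserves the loop
set's internal geometry (anchor sizes, anchor-anchor distances, loop
spacing).  The construction: delete assembly gaps to get a "no-gap"
coordinate system, slide all loops on a chromosome by one shared random
distance d (2 Mb < d < no-gap chromosome length - 2 Mb) with wrap-around,
map back to reference coordinates, and drop loops whose anchors land on a
gap.  Repeating with fresh d per chromosome gives independent null sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pgl_core import GenomicInterval, Loop, LoopSet

__all__ = ["GapTrack", "NoGapMap", "build_nogap_map", "rotate_loops", "make_null_sets"]

MIN_SHIFT_BP = 2_000_000


@dataclass
class GapTrack:
    """Per-chromosome assembly gaps + chromosome sizes."""

    chrom_sizes: dict[str, int]
    gaps: dict[str, list[GenomicInterval]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, gaps in self.gaps.items():
            size = self.chrom_sizes.get(chrom)
            if size is None:
                raise ValueError(f"gaps on unknown chromosome {chrom!r}")
            gaps.sort(key=lambda g: g.start)
            prev_end = 0
            for g in gaps:
                if g.start < prev_end:
                    raise ValueError(f"overlapping gaps on {chrom}")
                if g.end > size:
                    raise ValueError(f"gap beyond chromosome end on {chrom}")
                prev_end = g.end

    @classmethod
    def read_bed(cls, path, chrom_sizes: dict[str, int]) -> "GapTrack":
        gaps: dict[str, list[GenomicInterval]] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.split("\t")
                gaps.setdefault(f[0], []).append(
                    GenomicInterval(f[0], int(f[1]), int(f[2]))
                )
        return cls(chrom_sizes, gaps)


@dataclass
class NoGapMap:
    """Piecewise-linear bijection between reference and no-gap coordinates
    (outside gaps); positions inside gaps have no no-gap image."""

    chrom: str
    # reference starts of non-gap segments, their no-gap starts, lengths
    ref_starts: np.ndarray
    nogap_starts: np.ndarray
    seg_lengths: np.ndarray
    nogap_length: int

    def to_nogap(self, pos: np.ndarray) -> np.ndarray:
        """Map reference positions to no-gap coordinates; -1 inside gaps."""
        pos = np.asarray(pos, dtype=np.int64)
        seg = np.searchsorted(self.ref_starts, pos, side="right") - 1
        seg = np.clip(seg, 0, len(self.ref_starts) - 1)
        off = pos - self.ref_starts[seg]
        ok = (off >= 0) & (off < self.seg_lengths[seg])
        return np.where(ok, self.nogap_starts[seg] + off, -1)

    def to_ref(self, pos: np.ndarray) -> np.ndarray:
        pos = np.asarray(pos, dtype=np.int64)
        if ((pos < 0) | (pos >= self.nogap_length)).any():
            raise ValueError("no-gap position out of range")
        seg = np.searchsorted(self.nogap_starts, pos, side="right") - 1
        return self.ref_starts[seg] + (pos - self.nogap_starts[seg])


def build_nogap_map(track: GapTrack, chrom: str) -> NoGapMap:
    """No-gap coordinate map for one chromosome."""
    size = track.chrom_sizes[chrom]
    gaps = track.gaps.get(chrom, [])
    ref_starts, seg_lengths = [], []
    cursor = 0
    for g in gaps:
        if g.start > cursor:
            ref_starts.append(cursor)
            seg_lengths.append(g.start - cursor)
        cursor = g.end
    if cursor < size:
        ref_starts.append(cursor)
        seg_lengths.append(size - cursor)
    seg_lengths_arr = np.array(seg_lengths, dtype=np.int64)
    nogap_starts = np.concatenate([[0], np.cumsum(seg_lengths_arr)[:-1]])
    return NoGapMap(
        chrom,
        np.array(ref_starts, dtype=np.int64),
        nogap_starts,
        seg_lengths_arr,
        int(seg_lengths_arr.sum()),
    )


def _overlaps_gap(iv: GenomicInterval, gaps: list[GenomicInterval]) -> bool:
    return any(iv.start < g.end and g.start < iv.end for g in gaps)


def rotate_loops(
    loops: LoopSet,
    track: GapTrack,
    d_per_chrom: dict[str, int] | None = None,
    seed: int | None = None,
) -> tuple[LoopSet, dict]:
    """One rotation: shift every loop on a chromosome by a shared distance.

    Each loop is shifted as a unit by d in no-gap coordinates; a loop
    whose shifted extent runs past the chromosome end is instead moved to
    the beginning of the chromosome, so anchor lengths and anchor-anchor
    distances are preserved in no-gap space for every survivor (removal
    fraction is exactly 0 on a gap-free genome).  After mapping back to
    reference coordinates, loops with any anchor overlapping a gap are
    removed.  If ``d_per_chrom``
    is missing for a chromosome, d is drawn uniformly from
    (2 Mb, no-gap length - 2 Mb) with the seeded generator.
    """
    rng = np.random.default_rng(seed)
    maps = {c: build_nogap_map(track, c) for c in loops.chroms()}
    d_used: dict[str, int] = {}
    out: list[Loop] = []
    n_removed = 0
    for chrom, chrom_loops in sorted(loops.by_chrom().items()):
        m = maps[chrom]
        L = m.nogap_length
        if d_per_chrom is not None and chrom in d_per_chrom:
            d = int(d_per_chrom[chrom])
        else:
            if L <= 2 * MIN_SHIFT_BP + 2:
                raise ValueError(f"{chrom}: no-gap length too small to rotate")
            d = int(rng.integers(MIN_SHIFT_BP + 1, L - MIN_SHIFT_BP))
        if not MIN_SHIFT_BP < d < L - MIN_SHIFT_BP:
            raise ValueError(f"{chrom}: d={d} outside (2 Mb, no-gap length - 2 Mb)")
        d_used[chrom] = d
        gaps = track.gaps.get(chrom, [])
        for lp in chrom_loops:
            sA = int(m.to_nogap(np.array([lp.anchorA.start]))[0])
            sB = int(m.to_nogap(np.array([lp.anchorB.start]))[0])
            if sA < 0 or sB < 0:  # input anchor starts inside a gap
                n_removed += 1
                continue
            offB = sB - sA
            extent = offB + len(lp.anchorB)
            nsA = (sA + d) % L
            if nsA + extent > L:
                # loop crosses the chromosome end: move it to the beginning
                nsA = nsA + extent - L
                if nsA + extent > L:  # longer than half the chromosome
                    n_removed += 1
                    continue
            new_anchors = []
            ok = True
            for start, length in (
                (nsA, len(lp.anchorA)),
                (nsA + offB, len(lp.anchorB)),
            ):
                rs = int(m.to_ref(np.array([start]))[0])
                re = int(m.to_ref(np.array([start + length - 1]))[0]) + 1
                # re > rs + length iff the anchor spans a gap in reference
                # space; such anchors overlap the gap and are removed below
                iv = GenomicInterval(chrom, rs, re)
                if _overlaps_gap(iv, gaps):
                    ok = False
                    break
                new_anchors.append(iv)
            if ok:
                out.append(Loop(new_anchors[0], new_anchors[1], dict(lp.payload)))
            else:
                n_removed += 1
    stats = {
        "d_per_chrom": d_used,
        "n_input": len(loops),
        "n_removed": n_removed,
        "removal_fraction": n_removed / max(len(loops), 1),
    }
    return LoopSet(out, provenance=f"rotation(d={d_used})"), stats


def make_null_sets(
    loops: LoopSet, track: GapTrack, n_sets: int, seed: int
) -> tuple[list[LoopSet], list[dict]]:
    """``n_sets`` independent rotations (fresh d per chromosome per set).

    Deterministic under ``seed``; per-set removal fractions are reported.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    rng = np.random.default_rng(seed)
    sets, stats = [], []
    for k in range(n_sets):
        null, st = rotate_loops(loops, track, seed=int(rng.integers(2**31)))
        st["set_index"] = k
        sets.append(null)
        stats.append(st)
    return sets, stats
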