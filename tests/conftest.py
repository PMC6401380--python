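import numpy as np
import pytest

from loopvar.pgl_core import GenomicInterval, Loop, LoopSet


def mk_loop(chrom, a0, a1, b0, b1, **payload):
    return Loop(
        GenomicInterval(chrom, a0, a1), GenomicInterval(chrom, b0, b1), payload
    )


def random_loopset(rng, n, chroms=("chr1", "chr2"), span=1_000_000, width=50_000):
    """Small random loop set for oracle comparisons."""
    loops = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        a0 = int(rng.integers(0, span))
        a1 = a0 + int(rng.integers(1, width))
        b0 = int(rng.integers(0, span))
        b1 = b0 + int(rng.integers(1, width))
        loops.append(mk_loop(chrom, a0, a1, b0, b1, p=float(rng.random()), name=f"r{i}"))
    return LoopSet(loops)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


# --- independent oracles -----------------------------------------------------


def gap_1d(s1, e1, s2, e2):
    return max(s1 - e2, s2 - e1, 0)


def loops_close(l1, l2, slack):
    if l1.chrom != l2.chrom:
        return False
    return (
        gap_1d(l1.anchorA.start, l1.anchorA.end, l2.anchorA.start, l2.anchorA.end)
        <= slack
        and gap_1d(l1.anchorB.start, l1.anchorB.end, l2.anchorB.start, l2.anchorB.end)
        <= slack
    )


def brute_components(loops, slack):
    """Transitive closure by repeated sweeps (quadratic, obviously correct)."""
    groups = [{i} for i in range(len(loops))]
    changed = True
    while changed:
        changed = False
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                if any(
                    loops_close(loops[i], loops[j], slack)
                    for i in groups[gi]
                    for j in groups[gj]
                ):
                    groups[gi] |= groups[gj]
                    del groups[gj]
                    changed = True
                    break
            if changed:
                break
    return [frozenset(g) for g in groups]
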