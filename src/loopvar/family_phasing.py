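"""Pedigree-based correction of phased genotypes.

Hi-C (proximity-ligation) phasing produces long but imperfect haplotypes:
switch errors (the maternal/paternal assignment flips and stays flipped
until the next flip) and point errors (isolated wrong alleles).  In a
three-generation family, Mendelian inheritance pins down the parental
origin of most child alleles, so both error types can be found and fixed.

The machinery, per child-parent trio:

1. ``match_parent_haplotypes`` — identify which child haplotype descends
   from which parent by average concordance in 1-Mb bins.
2. ``recombination_scan`` — locate meiotic crossovers as extreme points of
   a cumulative matching score: +1 where the transmitted allele equals
   parental haplotype 1 only, -1 where it equals haplotype 2 only, 0
   otherwise.  An extreme point is called when the score retreats from a
   running extreme by at least ``min_excursion`` informative sites.
3. ``mendelian_fix`` — split each parent into crossover blocks, predict the
   ordered (paternal, maternal) allele pair at every site, and re-phase the
   child to match; every edit is logged.  Sites whose genotypes admit no
   Mendelian-consistent assignment are marked as violations.
4. ``family_consistency_filter`` — after all trios are fixed, drop any site
   with a remaining genotype-level violation anywhere in the family.

Trios are processed oldest generation first, so by the time the youngest
child is phased its parents' haplotypes have already been corrected.
Autosomes only; alleles are biallelic 0/1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "PhasedTable",
    "match_parent_haplotypes",
    "recombination_scan",
    "mendelian_fix",
    "family_consistency_filter",
    "phase_family",
    "read_ped",
    "write_ped",
    "write_vcf",
    "read_vcf",
]


@dataclass
class Pedigree:
    """Family relations: individual -> (father, mother), None for founders."""

    parents: dict[str, tuple[str | None, str | None]]

    def __post_init__(self) -> None:
        for ind, (fa, mo) in self.parents.items():
            for p in (fa, mo):
                if p is not None and p not in self.parents:
                    raise ValueError(f"unknown parent {p!r} of {ind!r}")
        if not self.topological_order():
            raise ValueError("pedigree has a cycle")

    @property
    def individuals(self) -> list[str]:
        return list(self.parents)

    def founders(self) -> list[str]:
        return [i for i, (fa, mo) in self.parents.items() if fa is None and mo is None]

    def trios(self) -> list[tuple[str, str, str]]:
        """(child, father, mother) triples, oldest generation first."""
        order = {ind: k for k, ind in enumerate(self.topological_order())}
        out = [
            (c, fa, mo)
            for c, (fa, mo) in self.parents.items()
            if fa is not None and mo is not None
        ]
        out.sort(key=lambda t: order[t[0]])
        return out

    def topological_order(self) -> list[str]:
        order: list[str] = []
        seen: set[str] = set()
        remaining = dict(self.parents)
        while remaining:
            progress = False
            for ind, (fa, mo) in list(remaining.items()):
                if all(p is None or p in seen for p in (fa, mo)):
                    order.append(ind)
                    seen.add(ind)
                    del remaining[ind]
                    progress = True
            if not progress:
                return []
        return order


@dataclass
class PhasedTable:
    """Phased biallelic genotypes over SNV sites, per individual.

    ``hap1``/``hap2`` map (individual, chrom) to int8 allele arrays aligned
    with ``positions[chrom]``; ``phased`` flags whether the site's allele
    order is meaningful for that individual.  For corrected non-founders,
    hap1 is the paternal and hap2 the maternal haplotype.
    """

    positions: dict[str, np.ndarray]
    hap1: dict[tuple[str, str], np.ndarray]
    hap2: dict[tuple[str, str], np.ndarray]
    phased: dict[tuple[str, str], np.ndarray]
    individuals: list[str] = field(default_factory=list)

    @property
    def chroms(self) -> list[str]:
        return list(self.positions)

    def het(self, ind: str, chrom: str) -> np.ndarray:
        return self.hap1[ind, chrom] != self.hap2[ind, chrom]

    def genotype(self, ind: str, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(minor-ordered) allele pair arrays: elementwise (min, max)."""
        a, b = self.hap1[ind, chrom], self.hap2[ind, chrom]
        return np.minimum(a, b), np.maximum(a, b)

    def copy(self) -> "PhasedTable":
        return PhasedTable(
            {c: p.copy() for c, p in self.positions.items()},
            {k: v.copy() for k, v in self.hap1.items()},
            {k: v.copy() for k, v in self.hap2.items()},
            {k: v.copy() for k, v in self.phased.items()},
            list(self.individuals),
        )

    def drop_sites(self, drop: dict[str, np.ndarray]) -> "PhasedTable":
        """Remove sites flagged True in ``drop`` (per chromosome) everywhere."""
        keep = {c: ~drop.get(c, np.zeros(len(p), bool)) for c, p in self.positions.items()}
        return PhasedTable(
            {c: p[keep[c]] for c, p in self.positions.items()},
            {(i, c): v[keep[c]] for (i, c), v in self.hap1.items()},
            {(i, c): v[keep[c]] for (i, c), v in self.hap2.items()},
            {(i, c): v[keep[c]] for (i, c), v in self.phased.items()},
            list(self.individuals),
        )


# ---------------------------------------------------------------------------
# haplotype matching
# ---------------------------------------------------------------------------


def match_parent_haplotypes(
    table: PhasedTable,
    child: str,
    father: str,
    mother: str,
    chrom: str,
    bin_bp: float = 1e6,
) -> dict:
    """Best parent-child haplotype combination for one chromosome.

    Concordance between each child haplotype and each of the four parental
    haplotypes is averaged over ``bin_bp`` bins at informative sites (child
    and parent both heterozygous).  The pairing of child haplotypes to
    parents maximizing total concordance is returned, with the margin over
    the alternative pairing; an exact tie raises (manual resolution).
    """
    pos = table.positions[chrom]
    child_haps = [table.hap1[child, chrom], table.hap2[child, chrom]]
    par_haps = {
        (father, 0): table.hap1[father, chrom],
        (father, 1): table.hap2[father, chrom],
        (mother, 0): table.hap1[mother, chrom],
        (mother, 1): table.hap2[mother, chrom],
    }
    het_c = table.het(child, chrom)
    bins = (pos // int(bin_bp)).astype(int)

    # child-het sites only: the child's phase is meaningless elsewhere.
    # Parent-homozygous sites are what actually separates the two pairings:
    # at double-het biallelic sites hap2 == 1 - hap1 for both individuals,
    # so concordances there are complementary and cancel between pairings.
    def binned_concordance(ch: np.ndarray, ph: np.ndarray, parent: str) -> float:
        mask = het_c
        if not mask.any():
            raise ValueError(f"no informative sites for {child}/{parent} on {chrom}")
        agree = (ch[mask] == ph[mask]).astype(float)
        return float(pd.Series(agree).groupby(bins[mask]).mean().mean())

    conc = {
        (ci, par): binned_concordance(child_haps[ci], hap, par[0])
        for ci in (0, 1)
        for par, hap in par_haps.items()
    }
    # score of assigning child hap ci to a parent: best of that parent's haps
    best = {
        (ci, p): max(conc[ci, (p, 0)], conc[ci, (p, 1)])
        for ci in (0, 1)
        for p in (father, mother)
    }
    s_fm = best[0, father] + best[1, mother]  # hap1 paternal
    s_mf = best[0, mother] + best[1, father]  # hap1 maternal
    if s_fm == s_mf:
        raise ValueError(
            f"tied parent-child haplotype combination for {child} on {chrom}"
        )
    paternal_hap = 0 if s_fm > s_mf else 1
    return {
        "paternal_child_hap": paternal_hap,
        "concordance": conc,
        "margin": abs(s_fm - s_mf),
    }


# ---------------------------------------------------------------------------
# crossover scan
# ---------------------------------------------------------------------------


def recombination_scan(
    child_alleles: np.ndarray,
    ph1: np.ndarray,
    ph2: np.ndarray,
    min_excursion: int = 10,
) -> dict:
    """Crossover detection on one transmitted-allele sequence.

    ``child_alleles`` is the allele sequence inherited from the parent (any
    proxy of it), aligned with the parent's two haplotypes ``ph1``/``ph2``.
    Per-site score: +1 if the allele matches ph1 only, -1 if ph2 only, 0
    otherwise; the cumulative score S is scanned for turning points whose
    flanking excursion reaches ``min_excursion`` informative sites.

    Returns ``breakpoints`` (site indices: first site after each break),
    ``segments`` as (start, end, matched_hap) covering all sites, and the
    cumulative score array ``S`` (length n+1, S[0] = 0).
    """
    s = np.zeros(len(child_alleles), dtype=np.int32)
    s[(child_alleles == ph1) & (child_alleles != ph2)] = 1
    s[(child_alleles == ph2) & (child_alleles != ph1)] = -1
    S = np.concatenate([[0], np.cumsum(s)])

    breakpoints: list[int] = []
    direction = 0
    mx = mn = S[0]
    mx_i = mn_i = 0
    for i in range(1, len(S)):
        v = S[i]
        if v > mx:
            mx, mx_i = v, i
        if v < mn:
            mn, mn_i = v, i
        if direction != -1 and mx - v >= min_excursion and mx_i < i:
            if mx_i > 0:  # an extreme at the boundary is not a turning point
                breakpoints.append(mx_i)
            direction = -1
            mn, mn_i = v, i
        elif direction != 1 and v - mn >= min_excursion and mn_i < i:
            if mn_i > 0:
                breakpoints.append(mn_i)
            direction = 1
            mx, mx_i = v, i

    edges = [0] + breakpoints + [len(child_alleles)]
    segments: list[tuple[int, int, int]] = []
    for a, b in zip(edges[:-1], edges[1:]):
        if a == b:
            continue
        net = int(S[b] - S[a])
        matched = 0 if net >= 0 else 1
        segments.append((a, b, matched))
    return {"breakpoints": breakpoints, "segments": segments, "S": S}


def _local_match(s: np.ndarray, window: int = 5) -> np.ndarray:
    """Local matched-haplotype signal from per-site scores.

    For each position, the sum of ``s`` over the nearest ``window`` nonzero
    entries on each side (inclusive of the site itself).  Positive favours
    haplotype 1, negative haplotype 2, 0 is undecided.  Captures short
    switch-error segments in the parent that a global excursion scan with a
    larger threshold would absorb.
    """
    nz = np.flatnonzero(s)
    if len(nz) == 0:
        return np.zeros(len(s), dtype=np.int32)
    c = np.concatenate([[0], np.cumsum(s[nz])])
    # for each site, index of the first informative site at or after it
    right = np.searchsorted(nz, np.arange(len(s)))
    lo = np.maximum(right - window, 0)
    hi = np.minimum(right + window, len(nz))
    return (c[hi] - c[lo]).astype(np.int32)


# ---------------------------------------------------------------------------
# Mendelian fixing
# ---------------------------------------------------------------------------


def _transmitted_direct(
    g_child: tuple[np.ndarray, np.ndarray],
    g_other: tuple[np.ndarray, np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Directly genotype-determined transmitted allele from the parent of
    interest, using the child genotype and the OTHER parent's genotype.

    Returns (defined mask, allele).  Defined when the child is homozygous
    (both parents transmitted that allele) or the child is heterozygous and
    the other parent is homozygous (the other parent's allele accounts for
    one child allele; the parent of interest transmitted the remaining one).
    """
    c_lo, c_hi = g_child
    o_lo, o_hi = g_other
    child_hom = c_lo == c_hi
    other_hom = o_lo == o_hi
    t = np.full(len(c_lo), -1, dtype=np.int8)
    t[child_hom] = c_lo[child_hom]
    m = ~child_hom & other_hom & ((o_lo == c_lo) | (o_lo == c_hi))
    # child het {0,1}: remaining allele is the one the other parent did not give
    t[m] = (c_lo[m] + c_hi[m]) - o_lo[m]
    return t >= 0, t


def _parent_prediction(
    table: PhasedTable,
    parent: str,
    chrom: str,
    t_def: np.ndarray,
    t_val: np.ndarray,
    min_excursion: int,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Predicted transmitted allele from ``parent`` at every site.

    Parent-homozygous sites are forced; at parent-het sites the matched
    haplotype comes from the crossover blocks of the Eq.-style scan over
    directly-determined transmitted alleles, refined by a local-window
    match so that short phasing-switch segments in the parent do not
    propagate; sites the scan cannot call keep the block haplotype.

    Returns (defined mask, predicted allele, scan result, per-site margin:
    the local-match confidence, infinite at forced or direct sites).
    """
    p1, p2 = table.hap1[parent, chrom], table.hap2[parent, chrom]
    het_p = p1 != p2
    n = len(p1)

    pred = np.full(n, -1, dtype=np.int8)
    pred[~het_p] = p1[~het_p]

    grid = np.flatnonzero(het_p & t_def)
    if len(grid) == 0:
        return (
            pred >= 0,
            pred,
            {"breakpoints": [], "segments": [], "S": np.zeros(1)},
            np.full(n, np.inf),
        )
    scan = recombination_scan(
        t_val[grid], p1[grid], p2[grid], min_excursion=min_excursion
    )
    # block haplotype per site (blocks defined on the grid, extended to all)
    block_hap = np.zeros(n, dtype=np.int8)
    for a, b, matched in scan["segments"]:
        lo = 0 if a == 0 else grid[a]
        hi = n if b == len(grid) else grid[b]
        block_hap[lo:hi] = matched

    # local refinement: per-site score on the full axis (0 off-grid)
    s_full = np.zeros(n, dtype=np.int32)
    s_grid = np.zeros(len(grid), dtype=np.int32)
    s_grid[(t_val[grid] == p1[grid]) & (t_val[grid] != p2[grid])] = 1
    s_grid[(t_val[grid] == p2[grid]) & (t_val[grid] != p1[grid])] = -1
    s_full[grid] = s_grid
    local = _local_match(s_full)
    hap = np.where(local > 0, 0, np.where(local < 0, 1, block_hap)).astype(np.int8)

    het_idx = np.flatnonzero(het_p)
    pred[het_idx] = np.where(hap[het_idx] == 0, p1[het_idx], p2[het_idx])
    margin = np.full(n, np.inf)
    margin[het_idx] = np.abs(local[het_idx]).astype(float)
    # direct determinations outrank any haplotype-derived prediction
    direct = het_p & t_def
    pred[direct] = t_val[direct]
    margin[direct] = np.inf
    return pred >= 0, pred, scan, margin


def mendelian_fix(
    table: PhasedTable,
    child: str,
    father: str,
    mother: str,
    min_excursion: int = 10,
) -> dict:
    """Re-phase one child against its parents, in place.

    For every site the ordered (paternal, maternal) transmitted pair is
    predicted from parental genotypes, crossover blocks and local haplotype
    matching; the child's phase is set to that pair whenever it is
    consistent with the child's genotype (hap1 = paternal).  Unphased child
    sites with a unique consistent assignment are phased.  Sites with no
    Mendelian-consistent assignment are marked violating, never altered.

    Returns per-chromosome edits, violations and crossover calls.
    """
    edits: list[dict] = []
    violations: dict[str, np.ndarray] = {}
    crossovers: dict[tuple[str, str], list[int]] = {}
    for chrom in table.chroms:
        g_c = table.genotype(child, chrom)
        g_f = table.genotype(father, chrom)
        g_m = table.genotype(mother, chrom)
        pos = table.positions[chrom]
        n = len(pos)

        def_f, t_f = _transmitted_direct(g_c, g_m)
        def_m, t_m = _transmitted_direct(g_c, g_f)
        _, F, scan_f, marg_f = _parent_prediction(
            table, father, chrom, def_f, t_f, min_excursion
        )
        _, M, scan_m, marg_m = _parent_prediction(
            table, mother, chrom, def_m, t_m, min_excursion
        )

        grid_f = np.flatnonzero(table.het(father, chrom) & def_f)
        grid_m = np.flatnonzero(table.het(mother, chrom) & def_m)
        crossovers[child, father, chrom] = [
            int(pos[grid_f[b]]) for b in scan_f["breakpoints"] if b < len(grid_f)
        ]
        crossovers[child, mother, chrom] = [
            int(pos[grid_m[b]]) for b in scan_m["breakpoints"] if b < len(grid_m)
        ]

        c_lo, c_hi = g_c
        ok = (np.minimum(F, M) == c_lo) & (np.maximum(F, M) == c_hi)

        # rescue conflicts the genotypes themselves can resolve: keep the
        # prediction with the larger local-match margin, set the other to
        # the allele the child genotype requires (when the parent carries it)
        need = (c_lo + c_hi).astype(np.int8)
        f_lo, f_hi = g_f
        m_lo, m_hi = g_m
        bad = ~ok
        fix_f = (need - M).astype(np.int8)  # trust M, re-derive F
        fix_m = (need - F).astype(np.int8)  # trust F, re-derive M
        can_f = bad & ((fix_f == f_lo) | (fix_f == f_hi)) & (fix_f >= 0)
        can_m = bad & ((fix_m == m_lo) | (fix_m == m_hi)) & (fix_m >= 0)
        use_f = can_f & (~can_m | (marg_m > marg_f))
        use_m = can_m & (~can_f | (marg_f > marg_m))
        tie = can_f & can_m & (marg_f == marg_m)
        use_f &= ~tie
        use_m &= ~tie
        F = np.where(use_f, fix_f, F)
        M = np.where(use_m, fix_m, M)
        ok = (np.minimum(F, M) == c_lo) & (np.maximum(F, M) == c_hi)
        violations[chrom] = ~ok

        h1 = table.hap1[child, chrom]
        h2 = table.hap2[child, chrom]
        ph = table.phased[child, chrom]
        changed = ok & ((h1 != F) | (h2 != M))
        n_flip = int((changed & ph & (h1 != h2)).sum())
        n_phased = int((changed & ~ph).sum())
        h1[ok] = F[ok]
        h2[ok] = M[ok]
        ph[ok] = True
        edits.append(
            {
                "child": child,
                "chrom": chrom,
                "n_sites": n,
                "n_edited": int(changed.sum()),
                "n_het_flips": n_flip,
                "n_newly_phased": n_phased,
                "n_violations": int((~ok).sum()),
            }
        )
    return {"edits": edits, "violations": violations, "crossovers": crossovers}


def family_consistency_filter(
    table: PhasedTable,
    pedigree: Pedigree,
    extra_violations: dict[str, np.ndarray] | None = None,
) -> tuple[PhasedTable, dict]:
    """Drop every site with a genotype-level Mendelian violation in any trio.

    A site passes for a trio when the child's genotype can be assembled from
    one allele of each parent.  Returns the filtered table and removal
    counts; applying the filter twice removes nothing more (idempotent).
    """
    drop: dict[str, np.ndarray] = {
        c: np.zeros(len(p), dtype=bool) for c, p in table.positions.items()
    }
    if extra_violations:
        for c, v in extra_violations.items():
            drop[c] |= v
    for child, father, mother in pedigree.trios():
        for chrom in table.chroms:
            c_lo, c_hi = table.genotype(child, chrom)
            f_lo, f_hi = table.genotype(father, chrom)
            m_lo, m_hi = table.genotype(mother, chrom)
            ok = np.zeros(len(c_lo), dtype=bool)
            for fa in (f_lo, f_hi):
                for ma in (m_lo, m_hi):
                    ok |= (np.minimum(fa, ma) == c_lo) & (np.maximum(fa, ma) == c_hi)
            drop[chrom] |= ~ok
    filtered = table.drop_sites(drop)
    stats = {c: int(v.sum()) for c, v in drop.items()}
    stats["total_removed"] = int(sum(stats.values()))
    return filtered, stats


def phase_family(
    table: PhasedTable,
    pedigree: Pedigree,
    min_excursion: int = 10,
    bin_bp: float = 1e6,
) -> dict:
    """Full pipeline: per-trio correction (oldest first) + family filter.

    Founder haplotype labels are left as given: with a single child per
    founder couple, a founder's own phasing switches cannot be told apart
    from the crossovers of their meiosis, so only transmitted-allele
    content (which the trio machinery reconstructs) is identifiable.
    """
    work = table.copy()
    all_edits: list[dict] = []
    combos: dict[tuple[str, str], dict] = {}
    crossovers: dict[tuple[str, str], list[int]] = {}
    violations: dict[str, np.ndarray] = {
        c: np.zeros(len(p), dtype=bool) for c, p in work.positions.items()
    }
    for child, father, mother in pedigree.trios():
        for chrom in work.chroms:
            try:
                combos[child, chrom] = match_parent_haplotypes(
                    work, child, father, mother, chrom, bin_bp=bin_bp
                )
            except ValueError:
                # heavily switch-corrupted phasing has no meaningful global
                # pairing; the Mendelian fix re-derives orientation per site
                combos[child, chrom] = None
        res = mendelian_fix(work, child, father, mother, min_excursion=min_excursion)
        all_edits.extend(res["edits"])
        for c, v in res["violations"].items():
            violations[c] |= v
        crossovers.update(res["crossovers"])
    filtered, removal = family_consistency_filter(work, pedigree, violations)
    return {
        "table": filtered,
        "unfiltered": work,
        "edits": pd.DataFrame(all_edits),
        "combos": combos,
        "crossovers": crossovers,
        "removal": removal,
    }


# ---------------------------------------------------------------------------
# I/O: PED and a phased-GT VCF subset
# ---------------------------------------------------------------------------


def write_ped(pedigree: Pedigree, path, family_id: str = "FAM1") -> None:
    with open(path, "w") as fh:
        for ind, (fa, mo) in pedigree.parents.items():
            fh.write(
                "\t".join([family_id, ind, fa or "0", mo or "0", "0", "0"]) + "\n"
            )


def read_ped(path) -> Pedigree:
    parents: dict[str, tuple[str | None, str | None]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split()
            parents[f[1]] = (f[2] if f[2] != "0" else None, f[3] if f[3] != "0" else None)
    return Pedigree(parents)


def write_vcf(table: PhasedTable, path) -> None:
    """Minimal biallelic phased-GT VCF (text, uncompressed)."""
    inds = table.individuals
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, pos in table.positions.items():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(inds)
            + "\n"
        )
        for chrom, pos in table.positions.items():
            h1 = np.stack([table.hap1[i, chrom] for i in inds])
            h2 = np.stack([table.hap2[i, chrom] for i in inds])
            ph = np.stack([table.phased[i, chrom] for i in inds])
            for k, p in enumerate(pos):
                gts = [
                    f"{h1[j, k]}{'|' if ph[j, k] else '/'}{h2[j, k]}"
                    for j in range(len(inds))
                ]
                fh.write(
                    f"{chrom}\t{int(p) + 1}\t.\tA\tG\t.\tPASS\t.\tGT\t"
                    + "\t".join(gts)
                    + "\n"
                )


def read_vcf(path) -> PhasedTable:
    """Read the phased-GT VCF subset written by :func:`write_vcf`."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    inds = list(vcf.samples)
    rows: dict[str, list] = {}
    for v in vcf:
        rows.setdefault(v.CHROM, []).append((v.POS - 1, np.array(v.genotypes)))
    positions: dict[str, np.ndarray] = {}
    hap1: dict[tuple[str, str], np.ndarray] = {}
    hap2: dict[tuple[str, str], np.ndarray] = {}
    phased: dict[tuple[str, str], np.ndarray] = {}
    for chrom, items in rows.items():
        positions[chrom] = np.array([p for p, _ in items], dtype=np.int64)
        g = np.stack([gt for _, gt in items])  # sites x individuals x 3
        for j, ind in enumerate(inds):
            hap1[ind, chrom] = g[:, j, 0].astype(np.int8)
            hap2[ind, chrom] = g[:, j, 1].astype(np.int8)
            phased[ind, chrom] = g[:, j, 2].astype(bool)
    return PhasedTable(positions, hap1, hap2, phased, inds)
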