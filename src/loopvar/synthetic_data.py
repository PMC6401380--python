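"""Synthetic data with ground truth for every pipeline stage.

Emulates the data a family Hi-C study produces — a small genome with
assembly gaps, chromatin loops with cell-type and haplotype effects on
contact propensity, noisy multi-resolution caller output, pedigree
genotypes corrupted with phasing errors, phased contacts, and molecular
phenotype fold changes coupled to loop fold changes — at a scale where the
full pipeline runs in minutes on one CPU.

Default magnitudes follow the study design being emulated: 7 individuals
(two founder couples, two parents, one child), 11 + 13 Hi-C samples across
two cell types, loop spans log-normal over roughly 70 kb–1 Mb,
negative-binomial contact counts (dispersion 0.05), ~50 informative phased
contacts per loop per individual, 1% of loops allelically imbalanced at
0.75, and phenotype fold changes an order of magnitude wider than loop
fold changes.  All randomness flows from one seed; identical seeds give
identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .pgl_core import GenomicInterval, Loop, LoopSet
from .family_phasing import Pedigree, PhasedTable

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_genome",
    "simulate_loops",
    "simulate_contacts",
    "simulate_contact_records",
    "simulate_phased_contacts",
    "simulate_caller_outputs",
    "simulate_pedigree",
    "simulate_coupled_fold_changes",
]

DEFAULT_PEDIGREE = {
    "pgf": (None, None),
    "pgm": (None, None),
    "mgf": (None, None),
    "mgm": (None, None),
    "father": ("pgf", "pgm"),
    "mother": ("mgf", "mgm"),
    "child": ("father", "mother"),
}


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the study conditions."""

    seed: int = 0
    # genome
    n_chroms: int = 2
    chrom_size_bp: int = 30_000_000
    gap_fraction: float = 0.05
    n_gaps_per_chrom: int = 6
    # loops
    n_loops: int = 500
    anchor_width_bp: int = 10_000
    span_log_mean: float = float(np.log(2.2e5))
    span_log_sd: float = 0.55
    span_min_bp: int = 70_000
    span_max_bp: int = 1_000_000
    intensity_log_sd: float = 0.5
    # cell-type effects (CTALs)
    ctal_fraction: float = 0.10
    ctal_log2fc_min: float = 0.5
    ctal_log2fc_max: float = 2.0
    # haplotype effects (HTALs)
    htal_fraction: float = 0.01
    htal_imbalance: float = 0.75
    # contact depth
    mean_contacts_per_loop: float = 100.0
    dispersion: float = 0.05
    informative_contacts_per_individual: float = 50.0
    n_ipsc_samples: int = 11
    n_cm_samples: int = 13
    n_individuals: int = 7
    background_contacts_per_mb: float = 30.0
    # phenotype coupling: loop log2FC = beta * phenotype log2FC + noise
    coupling_beta: float = 0.1
    coupling_sigma: float = 0.1
    phenotype_log2fc_sd: float = 2.0
    # pedigree phasing
    n_het_sites_per_chrom: int = 30_000
    switch_error_rate: float = 0.01
    point_error_rate: float = 0.001
    unphased_rate: float = 0.02
    # caller emulation
    fithic_resolutions: tuple = tuple(range(4000, 12001, 400))
    hiccups_resolutions: tuple = tuple(range(5000, 25001, 1000))
    dropout: float = 0.15
    jitter_prob: float = 0.2
    n_spurious_per_caller: int = 150

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("fithic_resolutions", "hiccups_resolutions"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def validate(self) -> None:
        for name in (
            "gap_fraction",
            "ctal_fraction",
            "htal_fraction",
            "dropout",
            "jitter_prob",
            "switch_error_rate",
            "point_error_rate",
            "unphased_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.5 < self.htal_imbalance < 1.0:
            raise ValueError("htal_imbalance must be in (0.5, 1)")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    config: SimulationConfig
    chrom_sizes: dict[str, int]
    gaps: dict[str, list[GenomicInterval]]
    loops: LoopSet
    loop_table: pd.DataFrame
    pedigree: Pedigree | None = None
    true_phasing: PhasedTable | None = None
    crossovers: dict | None = None
    error_sites: dict | None = None


# ---------------------------------------------------------------------------
# genome & loops
# ---------------------------------------------------------------------------


def simulate_genome(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, int], dict[str, list[GenomicInterval]]]:
    """Chromosome sizes and non-overlapping assembly gaps."""
    sizes = {f"chr{i + 1}": cfg.chrom_size_bp for i in range(cfg.n_chroms)}
    gaps: dict[str, list[GenomicInterval]] = {}
    for chrom, size in sizes.items():
        total_gap = int(cfg.gap_fraction * size)
        if total_gap == 0 or cfg.n_gaps_per_chrom == 0:
            gaps[chrom] = []
            continue
        w = rng.dirichlet(np.ones(cfg.n_gaps_per_chrom)) * total_gap
        widths = np.maximum(w.astype(int), 1)
        starts = np.sort(
            rng.integers(1, size - int(widths.max()) - 1, size=cfg.n_gaps_per_chrom)
        )
        out: list[GenomicInterval] = []
        prev_end = 0
        for s, wd in zip(starts, widths):
            s = max(int(s), prev_end + 1)
            e = min(int(s + wd), size - 1)
            if e > s:
                out.append(GenomicInterval(chrom, s, e))
                prev_end = e
        gaps[chrom] = out
    return sizes, gaps


def simulate_loops(cfg: SimulationConfig, rng: np.random.Generator) -> GroundTruth:
    """Loops with true cell-type and haplotype effects.

    Loop spans (anchor-start to anchor-start distance) are log-normal,
    clipped to [span_min_bp, span_max_bp]; anchors avoid assembly gaps.
    A ``ctal_fraction`` of loops get a cell-type log2 fold change with
    magnitude uniform in [ctal_log2fc_min, ctal_log2fc_max] and random
    sign (iPSC-positive convention); an ``htal_fraction`` get allelic
    imbalance ``htal_imbalance`` toward a random parental haplotype.
    """
    sizes, gaps = simulate_genome(cfg, rng)
    chroms = list(sizes)
    rows = []
    loops = []
    w = cfg.anchor_width_bp
    i = 0
    while i < cfg.n_loops:
        chrom = chroms[i % len(chroms)]
        size = sizes[chrom]
        span = float(
            np.clip(
                rng.lognormal(cfg.span_log_mean, cfg.span_log_sd),
                cfg.span_min_bp,
                cfg.span_max_bp,
            )
        )
        start_a = int(rng.integers(1_000_000, size - 1_000_000 - span - w))
        start_b = int(start_a + span)
        a = GenomicInterval(chrom, start_a, start_a + w)
        b = GenomicInterval(chrom, start_b, start_b + w)
        if any(a.overlaps(g) or b.overlaps(g) for g in gaps[chrom]):
            continue
        loop_id = f"L{i:05d}"
        loops.append(Loop(a, b, {"name": loop_id, "truth_id": loop_id}))
        rows.append(
            {
                "loop_id": loop_id,
                "chrom": chrom,
                "startA": a.start,
                "endA": a.end,
                "startB": b.start,
                "endB": b.end,
                "intensity": float(rng.lognormal(0.0, cfg.intensity_log_sd)),
            }
        )
        i += 1
    table = pd.DataFrame(rows).set_index("loop_id")

    n = len(table)
    table["log2fc"] = 0.0
    table["class"] = "none"
    n_ctal = int(round(cfg.ctal_fraction * n))
    ctal_idx = rng.choice(n, size=n_ctal, replace=False)
    mag = rng.uniform(cfg.ctal_log2fc_min, cfg.ctal_log2fc_max, size=n_ctal)
    sign = rng.choice([-1.0, 1.0], size=n_ctal)
    table.iloc[ctal_idx, table.columns.get_loc("log2fc")] = mag * sign
    table.iloc[ctal_idx, table.columns.get_loc("class")] = "CTAL"

    table["imbalance_f"] = 0.5
    table["imbalance_maternal"] = False
    n_htal = max(1, int(round(cfg.htal_fraction * n)))
    htal_idx = rng.choice(
        np.setdiff1d(np.arange(n), ctal_idx), size=n_htal, replace=False
    )
    table.iloc[htal_idx, table.columns.get_loc("imbalance_f")] = cfg.htal_imbalance
    table.iloc[htal_idx, table.columns.get_loc("imbalance_maternal")] = rng.random(
        n_htal
    ) < 0.5
    table.loc[table["imbalance_f"] > 0.5, "class"] = "HTAL"

    return GroundTruth(
        config=cfg,
        chrom_sizes=sizes,
        gaps=gaps,
        loops=LoopSet(loops, provenance="synthetic"),
        loop_table=table,
    )


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------


def sample_metadata(cfg: SimulationConfig) -> pd.DataFrame:
    """Sample sheet: sample id, individual, cell type."""
    rows = []
    for k in range(cfg.n_ipsc_samples):
        rows.append(
            {
                "sample": f"iPSC_{k:02d}",
                "individual": f"ind{k % cfg.n_individuals}",
                "cell_type": "iPSC",
            }
        )
    for k in range(cfg.n_cm_samples):
        rows.append(
            {
                "sample": f"CM_{k:02d}",
                "individual": f"ind{k % cfg.n_individuals}",
                "cell_type": "CM",
            }
        )
    return pd.DataFrame(rows).set_index("sample")


def simulate_contacts(
    truth: GroundTruth, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-loop, per-sample raw contact counts (negative binomial).

    Counts are NB with mean = depth x loop intensity x cell-type
    multiplier (2^(+/- log2FC/2) split between cell types, iPSC-positive)
    and dispersion ``cfg.dispersion``.  Returns (counts, metadata).
    """
    cfg = truth.config
    meta = sample_metadata(cfg)
    t = truth.loop_table
    base = cfg.mean_contacts_per_loop * t["intensity"].to_numpy()
    half = 0.5 * t["log2fc"].to_numpy()
    mu_by_type = {
        "iPSC": base * 2.0 ** half,
        "CM": base * 2.0 ** (-half),
    }
    phi = cfg.dispersion
    cols = {}
    for sample, row in meta.iterrows():
        mu = mu_by_type[row["cell_type"]]
        # NB via gamma-Poisson mixture; phi -> 0 degenerates to Poisson
        lam = rng.gamma(1.0 / phi, phi * mu) if phi > 0 else mu
        cols[sample] = rng.poisson(lam)
    counts = pd.DataFrame(cols, index=t.index)
    return counts, meta


def simulate_contact_records(
    truth: GroundTruth,
    rng: np.random.Generator,
    counts: pd.DataFrame,
    samples: list[str] | None = None,
    background: bool = True,
) -> pd.DataFrame:
    """Explicit contact records realizing given per-loop counts.

    Ends are uniform within the anchors; off-loop background contacts with
    power-law distance decay are appended when ``background`` is True.
    Columns: chrom, pos1, pos2, sample.
    """
    cfg = truth.config
    t = truth.loop_table
    if samples is None:
        samples = list(counts.columns)
    frames = []
    for sample in samples:
        cvec = counts[sample].to_numpy()
        reps = np.repeat(np.arange(len(t)), cvec)
        sa = t["startA"].to_numpy()[reps]
        sb = t["startB"].to_numpy()[reps]
        chrom = t["chrom"].to_numpy()[reps]
        p1 = sa + rng.integers(0, cfg.anchor_width_bp, size=len(reps))
        p2 = sb + rng.integers(0, cfg.anchor_width_bp, size=len(reps))
        frames.append(
            pd.DataFrame({"chrom": chrom, "pos1": p1, "pos2": p2, "sample": sample})
        )
        if background:
            for chrom_name, size in truth.chrom_sizes.items():
                n_bg = rng.poisson(cfg.background_contacts_per_mb * size / 1e6)
                q1 = rng.integers(0, size, size=n_bg)
                # distance decay ~ pareto, floored at the 2 kb intake filter
                d = (2_000 * (1 + rng.pareto(1.0, size=n_bg))).astype(int)
                q2 = np.minimum(q1 + d, size - 1)
                frames.append(
                    pd.DataFrame(
                        {
                            "chrom": chrom_name,
                            "pos1": q1,
                            "pos2": q2,
                            "sample": sample,
                        }
                    )
                )
    return pd.concat(frames, ignore_index=True)


def simulate_phased_contacts(
    truth: GroundTruth, rng: np.random.Generator, as_records: bool = False
) -> pd.DataFrame:
    """Informative (haplotype-assignable) contacts per loop per individual.

    The number of informative contacts per loop per individual is Poisson
    with the configured mean (cell types pooled); each is maternal with
    probability f (the loop's true imbalance, oriented by the truth table)
    — Binomial thinning.  Returns per-loop per-individual maternal and
    paternal counts, or explicit labelled records when ``as_records``.
    """
    cfg = truth.config
    t = truth.loop_table
    individuals = [f"ind{k}" for k in range(cfg.n_individuals)]
    rows = []
    for ind in individuals:
        n_inf = rng.poisson(
            cfg.informative_contacts_per_individual, size=len(t)
        )
        f = np.where(
            t["imbalance_maternal"].to_numpy(),
            t["imbalance_f"].to_numpy(),
            1.0 - t["imbalance_f"].to_numpy(),
        )
        n_mat = rng.binomial(n_inf, f)
        rows.append(
            pd.DataFrame(
                {
                    "loop_id": t.index,
                    "individual": ind,
                    "n_maternal": n_mat,
                    "n_paternal": n_inf - n_mat,
                }
            )
        )
    df = pd.concat(rows, ignore_index=True)
    if not as_records:
        return df
    # explode to one labelled record per contact, ends inside the anchors
    t_idx = t.reset_index()
    merged = df.merge(t_idx, on="loop_id")
    frames = []
    for hap, col in (("M", "n_maternal"), ("P", "n_paternal")):
        reps = merged.loc[merged[col] > 0]
        idx = np.repeat(reps.index.to_numpy(), reps[col].to_numpy())
        sub = merged.loc[idx]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": sub["chrom"].to_numpy(),
                    "pos1": sub["startA"].to_numpy()
                    + rng.integers(0, cfg.anchor_width_bp, size=len(sub)),
                    "pos2": sub["startB"].to_numpy()
                    + rng.integers(0, cfg.anchor_width_bp, size=len(sub)),
                    "individual": sub["individual"].to_numpy(),
                    "hap_labels": hap,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# caller outputs
# ---------------------------------------------------------------------------


def _snap(start: int, res: int, jitter: int) -> int:
    return max(0, (start // res + jitter) * res)


def simulate_caller_outputs(
    truth: GroundTruth, rng: np.random.Generator
) -> dict[str, dict[int, LoopSet]]:
    """Noisy multi-resolution caller call tables for two caller families.

    True loops are emitted at >= 7 (fithic_like) or >= 3 (hiccups_like)
    resolutions, anchors snapped to the resolution grid with occasional
    one-bin jitter and per-resolution drop-out.  Spurious calls appear at
    random matrix positions in at most 2 resolutions.  Payloads carry
    ``truth_id`` ("SPURIOUS_*" for spurious calls) so recovery can be
    scored after harmonization.
    """
    cfg = truth.config
    out: dict[str, dict[int, LoopSet]] = {}
    plan = {
        "fithic_like": (list(cfg.fithic_resolutions), 7),
        "hiccups_like": (list(cfg.hiccups_resolutions), 3),
    }
    t = truth.loop_table
    for caller, (resolutions, min_support) in plan.items():
        calls: dict[int, list[Loop]] = {r: [] for r in resolutions}
        for loop_id, row in t.iterrows():
            emit = [r for r in resolutions if rng.random() > cfg.dropout]
            while len(emit) < min_support:
                extra = resolutions[int(rng.integers(len(resolutions)))]
                if extra not in emit:
                    emit.append(extra)
            for res in emit:
                j1 = int(rng.integers(-1, 2)) if rng.random() < cfg.jitter_prob else 0
                j2 = int(rng.integers(-1, 2)) if rng.random() < cfg.jitter_prob else 0
                sa = _snap(int(row["startA"]), res, j1)
                sb = _snap(int(row["startB"]), res, j2)
                if sb <= sa:
                    sb = sa + res
                calls[res].append(
                    Loop(
                        GenomicInterval(row["chrom"], sa, sa + res),
                        GenomicInterval(row["chrom"], sb, sb + res),
                        {
                            "q": float(10.0 ** -rng.uniform(2.5, 9)),
                            "caller": caller,
                            "resolution": res,
                            "truth_id": loop_id,
                        },
                    )
                )
        chroms = list(truth.chrom_sizes)
        for k in range(cfg.n_spurious_per_caller):
            chrom = chroms[int(rng.integers(len(chroms)))]
            size = truth.chrom_sizes[chrom]
            n_res = int(rng.integers(1, 3))
            sid = f"SPURIOUS_{caller}_{k}"
            sa = int(rng.integers(0, size - 5_000_000))
            sb = int(sa + rng.integers(2_000_000, 5_000_000))  # far off-diagonal
            for res in rng.choice(resolutions, size=n_res, replace=False):
                res = int(res)
                a0 = (sa // res) * res
                b0 = (sb // res) * res
                calls[res].append(
                    Loop(
                        GenomicInterval(chrom, a0, a0 + res),
                        GenomicInterval(chrom, b0, b0 + res),
                        {
                            "q": float(10.0 ** -rng.uniform(2.1, 4)),
                            "caller": caller,
                            "resolution": res,
                            "truth_id": sid,
                        },
                    )
                )
        out[caller] = {
            res: LoopSet(lps, provenance=f"{caller}@{res}")
            for res, lps in calls.items()
        }
    return out


# ---------------------------------------------------------------------------
# pedigree genotypes
# ---------------------------------------------------------------------------


def simulate_pedigree(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[PhasedTable, PhasedTable, Pedigree, dict]:
    """Three-generation, seven-member pedigree with phasing errors.

    Founder haplotypes are drawn site-wise from per-site allele
    frequencies; children inherit recombined gametes (1-2 crossovers per
    chromosome per meiosis, uniform positions).  The corrupted copy adds
    switch errors (state flips persisting until the next flip), point
    errors (isolated allele flips) and unphased sites at the configured
    rates.  hap1 is paternal for non-founders in the truth table.

    Returns (truth, corrupted, pedigree, ground_truth_dict).
    """
    ped = Pedigree(dict(DEFAULT_PEDIGREE))
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    def _distinct_positions(k: int) -> np.ndarray:
        pos = np.unique(rng.integers(0, cfg.chrom_size_bp, size=int(k * 1.2)))
        while len(pos) < k:
            pos = np.unique(
                np.concatenate([pos, rng.integers(0, cfg.chrom_size_bp, size=k)])
            )
        return np.sort(rng.choice(pos, size=k, replace=False)).astype(np.int64)

    positions = {c: _distinct_positions(cfg.n_het_sites_per_chrom) for c in chroms}
    hap1: dict[tuple[str, str], np.ndarray] = {}
    hap2: dict[tuple[str, str], np.ndarray] = {}
    crossovers: dict[tuple[str, str, str], list[int]] = {}

    def gamete(parent: str, chrom: str) -> np.ndarray:
        n = len(positions[chrom])
        n_xo = int(rng.integers(1, 3))
        cuts = np.sort(rng.choice(np.arange(1, n), size=n_xo, replace=False))
        phase = np.zeros(n, dtype=bool)
        state = bool(rng.integers(2))
        prev = 0
        for cut in list(cuts) + [n]:
            phase[prev:cut] = state
            state = not state
            prev = cut
        return np.where(phase, hap2[parent, chrom], hap1[parent, chrom]), [
            int(positions[chrom][c]) for c in cuts
        ]

    for chrom in chroms:
        maf = rng.uniform(0.1, 0.9, size=len(positions[chrom]))
        for f in ped.founders():
            hap1[f, chrom] = (rng.random(len(maf)) < maf).astype(np.int8)
            hap2[f, chrom] = (rng.random(len(maf)) < maf).astype(np.int8)
    for child, father, mother in ped.trios():
        for chrom in chroms:
            pat, cuts_f = gamete(father, chrom)
            mat, cuts_m = gamete(mother, chrom)
            hap1[child, chrom] = pat.astype(np.int8)
            hap2[child, chrom] = mat.astype(np.int8)
            crossovers[child, father, chrom] = cuts_f
            crossovers[child, mother, chrom] = cuts_m

    inds = ped.individuals
    phased_true = {
        (i, c): np.ones(len(positions[c]), dtype=bool) for i in inds for c in chroms
    }
    truth = PhasedTable(positions, hap1, hap2, phased_true, inds)

    corrupted = truth.copy()
    error_sites: dict[tuple[str, str], dict] = {}
    for ind in inds:
        for chrom in chroms:
            n = len(positions[chrom])
            h1 = corrupted.hap1[ind, chrom]
            h2 = corrupted.hap2[ind, chrom]
            flips = rng.random(n) < cfg.switch_error_rate
            state = (np.cumsum(flips) % 2).astype(bool)
            swap = state
            h1[swap], h2[swap] = h2[swap].copy(), h1[swap].copy()
            point = rng.random(n) < cfg.point_error_rate
            which = rng.integers(2, size=n).astype(bool)
            h1[point & which] = 1 - h1[point & which]
            h2[point & ~which] = 1 - h2[point & ~which]
            unph = rng.random(n) < cfg.unphased_rate
            corrupted.phased[ind, chrom][unph] = False
            error_sites[ind, chrom] = {
                "switch_flip_sites": np.flatnonzero(flips),
                "switched_state": state,
                "point_error_sites": np.flatnonzero(point),
                "unphased_sites": np.flatnonzero(unph),
            }
    gt = {"crossovers": crossovers, "error_sites": error_sites}
    return truth, corrupted, ped, gt


# ---------------------------------------------------------------------------
# phenotype coupling
# ---------------------------------------------------------------------------


def simulate_coupled_fold_changes(
    truth: GroundTruth, rng: np.random.Generator, n_pairs: int | None = None
) -> pd.DataFrame:
    """Loop/phenotype log2 fold-change pairs with linear coupling.

    Phenotype fold changes are wide (sd ``phenotype_log2fc_sd``, i.e. gene
    expression can change hundreds-fold); loop fold changes follow them
    attenuated by ``coupling_beta`` plus noise — looping varies only a few
    fold while coupled phenotypes swing much further.
    """
    cfg = truth.config
    n = n_pairs if n_pairs is not None else len(truth.loop_table)
    ph = rng.normal(0.0, cfg.phenotype_log2fc_sd, size=n)
    lp = cfg.coupling_beta * ph + rng.normal(0.0, cfg.coupling_sigma, size=n)
    ids = list(truth.loop_table.index[:n])
    ids += [f"extra{k}" for k in range(n - len(ids))]
    return pd.DataFrame(
        {"loop_id": ids, "phenotype_log2fc": ph, "loop_log2fc": lp}
    )
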