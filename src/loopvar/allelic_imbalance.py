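"""Haplotype-associated loops (HTALs) from phased Hi-C contacts.

Contacts overlapping phased heterozygous SNVs can be assigned to the
maternal or paternal haplotype; at each loop the two haplotypes' contact
counts are compared with a binomial-normal approximation on the greater
allele (half-normal p-value, since the tested fraction is > 0.5 by
construction), combined across individuals with Fisher's method, and
called genome-wide significant at BH q < 0.05.  A deterministic power
grid over contact depth, imbalance fraction and alpha reproduces the
design calculation for this test; an exact-binomial mode is provided as a
labelled alternative.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .pgl_core import LoopSet

__all__ = [
    "assign_contacts",
    "loop_z",
    "meta_fisher",
    "htal_call",
    "allelic_fold_change",
    "imbalance_table",
    "power_grid",
    "DEFAULT_WINDOW_BP",
]

DEFAULT_WINDOW_BP = 25_000
HTAL_Q = 0.05
_TINY = np.finfo(float).tiny


def assign_contacts(
    contacts: pd.DataFrame,
    loops: LoopSet,
    window_bp: int = DEFAULT_WINDOW_BP,
    individual_col: str = "individual",
) -> pd.DataFrame:
    """Attach haplotype-labelled contacts to loops; count per individual.

    ``contacts`` columns: chrom, pos1, pos2, ``individual_col`` and
    ``hap_labels`` — the haplotype labels of every het SNV the contact
    overlaps, comma-separated ("M"/"P"; empty = no SNV).  A contact is
    informative for a loop iff its ends fall within the two opposing
    anchors each padded by ``window_bp`` and all its SNV labels agree;
    contacts with no label are uninformative and mixed-label contacts are
    discarded as conflicting.

    Returns per-loop, per-individual maternal/paternal counts (loop order
    follows ``loops``; loop_id from the payload "name" when present).
    """
    labels = contacts["hap_labels"].fillna("").astype(str)
    parsed = labels.str.replace(" ", "", regex=False).str.split(",")
    assign = np.full(len(contacts), "uninformative", dtype=object)
    for i, labs in enumerate(parsed):
        labs = [x for x in labs if x]
        if not labs:
            continue
        uniq = set(labs)
        if uniq == {"M"}:
            assign[i] = "maternal"
        elif uniq == {"P"}:
            assign[i] = "paternal"
        else:
            assign[i] = "conflict"
    informative = contacts.loc[(assign == "maternal") | (assign == "paternal")].copy()
    informative["assignment"] = assign[(assign == "maternal") | (assign == "paternal")]

    rows = []
    for li, lp in enumerate(loops):
        loop_id = lp.payload.get("name", f"loop_{li}")
        sub = informative.loc[informative["chrom"] == lp.chrom]
        if len(sub) == 0:
            continue
        p1 = sub["pos1"].to_numpy()
        p2 = sub["pos2"].to_numpy()
        a0, a1 = lp.anchorA.start - window_bp, lp.anchorA.end + window_bp
        b0, b1 = lp.anchorB.start - window_bp, lp.anchorB.end + window_bp
        hit = ((p1 >= a0) & (p1 < a1) & (p2 >= b0) & (p2 < b1)) | (
            (p1 >= b0) & (p1 < b1) & (p2 >= a0) & (p2 < a1)
        )
        if not hit.any():
            continue
        g = sub.loc[hit].groupby([individual_col, "assignment"]).size()
        for ind in g.index.get_level_values(0).unique():
            rows.append(
                {
                    "loop_id": loop_id,
                    "individual": ind,
                    "n_maternal": int(g.get((ind, "maternal"), 0)),
                    "n_paternal": int(g.get((ind, "paternal"), 0)),
                }
            )
    return pd.DataFrame(
        rows, columns=["loop_id", "individual", "n_maternal", "n_paternal"]
    )


def loop_z(n_maternal: int, n_paternal: int) -> tuple[float, float]:
    """Half-normal imbalance test on the greater allele count.

    Z = (k - n/2) / sqrt(n/4) with k the greater of the two counts;
    p = 2 (1 - Phi(Z)), clamped into (0, 1].  n = 0 is an error (such
    records are skipped upstream, not given p = 1).
    """
    n = n_maternal + n_paternal
    if n <= 0:
        raise ValueError("loop_z requires at least one informative contact")
    k = max(n_maternal, n_paternal)
    z = (k - n / 2.0) / np.sqrt(n / 4.0)
    p = float(np.clip(2.0 * stats.norm.sf(z), _TINY, 1.0))
    return float(z), p


def meta_fisher(p_values) -> tuple[float, int, float]:
    """Fisher's method: chi2 = -2 sum(ln p), df = 2k, upper-tail p."""
    p = np.asarray(list(p_values), dtype=float)
    if len(p) == 0:
        raise ValueError("meta_fisher requires at least one p-value")
    if (p <= 0).any():
        import warnings

        warnings.warn("p-values <= 0 clamped to the smallest positive float")
        p = np.maximum(p, _TINY)
    chi2 = float(-2.0 * np.log(p).sum())
    df = 2 * len(p)
    return chi2, df, float(stats.chi2.sf(chi2, df))


def allelic_fold_change(n_maternal: float, n_paternal: float) -> float:
    """log2 of greater over lesser allele count (>= 0 by construction).

    A pseudocount of 0.5 is added to both counts when either is zero.
    """
    a, b = float(n_maternal), float(n_paternal)
    if a == 0 or b == 0:
        a, b = a + 0.5, b + 0.5
    return float(np.log2(max(a, b) / min(a, b)))


def imbalance_table(
    counts: pd.DataFrame, n_min: int = 1, alpha_q: float = HTAL_Q
) -> pd.DataFrame:
    """Per-loop meta-analysis across individuals.

    ``counts``: rows (loop_id, individual, n_maternal, n_paternal).
    Individuals with fewer than ``n_min`` informative contacts at a loop
    are excluded from that loop's meta-analysis; df = 2 x contributors.
    Fold change uses the pooled counts (greater over lesser allele).
    """
    rows = []
    for loop_id, sub in counts.groupby("loop_id", sort=True):
        n = (sub["n_maternal"] + sub["n_paternal"]).to_numpy()
        use = sub.loc[n >= max(n_min, 1)]
        if len(use) == 0:
            continue
        ps = [
            loop_z(int(r.n_maternal), int(r.n_paternal))[1]
            for r in use.itertuples()
        ]
        chi2, df, p_meta = meta_fisher(ps)
        nm, npat = int(use["n_maternal"].sum()), int(use["n_paternal"].sum())
        rows.append(
            {
                "loop_id": loop_id,
                "n_individuals": len(use),
                "chi2": chi2,
                "df": df,
                "p_meta": p_meta,
                "n_maternal": nm,
                "n_paternal": npat,
                "log2_afc": allelic_fold_change(nm, npat),
            }
        )
    out = pd.DataFrame(rows).set_index("loop_id")
    out = htal_call(out, alpha_q=alpha_q)
    return out


def htal_call(meta: pd.DataFrame, alpha_q: float = HTAL_Q) -> pd.DataFrame:
    """BH FDR over all tested loops; HTAL iff q < ``alpha_q``."""
    out = meta.copy()
    out["q"] = stats.false_discovery_control(out["p_meta"].to_numpy(), method="bh")
    out["is_htal"] = out["q"] < alpha_q
    return out


def power_grid(
    n_values=range(5, 101, 5),
    f_values=None,
    alphas=None,
    n_individuals: int = 7,
    mode: str = "deterministic",
) -> pd.DataFrame:
    """Design power to detect allelic imbalance at a loop.

    ``deterministic`` (the default design calculation): the Z score is
    computed from the expected greater-allele count k = f n, its
    half-normal p compared to each alpha; power is 100% when p <= alpha,
    else 0%.  The same table carries the ``power_combined`` column from
    the Fisher meta-p of ``n_individuals`` identical per-individual p's.
    ``binomial`` (labelled alternative, never the default): exact power
    P(p(K) <= alpha) with K ~ Binomial(n, f), by enumeration over k.

    Grid defaults: n = 5..100 step 5; f = 0.55..0.95 step 0.05;
    alpha = a x 10^-x for a in 1..9, x in 2..6.
    """
    if f_values is None:
        f_values = np.round(np.arange(0.55, 0.951, 0.05), 2)
    if alphas is None:
        alphas = sorted(
            float(a) * 10.0 ** (-x) for a in range(1, 10) for x in range(2, 7)
        )
    if mode not in ("deterministic", "binomial"):
        raise ValueError(f"unknown mode: {mode}")
    rows = []
    for n, f in itertools.product(n_values, f_values):
        if f <= 0.5:
            raise ValueError("imbalance fraction must exceed 0.5")
        if mode == "deterministic":
            k = f * n
            z = (k - n / 2.0) / np.sqrt(n / 4.0)
            p = float(np.clip(2.0 * stats.norm.sf(z), _TINY, 1.0))
            _, _, p_meta = meta_fisher([p] * n_individuals)
            for alpha in alphas:
                rows.append(
                    {
                        "n_contacts": n,
                        "f": f,
                        "alpha": alpha,
                        "power_pct": 100.0 if p <= alpha else 0.0,
                        "power_combined_pct": 100.0 if p_meta <= alpha else 0.0,
                    }
                )
        else:
            ks = np.arange(0, n + 1)
            greater = np.maximum(ks, n - ks)
            z = (greater - n / 2.0) / np.sqrt(n / 4.0)
            p_of_k = np.clip(2.0 * stats.norm.sf(z), _TINY, 1.0)
            pmf = stats.binom.pmf(ks, n, f)
            for alpha in alphas:
                rows.append(
                    {
                        "n_contacts": n,
                        "f": f,
                        "alpha": alpha,
                        "power_pct": float(100.0 * pmf[p_of_k <= alpha].sum()),
                    }
                )
    return pd.DataFrame(rows)
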