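"""Diversity, differentiation, genetic distance, NJ trees, and IBD.

Implements the per-population diversity metrics (rarefied allelic richness,
observed/expected heterozygosity, F_IS), the Weir & Cockerham (1984)
variance-components F_ST estimator theta, Nei's D_A genetic distance,
neighbor-joining trees with locus bootstrap support, the Mantel test of
isolation-by-distance on linearized F_ST, and summaries of simulated drift
trajectories (global F_ST / H_t / H_o / H_s by generation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotypes import MISSING, DistanceMatrix, GenotypeMatrix
from .simulate import TrajectoryRecord

# ---------------------------------------------------------------------------
# per-population counts


def _pop_counts(g: GenotypeMatrix) -> tuple[list, np.ndarray, np.ndarray, np.ndarray]:
    """Per population and locus: sample size n, allele freq p, het fraction h.

    Returns (pop order, n (P,L), p (P,L), h (P,L)); entries with n == 0 have
    p = h = NaN.
    """
    pops = g.populations
    P, L = len(pops), g.n_loci
    n = np.zeros((P, L))
    p = np.full((P, L), np.nan)
    h = np.full((P, L), np.nan)
    by_pop = g.by_population()
    for i, pop in enumerate(pops):
        d = g.dosages[by_pop[pop]]
        obs = d != MISSING
        ni = obs.sum(axis=0)
        n[i] = ni
        with np.errstate(invalid="ignore", divide="ignore"):
            p[i] = np.where(ni > 0, np.where(obs, d, 0).sum(axis=0) / (2 * ni), np.nan)
            h[i] = np.where(ni > 0, np.where(obs, d == 1, 0).sum(axis=0) / ni, np.nan)
    return pops, n, p, h


# ---------------------------------------------------------------------------
# diversity


def rarefied_allele_count(counts: Sequence[int], g: int) -> float:
    """Expected number of alleles in a hypergeometric subsample of g genes.

    ``counts`` are the per-allele gene counts at one locus in one population.
    """
    counts = np.asarray(counts, dtype=int)
    tot = counts.sum()
    if g > tot:
        raise ValueError("rarefaction depth exceeds available genes")

    def log_choose(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    ar = 0.0
    for c in counts:
        if c == 0:
            continue
        if tot - c < g:
            pr_absent = 0.0
        else:
            pr_absent = np.exp(log_choose(tot - c, g) - log_choose(tot, g))
        ar += 1.0 - pr_absent
    return float(ar)


def diversity(g: GenotypeMatrix, rarefaction_n: int | None = None) -> pd.DataFrame:
    """Per-population diversity table: n, Ar, Ho, He, Fis.

    Ho is the fraction of heterozygotes; He is Nei's unbiased expected
    heterozygosity ``2n/(2n-1) * 2p(1-p)``; Ar is the expected allele count
    in a rarefied sample of ``rarefaction_n`` genes (default: the smallest
    per-population non-missing gene count over loci); Fis = 1 - Ho/He using
    per-population means over loci.  A population monomorphic at every locus
    has undefined Fis (NaN).
    """
    pops, n, p, h = _pop_counts(g)
    genes = 2 * n
    if rarefaction_n is None:
        positive = genes[genes > 0]
        if positive.size == 0:
            raise ValueError("no genotyped loci in any population")
        rarefaction_n = int(positive.min())
    rows = []
    for i, pop in enumerate(pops):
        ok = n[i] > 0
        ho = float(np.nanmean(h[i, ok]))
        ni = n[i, ok]
        pi = p[i, ok]
        he_l = (2 * ni / (2 * ni - 1)) * 2 * pi * (1 - pi)
        he = float(np.mean(he_l))
        ar_l = []
        for j in np.nonzero(ok)[0]:
            tot = int(2 * n[i, j])
            c1 = int(round(p[i, j] * tot))
            depth = min(rarefaction_n, tot)
            ar_l.append(rarefied_allele_count([c1, tot - c1], depth))
        ar = float(np.mean(ar_l))
        fis = np.nan if he == 0 else 1.0 - ho / he
        rows.append(
            {"population": pop, "n": int(n[i].max()), "Ar": ar, "Ho": ho, "He": he,
             "Fis": fis}
        )
    return pd.DataFrame(rows).set_index("population")


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) theta


def wc_components(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """WC84 per-locus variance components (a, b, c) for biallelic loci.

    Parameters are per-population sample sizes (individuals), allele
    frequencies and observed heterozygote fractions, each of shape
    (n_pops, n_loci).  Populations with n == 0 at a locus are excluded from
    that locus.  Components are the among-population (a), among-individual
    within-population (b) and within-individual (c) terms; theta is
    ``sum(a) / sum(a + b + c)`` over loci.
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    h = np.asarray(h, dtype=float)
    valid = n > 0
    r = valid.sum(axis=0).astype(float)  # populations observed per locus
    n_ = np.where(valid, n, 0.0)
    p_ = np.where(valid, p, 0.0)
    h_ = np.where(valid, h, 0.0)

    nsum = n_.sum(axis=0)
    nbar = nsum / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (nsum - (n_**2).sum(axis=0) / nsum) / (r - 1)
        pbar = (n_ * p_).sum(axis=0) / nsum
        s2 = (n_ * (p_ - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_ * h_).sum(axis=0) / nsum

        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - ((r - 1) / r) * s2
            - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2.0
    # loci monomorphic over all observed pops contribute nothing
    mono = (pbar <= 0) | (pbar >= 1)
    bad = (r < 2) | ~np.isfinite(a)
    for arr in (a, b, c):
        arr[mono | bad] = 0.0
    return a, b, c


@dataclass
class FstResult:
    """Global and pairwise Weir-Cockerham theta with per-locus components."""

    global_theta: float
    pairwise: DistanceMatrix
    components: tuple[np.ndarray, np.ndarray, np.ndarray]


def theta_from_components(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    denom = (a + b + c).sum()
    if denom == 0:
        return np.nan
    return float(a.sum() / denom)


def wc_fst(g: GenotypeMatrix, pops: Sequence | None = None) -> FstResult:
    """Weir & Cockerham (1984) theta, global and for every population pair."""
    all_pops, n, p, h = _pop_counts(g)
    if pops is not None:
        idx = [all_pops.index(q) for q in pops]
        all_pops = [all_pops[i] for i in idx]
        n, p, h = n[idx], p[idx], h[idx]
    if len(all_pops) < 2:
        raise ValueError("need at least two populations for FST")
    a, b, c = wc_components(n, p, h)
    global_theta = theta_from_components(a, b, c)
    P = len(all_pops)
    pw = np.zeros((P, P))
    for i in range(P):
        for j in range(i + 1, P):
            ai, bi, ci = wc_components(n[[i, j]], p[[i, j]], h[[i, j]])
            pw[i, j] = pw[j, i] = theta_from_components(ai, bi, ci)
    return FstResult(global_theta, DistanceMatrix(all_pops, pw), (a, b, c))


def global_theta_from_freqs(
    freqs: np.ndarray,
    pop_sizes: Sequence[int],
    rng: np.random.Generator | None = None,
    sample_n: int | Sequence[int] | None = None,
) -> float:
    """Global theta from population allele frequencies.

    ``sample_n`` is the per-population number of diploid individuals the
    estimator sees (default 25 each, capped at the population size, matching
    the study's equal-sample design; pass ``pop_sizes`` to census the whole
    population).  When ``rng`` is given, Hardy-Weinberg genotype counts are
    materialized for those individuals; otherwise the HW expectations
    (p^2, 2pq, q^2) are used directly, which is the same in expectation and
    deterministic.
    """
    freqs = np.asarray(freqs, dtype=float)
    P, L = freqs.shape
    sizes = np.asarray(pop_sizes, dtype=np.int64)
    if sample_n is None:
        ns = np.minimum(sizes, 25)
    else:
        ns = np.broadcast_to(np.asarray(sample_n, dtype=np.int64), (P,)).copy()
        ns = np.minimum(ns, sizes)
    if rng is None:
        p, h = freqs, 2 * freqs * (1 - freqs)
    else:
        N = ns[:, None]
        n_aa = rng.binomial(N, freqs**2 * np.ones((P, L)))
        rest = N - n_aa
        with np.errstate(invalid="ignore", divide="ignore"):
            cond = np.where(freqs < 1, 2 * freqs * (1 - freqs) / (1 - freqs**2), 0.0)
        n_het = rng.binomial(rest, np.clip(cond, 0, 1))
        p = (2 * n_aa + n_het) / (2 * N)
        h = n_het / N
    ns_mat = ns[:, None].astype(float) * np.ones((1, L))
    a, b, c = wc_components(ns_mat, p, h)
    return theta_from_components(a, b, c)


# ---------------------------------------------------------------------------
# Nei's DA distance and neighbor-joining


def _pop_freqs(g: GenotypeMatrix) -> tuple[list, np.ndarray]:
    pops, n, p, _ = _pop_counts(g)
    return pops, p


def nei_da_from_freqs(px: np.ndarray, py: np.ndarray) -> float:
    """D_A between two populations' biallelic frequency vectors."""
    ok = np.isfinite(px) & np.isfinite(py)
    if not ok.any():
        return np.nan
    px, py = px[ok], py[ok]
    shared = np.sqrt(px * py) + np.sqrt((1 - px) * (1 - py))
    return float(1.0 - shared.mean())


def nei_da(g: GenotypeMatrix) -> DistanceMatrix:
    """Nei, Tajima & Tateno (1983) D_A distance between all population pairs."""
    pops, p = _pop_freqs(g)
    if len(pops) < 2:
        raise ValueError("need at least two populations for DA")
    P = len(pops)
    d = np.zeros((P, P))
    for i in range(P):
        for j in range(i + 1, P):
            d[i, j] = d[j, i] = nei_da_from_freqs(p[i], p[j])
    return DistanceMatrix(pops, d)


def _nj_newick(d: DistanceMatrix) -> "object":
    from skbio import DistanceMatrix as SkDM
    from skbio.tree import nj

    # skbio requires strictly valid hollow matrices
    vals = np.array(d.values, dtype=float)
    np.fill_diagonal(vals, 0.0)
    return nj(SkDM(vals, ids=[str(l) for l in d.labels]))


def _bipartitions(tree, taxa: frozenset) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree, as canonical tip sets."""
    parts = set()
    for node in tree.non_tips(include_self=False):
        tips = frozenset(t.name for t in node.tips())
        comp = taxa - tips
        if len(tips) < 2 or len(comp) < 2:
            continue
        parts.add(min(tips, comp, key=lambda s: (len(s), sorted(s))))
    return parts


def nj_tree(
    d: DistanceMatrix,
    bootstrap: int = 0,
    g: GenotypeMatrix | None = None,
    seed: int = 0,
) -> str:
    """Neighbor-joining tree on D_A; optional locus-bootstrap clade support.

    With ``bootstrap > 0`` (requires ``g``), loci are resampled with
    replacement, D_A and the NJ tree recomputed, and each internal node of
    the original tree is labelled with the percentage of bootstrap trees
    containing its bipartition.  Returns a newick string.
    """
    if len(d.labels) < 3:
        raise ValueError("need at least 3 taxa for an unrooted NJ tree")
    tree = _nj_newick(d)
    if bootstrap > 0:
        if g is None:
            raise ValueError("bootstrap requires the genotype matrix")
        rng = np.random.default_rng(seed)
        taxa = frozenset(str(l) for l in d.labels)
        counts: dict[frozenset, int] = {}
        for _ in range(bootstrap):
            take = rng.integers(0, g.n_loci, size=g.n_loci)
            gb = GenotypeMatrix(  # fresh locus ids: resampling duplicates loci
                dosages=g.dosages[:, take],
                pop_labels=g.pop_labels,
                locus_ids=np.array([f"b{j}" for j in range(g.n_loci)], dtype=object),
            )
            bd = nei_da(gb)
            for part in _bipartitions(_nj_newick(bd), taxa):
                counts[part] = counts.get(part, 0) + 1
        for node in tree.non_tips(include_self=False):
            tips = frozenset(t.name for t in node.tips())
            comp = taxa - tips
            if len(tips) < 2 or len(comp) < 2:
                continue
            key = min(tips, comp, key=lambda s: (len(s), sorted(s)))
            node.name = str(round(100.0 * counts.get(key, 0) / bootstrap))
    return str(tree).strip()


# ---------------------------------------------------------------------------
# Mantel isolation-by-distance


@dataclass
class MantelResult:
    slope: float
    correlation: float
    p_value: float
    n_permutations: int


def mantel_ibd(
    fst: DistanceMatrix,
    dist: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
) -> MantelResult:
    """One-tailed Mantel test of linearized F_ST against waterway distance.

    The genetic matrix is linearized as FST/(1-FST) before testing; the
    permutation p-value is ``(#{permuted r >= observed r} + 1)/(n_perm+1)``,
    one-tailed for positive isolation-by-distance.
    """
    if list(fst.labels) != list(dist.labels):
        order = [fst.labels.index(l) for l in dist.labels]
        if sorted(fst.labels) != sorted(dist.labels):
            raise ValueError("matrix labels do not match")
        fst = DistanceMatrix(dist.labels, fst.values[np.ix_(order, order)])
    vals = fst.values
    if np.any(vals >= 1.0):
        raise ValueError(
            "FST = 1 entries linearize to infinity; drop those population pairs"
        )
    lin = vals / (1.0 - vals)
    k = len(dist.labels)
    iu = np.triu_indices(k, 1)
    x = lin[iu]
    y = dist.values[iu]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate (constant) distance matrix: r undefined")
    r_obs = float(np.corrcoef(x, y)[0, 1])
    slope = float(np.polyfit(y, x, 1)[0])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(k)
        xp = lin[np.ix_(perm, perm)][iu]
        if np.corrcoef(xp, y)[0, 1] >= r_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return MantelResult(slope, r_obs, p, n_perm)


# ---------------------------------------------------------------------------
# drift-trajectory summaries


def trajectory_summaries(
    records: Iterable[TrajectoryRecord],
    pop_sizes: Sequence[int],
) -> pd.DataFrame:
    """Summaries of simulated drift by generation, across replicates.

    For each generation: mean and SD over replicates of global theta, pooled
    expected heterozygosity H_t (from the metapopulation mean frequency),
    global observed heterozygosity H_o (expected heterozygote fraction
    pooled over populations), and mean local observed heterozygosity H_s.
    SD columns are NaN with a single replicate.
    """
    pop_sizes = np.asarray(pop_sizes, dtype=float)
    w = pop_sizes / pop_sizes.sum()
    per_gen: dict[int, dict[str, list[float]]] = {}
    for rec in records:
        f = rec.freqs
        het = 2 * f * (1 - f)
        pbar = w @ f
        entry = per_gen.setdefault(
            rec.generation, {"fst": [], "ht": [], "ho": [], "hs": []}
        )
        entry["fst"].append(global_theta_from_freqs(f, pop_sizes.astype(int)))
        entry["ht"].append(float(np.mean(2 * pbar * (1 - pbar))))
        entry["ho"].append(float(np.mean(w @ het)))
        entry["hs"].append(float(np.mean(het)))
    rows = []
    for gen in sorted(per_gen):
        e = per_gen[gen]
        row = {"generation": gen, "n_replicates": len(e["fst"])}
        for key, name in (("fst", "global_fst"), ("ht", "Ht"), ("ho", "Ho"), ("hs", "Hs")):
            arr = np.asarray(e[key])
            row[f"{name}_mean"] = float(arr.mean())
            row[f"{name}_sd"] = float(arr.std(ddof=1)) if len(arr) > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def first_crossing(
    table: pd.DataFrame, threshold: float, column: str = "global_fst_mean"
) -> float:
    """First generation at which the mean trajectory reaches ``threshold``.

    Linear interpolation between tabulated generations; NaN if never reached.
    """
    gens = table["generation"].to_numpy(dtype=float)
    vals = table[column].to_numpy(dtype=float)
    above = vals >= threshold
    if not above.any():
        return float("nan")
    i = int(np.argmax(above))
    if i == 0:
        return float(gens[0])
    g0, g1 = gens[i - 1], gens[i]
    v0, v1 = vals[i - 1], vals[i]
    if v1 == v0:
        return float(g1)
    return float(g0 + (threshold - v0) * (g1 - g0) / (v1 - v0))
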