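"""Maximum-likelihood admixture model: EM fitting, cross-validated K,
label-switching alignment, and population-level Q averaging.

The model is the standard unsupervised admixture likelihood for unlinked
biallelic loci: individual i carries ancestry proportions q_i (summing to
one over K clusters), cluster k has allele frequency f_kj at locus j, and
the diploid dosage g_ij is Binomial(2, sum_k q_ik f_kj).  Fitting is by EM
(FRAPPE-style multiplicative updates), which increases the log-likelihood
monotonically — a property the tests assert on every fit.  The number of
clusters is chosen by masking a fraction of genotype entries, refitting,
and scoring held-out binomial deviance (the cross-validation scheme of the
widely used admixture software).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .genotypes import MISSING, GenotypeMatrix

_F_EPS = 1e-6  # keeps cluster frequencies off 0/1 so log-likelihood is finite


@dataclass
class AncestryFit:
    """Result of one admixture-model fit."""

    K: int
    Q: np.ndarray  # (n, K) ancestry proportions, rows sum to 1
    F: np.ndarray  # (K, L) cluster allele frequencies
    loglik: float
    n_iter: int
    converged: bool
    seed: int
    loglik_history: np.ndarray = field(default=None, repr=False)


def _loglik(G, W, Q, F) -> float:
    P = np.clip(Q @ F, 1e-12, 1 - 1e-12)
    Gz = np.where(W, G, 0.0)
    return float(np.sum(Gz * np.log(P) + np.where(W, 2.0 - G, 0.0) * np.log1p(-P)))


def _em_once(
    G: np.ndarray,
    W: np.ndarray,
    K: int,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    n, L = G.shape
    Q = rng.dirichlet(np.ones(K), size=n)
    F = rng.uniform(0.05, 0.95, size=(K, L))
    Gz = np.where(W, G, 0.0)
    G2z = np.where(W, 2.0 - G, 0.0)
    ll_hist = []
    ll_prev = -np.inf
    converged = False
    for it in range(max_iter + 1):
        P = np.clip(Q @ F, 1e-12, 1 - 1e-12)
        ll = float(np.sum(Gz * np.log(P) + G2z * np.log1p(-P)))
        if not np.isfinite(ll):
            raise FloatingPointError(f"non-finite log-likelihood at iteration {it}")
        ll_hist.append(ll)
        # (Q, F) producing the last history entry are the ones returned
        if it > 0 and abs(ll - ll_prev) <= tol * abs(ll):
            converged = True
            break
        if it == max_iter:
            break
        ll_prev = ll
        R0 = Gz / P
        R1 = G2z / (1.0 - P)
        Qn = Q * (R0 @ F.T + R1 @ (1.0 - F).T)
        Qn /= Qn.sum(axis=1, keepdims=True)
        num = F * (Q.T @ R0)
        den = num + (1.0 - F) * (Q.T @ R1)
        with np.errstate(invalid="ignore", divide="ignore"):
            Fn = np.where(den > 0, num / den, F)
        Q, F = Qn, np.clip(Fn, _F_EPS, 1.0 - _F_EPS)
    return Q, F, np.asarray(ll_hist), converged


def fit_admixture(
    g: GenotypeMatrix,
    K: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 1000,
    n_restarts: int = 1,
) -> AncestryFit:
    """Fit the admixture model for a fixed K by EM.

    Missing genotypes are excluded from the likelihood; each restart draws a
    fresh random start (Dirichlet Q, uniform F) and the best final
    log-likelihood is kept.  K = 1 is solved in closed form (F equals the
    sample allele frequencies).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > g.n_individuals:
        raise ValueError(f"K={K} exceeds the number of individuals ({g.n_individuals})")
    G = g.dosages.astype(float)
    W = g.dosages != MISSING
    if K == 1:
        p = g.allele_freq()
        p = np.where(np.isfinite(p), p, 0.5)
        F = np.clip(p, _F_EPS, 1 - _F_EPS)[None, :]
        Q = np.ones((g.n_individuals, 1))
        ll = _loglik(G, W, Q, F)
        return AncestryFit(1, Q, F, ll, 0, True, seed, np.asarray([ll]))
    best = None
    for r in range(n_restarts):
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(r,))
        rng = np.random.default_rng(ss)
        Q, F, hist, conv = _em_once(G, W, K, rng, tol, max_iter)
        if best is None or hist[-1] > best.loglik:
            best = AncestryFit(K, Q, F, float(hist[-1]), len(hist), conv, seed, hist)
    return best


def predict_dosage(fit: AncestryFit) -> np.ndarray:
    """Model-expected dosage 2 * sum_k q_ik f_kj."""
    return 2.0 * (fit.Q @ fit.F)


def cv_error(
    g: GenotypeMatrix,
    K: int,
    folds: int = 5,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> float:
    """Masked-entry cross-validation error for one K.

    Non-missing genotype entries are partitioned into ``folds`` random
    folds; each fold is masked in turn, the model refit from scratch, and
    the masked entries scored by mean binomial deviance between the
    observed dosage and the model-expected dosage.  Returns the mean over
    folds.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    obs_i, obs_j = np.nonzero(g.dosages != MISSING)
    n_obs = len(obs_i)
    rng = np.random.default_rng(seed)
    assign = rng.permutation(n_obs) % folds
    errors = []
    for f in range(folds):
        mask = assign == f
        gm = GenotypeMatrix(
            dosages=g.dosages.copy(),
            pop_labels=g.pop_labels,
            locus_ids=g.locus_ids,
            ind_ids=g.ind_ids,
        )
        gm.dosages[obs_i[mask], obs_j[mask]] = MISSING
        # a locus fully masked has unidentifiable frequency; skip its entries
        informative = (gm.dosages != MISSING).any(axis=0)
        fit = fit_admixture(gm, K, seed=seed * folds + f, tol=tol, max_iter=max_iter)
        ghat = np.clip(predict_dosage(fit), 1e-9, 2 - 1e-9)
        gi, gj = obs_i[mask], obs_j[mask]
        keep = informative[gj]
        gi, gj = gi[keep], gj[keep]
        gobs = g.dosages[gi, gj].astype(float)
        gpre = ghat[gi, gj]
        with np.errstate(invalid="ignore", divide="ignore"):
            t1 = np.where(gobs > 0, gobs * np.log(gobs / gpre), 0.0)
            t2 = np.where(gobs < 2, (2 - gobs) * np.log((2 - gobs) / (2 - gpre)), 0.0)
        errors.append(float(np.mean(t1 + t2)))
    return float(np.mean(errors))


@dataclass
class CVResult:
    """Cross-validation errors over a K range."""

    errors: dict[int, float]

    @property
    def best_K(self) -> int:
        return min(self.errors, key=lambda k: (self.errors[k], k))


def cv_scan(
    g: GenotypeMatrix,
    k_range: range | list[int],
    folds: int = 5,
    seed: int = 0,
    **fit_kw,
) -> CVResult:
    """Cross-validation error for each K in ``k_range``."""
    return CVResult({int(K): cv_error(g, int(K), folds, seed, **fit_kw) for K in k_range})


# ---------------------------------------------------------------------------
# label-switching alignment


def _column_cost(Qa: np.ndarray, Qb: np.ndarray) -> np.ndarray:
    """K x K cost matrix of 1 - Pearson correlation between Q columns."""
    K = Qa.shape[1]
    A = Qa - Qa.mean(axis=0)
    B = Qb - Qb.mean(axis=0)
    sa = np.sqrt((A**2).sum(axis=0))
    sb = np.sqrt((B**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (A.T @ B) / np.outer(sa, sb)
    corr[~np.isfinite(corr)] = 0.0
    cost = 1.0 - corr
    # exact ties resolve toward the identity permutation
    cost[np.diag_indices(K)] -= 1e-12
    return cost


def permute_fit(fit: AncestryFit, perm: np.ndarray) -> AncestryFit:
    """Relabel clusters: new column k is old column perm[k]."""
    return AncestryFit(
        K=fit.K,
        Q=fit.Q[:, perm],
        F=fit.F[perm],
        loglik=fit.loglik,
        n_iter=fit.n_iter,
        converged=fit.converged,
        seed=fit.seed,
        loglik_history=fit.loglik_history,
    )


def align_replicates(
    fits: list[AncestryFit], reference: AncestryFit | None = None
) -> tuple[list[AncestryFit], list[np.ndarray]]:
    """Align cluster labels across replicate fits.

    Each fit's columns are permuted to maximize the summed column-wise
    correlation with the reference (the first fit unless given), solving the
    K x K assignment problem exactly.  Returns the aligned fits and the
    permutation applied to each (new column k <- old column perm[k]).
    """
    if not fits:
        return [], []
    ref = reference if reference is not None else fits[0]
    if any(f.K != ref.K for f in fits):
        raise ValueError("all fits must share K")
    aligned = []
    perms = []
    for f in fits:
        cost = _column_cost(ref.Q, f.Q)
        _, cols = linear_sum_assignment(cost)
        aligned.append(permute_fit(f, cols))
        perms.append(cols)
    return aligned, perms


def average_q(fits: list[AncestryFit], pop_labels: np.ndarray) -> pd.DataFrame:
    """Mean Q per population per cluster, across individuals and replicates.

    Fits must already be aligned and share the individual ordering that
    ``pop_labels`` describes.  Rows sum to 1.
    """
    if not fits:
        raise ValueError("no fits to average")
    Qbar = np.mean([f.Q for f in fits], axis=0)
    df = pd.DataFrame(Qbar, columns=[f"cluster{k}" for k in range(fits[0].K)])
    df["population"] = np.asarray(pop_labels, dtype=object)
    out = df.groupby("population", sort=False).mean()
    return out


def map_populations_to_clusters(mean_q: pd.DataFrame) -> dict:
    """Optimal one-to-one mapping of populations to their dominant clusters.

    Solves the assignment problem maximizing the summed mean-Q "diagonal";
    never greedy, so two populations cannot claim the same cluster.  Exact
    cost ties resolve to the lower cluster index.
    """
    M = mean_q.to_numpy()
    cost = -M.copy()
    k = min(cost.shape)
    cost[np.diag_indices(k)] -= 1e-12
    rows, cols = linear_sum_assignment(cost)
    return {mean_q.index[r]: int(c) for r, c in zip(rows, cols)}


def distinct_cluster_assignment(
    mean_q_by_gen: dict[int, pd.DataFrame],
    reference_generation: int | None = None,
) -> pd.DataFrame:
    """Per-population assignment to its eventual distinct cluster, by generation.

    The population -> cluster mapping is fixed on the reference (by default
    the last) generation's mean-Q table and then read off at every
    generation.  Returns a long table (population, generation, assignment).
    """
    gens = sorted(mean_q_by_gen)
    ref_gen = reference_generation if reference_generation is not None else gens[-1]
    mapping = map_populations_to_clusters(mean_q_by_gen[ref_gen])
    rows = []
    for gen in gens:
        mq = mean_q_by_gen[gen]
        for pop, k in mapping.items():
            rows.append(
                {"population": pop, "generation": gen,
                 "assignment": float(mq.iloc[list(mq.index).index(pop), k]),
                 "cluster": k}
            )
    return pd.DataFrame(rows)
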