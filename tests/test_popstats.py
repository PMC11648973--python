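"""Diversity, FST, DA, NJ trees, Mantel, trajectory summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from popdrift.genotypes import MISSING, DistanceMatrix, GenotypeMatrix
from popdrift import popstats
from popdrift.popstats import (
    diversity,
    first_crossing,
    mantel_ibd,
    nei_da,
    nei_da_from_freqs,
    nj_tree,
    rarefied_allele_count,
    trajectory_summaries,
    wc_components,
    wc_fst,
)

from conftest import random_matrix


def _gm(dosages, pops, loci=None):
    dosages = np.asarray(dosages, dtype=np.int8)
    loci = loci or [f"l{j}" for j in range(dosages.shape[1])]
    return GenotypeMatrix(dosages, np.asarray(pops, dtype=object),
                          np.asarray(loci, dtype=object))


class TestDiversity:
    def test_all_heterozygote_population(self):
        g = _gm(np.ones((6, 4)), ["p"] * 6)
        t = diversity(g)
        assert t.loc["p", "Ho"] == 1.0
        assert t.loc["p", "Fis"] < 0

    def test_monomorphic_locus(self):
        g = _gm(np.zeros((5, 3)), ["p"] * 5)
        t = diversity(g)
        assert t.loc["p", "Ar"] == 1.0
        assert t.loc["p", "He"] == 0.0
        assert np.isnan(t.loc["p", "Fis"])

    def test_rarefaction_matches_exhaustive_enumeration(self):
        # 5 individuals, allele counts 3/7 at one locus; enumerate all
        # C(10, g) gene subsamples and average the allele count
        counts = [3, 7]
        genes = [0] * 3 + [1] * 7
        for depth in (2, 4, 6):
            vals = [len(set(s)) for s in itertools.combinations(genes, depth)]
            assert rarefied_allele_count(counts, depth) == pytest.approx(
                np.mean(vals), abs=1e-12
            )

    def test_rarefied_richness_monotone_in_depth(self):
        g = random_matrix(8, 15, missing_rate=0.0, seed=3)
        a2 = diversity(g, rarefaction_n=2)["Ar"]
        a6 = diversity(g, rarefaction_n=6)["Ar"]
        a12 = diversity(g, rarefaction_n=12)["Ar"]
        assert (a2 <= a6 + 1e-12).all() and (a6 <= a12 + 1e-12).all()

    def test_unbiased_he_correction(self):
        # one locus, p=0.5, n=2 -> He = (4/3) * 0.5 = 2/3
        g = _gm([[0], [2]], ["p", "p"])
        assert diversity(g).loc["p", "He"] == pytest.approx(2 / 3)


def brute_force_wc(n, p, h):
    """Loop-based WC84 components, straight from the published formulas."""
    a_l, b_l, c_l = [], [], []
    for j in range(p.shape[1]):
        use = n[:, j] > 0
        r = use.sum()
        ni = n[use, j]
        pi = p[use, j]
        hi = h[use, j]
        nbar = ni.mean()
        pbar = (ni * pi).sum() / (r * nbar)
        if r < 2 or pbar <= 0 or pbar >= 1:
            a_l.append(0.0); b_l.append(0.0); c_l.append(0.0)
            continue
        nc = (r * nbar - (ni**2).sum() / (r * nbar)) / (r - 1)
        s2 = (ni * (pi - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (ni * hi).sum() / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                           / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        a_l.append(a); b_l.append(b); c_l.append(c)
    return np.array(a_l), np.array(b_l), np.array(c_l)


class TestWcFst:
    def test_identical_hw_populations_near_zero(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.2, 0.8, 500)
        d = np.vstack([
            rng.binomial(1, p, (25, 500)) + rng.binomial(1, p, (25, 500))
            for _ in range(3)
        ]).astype(np.int8)
        g = _gm(d, ["a"] * 25 + ["b"] * 25 + ["c"] * 25)
        assert abs(wc_fst(g).global_theta) < 0.02

    def test_fixed_alternative_alleles_is_one(self):
        d = np.vstack([np.zeros((10, 20)), np.full((10, 20), 2)])
        g = _gm(d, ["a"] * 10 + ["b"] * 10)
        assert wc_fst(g).global_theta == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 15, size=(3, 5)).astype(float)
        p = rng.uniform(0, 1, size=(3, 5))
        h = np.minimum(rng.uniform(0, 1, size=(3, 5)), 2 * p * (1 - p) + 0.2)
        a, b, c = wc_components(n, p, h)
        ae, be, ce = brute_force_wc(n, p, h)
        np.testing.assert_allclose(a, ae, atol=1e-10)
        np.testing.assert_allclose(b, be, atol=1e-10)
        np.testing.assert_allclose(c, ce, atol=1e-10)

    def test_pairwise_matrix_symmetric(self):
        g = random_matrix(30, 40, n_pops=3, missing_rate=0.05, seed=1)
        r = wc_fst(g)
        assert np.allclose(r.pairwise.values, r.pairwise.values.T)


class TestNeiDa:
    def test_identical_frequencies_zero(self):
        assert nei_da_from_freqs(np.array([0.3, 0.7]), np.array([0.3, 0.7])) == 0

    def test_fixed_alternative_is_one(self):
        d = np.vstack([np.zeros((5, 10)), np.full((5, 10), 2)])
        g = _gm(d, ["a"] * 5 + ["b"] * 5)
        assert nei_da(g).values[0, 1] == pytest.approx(1.0)

    def test_two_locus_hand_computation(self):
        x = np.array([0.2, 0.8])
        y = np.array([0.6, 0.4])
        # per locus: sqrt(px*py) + sqrt((1-px)(1-py))
        l1 = np.sqrt(0.2 * 0.6) + np.sqrt(0.8 * 0.4)
        l2 = np.sqrt(0.8 * 0.4) + np.sqrt(0.2 * 0.6)
        assert nei_da_from_freqs(x, y) == pytest.approx(1 - (l1 + l2) / 2)

    def test_symmetry_and_bounds(self):
        g = random_matrix(20, 30, n_pops=3, seed=2)
        d = nei_da(g)
        assert np.allclose(d.values, d.values.T)
        assert (d.values >= 0).all() and (d.values <= 1).all()


def _tree_distances(newick):
    """Leaf-to-leaf path lengths parsed with scikit-bio."""
    from io import StringIO
    from skbio import TreeNode

    t = TreeNode.read(StringIO(newick))
    tips = sorted(x.name for x in t.tips())
    return {
        (a, b): t.find(a).distance(t.find(b))
        for a, b in itertools.combinations(tips, 2)
    }


class TestNjTree:
    def test_three_taxon_branch_lengths_solve_three_point_formulas(self):
        d = DistanceMatrix(["A", "B", "C"],
                           np.array([[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]]))
        nwk = nj_tree(d)
        dist = _tree_distances(nwk)
        assert dist[("A", "B")] == pytest.approx(0.4, abs=1e-6)
        assert dist[("A", "C")] == pytest.approx(0.6, abs=1e-6)
        assert dist[("B", "C")] == pytest.approx(0.8, abs=1e-6)

    def test_recovers_additive_five_taxon_topology(self):
        # tree ((A:1,B:2):1,(C:1.5,D:0.5):2,E:3) -> additive distances
        dd = {
            ("A", "B"): 3, ("A", "C"): 4.5, ("A", "D"): 3.5, ("A", "E"): 5,
            ("B", "C"): 5.5, ("B", "D"): 4.5, ("B", "E"): 6,
            ("C", "D"): 2, ("C", "E"): 6.5, ("D", "E"): 5.5,
        }
        labels = ["A", "B", "C", "D", "E"]
        m = np.zeros((5, 5))
        for (x, y), v in dd.items():
            i, j = labels.index(x), labels.index(y)
            m[i, j] = m[j, i] = v
        nwk = nj_tree(DistanceMatrix(labels, m))
        dist = _tree_distances(nwk)
        for pair, v in dd.items():
            assert dist[pair] == pytest.approx(v, abs=1e-6)

    def test_fewer_than_three_taxa_rejected(self):
        d = DistanceMatrix(["A", "B"], np.array([[0, 1.0], [1.0, 0]]))
        with pytest.raises(ValueError):
            nj_tree(d)

    def test_bootstrap_supports_clear_split(self):
        rng = np.random.default_rng(3)
        # two diverged groups of two populations each
        base = rng.uniform(0.1, 0.9, 60)
        shift = np.clip(base + 0.6 * np.sign(base - 0.5) * -1, 0.02, 0.98)
        def sample(p):
            return (rng.binomial(1, p, (12, 60)) + rng.binomial(1, p, (12, 60)))
        d = np.vstack([sample(base), sample(base), sample(shift), sample(shift)])
        g = _gm(d.astype(np.int8), sum([[x] * 12 for x in "abcd"], []))
        da = nei_da(g)
        nwk = nj_tree(da, bootstrap=50, g=g, seed=0)
        assert any(ch.isdigit() for ch in nwk)  # support labels present
        nwk0 = nj_tree(da, bootstrap=0)
        assert ")100" not in nwk0 and ")5" not in nwk0


class TestMantel:
    def _dm(self, vals, labels):
        return DistanceMatrix(labels, np.asarray(vals, dtype=float))

    def test_proportional_matrices_give_r_one_min_p(self):
        labels = list("abcde")
        rng = np.random.default_rng(4)
        fst = np.zeros((5, 5))
        iu = np.triu_indices(5, 1)
        fst[iu] = rng.uniform(0.05, 0.3, len(iu[0]))
        fst += fst.T
        lin = fst / (1 - fst)
        res = mantel_ibd(self._dm(fst, labels), self._dm(lin * 3.7, labels),
                         n_perm=99, seed=0)
        assert res.correlation == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_fst_of_one_rejected_with_guidance(self):
        labels = list("abc")
        fst = np.array([[0, 1.0, 0.2], [1.0, 0, 0.2], [0.2, 0.2, 0]])
        dist = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError, match="drop"):
            mantel_ibd(self._dm(fst, labels), self._dm(dist, labels))

    def test_constant_distances_rejected(self):
        labels = list("abcd")
        fst = np.full((4, 4), 0.1); np.fill_diagonal(fst, 0)
        dist = np.full((4, 4), 2.0); np.fill_diagonal(dist, 0)
        with pytest.raises(ValueError, match="undefined|constant"):
            mantel_ibd(self._dm(fst, labels), self._dm(dist, labels))

    def test_agrees_with_skbio_correlation(self):
        from skbio.stats.distance import mantel as sk_mantel
        from skbio import DistanceMatrix as SkDM

        labels = list("abcdef")
        rng = np.random.default_rng(5)
        def rand_dm():
            m = np.zeros((6, 6))
            iu = np.triu_indices(6, 1)
            m[iu] = rng.uniform(0.01, 0.4, len(iu[0]))
            return m + m.T
        fst, dist = rand_dm(), rand_dm()
        res = mantel_ibd(self._dm(fst, labels), self._dm(dist, labels),
                         n_perm=199, seed=0)
        lin = fst / (1 - fst)
        r_sk, _, _ = sk_mantel(SkDM(lin, labels), SkDM(dist, labels),
                               permutations=0)
        assert res.correlation == pytest.approx(float(r_sk), abs=1e-10)

    def test_type_one_error_rate_near_alpha(self):
        # independent matrices: rejection rate at alpha=.05 within binomial CI
        rng = np.random.default_rng(6)
        labels = list("abcdefgh")
        rejections = 0
        trials = 200
        for t in range(trials):
            def rand_dm():
                m = np.zeros((8, 8))
                iu = np.triu_indices(8, 1)
                m[iu] = rng.uniform(0.01, 0.4, len(iu[0]))
                return m + m.T
            res = mantel_ibd(self._dm(rand_dm(), labels),
                             self._dm(rand_dm(), labels), n_perm=99, seed=t)
            rejections += res.p_value <= 0.05
        rate = rejections / trials
        assert 0.05 - 3 * np.sqrt(0.05 * 0.95 / trials) <= rate \
            <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / trials) + 0.01


class TestTrajectories:
    def _records(self, reps=3, seed=0):
        from popdrift.simulate import SimulationConfig, run_simulation

        cfg = SimulationConfig(pop_sizes=(30, 50, 80), pop_labels=("a", "b", "c"),
                               n_loci=300, checkpoints=(0, 5, 15, 30),
                               n_replicates=reps, seed=seed)
        return list(run_simulation(cfg, emit_genotypes=False)), cfg

    def test_founding_generation_undifferentiated(self):
        recs, cfg = self._records()
        t = trajectory_summaries(recs, cfg.pop_sizes)
        g0 = t[t.generation == 0].iloc[0]
        assert abs(g0.global_fst_mean) < 0.02
        assert g0.Hs_mean == pytest.approx(0.5, abs=0.02)

    def test_fst_monotone_in_generation(self):
        recs, cfg = self._records(reps=5)
        t = trajectory_summaries(recs, cfg.pop_sizes)
        fst = t.sort_values("generation").global_fst_mean.to_numpy()
        assert (np.diff(fst) > -0.005).all() and fst[-1] > fst[0]

    def test_single_replicate_sd_is_missing(self):
        recs, cfg = self._records(reps=1)
        t = trajectory_summaries(recs, cfg.pop_sizes)
        assert t.global_fst_sd.isna().all()

    def test_first_crossing_interpolates(self):
        tab = pd.DataFrame({"generation": [0, 10, 20],
                            "global_fst_mean": [0.0, 0.1, 0.2]})
        assert first_crossing(tab, 0.15) == pytest.approx(15.0)
        assert np.isnan(first_crossing(tab, 0.5))
        assert first_crossing(tab, 0.0) == 0.0
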