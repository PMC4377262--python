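"""theta, genotypic differentiation, Da distances and neighbor joining."""

import itertools
import math
from io import StringIO

import numpy as np
import pytest

from margin_adapt import (GenotypeMatrix, bootstrap_theta_ci,
                          genotypic_differentiation_test, nei_da_matrix,
                          neighbor_joining, weir_cockerham_theta)
from margin_adapt.differentiation import (DistanceMatrixDa, UndefinedThetaError,
                                          nj_bootstrap_support)
from .conftest import random_genotype_matrix


def make_matrix(pop_calls: dict[str, list]) -> GenotypeMatrix:
    inds, pops, rows = [], [], []
    for pop, calls in pop_calls.items():
        for i, c in enumerate(calls):
            inds.append(f"{pop}_{i}")
            pops.append(pop)
            rows.append(c)
    calls = np.array(rows, dtype=np.int32)
    if calls.ndim == 2:
        calls = calls[:, None, :]
    loci = [f"L{j + 1}" for j in range(calls.shape[1])]
    return GenotypeMatrix(inds, loci, pops, calls)


def theta_oracle(geno: GenotypeMatrix) -> float:
    """Independent plain-loop transcription of the 1984 component formulas."""
    num = den = 0.0
    pops = geno.sample_names
    for j in range(geno.n_loci):
        data = []
        for s in pops:
            calls = geno.calls[geno.sample_index(s), j, :]
            calls = [tuple(c) for c in calls if 0 not in c]
            if calls:
                data.append(calls)
        r = len(data)
        if r < 2:
            continue
        ns = [len(d) for d in data]
        nbar = sum(ns) / r
        if nbar <= 1:
            continue
        alleles = sorted({a for d in data for pair in d for a in pair})
        if len(alleles) < 2:
            continue
        nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
        for u in alleles:
            p = [sum(pair.count(u) for pair in d) / (2 * len(d)) for d in data]
            h = [sum(1 for pair in d if pair[0] != pair[1] and u in pair) / len(d)
                 for d in data]
            pbar = sum(n * pi for n, pi in zip(ns, p)) / (r * nbar)
            hbar = sum(n * hi for n, hi in zip(ns, h)) / (r * nbar)
            s2 = sum(n * (pi - pbar) ** 2 for n, pi in zip(ns, p)) / ((r - 1) * nbar)
            a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                     - hbar / 4) / (nbar - 1))
            b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                       - (2 * nbar - 1) / (4 * nbar) * hbar)
            c = hbar / 2
            num += a
            den += a + b + c
    return num / den


class TestTheta:
    def test_complete_fixation(self):
        g = make_matrix({"A": [[1, 1]] * 10, "B": [[2, 2]] * 10})
        assert weir_cockerham_theta(g).theta == pytest.approx(1.0, abs=1e-12)

    def test_identical_samples_near_zero(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(1, 5, size=(20, 3, 2)).tolist()
        g = make_matrix({"A": calls, "B": calls})
        th = weir_cockerham_theta(g).theta
        assert th <= 0.0
        assert abs(th) < 0.05

    def test_matches_bruteforce_oracle_on_toy_table(self):
        g = make_matrix({
            "A": [[[1, 2], [3, 3]], [[1, 1], [3, 4]], [[2, 2], [4, 4]],
                  [[1, 2], [3, 4]]],
            "B": [[[2, 2], [3, 3]], [[2, 2], [3, 3]], [[1, 2], [4, 4]],
                  [[2, 2], [3, 4]], [[2, 2], [3, 3]]],
        })
        res = weir_cockerham_theta(g)
        assert res.theta == pytest.approx(theta_oracle(g), abs=1e-10)

    def test_monomorphic_undefined(self):
        g = make_matrix({"A": [[1, 1]] * 4, "B": [[1, 1]] * 4})
        with pytest.raises(UndefinedThetaError):
            weir_cockerham_theta(g)

    def test_invariances(self):
        rng = np.random.default_rng(3)
        g = random_genotype_matrix(rng, n_pops=3, max_n=12, max_loci=3)
        th = weir_cockerham_theta(g).theta
        # allele relabeling
        relab = g.calls.copy()
        relab[relab > 0] = 10 - relab[relab > 0]
        g2 = GenotypeMatrix(g.individuals, g.loci, g.populations, relab)
        assert weir_cockerham_theta(g2).theta == pytest.approx(th, abs=1e-12)
        # locus order
        g3 = g.subset(loci=list(reversed(g.loci)))
        assert weir_cockerham_theta(g3).theta == pytest.approx(th, abs=1e-12)

    def test_pairwise_symmetry(self, study_genotypes):
        t12 = weir_cockerham_theta(study_genotypes, ["RI-20", "RI-40"]).theta
        t21 = weir_cockerham_theta(study_genotypes, ["RI-40", "RI-20"]).theta
        assert t12 == pytest.approx(t21, abs=1e-12)


class TestBootstrapCI:
    def test_zero_width_for_identical_loci(self):
        calls_a = [[[1, 2], [1, 2]]] * 8 + [[[1, 1], [1, 1]]] * 4
        calls_b = [[[2, 2], [2, 2]]] * 8 + [[[1, 2], [1, 2]]] * 4
        g = make_matrix({"A": calls_a, "B": calls_b})
        lo, hi = bootstrap_theta_ci(g, n_boot=200, seed=1)
        assert lo == pytest.approx(hi, abs=1e-12)

    def test_seed_reproducibility(self, study_genotypes):
        ci1 = bootstrap_theta_ci(study_genotypes, n_boot=300, seed=42)
        ci2 = bootstrap_theta_ci(study_genotypes, n_boot=300, seed=42)
        assert ci1 == ci2

    def test_single_locus_degenerate(self):
        g = make_matrix({"A": [[1, 1]] * 5, "B": [[1, 2]] * 5})
        res = weir_cockerham_theta(g)
        lo, hi = bootstrap_theta_ci(res.per_locus_components, n_boot=100, seed=0)
        assert lo == hi == pytest.approx(res.theta)


class TestGenotypicDifferentiation:
    def test_maximal_differentiation(self):
        g = make_matrix({"A": [[1, 1]] * 20, "B": [[2, 2]] * 20})
        p = genotypic_differentiation_test(g, n_perm=199, seed=0)
        assert p == pytest.approx(1 / 200)

    def test_type_one_error_on_split_panmictic_sample(self):
        rng = np.random.default_rng(11)
        n_sims = 500
        rej = 0
        for _ in range(n_sims):
            calls = rng.integers(1, 5, size=(40, 3, 2)).tolist()
            g = make_matrix({"A": calls[:20], "B": calls[20:]})
            p = genotypic_differentiation_test(
                g, n_perm=199, seed=int(rng.integers(2**31 - 1)))
            rej += p <= 0.05
        assert 0.03 <= rej / n_sims <= 0.07

    def test_fisher_combination_agrees_on_strong_signal(self):
        rng = np.random.default_rng(2)
        calls_a = rng.choice([1, 2], size=(20, 3, 2)).tolist()
        calls_b = rng.choice([3, 4], size=(20, 3, 2)).tolist()
        g = make_matrix({"A": calls_a, "B": calls_b})
        p_sum = genotypic_differentiation_test(g, n_perm=199, seed=1)
        p_fis = genotypic_differentiation_test(g, n_perm=199, seed=1,
                                               combine="fisher")
        assert p_sum == p_fis == pytest.approx(1 / 200)
        with pytest.raises(ValueError, match="combine"):
            genotypic_differentiation_test(g, combine="mean")

    def test_matches_exhaustive_enumeration_tiny(self):
        """Permutation p agrees with exhaustive label enumeration."""
        g = make_matrix({"A": [[1, 1], [1, 2], [2, 2]],
                         "B": [[2, 2], [2, 2], [1, 2]]})
        from margin_adapt.diversity import _g_statistic, _genotype_codes
        codes = _genotype_codes(g.calls[:, 0, :])
        labels0 = np.array([0, 0, 0, 1, 1, 1])

        def g_of(lab):
            t = np.zeros((2, codes.max() + 1))
            np.add.at(t, (lab, codes), 1)
            return _g_statistic(t)

        g_obs = g_of(labels0)
        perms = [g_of(np.array(p)) for p in
                 set(itertools.permutations(labels0))]
        exact = np.mean([x >= g_obs - 1e-9 for x in perms])
        p_mc = genotypic_differentiation_test(g, n_perm=1999, seed=5)
        assert abs(p_mc - exact) < 3 * math.sqrt(exact * (1 - exact) / 2000) + 1e-3


class TestDa:
    def test_identical_frequencies_zero(self):
        calls = [[[1, 2]], [[1, 1]], [[2, 2]]]
        g = make_matrix({"A": calls, "B": calls})
        assert nei_da_matrix(g).value("A", "B") == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_alleles_one(self):
        g = make_matrix({"A": [[1, 2]] * 5, "B": [[3, 4]] * 5})
        assert nei_da_matrix(g).value("A", "B") == pytest.approx(1.0)

    def test_half_fixed_example(self):
        g = make_matrix({"A": [[1, 2], [1, 2]], "B": [[1, 1], [1, 1]]})
        assert nei_da_matrix(g).value("A", "B") == \
            pytest.approx(1 - math.sqrt(0.5), abs=1e-12)

    def test_bounds_and_diagonal(self, study_genotypes):
        da = nei_da_matrix(study_genotypes)
        assert (da.matrix >= -1e-12).all() and (da.matrix <= 1 + 1e-12).all()
        assert np.allclose(np.diag(da.matrix), 0)


def _tip_distances(newick: str) -> dict[frozenset, float]:
    from skbio import TreeNode
    tree = TreeNode.read(StringIO(newick))
    tips = list(tree.tips())
    out = {}
    for t1, t2 in itertools.combinations(tips, 2):
        out[frozenset((t1.name, t2.name))] = t1.distance(t2)
    return out


class TestNeighborJoining:
    def test_recovers_additive_tree(self):
        # tree: (A:1,B:2):1 joined to (C:3,D:4) -> additive distances
        labels = ["A", "B", "C", "D"]
        d = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], dtype=float) / 10.0
        nwk = neighbor_joining(DistanceMatrixDa(labels, d))
        got = _tip_distances(nwk)
        for (i, j) in itertools.combinations(range(4), 2):
            pair = frozenset((labels[i], labels[j]))
            assert got[pair] == pytest.approx(d[i, j], abs=1e-10)

    def test_equidistant_three_taxa(self):
        d = 0.4 * (1 - np.eye(3))
        nwk = neighbor_joining(DistanceMatrixDa(["A", "B", "C"], d))
        got = _tip_distances(nwk)
        for pair, dist in got.items():
            assert dist == pytest.approx(0.4, abs=1e-10)

    def test_taxon_order_invariance(self):
        labels = ["A", "B", "C", "D"]
        d = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], dtype=float) / 10.0
        from margin_adapt.differentiation import _bipartitions
        nwk1 = neighbor_joining(DistanceMatrixDa(labels, d))
        perm = [2, 0, 3, 1]
        d2 = d[np.ix_(perm, perm)]
        nwk2 = neighbor_joining(
            DistanceMatrixDa([labels[i] for i in perm], d2))
        taxa = frozenset(labels)
        assert _bipartitions(nwk1, taxa) == _bipartitions(nwk2, taxa)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError, match="3 taxa"):
            neighbor_joining(DistanceMatrixDa(["A", "B"], np.zeros((2, 2))))

    def test_bootstrap_support_full_for_strong_structure(self):
        """Two clearly distinct population pairs give near-total support."""
        rng = np.random.default_rng(21)
        def pop(allele_pool):
            return rng.choice(allele_pool, size=(15, 5, 2)).astype(np.int32).tolist()
        g = make_matrix({
            "A": pop([1, 2]), "B": pop([1, 2, 3]),
            "C": pop([7, 8]), "D": pop([7, 8, 9]),
        })
        _, support = nj_bootstrap_support(g, n_boot=50, seed=9)
        assert support  # 4 taxa -> one internal split
        (split,) = support
        assert split in ({"A", "B"}, {"C", "D"})
        assert support[split] >= 48
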