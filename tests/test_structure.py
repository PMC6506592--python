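"""Weir-Cockerham theta and DAPC model selection."""

import numpy as np
import pytest

from larvorigin.structure import (
    DAPC,
    cluster_composition,
    fst_matrix,
    fst_permutation_p,
    kmeans_bic,
    pairwise_fst,
    weir_cockerham_theta,
)
from larvorigin.synthgen import PopulationModel, make_allele_freqs, simulate_adults
from conftest import make_table


def brute_force_theta(groups):
    """Independent scalar transcription of the WC84 variance components.

    ``groups``: list of lists of (a, b) genotype tuples for ONE locus.
    Numerator and denominator accumulated per allele with plain Python
    arithmetic; serves as the oracle for the vectorised implementation.
    """
    r = len(groups)
    n_i = [len(g) for g in groups]
    nbar = sum(n_i) / r
    n_total = sum(n_i)
    nc = (n_total - sum(n * n for n in n_i) / n_total) / (r - 1)
    alleles = sorted({a for g in groups for geno in g for a in geno})
    num = den = 0.0
    for al in alleles:
        p_i = [sum(int(g0 == al) + int(g1 == al) for g0, g1 in g) / (2 * n)
               for g, n in zip(groups, n_i)]
        h_i = [sum(bool((g0 == al) != (g1 == al)) for g0, g1 in g) / n
               for g, n in zip(groups, n_i)]
        pbar = sum(n * p for n, p in zip(n_i, p_i)) / n_total
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(n_i, h_i)) / n_total
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den


class TestWeirCockerham:
    def test_oracle_equivalence_toy(self):
        rng = np.random.default_rng(21)
        genosA = [tuple(sorted(rng.integers(1, 3, 2))) for _ in range(10)]
        genosB = [tuple(sorted(rng.integers(1, 3, 2))) for _ in range(10)]
        tA = make_table(["L1"], {"A": [(g,) for g in genosA]})
        tB = make_table(["L1"], {"B": [(g,) for g in genosB]})
        theta = pairwise_fst(tA, tB)
        oracle = brute_force_theta([genosA, genosB])
        assert theta == pytest.approx(oracle, abs=1e-12)

    def test_oracle_equivalence_multiallelic_multilocus(self):
        rng = np.random.default_rng(22)
        nloc = 3
        groups_per_locus = []
        tables = {}
        for pop, n in (("A", 8), ("B", 12), ("C", 10)):
            tables[pop] = [
                tuple(tuple(sorted(rng.integers(1, 6, 2))) for _ in range(nloc))
                for _ in range(n)
            ]
        tabs = [
            make_table([f"L{j}" for j in range(nloc)], {p: tables[p]})
            for p in ("A", "B", "C")
        ]
        theta, skipped = weir_cockerham_theta(tabs)
        assert skipped == []

        # ratio of sums over loci, with scalar per-allele component arithmetic
        def components(groups):
            r = len(groups)
            n_i = [len(g) for g in groups]
            nbar = sum(n_i) / r
            n_total = sum(n_i)
            nc = (n_total - sum(n * n for n in n_i) / n_total) / (r - 1)
            alleles = sorted({a for g in groups for geno in g for a in geno})
            num = den = 0.0
            for al in alleles:
                p_i = [sum(int(x == al) + int(y == al) for x, y in g) / (2 * n)
                       for g, n in zip(groups, n_i)]
                h_i = [sum((x == al) != (y == al) for x, y in g) / n
                       for g, n in zip(groups, n_i)]
                pbar = sum(n * p for n, p in zip(n_i, p_i)) / n_total
                s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * nbar)
                hbar = sum(n * h for n, h in zip(n_i, h_i)) / n_total
                a = (nbar / nc) * (
                    s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
                )
                b = (nbar / (nbar - 1)) * (
                    pbar * (1 - pbar) - (r - 1) / r * s2
                    - (2 * nbar - 1) / (4 * nbar) * hbar
                )
                num += a
                den += a + b + hbar / 2
            return num, den

        num = den = 0.0
        for j in range(nloc):
            groups = [[ind[j] for ind in tables[p]] for p in ("A", "B", "C")]
            a, d = components(groups)
            num += a
            den += d
        assert theta == pytest.approx(num / den, abs=1e-12)

    def test_complete_differentiation(self):
        tA = make_table(["L1"], {"A": [((1, 1),)] * 10})
        tB = make_table(["L1"], {"B": [((2, 2),)] * 10})
        assert pairwise_fst(tA, tB) == pytest.approx(1.0)

    def test_no_differentiation_split(self, small_adults):
        # one population split randomly in two halves: theta near 0
        rng = np.random.default_rng(3)
        one_pop = small_adults.split_by("pop")["pop1"]
        thetas = []
        for _ in range(10):
            perm = rng.permutation(one_pop.n_individuals)
            half = one_pop.n_individuals // 2
            thetas.append(
                pairwise_fst(one_pop.subset(perm[:half]), one_pop.subset(perm[half:]))
            )
        assert abs(np.mean(thetas)) < 0.01
        assert max(abs(t) for t in thetas) < 0.05

    def test_all_loci_undefined_errors(self):
        tA = make_table(["L1"], {"A": [((1, 1),)]})  # single individual: nbar <= 1
        tB = make_table(["L1"], {"B": [((1, 2),)]})
        with pytest.raises(ValueError):
            pairwise_fst(tA, tB)

    def test_recovers_balding_nichols_target(self):
        # multi-locus theta within +/-30% of the drift parameter
        for f in (0.01, 0.05, 0.1):
            m = PopulationModel(n_pops=10, n_loci=14, fst_target=f, seed=100)
            freqs = make_allele_freqs(m)
            adults = simulate_adults(freqs, {p: 50 for p in m.pop_names}, seed=200)
            theta, _ = weir_cockerham_theta(list(adults.split_by("pop").values()))
            assert abs(theta - f) < 0.3 * f


class TestFstPermutation:
    def test_extreme_case(self):
        tA = make_table(["L1"], {"A": [((1, 1),)] * 12})
        tB = make_table(["L1"], {"B": [((2, 2),)] * 12})
        p = fst_permutation_p(tA, tB, n_perm=99, seed=1)
        assert p == pytest.approx(1 / 100)

    def test_determinism(self, small_adults):
        byp = small_adults.split_by("pop")
        a = fst_permutation_p(byp["pop1"], byp["pop2"], 99, seed=5)
        b = fst_permutation_p(byp["pop1"], byp["pop2"], 99, seed=5)
        assert a == b

    def test_null_mean_near_half(self, small_adults):
        one = small_adults.split_by("pop")["pop1"]
        rng = np.random.default_rng(9)
        ps = []
        for k in range(12):
            perm = rng.permutation(one.n_individuals)
            half = one.n_individuals // 2
            ps.append(
                fst_permutation_p(
                    one.subset(perm[:half]), one.subset(perm[half:]), 99, seed=k
                )
            )
        assert 0.2 < np.mean(ps) < 0.8


class TestFstMatrix:
    def test_symmetry_and_near_zero_for_identical(self, small_cohorts):
        sub = {
            k: v for k, v in list(small_cohorts.split_by("cohort").items())[:3]
        }
        fm = fst_matrix(sub)
        np.testing.assert_array_equal(fm.theta, fm.theta.T)
        assert np.all(np.diag(fm.theta) == 0)

    def test_block_structure_two_sources(self):
        m = PopulationModel(n_pops=2, n_loci=14, fst_target=0.15, seed=31)
        freqs = make_allele_freqs(m)
        adults = simulate_adults(
            freqs, {"pop1": 120, "pop2": 120}, seed=32
        )
        byp = adults.split_by("pop")
        cohorts = {}
        rng = np.random.default_rng(33)
        for pop, tab in byp.items():
            perm = rng.permutation(tab.n_individuals)
            cohorts[f"{pop}-a"] = tab.subset(perm[:60])
            cohorts[f"{pop}-b"] = tab.subset(perm[60:])
        fm = fst_matrix(cohorts)
        idx = {lab: i for i, lab in enumerate(fm.labels)}
        within = [
            fm.theta[idx["pop1-a"], idx["pop1-b"]],
            fm.theta[idx["pop2-a"], idx["pop2-b"]],
        ]
        between = [
            fm.theta[idx["pop1-a"], idx["pop2-a"]],
            fm.theta[idx["pop1-a"], idx["pop2-b"]],
            fm.theta[idx["pop1-b"], idx["pop2-a"]],
            fm.theta[idx["pop1-b"], idx["pop2-b"]],
        ]
        assert max(within) < min(between)


class TestDAPC:
    def test_recovers_planted_k2(self):
        m = PopulationModel(n_pops=2, n_loci=14, fst_target=0.3, seed=5)
        freqs = make_allele_freqs(m)
        adults = simulate_adults(freqs, {p: 100 for p in m.pop_names}, seed=6)
        res = DAPC(adults, k_max=5, seed=7).fit()
        assert res.k == 2
        truth = (adults.metadata["pop"] == "pop2").to_numpy().astype(int)
        agree = max(
            (res.assignments == truth).mean(), (res.assignments != truth).mean()
        )
        assert agree >= 0.95

    def test_bic_k1_closed_form(self, small_adults):
        res = DAPC(small_adults, k_max=3, seed=1).fit()
        scores = res.pc_scores
        n = scores.shape[0]
        wss = float(((scores - scores.mean(axis=0)) ** 2).sum())
        assert res.bic_profile[0] == pytest.approx(kmeans_bic(n, wss, 1), rel=1e-12)

    def test_duplicated_individuals_cocluster(self):
        # identical genotypes always land in the same cluster; note the
        # selected k itself is not invariant under duplication because the
        # BIC fit term scales with n while the penalty scales with ln(n)
        m = PopulationModel(n_pops=2, n_loci=14, fst_target=0.3, seed=8)
        freqs = make_allele_freqs(m)
        adults = simulate_adults(freqs, {p: 60 for p in m.pop_names}, seed=9)
        import pandas as pd
        from larvorigin.genio import GenotypeTable

        n = adults.n_individuals
        dup = GenotypeTable(
            loci=list(adults.loci),
            ids=adults.ids + [f"{i}+dup" for i in adults.ids],
            calls=np.concatenate([adults.calls, adults.calls]),
            metadata=pd.concat(
                [
                    adults.metadata,
                    adults.metadata.set_axis(
                        [f"{i}+dup" for i in adults.ids]
                    ),
                ]
            ),
        )
        res = DAPC(dup, k_max=4, seed=10).fit()
        np.testing.assert_array_equal(res.assignments[:n], res.assignments[n:])

    def test_constant_matrix_rejected(self):
        t = make_table(["L1"], {"p": [((1, 1),)] * 12})
        with pytest.raises(ValueError, match="no polymorphism"):
            DAPC(t, k_max=2).fit()


class TestClusterComposition:
    def test_hand_counts_and_invariance(self):
        m = PopulationModel(n_pops=2, n_loci=14, fst_target=0.3, seed=50)
        freqs = make_allele_freqs(m)
        adults = simulate_adults(freqs, {p: 30 for p in m.pop_names}, seed=51)
        res = DAPC(adults, k_max=3, seed=52).fit()
        labels = np.array(["c1"] * 30 + ["c2"] * 30)
        comp = cluster_composition(res, labels)
        np.testing.assert_allclose(comp.sum(axis=1), 1.0, atol=1e-9)
        # one cohort, one cluster -> proportion 1
        one = cluster_composition(res, np.array(["all"] * 60))
        assert one.to_numpy().sum() == pytest.approx(1.0)

    def test_split_7_3(self):
        class Dummy:
            k = 2
            assignments = np.array([0] * 7 + [1] * 3)
            ids = [str(i) for i in range(10)]

        comp = cluster_composition(Dummy(), np.array(["c"] * 10))
        assert comp.loc["c", 0] == pytest.approx(0.7)
        assert comp.loc["c", 1] == pytest.approx(0.3)
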