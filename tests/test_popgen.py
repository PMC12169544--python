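"""Heterozygosity/FIS, windowed pi, Nei FST, and genotype PCA, each checked
against brute-force evaluation of the defining formulas."""

import numpy as np
import pytest

from shorthap import popgen
from shorthap.variants import MISSING, SnpRecord


def rec(pos, gts, contig="c1"):
    return SnpRecord(contig, pos, "A", "C", np.asarray(gts, dtype=np.int8), {})


# ---------------------------------------------------------------- oracles


def nei_chesser_locus(genos: np.ndarray) -> tuple[float, float] | None:
    """Brute-force per-locus (Ho, Hs) for one population: Nei–Chesser
    Hs = n/(n-1) (1 - p^2 - q^2 - Ho/(2n)) over non-missing diploids."""
    g = [x for x in genos if x != MISSING]
    n = len(g)
    if n < 2:
        return None
    ho = sum(x == 1 for x in g) / n
    p = sum(g) / (2 * n)
    hs = n / (n - 1) * (1 - p**2 - (1 - p)**2 - ho / (2 * n))
    return ho, hs


def nei_fst_oracle(geno_a: np.ndarray, geno_b: np.ndarray) -> float:
    """Brute-force pairwise Nei FST = (Ht - Hs)/Ht, ratio of averages, with
    Nei-Chesser sample-size corrections for two populations."""
    hs_list, ht_list = [], []
    for la, lb in zip(geno_a.T, geno_b.T):
        sa, sb = nei_chesser_locus(la), nei_chesser_locus(lb)
        if sa is None or sb is None:
            continue
        (ho_a, hs_a), (ho_b, hs_b) = sa, sb
        na = sum(x != MISSING for x in la)
        nb = sum(x != MISSING for x in lb)
        pa = sum(x for x in la if x != MISSING) / (2 * na)
        pb = sum(x for x in lb if x != MISSING) / (2 * nb)
        hs = (hs_a + hs_b) / 2
        ho = (ho_a + ho_b) / 2
        p_bar = (pa + pb) / 2
        n_h = 2 / (1 / na + 1 / nb)
        ht = 1 - p_bar**2 - (1 - p_bar)**2 + hs / (2 * n_h) - ho / (4 * n_h)
        hs_list.append(hs)
        ht_list.append(ht)
    m_hs, m_ht = np.mean(hs_list), np.mean(ht_list)
    return (m_ht - m_hs) / m_ht


# ---------------------------------------------------------------- het_stats


class TestHetStats:
    def test_all_heterozygous_hand_value(self):
        """10 diploids all het: Ho = 1, p = 0.5, Hs = (10/9)(1-0.5-0.05) = 0.5,
        FIS = 1 - 1/0.5 = -1."""
        geno = np.full((10, 1), 1, dtype=np.int8)
        df = popgen.het_stats(geno, [f"s{i}" for i in range(10)],
                              {f"s{i}": "P" for i in range(10)})
        assert df.loc["P", "Ho"] == pytest.approx(1.0)
        assert df.loc["P", "Hs"] == pytest.approx(0.5)
        assert df.loc["P", "FIS"] == pytest.approx(-1.0)

    def test_monomorphic_locus_skipped(self):
        geno = np.array([[0, 1], [0, 1], [0, 1], [0, 1]], dtype=np.int8)
        df = popgen.het_stats(geno, list("abcd"), {s: "P" for s in "abcd"})
        assert df.loc["P", "n_loci"] == 1  # only the polymorphic column

    def test_ho_equals_hs_gives_fis_zero(self):
        # craft Ho = Hs at one locus: 4 diploids, genotypes 0,1,1,2 ->
        # Ho = 0.5, p = 0.5, Hs = (4/3)(1 - 0.5 - 0.0625) = 0.583... not equal;
        # instead use the identity FIS = 1 - Ho/Hs directly
        geno = np.array([[0], [1], [1], [2]], dtype=np.int8)
        df = popgen.het_stats(geno, list("abcd"), {s: "P" for s in "abcd"})
        assert df.loc["P", "FIS"] == pytest.approx(1 - df.loc["P", "Ho"] / df.loc["P", "Hs"])

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            geno = rng.choice([-1, 0, 1, 2], size=(10, 5),
                              p=[0.1, 0.35, 0.3, 0.25]).astype(np.int8)
            samples = [f"s{i}" for i in range(10)]
            df = popgen.het_stats(geno, samples, {s: "P" for s in samples})
            ho_vals, hs_vals = [], []
            for col in geno.T:
                st = nei_chesser_locus(col)
                if st is None or st[1] <= 0:
                    continue
                ho_vals.append(st[0])
                hs_vals.append(st[1])
            if not hs_vals:
                continue
            assert df.loc["P", "Ho"] == pytest.approx(np.mean(ho_vals))
            assert df.loc["P", "Hs"] == pytest.approx(np.mean(hs_vals))


# ---------------------------------------------------------------- windowed_pi


class TestWindowedPi:
    def test_hand_arithmetic(self):
        """One site, 10 chromosomes, 4 alt / 6 ref: pi_site = 2*4*6/90, window
        value divides by 50 kb."""
        geno = [2, 2, 0, 0, 0]  # 4 alt, 6 ref over 5 diploids
        df, mean = popgen.windowed_pi([rec(100, geno)], 50_000)
        assert mean == pytest.approx((2 * 4 * 6 / 90) / 50_000)
        assert df.iloc[0]["pi"] == pytest.approx(1.0667e-5, rel=1e-3)

    def test_empty_window_omitted(self):
        df, _ = popgen.windowed_pi([rec(100, [1, 1])], 1000)
        assert set(df["window_start"]) == {0}

    def test_fixed_alt_zero(self):
        _, mean = popgen.windowed_pi([rec(100, [2, 2, 2])])
        assert mean == 0.0

    def test_invariant_to_allele_label_swap(self):
        rng = np.random.default_rng(3)
        records = [rec(int(p), rng.choice([-1, 0, 1, 2], size=8))
                   for p in rng.integers(1, 200_000, size=60)]
        swapped = [SnpRecord(r.contig, r.position, r.alt, r.ref,
                             np.where(r.genotypes == MISSING, MISSING,
                                      2 - r.genotypes).astype(np.int8), {})
                   for r in records]
        _, m1 = popgen.windowed_pi(records)
        _, m2 = popgen.windowed_pi(swapped)
        assert m1 == pytest.approx(m2)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(4)
        records = [rec(int(p), rng.choice([-1, 0, 1, 2], size=6))
                   for p in sorted(rng.choice(100_000, size=40, replace=False) + 1)]
        df, mean = popgen.windowed_pi(records, 10_000)
        acc = {}
        for r in records:
            g = [x for x in r.genotypes if x != MISSING]
            n = 2 * len(g)
            if n < 2:
                continue
            ca = sum(g)
            acc.setdefault((r.position - 1) // 10_000, 0.0)
            acc[(r.position - 1) // 10_000] += 2 * ca * (n - ca) / (n * (n - 1))
        expected = np.mean([v / 10_000 for v in acc.values()])
        assert mean == pytest.approx(expected)

    def test_bad_window_size(self):
        with pytest.raises(ValueError, match="window_size"):
            popgen.windowed_pi([], 0)


# ---------------------------------------------------------------- FST


class TestPairwiseNeiFst:
    samples = [f"s{i}" for i in range(8)]
    assignment = {f"s{i}": ("P" if i < 4 else "Q") for i in range(8)}

    def test_identical_all_het_populations_zero(self):
        # p = 0.5 and Ho = 1 in both: the corrected Ht equals Hs exactly
        geno = np.full((8, 3), 1, dtype=np.int8)
        fst = popgen.pairwise_neifst(geno, self.samples, self.assignment)
        assert fst.loc["P", "Q"] == pytest.approx(0.0, abs=1e-12)
        assert fst.loc["P", "P"] == 0.0

    def test_fixed_difference_approaches_one(self):
        n = 40
        geno = np.concatenate([np.zeros((n, 20)), np.full((n, 20), 2)]).astype(np.int8)
        samples = [f"s{i}" for i in range(2 * n)]
        assignment = {s: ("P" if i < n else "Q") for i, s in enumerate(samples)}
        fst = popgen.pairwise_neifst(geno, samples, assignment)
        assert fst.loc["P", "Q"] > 0.95

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(8)
        geno = rng.choice([0, 1, 2], size=(8, 30)).astype(np.int8)
        fst = popgen.pairwise_neifst(geno, self.samples, self.assignment)
        assert np.allclose(fst.values, fst.values.T)
        assert np.all(np.diag(fst.values) == 0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            geno = rng.choice([-1, 0, 1, 2], size=(8, 5),
                              p=[0.05, 0.4, 0.3, 0.25]).astype(np.int8)
            fst = popgen.pairwise_neifst(geno, self.samples, self.assignment)
            expected = nei_fst_oracle(geno[:4], geno[4:])
            assert fst.loc["P", "Q"] == pytest.approx(expected)

    def test_permuted_labels_near_zero(self):
        """Random label permutations on panmictic genotypes: mean FST ~ 0."""
        rng = np.random.default_rng(30)
        n, m = 20, 200
        p = rng.uniform(0.2, 0.8, size=m)
        geno = rng.binomial(2, p, size=(n, m)).astype(np.int8)
        samples = [f"s{i}" for i in range(n)]
        values = []
        for _ in range(20):
            perm = rng.permutation(n)
            assignment = {samples[i]: ("P" if r < n // 2 else "Q")
                          for r, i in enumerate(perm)}
            fst = popgen.pairwise_neifst(geno, samples, assignment)
            values.append(fst.loc["P", "Q"])
        assert abs(np.mean(values)) < 0.01

    def test_tiny_population_missing(self):
        assignment = {"s0": "P", **{f"s{i}": "Q" for i in range(1, 8)}}
        geno = np.ones((8, 4), dtype=np.int8)
        fst = popgen.pairwise_neifst(geno, self.samples, assignment)
        assert np.isnan(fst.loc["P", "Q"])


# ---------------------------------------------------------------- PCA


class TestGenotypePca:
    def test_two_clusters_separate_on_pc1(self):
        geno = np.concatenate([np.zeros((4, 50)), np.full((4, 50), 2)]).astype(np.int8)
        res = popgen.genotype_pca(geno, [f"s{i}" for i in range(8)])
        pc1 = res.coordinates[:, 0]
        assert len(set(np.round(pc1[:4], 9))) == 1
        assert len(set(np.round(pc1[4:], 9))) == 1
        assert np.sign(pc1[0]) != np.sign(pc1[4])

    def test_duplicate_sample_identical_coordinates(self):
        rng = np.random.default_rng(12)
        geno = rng.choice([0, 1, 2], size=(5, 40)).astype(np.int8)
        geno = np.vstack([geno, geno[0]])
        res = popgen.genotype_pca(geno, [f"s{i}" for i in range(6)])
        assert np.allclose(res.coordinates[0], res.coordinates[5])

    def test_matches_dense_eigen_oracle(self):
        rng = np.random.default_rng(13)
        geno = rng.choice([0, 1, 2], size=(10, 30)).astype(np.int8)
        res = popgen.genotype_pca(geno, [f"s{i}" for i in range(10)])
        X = geno.astype(float)
        X -= X.mean(axis=0)
        evals = np.sort(np.linalg.eigvalsh(X @ X.T / (X.shape[0] - 1)))[::-1]
        ratio = evals / evals.sum()
        assert np.allclose(res.explained_variance_ratio,
                           ratio[:len(res.explained_variance_ratio)], atol=1e-8)
        assert res.explained_variance_ratio.sum() <= 1 + 1e-9
        assert np.all(np.diff(res.explained_variance_ratio) <= 1e-12)

    def test_missing_entries_mean_imputed(self):
        geno = np.array([[0, 2], [2, 0], [1, MISSING]], dtype=np.int8)
        res = popgen.genotype_pca(geno, ["a", "b", "c"])
        assert np.isfinite(res.coordinates).all()

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            popgen.genotype_pca(np.zeros((1, 5), dtype=np.int8), ["a"])
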