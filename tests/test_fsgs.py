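import numpy as np
import pytest

from dioecia import (
    DistanceClassSpec,
    PopulationError,
    SimulationParams,
    autocorrelogram,
    between_class_autocorrelogram,
    kinship_log_regression,
    kinship_matrix,
    pairwise_distances,
    simulate_study,
    sp_analysis,
    sp_statistic,
)
from dioecia.fsgs import KinshipResult

from conftest import make_population, random_hwe_population

A, B, C = 1, 2, 3


def loiselle_brute_force(pop):
    """Per-allele, per-pair reimplementation of the kinship estimator
    with plain Python loops — the independent oracle."""
    n, L = pop.n, pop.n_loci
    called = (pop.genotypes >= 0).all(axis=2)
    out = np.full((n, n), np.nan)
    # reference frequencies and sample sizes, straight from counting
    locus_stats = []
    for l in range(L):
        obs = [tuple(pop.genotypes[i, l]) for i in range(n) if called[i, l]]
        alleles = sorted({a for g in obs for a in g})
        counts = {a: sum(g.count(a) for g in obs) for a in alleles}
        total = sum(counts.values())
        p = {a: counts[a] / total for a in alleles}
        locus_stats.append((p, len(obs)))
    for i in range(n):
        for j in range(n):
            num = den = 0.0
            for l in range(L):
                if not (called[i, l] and called[j, l]):
                    continue
                p, n_ref = locus_stats[l]
                w = sum(q * (1 - q) for q in p.values())
                if w == 0 or n_ref < 2:
                    continue
                gi, gj = pop.genotypes[i, l], pop.genotypes[j, l]
                for a, pa in p.items():
                    xia = (int(gi[0] == a) + int(gi[1] == a)) / 2
                    xja = (int(gj[0] == a) + int(gj[1] == a)) / 2
                    num += (xia - pa) * (xja - pa) + pa * (1 - pa) / (n_ref - 1)
                den += w
            if den > 0:
                out[i, j] = num / den
    return out


class TestKinship:
    def test_two_individual_hand_case(self):
        pop = make_population([[(A, A)], [(B, B)]])
        f = kinship_matrix(pop).multilocus()
        assert f[0, 1] == pytest.approx(0.0, abs=1e-15)

    def test_symmetry(self):
        pop = random_hwe_population(3, n=20)
        f = kinship_matrix(pop).multilocus()
        assert np.allclose(f, f.T, equal_nan=True)

    def test_matches_brute_force_with_missing_data(self):
        rng = np.random.default_rng(7)
        for seed in range(10):
            pop = random_hwe_population(seed, n=12, n_loci=4, n_alleles=3)
            geno = pop.genotypes.copy()
            drop = rng.random((pop.n, pop.n_loci)) < 0.2
            geno[drop] = -1
            pop.genotypes = geno
            f = kinship_matrix(pop).multilocus()
            oracle = loiselle_brute_force(pop)
            assert np.allclose(f, oracle, atol=1e-12, equal_nan=True)

    def test_null_mean_matches_finite_sample_expectation(self):
        """HWE genotypes with sample-estimated reference frequencies:
        the all-pair mean kinship is +1/(2(n-1)) exactly in expectation
        (the -Var(x)/(n-1) closure term plus the p(1-p)/(n-1) sampling
        correction), i.e. O(1/n), vanishing for large samples."""
        means = []
        for seed in range(30):
            pop = random_hwe_population(seed, n=100, n_loci=9, n_alleles=7)
            f = kinship_matrix(pop).multilocus()
            iu, ju = np.triu_indices(pop.n, k=1)
            means.append(np.nanmean(f[iu, ju]))
        grand = np.mean(means)
        assert grand == pytest.approx(1 / (2 * 99), abs=0.002)

    def test_all_monomorphic_raises(self):
        pop = make_population([[(A, A)], [(A, A)]])
        with pytest.raises(PopulationError):
            kinship_matrix(pop)


def _prescribed_kinship(f_matrix, n_loci=2):
    """KinshipResult whose multilocus matrix equals ``f_matrix`` exactly
    (every locus carries the same numerator)."""
    n = f_matrix.shape[0]
    from dioecia.diversity import AlleleFrequencies

    freqs = AlleleFrequencies(
        loci=tuple(f"L{k}" for k in range(n_loci)),
        alleles=[np.array([1, 2])] * n_loci,
        freqs=[np.array([0.5, 0.5])] * n_loci,
        counts=[np.array([n, n])] * n_loci,
    )
    return KinshipResult(
        ids=np.array([f"T{k}" for k in range(n)], dtype=object),
        locus_num=np.stack([0.5 * f_matrix] * n_loci),
        locus_weight=np.full(n_loci, 0.5),
        valid=np.ones((n_loci, n, n), dtype=bool),
        freqs=freqs,
        n_ref=np.full(n_loci, n),
    )


class TestRegression:
    def test_exact_ols_on_three_points(self):
        # pairs (ln d, F): (0, 0.1), (1, 0.05), (2, 0.0) -> slope -0.05
        f = np.zeros((3, 3))
        f[0, 1] = f[1, 0] = 0.1
        f[0, 2] = f[2, 0] = 0.05
        f[1, 2] = f[2, 1] = 0.0
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = 1.0
        d[0, 2] = d[2, 0] = np.e
        d[1, 2] = d[2, 1] = np.e**2
        kin = _prescribed_kinship(f)
        b, se, p = kinship_log_regression(kin, d, n_perm=99, rng_seed=0)
        assert b == pytest.approx(-0.05)
        assert se == pytest.approx(0.0, abs=1e-12)  # identical loci

    def test_flat_kinship_gives_zero_slope(self):
        f = np.full((4, 4), 0.02)
        d = np.abs(np.subtract.outer(np.arange(4.0), np.arange(4.0))) * 10 + \
            np.where(np.eye(4, dtype=bool), 0, 5)
        kin = _prescribed_kinship(f)
        b, _, _ = kinship_log_regression(kin, d, n_perm=99, rng_seed=0)
        assert b == pytest.approx(0.0, abs=1e-14)

    def test_single_locus_jackknife_raises(self):
        f = np.random.default_rng(0).normal(size=(4, 4))
        f = (f + f.T) / 2
        kin = _prescribed_kinship(f, n_loci=1)
        d = np.abs(np.subtract.outer(np.arange(4.0), np.arange(4.0))) * 7 + \
            np.where(np.eye(4, dtype=bool), 0, 3)
        with pytest.raises(PopulationError):
            kinship_log_regression(kin, d, n_perm=99, rng_seed=0)


class TestSpStatistic:
    @pytest.mark.parametrize(
        "b_log, f1, expected",
        [
            (-0.0121, 0.0531, 0.0128),
            (-0.01, 0.0771, 0.0108),
            (-0.01, 0.0502, 0.0105),
            (0.0, 0.5, 0.0),
        ],
    )
    def test_reference_values(self, b_log, f1, expected):
        assert sp_statistic(b_log, f1) == pytest.approx(expected, abs=5e-5)

    def test_rejects_f1_at_one(self):
        with pytest.raises(PopulationError):
            sp_statistic(-0.01, 1.0)

    def test_identity_holds_on_analyzed_data(self):
        pop = random_hwe_population(9, n=60, n_loci=6, n_alleles=5)
        res = sp_analysis(pop, classes=DistanceClassSpec((60, 120, 180)),
                          n_perm=99, rng_seed=1)
        assert res.sp == -res.b_log / (1 - res.f1)  # bitwise identity


class TestAutocorrelogram:
    def test_single_all_pair_class_is_permutation_invariant(self):
        pop = random_hwe_population(4, n=25)
        kin = kinship_matrix(pop)
        d = pairwise_distances(pop)
        spec = DistanceClassSpec((d.max() + 1,))
        corr = autocorrelogram(kin, d, spec, n_perm=199, rng_seed=0)
        row = corr.table.iloc[0]
        assert row["p"] == pytest.approx(1.0)
        assert row["env_low"] == pytest.approx(row["mean_f"], abs=1e-12)
        assert row["env_high"] == pytest.approx(row["mean_f"], abs=1e-12)

    def test_empty_class_raises(self):
        pop = random_hwe_population(5, n=10)
        kin = kinship_matrix(pop)
        d = pairwise_distances(pop)
        with pytest.raises(PopulationError, match="empty distance class"):
            autocorrelogram(kin, d, DistanceClassSpec((0.001, 500)),
                            n_perm=99, rng_seed=0)

    def test_structured_population_flags_first_class(self):
        """Tight seed shadows (20 m kernel) create detectable kinship
        among nearby seedlings."""
        study = simulate_study(
            SimulationParams(
                n_adults=100, n_seeds=300, seed_kernel_mean=20.0,
                jc_d50=-1e6, genotyping_error=0.0, missing_rate=0.0,
                rng_seed=17,
            )
        )
        res = sp_analysis(
            study.seedlings,
            classes=DistanceClassSpec((20, 40, 60, 80, 100)),
            n_perm=199, rng_seed=3,
        )
        assert res.f1 > res.correlogram.table["env_high"].iloc[0]
        assert res.sp > 0
        assert res.b_p < 0.05


class TestBetweenClass:
    def test_parent_offspring_signal_with_no_dispersal(self):
        study = simulate_study(
            SimulationParams(
                n_adults=80, n_seeds=120, seed_kernel_mean=1e-9,
                jc_d50=-1e6, genotyping_error=0.0, missing_rate=0.0,
                rng_seed=23,
            )
        )
        corr = between_class_autocorrelogram(
            study.seedlings, study.adults,
            classes=DistanceClassSpec((20, 100, 400, 1100)),
            n_perm=99, rng_seed=1,
        )
        first = corr.table["mean_f"].iloc[0]
        overall = np.average(
            corr.table["mean_f"], weights=corr.table["n_pairs"]
        )
        # co-located parent-offspring pairs: ~0.25-scale kinship signal
        assert first > 0.1
        assert first > 5 * abs(overall)

    def test_swap_symmetry_of_observed_means(self):
        a = random_hwe_population(1, n=15)
        b = random_hwe_population(2, n=15)
        b.ids = np.array([f"U{k}" for k in range(b.n)], dtype=object)
        spec = DistanceClassSpec((150, 300, 450))
        c1 = between_class_autocorrelogram(a, b, spec, n_perm=99, rng_seed=0)
        c2 = between_class_autocorrelogram(b, a, spec, n_perm=99, rng_seed=0)
        assert np.allclose(c1.table["mean_f"], c2.table["mean_f"])
        assert (c1.table["n_pairs"] == c2.table["n_pairs"]).all()

    def test_overlapping_cohorts_rejected(self):
        a = random_hwe_population(1, n=10)
        with pytest.raises(PopulationError):
            between_class_autocorrelogram(a, a, n_perm=99)
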