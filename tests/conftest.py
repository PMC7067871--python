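import numpy as np
import pytest

from dioecia import Population, SimulationParams, Window, simulate_study


def make_population(genotype_rows, xy=None, window=Window(100, 100), sex=None,
                    dbh=None, cohort=None, loci=None):
    """Small handmade population: genotype_rows is a list of per-individual
    lists of (a, b) allele pairs (use -1 for a missing allele)."""
    n = len(genotype_rows)
    n_loci = len(genotype_rows[0])
    if loci is None:
        loci = [f"L{k+1}" for k in range(n_loci)]
    if xy is None:
        rng = np.random.default_rng(0)
        xy = np.column_stack([rng.uniform(0, window.width, n),
                              rng.uniform(0, window.height, n)])
    return Population(
        ids=np.array([f"T{k+1}" for k in range(n)], dtype=object),
        xy=np.asarray(xy, dtype=float),
        dbh=np.asarray(dbh if dbh is not None else np.full(n, 15.0), dtype=float),
        sex=np.asarray(sex if sex is not None else ["male"] * n, dtype=object),
        cohort=np.asarray(cohort if cohort is not None else [None] * n, dtype=object),
        loci=tuple(loci),
        genotypes=np.asarray(genotype_rows, dtype=np.int64),
        window=window,
    )


def random_hwe_population(seed, n=50, n_loci=5, n_alleles=4,
                          window=Window(300, 300)):
    """HWE genotypes at equifrequent alleles, uniform coordinates: no
    spatial genetic structure by construction."""
    rng = np.random.default_rng(seed)
    geno = rng.integers(0, n_alleles, size=(n, n_loci, 2))
    xy = np.column_stack([rng.uniform(0, window.width, n),
                          rng.uniform(0, window.height, n)])
    return make_population(geno, xy=xy, window=window)


@pytest.fixture(scope="session")
def small_study():
    """One modest synthetic study reused by several integration tests."""
    params = SimulationParams(
        n_adults=120, n_seeds=400, rng_seed=11,
        genotyping_error=0.01, missing_rate=0.02,
        jc_d50=-1e6,  # thinning off: all seeds establish
    )
    return simulate_study(params)
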