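"""Spatially explicit forward simulator of a dioecious tree stand.

Generates a mapped adult population inside a rectangular plot, then a
seed cohort with a known pedigree: mothers drawn uniformly among females,
fathers among males with weight exp(-d/lambda_p) (exponential pollen
kernel), seed deposition displaced from the mother by an exponential
distance with uniform direction (rejection-sampled to stay inside the
plot), and distance-dependent establishment following a logistic
Janzen-Connell survival curve on the distance to the nearest parent.
Genotyping error replaces a true genotype with a random Hardy-Weinberg
draw at the population allele frequencies — exactly the error process the
parentage likelihood models — and a missing-data process blanks loci.

Every run is fully reproducible from ``rng_seed``; the returned
:class:`SimulationTruth` (true parents, true dispersal distances,
survival flags) is the recovery oracle for all downstream estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import MISSING, Population, PopulationError, Window
from .diversity import AlleleFrequencies, allele_frequencies


@dataclass(frozen=True)
class SimulationParams:
    """Study-scale defaults: a 30 ha (1000 x 300 m) plot, ~350 mapped
    stems, 9 microsatellite loci with ~6-7 alleles each (He ~ 0.5), a
    male-biased sex ratio, exponential pollen/seed kernels on the order
    of the plot scale, and a Janzen-Connell half-distance of 150 m.

    sex_ratio is the proportion male among sexed adults.  jc_d50 is the
    parent distance (m) at which establishment probability is 0.5 and
    jc_slope (m) the logistic width; genotyping_error is the per-locus
    probability that an observed genotype is a random HWE draw.
    """

    window: Window = field(default_factory=lambda: Window(1000.0, 300.0))
    n_adults: int = 210
    sex_ratio: float = 0.6
    n_loci: int = 9
    alleles_per_locus: int = 7
    #: symmetric Dirichlet concentration for founder allele frequencies;
    #: 1.0 = flat (mean He ~ 0.75 at 7 alleles), ~0.2 skews frequencies
    #: toward the He ~ 0.5 typical of field microsatellite panels
    dirichlet_concentration: float = 1.0
    pollen_kernel_mean: float = 300.0
    seed_kernel_mean: float = 150.0
    jc_d50: float = 150.0
    jc_slope: float = 30.0
    n_seeds: int = 500
    genotyping_error: float = 0.0923
    missing_rate: float = 0.02
    undetermined_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.sex_ratio < 1):
            raise PopulationError("sex_ratio must be in (0, 1): both sexes required")
        if self.n_adults < 2:
            raise PopulationError("need at least 2 adults")
        if self.pollen_kernel_mean <= 0 or self.seed_kernel_mean <= 0:
            raise PopulationError("kernel means must be positive")
        for name in ("genotyping_error", "missing_rate", "undetermined_rate"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise PopulationError(f"{name} must be in [0, 1)")
        if self.n_loci < 1 or self.alleles_per_locus < 1:
            raise PopulationError("need >= 1 locus and >= 1 allele per locus")


@dataclass
class SimulationTruth:
    """True pedigree and dispersal record, one row per generated seed.

    Columns of ``table``: offspring id, mother id, father id, pollen
    distance (mother-father, m), seed distance (deposition-mother, m),
    father distance (deposition-father, m), deposition x/y, survived
    flag.  ``true_genotypes`` are the pre-error offspring genotypes.
    """

    table: pd.DataFrame
    true_genotypes: np.ndarray
    loci: tuple[str, ...]

    @property
    def survivors(self) -> pd.DataFrame:
        return self.table[self.table["survived"]]

    def distances(self, kind: str, survivors_only: bool = False) -> np.ndarray:
        """True dispersal distances; kind in {'pollen', 'seed', 'father'}."""
        col = {"pollen": "pollen_dist", "seed": "seed_dist", "father": "father_dist"}[kind]
        tab = self.survivors if survivors_only else self.table
        return tab[col].to_numpy(float)


def _founder_frequencies(params: SimulationParams, rng: np.random.Generator) -> list[np.ndarray]:
    alpha = np.full(params.alleles_per_locus, params.dirichlet_concentration)
    return [rng.dirichlet(alpha) for _ in range(params.n_loci)]


def _hwe_genotypes(freqs: list[np.ndarray], n: int, rng: np.random.Generator) -> np.ndarray:
    geno = np.empty((n, len(freqs), 2), dtype=np.int64)
    for l, p in enumerate(freqs):
        geno[:, l, 0] = rng.choice(p.size, size=n, p=p)
        geno[:, l, 1] = rng.choice(p.size, size=n, p=p)
    return geno


def simulate_adults(params: SimulationParams,
                    rng: np.random.Generator | None = None) -> Population:
    """Adults uniform in the window, sexed by a Bernoulli(sex_ratio)
    draw, genotyped under Hardy-Weinberg at flat-Dirichlet founder
    frequencies.  Raises if the draw yields a single-sex stand."""
    rng = np.random.default_rng(params.rng_seed) if rng is None else rng
    n = params.n_adults
    xy = np.column_stack(
        [rng.uniform(0, params.window.width, n), rng.uniform(0, params.window.height, n)]
    )
    male = rng.random(n) < params.sex_ratio
    if male.all() or (~male).all():
        raise PopulationError(
            "single-sex adult draw; re-run with another rng_seed or sex_ratio"
        )
    sex = np.where(male, "male", "female").astype(object)
    if params.undetermined_rate > 0:
        undet = rng.random(n) < params.undetermined_rate
        # keep at least one of each sex determinable
        if (~undet & male).any() and (~undet & ~male).any():
            sex[undet] = "undetermined"
    # adults span cohorts II and III; mildly right-skewed diameters
    dbh = 10.0 + rng.lognormal(mean=np.log(8.0), sigma=0.7, size=n)
    freqs = _founder_frequencies(params, rng)
    geno = _hwe_genotypes(freqs, n, rng)
    loci = tuple(f"L{k+1}" for k in range(params.n_loci))
    pop = Population(
        ids=np.array([f"A{k+1}" for k in range(n)], dtype=object),
        xy=xy,
        dbh=dbh,
        sex=sex,
        cohort=np.array([None] * n, dtype=object),
        loci=loci,
        genotypes=geno,
        window=params.window,
    )
    return pop.with_cohorts_from_dbh()


def _sample_deposition(mx: float, my: float, mean: float, window: Window,
                       rng: np.random.Generator, max_tries: int = 10_000) -> tuple[float, float, float]:
    """Exponential displacement, uniform direction, redrawn until inside
    the window (the plot truncates the observable kernel)."""
    for _ in range(max_tries):
        d = rng.exponential(mean)
        theta = rng.uniform(0, 2 * np.pi)
        x, y = mx + d * np.cos(theta), my + d * np.sin(theta)
        if 0 <= x <= window.width and 0 <= y <= window.height:
            return x, y, d
    raise PopulationError("deposition rejection sampling failed; kernel too wide")


def simulate_progeny(
    adults: Population,
    params: SimulationParams,
    rng: np.random.Generator | None = None,
) -> tuple[Population, SimulationTruth]:
    """Generate ``n_seeds`` offspring with a known pedigree.

    The full seed set is the "effective" dispersal sample; the survivors
    of the Janzen-Connell filter are the "realized" sample (they become
    the established seedling cohort I).  Offspring genotypes are exact
    Mendelian draws from the parents (error is applied separately by
    :func:`apply_genotyping_error`).
    """
    rng = np.random.default_rng(params.rng_seed + 1) if rng is None else rng
    females = np.flatnonzero(adults.sex == "female")
    males = np.flatnonzero(adults.sex == "male")
    if females.size == 0 or males.size == 0:
        raise PopulationError("progeny simulation needs both sexes among adults")
    n = params.n_seeds
    mother_idx = rng.choice(females, size=n)
    # pollen kernel: father weight ~ exp(-d(mother, male) / lambda_p)
    dx = adults.xy[females][:, None, :] - adults.xy[males][None, :, :]
    dist_fm = np.sqrt((dx**2).sum(axis=2))  # (n_f, n_m)
    female_pos = {f: k for k, f in enumerate(females)}
    father_idx = np.empty(n, dtype=np.int64)
    for s in range(n):
        w = np.exp(-dist_fm[female_pos[mother_idx[s]]] / params.pollen_kernel_mean)
        father_idx[s] = males[rng.choice(males.size, p=w / w.sum())]

    # Mendelian transmission: one uniformly chosen allele from each parent
    pick_m = rng.integers(0, 2, size=(n, adults.n_loci))
    pick_f = rng.integers(0, 2, size=(n, adults.n_loci))
    row_ix = np.arange(n)[:, None]
    loc_ix = np.arange(adults.n_loci)[None, :]
    geno = np.empty((n, adults.n_loci, 2), dtype=np.int64)
    geno[:, :, 0] = adults.genotypes[mother_idx][row_ix, loc_ix, pick_m]
    geno[:, :, 1] = adults.genotypes[father_idx][row_ix, loc_ix, pick_f]

    dep = np.empty((n, 2))
    seed_dist = np.empty(n)
    for s in range(n):
        mx, my = adults.xy[mother_idx[s]]
        dep[s, 0], dep[s, 1], seed_dist[s] = _sample_deposition(
            mx, my, params.seed_kernel_mean, params.window, rng
        )
    pollen_dist = np.sqrt(
        ((adults.xy[mother_idx] - adults.xy[father_idx]) ** 2).sum(axis=1)
    )
    father_dist = np.sqrt(((dep - adults.xy[father_idx]) ** 2).sum(axis=1))

    d_star = np.minimum(seed_dist, father_dist)
    p_surv = 1.0 / (1.0 + np.exp(-(d_star - params.jc_d50) / params.jc_slope))
    survived = rng.random(n) < p_surv

    ids = np.array([f"S{k+1}" for k in range(n)], dtype=object)
    truth = SimulationTruth(
        table=pd.DataFrame(
            {
                "offspring": ids,
                "mother": adults.ids[mother_idx],
                "father": adults.ids[father_idx],
                "pollen_dist": pollen_dist,
                "seed_dist": seed_dist,
                "father_dist": father_dist,
                "x": dep[:, 0],
                "y": dep[:, 1],
                "survived": survived,
            }
        ),
        true_genotypes=geno,
        loci=adults.loci,
    )
    offspring = Population(
        ids=ids,
        xy=dep,
        dbh=rng.uniform(0.5, 5.0, size=n),  # seedlings: cohort I by size
        sex=np.array(["undetermined"] * n, dtype=object),
        cohort=np.array(["I"] * n, dtype=object),
        loci=adults.loci,
        genotypes=geno,
        window=params.window,
    )
    return offspring, truth


def apply_genotyping_error(
    pop: Population,
    error_rate: float,
    missing_rate: float,
    rng_seed: int | np.random.Generator = 0,
    freqs: AlleleFrequencies | None = None,
) -> Population:
    """Independently per individual per locus: with probability
    ``error_rate`` replace the genotype by a random HWE draw at the
    population allele frequencies, then with probability ``missing_rate``
    blank the locus.  This is the generative counterpart of the
    parentage error model."""
    if not (0 <= error_rate < 1) or not (0 <= missing_rate < 1):
        raise PopulationError("rates must be in [0, 1)")
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator) else rng_seed
    if freqs is None:
        freqs = allele_frequencies(pop)
    out = pop.subset(np.arange(pop.n))
    geno = out.genotypes.copy()
    for l in range(pop.n_loci):
        labels, p = freqs.alleles[l], freqs.freqs[l]
        err = rng.random(pop.n) < error_rate
        n_err = int(err.sum())
        if n_err:
            geno[err, l, 0] = labels[rng.choice(labels.size, size=n_err, p=p)]
            geno[err, l, 1] = labels[rng.choice(labels.size, size=n_err, p=p)]
        miss = rng.random(pop.n) < missing_rate
        geno[miss, l, :] = MISSING
    out.genotypes = geno
    return out


@dataclass
class StudyData:
    """One synthetic study: adults, the established (surviving) seedling
    cohort with observation error applied, and the truth record."""

    adults: Population
    seedlings: Population
    truth: SimulationTruth
    params: SimulationParams


def simulate_study(params: SimulationParams) -> StudyData:
    """Adults -> seeds -> Janzen-Connell thinning -> observed seedlings.

    Genotyping error and missingness are applied to the surviving
    seedlings (their observed genotypes), using adult allele frequencies
    as the HWE reference, matching the parentage likelihood."""
    rng = np.random.default_rng(params.rng_seed)
    adults = simulate_adults(params, rng)
    offspring, truth = simulate_progeny(adults, params, rng)
    survivors = offspring.subset(truth.table["survived"].to_numpy(bool))
    seedlings = apply_genotyping_error(
        survivors,
        params.genotyping_error,
        params.missing_rate,
        rng,
        freqs=allele_frequencies(adults),
    )
    return StudyData(adults=adults, seedlings=seedlings, truth=truth, params=params)
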