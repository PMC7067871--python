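"""Fine-scale spatial genetic structure (FSGS).

Pairwise kinship uses the Loiselle-type estimator: per locus l, with
allele dosages x_ia in {0, 0.5, 1} and reference frequencies p_a
estimated from n individuals,

    F_ij,l = sum_a [ (x_ia - p_a)(x_ja - p_a) + p_a(1-p_a)/(n-1) ]
             / sum_a p_a(1-p_a),

combined across loci weighting by the polymorphic-information term
w_l = sum_a p_a(1-p_a); a pair missing a locus drops that locus from
both sums.  The spatial analysis bins pairs into half-open distance
classes, tests each class mean against a null built by permuting
genotypes over the fixed coordinates, regresses F_ij on ln(d_ij) over
all pairs, and summarizes FSGS intensity with Sp = -b_log / (1 - F1)
where F1 is the first-class mean kinship.  Slope uncertainty comes from
a delete-one-locus jackknife.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import (
    DistanceClassSpec,
    Population,
    PopulationError,
    pairwise_distances,
)
from .diversity import AlleleFrequencies, allele_frequencies


@dataclass
class KinshipResult:
    """Pairwise kinship with per-locus components.

    ``locus_num[l]`` is the (n, n) numerator matrix at locus l (already
    including the 1/(n-1) sampling-bias term), ``locus_weight[l]`` the
    denominator weight, ``valid[l]`` marks pairs with both genotypes
    read.  The multilocus matrix is the weight-combined ratio.
    """

    ids: np.ndarray
    locus_num: np.ndarray  # (L, n, n)
    locus_weight: np.ndarray  # (L,)
    valid: np.ndarray  # (L, n, n) bool
    freqs: AlleleFrequencies
    n_ref: np.ndarray  # (L,) reference individuals per locus

    @property
    def n(self) -> int:
        return len(self.ids)

    def multilocus(self, exclude_locus: int | None = None) -> np.ndarray:
        """(n, n) multilocus F_ij; NaN where no locus is co-typed.
        ``exclude_locus`` supports the jackknife."""
        keep = np.ones(len(self.locus_weight), dtype=bool)
        if exclude_locus is not None:
            keep[exclude_locus] = False
        num = np.einsum("lij->ij", self.locus_num[keep] * self.valid[keep])
        den = np.einsum("l,lij->ij", self.locus_weight[keep], self.valid[keep])
        with np.errstate(invalid="ignore", divide="ignore"):
            out = num / den
        out[den <= 0] = np.nan
        return out


def kinship_matrix(pop: Population, reference: Population | None = None) -> KinshipResult:
    """Loiselle-type pairwise kinship of ``pop`` relative to allele
    frequencies estimated from ``reference`` (default: ``pop`` itself).

    Monomorphic loci carry zero weight.  Raises if every locus is
    monomorphic in the reference.
    """
    ref = pop if reference is None else reference
    freqs = allele_frequencies(ref)
    if tuple(ref.loci) != tuple(pop.loci):
        raise PopulationError("population and reference must share the locus list")
    n, L = pop.n, pop.n_loci
    called_pop = pop.called()
    called_ref = ref.called()
    locus_num = np.zeros((L, n, n))
    locus_weight = np.zeros(L)
    valid = np.zeros((L, n, n), dtype=bool)
    n_ref = called_ref.sum(axis=0).astype(np.int64)
    any_poly = False
    for l in range(L):
        labels, p = freqs.alleles[l], freqs.freqs[l]
        w = float(np.sum(p * (1 - p)))
        if w <= 0 or n_ref[l] < 2:
            continue  # monomorphic or unusable: zero weight
        any_poly = True
        pop_alleles = pop.genotypes[called_pop[:, l], l, :]
        if not np.isin(pop_alleles, labels).all():
            raise PopulationError(
                f"locus {pop.loci[l]}: alleles outside the reference frequency set"
            )
        lut = {a: k for k, a in enumerate(labels)}
        dosage = np.zeros((n, labels.size))
        for i in np.flatnonzero(called_pop[:, l]):
            a, b = pop.genotypes[i, l]
            dosage[i, lut[a]] += 0.5
            dosage[i, lut[b]] += 0.5
        centered = dosage - p[None, :]
        bias = float(np.sum(p * (1 - p)) / (n_ref[l] - 1))
        locus_num[l] = centered @ centered.T + bias
        locus_weight[l] = w
        valid[l] = np.outer(called_pop[:, l], called_pop[:, l])
    if not any_poly:
        raise PopulationError("all loci monomorphic in reference; kinship undefined")
    return KinshipResult(
        ids=pop.ids,
        locus_num=locus_num,
        locus_weight=locus_weight,
        valid=valid,
        freqs=freqs,
        n_ref=n_ref,
    )


@dataclass
class Autocorrelogram:
    """Per-distance-class mean kinship with a permutation null.

    ``table`` columns: ``lower``, ``upper`` (m), ``n_pairs``, ``mean_f``,
    ``env_low``/``env_high`` (95% permutation envelope) and the
    two-sided permutation ``p``.
    """

    table: pd.DataFrame
    n_perm: int

    @property
    def first_class_mean(self) -> float:
        return float(self.table["mean_f"].iloc[0])

    def significant(self) -> np.ndarray:
        """Classes whose observed mean falls outside the envelope."""
        t = self.table
        return ((t["mean_f"] > t["env_high"]) | (t["mean_f"] < t["env_low"])).to_numpy()


def _envelope_bounds(null: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Order-statistic envelope: the m-th smallest / largest null value
    with m = floor(alpha/2 * (n_perm + 1)), so a null observation falls
    outside with probability ~alpha."""
    n_perm = null.shape[0]
    m = max(1, int(np.floor(alpha / 2 * (n_perm + 1))))
    srt = np.sort(null, axis=0)
    return srt[m - 1], srt[n_perm - m]


def _two_sided_rank_p(obs: float, null: np.ndarray) -> float:
    # tie tolerance absorbs float jitter from permutation-dependent
    # summation order (degenerate nulls must give p = 1)
    atol = 1e-9 * max(1e-30, float(np.nanmax(np.abs(null))), abs(obs))
    ge = int(np.sum(null >= obs - atol)) + 1
    le = int(np.sum(null <= obs + atol)) + 1
    return min(1.0, 2.0 * min(ge, le) / (null.size + 1))


def _class_means(values: np.ndarray, class_idx: np.ndarray, n_classes: int) -> np.ndarray:
    ok = np.isfinite(values)
    sums = np.bincount(class_idx[ok], weights=values[ok], minlength=n_classes)
    cnts = np.bincount(class_idx[ok], minlength=n_classes)
    with np.errstate(invalid="ignore"):
        return np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)


def _pair_permutation_null(
    fmat: np.ndarray,
    pi: np.ndarray,
    pj: np.ndarray,
    class_idx: np.ndarray,
    n_classes: int,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null class means from permuting genotypes over fixed coordinates:
    pair (i, j) reads F at the permuted individuals."""
    null = np.empty((n_perm, n_classes))
    for b in range(n_perm):
        perm = rng.permutation(fmat.shape[0])
        null[b] = _class_means(fmat[perm[pi], perm[pj]], class_idx, n_classes)
    return null


def autocorrelogram(
    kin: KinshipResult,
    distances: np.ndarray,
    classes: DistanceClassSpec = DistanceClassSpec(),
    n_perm: int = 10_000,
    rng_seed: int | np.random.Generator = 0,
    pair_mask: np.ndarray | None = None,
) -> Autocorrelogram:
    """Kinship autocorrelogram with permutation envelopes.

    ``pair_mask`` (optional, (n, n) bool) restricts the analysis to a
    subset of pairs — used for the between-cohort variant.  Raises if a
    distance class contains no pairs.
    """
    if n_perm < 99:
        raise PopulationError("need at least 99 permutations")
    n = kin.n
    if distances.shape != (n, n):
        raise PopulationError("distance matrix does not match kinship")
    fmat = kin.multilocus()
    iu, ju = np.triu_indices(n, k=1)
    if pair_mask is not None:
        keep = pair_mask[iu, ju] | pair_mask[ju, iu]
        iu, ju = iu[keep], ju[keep]
    class_idx = classes.classify(distances[iu, ju])
    in_class = class_idx >= 0
    pi, pj, ci = iu[in_class], ju[in_class], class_idx[in_class]
    counts = np.bincount(ci, minlength=classes.n_classes)
    if (counts == 0).any():
        empty = [classes.bounds()[k] for k in np.flatnonzero(counts == 0)]
        raise PopulationError(f"empty distance classes {empty}")
    observed = _class_means(fmat[pi, pj], ci, classes.n_classes)
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    null = _pair_permutation_null(fmat, pi, pj, ci, classes.n_classes, n_perm, rng)
    env_low, env_high = _envelope_bounds(null)
    pvals = [_two_sided_rank_p(observed[k], null[:, k]) for k in range(classes.n_classes)]
    bounds = classes.bounds()
    table = pd.DataFrame(
        {
            "lower": [b[0] for b in bounds],
            "upper": [b[1] for b in bounds],
            "n_pairs": counts,
            "mean_f": observed,
            "env_low": env_low,
            "env_high": env_high,
            "p": pvals,
        }
    )
    return Autocorrelogram(table=table, n_perm=n_perm)


def kinship_log_regression(
    kin: KinshipResult,
    distances: np.ndarray,
    n_perm: int = 10_000,
    rng_seed: int | np.random.Generator = 0,
    max_distance: float | None = None,
    pair_mask: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """OLS slope b_log of pairwise F_ij on ln(d_ij) over all pairs.

    Returns ``(b_log, jackknife_se, permutation_p)``: SE from deleting
    one locus at a time, p from the genotype-over-location permutation
    null.  Pairs at zero distance (co-located stems) are excluded with a
    warning; ``max_distance`` optionally restricts the pair set.
    """
    n = kin.n
    fmat = kin.multilocus()
    iu, ju = np.triu_indices(n, k=1)
    if pair_mask is not None:
        keep = pair_mask[iu, ju] | pair_mask[ju, iu]
        iu, ju = iu[keep], ju[keep]
    d = distances[iu, ju]
    if (d == 0).any():
        warnings.warn(
            f"excluding {int((d == 0).sum())} co-located pairs from the regression",
            stacklevel=2,
        )
    keep = d > 0
    if max_distance is not None:
        keep &= d <= max_distance
    pi, pj, d = iu[keep], ju[keep], d[keep]
    x = np.log(d)
    y = fmat[pi, pj]
    ok = np.isfinite(y)
    pi, pj, x, y = pi[ok], pj[ok], x[ok], y[ok]
    if np.unique(x).size < 3:
        raise PopulationError("need >= 3 pairs with distinct distances")

    xc = x - x.mean()
    sxx = float(np.sum(xc**2))

    def slope_of(values: np.ndarray) -> float:
        return float(np.sum(xc * (values - values.mean())) / sxx)

    b = slope_of(y)

    # delete-one-locus jackknife on the slope
    usable = np.flatnonzero(kin.locus_weight > 0)
    if usable.size < 2:
        raise PopulationError("jackknife SE needs >= 2 polymorphic loci")
    pseudo = []
    for l in usable:
        f_del = kin.multilocus(exclude_locus=int(l))
        y_del = f_del[pi, pj]
        ok_del = np.isfinite(y_del)
        if ok_del.sum() < 3:
            continue
        xd = x[ok_del] - x[ok_del].mean()
        yd = y_del[ok_del]
        pseudo.append(float(np.sum(xd * (yd - yd.mean())) / np.sum(xd**2)))
    pseudo_arr = np.array(pseudo)
    k = pseudo_arr.size
    se = float(np.sqrt((k - 1) / k * np.sum((pseudo_arr - pseudo_arr.mean()) ** 2)))

    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    null = np.empty(n_perm)
    for it in range(n_perm):
        perm = rng.permutation(n)
        yp = fmat[perm[pi], perm[pj]]
        okp = np.isfinite(yp)
        xp = x[okp] - x[okp].mean()
        null[it] = np.sum(xp * (yp[okp] - yp[okp].mean())) / np.sum(xp**2)
    p = _two_sided_rank_p(b, null)
    return b, se, p


def sp_statistic(b_log: float, f1: float) -> float:
    """FSGS intensity Sp = -b_log / (1 - F1), with F1 the mean kinship of
    the first distance class."""
    if f1 >= 1:
        raise PopulationError("first-class mean kinship must be < 1")
    return -b_log / (1.0 - f1)


@dataclass
class SpResult:
    """Sp summary for one cohort: regression slope (with jackknife SE and
    permutation p), first-class mean kinship and Sp, plus the full
    autocorrelogram."""

    b_log: float
    b_se: float
    b_p: float
    f1: float
    sp: float
    correlogram: Autocorrelogram


def sp_analysis(
    pop: Population,
    classes: DistanceClassSpec = DistanceClassSpec(),
    n_perm: int = 10_000,
    rng_seed: int = 0,
    reference: Population | None = None,
    max_distance: float | None = None,
) -> SpResult:
    """One-call FSGS analysis of a (sub)population: kinship ->
    autocorrelogram -> ln-distance regression -> Sp."""
    kin = kinship_matrix(pop, reference=reference)
    dmat = pairwise_distances(pop)
    rng = np.random.default_rng(rng_seed)
    corr = autocorrelogram(kin, dmat, classes, n_perm=n_perm, rng_seed=rng)
    b, se, p = kinship_log_regression(
        kin, dmat, n_perm=n_perm, rng_seed=rng, max_distance=max_distance
    )
    f1 = corr.first_class_mean
    return SpResult(b_log=b, b_se=se, b_p=p, f1=f1,
                    sp=sp_statistic(b, f1), correlogram=corr)


def _concat(a: Population, b: Population) -> Population:
    if tuple(a.loci) != tuple(b.loci):
        raise PopulationError("cohorts must share the locus list")
    return Population(
        ids=np.concatenate([a.ids, b.ids]),
        xy=np.vstack([a.xy, b.xy]),
        dbh=np.concatenate([a.dbh, b.dbh]),
        sex=np.concatenate([a.sex, b.sex]),
        cohort=np.concatenate([a.cohort, b.cohort]),
        loci=a.loci,
        genotypes=np.vstack([a.genotypes, b.genotypes]),
        window=a.window,
    )


def between_class_autocorrelogram(
    cohort_a: Population,
    cohort_b: Population,
    classes: DistanceClassSpec = DistanceClassSpec(),
    n_perm: int = 10_000,
    rng_seed: int = 0,
) -> Autocorrelogram:
    """Kinship autocorrelogram restricted to pairs with one member from
    each cohort (e.g. seedlings vs large adults), reference allele
    frequencies from the union, null permuting genotypes over all union
    locations."""
    if cohort_a.n == 0 or cohort_b.n == 0:
        raise PopulationError("both cohorts must be nonempty")
    if set(cohort_a.ids.tolist()) & set(cohort_b.ids.tolist()):
        raise PopulationError("cohorts must be disjoint")
    union = _concat(cohort_a, cohort_b)
    kin = kinship_matrix(union)
    dmat = pairwise_distances(union)
    mask = np.zeros((union.n, union.n), dtype=bool)
    mask[: cohort_a.n, cohort_a.n:] = True
    return autocorrelogram(
        kin, dmat, classes, n_perm=n_perm, rng_seed=rng_seed, pair_mask=mask
    )
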