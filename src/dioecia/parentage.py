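"""Likelihood parentage assignment with a genotyping-error model.

Candidate parents are scored with multilocus LOD ratios against a
random-parent hypothesis.  The error model is a single per-locus rate
epsilon: with probability epsilon the observed offspring genotype is an
independent Hardy-Weinberg draw at the population allele frequencies, so

    P(g_obs | parents) = (1 - eps) * P_Mendel(g_obs | g_m, g_f)
                         + eps * P_HWE(g_obs).

Assignment confidence is calibrated by simulation: offspring are
generated both with the true father inside and outside the candidate
pool, and the LOD cutoffs at which at least 95% / 80% of best-candidate
assignments are correct become the two confidence tiers.  Exclusion
probabilities (the chance a random unrelated candidate is
genotype-incompatible) are computed per locus from the allele-frequency
moments and combined multiplicatively across loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import MISSING, Population, PopulationError
from .diversity import AlleleFrequencies, allele_frequencies

#: LOD gap below which two best candidates are declared tied (unassigned).
TIE_TOLERANCE = 1e-9


@dataclass(frozen=True)
class ErrorModel:
    """Per-locus probability that an observed genotype is a random HWE
    draw instead of the Mendelian one."""

    epsilon: float = 0.0923

    def __post_init__(self) -> None:
        if not (0 <= self.epsilon < 1):
            raise PopulationError("epsilon must be in [0, 1)")


@dataclass(frozen=True)
class CalibrationParams:
    """Simulation settings for the LOD confidence tiers."""

    n_sim: int = 2000
    rng_seed: int = 0
    tiers: tuple[float, ...] = (0.95, 0.80)


# ---------------------------------------------------------------------------
# per-locus genotype tables


class LocusTables:
    """Genotype enumeration and transition tables for one locus.

    Unordered genotypes (i <= j over allele indices) are enumerated once;
    ``mendel[gm, gf, go]`` is the Mendelian transmission probability,
    ``hwe[go]`` the Hardy-Weinberg genotype probability and
    ``trans_mo[gm, go]`` the mother-offspring transition with a random
    father drawn from the allele frequencies.
    """

    def __init__(self, labels: np.ndarray, p: np.ndarray):
        self.labels = np.asarray(labels)
        self.p = np.asarray(p, dtype=float)
        a = self.labels.size
        pairs = [(i, j) for i in range(a) for j in range(i, a)]
        self.genos = np.array(pairs, dtype=np.int64)
        self.n_genos = len(pairs)
        self.geno_id = np.full((a, a), -1, dtype=np.int64)
        for g, (i, j) in enumerate(pairs):
            self.geno_id[i, j] = self.geno_id[j, i] = g
        hwe = np.empty(self.n_genos)
        for g, (i, j) in enumerate(pairs):
            hwe[g] = self.p[i] ** 2 if i == j else 2 * self.p[i] * self.p[j]
        self.hwe = hwe
        # Mendel: average over the four equally likely transmissions
        G = self.n_genos
        mendel = np.zeros((G, G, G))
        for gm, (m1, m2) in enumerate(pairs):
            for gf, (f1, f2) in enumerate(pairs):
                for am in (m1, m2):
                    for af in (f1, f2):
                        mendel[gm, gf, self.geno_id[am, af]] += 0.25
        self.mendel = mendel
        self.trans_mo = np.einsum("f,mfo->mo", hwe, mendel)

    def encode(self, alleles: np.ndarray) -> int:
        """Genotype index for an (allele-label) pair; -1 if either allele
        is missing.  Raises on labels absent from the frequency set."""
        a, b = alleles
        if a == MISSING or b == MISSING:
            return -1
        ia = np.searchsorted(self.labels, a)
        ib = np.searchsorted(self.labels, b)
        if (ia >= self.labels.size or self.labels[ia] != a
                or ib >= self.labels.size or self.labels[ib] != b):
            raise PopulationError(
                f"allele outside the reference frequency set: {a}/{b}"
            )
        return int(self.geno_id[ia, ib])


def build_tables(freqs: AlleleFrequencies) -> list[LocusTables]:
    return [LocusTables(freqs.alleles[l], freqs.freqs[l]) for l in range(len(freqs.loci))]


def encode_population(pop: Population, tables: Sequence[LocusTables]) -> np.ndarray:
    """(n, L) genotype indices; -1 where a locus is not fully read."""
    out = np.full((pop.n, pop.n_loci), -1, dtype=np.int64)
    for l, tab in enumerate(tables):
        for i in range(pop.n):
            out[i, l] = tab.encode(pop.genotypes[i, l])
    return out


def transition_probability(
    g_offspring: tuple[int, int] | None,
    g_mother: tuple[int, int] | None,
    g_father: tuple[int, int] | None,
    locus_freqs: Mapping[int, float],
    error: ErrorModel = ErrorModel(0.0),
) -> float:
    """Single-locus P(observed offspring | parents) under the error
    model.  A missing genotype (``None`` or a missing allele) makes the
    locus uninformative: likelihood 1."""
    labels = np.array(sorted(locus_freqs), dtype=np.int64)
    p = np.array([locus_freqs[a] for a in labels], dtype=float)
    tab = LocusTables(labels, p)

    def enc(g):
        if g is None:
            return -1
        pair = tuple(MISSING if a is None else a for a in g)
        return tab.encode(np.array(pair))

    go, gm, gf = enc(g_offspring), enc(g_mother), enc(g_father)
    if go < 0 or gm < 0 or gf < 0:
        return 1.0
    eps = error.epsilon
    return float((1 - eps) * tab.mendel[gm, gf, go] + eps * tab.hwe[go])


# ---------------------------------------------------------------------------
# exclusion probabilities


@dataclass
class ExclusionResult:
    """Per-locus and combined non-exclusion/exclusion probabilities.

    ``q1``: a random candidate excluded as the only known parent;
    ``q2``: excluded as second parent given one known parent;
    ``q3``: a random unrelated pair excluded as the parent pair.
    Combined across loci as 1 - prod(1 - q)."""

    per_locus: pd.DataFrame
    combined_q1: float
    combined_q2: float
    combined_q3: float


def _locus_exclusion(p: np.ndarray) -> tuple[float, float, float]:
    """Closed-form per-locus exclusion probabilities (allele-frequency
    moments), averaging over offspring (and known-parent) genotypes
    under HWE with error-free logic."""
    s2 = float(np.sum(p**2))
    s3 = float(np.sum(p**3))
    s4 = float(np.sum(p**4))
    s5 = float(np.sum(p**5))
    s6 = float(np.sum(p**6))
    q1 = 1 - 4 * s2 + 2 * s2**2 + 4 * s3 - 3 * s4
    q2 = 1 - 2 * s2 + s3 + 2 * s4 - 3 * s5 - 2 * s2**2 + 3 * s2 * s3
    q3 = 1 + 4 * s4 - 4 * s5 - 3 * s6 - 8 * s2**2 + 8 * s2 * s3 + 2 * s3**2
    return q1, q2, q3


def exclusion_probabilities(freqs: AlleleFrequencies) -> ExclusionResult:
    """Exclusion power of the marker panel; raises only implicitly (a
    fully monomorphic panel yields combined Q = 0)."""
    rows = []
    for l, locus in enumerate(freqs.loci):
        q1, q2, q3 = _locus_exclusion(freqs.freqs[l])
        rows.append({"locus": locus, "q1": q1, "q2": q2, "q3": q3})
    df = pd.DataFrame(rows)
    comb = {c: 1.0 - float(np.prod(1.0 - df[c].to_numpy())) for c in ("q1", "q2", "q3")}
    return ExclusionResult(per_locus=df, combined_q1=comb["q1"],
                           combined_q2=comb["q2"], combined_q3=comb["q3"])


# ---------------------------------------------------------------------------
# LOD machinery


def _paternity_lods(
    go: np.ndarray,  # (L,) offspring genotype indices
    gm: np.ndarray,  # (L,) mother genotype indices
    cand: np.ndarray,  # (n_cand, L) candidate genotype indices
    tables: Sequence[LocusTables],
    eps: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Multilocus LOD per candidate and Mendelian-mismatch counts.

    LOD = sum_l ln[ P(g_o | g_m, candidate) / P(g_o | g_m, random male) ];
    a locus missing in the offspring, mother or candidate contributes 0.
    """
    n_cand = cand.shape[0]
    lod = np.zeros(n_cand)
    mismatches = np.zeros(n_cand, dtype=np.int64)
    for l, tab in enumerate(tables):
        if go[l] < 0 or gm[l] < 0:
            continue
        cl = cand[:, l]
        ok = cl >= 0
        if not ok.any():
            continue
        mend = tab.mendel[gm[l], cl[ok], go[l]]
        num = (1 - eps) * mend + eps * tab.hwe[go[l]]
        den = (1 - eps) * tab.trans_mo[gm[l], go[l]] + eps * tab.hwe[go[l]]
        with np.errstate(divide="ignore"):
            lod[ok] += np.log(num) - np.log(den)
        mismatches[ok] += (mend == 0).astype(np.int64)
    return lod, mismatches


def _pair_lods(
    go: np.ndarray,
    females: np.ndarray,  # (n_f, L)
    males: np.ndarray,  # (n_m, L)
    tables: Sequence[LocusTables],
    eps: float,
) -> tuple[np.ndarray, np.ndarray]:
    """(n_f, n_m) joint LOD = sum_l ln[P(g_o|g_f,g_m)/P_HWE(g_o)] and
    mismatch counts; a locus missing anywhere contributes 0 for that
    pair."""
    n_f, n_m = females.shape[0], males.shape[0]
    lod = np.zeros((n_f, n_m))
    mism = np.zeros((n_f, n_m), dtype=np.int64)
    for l, tab in enumerate(tables):
        if go[l] < 0:
            continue
        gf = females[:, l]
        gm = males[:, l]
        okf, okm = gf >= 0, gm >= 0
        gf_safe = np.where(okf, gf, 0)
        gm_safe = np.where(okm, gm, 0)
        mend = tab.mendel[gf_safe[:, None], gm_safe[None, :], go[l]]
        num = (1 - eps) * mend + eps * tab.hwe[go[l]]
        with np.errstate(divide="ignore"):
            contrib = np.log(num) - np.log(tab.hwe[go[l]])
        mask = okf[:, None] & okm[None, :]
        lod += np.where(mask, contrib, 0.0)
        mism += np.where(mask, mend == 0, False).astype(np.int64)
    return lod, mism


def _threshold_from_sims(lods: np.ndarray, correct: np.ndarray, tier: float) -> float:
    """Smallest LOD cutoff whose accepted set keeps cumulative accuracy
    >= tier (walking down from the highest simulated best-LOD);
    +inf when no prefix qualifies."""
    order = np.argsort(-lods)
    acc = np.cumsum(correct[order]) / np.arange(1, lods.size + 1)
    qualifying = np.flatnonzero(acc >= tier)
    if qualifying.size == 0:
        return np.inf
    return float(lods[order][qualifying[-1]])


def _simulate_offspring_genotype(
    gm: np.ndarray,
    gf: np.ndarray | None,
    tables: Sequence[LocusTables],
    eps: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One simulated offspring (genotype indices) from parent genotype
    indices; a missing parent locus (or absent father) draws that gamete
    from the allele frequencies; error then replaces the genotype with an
    HWE draw at rate eps."""
    L = len(tables)
    out = np.empty(L, dtype=np.int64)
    for l, tab in enumerate(tables):
        if gm[l] >= 0:
            am = tab.genos[gm[l]][rng.integers(0, 2)]
        else:
            am = rng.choice(tab.p.size, p=tab.p)
        if gf is not None and gf[l] >= 0:
            af = tab.genos[gf[l]][rng.integers(0, 2)]
        else:
            af = rng.choice(tab.p.size, p=tab.p)
        g = tab.geno_id[am, af]
        if eps > 0 and rng.random() < eps:
            a1 = rng.choice(tab.p.size, p=tab.p)
            a2 = rng.choice(tab.p.size, p=tab.p)
            g = tab.geno_id[a1, a2]
        out[l] = g
    return out


def calibrate_paternity_thresholds(
    mother_enc: np.ndarray,
    cand_enc: np.ndarray,
    tables: Sequence[LocusTables],
    eps: float,
    calibration: CalibrationParams,
) -> dict[float, float]:
    """LOD tier thresholds from simulated offspring with the true father
    alternately inside and outside the candidate pool."""
    rng = np.random.default_rng(calibration.rng_seed)
    n_sim = calibration.n_sim
    n_cand = cand_enc.shape[0]
    lods = np.empty(n_sim)
    correct = np.zeros(n_sim, dtype=bool)
    for s in range(n_sim):
        gm = mother_enc[rng.integers(0, mother_enc.shape[0])]
        inside = s % 2 == 0
        true_f = int(rng.integers(0, n_cand)) if inside else None
        gf = cand_enc[true_f] if inside else None
        go = _simulate_offspring_genotype(gm, gf, tables, eps, rng)
        lod, _ = _paternity_lods(go, gm, cand_enc, tables, eps)
        best = int(np.argmax(lod))
        lods[s] = lod[best]
        runner = np.partition(lod, -2)[-2] if n_cand > 1 else -np.inf
        with np.errstate(invalid="ignore"):
            tied = bool(lod[best] - runner < TIE_TOLERANCE)
        correct[s] = inside and best == true_f and not tied
    return {tier: _threshold_from_sims(lods, correct, tier)
            for tier in calibration.tiers}


def calibrate_pair_thresholds(
    female_enc: np.ndarray,
    male_enc: np.ndarray,
    tables: Sequence[LocusTables],
    eps: float,
    calibration: CalibrationParams,
) -> dict[float, float]:
    """LOD tier thresholds for parent-pair assignment (true pair inside
    vs both parents outside the candidate pools)."""
    rng = np.random.default_rng(calibration.rng_seed)
    n_sim = calibration.n_sim
    lods = np.empty(n_sim)
    correct = np.zeros(n_sim, dtype=bool)
    for s in range(n_sim):
        inside = s % 2 == 0
        if inside:
            fi = int(rng.integers(0, female_enc.shape[0]))
            mi = int(rng.integers(0, male_enc.shape[0]))
            gm, gf = female_enc[fi], male_enc[mi]
        else:
            gm = gf = None
        go = _simulate_offspring_genotype(
            gm if gm is not None else np.full(len(tables), -1, dtype=np.int64),
            gf, tables, eps, rng,
        )
        lod, _ = _pair_lods(go, female_enc, male_enc, tables, eps)
        flat = lod.ravel()
        best = int(np.argmax(flat))
        lods[s] = flat[best]
        runner = np.partition(flat, -2)[-2] if flat.size > 1 else -np.inf
        with np.errstate(invalid="ignore"):
            tied = bool(flat[best] - runner < TIE_TOLERANCE)
        bf, bm = np.unravel_index(best, lod.shape)
        correct[s] = inside and (bf, bm) == (fi, mi) and not tied
    return {tier: _threshold_from_sims(lods, correct, tier)
            for tier in calibration.tiers}


def _tier_label(lod: float, thresholds: dict[float, float]) -> str | None:
    for tier in sorted(thresholds, reverse=True):
        if lod >= thresholds[tier]:
            return f"{int(round(tier * 100))}%"
    return None


# ---------------------------------------------------------------------------
# public assignment interfaces


def assign_paternity(
    offspring: Population,
    mother_ids: Sequence[str],
    adults: Population,
    candidate_males: Population | None = None,
    freqs: AlleleFrequencies | None = None,
    error: ErrorModel = ErrorModel(),
    calibration: CalibrationParams = CalibrationParams(),
) -> pd.DataFrame:
    """Paternity of offspring with known mothers (e.g. seeds sampled on
    the maternal tree) among candidate males.

    Returns one row per offspring: assigned father (or None), multilocus
    LOD, confidence tier, Mendelian mismatch count and the mother-father
    (pollen) distance.  With epsilon = 0 a uniquely compatible candidate
    is assigned outright at the top tier (pure exclusion logic); ties
    within 1e-9 LOD are left unassigned.
    """
    if candidate_males is None:
        candidate_males = adults.by_sex("male")
    if candidate_males.n == 0:
        raise PopulationError("no candidate males")
    if len(mother_ids) != offspring.n:
        raise PopulationError("mother_ids must align with offspring")
    if freqs is None:
        freqs = allele_frequencies(adults)
    tables = build_tables(freqs)
    eps = error.epsilon
    off_enc = encode_population(offspring, tables)
    cand_enc = encode_population(candidate_males, tables)
    midx = adults.index_of(mother_ids)
    mother_enc = encode_population(adults, tables)[midx]

    thresholds = calibrate_paternity_thresholds(
        mother_enc, cand_enc, tables, eps, calibration
    )
    rows = []
    top_tier = f"{int(round(max(calibration.tiers) * 100))}%"
    for o in range(offspring.n):
        go, gm = off_enc[o], mother_enc[o]
        lod, mism = _paternity_lods(go, gm, cand_enc, tables, eps)
        father = None
        tier = None
        best_lod = np.nan
        n_mism = 0
        if (go >= 0).any():
            finite = np.isfinite(lod)
            best = int(np.argmax(lod))
            best_lod = float(lod[best])
            runner = np.partition(lod, -2)[-2] if cand_enc.shape[0] > 1 else -np.inf
            with np.errstate(invalid="ignore"):
                tied = bool(best_lod - runner < TIE_TOLERANCE)
            if eps == 0 and finite.sum() == 1 and np.isfinite(best_lod):
                father = candidate_males.ids[best]
                tier = top_tier
            elif np.isfinite(best_lod) and not tied:
                tier = _tier_label(best_lod, thresholds)
                if tier is not None:
                    father = candidate_males.ids[best]
            if father is not None:
                n_mism = int(mism[best])
        pollen = np.nan
        if father is not None:
            fpos = int(np.flatnonzero(candidate_males.ids == father)[0])
            mpos = int(midx[o])
            pollen = float(
                np.hypot(*(adults.xy[mpos] - candidate_males.xy[fpos]))
            )
        rows.append(
            {
                "offspring": offspring.ids[o],
                "mother": mother_ids[o],
                "father": father,
                "lod": best_lod,
                "tier": tier,
                "mismatches": n_mism,
                "pollen_dist_m": pollen,
                "seed_dist_m": np.nan,
            }
        )
    return pd.DataFrame(rows)


def assign_parent_pair(
    offspring: Population,
    candidate_females: Population,
    candidate_males: Population,
    freqs: AlleleFrequencies | None = None,
    error: ErrorModel = ErrorModel(),
    calibration: CalibrationParams = CalibrationParams(),
) -> pd.DataFrame:
    """Joint mother+father assignment for offspring of unknown parentage
    (established seedlings).  Dioecy fixes the parent roles: the female
    member of the best pair is the mother.  Derived distances follow the
    two field definitions: mother-father = realized pollen,
    offspring-mother = realized seed."""
    if candidate_females.n == 0 or candidate_males.n == 0:
        raise PopulationError("need candidates of both sexes")
    if freqs is None:
        freqs = allele_frequencies(_union_freq_source(candidate_females, candidate_males))
    tables = build_tables(freqs)
    eps = error.epsilon
    off_enc = encode_population(offspring, tables)
    f_enc = encode_population(candidate_females, tables)
    m_enc = encode_population(candidate_males, tables)
    thresholds = calibrate_pair_thresholds(f_enc, m_enc, tables, eps, calibration)
    top_tier = f"{int(round(max(calibration.tiers) * 100))}%"
    rows = []
    for o in range(offspring.n):
        go = off_enc[o]
        lod, mism = _pair_lods(go, f_enc, m_enc, tables, eps)
        mother = father = None
        tier = None
        best_lod = np.nan
        n_mism = 0
        if (go >= 0).any():
            flat = lod.ravel()
            best = int(np.argmax(flat))
            best_lod = float(flat[best])
            runner = np.partition(flat, -2)[-2] if flat.size > 1 else -np.inf
            with np.errstate(invalid="ignore"):
                tied = bool(best_lod - runner < TIE_TOLERANCE)
            bf, bm = np.unravel_index(best, lod.shape)
            if eps == 0 and np.isfinite(flat).sum() == 1 and np.isfinite(best_lod):
                mother, father = candidate_females.ids[bf], candidate_males.ids[bm]
                tier = top_tier
            elif np.isfinite(best_lod) and not tied:
                tier = _tier_label(best_lod, thresholds)
                if tier is not None:
                    mother = candidate_females.ids[bf]
                    father = candidate_males.ids[bm]
            if mother is not None:
                n_mism = int(mism[bf, bm])
        pollen = seed = np.nan
        if mother is not None:
            mxy = candidate_females.xy[int(np.flatnonzero(candidate_females.ids == mother)[0])]
            fxy = candidate_males.xy[int(np.flatnonzero(candidate_males.ids == father)[0])]
            pollen = float(np.hypot(*(mxy - fxy)))
            seed = float(np.hypot(*(offspring.xy[o] - mxy)))
        rows.append(
            {
                "offspring": offspring.ids[o],
                "mother": mother,
                "father": father,
                "lod": best_lod,
                "tier": tier,
                "mismatches": n_mism,
                "pollen_dist_m": pollen,
                "seed_dist_m": seed,
            }
        )
    return pd.DataFrame(rows)


def _union_freq_source(a: Population, b: Population) -> Population:
    from .fsgs import _concat

    return _concat(a, b)


def estimate_genotyping_error(
    mothers: Population,
    offspring: Population,
    mother_ids: Sequence[str],
) -> float:
    """Mismatch-rate estimate of the genotyping-error probability from
    known mother-offspring duos: the fraction of co-typed locus
    comparisons where the offspring shares no allele with its mother."""
    if len(mother_ids) != offspring.n:
        raise PopulationError("mother_ids must align with offspring")
    midx = mothers.index_of(mother_ids)
    comparisons = 0
    mismatches = 0
    for o in range(offspring.n):
        for l in range(offspring.n_loci):
            og = offspring.genotypes[o, l]
            mg = mothers.genotypes[midx[o], l]
            if (og < 0).any() or (mg < 0).any():
                continue
            comparisons += 1
            if not (og[0] in mg or og[1] in mg):
                mismatches += 1
    if comparisons == 0:
        raise PopulationError("no co-typed mother-offspring locus comparisons")
    return mismatches / comparisons
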