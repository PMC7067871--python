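"""Genetic-diversity estimators for codominant multilocus data.

Per locus and averaged across loci: allele number Na, allelic richness Ar
(rarefaction to a common gene count), observed heterozygosity Ho, unbiased
expected heterozygosity He = n/(n-1) * (1 - sum p_a^2) and the fixation
index F = 1 - Ho/He, with a bootstrap-over-loci confidence interval for
the multilocus F.  Genotypes with either allele unread are excluded from
the locus entirely (no imputation).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .datamodel import Population, PopulationError


@dataclass
class AlleleFrequencies:
    """Reference allele frequencies per locus.

    ``alleles[l]`` are the sorted distinct allele labels at locus l,
    ``freqs[l]`` the matching relative frequencies (sum 1), ``counts[l]``
    the raw gene counts and ``n_genes[l] = counts[l].sum()`` (twice the
    fully genotyped individuals).
    """

    loci: tuple[str, ...]
    alleles: list[np.ndarray]
    freqs: list[np.ndarray]
    counts: list[np.ndarray]

    @property
    def n_genes(self) -> np.ndarray:
        return np.array([c.sum() for c in self.counts], dtype=np.int64)

    def as_dict(self, locus: str) -> dict[int, float]:
        l = self.loci.index(locus)
        return dict(zip(self.alleles[l].tolist(), self.freqs[l].tolist()))


def allele_frequencies(pop: Population) -> AlleleFrequencies:
    """Count both alleles of every fully read genotype, per locus."""
    called = pop.called()
    alleles_out, freqs_out, counts_out = [], [], []
    for l, locus in enumerate(pop.loci):
        obs = pop.genotypes[called[:, l], l, :].ravel()
        if obs.size == 0:
            raise PopulationError(f"locus {locus} has zero complete genotypes")
        labels, counts = np.unique(obs, return_counts=True)
        alleles_out.append(labels.astype(np.int64))
        counts_out.append(counts.astype(np.int64))
        freqs_out.append(counts / counts.sum())
    return AlleleFrequencies(pop.loci, alleles_out, freqs_out, counts_out)


@dataclass
class DiversitySummary:
    """Per-locus and mean diversity statistics (Table-style output)."""

    per_locus: pd.DataFrame  # columns: locus, n, na, ho, he, f
    n_individuals: int

    @property
    def na(self) -> float:
        return float(self.per_locus["na"].mean())

    @property
    def ho(self) -> float:
        return float(self.per_locus["ho"].mean())

    @property
    def he(self) -> float:
        return float(self.per_locus["he"].mean())

    @property
    def f(self) -> float:
        """Multilocus fixation index: 1 - mean(Ho)/mean(He) over
        polymorphic loci."""
        poly = self.per_locus[self.per_locus["he"] > 0]
        if poly.empty:
            return float("nan")
        return float(1.0 - poly["ho"].mean() / poly["he"].mean())


def diversity_summary(pop: Population) -> DiversitySummary:
    """Na, Ho, unbiased He and F per locus plus multilocus means.

    Monomorphic loci report He = 0 and F = NaN and are excluded from the
    multilocus F.
    """
    if pop.n < 2:
        raise PopulationError("need at least 2 individuals")
    called = pop.called()
    rows = []
    for l, locus in enumerate(pop.loci):
        g = pop.genotypes[called[:, l], l, :]
        n_ind = g.shape[0]
        if n_ind == 0:
            raise PopulationError(f"locus {locus} has zero complete genotypes")
        labels, counts = np.unique(g.ravel(), return_counts=True)
        n_genes = counts.sum()
        p = counts / n_genes
        na = labels.size
        ho = float(np.mean(g[:, 0] != g[:, 1]))
        if na > 1 and n_genes > 1:
            he = float(n_genes / (n_genes - 1) * (1.0 - np.sum(p**2)))
        else:
            he = 0.0
        f = 1.0 - ho / he if he > 0 else float("nan")
        rows.append(
            {"locus": locus, "n": n_ind, "na": na, "ho": ho, "he": he, "f": f}
        )
    return DiversitySummary(per_locus=pd.DataFrame(rows), n_individuals=pop.n)


def _rarefied_richness(counts: np.ndarray, g: int) -> float:
    n = int(counts.sum())
    if g > n:
        raise PopulationError(f"rarefaction size {g} exceeds gene count {n}")
    denom = comb(n, g)
    total = 0.0
    for na in counts:
        m = n - int(na)
        total += 1.0 - (comb(m, g) / denom if m >= g else 0.0)
    return total


def allelic_richness(pop: Population, g: int | None = None) -> pd.Series:
    """Allelic richness Ar(g): expected allele count in a random draw of
    ``g`` genes, per locus (hypergeometric rarefaction).

    ``g`` defaults to the smallest per-locus gene count, the standard
    choice when comparing cohorts of unequal size.
    """
    freqs = allele_frequencies(pop)
    n_genes = freqs.n_genes
    if g is None:
        g = int(n_genes.min())
    if g < 1:
        raise PopulationError("rarefaction size must be >= 1")
    if g > n_genes.min():
        raise PopulationError(
            f"rarefaction size {g} exceeds the smallest locus gene count {n_genes.min()}"
        )
    ar = {locus: _rarefied_richness(freqs.counts[l], g)
          for l, locus in enumerate(freqs.loci)}
    return pd.Series(ar, name=f"ar_g{g}")


def _multilocus_f(per_locus: pd.DataFrame, locus_idx: np.ndarray) -> float:
    sub = per_locus.iloc[locus_idx]
    sub = sub[sub["he"] > 0]
    if sub.empty:
        return float("nan")
    return float(1.0 - sub["ho"].mean() / sub["he"].mean())


def bootstrap_f_ci(
    pop: Population,
    n_boot: int = 1000,
    rng_seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
) -> tuple[float, float, float]:
    """Multilocus F with a percentile CI from resampling loci with
    replacement.  Returns ``(f_hat, lower, upper)``."""
    if n_boot < 100:
        raise PopulationError("need at least 100 bootstrap replicates")
    summ = diversity_summary(pop)
    usable = summ.per_locus[summ.per_locus["he"] > 0]
    if usable.empty:
        raise PopulationError("all loci monomorphic; F undefined")
    n_loci = len(summ.per_locus)
    rng = np.random.default_rng(rng_seed)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n_loci, size=n_loci)
        reps[b] = _multilocus_f(summ.per_locus, idx)
    reps = reps[np.isfinite(reps)]
    lower, upper = np.percentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return summ.f, float(lower), float(upper)


def cohort_table(pop: Population, n_boot: int = 1000, rng_seed: int = 0) -> pd.DataFrame:
    """Per-cohort diversity table: N, Na, Ar, Ho, He, F (bootstrap CI).

    Ar is rarefied to the smallest per-locus gene count across cohorts so
    the cohorts are directly comparable.
    """
    cohorts = [c for c in ("I", "II", "III") if (pop.cohort == c).any()]
    if not cohorts:
        raise PopulationError("no cohorts assigned")
    g = min(
        int(allele_frequencies(pop.by_cohort(c)).n_genes.min()) for c in cohorts
    )
    rows = []
    for c in cohorts:
        sub = pop.by_cohort(c)
        summ = diversity_summary(sub)
        ar = allelic_richness(sub, g)
        f_hat, lo, hi = bootstrap_f_ci(sub, n_boot=n_boot, rng_seed=rng_seed)
        rows.append(
            {
                "cohort": c,
                "n": sub.n,
                "na": summ.na,
                "ar": float(ar.mean()),
                "ho": summ.ho,
                "he": summ.he,
                "f": f_hat,
                "f_ci_low": lo,
                "f_ci_high": hi,
            }
        )
    return pd.DataFrame(rows)
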