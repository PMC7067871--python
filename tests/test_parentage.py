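from itertools import combinations_with_replacement as cwr

import numpy as np
import pytest

from dioecia import (
    CalibrationParams,
    ErrorModel,
    PopulationError,
    assign_parent_pair,
    assign_paternity,
    estimate_genotyping_error,
    exclusion_probabilities,
    transition_probability,
)
from dioecia.datamodel import MISSING
from dioecia.diversity import AlleleFrequencies, allele_frequencies
from dioecia.parentage import _locus_exclusion

from conftest import make_population

A, B = 1, 2


def make_freqs(freq_lists):
    return AlleleFrequencies(
        loci=tuple(f"L{k+1}" for k in range(len(freq_lists))),
        alleles=[np.arange(1, len(p) + 1) for p in freq_lists],
        freqs=[np.asarray(p, dtype=float) for p in freq_lists],
        counts=[np.round(np.asarray(p) * 1000).astype(np.int64) for p in freq_lists],
    )


def enumerate_exclusion(p):
    """Exhaustive enumeration over every genotype configuration at one
    locus under HWE — the independent oracle for exclusion power."""
    A_ = len(p)
    genos = list(cwr(range(A_), 2))

    def hwe(g):
        i, j = g
        return p[i] ** 2 if i == j else 2 * p[i] * p[j]

    def mendel(go, gm, gf):
        return sum(
            0.25
            for am in gm
            for af in gf
            if tuple(sorted((am, af))) == go
        )

    q1 = sum(
        hwe(go) * hwe(gc)
        for go in genos
        for gc in genos
        if not any(a in gc for a in go)
    )
    q2 = sum(
        hwe(gm) * hwe(gf) * mendel(go, gm, gf) * hwe(gc)
        for gm in genos
        for gf in genos
        for go in genos
        if mendel(go, gm, gf) > 0
        for gc in genos
        if mendel(go, gm, gc) == 0
    )
    q3 = sum(
        hwe(go) * hwe(g1) * hwe(g2)
        for go in genos
        for g1 in genos
        for g2 in genos
        if mendel(go, g1, g2) == 0
    )
    return q1, q2, q3


class TestExclusion:
    def test_biallelic_second_parent_hand_value(self):
        ex = exclusion_probabilities(make_freqs([[0.5, 0.5]]))
        assert ex.per_locus["q2"].iloc[0] == pytest.approx(0.1875, abs=1e-12)

    def test_two_loci_combination(self):
        ex = exclusion_probabilities(make_freqs([[0.5, 0.5]] * 2))
        assert ex.combined_q2 == pytest.approx(1 - 0.8125**2, abs=1e-12)

    def test_monomorphic_locus_contributes_nothing(self):
        ex = exclusion_probabilities(make_freqs([[1.0]]))
        assert (ex.combined_q1, ex.combined_q2, ex.combined_q3) == (0.0, 0.0, 0.0)

    @pytest.mark.parametrize(
        "p",
        [
            [0.5, 0.5],
            [0.2, 0.3, 0.5],
            [0.1, 0.2, 0.3, 0.4],
            [0.7, 0.1, 0.1, 0.1],
        ],
    )
    def test_closed_form_matches_enumeration(self, p):
        q = _locus_exclusion(np.asarray(p))
        assert q == pytest.approx(enumerate_exclusion(p), abs=1e-12)

    def test_combined_nondecreasing_in_loci(self):
        panels = [make_freqs([[0.3, 0.3, 0.4]] * k) for k in (1, 3, 6, 9)]
        qs = [exclusion_probabilities(f).combined_q2 for f in panels]
        assert all(b >= a for a, b in zip(qs, qs[1:]))


class TestTransitionProbability:
    FREQS = {A: 0.5, B: 0.5}

    def test_impossible_transmission(self):
        assert transition_probability((A, B), (A, A), (A, A), self.FREQS) == 0.0

    def test_forced_heterozygote(self):
        assert transition_probability((A, B), (A, A), (B, B), self.FREQS) == 1.0

    def test_error_mixture_hand_value(self):
        p = transition_probability(
            (A, B), (A, A), (A, A), self.FREQS, ErrorModel(0.0923)
        )
        assert p == pytest.approx(0.0923 * 0.5, abs=1e-12)

    def test_missing_genotype_is_uninformative(self):
        assert transition_probability(None, (A, A), (A, A), self.FREQS) == 1.0
        assert transition_probability((A, None), (A, A), (A, A), self.FREQS) == 1.0

    def test_unknown_allele_rejected(self):
        with pytest.raises(PopulationError):
            transition_probability((A, 9), (A, A), (A, A), self.FREQS)


def _paternity_setup():
    """Mother T1 (AA), candidates: T2 (BB, the only compatible father for
    an AB offspring whose maternal allele is A) and T3 (AA)."""
    adults = make_population(
        [[(A, A)], [(B, B)], [(A, A)]],
        sex=["female", "male", "male"],
        xy=[(0, 0), (30, 40), (10, 0)],
    )
    offspring = make_population([[(A, B)]], xy=[(5, 5)])
    offspring.ids = np.array(["S1"], dtype=object)
    return adults, offspring


class TestPaternity:
    def test_unique_compatible_male_assigned_without_error_model(self):
        adults, offspring = _paternity_setup()
        out = assign_paternity(
            offspring, ["T1"], adults, error=ErrorModel(0.0),
            calibration=CalibrationParams(n_sim=200, rng_seed=0),
        )
        row = out.iloc[0]
        assert row["father"] == "T2"
        assert row["tier"] == "95%"
        assert row["pollen_dist_m"] == pytest.approx(50.0)

    def test_all_loci_missing_unassigned(self):
        adults, offspring = _paternity_setup()
        offspring.genotypes[:] = MISSING
        out = assign_paternity(
            offspring, ["T1"], adults, error=ErrorModel(0.0),
            calibration=CalibrationParams(n_sim=200, rng_seed=0),
        )
        assert out.iloc[0]["father"] is None
        assert out.iloc[0]["tier"] is None

    def test_tied_candidates_left_unassigned(self):
        adults = make_population(
            [[(A, A)], [(B, B)], [(B, B)]],  # two identical compatible males
            sex=["female", "male", "male"],
            xy=[(0, 0), (30, 40), (60, 80)],
        )
        offspring = make_population([[(A, B)]], xy=[(5, 5)])
        offspring.ids = np.array(["S1"], dtype=object)
        out = assign_paternity(
            offspring, ["T1"], adults, error=ErrorModel(0.01),
            calibration=CalibrationParams(n_sim=200, rng_seed=0),
        )
        assert out.iloc[0]["father"] is None

    def test_excluded_candidates_get_minus_infinity_lod(self):
        from dioecia.parentage import _paternity_lods, build_tables, encode_population

        adults, offspring = _paternity_setup()
        freqs = allele_frequencies(adults)
        tables = build_tables(freqs)
        off_enc = encode_population(offspring, tables)
        cand = encode_population(adults.subset([1, 2]), tables)
        gm = encode_population(adults.subset([0]), tables)[0]
        lod, mism = _paternity_lods(off_enc[0], gm, cand, tables, eps=0.0)
        assert np.isinf(lod[1]) and lod[1] < 0  # AA male cannot sire AB from AA
        assert mism[1] == 1
        assert np.isfinite(lod[0])


class TestParentPair:
    def test_true_pair_recovered_when_others_excluded(self):
        from dioecia import Window
        females = make_population(
            [[(A, A), (A, A)], [(B, B), (B, B)]],
            sex=["female", "female"], xy=[(0, 0), (100, 100)],
            window=Window(300, 300),
        )
        males = make_population(
            [[(B, B), (B, B)], [(B, B), (A, A)]],
            sex=["male", "male"], xy=[(30, 40), (200, 200)],
            window=Window(300, 300),
        )
        males.ids = np.array(["M1", "M2"], dtype=object)
        # offspring (A,B)/(A,A): every pair except (T1 x M2) is excluded
        # at one of the loci
        offspring = make_population([[(A, B), (A, A)]], xy=[(0, 10)])
        offspring.ids = np.array(["S1"], dtype=object)
        out = assign_parent_pair(
            offspring, females, males, error=ErrorModel(0.0),
            calibration=CalibrationParams(n_sim=200, rng_seed=1),
        )
        row = out.iloc[0]
        assert (row["mother"], row["father"]) == ("T1", "M2")
        assert row["pollen_dist_m"] == pytest.approx(np.hypot(200, 200))
        assert row["seed_dist_m"] == pytest.approx(10.0)

    def test_incompatible_with_every_pair_unassigned(self):
        females = make_population([[(A, A)]], sex=["female"], xy=[(0, 0)])
        males = make_population([[(A, A)]], sex=["male"], xy=[(50, 50)])
        males.ids = np.array(["M1"], dtype=object)
        offspring = make_population([[(B, B)]], xy=[(5, 5)])
        offspring.ids = np.array(["S1"], dtype=object)
        freqs = make_freqs([[0.5, 0.5]])
        out = assign_parent_pair(
            offspring, females, males, freqs=freqs, error=ErrorModel(0.0),
            calibration=CalibrationParams(n_sim=100, rng_seed=1),
        )
        assert out.iloc[0]["mother"] is None


class TestErrorEstimate:
    def test_zero_mismatches(self):
        mothers = make_population([[(A, B)]], sex=["female"])
        offspring = make_population([[(A, A)]])
        offspring.ids = np.array(["S1"], dtype=object)
        assert estimate_genotyping_error(mothers, offspring, ["T1"]) == 0.0

    def test_twelve_of_onethirty(self):
        """130 duo-locus comparisons with 12 maternal-allele mismatches
        give the mismatch rate 12/130 = 0.0923."""
        n_loci = 130
        mother_row = [(A, A)] * n_loci
        off_row = [(B, B)] * 12 + [(A, B)] * 118
        mothers = make_population([mother_row], sex=["female"])
        offspring = make_population([off_row])
        offspring.ids = np.array(["S1"], dtype=object)
        eps = estimate_genotyping_error(mothers, offspring, ["T1"])
        assert eps == pytest.approx(12 / 130)
        assert round(eps, 4) == 0.0923

    def test_no_cotyped_loci_raises(self):
        mothers = make_population([[(A, A)]], sex=["female"])
        offspring = make_population([[(MISSING, MISSING)]])
        offspring.ids = np.array(["S1"], dtype=object)
        with pytest.raises(PopulationError):
            estimate_genotyping_error(mothers, offspring, ["T1"])


def _equifrequent_freqs(n_loci=9, n_alleles=7):
    return make_freqs([[1 / n_alleles] * n_alleles] * n_loci)


def _simulate_panel(rng, freqs, n):
    geno = []
    for _ in range(n):
        row = []
        for l in range(len(freqs.loci)):
            p = freqs.freqs[l]
            row.append(tuple(freqs.alleles[l][rng.choice(p.size, size=2, p=p)]))
        geno.append(row)
    return geno


def test_recovery_accuracy_monotone_in_error_rate():
    """Assignment accuracy against simulator truth degrades as the
    genotyping-error rate grows."""
    rng = np.random.default_rng(5)
    freqs = _equifrequent_freqs(n_loci=8, n_alleles=6)
    n_mothers, n_cand, n_off = 5, 30, 60
    mothers = make_population(
        _simulate_panel(rng, freqs, n_mothers),
        sex=["female"] * n_mothers,
        xy=np.column_stack([np.linspace(1, 99, n_mothers)] * 2),
    )
    males = make_population(
        _simulate_panel(rng, freqs, n_cand), sex=["male"] * n_cand,
        xy=np.column_stack([np.linspace(0, 98, n_cand)] * 2),
    )
    males.ids = np.array([f"M{k}" for k in range(n_cand)], dtype=object)
    adults = None
    accs = []
    for eps in (0.0, 0.1, 0.45):
        correct = total = 0
        rng_eps = np.random.default_rng(17)
        off_rows, true_f, mother_ids = [], [], []
        for _ in range(n_off):
            mi = rng_eps.integers(0, n_mothers)
            fi = rng_eps.integers(0, n_cand)
            row = []
            for l in range(len(freqs.loci)):
                gm = mothers.genotypes[mi, l]
                gf = males.genotypes[fi, l]
                g = (gm[rng_eps.integers(0, 2)], gf[rng_eps.integers(0, 2)])
                if rng_eps.random() < eps:
                    p = freqs.freqs[l]
                    g = tuple(freqs.alleles[l][rng_eps.choice(p.size, size=2, p=p)])
                row.append(g)
            off_rows.append(row)
            true_f.append(f"M{fi}")
            mother_ids.append(f"T{mi+1}")
        offspring = make_population(off_rows)
        offspring.ids = np.array([f"S{k}" for k in range(n_off)], dtype=object)
        out = assign_paternity(
            offspring, mother_ids, mothers, candidate_males=males,
            freqs=freqs, error=ErrorModel(max(eps, 1e-6)),
            calibration=CalibrationParams(n_sim=400, rng_seed=3),
        )
        assigned = out[out["father"].notna()]
        total = len(out)
        correct = sum(
            assigned["father"].to_numpy() == np.array(true_f)[assigned.index]
        )
        accs.append(correct / total)
    assert accs[0] >= accs[1] >= accs[2] - 0.05
    assert accs[0] > 0.8
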