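"""Sex-ratio and size-structure statistics for dioecious stands.

The sex ratio is expressed as the proportion male, males/(males+females);
undetermined individuals (non-flowering in both census seasons) are
excluded from the ratio tests.  Departure from 1:1 is tested with a
likelihood-ratio G goodness-of-fit test, homogeneity of ratios across
diametric cohorts with the replicated-G decomposition
(sum_i G_i = G_pooled + G_heterogeneity), and intersex differences in
the diameter distribution with a two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import Population, PopulationError


@dataclass
class SexCounts:
    """Male/female/undetermined counts per cohort (plus pooled)."""

    table: pd.DataFrame  # index cohort; columns male, female, undetermined

    @classmethod
    def from_population(cls, pop: Population) -> "SexCounts":
        df = pd.DataFrame(
            {
                "cohort": [c if c is not None else "unassigned" for c in pop.cohort],
                "sex": pop.sex,
            }
        )
        tab = (
            df.pivot_table(index="cohort", columns="sex", aggfunc="size", fill_value=0)
            .reindex(columns=["male", "female", "undetermined"], fill_value=0)
        )
        tab.columns.name = None
        return cls(table=tab)

    def counts(self, cohort: str) -> tuple[int, int]:
        row = self.table.loc[cohort]
        return int(row["male"]), int(row["female"])

    def pooled(self) -> tuple[int, int]:
        return int(self.table["male"].sum()), int(self.table["female"].sum())


def _g_statistic(observed: np.ndarray, expected: np.ndarray) -> float:
    """G = 2 * sum O ln(O/E) with the 0*ln(0) = 0 convention."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    mask = observed > 0
    return float(2.0 * np.sum(observed[mask] * np.log(observed[mask] / expected[mask])))


def sex_ratio_gtest(males: int, females: int,
                    exact: bool = False) -> tuple[float, float, int, float]:
    """Test a male:female count against 1:1.

    Returns ``(proportion_male, G, df, p)``; p from the chi-square upper
    tail with 1 df, or from the exact two-sided binomial when
    ``exact=True`` (recommended for very small counts).
    """
    if males < 0 or females < 0 or males + females < 1:
        raise PopulationError("need at least one sexed individual")
    n = males + females
    prop = males / n
    g = _g_statistic([males, females], [n / 2, n / 2])
    if exact:
        p = stats.binomtest(males, n, 0.5).pvalue
    else:
        p = float(stats.chi2.sf(g, df=1))
    return prop, g, 1, p


def g_heterogeneity(counts: list[tuple[int, int]]) -> tuple[float, int, float]:
    """Replicated-G test of sex-ratio homogeneity across cohorts.

    G_het = sum_i G_i - G_pooled with df = k - 1; a large value means the
    male proportion differs among cohorts regardless of the pooled ratio.
    """
    if len(counts) < 2:
        raise PopulationError("need >= 2 cohorts")
    for m, f in counts:
        if m + f < 1:
            raise PopulationError("every cohort needs >= 1 sexed individual")
    g_each = sum(sex_ratio_gtest(m, f)[1] for m, f in counts)
    m_tot = sum(m for m, _ in counts)
    f_tot = sum(f for _, f in counts)
    g_pooled = sex_ratio_gtest(m_tot, f_tot)[1]
    g_het = g_each - g_pooled
    df = len(counts) - 1
    return g_het, df, float(stats.chi2.sf(g_het, df=df))


def ks_two_sample(sample_a: np.ndarray, sample_b: np.ndarray) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p), e.g. male vs
    female dbh distributions.  Returns ``(D, p)``."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise PopulationError("both samples must be nonempty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def demography_report(pop: Population) -> pd.DataFrame:
    """Per-cohort and pooled sex-ratio tests plus the heterogeneity G and
    the male-vs-female dbh KS test, as one tidy table."""
    sc = SexCounts.from_population(pop)
    cohorts = [c for c in ("I", "II", "III") if c in sc.table.index]
    rows = []
    pairs = []
    for c in cohorts:
        m, f = sc.counts(c)
        if m + f == 0:
            continue
        prop, g, df, p = sex_ratio_gtest(m, f)
        pairs.append((m, f))
        rows.append({"scope": f"cohort {c}", "males": m, "females": f,
                     "prop_male": prop, "stat": g, "df": df, "p": p})
    m, f = sc.pooled()
    prop, g, df, p = sex_ratio_gtest(m, f)
    rows.append({"scope": "pooled", "males": m, "females": f,
                 "prop_male": prop, "stat": g, "df": df, "p": p})
    if len(pairs) >= 2:
        g_het, df_het, p_het = g_heterogeneity(pairs)
        rows.append({"scope": "heterogeneity", "males": m, "females": f,
                     "prop_male": np.nan, "stat": g_het, "df": df_het, "p": p_het})
    male_dbh = pop.dbh[pop.sex == "male"]
    female_dbh = pop.dbh[pop.sex == "female"]
    if male_dbh.size and female_dbh.size:
        d, p_ks = ks_two_sample(male_dbh, female_dbh)
        rows.append({"scope": "dbh KS male vs female", "males": male_dbh.size,
                     "females": female_dbh.size, "prop_male": np.nan,
                     "stat": d, "df": np.nan, "p": p_ks})
    return pd.DataFrame(rows)
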