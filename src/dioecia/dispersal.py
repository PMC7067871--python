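"""Dispersal-distance distributions and the effective-vs-realized probe.

Three kernels are distinguished by how the sample was obtained:
``effective_pollen`` (paternity on seeds collected from known mothers,
i.e. before seed dispersal and establishment), ``realized_pollen`` and
``realized_seed`` (parent-pair assignment on established seedlings).
Comparing effective and realized kernels probes Janzen-Connell
filtering: distance-dependent mortality near parents shifts the realized
distributions toward longer distances.  Also provides near/far band
proportions, summary statistics, a two-sample comparison, and the
progeny-count fitness regressions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import Population, PopulationError

MODES = ("effective_pollen", "realized_pollen", "realized_seed")

#: Near / intermediate / far band breakpoints (m) from the dispersal
#: narrative: within-neighborhood (<=150), plot-scale (150-600), beyond.
DEFAULT_BANDS = (150.0, 600.0)


@dataclass
class DispersalSample:
    """Distances (m) for one dispersal mode plus the count of offspring
    left unassigned (interpreted as parents outside the plot)."""

    mode: str
    distances: np.ndarray
    n_unassigned: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise PopulationError(f"mode must be one of {MODES}")
        self.distances = np.asarray(self.distances, dtype=float)
        if (self.distances < 0).any():
            raise PopulationError("distances must be >= 0")

    @property
    def n(self) -> int:
        return self.distances.size


_MODE_COLUMN = {
    "effective_pollen": "pollen_dist_m",
    "realized_pollen": "pollen_dist_m",
    "realized_seed": "seed_dist_m",
}


def dispersal_distances(assignments: pd.DataFrame, mode: str) -> DispersalSample:
    """Extract the mode's defined distance from an assignment table
    (rows with no assigned parent are excluded and counted)."""
    if mode not in MODES:
        raise PopulationError(f"mode must be one of {MODES}")
    col = _MODE_COLUMN[mode]
    if col not in assignments.columns:
        raise PopulationError(f"assignment table lacks column {col!r} for mode {mode}")
    d = assignments[col].to_numpy(float)
    assigned = np.isfinite(d)
    if mode == "realized_seed" and assignments["mother"].isna().all():
        raise PopulationError("realized_seed needs mother assignments")
    return DispersalSample(
        mode=mode,
        distances=d[assigned],
        n_unassigned=int((~assigned).sum()),
    )


def band_proportions(sample: DispersalSample,
                     breaks: tuple[float, ...] = DEFAULT_BANDS) -> np.ndarray:
    """Fractions of distances in (0, b1], (b1, b2], ..., (b_k, inf);
    always sums to 1."""
    br = np.asarray(breaks, dtype=float)
    if br.size < 1 or np.any(np.diff(br) <= 0) or (br <= 0).any():
        raise PopulationError("breaks must be positive and strictly increasing")
    if sample.n == 0:
        raise PopulationError("empty dispersal sample")
    idx = np.searchsorted(br, sample.distances, side="left")
    return np.bincount(idx, minlength=br.size + 1) / sample.n


@dataclass
class KernelSummary:
    n: int
    mean: float
    se: float  # NaN for n < 2
    median: float
    min: float
    max: float


def kernel_summary(sample: DispersalSample) -> KernelSummary:
    """n, mean, SE of the mean (sd/sqrt(n), sample sd), median, range."""
    if sample.n == 0:
        raise PopulationError("empty dispersal sample")
    d = sample.distances
    se = float(np.std(d, ddof=1) / np.sqrt(d.size)) if d.size > 1 else float("nan")
    return KernelSummary(
        n=d.size,
        mean=float(np.mean(d)),
        se=se,
        median=float(np.median(d)),
        min=float(np.min(d)),
        max=float(np.max(d)),
    )


@dataclass
class KernelComparison:
    ks_d: float
    ks_p: float
    band_deltas: np.ndarray  # b minus a, per band
    verdict: str  # 'b larger', 'a larger' or 'mixed'


def compare_kernels(
    a: DispersalSample,
    b: DispersalSample,
    breaks: tuple[float, ...] = DEFAULT_BANDS,
) -> KernelComparison:
    """Two-sample KS plus per-band proportion differences.

    The directional verdict is 'b larger' when b's ECDF is <= a's at
    every breakpoint (b stochastically larger), symmetrically 'a
    larger', else 'mixed'.
    """
    if a.n == 0 or b.n == 0:
        raise PopulationError("both samples must be nonempty")
    d, p = stats.ks_2samp(a.distances, b.distances, method="asymp")
    pa = band_proportions(a, breaks)
    pb = band_proportions(b, breaks)
    br = np.asarray(breaks, dtype=float)
    ecdf_a = np.array([np.mean(a.distances <= x) for x in br])
    ecdf_b = np.array([np.mean(b.distances <= x) for x in br])
    if np.all(ecdf_b <= ecdf_a) and np.any(ecdf_b < ecdf_a):
        verdict = "b larger"
    elif np.all(ecdf_a <= ecdf_b) and np.any(ecdf_a < ecdf_b):
        verdict = "a larger"
    else:
        verdict = "mixed"
    return KernelComparison(ks_d=float(d), ks_p=float(p),
                            band_deltas=pb - pa, verdict=verdict)


def progeny_counts(assignments: pd.DataFrame, adults: Population,
                   role: str = "father") -> np.ndarray:
    """Number of assigned progeny per adult (zero for adults never
    assigned); ``role`` is 'father' or 'mother'."""
    if role not in ("father", "mother"):
        raise PopulationError("role must be 'father' or 'mother'")
    counts = assignments[role].dropna().value_counts()
    return np.array([int(counts.get(i, 0)) for i in adults.ids])


def fitness_regression(progeny_counts: np.ndarray,
                       predictor: np.ndarray) -> tuple[float, float, float]:
    """OLS of per-adult progeny count on a predictor (dbh, distance...).

    Returns ``(slope, r_squared, p)`` with the two-sided slope p-value.
    """
    y = np.asarray(progeny_counts, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if y.size != x.size or y.size < 3:
        raise PopulationError("need >= 3 matched observations")
    if np.allclose(x, x[0]):
        raise PopulationError("constant predictor")
    if np.allclose(y, y[0]):
        return 0.0, 0.0, 1.0  # flat response: nothing to explain
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue**2), float(res.pvalue)
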