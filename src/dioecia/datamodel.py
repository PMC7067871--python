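"""Core data containers for mapped, sexed, genotyped tree populations.

A :class:`Population` holds every individual of a rectangular study plot:
planar coordinates in meters, stem diameter (dbh, cm), a sex label
(``male`` / ``female`` / ``undetermined``), an optional diametric cohort,
and a multilocus codominant genotype (unordered integer allele pairs per
microsatellite locus, either allele may be missing).  All downstream
statistics — demography, diversity, kinship, spatial interaction,
parentage — consume this one container.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing allele in the integer genotype array.
MISSING = -1

SEXES = ("male", "female", "undetermined")
COHORTS = ("I", "II", "III")

#: String used for a missing allele in delimited files.
_MISSING_TOKEN = "?"


class PopulationError(ValueError):
    """Raised when input data violate a population invariant."""


@dataclass(frozen=True)
class Window:
    """Axis-aligned rectangular study plot, origin at (0, 0), meters."""

    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise PopulationError("window sides must be positive")

    @property
    def area(self) -> float:
        return self.width * self.height

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= 0) & (x <= self.width) & (y >= 0) & (y <= self.height)

    @classmethod
    def parse(cls, text: str) -> "Window":
        """Parse a ``"1000x300"``-style window string."""
        try:
            w, h = text.lower().split("x")
            return cls(float(w), float(h))
        except Exception as exc:  # noqa: BLE001
            raise PopulationError(f"cannot parse window {text!r}") from exc


@dataclass(frozen=True)
class SizeClassRule:
    """Diametric cohort boundaries.

    Default convention: cohort I is dbh in [0, ``lower``), cohort II is
    [``lower``, ``upper``] and cohort III is (``upper``, inf).  The middle
    cohort owns both boundary values; change ``middle_owns_lower`` /
    ``middle_owns_upper`` for the alternative conventions.
    """

    lower: float = 10.0
    upper: float = 20.0
    middle_owns_lower: bool = True
    middle_owns_upper: bool = True

    def assign(self, dbh: float) -> str:
        if dbh < 0 or not np.isfinite(dbh):
            raise PopulationError(f"dbh must be finite and >= 0, got {dbh}")
        below = dbh < self.lower if self.middle_owns_lower else dbh <= self.lower
        if below:
            return "I"
        above = dbh > self.upper if self.middle_owns_upper else dbh >= self.upper
        if above:
            return "III"
        return "II"


DEFAULT_SIZE_RULE = SizeClassRule()


def assign_size_class(dbh: float, rule: SizeClassRule = DEFAULT_SIZE_RULE) -> str:
    """Map a stem diameter (cm) to its diametric cohort ``I``/``II``/``III``."""
    return rule.assign(dbh)


@dataclass(frozen=True)
class DistanceClassSpec:
    """Half-open distance intervals (lower, upper] in meters.

    ``upper_bounds`` must be strictly increasing and positive; the first
    interval starts at 0 (exclusive).  The default mirrors classical
    autocorrelogram binning for a ~30 ha plot: 20 m steps to 100 m then
    25 m steps to 200 m.
    """

    upper_bounds: tuple[float, ...] = (20, 40, 60, 80, 100, 125, 150, 175, 200)

    def __post_init__(self) -> None:
        ub = tuple(float(b) for b in self.upper_bounds)
        if len(ub) < 1:
            raise PopulationError("need at least one distance class")
        if ub[0] <= 0 or any(b <= a for a, b in zip(ub, ub[1:])):
            raise PopulationError("upper bounds must be positive and strictly increasing")
        object.__setattr__(self, "upper_bounds", ub)

    @property
    def n_classes(self) -> int:
        return len(self.upper_bounds)

    def bounds(self) -> list[tuple[float, float]]:
        lows = (0.0,) + self.upper_bounds[:-1]
        return list(zip(lows, self.upper_bounds))

    def classify(self, d: np.ndarray) -> np.ndarray:
        """Class index per distance; -1 for distances beyond the last bound
        or equal to zero."""
        d = np.asarray(d, dtype=float)
        idx = np.searchsorted(np.asarray(self.upper_bounds), d, side="left")
        out = np.where((d > 0) & (d <= self.upper_bounds[-1]), idx, -1)
        return out.astype(np.int64)


@dataclass
class Individual:
    """Single-tree view; ``genotype`` maps locus -> (allele, allele),
    ``None`` for a missing allele."""

    id: str
    x: float
    y: float
    dbh: float
    sex: str
    cohort: str | None
    genotype: dict[str, tuple[int | None, int | None]]


@dataclass
class Population:
    """A mapped, sexed, genotyped stand inside a rectangular window.

    ``genotypes`` is an ``(n, n_loci, 2)`` integer array with
    :data:`MISSING` (−1) for an unread allele.  Allele labels are opaque
    integers (fragment sizes or arbitrary codes); only label equality is
    meaningful.
    """

    ids: np.ndarray
    xy: np.ndarray
    dbh: np.ndarray
    sex: np.ndarray
    cohort: np.ndarray
    loci: tuple[str, ...]
    genotypes: np.ndarray
    window: Window

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.xy = np.asarray(self.xy, dtype=float)
        self.dbh = np.asarray(self.dbh, dtype=float)
        self.sex = np.asarray(self.sex, dtype=object)
        self.cohort = np.asarray(self.cohort, dtype=object)
        self.loci = tuple(self.loci)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int64)
        n = len(self.ids)
        if self.xy.shape != (n, 2):
            raise PopulationError("xy must be (n, 2)")
        if self.genotypes.shape != (n, len(self.loci), 2):
            raise PopulationError("genotypes must be (n, n_loci, 2)")
        if len(set(self.ids.tolist())) != n:
            dupes = pd.Series(self.ids).value_counts()
            raise PopulationError(
                f"duplicate ids: {sorted(dupes[dupes > 1].index.tolist())}"
            )
        inside = self.window.contains(self.xy[:, 0], self.xy[:, 1])
        if not inside.all():
            bad = self.ids[~inside][:5].tolist()
            raise PopulationError(f"coordinates outside window for ids {bad}")
        if np.any(self.dbh < 0) or not np.all(np.isfinite(self.dbh)):
            raise PopulationError("dbh must be finite and >= 0")
        bad_sex = set(self.sex.tolist()) - set(SEXES)
        if bad_sex:
            raise PopulationError(f"unknown sex labels {sorted(bad_sex)}")
        bad_coh = set(self.cohort.tolist()) - set(COHORTS) - {None}
        if bad_coh:
            raise PopulationError(f"unknown cohort labels {sorted(bad_coh)}")

    # -- basic views ---------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def called(self) -> np.ndarray:
        """(n, n_loci) bool: genotype fully read (both alleles) at locus.

        A half-read genotype counts as missing everywhere downstream; no
        estimator imputes.
        """
        return (self.genotypes >= 0).all(axis=2)

    def index_of(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {i: k for k, i in enumerate(self.ids.tolist())}
        try:
            return np.array([lookup[i] for i in ids], dtype=np.int64)
        except KeyError as exc:
            raise PopulationError(f"unknown id {exc.args[0]!r}") from exc

    def subset(self, index: np.ndarray) -> "Population":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return Population(
            ids=self.ids[index],
            xy=self.xy[index],
            dbh=self.dbh[index],
            sex=self.sex[index],
            cohort=self.cohort[index],
            loci=self.loci,
            genotypes=self.genotypes[index],
            window=self.window,
        )

    def by_cohort(self, cohort: str) -> "Population":
        return self.subset(self.cohort == cohort)

    def by_sex(self, sex: str) -> "Population":
        return self.subset(self.sex == sex)

    def with_cohorts_from_dbh(self, rule: SizeClassRule = DEFAULT_SIZE_RULE) -> "Population":
        cohorts = np.array([rule.assign(d) for d in self.dbh], dtype=object)
        out = self.subset(np.arange(self.n))
        out.cohort = cohorts
        return out

    def individual(self, i: int) -> Individual:
        geno = {
            locus: tuple(None if a == MISSING else int(a) for a in self.genotypes[i, l])
            for l, locus in enumerate(self.loci)
        }
        return Individual(
            id=str(self.ids[i]),
            x=float(self.xy[i, 0]),
            y=float(self.xy[i, 1]),
            dbh=float(self.dbh[i]),
            sex=str(self.sex[i]),
            cohort=self.cohort[i],
            genotype=geno,  # type: ignore[arg-type]
        )

    # -- I/O -----------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "id": self.ids,
                "x": self.xy[:, 0],
                "y": self.xy[:, 1],
                "dbh": self.dbh,
                "sex": self.sex,
                "cohort": [c if c is not None else "" for c in self.cohort],
            }
        )
        for l, locus in enumerate(self.loci):
            df[locus] = [
                "/".join(
                    _MISSING_TOKEN if a == MISSING else str(int(a))
                    for a in self.genotypes[i, l]
                )
                for i in range(self.n)
            ]
        return df

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _parse_genotype(cell: str, locus: str, row_id: str) -> tuple[int, int]:
    text = str(cell).strip()
    parts = text.split("/")
    if len(parts) != 2:
        raise PopulationError(
            f"malformed genotype {cell!r} at locus {locus} for id {row_id!r}"
        )
    out = []
    for p in parts:
        p = p.strip()
        if p == _MISSING_TOKEN or p == "":
            out.append(MISSING)
        else:
            try:
                out.append(int(p))
            except ValueError as exc:
                raise PopulationError(
                    f"non-integer allele {p!r} at locus {locus} for id {row_id!r}"
                ) from exc
    return out[0], out[1]


_META_COLUMNS = ("id", "x", "y", "dbh", "sex", "cohort")


def population_from_frame(df: pd.DataFrame, window: Window,
                          loci: Sequence[str] | None = None) -> Population:
    """Build a validated :class:`Population` from a table.

    Columns: ``id, x, y, dbh, sex`` (required), ``cohort`` (optional) and
    one column per locus with ``a/b`` allele pairs (``?`` = missing).
    Unparseable rows raise; nothing is silently skipped.
    """
    required = ("id", "x", "y", "dbh", "sex")
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise PopulationError(f"missing required columns {missing_cols}")
    if loci is None:
        loci = [c for c in df.columns if c not in _META_COLUMNS]
    ids = df["id"].astype(str).to_numpy(dtype=object)
    n = len(ids)
    geno = np.full((n, len(loci), 2), MISSING, dtype=np.int64)
    for l, locus in enumerate(loci):
        for i in range(n):
            geno[i, l] = _parse_genotype(df[locus].iloc[i], locus, ids[i])
    if "cohort" in df.columns:
        cohort = np.array(
            [c if c in COHORTS else None for c in df["cohort"].astype(str)],
            dtype=object,
        )
    else:
        cohort = np.array([None] * n, dtype=object)
    return Population(
        ids=ids,
        xy=np.column_stack([df["x"].to_numpy(float), df["y"].to_numpy(float)]),
        dbh=df["dbh"].to_numpy(float),
        sex=df["sex"].astype(str).str.strip().str.lower().to_numpy(dtype=object),
        cohort=cohort,
        loci=tuple(loci),
        genotypes=geno,
        window=window,
    )


def read_population(path, window: Window) -> Population:
    """Read a delimited population table (see :func:`population_from_frame`)."""
    if isinstance(path, io.TextIOBase):
        df = pd.read_csv(path, dtype=str)
    else:
        df = pd.read_csv(path, dtype=str)
    return population_from_frame(df, window)


def pairwise_distances(pop: Population) -> np.ndarray:
    """Symmetric matrix of planar Euclidean distances (m) between all
    individuals."""
    if pop.n < 2:
        raise PopulationError("need at least 2 individuals for distances")
    from scipy.spatial.distance import pdist, squareform

    return squareform(pdist(pop.xy))


def validate_population(pop: Population) -> dict:
    """Diagnostics: per-locus missingness, monomorphic loci, cohort/sex
    counts.  Reporting only; never raises."""
    called = pop.called()
    per_locus_missing = 1.0 - called.mean(axis=0)
    monomorphic = []
    for l, locus in enumerate(pop.loci):
        alleles = pop.genotypes[called[:, l], l, :]
        labels = np.unique(alleles)
        if labels.size <= 1:
            monomorphic.append(locus)
    cohort_counts = pd.Series(
        [c if c is not None else "unassigned" for c in pop.cohort]
    ).value_counts().to_dict()
    sex_counts = pd.Series(pop.sex).value_counts().to_dict()
    return {
        "n": pop.n,
        "n_loci": pop.n_loci,
        "missing_rate": dict(zip(pop.loci, per_locus_missing.tolist())),
        "monomorphic_loci": monomorphic,
        "usable_loci": [l for l in pop.loci if l not in monomorphic],
        "cohort_counts": cohort_counts,
        "sex_counts": sex_counts,
        "window": (pop.window.width, pop.window.height),
    }
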