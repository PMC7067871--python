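"""Bivariate Ripley's K12/L12 with isotropic edge correction and a
random-labeling null.

K12(t) estimates the expected number of class-2 points within distance t
of a class-1 point, scaled by intensity; under independence of the two
patterns K12(t) = pi t^2.  The variance-stabilized transform
L12(t) = sqrt(K12(t)/pi) - t is zero-centered under independence:
L12 > 0 suggests association, L12 < 0 repulsion.  The null holds all
point locations fixed and permutes the class labels ("random labeling"),
which is the appropriate null when both classes arise from one
population (e.g. diametric cohorts of a single stand).

Edge effects in a rectangular window are handled with Ripley's isotropic
correction: each pair (i, j) is weighted by the reciprocal of the
fraction of the circle centered at i with radius d_ij that lies inside
the window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import PopulationError, Window


def isotropic_correction(points: np.ndarray, radii: np.ndarray, window: Window) -> np.ndarray:
    """Fraction of each circle (center ``points[i]``, radius
    ``radii[i]``) inside the rectangular window.

    Closed form for a rectangle: each near edge removes an arc of
    2*arccos(d_edge/r); two adjacent removed arcs overlap by
    arccos(a/r) + arccos(b/r) - pi/2 when the corner lies inside the
    circle (a^2 + b^2 < r^2).  Valid for r up to half the shorter window
    side, which keeps opposite-edge arcs disjoint.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    r = np.asarray(radii, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        # distances to the four edges: left, right, bottom, top
        e = np.stack(
            [pts[:, 0], window.width - pts[:, 0], pts[:, 1], window.height - pts[:, 1]],
            axis=1,
        )
        ratio = np.clip(e / r[:, None], -1.0, 1.0)
        edge_arcs = np.where(e < r[:, None], 2.0 * np.arccos(ratio), 0.0)
        exterior = edge_arcs.sum(axis=1)
        # corners: (left,bottom), (left,top), (right,bottom), (right,top)
        for ix, iy in ((0, 2), (0, 3), (1, 2), (1, 3)):
            inside = e[:, ix] ** 2 + e[:, iy] ** 2 < r**2
            overlap = np.arccos(ratio[:, ix]) + np.arccos(ratio[:, iy]) - np.pi / 2
            exterior = exterior - np.where(inside, np.maximum(overlap, 0.0), 0.0)
    frac = 1.0 - exterior / (2.0 * np.pi)
    return np.where(r > 0, frac, 1.0)


@dataclass
class RipleyResult:
    """Bivariate K/L estimate on a distance grid.

    ``table`` columns: ``t``, ``k12``, ``l12`` and, when an envelope was
    computed, ``env_low``/``env_high`` and a ``verdict`` in
    {association, repulsion, random} per the random-labeling test.
    """

    table: pd.DataFrame
    n1: int
    n2: int
    window: Window
    n_perm: int = 0

    @property
    def t(self) -> np.ndarray:
        return self.table["t"].to_numpy(float)

    @property
    def l12(self) -> np.ndarray:
        return self.table["l12"].to_numpy(float)


def _check_grid(t_grid: np.ndarray, window: Window) -> np.ndarray:
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size == 0 or (t <= 0).any() or np.any(np.diff(t) <= 0):
        raise PopulationError("t grid must be positive and strictly increasing")
    tmax_valid = min(window.width, window.height) / 2.0
    if t[-1] > tmax_valid:
        raise PopulationError(
            f"t max {t[-1]} exceeds validity bound {tmax_valid} (half the short side)"
        )
    return t


def default_t_grid(t_max: float = 150.0, step: float = 5.0) -> np.ndarray:
    """Grid matching common practice for a 1000 x 300 m plot: 0-150 m in
    5 m steps (the 0 endpoint is implicit; K(0) = 0)."""
    return np.arange(step, t_max + step / 2, step)


def _pair_bins(points_a: np.ndarray, points_b: np.ndarray, t: np.ndarray,
               window: Window) -> tuple[np.ndarray, np.ndarray]:
    """For all (a, b) pairs within t_max: bin index into the t grid and
    the 1/c edge-correction weight (circle centered on the class-a
    point)."""
    diff = points_a[:, None, :] - points_b[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2)).ravel()
    ai = np.repeat(np.arange(len(points_a)), len(points_b))
    keep = (d > 0) & (d <= t[-1])
    d, ai = d[keep], ai[keep]
    c = isotropic_correction(points_a[ai], d, window)
    bins = np.searchsorted(t, d, side="left")
    return bins, 1.0 / c


def _k_from_bins(bins: np.ndarray, w: np.ndarray, n_t: int, area: float,
                 n1: int, n2: int) -> np.ndarray:
    hist = np.bincount(bins, weights=w, minlength=n_t)
    return area / (n1 * n2) * np.cumsum(hist)


def ripley_l12(
    points_a: np.ndarray,
    points_b: np.ndarray,
    window: Window,
    t_grid: np.ndarray | None = None,
    symmetrized: bool = False,
) -> RipleyResult:
    """Bivariate K12 and L12 = sqrt(K12/pi) - t on a distance grid.

    Circles are centered on class-a points; ``symmetrized=True`` averages
    the two centerings, 0.5*(K12 + K21), making the estimate exactly
    label-exchange invariant.
    """
    pa = np.atleast_2d(np.asarray(points_a, dtype=float))
    pb = np.atleast_2d(np.asarray(points_b, dtype=float))
    if pa.size == 0 or pb.size == 0:
        raise PopulationError("both point sets must be nonempty")
    t = _check_grid(default_t_grid() if t_grid is None else t_grid, window)
    bins, w = _pair_bins(pa, pb, t, window)
    k12 = _k_from_bins(bins, w, t.size, window.area, len(pa), len(pb))
    if symmetrized:
        bins2, w2 = _pair_bins(pb, pa, t, window)
        k21 = _k_from_bins(bins2, w2, t.size, window.area, len(pb), len(pa))
        k12 = 0.5 * (k12 + k21)
    l12 = np.sqrt(k12 / np.pi) - t
    return RipleyResult(
        table=pd.DataFrame({"t": t, "k12": k12, "l12": l12}),
        n1=len(pa), n2=len(pb), window=window,
    )


def random_labeling_envelope(
    points_a: np.ndarray,
    points_b: np.ndarray,
    window: Window,
    t_grid: np.ndarray | None = None,
    n_perm: int = 999,
    rng_seed: int | np.random.Generator = 0,
    symmetrized: bool = False,
    alpha: float = 0.05,
) -> RipleyResult:
    """L12 with a pointwise random-labeling envelope.

    The pooled locations are held fixed; labels (n1 of class a) are
    reassigned uniformly at random ``n_perm`` times and L12 recomputed.
    The envelope is the order-statistic band at level ``alpha``;
    ``verdict`` flags association (above) or repulsion (below) per t.
    """
    if n_perm < 39:
        raise PopulationError("need at least 39 label permutations")
    pa = np.atleast_2d(np.asarray(points_a, dtype=float))
    pb = np.atleast_2d(np.asarray(points_b, dtype=float))
    n1, n2 = len(pa), len(pb)
    if n1 + n2 < 2:
        raise PopulationError("need at least 2 points in total")
    t = _check_grid(default_t_grid() if t_grid is None else t_grid, window)
    pooled = np.vstack([pa, pb])
    n = n1 + n2

    # precompute all ordered pairs once; each relabeling just reselects
    diff = pooled[:, None, :] - pooled[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2)).ravel()
    ii = np.repeat(np.arange(n), n)
    jj = np.tile(np.arange(n), n)
    keep = (ii != jj) & (d <= t[-1])
    d, ii, jj = d[keep], ii[keep], jj[keep]
    w = 1.0 / isotropic_correction(pooled[ii], d, window)
    bins = np.searchsorted(t, d, side="left")

    def l_of(labels_a: np.ndarray) -> np.ndarray:
        sel = labels_a[ii] & ~labels_a[jj]
        k = _k_from_bins(bins[sel], w[sel], t.size, window.area, n1, n2)
        if symmetrized:
            sel2 = labels_a[jj] & ~labels_a[ii]
            k2 = _k_from_bins(bins[sel2], w[sel2], t.size, window.area, n2, n1)
            # swap centering: weights were computed for circle centered
            # at ii, so reuse with roles exchanged
            k = 0.5 * (k + k2)
        return np.sqrt(k / np.pi) - t

    obs_labels = np.zeros(n, dtype=bool)
    obs_labels[:n1] = True
    observed = l_of(obs_labels)

    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    null = np.empty((n_perm, t.size))
    for b in range(n_perm):
        lab = np.zeros(n, dtype=bool)
        lab[rng.choice(n, size=n1, replace=False)] = True
        null[b] = l_of(lab)
    m = max(1, int(np.floor(alpha / 2 * (n_perm + 1))))
    srt = np.sort(null, axis=0)
    env_low, env_high = srt[m - 1], srt[n_perm - m]
    verdict = np.where(
        observed > env_high, "association",
        np.where(observed < env_low, "repulsion", "random"),
    )
    table = pd.DataFrame(
        {
            "t": t,
            "k12": np.pi * (observed + t) ** 2,
            "l12": observed,
            "env_low": env_low,
            "env_high": env_high,
            "verdict": verdict,
        }
    )
    return RipleyResult(table=table, n1=n1, n2=n2, window=window, n_perm=n_perm)
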