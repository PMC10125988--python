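"""Lattice-constrained spatial point-pattern statistics for GC somas.

Labeled GC somas do not form a free point process in the plane: they are a
subset ("events") of the irregular lattice formed by the whole soma
population.  Randomness of the labeled subset is therefore tested against
configurations generated *on the same lattice*: Bernoulli selections for
complete spatial randomness (CSR) and a permutation-based clustering
procedure for the clustered alternative.  The first-order nearest-neighbour
statistics G-hat (event-to-event) and F-hat (reference-point-to-event) and
the second-order Ripley K-hat are estimated without edge correction; the
study-area boundary is the convex hull of all lattice points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree, ConvexHull
from shapely.geometry import Point, Polygon

#: Defaults of the clustering permutation: neighbourhood radius (um) and trials.
CLUSTER_RADIUS_UM = 8.0
CLUSTER_TRIALS = 20000


class InsufficientEventsError(ValueError):
    """Raised when a statistic needs more events than the pattern has."""


class InvalidMaskError(ValueError):
    """Raised when an event mask is empty or full where a proper subset is needed."""


@dataclass(frozen=True)
class PointPattern:
    """2-D soma positions (um) with a labeled-subset event mask.

    ``coordinates`` holds *all* somas (the lattice); ``event_mask`` flags the
    labeled subset.  The analysis boundary is the convex hull of the lattice.
    """

    coordinates: np.ndarray
    event_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 2:
            raise ValueError("coordinates must be (n, 2)")
        if self.event_mask.shape != (self.coordinates.shape[0],):
            raise ValueError("event_mask must match coordinates")

    @property
    def events(self) -> np.ndarray:
        return self.coordinates[self.event_mask]

    @property
    def n_events(self) -> int:
        return int(self.event_mask.sum())

    @property
    def hull(self) -> Polygon:
        return Polygon(self.coordinates[ConvexHull(self.coordinates).vertices])

    @property
    def area(self) -> float:
        return float(ConvexHull(self.coordinates).volume)

    def with_mask(self, mask: np.ndarray) -> "PointPattern":
        return PointPattern(self.coordinates, np.asarray(mask, dtype=bool))

    @classmethod
    def from_csv(cls, path) -> "PointPattern":
        df = pd.read_csv(path)
        return cls(
            df[["x_um", "y_um"]].to_numpy(dtype=float),
            df["selected"].to_numpy(dtype=bool),
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "x_um": self.coordinates[:, 0],
                "y_um": self.coordinates[:, 1],
                "selected": self.event_mask.astype(int),
            }
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class SpatialFunctionEstimate:
    """One of the G/F/K function estimates on a distance grid."""

    distances: np.ndarray
    values: np.ndarray
    kind: Literal["G", "F", "K"]
    n_events: int


def g_function(pattern: PointPattern, grid: np.ndarray) -> SpatialFunctionEstimate:
    """Empirical CDF of event-to-event nearest-neighbour distances (inclusive <=)."""
    ev = pattern.events
    if ev.shape[0] < 2:
        raise InsufficientEventsError("G function needs >= 2 events")
    d, _ = cKDTree(ev).query(ev, k=2)
    nn = d[:, 1]
    grid = np.asarray(grid, dtype=float)
    values = np.searchsorted(np.sort(nn), grid, side="right") / nn.size
    return SpatialFunctionEstimate(grid, values, "G", ev.shape[0])


def sample_in_hull(
    hull: Polygon, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform (binomial-process) points inside a convex polygon, by rejection."""
    minx, miny, maxx, maxy = hull.bounds
    out = np.empty((n, 2), dtype=float)
    filled = 0
    while filled < n:
        cand = rng.uniform((minx, miny), (maxx, maxy), size=(max(2 * (n - filled), 16), 2))
        keep = np.array([hull.covers(Point(p)) for p in cand])
        take = cand[keep][: n - filled]
        out[filled : filled + take.shape[0]] = take
        filled += take.shape[0]
    return out


def f_function(
    pattern: PointPattern,
    grid: np.ndarray,
    n_ref_points: int | None = None,
    seed: int | None = None,
) -> SpatialFunctionEstimate:
    """Empirical CDF of reference-point-to-event nearest distances.

    Reference points are drawn uniformly inside the convex-hull boundary;
    by default as many reference points as events are used.
    """
    ev = pattern.events
    if ev.shape[0] < 1:
        raise InsufficientEventsError("F function needs >= 1 event")
    n_ref = n_ref_points if n_ref_points is not None else ev.shape[0]
    rng = np.random.default_rng(seed)
    refs = sample_in_hull(pattern.hull, n_ref, rng)
    d, _ = cKDTree(ev).query(refs, k=1)
    grid = np.asarray(grid, dtype=float)
    values = np.searchsorted(np.sort(d), grid, side="right") / d.size
    return SpatialFunctionEstimate(grid, values, "F", ev.shape[0])


def k_function(pattern: PointPattern, radii: np.ndarray) -> SpatialFunctionEstimate:
    """Ripley's K estimate without edge correction.

    K-hat(r) = (1/lambda-hat) (1/N) sum_i sum_{j != i} I(r_ij < r), with
    lambda-hat = N / hull area and a *strict* inequality.  Without edge
    correction K-hat is biased low at radii comparable to the boundary scale;
    it is meant for comparisons against null configurations estimated the
    same way, not against the theoretical pi r^2.
    """
    ev = pattern.events
    n = ev.shape[0]
    if n < 2:
        raise InsufficientEventsError("K function needs >= 2 events")
    area = pattern.area
    pd_ = np.sqrt(((ev[:, None, :] - ev[None, :, :]) ** 2).sum(-1))
    iu = np.triu_indices(n, k=1)
    pair_d = np.sort(pd_[iu])
    radii = np.asarray(radii, dtype=float)
    # ordered pair count with r_ij < r  (strict) = 2 * unordered count
    counts = 2 * np.searchsorted(pair_d, radii, side="left")
    lam = n / area
    values = counts / (lam * n)
    return SpatialFunctionEstimate(radii, values, "K", n)


def generate_random_configuration(
    lattice: PointPattern | np.ndarray, target_fraction: float, seed: int | None = None
) -> np.ndarray:
    """CSR-on-lattice event mask: independent Bernoulli trial per lattice point.

    The selected count is binomial around ``target_fraction * n`` (the
    selection is a Bernoulli trial per soma, not an exact-count draw).
    """
    coords = lattice.coordinates if isinstance(lattice, PointPattern) else lattice
    if not 0 < target_fraction < 1:
        raise ValueError("target_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    return rng.random(coords.shape[0]) < target_fraction


def generate_clustered_configuration(
    lattice: PointPattern | np.ndarray,
    random_mask: np.ndarray,
    radius: float = CLUSTER_RADIUS_UM,
    trials: int = CLUSTER_TRIALS,
    seed: int | None = None,
) -> np.ndarray:
    """Cluster a selected subset by label-permutation on the lattice.

    Each trial picks one selected (sGC) and one unselected (non-sGC) soma at
    random and computes, within a circle of ``radius`` around each, the ratio
    of *other* selected to *other* unselected somas (both picked somas are
    excluded from both counts; a zero denominator gives +inf).  The labels
    are exchanged when the ratio around the selected soma is strictly smaller
    than around the unselected one, so selected labels migrate toward
    selected-rich neighbourhoods.  The selected count is conserved; with the
    default 20,000 trials executed swaps reach a plateau.
    """
    coords = lattice.coordinates if isinstance(lattice, PointPattern) else lattice
    mask = np.asarray(random_mask, dtype=bool).copy()
    n = coords.shape[0]
    if mask.shape != (n,):
        raise InvalidMaskError("mask shape mismatch")
    if not mask.any() or mask.all():
        raise InvalidMaskError("mask must be a proper nonempty subset")
    tree = cKDTree(coords)
    neighbors = tree.query_ball_point(coords, r=radius)
    neighbors = [np.array([j for j in nb if j != i], dtype=np.intp)
                 for i, nb in enumerate(neighbors)]
    rng = np.random.default_rng(seed)
    sel = list(np.flatnonzero(mask))
    unsel = list(np.flatnonzero(~mask))
    sel_pos = {int(i): k for k, i in enumerate(sel)}
    unsel_pos = {int(i): k for k, i in enumerate(unsel)}

    def local_ratio(center: int, a: int, b: int) -> float:
        """(# selected)/(# unselected) within radius of `center`, excluding a and b."""
        nb = neighbors[center]
        if nb.size == 0:
            return np.nan
        m = mask[nb]
        excl_sel = excl_unsel = 0
        for p in (a, b):
            loc = nb == p
            if loc.any():
                if mask[p]:
                    excl_sel += 1
                else:
                    excl_unsel += 1
        n_sel = int(m.sum()) - excl_sel
        n_unsel = (nb.size - int(m.sum())) - excl_unsel
        if n_unsel == 0:
            return np.inf
        return n_sel / n_unsel

    for _ in range(trials):
        s = sel[rng.integers(len(sel))]
        u = unsel[rng.integers(len(unsel))]
        r_s = local_ratio(s, s, u)
        r_u = local_ratio(u, s, u)
        if np.isnan(r_s) or np.isnan(r_u):
            continue
        if r_s < r_u:
            mask[s], mask[u] = False, True
            ks, ku = sel_pos.pop(s), unsel_pos.pop(u)
            sel[ks] = u
            unsel[ku] = s
            sel_pos[u] = ks
            unsel_pos[s] = ku
    return mask


def csr_envelope(
    lattice: PointPattern,
    target_fraction: float,
    grid: np.ndarray,
    kind: Literal["G", "F", "K"] = "G",
    n_sim: int = 50,
    seed: int | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Pointwise Monte-Carlo CSR envelope for G/F/K on a fixed lattice.

    Returns a DataFrame with columns ``distance``, ``lo``, ``hi``, ``mean``
    from ``n_sim`` Bernoulli configurations at ``target_fraction``.
    """
    rng = np.random.default_rng(seed)
    fns = {"G": g_function, "F": f_function, "K": k_function}
    sims = np.empty((n_sim, len(grid)))
    for s in range(n_sim):
        mask = generate_random_configuration(lattice, target_fraction, rng.integers(2**31))
        pat = lattice.with_mask(mask)
        if kind == "F":
            est = f_function(pat, grid, seed=int(rng.integers(2**31)))
        else:
            est = fns[kind](pat, grid)
        sims[s] = est.values
    alpha = (1 - level) / 2
    return pd.DataFrame(
        {
            "distance": np.asarray(grid, dtype=float),
            "lo": np.quantile(sims, alpha, axis=0),
            "hi": np.quantile(sims, 1 - alpha, axis=0),
            "mean": sims.mean(axis=0),
        }
    )
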