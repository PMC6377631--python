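"""Crossover interference statistics.

Coefficient of coincidence (CoC): for an interval pair (i, j), the fraction
of samples with a CO in both intervals divided by the product of the two
single-interval CO fractions.  CoC = 1 means independence; CoC < 1 at short
distance is the signature of interference.  Two scalar diagnostics summarise
a CoC curve:

* ``distance_coc1`` — the inter-interval distance at which the curve first
  reaches 1; tracks the interference spread distance L.
* ``coc_at_min_distance`` — the CoC value at the smallest distance bin;
  tracks the non-interfering (class II) CO load T2prob.

A bootstrap procedure quantifies the confidence that an observed
between-group difference (D-value) of either diagnostic exceeds sampling
noise, and a two-pathway gamma renewal model provides an independent,
mechanism-free interference fit (shape ``nu``, escape fraction ``p``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .bf_sim import BivalentCOSet, ChromatidCOSet

__all__ = [
    "IntervalCounts",
    "CoCCurve",
    "CoCFeatures",
    "FeatureDistribution",
    "GammaFit",
    "make_intervals",
    "coc_matrix",
    "coc_curve",
    "curve_features",
    "bootstrap_features",
    "fit_gamma_model",
]


@dataclass
class IntervalCounts:
    """Per-sample CO counts in equal-width intervals on [0, 1]."""

    edges: np.ndarray  # length n_intervals + 1, strictly increasing, [0 .. 1]
    counts: np.ndarray  # (n_samples, n_intervals) non-negative ints
    level: str = "bivalent"  # or "chromatid"

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("interval edges must be strictly increasing")
        if self.counts.shape[1] != len(self.edges) - 1:
            raise ValueError("counts/edges shape mismatch")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_intervals(self) -> int:
        return self.counts.shape[1]

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass
class CoCCurve:
    """Mean CoC per inter-interval distance bin."""

    distances: np.ndarray
    coc: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.coc = np.asarray(self.coc, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if np.any(np.diff(self.distances) <= 0):
            raise ValueError("distance bins must be ordered")


@dataclass
class CoCFeatures:
    """The two scalar CoC diagnostics.

    ``distance_coc1`` is None when the curve never reaches 1.
    """

    distance_coc1: float | None
    coc_at_min_distance: float


@dataclass
class FeatureDistribution:
    """Bootstrap feature replicates, pairwise D-values and confidence."""

    replicate_features: list  # of CoCFeatures
    d_distance: np.ndarray  # pairwise |delta distance_coc1|
    d_cocmin: np.ndarray  # pairwise |delta coc_at_min_distance|
    observed_d_distance: float
    observed_d_cocmin: float
    confidence_distance: float  # percent of bootstrap D-values below observed
    confidence_cocmin: float


@dataclass
class GammaFit:
    """Two-pathway gamma renewal fit.

    nu : gamma shape (interference strength; 1 = Poisson)
    p : proportion of non-interfering (independently placed) COs
    """

    nu: float
    p: float
    loglik: float
    nu_grid: np.ndarray
    p_grid: np.ndarray
    loglik_surface: np.ndarray  # (len(nu_grid), len(p_grid))
    n_sim: int
    seed: int


def _position_lists(co_set) -> list:
    if isinstance(co_set, (BivalentCOSet, ChromatidCOSet)):
        if isinstance(co_set, BivalentCOSet):
            return co_set.transmissible().position_lists()
        return co_set.position_lists()
    # plain list of position arrays
    return [np.sort(np.asarray(p, dtype=float)) for p in co_set]


def _level_of(co_set) -> str:
    if isinstance(co_set, ChromatidCOSet):
        return "chromatid"
    return "bivalent"


def make_intervals(co_set, n_intervals: int) -> IntervalCounts:
    """Histogram CO positions into equal-width intervals on [0, 1].

    Intervals are half-open [a, b); a CO exactly on an internal edge falls
    in the right interval; position 1.0 falls in the last interval.
    """
    if n_intervals < 2:
        raise ValueError("n_intervals must be >= 2")
    pos_lists = _position_lists(co_set)
    edges = np.linspace(0.0, 1.0, n_intervals + 1)
    counts = np.zeros((len(pos_lists), n_intervals), dtype=int)
    for i, p in enumerate(pos_lists):
        p = np.asarray(p, dtype=float)
        if p.size and (p.min() < 0 or p.max() > 1):
            raise ValueError("CO positions must be in [0, 1]")
        idx = np.minimum((p * n_intervals).astype(int), n_intervals - 1)
        np.add.at(counts[i], idx, 1)
    return IntervalCounts(edges=edges, counts=counts, level=_level_of(co_set))


def coc_matrix(counts: IntervalCounts) -> np.ndarray:
    """CoC(i, j) = f_ij / (f_i * f_j) over sample presence fractions.

    Presence (>= 1 CO) is used, not raw counts.  The diagonal and any pair
    involving an interval where no sample has a CO are NaN (undefined).
    """
    if counts.n_intervals < 2 or counts.n_samples < 1:
        raise ValueError("need >= 2 intervals and >= 1 sample")
    presence = (counts.counts > 0).astype(float)
    f = presence.mean(axis=0)
    if np.all(f == 0):
        warnings.warn("all intervals empty; CoC matrix fully undefined")
    n = counts.n_samples
    fij = (presence.T @ presence) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        coc = fij / np.outer(f, f)
    coc[:, f == 0] = np.nan
    coc[f == 0, :] = np.nan
    np.fill_diagonal(coc, np.nan)
    return coc


def coc_curve(matrix: np.ndarray, edges: np.ndarray) -> CoCCurve:
    """Average the CoC matrix into a curve over inter-interval distances.

    Distance is measured between interval centers.  Undefined (NaN) entries
    are excluded from the mean; distance bins with no defined pairs are
    omitted from the curve.
    """
    edges = np.asarray(edges, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    k = len(centers)
    if matrix.shape != (k, k):
        raise ValueError("matrix/edges shape mismatch")
    dists, means, npairs = [], [], []
    for lag in range(1, k):
        vals = np.diagonal(matrix, offset=lag)
        defined = ~np.isnan(vals)
        if defined.sum() == 0:
            continue
        dists.append(centers[lag] - centers[0])
        means.append(float(np.mean(vals[defined])))
        npairs.append(int(defined.sum()))
    return CoCCurve(np.array(dists), np.array(means), np.array(npairs))


def curve_features(curve: CoCCurve) -> CoCFeatures:
    """Extract the two scalar diagnostics from a CoC curve.

    ``coc_at_min_distance`` is the curve value at the smallest distance bin.
    ``distance_coc1`` is the first upward crossing of 1, linearly
    interpolated; if the curve starts at or above 1 it is the smallest bin
    distance, and if the curve never reaches 1 it is None (undefined).
    """
    if len(curve.distances) < 2:
        raise ValueError("curve needs >= 2 points")
    coc_min_d = float(curve.coc[0])
    if curve.coc[0] >= 1.0:
        return CoCFeatures(distance_coc1=float(curve.distances[0]),
                           coc_at_min_distance=coc_min_d)
    above = np.flatnonzero(curve.coc >= 1.0)
    if above.size == 0:
        return CoCFeatures(distance_coc1=None, coc_at_min_distance=coc_min_d)
    j = above[0]
    x0, x1 = curve.distances[j - 1], curve.distances[j]
    y0, y1 = curve.coc[j - 1], curve.coc[j]
    d1 = x0 + (1.0 - y0) * (x1 - x0) / (y1 - y0)
    return CoCFeatures(distance_coc1=float(d1), coc_at_min_distance=coc_min_d)


def features_of(co_set, n_intervals: int = 15) -> CoCFeatures:
    """Convenience: CO set -> interval counts -> CoC curve -> features."""
    ic = make_intervals(co_set, n_intervals)
    return curve_features(coc_curve(coc_matrix(ic), ic.edges))


def bootstrap_features(
    co_set,
    subset_size: int,
    n_reps: int,
    observed_delta: tuple[float, float],
    seed: int,
    n_intervals: int = 15,
) -> FeatureDistribution:
    """Bootstrap the sampling noise of the two CoC diagnostics.

    Draws ``n_reps`` subsets of ``subset_size`` samples without replacement,
    computes the diagnostics per subset, forms all C(n_reps, 2) pairwise
    absolute differences (D-values), and reports for each observed
    cross-group D-value the percentage of bootstrap D-values strictly below
    it (the confidence that the observed difference exceeds
    sampling noise).
    """
    pos_lists = _position_lists(co_set)
    n = len(pos_lists)
    if subset_size > n:
        raise ValueError(f"subset_size {subset_size} > available samples {n}")
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 17]))
    feats = []
    for _ in range(n_reps):
        idx = rng.choice(n, size=subset_size, replace=False)
        feats.append(features_of([pos_lists[i] for i in idx], n_intervals))
    d_dist, d_cmin = [], []
    for a, b in combinations(range(n_reps), 2):
        fa, fb = feats[a], feats[b]
        if fa.distance_coc1 is not None and fb.distance_coc1 is not None:
            d_dist.append(abs(fa.distance_coc1 - fb.distance_coc1))
        d_cmin.append(abs(fa.coc_at_min_distance - fb.coc_at_min_distance))
    d_dist = np.array(d_dist)
    d_cmin = np.array(d_cmin)
    obs_d, obs_c = float(observed_delta[0]), float(observed_delta[1])
    conf_d = 100.0 * float(np.mean(d_dist < obs_d)) if d_dist.size else float("nan")
    conf_c = 100.0 * float(np.mean(d_cmin < obs_c))
    return FeatureDistribution(
        replicate_features=feats,
        d_distance=d_dist,
        d_cocmin=d_cmin,
        observed_d_distance=obs_d,
        observed_d_cocmin=obs_c,
        confidence_distance=conf_d,
        confidence_cocmin=conf_c,
    )


# ---------------------------------------------------------------------------
# gamma two-pathway model


def _inter_co_distances(pos_lists: list) -> np.ndarray:
    gaps = [np.diff(np.sort(p)) for p in pos_lists if len(p) >= 2]
    if not gaps:
        return np.array([])
    return np.concatenate(gaps)


def simulate_gamma_pathway(
    nu: float,
    p: float,
    mean_count: float,
    n_samples: int,
    rng: np.random.Generator,
) -> list:
    """Simulate CO position lists on [0, 1] under the two-pathway model.

    With probability ``p`` a CO comes from a homogeneous Poisson pathway;
    the remaining rate (1-p) * mean_count comes from a stationary gamma
    renewal process with shape ``nu`` and matched mean inter-arrival.
    Stationarity is approximated by starting the renewal process a burn-in
    of ten mean gaps before the observed interval.
    """
    lam1 = (1.0 - p) * mean_count
    lam2 = p * mean_count
    per_sample: list = [[] for _ in range(n_samples)]
    if lam1 > 0:
        mu = 1.0 / lam1  # mean gap
        burn = 10.0 * mu
        need = (burn + 1.0) / mu
        m = int(np.ceil(need + 6.0 * np.sqrt(need) + 10))
        gaps = rng.gamma(shape=nu, scale=mu / nu, size=(n_samples, m))
        times = np.cumsum(gaps, axis=1) - burn
        inside = (times >= 0.0) & (times <= 1.0)
        for i in range(n_samples):
            per_sample[i].extend(times[i][inside[i]])
    if lam2 > 0:
        k2 = rng.poisson(lam2, size=n_samples)
        for i in range(n_samples):
            if k2[i]:
                per_sample[i].extend(rng.uniform(0.0, 1.0, size=k2[i]))
    return [np.sort(np.array(s)) for s in per_sample]


def fit_gamma_model(
    co_set,
    nu_grid=None,
    p_grid=None,
    n_sim: int = 5000,
    seed: int = 0,
) -> GammaFit:
    """Fit (nu, p) by maximum likelihood over a grid.

    For each grid point, ``n_sim`` samples are simulated with the CO rate
    matched to the observed mean count; the simulated inter-CO distance
    distribution is histogrammed (bin width 0.02 of genetic length, with a
    pseudo-count to avoid empty bins) and the observed inter-CO distances
    are scored against it.
    """
    if nu_grid is None:
        nu_grid = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0, 12.0])
    if p_grid is None:
        p_grid = np.array([0.0, 0.05, 0.10, 0.15, 0.20, 0.30])
    nu_grid = np.asarray(nu_grid, dtype=float)
    p_grid = np.asarray(p_grid, dtype=float)
    pos_lists = _position_lists(co_set)
    obs = _inter_co_distances(pos_lists)
    if obs.size == 0:
        raise ValueError("degenerate CO set: no sample has >= 2 COs")
    mean_count = float(np.mean([len(p) for p in pos_lists]))
    bins = np.arange(0.0, 1.0 + 0.02, 0.02)
    obs_idx = np.clip(np.searchsorted(bins, obs, side="right") - 1, 0, len(bins) - 2)
    surface = np.full((len(nu_grid), len(p_grid)), -np.inf)
    for a, nu in enumerate(nu_grid):
        for b, p in enumerate(p_grid):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(seed), 1000 + a * 100 + b])
            )
            sim = simulate_gamma_pathway(nu, p, mean_count, n_sim, rng)
            d = _inter_co_distances(sim)
            if d.size == 0:
                continue
            h, _ = np.histogram(d, bins=bins)
            dens = (h + 0.5) / (h.sum() + 0.5 * (len(bins) - 1))
            surface[a, b] = float(np.sum(np.log(dens[obs_idx])))
    ia, ib = np.unravel_index(np.argmax(surface), surface.shape)
    return GammaFit(
        nu=float(nu_grid[ia]),
        p=float(p_grid[ib]),
        loglik=float(surface[ia, ib]),
        nu_grid=nu_grid,
        p_grid=p_grid,
        loglik_surface=surface,
        n_sim=n_sim,
        seed=seed,
    )
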