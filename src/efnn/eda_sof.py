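"""Empirical data analytics (EDA) operators and the self-organising fuzzy partitioner.

The partitioner groups the samples of each class into *data clouds*: shape-free
clusters attracted to prototypes that are local maxima of the multimodal data
density.  An offline pass identifies the initial clouds; afterwards the
partition evolves one sample at a time, updating its running mean, second
moment, scatter and influence radius recursively and founding new clouds when
a sample is either denser than every prototype, sparser than every prototype,
or farther than the influence radius from all of them.

Distances are squared Euclidean, either on the raw vectors or (``cosine``)
on the L2-normalised vectors — the latter equals ``2 * (1 - cosine similarity)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist

__all__ = [
    "SampleMatrix",
    "UniquePointTable",
    "Cloud",
    "ClassPartition",
    "sq_distance",
    "pairwise_sq_distances",
    "cumulative_proximity",
    "unimodal_density",
    "unique_table",
    "multimodal_density",
    "rank_by_density",
    "identify_prototypes",
    "form_clouds",
    "influence_radius",
    "select_representatives",
    "fit_offline",
    "update_online",
    "clouds_to_gaussians",
]

#: Absolute floor applied to Gaussian widths so no fuzzy set degenerates.
SIGMA_ABS_FLOOR = 1e-6

#: Relative floor: fraction of the global per-dimension spread.
SIGMA_REL_FLOOR = 0.1


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SampleMatrix:
    """K x n feature matrix plus a length-K integer class-label vector."""

    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2 or self.values.shape[0] != self.labels.shape[0]:
            raise ValueError("values must be K x n with one label per row")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("missing or non-finite values are not supported")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("class labels must be nonnegative integers")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


@dataclass
class UniquePointTable:
    """Distinct sample locations and how often each occurs."""

    uniques: np.ndarray   # (U, n)
    freqs: np.ndarray     # (U,)


@dataclass
class Cloud:
    """One data cloud: prototype, member mean, support and per-dimension spread.

    ``m2`` holds the running sum of squared deviations of the members from
    their mean (Welford accumulator), so ``member_spread`` is the ddof-1
    sample standard deviation of the members in each dimension.
    """

    prototype: np.ndarray
    center: np.ndarray
    support: int
    m2: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.prototype = np.asarray(self.prototype, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        if self.m2 is None:
            self.m2 = np.zeros_like(self.center)

    @property
    def member_spread(self) -> np.ndarray:
        if self.support < 2:
            return np.zeros_like(self.center)
        return np.sqrt(self.m2 / (self.support - 1))

    def absorb(self, x: np.ndarray) -> None:
        """Assign ``x`` to this cloud: shift the prototype toward the sample
        by the support-weighted mean rule and update the member statistics."""
        s = self.support
        self.prototype = (s * self.prototype + x) / (s + 1)
        delta = x - self.center
        self.center = self.center + delta / (s + 1)
        self.m2 = self.m2 + delta * (x - self.center)
        self.support = s + 1


@dataclass
class ClassPartition:
    """Evolving per-class cloud partition with recursive global statistics.

    ``mean``, ``second_moment`` and ``scatter`` track the raw feature space;
    ``t_mean`` / ``t_sq_mean`` track the metric's working space (identical to
    the raw space for Euclidean, the unit sphere for cosine) and drive the
    recursive density and radius updates.
    """

    class_id: int
    clouds: list[Cloud]
    mean: np.ndarray
    second_moment: np.ndarray
    scatter: np.ndarray
    radius: float | None
    count: int
    granularity: int = 12
    metric: str = "euclidean"
    t_mean: np.ndarray = None  # type: ignore[assignment]
    t_sq_mean: float = 0.0

    @property
    def n_clouds(self) -> int:
        return len(self.clouds)

    def prototypes(self) -> np.ndarray:
        return np.array([c.prototype for c in self.clouds])


# ---------------------------------------------------------------------------
# distances and densities
# ---------------------------------------------------------------------------

def _check_metric(metric: str) -> None:
    if metric not in ("euclidean", "cosine"):
        raise ValueError(f"unknown metric {metric!r}")


def _transform(X: np.ndarray, metric: str) -> np.ndarray:
    """Map points into the metric's working space (unit sphere for cosine).

    A zero vector cannot be normalised; it is kept at the origin and a
    warning is issued, which makes its squared distance to any normalised
    point equal that point's squared norm (= 1).
    """
    if metric == "euclidean":
        return np.asarray(X, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    if np.any(norms == 0.0):
        warnings.warn("zero vector under cosine metric left unnormalised")
    safe = np.where(norms == 0.0, 1.0, norms)
    return X / safe


def sq_distance(a, b, metric: str = "euclidean") -> float:
    """Squared distance between two vectors under the active metric."""
    _check_metric(metric)
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("vectors must have the same length")
    if metric == "cosine":
        a = _transform(a[None, :], metric)[0]
        b = _transform(b[None, :], metric)[0]
    d = a - b
    return float(d @ d)


def pairwise_sq_distances(X: np.ndarray, metric: str = "euclidean") -> np.ndarray:
    """K x K matrix of squared distances under the active metric."""
    _check_metric(metric)
    T = _transform(np.atleast_2d(X), metric)
    return cdist(T, T, metric="sqeuclidean")


def cumulative_proximity(X, metric: str = "euclidean") -> np.ndarray:
    """Sum of squared distances from every sample to all samples (self included)."""
    vals = X.values if isinstance(X, SampleMatrix) else np.atleast_2d(X)
    return pairwise_sq_distances(vals, metric).sum(axis=1)


def unimodal_density(X, metric: str = "euclidean") -> np.ndarray:
    """Normalised inverse cumulative proximity; larger for more central points.

    When every sample occupies the same location all proximities vanish and
    the density is defined as uniformly 1.
    """
    vals = X.values if isinstance(X, SampleMatrix) else np.atleast_2d(X)
    K = vals.shape[0]
    pi = cumulative_proximity(vals, metric)
    if np.all(pi == 0.0):
        warnings.warn("all samples identical; unimodal density set to 1")
        return np.ones(K)
    return pi.sum() / (2.0 * K * pi)


def unique_table(X) -> UniquePointTable:
    """Collapse exactly repeated rows into unique locations with frequencies.

    Uniques keep first-appearance order so downstream tie-breaks are stable.
    """
    vals = X.values if isinstance(X, SampleMatrix) else np.atleast_2d(X)
    uniq, first, counts = np.unique(vals, axis=0, return_index=True, return_counts=True)
    order = np.argsort(first)
    return UniquePointTable(uniques=uniq[order], freqs=counts[order])


def multimodal_density(table: UniquePointTable, X, metric: str = "euclidean") -> np.ndarray:
    """Frequency-weighted density evaluated at the unique locations."""
    vals = X.values if isinstance(X, SampleMatrix) else np.atleast_2d(X)
    K = vals.shape[0]
    Tu = _transform(table.uniques, metric)
    Tx = _transform(vals, metric)
    pi_u = cdist(Tu, Tx, metric="sqeuclidean").sum(axis=1)
    pi_x = cdist(Tx, Tx, metric="sqeuclidean").sum(axis=1)
    if np.all(pi_x == 0.0):
        warnings.warn("all samples identical; density set to 1 per unique point")
        return table.freqs.astype(float)
    return table.freqs * pi_x.sum() / (2.0 * K * pi_u)


# ---------------------------------------------------------------------------
# offline prototype identification
# ---------------------------------------------------------------------------

def rank_by_density(table: UniquePointTable, dmm: np.ndarray,
                    metric: str = "euclidean") -> np.ndarray:
    """Order unique points: densest first, then greedy nearest-neighbour chain.

    Ties in density or distance resolve to the lowest original index.
    """
    U = table.uniques.shape[0]
    T = _transform(table.uniques, metric)
    r = np.empty(U, dtype=int)
    r[0] = int(np.argmax(dmm))
    remaining = np.ones(U, dtype=bool)
    remaining[r[0]] = False
    D = cdist(T, T, metric="sqeuclidean")
    for k in range(1, U):
        d = np.where(remaining, D[r[k - 1]], np.inf)
        r[k] = int(np.argmin(d))
        remaining[r[k]] = False
    return r


def identify_prototypes(r: np.ndarray, dmm: np.ndarray) -> np.ndarray:
    """Unique-point indices that are strict local density maxima along the chain.

    Endpoints only need to exceed their single neighbour.  If no position
    qualifies (flat chain) the head of the chain is returned.
    """
    r = np.asarray(r, dtype=int)
    d = np.asarray(dmm, dtype=float)[r]
    U = r.size
    if U == 1:
        return r.copy()
    keep = np.zeros(U, dtype=bool)
    keep[0] = d[0] > d[1]
    keep[-1] = d[-1] > d[-2]
    if U > 2:
        interior = (d[1:-1] > d[2:]) & (d[1:-1] > d[:-2])
        keep[1:-1] = interior
    if not keep.any():
        keep[0] = True
    return r[keep]


def form_clouds(X_c: np.ndarray, prototypes: np.ndarray,
                metric: str = "euclidean") -> list[Cloud]:
    """Attract every class sample to its nearest prototype; drop empty clouds.

    Equidistant samples go to the lowest prototype index.
    """
    X_c = np.atleast_2d(X_c)
    prototypes = np.atleast_2d(prototypes)
    if prototypes.shape[0] == 0:
        raise ValueError("at least one prototype is required")
    D = cdist(_transform(X_c, metric), _transform(prototypes, metric),
              metric="sqeuclidean")
    winner = np.argmin(D, axis=1)
    clouds: list[Cloud] = []
    for p in range(prototypes.shape[0]):
        members = X_c[winner == p]
        if members.shape[0] == 0:
            continue
        center = members.mean(axis=0)
        m2 = ((members - center) ** 2).sum(axis=0)
        clouds.append(Cloud(prototype=prototypes[p].copy(), center=center,
                            support=members.shape[0], m2=m2))
    return clouds


def influence_radius(X_c: np.ndarray, level: int, metric: str = "euclidean") -> float:
    """Average radius of the influential local area at the given granularity.

    Level 1 is the mean squared distance over unordered distinct pairs; each
    further level averages only the pairs strictly below the previous radius,
    stopping early (keeping the last radius) once no pair qualifies.
    """
    X_c = np.atleast_2d(X_c)
    if X_c.shape[0] < 2:
        raise ValueError("influence radius undefined for fewer than 2 samples")
    if level < 1:
        raise ValueError("granularity level must be >= 1")
    d = pdist(_transform(X_c, metric), metric="sqeuclidean")
    G = float(d.mean())
    for _ in range(level - 1):
        sub = d[d < G]
        if sub.size == 0:
            break
        G = float(sub.mean())
    return G


def select_representatives(clouds: list[Cloud], dmm_at_centers: np.ndarray,
                           G: float, metric: str = "euclidean") -> list[Cloud]:
    """Keep clouds whose density exceeds every neighbour within radius ``G``.

    A cloud with no neighbours is always kept; equal neighbouring densities
    resolve in favour of the lower cloud index so at least one of a tied
    group survives.
    """
    if not clouds:
        raise ValueError("clouds must be nonempty")
    centers = np.array([c.center for c in clouds])
    D = cdist(_transform(centers, metric), _transform(centers, metric),
              metric="sqeuclidean")
    d = np.asarray(dmm_at_centers, dtype=float)
    kept: list[Cloud] = []
    for i in range(len(clouds)):
        nb = [j for j in range(len(clouds)) if j != i and D[i, j] <= G]
        ok = all(d[i] > d[j] or (d[i] == d[j] and i < j) for j in nb)
        if ok:
            kept.append(clouds[i])
    return kept


def _density_at(points: np.ndarray, X_c: np.ndarray, metric: str) -> np.ndarray:
    """Batch unimodal density of arbitrary points w.r.t. the class samples."""
    Tx = _transform(X_c, metric)
    Tp = _transform(np.atleast_2d(points), metric)
    pi_x = cdist(Tx, Tx, metric="sqeuclidean").sum(axis=1)
    pi_p = cdist(Tp, Tx, metric="sqeuclidean").sum(axis=1)
    if np.all(pi_x == 0.0):
        return np.ones(Tp.shape[0])
    with np.errstate(divide="ignore"):
        out = pi_x.sum() / (2.0 * X_c.shape[0] * pi_p)
    return np.where(pi_p == 0.0, np.inf, out)


def _partition_stats(X_c: np.ndarray, metric: str) -> tuple:
    K, n = X_c.shape
    mu = X_c.mean(axis=0)
    Xm = (X_c[:, :, None] * X_c[:, None, :]).mean(axis=0)
    if K > 1:
        Sigma = K / (K - 1) * (Xm - np.outer(mu, mu))
    else:
        Sigma = np.zeros((n, n))
    T = _transform(X_c, metric)
    t_mean = T.mean(axis=0)
    t_sq_mean = float((T ** 2).sum(axis=1).mean())
    return mu, Xm, Sigma, t_mean, t_sq_mean


def fit_offline(X: SampleMatrix, level: int = 12,
                metric: str = "euclidean") -> list[ClassPartition]:
    """Offline cloud identification per class.

    Pipeline per class: unique table -> multimodal densities -> density-ranked
    chain -> local-maximum prototypes -> cloud formation -> representative
    filtering at the level-``level`` influence radius -> final cloud formation
    around the surviving centers.  A single-sample class yields one cloud and
    borrows the radius of the whole dataset.
    """
    _check_metric(metric)
    parts: list[ClassPartition] = []
    classes = np.unique(X.labels)
    global_radius = None
    if X.n_samples >= 2:
        global_radius = influence_radius(X.values, level, metric)
    for c in classes:
        X_c = X.values[X.labels == c]
        table = unique_table(X_c)
        dmm = multimodal_density(table, X_c, metric)
        r = rank_by_density(table, dmm, metric)
        proto_idx = identify_prototypes(r, dmm)
        clouds = form_clouds(X_c, table.uniques[proto_idx], metric)
        if X_c.shape[0] >= 2:
            G = influence_radius(X_c, level, metric)
            centers = np.array([cl.center for cl in clouds])
            supports = np.array([cl.support for cl in clouds])
            dmm_centers = supports * _density_at(centers, X_c, metric)
            kept = select_representatives(clouds, dmm_centers, G, metric)
            clouds = form_clouds(X_c, np.array([cl.center for cl in kept]), metric)
        else:
            G = global_radius
        mu, Xm, Sigma, t_mean, t_sq = _partition_stats(X_c, metric)
        parts.append(ClassPartition(
            class_id=int(c), clouds=clouds, mean=mu, second_moment=Xm,
            scatter=Sigma, radius=G, count=X_c.shape[0], granularity=level,
            metric=metric, t_mean=t_mean, t_sq_mean=t_sq))
    return parts


# ---------------------------------------------------------------------------
# online evolving update
# ---------------------------------------------------------------------------

def update_online(part: ClassPartition, x: np.ndarray) -> ClassPartition:
    """Absorb one sample into the partition, evolving a new cloud on demand.

    The global mean, second moment and scatter follow the recursive update
    rules; the influence radius scales with the ratio of the average
    cumulative proximities before and after absorption.  A sample founds a
    new cloud when its recursive density exceeds the maximum or undercuts
    the minimum over all prototypes, or when its squared distance to every
    prototype exceeds the radius; otherwise it is assigned to the nearest
    prototype (lowest index on ties).
    """
    x = np.asarray(x, dtype=float).ravel()
    if part.count > 0 and x.shape[0] != part.mean.shape[0]:
        raise ValueError("sample dimension does not match the partition")
    metric = part.metric
    t_x = _transform(x[None, :], metric)[0]

    if part.count == 0:
        part.mean = x.copy()
        part.second_moment = np.outer(x, x)
        part.scatter = np.zeros((x.size, x.size))
        part.t_mean = t_x.copy()
        part.t_sq_mean = float(t_x @ t_x)
        part.clouds = [Cloud(prototype=x.copy(), center=x.copy(), support=1)]
        part.count = 1
        return part

    K = part.count
    v_old = part.t_sq_mean - float(part.t_mean @ part.t_mean)
    part.mean = K / (K + 1) * part.mean + x / (K + 1)
    part.second_moment = K / (K + 1) * part.second_moment + np.outer(x, x) / (K + 1)
    part.scatter = (K + 1) / K * (part.second_moment - np.outer(part.mean, part.mean))
    part.t_mean = K / (K + 1) * part.t_mean + t_x / (K + 1)
    part.t_sq_mean = K / (K + 1) * part.t_sq_mean + float(t_x @ t_x) / (K + 1)
    part.count = K + 1
    v_new = max(part.t_sq_mean - float(part.t_mean @ part.t_mean), 0.0)

    # radius: ratio of average cumulative proximities (2 * working-space variance)
    if part.radius is not None and v_old > 0.0:
        part.radius = part.radius * (v_new / v_old)
    elif part.radius is None and v_new > 0.0:
        part.radius = 2.0 * v_new   # level-1 fallback for partitions founded online

    protos = part.prototypes()
    t_protos = _transform(protos, metric)

    def density(z: np.ndarray) -> float:
        if v_new <= 0.0:
            return 1.0
        d2 = float((z - part.t_mean) @ (z - part.t_mean))
        return v_new / (d2 + v_new)

    dens_x = density(t_x)
    dens_p = np.array([density(tp) for tp in t_protos])
    d2_protos = ((t_protos - t_x) ** 2).sum(axis=1)

    new_proto = dens_x > dens_p.max() or dens_x < dens_p.min()
    if not new_proto and part.radius is not None:
        new_proto = float(d2_protos.min()) > part.radius

    if new_proto:
        part.clouds.append(Cloud(prototype=x.copy(), center=x.copy(), support=1))
    else:
        part.clouds[int(np.argmin(d2_protos))].absorb(x)
    return part


# ---------------------------------------------------------------------------
# Gaussian projection
# ---------------------------------------------------------------------------

def clouds_to_gaussians(part: ClassPartition,
                        global_spread: np.ndarray | None = None) -> list[tuple]:
    """One (center, sigma) pair per cloud, in cloud order.

    Sigma is the per-dimension member spread floored at a fraction of the
    global per-dimension spread (the partition's own scatter by default) and
    never below an absolute minimum, so singleton clouds still yield usable
    fuzzy sets.
    """
    if not part.clouds:
        raise ValueError("partition has no clouds")
    if global_spread is None:
        global_spread = np.sqrt(np.clip(np.diag(part.scatter), 0.0, None))
    floor = np.maximum(SIGMA_REL_FLOOR * np.asarray(global_spread, dtype=float),
                       SIGMA_ABS_FLOOR)
    out = []
    for cl in part.clouds:
        sigma = np.maximum(cl.member_spread, floor)
        out.append((cl.center.copy(), sigma))
    return out
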