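"""Cluster-based permutation t-tests over time points or sensors.

Paired (dependent-sample) t statistics are computed per feature, values
exceeding the cluster-forming threshold (the ``cluster_alpha`` quantile
of the t distribution) are grouped into contiguous clusters under the
adjacency relation (temporal contiguity by default, or a sensor
neighbourhood graph), and each cluster's mass (sum of t) is compared to
the permutation distribution of the maximal cluster mass obtained by
randomly swapping the condition labels within each unit.  The Monte-Carlo
p value includes the observed statistic in the null
(``p = (1 + #{null >= observed}) / (n_perm + 1)``), so attainable p
values are bounded below by ``1 / (n_perm + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components


@dataclass
class ClusterTestSpec:
    """Settings of the cluster permutation test.

    ``tail``: "two", or "one" with ``direction`` +1 (positive clusters)
    or -1.  ``adjacency``: None for 1-D temporal contiguity, else a
    boolean/sparse (n_features, n_features) neighbourhood matrix.
    """

    tail: str = "two"
    direction: int = 1
    n_perm: int = 1000
    cluster_alpha: float = 0.05
    adjacency: object = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.tail not in ("one", "two"):
            raise ValueError("tail must be 'one' or 'two'")
        if self.direction not in (1, -1):
            raise ValueError("direction must be +1 or -1")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if not 0.0 < self.cluster_alpha < 0.5:
            raise ValueError("cluster_alpha must lie in (0, 0.5)")


@dataclass
class Cluster:
    members: np.ndarray
    mass: float
    p_value: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    t_observed: np.ndarray
    max_null_distribution: np.ndarray
    spec: ClusterTestSpec

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < alpha]


def dependent_t(cond_a: np.ndarray, cond_b: np.ndarray) -> np.ndarray:
    """Paired t statistic per feature; NaN flags zero-variance features.

    ``cond_a`` and ``cond_b`` are (n_units, n_features) with units paired
    (participants or simulation replicates).
    """
    a = np.atleast_2d(np.asarray(cond_a, dtype=float))
    b = np.atleast_2d(np.asarray(cond_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("conditions must have matching shapes")
    n = a.shape[0]
    if n < 2:
        raise ValueError("paired t needs at least two units")
    d = a - b
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)),
                     np.where(mean == 0, 0.0, np.nan))
    return t


def _t_from_signs(signs: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Paired t per feature for each sign-flip row, vectorised.

    ``signs`` is (n_perm, n_units) of +/-1; ``d`` is (n_units,
    n_features).  Sign flips leave the per-unit squares unchanged, so the
    variance follows from the flipped mean and the fixed sum of squares.
    """
    n = d.shape[0]
    mean = signs @ d / n
    sumsq = (d ** 2).sum(axis=0)
    var = (sumsq[None, :] - n * mean ** 2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(var > 0, mean / np.sqrt(var / n), 0.0)


def _clusters_1d(above: np.ndarray) -> list[np.ndarray]:
    """Runs of True in a 1-D mask."""
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return []
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    return np.split(idx, splits)


def _clusters_graph(above: np.ndarray, adjacency) -> list[np.ndarray]:
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return []
    sub = sparse.csr_matrix(sparse.csr_matrix(adjacency)[np.ix_(idx, idx)])
    n_comp, labels = connected_components(sub, directed=False)
    return [idx[labels == c] for c in range(n_comp)]


def _find_clusters(t: np.ndarray, threshold: float, sign: int, adjacency):
    above = sign * t > threshold
    if adjacency is None:
        groups = _clusters_1d(above)
    else:
        groups = _clusters_graph(above, adjacency)
    return [(g, float(t[g].sum())) for g in groups]


def knn_adjacency(positions: np.ndarray, k: int = 4) -> sparse.csr_matrix:
    """Symmetric k-nearest-neighbour sensor adjacency from positions."""
    pos = np.asarray(positions, dtype=float)
    n = pos.shape[0]
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        adj[i, np.argsort(d[i])[:k]] = True
    adj |= adj.T
    return sparse.csr_matrix(adj)


def cluster_permutation(values_a: np.ndarray, values_b: np.ndarray,
                        spec: ClusterTestSpec | None = None) -> ClusterResult:
    """Paired cluster-based permutation test.

    ``values_a`` / ``values_b`` are (n_units, n_features).  The null
    distribution is built by randomly flipping, per unit, which condition
    is which (equivalent to permuting the paired condition labels).
    """
    spec = spec or ClusterTestSpec()
    a = np.atleast_2d(np.asarray(values_a, dtype=float))
    b = np.atleast_2d(np.asarray(values_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("conditions must have matching shapes")
    n_units, n_features = a.shape
    if n_features == 0:
        raise ValueError("no features to test")
    d = a - b
    dof = n_units - 1
    if spec.tail == "two":
        threshold = stats.t.ppf(1 - spec.cluster_alpha / 2, dof)
        signs_to_scan = (1, -1)
    else:
        threshold = stats.t.ppf(1 - spec.cluster_alpha, dof)
        signs_to_scan = (spec.direction,)

    t_obs = dependent_t(a, b)
    t_obs_clean = np.nan_to_num(t_obs, nan=0.0)
    observed = []
    for s in signs_to_scan:
        observed.extend(_find_clusters(t_obs_clean, threshold, s, spec.adjacency))

    rng = np.random.default_rng(spec.seed)
    flips = rng.integers(0, 2, size=(spec.n_perm, n_units)) * 2 - 1
    t_null = _t_from_signs(flips, d)
    max_null = np.zeros(spec.n_perm)
    for p in range(spec.n_perm):
        masses = []
        for s in signs_to_scan:
            masses.extend(abs(m) for _, m in
                          _find_clusters(t_null[p], threshold, s, spec.adjacency))
        max_null[p] = max(masses, default=0.0)

    clusters = []
    for members, mass in observed:
        p_val = (1 + int(np.sum(max_null >= abs(mass)))) / (spec.n_perm + 1)
        clusters.append(Cluster(members=members, mass=mass, p_value=p_val))
    clusters.sort(key=lambda c: c.p_value)
    return ClusterResult(clusters=clusters, t_observed=t_obs,
                         max_null_distribution=max_null, spec=spec)


def compare_coherence_conditions(series_a: np.ndarray, series_b: np.ndarray,
                                 times: np.ndarray,
                                 window: tuple[float, float] = (0.1, 0.5),
                                 spec: ClusterTestSpec | None = None
                                 ) -> ClusterResult:
    """Temporal cluster test between two per-unit coherence time courses.

    ``series_a`` / ``series_b`` are (n_units, n_samples) — one row per
    participant or replicate, already averaged over the selected sensors.
    Only samples inside ``window`` are tested, with temporal contiguity
    as adjacency.
    """
    times = np.asarray(times)
    mask = (times >= window[0]) & (times <= window[1])
    if not mask.any():
        raise ValueError("window contains no samples")
    return cluster_permutation(np.asarray(series_a)[:, mask],
                               np.asarray(series_b)[:, mask], spec)
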