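"""Spatiotemporal cluster-based permutation tests on channel x time maps.

One-sample tests (e.g., regression slopes against zero) use random
sign-flips of whole participant maps as the permutation scheme; paired
tests (median-split high vs low) swap conditions within participant,
which is algebraically a sign-flip of the difference maps. Clusters are
connected components of same-sign suprathreshold t-values under channel
adjacency x temporal contiguity; the cluster-level statistic is the
cluster mass (signed sum of member t-values), and the permutation null
records the maximum absolute mass per permutation (0 when no cluster
forms), which controls the family-wise error rate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

__all__ = [
    "Adjacency", "Cluster", "ClusterTestResult",
    "build_adjacency", "find_clusters",
    "one_sample_cluster_test", "paired_cluster_test",
]


@dataclass
class Adjacency:
    """Symmetric channel neighborhood structure."""

    ch_names: list[str]
    matrix: np.ndarray  # (n_ch, n_ch) bool, symmetric, zero diagonal

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=bool)
        if m.shape != (len(self.ch_names),) * 2:
            raise ValueError("adjacency matrix shape does not match channels")
        if not np.array_equal(m, m.T):
            raise ValueError("adjacency must be symmetric")
        if m.diagonal().any():
            raise ValueError("channels cannot neighbor themselves")
        self.matrix = m

    def neighbors(self, ch: str) -> set[str]:
        i = self.ch_names.index(ch)
        return {self.ch_names[j] for j in np.flatnonzero(self.matrix[i])}

    def subset(self, ch_names: list[str]) -> "Adjacency":
        idx = [self.ch_names.index(c) for c in ch_names]
        return Adjacency(list(ch_names), self.matrix[np.ix_(idx, idx)])


@dataclass
class Cluster:
    """A connected set of same-sign suprathreshold channel-time points."""

    points: list[tuple[int, int]]  # (channel index, time index)
    sum_t: float
    sign: int
    p_value: float | None = None

    def labeled_points(self, ch_names: list[str],
                       times: np.ndarray) -> list[tuple[str, float]]:
        return [(ch_names[c], float(times[t])) for c, t in self.points]

    @property
    def size(self) -> int:
        return len(self.points)


@dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    t_map: np.ndarray
    threshold_t: float
    df: int
    n_permutations: int
    cluster_forming_p: float
    seed: int | None
    mode: str  # "montecarlo" | "exhaustive"
    ch_names: list[str] = field(default_factory=list)
    times: np.ndarray | None = None

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value is not None and c.p_value < alpha]

    def max_mass_cluster(self) -> Cluster | None:
        if not self.clusters:
            return None
        return max(self.clusters, key=lambda c: abs(c.sum_t))

    def to_json(self) -> str:
        payload = {
            "threshold_t": self.threshold_t, "df": self.df,
            "n_permutations": self.n_permutations,
            "cluster_forming_p": self.cluster_forming_p,
            "seed": self.seed, "mode": self.mode,
            "clusters": [
                {
                    "sum_t": c.sum_t, "sign": c.sign, "p": c.p_value,
                    "points": (c.labeled_points(self.ch_names, self.times)
                               if self.ch_names and self.times is not None
                               else c.points),
                }
                for c in self.clusters
            ],
        }
        return json.dumps(payload, indent=2)


def build_adjacency(positions: dict[str, np.ndarray] | np.ndarray,
                    ch_names: list[str] | None = None,
                    max_dist: float = 0.062) -> Adjacency:
    """Channels within ``max_dist`` (same units as positions) are neighbors.

    The default distance is tuned to give roughly 4-6 neighbors per
    channel on a standard 10/20 template in meters.
    """
    if isinstance(positions, dict):
        ch_names = list(positions) if ch_names is None else ch_names
        coords = np.stack([np.asarray(positions[c], float) for c in ch_names])
    else:
        if ch_names is None:
            raise ValueError("ch_names required with an array of positions")
        coords = np.asarray(positions, dtype=float)
    if coords.shape[0] < 2 or not np.isfinite(coords).all():
        raise ValueError("need >= 2 channels with finite coordinates")
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    m = (d <= max_dist) & ~np.eye(len(ch_names), dtype=bool)
    isolated = [c for c, row in zip(ch_names, m) if not row.any()]
    if isolated:
        warnings.warn(f"channels with no neighbors: {isolated}")
    return Adjacency(list(ch_names), m)


def find_clusters(t_map: np.ndarray, threshold_t: float,
                  adjacency: Adjacency) -> list[Cluster]:
    """Connected components of same-sign points with |t| > threshold.

    Connectivity: adjacent timepoints on the same channel, or neighboring
    channels at the same timepoint.
    """
    if threshold_t <= 0:
        raise ValueError("threshold_t must be positive")
    t_map = np.asarray(t_map, dtype=float)
    n_ch, n_t = t_map.shape
    supra = np.abs(t_map) > threshold_t
    sign = np.sign(t_map)
    visited = np.zeros_like(supra)
    neigh = adjacency.matrix
    clusters: list[Cluster] = []
    for c0 in range(n_ch):
        for t0 in range(n_t):
            if not supra[c0, t0] or visited[c0, t0]:
                continue
            s = sign[c0, t0]
            stack = [(c0, t0)]
            visited[c0, t0] = True
            members: list[tuple[int, int]] = []
            while stack:
                c, t = stack.pop()
                members.append((c, t))
                for tt in (t - 1, t + 1):
                    if 0 <= tt < n_t and supra[c, tt] and not visited[c, tt] \
                            and sign[c, tt] == s:
                        visited[c, tt] = True
                        stack.append((c, tt))
                for cc in np.flatnonzero(neigh[c]):
                    if supra[cc, t] and not visited[cc, t] and sign[cc, t] == s:
                        visited[cc, t] = True
                        stack.append((cc, t))
            clusters.append(Cluster(
                points=sorted(members),
                sum_t=float(t_map[tuple(zip(*members))].sum()),
                sign=int(s),
            ))
    return clusters


def _t_maps_for_signs(x_flat: np.ndarray, sum_x2: np.ndarray,
                      signs: np.ndarray) -> np.ndarray:
    """One-sample t-maps for many sign-flip patterns at once.

    Sign flips leave per-point sums of squares unchanged, so only the
    mean needs recomputing per permutation.
    """
    n = x_flat.shape[0]
    mean = signs @ x_flat / n  # (B, P)
    var = (sum_x2[None, :] - n * mean**2) / (n - 1)
    var = np.clip(var, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    t[~np.isfinite(t)] = 0.0
    return t


def _max_cluster_mass(t_row: np.ndarray, shape: tuple[int, int],
                      threshold_t: float, adjacency: Adjacency) -> float:
    t_map = t_row.reshape(shape)
    if not (np.abs(t_map) > threshold_t).any():
        return 0.0
    clusters = find_clusters(t_map, threshold_t, adjacency)
    return max(abs(c.sum_t) for c in clusters) if clusters else 0.0


def one_sample_cluster_test(maps: np.ndarray, adjacency: Adjacency,
                            cluster_forming_p: float = 0.01,
                            n_perm: int | str = 5000,
                            seed: int | None = None,
                            ch_names: list[str] | None = None,
                            times: np.ndarray | None = None,
                            ) -> ClusterTestResult:
    """Group-level cluster permutation test of maps against zero.

    ``maps`` is (n_participants, n_channels, n_times). The pointwise
    statistic is a one-sample t-test (df = n-1) thresholded at the
    two-tailed ``cluster_forming_p``; the null is built from random
    sign-flips of whole participant maps (``n_perm`` draws, or every one
    of the 2^n patterns when ``n_perm="all"``). Cluster p-values are
    two-tailed: the fraction of null maxima of |mass| at or above the
    observed |mass|, with the Monte-Carlo estimator (1+m)/(1+N).
    Zero-variance points get t = 0 with a warning.
    """
    maps = np.asarray(maps, dtype=float)
    n, n_ch, n_t = maps.shape
    if n < 2:
        raise ValueError("cluster test requires >= 2 participants")
    df = n - 1
    threshold_t = float(scipy.stats.t.ppf(1 - cluster_forming_p / 2, df))

    x_flat = maps.reshape(n, -1)
    sum_x2 = (x_flat**2).sum(axis=0)
    t_obs = _t_maps_for_signs(x_flat, sum_x2, np.ones((1, n)))[0]
    zero_var = np.isclose(x_flat.var(axis=0, ddof=1), 0.0) & (np.abs(x_flat.mean(0)) > 0)
    if zero_var.any():
        warnings.warn(f"{int(zero_var.sum())} zero-variance points set to t = 0")
    t_map = t_obs.reshape(n_ch, n_t)

    clusters = find_clusters(t_map, threshold_t, adjacency)

    exhaustive = (n_perm == "all") or (isinstance(n_perm, (int, np.integer))
                                       and n_perm >= 2**n)
    if exhaustive:
        if n > 20:
            raise ValueError("exhaustive enumeration limited to n <= 20")
        bits = np.arange(2**n)
        signs = 1.0 - 2.0 * ((bits[:, None] >> np.arange(n)[None, :]) & 1)
        mode = "exhaustive"
        n_used = 2**n
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(int(n_perm), n))
        mode = "montecarlo"
        n_used = int(n_perm)

    null_max = np.empty(n_used)
    shape = (n_ch, n_t)
    chunk = max(1, int(2_000_000 / max(x_flat.shape[1], 1)))
    pos = 0
    for start in range(0, n_used, chunk):
        block = _t_maps_for_signs(x_flat, sum_x2, signs[start:start + chunk])
        for row in block:
            null_max[pos] = _max_cluster_mass(row, shape, threshold_t, adjacency)
            pos += 1

    for c in clusters:
        m = int((null_max >= abs(c.sum_t) - 1e-12).sum())
        if mode == "exhaustive":
            c.p_value = m / n_used
        else:
            c.p_value = (1 + m) / (1 + n_used)

    return ClusterTestResult(
        clusters=sorted(clusters, key=lambda c: -abs(c.sum_t)),
        t_map=t_map, threshold_t=threshold_t, df=df,
        n_permutations=n_used, cluster_forming_p=cluster_forming_p,
        seed=seed, mode=mode,
        ch_names=ch_names or [], times=times,
    )


def paired_cluster_test(high: np.ndarray, low: np.ndarray,
                        adjacency: Adjacency,
                        cluster_forming_p: float = 0.01,
                        n_perm: int | str = 5000,
                        seed: int | None = None,
                        ch_names: list[str] | None = None,
                        times: np.ndarray | None = None) -> ClusterTestResult:
    """Paired cluster permutation test (high vs low condition).

    Within-participant condition swaps are sign-flips of the difference
    maps, so this is the one-sample test applied to ``high - low``.
    """
    high = np.asarray(high, dtype=float)
    low = np.asarray(low, dtype=float)
    if high.shape != low.shape:
        raise ValueError(
            f"condition arrays not aligned by participant: {high.shape} vs {low.shape}"
        )
    return one_sample_cluster_test(
        high - low, adjacency, cluster_forming_p=cluster_forming_p,
        n_perm=n_perm, seed=seed, ch_names=ch_names, times=times,
    )
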