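"""Cluster-based permutation tests for phase-response correlations.

Per time sample the observed circular-linear correlation rho(t) is
compared against a null distribution obtained by permuting the response
vector across trials (phases fixed).  A one-sided t-score of the
observed value against the permutation null (observed minus null mean,
over null std) is thresholded at the alpha quantile of a t distribution
with n_perm - 1 degrees of freedom; supra-threshold samples are joined
into contiguous clusters (1-D) or into connected components of the
sensor-adjacency x time graph (2-D).  Each cluster's statistic is the
sum of its member t-scores, and its p-value is the fraction of
permutations whose *maximum* cluster statistic meets or exceeds it —
the max-statistic construction that controls the family-wise error over
samples (and sensors).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError
from scipy.stats import t as t_dist

from .circstats import circ_lin_corr_matrix

__all__ = [
    "Cluster",
    "ClusterResult",
    "cluster_permutation_1d",
    "cluster_permutation_2d",
    "delaunay_adjacency",
]


@dataclass(frozen=True)
class Cluster:
    """One supra-threshold cluster."""

    members: tuple  # sample indices (1-D) or (sensor, sample) pairs (2-D)
    statistic: float  # sum of member t-scores
    p_value: float


@dataclass
class ClusterResult:
    """Clusters with permutation p-values plus the traces behind them."""

    clusters: list[Cluster]
    n_permutations: int
    alpha_cluster_forming: float
    seed: int
    rho: np.ndarray = field(default_factory=lambda: np.zeros(0))
    t_scores: np.ndarray = field(default_factory=lambda: np.zeros(0))
    threshold: float = np.nan
    sensor_summed_rho2: np.ndarray | None = None  # 2-D tests only

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < 0.05]

    def to_json(self, fs: float | None = None, t0: float = 0.0) -> str:
        """Serialise cluster spans (in seconds when fs is given)."""
        out = []
        for c in self.clusters:
            entry = {"statistic": c.statistic, "p_value": c.p_value}
            members = np.asarray(c.members)
            if members.ndim == 1:
                lo, hi = int(members.min()), int(members.max())
                if fs:
                    entry["span_s"] = [t0 + lo / fs, t0 + hi / fs]
                entry["samples"] = [lo, hi]
            else:
                entry["members"] = members.tolist()
            out.append(entry)
        return json.dumps({
            "n_permutations": self.n_permutations,
            "alpha_cluster_forming": self.alpha_cluster_forming,
            "seed": self.seed,
            "clusters": out,
        }, indent=2)


def _contiguous_runs(mask: np.ndarray) -> list[np.ndarray]:
    """Maximal runs of True in a boolean vector."""
    if not mask.any():
        return []
    idx = np.flatnonzero(mask)
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    return np.split(idx, splits)


def _max_run_sums(T_mat: np.ndarray, threshold: float) -> np.ndarray:
    """Per row: maximum contiguous sum of entries above threshold
    (0 when a row has no supra-threshold samples)."""
    P, T = T_mat.shape
    supra = T_mat > threshold
    pad = np.zeros((P, 1), dtype=bool)
    edges = np.diff(np.concatenate([pad, supra, pad], axis=1).astype(np.int8),
                    axis=1)
    starts = np.flatnonzero(edges.ravel() == 1)
    ends = np.flatnonzero(edges.ravel() == -1)  # row-major pairing
    if starts.size == 0:
        return np.zeros(P)
    vals = np.where(supra, T_mat, 0.0)
    csum = np.concatenate([np.zeros((P, 1)), np.cumsum(vals, axis=1)],
                          axis=1).ravel()
    run_sums = csum[ends] - csum[starts]
    rows = starts // (T + 1)
    out = np.zeros(P)
    np.maximum.at(out, rows, run_sums)
    return out


def _null_scores(rho_obs, rho_perm):
    """t-scores of observed and permuted rho against the permutation
    null (per sample mean/std over permutations)."""
    mu = np.nanmean(rho_perm, axis=0)
    sd = np.nanstd(rho_perm, axis=0, ddof=1)
    sd = np.where(sd > 0, sd, np.inf)
    t_obs = (rho_obs - mu) / sd
    t_perm = (rho_perm - mu[None, :]) / sd[None, :]
    return t_obs, t_perm


def cluster_permutation_1d(
    phases: np.ndarray,
    z: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> ClusterResult:
    """Temporal cluster permutation test of phase-response correlation.

    phases : (Nt, T) per-trial phases; z : (Nt,) linear response.
    """
    phases = np.asarray(phases, dtype=float)
    z = np.asarray(z, dtype=float)
    Nt, T = phases.shape
    if z.size != Nt:
        raise ValueError("response length must equal the trial count")
    if Nt < 10:
        warnings.warn("fewer than 10 trials: permutation null will be "
                      "coarse", stacklevel=2)
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(z) for _ in range(n_perm)])
    rho_obs = circ_lin_corr_matrix(phases, z[None, :])[0]
    rho_perm = circ_lin_corr_matrix(phases, perms)
    if np.all(~np.isfinite(rho_obs)):
        warnings.warn("correlation degenerate at every sample; empty "
                      "result", stacklevel=2)
        return ClusterResult([], n_perm, alpha, seed, rho=rho_obs,
                             t_scores=np.full(T, np.nan))
    t_obs, t_perm = _null_scores(rho_obs, rho_perm)
    thr = t_dist.ppf(1 - alpha, df=n_perm - 1)
    null_max = _max_run_sums(np.nan_to_num(t_perm, nan=-np.inf), thr)
    clusters = []
    for run in _contiguous_runs(np.nan_to_num(t_obs, nan=-np.inf) > thr):
        stat = float(t_obs[run].sum())
        p = float(np.mean(null_max >= stat))
        clusters.append(Cluster(members=tuple(int(i) for i in run),
                                statistic=stat, p_value=p))
    return ClusterResult(clusters, n_perm, alpha, seed, rho=rho_obs,
                         t_scores=t_obs, threshold=float(thr))


def delaunay_adjacency(sensor_positions: np.ndarray,
                       prune_factor: float = 1.5) -> np.ndarray:
    """Sensor adjacency from a Delaunay triangulation of the positions
    projected to 2-D; edges longer than ``prune_factor`` times the
    median edge length are pruned.  Returns a symmetric boolean
    (N, N) matrix."""
    pos = np.asarray(sensor_positions, dtype=float)
    N = pos.shape[0]
    xy = pos[:, :2] if pos.shape[1] >= 2 else pos
    adj = np.zeros((N, N), dtype=bool)
    try:
        tri = Delaunay(xy)
    except QhullError:
        warnings.warn("Delaunay triangulation failed; sensors treated as "
                      "isolated", stacklevel=2)
        return adj
    edges = set()
    for simplex in tri.simplices:
        for i in range(3):
            a, b = sorted((simplex[i], simplex[(i + 1) % 3]))
            edges.add((a, b))
    lengths = {e: np.linalg.norm(xy[e[0]] - xy[e[1]]) for e in edges}
    cutoff = prune_factor * np.median(list(lengths.values()))
    for (a, b), length in lengths.items():
        if length <= cutoff:
            adj[a, b] = adj[b, a] = True
    return adj


def _label_2d(supra: np.ndarray, adjacency: np.ndarray) -> list[np.ndarray]:
    """Connected components of supra-threshold (sensor, time) nodes under
    temporal adjacency within a sensor and spatial adjacency at the same
    time sample.  Returns lists of flat indices into the (N, T) grid."""
    N, T = supra.shape
    idx = np.flatnonzero(supra.ravel())
    if idx.size == 0:
        return []
    pos = {flat: i for i, flat in enumerate(idx)}
    # union-find over supra nodes
    parent = np.arange(idx.size)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    nbrs = [np.flatnonzero(adjacency[s]) for s in range(N)]
    for flat in idx:
        s, t = divmod(flat, T)
        if t + 1 < T and supra[s, t + 1]:
            union(pos[flat], pos[flat + 1])
        for s2 in nbrs[s]:
            if s2 > s and supra[s2, t]:
                union(pos[flat], pos[s2 * T + t])
    groups: dict[int, list[int]] = {}
    for flat in idx:
        groups.setdefault(find(pos[flat]), []).append(flat)
    return [np.asarray(g) for g in groups.values()]


def cluster_permutation_2d(
    phases_per_sensor: np.ndarray,
    z: np.ndarray,
    adjacency: np.ndarray | None = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> ClusterResult:
    """Sensor x time cluster permutation test.

    phases_per_sensor : (N, Nt, T); z : (Nt,).  Clusters connect
    supra-threshold nodes that are temporal neighbours on the same
    sensor or spatial neighbours at the same sample.  Also reports the
    temporally summed squared correlation per sensor.
    """
    phases_per_sensor = np.asarray(phases_per_sensor, dtype=float)
    z = np.asarray(z, dtype=float)
    N, Nt, T = phases_per_sensor.shape
    if adjacency is None or not np.any(adjacency):
        if adjacency is None:
            adjacency = np.zeros((N, N), dtype=bool)
        else:
            warnings.warn("empty adjacency: sensors treated as isolated",
                          stacklevel=2)
    adjacency = np.asarray(adjacency, dtype=bool)
    if not np.array_equal(adjacency, adjacency.T):
        raise ValueError("adjacency must be symmetric")
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(z) for _ in range(n_perm)])
    t_obs = np.empty((N, T))
    t_perm = np.empty((n_perm, N, T))
    rho_all = np.empty((N, T))
    for s in range(N):
        rho_obs = circ_lin_corr_matrix(phases_per_sensor[s], z[None, :])[0]
        rho_p = circ_lin_corr_matrix(phases_per_sensor[s], perms)
        to, tp = _null_scores(rho_obs, rho_p)
        t_obs[s] = np.nan_to_num(to, nan=-np.inf)
        t_perm[:, s, :] = np.nan_to_num(tp, nan=-np.inf)
        rho_all[s] = rho_obs
    thr = t_dist.ppf(1 - alpha, df=n_perm - 1)
    null_max = np.zeros(n_perm)
    for p in range(n_perm):
        comps = _label_2d(t_perm[p] > thr, adjacency)
        if comps:
            null_max[p] = max(t_perm[p].ravel()[g].sum() for g in comps)
    clusters = []
    for g in _label_2d(t_obs > thr, adjacency):
        stat = float(t_obs.ravel()[g].sum())
        pval = float(np.mean(null_max >= stat))
        members = tuple((int(f // T), int(f % T)) for f in g)
        clusters.append(Cluster(members=members, statistic=stat,
                                p_value=pval))
    return ClusterResult(
        clusters, n_perm, alpha, seed,
        rho=rho_all, t_scores=t_obs, threshold=float(thr),
        sensor_summed_rho2=np.nansum(rho_all**2, axis=1),
    )
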