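"""Functional connectivity from spontaneous spike trains.

Pairwise coupling between channels is quantified by the spike time
tiling coefficient (STTC), a firing-rate-insensitive correlation built
from coincidence tiles of half-width dt (10 ms): with T_A the fraction
of the recording tiled by train A and P_A the fraction of A's spikes
falling within dt of a spike of B,

    STTC = 1/2 [ (P_A - T_B)/(1 - P_A T_B) + (P_B - T_A)/(1 - P_B T_A) ].

Forty representative channels are chosen by k-means on electrode
coordinates; edges whose observed STTC exceeds the (1 - alpha) quantile
of spike-time-jittered surrogates are kept, weighted by the observed
STTC. Node metrics (degree, strength, within-module degree z-score,
participation coefficient) are computed on a consensus Louvain module
partition, and before/after conditions are compared metric-by-metric
with Welch t-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

__all__ = [
    "SpikeTrain",
    "ConnectivityGraph",
    "sttc",
    "select_representative_channels",
    "build_graph",
    "node_metrics",
    "consensus_modules",
    "within_module_z",
    "participation_coeff",
    "compare_conditions",
]


@dataclass
class SpikeTrain:
    """Strictly increasing spike times on one channel over [0, T]."""

    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.size:
            if t.min() < 0 or t.max() > self.duration + 1e-9:
                raise ValueError("spike times must lie in [0, duration]")
            if (np.diff(t) <= 0).any():
                t = np.unique(t)
        self.times = t

    @property
    def n(self) -> int:
        return int(self.times.size)


@dataclass
class ConnectivityGraph:
    """STTC-weighted graph over representative channels."""

    graph: nx.Graph
    channel_ids: np.ndarray
    sttc_matrix: np.ndarray
    partition: dict | None = None  # node -> module id

    @property
    def adjacency(self) -> np.ndarray:
        ids = list(self.channel_ids)
        a = np.zeros((len(ids), len(ids)), dtype=int)
        pos = {c: i for i, c in enumerate(ids)}
        for u, v in self.graph.edges:
            a[pos[u], pos[v]] = a[pos[v], pos[u]] = 1
        return a


def _tiled_fraction(times: np.ndarray, dt: float, duration: float) -> float:
    """Fraction of [0, duration] within +-dt of a spike (tiles merged, clipped)."""
    if times.size == 0:
        return 0.0
    starts = np.clip(times - dt, 0.0, duration)
    ends = np.clip(times + dt, 0.0, duration)
    prev_end = np.concatenate(([-np.inf], ends[:-1]))
    covered = np.maximum(0.0, ends - np.maximum(starts, prev_end)).sum()
    return float(covered / duration)


def _prop_within(a: np.ndarray, b: np.ndarray, dt: float) -> float:
    """Fraction of spikes in a within +-dt of some spike in b."""
    if a.size == 0 or b.size == 0:
        return 0.0
    idx = np.searchsorted(b, a)
    left = np.abs(a - b[np.clip(idx - 1, 0, b.size - 1)])
    right = np.abs(b[np.clip(idx, 0, b.size - 1)] - a)
    return float((np.minimum(left, right) <= dt + 1e-12).mean())


def sttc(a: SpikeTrain, b: SpikeTrain, dt: float = 0.010) -> float:
    """Spike time tiling coefficient between two trains; result in [-1, 1]."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if abs(a.duration - b.duration) > 1e-9:
        raise ValueError("trains must share a common recording length")
    if a.n == 0 or b.n == 0:
        warnings.warn("STTC of an empty spike train is defined as 0", stacklevel=2)
        return 0.0
    ta = _tiled_fraction(a.times, dt, a.duration)
    tb = _tiled_fraction(b.times, dt, b.duration)
    pa = _prop_within(a.times, b.times, dt)
    pb = _prop_within(b.times, a.times, dt)
    out = 0.0
    for p, t in ((pa, tb), (pb, ta)):
        denom = 1.0 - p * t
        if abs(denom) < 1e-12:
            denom = np.copysign(1e-12, denom if denom != 0 else 1.0)
        out += 0.5 * (p - t) / denom
    return float(np.clip(out, -1.0, 1.0))


def select_representative_channels(
    positions: np.ndarray, k: int = 40, seed: int = 0
) -> np.ndarray:
    """K-means (k clusters, 10 restarts) on electrode coordinates; the
    channel nearest each final centroid represents its cluster. Duplicate
    nearest channels resolve to the next-nearest unclaimed channel."""
    pos = np.asarray(positions, dtype=float)
    if pos.shape[0] < k:
        raise ValueError(f"need at least {k} channels, got {pos.shape[0]}")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(pos)
    chosen: list[int] = []
    taken = set()
    for center in km.cluster_centers_:
        d = np.linalg.norm(pos - center, axis=1)
        for c in np.argsort(d, kind="stable"):
            if int(c) not in taken:
                chosen.append(int(c))
                taken.add(int(c))
                break
    return np.sort(np.asarray(chosen))


def _jitter(train: SpikeTrain, rng, jitter: float) -> SpikeTrain:
    t = train.times + rng.uniform(-jitter, jitter, size=train.n)
    return SpikeTrain(np.sort(np.clip(t, 0.0, train.duration)), train.duration)


def build_graph(
    trains: Sequence[SpikeTrain],
    channel_ids: Sequence[int] | None = None,
    positions: np.ndarray | None = None,
    dt: float = 0.010,
    n_surrogates: int = 100,
    alpha: float = 0.05,
    jitter: float = 0.050,
    seed: int = 0,
) -> ConnectivityGraph:
    """Significant-edge STTC graph.

    An edge (i, j) is kept iff the observed STTC exceeds the
    ``1 - alpha`` quantile of STTCs from ``n_surrogates`` surrogate
    rounds in which every spike of both trains is independently
    jittered by U(-jitter, +jitter). Kept edges carry the observed STTC
    as weight.
    """
    n = len(trains)
    ids = np.asarray(channel_ids if channel_ids is not None else np.arange(n))
    rng = np.random.default_rng(seed)
    obs = np.zeros((n, n))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n):
            for j in range(i + 1, n):
                obs[i, j] = obs[j, i] = sttc(trains[i], trains[j], dt)
        null = np.zeros((n_surrogates, n, n))
        for r in range(n_surrogates):
            jt = [_jitter(tr, rng, jitter) for tr in trains]
            for i in range(n):
                for j in range(i + 1, n):
                    null[r, i, j] = null[r, j, i] = sttc(jt[i], jt[j], dt)
    thresh = np.quantile(null, 1.0 - alpha, axis=0)
    g = nx.Graph()
    for i, c in enumerate(ids):
        attrs = {}
        if positions is not None:
            attrs["x"], attrs["y"] = map(float, positions[i][:2])
        g.add_node(int(c), **attrs)
    for i in range(n):
        for j in range(i + 1, n):
            if obs[i, j] > thresh[i, j]:
                g.add_edge(int(ids[i]), int(ids[j]), weight=float(obs[i, j]))
    return ConnectivityGraph(graph=g, channel_ids=ids, sttc_matrix=obs)


def node_metrics(
    g: ConnectivityGraph, partition: dict | None = None
) -> pd.DataFrame:
    """Per-node degree, strength, and (given a partition) within-module
    degree z-score and participation coefficient."""
    part = partition if partition is not None else g.partition
    rows = []
    z = within_module_z(g, part) if part else {}
    p = participation_coeff(g, part) if part else {}
    for node in g.channel_ids:
        node = int(node)
        deg = g.graph.degree(node)
        strength = sum(d["weight"] for _, _, d in g.graph.edges(node, data=True))
        rows.append({
            "channel": node, "degree": int(deg), "strength": float(strength),
            "within_module_z": z.get(node, np.nan),
            "participation": p.get(node, np.nan),
            "module": (part or {}).get(node, -1),
        })
    return pd.DataFrame(rows).set_index("channel")


def _louvain_partition(graph: nx.Graph, seed: int) -> dict:
    # negative weights (possible for raw STTC) are floored at 0 for
    # modularity optimization
    h = nx.Graph()
    h.add_nodes_from(graph.nodes)
    for u, v, d in graph.edges(data=True):
        h.add_edge(u, v, weight=max(d.get("weight", 1.0), 0.0))
    comms = nx.community.louvain_communities(h, weight="weight", seed=seed)
    return {node: m for m, com in enumerate(comms) for node in com}


def consensus_modules(
    g: ConnectivityGraph, n_runs: int = 100, seed: int = 0, max_iter: int = 10
) -> dict:
    """Consensus Louvain partition.

    ``n_runs`` stochastic Louvain runs build a co-assignment matrix;
    entries below 0.5 are zeroed and the runs repeat on the consensus
    graph until all runs agree (or ``max_iter`` rounds). Deterministic
    given the seed.
    """
    rng = np.random.default_rng(seed)
    nodes = [int(c) for c in g.channel_ids]
    pos = {c: i for i, c in enumerate(nodes)}
    work = g.graph
    partition = None
    for _ in range(max_iter):
        runs = [
            _louvain_partition(work, int(rng.integers(2**31)))
            for _ in range(n_runs)
        ]
        co = np.zeros((len(nodes), len(nodes)))
        for part in runs:
            lab = np.array([part[c] for c in nodes])
            co += lab[:, None] == lab[None, :]
        co /= n_runs
        first = runs[0]
        if all(
            ({c: part[c] for c in nodes} == {c: first[c] for c in nodes})
            or _same_partition(part, first, nodes)
            for part in runs
        ):
            partition = first
            break
        co[co < 0.5] = 0.0
        work = nx.Graph()
        work.add_nodes_from(nodes)
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                if co[i, j] > 0:
                    work.add_edge(nodes[i], nodes[j], weight=co[i, j])
    if partition is None:
        partition = _louvain_partition(work, int(rng.integers(2**31)))
    # renumber modules deterministically by smallest member channel
    order = sorted({m for m in partition.values()},
                   key=lambda m: min(c for c in nodes if partition[c] == m))
    remap = {m: i for i, m in enumerate(order)}
    final = {c: remap[partition[c]] for c in nodes}
    g.partition = final
    return final


def _same_partition(a: dict, b: dict, nodes) -> bool:
    la = [a[c] for c in nodes]
    lb = [b[c] for c in nodes]
    seen = {}
    for x, y in zip(la, lb):
        if seen.setdefault(x, y) != y:
            return False
    return len(set(la)) == len(set(lb))


def within_module_z(g: ConnectivityGraph, partition: dict) -> dict:
    """Within-module degree z-score; singleton or zero-spread modules get 0."""
    z = {}
    modules: dict[int, list[int]] = {}
    for c, m in partition.items():
        modules.setdefault(m, []).append(c)
    for members in modules.values():
        mem = set(members)
        kin = {
            c: sum(1 for nb in g.graph.neighbors(c) if nb in mem) for c in members
        }
        vals = np.array([kin[c] for c in members], dtype=float)
        sd = vals.std()
        mean = vals.mean()
        for c in members:
            z[c] = 0.0 if sd < 1e-12 or len(members) < 2 else (kin[c] - mean) / sd
    return z


def participation_coeff(g: ConnectivityGraph, partition: dict) -> dict:
    """P_i = 1 - sum_s (K_is / K_i)^2; isolated nodes get 0."""
    p = {}
    for c in partition:
        k = g.graph.degree(c)
        if k == 0:
            p[c] = 0.0
            continue
        per_mod: dict[int, int] = {}
        for nb in g.graph.neighbors(c):
            per_mod[partition[nb]] = per_mod.get(partition[nb], 0) + 1
        p[c] = 1.0 - sum((ks / k) ** 2 for ks in per_mod.values())
    return p


def compare_conditions(
    before: pd.DataFrame,
    after: pd.DataFrame,
    before_edges: Sequence[float] | None = None,
    after_edges: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Welch t-tests comparing node/edge metrics across two conditions.

    Returns one row per metric with n, mean, sd, quantiles per condition
    and the t statistic and two-sided p value.
    """
    metrics = {
        "degree": ("degree", "degree"),
        "strength": ("strength", "strength"),
        "within_module_z": ("within_module_z", "within_module_z"),
        "participation": ("participation", "participation"),
    }
    rows = []
    for name, (cb, ca) in metrics.items():
        xb = np.asarray(before[cb].dropna(), dtype=float)
        xa = np.asarray(after[ca].dropna(), dtype=float)
        rows.append(_ttest_row(name, xb, xa))
    if before_edges is not None and after_edges is not None:
        rows.append(_ttest_row(
            "edge_weight", np.asarray(before_edges, float), np.asarray(after_edges, float)
        ))
    return pd.DataFrame(rows).set_index("metric")


def _ttest_row(name, xb, xa):
    if xb.size > 1 and xa.size > 1 and (xb.std() > 0 or xa.std() > 0):
        t, p = stats.ttest_ind(xb, xa, equal_var=False)
    else:
        t, p = 0.0, 1.0
    qb = np.quantile(xb, [0.25, 0.5, 0.75]) if xb.size else [np.nan] * 3
    qa = np.quantile(xa, [0.25, 0.5, 0.75]) if xa.size else [np.nan] * 3
    return {
        "metric": name,
        "n_before": xb.size, "mean_before": xb.mean() if xb.size else np.nan,
        "sd_before": xb.std(ddof=1) if xb.size > 1 else np.nan,
        "q25_before": qb[0], "median_before": qb[1], "q75_before": qb[2],
        "n_after": xa.size, "mean_after": xa.mean() if xa.size else np.nan,
        "sd_after": xa.std(ddof=1) if xa.size > 1 else np.nan,
        "q25_after": qa[0], "median_after": qa[1], "q75_after": qa[2],
        "t": float(t), "p": float(p),
    }
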