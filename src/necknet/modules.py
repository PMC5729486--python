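"""Connectivity modules: simulated-annealing modularity optimization.

A connectivity module is a group of nodes densely linked among themselves
and sparsely linked to the rest of the network.  Partitions are scored with
the Newman-Girvan modularity

    Q = sum_m [ l_m / K  -  (d_m / 2K)^2 ]

(``l_m`` internal links, ``d_m`` total degree of module *m*, ``K`` links in
the network) and found by simulated annealing on -Q, the objective the
spin-glass community model reduces to at coupling gamma = 1.  The standard
error of Q is estimated by a delete-one-link jackknife, and each module is
tested with a one-sided Wilcoxon rank-sum test of its nodes' internal
versus external link counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
from scipy import stats

from .io import AnatomicalNetwork

__all__ = [
    "AnnealingSchedule",
    "ModulePartition",
    "modularity_q",
    "detect_modules",
    "consensus_modules",
    "jackknife_q_error",
    "is_strongly_modular",
    "module_significance",
    "merge_mirror_modules",
]

STRONG_MODULARITY_THRESHOLD = 0.3


@dataclass(frozen=True)
class AnnealingSchedule:
    """Cooling schedule for the annealer.

    ``t0=None`` calibrates the initial temperature so that roughly half of
    the uphill moves sampled from the initial state are accepted.  Each
    sweep proposes ``N`` single-node reassignments plus ``max(1, N//10)``
    merge/split moves, then multiplies the temperature by ``cooling``.
    The search stops after ``patience`` sweeps without improving the best
    Q seen, or at ``max_sweeps``.
    """

    t0: float | None = None
    cooling: float = 0.995
    patience: int = 50
    max_sweeps: int = 3000


@dataclass
class ModuleStats:
    module: int
    size: int
    internal_links: int
    external_links: int
    p_value: float | None  # None when the module has < 2 nodes


@dataclass
class ModulePartition:
    """A node -> module assignment with its quality statistics."""

    assignment: dict
    Q: float
    Q_error: float | None = None
    module_stats: list[ModuleStats] = field(default_factory=list)
    seed: int | None = None
    schedule: AnnealingSchedule | None = None

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values()))

    def module_sizes(self) -> dict:
        sizes: dict = {}
        for m in self.assignment.values():
            sizes[m] = sizes.get(m, 0) + 1
        return sizes

    def members(self) -> dict:
        out: dict = {}
        for node, m in self.assignment.items():
            out.setdefault(m, []).append(node)
        return {m: sorted(v) for m, v in out.items()}


def _graph(net) -> nx.Graph:
    return net.graph if isinstance(net, AnatomicalNetwork) else net


def _arrays(g: nx.Graph):
    nodes = sorted(g.nodes())
    index = {v: i for i, v in enumerate(nodes)}
    adj = [np.array([index[u] for u in g.neighbors(v)], dtype=np.int64)
           for v in nodes]
    deg = np.array([len(a) for a in adj], dtype=np.int64)
    return nodes, index, adj, deg


def _labels_from_assignment(nodes, assignment) -> np.ndarray:
    missing = [v for v in nodes if v not in assignment]
    if missing:
        raise ValueError(f"partition misses nodes: {missing[:5]}")
    if len(assignment) != len(nodes):
        raise ValueError("partition references nodes absent from the network")
    mods = {}
    labels = np.empty(len(nodes), dtype=np.int64)
    for i, v in enumerate(nodes):
        labels[i] = mods.setdefault(assignment[v], len(mods))
    return labels


def _q_from_labels(labels: np.ndarray, adj, deg) -> float:
    m = int(deg.sum()) // 2
    if m == 0:
        raise ValueError("modularity undefined for an edgeless graph")
    k = labels.max() + 1
    l_int = np.zeros(k)
    d_tot = np.zeros(k)
    for i, nbrs in enumerate(adj):
        c = labels[i]
        d_tot[c] += deg[i]
        l_int[c] += np.count_nonzero(labels[nbrs] == c)
    l_int /= 2.0
    return float(np.sum(l_int / m - (d_tot / (2.0 * m)) ** 2))


def modularity_q(net, partition: Mapping) -> float:
    """Newman-Girvan Q of a given partition."""
    g = _graph(net)
    assignment = getattr(partition, "assignment", partition)
    nodes, _, adj, deg = _arrays(g)
    labels = _labels_from_assignment(nodes, assignment)
    return _q_from_labels(labels, adj, deg)


# ---------------------------------------------------------------------------
# simulated annealing


def _anneal(adj, deg, rng, schedule: AnnealingSchedule) -> tuple[np.ndarray, float]:
    n = len(adj)
    m = int(deg.sum()) // 2
    two_m = 2.0 * m
    labels = np.arange(n, dtype=np.int64)  # start from singletons
    d_mod: dict[int, float] = {i: float(deg[i]) for i in range(n)}
    members: dict[int, set] = {i: {i} for i in range(n)}
    next_label = n

    def k_to(i: int, c: int) -> int:
        return int(np.count_nonzero(labels[adj[i]] == c))

    def delta_node(i: int, b: int) -> float:
        a = labels[i]
        if a == b:
            return 0.0
        kia = k_to(i, a)
        kib = k_to(i, b)
        return (kib - kia) / m - deg[i] * (
            d_mod.get(b, 0.0) - d_mod[a] + deg[i]
        ) / (2.0 * m * m)

    def apply_node(i: int, b: int) -> None:
        a = labels[i]
        labels[i] = b
        d_mod[a] -= deg[i]
        d_mod[b] = d_mod.get(b, 0.0) + deg[i]
        members[a].discard(i)
        if not members[a]:
            del members[a]
            del d_mod[a]
        members.setdefault(b, set()).add(i)

    def edges_between(ma: set, mb: set) -> int:
        small, other = (ma, mb) if len(ma) <= len(mb) else (mb, ma)
        lab = labels[next(iter(other))]
        return sum(int(np.count_nonzero(labels[adj[i]] == lab)) for i in small)

    # calibrate the initial temperature on uphill single-node moves
    t = schedule.t0
    if t is None:
        uphill = []
        mod_list = list(members)
        for _ in range(200):
            i = int(rng.integers(n))
            b = int(rng.choice(mod_list))
            dq = delta_node(i, b)
            if dq < 0:
                uphill.append(-dq)
        t = (float(np.mean(uphill)) / math.log(2.0)) if uphill else 0.01

    q = _q_from_labels(labels, adj, deg)
    best_q, best_labels = q, labels.copy()
    stale = 0
    n_sub = max(1, n // 10)

    for _ in range(schedule.max_sweeps):
        for _ in range(n):
            i = int(rng.integers(n))
            u = rng.random()
            if deg[i] and u < 0.9:
                b = int(labels[int(rng.choice(adj[i]))])
            elif u < 0.95:
                existing = list(members)
                b = int(existing[int(rng.integers(len(existing)))])
            else:  # propose splitting off into a fresh singleton module
                b = next_label
                next_label += 1
            if b == labels[i]:
                continue
            dq = delta_node(i, b)
            if dq >= 0 or rng.random() < math.exp(dq / t):
                apply_node(i, b)
                q += dq
        for _ in range(n_sub):
            mods = list(members)
            if rng.random() < 0.5 and len(mods) >= 2:
                a, b = rng.choice(len(mods), size=2, replace=False)
                a, b = mods[a], mods[b]
                e_ab = edges_between(members[a], members[b])
                dq = e_ab / m - d_mod[a] * d_mod[b] / (2.0 * m * m)
                if dq >= 0 or rng.random() < math.exp(dq / t):
                    for i in list(members[b]):
                        apply_node(i, a)
                    q += dq
            else:
                a = mods[int(rng.integers(len(mods)))]
                size = len(members[a])
                if size < 2:
                    continue
                group = list(members[a])
                mask = rng.random(size) < 0.5
                half = [i for i, s in zip(group, mask) if s]
                if not half or len(half) == size:
                    continue
                d_half = float(np.sum(deg[np.array(half)]))
                lab_half = set(half)
                e_cross = sum(
                    1
                    for i in half
                    for j in adj[i]
                    if labels[j] == a and int(j) not in lab_half
                )
                # undoing a merge of (half, rest): dq_split = -dq_merge
                d_rest = d_mod[a] - d_half
                dq = -(e_cross / m - d_half * d_rest / (2.0 * m * m))
                if dq >= 0 or rng.random() < math.exp(dq / t):
                    b = next_label
                    next_label += 1
                    for i in half:
                        apply_node(i, b)
                    q += dq
        if q > best_q + 1e-12:
            best_q, best_labels = q, labels.copy()
            stale = 0
        else:
            stale += 1
            if stale >= schedule.patience:
                break
        t *= schedule.cooling
    return best_labels, best_q


def _compact(labels: np.ndarray) -> np.ndarray:
    _, out = np.unique(labels, return_inverse=True)
    return out


def detect_modules(
    net,
    seed: int = 0,
    schedule: AnnealingSchedule | None = None,
    compute_error: bool = True,
) -> ModulePartition:
    """Detect connectivity modules by simulated annealing on Q.

    Deterministic given ``seed`` and ``schedule``.  Raises on disconnected
    networks (module structure of fragments is not comparable).
    """
    g = _graph(net)
    if g.number_of_nodes() == 0 or not nx.is_connected(g):
        raise ValueError("module detection requires a connected network")
    schedule = schedule or AnnealingSchedule()
    nodes, _, adj, deg = _arrays(g)
    rng = np.random.default_rng(seed)
    labels, q = _anneal(adj, deg, rng, schedule)
    labels = _compact(labels)
    assignment = {v: int(c) for v, c in zip(nodes, labels)}
    part = ModulePartition(
        assignment=assignment, Q=q, seed=seed, schedule=schedule
    )
    part.Q = modularity_q(g, assignment)  # recompute exactly
    if compute_error:
        part.Q_error = jackknife_q_error(g, assignment)
    part.module_stats = module_significance(g, assignment)
    return part


def consensus_modules(
    net,
    n_seeds: int = 20,
    seed: int = 0,
    schedule: AnnealingSchedule | None = None,
) -> tuple[ModulePartition, np.ndarray]:
    """Re-run detection with ``n_seeds`` seeds; return the best-Q partition
    and the node x node co-assignment frequency matrix (tree of node order:
    sorted node labels)."""
    g = _graph(net)
    nodes = sorted(g.nodes())
    n = len(nodes)
    co = np.zeros((n, n))
    best: ModulePartition | None = None
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_seeds):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        part = detect_modules(
            g, seed=sub_seed, schedule=schedule, compute_error=False
        )
        lab = np.array([part.assignment[v] for v in nodes])
        co += (lab[:, None] == lab[None, :]).astype(float)
        if best is None or part.Q > best.Q:
            best = part
    co /= n_seeds
    best.Q_error = jackknife_q_error(g, best.assignment)
    best.module_stats = module_significance(g, best.assignment)
    return best, co


# ---------------------------------------------------------------------------
# error and significance


def jackknife_q_error(net, partition: Mapping) -> float:
    """Delete-one-link jackknife standard error of Q, partition held fixed.

    Every link is treated as an independent observation:
    SE = sqrt( (K-1)/K * sum_e (Q_(-e) - mean Q_(-e))^2 ).
    """
    g = _graph(net)
    assignment = getattr(partition, "assignment", partition)
    nodes, index, adj, deg = _arrays(g)
    labels = _labels_from_assignment(nodes, assignment)
    m = g.number_of_edges()
    if m < 2:
        raise ValueError("jackknife requires at least 2 links")
    k = labels.max() + 1
    l_int = np.zeros(k)
    d_tot = np.zeros(k)
    for i, nbrs in enumerate(adj):
        c = labels[i]
        d_tot[c] += deg[i]
        l_int[c] += np.count_nonzero(labels[nbrs] == c)
    l_int /= 2.0

    q_loo = np.empty(m)
    for e, (u, v) in enumerate(sorted(map(tuple, map(sorted, g.edges())))):
        cu, cv = labels[index[u]], labels[index[v]]
        li = l_int.copy()
        dt = d_tot.copy()
        dt[cu] -= 1
        dt[cv] -= 1
        if cu == cv:
            li[cu] -= 1
        mm = m - 1
        q_loo[e] = float(np.sum(li / mm - (dt / (2.0 * mm)) ** 2))
    qbar = q_loo.mean()
    return float(np.sqrt((m - 1) / m * np.sum((q_loo - qbar) ** 2)))


def is_strongly_modular(q: float, q_error: float) -> bool:
    """Strong modularity rule: Q - Q_error must exceed 0.3 (strict)."""
    return (q - q_error) > STRONG_MODULARITY_THRESHOLD


def module_significance(net, partition: Mapping) -> list[ModuleStats]:
    """Wilcoxon rank-sum test of internal vs external links per module.

    For each module, the per-node internal link counts are compared with
    the per-node external link counts, one-sided (internal > external, the
    defining property of a connectivity module).  Modules of size < 2 get
    ``p_value=None``.  Exact null distribution when both samples have at
    most 25 observations and no ties; the tie-corrected normal
    approximation otherwise.
    """
    g = _graph(net)
    assignment = getattr(partition, "assignment", partition)
    nodes, index, adj, deg = _arrays(g)
    labels = _labels_from_assignment(nodes, assignment)
    out: list[ModuleStats] = []
    for mod in sorted(set(labels.tolist())):
        mask = labels == mod
        ids = np.nonzero(mask)[0]
        internal = np.array(
            [np.count_nonzero(labels[adj[i]] == mod) for i in ids]
        )
        external = deg[ids] - internal
        size = len(ids)
        int_links = int(internal.sum()) // 2
        ext_links = int(external.sum())
        if size < 2:
            p = None
        else:
            ties = len(np.unique(np.concatenate([internal, external]))) < (
                2 * size
            )
            method = "exact" if (size <= 25 and not ties) else "asymptotic"
            p = float(
                stats.mannwhitneyu(
                    internal, external, alternative="greater", method=method
                ).pvalue
            )
        out.append(ModuleStats(int(mod), size, int_links, ext_links, p))
    return out


# ---------------------------------------------------------------------------
# bilateral post-processing


def _mirror(label: str) -> str:
    if label.endswith("l"):
        return label[:-1] + "r"
    if label.endswith("r"):
        return label[:-1] + "l"
    return label


def merge_mirror_modules(partition: ModulePartition, net) -> ModulePartition:
    """Merge module pairs that are left/right mirror images of each other.

    Bilateral anatomies often split one anatomical module into a left and a
    right connectivity module; for summary purposes these can be fused when
    the node sets map onto each other under the l/r suffix swap.  Q and the
    module statistics are recomputed for the merged assignment.
    """
    g = _graph(net)
    members = partition.members()
    mods = sorted(members)
    merged_into = {m: m for m in mods}
    for i, a in enumerate(mods):
        for b in mods[i + 1:]:
            if merged_into[a] != a or merged_into[b] != b:
                continue
            sa = set(members[a])
            sb = set(members[b])
            if {_mirror(x) for x in sa} == sb:
                merged_into[b] = a
    assignment = {
        v: merged_into[m] for v, m in partition.assignment.items()
    }
    q = modularity_q(g, assignment)
    return ModulePartition(
        assignment=assignment,
        Q=q,
        Q_error=jackknife_q_error(g, assignment),
        module_stats=module_significance(g, assignment),
        seed=partition.seed,
        schedule=partition.schedule,
    )
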