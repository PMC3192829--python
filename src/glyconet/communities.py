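"""Fast-greedy modularity optimization and partition quality.

Modules are detected by agglomerative modularity maximization: every node
starts as a singleton community and the community pair whose merge yields
the largest modularity gain is merged repeatedly until no merge increases
Q = sum_c [l_c/m - (d_c/2m)^2] (l_c intra-community edges, d_c total degree
of community c, m total edges).  Edges are treated as unweighted and
undirected.  Ties in the modularity gain are broken deterministically on the
communities' canonical labels (the smallest member gene id), so identical
inputs always give identical partitions.

A reported module is a community with at least ``min_module_size`` members
(default 5, i.e. "more than four genes"); smaller communities stay
unassigned.  Module ids are assigned by decreasing size, ties by smallest
member id.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from sklearn.metrics import adjusted_rand_score

from .netinfer import CoexpressionNetwork

DEFAULT_MIN_MODULE_SIZE = 5


@dataclass
class ModulePartition:
    """Community assignment with reported modules and quality."""

    assignment: dict[str, str]        # gene -> community label (canonical member id)
    modularity_q: float
    modules: list[tuple[int, list[str]]]   # (module_id, sorted member genes)
    unassigned: list[str]
    min_module_size: int

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    def module_sizes(self) -> list[int]:
        return [len(members) for _, members in self.modules]

    def module_of(self) -> dict[str, int]:
        """gene -> reported module id (filtered communities only)."""
        out = {}
        for mid, members in self.modules:
            for g in members:
                out[g] = mid
        return out


def modularity(graph: nx.Graph, assignment: dict[str, str]) -> float:
    """Q recomputed from scratch for an arbitrary assignment (unweighted)."""
    m = graph.number_of_edges()
    if m == 0:
        raise ValueError("modularity undefined for an empty network")
    intra: dict[str, int] = {}
    deg: dict[str, int] = {}
    for node, d in graph.degree:
        c = assignment[node]
        deg[c] = deg.get(c, 0) + d
    for u, v in graph.edges:
        if assignment[u] == assignment[v]:
            c = assignment[u]
            intra[c] = intra.get(c, 0) + 1
    q = 0.0
    for c, d in deg.items():
        q += intra.get(c, 0) / m - (d / (2 * m)) ** 2
    return q


def fast_greedy_modules(
    net: CoexpressionNetwork | nx.Graph,
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
) -> ModulePartition:
    """Agglomerative greedy modularity maximization (CNM scheme).

    Deterministic: among merges with equal gain, the pair whose canonical
    (smallest-member-id) labels sort lowest is merged.  Merging stops at the
    first step where no gain is strictly positive; the returned Q is tracked
    incrementally and equals the from-scratch value on the final partition.
    """
    graph = net.graph if isinstance(net, CoexpressionNetwork) else net
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot partition an empty network")
    m = graph.number_of_edges()
    if m == 0:
        raise ValueError("cannot partition a network with no edges")

    # community state, keyed by canonical label = smallest member id
    members: dict[str, set[str]] = {n: {n} for n in graph.nodes}
    deg: dict[str, int] = {n: d for n, d in graph.degree}
    intra: dict[str, int] = {n: 0 for n in graph.nodes}
    between: dict[str, dict[str, int]] = {n: {} for n in graph.nodes}
    for u, v in graph.edges:
        if u == v:
            continue
        between[u][v] = between[u].get(v, 0) + 1
        between[v][u] = between[v].get(u, 0) + 1

    q = -sum((d / (2 * m)) ** 2 for d in deg.values())
    two_m_sq = 2.0 * m * m

    while True:
        best_gain = 0.0
        best_pair: tuple[str, str] | None = None
        for a in between:
            da = deg[a]
            for b, l_ab in between[a].items():
                if b <= a:
                    continue
                gain = l_ab / m - da * deg[b] / two_m_sq
                if gain > best_gain or (
                    best_pair is not None
                    and gain == best_gain
                    and (a, b) < best_pair
                ):
                    if gain > 0:
                        best_gain = gain
                        best_pair = (a, b)
        if best_pair is None:
            break
        a, b = best_pair  # a < b; merged community keeps label a
        q += best_gain
        members[a] |= members.pop(b)
        intra[a] = intra[a] + intra.pop(b) + between[a].pop(b)
        deg[a] += deg.pop(b)
        for c, l_bc in between.pop(b).items():
            if c == a:
                continue
            between[c].pop(b)
            between[a][c] = between[a].get(c, 0) + l_bc
            between[c][a] = between[a][c]

    assignment = {g: label for label, comm in members.items() for g in comm}
    partition = ModulePartition(
        assignment=assignment,
        modularity_q=float(q),
        modules=[],
        unassigned=[],
        min_module_size=min_module_size,
    )
    return filter_modules(partition, min_module_size)


def filter_modules(p: ModulePartition, min_module_size: int) -> ModulePartition:
    """Re-derive reported modules at a (possibly different) size floor.

    Communities below the floor move to ``unassigned``; module ids are
    renumbered 1..k by decreasing size, ties by smallest member gene id.
    """
    comms: dict[str, list[str]] = {}
    for g, c in p.assignment.items():
        comms.setdefault(c, []).append(g)
    kept = [sorted(v) for v in comms.values() if len(v) >= min_module_size]
    kept.sort(key=lambda mem: (-len(mem), mem[0]))
    modules = [(i + 1, mem) for i, mem in enumerate(kept)]
    assigned = {g for _, mem in modules for g in mem}
    unassigned = sorted(set(p.assignment) - assigned)
    return ModulePartition(
        assignment=dict(p.assignment),
        modularity_q=p.modularity_q,
        modules=modules,
        unassigned=unassigned,
        min_module_size=min_module_size,
    )


def partition_quality(p: ModulePartition, truth) -> tuple[float, float]:
    """(adjusted Rand index, recovered fraction) against planted labels.

    Both are restricted to planted-module members present in the network;
    ``recovered_fraction`` is the share of those members that ended up in
    some reported (size-filtered) module.
    """
    planted = [g for g in p.assignment if truth.module_of.get(g) is not None]
    if not planted:
        raise ValueError("network shares no genes with the planted modules")
    true_labels = [truth.module_of[g] for g in planted]
    pred_labels = [p.assignment[g] for g in planted]
    ari = float(adjusted_rand_score(true_labels, pred_labels))
    reported = set(p.module_of())
    recovered = float(np.mean([g in reported for g in planted]))
    return ari, recovered
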