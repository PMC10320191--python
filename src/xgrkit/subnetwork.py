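"""Prize-collecting Steiner tree subnetwork detection with permutation significance.

Gene scores x_i >= 0 (capped −log10 p for gene-level input, 1–10 display
scores for linked genes) become node prizes x_i − λ.  A Takahashi–Matsuyama
style heuristic grows a tree over the positive-prize seeds, connection costs
being the folded negative prizes of the nodes a path adds; growth restarts
from several roots (exhaustively on small components, from top seeds and
star-gain hubs on large ones) to catch solutions that share one expensive
connector among many seeds.  An exact maximum-weight connected-subtree
dynamic program on each grown tree then discards unprofitable branches —
this subsumes negative-leaf pruning and makes the solver exactly optimal
whenever the underlying graph is itself a tree.  λ is tuned by bisection so
the subnetwork reaches a desired size, and significance is estimated by a
degree-preserving score permutation test.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .knowledgebase import GeneNetwork

logger = logging.getLogger("xgrkit")

#: Cap on −log10(p) node scores, guarding against p = 0 underflow.
SCORE_CAP = 16.0

#: Additive edge length keeping all connection costs strictly positive.
EDGE_EPS = 1e-6


class SubnetworkError(ValueError):
    pass


@dataclass(frozen=True)
class NodeScore:
    gene_symbol: str
    x: float  # >= 0

    def __post_init__(self) -> None:
        if not math.isfinite(self.x) or self.x < 0:
            raise SubnetworkError(f"node score for {self.gene_symbol!r} must be finite and >= 0")


@dataclass
class Subnetwork:
    nodes: set[str]
    edges: set[tuple[str, str]]  # tree edges, gene_a < gene_b
    objective: float             # sum over nodes of (x_i - lambda_final)
    lambda_final: float = 0.0
    empirical_p: float | None = None
    permutations_used: int = 0

    @property
    def size(self) -> int:
        return len(self.nodes)


def scores_from_pvalues(pvalues: Mapping[str, float]) -> list[NodeScore]:
    """Convert gene-level p-values to node scores x = min(−log10 p, 16)."""
    out = []
    for gene in sorted(pvalues):
        p = pvalues[gene]
        if not 0.0 <= p <= 1.0:
            raise SubnetworkError(f"p-value for {gene!r} outside [0, 1]")
        x = SCORE_CAP if p == 0.0 else min(-math.log10(p), SCORE_CAP)
        out.append(NodeScore(gene, max(x, 0.0)))
    return out


def assign_prizes(
    scores: Sequence[NodeScore], lam: float, net: GeneNetwork
) -> dict[str, float]:
    """prize_i = x_i − λ over every network node; unscored nodes take x = 0."""
    if lam < 0:
        raise SubnetworkError("lambda must be >= 0")
    x = {s.gene_symbol: s.x for s in scores}
    return {node: x.get(node, 0.0) - lam for node in net.nodes}


# ---------------------------------------------------------------------------
# PCST heuristic
# ---------------------------------------------------------------------------

#: Components up to this many nodes try every node as a growth root; larger
#: ones fall back to a fixed number of seed and hub roots.
SMALL_COMPONENT_EXHAUSTIVE = 16

#: Growth restarts on large components: the top seeds by prize plus the top
#: hub candidates by star gain (own prize + adjacent seed prizes).
N_RESTART_ROOTS = 3


def _tree_dijkstra(
    adj: dict[str, list[str]], tree: set[str], prizes: Mapping[str, float]
) -> tuple[dict[str, float], dict[str, str | None]]:
    """Cheapest attachment paths from the current tree under node costs.

    The cost of a path is the folded negative prize of every node it adds;
    nodes already in the tree are free.  A tiny per-edge epsilon keeps costs
    strictly positive so ties resolve towards fewer hops, then towards
    lexicographically smaller nodes.
    """
    dist: dict[str, float] = {s: 0.0 for s in tree}
    pred: dict[str, str | None] = {s: None for s in tree}
    heap = [(0.0, s) for s in sorted(tree)]
    heapq.heapify(heap)
    done: set[str] = set()
    while heap:
        d, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        for v in adj[u]:
            nd = d + (0.0 if v in tree else max(-prizes[v], 0.0)) + EDGE_EPS
            if nd < dist.get(v, math.inf):
                dist[v] = nd
                pred[v] = u
                heapq.heappush(heap, (nd, v))
    return dist, pred


def _grow_tree(
    comp: set[str],
    adj: dict[str, list[str]],
    prizes: Mapping[str, float],
    root: str,
) -> tuple[set[str], set[tuple[str, str]]]:
    """Takahashi–Matsuyama growth from one root: repeatedly attach the seed
    with the cheapest path to the current tree until all seeds are spanned."""
    tree_nodes: set[str] = {root}
    tree_edges: set[tuple[str, str]] = set()
    remaining = {n for n in comp if prizes[n] > 0} - tree_nodes
    while remaining:
        dist, pred = _tree_dijkstra(adj, tree_nodes, prizes)
        target = min(remaining, key=lambda s: (dist.get(s, math.inf), s))
        if not math.isfinite(dist.get(target, math.inf)):
            break  # defensive: should not happen within one component
        path = [target]
        while pred[path[-1]] is not None:
            path.append(pred[path[-1]])
        for u, v in zip(path, path[1:]):
            tree_edges.add((u, v) if u < v else (v, u))
        tree_nodes.update(path)
        remaining -= tree_nodes
    return tree_nodes, tree_edges


def _candidate_roots(
    comp: set[str],
    adj: dict[str, list[str]],
    prizes: Mapping[str, float],
    seeds: Sequence[str],
) -> list[str]:
    """Growth restarts: exhaustive on small components, seeds + hubs on large.

    A single greedy growth can miss solutions that share one expensive
    connector between several seeds; restarting from a prospective hub lets
    the shared node be paid for before per-seed path costs are compared.
    """
    if len(comp) <= SMALL_COMPONENT_EXHAUSTIVE:
        return sorted(comp)
    star = {
        v: prizes[v] + sum(prizes[u] for u in adj[v] if prizes[u] > 0)
        for v in comp
    }
    hubs = sorted((v for v in comp if star[v] > 0), key=lambda v: (-star[v], v))
    roots = list(seeds[:N_RESTART_ROOTS]) + hubs[:N_RESTART_ROOTS]
    return list(dict.fromkeys(roots))


def _best_subtree(
    nodes: set[str],
    edges: set[tuple[str, str]],
    prizes: Mapping[str, float],
) -> tuple[set[str], set[tuple[str, str]], float]:
    """Exact maximum-weight connected subtree of a tree (node weights = prizes).

    Rooted DP: down[v] = prize[v] + Σ_children max(0, down[c]); the optimum is
    the best down[v] over all v, reconstructed by descending into children
    with down[c] > 0.  Ties broken towards the lexicographically smallest
    anchor node for reproducibility.
    """
    tree_adj: dict[str, list[str]] = {n: [] for n in nodes}
    for a, b in edges:
        tree_adj[a].append(b)
        tree_adj[b].append(a)
    root = min(nodes)
    order: list[str] = []
    parent: dict[str, str | None] = {root: None}
    stack = [root]
    while stack:
        u = stack.pop()
        order.append(u)
        for v in sorted(tree_adj[u]):
            if v != parent.get(u):
                parent[v] = u
                stack.append(v)
    down: dict[str, float] = {}
    for u in reversed(order):
        down[u] = prizes[u] + sum(
            max(0.0, down[c]) for c in tree_adj[u] if parent.get(c) == u
        )
    anchor = min(nodes, key=lambda n: (-down[n], n))
    best_nodes: set[str] = set()
    best_edges: set[tuple[str, str]] = set()
    stack = [anchor]
    while stack:
        u = stack.pop()
        best_nodes.add(u)
        for c in tree_adj[u]:
            if parent.get(c) == u and down[c] > 0.0:
                best_edges.add((u, c) if u < c else (c, u))
                stack.append(c)
    obj = sum(prizes[n] for n in sorted(best_nodes))
    return best_nodes, best_edges, obj


def pcst_heuristic(net: GeneNetwork, prizes: Mapping[str, float]) -> Subnetwork:
    """Heuristic prize-collecting Steiner tree over the gene network.

    Each connected component holding at least one seed (prize > 0) is solved
    independently: seed-spanning growth from every candidate root, each grown
    tree reduced by the exact maximum-weight-subtree DP, and the best tree
    kept.  Across components the tree with the largest objective wins (ties
    resolve towards the lexicographically smallest node set).  With no seeds
    anywhere the subnetwork is empty (objective 0).
    """
    if not net.nodes:
        raise SubnetworkError("empty network")
    adj: dict[str, list[str]] = {n: [] for n in net.nodes}
    for a, b in net.edges:
        adj[a].append(b)
        adj[b].append(a)
    best: tuple[float, tuple[str, ...]] | None = None
    best_sub: Subnetwork | None = None
    for comp in nx.connected_components(net.to_networkx()):
        comp = set(comp)
        seeds = sorted((n for n in comp if prizes[n] > 0),
                       key=lambda n: (-prizes[n], n))
        if not seeds:
            continue
        for root in _candidate_roots(comp, adj, prizes, seeds):
            grown_nodes, grown_edges = _grow_tree(comp, adj, prizes, root)
            nodes, edges, obj = _best_subtree(grown_nodes, grown_edges, prizes)
            key = (-obj, tuple(sorted(nodes)))
            if best is None or key < best:
                best = key
                best_sub = Subnetwork(nodes=nodes, edges=edges, objective=obj)
    if best_sub is None:
        return Subnetwork(nodes=set(), edges=set(), objective=0.0)
    return best_sub


# ---------------------------------------------------------------------------
# Size-targeted search and permutation test
# ---------------------------------------------------------------------------

def default_tol(target_n: int) -> int:
    return max(1, math.ceil(0.1 * target_n))


def search_subnetwork(
    net: GeneNetwork,
    scores: Sequence[NodeScore],
    target_n: int,
    tol: int | None = None,
    max_iter: int = 50,
    return_trace: bool = False,
):
    """Bisection on λ until the subnetwork size reaches ``target_n`` ± ``tol``.

    Larger λ shrinks the tree.  The λ = 0 solution is evaluated first (the
    largest attainable tree); bisection then narrows λ in [0, max(x)].  Among
    all iterates the one whose size is closest to ``target_n`` wins, ties
    broken by larger objective, then smaller λ.
    """
    if target_n < 1:
        raise SubnetworkError("target_n must be >= 1")
    if tol is None:
        tol = default_tol(target_n)
    in_net = [s for s in scores if s.gene_symbol in net.nodes]
    dropped = len(scores) - len(in_net)
    if dropped:
        logger.info("subnetwork: dropped %d scored genes absent from the network", dropped)
    max_x = max((s.x for s in in_net), default=0.0)

    def solve(lam: float) -> Subnetwork:
        sub = pcst_heuristic(net, assign_prizes(in_net, lam, net))
        return replace(sub, lambda_final=lam)

    trace: list[Subnetwork] = [solve(0.0)]
    if target_n > len(net.nodes):
        logger.warning("subnetwork: target_n=%d exceeds network size %d; "
                       "returning the lambda=0 solution", target_n, len(net.nodes))
    elif max_x > 0.0 and trace[0].size > target_n + tol:
        lo, hi = 0.0, max_x
        for _ in range(max_iter):
            lam = (lo + hi) / 2.0
            sub = solve(lam)
            trace.append(sub)
            if abs(sub.size - target_n) <= tol:
                break
            if sub.size > target_n:
                lo = lam
            else:
                hi = lam
    best = min(trace, key=lambda s: (abs(s.size - target_n), -s.objective, s.lambda_final))
    if return_trace:
        return best, trace
    return best


def permutation_significance(
    net: GeneNetwork,
    scores: Sequence[NodeScore],
    observed: Subnetwork,
    B: int = 100,
    bins: int = 10,
    seed: int | None = None,
    target_n: int | None = None,
    tol: int | None = None,
    max_iter: int = 50,
) -> tuple[float, np.ndarray]:
    """Degree-preserving permutation p-value for an observed subnetwork.

    Network nodes are binned by degree quantiles (at most ``bins`` bins, fewer
    when there are fewer distinct degrees); scores are shuffled within bins
    and the size-targeted search re-run with the same target/tolerance.
    empirical_p = (1 + #{b : objective_b >= observed}) / (1 + B).
    """
    if B < 1:
        raise SubnetworkError("permutation count B must be >= 1")
    if target_n is None:
        target_n = max(1, observed.size)
    g = net.to_networkx()
    nodes = sorted(net.nodes)
    degrees = np.array([g.degree(n) for n in nodes], dtype=float)
    x_map = {s.gene_symbol: s.x for s in scores}
    x = np.array([x_map.get(n, 0.0) for n in nodes], dtype=float)
    n_bins = min(bins, len(np.unique(degrees)))
    edges = np.quantile(degrees, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    bin_idx = np.clip(np.searchsorted(edges, degrees, side="right") - 1, 0, len(edges) - 2) \
        if len(edges) > 1 else np.zeros(len(nodes), dtype=int)
    groups = [np.flatnonzero(bin_idx == b) for b in range(max(1, len(edges) - 1))]
    rng = np.random.default_rng(seed)
    null = np.empty(B)
    for b in range(B):
        perm_x = x.copy()
        for idx in groups:
            if len(idx) > 1:
                perm_x[idx] = perm_x[rng.permutation(idx)]
        perm_scores = [NodeScore(n, float(v)) for n, v in zip(nodes, perm_x)]
        sub = search_subnetwork(net, perm_scores, target_n, tol=tol, max_iter=max_iter)
        null[b] = sub.objective
    p = (1 + int(np.sum(null >= observed.objective))) / (1 + B)
    return p, null
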