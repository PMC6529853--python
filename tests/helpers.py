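"""Shared test helpers: fixture builders and independent brute-force oracles.

The oracles here deliberately avoid the package's own code paths: graph
distances are recomputed with a hand-rolled BFS over the edge set, activity
scores with plain Python arithmetic, and the greedy trace is re-derived by
exhaustive enumeration of every admissible candidate at every step.
"""

from __future__ import annotations

import math

import networkx as nx
import pandas as pd

from icds import PathwayGraph, SearchParams, greedy_expand


def make_risk(rs: dict, p_s: dict | None = None) -> pd.DataFrame:
    """Minimal risk table: RS per gene, optional combined p (default tiny)."""
    genes = list(rs)
    df = pd.DataFrame(index=pd.Index(genes, name="gene"))
    df["RS"] = [rs[g] for g in genes]
    df["p_S"] = [(p_s or {}).get(g, 1e-6) for g in genes]
    return df


def pg_from_edges(pid: str, edges, extra_nodes=()) -> PathwayGraph:
    g = nx.Graph()
    g.add_edges_from(edges)
    g.add_nodes_from(extra_nodes)
    return PathwayGraph(pid, pid, g)


# ---------------------------------------------------------------- oracles


def bfs_distances(edges, source):
    """All shortest-path distances from ``source`` over an explicit edge set."""
    adj: dict = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for v in frontier:
            for w in adj.get(v, ()):
                if w not in dist:
                    dist[w] = dist[v] + 1
                    nxt.append(w)
        frontier = nxt
    return dist


def brute_induced_diameter(graph: PathwayGraph, genes) -> float:
    """Induced-subgraph diameter by all-pairs BFS over the induced edge set."""
    genes = set(genes)
    induced_edges = [(a, b) for a, b in graph.graph.edges
                     if a in genes and b in genes]
    best = 0.0
    for s in genes:
        dist = bfs_distances(induced_edges, s)
        for t in genes:
            if t not in dist:
                return math.inf
            best = max(best, dist[t])
    return best


def oracle_score(genes, risk: pd.DataFrame, normalization: str) -> float:
    vals = [float(risk["RS"][g]) for g in genes
            if g in risk.index and math.isfinite(risk["RS"][g])]
    assert vals, "oracle_score: no scored gene"
    return (sum(vals) / math.sqrt(len(vals)) if normalization == "sqrt"
            else sum(vals) / len(vals))


def oracle_admissible(graph: PathwayGraph, current: list, risk, params) -> list:
    """Every gene adjacent to the current set that carries an RS and keeps
    the induced diameter within the cap -- enumerated from scratch."""
    current_set = set(current)
    out = []
    for g in sorted(graph.graph.nodes):
        if g in current_set:
            continue
        if not any((g, m) in graph.edges or (m, g) in graph.edges
                   or graph.graph.has_edge(g, m) for m in current_set):
            continue
        if g not in risk.index or not math.isfinite(risk["RS"][g]):
            continue
        if brute_induced_diameter(graph, current_set | {g}) <= params.max_distance:
            out.append(g)
    return out


def oracle_rule(as_new: float, as_cur: float, params: SearchParams) -> bool:
    if params.acceptance_rule == "literal":
        return as_new > (1.0 + params.improvement_rate) * as_cur
    return as_new - as_cur > params.improvement_rate * abs(as_cur)


def verify_greedy_trace(graph: PathwayGraph, seed: str, risk: pd.DataFrame,
                        params: SearchParams) -> None:
    """Replay a greedy expansion and check every step by brute force.

    Asserts that each accepted gene was the admissible AS-maximizing
    candidate at its step (ties to the lexicographically smallest gene),
    that each accepted step satisfied the improvement rule, and that at
    termination no admissible candidate satisfies it.
    """
    sub = greedy_expand(graph, seed, risk, params)
    assert sub.genes[0] == seed
    current = [seed]
    as_cur = oracle_score(current, risk, params.score_normalization)
    for accepted in sub.genes[1:]:
        cands = oracle_admissible(graph, current, risk, params)
        assert cands, f"step accepted {accepted} but oracle finds no candidate"
        scored = sorted(((oracle_score(current + [g], risk, params.score_normalization), g)
                         for g in cands), key=lambda t: (-t[0], t[1]))
        best_as, best_gene = scored[0]
        assert accepted == best_gene, (
            f"accepted {accepted}, oracle says {best_gene} (AS {best_as})")
        assert oracle_rule(best_as, as_cur, params), "accepted step fails the rule"
        current.append(accepted)
        as_cur = best_as
    for g in oracle_admissible(graph, current, risk, params):
        as_new = oracle_score(current + [g], risk, params.score_normalization)
        assert not oracle_rule(as_new, as_cur, params), (
            f"terminated although {g} still qualifies")
    assert math.isclose(sub.score, as_cur, rel_tol=1e-12)


def chi2_sf_even_df(x: float, df: int) -> float:
    """Closed-form upper tail of chi-squared for even df (Poisson sum)."""
    assert df % 2 == 0 and df > 0
    k = df // 2
    term, total = 1.0, 1.0
    for j in range(1, k):
        term *= (x / 2.0) / j
        total += term
    return math.exp(-x / 2.0) * total
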