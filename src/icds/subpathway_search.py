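"""Greedy discovery of locally maximal-activity subpathways.

Within each pathway graph, expansion starts from seed genes whose combined
p-value is below 0.001 and repeatedly adds the neighboring gene that
maximizes the subpathway activity score

    AS = sum_i RS_i / sqrt(n)        (default normalization)

subject to an induced-diameter locality constraint (<= 3) and a relative
improvement rule with rate r = 0.05.  The sqrt(n)-normalized sum is the
aggregate z-score standard in greedy subnetwork search; it keeps scores
comparable across sizes while still rewarding growth over coherent
high-risk regions.  ``score_normalization="mean"`` switches to the plain
average of member RS values.

Overlapping candidates from the same pathway (Jaccard > 0.6) are merged,
and only subpathways with more than five and fewer than 100 genes are
kept.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import IcdsError
from .pathway_io import PathwayGraph, PathwayGraphSet, full_graph_max_distance, induced_diameter

logger = logging.getLogger("icds")


@dataclass(frozen=True)
class SearchParams:
    """Tunables of the greedy search; defaults follow the method definition."""

    seed_p_threshold: float = 0.001   # seed genes: p_S strictly below this
    improvement_rate: float = 0.05    # r: required relative AS gain per step
    max_distance: int = 3             # induced-diameter cap during expansion
    jaccard_merge: float = 0.6        # merge pairs with Jaccard strictly above
    min_size: int = 6                 # "more than five genes"
    max_size: int = 99                # "fewer than 100 genes"
    score_normalization: str = "sqrt"  # "sqrt" | "mean"
    acceptance_rule: str = "relative"  # "relative" | "literal"
    distance_scope: str = "induced"    # "induced" | "full"

    def __post_init__(self):
        if self.min_size >= self.max_size:
            raise IcdsError("SearchParams: min_size must be below max_size")
        for name in ("seed_p_threshold", "improvement_rate", "max_distance", "jaccard_merge"):
            if getattr(self, name) <= 0:
                raise IcdsError(f"SearchParams: {name} must be positive")
        if self.score_normalization not in ("sqrt", "mean"):
            raise IcdsError("SearchParams: score_normalization must be 'sqrt' or 'mean'")
        if self.acceptance_rule not in ("relative", "literal"):
            raise IcdsError("SearchParams: acceptance_rule must be 'relative' or 'literal'")
        if self.distance_scope not in ("induced", "full"):
            raise IcdsError("SearchParams: distance_scope must be 'induced' or 'full'")


@dataclass(frozen=True)
class Subpathway:
    """A candidate subpathway; ``genes`` are in acceptance order."""

    subpath_id: str
    pathway_id: str
    genes: tuple[str, ...]
    score: float                      # activity score AS
    seed: tuple[str, ...] = ()
    merged_from: tuple[str, ...] = ()

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)

    @property
    def size(self) -> int:
        return len(self.genes)


def _rs_lookup(risk: pd.DataFrame) -> pd.Series:
    if "RS" not in risk.columns:
        raise IcdsError("risk table lacks an 'RS' column")
    return risk["RS"]


def activity_score(genes, risk: pd.DataFrame, normalization: str = "sqrt") -> float:
    """Activity score over the member genes with a non-missing RS.

    ``n`` counts only genes contributing an RS; genes with missing RS are
    excluded from the aggregate.
    """
    rs = _rs_lookup(risk)
    vals = [float(rs[g]) for g in genes if g in rs.index and np.isfinite(rs[g])]
    if not vals:
        raise IcdsError("activity_score: no member gene has a risk score")
    total = float(np.sum(vals))
    n = len(vals)
    return total / math.sqrt(n) if normalization == "sqrt" else total / n


def select_seeds(risk: pd.DataFrame, graph: PathwayGraph,
                 threshold: float = 0.001) -> list[str]:
    """Genes in the pathway with combined p strictly below ``threshold``,
    ordered by decreasing RS (ties broken lexicographically)."""
    rs, p = _rs_lookup(risk), risk["p_S"]
    seeds = [g for g in graph.nodes
             if g in risk.index and np.isfinite(p[g]) and p[g] < threshold
             and np.isfinite(rs[g])]
    return sorted(seeds, key=lambda g: (-float(rs[g]), g))


def _accepts(as_new: float, as_cur: float, params: SearchParams) -> bool:
    if params.acceptance_rule == "literal":
        return as_new > (1.0 + params.improvement_rate) * as_cur
    # sign-safe relative improvement: reduces to the literal rule for AS > 0
    return as_new - as_cur > params.improvement_rate * abs(as_cur)


def greedy_expand(graph: PathwayGraph, seed: str, risk: pd.DataFrame,
                  params: SearchParams = SearchParams()) -> Subpathway:
    """Expand a seed gene into a locally maximal-activity subpathway.

    Each step considers the graph neighbors of the current gene set that
    carry a risk score and whose addition keeps the locality constraint,
    adopts the one maximizing the candidate AS (ties: lexicographically
    smallest gene), and stops when the best candidate fails the
    improvement rule.
    """
    rs = _rs_lookup(risk)
    if seed not in graph.nodes:
        raise IcdsError(f"seed {seed!r} not in pathway {graph.pathway_id}")
    if seed not in rs.index or not np.isfinite(rs[seed]):
        raise IcdsError(f"seed {seed!r} has a missing risk score")
    current: list[str] = [seed]
    current_set = {seed}
    as_cur = activity_score(current, risk, params.score_normalization)
    dist_cache: dict = {}

    def admissible(g: str) -> bool:
        members = current_set | {g}
        if params.distance_scope == "induced":
            return induced_diameter(graph, members) <= params.max_distance
        return full_graph_max_distance(graph, members, _cache=dist_cache) <= params.max_distance

    while True:
        frontier = set()
        for g in current:
            frontier |= set(graph.graph.neighbors(g))
        frontier -= current_set
        best_gene, best_as = None, -math.inf
        for g in sorted(frontier):
            if g not in rs.index or not np.isfinite(rs[g]):
                continue
            if not admissible(g):
                continue
            as_new = activity_score(current + [g], risk, params.score_normalization)
            if as_new > best_as:
                best_gene, best_as = g, as_new
        if best_gene is None or not _accepts(best_as, as_cur, params):
            break
        current.append(best_gene)
        current_set.add(best_gene)
        as_cur = best_as
    return Subpathway(subpath_id=f"{graph.pathway_id}:{seed}",
                      pathway_id=graph.pathway_id, genes=tuple(current),
                      score=as_cur, seed=(seed,))


def _jaccard(a: frozenset, b: frozenset) -> float:
    return len(a & b) / len(a | b)


def merge_subpathways(cands: list[Subpathway], params: SearchParams,
                      risk: pd.DataFrame) -> list[Subpathway]:
    """Union overlapping candidates (Jaccard strictly above the threshold).

    Within each pathway, pairs are examined in subpath_id order and merged
    to a fixed point; the union's AS is recomputed from scratch.  Merging
    may exceed the distance constraint -- only the size filter is applied
    afterwards.
    """
    by_pathway: dict[str, list[Subpathway]] = {}
    for c in cands:
        by_pathway.setdefault(c.pathway_id, []).append(c)
    out: list[Subpathway] = []
    for pid in by_pathway:
        pool = sorted(by_pathway[pid], key=lambda c: c.subpath_id)
        changed = True
        while changed:
            changed = False
            for i in range(len(pool)):
                for j in range(i + 1, len(pool)):
                    a, b = pool[i], pool[j]
                    if _jaccard(a.gene_set, b.gene_set) > params.jaccard_merge:
                        genes = tuple(a.genes) + tuple(g for g in b.genes
                                                       if g not in a.gene_set)
                        merged = Subpathway(
                            subpath_id=a.subpath_id, pathway_id=pid, genes=genes,
                            score=activity_score(genes, risk, params.score_normalization),
                            seed=tuple(sorted(set(a.seed) | set(b.seed))),
                            merged_from=tuple(sorted(set(a.merged_from or (a.subpath_id,))
                                                     | set(b.merged_from or (b.subpath_id,)))),
                        )
                        pool = [c for k, c in enumerate(pool) if k not in (i, j)]
                        pool.append(merged)
                        pool.sort(key=lambda c: c.subpath_id)
                        changed = True
                        break
                if changed:
                    break
        out.extend(pool)
    return out


def filter_by_size(cands: list[Subpathway], params: SearchParams) -> list[Subpathway]:
    """Keep subpathways with min_size <= |genes| <= max_size."""
    return [c for c in cands if params.min_size <= c.size <= params.max_size]


def find_candidate_subpathways(graphs: PathwayGraphSet, risk: pd.DataFrame,
                               params: SearchParams = SearchParams()) -> list[Subpathway]:
    """Full per-pathway procedure: seeds, expansion, dedup, merge, size filter.

    Final subpath ids follow the ``<pathway_id>_<n>`` convention with a
    running index per pathway.
    """
    all_cands: list[Subpathway] = []
    for pg in graphs:
        seeds = select_seeds(risk, pg, params.seed_p_threshold)
        if not seeds:
            continue
        expansions: list[Subpathway] = []
        seen_sets: set[frozenset[str]] = set()
        for idx, seed in enumerate(seeds, 1):
            sub = greedy_expand(pg, seed, risk, params)
            if sub.gene_set in seen_sets:
                continue
            seen_sets.add(sub.gene_set)
            expansions.append(replace(sub, subpath_id=f"{pg.pathway_id}_{idx}"))
        merged = merge_subpathways(expansions, params, risk)
        kept = filter_by_size(merged, params)
        for n, sub in enumerate(kept, 1):
            all_cands.append(replace(sub, subpath_id=f"{pg.pathway_id}_{n}"))
    return all_cands


def write_gmt(cands: list[Subpathway], graphs: PathwayGraphSet, path: str | Path) -> None:
    """GMT-style output: subpath_id, '<pathway name>|AS=<score>', gene list."""
    with open(path, "w") as fh:
        for c in cands:
            name = graphs[c.pathway_id].name if c.pathway_id in graphs else c.pathway_id
            fh.write("\t".join([c.subpath_id, f"{name}|AS={c.score:.6g}", *c.genes]) + "\n")


def candidates_frame(cands: list[Subpathway], graphs: PathwayGraphSet | None = None) -> pd.DataFrame:
    rows = []
    for c in cands:
        rows.append({
            "subpath_id": c.subpath_id,
            "pathway_id": c.pathway_id,
            "pathway_name": graphs[c.pathway_id].name if graphs and c.pathway_id in graphs else "",
            "size": c.size,
            "AS": c.score,
            "seed": ";".join(c.seed),
            "merged_from": ";".join(c.merged_from),
            "genes": ";".join(c.genes),
        })
    return pd.DataFrame(rows, columns=["subpath_id", "pathway_id", "pathway_name",
                                       "size", "AS", "seed", "merged_from", "genes"])


def write_candidates(cands: list[Subpathway], path: str | Path,
                     graphs: PathwayGraphSet | None = None) -> None:
    candidates_frame(cands, graphs).to_csv(path, sep="\t", index=False)


def read_candidates(path: str | Path) -> list[Subpathway]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for _, row in df.iterrows():
        out.append(Subpathway(
            subpath_id=row["subpath_id"], pathway_id=row["pathway_id"],
            genes=tuple(row["genes"].split(";")) if row["genes"] else (),
            score=float(row["AS"]),
            seed=tuple(row["seed"].split(";")) if row["seed"] else (),
            merged_from=tuple(row["merged_from"].split(";")) if row["merged_from"] else (),
        ))
    return out
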