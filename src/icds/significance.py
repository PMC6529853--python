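"""Permutation significance for candidate subpathways and BH-FDR control.

Two permutation nulls are available per candidate: a *global* null that
relabels genes over the entire gene universe of the pathway collection,
and a *local* null that relabels genes within the candidate's parent
pathway.  Relabeling a fixed node set and rescoring is equivalent to
drawing ``n`` risk scores without replacement from the pool and
aggregating them with the same score normalization as the search, so the
nulls are sampled that way.  Empirical p-values default to the
(M + 1) / (N + 1) estimator (M = permuted scores >= real score, ties
included), which never returns an exact zero; the literal M / N estimator
is available by configuration.  Benjamini-Hochberg adjustment is applied
across all candidates jointly, separately for each test.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import IcdsError
from .pathway_io import PathwayGraph, PathwayGraphSet
from .subpathway_search import Subpathway

logger = logging.getLogger("icds")

_VECTORIZED_CELL_BUDGET = 20_000_000  # N x pool cells above this fall back to a loop


@dataclass(frozen=True)
class PermutationConfig:
    n_perm: int = 10000
    rng_seed: int = 0
    mode: str = "both"              # "global" | "local" | "both"
    estimator: str = "plus_one"     # "plus_one" | "literal"
    fdr_threshold: float = 0.001
    significance_mode: str = "both"  # require "both" FDRs below threshold, or "either"

    def __post_init__(self):
        if self.n_perm < 1:
            raise IcdsError("PermutationConfig: n_perm must be >= 1")
        if self.mode not in ("global", "local", "both"):
            raise IcdsError("PermutationConfig: mode must be global, local or both")
        if self.estimator not in ("plus_one", "literal"):
            raise IcdsError("PermutationConfig: estimator must be plus_one or literal")
        if self.significance_mode not in ("both", "either"):
            raise IcdsError("PermutationConfig: significance_mode must be both or either")


@dataclass(frozen=True)
class SubpathwayResult:
    subpathway: Subpathway
    p1: float
    p2: float
    fdr1: float = float("nan")
    fdr2: float = float("nan")
    n_perm: int = 0
    null_pool: str = ""
    significant: bool = False


def _rng_for(seed: int, *keys) -> np.random.Generator:
    """Deterministic per-stream RNG independent of evaluation order."""
    entropy = [int(seed) & 0x7FFFFFFF]
    entropy += [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng(entropy)


def _finite_rs(risk: pd.DataFrame, genes) -> np.ndarray:
    rs = risk["RS"]
    pool = np.array([float(rs[g]) for g in genes
                     if g in rs.index and np.isfinite(rs[g])], dtype=float)
    return pool


def _null_sample(pool: np.ndarray, n: int, n_perm: int,
                 rng: np.random.Generator, normalization: str) -> np.ndarray:
    """``n_perm`` draws of ``n`` scores without replacement, aggregated."""
    P = len(pool)
    if n > P:
        raise IcdsError(f"null sample: pool of {P} smaller than subpathway of {n}")
    if n == P:
        sums = np.full(n_perm, pool.sum())
    elif n_perm * P <= _VECTORIZED_CELL_BUDGET:
        keys = rng.random((n_perm, P))
        idx = np.argpartition(keys, n - 1, axis=1)[:, :n]
        sums = pool[idx].sum(axis=1)
    else:
        sums = np.empty(n_perm)
        for i in range(n_perm):
            sums[i] = rng.choice(pool, size=n, replace=False).sum()
    return sums / np.sqrt(n) if normalization == "sqrt" else sums / n


def global_null(subpath: Subpathway, risk: pd.DataFrame, universe,
                cfg: PermutationConfig, normalization: str = "sqrt") -> np.ndarray:
    """Null activity scores from relabeling over the whole gene universe."""
    pool = _finite_rs(risk, universe)
    n = len([g for g in subpath.genes
             if g in risk.index and np.isfinite(risk["RS"][g])])
    rng = _rng_for(cfg.rng_seed, "global", subpath.subpath_id)
    return _null_sample(pool, n, cfg.n_perm, rng, normalization)


def local_null(subpath: Subpathway, risk: pd.DataFrame, parent: PathwayGraph,
               cfg: PermutationConfig, normalization: str = "sqrt") -> np.ndarray:
    """Null activity scores from relabeling within the parent pathway.

    The RNG stream is keyed by (seed, pathway, subpathway size), so
    same-size candidates of one pathway share a single pooled null sample;
    candidates of different sizes get their own null (pooling across sizes
    would conflate different null distributions).
    """
    pool = _finite_rs(risk, parent.nodes)
    n = len([g for g in subpath.genes
             if g in risk.index and np.isfinite(risk["RS"][g])])
    rng = _rng_for(cfg.rng_seed, "local", parent.pathway_id, n)
    return _null_sample(pool, n, cfg.n_perm, rng, normalization)


def empirical_p(real_as: float, null_scores: np.ndarray,
                estimator: str = "plus_one") -> float:
    """p = (M + 1) / (N + 1) by default; ties count toward M."""
    null_scores = np.asarray(null_scores, dtype=float)
    N = len(null_scores)
    if N < 1:
        raise IcdsError("empirical_p: need at least one null score")
    M = int((null_scores >= real_as).sum())
    if estimator == "literal":
        return M / N
    return (M + 1) / (N + 1)


def bh_fdr(p) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjustment, monotone, capped at 1."""
    arr = np.asarray(p, dtype=float)
    out = np.full(arr.shape, np.nan)
    mask = np.isfinite(arr)
    if mask.any():
        out[mask] = multipletests(arr[mask], method="fdr_bh")[1]
    return out


def score_and_rank(cands: list[Subpathway], risk: pd.DataFrame,
                   graphs: PathwayGraphSet, cfg: PermutationConfig = PermutationConfig(),
                   normalization: str = "sqrt") -> list[SubpathwayResult]:
    """Both permutation tests per candidate, joint BH per test, ranked output.

    Results are sorted by FDR2, then FDR1, then AS descending; a candidate
    is flagged significant when the configured combination of FDRs falls
    below ``cfg.fdr_threshold``.
    """
    if not cands:
        return []
    universe = graphs.gene_universe()
    p1s, p2s, pools = [], [], []
    for c in cands:
        pool_tag = []
        if cfg.mode in ("global", "both"):
            null1 = global_null(c, risk, universe, cfg, normalization)
            p1s.append(empirical_p(c.score, null1, cfg.estimator))
            pool_tag.append("global")
        else:
            p1s.append(float("nan"))
        if cfg.mode in ("local", "both"):
            parent = graphs[c.pathway_id]
            null2 = local_null(c, risk, parent, cfg, normalization)
            p2s.append(empirical_p(c.score, null2, cfg.estimator))
            n_rs = len([g for g in c.genes
                        if g in risk.index and np.isfinite(risk["RS"][g])])
            pool_tag.append(f"local:{c.pathway_id}:n={n_rs}")
        else:
            p2s.append(float("nan"))
        pools.append("+".join(pool_tag))
    fdr1 = bh_fdr(p1s)
    fdr2 = bh_fdr(p2s)

    def _passes(f1: float, f2: float) -> bool:
        checks = []
        if cfg.mode in ("global", "both"):
            checks.append(np.isfinite(f1) and f1 < cfg.fdr_threshold)
        if cfg.mode in ("local", "both"):
            checks.append(np.isfinite(f2) and f2 < cfg.fdr_threshold)
        return (any(checks) if cfg.significance_mode == "either" else all(checks))

    results = [SubpathwayResult(subpathway=c, p1=float(p1s[i]), p2=float(p2s[i]),
                                fdr1=float(fdr1[i]), fdr2=float(fdr2[i]),
                                n_perm=cfg.n_perm, null_pool=pools[i],
                                significant=_passes(fdr1[i], fdr2[i]))
               for i, c in enumerate(cands)]

    def _key(r: SubpathwayResult):
        f2 = r.fdr2 if np.isfinite(r.fdr2) else np.inf
        f1 = r.fdr1 if np.isfinite(r.fdr1) else np.inf
        return (f2, f1, -r.subpathway.score, r.subpathway.subpath_id)

    return sorted(results, key=_key)


def results_frame(results: list[SubpathwayResult],
                  graphs: PathwayGraphSet | None = None) -> pd.DataFrame:
    rows = []
    for r in results:
        c = r.subpathway
        rows.append({
            "subpath_id": c.subpath_id,
            "pathway_id": c.pathway_id,
            "pathway_name": graphs[c.pathway_id].name if graphs and c.pathway_id in graphs else "",
            "size": c.size,
            "AS": c.score,
            "p1": r.p1, "p2": r.p2,
            "FDR1": r.fdr1, "FDR2": r.fdr2,
            "significant": r.significant,
            "n_perm": r.n_perm,
            "null_pool": r.null_pool,
            "seed": ";".join(c.seed),
            "genes": ";".join(c.genes),
        })
    cols = ["subpath_id", "pathway_id", "pathway_name", "size", "AS", "p1", "p2",
            "FDR1", "FDR2", "significant", "n_perm", "null_pool", "seed", "genes"]
    return pd.DataFrame(rows, columns=cols)


def write_results(results: list[SubpathwayResult], path: str | Path,
                  graphs: PathwayGraphSet | None = None) -> None:
    results_frame(results, graphs).to_csv(path, sep="\t", index=False)
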