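"""Per-gene risk scores from expression, methylation and copy number.

For each gene and omics layer a two-sample Student's t-test yields a
p-value: tumor vs normal for expression (``p_gene``) and methylation
(``p_methy``), and copy-number-variated vs un-variated samples for the
expression contrast ``p_cnv``.  Per layer, p-values are Benjamini-Hochberg
adjusted across genes, then combined with Fisher's method,

    S = -2 * sum_m ln p_m ,        m over the gene's available layers,

which under the null follows a chi-squared distribution with 2k degrees of
freedom (k = number of available layers).  The combined p-value p_S is
mapped through the inverse normal CDF to the gene risk score
RS = Phi^-1(1 - p_S), so smaller p_S means larger RS.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import IcdsError
from .omics_io import AlignedOmics

logger = logging.getLogger("icds")

#: p-values are floored here before taking logarithms.
P_FLOOR = 1e-300
#: |RS| cap, roughly the double-precision limit of Phi^-1(1 - p).
RS_CLAMP = 8.2

MODES = ("icds", "g", "cnv", "m")
_MODE_LAYERS = {"icds": ("p_gene", "p_methy", "p_cnv"),
                "g": ("p_gene",), "cnv": ("p_cnv",), "m": ("p_methy",)}

RISK_COLUMNS = ("p_gene", "p_methy", "p_cnv",
                "p_gene_adj", "p_methy_adj", "p_cnv_adj",
                "k", "S", "p_S", "RS")


def _matrix_ttest(x: np.ndarray, y: np.ndarray, *, equal_var: bool = True,
                  min_group_size: int = 3) -> np.ndarray:
    """Row-wise two-sided two-sample t-test with NaN-aware group masks.

    ``x`` and ``y`` are gene x sample arrays holding each group's values
    (NaN marks a sample not in the group or missing).  Rows where either
    group has fewer than ``min_group_size`` finite values, or where both
    groups have zero variance (t undefined), yield NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1 = np.isfinite(x).sum(axis=1).astype(float)
    n2 = np.isfinite(y).sum(axis=1).astype(float)
    ok = (n1 >= min_group_size) & (n2 >= min_group_size)
    with np.errstate(invalid="ignore", divide="ignore"):
        m1 = np.where(n1 > 0, np.nansum(x, axis=1) / np.maximum(n1, 1), np.nan)
        m2 = np.where(n2 > 0, np.nansum(y, axis=1) / np.maximum(n2, 1), np.nan)
        s1 = np.nansum((x - m1[:, None]) ** 2, axis=1) / np.maximum(n1 - 1, 1)
        s2 = np.nansum((y - m2[:, None]) ** 2, axis=1) / np.maximum(n2 - 1, 1)
        degenerate = (s1 == 0) & (s2 == 0)
        if equal_var:
            df = n1 + n2 - 2
            sp2 = ((n1 - 1) * s1 + (n2 - 1) * s2) / np.maximum(df, 1)
            se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        else:
            vn1, vn2 = s1 / n1, s2 / n2
            se = np.sqrt(vn1 + vn2)
            df = (vn1 + vn2) ** 2 / np.maximum(
                vn1 ** 2 / np.maximum(n1 - 1, 1) + vn2 ** 2 / np.maximum(n2 - 1, 1), 1e-300)
        t = (m1 - m2) / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(ok & ~degenerate, p, np.nan)
    return np.where(np.isfinite(p), np.clip(p, P_FLOOR, 1.0), np.nan)


def two_group_pvalue(values_a: Sequence[float], values_b: Sequence[float], *,
                     equal_var: bool = True, min_group_size: int = 3) -> float:
    """Two-sided two-sample t-test p-value; NaN when a group is too small."""
    a = np.asarray(values_a, dtype=float)[None, :]
    b = np.asarray(values_b, dtype=float)[None, :]
    return float(_matrix_ttest(a, b, equal_var=equal_var,
                               min_group_size=min_group_size)[0])


def cnv_group_pvalue(expr_values: Sequence[float], cnv_calls: Sequence[float], *,
                     variated_threshold: int = 0, equal_var: bool = True,
                     min_group_size: int = 3) -> float:
    """Expression contrast between copy-number-variated and un-variated samples.

    The variated group holds samples with ``|call| > variated_threshold``
    (default: any non-zero call); samples with missing calls are excluded.
    """
    expr = np.asarray(expr_values, dtype=float)
    calls = np.asarray(cnv_calls, dtype=float)
    if expr.shape != calls.shape:
        raise IcdsError("cnv_group_pvalue: expression and calls not aligned")
    known = np.isfinite(calls)
    variated = known & (np.abs(calls) > variated_threshold)
    a = np.where(variated, expr, np.nan)[None, :]
    b = np.where(known & ~variated, expr, np.nan)[None, :]
    return float(_matrix_ttest(a, b, equal_var=equal_var,
                               min_group_size=min_group_size)[0])


def adjust_pvalues(p: Sequence[float], method: str | None = "fdr_bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; missing entries pass through.

    Order statistics are computed over the non-missing entries only.
    ``method=None`` disables adjustment (raw p-values returned).
    """
    arr = np.asarray(p, dtype=float)
    if method is None:
        return arr.copy()
    out = np.full(arr.shape, np.nan)
    mask = np.isfinite(arr)
    if mask.any():
        out[mask] = multipletests(arr[mask], method=method)[1]
    return out


def fisher_combine(p_list: Sequence[float]) -> tuple[float, float]:
    """Fisher's combined probability test over 1-3 available p-values.

    Returns ``(S, p_S)`` with S = -2 * sum(ln p) (p floored at 1e-300) and
    p_S the upper tail of chi-squared with 2k degrees of freedom.  An empty
    list yields ``(nan, nan)``: the gene gets no risk score but stays in
    the pathway graphs.
    """
    ps = [float(x) for x in p_list if np.isfinite(x)]
    if not ps:
        return (float("nan"), float("nan"))
    if any(x <= 0 or x > 1 for x in ps):
        raise IcdsError(f"fisher_combine: p-values must lie in (0, 1], got {ps}")
    S = -2.0 * sum(np.log(max(x, P_FLOOR)) for x in ps)
    p_S = float(stats.chi2.sf(S, df=2 * len(ps)))
    return (float(S), max(p_S, P_FLOOR))


def p_to_zscore(p_S: float) -> float:
    """RS = Phi^-1(1 - p_S), clamped to +/-8.2; strictly decreasing in p_S."""
    if not np.isfinite(p_S):
        return float("nan")
    return float(np.clip(stats.norm.isf(p_S), -RS_CLAMP, RS_CLAMP))


def _layer_group_values(layer, design):
    cols = list(layer.samples)
    groups = design.group_of
    t_idx = [i for i, s in enumerate(cols) if groups.get(s) == "tumor"]
    n_idx = [i for i, s in enumerate(cols) if groups.get(s) == "normal"]
    vals = layer.data.to_numpy(dtype=float)
    return vals[:, t_idx], vals[:, n_idx]


def build_risk_table(aligned: AlignedOmics, mode: str = "icds", *,
                     adjust: str | None = "fdr_bh", equal_var: bool = True,
                     min_group_size: int = 3,
                     variated_threshold: int = 0) -> pd.DataFrame:
    """Compute the per-gene risk table over the aligned layers.

    ``mode='icds'`` combines every layer available for a gene (df = 2k);
    modes ``g``/``cnv``/``m`` use exactly one layer, leaving genes without
    that layer with a missing RS.
    """
    if mode not in MODES:
        raise IcdsError(f"unknown mode {mode!r}; expected one of {MODES}")
    genes = list(aligned.genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    table = pd.DataFrame(index=pd.Index(genes, name="gene"),
                         columns=list(RISK_COLUMNS), dtype=float)

    # tumor-vs-normal contrasts on expression and methylation
    for col, layer in (("p_gene", aligned.expression), ("p_methy", aligned.methylation)):
        x, y = _layer_group_values(layer, aligned.design)
        p = _matrix_ttest(x, y, equal_var=equal_var, min_group_size=min_group_size)
        rows = [gene_pos[g] for g in layer.genes]
        table.iloc[rows, table.columns.get_loc(col)] = p

    # call-group contrast on expression, over samples shared by both layers
    expr, cnv = aligned.expression, aligned.cnv
    common = [s for s in expr.samples if s in set(cnv.samples)]
    if common:
        shared = [g for g in cnv.genes if g in set(expr.genes)]
        if shared:
            e = expr.data.loc[shared, common].to_numpy(dtype=float)
            c = cnv.data.loc[shared, common].to_numpy(dtype=float)
            known = np.isfinite(c)
            variated = known & (np.abs(c) > variated_threshold)
            a = np.where(variated, e, np.nan)
            b = np.where(known & ~variated, e, np.nan)
            p = _matrix_ttest(a, b, equal_var=equal_var, min_group_size=min_group_size)
            rows = [gene_pos[g] for g in shared]
            table.iloc[rows, table.columns.get_loc("p_cnv")] = p

    for col in ("p_gene", "p_methy", "p_cnv"):
        table[col + "_adj"] = adjust_pvalues(table[col].to_numpy(), method=adjust)

    used = [c + "_adj" for c in _MODE_LAYERS[mode]]
    padj = table[used].to_numpy(dtype=float)
    avail = np.isfinite(padj)
    k = avail.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(avail, np.log(np.clip(padj, P_FLOOR, 1.0)), 0.0)
    S = -2.0 * logs.sum(axis=1)
    p_S = np.full(len(genes), np.nan)
    has = k > 0
    p_S[has] = stats.chi2.sf(S[has], df=2 * k[has])
    p_S[has] = np.clip(p_S[has], P_FLOOR, 1.0)
    rs = np.full(len(genes), np.nan)
    rs[has] = np.clip(stats.norm.isf(p_S[has]), -RS_CLAMP, RS_CLAMP)

    table["k"] = k.astype(float)
    table["S"] = np.where(has, S, np.nan)
    table["p_S"] = p_S
    table["RS"] = rs
    if not has.any():
        raise IcdsError(f"mode {mode!r}: no gene has a computable risk score")
    n_clamped = int((np.abs(rs[has]) >= RS_CLAMP).sum())
    if n_clamped:
        logger.info("risk table: RS clamped to +/-%.1f for %d genes", RS_CLAMP, n_clamped)
    return table


def write_risk_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="gene")


def read_risk_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")
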