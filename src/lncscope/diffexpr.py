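"""Tumor-vs-control differential expression.

The calling rule is |log2 fold change| > 1 (strict) and raw p < 0.05. Fold
change is the ratio of group means on the FPKM scale with a pseudocount; the
test is a two-sided Welch t on log2(FPKM + 1), defensible at small unbalanced
group sizes. Benjamini-Hochberg q-values are reported alongside but do not
gate the significance flag.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import ExpressionMatrix, GeneAnnotation

logger = logging.getLogger(__name__)

DE_COLUMNS = [
    "gene_id",
    "biotype",
    "log2fc",
    "p_value",
    "q_value",
    "significant",
    "direction",
]

_VAR_FLOOR = 1e-8  # log2-scale variance floor for degenerate zero-variance groups


def log2_fold_change(
    expr: ExpressionMatrix, gene_id: str, pseudocount: float = 1.0
) -> float:
    """log2((mean tumor FPKM + c) / (mean control FPKM + c))."""
    if gene_id not in expr.values.index:
        raise KeyError(f"gene {gene_id!r} not in expression matrix")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    row = expr.values.loc[gene_id]
    mt = row[expr.tumor_samples].mean()
    mc = row[expr.control_samples].mean()
    return float(np.log2((mt + pseudocount) / (mc + pseudocount)))


def welch_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Welch t-test p-value with a variance floor.

    If both groups are constant with equal means the genes are
    indistinguishable and p = 1; constant groups with unequal means get a
    variance floor so the statistic stays finite.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 samples per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return 1.0
        vx = vy = _VAR_FLOOR
    else:
        vx, vy = max(vx, _VAR_FLOOR), max(vy, _VAR_FLOOR)
    se2 = vx / len(x) + vy / len(y)
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / (
        (vx / len(x)) ** 2 / (len(x) - 1) + (vy / len(y)) ** 2 / (len(y) - 1)
    )
    return float(2.0 * stats.t.sf(abs(t), df))


def de_test(expr: ExpressionMatrix, gene_id: str) -> float:
    """Welch p-value for one gene on log2(FPKM + 1) values."""
    if gene_id not in expr.values.index:
        raise KeyError(f"gene {gene_id!r} not in expression matrix")
    log = expr.log2p1().loc[gene_id]
    return welch_p(
        log[expr.tumor_samples].to_numpy(), log[expr.control_samples].to_numpy()
    )


def call_de(
    expr: ExpressionMatrix,
    annotation: Sequence[GeneAnnotation] | None = None,
    alpha: float = 0.05,
    fc_cut: float = 1.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene DE table with the strict |log2fc| > fc_cut, p < alpha rule.

    Returns a DataFrame with columns ``gene_id, biotype, log2fc, p_value,
    q_value, significant, direction``. All-zero genes are reported with
    p = 1 and log2fc = 0. When an annotation is supplied only shared gene
    ids are tested and biotypes are attached; otherwise biotype is "other".
    """
    biotypes = {g.gene_id: g.biotype for g in annotation} if annotation else {}
    if annotation is not None:
        genes = [g for g in expr.gene_ids if g in biotypes]
        if not genes:
            raise ValueError("no gene ids shared between matrix and annotation")
    else:
        genes = expr.gene_ids

    log = expr.log2p1()
    tumor = log[expr.tumor_samples].to_numpy()
    control = log[expr.control_samples].to_numpy()
    fpkm = expr.values
    mt = fpkm[expr.tumor_samples].mean(axis=1)
    mc = fpkm[expr.control_samples].mean(axis=1)
    log2fc_all = np.log2((mt + pseudocount) / (mc + pseudocount))

    idx = {g: i for i, g in enumerate(expr.gene_ids)}
    rows = []
    for g in genes:
        i = idx[g]
        if (fpkm.iloc[i] == 0).all():
            p, fc = 1.0, 0.0
        else:
            p = welch_p(tumor[i], control[i])
            fc = float(log2fc_all.iloc[i])
        rows.append((g, biotypes.get(g, "other"), fc, p))
    out = pd.DataFrame(rows, columns=["gene_id", "biotype", "log2fc", "p_value"])
    out["q_value"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    out["significant"] = (out["log2fc"].abs() > fc_cut) & (out["p_value"] < alpha)
    out["direction"] = np.where(
        ~out["significant"], "none", np.where(out["log2fc"] > 0, "up", "down")
    )
    return out[DE_COLUMNS]


def top_deregulated(results: pd.DataFrame, biotype: str, k: int) -> list[str]:
    """Top-k significant genes of a biotype by |log2fc|, ties by p then id."""
    if k < 1:
        raise ValueError("k must be >= 1")
    sub = results[(results["significant"]) & (results["biotype"] == biotype)].copy()
    sub["abs_fc"] = sub["log2fc"].abs()
    sub = sub.sort_values(
        ["abs_fc", "p_value", "gene_id"], ascending=[False, True, True]
    )
    if len(sub) < k:
        logger.info(
            "top_deregulated: only %d %s genes available (k=%d)",
            len(sub), biotype, k,
        )
    return list(sub["gene_id"].head(k))
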