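"""lncRNA-mRNA correlation network.

Pearson correlations are computed across all samples (tumor + control) on
log2(FPKM + 1); edges are retained under the strict rule r > 0.3 or
r < -0.3. Per-lncRNA summaries report the average retained positive and
negative correlations and the sum of |r| over retained edges, which ranks
lncRNAs for the "greatest sum of correlations" selection.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .types import ExpressionMatrix

logger = logging.getLogger(__name__)

EDGE_COLUMNS = ["lncrna_id", "mrna_id", "r", "retained"]
SUMMARY_COLUMNS = [
    "lncrna_id",
    "avg_positive_r",
    "avg_negative_r",
    "sum_abs_r",
    "n_retained",
]


def is_retained(r: float, cut: float = 0.3) -> bool:
    """Strict retention rule: r > cut or r < -cut (|r| = cut is dropped)."""
    return r > cut or r < -cut


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float | None:
    """Pearson product-moment correlation; None when either side is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if x.std() == 0.0 or y.std() == 0.0:
        return None
    r = float(np.corrcoef(x, y)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def build_edges(
    expr: ExpressionMatrix,
    top_lnc: Sequence[str],
    top_mrna: Sequence[str],
    cut: float = 0.3,
    within_group: str | None = None,
) -> pd.DataFrame:
    """All lncRNA x mRNA Pearson edges with the strict |r| > cut retention flag.

    Pairs where either gene is constant have no defined correlation and are
    dropped (logged). ``within_group`` restricts samples to one group; the
    default correlates across the whole cohort.
    """
    if not list(top_lnc) or not list(top_mrna):
        raise ValueError("empty gene list")
    missing = [g for g in [*top_lnc, *top_mrna] if g not in expr.values.index]
    if missing:
        raise KeyError(f"gene {missing[0]!r} not in expression matrix")
    log = expr.log2p1()
    if within_group is not None:
        cols = expr.group.index[expr.group == within_group]
        if len(cols) < 3:
            raise ValueError(f"fewer than 3 samples in group {within_group!r}")
        log = log[cols]

    lnc_mat = log.loc[list(top_lnc)].to_numpy()
    mrna_mat = log.loc[list(top_mrna)].to_numpy()
    lnc_sd = lnc_mat.std(axis=1)
    mrna_sd = mrna_mat.std(axis=1)

    # centered cross-correlation, vectorized over the full bipartite grid
    n = lnc_mat.shape[1]
    lc = lnc_mat - lnc_mat.mean(axis=1, keepdims=True)
    mc = mrna_mat - mrna_mat.mean(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        rmat = (lc @ mc.T) / (n * np.outer(lnc_sd, mrna_sd))
    rmat = np.clip(rmat, -1.0, 1.0)

    rows = []
    n_dropped = 0
    for i, lnc in enumerate(top_lnc):
        for j, mrna in enumerate(top_mrna):
            if lnc_sd[i] == 0.0 or mrna_sd[j] == 0.0:
                n_dropped += 1
                continue
            r = float(rmat[i, j])
            rows.append((lnc, mrna, r, is_retained(r, cut)))
    if n_dropped:
        logger.info("build_edges: dropped %d constant-gene pairs", n_dropped)
    return pd.DataFrame(rows, columns=EDGE_COLUMNS)


def summarize_lnc(edges: pd.DataFrame) -> pd.DataFrame:
    """Per-lncRNA averages of retained positive/negative r and sum of |r|."""
    rows = []
    for lnc, sub in edges.groupby("lncrna_id", sort=True):
        kept = sub[sub["retained"]]
        pos = kept.loc[kept["r"] > 0, "r"]
        neg = kept.loc[kept["r"] < 0, "r"]
        rows.append(
            (
                lnc,
                float(pos.mean()) if len(pos) else np.nan,
                float(neg.mean()) if len(neg) else np.nan,
                float(kept["r"].abs().sum()),
                int(len(kept)),
            )
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def select_top_lnc(summaries: pd.DataFrame, k: int = 10) -> list[str]:
    """lncRNAs ranked by sum of |r| (ties: more retained edges, then id)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = summaries.sort_values(
        ["sum_abs_r", "n_retained", "lncrna_id"],
        ascending=[False, False, True],
    )
    return list(ranked["lncrna_id"].head(k))
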