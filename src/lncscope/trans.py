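"""Trans-target prediction from RNA-RNA interaction (SUMENERGY) scores.

Filter chain, in order: (1) retain lncRNAs with SUMENERGY > 2000 for at
least 10 targets; (2) keep substrates of retained lncRNAs with SUMENERGY
> 1500; (3) drop promiscuous mRNAs predicted under more than 4 retained
lncRNAs. Surviving targets are stratified by linear fold change and p-value
into the five volcano quadrants (sig_up, ns_up, unchanged, ns_down,
sig_down).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ENERGY_TARGET = 2_000.0  # retention: score must exceed this ...
MIN_TARGETS = 10  # ... for at least this many targets
ENERGY_SUBSTRATE = 1_500.0  # substrate inclusion: score must exceed this
PROMISCUITY = 4  # mRNA predicted under more than this many lncRNAs is dropped

QUADRANTS = ("sig_up", "ns_up", "unchanged", "ns_down", "sig_down")

TARGET_COLUMNS = [
    "lncrna_id",
    "lnc_direction",
    "mrna_id",
    "sumenergy",
    "mrna_log2fc",
    "mrna_p",
    "quadrant",
]


def retain_lncrnas(
    scores: pd.DataFrame,
    energy_target: float = ENERGY_TARGET,
    min_targets: int = MIN_TARGETS,
) -> set[str]:
    """lncRNAs with strictly more than ``energy_target`` SUMENERGY for at
    least ``min_targets`` targets."""
    if scores.empty:
        return set()
    strong = scores[scores["sumenergy"] > energy_target]
    counts = strong.groupby("lncrna_id").size()
    return set(counts.index[counts >= min_targets])


def filter_substrates(
    scores: pd.DataFrame,
    retained: set[str],
    energy_substrate: float = ENERGY_SUBSTRATE,
) -> pd.DataFrame:
    """Rows of retained lncRNAs with SUMENERGY strictly above the cutoff."""
    keep = scores["lncrna_id"].isin(retained) & (
        scores["sumenergy"] > energy_substrate
    )
    return scores[keep].reset_index(drop=True)


def drop_promiscuous(
    scores: pd.DataFrame, promiscuity: int = PROMISCUITY
) -> tuple[pd.DataFrame, list[str]]:
    """Remove mRNAs predicted under more than ``promiscuity`` distinct lncRNAs.

    Applied after the substrate filter, so promiscuity is counted over
    retained lncRNAs only. Returns the filtered table and the dropped mRNAs.
    """
    if scores.empty:
        return scores.reset_index(drop=True), []
    counts = scores.groupby("mrna_id")["lncrna_id"].nunique()
    dropped = sorted(counts.index[counts > promiscuity])
    if dropped:
        logger.info("drop_promiscuous: removed %d mRNAs", len(dropped))
    return scores[~scores["mrna_id"].isin(dropped)].reset_index(drop=True), dropped


def assign_quadrant(log2fc: float, p: float, alpha: float = 0.05) -> str:
    """Volcano quadrant from linear fold change 2**log2fc and p-value."""
    fold = 2.0**log2fc
    if fold > 2.0:
        return "sig_up" if p < alpha else "ns_up"
    if fold < 0.5:
        return "sig_down" if p < alpha else "ns_down"
    return "unchanged"


def stratify_targets(
    scores: pd.DataFrame,
    de: pd.DataFrame,
    lnc_direction: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Quadrant-stratified targets of lncRNAs deregulated in one direction.

    ``scores`` should already have passed the full filter chain. Targets
    whose mRNA is missing from the DE table fall in ``unchanged`` (logged).
    Returns one row per (lncRNA, target) with columns ``TARGET_COLUMNS``.
    """
    if lnc_direction not in ("up", "down"):
        raise ValueError(f"lnc_direction must be 'up' or 'down', got {lnc_direction!r}")
    de_idx = de.set_index("gene_id")
    lnc_dirs = de_idx["direction"].to_dict()
    keep_lnc = {g for g, d in lnc_dirs.items() if d == lnc_direction}
    sub = scores[scores["lncrna_id"].isin(keep_lnc)]
    rows = []
    n_missing = 0
    for rec in sub.itertuples(index=False):
        if rec.mrna_id in de_idx.index:
            fc = float(de_idx.at[rec.mrna_id, "log2fc"])
            p = float(de_idx.at[rec.mrna_id, "p_value"])
            quad = assign_quadrant(fc, p, alpha)
        else:
            fc, p, quad = np.nan, np.nan, "unchanged"
            n_missing += 1
        rows.append(
            (
                rec.lncrna_id,
                lnc_direction,
                rec.mrna_id,
                float(rec.sumenergy),
                fc,
                p,
                quad,
            )
        )
    if n_missing:
        logger.info("stratify_targets: %d targets missing from DE table", n_missing)
    return pd.DataFrame(rows, columns=TARGET_COLUMNS)


def quadrant_counts(targets: pd.DataFrame) -> pd.Series:
    """Unique-gene count per quadrant (a gene counts once even if it is a
    target of several lncRNAs)."""
    counts = targets.groupby("quadrant")["mrna_id"].nunique()
    return counts.reindex(QUADRANTS, fill_value=0)


def predict_trans_targets(
    scores: pd.DataFrame,
    de: pd.DataFrame,
    lnc_direction: str,
    energy_target: float = ENERGY_TARGET,
    min_targets: int = MIN_TARGETS,
    energy_substrate: float = ENERGY_SUBSTRATE,
    promiscuity: int = PROMISCUITY,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Full filter chain + stratification; returns targets and a stage log."""
    retained = retain_lncrnas(scores, energy_target, min_targets)
    substrates = filter_substrates(scores, retained, energy_substrate)
    cleaned, dropped = drop_promiscuous(substrates, promiscuity)
    targets = stratify_targets(cleaned, de, lnc_direction, alpha)
    info = {
        "n_input_rows": int(len(scores)),
        "n_retained_lncrnas": len(retained),
        "retained_lncrnas": sorted(retained),
        "n_substrate_rows": int(len(substrates)),
        "dropped_promiscuous": dropped,
        "quadrant_counts": quadrant_counts(targets).to_dict(),
    }
    return targets, info
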