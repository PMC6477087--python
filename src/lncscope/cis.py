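"""Genomic-distance (cis) classification of lncRNAs.

Each lncRNA is classified by the gap to its nearest gene of any biotype:
``overlap`` (intervals intersect), ``adjoining`` (gap <= 5 kb), ``proximal``
(5 kb < gap <= 10 kb), ``others`` (> 10 kb or no same-chromosome gene).
Significantly deregulated lncRNAs are then paired with significantly
deregulated protein-coding genes inside the overlap/adjoining/proximal
classes, labeling each pair concordant or anti-correlated by DE direction.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .types import CODING, LNCRNA, GeneAnnotation

ADJOINING_BP = 5_000
PROXIMAL_BP = 10_000

DISTANCE_CLASSES = ("overlap", "adjoining", "proximal", "others")

PAIR_COLUMNS = [
    "lncrna_id",
    "neighbor_id",
    "distance_class",
    "gap_bp",
    "lnc_direction",
    "neighbor_direction",
    "concordance",
    "primary",
]


def interval_gap(a: GeneAnnotation, b: GeneAnnotation) -> float:
    """Gap in bp between gene bodies; 0 when overlapping, inf across chroms."""
    if a.chrom != b.chrom:
        return math.inf
    if a.start < b.end and b.start < a.end:
        return 0
    return b.start - a.end if a.end <= b.start else a.start - b.end


def classify_gap(
    gap: float, adjoining: int = ADJOINING_BP, proximal: int = PROXIMAL_BP
) -> str:
    if gap == 0:
        return "overlap"
    if gap <= adjoining:
        return "adjoining"
    if gap <= proximal:
        return "proximal"
    return "others"


def classify_lnc(
    lnc: GeneAnnotation,
    all_genes: Sequence[GeneAnnotation],
    adjoining: int = ADJOINING_BP,
    proximal: int = PROXIMAL_BP,
) -> tuple[str, str | None, float]:
    """Distance class, nearest neighbor id, and gap for one lncRNA.

    The candidate set is every other gene irrespective of biotype; ties on
    gap resolve to the smaller gene id.
    """
    best_gap, best_id = math.inf, None
    for g in all_genes:
        if g.gene_id == lnc.gene_id:
            continue
        gap = interval_gap(lnc, g)
        if gap < best_gap or (gap == best_gap and best_id and g.gene_id < best_id):
            best_gap, best_id = gap, g.gene_id
    return classify_gap(best_gap, adjoining, proximal), best_id, best_gap


def neighbors_within(
    lnc: GeneAnnotation,
    candidates: Sequence[GeneAnnotation],
    max_gap: int,
) -> list[tuple[GeneAnnotation, float]]:
    """All candidate genes with gap <= max_gap from the lncRNA, sorted by gap."""
    hits = []
    for g in candidates:
        if g.gene_id == lnc.gene_id:
            continue
        gap = interval_gap(lnc, g)
        if gap <= max_gap:
            hits.append((g, gap))
    hits.sort(key=lambda t: (t[1], t[0].gene_id))
    return hits


def pair_with_de_neighbors(
    de: pd.DataFrame,
    annotation: Sequence[GeneAnnotation],
    adjoining: int = ADJOINING_BP,
    proximal: int = PROXIMAL_BP,
) -> pd.DataFrame:
    """Pair significant lncRNAs with significant protein-coding neighbors.

    Only neighbors in the overlap/adjoining/proximal classes qualify
    (gap <= the proximal threshold). Multiple qualifying neighbors all pair;
    the nearest carries ``primary=True``. Returns an empty frame when no
    lncRNA has a qualifying neighbor.
    """
    sig = de[de["significant"]]
    directions = dict(zip(sig["gene_id"], sig["direction"]))
    by_id = {g.gene_id: g for g in annotation}
    sig_lnc = [
        by_id[g] for g in sig.loc[sig["biotype"] == LNCRNA, "gene_id"] if g in by_id
    ]
    sig_coding = [
        by_id[g] for g in sig.loc[sig["biotype"] == CODING, "gene_id"] if g in by_id
    ]
    rows = []
    for lnc in sig_lnc:
        hits = neighbors_within(lnc, sig_coding, max_gap=proximal)
        for rank, (g, gap) in enumerate(hits):
            lnc_dir = directions[lnc.gene_id]
            nb_dir = directions[g.gene_id]
            rows.append(
                (
                    lnc.gene_id,
                    g.gene_id,
                    classify_gap(gap, adjoining, proximal),
                    int(gap),
                    lnc_dir,
                    nb_dir,
                    "concordant" if lnc_dir == nb_dir else "anti-correlated",
                    rank == 0,
                )
            )
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def classify_all(
    lncs: Sequence[GeneAnnotation],
    all_genes: Sequence[GeneAnnotation],
    adjoining: int = ADJOINING_BP,
    proximal: int = PROXIMAL_BP,
) -> pd.DataFrame:
    """Distance class of every lncRNA in ``lncs`` against ``all_genes``.

    Sorted-boundary scan per chromosome: O(n log n) rather than the
    all-pairs loop of :func:`classify_lnc`.
    """
    frame = pd.DataFrame(
        [(g.gene_id, g.chrom, g.start, g.end) for g in all_genes],
        columns=["gene_id", "chrom", "start", "end"],
    )
    rows = []
    for lnc in lncs:
        sub = frame[(frame["chrom"] == lnc.chrom) & (frame["gene_id"] != lnc.gene_id)]
        if sub.empty:
            rows.append((lnc.gene_id, "others", None, math.inf))
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        overlap = (starts < lnc.end) & (lnc.start < ends)
        gaps = np.where(
            overlap,
            0,
            np.where(ends <= lnc.start, lnc.start - ends, starts - lnc.end),
        )
        order = np.lexsort((sub["gene_id"].to_numpy(), gaps))
        best = order[0]
        gap = float(gaps[best])
        rows.append(
            (
                lnc.gene_id,
                classify_gap(gap, adjoining, proximal),
                sub["gene_id"].iloc[best],
                gap,
            )
        )
    return pd.DataFrame(
        rows, columns=["lncrna_id", "distance_class", "nearest_id", "gap_bp"]
    )
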