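"""Seeded recovery and calibration experiments on synthetic cohorts.

Each function generates cohorts under the study conditions (7 tumors vs 3
controls, log2-scale noise SD 0.5, FPKM-like values) or, for correlation
experiments, at the sample size stated in its docstring, runs the relevant
pipeline stage, and reports a recovery or error rate. These are the
quantities the package's acceptance checks monitor.
"""

from __future__ import annotations

import numpy as np

from . import corr as corr_mod
from .cis import pair_with_de_neighbors
from .diffexpr import call_de
from .synthetic import CisPair, SimConfig, TransBlock, generate_cohort

CIS_GAP_LADDER = (0, 100, 4_999, 5_001, 9_999, 10_050)
CIS_EXPECTED_CLASSES = {
    "LNC0001": "overlap",
    "LNC0002": "adjoining",
    "LNC0003": "adjoining",
    "LNC0004": "proximal",
    "LNC0005": "proximal",
    # LNC0006 at 10,050 bp falls in "others" and must not be paired
}


def de_recovery_rate(
    seed: int, n_rep: int = 10, n_planted: int = 50, effect: float = 2.0
) -> float:
    """Fraction of planted up-regulated genes called up.

    Each replicate plants ``n_planted`` log2 effects of ``effect`` on mRNAs
    in a 200-gene cohort (7 tumors vs 3 controls, noise SD 0.5).
    """
    recovered = total = 0
    for rep in range(n_rep):
        planted = tuple(
            (f"MRNA{i:04d}", effect) for i in range(1, n_planted + 1)
        )
        cfg = SimConfig(planted_de=planted, seed=seed + rep)
        cohort = generate_cohort(cfg)
        de = call_de(cohort.expression, cohort.annotation).set_index("gene_id")
        for gid, _ in planted:
            total += 1
            if de.at[gid, "direction"] == "up":
                recovered += 1
    return recovered / total


def null_false_positive_rate(seed: int, n_rep: int = 100) -> float:
    """Fraction of genes passing the DE rule when nothing is planted."""
    n_sig = n_genes = 0
    for rep in range(n_rep):
        cfg = SimConfig(n_mrna=150, n_lncrna=50, seed=seed + rep)
        cohort = generate_cohort(cfg)
        de = call_de(cohort.expression)
        n_sig += int(de["significant"].sum())
        n_genes += len(de)
    return n_sig / n_genes


def cis_class_recovery_rate(seed: int, n_rep: int = 5) -> float:
    """Fraction of noise-free replicates recovering every planted cis pair
    with the correct distance class (and excluding the >10 kb pair)."""
    n_ok = 0
    for rep in range(n_rep):
        pairs = tuple(
            CisPair(f"LNC{i + 1:04d}", f"MRNA{i + 1:04d}", gap, 0.5)
            for i, gap in enumerate(CIS_GAP_LADDER)
        )
        planted = tuple(
            (g, 2.0) for p in pairs for g in (p.lnc, p.mrna)
        )
        cfg = SimConfig(
            n_mrna=30, n_lncrna=10, planted_de=planted, cis_pairs=pairs,
            noise_sd=0.0, seed=seed + rep,
        )
        cohort = generate_cohort(cfg)
        de = call_de(cohort.expression, cohort.annotation)
        found = pair_with_de_neighbors(de, cohort.annotation)
        got = dict(zip(found["lncrna_id"], found["distance_class"]))
        if got == CIS_EXPECTED_CLASSES:
            n_ok += 1
    return n_ok / n_rep


def trans_driver_top10_rate(
    seed: int, n_rep: int = 100, r: float = 0.8, n_per_group: int = 10
) -> float:
    """Fraction of replicates ranking the planted trans-driver lncRNA in the
    top 10 by sum of correlations, at n = 20 samples."""
    n_hit = 0
    block = TransBlock("LNC0001", tuple(f"MRNA{i:04d}" for i in range(1, 11)), r)
    for rep in range(n_rep):
        cfg = SimConfig(
            n_tumor=n_per_group, n_control=n_per_group,
            n_mrna=40, n_lncrna=30, trans_blocks=(block,), seed=seed + rep,
        )
        cohort = generate_cohort(cfg)
        edges = corr_mod.build_edges(
            cohort.expression, cfg.lnc_ids(), cfg.mrna_ids()
        )
        summaries = corr_mod.summarize_lnc(edges)
        if "LNC0001" in corr_mod.select_top_lnc(summaries, k=10):
            n_hit += 1
    return n_hit / n_rep


def correlation_calibration(
    seed: int, targets: tuple[float, ...] = (0.3, 0.6, 0.9), n_rep: int = 200
) -> dict[float, float]:
    """Mean sample Pearson r of a planted pair at n = 20, per target r."""
    out = {}
    for target in targets:
        rs = []
        for rep in range(n_rep):
            cfg = SimConfig(
                n_tumor=10, n_control=10, n_mrna=1, n_lncrna=1,
                cis_pairs=(CisPair("LNC0001", "MRNA0001", 1000, target),),
                seed=seed + rep,
            )
            log = generate_cohort(cfg).expression.log2p1()
            rs.append(
                float(np.corrcoef(log.loc["LNC0001"], log.loc["MRNA0001"])[0, 1])
            )
        out[target] = float(np.mean(rs))
    return out
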