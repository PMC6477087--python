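"""End-to-end orchestration: validate -> DE -> correlation network -> cis
classification -> trans targets -> cohort summary, from one configuration.

Stage outputs are written as TSVs (``de.tsv``, ``edges.tsv``,
``lnc_summary.tsv``, ``cis_pairs.tsv``, ``trans_targets.tsv``) plus a
``report.json`` with per-stage counts, the echoed configuration, the package
version, and input checksums, so a run is auditable and exactly repeatable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import cis as cis_mod
from . import corr as corr_mod
from . import diffexpr as de_mod
from . import io as lio
from . import trans as trans_mod
from .cohort import summarize_cohort
from .synthetic import CisPair, SimConfig, TransBlock, generate_cohort, \
    generate_interaction_table, write_fixture
from .types import CODING, LNCRNA

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    gtf: str
    expression: str
    samples: str
    interactions: str | None = None
    alpha: float = 0.05
    fc_cut: float = 1.0
    corr_cut: float = 0.3
    top_lnc: int = 400
    k: int = 10
    adjoining: int = 5_000
    proximal: int = 10_000
    energy_target: float = 2_000.0
    energy_substrate: float = 1_500.0
    min_targets: int = 10
    promiscuity: int = 4
    seed: int = 0
    outdir: str = "lncscope_out"

    def validate(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        positive = [
            "fc_cut", "corr_cut", "top_lnc", "k", "adjoining", "proximal",
            "energy_target", "energy_substrate", "min_targets", "promiscuity",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the report dict (also written as JSON)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "inputs": {},
        "stages": {},
        "complete": False,
    }
    stage = "validate"
    try:
        for name, path in (
            ("gtf", config.gtf),
            ("expression", config.expression),
            ("samples", config.samples),
            ("interactions", config.interactions),
        ):
            if path is not None:
                report["inputs"][name] = {"path": str(path), "sha256": _sha256(path)}

        stage = "annotation"
        annotation = lio.read_gtf(config.gtf)
        stage = "expression"
        expr = lio.read_expression(config.expression, config.samples)
        samples = lio.read_sample_sheet(config.samples)

        stage = "cohort_summary"
        summary = summarize_cohort(samples)
        report["stages"]["cohort"] = dataclasses.asdict(summary)

        stage = "differential_expression"
        de = de_mod.call_de(
            expr, annotation, alpha=config.alpha, fc_cut=config.fc_cut
        )
        de.to_csv(outdir / "de.tsv", sep="\t", index=False, float_format="%.6g")
        sig = de[de["significant"]]
        report["stages"]["de"] = {
            "n_tested": int(len(de)),
            "n_up_coding": int(
                ((sig["biotype"] == CODING) & (sig["direction"] == "up")).sum()
            ),
            "n_down_coding": int(
                ((sig["biotype"] == CODING) & (sig["direction"] == "down")).sum()
            ),
            "n_up_lncrna": int(
                ((sig["biotype"] == LNCRNA) & (sig["direction"] == "up")).sum()
            ),
            "n_down_lncrna": int(
                ((sig["biotype"] == LNCRNA) & (sig["direction"] == "down")).sum()
            ),
        }

        stage = "correlation_network"
        top_lnc = de_mod.top_deregulated(de, LNCRNA, config.top_lnc)
        sig_mrna = list(sig.loc[sig["biotype"] == CODING, "gene_id"])
        if top_lnc and sig_mrna:
            edges = corr_mod.build_edges(
                expr, top_lnc, sig_mrna, cut=config.corr_cut
            )
            summaries = corr_mod.summarize_lnc(edges)
            top10 = corr_mod.select_top_lnc(summaries, k=config.k)
        else:
            edges = pd.DataFrame(columns=corr_mod.EDGE_COLUMNS)
            summaries = pd.DataFrame(columns=corr_mod.SUMMARY_COLUMNS)
            top10 = []
        edges.to_csv(outdir / "edges.tsv", sep="\t", index=False, float_format="%.6g")
        summaries.to_csv(
            outdir / "lnc_summary.tsv", sep="\t", index=False, float_format="%.6g"
        )
        report["stages"]["correlation"] = {
            "n_edges": int(len(edges)),
            "n_retained": int(edges["retained"].sum()) if len(edges) else 0,
            "top_lncrnas": top10,
        }

        stage = "cis_classification"
        pairs = cis_mod.pair_with_de_neighbors(
            de, annotation, adjoining=config.adjoining, proximal=config.proximal
        )
        pairs.to_csv(outdir / "cis_pairs.tsv", sep="\t", index=False)
        by_class = (
            pairs.groupby("distance_class").size().to_dict() if len(pairs) else {}
        )
        report["stages"]["cis"] = {
            "n_pairs": int(len(pairs)),
            "pairs_per_class": {
                c: int(by_class.get(c, 0)) for c in cis_mod.DISTANCE_CLASSES
            },
            "n_concordant": int((pairs["concordance"] == "concordant").sum())
            if len(pairs)
            else 0,
        }

        stage = "trans_targets"
        if config.interactions is not None:
            scores = lio.read_interactions(config.interactions)
            frames = []
            infos = {}
            for direction in ("up", "down"):
                targets, info = trans_mod.predict_trans_targets(
                    scores,
                    de,
                    direction,
                    energy_target=config.energy_target,
                    min_targets=config.min_targets,
                    energy_substrate=config.energy_substrate,
                    promiscuity=config.promiscuity,
                    alpha=config.alpha,
                )
                frames.append(targets)
                infos[direction] = {
                    "n_targets": int(len(targets)),
                    "quadrant_counts": info["quadrant_counts"],
                }
            nonempty = [f for f in frames if len(f)]
            all_targets = (
                pd.concat(nonempty, ignore_index=True)
                if nonempty
                else pd.DataFrame(columns=trans_mod.TARGET_COLUMNS)
            )
            all_targets.to_csv(
                outdir / "trans_targets.tsv", sep="\t", index=False,
                float_format="%.6g",
            )
            retained = trans_mod.retain_lncrnas(
                scores, config.energy_target, config.min_targets
            )
            report["stages"]["trans"] = {
                "n_retained_lncrnas": len(retained),
                "per_direction": infos,
            }
        else:
            report["stages"]["trans"] = {"skipped": "no interaction table supplied"}
    except Exception as exc:
        report["failed_stage"] = stage
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    report["complete"] = True
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def demo_config(seed: int = 7) -> SimConfig:
    """The default demonstration cohort: 7 tumors vs 3 controls with planted
    effects spanning every distance class and both concordance patterns, one
    energy-retained trans-driver lncRNA, and one promiscuous mRNA."""
    de_effects = []
    # strongly deregulated mRNAs, both directions; 16-25 are the trans block
    for i in range(1, 11):
        de_effects.append((f"MRNA{i:04d}", 3.5))
    for i in range(11, 16):
        de_effects.append((f"MRNA{i:04d}", -3.5))
    for i in range(16, 26):
        de_effects.append((f"MRNA{i:04d}", 3.5))
    # deregulated lncRNAs incl. the cis partners and the trans driver
    for i in range(1, 7):
        de_effects.append((f"LNC{i:04d}", -3.5 if i % 2 else 3.5))
    de_effects.append(("LNC0010", 3.5))
    cis_pairs = (
        CisPair("LNC0001", "MRNA0001", 0, 0.6),       # overlap, anti (lnc down/mRNA up)
        CisPair("LNC0002", "MRNA0002", 100, 0.6),     # adjoining
        CisPair("LNC0003", "MRNA0003", 4_999, 0.6),   # adjoining boundary
        CisPair("LNC0004", "MRNA0004", 5_001, 0.6),   # proximal
        CisPair("LNC0005", "MRNA0005", 9_999, 0.6),   # proximal boundary
        CisPair("LNC0006", "MRNA0006", 10_050, 0.6),  # others: excluded from pairing
    )
    trans = (TransBlock("LNC0010", tuple(f"MRNA{i:04d}" for i in range(16, 26)), 0.6),)
    return SimConfig(
        planted_de=tuple(de_effects),
        cis_pairs=cis_pairs,
        trans_blocks=trans,
        seed=seed,
    )


def make_demo(seed: int = 7, outdir: str | Path = "demo") -> Path:
    """Write the default synthetic cohort plus a ready-to-run YAML config."""
    outdir = Path(outdir)
    config = demo_config(seed)
    cohort = generate_cohort(config)
    driver = config.trans_blocks[0]
    cohort.interactions = generate_interaction_table(
        config,
        truth_targets=[(driver.lnc, m) for m in driver.members]
        + [(driver.lnc, f"MRNA{i:04d}") for i in range(11, 13)],
        n_background=40,
        n_promiscuous=1,
    )
    manifest = write_fixture(cohort, outdir)
    run_cfg = PipelineConfig(
        gtf=str(manifest["annotation"]),
        expression=str(manifest["expression"]),
        samples=str(manifest["samples"]),
        interactions=str(manifest["interactions"]),
        seed=seed,
        outdir=str(outdir / "results"),
    )
    with open(outdir / "run.yaml", "w") as fh:
        yaml.safe_dump(run_cfg.to_dict(), fh, sort_keys=False)
    return outdir
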