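"""Synthetic tumor/control cohort generator.

Emulates the data structure of a small bulk RNA-seq study of retinoblastoma
(7 tumors, 3 retina controls): an FPKM-like expression matrix with
log-normal noise, planted up/down differential-expression effects,
lncRNA-mRNA pairs cis-coupled at controlled genomic gaps, trans correlation
blocks driven by single lncRNAs, and an RNA-RNA interaction-score table
with true targets, background pairs, and promiscuous mRNAs.

Expression model, per gene g and sample s (log2 scale)::

    log2 x[g, s] = baseline + effect_g * 1[s in tumor]
                   + lambda_g * f_k(g)[s] + noise_sd * eps[g, s]

where f_k is a per-sample standard-normal latent factor shared by the
members of correlation block k, and the loading ``lambda = noise_sd *
sqrt(|r| / (1 - |r|))`` makes the expected Pearson correlation of two block
members equal the signed target r. FPKM values are ``2 ** log2x``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as lio
from .types import (
    CODING,
    CONTROL,
    LNCRNA,
    TUMOR,
    CohortSample,
    ExpressionMatrix,
    GeneAnnotation,
)

GENE_LENGTH = 2_000
GENE_SPACING = 50_000  # keeps unpaired genes in the "others" distance class


@dataclass(frozen=True, slots=True)
class CisPair:
    """A lncRNA planted at a controlled gap from an mRNA, with a target
    signed Pearson correlation between the two."""

    lnc: str
    mrna: str
    gap_bp: int
    r: float


@dataclass(frozen=True, slots=True)
class TransBlock:
    """A lncRNA driving a block of distant mRNAs at a target signed r."""

    lnc: str
    members: tuple[str, ...]
    r: float


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for one synthetic cohort.

    Defaults mirror the study design: 7 tumors vs 3 controls, log2-scale
    noise SD 0.5 around a baseline of 4 (~16 FPKM).
    """

    n_tumor: int = 7
    n_control: int = 3
    n_mrna: int = 150
    n_lncrna: int = 50
    chrom_length: int = 50_000_000
    planted_de: tuple[tuple[str, float], ...] = ()
    cis_pairs: tuple[CisPair, ...] = ()
    trans_blocks: tuple[TransBlock, ...] = ()
    noise_sd: float = 0.5
    baseline_log2_mean: float = 4.0
    seed: int = 0

    def mrna_ids(self) -> list[str]:
        return [f"MRNA{i:04d}" for i in range(1, self.n_mrna + 1)]

    def lnc_ids(self) -> list[str]:
        return [f"LNC{i:04d}" for i in range(1, self.n_lncrna + 1)]

    def validate(self) -> None:
        if self.n_tumor < 2:
            raise ValueError(f"n_tumor must be >= 2, got {self.n_tumor}")
        if self.n_control < 2:
            raise ValueError(f"n_control must be >= 2, got {self.n_control}")
        if self.n_mrna < 1 or self.n_lncrna < 1:
            raise ValueError("n_mrna and n_lncrna must be >= 1")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        known = set(self.mrna_ids()) | set(self.lnc_ids())
        for gene, _ in self.planted_de:
            if gene not in known:
                raise ValueError(f"planted_de references unknown gene {gene!r}")
        for p in self.cis_pairs:
            if p.gap_bp < 0:
                raise ValueError(f"cis_pairs: negative gap for {p.lnc!r}")
            if not (-1.0 < p.r < 1.0):
                raise ValueError(f"cis_pairs: target r out of (-1, 1) for {p.lnc!r}")
            if p.lnc not in known or p.mrna not in known:
                raise ValueError(
                    f"cis_pairs references unknown gene "
                    f"{p.lnc if p.lnc not in known else p.mrna!r}"
                )
        lnc_used = [p.lnc for p in self.cis_pairs]
        if len(set(lnc_used)) != len(lnc_used):
            raise ValueError("cis_pairs: a lncRNA may appear in only one pair")
        for b in self.trans_blocks:
            if not (-1.0 < b.r < 1.0):
                raise ValueError(f"trans_blocks: target r out of (-1, 1) for {b.lnc!r}")
            for m in (b.lnc, *b.members):
                if m not in known:
                    raise ValueError(f"trans_blocks references unknown gene {m!r}")


@dataclass
class SyntheticCohort:
    annotation: list[GeneAnnotation]
    expression: ExpressionMatrix
    samples: list[CohortSample]
    interactions: pd.DataFrame
    truth: dict
    config: SimConfig


def _build_annotation(config: SimConfig) -> list[GeneAnnotation]:
    """Lay genes on one chromosome, unpaired genes >10 kb apart, cis-paired
    lncRNAs relocated next to their mRNA partner at the configured gap."""
    genes: dict[str, GeneAnnotation] = {}
    pos = 10_000
    for gid in config.mrna_ids():
        genes[gid] = GeneAnnotation(gid, "chr1", pos, pos + GENE_LENGTH, "+", CODING)
        pos += GENE_SPACING
    paired = {p.lnc: p for p in config.cis_pairs}
    for gid in config.lnc_ids():
        pair = paired.get(gid)
        if pair is None:
            genes[gid] = GeneAnnotation(
                gid, "chr1", pos, pos + GENE_LENGTH, "+", LNCRNA
            )
            pos += GENE_SPACING
            continue
        anchor = genes[pair.mrna]
        if pair.gap_bp == 0:
            # overlap: nested inside the partner gene body
            start = anchor.start + anchor.length // 4
            end = start + anchor.length // 2
        else:
            start = anchor.end + pair.gap_bp
            end = start + GENE_LENGTH
        genes[gid] = GeneAnnotation(gid, "chr1", start, end, "-", LNCRNA)
    last = max(g.end for g in genes.values())
    if last > config.chrom_length:
        raise ValueError(
            f"chrom_length {config.chrom_length} too small for layout "
            f"(needs {last})"
        )
    return [genes[g] for g in [*config.mrna_ids(), *config.lnc_ids()]]


def _build_samples(config: SimConfig) -> list[CohortSample]:
    ages = [72, 36, 24, 36, 12, 36, 8]  # months, cycled over tumors
    sexes = ["male", "male", "female", "female", "female", "male", "male"]
    invas = [
        "invasive", "non-invasive", "non-invasive", "non-invasive",
        "invasive", "non-invasive", "invasive",
    ]
    samples = [
        CohortSample(
            sample_id=f"T{i + 1}",
            group=TUMOR,
            age_months=ages[i % len(ages)],
            sex=sexes[i % len(sexes)],
            invasiveness=invas[i % len(invas)],
            laterality="OD",
        )
        for i in range(config.n_tumor)
    ]
    samples += [
        CohortSample(sample_id=f"C{i + 1}", group=CONTROL, age_months=60 * (i + 1))
        for i in range(config.n_control)
    ]
    return samples


def _loading(r: float, noise_sd: float) -> float:
    """Latent-factor loading giving expected pairwise Pearson r (magnitude)."""
    a = abs(r)
    return noise_sd * np.sqrt(a / (1.0 - a))


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Deterministically generate a full cohort from the configuration.

    Identical config (including seed) gives bit-identical output; per-gene
    noise streams are keyed by gene id position so adding genes does not
    reshuffle existing ones.
    """
    config.validate()
    annotation = _build_annotation(config)
    samples = _build_samples(config)
    gene_order = [g.gene_id for g in annotation]
    sample_ids = [s.sample_id for s in samples]
    n_samples = len(sample_ids)
    tumor_mask = np.array([s.group == TUMOR for s in samples], dtype=float)

    effects = dict(config.planted_de)

    # latent factors: one per-sample vector per correlation block; a gene in
    # several blocks accumulates every contribution
    contributions: dict[str, list[np.ndarray]] = {}

    def _add(gid: str, loading: float, f: np.ndarray) -> None:
        contributions.setdefault(gid, []).append(loading * f)

    for k, pair in enumerate(config.cis_pairs):
        rng = np.random.default_rng([config.seed, 2, k])
        f = rng.standard_normal(n_samples)
        lam = _loading(pair.r, config.noise_sd)
        _add(pair.lnc, lam, f)
        _add(pair.mrna, np.sign(pair.r) * lam, f)
    for k, block in enumerate(config.trans_blocks):
        rng = np.random.default_rng([config.seed, 3, k])
        f = rng.standard_normal(n_samples)
        lam = _loading(block.r, config.noise_sd)
        _add(block.lnc, lam, f)
        for m in block.members:
            _add(m, np.sign(block.r) * lam, f)

    log2x = np.empty((len(gene_order), n_samples))
    for i, gid in enumerate(gene_order):
        rng = np.random.default_rng([config.seed, 1, i])
        eps = rng.standard_normal(n_samples)
        row = config.baseline_log2_mean + config.noise_sd * eps
        row = row + effects.get(gid, 0.0) * tumor_mask
        for contrib in contributions.get(gid, ()):
            row = row + contrib
        log2x[i] = row
    fpkm = np.maximum(2.0**log2x, 0.0)
    values = pd.DataFrame(fpkm, index=gene_order, columns=sample_ids)
    expr = ExpressionMatrix(values, {s.sample_id: s.group for s in samples})

    truth = {
        "planted_de": list(config.planted_de),
        "cis_pairs": list(config.cis_pairs),
        "trans_blocks": list(config.trans_blocks),
        "true_targets": [],
        "promiscuous": [],
    }
    return SyntheticCohort(
        annotation=annotation,
        expression=expr,
        samples=samples,
        interactions=pd.DataFrame(columns=["lncrna_id", "mrna_id", "sumenergy"]),
        truth=truth,
        config=config,
    )


def generate_interaction_table(
    config: SimConfig,
    truth_targets: Sequence[tuple[str, str]],
    n_background: int = 0,
    n_promiscuous: int = 0,
) -> pd.DataFrame:
    """Interaction-score table with planted structure.

    True targets draw SUMENERGY uniformly in (2000, 4000]; background pairs
    in (0, 1500]; each promiscuous mRNA gets scores > 1500 under 5 distinct
    lncRNAs so the >4-lncRNA exclusion rule fires on it downstream.
    """
    mrna_ids, lnc_ids = config.mrna_ids(), config.lnc_ids()
    known = set(mrna_ids) | set(lnc_ids)
    for lnc, mrna in truth_targets:
        if lnc not in known or mrna not in known:
            raise ValueError(f"truth target references unknown gene ({lnc}, {mrna})")
    truth_mrnas = {m for _, m in truth_targets}
    free_mrnas = [m for m in mrna_ids if m not in truth_mrnas]
    if n_promiscuous > len(free_mrnas):
        raise ValueError(
            f"n_promiscuous={n_promiscuous} exceeds available mRNAs "
            f"({len(free_mrnas)})"
        )
    if len(lnc_ids) < 5 and n_promiscuous > 0:
        raise ValueError("need at least 5 lncRNAs to plant promiscuous mRNAs")
    rng = np.random.default_rng([config.seed, 4])
    rows: list[tuple[str, str, float]] = []
    for lnc, mrna in truth_targets:
        rows.append((lnc, mrna, float(2000.0 + 2000.0 * rng.uniform(1e-9, 1.0))))
    seen = {(l, m) for l, m, _ in rows}
    n_placed = 0
    while n_placed < n_background:
        lnc = lnc_ids[rng.integers(len(lnc_ids))]
        mrna = mrna_ids[rng.integers(len(mrna_ids))]
        if (lnc, mrna) in seen:
            continue
        seen.add((lnc, mrna))
        rows.append((lnc, mrna, float(1500.0 * rng.uniform(1e-9, 1.0))))
        n_placed += 1
    promiscuous = list(free_mrnas[:n_promiscuous])
    for mrna in promiscuous:
        placed = 0
        order = list(rng.permutation(len(lnc_ids)))
        for h in order:
            if placed == 5:
                break
            lnc = lnc_ids[int(h)]
            if (lnc, mrna) in seen:
                continue
            seen.add((lnc, mrna))
            rows.append((lnc, mrna, float(1500.0 + 2500.0 * rng.uniform(1e-9, 1.0))))
            placed += 1
        if placed < 5:
            raise ValueError(f"could not plant 5 hosts for promiscuous {mrna!r}")
    return pd.DataFrame(rows, columns=["lncrna_id", "mrna_id", "sumenergy"])


FIXTURE_FILES = {
    "annotation": "annotation.gtf",
    "expression": "expression.tsv",
    "samples": "samples.tsv",
    "interactions": "interactions.tsv",
}


def write_fixture(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write GTF + expression/sample/interaction TSVs; returns the manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}
    try:
        manifest["annotation"] = directory / FIXTURE_FILES["annotation"]
        lio.write_gtf(cohort.annotation, manifest["annotation"])
        manifest["expression"] = directory / FIXTURE_FILES["expression"]
        lio.write_expression(cohort.expression, manifest["expression"])
        manifest["samples"] = directory / FIXTURE_FILES["samples"]
        lio.write_sample_sheet(cohort.samples, manifest["samples"])
        manifest["interactions"] = directory / FIXTURE_FILES["interactions"]
        lio.write_interactions(cohort.interactions, manifest["interactions"])
    except OSError as exc:
        raise OSError(f"failed writing fixture under {directory}: {exc}") from exc
    return manifest
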