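"""Core containers for the tumor-vs-normal lncRNA/mRNA profiling pipeline.

Annotation records and clinical samples are small frozen dataclasses; bulk
results (differential expression tables, correlation edges, neighbor pairs,
trans-target tables) are plain :class:`pandas.DataFrame` objects with fixed
column contracts documented in the producing module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

CODING = "coding"
LNCRNA = "lncRNA"
OTHER = "other"
BIOTYPES = (CODING, LNCRNA, OTHER)

TUMOR = "tumor"
CONTROL = "control"


@dataclass(frozen=True, slots=True)
class GeneAnnotation:
    """One gene interval.

    Coordinates are 0-based half-open internally; GTF input/output is
    1-based inclusive and converted at the io boundary.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    biotype: str = OTHER

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id!r}: require 0 <= start < end, "
                f"got ({self.start}, {self.end})"
            )
        if self.biotype not in BIOTYPES:
            raise ValueError(f"gene {self.gene_id!r}: unknown biotype {self.biotype!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def annotation_frame(genes: Iterable[GeneAnnotation]) -> pd.DataFrame:
    """Tabular view of an annotation collection (one row per gene)."""
    rows = [
        (g.gene_id, g.chrom, g.start, g.end, g.strand, g.biotype) for g in genes
    ]
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "biotype"]
    )


def check_unique_gene_ids(genes: Sequence[GeneAnnotation]) -> None:
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate gene ids in annotation: {dupes[:5]}")


@dataclass(frozen=True, slots=True)
class CohortSample:
    """One clinical sample: tumor specimen or normal retina control."""

    sample_id: str
    group: str  # tumor | control
    age_months: Optional[int] = None
    sex: str = "unknown"  # male | female | unknown
    invasiveness: str = "not-applicable"  # invasive | non-invasive | not-applicable
    laterality: Optional[str] = None

    def __post_init__(self) -> None:
        if self.group not in (TUMOR, CONTROL):
            raise ValueError(f"sample {self.sample_id!r}: bad group {self.group!r}")
        if self.age_months is not None and self.age_months < 0:
            raise ValueError(f"sample {self.sample_id!r}: negative age")
        if self.sex not in ("male", "female", "unknown"):
            raise ValueError(f"sample {self.sample_id!r}: bad sex {self.sex!r}")
        if self.invasiveness not in ("invasive", "non-invasive", "not-applicable"):
            raise ValueError(
                f"sample {self.sample_id!r}: bad invasiveness {self.invasiveness!r}"
            )
        if self.group == CONTROL and self.invasiveness != "not-applicable":
            raise ValueError(
                f"control sample {self.sample_id!r} must have "
                "invasiveness=not-applicable"
            )


class ExpressionMatrix:
    """Genes x samples FPKM-like matrix with tumor/control group labels.

    Values must be finite and non-negative. ``values`` is a DataFrame indexed
    by gene id with sample ids as columns; ``group`` maps each sample id to
    ``"tumor"`` or ``"control"``.
    """

    def __init__(self, values: pd.DataFrame, group: Mapping[str, str]):
        values = values.astype(float)
        if values.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        arr = values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("expression matrix contains non-finite values")
        if (arr < 0).any():
            bad = values.index[(arr < 0).any(axis=1)][0]
            raise ValueError(f"negative expression value for gene {bad!r}")
        missing = [s for s in values.columns if s not in group]
        if missing:
            raise ValueError(f"sample {missing[0]!r} has no group label")
        labels = {s: group[s] for s in values.columns}
        bad_labels = {v for v in labels.values() if v not in (TUMOR, CONTROL)}
        if bad_labels:
            raise ValueError(f"unknown group labels: {sorted(bad_labels)}")
        if TUMOR not in labels.values() or CONTROL not in labels.values():
            raise ValueError("both tumor and control groups must be non-empty")
        self.values = values
        self.group = pd.Series(labels, name="group")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def tumor_samples(self) -> list[str]:
        return list(self.group.index[self.group == TUMOR])

    @property
    def control_samples(self) -> list[str]:
        return list(self.group.index[self.group == CONTROL])

    def log2p1(self) -> pd.DataFrame:
        """log2(FPKM + 1) transform used by the test and correlation stages."""
        return np.log2(self.values + 1.0)

    def all_zero_genes(self) -> list[str]:
        mask = (self.values == 0).all(axis=1)
        return list(self.values.index[mask])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        nt, nc = len(self.tumor_samples), len(self.control_samples)
        return (
            f"ExpressionMatrix({self.values.shape[0]} genes, "
            f"{nt} tumor + {nc} control samples)"
        )
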