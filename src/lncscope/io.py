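"""Readers and writers for the pipeline's on-disk formats.

Formats: GTF 2.2 annotation (1-based inclusive on disk, 0-based half-open in
memory), TSV expression matrix (first column ``gene_id``, header row = sample
ids), TSV sample sheet, and a TSV RNA-RNA interaction-score table
(``lncrna_id``, ``mrna_id``, ``sumenergy``).
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd
import pyranges as pr

from .types import (
    CODING,
    LNCRNA,
    OTHER,
    CohortSample,
    ExpressionMatrix,
    GeneAnnotation,
    check_unique_gene_ids,
)

PathLike = Union[str, Path]

# Ensembl release-75 era vocabulary for long non-coding biotypes.
LNCRNA_BIOTYPES = frozenset(
    {
        "lncRNA",
        "lincRNA",
        "antisense",
        "processed_transcript",
        "sense_intronic",
        "sense_overlapping",
        "3prime_overlapping_ncrna",
    }
)
CODING_BIOTYPES = frozenset({"protein_coding"})


def map_biotype(raw: str) -> str:
    if raw in CODING_BIOTYPES:
        return CODING
    if raw in LNCRNA_BIOTYPES:
        return LNCRNA
    return OTHER


def _validate_gtf_lines(path: Path) -> None:
    """Light structural pass so malformed input fails with a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(
                    f"{path}: line {lineno}: expected 9 tab-separated GTF "
                    f"fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinates "
                    f"{fields[3]!r}/{fields[4]!r}"
                ) from None
            if start < 1 or end < start:
                raise ValueError(
                    f"{path}: line {lineno}: bad coordinate range {start}-{end}"
                )
            if "gene_id" not in fields[8]:
                raise ValueError(
                    f"{path}: line {lineno}: missing gene_id attribute"
                )


def read_gtf(path: PathLike) -> list[GeneAnnotation]:
    """Read a GTF and collapse features to one envelope interval per gene.

    The gene interval spans the min start / max end over all of the gene's
    features; biotype comes from the ``gene_biotype`` attribute.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_gtf_lines(path)
    df = pr.read_gtf(str(path)).df  # pyranges converts to 0-based half-open
    if df.empty:
        return []
    if "gene_biotype" not in df.columns:
        df["gene_biotype"] = ""
    grouped = df.groupby("gene_id", sort=True)
    genes = []
    for gene_id, sub in grouped:
        chroms = sub["Chromosome"].astype(str).unique()
        if len(chroms) > 1:
            raise ValueError(
                f"{path}: gene {gene_id!r} spans chromosomes {sorted(chroms)}"
            )
        strands = set(sub["Strand"].astype(str)) if "Strand" in sub else {"."}
        strand = strands.pop() if len(strands) == 1 else "."
        biotype = map_biotype(str(sub["gene_biotype"].iloc[0]))
        genes.append(
            GeneAnnotation(
                gene_id=str(gene_id),
                chrom=str(chroms[0]),
                start=int(sub["Start"].min()),
                end=int(sub["End"].max()),
                strand=strand if strand in "+-" else ".",
                biotype=biotype,
            )
        )
    check_unique_gene_ids(genes)
    return genes


_INVERSE_BIOTYPE = {CODING: "protein_coding", LNCRNA: "lincRNA", OTHER: "misc_RNA"}


def write_gtf(genes: Iterable[GeneAnnotation], path: PathLike) -> None:
    """Write one ``gene`` feature line per record (1-based inclusive)."""
    path = Path(path)
    with open(path, "w") as fh:
        for g in genes:
            attrs = (
                f'gene_id "{g.gene_id}"; '
                f'gene_biotype "{_INVERSE_BIOTYPE[g.biotype]}";'
            )
            fh.write(
                f"{g.chrom}\tlncscope\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand if g.strand in '+-' else '.'}\t.\t{attrs}\n"
            )


def read_expression(
    path: PathLike, sample_sheet_path: PathLike
) -> ExpressionMatrix:
    """Read an expression TSV and attach group labels from the sample sheet.

    Every matrix column must appear in the sheet; negative values are
    rejected. All-zero genes are retained (callers may flag them).
    """
    samples = read_sample_sheet(sample_sheet_path)
    groups = {s.sample_id: s.group for s in samples}
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    unknown = [c for c in df.columns if c not in groups]
    if unknown:
        raise ValueError(
            f"{path}: sample {unknown[0]!r} not present in sample sheet"
        )
    return ExpressionMatrix(df, groups)


def write_expression(expr: ExpressionMatrix, path: PathLike) -> None:
    out = expr.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.6g")


_AGE_RE = re.compile(r"^\s*(\d+)\s*(y|yr|yrs|year|years|m|mo|month|months)\s*$", re.I)

SAMPLE_SHEET_COLUMNS = [
    "sample_id",
    "group",
    "age",
    "sex",
    "invasiveness",
    "laterality",
]


def parse_age_months(raw: object) -> int | None:
    """Parse clinical age strings like ``"6 Y"`` or ``"8 Months"`` to months."""
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None
    text = str(raw).strip()
    if text.upper() in ("", "N/A", "NA", "UNKNOWN"):
        return None
    m = _AGE_RE.match(text)
    if not m:
        raise ValueError(f"unparseable age string: {text!r}")
    value, unit = int(m.group(1)), m.group(2).lower()
    return value * 12 if unit.startswith("y") else value


def _norm_sex(raw: object) -> str:
    text = str(raw).strip().lower()
    if text in ("male", "m"):
        return "male"
    if text in ("female", "f"):
        return "female"
    return "unknown"


def _norm_invasiveness(raw: object, group: str) -> str:
    text = str(raw).strip().lower()
    if text in ("invasive",):
        return "invasive"
    if text in ("non-invasive", "noninvasive", "non invasive"):
        return "non-invasive"
    if group == "control" or text in ("n/a", "na", "", "nan", "not-applicable"):
        return "not-applicable"
    raise ValueError(f"unrecognized invasiveness value: {raw!r}")


def read_sample_sheet(path: PathLike) -> list[CohortSample]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("N/A")
    missing = [c for c in ("sample_id", "group") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: sample sheet missing column {missing[0]!r}")
    samples = []
    for _, row in df.iterrows():
        group = str(row["group"]).strip().lower()
        lat = str(row.get("laterality", "N/A")).strip()
        samples.append(
            CohortSample(
                sample_id=str(row["sample_id"]).strip(),
                group=group,
                age_months=parse_age_months(row.get("age")),
                sex=_norm_sex(row.get("sex", "unknown")),
                invasiveness=_norm_invasiveness(row.get("invasiveness"), group),
                laterality=None if lat.upper() in ("N/A", "NA", "") else lat,
            )
        )
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate sample ids")
    return samples


def write_sample_sheet(samples: Sequence[CohortSample], path: PathLike) -> None:
    rows = []
    for s in samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "group": s.group,
                "age": "N/A" if s.age_months is None else f"{s.age_months} Months",
                "sex": s.sex if s.sex != "unknown" else "N/A",
                "invasiveness": (
                    s.invasiveness if s.invasiveness != "not-applicable" else "N/A"
                ),
                "laterality": s.laterality or "N/A",
            }
        )
    pd.DataFrame(rows, columns=SAMPLE_SHEET_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_interactions(path: PathLike) -> pd.DataFrame:
    """Read (lncrna_id, mrna_id, sumenergy) rows.

    Duplicate (lncRNA, mRNA) pairs are collapsed keeping the maximum score;
    scores must be positive numbers.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["lncrna_id", "mrna_id", "sumenergy"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: interaction table missing column {missing[0]!r}")
    if df.empty:
        return pd.DataFrame(columns=required).astype({"sumenergy": float})
    scores = pd.to_numeric(df["sumenergy"], errors="coerce")
    if scores.isna().any():
        row = int(scores.index[scores.isna()][0]) + 2  # 1-based incl. header
        raise ValueError(
            f"{path}: non-numeric sumenergy at row {row}: "
            f"{df['sumenergy'][scores.isna()].iloc[0]!r}"
        )
    df = df.assign(sumenergy=scores)
    if (df["sumenergy"] <= 0).any():
        raise ValueError(f"{path}: sumenergy values must be > 0")
    df = (
        df.groupby(["lncrna_id", "mrna_id"], sort=False, as_index=False)["sumenergy"]
        .max()
    )
    return df[required].reset_index(drop=True)


def write_interactions(table: pd.DataFrame, path: PathLike) -> None:
    table[["lncrna_id", "mrna_id", "sumenergy"]].to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def validate_inputs(
    gtf: PathLike, expression: PathLike, samples: PathLike,
    interactions: PathLike | None = None,
) -> list[str]:
    """Validate a full input set; return a list of problems (empty = valid)."""
    problems: list[str] = []
    genes = None
    try:
        genes = read_gtf(gtf)
    except Exception as exc:
        problems.append(f"annotation: {exc}")
    expr = None
    try:
        expr = read_expression(expression, samples)
    except Exception as exc:
        problems.append(f"expression/samples: {exc}")
    if genes is not None and expr is not None:
        shared = set(g.gene_id for g in genes) & set(expr.gene_ids)
        if not shared:
            problems.append("no gene ids shared between annotation and matrix")
    if interactions is not None:
        try:
            read_interactions(interactions)
        except Exception as exc:
            problems.append(f"interactions: {exc}")
    return problems
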