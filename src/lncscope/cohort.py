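"""Clinical-cohort summaries.

Summarizes a retinoblastoma-style sample sheet: tumor/control counts, sex
split, invasiveness split, and mean age at enucleation of the tumor samples.
A transcription of the study cohort (7 tumors, 3 retina controls) ships with
the package and is loadable via :func:`load_study_cohort`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

from .io import read_sample_sheet
from .types import TUMOR, CohortSample


@dataclass(frozen=True, slots=True)
class CohortSummary:
    n_tumors: int
    n_controls: int
    n_male: int
    n_female: int
    n_invasive: int
    n_noninvasive: int
    mean_age_months: float

    def format_age(self) -> str:
        """Render the mean age as ``"Y years M months"``."""
        years, months = divmod(round(self.mean_age_months), 12)
        return f"{years} years {months} months"


def summarize_cohort(samples: Sequence[CohortSample]) -> CohortSummary:
    """Counts by sex and invasiveness plus mean tumor age in months.

    The mean is taken over tumor samples with a known age; unknown sex is
    excluded from the sex counts (controls typically carry no demographics).
    """
    if not samples:
        raise ValueError("empty sample collection")
    tumors = [s for s in samples if s.group == TUMOR]
    if not tumors:
        raise ValueError("no tumor samples in cohort")
    ages = [s.age_months for s in tumors if s.age_months is not None]
    if not ages:
        raise ValueError("no tumor sample has a known age")
    return CohortSummary(
        n_tumors=len(tumors),
        n_controls=len(samples) - len(tumors),
        n_male=sum(s.sex == "male" for s in tumors),
        n_female=sum(s.sex == "female" for s in tumors),
        n_invasive=sum(s.invasiveness == "invasive" for s in tumors),
        n_noninvasive=sum(s.invasiveness == "non-invasive" for s in tumors),
        mean_age_months=sum(ages) / len(ages),
    )


def load_study_cohort() -> list[CohortSample]:
    """The packaged retinoblastoma cohort sheet: 7 tumors, 3 retina controls."""
    ref = resources.files("lncscope.data").joinpath("clinical_cohort.tsv")
    with resources.as_file(ref) as path:
        return read_sample_sheet(path)
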