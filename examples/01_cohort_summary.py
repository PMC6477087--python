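"""Summarize the packaged clinical table of the tumor cohort.

Seven retinoblastoma tumors and three normal retina controls; the summary
reports the sex and invasiveness splits and the mean age at enucleation.
"""

from lncscope.cohort import load_study_cohort, summarize_cohort

samples = load_study_cohort()
summary = summarize_cohort(samples)

print(f"tumors: {summary.n_tumors}, controls: {summary.n_controls}")
print(f"sex split: {summary.n_male} male / {summary.n_female} female")
print(
    f"invasiveness: {summary.n_invasive} invasive / "
    f"{summary.n_noninvasive} non-invasive"
)
print(
    f"mean tumor age: {summary.mean_age_months} months "
    f"({summary.format_age()})"
)
# The mean age is computed over the seven tumor samples only; control
# retina donors carry no tumor demographics.
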