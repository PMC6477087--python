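# lncscope

Tumor-vs-normal transcriptional profiling of coding and long non-coding
RNAs (lncRNAs), built for small bulk RNA-seq cohorts of the kind produced
by pediatric tumor studies — the motivating design is a retinoblastoma
cohort of 7 tumors and 3 normal retina controls. The package starts from a
gene-level FPKM matrix (read-level processing is upstream, out of scope)
and answers three questions about deregulated lncRNAs: which genes change,
which lncRNAs plausibly act *in cis* on their genomic neighbors, and which
plausibly act *in trans* through predicted RNA–RNA interactions.

## The analysis

**Differential expression.** For each gene, the tumor/control contrast is
log2FC = log2((mean tumor FPKM + 1) / (mean control FPKM + 1)) with a
two-sided Welch *t*-test on log2(FPKM + 1). A gene is called deregulated
when |log2FC| > 1 and *p* < 0.05 (both strict); Benjamini–Hochberg
*q*-values are reported but do not gate the call.

**Correlation network.** Pearson *r* between each top deregulated lncRNA
and each significant mRNA, across all samples on log2(FPKM + 1). Edges with
*r* > 0.3 or *r* < −0.3 are retained; lncRNAs are ranked by Σ|r| over their
retained edges and the top 10 selected.

**Cis classification.** Each lncRNA is binned by the gap between gene
bodies to its nearest gene of any biotype: *overlap* (intersecting),
*adjoining* (≤ 5 kb), *proximal* (≤ 10 kb), *others* (> 10 kb). Significant
lncRNAs are paired with significant protein-coding neighbors inside the
first three bins and labeled concordant or anti-correlated by direction.

**Trans targets.** From a table of (lncRNA, mRNA, SUMENERGY) RNA–RNA
interaction scores: retain lncRNAs with SUMENERGY > 2000 for ≥ 10 targets,
keep substrates with SUMENERGY > 1500, drop mRNAs predicted under > 4
lncRNAs (taken as false positives), then stratify surviving targets into
volcano quadrants (> 2-fold up/down × *p* < 0.05) and emit per-quadrant
gene lists ready for external enrichment tools.

A synthetic cohort generator (`lncscope.synthetic`) produces annotation,
expression, sample-sheet and interaction fixtures with planted DE effects,
cis-coupled pairs at controlled genomic gaps, latent-factor trans blocks
with calibrated Pearson *r*, and interaction tables with true targets,
background and promiscuous mRNAs — so the whole pipeline is testable
without any download.

## Worked example

`examples/` contains one short script per capability. The full run:

```sh
python examples/06_full_pipeline.py
```

writes the default synthetic cohort and runs every stage, printing (seed 7):

```
"cohort":      {"n_tumors": 7, "n_controls": 3, "n_male": 4, "n_female": 3,
                "n_invasive": 3, "n_noninvasive": 4, "mean_age_months": 32.0}
"de":          {"n_tested": 200, "n_up_coding": 18, "n_down_coding": 5,
                "n_up_lncrna": 4, "n_down_lncrna": 3}
"correlation": {"n_edges": 161, "n_retained": 161, "top_lncrnas": [...]}
"cis":         {"n_pairs": 4, "pairs_per_class": {"overlap": 1,
                "adjoining": 2, "proximal": 1, "others": 0}}
"trans":       {"n_retained_lncrnas": 1, ... "sig_up": 12 ...}
```

Reading the numbers: the cohort block summarizes the clinical sheet (mean
tumor age 32 months = 2 years 8 months); the DE block recovers the planted
up/down effects among 200 genes; the cis block finds the planted
lncRNA/neighbor pairs in the overlap/adjoining/proximal bins while the
pair planted at 10,050 bp is correctly excluded; the trans block retains
exactly the one lncRNA with ≥ 10 strong interaction scores and places its
12 true targets in the significant-up volcano quadrant.

The same stages are available as a CLI (`lncscope demo`, `lncscope run
--config run.yaml`, plus `de` / `corr` / `cis` / `trans` / `cohort-summary`
/ `validate-inputs` subcommands) for shell use.

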