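# Methods

## Scope and data model

The pipeline operates on four inputs: a GTF 2.2 gene annotation, a
gene × sample FPKM-like expression matrix (TSV), a clinical sample sheet
distinguishing tumor from control, and optionally a table of RNA–RNA
interaction scores (lncRNA, mRNA, SUMENERGY). Read-level processing (QC,
alignment, FPKM estimation), fusion discovery and gene-ontology enrichment
are deliberately upstream/downstream of this package: it consumes a
gene-level matrix and emits gene lists ready for external enrichment.

Coordinates are 0-based half-open internally and 1-based inclusive on disk
(GTF convention); the conversion is exercised both ways in the tests. A
gene's interval is the envelope (min start, max end) over all its GTF
features — the analysis classifies at gene level, and the envelope is the
weakest assumption that yields one interval per gene. Biotypes are mapped
from `gene_biotype` with an Ensembl-75-era lncRNA vocabulary (`lincRNA`,
`antisense`, `processed_transcript`, `sense_intronic`,
`sense_overlapping`, `3prime_overlapping_ncrna`, plus the modern `lncRNA`
label); `protein_coding` maps to coding and everything else to other.

## Differential expression

Two-group contrast on log2(FPKM + 1): Welch's unequal-variance *t*-test,
two-sided. At the motivating design (7 tumors vs 3 controls) a
count-model with dispersion shrinkage would be preferable on raw counts,
but the pipeline starts from FPKM-like continuous values; Welch on the log
scale is defensible there, fully specifiable, and testable against the
textbook formula. The effect size is
log2((mean tumor FPKM + c)/(mean control FPKM + c)) with pseudocount
c = 1.0 on the FPKM scale (avoids −∞ on zero rows; in the c → 0 limit the
statistic is exactly scale-invariant). The call is strict:
|log2FC| > 1 **and** raw *p* < 0.05. Benjamini–Hochberg *q*-values
(statsmodels) are attached for the user but do not gate the flag, because
the calling rule is defined on raw *p*.

Degenerate inputs: genes constant in both groups with equal means get
*p* = 1; constant groups with unequal means get a variance floor
(ε = 1e−8 on the log2 scale) so the statistic stays finite; all-zero genes
are reported non-significant with *p* = 1 and log2FC = 0.

Ranking for "top deregulated" lists: significant genes of the requested
biotype by |log2FC| descending, ties by smaller *p*, then lexicographic
gene id — fully deterministic.

## Correlation network

Pearson *r* between lncRNA/mRNA pairs on log2(FPKM + 1) across **all**
samples jointly (tumor + control): per-group correlation at n = 7 or 3
would be unstable, and the joint correlation is what links expression
change to expression change. A `within_group` option restricts to one
group for users who want it. Retention is strict: *r* > 0.3 or *r* < −0.3;
|r| exactly 0.3 is dropped. Pairs where either gene is constant have no
defined correlation and are dropped with a log message rather than
imputed. The per-lncRNA summary reports the mean retained positive *r*,
mean retained negative *r* (absent when no such edges), and Σ|r| over
retained edges. "Sum of correlations" is taken as Σ|r| rather than the
signed sum, because positive and negative regulation would otherwise
cancel; ranking ties break by retained-edge count, then gene id. Default
list sizes: up to 400 top deregulated lncRNAs against all significant
mRNAs, both configurable.

## Cis classification

The distance measure is the gap between gene bodies (closest interval
boundaries), strand-agnostic. TSS-anchored distances are a plausible
alternative; gene-body gap is the weakest assumption and the thresholds
are exposed (`adjoining`, `proximal`) so anchor variants can be emulated.
Bins: overlap (intervals intersect, gap 0), adjoining (0 < gap ≤ 5000),
proximal (5000 < gap ≤ 10000), others (> 10000) — "within" read as
inclusive on the near side, "others" strictly beyond 10 kb. In the
half-open convention two exactly touching intervals have a zero-base gap
and classify as overlap; the generator never produces that degenerate
layout, and the boundary tests pin the behavior.

Candidates for classification are **all** genes irrespective of biotype;
candidates for pairing are significant protein-coding genes only. Each
significant lncRNA pairs with every qualifying neighbor within the
proximal bin; the nearest is flagged primary, and concordance labels the
pair concordant (same DE direction) or anti-correlated. The vectorized
classifier (`classify_all`) is tested for exact agreement with an
all-pairs brute-force scan.

## Trans-target filter chain

Order matters and is fixed: (1) retain lncRNAs with SUMENERGY strictly
above 2000 for at least 10 targets; (2) keep rows of retained lncRNAs with
SUMENERGY strictly above 1500; (3) drop mRNAs predicted under strictly
more than 4 **retained** lncRNAs. Counting promiscuity after retention is
deliberate — the exclusion is defined within the filtered analysis — and
the test suite carries a counterexample showing that reordering changes
the result. SUMENERGY values are treated as opaque positive reals; the
package does not compute duplex energies. Surviving targets of lncRNAs
deregulated in the requested direction are stratified by linear fold
change 2^log2FC: sig_up (> 2-fold, *p* < 0.05), ns_up (> 2-fold,
*p* ≥ 0.05), sig_down (< 0.5-fold, *p* < 0.05), ns_down, else unchanged;
exactly 2-fold is unchanged (strict reading throughout). The significance
gate for the quadrants is *p* < 0.05, exposed as a parameter.

## Synthetic cohort generator

The generator emulates the study conditions, not a dial to tune: defaults
are 7 tumors vs 3 controls, log2-scale Gaussian noise SD 0.5 around a
baseline log2 mean of 4 (≈ 16 FPKM), 150 mRNAs + 50 lncRNAs on one
chromosome. Expression is log-normal on the FPKM scale — the analysis
consumes FPKM-like continuous values, so count-level (negative-binomial)
realism is unnecessary. Per gene g and sample s:

    log2 x[g,s] = baseline + effect_g·1[s ∈ tumor] + Σ_k λ_k·f_k[s] + σ·ε[g,s]

Planted DE effects shift tumor samples only. Correlation structure comes
from per-sample standard-normal latent factors shared by block members
with loading λ = σ·sqrt(|r|/(1−|r|)), which makes the expected pairwise
Pearson *r* of two single-block members equal the signed target r
(analytically invertible, hence testable: calibration over 200 replicates
at n = 20 holds the mean sample r within ±0.05 of targets 0.3/0.6/0.9).
Genes in several blocks accumulate contributions, which attenuates each
pairwise r — the calibration experiments use single-membership genes.
Noise SD 0.5 is a modeling choice (per-gene dispersions are not available
for the motivating data); at σ = 0 genes are constant within groups and
correlations are undefined, which the code reports rather than fabricates.

Annotation layout places unpaired genes 50 kb apart (so their default
distance class is others) and relocates each cis-paired lncRNA next to its
partner at the configured gap; gap 0 nests the lncRNA inside the partner.
Determinism: every random stream is derived from (seed, stream-kind,
index), so identical configs are bit-identical and adding genes does not
reshuffle existing ones.

The interaction-table generator draws true-target SUMENERGY uniformly in
(2000, 4000], background in (0, 1500], and gives each promiscuous mRNA
scores in (1500, 4000] under exactly 5 distinct lncRNAs so the > 4
exclusion fires.

What the generator does **not** emulate: library-size and gene-length
biases, count discreteness and overdispersion, batch effects, correlated
background co-expression, and annotation complexity (isoforms, nested
genes). Passing recovery tests therefore demonstrates that the pipeline's
logic is correct under its stated model, not that the thresholds are
optimal for any real cohort.

## Experiment sizes

The seeded experiments behind `scripts/acceptance.py` and the acceptance
tests use: planted-DE recovery over 10 replicates × 50 planted genes
(effect 2.0, σ 0.5, 7 vs 3); null false-positive rate over 100 replicate
200-gene cohorts; cis-class recovery over 5 noise-free replicates of the
six-gap ladder {0, 100, 4999, 5001, 9999, 10050}; trans-driver top-10
ranking over 100 replicates at r = 0.8, n = 20 (30 lncRNAs × 40 mRNAs);
correlation calibration over 200 replicates per target r. These sizes give
stable rates while keeping a full run under ten seconds on one CPU.

## Known limitations

- The two-group test is not a count model; genes with FPKM near zero in
  one group can show large fold changes driven by the pseudocount.
- Correlation across tumor + control jointly conflates group-mean shifts
  with within-group co-variation; that is the intended reading of the
  network stage, but users comparing regimes should use `within_group`.
- The cis classifier is strand-agnostic and does not special-case
  antisense overlap beyond the biotype label.
- Interaction scores are taken at face value; no sequence-based energy
  computation or database access is performed.
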