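# Methods

This note documents the statistical models behind `epimr`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions.

## Study design the package assumes

Two cell populations are compared: an *origin* condition (tumour-initiating
cells, e.g. Ink4a/Arf-null astrocytes overexpressing EGFRvIII) and a
*tumour* condition (glioma-propagating cells derived from the resulting
primary tumours), with biological replicates on both sides (default 3 vs 3).
For each population the inputs are raw RNA-seq gene counts, per-sample
H3K27me3 coverage tracks plus a control (total H3 or input) track, gene
annotation with TSS and strand, and promoter sequences. The integration
asks which transcription factor can account for the transition: motif
enriched in DEG promoters, itself repressed, and de novo H3K27me3-marked.

## Differential expression

Counts are modelled per gene as negative binomial, Var = μ + αμ².
Normalization uses the plain median-of-ratios estimator referenced to the
per-gene geometric mean (genes with a zero in any sample are excluded from
the reference set; all-zero genes are dropped from normalization and
reported as NS with p = 1).

The dispersion α is estimated by pooled within-group method of moments,
clipped to [1e-8, 10], then shrunk in log space with weight 0.5 toward a
parametric trend α(μ) = a₁/μ + a₀ fitted across genes by least squares.
The contrast is a Wald statistic on log₂((μ_t + ½)/(μ_o + ½)) with the
delta-method standard error SE² = [(1/μ_o + α)/n_o + (1/μ_t + α)/n_t]/ln²2.
Because the trend shrinkage contributes roughly one residual-degree-of-
freedom's worth of prior information per gene, the statistic is referred to
a t distribution with 2·(n_o + n_t − 2) degrees of freedom rather than the
normal; at the default 3 vs 3 this brings the raw type-I error to the
nominal 5% level (the pure normal reference is anti-conservative at this
sample size, and the unmoderated t at 4 df over-corrects). Multiplicity is
controlled by Benjamini–Hochberg; a gene is UP/DOWN when q ≤ α and
|log₂FC| ≥ `lfc_min` (default 0 — no fold-change cutoff).

This engine is deliberately a transparent, self-contained estimator rather
than a wrapper around an external DE tool, so that every quantity it
produces has a computable oracle.

## H3K27me3 TSS windows and target calling

Coverage is averaged into 100-bp bins over a 6-kb window centred on the
TSS (3 kb upstream, 3 kb downstream). Intervals are 0-based half-open; the
TSS of a minus-strand gene is `end − 1`, and bin order is reversed for
minus-strand genes exactly once, so negative bins are always biologically
upstream. Bins that fall off the chromosome are NaN and are excluded from
all means.

A gene is a target in a sample when its summed window signal exceeds the
control expectation. The test is the one-sided Poisson rate comparison in
its exact conditional form: given the rounded window sums S (signal) and C
(control), S | S+C ~ Binomial(S+C, L_s/(L_s+L_c)) under the null of equal
per-read window propensity, where L are total library sizes. The
conditional form is used because the control window count is itself noisy;
plugging it in as a fixed Poisson mean would roughly double the null
variance left unaccounted for and inflate the false-positive rate. BH is
applied across genes; the whole-window sum (rather than a per-bin maximum)
is the default statistic because H3K27me3 forms broad domains; a per-bin
mode is available behind the `per_bin` flag. Control scaling uses total
library size only — windows are 6 kb, too small for local background
estimation to help.

*De novo* targets are genes called in **every** tumour sample and in **no**
origin sample (intersection-minus-union). This is the strictest reading of
"consistently acquired"; it makes the set monotone non-increasing as
tumour samples are added.

Called targets are classified by the flank asymmetry U/D, where U and D
are mean densities over the upstream and downstream window halves:
|log₂(U/D)| ≥ 1 assigns UP or DOWN by sign, otherwise the profile counts
as TSS-centred. The 2-fold threshold is the minimal interpretable
asymmetry (no published value exists for it) and is configurable. The
expression consequence of the classes is assessed with two-sided
Mann–Whitney tests — exact null when both classes have ≤ 12 members and no
ties, normal approximation with tie correction otherwise.

## Promoter motif enrichment

PFMs are parsed from JASPAR text format; frequencies add a pseudocount of
0.01 per cell and renormalize per column. Scores are log-odds against a
uniform background (configurable composition); the best site score of a
promoter is the maximum over all offsets and both strands, min–max
normalized to [0, 1] by the per-column extremes, so a consensus match is
exactly 1. Offsets containing non-ACGT letters are skipped.

Enrichment follows the Pscan convention: the background promoter
population is treated as the *population*, so for each motif
z = (mean_fg − mean_bg)/(sd_bg/√n_fg) with a one-sided upper-tail p and
Bonferroni correction over motifs. A Welch two-sample variant is not the
default because the foreground is a subset of the population, not an
independent sample. The default promoter window when extracting promoters
from coordinates is −450..+50 around the TSS; the synthetic generator uses
500-bp promoters.

## Master-regulator shortlist

Motif-enriched TFs (Bonferroni p < α) are mapped to their own genes via a
user-supplied two-column table (no fuzzy matching), sorted by DE q-value
then |log₂FC| then gene id, annotated MARKED/UNMARKED by de novo
membership of their own gene, and shortlisted iff enriched AND direction
DOWN at q < α AND MARKED. Overlap statistics (ORA against GMT sets, pairwise
set overlaps) use the exact hypergeometric upper tail; the universe is the
set of genes present in both annotation and expression matrix. BH is used
across gene sets in ORA; Bonferroni is retained only for motifs.

## GSEA, co-expression, retention

GSEA uses the weighted Kolmogorov–Smirnov running sum: hits increment
proportionally to |score|^w (w = 1 default; normalized to total 1 over set
members), misses decrement 1/(N − |S|); the enrichment score is the signed
maximum deviation. The null permutes set-membership labels over the ranked
list — with 3-replicate designs, sample permutation is impossible — and the
nominal p uses the +1 correction, so p ∈ (0, 1] and is bit-reproducible
given (n_perm, seed).

Co-expression neighborhoods keep genes with |Pearson r| ≥ 0.5 against the
focal gene across the compendium profiles (or top-k by |r|); 0.5 is the
operationalization of "high confidence" and is exposed. Cluster retention
in a matched tumour counts a gene as retained when it lies on the same
side of the expression-distribution quantile threshold (default: median)
in batch and tumour; the null redraws size-matched random gene sets, giving
a z-score and a +1-corrected empirical p.

## Survival

Strata come from fold change against the cohort median expression: HIGH if
fc > 2, LOW if fc < 0.5, MID otherwise, with strict inequalities (boundary
values are MID). The LOW threshold mirrors the HIGH one; a single cutoff
cannot produce three groups, so the mirrored pair is the coherent reading
of the high/low convention, and both thresholds are parameters. The
Kaplan–Meier estimator uses the standard simultaneous-risk-set convention
for ties, censoring ties breaking after events at the same time; with no
events a flat S ≡ 1 curve is returned with a warning. The log-rank test is
the k-group Mantel–Cox form: summed observed-minus-expected event vectors
against their hypergeometric covariance, χ² with k − 1 df. It matches
lifelines to machine precision on random cohorts (checked in the suite).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical *shape* of the study inputs with
known ground truth:

- counts: NB(mean = baseline·2^lfc·group, α), baselines log-normal
  (log-mean log 100, log-sd 1), dispersion 0.05, planted |log₂FC| = 2 on
  100 genes per direction of 1,000 — effect sizes at which a 3 vs 3 design
  has high but not saturated power;
- ChIP: independent Poisson per bin, background 10 reads/bin, enrichment
  factor 8 in marked bins; class layouts UP (upstream half), DOWN
  (downstream half), TSS (both flanks with the two central bins at
  background — the sharp central dip); control is pure background. The
  background model of the real tracks is not published; Poisson is our
  choice and window sums inherit its variance;
- promoters: i.i.d. uniform ACGT (configurable), planted sites drawn
  exactly from the PWM's count distribution at non-overlapping offsets, in
  70% of planted-DEG promoters for the master regulator's motif;
- the planted master regulator is repressed (lfc −2), de novo marked
  (class TSS), and its PWM maps to its own gene; 49 decoy PWMs with no
  planted sites map to non-DEG genes;
- survival: exponential event times per group (one parameter, closed-form
  oracles), exponential censoring tuned to the requested censoring
  probability, expression bands that reproduce the intended strata;
- compendium: one latent factor with loading √0.9 for module genes across
  106 profiles.

One global seed determines everything through fixed-order sub-seeding, so
partial re-runs are reproducible. Not emulated: read-level sequencing,
fragment-size effects, GC bias, diploid genomes, batch effects beyond
group labels, dinucleotide promoter composition, and tied survival times.
Consequently, passing tests demonstrate the correctness and calibration of
the statistical machinery under the stated models — not robustness to
artefacts real libraries can contain.

## Numerical conventions and problem sizes

Degenerate inputs fail loudly: empty designs, negative dispersion,
non-dividing bin sizes, zero-signal controls, constant focal genes, empty
clusters, zero medians, single groups. Ties are broken deterministically
(regulator ranking: q, then |log₂FC|, then gene id; KM: events before
censorings). All Monte-Carlo operations take explicit seeds. The test
suite and acceptance script use 1,000-gene bundles with 20 (tests) or 10
(script) seeds for end-to-end recovery, 500-replicate null batteries for
caller calibration, and 100–1,000 simulations for survival power and
calibration — sizes chosen so the planted effects sit comfortably above
their detection thresholds while the full battery stays fast on a single
CPU.

## Known limitations

- The DE engine is a transparent stand-in for heavier tooling; exact
  replication of counts produced by other pipelines is not a goal.
- The per-sample target-calling statistic (window-sum Poisson/binomial) is
  a deliberate simplification; no peak-shape or broad-domain segmentation
  is attempted.
- The retention statistic and the promoter-window convention are package
  choices where no public specification exists; both are parameters.
- Motif enrichment assumes promoters of equal information content; no
  GC/dinucleotide background correction is applied.
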