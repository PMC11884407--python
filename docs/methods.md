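# Methods

`suppressor-screen` implements a multi-omics screening procedure for
tumor-secreted factors that suppress lymphocyte cytotoxicity in the tumor
microenvironment (TME). The motivating application is neuroblastoma, where
tumor-secreted MIF and MDK blunt NK/T-cell killing and limit CAR T-cell
efficacy, but every stage is generic over the inputs. This note describes
the model behind each stage, the knobs that matter, what the synthetic
benchmark does and does not emulate, and the numerical choices that were
genuinely open.

## 1. Cytotoxicity scoring

Counts are depth-normalized per cell to a fixed target sum (default 10,000)
and log1p-transformed. The cytotoxicity score of a cell is a bin-matched
control module score over seven effector genes

    NKG7, CCL5, CST7, PRF1, GZMA, GZMB, IFNG:

genes are ranked by mean log-normalized expression and cut into `n_bins`
(default 25) equal-size quantile bins; for each score gene, `n_ctrl`
(default 100) control genes are sampled (seeded, without replacement up to
bin size) from the same bin; the score is the mean over score genes minus
the mean over all sampled controls. Subtracting bin-matched controls cancels
per-cell depth/complexity, so the score is invariant to adding a constant to
every gene. Per-(tumor, subset) scores are plain means over cells; groups
with fewer than `min_cells` (default 5) cells are emitted as missing and
excluded from downstream correlations — cross-tumor correlations over
smaller groups are dominated by sampling noise.

The exact scoring variant and normalization were open choices; the
binned-control construction with 25 bins / 100 controls is the de-facto
standard parameterization of this score family, and everything is exposed in
the run configuration.

## 2. Ligand–receptor interaction inference

For each (ligand, receptor-complex) channel between a sender and a receiver
subset, ensemble expression is the 10%-trimmed mean of log-normalized
expression over the subset's cells; receptor complexes take the geometric
mean over subunits, zero if any subunit is zero. Communication probability
is the saturating mass-action form

    P = (L·R)^n / (Kh^n + (L·R)^n),  default n = 1, Kh = 0.5,

on log-normalized ensemble values. Significance comes from a permutation
null: subset labels are shuffled over all cells (by default globally,
ignoring tumor structure; `--stratified-null` permutes within tumor for
users who want exchangeability by sample), the probability is recomputed for
each of `n_perm` (default 100) permutations, and

    p = (1 + #{null ≥ observed}) / (1 + n_perm),

so p is never exactly zero. Design choices made here, all in config: a
symmetric trimmed mean rather than a trimean for the ensemble; no
agonist/antagonist/cofactor terms; one shared permutation set per batch call
(each channel still gets an exact add-one p).

## 3. The suppression screen

For every tested (ligand, sender subset, receiver subset) channel, the
ligand's per-tumor mean expression in sender cells is correlated across
tumors (Pearson by default — the conventional reading of "r" — Spearman via
config) with the receiver subset's per-tumor mean cytotoxicity score. The
correlations are computed over tumor means, not cells: with ~24 tumors,
tumor-level aggregation is the only interpretation under which the screen's
sample size matches the design. A channel survives iff

    r < 0 and p_r < alpha   AND   p_interaction < alpha,    alpha = 0.05.

No multiple-testing correction is applied inside the screen — the raw-alpha
overlay is the procedure's operating point (an optional Benjamini–Hochberg
flag exists, off by default); correction appears only in the survival
validation. Surviving channels are grouped per (ligand, sender); the
candidate is *selected* when the sum of its r values over the three receiver
subsets (NK, CD8T, gdT; undefined or missing r contributes 0) is negative.
One significant channel is enough for inclusion; the negative sum requires
the overall association across receivers to be suppressive. Candidates are
annotated — never filtered — with membership in a user-supplied
secreted-protein list, matched case-sensitively (a case-insensitive-only
match warns instead of silently failing).

Constant expression vectors produce a record with undefined r and
`passes_correlation = False` rather than an exception, so one degenerate
gene cannot abort a screen.

## 4. Bulk-cohort validation

Bulk expression is linear scale (RPM-like) on read; transforms happen inside
operations. The bulk cytotoxicity score is the mean over the seven score
genes of per-gene z-scored log2(1+expression) — binned controls are
undefined for a 7-gene signature on bulk profiles, so the z-mean
construction is the documented divergence from the single-cell score. A
candidate *replicates* when Pearson r between log2(1+expression) and the
bulk score is negative with p < alpha in every cohort where the gene is
present, with at least two cohorts contributing.

The Kaplan–Meier estimator and the Mantel–Cox log-rank test are implemented
from scratch (they are the statistical core of the cut-point scan); deaths
are processed before censorings at tied times, and the log-rank variance
term uses the standard hypergeometric form with the n−1 correction. The
cut-point scan tries every observed expression value leaving at least
`ceil(min_group_frac · n)` samples (default 10%) on each side as a "≤ cutoff
vs > cutoff" split, runs the log-rank test at each, takes the cutoff with
the smallest raw p (ties → smaller cutoff), and Bonferroni-corrects by the
number of cutoffs actually tried. Splits depend only on expression ranks, so
the corrected p is invariant under strictly monotone transforms. The worse-
survival direction is reported (observed vs expected events in the high
group) but not used for selection; `--require-direction` is available.

The scan-recovery benchmark judges success by split agreement: the chosen
dichotomy must agree with the two planted populations for ≥ 90% of samples.
A minimum-p scan legitimately shifts its optimum by a few patients around
the planted boundary even when the association is overwhelming, so strict
membership of the cutoff in the empirical expression gap is not a meaningful
recovery criterion.

## 5. Secretome ranking

iBAQ is the protein's non-normalized intensity divided by its number of
measurable peptides (taken from the input table — in-silico digestion is out
of scope), a proxy for molar abundance. Proteins are ranked per sample by
descending iBAQ with deterministic lexicographic tie-breaks; a gene takes
its best protein rank. Detection means a row with iBAQ > 0. Top-k (default
k = 100) membership, consensus across samples (in the top k of every sample
and detected in all), and the worst (maximum) percentile across samples are
reported; the max-over-samples convention makes a "top X%" statement hold in
every sample where the gene was detected.

## 6. The synthetic benchmark

The generator plants known structure so every stage is testable by recovery
without any external data.

**Single-cell cohorts.** Default: 24 tumors × 200 cells (tumor 60, NK 40,
CD8T 40, γδ-T 30, myeloid 30), 300 genes, negative-binomial counts
(dispersion θ = 10, variance μ + μ²/θ) with log-normal library-size factors
(σ = 0.3). Each tumor carries a latent suppression level u_t ~ Uniform(0,1).
With z_t the sample-standardized u_t, cytotoxicity-gene means in receiver
cells scale by exp(−0.6·z_t) and the planted suppressor ligand's mean in its
sender cells by exp(0.5·l_t), where l_t has exact sample correlation
ρ = |effect_r| with z_t (Gram–Schmidt construction). The exact-sample-
correlation construction is the calibration: the expected sample correlation
of an i.i.d. bivariate draw is below ρ at n = 24, which would consume most
of the calibration budget before any measurement noise. Realized cross-tumor
correlations between sender ligand expression and receiver cytotoxicity
score land within a few hundredths of effect_r (mean ≈ −0.765 at −0.8 over
200 replicates; the residual attenuation is measurement noise in per-tumor
means).

Null ligands and all receptors are expressed uniformly across subsets,
independent of u_t; planted suppressors are strongly sender-enriched. The
expected per-subset library mass is equalized by rescaling filler genes —
otherwise depth normalization couples every gene to the subset-specific
cytotoxicity/ligand mass and null ligands would not be exchangeable under
the label-permutation null. With this construction, null-channel permutation
p-values are uniform (KS ≈ 0.05 against Uniform(0,1) over independent
datasets). Note that channels measured on the *same* cohort share cells and
are correlated; calibration checks therefore pool channels from several
independent cohorts.

Not emulated, deliberately: doublets, ambient RNA, batch effects, realistic
transcriptome-wide co-expression, cell-type-specific library-size
differences. A passing recovery benchmark therefore shows the procedure
works when its assumptions hold at realistic noise levels, not that real
tissue artifacts cannot break it.

**Bulk cohorts.** A per-sample latent infiltration level drives the seven
score genes up (log2 signal 1.0, gene noise 0.5) and each planted suppressor
down at its effect_r; all other genes are independent log-normals. Event
times are exponential with log-hazard log(h0) + Σ log(HR_g)·z_g over planted
survival genes (default h0 = 0.1, suppressor HR = 2 per unit z of
log2(1+expression)); censoring is an independent exponential tuned so the
expected censored fraction equals `censoring_rate` (default 0.3) in the
covariate-free case. Default sizes 498 and 122 samples mirror large public
neuroblastoma cohorts.

**Secretome.** Log-normal background intensities (log-mean 15, log-sd 2),
uniform integer peptide counts in [5, 50]. Planted genes are placed at an
empirical quantile u ~ Uniform(0.91, 0.999) of the per-sample background
iBAQ distribution and their intensity back-derived as iBAQ × n_peptides:
planting on the iBAQ scale (the scale on which ranks are computed) is what
guarantees the planted gene sits in the top decile of every sample; the
0.91 inset keeps it there after the planted rows themselves join the table.

**Seeding.** All randomness descends from one integer master seed through
`numpy.random.SeedSequence.spawn` in a fixed documented order (one child
stream per independent noise source), so identical parameters and seed
reproduce every table bit for bit.

## 7. Benchmark problem sizes

The recovery and calibration benchmarks run at the study's default
conditions: 100 seeds for the full-screen recovery sweep (24 tumors, 1
suppressor at effect_r = −0.8, 20 null ligands, 100 permutations), 210
null channels at 199 permutations for p-value calibration, 50 random
fixtures for the survival oracles, 100/500 seeds for the cut-point scan
power/null characteristics, and two bulk cohorts of 200 samples × 520 genes
for the replication null. These sizes give binomial standard errors well
inside the tolerances they are checked against.

## 8. Known limitations

- The interaction model is the minimal mass-action core of cell–cell
  communication inference: no cofactors, no pathway aggregation, no
  agonist/antagonist modulation.
- The global permutation null ignores tumor structure (as is conventional);
  the stratified option is provided but is not the default.
- The cut-point scan's Bonferroni correction multiplies by the number of
  cutoffs scanned per gene; it does not correct across genes.
- Cross-tumor correlations at n ≈ 24 have wide confidence intervals; the
  screen's raw-alpha overlay is a discovery filter, not an inference
  procedure, which is why bulk replication and survival validation follow.
- Gene identity is symbol-based and case-sensitive throughout; supply an
  alias map upstream if inputs mix symbol conventions.
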