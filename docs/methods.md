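# Methods

This note documents the models, parameter choices and numerical decisions
behind `somagerm`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Count model and normalization

Counts are treated as negative binomial. The simulator draws gene means from
a log-normal program, scales each cell by a mean-one log-normal library
factor (σ = 0.35), and samples gamma–Poisson with dispersion φ (default 0.4,
so variance m + φm²) — a standard desk-scale emulation of droplet scRNA-seq
overdispersion. It deliberately omits doublets, ambient RNA, batch effects
and cell-cycle structure, so test results bound what the *methods* do under
a well-specified noise model, not how they behave under real-data artifacts.

Normalization is log1p of counts-per-10k with the natural log:
`v = ln(1 + 10⁴·c/total)`. Cells with zero totals are an error rather than
silently dropped. Fold changes for DEG calling are computed on the linear
scale (expm1 of normalized means) with a pseudocount of 1e-9 to keep ratios
finite; the 1.5-fold threshold is applied on that linear ratio.

## Differential expression

Per gene, a two-sided Wilcoxon rank-sum test: exact enumeration (scipy) when
both groups have ≤ 10 cells and the column has no ties, otherwise the
tie-corrected normal approximation with continuity correction; a column with
zero rank variance gets p = 1. A gene is a DEG when raw p < 0.05 **and**
fold change ≥ 1.5 or ≤ 1/1.5; BH-adjusted p-values are reported alongside.
Enrichment is the hypergeometric upper tail (one-sided Fisher) with BH
correction across gene sets, flagged at adjusted p < 0.05.

## Communication probability model

The per-pair probability is a Hill saturation of the ligand × receptor
product with a hyperbolic antagonist factor (see README for the formula).
The constants — K = 0.5, n = 1, K_ant = 0.5, expression summary = mean of
log-normalized values thresholded at a 10% expressed fraction — are declared
model choices of this package, kept deliberately simple so that every
expected value in the tests is analytic (closed-form probabilities,
monotonicity in each argument, exact limits). Receptor multimers are
summarized by the geometric mean, so any missing subunit zeroes the
receptor. The antagonist level is the mean over sender and receiver types:
antagonism is modeled as short-range sequestration of the ligand near the
signaling interface, with no spatial or diffusion modeling.

Significance uses a global cell-type label permutation with the add-one
estimator p = (1 + #{P_perm ≥ P_obs})/(1 + n_perm), n_perm = 100 by default
(minimum 20), fixed seed. The estimator is bounded below by 1/(1+n_perm) and
never exactly zero. Calibration is checked on a null simulation in which
labels carry no expression signal: the pooled fraction of p-values below
0.05 sits at 10/201 ≈ 0.05 by construction of the discrete estimator.
"Significant" always means p below the threshold **and** P > 0. Pathway and
aggregate levels sum only significant pair probabilities, so the pathway
matrices partition the aggregate strength exactly, and outgoing/incoming
profiles are exact marginals.

## Sex-identity scoring and the toward-female trend

Pseudobulk profiles are arithmetic means of normalized values per group.
Identity scores are Pearson correlations against male and female reference
profiles, restricted to genes whose mean reference expression exceeds a 0.1
detection floor (at least 10 genes required); no further standardization is
applied. The toward-female classification of a DEG is a pure sign test:
toward_female iff sign(mutant − WT change) equals sign(female − WT reference
difference), with zero reference difference classed divergent. Because the
rule is sign-based, the references must share a scale: the pipeline compares
reference *programs* on their common linear scale (per-program re-scaling
would shift genes the programs share), while correlation scores use the
log-normalized transform of the same programs.

## Synthetic study design

Defaults emulate the study the package supports: 8 testis cell types × 150
cells per type per condition per timepoint × 2 conditions (WT, mutant) × 3
timepoints (d3_5, d6_8, d9_11), 2 000 genes — about 30 s end-to-end on one
CPU. The feminizing cell type (CySC) has mutant expected expression
(1−α_t)·male + α_t·female with the non-decreasing schedule α = (0.25, 0.5,
0.75); the biology motivating it gives no quantitative per-age blend, so the
schedule is a simulation knob chosen to produce a clear age gradient, not an
estimate. 30% of genes are sex-biased (≥ 2-fold between programs, half in
each direction), and 10% are mutant-dysregulated independently of sex
(2–6-fold, random direction) — the latter provide the "divergent" arm of the
toward-female dichotomy, yielding an expected toward-female fraction near
600/(600+200) = 75% at full power, mirroring the roughly 3:1 split reported
for feminizing cyst cells.

The default planted circuit is the insulin axis: ligand Dilp6 from hub cells
onto germline InR with additive linear-scale means 2.0 (WT) → 6.0 (mutant),
and the antagonist ImpL2 expressed at 4.0 in WT and absent in the mutant —
circuit genes start from a zero baseline so the planted strengths fully
determine their expression, which keeps expected communication probabilities
analytic. Injection happens on the mean scale before sampling.

Peak fixtures place genes every 10 kb on a toy chromosome, alternate
strands, and plant WT-only promoter peaks (score 8.0, midpoint within 1 kb
of the TSS) over a subset of male-high genes — so the same genes are DEGs in
the feminized type — plus condition-shared decoy peaks (score 5.0).
Replicates are jittered by ≤ 50 bp (default 30).

## Interval and binding-site conventions

All coordinates are 0-based half-open (BED); a 1-bp overlap counts.
Reproducible peaks keep first-replicate coordinates with the mean partner
score. Peak-to-gene distance runs from the peak midpoint to the nearest TSS,
strand-aware with negative = upstream; equidistant ties break to the
lexicographically smaller gene id. Promoter classes are |d| ≤ 1 kb and
≤ 3 kb (inclusive, configurable). Differential binding compares
overlap-matched peak scores at |log2FC| ≥ 1, with presence/absence rules for
condition-exclusive peaks; this explicit score-fold rule is a declared,
deterministic substitute for heavier differential-binding machinery. Direct
targets are the exact intersection of downregulated-binding genes with DEG
genes; modes: binding down + expression down ⇒ activated_by_factor, binding
down + expression up ⇒ repressed_by_factor, anything else unresolved.

## Determinism and seeds

A single pipeline seed fans out to per-stage child seeds via numpy
`SeedSequence(seed, spawn_key=(stage_index,))` (reduced mod 2³¹), so stages
rerun in isolation reproduce their in-pipeline results. All artifacts are
written with fixed float formatting and sorted orders; the run report's
fingerprint is a SHA-256 over every artifact, and reruns with the same
config are byte-identical.

## Known limitations

- The communication model is phenomenological; its constants are not fitted
  to data, and absolute probabilities are only meaningful relative to the
  same parameterization.
- The permutation test shuffles labels globally and therefore tests the
  exchangeability null per (sender, receiver, pair); p-values across pairs
  share permutations and are not independent.
- The toward-female rule is sign-only and ignores effect size; genes with a
  tiny but nonzero reference difference count as fully informative.
- Peak matching is best-overlap and single-partner; complex many-to-many
  peak topologies are resolved greedily.
- The simulator's fidelity limits are listed above; passing tests certify
  correctness of the implementations under the stated models, not
  robustness to real-data artifacts they do not include.
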