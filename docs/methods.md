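# Methods

This note documents the models, estimators, and design choices implemented in
`shortsplice`, and what the synthetic cohort does and does not emulate.

## Retention quantification

The intron retention rate is a percent-spliced-in value with inclusion reads
down-weighted by 0.5, `PSI = 0.5·I/(0.5·I + S)`. The weighting reflects that
a retained intron exposes two informative exon–intron boundaries whereas a
spliced transcript yields a single junction read; an intron with no junction
reads at all is *missing*, not PSI = 0. Quality filters: a sample-level
estimate needs `min_junction_reads` (default 10, inclusive) junction reads;
a (intron, condition, timepoint) triple is kept only when all
`n_replicates` (3) estimates survive and their sample SD is below
`max_replicate_sd` (0.1). The inclusive ≥10 reading is used uniformly for
both the PSI filter and the DSI support gate and is a config knob, since the
two gates are stated once as strict and once as inclusive in the source
protocols this package systematizes.

## Differential splicing

Per timepoint, junction counts are pooled across the three replicates within
each condition, and equality of inclusion proportions is tested with a
two-sided binomial likelihood-ratio test (effective successes = round(0.5·I),
failures = S; G ~ χ²₁). This is a deliberate, desk-scale substitute for
external splicing engines: it is count-aware and closed-form, but it ignores
replicate-level overdispersion. The |ΔPSI| ≥ `min_abs_dpsi` (0.1) gate makes
the caller robust to the resulting anticonservatism at large depth: tiny but
ultra-significant proportion differences are never called. ΔPSI is computed
from the pooled per-condition counts (whether to pool or average replicates
is not specified by the protocols; pooling is the variance-minimizing
choice and is documented here). Sign convention: ΔPSI = symbiotic −
aposymbiotic, so positive means higher retention in symbiotic cells. BH-FDR
runs across all tested introns within a timepoint; the pooled DSI set is the
deduplicated union over timepoints, keeping each intron's largest-|ΔPSI|
record.

## Expression

Normalization is a median-of-ratios scheme: the pseudo-reference profile is
the geometric mean of library-scaled (per-million) sample profiles over genes
with no zero count, and each sample's size factor is the median ratio of its
raw counts to that reference. Building the reference from library-scaled
profiles makes normalization *exactly* invariant to rescaling any single
library while keeping the median's robustness to composition effects;
normalized values are therefore on a counts-per-million-like scale. The DEG
caller is Welch's t on log2(normalized + 1) with |log2FC| ≥ 1, BH-FDR ≤ 0.05,
and an abundance gate (normalized counts > 10 in ≥3 replicates). A
negative-binomial engine is intentionally out of scope — the DEG list is only
an upstream input to the regression screen, and the caller accepts externally
produced DE tables.

## Splicing-factor regression screen

For each (DSI intron, factor gene) pair: OLS of
`PSI_z ~ β₀ + β₁·ln(counts+1)_z + β₂·cell_type` across the 48 replicate
samples, with PSI and log factor expression z-transformed (mean 0, sample SD
1 over non-missing entries; constant vectors are dropped and logged). Pairs
are fitted on complete observations only, minimum 10. The OLS is solved in
closed form (normal equations, t-tests on 45 df) for speed and is verified
against statsmodels in the test-suite. FDR (BH, α = 0.1) is applied to the
β₁ p-value family and the β₂ family separately, each across *all* pairs —
the protocols state a single threshold without a family structure, and one
family per coefficient is the most conservative reading that still uses one
threshold. The confound rule sets β₁ := 0 whenever β₂ is significant; a pair
is *retained* when β₁ is significant and β₂ is not. Factor classification:
mean adjusted β₁ over retained introns; negative = enhancer (more factor →
less retention), positive = repressor. Ranking: retained-pair count, ties by
|mean coefficient| then identifier. Cell type is coded aposymbiotic = 0,
symbiotic = 1. Timepoint is not a covariate (the model has exactly the two
stated regressors).

## Pattern analysis

PCA treats samples (columns of the DSI × sample PSI matrix) as observations
after per-intron centering; no further scaling is applied by default (raw
retention rates, a `zscore_rows` flag exists). k-means runs on per-intron
z-scores with k = 2, 50 seeded restarts, best by within-cluster sum of
squares; cluster 1 is by convention the cluster with the higher mean
symbiotic z-score. Missing matrix cells are row-mean imputed by default in
the pipeline (complete-case is available).

## Intron orthology and age

Gene orthologs: reciprocal best hits by pairwise local alignment (BLOSUM62,
gap open 10, extend 1); ties for best on either side drop the pair. Intron
positions are compared through "junction windows": up to 10 amino acids each
side of the splice junction in the encoded protein, truncated at the termini,
excluded when either side is shorter than `min_window_flank` (default 4)
residues. Windows are aligned globally with the same scoring; identity =
matched columns / all alignment columns including gaps (a conservative
denominator; a gapless mode exists). A window pair is an intron ortholog when
identity ≥ 0.40, the score is mutual-best across species, and the intron
phase (0/1/2) matches — 20-residue windows cannot otherwise distinguish
near-adjacent positions, so phase agreement is required even though the
source protocols do not mention it.

Ages follow Dollo parsimony (a single gain, unlimited losses): for a
reference-species intron, the minimum-loss gain node is exactly the MRCA of
the species carrying it, so the age group is the 1-based index of that MRCA
on the path from the reference leaf to the root (reference-only = 1, root =
maximum; 3 on the default 4-taxon tree). Species whose gene ortholog is
absent are treated as missing data and excluded from the MRCA — absence of
the gene says nothing about the intron. Introns in genes with no orthologs
at all form age group 0; genes with orthologs in fewer than 3 of the 4
examined species are excluded from dating. The implementation is tested
against a brute-force enumeration of all single-gain/any-loss scenarios on
every presence pattern of the 4-taxon tree. Age-stratified statistics use
SE = √(p(1−p)/n) for the DSI share and a Cochran–Armitage chi-square trend
test (verified against R's `prop.trend.test`), with Mann–Whitney tests on
PSI and GC, Kolmogorov–Smirnov on length distributions, and a gene-level
expression comparison by maximum intron age.

## Synthetic cohort

The generator emulates the assumed study design: 2 conditions × 8 timepoints
× 3 replicates (48 samples), ~2.7 introns/gene (Poisson), intron lengths
15 + Geometric(p = 0.07) − 1 capped at 100 nt (median 24), intron GC ≈ 18 %
vs exon GC ≈ 31 % (codon sampling with per-base GC weights), GT..AG
boundaries by construction. Baseline retention is logit-normal (mean −3.2,
SD 0.6) with a planted positive GC slope (+6 logit units per GC fraction)
and a negative age slope (−0.4 per age class), matching the qualitative
trends the analyses are meant to detect. Junction counts: depth ~ lognormal
(median 60, σ = 0.6, shared across introns — no depth model is prescribed
anywhere, so this is a declared stand-in), inclusion ~ Binomial(depth, p)
with p = 2·PSI/(1 + PSI), which inverts the 0.5-weighted PSI formula so the
plug-in estimator is consistent.

Planted effects: a `frac_dsi` (0.08) subset of introns gets a condition
offset of exactly `delta_psi_effect` (0.3) on the probability scale (side
randomized, clipped so the offset survives); 10 enhancer and 10 repressor
factors (of 40) each drive 5 target introns through a latent per-sample
activity with standardized effect 1.0 and residual SD 0.5. Factor activity
is drawn independently of condition by default so that the screen's confound
rule does not erase every planted link (a condition shift is available as a
knob, default 0). Expression: lognormal gene baselines, Poisson sampling,
per-sample library-size factors (SD 0.15 on the log scale), a 10 % DEG
fraction at log2FC = 2; factor genes' log expression tracks their latent
activity. Species histories: each intron's birth node is drawn over the
reference-to-root path with shares (0.47, 0.43, 0.10) for ages 1–3; each
branch below the gain loses the intron with probability 0.01 (reference
lineage protected, since reference introns are observed by construction);
33 % of genes have no orthologs, and orthologous genes are present per
non-reference species with probability 0.95. Ortholog proteins diverge by
10 % random substitutions (no indels), so junction windows exist at
homologous positions by construction.

What the generator does **not** emulate: read-level sequencing artifacts,
splice-site strength, overdispersed biological replicate noise beyond a
small logit jitter (SD 0.1), intron gains off the reference lineage,
indel divergence between orthologs, and NMD feedback between retention and
expression. Passing tests therefore demonstrate correctness of the
estimators and decision rules under the declared generative model, not
robustness to every artifact of real RNA-seq.

## Problem sizes and numerics

Default analysis runs use 150-gene cohorts (~400 introns, 48 samples), which
exercise every stage in seconds; statistical property checks use 200-gene
cohorts (~500 introns), 1,000-intron presence histories, and 200-intron /
40-factor regression benches. Numerical details: PSI of 0/0 is NaN; the LRT
uses xlogy to handle empty cells and clips negative G to 0; BH is from
statsmodels; k-means label order is resolved by the symbiotic-mean
convention; odds ratios use a Haldane 0.5 correction only when a cell is
zero; z-transforms use the sample SD (ddof = 1). All randomness flows from
a single integer seed per run; reruns are byte-identical.

## Known limitations

- The binomial DSI test treats pooled replicates as one sample; replicate
  overdispersion inflates the raw test statistic (mitigated by the ΔPSI
  gate, quantified by the null false-positive suite).
- The confound rule is conservative by design: any factor whose targets
  respond through the condition mean is zeroed, including true regulators
  acting along that axis.
- Age assignment can only be as deep as the carriers it sees: a lost or
  unmatched deep carrier makes an intron look younger (quantified by the
  birth-node recovery suite).
- The all-vs-all RBH search is exact, desk-scale alignment; genome-scale
  proteomes would need a heuristic search front-end.
- A3SS event discovery from alignments is out of scope; the frame and
  enrichment analyses consume event tables.
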