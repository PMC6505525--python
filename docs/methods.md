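# Methods

`t2dnet` implements an inference chain that links pancreatic-islet
chromatin architecture to candidate effector genes of type 2 diabetes
(T2D) risk signals: unified chromatin-loop calls → regulatory-element
enrichment at loop anchors → enhancer–gene assignment → expression
association → Bayesian fine-mapping with functional priors → allelic
imbalance → eQTL testing and colocalization. Every stage is exercised on
synthetic data with known ground truth; this note records the models,
the parameter choices, and what the synthetic experiments do and do not
demonstrate.

## Interval conventions

All coordinates are 0-based half-open (BED convention); GTF-style inputs
are converted on read. Chromosome names are used verbatim. Accessible
sites that straddle several chromatin-state segments are split into one
element per state, so elements tile the site base-for-base; bases outside
the segmentation receive the low-signal catch-all label `Quies/low`. The
chromatin-state vocabulary is the 8-label set of a 9-state histone-mark
segmentation with the two quiescent states merged: CTCF, Txn, TssA,
TssFlnk, EnhWk, EnhA1, EnhA2, Quies/low.

## Loop unification

Loop calls from several contact maps (three individual samples and a
pooled map, each at 5/10/25 kb resolution) are clustered: two calls match
when both ordered anchor-midpoint distances are ≤ 20 kb, and matching is
closed transitively. Each cluster keeps its highest-resolution call;
resolution ties are broken by the deepest source map. The representative
records every source containing a matching call. Merging is idempotent and
never increases the number of loops.

## Anchor enrichment and pair co-localization

Enrichment of each chromatin-state class at anchors is measured as the
proportion of that class's sites overlapping an anchor (directly, or
within a 25 kb window) against a size-matched null: each site is
re-placed uniformly on its own chromosome, preserving its length, 7000
times. Fold is observed over the null mean; the empirical p-value uses
the add-one convention `(1 + #{null ≥ obs}) / (1 + n_perm)`, so the
reportable floor at 7000 permutations is 1/7001 ≈ 1.4×10⁻⁴. Permuted
placements may overlap each other and are not excluded from any
blacklist.

Pair co-localization asks whether state A at one anchor predicts state B
at the other. Each loop contributes its two oriented anchor pairs; the
2×2 table cross-classifies oriented pairs by A-at-first × B-at-second and
is tested with Fisher's exact test (two-sided). Pairs whose table has a
zero marginal are reported as not estimable.

## Enhancer–gene assignment

Promoter windows are −5 kb/+2 kb around the TSS, strand-aware (the 5 kb
arm extends upstream; a strand-blind switch is provided since the
convention is not universal), clamped at the chromosome start. An
enhancer–gene edge requires the active enhancer (EnhA1) at one anchor and
the gene's promoter at the *opposite* anchor of the same loop, each
optionally within a 25 kb flank; same-anchor co-occupancy never counts.
Degree counts deduplicate on (enhancer, gene, loop). For GWAS signals,
candidate genes are the union of loop-mediated genes (25 kb flanks both
ends) and promoter-proximal genes (enhancer within 25 kb of the promoter
region); the far looser ±1 Mb-window and TAD gene sets are computed for
comparison.

## Expression versus loop degree

RPKM is converted to TPM per sample (each column then sums to 10⁶
exactly). A gene is "expressed in islets" when ln(TPM) > 1; the
expressed × has-enhancer-loop 2×2 table is tested with the uncorrected
Pearson chi-square (counts are large; a Yates flag exists). Tissue-
relative expression uses: quantile normalization within each tissue to
the mean empirical distribution (average-rank ties), natural log of
(value + 1) to admit zeros, then per-gene standardization across tissues
(constant rows get z = 0, with a 1e-9-scale tolerance for float noise).
The islet Z-score is regressed on enhancer-loop count by OLS.

Note a structural property verified during development: quantile
normalization absorbs any islet-specific shift that is concentrated in
one region of the expression distribution. When the synthetic generator
couples absolute expression to loop degree (its default, which is what
drives the contingency and rank-correlation signals), the realized
z-space slope is therefore ~15% below the injected value; the dedicated
slope-recovery experiment switches that coupling off so the injected
slope (0.14 per loop, matching the scale of islet-specific regulation)
is the quantity the chain should recover. In the full small-bundle
pipeline the slope is further attenuated because loop counts are the
*recovered* degrees, not the generator's truth.

## Fine-mapping with functional priors

Per-variant approximate Bayes factors use Wakefield's form
`ABF = sqrt(V/(V+W)) · exp(z²/2 · W/(V+W))` with `V = se²`. The prior
variance W on the log-odds effect is 0.04 (prior SD 0.2), the
conventional choice for binary-trait GWAS; it is configurable, and the
eQTL side uses W = 0.15² on standardized effects. All Bayes-factor
arithmetic is done in log space.

The hierarchical enrichment model treats non-overlapping windows of
consecutive variants (window size chosen so the mean span is ≈ 1 Mb):
a window is causal with probability Π = logistic(κ), and the causal
variant within a causal window is multinomial with weights
softmax(γ·x_v) over binary annotations x_v. The window marginal
likelihood is `(1−Π) + Π Σ_v π_v ABF_v`. Fitting is by L-BFGS with an
analytic gradient (per window, writing r = ΠS/((1−Π)+ΠS): ∂κ = r − Π and
∂γ = r(E_post[x] − E_prior[x])). The joint model is built greedily,
admitting an annotation only when it raises the log-likelihood by ≥ 1
(an AIC-scale step, so annotations carrying no signal do not
accumulate). A ridge penalty p·Σγ², selected on the grid 0–0.5 in steps
of 0.01 by 10-fold cross-validated likelihood over windows with backward
pruning, is available; the default pipeline run uses p = 0 because the
synthetic bundles contain few annotations and no overfitting pressure.
95% CIs are profile-likelihood intervals (χ²₁ cutoff, bisection).

Per signal, prior_v ∝ exp(γ·x_v) (1 for unannotated variants),
PPA_v = prior_v·ABF_v normalized over the signal, and the 99% credible
set is the smallest PPA-descending prefix reaching 0.99 (ties broken by
variant id). Cumulative PPA (cPPA) sums PPA over enhancer
(EnhA1/EnhA2/EnhWk), promoter (TssA/TssFlnk), CTCF and transcribed
groups; signals are k-means clustered on cPPA vectors (k = 4 by default — enough
to separate enhancer, promoter, CTCF/transcribed and un-annotated
signal groups — with a silhouette-based override;
fixed seed and 10 restarts), and the "enhancer cluster" is the one with
the highest mean enhancer cPPA. Enhancer-cluster membership is tested
against insulin-secretion phenotype association with an uncorrected
chi-square on the 2×2 and an exact binomial test at the un-annotated
signals' rate. The genome-wide scan multiplies the within-window prior
by the window-level prior Π, normalizes over the window's
variants-plus-null configuration, and retains windows with any
enhancer-overlapping variant at PPA > 0.01.

## Allelic imbalance

Per sample and heterozygous variant, an exact binomial test of ref/alt
read counts against 0.5, after requiring ≥ 2 reads per allele
(accessibility) or ≥ 3 (conformation). The minimum-likelihood ("minlike")
two-sided definition is used for reported p-values.

For combining across samples, each sample is scored with the **mid-p
signed normal score** z = Φ⁻¹(P(X<k) + pmf(k)/2): mapping the exact
two-sided p through Φ⁻¹(1−p/2) (available as `z_mode="from_p"`) leaves
the null score variance near 0.8 at 50× coverage — the discrete test has
a point mass at p = 1 and conservative tail sums — which deflates the
combined type-I error to ≈ 0.03; the mid-p score restores Var(z) ≈ 0.99
and a combined type-I error of ≈ 0.047 at α = 0.05. Scores are combined
with Stouffer's method weighted by total sample sequencing depth
(`Z = Σwz/√Σw²`; a √depth option is provided as the variance-optimal
weighting), giving a combined two-sided p per variant and
Benjamini–Hochberg q-values, with calls at q < 0.1. Conformation
(Hi-C) evidence is combined with Fisher's method instead. Directional
concordance between assays takes, per signal, the highest-PPA
significantly imbalanced variant observed in both assays and tests the
same-direction count against 50% with an exact binomial test. Positive z
means the alternate allele is over-represented.

Motif disruption: a variant disrupts a footprint when its position in the
motif's position frequency matrix has Shannon entropy < 1.0 bits
(columns must sum to 1 ± 1e-6).

## eQTL meta-analysis, class comparison, colocalization

Two studies (118 and 112 islet samples) are combined by sample-size-
weighted Z meta-analysis (w = √n), keeping only variant–gene pairs tested
in both studies at MAF > 0.01. LD pruning is greedy: sort by p (ties by
variant id), keep the best remaining, drop everything with r² > 0.5 to a
kept variant — deterministic and order-independent. Regulatory-class
comparisons use two-sided Wilcoxon rank-sum tests on −log₁₀(p), with a
distance-matched control drawn per 20-quantile bin of the looped class's
distance distribution, without replacement, at a fixed seed.

Per signal, the test variant is the highest-PPA enhancer variant present
in the eQTL data (falling back to the next most probable); per-gene
p-values are Bonferroni-corrected by the signal's candidate count and
called at corrected p < 0.05. Colocalization enumerates single- and
two-variant causal configurations with priors p1 = p2 = 1×10⁻⁴ and
p12 = 1×10⁻⁵: H0 mass 1; H1 ∝ p1·ΣBF₁; H2 ∝ p2·ΣBF₂;
H3 ∝ p1p2(ΣBF₁·ΣBF₂ − ΣBF₁BF₂); H4 ∝ p12·ΣBF₁BF₂, all in log space; a
signal is "shared" when PP4 > PP3.

## The synthetic-data generator

The generator's defaults are the study conditions, not tuning knobs:

- **Genome**: 4 chromosomes × 30 Mb; chromatin-state segments with
  exponential lengths (mean 20 kb) and configurable state proportions
  (enhancer states ≈ 17%, promoters ≈ 10%, quiescent 60%); 3000
  accessible sites split along the segmentation; 1200 genes, 60% of TSSs
  placed at active-promoter (TssA) site elements as in real genomes;
  sequential TADs of 0.4–1.2 Mb.
- **Loops**: 600 base loops with log-normal anchor spans (median 255 kb,
  ~10% over 1 Mb). With weight `ep_loop_enrichment` (default 3) a loop
  connects an EnhA1 element to a gene promoter. The pooled set carries
  the unjittered 5 kb reference calls; three per-sample sets re-emit each
  loop with probability 0.7, ±8 kb anchor jitter and possibly coarser
  resolution, so unification must collapse the duplicates.
- **GWAS**: 50 signal windows and 150 null windows of 50 variants across
  1 Mb spans. In a signal window the causal variant is drawn with
  probability ∝ exp(γ·x) with true EnhA1 ln-enrichment 3.9; the causal
  log-odds effect is N(0, 0.2²) conditioned on |β| ≥ 0.1 (half the prior
  SD — a "real" signal, and consistent with the W = 0.04 analysis prior),
  observed with se = 0.05; nulls are pure noise. Annotations are actual
  overlaps with the state segmentation, so roughly 6% of variants are
  enhancer-annotated. No LD is simulated (the one-causal-variant model
  the prior-reweighting assumes); a block-r² lookup helper exists for
  pruning tests.
- **Allele counts**: 23 accessibility samples and 3 conformation samples
  with log-normal library depths; per variant-sample coverage Poisson(50)
  (accessibility) or Poisson(10) (conformation); truly imbalanced
  variants draw alt reads at ratio 0.65 (random direction), nulls at 0.5.
  All samples are heterozygous by default (`het_rate` is configurable).
- **eQTL / colocalization**: per signal one target gene (the nearest);
  shared or distinct causal variant with probability 0.5; the causal
  standardized effect is 0.45 (a strong cis-eQTL, ~20% explained variance
  at these study sizes). In the dedicated colocalization experiments the
  disease lead |z| is drawn N(6,1) truncated at the genome-wide
  significance threshold 5.45, because only significant risk signals are
  ever colocalized.
- **Expression**: cross-tissue log-expression with gene baselines
  N(2, 2²) and unit tissue noise over 54 tissues (islets first); the
  islet column gains 0.14·(loops − mean), and baselines gain
  1.5·log1p(loops) shared across tissues (absolute coupling; see above).

All randomness flows from one master seed through named substreams;
identical configurations produce byte-identical files.

What passing tests show — and what they do not: the synthetic data have
no LD, no mapping bias, no batch structure in expression, independent
variants within signals, and annotations derived from the same
segmentation used for analysis. Recovery and calibration results
therefore validate the statistical machinery and its implementation
under the stated model, not robustness to the violations real data
exhibit (LD leakage into credible sets, reference-mapping bias in allele
counts, shared samples between eQTL studies, and so on).

## Numerical choices and degenerate inputs

- Log-space throughout fine-mapping and colocalization; segment
  logsumexp via shifted `reduceat`.
- Empirical p-values use the add-one convention and can never be 0.
- Credible-set and LD-prune ties break lexicographically by variant id;
  merge representatives sort by (resolution, −depth).
- Constant expression rows give z = 0; all-zero coverage gives an
  all-zero anchor profile; a state with no sites is omitted with a
  warning; a signal with no enhancer variant is a caller error.
- k-means uses a fixed seed and 10 restarts, so pipeline reruns are
  bit-identical.

## Problem sizes

Default experiment sizes were chosen so the statistical checks are well
powered while a full run stays interactive: enrichment recovery uses
2000 windows × 20 variants (50 replicates for coverage), credible-set
calibration 220 signals, imbalance calibration 2000 variants × 23
samples, colocalization 100 replicates per configuration, expression
recovery 5000 genes, and the end-to-end bundle the genome above.

## Known limitations

- The enrichment model assumes at most one causal variant per window and
  exact single-annotation overlap semantics; overlapping annotations are
  handled multiplicatively (γ·x), which the one-hot chromatin states
  never exercise.
- Profile-likelihood CIs can be one-sided (−∞ bound) for annotations with
  no annotated causal variants; such annotations are usually excluded by
  the forward-selection gain threshold.
- The permutation null places sites uniformly per chromosome; it does not
  model accessibility-site clustering, so real-data folds would be
  conservative relative to a clustered null.
- The depth-weighted Stouffer combination follows the stated procedure;
  with very unequal library depths the √depth option is statistically
  preferable.
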