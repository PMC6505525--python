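# t2dnet

Chromatin-loop-anchored fine-mapping and effector-gene assignment for
pancreatic-islet type 2 diabetes (T2D) risk signals.

Most T2D risk variants fall in non-coding islet regulatory elements, and
the genes they act on are usually unknown because enhancers can regulate
promoters hundreds of kilobases away. `t2dnet` implements, as a tested
and reusable pipeline, the inference chain that connects islet chromatin
architecture to candidate effector genes:

1. **Loop unification** — chromatin-loop calls from several contact maps
   and resolutions are merged (anchors matched within 20 kb; highest
   resolution kept, ties broken by sequencing depth).
2. **Anchor enrichment** — chromatin-state classes are tested for
   enrichment at loop anchors against a size-matched permutation null
   (7000 permutations), and state pairs for co-localization across
   anchors (Fisher's exact test).
3. **Enhancer–gene mapping** — active enhancers are linked to genes
   whose promoters (−5 kb/+2 kb of the TSS) sit at the opposite loop
   anchor, or lie within 25 kb; compared against ±1 Mb-window and TAD
   gene sets.
4. **Expression** — RPKM→TPM, expressed-gene contingency, Spearman
   loop–expression correlation, and regression of cross-tissue islet
   expression Z-scores on enhancer-loop count.
5. **Fine-mapping** — Wakefield approximate Bayes factors
   (`ABF = √(V/(V+W)) · e^{z²W/2(V+W)}`, W = 0.04), a hierarchical
   annotation-enrichment model over ~1 Mb windows
   (`L_w = (1−Π) + Π Σ_v softmax(γ·x_v) ABF_v`), functional priors
   ∝ exp(γ·x), PPAs, 99% credible sets, cPPA k-means signal clustering,
   insulin-secretion overlap tests, and a genome-wide scan at PPA > 0.01.
6. **Allelic imbalance** — exact per-sample binomial tests at
   heterozygous variants (≥2 reads/allele for ATAC, ≥3 for Hi-C),
   depth-weighted Stouffer combination with mid-p signed scores, BH
   q-values (q < 0.1), Fisher combination for conformation data, and a
   binomial test of cross-assay directional concordance.
7. **eQTL and colocalization** — sample-size-weighted meta-analysis of
   two islet studies (n = 118, 112; MAF > 0.01), greedy LD pruning
   (r² > 0.5), regulatory-class comparisons with a distance-matched
   control, per-signal Bonferroni-corrected target-gene tests, and
   Bayesian colocalization (priors 10⁻⁴/10⁻⁴/10⁻⁵; shared ⇔ PP4 > PP3).

The real data behind such analyses are restricted and consortium-scale,
so the package ships a first-class **synthetic-data generator**
(`t2dnet.simulate`) that emulates every input with known ground truth —
loop spans log-normal around 255 kb, 23 accessibility samples, eQTL
study sizes 118/112, 54 expression tissues, enhancer ln-enrichment 3.9,
islet expression slope 0.14 — so every stage is testable end to end.
See `docs/methods.md` for the models, parameter choices, and what the
synthetic experiments do and do not demonstrate.

## Worked example

Run the full pipeline on the default synthetic bundle:

```python
from t2dnet import RunConfig, SimulationConfig, run_pipeline

config = RunConfig(seed=1, simulation=SimulationConfig(seed=1))
results = run_pipeline(config, "demo_run")
```

Selected output (printed from `results`; your numbers are identical at
seed 1):

```
merged loops:            525
median anchor distance:  276 kb
EnhA1 anchor fold:       2.89 (empirical p = 1.43e-04)
EnhA1 ln-enrichment:     4.62 (95% CI 3.63-5.92)
islet z ~ loops slope:   0.054 +/- 0.040
imbalanced variants:     39 at q < 0.1
ATAC/Hi-C concordance:   30/35 (p = 2.24e-05)
eQTL target genes:       8 significant of 20 tested; shared causal at 8
```

Reading this: 1862 raw loop calls from four synthetic contact maps
collapse to 525 unified loops. Active-enhancer (EnhA1) elements are
2.9-fold enriched within 25 kb of anchors, at the permutation floor
p = 1/7001 (the generator plants enhancer–promoter loops at weight 3).
The enrichment model recovers the planted EnhA1 ln-enrichment (truth
3.9) within its 95% CI. The islet expression slope at this small bundle
scale is noisy and attenuated because it is computed from *recovered*
loop degrees (the calibrated 5000-gene recovery experiment lives in the
acceptance checks). Of the causal enhancer variants planted with
allelic ratio 0.65, 39 are called imbalanced at q < 0.1, their
accessibility and conformation directions agree at 30/35, and 8 signals
get a significant, colocalized eQTL target gene. `demo_run/` holds the
per-stage TSV/JSON outputs, the generated inputs plus
`ground_truth.json`, and a manifest with checksums — reruns with the
same config and seed are byte-identical.

The same stages are available from the shell:

```bash
t2dnet simulate --seed 1 --out bundle/
t2dnet loops merge bundle/loops_*.bedpe --out merged.bedpe
t2dnet finemap fit-enrich bundle/gwas.tsv --penalty 0 --out model.json
t2dnet finemap ppa bundle/gwas.tsv --model model.json --out ppa.tsv
t2dnet imbalance run bundle/atac_counts.tsv --assay atac --out imbalance.tsv
t2dnet run --out full_run/ --seed 1
```

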