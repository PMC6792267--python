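# svcis

**Somatic structural variant breakpoints versus gene expression and
CpG-island methylation in cancer cohorts.**

Somatic structural variants (SSVs) can deregulate genes without touching
their coding sequence: a breakpoint near a gene may delete a regulatory
element, break a TAD boundary, fuse an active enhancer within reach of a
silent promoter, or rearrange chromatin with a very different DNA
methylation state next to a CpG island (CGI). `svcis` is a pipeline for
detecting and contextualizing such effects in a multi-omic cohort —
breakpoint calls (BEDPE), an expression matrix, an Illumina-450K-style
methylation beta matrix, gene-level copy number, and sample metadata — and
ships a synthetic cohort generator with a planted-effect ledger so the
whole pipeline can be calibration- and recovery-tested end to end.

It is intended for computational cancer-genomics groups who have SSV calls
and molecular matrices in hand and want a tested, reusable implementation
of the scan machinery rather than a per-project script pile.

## The statistics at the core

For each feature (gene *g* or CGI probe mapped to its gene) and samples
*s = 1…n*, an ordinary-least-squares model

&nbsp;&nbsp;&nbsp;&nbsp;*y*<sub>gs</sub> = β₀ + β₁ *x*<sub>gs</sub> + **γ**ᵀ **c**<sub>s</sub> + ε<sub>gs</sub>

is fit, where *y* is log2(expression + 1) or logit(beta clamped to
[10⁻³, 1−10⁻³]), and *x* is one of

* a binary window indicator: ≥ 1 breakpoint in 0–20 / 20–50 / 50–100 kb
  upstream or downstream of the TSS, or in the gene body;
* log2 of the distance from the breakpoint closest to the gene start,
  capped and imputed at 1 Mb ("distance metric");
* the log2-transformed per-sample SSV total (burden scans).

Covariates **c** always include dummy-coded cancer type, plus any of:
gene-level CNA log2 ratio, WGS pass (low/high coverage), log total
breakpoint count, purity, ploidy, age, overall methylation, or the
feature's own proximal-breakpoint distance. Features with fewer than three
breakpoint carriers are not tested. The two-sided t test on β₁ yields
p-values; false discovery rates are Storey–Tibshirani q-values (cubic-
spline π₀ estimate; π₀ = 1 reduces exactly to Benjamini–Hochberg). A
patient-shuffling permutation null (whole breakpoint profiles permuted
across samples) quantifies the excess of observed hits over chance.

Downstream context: TAD-disruption classification (breakpoints not sharing
a TAD) and enrichment among effect-associated SSVs; orientation-aware
enhancer-hijack flags (no native enhancer within 1 Mb, fused enhancer
within a 500 kb budget through the junction); normal-tissue methylation of
the rearranged region (50 kb at the mate breakpoint) versus the CGI across
the junction; per-sample burden profiles (collapsed SSV totals, global SSV
index standardized within WGS-pass strata, overall methylation/CNA indices,
gene-set signature scores) and their molecular correlates.

See `docs/methods.md` for the full model description, the synthetic-cohort
design, and known limitations.

## Worked example

Simulate a cohort with planted effects and run the full pipeline:

```python
from svcis.pipeline import run_pipeline, write_report

manifest = run_pipeline({"seed": 7, "simulate": {}}, outdir="out")
print(write_report(manifest))
```

which prints (abridged):

```
svcis run report
================
config hash : 0538ea017bafc3f2
seed        : 7

simulate                 rows=21689    seed=7
features                 rows=2000     mode=distance, d_max=1000000, windows=[]
scan_expr                rows=2000     covariates=['cancer_type', 'cna', 'wgs_pass', 'total_bp_count'], n_significant=65
scan_meth                rows=6000     covariates=['cancer_type', 'cna', 'wgs_pass', 'total_bp_count'], n_significant=67
context_tad              rows=2425     frac_all=0.5606, frac_subset=0.8107, p=7.29e-153
methshift                rows=27417    window=50000
burden_meth              rows=6000     n_significant=6000, n_significant_overall_meth_adjusted=0
recovery_expr            rows=65       n_discoveries=65, n_true=60, precision=0.9231, recall=1.0, sign_accuracy=1.0, empirical_fdr=0.0769
recovery_meth            rows=67       n_discoveries=67, n_true=60, precision=0.8955, recall=1.0, sign_accuracy=1.0, empirical_fdr=0.1045

scan_expr: 65 significant at FDR<5% (35 positive / 30 negative), 2000 tested
scan_meth: 67 significant at FDR<5% (34 positive / 33 negative), 6000 tested
```

Reading this: the simulated cohort (300 samples, 2,000 genes, 6,000 CGI
probes, ~60 SSVs/sample) carries 60 planted expression effects and 60
planted methylation effects; the distance-metric scans recover all of them
(`recall=1.0`, correct signs) at FDR < 5% with a handful of false
discoveries. SSVs tied to altered expression span TADs far more often than
background (81% vs 56%, chi-squared p ≈ 10⁻¹⁵³), and the genome-wide
burden–hypomethylation coupling produces 6,000 burden-correlated probes
that collapse to 0 once overall methylation enters the model — the
covariate-absorption contrast the burden analysis is designed to expose.

The same stages are scriptable from the shell:

```bash
svcis simulate --seed 7 --out bundle/
svcis scan --response bundle/expression.tsv --ssvs bundle/ssvs.bedpe \
    --genes bundle/genes.tsv --samples bundle/samples.tsv \
    --cna bundle/cna.tsv --covars cancer_type,cna --fdr 0.05 --out scan.tsv
svcis run --config config.yaml --out out/
```

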