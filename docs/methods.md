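# Methods

## The problem

Somatic structural variants (SSVs) — deletions, duplications, inversions,
translocations — join two genomic coordinates at a breakpoint junction and
can deregulate nearby genes without changing their coding sequence:
by removing or repositioning regulatory elements, by breaking topologically
associated domain (TAD) boundaries, by fusing an active enhancer into reach
of a silent promoter, or by rearranging chromatin of a very different
methylation state next to a CpG island (CGI). `svcis` implements the
statistical machinery to detect such effects in a multi-omic cancer cohort:
per-gene and per-CGI-probe association scans of expression and methylation
against breakpoint proximity, permutation nulls, rearrangement-context
annotation, and per-sample structural-variation-burden correlates.

## Breakpoint predictors

Two gene-by-sample predictor matrices are built from the breakpoint calls.

**Genomic region windows.** For a named window relative to the gene —
0–20 kb, 20–50 kb, 50–100 kb upstream or downstream of the TSS, or the gene
body — the matrix records the presence/absence (1/0) of at least one
breakpoint of that sample in the window. Windows are strand-aware
(a documented flag switches to unstranded left/right). Flank windows are
half-open `[near, far)` in distance from the TSS, so a breakpoint exactly
20 kb upstream belongs to the 20–50 kb window and the canonical windows
partition the flank. The gene body includes both the TSS and the gene end;
breakpoints inside the body are counted only in the gene-body window. This
disjoint choice is a design decision, not an inference: counting body hits
also in flank windows would only add carriers for genes longer than the
window span.

**Distance metric.** For each gene and sample, the absolute distance from
the breakpoint closest to the gene start (the strand-aware TSS; for minus-
strand genes the gene end coordinate), capped at `D_max` = 1 Mb and imputed
at 1 Mb where no breakpoint falls within range. A breakpoint exactly at the
TSS is stored as 1 bp so the engine's log2 transform is defined. The
predictor entering the model is `log2(distance)`.

## Association engine

Each feature is tested by ordinary least squares:

    y ~ x + cancer_type + (optional numeric covariates)

with `y` the transformed response — `log2(x + 1)` for expression, the logit
of beta values clamped to `[1e-3, 1 - 1e-3]` for methylation — and `x` the
binary window indicator, `log2(distance)`, or the log SSV total for burden
scans. Cancer type is always dummy-encoded with a reference level; numeric
covariates (gene-level CNA log2 ratio, purity, ploidy, age, log total
breakpoint count, overall methylation, the feature's own proximal-breakpoint
distance) are mean-imputed within the scanned sample set where missing. The
expression pseudocount and the clamping epsilon are configurable; both are
conventions rather than substantive choices at the data scales involved.

A two-sided t test on the `x` coefficient gives the p-value. Features with
fewer than three carriers (window mode: 1-entries; distance mode: entries
below the cap) are skipped, as are features whose predictor is constant or
whose non-missing fraction falls below 80% of the scanned samples
(threshold configurable). Collinear covariate columns are dropped greedily
by detected rank deficiency — never the intercept or the predictor; a
deficiency involving the predictor itself marks the feature degenerate.

**Sign convention.** For the distance predictor the reported direction is
the negated coefficient sign, so "+" always reads "response higher with a
nearby breakpoint", matching the window-mode convention.

**FDR.** q-values follow Storey–Tibshirani: `pi0` is estimated on the
lambda grid 0, 0.05, …, 0.90 with a cubic smoothing spline evaluated at the
largest lambda and clamped into (0, 1]; q-values are the pi0-scaled step-up
minima. With `pi0` forced to 1 the procedure reduces exactly to
Benjamini–Hochberg, which is the oracle check in the test suite.

**Permutation null.** The patient-shuffling null permutes the sample labels
of the predictor columns as a unit — each sample's entire breakpoint
profile moves together, preserving the correlation structure among features
— while responses and covariates stay with their samples. The default of
100 permutations is a cost/stability compromise; the count is a parameter.

**Within-type scans** replace the cancer-type covariate with project
dummies (`cancer_type_column="project"`), since several sequencing projects
can share a tissue type; where a type maps to a single project the dummy
block is empty and the model contains intercept, predictor, and any numeric
covariates.

## Downstream analyses

**Differential methylation by type** uses Welch's unequal-variance t test
on clamped-logit betas, one cancer type against all others (group sizes and
variances differ strongly between types, making the pooled-variance test
inappropriate). **Set overlap** between hit sets is tested on the 2×2 table
with a chi-squared test without continuity correction (the default at the
count scales involved), or a one-sided Fisher/hypergeometric test in
enrichment mode; the expected overlap under independence is
`|A|·|B|/|U|`. The overlap universe is the set of features tested in both
analyses, configurable. **Residual correlation** between expression and
methylation of a gene regresses both transformed vectors on the covariates
and Pearson-correlates the residuals, with the t-transform p-value using
degrees of freedom reduced by the number of covariates.

**TAD disruption.** An SSV is disrupting when its two breakpoints do not
fall in the same TAD; inter-chromosomal junctions always disrupt. A
breakpoint in an inter-TAD gap counts as disrupting by default (a flag
yields a separate "not classifiable" category instead). TADs must be
non-overlapping per chromosome; overlap is rejected at load. Enrichment of
disruption in an SSV subset is a chi-squared test of subset vs rest.

**Enhancer hijacking.** Associations are (gene, sample) pairs whose closest
qualifying breakpoint lies 0–500 kb upstream of the TSS with the gene-side
flank retained at the junction (orientation "−" for plus-strand genes, "+"
for minus-strand genes), so the mate is fused on the distal side. The
association is a hijack when (a) the unaltered gene has no applicable
enhancer — ubiquitous, or tagged for the sample's cancer type — within
1 Mb of the TSS, and (b) an applicable enhancer sits on the mate's retained
flank within the remaining fused-distance budget:
`|TSS − breakpoint| + |mate − enhancer midpoint| ≤ 500 kb`. The additive
fused-distance arithmetic assumes no further rearrangement inside the
region; it is a documented approximation, since only the single junction is
reconstructed.

**Rearranged-region methylation.** For each SSV–CGI association, the mean
normal-tissue beta over a 50 kb window anchored at the mate breakpoint and
extending into its retained flank (a flag centers the window instead) is
compared with the normal-tissue beta at the CGI probe; `delta = region −
CGI`. Cancer types resolve to surrogate normal tissues through an explicit
map; types without a surrogate are dropped with a warning. Subsets of
associations with cancer hyper-/hypo-methylation (scan FDR < 5% and carrier
deviation beyond ±0.4 SD) are summarised with their mean delta and standard
error, a Spearman rank correlation between subset membership and delta, and
a Welch two-sample comparison — two statistics because the pairing of
variables in a rank test over subsets is genuinely ambiguous; both are
labelled in the output.

**Burden correlates.** SSV calls are first collapsed: calls of a sample
with both breakpoint ends strictly less than 10 bp apart are single-linkage
clustered and replaced by the lowest-coordinate member (cross-class merges
allowed; a flag forbids them). The per-sample total is log2(count+1)
transformed and standardized to SD-from-median separately within the
low-pass and high-pass WGS strata — the global SSV index. "SD from median"
is implemented literally: median-centred, scaled by the ordinary ddof-1
standard deviation, not a robust scale estimate. Overall methylation is the
per-sample median beta over all probes; overall CNA the SD of gene-level
log2 ratios. Signature scores average SD-from-median-normalized log2
expression over a gene set, normalized across all samples or within each
cancer type (the convention for immune-infiltrate signatures). Burden scans
delegate to the association engine with the log SSV total as predictor and
always include WGS pass and project in the design, the two technical
drivers of detected SSV counts.

## Alteration calls

A carrier's expression or methylation is called altered when its
transformed value deviates from the feature's cross-sample median by more
than ±0.4 SD (both thresholds configurable); amplification/deletion is
|log2 tumor/normal| > 1. The legend-style "> 0.4 SD or < −4 SD" asymmetry
that sometimes appears in figure captions of this literature is treated as
a typographical artifact; the implementation is symmetric.

## Synthetic cohorts

The generator emits a full input bundle plus a planted-effect ledger. The
default ("desk") scale: 300 samples across 3 cancer types (40/35/25%), a
3-chromosome genome of 100 Mb each, 2,000 genes, 3 CGI probes per gene with
a promoter/gene-body/other mix of 47/43/10%, about 60 SSVs per sample with
a deletion/duplication/inversion/translocation mix of 35/25/20/20% and
log-uniform sizes from 1 kb to 10 Mb, and a log-normal per-sample burden
multiplier (sigma 0.6). These sizes keep the full pipeline — simulation,
both scans, context, burden — within a few seconds per cohort so that
multi-replicate calibration runs stay cheap, while leaving per-gene carrier
counts (a few to a few hundred per gene across windows) in a regime where
the min-carrier rule and the FDR machinery are actually exercised.

Structure emulated:

* expression: per-gene log2 baseline uniform in [3, 9], per-type offsets
  (SD 0.7), CNA dosage at 0.5 log2 expression per log2 copy ratio, residual
  noise SD 0.5;
* methylation: class-typical baselines (promoter islands beta 0.10, gene
  bodies 0.50, others 0.65) with per-probe (SD 0.4) and per-type (SD 0.3)
  logit offsets and logit noise SD 0.5, clamped to [0.001, 0.999];
* CNA: genes with a breakpoint within 100 kb gain or lose copy with
  probability 0.3 (amplitude 0.5–1.5, random sign) over N(0, 0.15) noise;
* planted cis-effects: 30 genes up and 30 down in expression (±1.0 log2),
  30 CGI probes up and 30 down in methylation (±1.0 logit), each in 10% of
  samples, with the carrier's SSV placed 1–50 kb upstream of the target
  gene. Hypermethylation targets promoter probes and hypomethylation
  gene-body probes, the probe-class asymmetry reported for SSV-associated
  methylation change in cancer; hypomethylation mates land in a
  low-methylation genomic zone and hypermethylation mates in a
  high-methylation zone of the normal methylome panel;
* enhancer hijacking: 5 of the overexpressed genes sit in an enhancer
  desert (no enhancer within 1.2 Mb) and their carrier SSVs fuse a distal
  ubiquitous enhancer within the 500 kb budget with the correct
  orientations;
* TAD geometry: planted carrier SSVs span TADs with probability 0.9
  (inter-chromosomal mates; the remainder stay within the TAD of the
  breakpoint), background SSVs span as their sizes dictate (about half);
* burden coupling: a global methylation shift of −0.15 logit per global-
  SSV-index unit applied to every probe — a "slight but global"
  hypomethylation with burden — and a 30-gene expression module rising 0.3
  log2 per index unit. The coupling is applied on the logit scale, the
  modeling scale of every other methylation effect; a beta-scale shift
  would be amplified by 1/(b(1−b)) on the logit scale for low-beta promoter
  probes, i.e. it would encode a strong probe-class interaction rather than
  a global shift;
* WGS pass: samples are labelled low/high-pass (45/55%), which defines the
  strata of the global SSV index. Differential detection sensitivity can be
  emulated (`low_pass_detection` keeps each SSV of a low-pass sample with
  the given probability) but defaults to off, so the stated planted-effect
  conditions — carrier fraction, effect size — hold exactly as configured.

All randomness flows from one `numpy` generator seeded by the config;
identical seeds give byte-identical bundles.

**What the generator does not emulate.** Real karyotype structure
(chromothripsis, chained events), read-level evidence and caller error
modes, CNA segment structure (gene-level values are independent draws),
linkage between neighbouring genes' expression, probe cross-reactivity,
and tumor purity effects on betas. Passing recovery tests therefore show
that the statistical machinery detects the planted generative structure at
the configured signal-to-noise — not that effect sizes or hit counts on
real cohorts would match.

## Recovery scoring and calibration

`evaluate_recovery` compares scan discoveries (q below threshold) to the
ledger: precision, recall, sign accuracy over true discoveries, and
empirical FDR (false discoveries over discoveries). The pipeline's default
scan covariates are cancer type, CNA, WGS pass, and log total breakpoint
count: the last two are needed because the simulated burden coupling makes
every methylation probe weakly dependent on a sample-level factor that
correlates with breakpoint proximity genome-wide; without them the
empirical FDR of the methylation scan is inflated by a systematic
confound rather than by statistical noise. The cancer-type + CNA covariate
pair alone remains available through `ScanConfig` for comparisons.

## Numerical choices

* OLS via `numpy.linalg.lstsq` with an explicit normal-equations oracle in
  the tests (agreement to 1e-8 relative on random small designs) and a
  statsmodels cross-check.
* `pi0` clamped to [1/m, 1]; with fewer than 8 p-values, or a flat grid,
  the last grid estimate is used directly instead of the spline.
* Distance ties between two equidistant breakpoints resolve to the same
  distance value (only the minimum matters); distance 0 floors at 1 bp.
* Degenerate strata (zero SD) yield index 0 with a warning rather than an
  error, so single-stratum toy inputs stay usable.
* The methylome-shift stage bounds the unsubsetted background at 20,000
  seeded-sampled associations to keep the stage linear-time at desk scale.

## Known limitations

* BEDPE is the only SSV input dialect (no VCF), and hg-style liftover is
  out of scope; coordinates are 0-based half-open internally.
* The hijack rule reconstructs a single junction; multi-junction derivative
  chromosomes are not modelled.
* Within-type scans with one project per type reduce to unadjusted models
  plus numeric covariates; no shrinkage across types is attempted.
* The permutation null re-fits every feature per permutation; at much
  larger scales a batched implementation would be needed.
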