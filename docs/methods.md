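# Methods

## Positivity model

The core statistical rule is control-anchored thresholding: for antigen
*a*, the threshold is `t_a = mean_a + 2·sd_a` computed over a designated
control group (healthy/LTBI serum, or normal-adjacent tissue), with the
sample standard deviation (ddof = 1). A sample is called positive iff its
normalized RFU is *strictly* greater than `t_a`; boundary equality is
negative. Antigens with fewer than two non-missing control values are
excluded from calling; zero-variance antigens are kept but flagged
degenerate. With Gaussian noise and known parameters the rule's
false-positive rate is the 2-SD upper tail ≈ 0.0228; with the threshold
*estimated* from n = 30 controls the exact null exceedance is
`P(t₂₉ > 2/√(1+1/30)) ≈ 0.0294`, and mild right-skew plus normalization
noise push the realized rate to ≈ 0.031–0.034. This is the calibration the
test suite verifies; it is a property of estimated thresholds, not a bug.

Per-sample positive counts are categorized on the symbol grid
(0 absent, 1–29 weak, 30–47 moderate, 48–63 strong, 64–80 very strong,
&gt;80 PSA). PSA — polyspecific, "sticky" samples — are reported in the
reactivity grid but excluded by default from forest aggregation and panel
discovery (configurable), since such counts reflect nonspecific binding
rather than titer.

## Antigen ratios and the subclass forest statistic

For one sample and channel the antigen ratio is
`positive count / negative count`; an all-positive sample has an undefined
(infinite) ratio and is dropped from aggregation. For a subclass *s* of
isotype *i* the forest statistic is the mean over samples of
`ratio_i − ratio_s`, with the reported 5% and 95% bounds taken as the
endpoints of a two-sided 90% Student-t interval (a seeded percentile
bootstrap with B = 2000 is available). The construction of the "95% and
5% CI" was a genuinely open choice; the t-interval was chosen because it
is exact under normality, has zero width for constant differences, and
reproduces the identity case (subclass calls = isotype calls ⇒ difference
exactly 0). Interpretation: the more negative the statistic, the larger
the share of the isotype's reactivity carried by that subclass.

Group-level RFU comparisons use one-way ANOVA plus Welch t-tests of each
group against the control with Bonferroni correction over the non-control
family (Dunnett would be slightly more powerful but is not what the
analysis claims); stars at 0.05/0.01/0.001/0.0001. Paired IgG-vs-IgA
positive-proportion comparisons use Wilcoxon signed-rank per group,
Bonferroni over groups.

## Combinatorial ROC panel discovery

Antigens are screened one at a time (case vs pooled disease controls) with
a two-sided Mann–Whitney test — robust to the log-normal RFU tail; Welch
is an option — and BH-adjusted. Candidates are the antigens passing FDR
1%; when fewer survive than the minimum panel size, discovery proceeds
with every antigen at raw p < 0.05 (logged), matching how such studies
proceed when FDR retains nothing. Candidates are ranked by adjusted then
raw p; the top 20 enter an exhaustive enumeration of subsets of sizes 2–6
(capped at 200 000 panels).

Each panel scores a sample by the number of member markers at or above
their per-marker Youden cutoff; evaluating the count thresholds "≥1
positive" … "all positive" and keeping the Youden-best is exactly the
panel-level optimal cutpoint on the count score. Panels are ranked by ROC
AUC (trapezoidal, tie-averaged, so AUC = U/(n₁n₀)), ties by sensitivity,
specificity, then marker ids; roman-numeral labels follow enumeration
order. All performance is apparent (no train/test split), as in the
combinatorial-ROC practice this reproduces; an important consequence,
verified by the validation experiments, is that with weak planted signals
(per-marker AUC ≈ 0.75) the top *apparent* panel frequently includes a
lucky noise marker alongside true ones — panel membership at such effect
sizes should be read as a candidate set, not a certainty.

The Youden cutpoint maximizes sensitivity + specificity − 1 over midpoints
between adjacent distinct scores (positives at score ≥ cutoff); ties break
toward higher specificity, then the lower cutoff. All-equal scores yield a
flagged degenerate cutpoint (sens 1, spec 0).

## Glycoprofiling and clustering

Lectin channels (RCA/ECL β1,4-Gal, SNA α2,6-SA, LCA α1,6-Fuc) go through
the *identical* thresholding code path as antibody channels. A cohort's
positive set contains antigens above threshold in at least one sample by
default (a prevalence fraction is configurable); total glycosylation per
cohort is the mean ± SEM of the pooled positive-antigen RFUs. Case vs
pooled-control contrasts are per-antigen Mann–Whitney with Bonferroni over
the antigens of each lectin; the per-lectin significant-antigen count is
the headline output.

For clustering, feature-by-antigen matrices (per-channel mean RFU over the
case cohort) are floored at ε = 1, log2-transformed and divided by the row
SD — scaling without centering, so values stay positive; z-scoring is an
option. Clustering is agglomerative with correlation distance and average
linkage by default (correlation matches the "shared antigen binding"
semantics; Euclidean/complete are options), deterministic given row
order, with cophenetic distances and newick export. Both feature and
antigen dendrograms are computed.

## Synthetic cohort generator

The generator emulates spot-level output of a two-colour antigen
microarray. Per (sample, channel, antigen) a latent log-signal is drawn as

```
t = log(500) + antigen offset (log-sd 0.30) + specimen/channel offset
    + planted effect + N(0, 0.025)
```

and each replicate spot reports `foreground = background + exp(t + N(0, 0.03))`
with background ~ N(100, 15) truncated at 0 and a local-background
estimate carrying N(0, 5) error. Planted effects are log2 fold-changes per
(group, channel, antigen) with an optional penetrance (probability an
individual case carries the elevation). Polyspecific (sample, channel)
pairs elevate a uniformly random set of 81–150 antigens by 3 log2-fold, so
the >80 PSA rule fires by construction. Tissue samples carry a 5× IgA
baseline (serum, 5× IgG), echoing the qualitative isotype asymmetry of the
two compartments. Every (sample, channel) pair uses its own substream of
the global seed, so extending a cohort never perturbs existing draws.

The baseline log-sd values (0.025 between samples, 0.03 between
replicates, i.e. CVs of ~2.5–3%) model only the *non-specific background
binding* of a tight single-batch assay: they were fixed by a design
calculation so that the mean+2SD rule operates in its intended
near-Gaussian regime (null call rate ≈ 0.032 with n = 30 estimated
thresholds — see above for why ~0.029 is the floor). Real serology
cohorts show far larger between-sample spread for *reactive* antigens;
that spread is represented here by planted effects, not by the baseline.
Consequently the passing tests demonstrate correctness and calibration of
the machinery, not clinical performance on real sera: batch effects,
antigen cross-reactivity, dye bias and spatial artifacts are all outside
the generator.

## Numerical and degenerate-input conventions

* Negative net intensities are retained through aggregation (thresholding
  decides positivity) and floored at ε = 1 only for log transforms.
* Replicate CV is undefined (NaN) when the replicate mean ≤ 0 or fewer
  than two replicates survive QC; entries with all replicates flagged
  become missing and are reported.
* Saturated spots (≥ 65535) and scanner-flagged spots are excluded from
  aggregation; a replicate-CV warning fires above 20% (configurable).
* Median-scale normalization computes scale factors on values floored at
  ε; samples with non-positive medians are left unscaled and logged.
* BH/Bonferroni run through `statsmodels.stats.multitest`; AUC through
  `sklearn.metrics.roc_auc_score`; clustering through
  `scipy.cluster.hierarchy` — each verified in the test suite against an
  independent from-scratch oracle (definitional step-up, pair counting,
  naive agglomerative average linkage).

## Problem sizes used in validation

The packaged validation experiments run the default 262-antigen design
with 20 replicates for null calibration, forest ordering and feature
co-clustering, and 50 replicates for planted-panel recovery (enumerating
~21 700 panels per replicate from the top 20 candidates, sizes 2–5);
together they complete in about a minute on one CPU.

## Known limitations

* No dye-bias correction between the two fluorescence channels; no
  spatial/print-tip artifact modelling.
* Apparent panel performance only; the optional bootstrap-optimism
  correction is off by default.
* Whether serum thresholds should pool all control cohorts or the healthy
  group only is design-dependent; the default is the healthy group,
  configurable per specimen.
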