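# Methods

`mirc` implements a multi-compartment small-RNA expression analysis of the
kind used to profile hepatocellular carcinoma: paired tumor tissue,
adjacent normal tissue, whole serum and serum-exosome samples per patient,
plus control serum from healthy donors. This note describes the models and
procedures, their assumptions, the parameters that matter, and the choices
made where the design was genuinely open.

## Synthetic cohort model

No patient data ship with the package; every analysis stage is exercised
against a generative model (`mirc.simulate`) that reproduces the structural
features the downstream statistics rely on.

**Counts.** Each biological feature (miRNA, snoRNA, tRNA, scRNA, other)
receives a baseline abundance drawn log-normally within its RNA class
(log2 mean 5, sd 2 — a heavy-tailed profile typical of small-RNA
libraries). Per compartment, class totals are rescaled so the *expected*
read-mass fraction of each class equals the configured composition
(`class_composition`); the defaults encode tRNA-depleted exosomes,
snoRNA-rich tissue and scRNA-high serum. Counts are negative binomial with
mean `mu` and variance `mu + phi*mu^2`, one dispersion `phi` shared across
features (default 0.2, a mid-range value for bulk small-RNA data;
`phi = 0` gives the Poisson limit). Library sizes are log-uniform within
`lib_size_range` (default 0.5M–2M reads) and expected per-sample totals are
normalised to the library size, i.e. effects are compositional, as in real
sequencing where depth is set by the machine, not the biology.

**Calibrators.** Ten spike-in features are drawn with sample-independent
means: they are added at library preparation, so they carry no compartment,
library-size or degradation signal. They are excluded from library sizes
and from all biological summaries.

**Sample age.** Each sample gets an age (uniform 0–10, arbitrary consistent
units); every biological feature gets a fixed degradation sensitivity
(uniform 0–1) and its abundance is multiplied by
`2^(-age_effect_sd * sensitivity * age)` before sampling. Because totals
are depth-normalised, the observable effect is compositional: age becomes a
major axis of profile variation (as degradation is in archived specimens)
without changing read totals. Calibrators are exempt. The magnitude of this
effect in real data is not quantified anywhere we could anchor it, so
`age_effect_sd` is a free parameter (default 0.05 per age unit).

**Planted effects.** A `PlantedEffect(feature, contrast, log2fc, scope)`
multiplies the feature's abundance by `2^log2fc` in the positive group of
the named contrast (tumor, exosome, cancer serum, HBV+, cirrhotic, or
transplantation samples), within a compartment scope. The default cohort
plants a concordant onco-miR analog (up +2 in both tumor-vs-normal and
exosome-vs-serum), a discordant control, a cancer-serum marker (+1.95,
i.e. close to four-fold) and an HBV-associated serum miRNA.

**mRNA layer.** Genes are Gaussian in log2 (baseline N(8, 2), per-sample
noise 0.5). For each differentially expressed miRNA, `n_planted_targets`
genes (default 5) are rewired to
`baseline + repression_slope * centered(log2 miRNA) + noise` — pure
transcriptional repression, no ceiling/floor effects. The target table
contains every planted pair with a context score drawn U(−1, −0.45)
(guaranteed below the −0.4 screening cut, so cascade recall measures the
pipeline, not the score draw) plus decoy pairs at `target_density` with
scores U(−1, 0), which straddle the cut and exercise it.

**Survival.** Event times are exponential; the High group's hazard is
multiplied by `exp(survival_beta)`. Censoring is an independent uniform
time C ~ U(0, u) with u solved numerically so the marginal censoring
probability equals `censor_rate`. Exponential + uniform is the simplest
model consistent with a proportional-hazards analysis; nothing in the
pipeline depends on the baseline hazard shape.

**What the generator does not emulate:** read-level artifacts (adapter and
ligation bias, isomiR sequence structure), feature–feature count
correlations beyond the compositional constraint, batch/library-kit
effects, non-proportional hazards, and informative censoring. Passing
tests therefore demonstrate correctness of the statistics under their
stated assumptions, not robustness to these real-data complications.

## Normalization

Library size is the column sum over *non-calibrator* features — spike-ins
must not absorb biological signal. Unlogged CPM is
`count / (libsize * size_factor) * 1e6`; logged CPM is
`log2((count + c) / (libsize * sf + 2c) * 1e6)` with prior count
`c = 0.5`, the offset convention of the weighted linear-model DE framework
this engine mirrors. Calibrator size factors are per-sample geometric means
of calibrator counts, rescaled to unit geometric mean across samples; a
sample whose calibrators are all zero is an error (no pseudocount — such a
library is broken, not small). Whether spike-in factors replace or
complement CPM is analysis-dependent; the pipeline default composes them
with CPM as effective library sizes.

The expression filter keeps features with CPM ≥ `min_cpm` (default 1) in
at least `min_fraction` (default 50%) of the comparison's samples — both
thresholds inclusive, applied per comparison. Quantile normalization maps
every column onto the row-wise mean of per-column order statistics, ties
receiving the mean of their tied reference values. PCA operates on
feature-centered (not scaled) log2 values via SVD.

## Differential expression

Per feature, a linear model is fitted to log2 CPM by weighted least
squares. The design always contains an intercept and a binary group
column; clinical covariates (e.g. sample age, entered as a single
continuous column) and fixed-effect patient indicators for paired designs
are appended. Rank-deficient designs (a covariate confounded with the
group) are rejected with a diagnostic rather than silently dropped.

**Precision weights.** An unweighted fit yields per-feature residual sds;
a LOWESS (span 0.5, fitted on features with positive residual df) of
sqrt(residual sd) against mean log2 count forms the mean–variance trend.
Each observation's sd is predicted from the trend at its fitted log2
count, and its weight is predicted-sd to the power −4; predictions beyond
the trend's range are clipped to its endpoints.

**Empirical-Bayes moderation.** Residual variances s² with d residual df
are shrunk toward a prior: s̃² = (d0·s0² + d·s²)/(d0 + d). The prior
(d0, s0²) is fitted by moment matching on log s²: the excess of
var(log s²) over trigamma(d/2) identifies d0 through trigamma inversion
(Newton iteration), and s0² follows from the mean. When there is no excess
variance, d0 = ∞ and all features share the prior variance. The moderated
t is the coefficient over its unscaled sd times s̃, referred to a t
distribution with d + d0 degrees of freedom (normal when d0 = ∞). Imposing
d0 = 0 recovers the classical per-feature t exactly; imposing d0 = ∞
yields the pooled-variance t (the pooled value being the arithmetic mean
of the per-feature variances). Benjamini–Hochberg step-up adjustment is
applied per contrast; "significant" means adjusted p < 0.05, two-sided,
throughout.

Matched-tissue contrasts default to the paired design; whether a given
real analysis was paired is often unclear, so both are supported.

## Concordance

Two DE tables are compared set-wise: union of significant features,
intersection with per-sample-type expressed sets, sign concordance of
log fold changes (a logFC of exactly 0 carries no direction and is
excluded), both-significant and both-significant-same-sign, plus the
Pearson correlation of logFC pairs over the both-significant set (absent
with fewer than 3 pairs). Direction validation counts
discovery-significant features present in the validation table (undetected
features leave the denominator) whose sign is preserved.

## Target cascade

Four ordered filters over a miRNA→gene candidate table with weighted
context scores: (1) miRNA expression — 75th percentile (linear
interpolation between order statistics) of log2 CPM strictly above 10;
(2) context score strictly below −0.4; (3) directional consistency — per
gene, the fraction of its targeting DE miRNAs in the majority direction
must strictly exceed 0.75, and only majority-direction pairs survive (the
published wording of this rule is internally inconsistent — "more than
75%" versus "all" — and this majority-fraction reading is the implemented
resolution, not a silent assumption); (4) anticorrelation — Pearson
r < 0 over shared samples (Spearman available; no p-value threshold, since
the published rule is a sign rule). Anticorrelation defaults to tumor
samples, configurable, as the compartment in which the repression is
expected to act. Note that r < 0 alone passes about half of null pairs —
the cascade's specificity comes from the conjunction of filters, which the
null-data property test documents.

Enrichment of the surviving genes is a one-sided hypergeometric
over-representation test per gene set, BH-adjusted across sets, reported
at adjusted p < 0.01; the universe is the detected-gene set (in the
pipeline: genes detected in at least half the samples). Up/down gene
classes for enrichment use adjusted p < 0.05 and |logFC| > 0.5.

## Survival

High/Low groups split patients at the median expression (ties to Low —
deterministic and conservative toward the Low group). Kaplan–Meier is the
product-limit estimator; without censoring it equals the empirical
survival function exactly. The log-rank test uses the standard
hypergeometric variance per event time. The Cox fit is univariate on the
binary group with Breslow tie handling, Newton–Raphson from beta = 0,
tolerance 1e-8, at most 50 iterations with step-halving on partial-
likelihood decrease; a group without events or a monotone likelihood is
reported as non-converged with absent estimates rather than a divergent
number. The reported p is the two-sided Wald test (the score test at
beta = 0, which equals the log-rank statistic absent ties, is available
separately). The screen fits every requested feature and applies
Bonferroni with m = number of features tested.

## Numerical and testing choices

Problem sizes in the test and acceptance suites are chosen to make
Monte-Carlo error small relative to the property being checked while
keeping the default run fast: null calibration uses 5000 features at
n = 10/group; power uses 10 planted features at n = 15/group with NB
dispersion 0.2; concordance recovery uses 100 replicates at n = 30/group;
cascade recovery plants 20 pairs among 200 decoys over 1000 genes (the
gene panel is wide enough that decoy pairs rarely collide with planted
genes, so recall reflects the filters, not collision luck); survival
screen power is measured at the m = 100 Bonferroni threshold over many
single-feature replicates — the factor m is fixed, so null features cannot
change the planted feature's call — with full screens run separately to
exercise the machinery. The screen's power scenario (hazard ratio 3,
n = 78) assumes complete follow-up.

Determinism: every stochastic routine takes an explicit seed or
`numpy.random.Generator`; the pipeline manifest records a SHA-256 hash of
every output, and reruns with the same config and seed are byte-identical.

## Known limitations

The DE engine implements the single-channel weighted-LS path only: no
random effects, no array quality weights, no duplicate-correlation for
repeated measures beyond fixed-effect pairing. isomiRs are ordinary
features; no collapsing rules. The Cox fit is univariate binary by design;
multivariable adjustment, Efron ties and proportionality diagnostics are
out of scope. Enrichment consumes user-supplied gene sets as flat sets —
no ontology graph handling or term de-redundancy.
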