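# Methods

This note documents the models, the synthetic-cohort generator, the
numerical choices, and what the test suite does and does not establish.

## Control-referenced signature scoring (ALADIN, IGS)

Scores are a three-level average. For probe p and sample s,
z_ps = (x_ps − μ_p)/σ_p, where μ_p and σ_p are the mean and the n−1
standard deviation of the designated normal-control (NC) cohort. Gene-level
z is the unweighted mean over the gene's probes; a signature score is the
unweighted mean over the signature's genes. Consequences worth knowing:

- NC samples self-referenced have per-probe z mean 0 and sd 1 exactly, so
  every NC cohort mean signature score is 0 by construction.
- Averaging on the z scale (not the raw scale) makes the score invariant to
  probe-specific additive offsets, which is why the generator plants fixed
  per-probe offsets: collapsing by raw means would not remove them.
- Probes with zero NC variance are dropped and listed, not epsilon-inflated;
  an epsilon would let an arbitrary constant dominate gene averages.
- At NC cohort sizes around 20, E[1/σ̂] exceeds 1/σ by roughly 3%
  (3/(4(n−1))), so a planted shift of Δ log2 units with unit probe noise
  scores slightly above Δ on average. Tests account for this.
- The reference is always built on the discovery NC cohort and can be
  serialized; held-out samples are scored without touching their own
  statistics.

The IGS cell-type scores use the identical machinery over marker panels and
are meant for ranking and group separation, not absolute abundance.

## Consensus severity score

PCA is probe-centered SVD; the sign convention makes the largest-magnitude
loading of each component positive, so projections are deterministic.
Variance explained is reported as sample-covariance eigenvalues (ddof 1).
Per clinical group a maximum-likelihood bivariate Gaussian (covariance
denominator n, plus a 1e-6 ridge) is fitted on (PC1, PC2) of the discovery
cohort only. A sample's severity is

    score(x) = 10 · Σ_g w_g · P(g | x),  w = {NC: 0, AAP: 0.5, ATAU: 1},

with equal group priors (cohort sizes are design choices, not population
frequencies) and posteriors computed from log-densities with a max-shift,
so points far outside all three densities still score without under/overflow.
The score is bounded in [0, 10] and equals exactly 5 wherever the three
densities agree. The mapping from posterior to severity is a design choice
among several that satisfy the boundedness and ordering requirements; a
normalized projection onto the NC→AT/AU centroid axis is available as
`method="axis"` for sensitivity analysis. On well-separated cohorts the
posterior variant saturates (medians near 0/5/10); the ordering and the
nonparametric group comparisons, not the absolute medians, are the
meaningful output.

Validation-set support is deliberately leakage-free: held-out samples are
projected through the discovery centering and loadings. The validation
clustering check uses 1 − Pearson correlation over the signature probes with
average linkage, cut at two clusters, scored as the best two-way matching
accuracy against AA vs NC.

## Differential expression

Per probe, ordinary least squares of log2 expression on intercept + group +
covariates (gender by default). Residual variances are shrunk across probes
toward a scaled inverse-chi-square prior fitted by method of moments on
log-variances (digamma/trigamma matching, Newton inversion of trigamma);
when the observed spread of log-variances does not exceed chi-square
sampling noise, the prior df is infinite and the common variance is the
arithmetic mean. The moderated t uses the shrunken variance with df
augmented by the prior df. `moderated=False` gives the ordinary t for
sensitivity analysis. The implementation is cross-checked against
`limma::eBayes` in the test suite. BH adjustment and the rank tests
(Mann–Whitney with exact enumeration for tie-free n ≤ 12, tie-corrected
normal approximation otherwise; Kruskal–Wallis) are delegated to
statsmodels/scipy behind the module's interface, with a brute-force
step-up oracle and a full permutation oracle in the tests. Signature
selection takes q < 0.05 and |log2FC| ≥ log2(1.5), sorted by p with probe-id
tie-breaks for deterministic output.

## Batch correction

The standard two-step parametric empirical-Bayes location/scale adjustment:
probes are standardized under a model with one-hot batch indicators plus
protected covariates (group, gender); per-batch per-probe locations get a
normal prior and scales an inverse-gamma prior, both moment-matched across
probes, solved by the usual fixed-point iteration; shrunken batch
parameters are removed and the covariate-bearing standardization mean is
restored. Implementation matches `sva::ComBat` to ~1e-4 on test fixtures.
Degenerate designs (single-sample batches, every-sample-its-own-batch,
batch confounded with a covariate) are rejected with named errors. Probes
with zero pooled or within-batch variance are location-adjusted only and
counted in a warning. Because the batch locations are shrunk, per-probe
grand means move slightly (order of the shrinkage residual); exact
preservation would hold only without shrinkage. A single batch returns the
input unchanged, which is also the validation-set path (`--no-batch-correct`).

## Infiltrate mixture model

Bulk linear-scale expression is modeled as a convex mixture
(1 − Σ f_c)·skin + Σ_c f_c·ref_c. Fractions are estimated per sample by
NNLS on the shared gene space with coefficients renormalized to the
simplex; burden = 1 − skin coefficient; per-type shares divide by the
burden (0 when the burden is 0). The basis must be full rank and share
≥ 100 genes with the data. On noiseless interior-simplex mixtures recovery
is exact to numerical tolerance. Gene-level linear input is obtained by
collapsing probes with a log2-scale mean and exponentiating; the fixed
probe offsets survive this collapse as gene-specific multiplicative
distortions, which is the main driver of the residual burden error
(≈0.3–0.4 percentage points MAE, and a slight positive bias for near-zero
burdens) on noisy cohorts.

The Th1:Th2 statistic is log2 of the ratio of mean linear-scale Th1-marker
to Th2-marker signal — linear-scale means so that doubling the Th1 signal
gives exactly +1 and the statistic is free of the NC reference — tested
AA (AAP ∪ AT/AU) vs NC by Mann–Whitney U.

## Synthetic cohort generator

The generator is the study-design stand-in and its defaults are the
conditions all power-style checks run at:

- Group sizes 23 NC / 20 AAP / 20 AT/AU (discovery-style); a 13/8/12
  validation cohort is generated separately without batch structure.
- ~2000 genes with 1–4 probes per gene (probabilities 0.4/0.3/0.2/0.1),
  fixed per-probe offsets N(0, 0.3), i.i.d. log2 noise sd 0.4, 20 control
  probes, 40 sex-chromosome probes, present/absent calls i.i.d. at 1%.
- Reference profiles: skin background log2 ~ U(5, 10); each immune profile
  tracks skin except its markers (6 per cell type), which are nearly silent
  everywhere (log2 ~ 3–5) and strongly expressed in their own type
  (log2 ~ 12–14, dominance enforced ≥ 8×). This mirrors how e.g. CD8A
  behaves in scalp tissue and is what makes ~1% admixture detectable.
- Admixture fractions per sample are drawn around group means (cv 0.2):
  totals 0.2% NC / 0.8% AAP / ~1.45% AT/AU, CD8-dominated in disease, Th1
  planted at twice Th2 in disease and equal in NC. The absolute totals are
  emulation choices consistent with a sub-percent-to-1.5% burden range.
- Signature shifts (log2): CTL +0.6/+1.2, IFN +0.5/+1.0, KRT −0.5/−1.0 for
  AAP/AT-AU. Mixing is linear-scale first, log2 afterward, so marker signal
  dilutes realistically; signature shifts are additive on log2.
- Batch effects: per-batch per-probe N(mean_b, 0.2) additive shifts on a
  balanced two-batch design; gender effects per gene N(0, 0.1) plus
  dimorphic sex-chromosome probes (all gender structure switches off when
  the gender sd is 0, giving a clean null generator).
- Disease duration ~ U(0, 12) years for AA samples; optionally CTL/IFN
  shifts are multiplied by an attenuation factor for AT/AU samples with
  ≥ 5 years, to exercise the duration-stratified comparison.

Every draw is recorded in a `GroundTruth` object that round-trips through
JSON, so downstream stages are scored as parameter recovery.

What the generator does **not** emulate: probe-level intensity artifacts,
correlated gene-gene noise, realistic gene-length/GC structure, dependence
between detection calls and intensity, or uncertainty in the reference
profiles themselves. Passing tests therefore demonstrate correctness of the
algorithms under the stated generative model, not clinical performance on
real arrays.

## Problem sizes and determinism

Unit and behavioural tests run cohorts of ~2000 genes (≈4000 probes ×
63 samples), with 10–20 replicate seeds for calibration and power checks;
the end-to-end determinism check uses a 96-sample × ~19,500-probe cohort,
chosen as a realistic full-array scale that still runs in seconds. All
randomness flows through `numpy.random.default_rng` seeded from a single
integer; identical configuration implies bit-identical output, which the
suite asserts at scale.

## Known limitations

- The severity mapping saturates on well-separated data; scores should be
  read as ordinal risk, not calibrated probabilities.
- Absolute infiltrate fractions require a reference basis; with user-supplied
  profiles on real data the estimates inherit whatever bias those profiles
  carry. The IGS ranks need no references and are the more robust output.
- The probe→gene map must be one-to-one; multi-mapped probes should be
  resolved or dropped upstream.
- Non-parametric priors for the batch correction and gene-level (as opposed
  to probe-level) differential expression are out of scope.
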