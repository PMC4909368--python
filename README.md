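# aa-sigscope

Signature scoring and severity quantitation for alopecia areata (AA)
transcriptomics. Scalp-biopsy expression profiling of AA patients shows a
graded molecular gradient from normal controls (NC) through patchy disease
(AAP) to totalis/universalis (AT/AU). This package re-implements, as a
tested pipeline over a fully synthetic ground-truthed cohort, the scoring
machinery that quantifies that gradient:

- **ALADIN scores** — three control-referenced signature z-scores per
  sample. For each probe, z = (x − μ_NC)/σ_NC against the normal-control
  cohort; gene z = mean of its probes' z; signature score = mean gene z over
  the cytotoxic-T-lymphocyte (CTL), interferon-response (IFN) and hair-
  keratin (KRT) gene sets. CTL and IFN rise with disease, KRT falls.
- **Consensus severity score** — samples are projected onto the first two
  principal components of the disease-signature probes; each clinical group
  gets a bivariate Gaussian density, and a sample's severity is the
  posterior-weighted group label, `score(x) = 10 Σ_g w_g P(g|x)` with
  w = {NC: 0, AAP: ½, AT/AU: 1}, bounded in [0, 10].
- **Immune infiltrate quantitation** — immune-gene-signature (IGS) scores
  per cell type (CD8 T, NK, Th1, Th2) for ranking and separation tests;
  absolute infiltrate fractions by non-negative least squares of
  linear-scale expression on [skin, cell-type] reference profiles
  (burden = 1 − skin coefficient); and the per-sample log2(Th1/Th2)
  marker-signal ratio tested AA vs NC by Mann–Whitney U.
- **Supporting statistics** — probe filtering (sex chromosomes, control
  probes, unannotated probes, never-present probes), parametric
  empirical-Bayes location/scale batch correction protecting group and
  gender, and moderated-t differential expression with BH FDR control and
  |FC| > 1.5 / FDR < 0.05 signature selection.

Because the original raw arrays are not bundled, a synthetic cohort
generator (`aa_sigscope.synthetic`) emulates the study design — 23/20/20
discovery groups, multi-probe genes, batch and gender effects, and
linear-scale admixture of immune-cell profiles at realistic ~0.5–2%
fractions — and records every planted parameter so each stage is evaluated
as a parameter-recovery problem.

## Worked example

```sh
python analysis/01_simulate_cohorts.py --seed 1
python analysis/02_preprocess.py
python analysis/03_differential_expression.py
python analysis/04_severity_terrain.py
python analysis/05_immune_infiltrate.py
python analysis/06_aladin_scores.py
```

The drivers write tables under `results/` and print their findings. With
seed 1 the severity stage reports

```
median severity: NC 0.00, AAP 5.00, AT/AU 10.00
NC_vs_AAP     p = 3.8e-09
NC_vs_ATAU    p = 3.8e-09
AAP_vs_ATAU   p = 4.7e-10
validation clustering: ... two-cluster agreement with AA/NC labels = 1.00
```

i.e. the three groups are fully graded on the 0–10 scale and separable by
nonparametric tests, and the discovery signature splits the held-out
validation cohort perfectly. The infiltrate stage reports

```
estimated total burden (%): NC 0.46, AAP 0.79, AT/AU 1.34 (planted 0.15 / 0.82 / 1.44)
Th1:Th2 log-ratio, AA vs NC: p = 2.6e-04, median_AA = 0.46, median_NC = 0.14
```

— the mixture model recovers the planted sub-percent infiltrate burden
(graded ~0.8% → ~1.4% with severity) and detects the planted Th1
polarization of disease samples.

The same steps are scriptable through the `aa-sigscope` CLI
(`simulate`, `preprocess`, `de`, `severity`, `infiltrate`, `aladin`); see
`aa-sigscope --help`.

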