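# episig

Disorder-specific DNA methylation **episignatures** for rare-disease
diagnostics: simulation, signature discovery, calibrated one-vs-rest
classification, clustering/MDS evidence, imprinted/repeat-locus screening,
and three-way clinical-style reporting.

Many Mendelian neurodevelopmental disorders (defects in chromatin and DNA
methylation machinery, imprinting disorders, fragile X) leave reproducible
genome-wide methylation patterns in peripheral blood. Given a probe × sample
matrix of array beta values (methylation fractions in [0, 1]), a reference
cohort of affected cases and population controls per disorder, one can
derive each disorder's episignature and then classify new patients —
typically patients with a variant of unknown significance (VUS) or an
unexplained phenotype. This package implements that analysis end to end,
together with a synthetic-cohort generator that provides ground truth for
every stage, so the whole pipeline is testable at desk scale.

## The model

For each disorder *d* with selected probe set *P_d*:

- **Signature discovery.** Probes are selected by a per-probe Welch test of
  cases vs controls with Benjamini–Hochberg correction (α = 0.01) and an
  absolute effect floor |Δβ| ≥ 0.10, ranked by |Δβ|·(−log₁₀ p) and truncated
  to 500 probes.
- **Classification.** A linear maximum-margin classifier (SVM, C = 1,
  balanced class weights) on β over *P_d*, trained one-vs-rest: positive
  class = cases of *d*, negative class = all other disorders' cases plus
  controls. The decision value is f = w·β + b.
- **Calibration.** Decision values map to a **Methylation Variant
  Pathogenicity (MVP) score** through Platt scaling,

      MVP(f) = 1 / (1 + exp(A·f + B)),

  with (A, B) maximising the Bernoulli likelihood of Platt's smoothed
  targets on *out-of-fold* decision values from stratified cross-validation.
- **Decision bands.** MVP > 0.5 positive, MVP < 0.1 negative, the closed
  band [0.1, 0.5] inconclusive. Technical replicates must agree within 0.05.
- **Secondary evidence.** Ward-linkage hierarchical clustering and classical
  MDS (principal coordinates) of the test sample against references, with a
  centroid margin in [−1, 1] quantifying whether the sample sits with cases,
  with controls, or in between.
- **Locus screening.** Imprinted DMRs (normally β ≈ 0.5) and repeat-
  expansion promoter loci (normally β ≈ 0) are screened by locus-mean
  z-scores against the control reference range; the aberrant cell fraction
  is estimated under a linear two-population mixture, with a ≈20% detection
  floor imposed by normal control variability.

## Worked example

```python
import episig as ep

cohort = ep.simulate_cohort(ep.SimulationConfig(
    n_background_probes=3000,
    disorders=(ep.DisorderSim("SYND_A", 80, 0.15, 12, 3),
               ep.DisorderSim("SYND_B", 80, 0.15, 12, 3)),
    n_controls=40, n_test_controls=4, seed=19,
))
kdb = ep.build_kdb(cohort.beta, cohort.sheet, cv_folds=6, seed=19)
res = ep.score_sample(kdb.classifiers, cohort.beta.sample("test_SYND_A_0000"))
print(res.scores)
```

prints (from `examples/03_train_and_score.py`):

```
sample                 truth          SYND_A   SYND_B
test_SYND_A_0000       SYND_A          0.930    0.019
test_SYND_B_0000       SYND_B          0.019    0.930
testctrl_0000          control         0.019    0.018
```

Held-out cases score near 1 for their own disorder (positive, > 0.5) and
near 0 for the others; controls score near 0 everywhere (negative, < 0.1).
`examples/` contains one short script per capability: simulation, signature
discovery, training/scoring, clustering evidence + reporting, and locus
screening. A thin CLI mirrors the same steps:

```
episig simulate --out sim/
episig train --beta sim/beta.tsv --sheet sim/samples.csv \
             --annotation sim/annotation.csv --kdb kdb/
episig score --beta sim/beta.tsv --kdb kdb/ --out scores.csv
episig report --beta sim/beta.tsv --sheet sim/samples.csv \
              --annotation sim/annotation.csv --kdb kdb/ --sample <id>
```

## Layout

- `src/episig/` — `types` (containers), `io` (readers/writers + the
  versioned knowledge database), `simulate`, `signature`, `classify`,
  `evidence`, `loci`, `report`, `pipeline`, `cli`.
- `docs/methods.md` — model, assumptions, parameter choices, limitations.
- `tests/` — unit, property and end-to-end suites.
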