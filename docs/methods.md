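# Methods

## Scope and data model

The analysis substrate is a probe × sample matrix of methylation beta
values (fractions of methylated signal, in [0, 1]), with probes in rows and
samples in columns — the usual array-export orientation. Transposed input
is never fixed silently; it surfaces as duplicate-identifier failures.
Missing values are permitted in input; a sample missing more than 10% of a
signature's probes is refused a score for that disorder (recorded as a
coverage error, not an exception), because the classifier is a fixed-length
dot product. Remaining missing probes are mean-imputed from the signature's
control reference. Genomic coordinates are 1-based; the genome build is
free-text metadata and never interpreted.

The knowledge database (KDB) is a versioned directory: a JSON manifest,
one JSON file per signature and per classifier, and a CSV of per-probe
control means/SDs. JSON serialisation preserves floats exactly, so a
persist/load round trip reproduces weights and Platt parameters bit for
bit. Every classifier must reference a signature of the same version;
reports carry the KDB version.

## Signature discovery

Probe selection runs a per-probe Welch two-sample test (cases vs controls)
on the beta scale, Benjamini–Hochberg correction at α = 0.01, and an
absolute effect floor |Δβ| ≥ 0.10. Survivors are ranked by
|Δβ|·(−log₁₀ p) with a lexicographic probe-id tie-break — this makes the
truncation at `max_probes` (default 500) reproducible — and p-values are
floored at 1e-300 before the log. Clinical pipelines in this area often use
moderated-variance tests and matched-control selection; the Welch/BH engine
here is a deliberate, clearly-isolated substitute (swap it behind
`SelectionParams`), and control matching is reduced to "all reference
controls". A signature is classed `moderate` (reduced sensitivity) when it
has fewer than 50 probes or fewer than 10 training cases, else `robust`.
Zero surviving probes raise an explicit error rather than returning an
empty signature.

Merging signatures (for protein-complex-level groups) takes the union of
probes and recomputes means as sample-count-weighted averages of the parts,
which equals pooling the underlying reference samples when the parts came
from disjoint cohorts.

## Classification and calibration

One linear SVM per disorder (C = 1, balanced class weights) on the
signature probes; positive class = that disorder's reference cases,
negative class = every other disorder's cases plus all controls. Linear
margins suit the p ≫ n regime of probe matrices; training is on beta values
directly (not M-values), consistent with the simulator's ground truth.

Platt calibration fits P(f) = 1/(1+exp(A·f+B)) by minimising the Bernoulli
negative log-likelihood with Platt's smoothed targets
t⁺ = (N⁺+1)/(N⁺+2), t⁻ = 1/(N⁻+2) (L-BFGS-B with analytic gradient, a
1e-8 ridge on (A, B) to pin the degenerate constant-decision case, and
softplus/logistic evaluation throughout, so perfectly separated decisions
still yield a finite optimum). Critically, calibration uses **out-of-fold**
decision values from stratified K-fold CV (default 10-fold) before the
final weights are refitted on all data: in-sample decisions on separable
p ≫ n data would make every score saturate, and permuted-label models
would not look flat. The MVP score is evaluated through the numerically
stable logistic and clipped to the open interval (0, 1); |f| = 1e4 cannot
overflow.

Decision bands follow the strict/closed convention: score > 0.5 positive,
score < 0.1 negative, the closed band [0.1, 0.5] inconclusive (so 0.5
itself is inconclusive). Multiple simultaneous positives are all reported
and flagged for review; no argmax suppression, since the one-vs-rest
classifiers are independent.

Because the decision value is linear in beta, a linear case/control mixture
at fraction m moves the decision value exactly proportionally, and the
monotone Platt link makes the MVP score non-decreasing in m. Halving the
effective gene dosage (heterozygous-female dilution, dosage factor 0.5)
lands the decision value exactly midway between the full-case and control
decisions.

## Clustering and MDS evidence

Secondary evidence quantifies what a reviewer reads off the plots: Ward-
linkage/Euclidean agglomerative clustering of references plus the test
sample cut at k = 2 (side assignment by reference majority; if both
reference groups fall on one side the signature is declared non-separating),
and the centroid margin (d_control − d_case)/max(d_control, d_case) in
[−1, 1]. Calls: `with_cases` / `with_controls` when tree side and a margin
of at least 0.2 agree, `intermediate` otherwise — the machine-checkable
version of "plots between the two". The floor of 0.2 is configurable. The
embedding is classical metric MDS (principal coordinates) over the
signature probes; the axis sign is fixed by forcing the case centroid to
non-negative first coordinate. Within-cloud distances are noise-dominated,
so only the rank order of large (between-cloud) distances is meaningful in
2-D, and that is what the tests assert. PCA would serve equally behind the
same interface; PCoA on Euclidean distances is the default (equivalent up
to the distance choice).

## Locus screening

Imprinted DMRs are screened via the locus mean (≥ 3 usable probes) against
the control reference range: a call requires |z| > 3 **and**
|Δ| > 0.10 — the combined guard protects against tiny control SDs — and an
estimated aberrant fraction of at least 0.2. The fraction estimator assumes
the same linear two-population mixture the simulator uses:
|observed − control| / |target − control| with target 1 (gain) or 0 (loss),
clipped to [0, 1]. With control variability of ~0.02 in beta units, 30%
mosaicism is reliably detected and 10% is not — the practical >20%
detection floor. Elevated repeat loci in females are always reported
indeterminate (the unaffected X masks the signal); affected males show
near-full promoter hypermethylation and are called directly.

## Report composition

Rules apply in order, first match deciding: (1) positive score confirmed by
clustering → positive; (2) positive score contradicted by clustering
(clusters with controls) or not confirmed (intermediate) → inconclusive
with a discordance flag — the spec'd rule table covers only the
confirmed/contradicted cases, and mapping the unconfirmed intermediate case
to inconclusive is its natural completion; (3) all scores negative but
cluster evidence intermediate and trending case-ward → inconclusive;
(4) any score in the inconclusive band → inconclusive; (5) a non-normal
locus call → positive for that locus; (6) otherwise negative. Placing locus
positives after the episignature inconclusive rules is a declared choice
(no precedence is established practice); every non-trivial outcome carries
a review flag naming its evidence item, and phenotype-level expert
judgment is explicitly out of scope. Percentages in cohort summaries are
half-up rounded to one decimal.

## The simulator

The generator emulates exactly the data features the pipeline relies on,
with defaults that define the standard panel used by the test suite:

| parameter | default | meaning |
|---|---|---|
| background probes | 20,000 | three-component Beta mixture, weights 0.45/0.45/0.10 near-0/near-1/intermediate — the canonical bimodal genome-wide shape |
| disorders | 3 × (200 probes, Δβ = 0.15, 20 cases, 10 test cases) | signature probes shifted on the beta scale, clipped to [0, 1] with a logged warning |
| controls / test controls | 100 / 30 | reference and held-out populations |
| technical_sd | 0.01 | additive Gaussian noise per observation, clipped; the paper-scale replicate magnitude is not published, so this is a declared stand-in exposed in config |
| locus_biological_sd | 0.02 | per-sample locus-level control variability; sets the ~20% mosaicism floor |
| imprinted / repeat loci | 2 × 10 probes at β≈0.5; 1 × 10 probes at β≈0.05 | aberrant samples mix toward 1/0 (imprinted) or 0.9 (repeat) |

Signature-probe baselines are drawn uniformly from an interval that leaves
room for the shift, so the planted case-control difference equals the
configured delta without clipping at default settings. Shifts are applied
on the beta scale (not logit/M-value scale) to keep the ground truth
directly interpretable for delta-recovery tests — a declared deviation from
common M-value practice. Each sample's noise stream derives from a stable
blake2b hash of (seed, sample id), so identical (config, seed) runs are
bitwise identical and adding samples never perturbs existing ones.
Replicates reuse their source sample's biology stream and differ only in
technical noise. Batch effects are additive per-batch offsets assigned
round-robin.

Not modelled: probe-level biological covariance, cell-type composition,
age/sex methylation drift, and array chemistry artefacts. Passing tests
therefore demonstrate the correctness and calibration of the machinery
under the declared generative model, not clinical performance on real
arrays, where confounder handling and matched references carry much of the
difficulty.

## Problem sizes and numerical choices

The end-to-end checks run on the standard panel above (~20,600 probes,
220 samples); probe-recovery and mosaic-monotonicity checks repeat across
20 seeds at 20,000-background and 1,500-background scale respectively, and
locus power uses 200 replicates per condition — sizes chosen so the full
suite exercises every claim in minutes on one CPU. Degenerate inputs are
handled explicitly: zero technical noise is the identity, empty cohorts and
single-class training raise typed errors, equal centroid distances give
margin 0 (intermediate), and constant-decision Platt fits return a flat
link at the smoothed prior.

## Known limitations

- The probe-selection thresholds and control-matching of clinical
  episignature pipelines are not public; the defaults here are declared
  substitutes, so absolute signature sizes should not be compared to
  clinical panels.
- Scores are calibrated within the simulated generative model; real-world
  MVP calibration depends on reference database composition.
- The locus fraction estimator is unbiased only under the linear mixture
  assumption and a correct control mean.
- The clinical headline yields computed from published outcome counts are
  arithmetic on inputs, not a re-analysis of patient data.
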