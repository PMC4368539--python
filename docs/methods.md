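# Methods

## Design and data model

The pipeline analyses a factorial RPPA experiment: 2 genotypes (control,
trisomic) × 2 CFC paradigms (SC: shock-context, cannot learn; CS:
context-shock, learns) × 2 drugs (saline, memantine) = 8 groups of mice.
Brains are dissected into regions (default hippocampus, cortex) and
subcellular fractions (default nuclear, cytosolic, membrane); each lysate
is spotted as a five-point dilution series in three replicates, paired with
a total-protein stain signal. A *measurement* is one spot; an *instance*
(protein × region × fraction) is the unit of all downstream inference.

## Synthetic-data generator

The generator is first-class, tested code: it is what makes the statistics
and the classifier verifiable against planted truths.

* **Group means.** An effect table gives each instance a true mean
  normalized abundance per group (positive, linear scale). Archetype
  constructors build these means so that the implied pairwise contrasts
  equal requested percent magnitudes exactly; e.g. `B_PLUS_FL` with
  NL = 40, baseline = 20 yields B = +20%, FL = +20%, RL = +20%, NL = +40%.
* **Stain and dilution.** The stain signal carries the loading and halves
  at each dilution step (the step factor is configurable; twofold is the
  default). The raw signal is `mean × stain × exp(noise)`, so raw/stain is
  dilution-free and equals the planted mean exactly at zero noise.
* **Noise.** Multiplicative log-normal at the three nested levels the
  analysis model estimates — mouse (default SD 0.05), dilution series
  within mouse (0.03), spot residual (0.05). Intensities are positive and
  the model is fitted on logs, which makes log-normal the natural choice;
  the magnitudes are moderate values typical of replicate RPPA spots and
  are user-tunable (no published variance components exist for this
  design). Draws are independent per instance, mirroring the per-protein
  fitting; real arrays would correlate mouse effects across proteins, which
  this generator deliberately does not emulate (it does not affect
  per-instance inference).
* **Contamination.** Technical outliers multiply a spot's log residual by
  `outlier_scale` (default 10) at rate `outlier_rate` (default 0);
  low-signal screenings force all of an instance's means to 0.05 at rate
  `low_signal_rate` (default 0), exercising the reliability floor.
* **Sizes.** Groups default to 8 mice (the study design used 7–10;
  the midpoint keeps simulated power representative), 85 proteins, and the
  full region × fraction grid.

What passing recovery tests show is therefore internal consistency — the
estimators and classifier recover what this generative model plants — not
robustness to features the generator omits: spatial array artifacts,
print-run batch effects, scanner saturation, non-log-normal tails, or
cross-protein correlation.

## Preprocessing

* Normalization: `normalized = raw / stain` per spot; non-positive stain
  flags the spot invalid instead of dividing.
* Reliability floor: an instance whose **median** normalized intensity is
  below 0.1 is discarded wholesale. The rule is instance-level because the
  screening being judged unreliable is the antibody in that fraction, not
  an individual spot; the boundary (median exactly 0.1) is retained.
* k-SD exclusion: per instance, mean and sample SD are computed over all
  unflagged spots pooled across groups (pooling level configurable to
  per-group), and spots deviating **strictly more** than k = 3 SDs are
  excluded in a single pass — no re-iteration, so the rule cannot cascade.
  A value exactly at 3 SD is "within" and retained. Instances left with
  fewer than 3 usable spots are unestimable.
* An optional MAD rule within replicate triplets exists for gross technical
  outliers but is **off by default**, so the documented 3-SD rule is the
  only active spot exclusion.

Nothing is deleted: rows gain boolean `qc_*` flags and flagged spots never
reach the model.

## Estimation

Each of the nine contrasts is fitted as its own two-group model (the
reported quantities are pairwise mean differences, so a global 8-group
model would only complicate the variance structure):

    log y ~ group + (1 | mouse) + (1 | dilution-series within mouse) + residual

REML via statsmodels `MixedLM`. The log scale follows from the
multiplicative dilution design and the percent-difference reporting; a
linear-scale option exists for sensitivity checks. Back-transformation:
percent = `100·(exp(β)−1)`, SEM by the delta method
(`100·exp(β)·se(β)`). p-values use a t reference with
df = n_a + n_b − 2: mice are the independent units, and the normal
reference MixedLM reports would be anti-conservative at 7–10 mice per arm.

Degenerate fits (zero within-arm variance, non-convergence, non-finite
standard errors) fall back deterministically to the nested means-of-means
estimator — replicates → dilution means → mouse means — with a Welch test
on mouse-level means; with zero variance the p-value degenerates to 0
(means differ) or 1 (equal). Fallbacks are recorded per result
(`method` column) and logged, never silent. On balanced data the
mixed-model fixed effect and the nested means-of-means coincide exactly
(the within-mouse covariance is exchangeable, so GLS weights every mouse
equally); the test suite asserts this equality at 1e-8 on datasets kept
balanced by construction, because a spot removed by the k-SD rule
unbalances the nesting and the two estimators then weight mice differently.

Significance is Bonferroni-gated per region × fraction family: m = number
of proteins analysed there, threshold α/m (0.05/73 ≈ 6.85·10⁻⁴ for the
largest hippocampal family). The family is per fraction because that is
the scale at which protein panels were screened and reported.

## Pattern classification

Inputs are the five informative contrasts (NL, FL, B, RL, B-tm) per
instance. Non-significant terms contribute zero to sums (the sums are of
*named significant effects*; a `point_estimate` policy exists for
sensitivity analysis). A sum x matches a target when |x − target| ≤
tolerance (default 10 percentage points, absolute) and, for non-zero
targets, sign(x) = sign(target) — the sign gate prevents a significant
decrease from "explaining" an increase of similar size. The sign test is
applied to the summed value, not to each term: a drug response can
legitimately overshoot and be partially walked back in rescued learning.

With NL significant, candidates are evaluated in fixed precedence —
FL = NL; B = NL (FL silent); B + FL = NL; then the memantine-requiring
family RL = NL (B-tm silent); B-tm = NL or B + B-tm = NL (RL silent);
B-tm + RL = NL; B + RL = NL (B-tm silent); B + B-tm + RL = NL — returning
the first admissible match; admissibility requires the candidate's dynamic
terms significant. The precedence is simplest-explanation-first and never
attributes to the drug a response already adequate without it. Unmatched
NL-responders are `NL_UNRESOLVED` with the closest candidate's residual
recorded for diagnostics. With NL silent but B significant, the instance is
a baseline abnormality: compensated in FL (opposite-sign FL cancelling B),
compensated by the drug (B + B-tm + RL ≈ 0 with FL silent), or
uncompensated. Remaining instances are single-comparison responders or
stable.

Each assignment carries `residual_pp = |sum − target|` and a band
(within/beyond 10 pp). The published rosters' own ≤10%/>10% split is not
consistently derivable from the printed values under either an absolute or
a relative reading, so the band is reported but never asserted against
those rosters. Similarly, at the default 10 pp tolerance the classifier
reproduces the published tight-band roster entries but leaves loose-band
entries (sums up to ~40 pp from NL, e.g. pERK cytosolic) unresolved; the
family-membership test therefore runs at a 40 pp tolerance, the smallest
round value covering the printed rosters, and the default stays at 10
because it reproduces the most worked examples.

## Validation studies

All simulation studies are deterministic given a seed and run the full
pipeline (generate → preprocess → fit → gate → classify):

* **Zero-noise exactness**: planted contrasts of −50…+120% recovered to
  machine precision.
* **Oracle agreement**: mixed-model vs nested-means point estimates on 50
  balanced noisy datasets, max |Δ| < 1e-8 (observed ~1e-13).
* **Effect recovery**: planted NL magnitudes {−50, −20, 0, +20, +50, +120},
  34 replicates each (204 fits), 8 mice/arm, default noise: mean absolute
  error ≈ 2.6 pp (asserted < 3).
* **Type-I control**: 1000 global-null instances gated at 0.05/73:
  family-wise significant fraction ≈ 0.001 (asserted ≤ 0.05).
* **Archetype recovery**: noise-free instances reclassify to their planted
  archetype with 100% accuracy; at default noise, 8 NL-anchored archetypes
  with every planted term ≥ 20 pp (12 replicates each, 96 instances)
  recover at ≈ 92–95% (asserted ≥ 90%). Simulated replicates are gated at
  the emulated family size m = 73, not at the replicate count: the number
  of Monte-Carlo copies in a batch is an implementation convenience, and
  letting it tighten the Bonferroni threshold would make measured accuracy
  an artifact of batch size.

Problem sizes were chosen to give stable Monte-Carlo estimates of each
quantity while keeping the default validation run in the minutes range on
one CPU.

## Known limitations

* The generator's independence assumptions (above) limit what recovery
  rates say about real arrays; the packaged published-table fixtures are
  the only real-data anchor.
* Printed-table transcriptions carry the print's own inconsistencies: two
  count-matrix cells disagree by one with a literal recount of the
  per-protein table's bold flags, and one significance flag (CAMKII FL,
  +0.2%) is implausible as printed; both are preserved as printed and
  flagged in fixture metadata, and tests assert only on robust cells.
* Only hippocampal nuclear/cytosolic per-protein values were published;
  cortex and membrane results are covered by simulation-based properties
  only.
* Single post-training time point: the patterns say nothing about response
  dynamics, and no attempt is made to classify instances missing any of
  the five classifier contrasts.
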