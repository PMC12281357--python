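# Methods

## Scope and data model

`resilio` implements a discovery-and-validation workflow for DNA-methylation
correlates of a continuous psychometric trait that has been dichotomized at
its tails — here the CD-RISC resilience score (25 items × 0–4, total
0–100; a response with more than 6 missing items is excluded, otherwise
missing items are mean-imputed from the observed ones). The central object
is a `MethylationDataset`: a probes × samples β matrix (β ∈ (0,1)), a probe
manifest (1-based hg-style coordinates, gene label, feature class, SNP /
multi-hit / sex-chromosome flags) and a sample sheet (score, group, age,
menstrual status, detection mode, ER/PR/HER2, smoking, batch). All
modelling happens on M values, M = log₂(β/(1−β)), with β clipped into
[ε, 1−ε], ε = 10⁻³; the logit transform stabilises variance and keeps
residuals approximately Gaussian away from the β boundaries.

## Preprocessing

**Probe filter cascade** (defaults in parentheses): (1) detection
p > .01 in more than 5% of samples; (2) fewer than 3 beads in ≥ 5% of
samples — both applied per probe across samples; (3) non-CpG probes (id
prefix); (4) SNP-flagged; (5) multi-hit; (6) sex-chromosome probes. The
rules are independent predicates, so the surviving set does not depend on
application order; the report counts removals in the order applied.

**Batch adjustment** is per-probe, per-batch location/scale
standardisation: each batch's M values are z-scored (ddof = 0) and mapped
back to the probe's grand mean/SD. This removes pure location and scale
batch shifts exactly and preserves the per-probe grand moments to machine
precision. It deliberately omits the empirical-Bayes shrinkage of full
ComBat: at the cohort sizes involved the shrinkage changes little, and the
exact method is easy to reason about and test. Singleton batches are
refused.

**Cell-type deconvolution** solves, per sample, a non-negative least
squares of the observed β at reference probes against per-cell-type
reference profiles, with a heavily weighted (10³) sum-to-one row enforcing
the simplex constraint, followed by renormalisation. For mixtures exactly
representable by the reference the solution is exact (residual ≈ 0,
recovery error < 10⁻⁶ in tests).

**PCA–covariate scan**: PCA on centred M values (samples as observations);
each PC is tested against each covariate — Pearson correlation test for
numeric, one-way ANOVA for categorical — yielding a PCs × covariates
p-value table plus variance explained. Constant covariates are skipped.

## Percentile-subset differential methylation

For retention fraction q ∈ {1.0, 0.9, …, 0.1, 0.05}, the low group keeps
its ⌈q·n⌉ lowest scorers and the high group its ⌈q·n⌉ highest, ties broken
by sample id; members are therefore nested across subsets. Subsets with
fewer than 3 samples per group are dropped with a warning.

Per subset and per CpG, ordinary least squares of M on
{intercept, group, age, menstrual status, detection mode, ER status}
(categoricals dummy-coded; constant or rank-deficient columns dropped with
a logged warning, and covariates are shed last-first if a tiny subset would
otherwise exhaust residual degrees of freedom). The group coefficient on
the M scale is the log₂ fold change; the sign convention — positive =
hypermethylated in the LOW-resilience group — is stated in output headers.

Residual variances are moderated by empirical Bayes: with d residual df,
the prior (d₀, s₀²) of a scaled inverse-χ² distribution is estimated by
method of moments on log s² (the trigamma equation
trigamma(d₀/2) = Var(log s²) − trigamma(d/2) is inverted numerically;
a non-positive right side gives d₀ = ∞ and a common variance). The
posterior variance s̃² = (d₀s₀² + d·s²)/(d₀ + d) is a convex combination of
s² and s₀²; the moderated t = β̂/(s̃·SE-factor) has d + d₀ df. In the
d₀ → ∞ limit the statistic collapses to the common-variance t, and with no
covariates the coefficient equals the closed-form group mean difference —
both verified to 10⁻¹² in tests.

DMP calling follows the raw-p rule (p < .05 AND |log₂FC| > 0.5);
Benjamini-Hochberg q-values are reported alongside but not used for
calling, since at these effect sizes genome-wide FDR control is known to be
conservative for EPIC data — the consistency layer is the false-positive
control instead. Per probe, the cross-subset scan reports the number of
subsets calling it a DMP, the longest consecutive run over the ordered
sequence (100% → 5%), and the **dose-response statistic**: the Spearman
correlation of per-subset log₂FC with the per-subset high-minus-low mean
score difference. Spearman (not Pearson) because the claim being tested is
monotone dose-response, not linearity.

Feature-class enrichment of a DMP set against the QC-passing background
uses a two-proportion z-test per class.

## Bump-hunting DMRs

Probes are partitioned into maximal clusters with inter-probe gap
≤ 500 bp. Within clusters of ≥ 3 probes the coefficients are smoothed by a
centred running mean (window 3, shrinking at edges); smaller clusters use
raw coefficients. The cutoff is the 99th percentile of all |smoothed|
values genome-wide (configurable, recorded in output metadata — the
upstream tools' "default settings" are version-dependent, so these
defaults are this package's own convention). Candidate regions are maximal
same-sign runs of smoothed values above the cutoff; singletons are allowed.
The **area** is computed from the *unsmoothed* coefficients
(|Σ coefficients| over member probes), because the area definition refers
to the estimated model coefficients, not their smoothed version.

The permutation null permutes only the group indicator (covariate columns
fixed), refits the per-probe coefficients, re-runs the bump finder
(cutoff re-estimated per permutation) and records the maximum region area.
Per-region p = (1 + #{null max ≥ area}) / (1 + n_perm) — a family-wise
p-value with minimum 1/(n_perm+1). Across independent null cohorts the top
region's p is uniform on its support (verified by KS test; note that
replicates must use independent array layouts, since a shared probe
baseline landscape correlates replicate p-values).

Regions are matched across subsets by shared gene label, else by ≥ 1 bp
coordinate overlap; per region key the scan reports presence, longest
consecutive run, and the Spearman trend of area against subset distality.
BED export converts the 1-based inclusive coordinates to 0-based half-open.

## Matched-triplet classifier

Triplets (1 low ≤ 50, 2 highs ≥ 80) are built greedily in ascending score
order: exact agreement on ER/PR/HER2; never-smoker lows accept only
never-smoker highs, ever-smoker lows prefer ever-smokers; among feasible
candidates the two with smallest |age difference| win, ties by id. Greedy
sequential matching (rather than optimal bipartite matching) is
deterministic and auditable — all matching distances are reported.
Infeasible lows are excluded with a warning.

Each resampling iteration: (1) split whole triplets 50/20/30
(largest-remainder rounding) into train/confirmation/test; (2) feature
selection — bump-hunting on the training coefficients, keep CpGs in
regions of ≥ 5 probes, retain those whose train and confirmation
fold-change signs agree; (3) tune a random forest on train+confirmation by
m = 3 repeats of stratified k = 5-fold CV, scoring each configuration by
mean Youden's J with the threshold chosen per fold by exhaustive scan over
the observed probabilities; (4) refit the winner on all train+confirmation
data, set the deployed threshold by the J-maximiser over its pooled
out-of-fold probabilities (the literature rarely states how the single
final threshold is derived; this choice uses only non-test data); (5)
evaluate AUC (rank/trapezoidal) and SN/SP at the threshold on the test
triplets. Iterations with < 2 features or an unfittable CV are recorded as
degenerate and excluded from metric means. The 1:2 class imbalance is
handled by the J-optimal threshold only — no resampling of classes.

The documented default hyperparameter grid is
mtry ∈ {√p, p/3, p} × trees ∈ {250, 500, 1000} × min node ∈ {1, 5, 10} ×
max depth ∈ {∞, 4, 8} with Gini splitting; desk-scale runs (tests, the
acceptance script, pipeline defaults) use a reduced single-configuration
grid (mtry = √p, 50–100 trees, min node 1, unlimited depth), which is a
problem-size choice, not a statistical one — at a few features and tens of
samples the forest is insensitive to the grid.

CpGs are ranked by selection frequency across iterations (ties by id).
The final model uses the top-n ranked CpGs plus age (n chosen from a grid
by CV AUC on the full classifier set, ties to the smaller n) and is
evaluated once on an independent validation cohort — overlap between
validation and classifier samples is refused.

## Synthetic cohorts

The generator emulates the study conditions end to end:

- **Scores**: truncated-normal mixture — low group mean 56, SD 7.5, range
  [32, 65]; high group mean 84, SD 5.5, range [77, 100] (the tail-selected
  cohort's architecture). The dose-response midpoint defaults to 71 (the
  midpoint of the gap between group ranges) and the half-range to 39
  (midpoint − 32, the larger tail distance).
- **β values**: per-probe baseline M from a three-component Gaussian
  mixture (≈ 40/20/40% at M ≈ −3.5/0/+3.5), giving the familiar bimodal β
  distribution; residual noise SD 0.5 M-units. Baselines, manifest
  structure and covariate-affected probe sets derive from a separate
  `array_seed` (default 777), so independently seeded cohorts share the
  array — exactly as real discovery and validation cohorts share probe
  biology. Without this, cross-cohort validation would be structurally
  impossible.
- **Spiked regions**: contiguous probe runs; a sample with score s below
  the midpoint is shifted by
  direction · max_effect · ((midpoint − s)/half_range)^dose_exponent on the
  M scale (zero at and above the midpoint), so the group difference at the
  extreme tails equals max_effect and grows monotonically toward the low
  tail. Default scenario: three regions of 8/7/6 probes,
  max_effect 1.2, exponent 1, alternating hyper/hypo direction.
- **QC failures**: independent per-class rates (detection .04, beads .03,
  non-CpG .02, SNP .03, multi-hit .02, sex-chromosome .03) give ≈ 84–85%
  retention. Spiked and cell-reference probes are protected from flags so
  the signal survives QC by construction.
- **Structure**: optional covariate effects (age, menopause by default,
  0.3 M-units on 10% of probes), per-batch location/scale shifts, and
  Dirichlet cell-type fractions mixed through a reference profile matrix on
  designated reference probes.

What the generator does **not** emulate: probe-type (I/II) chemistry and
its β compression, spatial correlation of noise beyond the spiked runs,
genotype artefacts, or realistic linkage between clinical covariates and
methylation beyond the injected global effects. Passing tests therefore
demonstrate correctness of the machinery and recoverability of
dose-responsive signal under idealised noise — not performance on real
arrays.

## Numerical and reproducibility choices

- All randomness flows from explicit integer seeds (`numpy`
  `default_rng`); no global RNG state. Pipeline outputs carry a config
  hash and seed, and the run manifest records sha256 checksums but no
  timestamps, so a rerun with the same config is byte-identical.
- Youden thresholds break ties toward the higher threshold; probability
  ties are handled by scanning only observed values (prediction is
  positive at prob ≥ threshold).
- p-values are floored at the smallest positive float; variances at
  10⁻³⁰⁰ before logs.
- Problem sizes used by the test suite and acceptance script (chosen so a
  relative 99th-percentile cutoff behaves as it does on a full-size array,
  where spiked probes are ≪ 1% of probes): null calibration 10,000 probes ×
  200 samples; DMP/DMR recovery 3,000 probes × 400 samples (the 5% subset
  then keeps ~10 samples per tail, matching the discovery design);
  classifier loops 3,000 probes × 200 samples at 50 iterations. At much
  smaller arrays the spiked probes would exceed the top-1% cutoff budget
  and region recovery degrades by construction, not by defect.
- The null-classifier check runs feature selection at cutoff quantile 0.90
  and min 3 probes: under a pure null the production settings (0.99, ≥ 5)
  almost never emit features, which would leave the null AUC unmeasured;
  the permissive setting makes the check informative without touching the
  production defaults.

## Limitations

The percentile subsets are nested, not independent — consistency across
them guards against subset-specific flukes but cannot substitute for
external validation, which is why the classifier is validated on a
separate cohort. Raw-p DMP calling without multiplicity correction is
deliberate and inherited from the discovery design; the q-values are
reported for transparency. Greedy matching can exclude lows that an
optimal matcher would place. The classifier predicts dichotomized status
at one time point; trajectories over time are out of scope.
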