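# Methods

This note documents the statistical procedures implemented in
`reasonscore`, the choices made where the design was genuinely open, and
what the bundled synthetic-data generator does and does not emulate.

## Input contract

The pipeline starts from an already-normalized beta-value matrix (probes ×
samples, β ∈ [0,1]) with a matching detection-p matrix, a probe manifest
(chromosome, position, gene symbols, SNP and cross-reactive flags), a
clinical table with a binary 5-year disease-specific vital status, and
optionally a gene-expression count matrix and GMT gene sets. Raw IDAT
processing and normalization are out of scope; they are replaced by this
input contract.

## Probe-filter cascade

Stages run in a fixed order (sex chromosomes → SNP → unmapped → detection
→ cross-reactive → uninformative β → top variance) and each appends a
`(stage, n_in, n_removed, n_out)` record whose chaining is validated. Two
conventions matter:

* **Detection**: a probe is kept iff detection p < 0.01 in *at least* 50%
  of samples — the boundary is inclusive.
* **Top variance**: unbiased sample variance of β, descending, keep
  `floor(0.30 · n)` probes; ties at the cut break lexicographically by
  probe id so the retained set is invariant to input row order. The floor
  is forced by the standard workflow's arithmetic (317,016 × 0.30 =
  95,104.8 → 95,104).
* A probe that is both SNP-flagged and gene-unmapped is counted in the SNP
  stage, since stages apply sequentially. The published stage totals are
  consistent only if the two sets are disjoint, which the engineered test
  fixture makes true by construction.

## Surrogate-variable adjustment

Surrogate variables are the right singular vectors of the **row-centered**
M-value matrix. Centering — rather than residualizing on the outcome — is
deliberate: the residual matrix of an outcome regression is exactly
orthogonal to the outcome, so its singular vectors could never correlate
with survival and the protective exclusion rule below would be vacuous.
With centering, a component that happens to track the outcome is visible
and removable.

* **How many components** (`n_sv="auto"`): parallel analysis. Each
  permutation shuffles every probe's values independently across samples
  (preserving row means and variances, hence comparable null spectra) and
  records the singular values; a component is kept when its singular value
  exceeds the 95th percentile of the corresponding permuted values
  (20 permutations by default, deterministic under `random_state`).
* **Exclusion rule**: a surrogate with |Pearson r| > 0.2 against the
  binary outcome (point-biserial; sign-agnostic) is excluded from the
  downstream design so the adjustment cannot absorb the survival contrast.
* Signs are fixed so each component's largest-magnitude loading is
  positive; components are orthonormal by construction.

This is a deterministic "two-step" style estimator, not the iterative
empirically reweighted algorithm; the fully iterative variant needs the
original data scale to matter and is unnecessary for the planted
structures the pipeline is validated on.

## Differential methylation

Modeling is on M-values, M = log2(β/(1−β)) with β clipped to
[1e-6, 1−1e-6]; the output table also carries the raw mean β difference
(deceased − survived) as a companion effect scale, since a "fold change"
on methylation data is scale-ambiguous.

Each probe is fit by OLS on `[intercept, outcome, retained SVs]`. The
variance prior (d₀, s₀²) is estimated by the method of moments on log
residual variances: with e_g = log s²_g − ψ(df/2) + log(df/2),

* trigamma(d₀/2) = Var(e) − trigamma(df/2) (solved by Newton iteration),
* s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2)).

If the spread of log variances does not exceed what the residual
chi-square alone implies, d₀ = ∞ and every probe shrinks fully to s₀²
(normal reference distribution). Otherwise

    s²_post = (d₀·s₀² + df·s²)/(d₀ + df),  t = effect / sqrt(s²_post·v),

with v the design leverage of the outcome column and d₀ + df total degrees
of freedom. Adjusted p-values are Benjamini–Hochberg (backed by
statsmodels); the signature is all CpGs at adjusted p < 0.1 (the lenient
threshold appropriate to a small exploratory cohort), each gene's risk
direction being the sign of the effect at its most significant CpG.
Probes with zero residual variance (constant M) receive the fully shrunk
posterior variance and are flagged.

## State-transition scoring

β maps to three ordered states. The published thresholds name < 0.3 as
unmethylated and 0.33–0.75 as hemi-methylated, leaving [0.30, 0.33)
unassigned; the map here merges that sliver into the unmethylated state
(single boundary at 0.33, configurable), and the hemi interval is closed
on both ends: UNMETH < 0.33 ≤ HEMI ≤ 0.75 < FULL.

The transition baseline is the key interpretive choice: the reference
state of a CpG is the state of the **median β among 5-year survivors**
(lower-middle value for even counts, so the reference is always an
observed β). A patient's CpG transitions HYPER/HYPO when its state is
above/below the reference; a gene scores one risk point when **any** of
its CpGs shows a transition matching the gene's risk direction (OR rule —
maximal sensitivity for a presence/absence score). Within-state movement
never scores. The molecular score is the count of risk-positive signature
genes, 0–12 with the default panel.

## Clinicopathologic score

Continuous features (age) are dichotomized first: the cut maximizing the
2×2 Pearson chi-square against outcome over a clinically sensible grid
(multiples of 5 inside the observed range; ties take the smaller cut) —
this grid is the operational proxy for manually adjusted, clinically
sensible cut-offs. The tree then grows greedily: at each node every
one-vs-rest level split of every feature (both children ≥ `min_leaf` = 20)
is scored by chi-square p-value; the best split is admitted only if its
p-value, **Bonferroni-corrected for the number of candidate splits
examined at that node**, is below `stop_alpha` = 0.05. Without that
correction a node examining ~13 candidates would split pure noise roughly
half the time; with it, pure-noise cohorts yield a single-leaf tree at the
nominal rate, while genuine effects (node p-values orders of magnitude
smaller) are unaffected. Depth is capped at 4.

Each decision node becomes a rule: the risk side is the branch with the
higher death rate; its odds ratio against the other branch
(Haldane–Anscombe +0.5 on all cells when any is zero) is rounded
half-to-even to integer points. Rules are evaluated independently when
scoring (a patient sums the points of every rule they satisfy), features
with ≥ 5% missing values are excluded from derivation rather than imputed,
a missing value skips that rule for that patient, and an unseen category
level is an error.

## Composite score and evaluation

Total = clinical points + molecular gene count, unweighted — presence or
absence of each risk factor contributes additively. The concordance index
counts, over all (death, survivor) pairs, wins for the death's score with
ties credited ½; this equals the AUROC for a binary outcome and ranges
from 0.5 (random) to 1 (perfect). Pairs are enumerated exactly up to
10,000 patients and by an equivalent sort/searchsorted path beyond
(cross-checked against brute force in the tests). Confidence intervals are
patient-level percentile bootstrap (2,000 resamples by default, seeded;
resamples lacking an outcome class carry no informative pairs and are
skipped). Time-to-event concordance with censoring is out of scope — the
outcome is fixed-horizon binary status.

## Downstream analyses

Expression counts pass an expressed-gene filter (≥ 10 counts in ≥ 90% of
samples, boundary inclusive) and are log2(count+1)-transformed before
Pearson correlation with the gene's signature-CpG β (raw-scale mode
available); p-values come from the t transform of r. Over-representation
uses the one-sided upper-tail hypergeometric p, P(X ≥ k) with parameters
(N universe, K set, n query), Bonferroni-corrected over the sets actually
tested (zero-overlap sets are skipped and logged). The background universe
defaults to **all** genes surviving the methylation analysis, significant
or not: a universe of only non-significant genes would exclude the query
from its own reference population.

## Synthetic-data generator

The generator produces the joint structure the pipeline assumes — it is a
stand-in labelled as such in `truth.json`, not a model of array chemistry.

* **Clinical**: ten features drawn independently from realistic
  early-stage oral-cavity marginals (60% male, 93% white, mean age 64,
  68% tobacco, 35% PNI, 6.9% LVI, 69% stage II, ...); outcome from a
  logistic model over configurable per-feature odds ratios, intercept
  solved so the realized expected event rate matches the target (0.14
  TCGA-like by default; 0.37 for an internal-cohort style).
* **Planted clinical effects** default to two factors, age ≥ 65 at OR 3
  and PNI at OR 4 — strong enough to be clinically plausible and to put
  the derived score's discrimination in the 0.66–0.72 c-index regime
  reported for non-molecular panels.
* **Methylation**: per-probe baselines from a two-component logit-normal
  mixture (means near β = 0.2 and 0.8); per-probe noise SD lognormal
  around 0.5 logit units so the variance prior is non-degenerate;
  configurable fractions of X/Y, SNP, unmapped, cross-reactive, constant
  and detection-failing probes. Signature CpGs (13 over 12 genes by
  default, round-robin so one gene carries two) sit in the dynamic
  mid-range (β 0.30–0.55) and are shifted by ± `delta_beta` (0.25 default,
  β scale, clipped — never an error) in deceased patients, one direction
  per gene.
* **Batch structure**: additive logit-scale shift per batch; batch-0
  membership is tilted by outcome so the φ coefficient with death matches
  `batch_outcome_corr` (0.10 default — "partially correlated").
* **Expression**: Poisson counts with a log-scale latent partially
  correlated with the gene's planted-CpG β. The latent correlation is the
  target divided by 0.95, the analytically derived product of the
  exp-link attenuation (s = 0.4 log scale) and Poisson shot-noise
  attenuation at the default mean of 300 counts — so the realized
  count–β Pearson r lands near the target. Default targets are the six
  signed correlations typical of such signatures (+0.46, +0.42, +0.31,
  −0.38, −0.60, +0.36). Background genes are independent
  gamma-mixed-Poisson (negative-binomial-like) counts.
* All randomness flows from one seed through per-stage child streams; a
  fixed seed yields a byte-identical written bundle.

**What passing tests do not show**: features are sampled independently
(no tobacco-alcohol or stage-grade correlation), methylation noise is
logit-normal rather than array-chemistry-driven, probe annotations are
assigned at random rather than from a real manifest, and expression
dispersion is gene-wise constant. Recovery results on this generator
demonstrate correctness of the procedures, not clinical performance on
real cohorts.

## Problem sizes used in the checked examples

The bundled validation suite uses cohorts of 58–500 patients and
1,200–5,000 probes (plus one full-array-sized 485,512-probe engineered
fixture for the filter bookkeeping), 20–50 seeds for stochastic
properties, and 100–2,000 bootstrap resamples; these sizes were chosen to
give stable pass/fail behavior for each property being demonstrated.

## Known limitations

* The survivor-median reference for state transitions and the
  [0.30, 0.33) gap closure are interpretive choices, exposed as
  configuration rather than silently fixed.
* The surrogate estimator is the deterministic SVD variant; on data whose
  unwanted variation is weak and diffuse it will under-select components
  relative to iterative reweighting.
* The clinical tree reports no honest post-selection inference; its
  points are descriptive integers, not calibrated effects.
* The c-index here has no censoring adjustment; patients must have known
  5-year status.
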