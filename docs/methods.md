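# Methods

## Model and score

The analysis treats the integrated patients × variables frame as data from
a Bayesian network over mixed variable types.  Local conditional models
are Gaussian linear regressions for continuous nodes and logistic
regressions for binary nodes; additive genotype dosages (0/1/2) enter as
numeric regressors and are constrained to be structural roots.  The
network score is decomposable and minimized:

    score(G) = Σ_v  −2·loglik(v | Pa(v)) + n_params(v)·log n + pen(Pa(v))

`n_params` counts the intercept, one coefficient per parent, and — for
Gaussian nodes — the residual variance (so a continuous node with k
parents contributes k + 2 parameters, a binary node k + 1).  This
convention is stated explicitly because BIC parameter counts vary across
packages; likelihood-ratio comparisons between structures are unaffected,
but absolute score values depend on it.

The class-aware penalty charges `2γ·(log|C| + log|S_c|)` per parent drawn
from class c (the `per_term` style, the default), with γ = ½ so the
charge is exactly `log|C| + log|S_c|`.  An alternative `combinatorial`
style charges `log|C| + log C(|S_c|, k_c)` per class used, i.e. the
log-count of unordered same-size parent sets.  The two differ by
`log k!` per class; with a single class they reduce to `k·log s` and
`log C(s, k)` respectively, both E-BIC-type model-space penalties at
γ = ½.  Both styles are provided because each has a defensible reading of
"prior over fragments of the same size"; `per_term` is the default since
it is the incremental form, and parent sets are treated as unordered.
The prior enters additively on the log scale.

Two structural facts follow from the score and are relied on throughout:
the empty network is the default state (an edge must overcome both the
BIC term and the class term), and two linear-Gaussian variables score
identically in either orientation (Markov equivalence), so single-edge
orientation is determined only by constraints, colliders, or mixed
families — not by likelihood.

## Search and ensemble

Structure search is greedy hill climbing from the empty DAG: at each step
the best strictly score-improving legal move (add, delete, or reverse an
edge) is applied, with a tabu list of the last 50 visited structures and
seeded random restarts (default 4 perturbation moves from the incumbent
best).  Legal moves respect acyclicity, root classes (genotypes by
default), optional ordered class tiers, optional sink nodes, and a
per-node parent cap (default 3, reflecting the sparseness assumption that
local neighborhoods in this domain have a handful of strong parents; it
also bounds fit cost).  The search is deterministic given (data, seed);
ties between equal-scoring moves break by enumeration order over the
dataset's column order.  For p ≤ 5 an exhaustive enumerator scores every
legal DAG and serves as the optimality oracle in tests; hill climbing with
20 restarts attains its optimum in 40/40 seeded trials at p = 3 and 4.

Ensembles fit `n_networks` independent searches, by default each on a
seeded with-replacement bootstrap of patients (`seed_only` varies only the
search seed).  Member seeds spawn from a single `SeedSequence`, so results
are reproducible from one base seed and insensitive to fitting order.
The consensus graph reports each directed edge's fraction of members;
the reporting filter is strict (`frequency > 0.05`), so an edge in exactly
1 of 20 members is not reported.  Orientation within a Markov-equivalence
class is whatever the searches produced; consensus is per directed edge
with no CPDAG collapsing, so a flip-ambiguous edge may split its frequency
across the two directions.  Recovery checks therefore also examine the
endpoint-pair frequency (sum of both directions).

## Counterfactual simulation

`do(node = x)` severs the node's incoming edges, clamps it, and recomputes
only its descendants in topological order through each member's fitted
local models; non-descendants keep the patient's observed values.
Propagation is by conditional mean; logistic nodes propagate the expected
probability, which downstream models consume as a continuous input — an
approximation that is exact for the phenotype itself and biased only for
nodes downstream of a binary node.  Baselines clamp the node at its
observed value and propagate identically, so a null intervention is
exactly the baseline and targets with no directed path from the node are
untouched.  A stochastic mode (seeded) resamples Gaussian local noise for
distributional output; the deterministic mean propagation is the default.
On a fitted chain with coefficients b1 = 0.8, b2 = 0.5 the simulated
unit shift reproduces b1·b2 = 0.40 within estimation error at n = 2,000.

## Synthetic ground truth

The generator emulates the study conditions this machinery targets: a
lipoprotein causal neighborhood with an additive genotype instrument.
Default topology (11 named variables, 10 edges):

    rs_LIPC → LIPC_expr → LDL_TG → {ASCAD, sdLDL, ApoB, CRP}
    TG → LDL_TG ← POA        CRP → {fibrinogen, galectin3}

plus `n_nuisance_per_class` unconnected noise variables in each of the 7
classes present (default 1, giving p = 18).  No published effect sizes
exist for these edges, so magnitudes are package choices, frozen in
`synthetic.py` and echoed into every serialized spec:

- `rs_LIPC`: MAF 0.30; nuisance genotypes MAF 0.25.
- LDL_TG sits on a mg/dl-like scale, marginal ≈ N(18.3, 6.1), so its
  empirical quartile cut points land near the clinically reported
  brackets (≈14 / 17 / 22 mg/dl); all other continuous nodes are near
  unit scale.
- The phenotype link is logistic with slope 0.0705 per mg/dl of LDL_TG
  (≈0.43 per SD) and intercept −1.20, giving ≈52% prevalence and an
  unadjusted Q4-vs-Q1 odds ratio near 3 at cohort-scale n ≈ 665 — the
  magnitude regime of the motivating application, used as a loose
  calibration check only, never asserted exactly.
- Remaining edge weights give parent–child correlations of roughly
  0.3–0.6, detectable but not overwhelming at n = 600.

The generator is linear-Gaussian with a logistic phenotype because that is
the minimal family supporting the BIC scoring and mean-propagation
counterfactuals; it does not emulate latent confounding (nuisance
variables are pure noise), nonlinear links, heavy tails, measurement-batch
structure, or tens-of-thousands-dimensional omics.  Passing recovery
tests therefore demonstrates correctness of scoring/search/consensus
mechanics under the assumed family, not robustness to real-data
violations of it.

## Preprocessing formulas

- Intensity normalization: per feature, output = raw − regression-predicted
  log-intensity + mean raw log-intensity; design is linear or a natural
  cubic spline basis (hand-built truncated-power construction) with 4
  interior knots at covariate quantiles.  Per-feature means are preserved
  to 1e−9 by construction and the operation is idempotent; a constant
  covariate degrades to the identity with a warning.  Which processing
  covariates enter the design is a configuration choice (all numeric
  covariate columns by default).
- Run-day normalization divides each feature by its within-day median
  (medians exactly 1.0 afterwards); zero medians flag the feature and
  leave it unscaled.  Missing values are imputed with the feature's
  observed post-normalization minimum.
- Paired t-tests run independently per feature; zero-variance difference
  vectors return t = 0, p = 1, flagged.  A covariate-adjusted companion
  fits the same per-feature linear model with clinical covariate terms and
  reports the group contrast's F-test.
- Storey q-values estimate π0 at a single λ = 0.5 (configurable), clipped
  into (0, 1], with step-down cumulative-minimum enforcement; under
  uniform p-values (m = 2,000) the π0 estimate falls in [0.8, 1.0].

## Association stages

Kendall tau-b (tie-corrected, scipy) screens biomarkers against outcome
measures at raw p < 0.05 — deliberately uncorrected, as a nominal screen.
Heatmap ordering clusters rows and columns independently by average
linkage on 1 − tau distances between correlation profiles.  Quantile-bin
logistic models use interpolated sample-quantile edges with ties assigned
to the lower bin ([low, high) bins, last closed); odds ratios are
exp(coefficients) with Wald 95% CIs, and the trend test refits with the
ordinal bin score 1..n_bins (Wald).  Wald was chosen over profile
likelihood for CIs and trend because the downstream use is magnitude
reporting, not boundary-precision inference.  SNP models report the
per-allele beta (linear) or OR with the log-odds SE (logistic).
Separation in any logistic fit triggers a ridge-stabilized refit (fixed
small ridge), flagged in the output.  Cumulative incidence curves report
the case fraction among patients at or below each observed biomarker
value, with an arbitrary boolean subset filter (e.g. excluding
statin-treated patients).

## Numerical and scale choices

Local fits inside the search loop are a closed-form least-squares Gaussian
fit and a Newton/IRLS logistic with backtracking line search, chosen for
speed and determinism over thousands of fragment refits per climb;
statsmodels provides the independent cross-check in tests and backs the
user-facing association models.  Collinear parents resolve to the
least-norm solution (flagged); logistic separation refits with ridge 1e−2
(flagged).  Zero-variance continuous columns standardize to zeros with a
warning.  MLE (1/n) variance is used throughout the Gaussian likelihood.

Default problem sizes in the test and acceptance runs — n = 600 patients,
p = 18 variables, 50 bootstrap members, 40 enumeration trials at p ≤ 4,
10–20 pure-noise replicates — were chosen so the full suite demonstrates
each property at convincing power while remaining a desk-scale
computation; all are configuration parameters, not limits of the
implementation.

## Known limitations

- At E-BIC γ = ½ the single-edge entry threshold on pure noise
  (p = 10, n = 300) is |r| ≈ 0.16 while the expected maximum chance
  correlation over 45 pairs is ≈0.15, so roughly one noise dataset in
  five admits a spurious edge into the score optimum, and bootstrap
  consensus frequencies amplify near-threshold correlations.  The
  false-discovery property of the fully-disconnected default is an
  asymptotic/large-penalty property (it strengthens with larger |S_c|,
  larger n, or larger γ), not a finite-sample guarantee at these sizes.
- Consensus frequencies are per directed edge; flip-ambiguous edges split
  frequency across orientations rather than being collapsed to a CPDAG.
- Mean propagation through binary intermediates is an approximation; no
  identification analysis is performed — the linear-Gaussian assumption
  carries the causal interpretation.
- No discrete multinomial or nonparametric local models; exhaustive
  enumeration is limited to p ≤ 5; no latent-variable discovery.
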