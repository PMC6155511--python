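# Methods

## The detection model

`repenroll` treats a cohort of N enrolled survey respondents as points in a
K-dimensional response space. The clustering fields are Likert-type screener
items used *as their integer codes* (no optimal scaling), self-reported age,
and enrollment order; each field is divided by its own standard deviation so
that a one-standard-deviation difference contributes equally regardless of the
field's native scale. Centering is omitted — it cannot change Euclidean
pairwise distances — and only matters if standardized coordinates themselves
are reported.

Complete-linkage agglomeration is used because its merge height is the
*maximum* within-cluster dissimilarity: a cluster that persists to a low
height under complete linkage is tight in the worst-case sense, which is the
signature of one person re-submitting near-identical screeners. Cutting the
dendrogram at height *h* uses the strict convention (two respondents share a
cluster iff every merge joining them happened at height < *h*). Per-cluster
fit is summarized by the average silhouette width (ASW), where b(i) is the
mean distance to the cluster minimizing that mean ("closest other cluster"),
members of singleton clusters get s(i) = 0 by convention, and a single-cluster
partition is all zeros.

The evidence statistic per cluster is

    SSW_c = N_c / max_j N_j + ASW_c / max_j ASW_j,

both components normalized by the *observed* maxima so size and tightness
carry equal weight. Simulated clusters are normalized by those same observed
maxima to keep the scale comparable. If no cluster at the chosen height has
positive ASW, the normalization is undefined and the fit raises with advice
to revisit the height — silently flipping signs would invert the ranking.

## The null model

Because the analyzed cohort is conditioned on passing an eligibility score
cutoff and completing the baseline questionnaire, independent-null cohorts
cannot be resampled from the cohort's own marginals. The null model is
estimated from the *unrestricted* applicant pool:

- per-field category proportions and the Pearson correlation matrix of the
  numeric codes (the Gaussian-copula / GenOrd convention; a polychoric target
  would simulate a different observable correlation);
- the screener's per-item level weights and the score cutoff (eligible at
  score >= cutoff, non-strict);
- a logistic model for baseline-questionnaire completion, linear in age and
  the item codes (fit on score-eligible pool members).

Simulation draws multivariate-normal deviates under an **intermediate**
correlation matrix and cuts them at the standard-normal quantiles of the
cumulative marginals. The intermediate correlation for each field pair is
found by Brent root-finding on the exact discretized correlation, computed
from bivariate-normal orthant probabilities:

    cov(X, Y) = sum_a sum_b D_a D_b [Phi2(t_a, t_b; rho) - Phi(t_a) Phi(t_b)],

where t are the marginal thresholds and D the code increments. Tolerance is
1e-4 in the achieved correlation; targets outside the attainable range of the
discretized pair raise with that range. If the assembled matrix is not
positive definite it is repaired by eigenvalue clipping (floor 1e-8, rescaled
to unit diagonal); the Frobenius-norm adjustment is recorded on the model and
a repair moving any entry by more than 0.05 is an error under strict mode.
Bounded integer fields (age 18-25) are treated as ordinal with one category
per value so a single simulation mechanism serves all fields.

Rejection sampling simulates in batches (initially 4N, growing geometrically,
capped at 1000 batches, with an error below an acceptance rate of 1e-4),
keeps rows that are score-eligible *and* drawn as completers, stops at exactly
N, and appends a uniformly random permutation as enrollment order (under
independence, enrollment characteristics are stable over time). One master
seed spawns per-simulation substreams, so increasing M leaves earlier
simulations unchanged.

Exceedance counting and flagging both use strict inequalities
(SSW_c > max SSW* and Pr > tau). No multiplicity correction is applied and
the exceedance probability is not a p-value.

## Calibration under the null

The normalization is deliberately asymmetric: the observed dataset's SSW uses
its own maxima (so no component ratio exceeds 1 and the top statistic is
capped at 2), while simulated cohorts are normalized by the observed maxima
and can exceed 2. Under the null this places the observed maximum
stochastically *below* the simulated maxima: across 100 cohorts drawn from
the packaged null model (N = 400, M = 200) the median per-dataset maximum
exceedance probability was ~0.42 and the 99th percentile ~0.89, so at
tau = 0.95 essentially no null dataset is flagged. The dataset-level false
alarm rate is therefore far below 1 - tau: the procedure is conservative, and
tau behaves as an ordering knob for sensitivity rather than a calibrated
error rate. This matches the validation study's near-perfect specificity and
is a property users should know when interpreting tau.

## The synthetic validation study

`SyntheticScenario` plants one correlated group in an otherwise independent
cohort. The group's latent Gaussian uses block covariance
[(1-r) I_m + r J_m] (x) S with S the intermediate (within-person) correlation
— so each planted row is marginally identical to background — and
between-person factor r in [0, 1) (r = 1 is excluded: Sigma becomes
rank-deficient). Planted rows face the same eligibility and completion
screens as background, so the realized cluster size varies (and is highly
variable at large r, where the whole group passes or fails together); a
`screen_cluster=False` switch fixes the size for algebraic checks. The
planted rows occupy a contiguous window of enrollment order by default
(repeat enrollers act in bursts), with a scattered option.

Reported rates: *detection rate* = fraction of replicate datasets flagging at
least one cluster (the weakest reading of "identified clustering");
*conditional identification rate* = flagged truly-clustered rows among
detecting datasets; *sensitivity* = flagged truly-clustered rows overall;
*specificity* = background rows not flagged. With constant cluster size,
sensitivity = detection rate x conditional identification rate exactly.

## Packaged defaults and problem sizes

The packaged population (`defaults.py`) is a synthetic 8-item weighted
screener plus age: per-item level weights summing to a maximum score of 89,
eligibility cutoff 27, moderate positive correlation (0.28) among the six
sun-sensitivity items, weaker (0.15) links to family history and mole count,
age nearly independent (0.02), and a logistic completion model giving ~60%
completion among eligibles (overall acceptance ~0.44). It mimics the
*structure* of a real risk screener; it is not fit to any study data.

Defaults elsewhere: `sd_mode="sample"` (N-1 denominator; exposed because
cluster counts can shift slightly), cut height chosen by the user from
`height_diagnostics` (4.5 is the package's validation default), M = 1000 and
tau = 0.95 for production runs. The test suite and `scripts/acceptance.py`
use the package's reduced validation scale — null calibration at N = 400,
M = 200; validation at 640 background rows and 62 cluster draws, 20
replicates, M = 200 — which keeps Monte Carlo noise acceptable while the full
paper-scale study (about 1300 background rows, M = 1000, 100 replicates) is a
few CPU-hours. At the reduced scale the planted r = 0.8 cluster is recovered
with sensitivity ~0.5 and specificity ~0.997; the detection rate (~0.40) is
lower than at full scale because the realized cluster is a slightly smaller
fraction of a noisier cohort.

## What the generator does and does not emulate

The synthetic population reproduces marginals, pairwise Pearson correlation,
eligibility screening, completion filtering and temporal clumping of repeat
enrollers. It does not emulate free-text fields, item nonresponse,
within-person response drift across repeated enrollments beyond the single
block-correlation factor, or adversaries who deliberately vary their answers
— passing tests show the statistic behaves as designed under the stated
model, not that every real repeat enroller is detectable.

## Numerical choices and limitations

- scipy's complete-linkage implementation (nn-chain) is the production path;
  its tie-breaking among exactly equal merge heights is deterministic but not
  lexicographic, so integer-coded data with exact distance ties can yield a
  different (equally valid) dendrogram than a lexicographic rule. The strict
  height cut is implemented exactly by thresholding one ulp below h.
- Silhouettes are computed vectorized from the distance matrix and checked
  against direct-formula and scikit-learn references in the tests.
- Quality metrics: the run statistic is (longest run - 1)/(items - 1) averaged
  over pages with at least `page_min` (default 5) items — a documented choice
  where several normalizations exist; synonym pairs are chosen greedily by
  descending absolute correlation; even-odd consistency uses the
  Spearman-Brown step-up correction. Degenerate (zero-variance) respondents
  yield missing values rather than zeros. Latent-class modeling is not
  implemented; externally fitted class labels are summarized and
  cross-tabulated only. For mixed-type class models, skewed continuous
  metrics can be decile-binned first (`pd.qcut(metric, 10, labels=False)`)
  before being handed to an external latent-class fitter.
- Clustering fields must be complete; `load_survey` rejects incomplete rows
  with a row-level report (error by default, warn-and-drop on request).
  Quality-metric computations skip missing values pairwise instead.
- Memory: per null simulation only cluster sizes and ASWs are retained, never
  the simulated matrices.
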