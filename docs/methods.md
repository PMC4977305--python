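# Methods

This note documents the statistical models implemented in `proteoreg`,
their assumptions, the defaults and why, and what the synthetic-data
generator does and does not emulate.

## The design and its coding

The packaged experiment is a 32-run design over five environmental
factors: four continuous (acetate 0–1 g·L⁻¹, light 0–200 µmol photons
m⁻²·s⁻¹, NH₄⁺ 0–15 mM, NO₃⁻ 0–20 mM) and one ordinal (CO₂ at 0.035 % or
1.5 %). It is a two-level fractional factorial augmented with center
points and axial-type points, so linear, quadratic and second-order
interaction effects are estimable. Three replicated center-point runs
(one triple at high CO₂, one pair at low CO₂) supply 3 pure-error degrees
of freedom. The factor columns are near-orthogonal: max |Pearson R| =
0.157 with min p = 0.391 across the ten pairs.

Model terms are built from coded factors. The ordinal factor is always
coded 0/1 by ascending modality. Continuous factors default to **unit**
coding ([low, high] → [0, 1]): it keeps quadratic columns well-scaled,
makes coefficients comparable to the factor ranges, and is row-independent
so prediction grids can be coded without reference data. `raw` and
`standardized` codings and a `center_polynomials` flag ((x − x̄)² instead
of x²) are available because regression software differs in whether it
centers polynomials; coefficients depend on this choice but fitted
surfaces do not. β-weights (coefficient × sd(column)/sd(y)) are reported
alongside and are comparable across variables regardless of coding.

The candidate term set for all per-variable modeling is fixed at 19
terms: 4 linear, 4 quadratic, 6 continuous×continuous interactions, the
CO₂ main effect and 4 continuous×CO₂ interactions.

Replicate-group detection uses exact floating-point equality of settings;
design files are expected to carry exact printed values.

## Synthetic data

`make_truth`/`simulate` generate abundance matrices from the same
second-order equation the models fit: y = b₀ + Σb·(coded columns) + ε
with ε ~ N(0, σ²) i.i.d. per variable. Variables are grouped into
clusters that share a term signature (identical active terms, coefficients
jittered ≤10 %), emulating blocks of co-regulated proteins. Missing cells
are masked completely at random at a per-variable rate. Defaults mirror
the real experiment's shape: 135 spots + 19 assays over the 32-run
design, 8 clusters, 2–4 active terms per cluster with coded-scale
magnitudes 0.5–2 of random sign, noise σ = 0.25 (roughly 10–25 % of a
typical response range). The demo writer places missing values the way
the real assay data show them — spots complete, eight assay cells absent,
concentrated in three runs including a center point — because
complete-case multi-response PLS cannot survive scattered per-cell
missingness once there are hundreds of variables.

What the generator does **not** emulate: dye/gel batch effects,
heteroscedastic or heavy-tailed noise, intensity-dependent variance,
non-second-order response shapes, and informative missingness. Passing
tests therefore demonstrate correctness of the estimators under the
model's own assumptions, not robustness to real 2D-DIGE artifacts.

## PLS core

NIPALS with autoscaling (center + unit variance per column) on both
blocks; deflation of X and Y per factor; convergence tolerance 1e-12 on
the weight vector, max 500 iterations; the single-response case
short-circuits to the closed form w ∝ Xᵀy. Per-response variance
explained by factor a is (tᵀt)q²/SS_tot, which for a single-predictor
one-factor model equals the squared Pearson correlation. With A = rank(X)
factors PLS predictions coincide with OLS.

Latent-factor selection: leave-one-out PRESS (explicit refits, errors on
the original response scale) followed by van der Voet tests comparing
each candidate A to the PRESS-minimal one via sign-flip randomization of
the paired per-run squared-error differences. The randomization is
exhaustive (all 2ⁿ sign assignments) for n ≤ 14 and otherwise uses 10 000
seeded draws. The selected A* is the smallest candidate with p > α;
α = 0.10 by default (the test's published form gives no canonical level;
0.10 is a common software default) and configurable.

VIP follows Wold's formulation, VIP_j = √(p·Σₐ SSYₐ(w_ja/‖wₐ‖)²/Σₐ SSYₐ),
so ΣVIP² = p; cluster summaries report the coefficient sign only where
VIP > 1.

## Screening

Four strategies, each marking a pass per variable, with selection at ≥3
votes of 4. Class-specific defaults (spots / assays): strategy 1 variance
threshold 0.30 with a relaxed 0.19 for the nitrate models of spots;
strategy 2 whole-model p ≤ 0.075 / 0.05; strategy 3 threshold 0.30 / 0.65
at 2 / 4 latent factors; strategy 4 whole-model p ≤ 0.10 / 0.05. The MLR
strategies read "statistical significance" as the whole-model ANOVA p; a
`p_kind="best_effect"` option uses the smallest per-effect p instead.
Strategies 2 and 4 include an intercept but no CO₂ main effect (a flag
adds it). The PLSR strategies are multi-response (all variables of a
class jointly) and require complete data within each CO₂ stratum;
incomplete runs are dropped, variables constant within a stratum are
excluded from that stratum's block, and zero-variance variables are
auto-failed with a warning rather than erroring the batch. No
multiplicity correction is applied at this stage.

## Clustering and imputation

Variables are standardized to mean 0, variance 1 over their non-missing
cells. Missing cells are imputed by conditional-mean (regression)
prediction: a single covariance matrix is estimated by the pairwise
method over the whole data set, and for each run ŷ_M = μ_M +
Σ_MO Σ_OO⁻¹ (y_O − μ_O); Σ_OO receives a ridge ε·I with
ε = 1e-8·trace/dim when its condition number exceeds 1e12 (pairwise
covariance matrices need not be positive definite). Observed cells are
never altered. Because the moments are pairwise estimates, a variable
duplicated from another is imputed to its partner's value only up to an
O(1/n) perturbation — exactness holds in the limit, not cell-for-cell.

Clustering is Ward's minimum-variance agglomeration on Euclidean geometry
with runs as the feature axis (scipy linkage, deterministic). Merge
heights are monotone; only cut memberships, not height conventions, are
treated as reproducible across software. k is a parameter (default 8,
chosen by inspection in the source study; no automatic selection).
Assays are co-assigned by re-clustering spots + assays jointly.

## Cluster profiles

PCA eigendecomposes the pairwise-complete correlation matrix of the
variables; variance proportions are eigenvalues over their sum (so they
total 100 % even when pairwise estimation perturbs the spectrum), and
loading signs are fixed by making each component's largest-magnitude
entry positive. Scores are computed from standardized data with missing
cells contributing 0 (the mean); memberships and variance proportions,
not scores, are the comparable outputs when data are incomplete.

In-cluster PLSR uses the five environmental predictors (continuous
factors + 0/1 CO₂) with all cluster members as joint responses, search
range 5, and PRESS + van der Voet selection as above.

ANCOVA stacks the standardized cluster members in long format and fits
the full 19-term environmental model plus variable-identity main effects
and identity×{continuous, CO₂} interactions. Identity is effect-coded
(sum-to-zero) so each interaction measures a variable's deviation from
the cluster-average regulation — including the reference level, whose
deviation is recovered as the negative sum contrast; dummy coding is
available by flag. A deviation with p ≤ 0.05 (t test on the contrast,
equivalent to the 1-df extra-sum-of-squares F) flags that (variable,
factor) pair as divergent, reported with its β-weight. No stepwise
selection inside ANCOVA, and no multiplicity correction by default (a
Benjamini–Hochberg option exists). Single-variable clusters degrade to a
plain MLR.

## Per-variable response-surface models

**Stepwise.** Forward selection from the intercept-only model, adding at
each step the candidate term that most lowers AICc with
AICc = n·ln(SSE/n) + 2k′ + 2k′(k′+1)/(n−k′−1), where k′ counts the
intercept and the error variance along with the term coefficients (the
information-criterion convention of Burnham & Anderson). Candidates that
would exhaust residual degrees of freedom are skipped, and SSE is floored
at 1e-14·SST so an essentially exact fit cannot be "improved" by further
terms through floating-point noise. Two extensions make the search
reliable on this design, where x and x² unit-coded columns correlate at
r ≈ 0.97: (i) a backward purge after the forward pass removes any term
whose removal lowers AICc (forward search can walk through a term that
later additions make redundant and cannot otherwise shed it); (ii) when
no single addition lowers AICc, candidate pairs are tried before stopping
(a near-cancelling linear + quadratic pair such as 1.5x − 1.56x² is
invisible to one-term steps but jointly explains the response). Both
default on and can be disabled (`purge=False`, `lookahead=False`) to
recover the literal forward-only rule. With them, noise-free generating
term sets of ≤4 terms are recovered exactly in 1002/1002 simulated
responses; without them the forward-only rule misses 10–25 %. No
effect-heredity constraint is imposed (an optional weak-heredity flag is
out of scope for the default path).

**Fit and diagnostics.** OLS on the coded columns; R² = SSM/SST; R²
adjusted and RMSE_F with denominator n−k−1 (k = coefficients excluding
the intercept); response average scale ȳ − y_MIN reported as the
reference for error magnitudes; whole-model F = (SSM/k)/(SSE/(n−k−1));
per-effect F by refitting without the effect (1-df extra sum of squares);
lack-of-fit F = MS_lof/MS_pure with pure error pooled over replicate
groups, flagged unavailable when pure-error df = 0; β-weights as above.
Runs with missing response are dropped per variable.

**Cross-validation.** k-fold with k = 4; folds are a seeded random
partition balanced to sizes {8,8,8,8} on 32 runs, or a user-supplied fold
file when externally defined subsets must be reproduced. The term set is
held fixed; RMSE_CV = √(Σ(y_v − ŷ_v)²/v) with no df correction, reported
per fold and pooled (both, since either aggregation is defensible).

**Profiles.** One-factor prediction curves evaluate the fitted equation
along a grid with the remaining factors fixed; grid points outside the
factor range are evaluated but flagged with an extrapolation warning.
Linear terms give straight lines, a negative quadratic a concave curve
with vertex at −bᵢ/(2bᵢᵢ) on the coded scale, and an interaction shifts
the profile slope by bᵢⱼ per coded unit of the interacting factor.

## Numerical choices and degenerate inputs

Least squares uses `numpy.linalg.lstsq` with an explicit rank check;
rank-deficient term sets raise rather than silently pseudo-inverting.
Ties in stepwise scores break by candidate order (deterministic). NIPALS
raises when a block is numerically exhausted before the requested factor
count. Constant variables raise in standardization and are auto-failed in
screening. All randomness (simulation, CV folds, randomization tests)
flows from named integer seeds; there is no global random state, and
identical configurations produce byte-identical pipeline artifacts.

## Problem sizes used in tests and the acceptance script

The test suite and `scripts/acceptance.py` run desk-scale versions of
every study: 50 noise-free truths for exact stepwise recovery, 200
simulated responses for ±3 SE coverage at σ = 10 % of the response scale,
100 seeds for the clustering-beats-random check at σ = 25 % of effect
size, 40 pure-noise matrices for the screening null/oracle agreement, and
one full 154-variable demo pipeline. These sizes give stable pass/fail
behavior for the properties checked while keeping a full run in the
low minutes on one CPU.

## Known limitations

Screening's multi-response PLS strategies require complete strata and so
tolerate only missingness concentrated in few runs, as in the motivating
data. The ANCOVA assumes a shared residual variance across cluster
members after standardization. Ward merge heights follow scipy's
convention and are not comparable across packages (memberships are).
PCA scores under missingness depend on the mean-substitution convention.
The stepwise lookahead examines pairs only; a truth whose terms cancel
only in triples would still be missed, though none arose in 10³ draws
from the generator's coefficient distribution.
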