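# Methods

## Scope and data model

The package analyses woman-level maternal-care microdata of the kind
produced by large stratified household surveys (DHS/NFHS family): one record
per eligible woman with a relative sampling weight, a continuous asset-based
wealth score plus its quintile label, six categorical covariates (residence,
age group, birth order, education, caste, mass-media exposure) and raw
care-utilisation fields. Eligibility is a half-open window on months since
the last birth (`< 60` by default): "births in the five years preceding the
survey" excludes a birth exactly at the boundary, the usual DHS convention.

Missing data are handled by listwise deletion over the analysis columns
only, with a per-column missingness report in the log; the pipeline makes no
imputation. Rows violating domain invariants (non-positive weight,
out-of-domain category, negative count) are rejected individually with
row-level diagnostics rather than failing the load. The pipeline is
population-agnostic: if a source file carries several analysis populations,
an optional `religion` (or any upstream) filter must be applied before or at
load time.

## Ranking and the concentration index

Fractional ranks use the Lerman–Yitzhaki construction: with weights
normalised to sum to one and records sorted by the ranking score,
`R_i = cum_before_i + w̃_i/2`. A block of tied scores shares the weighted
midpoint of the whole block, which makes the index invariant to within-tie
record order. The weighted mean of the ranks is exactly ½, so the index
reduces to `C = (2/μ) Σ w̃_i y_i R_i − 1`.

Two ranking bases are supported, because grouped and continuous rankings are
both common in applied work: `continuous_score` (default) ranks on the
wealth score itself; `quintile_groups` gives all members of a wealth
quintile the tied midpoint rank of that quintile. When the two disagree by
more than 0.005 on an outcome the run metadata records both values.

The weighted covariance is the population form (no n−1 correction). This is
deliberate: it is what makes the decomposition identity below hold to
machine precision rather than approximately.

`ci_from_curve` integrates the piecewise-linear concentration curve by exact
trapezoids (`C = 1 − 2∫L dp`) and serves as an independent oracle: for
distinct scores the covariance and curve-area computations agree to 1e-10
(property-tested). No standard errors are attached to any index; the
analyses this pipeline mirrors report none, and survey-design-consistent
variance estimation is out of scope.

Group-wise indices (`ci_by_group`) recompute ranks *within* each group, so a
state's index reflects its own wealth distribution. Groups below a
configurable minimum sample size (default 250) are skipped with a log entry,
mirroring the practice of excluding small-sample strata from state
comparisons.

Quintile assignment places each tied block of scores wholly in the quintile
containing the block's lower cumulative-weight edge; cumulative weights are
rounded to 12 decimals before the 20/40/60/80% cuts so records landing
exactly on a boundary go to the upper quintile regardless of float noise.
Fewer than five distinct scores triggers a degenerate-split warning.

## Outcome models and decomposition

The default outcome model is the weighted least-squares linear probability
model (`lpm`). Its residuals have weighted mean zero, so

`C = Σ_k (β_k x̄_k / μ) C_k + GCε/μ`

is an algebraic identity, verified at 1e-10 on every run before tables are
written. The alternative `logit_ame` fits a weighted logit and reports
finite-difference average marginal effects (weighted mean of
`p̂(x_k←1) − p̂(x_k←0)` holding other regressors at observed values); since
AMEs do not satisfy the linear identity, the residual is then defined as
total − explained, and the tables label which model produced them. Published
decomposition tables of this kind are headed "marginal effect" without
naming the regression family; both interpretations are therefore available,
with `lpm` the default because exactness makes the arithmetic auditable.

Reference categories follow the conventional layout: rural residence, age
15–24, first birth order, no education, "Others" caste, no media exposure
(overridable). Each regressor's own index `C_k` is computed with the *same*
ranks and weights as the outcome's — required for the identity; constant or
collinear dummy columns are dropped with a logged notice. The continuous
wealth score is only ever the ranking variable, never a regressor.
Percentage contributions divide by the total index by default (the explained
part is selectable); the denominator is recorded in the output because the
two conventions differ exactly when the residual is large.

Quasi-separation in the logit is detected by a linear predictor exceeding 20
in absolute value (fitted probabilities within ~2e-9 of 0/1) — statsmodels'
IRLS "converges" silently in that regime — and triggers a warning plus an
LPM fallback; genuine non-convergence raises.

## Synthetic populations

The generator emulates the *structure* of the real surveys, not any
particular realisation: ~14 state strata with fixed shares, lognormal
relative weights (σ = 0.5 by default, a typical relative-weight spread for
national surveys), a standard-normal latent wealth score, covariates whose
category probabilities tilt logistically with the wealth *rank* (so planted
covariate concentration indices are distribution-free), and outcomes drawn
from logistic models on the covariate dummies and the wealth rank. Raw care
fields are back-filled consistently with the drawn indicator (a full-ANC
woman gets ≥4 visits, ≥1 tetanus dose, ≥100 IFA; a negative case violates
one randomly chosen criterion), keeping the recode functions on the real
execution path. One integer seed feeds a single `numpy` Generator stream;
there is no other randomness in the package.

Two presets, `nfhs3_like` and `nfhs4_like`, target the published
round-level coverage of the two survey rounds (full ANC 9.3%/17.1%, SBA
38.7%/75%, PNC 33%/55%) with pro-rich gradients throughout; the later round
has higher education and media-exposure prevalence and attenuated wealth
slopes, reproducing the qualitative pattern of rising coverage with
declining inequality. Preset intercepts are solved by `brentq`
root-finding of the weighted mean logistic response against the target
coverage on a fixed-seed calibration draw of 40 000 records — deterministic
and done once at preset construction. Effect sizes are stated, plausible
log-odds (education and media strongest, higher birth order negative); exact
calibration of indices or decomposition rows to any published table is
neither claimed nor attempted, because those derive from restricted-access
microdata.

What a green test on synthetic data establishes: that the estimators
recover structure that was planted (gradients, null effects, factor
attributions) and that the algebraic identities hold under weights, ties and
stratification. What it does not establish: anything about nonresponse,
cluster design effects, the asset-PCA construction of the wealth score, or
recall error in self-reported care — none of which the generator emulates.

## Reporting

`run_analysis` chains filter → recode → rank → index → decompose → gap
table, logging row counts at each stage; identical (input, config) pairs
yield byte-identical outputs, and the serialised metadata echoes the full
configuration and every design toggle in force. Numbers are written at full
precision; 3-decimal display rounding is left to consumers because rounding
before summation is precisely what breaks additivity in printed tables (the
±0.001 slack seen in published decompositions).

## Known limitations

- The plain concentration index is used for bounded (binary) outcomes; the
  Wagstaff or Erreygers normalisations are noted but not implemented, to
  match the analyses this pipeline mirrors.
- No inference: no standard errors, significance tests or dominance tests.
- Between-round (Oaxaca-style) decomposition of the *change* in inequality
  is out of scope.
- Gap-table cells with an empty poor or non-poor stratum are reported as
  missing (NaN), never 0 — a structural zero and an empty cell are different
  facts, and published tables do not always distinguish them.
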