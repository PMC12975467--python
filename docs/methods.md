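# Methods

## The question the package answers

Given a set of numeric questionnaire indicators (e.g., subscale scores of
a suicidal-ideation inventory), is the latent structure that generated
them **taxonic** — a discrete class (taxon) plus its complement — or
**dimensional** — continuous variation along one underlying factor?
Taxometric procedures attack this by computing characteristic curves from
the data and comparing them against curves from simulated datasets that
reproduce the empirical marginals and correlations under each candidate
structure.

## Pipeline

1. **Screening filter** (optional): cases scoring 0 on *all* designated
   screening columns are removed, mirroring the skip structure of
   instruments whose later items are contingent on endorsing early ones.
   Retained rows are untouched and keep their order.
2. **Subscale scoring** (optional): factor scores as row sums over item
   columns; an item belongs to at most one factor.
3. **log10 transform** (optional sensitivity variant): x → log10(x + 1).
   The +1 offset is the minimal zero-safe convention for bounded item
   scales that contain zeros; it preserves strict monotonicity and maps
   0 to 0.
4. **Indicator validity**: cases are ranked on the sum of standardized
   indicators and the top round(n·P) flagged as the putative taxon
   (P = assumed base rate, default 0.25; boundary ties broken by stable
   case order for reproducibility). Cohen's d between putative groups
   (pooled-SD denominator, sign preserved) must reach **1.25** —
   inclusive — for an indicator to enter the analysis; at least three
   must survive. Descriptives use the n−1 SD, standardized-third-moment
   skewness and *excess* kurtosis.
5. **Curve procedures** (below) on the empirical data.
6. **Comparison ensembles**: `n_sets` (default 100) simulated datasets
   per candidate structure, with curves computed under identical
   settings.
7. **CCFI** per method, mean CCFI, interpretation band; optional CCFI
   profile over assumed base rates.

## Curve procedures

**MAMBAC.** For each ordered indicator pair, cases are sorted by the
input indicator and, at 50 cut positions starting 25 cases from each end,
y = mean(output above cut) − mean(output below cut). Ties in the input
are resolved by a random permutation, averaged over 10 replications
(skipped when the input is tie-free, where replications are a no-op).
Taxonic data produce a peaked curve with the peak near the taxon
boundary — at rank (1−P)·n, i.e. right of the midpoint for small base
rates; dimensional data produce a dish shape. Base-rate estimate: on a
noiseless two-group mixture with groups at 0 and D (taxon high), the raw
curve ends tend to y_first → D·p and y_last → D·(1−p), so
p̂ = y_first/(y_first + y_last) recovers p exactly; within-group variance
attenuates the estimate toward 0.5. (A min-shifted variant of this
curve-end heuristic was rejected because simulation showed it
anti-correlates with the true rate.)

**MAXEIG.** Each indicator takes a turn as the input; cases sorted by the
input are covered by 50 equal-count windows with 90% overlap. Within each
window the covariance matrix of the remaining indicators has its diagonal
zeroed and y is its largest eigenvalue (non-negative, since the matrix
has zero trace; for two outputs it equals |cov|). The x grid is the
window center in **case-rank units**: bounded item scores are heavily
tied, and long runs of identical values can make the within-window means
of the input coincide across consecutive windows, which would break both
the strictly-increasing grid and comparability across datasets; rank
units depend only on n and the settings. Base-rate estimate: the
proportion of cases above the peak window's center.

**L-Mode.** One factor is extracted by principal-axis factoring
(iterated communalities, SMC start); regression-method factor scores are
standardized and reflected so skewness ≥ 0 (taxon on the right). A
Gaussian KDE (Silverman bandwidth) on a 512-point uniform grid spanning
the scores ±0.5 provides the curve; comparison datasets are evaluated on
the empirical grid so curves align pointwise. The density argmax left of
0 (m_L) and right of 0 (m_R) — excluding the two outermost grid points —
yield p̂_L = m_L²/(1+m_L²), p̂_R = 1/(1+m_R²), p̂ = their mean. These are
exact on a standardized two-point mixture, whose support is
a = −√(p/(1−p)), b = √((1−p)/p).

## Comparison data

Simulated datasets reproduce the empirical marginals and correlation
structure while imposing a candidate latent structure:

- **Dimensional**: one population matching the whole-sample correlation
  matrix.
- **Taxonic**: cases are split into putative taxon and complement at the
  assumed base rate; each group's correlation matrix and marginals are
  reproduced separately and the groups concatenated, giving every
  simulated dataset exactly round(n·P) taxon cases.

Each dataset comes from an iterative rank-reordering algorithm: a fixed
matrix of standard-normal deviates is transformed to an intermediate
correlation matrix (initialized at the target), each column is replaced
by the rank-ordered bootstrap marginal, the achieved correlation is
measured, and the intermediate matrix is adjusted by the residual
(eigenvalues clipped at 10⁻⁶ and the diagonal renormalized when the
update leaves the valid cone). The best iterate by off-diagonal RMSR is
kept; iteration stops after 10 non-improving steps or 100 iterations.
Marginals are bootstrap-resampled from the empirical columns so
ensembles vary (an exact-marginal mode exists for debugging); every
output column is exactly a permutation of its marginal vector. Achieved
correlation RMSR is typically ≤ 0.02 at n = 1,000 even for strongly
skewed marginals.

## CCFI

fit_tax and fit_dim are the RMS residuals between the empirical averaged
curve and each ensemble's mean curve (an alternative — mean of
per-dataset RMSRs — is available behind `per_set_fit`); curves are
compared on raw values, no renormalization.
CCFI = fit_dim/(fit_dim + fit_tax) ∈ [0, 1]; 0.5 when both fits vanish
(with a warning). Interpretation: < 0.40 dimensional, > 0.60 taxonic,
otherwise ambiguous (both bounds themselves count as ambiguous). The
overall verdict uses the unweighted mean CCFI across methods; rounding
to two decimals happens only at the reporting layer, never before
aggregation.

**CCFI profile**: the analysis is repeated across assumed base rates
0.025…0.975 in steps of 0.025 (the dimensional ensemble is
rate-independent and computed once). Rates whose putative groups would
have fewer than k+2 cases are skipped, not clamped. Aggregates: mean
over methods at each rate, mean over rates per method, and the mean of
the per-method aggregates.

## Synthetic data

The generator provides datasets with *known* structure:

- **Taxonic**: exactly round(n·p) taxon cases (deterministic, so
  recovery tests carry no base-rate sampling noise); within-group
  multivariate normal with exchangeable correlation `within_r`, unit
  variances; taxon means shifted by the per-indicator separation d.
- **Dimensional**: x_ij = λ_j f_i + √(1−λ_j²) e_ij.
- **Matched pairs**: the mixture implies pairwise correlations
  r_ij = (within_r + p(1−p)d_i d_j)/√((1+p(1−p)d_i²)(1+p(1−p)d_j²));
  loadings solving λ_i λ_j = r_ij give a dimensional twin that differs
  from the taxonic member only in latent structure (for equal d and
  within_r = 0, λ = √(p(1−p)d²/(1+p(1−p)d²))).

Bounded questionnaire shapes are emulated by a monotone marginal
transform: optional skew induction by (x+6)^a (rank-preserving),
rescaling to a target mean/SD, clipping to the scale bounds and rounding
to integers. The presets `bss_like` (n = 547, three factor-sum
indicators) and `sidas_like` (n = 989, three 0–10 items) carry transform
constants calibrated once by coarse grid search against the published
descriptive moments of the emulated scales; tests assert bands (±0.75 on
means), not exact values. Default preset structure is taxonic with
separations equal to the published putative-group d values and
within-group correlation 0.30 (a moderate nuisance-covariance level; the
true inter-indicator correlations of the study data are not published).

What the generator does **not** emulate: item-level response processes,
careless responding, missingness patterns, demographic covariates, and
the unpublished empirical correlation matrices. Passing recovery tests
therefore shows the machinery discriminates known structures under
realistic marginal shapes — not that any specific empirical dataset is
taxonic or dimensional.

## Numerical choices

- Randomness: one master seed; each stage (curve tie-breaking,
  dimensional ensemble, taxonic ensemble, profile) draws from its own
  child stream keyed by (seed, stage id), so toggling the profile never
  perturbs the fixed-rate results; identical config + seed reproduces
  byte-identical report numbers.
- Ties: putative-classification boundary ties broken by stable case
  order (logged); MAMBAC input ties by seeded random permutation,
  averaged over replications.
- round(n·P) uses half-up rounding (547·0.25 → 137).
- Degenerate inputs: constant indicators get NaN skew/kurtosis flags and
  a unit pseudo-SD in the ranking total; undefined correlations inside
  tiny comparison groups are replaced by 0; a singular correlation
  matrix aborts L-Mode with a clear error.
- Missing data default to a hard failure naming the first offending row
  and column; `drop_case` removes and counts offenders.

## Problem sizes used in validation

Recovery studies run at k = 3, n = 600, p = 0.25, within-group r = 0.1,
d = 2.0 (strong) or 0.8 (weak), with 50 comparison datasets per
structure and 20 seeds; profile smoke checks use coarse grids and
smaller ensembles. These sizes give stable verdicts (taxonic/dimensional
recovery is essentially saturated at 20/20) while keeping the whole
validation quick on one CPU.

## Known limitations

- The curve-end and peak-window base-rate heuristics are crude; they are
  exact only on noiseless two-point mixtures and attenuate toward 0.5
  under within-group variance (method-to-method spread of the estimates
  is expected, as in published applications).
- With weak separations (d below the 1.25 validity floor) the CCFI leans
  dimensional rather than ambiguous: the taxonic comparison ensemble
  always imposes truncation-induced group separation on its simulated
  datasets, which overshoots the weak empirical structure, while a weak
  mixture is statistically close to its matched factor model.
- MAMBAC/MAXEIG x grids are rank-based, so curves from datasets of
  different n are not directly comparable (the pipeline never needs
  that).
- CCFI values carry Monte-Carlo noise of order 0.01–0.03 at
  n_sets = 50–100; no inferential intervals are provided.
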