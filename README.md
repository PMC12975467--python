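# taxometrics

Taxometric analysis of questionnaire indicators: the coherent-cut-kinetics
procedures **MAMBAC**, **MAXEIG** and **L-Mode**, structure-matched
simulated comparison data, and the **comparison-curve fit index (CCFI)**
with its ambiguity band and base-rate profiles.

## The problem

Is a construct measured by a set of questionnaire scores — here,
suicidal-ideation indicators such as the factor scores of the Beck Scale
for Suicide Ideation or the items of the Suicidal Ideation Attributes
Scale — **taxonic** (a discrete latent class, the *taxon*, plus its
complement) or **dimensional** (continuous variation along a latent
factor)? The answer matters for whether screening should use cutoffs or
treat severity as a continuum.

Taxometric procedures answer it by computing characteristic curves from
the data and comparing them against curves from simulated datasets that
keep the empirical marginals and correlations but impose a known latent
structure:

- **MAMBAC** — for each ordered indicator pair, the difference between
  the output indicator's means above and below a moving cut along the
  input indicator: peaked for taxonic data, dish-shaped for dimensional.
- **MAXEIG** — the largest eigenvalue of the zero-diagonal covariance
  matrix of the remaining indicators within overlapping windows along an
  input indicator: peaked under taxonicity.
- **L-Mode** — kernel density of one-factor scores: bimodality indicates
  taxonicity, and the mode locations m_L, m_R give base-rate estimates
  p̂_L = m_L²/(1+m_L²), p̂_R = 1/(1+m_R²).

For each method the fit of the empirical curve to the taxonic and
dimensional comparison ensembles (RMS residual against the ensemble mean
curve) combines into

```
CCFI = fit_dim / (fit_dim + fit_tax)          ∈ [0, 1]
```

0 → dimensional, 1 → taxonic, values in (0.40, 0.60) → ambiguous; the
verdict uses the mean CCFI across methods. Because the assumed taxon
base rate (default 25%) is itself an assumption, a **CCFI profile**
recomputes everything across base rates 0.025…0.975 in steps of 0.025.

Indicators enter the analysis only if they separate the putative taxon
(top round(n·P) cases by standardized total) from its complement with
Cohen's d ≥ 1.25, and at least three must pass.

## Worked example

```python
import taxometrics as tx

# a dataset with known taxonic structure: 25% taxon, separation d = 2
spec = tx.SyntheticSpec("taxonic", n=600, k=3, base_rate=0.25,
                        separation=2.0, within_r=0.1)
matrix, membership = tx.simulate_taxonic(spec, 7)

result = tx.run_full_analysis(tx.RunConfig(n_sets=50, seed=7),
                              matrix=matrix)
print(result.report["ccfi"])
print(result.report["base_rates"])
```

prints (abridged):

```
{'per_method': {'mambac': {...'ccfi': 0.88},
                'maxeig': {...'ccfi': 0.81},
                'lmode':  {...'ccfi': 0.81}},
 'mean_ccfi': 0.83, 'interpretation': 'taxonic'}
{'per_method': {'mambac': 0.29, 'maxeig': 0.27, 'lmode': 0.6},
 'mean': 0.39}
```

All three method CCFIs exceed 0.60, so the mean CCFI of 0.83 correctly
labels the generating structure taxonic; the base-rate estimates bracket
the true 25% (the L-Mode mode heuristic overestimates, as is typical).
Running the same config on the matched dimensional twin
(`tx.matched_pair(spec, 7)[1]`) yields a mean CCFI around 0.3.

From a shell, the same analysis on a CSV file:

```bash
taxometrics simulate --preset sidas_like --structure taxonic --seed 1 --out data/
taxometrics run --input data/sidas_like_taxonic.csv \
    --indicators closeness_to_attempt,distress,interference \
    --n-sets 100 --seed 42 --out results/
```

which writes `report.json`, `validity.csv`, one `curves_<method>.csv`
per procedure and, with `--profile`, `profile.csv`.

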