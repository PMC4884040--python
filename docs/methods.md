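# Methods

## Data model

The unit of analysis is a *population unit*: a region, facility or
socioeconomic group with a population count `pop_i` and a resource amount
`res_i` (one resource per run, same physical unit in every row). Shares are
`P_i = pop_i/Σpop` and `Y_i = res_i/Σres`; per-capita resource is
`y_i = res_i/pop_i`. Individual-level data is the special case `pop_i = 1`.
All arithmetic is double precision; nothing is rounded before output.

Both totals must be positive — every measure here is ratio-based. Units with
`pop = 0, res = 0` carry no information and are dropped from curves; units
with `pop = 0, res > 0` are kept in the Lorenz cumulation ordered last
(their per-capita level is effectively infinite — dropping them would break
the curve's (1,1) endpoint and understate inequality) but cannot enter
rank-based or per-capita-based measures, which raise instead.

## Curves and Gini

The Lorenz curve cumulates (population share, resource share) over units
sorted ascending by per-capita resource; the concentration curve uses the
same cumulation sorted by the living-standards score, poorest first. Curves
are stored as exact polygon vertices — the trapezoid rule is exact on
polygons, so no resampling is ever needed. Ties in the sort key cannot
change the polygon as a function; a stable sort by input order keeps the
vertex list reproducible.

Gini is computed by the cumulative-share summation
`G = Σ P_i S_{i+1} − Σ P_{i+1} S_i` over the Lorenz ordering, which is
algebraically identical to twice the area between the curve and the
diagonal (the test suite holds the two routes together at 1e−12). No
finite-sample `n/(n−1)` correction is applied by default; a flag enables it.
The equity bands (below 0.3 equitable, 0.3–0.4 normal, above 0.4 alert,
above 0.6 highly inequitable) are applied with the 0.3–0.4 band closed on
both ends, the only overlap-free reading of the published rule.

## Concentration index

`CI = 2·cov_w(X, H)/mean_w(H)` with population weights, per-capita resource
`H`, and fractional ranks `X_i` = cumulative population share of all poorer
units + ½ of the unit's own share. Midpoint ranks make the weighted mean
rank exactly 0.5; SES ties receive the midpoint rank of the whole tied
block. With these conventions the covariance form coincides with twice the
signed area between the concentration curve and the diagonal (checked at
n = 10, 100, 1000). Negative CI: resource concentrated among the poor.
Reported values are not rescaled to the finite-sample attainable bounds
±(1 − 1/n).

## Theil index and decomposition

The mean-log-deviation form `T = Σ P_i ln(P_i/Y_i)` with natural logs (the
base only rescales the value, never the zero point; the report metadata
records `log_base: e`). For grouped data, `between = Σ_g P_g ln(P_g/Y_g)`
on group aggregates and `within = Σ_g P_g T_g` with `T_g` computed on
shares renormalized inside group g. `within + between = total` is an
algebraic identity, enforced at 1e−10. Contribution rates are each
component's share of `within + between` (normalizing by the independently
computed total is ill-conditioned when the total is near zero).

A populated unit with zero resource makes `T` diverge; the index returns
+inf with the offending units listed rather than raising or silently
dropping rows (dropping would bias the result). The decomposition requires
a finite total. Note the direction convention: larger Theil = more
inequality, zero = proportionality; the index is not bounded by 1.

## Atkinson index

`A_ε = 1 − EDE/ȳ`, where EDE is the population-weighted power mean of
order 1−ε of per-capita resource; at ε = 1 the geometric-mean form is used.
The two branches agree in the ε → 1 limit (tested at ε = 1 ± 1e−6). The
default aversion is ε = 2, the conventional setting for revealing moderate
imbalance; higher ε weights the lower tail more. A zero-resource populated
unit drives the EDE to zero for ε ≥ 1, so the index is exactly 1 there —
returned as a flagged degenerate value. `1 − A` is reported as the EDE
fraction: the share of the current total that, equally spread, yields the
same allocation level.

## Chi-square equity test

Pearson's `X² = Σ (obs_i − exp_i)²/exp_i` against the population-
proportional expectation `exp_i = P_i · Σres`, df = k − 1 (the expectations
are constrained only by the fixed total), critical value from the
chi-square distribution at 1 − α (default α = 0.05). Verdict "equitable"
iff the statistic is below the critical value, equivalently p > α. The
statistic is **not** scale-free — halving the measurement unit doubles it —
and it is applied to resource amounts, not classical counts, so
non-integer inputs get a warning rather than an error, as does any
expected value below 5. The expectation base can be swapped (land area, a
custom need column) for sensitivity analyses. Comparing the statistic over
the years of a panel yields a trend annotation: improving (strictly
falling), worsening, stable, or mixed.

## Need standardization

Named direct/indirect standardization has many variants; the textbook
demographic forms are used here, and this is the part of the package where
the methodology is least standardized in the literature — results should
state which method and reference profile were used.

*Indirect*: each unit's need-expected resource is
`E_i = Σ_s count_{i,s} · m_s` from its stratum composition and reference
per-person means `m_s`; the adjusted allocation is
`obs_i − E_i + r̄·pop_i`. The reference means act as *relative* need
weights: `E` is rescaled so `Σ E_i = Σ obs_i`, which makes the adjustment
total-preserving (exactly, up to the optional flooring) and means only the
ratios of the `m_s` matter. Negative adjusted values — possible when a
unit's holding is far below its need expectation — are floored at 0 with a
warning, because downstream indices require nonnegative resources.

*Direct*: each unit's stratum-specific rates `res_{i,s}/count_{i,s}` are
applied to the pooled stratum composition. This needs per-unit per-stratum
resource amounts; unit totals alone cannot identify stratum rates.

Standardization is idempotent **by construction, not by algebra**: the
additive correction is profile-fixed, so naively applying it twice would
double it. The output therefore carries a digest of the profile and method
in its metadata and `standardize()` returns already-adjusted input
unchanged — double adjustment is treated as a pipeline error to absorb, not
an operation with meaning.

## Synthetic generator and oracles

The generator emulates a provincial panel: `n_units` county-level units
(default 39, a realistic county count for a large municipality), per-capita
resource lognormal with log-sd σ (default 0.5, which places Gini ≈ 0.27–0.33
— the band typical of per-population bed/doctor allocations), 3
macro-regions with mean multipliers (1.6, 0.9, 0.7) creating a
center-vs-periphery between-group component, equal unit populations by
default (a lognormal population model is available), and panel years
1998/2002/2007/2012 with an optional per-year σ path. Seeds are mandatory;
there is no global random state.

For the lognormal family the indices have closed forms — Gini =
2Φ(σ/√2) − 1, Theil (MLD form) = σ²/2, Atkinson(ε) = 1 − exp(−ε·σ²/2) —
re-derived independently by numerical quadrature in the test suite and used
as oracles: sampled indices on 100,000 equal-population units must land
within 0.01 of them (three seeds). By default the SES score equals
per-capita resource so that CI = Gini exactly and the concentration
machinery is cross-validated against the Lorenz machinery; the
`independent` SES mode gives CI ≈ 0 at any Gini, exercising the conceptual
difference between the two measures.

What the generator does **not** emulate: spatial autocorrelation between
neighbouring units, measurement error in resource counts, year-to-year
serial dependence (panel years are drawn independently), or realistic SES
gradients. Passing tests therefore demonstrate correctness of the
estimators on cleanly specified populations, not robustness to real survey
artefacts.

## Numerical conventions

- Curve endpoints are pinned to exactly (0,0) and (1,1) after cumulation
  (cumsum leaves ~1e−16 residue).
- Gini clips a possible −1e−16 rounding residue to 0 at exact equality.
- The "proportionate" CI label uses a 1e−12 zero tolerance.
- Chi-square critical values and p-values come from `scipy.stats.chi2`;
  verdict-by-critical-value and verdict-by-p-value agree to quantile
  precision.
- Problem sizes in the validation suite (1,000 random distributions for the
  geometric identities, 100,000 units for oracle recovery) were chosen so
  the whole suite runs in a few seconds while leaving Monte-Carlo error an
  order of magnitude below the 0.01 oracle tolerance.

## Known limitations

- No sampling variability: no standard errors, bootstrap intervals or
  dominance tests for curves; all measures are point estimates.
- No Erreygers/Wagstaff-type corrected concentration indices; the plain
  covariance form only.
- No regression-based (econometric) indirect standardization.
- No composite index combining the six measures — any such weighting would
  be arbitrary; users should read the measures side by side.
- The chi-square test inherits the usual caveats of applying Pearson's
  statistic to non-count magnitudes; treat its verdict as descriptive.
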