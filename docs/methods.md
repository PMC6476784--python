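# Methods

## The problem

Extracellular acid-base variables that cannot be measured directly —
CO2 tension (pCO2) and bicarbonate ([HCO3-]) of coelomic fluid — are
calculated from two measurable quantities, pH and total CO2 content (TCO2),
through the Henderson-Hasselbalch equilibrium:

    pH   = pK'1 + log10([HCO3-] / (alpha * pCO2))
    TCO2 = [HCO3-] + alpha * pCO2

`alpha` is the physical CO2 solubility of the fluid (mmol L-1 mmHg-1) and
pK'1 the *apparent* first dissociation constant.  pK'1 is not a universal
constant: it absorbs ionic-strength and protein effects, varies with
temperature, and — the central subject of this package — varies
substantially between individuals of the same species.  The package
quantifies how the choice of pK'1 source changes both the calculated
variables and the factorial inference built on them, for a design crossing
three seawater temperatures (10, 15, 20 degC) with two seawater pCO2 levels
(ambient ~380-390 uatm, elevated ~1000 uatm; ocean-warming x
ocean-acidification scenarios).

## Estimating individual pK'1 (tonometry)

A fluid sample is equilibrated against a ladder of known CO2 tensions
(default six tensions spanning 0.04-1.01 kPa) at the animal's own exposure
temperature, measuring pH and TCO2 at each step.  Rearranging the
equilibrium gives a per-step estimate

    pK'1 = pH - log10((TCO2 - alpha*pCO2) / (alpha*pCO2)),

with the pump's set tension taken as the true pCO2 (precision gas-mixing
pumps justify ignoring tension error in estimation; the simulator can still
add measurement noise to pH and TCO2).  The individual's pK'1 is the
arithmetic mean of the per-step values.  The mean was chosen over a
regression-based aggregate because it is the simplest faithful statistic
and fully auditable; the per-step vector and its SD are retained on the
result object so alternatives can be compared.  Steps whose measured TCO2
does not exceed dissolved CO2 (which would make the bicarbonate ratio
nonpositive) are excluded with a logged warning rather than failing the
series; estimation fails only below two usable steps.

The same titration yields the non-bicarbonate buffer (NBB) line: ordinary
least squares of derived [HCO3-] on pH.  Echinoderm coelomic fluid is
protein-poor, so slopes are shallow and negative (default simulated slope
-2 mmol L-1 per pH unit).

## The three pK'1 sourcing strategies

1. **individual** — each animal's own tonometry-derived constant;
2. **species-mean** — the mean constant of conspecifics in the same
   treatment cell (temperature x pCO2 level; six entries);
3. **cross-species** — published constants from decapod hemolymph, keyed by
   temperature only (6.057, 6.029, 6.000 at 10, 15, 20 degC).

The shipped species-mean defaults (6.445/6.256/6.158 ambient,
6.466/6.281/6.069 elevated at 10/15/20 degC) are also the simulator's
cell-mean targets, so simulated studies occupy the same region of
parameter space as real ones.  All pressure arithmetic is internal to mmHg
(the unit of alpha, 1 kPa = 7.500617 mmHg exactly); kPa appears only at
I/O boundaries, which avoids silent unit mixing.  Solubility and pK'
lookups are strict by default (the design has exactly three temperatures);
linear interpolation is opt-in, extrapolation refused.

## Statistics

Each response (pH, log10 TCO2, pK'1, log10 pCO2, log10 [HCO3-]; the log10
transforms reflecting the skew of concentration- and pressure-like
quantities) is fitted as a two-way fixed-effects linear model with
sum-to-zero contrasts, reported with type-III (partial) sums of squares —
the convention under which mainstream commercial ANOVA output is
reproduced, and the one a reader of such output expects.  Body volume and
wet mass enter as covariates when present and are screened: any covariate
with type-III p > alpha is dropped and the model refitted (logged), so the
ANCOVA collapses to an ANOVA when morphometrics are uninformative.

Assumption checks are Shapiro-Wilk on model residuals and median-centred
Levene across the six cells (the classical tests for this purpose; both
configurable).  The transform verdict follows a raw-first flow: keep raw
if it passes, otherwise accept log10 if that passes, otherwise proceed on
the raw scale — a defensible choice for balanced designs with ~20
replicates per cell, which are robust to moderate assumption violations.
A residual-vs-factor check (one-way ANOVA of unstandardised residuals on
each factor) confirms the factorial structure left no systematic signal.

Pairwise comparisons use estimated marginal means with Fisher's LSD:
unweighted averages of cell means, variance MSE/K^2 * sum(1/n_cell),
t tests on the pooled error df with **no** multiplicity adjustment, plus a
greedy compact-letter display.  Mortality is tested by Pearson chi-square
of independence without continuity correction on an alive/dead table;
the pipeline tabulates per-treatment counts and drops zero-death
treatments before testing (an approximate reconstruction — with deaths in
four of six treatments this gives df = 3), while the underlying operation
accepts any contingency table.

Inter-individual spread is summarised as the relative range
(max - min)/min * 100 (reported to 2 decimals) plus the coefficient of
variation.  Significance patterns — boolean verdicts per (approach,
response, term) at alpha = 0.05 — are compared across strategies; the diff
report lists every (response, term) where the verdicts disagree.  No
correction is applied across responses.

## The synthetic-data generator

`SimConfig` defaults encode the target study conditions: 21 individuals
per cell (design range 19-23), the six cell-mean constants above,
sigma_pk = 0.35 (chosen a priori so the pK'1 population, truncated to the
plausible envelope [5.50, 7.51], spans roughly 5.5-7.5 study-wide), six
tonometry tensions in [0.04, 1.01] kPa, measurement noise sigma_pH = 0.02
and sigma_TCO2 = 0.05 mmol/L, and per-treatment mortality of 9% in four
cells and zero in the two warmed ambient-pCO2 cells.

Per individual, the generator draws the apparent constant and a
*physiologically structured* state — true pCO2 carries the temperature
main effect (defaults 0.90/0.85/0.40 kPa at 10/15/20 degC: a drop at the
warmest temperature; log-normal noise, sigma 0.18 decades) and true
[HCO3-] carries the seawater-pCO2 main effect (+1.4 mmol/L under elevated
pCO2, additive noise sigma 0.8) — then closes the equilibrium to produce
the recorded pH and TCO2.  Records are redrawn (up to 100 times) until pH,
TCO2 and pK'1 fall inside the observed-range envelopes, so simulated
summaries stay inside plausible physiological bounds; the truncation
biases the most off-centre cell mean by at most +0.04 pK units (closed
form via the truncated-normal expectation, tested).

**Which constant closes the in-vivo equilibrium** is the one genuinely
open design choice, controlled by `pk_in_vivo`:

* `"treatment_mean"` (default): the in-vivo pH is consistent with the
  *cell-mean* constant; the individual's own constant is expressed only in
  vitro.  This models the apparent pK'1 spread as a property of the
  sampled fluid under tonometry that is not mirrored one-for-one in the
  live animal's chemistry.  It is the regime that reproduces the ordering
  seen in real urchin data: calculating pCO2 with each individual's own
  constant *widens* the spread relative to mean-constant strategies, and
  raising sigma_pk widens only the individual-strategy range.
* `"individual"`: the equilibrium is closed with the individual's own
  constant, making every record exactly round-trip consistent with its
  `true_pk1` (to 1e-9 before measurement noise).  This is the right mode
  for end-to-end recovery tests — but it algebraically forces the
  *opposite* range ordering: because the recorded pH then absorbs the
  individual constant, the individual-strategy calculation returns the
  true pCO2 exactly, while mean-constant strategies inherit the full
  sigma_pk spread.  The two orderings cannot hold at once; the default
  follows the empirically observed one.

Tonometry series are generated by intersecting the individual's NBB line
(configured slope, anchored at the sample's own consistent state) with the
equilibrium at each set tension — a scalar root-find in [HCO3-] (Brent's
method; the objective is strictly decreasing, so the root is unique) —
after which pH is *defined* from the root via the equilibrium, so
noise-free steps recover the generating constant to machine precision
regardless of root tolerance.

What the generator does **not** emulate: seawater carbonate-system
chemistry (treatments act only through effect parameters), metabolic or
ion-transport mechanisms, carbamate and other minor CO2 species,
within-individual repeat sampling, or any correlation between
morphometrics and acid-base state (morphometric covariates are
deliberately uninformative, exercising the covariate-screening path).
Passing tests therefore demonstrate the pipeline's correctness and the
qualitative strategy contrast under the stated generative model — not
physiological realism beyond the encoded envelopes and effect structures.

## Numerical choices

* Pressure conversion multiplies by 7.500617 in one direction and divides
  in the other: round trips are exact to one ulp.
* Equilibrium formulas reject their domain edges explicitly (TCO2 below
  dissolved CO2, nonpositive TCO2/alpha) with errors naming the offending
  quantity.
* A numerically perfect ANOVA fit (error SS below 1e-12 of total SS) is
  reported as F = inf, p = 0 rather than NaN.
* Compact letters use the standard insert-absorb heuristic; ties in EMM
  ordering are broken by descending mean.
* Degenerate inputs (constant response, zero residuals, identical pH in a
  buffer-line fit) are flagged or rejected, never silently fitted.

## Known limitations

* Exact published F statistics from the original animal dataset are not
  reproducible here (that dataset is external); the package reproduces the
  machinery and the qualitative contrasts, and accepts real data in the
  documented CSV schemas.
* The percent-range spread of simulated pK'1 (~25-30% with default
  sigma_pk) sits below the ~36% attainable only when both envelope
  extremes are realised; the envelope truncation trades spread fidelity
  for cell-mean fidelity.
* Fisher's LSD is deliberately unadjusted; with many contrasts its
  family-wise error grows, which is inherent to the method, not a defect.
* The mortality-table reconstruction (dropping zero-death treatments) is
  one of several defensible groupings; supply your own table to
  `mortality_chi_square` for a different one.
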