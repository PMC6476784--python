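# coelomic

Individual-level acid-base analysis of echinoderm coelomic fluid under
crossed seawater temperature x pCO2 exposures.

## The problem

Extracellular pCO2 and bicarbonate cannot be measured directly in small
marine invertebrates; they are calculated from measured pH and total CO2
(TCO2) through the Henderson-Hasselbalch equilibrium

    pH   = pK'1 + log10([HCO3-] / (alpha * pCO2))
    TCO2 = [HCO3-] + alpha * pCO2

where `alpha` is the CO2 solubility of the fluid and pK'1 its *apparent*
first dissociation constant.  Common practice plugs in a species-mean or
even another species' pK'1 — yet pK'1 varies widely between individuals.
This package is for comparative ecophysiologists who want to quantify how
that choice changes the answer in a factorial ocean-warming x
ocean-acidification experiment (three temperatures x two seawater pCO2
levels).  It provides:

* **chemistry** — gas-tension units, temperature-dependent solubility, and
  the four working rearrangements of the equilibrium;
* **tonometry** — per-individual pK'1 estimation from equilibration series
  and non-bicarbonate buffer (NBB) lines;
* **approaches** — in-vivo pCO2/[HCO3-] under three pK'1 sourcing
  strategies (individual, conspecific treatment mean, cross-species) and
  their divergence;
* **stats** — type-III factorial ANOVA/ANCOVA with covariate screening,
  assumption checks, estimated-marginal-means pairwise tests with Fisher's
  LSD, variation metrics, a mortality chi-square, and cross-strategy
  significance-pattern comparison;
* **simulate** — a calibrated synthetic-study generator so the whole
  pipeline is testable without animal data;
* a **CLI** (`coelomic simulate | pk | compute | compare | stats | run-all`).

See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
from coelomic import (SimConfig, generate_study, estimate_individual_pk,
                      fit_nbb_line, alpha_at, pco2_from_state, hco3_from_tco2)

# a synthetic study: 6 treatment cells x 21 urchins, tonometry per survivor
records, series = generate_study(SimConfig(), seed=1)

r, s = records[0], series[0]
print(r.individual_id, r.temperature_c, r.pco2_level, r.ph_cf, r.tco2_cf_mmol_l)
# amb10_01 10.0 ambient 7.391 5.415

est = estimate_individual_pk(s)        # this animal's apparent constant
print(round(est.pk1, 3), round(est.sd, 4), est.n_used)
# 6.572 0.0068 6        (mean of 6 per-step pK' values, sample SD, steps used)

line = fit_nbb_line(s)                 # its non-bicarbonate buffer line
print(round(line.slope, 2), round(line.r_squared, 3))
# -1.94 0.999            (mmol HCO3- per pH unit; shallow, as expected for
#                         protein-poor coelomic fluid)

alpha = alpha_at(10.0)                 # CO2 solubility at 10 degC
pco2 = pco2_from_state(r.tco2_cf_mmol_l, r.ph_cf, est.pk1, alpha)
print(round(pco2.kpa, 3), round(hco3_from_tco2(r.tco2_cf_mmol_l, pco2, alpha), 3))
# 1.639 4.702            (in-vivo pCO2 in kPa and [HCO3-] in mmol/L under
#                         this animal's own constant)
```

The full pipeline from the shell:

```bash
coelomic simulate --out sim --seed 1
coelomic run-all --individuals sim/individuals.csv \
                 --tonometry sim/tonometry.csv --out run
```

`run/report.txt` summarises pK'1 variation, the per-strategy pCO2/[HCO3-]
ranges, all fifteen ANOVA tables (5 responses x 3 strategies) and the
cross-strategy significance differences.  On the seed-1 study the
individual-constant strategy spans pCO2 0.10-5.77 kPa against 0.14-1.78 kPa
for the treatment-mean strategy — using a mean constant underestimates the
spread — and the strategies disagree on whether seawater pCO2 affects
coelomic pCO2, while agreeing that temperature does.

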