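# metahet

Heterozygosity, demography and extinction risk in a butterfly
metapopulation: a tested simulation-and-analysis pipeline.

## The problem

In highly dynamic metapopulations — such as the Glanville fritillary
(*Melitaea cinxia*) system of small host-plant patches with frequent local
extinction and recolonization — genome-wide genetic diversity, demography
and environment are entangled: small populations both drift to low expected
heterozygosity (He) and die for purely demographic reasons.  Whether low He
*itself* predicts local extinction and overwinter nest mortality therefore
depends on carefully controlling demographic covariates, and on knowing how
much statistical power the data provide.

`metahet` implements that analysis end to end for researchers in
conservation and population genetics, with a synthetic-data generator that
reproduces the system's statistical structure so every stage is testable
without field data:

| module | what it does |
| --- | --- |
| `synthgen` | simulates patches, yearly fall/spring surveys, larval nests, and 245-SNP full-sib genotypes under a stochastic patch-occupancy model with inbreeding load |
| `hetcalc` | genotype filtering (call rate ≥ 95%, ≥ 2 genotypes per unit) and Nei–Chesser gene diversity He/Ho per nest or population |
| `covars` | incidence-function-model connectivity `S_i = Σ_j exp(−α d_ij) N_j`, neighbourhood trend `Ntrend_i = S_i(t) − S_i(t−1)`, 1/2-generation population-trend categories, and the filtered, z-standardized analysis tables |
| `fitcore` | binomial logistic regression by IRLS with Wald tests, and the six fixed-effect model structures (He alone; + covariates; He×size/connectivity; He×year; He×trend over 1 or 2 generations) |
| `inbreedload` | heterozygosity-based inbreeding `Fh = (H0 − H)/H0`, survival under load `S = S0 e^(−B·Fh)`, and haploid lethal equivalents `B = −ln(S_Fh,max/S_Fh,0)/Fh,max` |
| `powersim` | Monte-Carlo power: per year and pooled, the probability that a logistic regression detects the He effect on nest mortality (B = 1, 2.5, 5; S0 = 0.7) or on extinction (log odds `L = 1.58 − 6.14·H`) at P ≤ 0.05 over 5,000 replicates |

## Worked example

```python
import pandas as pd
from metahet import synthgen, hetcalc, covars, fitcore

ds = synthgen.simulate(synthgen.GeneratorConfig(seed=1))

def level(level_name):
    gt = hetcalc.filter_units(hetcalc.filter_individuals(ds.genotypes), level_name)
    return hetcalc.heterozygosity(gt, level_name)

het = pd.concat([level("nest"), level("population")], ignore_index=True)
df = covars.build_analysis_table(ds.patches, ds.survey, het, ds.nests,
                                 "annual_ext", model_id=1)
fit = fitcore.fit_model(df, 1, "annual_ext")
print(f"n = {fit.n_obs}")
print(f"He coefficient = {fit.coef_for('he_z'):+.3f}, "
      f"p = {fitcore.wald_pvalue(fit, 'he_z'):.2g}")
```

prints

```
n = 557
He coefficient = -0.698, p = 4.5e-13
```

i.e. on the synthetic metapopulation, one standard deviation of population
He lowers the log odds of annual extinction by 0.70 when He is the sole
predictor — the classic marginal association that the richer models (2–6)
then decompose against demography.

The same pipeline is available from the shell:

```bash
metahet simulate --out data/ --seed 1
metahet het --genotypes data/genotypes.csv --level nest --out nest_het.csv
metahet power --het nest_het.csv --kind nest --b 1,2.5,5 --reps 5000 --seed 1 --out power.csv
```

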