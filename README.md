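# ontopool

Ontology-structured Bayesian hierarchical meta-analysis of
comorbidity-treatment interactions, with a full simulation-study harness.

## The problem

Patients with multimorbidity are common in clinical trials but individual
trials are almost never powered to estimate how a treatment's effect differs
for patients with a given comorbidity.  One way to rescue these subgroup
analyses is to *partially pool* interaction estimates across related trials,
using an existing drug ontology — the WHO Anatomic Therapeutic Chemical
(ATC) classification — to decide which drugs may plausibly behave alike:
trials nest within drugs (ATC level-7 codes), drugs nest within classes
(level-5 codes, e.g. DPP-4 inhibitors, SGLT-2 inhibitors).

`ontopool` implements that model and the simulation machinery to study it.
Given trial-level interaction estimates y_z with standard errors s_z, the
**full model** is

    y_z     ~ N(mu_z,    s_z^2)          observed estimate per trial
    mu_z    ~ N(beta_d,  tau_d^2)        trials within drug d
    beta_d  ~ N(gamma_c, sigma_c^2)      drugs within class c
    gamma_c ~ N(alpha,   zeta^2)         classes within the drug grouping

with alpha ~ N(0, 2^2) and independent half-N(0, 1^2) priors on every
between-level SD.  The comparator **single-drug model** keeps only the two
lowest levels per drug, with beta_d ~ N(0, 2^2).  Drug-level effects beta_d
are the estimands throughout.

The simulation harness generates trial-level estimates down the same
hierarchy (overall effect −0.1 standardized units; class/drug/trial SDs per
scenario; per-trial SE `2/sqrt(n·p·(1−p))` from enrollment n and comorbidity
prevalence p, default 20%), fits both models to each replicate, and reports
bias, MSE, RMSE, relative precision (from empirical SEs of the point
estimates) and coverage, each with Monte Carlo standard errors, plus
per-drug "detection class" proportions (which model's 95% credible interval
excludes zero).

Because no per-trial composition of the original 161-trial network of
non-insulin glucose-lowering drug trials is public, the package ships a
documented stand-in network that matches the published aggregates exactly
(161 trials, 24 drugs, 7 ATC classes, 210,046 participants) and their
qualitative features (right-skewed trial counts and enrollments, classes of
very different sizes, single-trial drugs).  Swap in the real table with
`read_network("...")` to reproduce structure-dependent quantities.

Inference is by a blocked Gibbs sampler written for this model: the
trial-level means are marginalised analytically, all location parameters
are drawn jointly and exactly per sweep, and the half-normal-prior scales
are updated by vectorised slice sampling with an interweaved (non-centered)
exact re-update.  A conjugate closed-form oracle (all scales fixed) and a
simulation-based-calibration suite validate the engine.

## Worked example

```python
import numpy as np
from ontopool import (
    default_network, standard_scenarios, simulate_batch,
    fit_full_batch, fit_singles_batch, InferenceSettings,
)
import ontopool.performance as perf

net = default_network()                      # 161 trials / 24 drugs / 7 classes
scen = standard_scenarios()["trial-high"]    # SDs (0.05, 0.05, 0.25)
reps = simulate_batch(net, scen, n_reps=100, base_seed=11)
Y, s = np.stack([d.y for d in reps]), reps[0].s

full   = fit_full_batch(net, Y, s, settings=InferenceSettings.batch(seed=1))
single = fit_singles_batch(net, Y, s, settings=InferenceSettings.batch(seed=2))
rf = perf.estimate_records(reps, full, "full")
rs = perf.estimate_records(reps, single, "single")

print("bias  full  %+.3f" % perf.bias(rf)[0])
print("rmse  s/f   %.3f / %.3f" % (perf.rmse(rs)[0], perf.rmse(rf)[0]))
print("rel. precision %+.0f%%" % perf.relative_precision(rs, rf)[0])
```

prints (seeds as above):

```
bias  full  +0.002
rmse  s/f   0.163 / 0.083
rel. precision +284%
```

i.e. the full model is essentially unbiased, roughly halves the RMSE of the
single-drug meta-analyses when trial-level noise is high but drugs and
classes are similar, and its drug-level estimates are several times more
precise — the information-sharing gain that makes small subgroup effects
detectable for drugs with few or small trials.

The same pipeline is scriptable from the shell:

```sh
ontopool make-network network.csv
ontopool run-study --config study.yaml
```

`run-study` writes `estimate_records.csv`, `performance.csv`,
`detection.csv`, `class_relative_precision.csv` and a `manifest.json` that
fully determines the run.

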