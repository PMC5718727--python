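# dxcea

Cost-effectiveness analysis of sequential diagnostic strategies for
clinically significant (CS) prostate cancer, combining multiparametric
MRI (MPMRI), transrectal ultrasound-guided biopsy (TRUSB) and template
prostate mapping biopsy (TPMB, the perfect reference test).

It is written for health economists and methodologists who want a
tested, scriptable re-implementation of this class of diagnostic
decision model rather than a spreadsheet: every component — the exact
decision-tree engine, the cohort Markov model, the calibration routine
and the probabilistic machinery — is a plain Python function with a
test suite and an independent oracle.

## The model

**Decision tree.** Men referred with a suspicion of prostate cancer
belong to one of four true-status subgroups — no cancer, low-risk
(non-CS), intermediate-risk (CS), high-risk (CS) — defined against the
TPMB reference standard. A *strategy* is a labelled sequence of up to
three tests with history-dependent routing (e.g. `M7 222`: MPMRI for
all men at definition 2 and Likert cut-off ≥2; MRI-targeted TRUSB at
histology definition 2 in men with a suspicion of CS cancer; a second
targeted TRUSB in those in whom CS cancer was not detected). Each test
classifies a man as NC / non-CS / CS with subgroup-conditional
probabilities taken from packaged performance tables; results are
conditionally independent given subgroup and test context, with history
dependence carried by the five TRUSB contexts (first biopsy, repeat
after NC, repeat after non-CS, MRI-targeted, MRI-targeted repeat). The
engine enumerates all branches exactly; the final diagnosis is the most
severe *biopsy* result on the path — imaging suspicion alone never
diagnoses cancer. The default grid yields 400 labelled variants of the
32 combinations M1–M7, N1–N7, T1–T9, P1–P9.

**Long-term outcomes.** Each (subgroup, diagnosis) cell maps to a
management — radical treatment after a CS diagnosis, surveillance for
other men with cancer, none otherwise — and enters a cohort Markov
model (localised → metastatic → dead, with age-indexed background
mortality). QALYs and costs accrue per annual cycle and are discounted
at 3.5% per annum. Per-cycle transition probabilities can be calibrated
to overall-survival and metastasis-free targets by bounded weighted
least squares with seeded multi-start.

**Economics.** Strategies are ranked on two planes: CS cancers detected
per man vs testing cost, and QALYs vs lifetime cost. The efficiency
frontier removes dominated and extended-dominated strategies; the slope
between adjacent members is the incremental cost-effectiveness ratio
(ICER = Δcost/ΔQALY), and net monetary benefit (λ·effect − cost) links
the frontier to willingness-to-pay thresholds (£13 000, £20 000,
£30 000/QALY by default). Probabilistic sensitivity analysis draws
Dirichlet-perturbed classification rows (structural zeros frozen),
gamma costs and beta utilities/transitions — all mean-preserving — and
yields CEAC/CEAF curves and per-strategy frontier probabilities.

The packaged tables carry only published point estimates; the original
study's individual-level data, unit costs, utilities and transition
inputs are not public, so long-term results are computed under clearly
labelled synthetic parameter bundles (see `dxcea.synthetic` and
`docs/methods.md`) and printed ICERs of the original analysis are not
reproduced.

## Worked example

```python
from dxcea import SyntheticConfig, generate_parameter_set, run_base_case

bundle = generate_parameter_set(SyntheticConfig(seed=7, perf_ess=None))
result = run_base_case(bundle, ["M1 115", "M7 223", "T7 223", "M7 222", "P4 2"])
cols = ["label", "sensitivity", "detection", "testing_cost", "qalys",
        "total_cost", "qaly_frontier", "qaly_icer"]
print(result.table[cols].round(3).to_string(index=False))
print("cost-effective strategy by threshold:", result.best_by_threshold)
```

prints

```
 label  sensitivity  detection  testing_cost  qalys  total_cost  qaly_frontier  qaly_icer
M1 115        0.291      0.116       443.312  9.459    4317.230           True        NaN
M7 223        0.900      0.360       889.749  9.713    5467.229           True   4532.292
T7 223        0.938      0.375       960.163  9.729    5574.656           True   6557.510
M7 222        0.967      0.387      1154.378  9.742    5797.713           True  17473.444
  P4 2        1.000      0.400      1340.285  9.752    6016.535           True  22848.452
cost-effective strategy by threshold: {13000.0: 'T7 223', 20000.0: 'M7 222', 30000.0: 'P4 2'}
```

Reading it: `sensitivity` is P(CS diagnosis | CS cancer) under the
packaged tables — 1.0 for `P4 2`, whose undetected men all end in the
perfect test; `detection` is CS cancers correctly diagnosed per man
referred; `testing_cost` is the expected spend on tests per man (GBP,
synthetic unit costs); `qalys`/`total_cost` are discounted lifetime
totals per man under the synthetic long-term parameters; the ICER
column is each frontier member's cost per additional QALY versus the
previous member — a strictly increasing chain. At a £20 000/QALY
threshold the scan-first strategy `M7 222` maximises net benefit under
this parameter draw; the TPMB-backed `P4 2` requires ~£23 000/QALY.

The same pipeline is scriptable from the shell:

```sh
dxcea synth --seed 7 --exact-tables --out params/
dxcea run-base-case --params params/bundle.yaml --out results.csv
dxcea run-psa --params params/bundle.yaml --out psa/ --n 1000 --seed 1
dxcea scenario --params params/bundle.yaml --override test_costs.mpmri=600 --out scenario.csv
```

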