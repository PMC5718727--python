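# Methods

This note records the model, its assumptions, and the design choices
made where the design was genuinely open. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Decision-tree component

Four true-status subgroups (no cancer, low-risk, intermediate-risk,
high-risk) are fixed per man; intermediate and high risk constitute
clinically significant (CS) disease. Tests classify men as NC, non-CS
or CS. The engine propagates each subgroup through a strategy's stages
by exact enumeration: a stage fires when its routing predicate matches
the history, multiplies branch probabilities by the subgroup-conditional
row of its test context, and the walk ends after at most three tests.

Assumptions and conventions:

* **Conditional independence given context.** Successive results are
  independent given the subgroup and the test context. All history
  dependence is carried by context selection — the five TRUSB contexts
  (1 first blind biopsy; 2 repeat after NC; 3 repeat after non-CS;
  4 MRI-targeted first biopsy; 5 MRI-targeted repeat). This is exactly
  the conditioning the packaged tables provide; no richer dependence is
  modelled.
* **Diagnosis rule.** The final diagnosis is the maximum-severity
  biopsy result on the path (CS > non-CS > NC); a CS diagnosis requires
  a biopsy, and imaging suspicion alone exits as a no-cancer diagnosis.
  When biopsy results conflict, taking the maximum is the clinically
  conservative reading; the rule is localised in
  `PathState.diagnosis` should an alternative be needed.
* **Biopsies in cancer-free men** return NC with probability 1 (a
  biopsy cannot find absent cancer). Together with the packaged
  low-risk rows, whose CS probability is zero, this makes every
  strategy perfectly specific — a property the suite checks
  exhaustively.
* **TPMB is the reference standard**: it maps truth to class exactly
  (no cancer → NC, low-risk → non-CS, CS → CS) irrespective of the
  histology definition digit, which is retained only for labelling.
* **MPMRI after a negative TRUSB** (T5–T9/P5–P9) reuses the first-line
  MPMRI rows, and a repeat biopsy after both a prior TRUSB and a
  suspicious scan uses TRUSB context 5 even when the prior biopsy found
  non-CS cancer; no closer-conditioned rows exist.
* **Cut-off semantics.** Cut-offs 2–4 mean "Likert ≥ k"; cut-off 5
  means "= 5". Nested cut-offs imply referral probabilities that are
  non-increasing in the cut-off, which the suite asserts.

### Combination grid

The published description of the 32 combinations is partial (the full
sequence definitions live in unavailable supplementary material), so
the grid here is reconstructed from the printed descriptions it must
reproduce: M1/M3/M4/M7, T6/T7, P4 and the M7/T7 figure walk-through.
M-combinations pair a first-biopsy trigger (suspicion of CS vs any
suspicion) with a re-biopsy trigger (none / non-CS found / NC found /
CS not found, always restricted to men with CS suspicion on the scan);
T-combinations pair a repeat-biopsy or scan trigger on the first TRUSB
result with a second-biopsy suspicion trigger; T5/T8/T9's triggers are
this package's own inference on that grid. N/P-combinations replace the
final biopsy stage of their M/T counterpart with TPMB, keeping the
routing predicates — the only reading consistent with the printed
two-test description of P4 ("TRUSB for all men, TPMB in men in whom CS
cancer was not detected") and the three-test limit. A consequence is
that perfect sensitivity is a property of routing, not of the family
letter: it holds exactly for strategies whose every non-CS-diagnosed
pathway ends in TPMB (`undetected_terminate_in_tpmb`, satisfied by the
P1 and P4 variants), and the suite verifies sensitivity 1.0 for exactly
that structurally identified set.

The default variant grid (2 histology definitions × 2 MPMRI definitions
× 4 cut-offs where applicable) yields 400 labelled strategies. The
original analysis reports 383 after feasibility pruning whose rules are
not public; the enumerator flags the discrepancy with a warning and
exposes exclusion hooks rather than guessing the pruning.

### Packaged tables

Two delimited text files transcribe the published point estimates for
TRUSB (five contexts × two histology definitions) and MPMRI (two
definitions × four cut-offs). Two transcribed rows (MPMRI definition 2,
intermediate-risk, cut-offs ≥4 and =5) sum to 0.99 and 1.01 — an
artefact of two-decimal rounding in the source — and are renormalised
proportionally on load, with a warning. All other rows sum to 1
exactly.

## Microsimulation oracle

`microsim_oracle` routes individual men through the same stage logic
with sampled results, allocating men to subgroups deterministically by
largest remainder so the conditional margins are plain binomials at
known sample sizes. It exists to validate the exact engine, including
on random row-stochastic tables. The grid-wide agreement test compares
400 strategies at 100 000 men each; because ~1 chance exceedance of a
3-SE band is expected among 400 independent comparisons, that test was
designed a priori with a multiplicity allowance (all |z| ≤ 4.5, ≥99%
within 3 SE, headline strategies individually at 3 SE).

## Cohort Markov model

States: localised, metastatic, dead (cancer-free men are the localised
state with zero disease transitions). Per cycle, background mortality
(default: Gompertz, a = 4.3e-5, b = 0.087 per year, roughly an annual
death probability of 1% at age 65 doubling every 8 years) combines
multiplicatively with disease-specific death; survivors of the
localised state then progress with probability `p_localised_to_metastatic`.
Defaults: 1-year cycles, start age 65, horizon to age 100, accrual at
the start of the cycle with no half-cycle correction (a flag enables
trapezoidal accrual), discounting at 3.5%/year for both costs and
effects, 2015 GBP.

Management: radical treatment after a CS diagnosis (one-off cost at
diagnosis plus a transition regime with slower progression),
surveillance otherwise for men with cancer (per-cycle cost, untreated
transitions — i.e. a missed CS cancer progresses without the treatment
benefit and without a delayed-detection pathway), nothing for
cancer-free men. Metastatic occupancy accrues a per-cycle cost and a
utility decrement; TPMB carries a one-off utility decrement per test
and TRUSB none. Radiotherapy and treatment-complication states are out
of scope; complications enter only through costs and decrements.

## Calibration

Given targets (subgroup, management, time, overall survival or
metastasis-free fraction, value, weight), the three per-cycle
transition probabilities are fitted by weighted least squares — the
transparent default in the absence of a stated objective, with weights
available to emulate precision differences — using L-BFGS-B within
bounds, a 1e-8 objective tolerance, and seeded uniform multi-starts
(the infeasible corner p_lm + p_ld > 1 is projected with a smooth
penalty). Metastasis-free fraction is read as localised occupancy
(alive and never metastatic); times between cycle boundaries are
interpolated linearly. The result carries an identifiability diagnostic
(distinct informative targets vs three free parameters). Parameter
recovery on noiseless model-implied targets is verified to 1e-3.

## Economics

Frontier construction removes strictly and weakly dominated points
(exact ties on both axes keep the lexicographically first label), then
extended-dominated points, leaving a strictly increasing ICER chain;
it is tested for equivalence with a brute-force threshold-sweep oracle.
CEAC at a threshold is the fraction of simulations in which a strategy
maximises net benefit (ties to the first label in sort order); CEAF
attaches to the strategy with the highest *expected* net benefit — the
standard convention, adopted because no definition is printed. The
per-strategy frontier probability is frontier *membership* per
simulation (net-benefit optimality per simulation is available through
`ceac_ceaf`); membership is the default because it matches the
three-way mean-frontier / possible / never classification of
strategies. Currency is GBP throughout; the euro column is a
presentation-layer conversion at a config-declared rate.

PSA families follow the standard conjugate conventions for
cost-effectiveness models — Dirichlet rows (concentration = point
estimate × effective sample size, structural zeros frozen), gamma
costs, beta probabilities and decrements — all mean-preserving, so the
probabilistic base case is anchored to the deterministic run (verified
at n = 1000 within Monte-Carlo error). Default 1000 simulations; all
randomness flows from one `numpy` PCG64 generator seeded at the call.

## Synthetic study conditions

Because the original individual-level data, unit costs, utilities and
transition inputs are not public, the long-term layer runs under
synthetic bundles generated by `dxcea.synthetic`. Chosen once, as
realistic UK secondary-care magnitudes, and labelled synthetic
throughout: prevalence (0.42, 0.18, 0.25, 0.15) over (no cancer, low,
intermediate, high) — roughly 40% CS among referred men; unit costs
£350 (MPMRI), £450 (TRUSB), £1100 (TPMB) including expected
complication management; £7000 radical treatment, £250/year
surveillance, £2200/year metastatic disease; baseline utility 0.82 at
65 declining 0.004/year, metastatic decrement 0.20–0.30, TPMB one-off
decrement 0.003–0.008; annual progression ranges per subgroup (e.g.
intermediate-risk surveillance localised→metastatic 0.03–0.06) with a
radical-treatment progression multiplier drawn in 0.3–0.7, so the
treatment-benefit ordering holds in every draw. Bundles are
bit-reproducible from their seed.

What the generator does *not* emulate: correlation between test
accuracies and costs, non-stationary (age- or time-varying) disease
transitions, delayed re-testing of men under surveillance, and any
resemblance of its absolute cost/utility levels to the original
study's. Passing tests therefore establish the correctness of the
machinery — exact propagation, conservation, calibration inversion,
frontier logic — not the original analysis's ICERs, which depend on
unavailable inputs and are deliberately not reproduced.

## Problem sizes

The suite evaluates the full 400-strategy grid exactly, cross-checks
every strategy against a 100 000-man microsimulation, and runs the PSA
checks at 1000 simulations over the four headline strategies; the
acceptance script enumerates the full tree for one strategy and guards
it with a 100 000-man microsimulation.
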