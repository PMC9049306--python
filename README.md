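# scdsim

An individual-based state-transition microsimulation of sickle cell
disease (SCD) for cost-effectiveness analysis of curative therapies.

SCD is a multi-system disease: recurrent vaso-occlusion and hemolysis
drive acute pain episodes, strokes, infections, and progressive organ
damage over a patient's lifetime.  Gene therapies and stem cell
transplant promise durable benefit at one-time prices above a million
dollars, and valuing them fairly requires a model that carries a
patient's full disease history — something memoryless Markov cohort
models cannot do.  `scdsim` is built for health-economic modelers and
methods researchers who need that machinery end to end: claims-style
cohort derivation, penalized-regression transition indices, an annual-
cycle microsimulation with four parallel disease dimensions, calibration
to published lifetime prevalences, and societal-perspective QALY/ICER/PSA
analysis.  Because real Medicaid/Medicare claims cannot ship with a
package, `scdsim` includes a synthetic claims generator that emulates
their structure, so every stage runs and is testable out of the box.

## The model in brief

A simulated person occupies a combination of health states across four
parallel dimensions — chronic pain, acute events (13 instantaneous
conditions), chronic disorders (absorbing), and treatment complications —
26 disease conditions in all.  Each annual cycle, transition
probabilities come from penalized logistic "prediction indices": for an
attribute *a*,

    P(a this year) = expit( β₀ₐ + βₐ · x ),

where *x* stacks previous-year health status, disease history (event
counts, disorder durations), treatments, complications, sex, age-band and
birth-cohort indicators.  Treatment use, complications, and utilization
(log-link counts) have their own index families with their own covariate
timing.  Curative strategies apply risk ratios to responders
(probability `p_symptom_free`), add therapy-specific complication risks,
and carry a one-time price.  Calibration solves per-attribute intercept
shifts δₐ so that simulated lifetime prevalence under Common Care matches
published targets:

    find δₐ :  Prev_sim(β₀ₐ + δₐ) = Prev_target(a)  (±2 percentage points)

Costs and QALYs are discounted at 3%/year; the societal perspective adds
time-use and caregiver costs to the healthcare-sector components.  See
`docs/methods.md` for the full account.

## Worked example

Simulate 2,000 lifetimes per strategy from the pooled public-payer
population and compare Common Care with gene therapy
(`examples/03_simulate_strategies.py`):

```
                                                    common care gene therapy
                  mean survival from entry (years)         34.9         34.8
                      acute events per person-year         0.16         0.10
lifetime prevalence vaso_occlusive_pain_episodes (%)         68.9         39.0
              lifetime prevalence chronic_pain (%)         32.4         19.1
                    lifetime prevalence stroke (%)         14.3          7.8
     lifetime prevalence chronic_renal_disease (%)         29.9         24.9
```

Gene therapy is offered at entry to individuals with severe disease
history (≥3 severe acute events or any stroke); responders stop accruing
pain episodes and acute events, so cohort-level prevalences fall without
reaching zero.  Valuing those trajectories
(`examples/04_cost_effectiveness.py`) prints:

```
   common_care: 17.24 QALYs, $311,559 societal, $137,019 healthcare-sector
  gene_therapy: 17.22 QALYs, $1,313,953 societal, $1,136,348 healthcare-sector

gene_therapy vs common_care: dominated (Δcost $1,002,394)

acceptability curve (probability gene therapy is cost-effective):
  willingness to pay $        0/QALY: 0.00
  willingness to pay $  100,000/QALY: 0.00
  willingness to pay $  500,000/QALY: 0.00
  willingness to pay $2,000,000/QALY: 0.10
```

Under the default placeholder effectiveness the mean QALY gain is within
Monte-Carlo noise of zero at this cohort size, so gene therapy at a $1.8M
price is dominated here (in other runs it shows an ICER in the tens of
millions per QALY) and the acceptability curve stays near zero until
willingness-to-pay reaches the millions.  These defaults are scenario
parameters, not estimates; the point of the package is the machinery for
exploring them.

The other examples show the claims side: `01_generate_and_derive.py`
(synthetic claims → case identification → annual panel → attrition table)
and `02_fit_prediction_indices.py` (beneficiary-level 50/25/25 split and
an elastic-net incidence fit).

## Command-line pipeline

The same stages run as a CLI with one subcommand each, sharing a YAML
configuration and one master seed:

```bash
scdsim all --config examples/demo_config.yaml
# or stage by stage:
scdsim generate --outdir demo_out --seed 42
scdsim derive   --outdir demo_out --seed 42
scdsim fit      --outdir demo_out --seed 42
scdsim calibrate --outdir demo_out --seed 42
scdsim simulate --outdir demo_out --seed 42
scdsim cea      --outdir demo_out --seed 42
```

Outputs are plain CSV/JSON (claims tables, `panel.csv`, `indices.json`,
`calibrated_indices.json`, trajectories, `cea_summary.csv`, `icers.csv`,
`psa_draws.csv`, `ceac.csv`) plus a `manifest.json` recording the
configuration hash, seed, and per-stage row counts.  Reruns with the same
configuration are bit-identical.

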