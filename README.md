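# ordthresh

Estimation of individual physicians' **treatment-risk thresholds** from
ordinal, uncertainty-bearing treatment recommendations.

## The problem

A rational treatment decision compares a patient's disease risk against the
clinician's threshold: treat above it, observe below it. Physicians are
demonstrably poor at stating probabilities directly, so asking them "what is
your threshold?" does not work. But when an evidence-based risk calculator
can score every case objectively, the threshold can be *inferred* from
ordinary behaviour: show the physician a set of cases, record how likely
they would be to recommend treatment on a 7-point scale from "Definitely
No" to "Definitely Yes", and find the risk level at which they are
maximally unsure.

The motivating application is ocular hypertension (elevated intraocular
pressure), a risk factor for glaucoma whose 5-year conversion risk can be
computed per patient from age, intraocular pressure (IOP), cup-disc ratio
(CDR), pattern standard deviation (PSD), central corneal thickness (CCT)
and diabetes status. The machinery applies unchanged to any condition with
a per-patient risk score (cardiovascular risk, cancer mortality, ...).

## The model

The 7-point responses are collapsed to three ordered levels,
No < Unsure < Yes, and each physician's responses are fitted with a
proportional-odds (cumulative-logit) model in the case risk *r*:

    logit P(t ≥ j | r) = α_j + β·r ,   j ∈ {Unsure, Yes}

Because No is the lowest level and Yes the highest,

    P(No | r)  = 1 − P(t ≥ Unsure | r),
    P(Yes | r) = P(t ≥ Yes | r).

The **treatment threshold** r\* is the risk at which Yes and No are equally
likely; setting the two expressions equal and solving gives the closed form

    r* = −(α_U + α_Y) / (2β).

Physicians who used only No and Yes are fitted with binary logistic
regression (threshold −α/β, the P = 0.5 point — the same balance
definition). Physicians who never recommended treatment are assigned the
midpoint of the highest case risk and 100%; those who always recommended it,
the midpoint of the lowest case risk and 0%. Per-fit diagnostics are the
Nagelkerke pseudo-R² and the concordance index (ROC AUC generalized to
ordered categories). Population-level thresholds are summarized by a
maximum-likelihood beta fit with standard errors.

The package also ships first-class simulators — a truncated-normal case
generator, a configurable linear-predictor risk model, and a
proportional-odds physician panel whose latent thresholds follow a beta
distribution — so the estimator can be validated end to end by parameter
recovery without human subjects.

## Worked example

Simulate 50 ocular-hypertension cases, score them with the illustrative
risk model, have 50 simulated physicians (latent thresholds from
Beta(2.56, 9.14)) rate all of them, estimate every threshold, and refit the
population distribution:

```
ordthresh run-pipeline \
    --population-config examples/population.yaml \
    --risk-config examples/risk_model.yaml \
    --panel-config examples/panel.yaml \
    --seed 42 --outdir out/
```

`out/population.json` from this exact command contains:

```
"beta_fit": {
  "shape_a": 2.46548368013101,  "se_a": 0.46475172004599163,
  "shape_b": 7.967888462666534, "se_b": 1.611159457192377,
  "n": 50
},
"summary": {
  "mean_threshold": 0.23809382529822845,
  "modal_interval": [0.15, 0.2],
  "method_counts": {"ordinal": 43, "separation_midpoint": 7}
}
```

Reading: the 50 recovered thresholds average 23.8% 5-year risk, their
modal histogram bin is 15–20%, and the refitted beta shapes (2.47, 7.97)
sit within one standard error of the generating values (2.56, 9.14) — the
estimator recovers the threshold population it was given. 43 physicians
were fitted by ordinal regression; 7 highly-consistent ones produced
completely separated responses and got the empirical-gap midpoint.

Each stage is also available separately (`simulate-cases`, `compute-risk`,
`simulate-responses`, `estimate-thresholds`, `fit-population`), and the
same operations are importable from Python (`ordthresh.estimate_threshold`,
`ordthresh.fit_beta_mle`, ...).

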