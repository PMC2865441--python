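# Illustrative ocular-hypertension population summary statistics.
# Values are plausible for an elevated-eye-pressure cohort but are NOT the
# published statistics of any real trial; supply your own for real studies.
# Bounds emulate eligibility truncation (rejection-resampled, not clipped).
factors:
  age:   {mean: 55.0,  sd: 10.0, lower: 40.0,  upper: 80.0}   # years
  iop:   {mean: 25.0,  sd: 3.0,  lower: 24.0,  upper: 32.0}   # mmHg
  cdr:   {mean: 0.4,   sd: 0.2,  lower: 0.0,   upper: 0.8}    # cup-disc ratio
  psd:   {mean: 1.9,   sd: 0.2,  lower: 0.5,   upper: 3.0}    # dB
  cct:   {mean: 573.0, sd: 38.0, lower: 450.0, upper: 700.0}  # micrometres
p_diabetes: 0.10
p_female: 0.57
n_cases: 50
seed: 20100408
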