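# Illustrative 5-year glaucoma risk model (logistic link).
# Coefficient signs follow the known direction of the risk factors
# (higher pressure / larger cup-disc ratio / thinner cornea -> higher risk);
# the magnitudes are NOT those of any published risk calculator.  With the
# illustrative population config, this model yields a right-skewed risk
# distribution with mean about 0.14.
link: logistic
intercept: -0.87
coefficients:
  age: 0.02        # per year
  iop: 0.12        # per mmHg
  cdr: 1.8         # per unit ratio
  psd: 0.4         # per dB
  cct: -0.012      # per micrometre
  diabetes: -0.4   # indicator
risk_horizon_years: 5
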