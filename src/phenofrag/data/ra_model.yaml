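# Default RA scoring model: a fixed (pre-fitted) penalized-logistic-regression
# surrogate applied, not trained, by this package. Weight signs follow the
# published algorithm's structure: RA diagnoses and positive rheumatoid-factor
# results pull the probability up; SLE and psoriatic-arthritis diagnoses and
# the total encounter volume pull it down. Counts enter through log1p to
# temper skew. A screened patient is called a case when the probability
# reaches the cutoff.
intercept: -2.0
weights:
  n_ra_dx: 2.0
  n_sle_dx: -1.0
  n_pa_dx: -1.0
  n_rf_lab: 0.2
  n_rf_positive: 1.0
  n_encounters: -0.15
transform: log1p
cutoff: 0.632
# lab value (IU/mL) at or above which a rheumatoid-factor test is positive
rf_positive_threshold: 15.0
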