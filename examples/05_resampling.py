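"""Resampling-based accuracy check on one large dataset.

Emulates the situation where a very large survey dataset establishes which
response-style structure holds, and one asks how reliably a smaller study
(fewer people, fewer items) would reach the same conclusion.  People and
items are sampled without replacement; unendorsed categories in a subsample
are patched by filling an item's first missing value.
"""

from respstyles import FitOptions, GenCondition, generate_dataset, resample_study

# stand-in for a large real dataset: two-dimensional response styles, N=4000
condition = GenCondition("ers_plus_mrs", 4000, 10, 1, sigma_rs=1.0,
                         r_rs=0.3, slope_corr=0, seed=15)
data, *_ = generate_dataset(condition)

records = resample_study(data, n_people=500, item_subset_size=10,
                         n_resamples=10, assumed_true_model="ers_plus_mrs",
                         seed=2,
                         options=FitOptions(tol_loglik=2e-3, tol_param=2e-3,
                                            max_cycles=120))
for criterion in ("aic", "bic", "combined"):
    pct = 100 * (records[f"selected_{criterion}"] == "ers_plus_mrs").mean()
    print(f"{criterion}: {pct:.0f}% of resamples select the two-dimensional "
          "response-style model")
print("\nAt N = 500 the AIC typically keeps finding both response styles "
      "while the more conservative BIC starts falling back to simpler "
      "models — the cost of parsimony when two styles are truly present.")
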