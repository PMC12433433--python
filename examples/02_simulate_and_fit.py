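"""Simulate bipolar response-style data and recover the parameters.

Generates N = 1000 respondents on 10 five-category items whose answers mix a
substantive trait with a bipolar extreme/midpoint response style (SD 1), then
fits the matching model by marginal maximum likelihood and compares estimated
to generating item slopes.
"""

import numpy as np

from respstyles import FitOptions, GenCondition, ModelSpec, fit_mnrm, generate_dataset

condition = GenCondition("ers_mrs", 1000, 10, 1, sigma_rs=1.0, seed=7)
data, items, traits, _ = generate_dataset(condition)
print(f"simulated {data.n_persons} x {data.n_items} responses; "
      f"category shares {np.bincount(data.responses.ravel(), minlength=5) / data.responses.size}")

fit = fit_mnrm(data, ModelSpec.create("ers_mrs", 10, 1),
               FitOptions(tol_loglik=1e-5))
print(f"converged={fit.converged} after {fit.n_cycles} EM cycles, "
      f"loglik={fit.loglik:.1f}")

true_sub = np.array([it.slopes[0] for it in items])
true_rs = np.array([it.slopes[1] for it in items])
print("substantive slopes  true vs estimated "
      f"(r = {np.corrcoef(true_sub, fit.slopes[:, 0])[0, 1]:.3f})")
for j in range(10):
    print(f"  item {j + 1:2d}: {true_sub[j]:.2f}  {fit.slopes[j, 0]:.2f}")
print(f"response-style slope correlation: "
      f"{np.corrcoef(true_rs, fit.slopes[:, 1])[0, 1]:.3f}")
print("The generating intercepts (-2,-1,0,-1,-2) are reported in the "
      "first-category-zero form (0,1,2,1,0); mean estimated intercepts:",
      np.round(fit.intercepts.mean(axis=0), 2))
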