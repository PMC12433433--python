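"""Category response curves under the three response-style models.

Builds one item with the generating parameters (unit slopes, intercepts
(-2,-1,0,-1,-2)) and prints the probability of each answer category along a
latent-trait grid.  Under the null model the curves cross symmetrically; a
positive bipolar response-style score shifts mass to the endpoints and away
from the midpoint.
"""

import numpy as np

from respstyles import ItemParameters, build_scoring_matrix, probability_curves

grid = np.linspace(-2, 2, 5)

null_sm = build_scoring_matrix("null", 5, 1)
item = ItemParameters([1.0], [-2, -1, 0, -1, -2])
curves = probability_curves(item, null_sm, grid)
print("null model: P(category | substantive trait)")
print("theta:    " + "  ".join(f"{t:+.1f} " for t in grid))
for k in range(5):
    print(f"  cat {k + 1}: " + "  ".join(f"{p:.3f}" for p in curves[k]))

bi_sm = build_scoring_matrix("ers_mrs", 5, 1)
bi_item = ItemParameters([1.0, 1.0], [-2, -1, 0, -1, -2])
rs_curves = probability_curves(bi_item, bi_sm, grid, varied_dim=1)
print("\nbipolar ERS/MRS model: P(category | response-style trait), "
      "substantive trait at 0")
for k in range(5):
    print(f"  cat {k + 1}: " + "  ".join(f"{p:.3f}" for p in rs_curves[k]))
print("\nA positive response-style score raises the endpoint categories "
      "(1 and 5) and lowers the midpoint (3); a negative score does the "
      "reverse.")
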