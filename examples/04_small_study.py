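"""A reduced Monte-Carlo study of classification accuracy.

Runs one null cell and one strong bipolar cell with 10 replications each and
prints how often each information criterion recovers the data-generating
model.  The full factorial design (264 cells x 250 replications) uses the
same machinery via `run_study(StudyConfig())`.
"""

import pandas as pd

from respstyles import StudyConfig, classification_accuracy, run_study
from respstyles.study import STUDY_FIT_OPTIONS

config = StudyConfig(regimes=("null", "ers_mrs"), n_levels=(500,),
                     j_levels=(10,), d_levels=(1,), sigma_levels=(1.5,),
                     replications=10, base_seed=1,
                     fit_options=STUDY_FIT_OPTIONS)
records = run_study(config)
print(f"{len(records)} replications across {records[['kind']].nunique().iloc[0]} regimes")

for criterion in ("aic", "bic", "combined"):
    acc = classification_accuracy(records, ("kind",), criterion)
    print(f"\n{criterion.upper()} percent correct by generating model:")
    print(acc.to_string(index=False))
print("\nEach percentage is the share of replications in which the "
      "criterion's chosen model equals the generating model.")
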