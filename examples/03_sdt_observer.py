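"""Simulate one observer through a session and compute d' and criterion.

The observer draws unit-variance Gaussian evidence with mean d' on target
trials and answers "present" above its decision cut.  The analysis inverts
hit and false-alarm rates into d' = z(H) - z(F) and c = -(z(H) + z(F))/2,
with a 0.25-count correction for perfect or empty cells.
"""

import numpy as np
import pandas as pd

from threatdetect import sdt
from threatdetect.observer import ObserverParams, simulate_trials
from threatdetect.schedule import build_session

session = build_session(seed=2, subject_id=0)
trials = session.trials()
trials["subject_id"] = 0
responses = simulate_trials(ObserverParams(), trials, np.random.default_rng(2))
merged = sdt.classify_trials(pd.concat([trials, responses], axis=1))

cells = sdt.aggregate_cells(merged, "condition")
print(cells[["condition", "n_hit", "n_fa", "hit_rate", "fa_rate", "dprime", "criterion"]])
ctx = sdt.aggregate_cells(merged, "context")
print(ctx[["prior_context", "dprime", "criterion"]])
# One session gives noisy estimates (64 targets + 64 lures per condition);
# the criterion is clearly higher after rare than after frequent blocks.
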