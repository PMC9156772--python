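"""Titrate backward-mask contrast with the 3-down-1-up staircase.

The mask gets harder (contrast up) after three consecutive correct responses
and easier after any error, converging on the ~79.4%-correct point of the
observer's psychometric function.  The converged level is the mean reversal
contrast excluding the first three reversals; drifting tracks trigger a
restart at 50% or 70% contrast.
"""

import numpy as np

from threatdetect.observer import ObserverParams
from threatdetect.staircase import calibrate_contrast, check_track, reversal_average

observer = ObserverParams()
cal = calibrate_contrast(observer, rng=np.random.default_rng(0))
print(f"titrated mask contrast: {cal['contrast']:.3f}")
print(f"mean accuracy during the staircase blocks: {cal['accuracy']:.3f}")
for i, track in enumerate(cal["tracks"]):
    print(
        f"track {i}: {len(track.reversals)} reversals, "
        f"reversal average {reversal_average(track):.3f}, verdict {check_track(track)}"
    )
# Expect a contrast near 0.5 and accuracy near 0.75, matching the titration
# goal; block-to-block accuracy varies by several percent at 40 trials.
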