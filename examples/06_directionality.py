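"""Bidirectional network: the alpha offset selects who drives whom.

With reciprocal projections, conditional spectral Granger causality
(conditioned on the shared alpha drive) shows gamma-band causality from
area 1 to area 2 at -90 deg, the reverse at +90 deg, and alternating
directionality at zero offset.
"""

import numpy as np

from alphagate.scenarios import scenario_bidirectional

out = scenario_bidirectional(seed=0, n_trials=3)
for dphi, g in out["gc"].items():
    print(f"dphi {dphi:+.0f} deg: GC 1->2 {g['gamma_1to2']:.3f}   "
          f"GC 2->1 {g['gamma_2to1']:.3f}")
labels = [w["dominant"] for w in out["sliding"]]
frac = np.mean([l == "x->y" for l in labels])
print(f"sliding windows at dphi=0: {len(labels)} windows, "
      f"{frac:.0%} dominated by 1->2 (direction alternates over time)")
print("The sign of the alpha phase difference sets the direction of")
print("gamma-band communication between reciprocally connected areas.")
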