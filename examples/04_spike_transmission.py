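"""Spike-level view: gamma-phase locking and transmission probability.

Compares the best (-90 deg) and worst (+90 deg) alpha offsets: how
strongly area-1 spikes lock to area-2's gamma rhythm, and how the
probability that a sender spike is answered by one of its targets within
1-4 ms depends on the sender's gamma phase (rate-equalized bins).
"""

import numpy as np

from alphagate.scenarios import scenario_spike_coupling

out = scenario_spike_coupling(seed=0, n_trials=3)
for label, dphi in (("plus", -90), ("minus", +90)):
    d = out[label]
    nl = d["nonlocal"]
    depth = nl.max() / nl.min()
    peak = d["bin_centers"][np.argmax(nl)]
    print(f"dphi {dphi:+d}: area-1 spikes vs area-2 gamma -> "
          f"peak {peak:+.0f} deg, modulation depth x{depth:.2f}")
t = out["plus"]["trans1"]
c = out["plus"]["bin_centers"]
print(f"transmission probability (best offset) peaks at sender phase "
      f"{c[np.argmax(t)]:+.0f} deg; range {t.min():.3f}-{t.max():.3f}")
print("Locking of sender spikes to the receiver's rhythm is stronger at")
print("the optimal offset, and spikes transmit best at the gamma phase")
print("where the sender's population is most active.")
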