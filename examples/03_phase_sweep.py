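"""The headline effect: gamma coherence versus the alpha phase difference.

Sweeps the inter-areal alpha offset over a 30-degree grid (3 trials per
point for speed) and prints the coherence curve with its extremes.
Negative offsets mean the sending area's excitable window leads in time.
"""

import numpy as np

from alphagate.scenarios import DPHI_GRID, scenario_phase_sweep

sweep = scenario_phase_sweep(seed=0, dphi_grid=DPHI_GRID, n_trials=3)
print("dphi (deg)   gamma coherence")
for _, row in sweep.iterrows():
    bar = "#" * int(40 * row.gamma_coherence)
    print(f"  {row.dphi:+7.0f}   {row.gamma_coherence:.3f} {bar}")
coh = sweep["gamma_coherence"].to_numpy()
d = sweep["dphi"].to_numpy()
print(f"max at {d[np.argmax(coh)]:+.0f} deg, min at {d[np.argmin(coh)]:+.0f} deg, "
      f"depth x{coh.max() / coh.min():.1f}")
print("Communication is gated by the relative alpha phase: the channel is")
print("open when the sender leads by about a quarter alpha cycle.")
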