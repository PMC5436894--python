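"""Cross-frequency coupling: gamma power locked to the alpha phase.

Adds the 23 pA sin^2 alpha drive to one area's interneurons and shows
(i) the E-population spectrum now has both an alpha and a gamma peak and
(ii) time-resolved gamma power is concentrated around the phase where
inhibition is released.
"""

import numpy as np

from alphagate import AlphaConfig, AreaSpec, NetworkSpec, run_simulation
from alphagate.network import compute_sth
from alphagate.spectral import alpha_gamma_coupling, gamma_power_trace, multitaper_psd

spec = NetworkSpec(areas=[AreaSpec()])
res = run_simulation(spec, alpha=AlphaConfig(), duration=2000.0, seed=0)
e = compute_sth(res, 0, ("RS",))
psd = multitaper_psd(e - e.mean())
f, p = psd.freqs, psd.values
alpha_peak = f[(f >= 5) & (f <= 15)][np.argmax(p[(f >= 5) & (f <= 15)])]
gamma_peak = f[(f >= 25) & (f <= 60)][np.argmax(p[(f >= 25) & (f <= 60)])]
print(f"spectral peaks: alpha {alpha_peak:.1f} Hz, gamma {gamma_peak:.1f} Hz")

power, valid = gamma_power_trace(e - e.mean())
phase = res.alpha_phases[0].phases[::2][: e.size]  # 0.5 ms -> 1 ms sampling
centers, means = alpha_gamma_coupling(phase, power, n_bins=12, valid=valid)
best = centers[np.nanargmax(means)]
print("gamma power by alpha phase bin (deg -> power):")
for c, m in zip(centers, means):
    print(f"  {c:+7.1f}  {m:6.2f}")
print(f"gamma power peaks near {best:+.0f} deg, the release from")
print("inhibition (the alpha current is minimal at phase 0).")
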