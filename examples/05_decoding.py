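"""Information transfer: decoding which stimulus the sending area saw.

Two stimuli target disjoint halves of area 1; each half projects to the
matching half of area 2.  A linear max-margin decoder reads area 2's
subpopulation mean spike counts in the 30 ms after onset.  Accuracy and
mutual information are printed for a favorable, neutral, and unfavorable
alpha offset.
"""

from alphagate.scenarios import scenario_decoding

df = scenario_decoding(seed=0, dphi_grid=(-90, 0, 90), n_presentations=20)
print(df[["dphi", "accuracy", "mi_bits", "n_presentations"]].to_string(index=False))
print("The stimulus identity is recoverable downstream when the sender's")
print("alpha leads (open channel); at the opposite offset the gate closes")
print("and the transmitted information collapses.")
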