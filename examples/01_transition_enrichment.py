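"""Chromatin-state transition enrichment on a simulated two-stage genome.

Builds a 100 000-bin genome with one ordered state transition
(ReprPC -> EnhA) planted at fold enrichment 4, counts per-bin transitions,
computes the 1000-shuffle permutation null, and prints the enrichment table
for the strongest directional transitions.
"""

from statefate import SimulationConfig, transition_enrichment
from statefate.simulate import simulate_state_tracks

cfg = SimulationConfig()
track_de, track_pe, _ = simulate_state_tracks(cfg, seed=7)

enr = transition_enrichment(track_de, track_pe, method="permutation", n_perm=1000, seed=7)
table = enr.to_frame()
directional = table[table.s_from != table.s_to].sort_values("FE", ascending=False)

print("top directional transitions (O = observed bins, E = shuffled "
      "expectation, ES = O/E, FE = ES forward / ES reverse):")
print(directional.head(5).to_string(index=False, float_format="%.3f"))
print()
print("The planted ReprPC->EnhA transition tops the list with FE ~ 4: it is "
      "~4x more enriched over the shuffle null than its reverse, i.e. a "
      "directed repressed-to-active-enhancer switch between the two stages. "
      "'grey' display cells would mark transitions with fewer than 200 bins.")
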