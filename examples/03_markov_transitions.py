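"""Estimate the one-step transition kernel of efficiency states.

Each year's 20 scores are split into 4 ordered states by exact
Fisher-Jenks natural breaks; one-step moves between consecutive years are
tabulated into a row-stochastic matrix. Large diagonal entries mean states
are sticky: a province rarely leaves its efficiency class in one year.
"""

import numpy as np

import effimarkov as em

panel = em.datasets.load_efficiency_panel()
breaks = em.fit_state_breaks(panel, k=4, pool="per_year")
states = em.classify_states(panel, breaks)
tm = em.transition_matrix(states)

print("transition probabilities (rows: origin state 1=low .. 4=high)")
print(tm.to_frame())
print("\norigin-state totals:", tm.origin_totals.tolist())
print("diagonal:", np.round(np.diag(tm.probs), 4).tolist())
types = em.transition_type_map(states, 2010, 2019)
print("\n2010 -> 2019 movements:", types.value_counts().to_dict())
print("upward:", ", ".join(sorted(types[types == 'upward'].index)))
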