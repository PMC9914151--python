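"""Score a DEA panel with the super-efficiency slack-based measure.

Builds a small synthetic panel whose efficient frontier is known by
construction, scores every decision-making unit, and prints the scores:
values >= 1 mark frontier (super-efficient) units, values < 1 measure how
far a dominated unit is from the frontier after accounting for all input
excesses and output shortfalls.
"""

import effimarkov as em

panel, truth = em.gen_dea_panel(em.FrontierSpec(n_dmu=6, n_efficient=2, seed=3))
eff, report = em.efficiency_table(panel, em.DEAConfig(returns_to_scale="vrs"))

print("unit   rho     status         truly efficient?")
for (_, row), (_, t) in zip(eff.data.iterrows(), truth.iterrows()):
    status = "efficient" if row.rho >= 1 - 1e-6 else "inefficient"
    print(f"{row.unit}  {row.rho:6.3f}  {status:12s}   {t.efficient}")
print("\nA score of e.g. 0.5 means the unit could on average halve its")
print("input use (given its outputs) relative to the best practice frontier.")
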