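"""Simulate a cross-species gill dataset and recover the planted
up-regulated orthologs.

Generates the default comparative design — 6 Antarctic and 8 temperate
species, 2000 single-copy orthologs, 5% planted at a 10-fold Antarctic
up-regulation — assembles the orthologs x species TPM table (averaging
libraries, imputing missing orthologs as 0), and runs the consistency
score + Welch/BH analysis with the published thresholds (CS >= 36,
q < 0.05).
"""

import cryogill as cg

params = cg.SimulationParams(seed=1)
matrices, config, truth = cg.simulate_cross_species(params)
table = cg.build_ortholog_table(matrices, cg.identity_membership(matrices), config)
deg = cg.differential_expression(table, cs_min=36, q_max=0.05)

selected = set(deg.index[deg["selected"]])
planted = set(truth.planted_deg)
tp = selected & planted

print(f"orthologs tested      : {len(deg)}")
print(f"planted up-regulated  : {len(planted)} (true fold change 10)")
print(f"selected candidates   : {len(selected)}")
print(f"sensitivity           : {len(tp) / len(planted):.3f}")
print(f"false-discovery prop. : {len(selected - planted) / max(len(selected), 1):.3f}")
print()
print("top 5 candidates by q-value (CS out of 48, FC = group-mean ratio):")
print(cg.shortlist(deg).head(5).to_string())
# Sensitivity near 1 and FDP well under 0.10 mean the CS >= 36 & q < 0.05
# rule recovers almost all planted effects with few false calls.
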