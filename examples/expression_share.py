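"""Expression share of a gene set: the percentage of a species' total
ortholog TPM contributed by a designated gene family.

The real analysis applies this to carbonic anhydrases on the BUSCO
ortholog set (Antarctic gills devote several percent of their
transcriptional effort to them). Here the planted up-regulated
orthologs play the role of the gene family, so the Antarctic share is
visibly higher.
"""

import cryogill as cg

params = cg.SimulationParams(seed=1)
matrices, config, truth = cg.simulate_cross_species(params)
table = cg.build_ortholog_table(matrices, cg.identity_membership(matrices), config)

share, summary = cg.expression_share(table, list(truth.planted_deg))
print("per-species share of total ortholog TPM (%):")
print(share.round(2).to_string())
print("\ngroup summary (mean +/- sample sd over species):")
for grp, row in summary.iterrows():
    print(f"  {grp:9s}: {row.mean_pct:5.2f} +/- {row.sd_pct:4.2f} % "
          f"(n={int(row.n_species)})")
# The planted 10-fold up-regulation concentrates a much larger slice of
# the Antarctic species' transcriptional effort in the planted set.
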