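"""Trait-relevant markers versus random markers in cross-validation.

The headline experiment: within every training fold a LOD scan ranks the
bin markers, the top-k become that fold's trait-relevant markers (TRMs),
and GBLUP accuracy (r_MG, the correlation between predictions and the
held-out phenotypes) is compared against k randomly drawn markers.
"""

import trmgs as t

chroms = [t.ChromSpec(f"c{i + 1}", 200_000_000, 180.0) for i in range(10)]
founders = t.simulate_founders(4000, chroms, seed=51)
ril = t.make_ril_population(founders, 212, seed=52)
binmap = t.make_binmap(ril)

arch = t.random_architecture(ril.n_markers, 30, fa=0.5, seed=53,
                             var_env=0, var_gxe=0, var_rep=0, var_resid=1.0)
records, _ = t.simulate_phenotypes(ril, arch, 1, 1, seed=54)
y = records.set_index("individual")["value"].reindex(ril.ids)

data = t.CVData(geno=ril, blues=y, population="RIL", binmap=binmap)
plan = t.make_folds(ril.ids, k=5, n_reps=3, seed=55)

table = t.sweep(data, plan, marker_ladder=[20, 100, 500, "all"],
                sources=("TRM", "RAN"), models=("A",), seed=56)
summary = t.aggregate_accuracy(table)
print(summary[["marker_source", "n_markers", "r_mg_mean", "r_mg_sd"]]
      .to_string(index=False))
print("\nWith few markers the in-fold TRMs clearly beat random draws; the")
print("two converge as the marker count approaches the full bin map, and")
print("TRM accuracy plateaus by ~500 markers — the rationale for cheap")
print("targeted genotyping panels in selection programs.")
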