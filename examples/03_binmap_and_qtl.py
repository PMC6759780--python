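"""Recombination bin map and a composite-interval-mapping QTL scan.

Collapses dense RIL genotypes into recombination bins with the 15-SNP
sliding window, builds the Kosambi genetic map, scans a simulated
30-QTL trait with background cofactors, and declares QTL against a
permutation-derived genome-wide LOD threshold.
"""

import trmgs as t

chroms = [t.ChromSpec(f"c{i + 1}", 150_000_000, 150.0) for i in range(5)]
founders = t.simulate_founders(3000, chroms, seed=11)
ril = t.make_ril_population(founders, 200, seed=12)

binmap = t.make_binmap(ril)
summary = t.map_summary(binmap)
total = summary.iloc[-1]
print(f"Bin map: {int(total['n_bins'])} bins over {total['physical_mb']:.0f} Mb, "
      f"{total['map_cm']:.1f} cM "
      f"(mean interval {total['mean_interval_cm']:.2f} cM, "
      f"{100 * total['frac_lt_1mb']:.1f}% of bins < 1 Mb)")

arch = t.random_architecture(ril.n_markers, 30, fa=0.5, seed=13,
                             var_env=0, var_gxe=0, var_rep=0, var_resid=1.0)
records, _ = t.simulate_phenotypes(ril, arch, 1, 1, seed=14)
y = records.set_index("individual")["value"].reindex(ril.ids).to_numpy()

scan = t.cim_scan(y, binmap, n_cofactors=5)
threshold = t.permutation_threshold(y, binmap, n_perm=200, alpha=0.05, seed=15)
qtls = t.call_qtl(scan, threshold, trait="sim")
print(f"\nGenome-wide LOD threshold (200 permutations, alpha 0.05): "
      f"{threshold:.2f}")
print(f"{len(qtls)} QTL declared; each with a 1.5-LOD support interval:")
for q in qtls:
    print(f"  {q.chrom}: peak {q.peak_cm:.1f} cM, LOD {q.lod:.1f}, "
          f"PVE {q.pve:.1f}%, interval "
          f"{q.interval_bp[0] / 1e6:.1f}-{q.interval_bp[1] / 1e6:.1f} Mb")
print("Only a handful of the 30 simulated QTL clear the threshold at n=200 —")
print("the usual power ceiling of a single biparental population.")
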