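"""Marker QC and per-line BLUEs from a replicated trial.

Injects realistic missingness into an F2, applies the three marker filters
(missingness > 0.10, MAF <= 0.05, segregation-distortion chi-square at
P <= 0.01), then reduces the multi-environment records to one BLUE per line
and reports the broad-sense heritability implied by the variance components.
"""

import trmgs as t

chroms = [t.ChromSpec(f"c{i + 1}", 100_000_000, 120.0) for i in range(5)]
founders = t.simulate_founders(2000, chroms, seed=1)
f2 = t.make_f2_population(founders, 200, seed=3)
noisy = t.inject_missing(f2, rate=0.02, seed=7)

report = t.qc_report(noisy, expected_ratio=(1, 2, 1))
kept = report["kept"].sum()
print(f"QC: kept {kept}/{len(report)} markers "
      f"(mean missingness {report['missing_frac'].mean():.3f}, "
      f"mean MAF {report['maf'].mean():.3f})")

arch = t.random_architecture(f2.n_markers, 25, fa=0.5, seed=5)
records, _ = t.simulate_phenotypes(f2, arch, n_envs=2, n_reps=2, seed=6)
fit = t.fit_blue(records)
h2 = t.broad_sense_h2(fit)
vc = fit.varcomps["trait"]
print(f"BLUEs for {len(fit.blues)} lines; variance components: "
      f"GxE {vc['var_gxe']:.3f}, rep {vc['var_rep']:.3f}, "
      f"residual {vc['var_resid']:.3f}")
print(f"Broad-sense heritability (entry-mean basis): {h2['trait']:.2f}")
print("BLUEs are the phenotypes used by all downstream mapping and prediction.")
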