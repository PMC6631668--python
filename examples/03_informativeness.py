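"""Informativeness for assignment and marker-equivalence extrapolation.

Computes the In statistic for random SNP subsets of growing size, fits
the linear size-informativeness relation, and asks how many SNPs match a
given target informativeness.  The target here is 2.48, a typical
13-locus microsatellite panel value, and a reference relation
I = 0.023 N + 0.0038 for a ~90-SNP diagnostic panel is inverted for
comparison.
"""

import radpanel as rp
from radpanel.evaluate import RegressionFit

m, pops, _ = rp.simulate_two_lineage_genotypes(
    n_pops=2, n_per_pop=100, n_loci=92, divergence_F=0.10, seed=5)

n_poly = sum(len(m.alleles_at(l)) >= 2 for l in m.locus_ids)
curve = rp.informativeness_curve(m, pops,
                                 sizes=[10, 20, 40, 60, 80, n_poly],
                                 replicates=100, seed=5)
print(curve.to_frame().round(4).to_string(index=False))

fit = rp.fit_informativeness_regression(curve)
print(f"\nfitted: I = {fit.slope:.4f} * N + {fit.intercept:.4f}  "
      f"(r^2 = {fit.r_squared:.3f})")
print("equivalent markers for target I=2.48 under the fitted relation:",
      rp.equivalent_marker_count(fit, 2.48))

reference = RegressionFit(slope=0.023, intercept=0.0038, r_squared=0.98)
print("equivalent markers under the reference relation I = 0.023 N + 0.0038:",
      rp.equivalent_marker_count(reference, 2.48))
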