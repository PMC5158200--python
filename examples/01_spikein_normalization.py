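"""Spike-in calibration of a simulated hybridization-count run.

Simulates a miRNA counting experiment with four positive controls
(POS_B..POS_E on a 32/8/2/0.5 dilution ladder), fits each sample's linear
response, applies E = (R - B)/slope, and shows that the planted abundances
are recovered.
"""

import numpy as np

from shrnakit import ncounter, synthetic

cfg = synthetic.SimConfig(n_mirnas=8, noise_cv=0.02, seed=1)
matrix = synthetic.simulate_ncounter(cfg)
print(f"simulated {matrix.counts.shape[0]} features x {matrix.counts.shape[1]} samples")
print(matrix.counts.iloc[:6, :3], "\n")

fits = ncounter.fit_all_samples(matrix, cfg.spike_concs)
print("per-sample calibration (slope = counts per concentration unit):")
print(ncounter.fit_report(fits).round(2).head(3), "\n")

nm = ncounter.global_normalize(ncounter.normalize_spikein(matrix, fits))
est = nm.values.mean(axis=1)
truth = matrix.true_abundance.iloc[:, 0]
scalar = est.sum() / truth.sum()
err = np.abs(est / (scalar * truth) - 1)
print("per-feature recovered abundance vs planted truth (global scale aligned):")
for feat in nm.feature_ids[:5]:
    print(f"  {feat}: est={est[feat]:8.2f}  truth={truth[feat]:8.2f}  rel err={err[feat]:.3%}")
print(f"median relative error: {err.median():.3%}")
print("-> the spike-in line inverts the hybridization model; at noise 0 the"
      " recovery is exact.")
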