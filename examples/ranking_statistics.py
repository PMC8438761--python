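"""Rank a synthetic ligand panel against noisy 'experimental' affinities.

A 22-ligand panel with evenly spaced true binding free energies gets
Gaussian experimental noise (SD 1 kcal/mol); the ranking report then
recovers a correlation attenuated by the noise, with bootstrap SEs from
resampling ligand pairs.
"""

import numpy as np

from esmacs import gen_ligand_panel, ranking_report

true, expt = gen_ligand_panel(22, (-11.0, -3.1), expt_noise_sd=1.0, seed=7)
report = ranking_report(list(true.items()), expt, n_boot=5000, seed=7,
                        protocol="ground-truth panel")

tv = np.var(list(true.values()))
print(f"n_ligands = {report.n_ligands}, n_boot = {report.n_boot}")
print(f"MUE (offset-corrected) = {report.mue:.2f} ({report.mue_se:.2f}) kcal/mol")
print(f"PI  = {report.pi:.2f} ({report.pi_se:.2f})")
print(f"r^2 = {report.r2:.2f} ({report.r2_se:.2f})   "
      f"[noise-attenuation prediction {tv / (tv + 1.0):.2f}]")
print(f"rs  = {report.rs:.2f} ({report.rs_se:.2f})")
print("\nBracketed values are bootstrap standard errors; with unit "
      "experimental noise the r^2 is expected to attenuate to "
      "var(true)/(var(true)+1), and the offset-corrected MUE approaches "
      "the noise SD.")
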