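"""Sample causal-variant sets under the six bundled genetic architectures.

Each architecture couples variant frequency and relative risk differently
(strong / moderate / weak purifying selection; rare-only restriction;
bidirectional effects).  Causal effects are accumulated at random exonic
variants until the locus explains 1% of liability variance (within the
0.95-1.05 acceptance window), mimicking a locus with aggregate effect
comparable to a strong common-variant association.
"""

import numpy as np

from rvpower.architecture import (DiseaseModel, default_architecture,
                                  sample_locus_effects)
from rvpower.panel import ExpansionParams, exome_calibrated_panel

panel = exome_calibrated_panel(seed=3,
                               params=ExpansionParams(target_n=4000))
disease = DiseaseModel(prevalence=0.08)

print(f"{'arch':5s} {'selection':9s} {'n_causal':>8s} {'achieved VE':>11s} "
      f"{'median RR':>9s} {'median MAF':>10s} {'protective':>10s}")
for arch_id in ("ar1", "ar2", "ar3", "ar4", "ar5", "ar6"):
    arch = default_architecture(arch_id)
    eff = sample_locus_effects(panel, arch, target_ve=0.01,
                               disease=disease, seed=11)
    rrs = np.array(eff.rrs)
    prot = int((rrs < 1).sum())
    risk_rr = np.where(rrs < 1, 1 / rrs, rrs)
    print(f"{arch_id:5s} {arch.selection:9s} {len(eff):8d} "
          f"{eff.achieved_ve:11.4f} {np.median(risk_rr):9.2f} "
          f"{np.median(eff.mafs):10.2g} {prot:10d}")

print("\nStrong selection (ar1/ar4) concentrates effects on few rare,"
      "\nlarge-RR variants; weak selection (ar3) spreads modest effects"
      "\nacross the spectrum; ar6 mixes risk and protective directions.")
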