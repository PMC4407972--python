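"""Greedy forward selection of a composite battery of gene-based tests.

Starting from one strong test, tests are added whenever they detect loci
the current composite misses by a p-value margin; the composite's
detection rule is the minimum p over its members.  The false-positive cost
of combining tests is then quantified with an empirically FPR-corrected
threshold from matched null simulations.
"""

import pandas as pd

from rvpower.architecture import (DiseaseModel, LocusEffects,
                                  default_architecture,
                                  sample_locus_effects)
from rvpower.assoc import TestSpec, run_test_battery
from rvpower.cohort import sample_cohort
from rvpower.evaluate import forward_select_composite
from rvpower.panel import ExpansionParams, exome_calibrated_panel

panel = exome_calibrated_panel(seed=13,
                               params=ExpansionParams(target_n=4000))
arch = default_architecture("ar2")
disease = DiseaseModel()
tests = ("KBAC", "SKAT-O", "MIST", "BURDEN", "UNIQ", "VT")
spec = TestSpec(n_permutations=2000)

def batch(effects_fn, n_rep, seed0):
    rows = []
    for rep in range(n_rep):
        eff = effects_fn(rep)
        ds = sample_cohort(panel, eff, disease, n_case=400, n_control=400,
                           seed=seed0 + rep)
        rows.append({res.test: res.p_value for res in
                     run_test_battery(ds, spec, seed=seed0 + 7000 + rep,
                                      tests=tests)})
    return pd.DataFrame(rows)

causal = batch(lambda r: sample_locus_effects(panel, arch, 0.01, disease,
                                              seed=500 + r), 40, 600)
null = batch(lambda r: LocusEffects([], [], [], 0.0, 0.0), 150, 800)

comp = forward_select_composite(causal, start="KBAC", margin=10.0,
                                alpha=0.01, null_results_by_test=null,
                                target_fpr=0.01)
print("selected composite:", " + ".join(comp.tests))
print(f"unadjusted sensitivity at alpha=0.01: {comp.sensitivity:.2f}")
print(f"best single member (KBAC): {(causal['KBAC'] < 0.01).mean():.2f}")
print(f"FPR-corrected threshold: {comp.fpr_adjusted_threshold:.4f}")
print(f"FPR-adjusted sensitivity: {comp.fpr_adjusted_sensitivity:.2f}")
print("\nThe composite never loses to its best member before FPR "
      "correction; the adjusted row shows how much of the gain survives "
      "once the extra false positives are paid for.")
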