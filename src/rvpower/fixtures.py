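"""Tiny deterministic datasets for exhaustive-oracle testing and worked
examples.

The 8-individual cohort is small enough that every permutation test can be
checked against full enumeration of the C(8,4) = 70 case assignments; the
carrier counts below are documented so they can be verified by hand.
"""

from __future__ import annotations

import os

import numpy as np

from .cohort import CohortDataset

__all__ = ["toy_cohort", "null_toy_cohort", "make_fixtures"]

# 8 individuals x 6 sites; rows 0-3 are cases.  Hand enumeration:
# site 0: singleton in case 0           (case-unique)
# site 1: doubleton, cases 1 and 2      (case-unique)
# site 2: singleton in control 4
# site 3: case 3 het + control 5 het    (shared)
# site 4: common-ish: dosages 1 in individuals 0,2,4,6
# site 5: singleton hom in case 1
_TOY_GENO = np.array([
    # s0 s1 s2 s3 s4 s5
    [1, 0, 0, 0, 1, 0],   # case 0
    [0, 1, 0, 0, 0, 2],   # case 1
    [0, 1, 0, 0, 1, 0],   # case 2
    [0, 0, 0, 1, 0, 0],   # case 3
    [0, 0, 1, 0, 1, 0],   # control 4
    [0, 0, 0, 1, 0, 0],   # control 5
    [0, 0, 0, 0, 1, 0],   # control 6
    [0, 0, 0, 0, 0, 0],   # control 7
], dtype=np.uint8)


def toy_cohort():
    """8-individual fixture with case-skewed rare variation."""
    return CohortDataset(
        genotypes=_TOY_GENO.copy(),
        phenotype=np.array([1, 1, 1, 1, 0, 0, 0, 0]),
        positions=np.array([10, 25, 40, 55, 70, 85]),
        exonic=np.ones(6, bool),
        causal_mask=np.array([True, True, False, False, False, True]))


def null_toy_cohort(seed=7, n=8, m=5):
    """Random small cohort with no phenotype-genotype relation."""
    rng = np.random.default_rng(seed)
    geno = rng.binomial(1, 0.25, size=(n, m)).astype(np.uint8)
    geno[:, geno.sum(axis=0) == 0] = 0
    keep = (geno.sum(axis=0) > 0) & (geno.sum(axis=0) < n)
    geno = geno[:, keep]
    phen = np.zeros(n, np.int8)
    phen[: n // 2] = 1
    return CohortDataset(geno, phen, np.arange(geno.shape[1]) * 10 + 5,
                         np.ones(geno.shape[1], bool),
                         np.zeros(geno.shape[1], bool))


def make_fixtures(seed=1, out_dir="fixtures"):
    """Write the bundled toy cohorts (VCF + phenotype TSV + causal sidecar)
    and one 3K-calibrated locus panel sampled down for calibration tests."""
    from . import io as io_mod
    from . import panel as panel_mod

    os.makedirs(out_dir, exist_ok=True)
    toy = toy_cohort()
    io_mod.write_cohort_vcf(toy, os.path.join(out_dir, "toy_cohort.vcf"))
    io_mod.write_phenotype_tsv(toy, os.path.join(out_dir, "toy_cohort.phe.tsv"))
    null = null_toy_cohort(seed)
    io_mod.write_cohort_vcf(null, os.path.join(out_dir, "null_cohort.vcf"))
    io_mod.write_phenotype_tsv(null, os.path.join(out_dir, "null_cohort.phe.tsv"))
    small = panel_mod.exome_calibrated_panel(
        seed=seed, params=panel_mod.ExpansionParams(target_n=1000))
    io_mod.write_panel_vcf(small, os.path.join(out_dir, "panel_1k.vcf"))
    return {"toy": toy, "null": null, "panel": small}
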