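"""Readers and writers for the package's on-disk formats.

Panels and cohorts travel as VCF 4.2 (phased GT for panels, unphased for
cohorts) or IMPUTE2 ``.hap``/``.legend`` pairs; phenotypes as PLINK-style
FID/IID/STATUS TSV; frequency-RR maps, SFS and LD profiles, and result
tables as TSV.  Internal coordinates are 0-based half-open; VCF output is
1-based.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .architecture import FreqRRMap
from .cohort import CohortDataset
from .errors import ParameterError
from .panel import HaplotypePanel

__all__ = [
    "write_panel_vcf", "read_panel_vcf",
    "write_hap_legend", "read_hap_legend",
    "write_cohort_vcf", "write_phenotype_tsv", "read_phenotype_tsv",
    "write_freq_rr_map", "read_freq_rr_map",
    "write_group_file", "read_group_file",
    "write_results_tsv", "read_results_tsv",
]

_CONTIG = "simulated_locus"


def _vcf_header(n_samples, region_length, sample_prefix):
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={_CONTIG},length={region_length}>",
        '##INFO=<ID=EXONIC,Number=0,Type=Flag,Description="Site lies in a '
        'simulated exon block">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    samples = [f"{sample_prefix}{i}" for i in range(n_samples)]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples))
    return lines


def write_panel_vcf(panel, path, sample_prefix="ind"):
    """Write a phased panel as VCF 4.2 (GT with '|' separators)."""
    lines = _vcf_header(panel.n_individuals, panel.region_length,
                        sample_prefix)
    h = panel.haplotypes
    for j in range(panel.n_sites):
        info = "EXONIC" if panel.exonic[j] else "."
        gts = [f"{h[2 * i, j]}|{h[2 * i + 1, j]}"
               for i in range(panel.n_individuals)]
        lines.append(f"{_CONTIG}\t{panel.positions[j] + 1}\tvar{j}\tA\tT\t."
                     f"\tPASS\t{info}\tGT\t" + "\t".join(gts))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_panel_vcf(path, region_length=None, exon_intervals=None):
    """Read a phased panel from VCF (any reader-compatible VCF with GT).

    Sites without an EXONIC flag are treated as non-exonic; supply
    ``exon_intervals`` to override.  Unphased records are accepted (alleles
    taken in written order).
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    haps, positions, exonic = [], [], []
    for var in vcf:
        arr = np.asarray(var.genotype.array())
        alleles = arr[:, :2].T.reshape(-1, order="F")
        if np.any(alleles < 0):
            raise ParameterError("missing genotypes are not supported")
        positions.append(var.POS - 1)
        exonic.append(bool(var.INFO.get("EXONIC", False)))
        haps.append(alleles.astype(np.uint8))
    if not haps:
        raise ParameterError("VCF contains no variant records")
    haps = np.asarray(haps).T
    positions = np.asarray(positions)
    if region_length is None:
        region_length = int(positions.max()) + 1
    if exon_intervals is None:
        exon_intervals = _intervals_from_flags(positions, exonic,
                                               region_length)
    return HaplotypePanel(haps, positions, exonic, region_length,
                          exon_intervals, provenance="base")


def _intervals_from_flags(positions, exonic, region_length):
    """Minimal covering intervals for flagged positions (fallback when a
    user panel does not carry explicit exon annotation)."""
    pos = np.asarray(positions)[np.asarray(exonic, bool)]
    if pos.size == 0:
        return [(0, int(region_length))]
    breaks = np.flatnonzero(np.diff(pos) > 100)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [pos.size - 1]])
    return [(int(pos[s]), int(pos[e]) + 1) for s, e in zip(starts, ends)]


def write_hap_legend(panel, prefix):
    """IMPUTE2-style ``.hap`` (sites x haplotypes, 0/1) and ``.legend``."""
    np.savetxt(f"{prefix}.hap", panel.haplotypes.T, fmt="%d", delimiter=" ")
    leg = pd.DataFrame({
        "id": [f"var{j}" for j in range(panel.n_sites)],
        "position": panel.positions + 1,
        "a0": "A", "a1": "T",
        "exonic": panel.exonic.astype(int),
    })
    leg.to_csv(f"{prefix}.legend", sep=" ", index=False)


def read_hap_legend(prefix, region_length=None, exon_intervals=None):
    haps = np.loadtxt(f"{prefix}.hap", dtype=np.uint8, ndmin=2).T
    leg = pd.read_csv(f"{prefix}.legend", sep=r"\s+")
    positions = leg["position"].to_numpy() - 1
    exonic = leg["exonic"].astype(bool).to_numpy() if "exonic" in leg \
        else np.ones(positions.size, bool)
    if region_length is None:
        region_length = int(positions.max()) + 1
    if exon_intervals is None:
        exon_intervals = _intervals_from_flags(positions, exonic,
                                               region_length)
    return HaplotypePanel(haps, positions, exonic, region_length,
                          exon_intervals, provenance="base")


def write_cohort_vcf(dataset, path, sample_prefix="s"):
    """Unphased genotype VCF plus nothing else; pair with
    :func:`write_phenotype_tsv` and the causal-mask sidecar."""
    n = dataset.genotypes.shape[0]
    lines = _vcf_header(n, int(dataset.positions.max()) + 1, sample_prefix)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    for j in range(dataset.n_sites):
        info = "EXONIC" if dataset.exonic[j] else "."
        gts = [gt_map[int(g)] for g in dataset.genotypes[:, j]]
        lines.append(f"{_CONTIG}\t{dataset.positions[j] + 1}\tvar{j}\tA\tT"
                     f"\t.\tPASS\t{info}\tGT\t" + "\t".join(gts))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    mask_path = os.path.splitext(path)[0] + ".causal.tsv"
    pd.DataFrame({"id": [f"var{j}" for j in range(dataset.n_sites)],
                  "position": dataset.positions + 1,
                  "causal": dataset.causal_mask.astype(int)}
                 ).to_csv(mask_path, sep="\t", index=False)


def write_phenotype_tsv(dataset, path, sample_prefix="s"):
    """PLINK-compatible FID IID STATUS table (1 = case, 0 = control)."""
    n = dataset.genotypes.shape[0]
    pd.DataFrame({"FID": [f"{sample_prefix}{i}" for i in range(n)],
                  "IID": [f"{sample_prefix}{i}" for i in range(n)],
                  "STATUS": dataset.phenotype.astype(int)}
                 ).to_csv(path, sep="\t", index=False)


def read_phenotype_tsv(path):
    df = pd.read_csv(path, sep="\t")
    return df["STATUS"].to_numpy().astype(np.int8)


def read_cohort_vcf(path, phenotype_path, causal_path=None):
    """Reassemble a :class:`CohortDataset` from its exported files."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    genotypes, positions, exonic = [], [], []
    for var in vcf:
        arr = np.asarray(var.genotype.array())[:, :2]
        genotypes.append(arr.sum(axis=1).astype(np.uint8))
        positions.append(var.POS - 1)
        exonic.append(bool(var.INFO.get("EXONIC", False)))
    geno = np.asarray(genotypes).T
    phen = read_phenotype_tsv(phenotype_path)
    if causal_path is None:
        causal_path = os.path.splitext(path)[0] + ".causal.tsv"
    if os.path.exists(causal_path):
        causal = pd.read_csv(causal_path, sep="\t")["causal"].astype(bool)
        causal = causal.to_numpy()
    else:
        causal = np.zeros(geno.shape[1], bool)
    return CohortDataset(geno, phen, np.asarray(positions),
                         np.asarray(exonic, bool), causal)


def write_freq_rr_map(freq_rr_map, path):
    """Serialize a frequency-RR grid as TSV (rows = MAF bins)."""
    df = pd.DataFrame(freq_rr_map.weights,
                      columns=[f"rr_{lo:g}_{hi:g}" for lo, hi in
                               zip(freq_rr_map.rr_edges[:-1],
                                   freq_rr_map.rr_edges[1:])])
    df.insert(0, "maf_lo", freq_rr_map.maf_edges[:-1])
    df.insert(1, "maf_hi", freq_rr_map.maf_edges[1:])
    df.to_csv(path, sep="\t", index=False)


def read_freq_rr_map(path):
    df = pd.read_csv(path, sep="\t")
    maf_edges = np.concatenate([df["maf_lo"].to_numpy(),
                                [df["maf_hi"].iloc[-1]]])
    rr_cols = [c for c in df.columns if c.startswith("rr_")]
    rr_edges = [float(c.split("_")[1]) for c in rr_cols]
    rr_edges.append(float(rr_cols[-1].split("_")[2]))
    return FreqRRMap(maf_edges, np.asarray(rr_edges),
                     df[rr_cols].to_numpy())


def write_group_file(groups, path):
    """Two-column gene-to-variant-id group file (one row per membership)."""
    rows = [(gene, vid) for gene, vids in groups.items() for vid in vids]
    pd.DataFrame(rows, columns=["gene", "variant"]).to_csv(
        path, sep="\t", index=False, header=False)


def read_group_file(path):
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "variant"])
    return {g: list(sub["variant"]) for g, sub in df.groupby("gene",
                                                             sort=False)}


def write_results_tsv(results, path):
    results.to_csv(path, sep="\t", index=False)


def read_results_tsv(path):
    return pd.read_csv(path, sep="\t")
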