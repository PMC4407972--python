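"""Aggregation of test results into power, calibration, concordance,
combined gene/single-variant sensitivity, and composite-test selection."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .architecture import DiseaseModel, _penetrances
from .errors import ParameterError, ResolutionError

__all__ = [
    "exome_wide_threshold",
    "expected_null_hits",
    "estimate_power",
    "binomial_ci",
    "fpr_corrected_threshold",
    "concordance",
    "combined_power",
    "CompositeTest",
    "forward_select_composite",
    "discordance_profile",
    "case_control_frequencies",
    "power_single_variant",
]


def exome_wide_threshold(alpha=0.05, n_genes=20_000):
    """Bonferroni significance threshold for an exome-wide gene scan."""
    if n_genes < 1:
        raise ParameterError("n_genes must be >= 1")
    return alpha / n_genes


def expected_null_hits(alpha, n_genes=20_000):
    """Expected number of genes passing ``alpha`` under the global null."""
    return alpha * n_genes


def binomial_ci(k, n, level=0.95):
    """Exact (Clopper-Pearson) binomial confidence interval."""
    a = (1 - level) / 2
    lo = stats.beta.ppf(a, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - a, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)


def estimate_power(results, alpha, group_cols=None, level=0.95):
    """Power per group: fraction of replicates with p strictly below
    ``alpha`` (ties at alpha count as non-detections), with exact binomial
    confidence intervals.

    ``results`` is a tidy DataFrame with a ``p`` column; grouping uses
    ``group_cols`` or every recognized design column present.
    """
    if "p" not in results.columns:
        raise ParameterError("results must have a 'p' column")
    if group_cols is None:
        candidates = ["gene", "test", "architecture", "ve", "n",
                      "maf_threshold"]
        group_cols = [c for c in candidates if c in results.columns]
    rows = []
    grouped = results.groupby(group_cols, sort=True) if group_cols else \
        [((), results)]
    for key, grp in grouped:
        if not isinstance(key, tuple):
            key = (key,)
        p = grp["p"].to_numpy()
        n = p.size
        k = int(np.sum(p < alpha))
        lo, hi = binomial_ci(k, n, level)
        rows.append(dict(zip(group_cols, key), alpha=alpha, power=k / n,
                         n_replicates=n, ci_low=lo, ci_high=hi))
    return pd.DataFrame(rows)


def fpr_corrected_threshold(null_results, target_fpr):
    """Per-test empirically corrected p-value threshold.

    For each test, the largest p-cutoff whose empirical null exceedance is
    at most ``target_fpr`` (an order statistic of the null p-values).
    ``null_results`` is a DataFrame with columns ``test`` and ``p`` or a
    mapping from test name to an array of null p-values.
    """
    if isinstance(null_results, pd.DataFrame):
        items = {t: g["p"].to_numpy() for t, g in null_results.groupby("test")}
    else:
        items = {t: np.asarray(v, float) for t, v in null_results.items()}
    out = {}
    for test, ps in items.items():
        n = ps.size
        if n < 1.0 / target_fpr:
            raise ResolutionError(
                f"{n} null replicates cannot resolve FPR {target_fpr:g}")
        k = int(np.floor(target_fpr * n))
        out[test] = float(np.sort(ps)[k]) if k < n else 1.0
    return out


def concordance(results_a, results_b, p_cut=0.1):
    """Squared Pearson correlation of -log10 p over shared loci where both
    tests report p <= ``p_cut``.

    Returns a dict with keys ``r2``, ``n_pairs`` and ``reason`` (non-None
    when the correlation is undefined: fewer than 3 qualifying pairs).
    """
    a = np.asarray(results_a, float)
    b = np.asarray(results_b, float)
    if a.size != b.size:
        raise ParameterError("result vectors must be aligned")
    keep = (a <= p_cut) & (b <= p_cut) & np.isfinite(a) & np.isfinite(b)
    n = int(keep.sum())
    if n < 3:
        return {"r2": np.nan, "n_pairs": n,
                "reason": f"only {n} loci with both p <= {p_cut}"}
    la, lb = -np.log10(a[keep]), -np.log10(b[keep])
    if np.ptp(la) == 0 or np.ptp(lb) == 0:
        return {"r2": np.nan, "n_pairs": n, "reason": "constant -log10 p"}
    r = np.corrcoef(la, lb)[0, 1]
    return {"r2": float(r ** 2), "n_pairs": n, "reason": None}


def combined_power(gene_results, sv_results, alpha_gene=2.5e-6,
                   alpha_sv=5e-8):
    """Decompose detections per locus into single-variant-only, gene-only,
    both, and neither, and report union power and the gene-only increment."""
    pg = np.asarray(gene_results, float)
    ps = np.asarray(sv_results, float)
    if pg.size != ps.size:
        raise ParameterError("result vectors must be aligned")
    gene_hit = pg < alpha_gene
    sv_hit = ps < alpha_sv
    n = pg.size
    return {
        "n": n,
        "sv_only": float(np.mean(sv_hit & ~gene_hit)),
        "gene_only": float(np.mean(gene_hit & ~sv_hit)),
        "both": float(np.mean(gene_hit & sv_hit)),
        "neither": float(np.mean(~gene_hit & ~sv_hit)),
        "sv_power": float(np.mean(sv_hit)),
        "gene_power": float(np.mean(gene_hit)),
        "union_power": float(np.mean(gene_hit | sv_hit)),
        "gene_only_increment": float(np.mean(gene_hit & ~sv_hit)),
    }


@dataclass
class CompositeTest:
    """A greedily selected set of tests used through their per-locus
    minimum p-value."""

    tests: list
    start: str
    margin: float
    alpha: float
    sensitivity: float
    fpr_adjusted_sensitivity: float | None = None
    fpr_adjusted_threshold: float | None = None
    selection_novel_counts: list = field(default_factory=list)


def forward_select_composite(results_by_test, start, margin=10.0,
                             alpha=1e-4, null_results_by_test=None,
                             target_fpr=None):
    """Stepwise forward selection of a composite test battery.

    ``results_by_test``: DataFrame, one row per locus replicate, one column
    of p-values per test.  At each step the candidate reporting the greatest
    number of novel signals is added; a novel signal is a row where the
    candidate's p times ``margin`` is below the minimum p of the included
    tests and the candidate's p is below ``alpha``.  Selection stops when no
    candidate adds a novel signal.

    Unadjusted sensitivity applies the minimum-p rule at ``alpha``.  If null
    results are supplied, the minimum-p composite null yields an
    FPR-corrected threshold (at ``target_fpr``, default ``alpha``) and the
    adjusted sensitivity.
    """
    if start not in results_by_test.columns:
        raise ParameterError(f"unknown start test {start!r}")
    if margin < 1:
        raise ParameterError("margin must be >= 1")
    included = [start]
    novel_counts = []
    while True:
        current_min = results_by_test[included].min(axis=1)
        best, best_count = None, 0
        for cand in results_by_test.columns:
            if cand in included:
                continue
            pc = results_by_test[cand]
            novel = int(((pc * margin < current_min) & (pc < alpha)).sum())
            if novel > best_count:
                best, best_count = cand, novel
        if best is None:
            break
        included.append(best)
        novel_counts.append((best, best_count))
    min_p = results_by_test[included].min(axis=1)
    sensitivity = float((min_p < alpha).mean())
    comp = CompositeTest(tests=included, start=start, margin=margin,
                         alpha=alpha, sensitivity=sensitivity,
                         selection_novel_counts=novel_counts)
    if null_results_by_test is not None:
        null_min = null_results_by_test[included].min(axis=1).to_numpy()
        thr = fpr_corrected_threshold({"composite": null_min},
                                      target_fpr or alpha)["composite"]
        comp.fpr_adjusted_threshold = thr
        comp.fpr_adjusted_sensitivity = float((min_p < thr).mean())
    return comp


def discordance_profile(results_a, results_b, datasets, p_cut=0.01,
                        rare_maf=0.01):
    """Locus properties where one test (but not the other) reports
    p < ``p_cut``: aggregate case:control minor-allele ratio, case-unique
    allele count, and the top single-variant p at the locus."""
    from .assoc import test_single_fisher

    a = np.asarray(results_a, float)
    b = np.asarray(results_b, float)
    rows = []
    for i, ds in enumerate(datasets):
        a_only = a[i] < p_cut <= b[i]
        b_only = b[i] < p_cut <= a[i]
        if not (a_only or b_only):
            continue
        case, ctrl = ds.minor_allele_counts()
        rare = ds.maf < rare_maf
        case_sum = int(case[rare].sum())
        ctrl_sum = int(ctrl[rare].sum())
        ratio = case_sum / ctrl_sum if ctrl_sum else np.inf
        uniq = int(case[rare & (ctrl == 0)].sum())
        top_p = test_single_fisher(ds).p_value
        rows.append({"locus": i, "group": "a_only" if a_only else "b_only",
                     "case_control_ratio": ratio,
                     "case_unique_count": uniq,
                     "top_single_variant_p": top_p})
    return pd.DataFrame(rows, columns=["locus", "group",
                                       "case_control_ratio",
                                       "case_unique_count",
                                       "top_single_variant_p"])


# ---------------------------------------------------------------------------
# analytic single-variant power
# ---------------------------------------------------------------------------

def case_control_frequencies(maf, rr, prevalence=0.08,
                             controls="unselected"):
    """Expected risk-allele frequency in cases and controls under the
    prevalence-constrained additive relative-risk model.

    ``controls='unselected'`` uses the population frequency for controls
    (the convention of standard power calculators); ``'screened'``
    conditions controls on being disease-free.
    """
    disease = DiseaseModel(prevalence)
    pg, f = _penetrances(maf, rr, disease)
    dose = np.array([0.0, 0.5, 1.0])  # allele fraction per genotype
    p_case = float(np.sum(dose * pg * f) / prevalence)
    if controls == "unselected":
        p_ctrl = maf
    elif controls == "screened":
        p_ctrl = float(np.sum(dose * pg * (1 - f)) / (1 - prevalence))
    else:
        raise ParameterError("controls must be 'unselected' or 'screened'")
    return p_case, p_ctrl


def power_single_variant(maf, rr, n_case=1500, n_control=1500,
                         prevalence=0.08, alpha=5e-8, method="analytic",
                         controls="unselected", n_sim=10_000, seed=None):
    """Power of two-sided single-variant allelic association.

    ``method='analytic'`` uses the normal approximation to the two-sample
    allele-frequency comparison; ``'fisher-mc'`` simulates allele counts and
    applies Fisher's exact test ``n_sim`` times.
    """
    if not 0 < alpha <= 1:
        raise ParameterError("alpha must be in (0, 1]")
    p1, p2 = case_control_frequencies(maf, rr, prevalence, controls)
    if method == "analytic":
        if rr == 1:
            return float(alpha)
        pbar = (n_case * p1 + n_control * p2) / (n_case + n_control)
        se = np.sqrt(pbar * (1 - pbar) * (1 / (2 * n_case) + 1 / (2 * n_control)))
        ncp = (p1 - p2) / se
        za = stats.norm.isf(alpha / 2)
        return float(stats.norm.sf(za - ncp) + stats.norm.cdf(-za - ncp))
    if method == "fisher-mc":
        rng = np.random.default_rng(seed)
        a = rng.binomial(2 * n_case, p1, n_sim)
        u = rng.binomial(2 * n_control, p2, n_sim)
        hits = 0
        for ai, ui in zip(a, u):
            p = stats.fisher_exact([[ai, 2 * n_case - ai],
                                    [ui, 2 * n_control - ui]])[1]
            hits += p < alpha
        return hits / n_sim
    raise ParameterError("method must be 'analytic' or 'fisher-mc'")
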