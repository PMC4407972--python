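"""Case-control cohort generation at a simulated locus.

Individuals are formed by pairing fresh Li & Stephens mosaic haplotypes
drawn from a reference panel; disease status is assigned by Bernoulli
sampling of a multiplicative relative-risk model whose baseline is solved so
the population risk equals the disease prevalence.  Sampling continues until
the case and control quotas are filled (rejection-sampling equivalent of
ascertained case-control collection).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .architecture import DiseaseModel, LocusEffects
from .errors import ExhaustionError, InfeasibleEffectError, ParameterError
from .panel import ExpansionParams, _mosaic_batch

__all__ = [
    "CohortDataset",
    "individual_risk",
    "baseline_risk",
    "sample_cohort",
    "causal_fraction_filter",
]


@dataclass
class CohortDataset:
    """Unphased genotypes and phenotypes for one simulated locus replicate.

    genotypes : (individuals x sites) dosage matrix with values 0/1/2.
    phenotype : 1 = case, 0 = control.
    causal_mask : evaluation-only flag per site (never used by tests).
    """

    genotypes: np.ndarray
    phenotype: np.ndarray
    positions: np.ndarray
    exonic: np.ndarray
    causal_mask: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        g = np.asarray(self.genotypes)
        if g.ndim != 2 or not np.isin(g, (0, 1, 2)).all():
            raise ParameterError("genotype dosages must be 0/1/2")
        self.genotypes = g.astype(np.uint8)
        self.phenotype = np.asarray(self.phenotype, np.int8)
        if self.phenotype.size != g.shape[0]:
            raise ParameterError("phenotype length must match individuals")
        self.positions = np.asarray(self.positions, np.int64)
        self.exonic = np.asarray(self.exonic, bool)
        self.causal_mask = np.asarray(self.causal_mask, bool)

    @property
    def n_case(self):
        return int(self.phenotype.sum())

    @property
    def n_control(self):
        return int((self.phenotype == 0).sum())

    @property
    def n_sites(self):
        return self.genotypes.shape[1]

    @property
    def maf(self):
        """Observed sample MAF per site (recomputed from the matrix)."""
        f = self.genotypes.mean(axis=0) / 2.0
        return np.minimum(f, 1 - f)

    @property
    def minor_is_alt(self):
        """True where the 1-coded allele is the minor allele in-sample."""
        return self.genotypes.mean(axis=0) / 2.0 <= 0.5

    def minor_allele_counts(self):
        """Case and control minor-allele counts per site."""
        alt_case = self.genotypes[self.phenotype == 1].sum(axis=0)
        alt_ctrl = self.genotypes[self.phenotype == 0].sum(axis=0)
        flip = ~self.minor_is_alt
        case = np.where(flip, 2 * self.n_case - alt_case, alt_case)
        ctrl = np.where(flip, 2 * self.n_control - alt_ctrl, alt_ctrl)
        return case.astype(int), ctrl.astype(int)

    def subset_sites(self, keep):
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        keep = np.sort(keep)
        return CohortDataset(self.genotypes[:, keep], self.phenotype,
                             self.positions[keep], self.exonic[keep],
                             self.causal_mask[keep])


def _rr_factors(dosages, rr):
    """Per-variant multiplicative risk factor under additive coding:
    1, RR, 2*RR - 1 for dosage 0, 1, 2."""
    return 1.0 + (rr - 1.0) * dosages


def baseline_risk(effects, disease, mafs=None):
    """Baseline (zero-dosage) risk f0 solved so the population mean risk
    equals the prevalence, assuming HWE and independence between causal
    variants at their panel frequencies."""
    mafs = np.asarray(effects.mafs if mafs is None else mafs, float)
    rrs = np.asarray(effects.rrs, float)
    mean_factor = 1.0
    for q, rr in zip(mafs, rrs):
        p0, p1, p2 = (1 - q) ** 2, 2 * q * (1 - q), q * q
        mean_factor *= p0 + p1 * rr + p2 * (2 * rr - 1)
    if mean_factor <= 0:
        raise InfeasibleEffectError("population mean risk factor is not positive")
    return disease.prevalence / mean_factor


def individual_risk(dosages, effects, disease=DiseaseModel()):
    """P(disease | genotype) = f0 * prod_v RR_v(g_v) for each individual.

    ``dosages`` holds the causal-site dosage columns in the order of
    ``effects``.  Raises :class:`InfeasibleEffectError` if any computed risk
    reaches 1 (no clipping is applied).
    """
    dosages = np.atleast_2d(np.asarray(dosages, float))
    if len(effects) == 0:
        return np.full(dosages.shape[0], disease.prevalence)
    if dosages.shape[1] != len(effects):
        raise ParameterError("dosage columns must match the causal set")
    f0 = baseline_risk(effects, disease)
    rrs = np.asarray(effects.rrs, float)
    risk = f0 * np.prod(_rr_factors(dosages, rrs[None, :]), axis=1)
    if np.any(risk >= 1) or np.any(risk <= 0):
        raise InfeasibleEffectError("individual risk outside (0, 1)")
    return risk


def sample_cohort(panel, effects, disease=DiseaseModel(), n_case=1500,
                  n_control=1500, seed=None, rho=None, theta=None,
                  max_draws=4_000_000):
    """Sample an ascertained case-control cohort from a haplotype panel.

    Individuals are diploids formed from two fresh mosaic haplotypes
    (Li & Stephens perturbation of the panel, no new columns); status is
    Bernoulli(individual risk), and sampling repeats until both quotas are
    filled.  For a null locus (no causal variants) labels are exchangeable,
    so individuals are drawn directly and split into the requested quotas.
    Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    defaults = ExpansionParams()
    rho = defaults.rho if rho is None else rho
    theta = defaults.theta if theta is None else theta
    n_total = n_case + n_control
    causal = np.asarray(effects.site_indices, int)

    def draw(n_ind):
        haps = _mosaic_batch(panel.haplotypes, panel.positions, 2 * n_ind,
                             rho, theta, rng)
        return (haps[0::2].astype(np.uint8) + haps[1::2].astype(np.uint8))

    if len(effects) == 0:
        geno = draw(n_total)
        phen = np.zeros(n_total, np.int8)
        phen[:n_case] = 1  # exchangeable under the null
        return _finalize(panel, geno, phen, causal)

    f0 = baseline_risk(effects, disease)
    rrs = np.asarray(effects.rrs, float)

    def risks(geno):
        return f0 * np.prod(_rr_factors(geno[:, causal].astype(float),
                                        rrs[None, :]), axis=1)

    # Ascertained sampling: the case pool is thinned with probability
    # proportional to the individual risk, the control pool with
    # probability proportional to 1 - risk; this reproduces exactly the
    # conditional genotype distributions P(g | case) and P(g | control) of
    # the Bernoulli-status scheme, and degrades gracefully (acceptance
    # clipped at 1, recorded) in the negligible tail where the
    # multiplicative model would exceed unit risk.
    case_g, ctrl_g = [], []
    need_case, need_ctrl = n_case, n_control
    drawn = 0
    n_clipped = 0
    scale = None
    batch = max(1024, int(1.2 * n_case / disease.prevalence / 4))
    while need_case > 0 or need_ctrl > 0:
        if drawn >= max_draws:
            raise ExhaustionError("case/control quotas unreachable within "
                                  f"{max_draws} sampled individuals")
        b = min(batch, max_draws - drawn)
        geno = draw(b)
        drawn += b
        risk = risks(geno)
        if scale is None:
            scale = max(1.0, 1.1 * float(risk.max()))
        p_case = risk / scale
        n_clipped += int(np.sum(p_case > 1))
        u = rng.random(b)
        if need_case > 0:
            take = np.flatnonzero(u < np.minimum(p_case, 1.0))[:need_case]
            case_g.append(geno[take])
            need_case -= take.size
        if need_ctrl > 0:
            take = np.flatnonzero(u >= np.minimum(risk, 1.0))[:need_ctrl]
            ctrl_g.append(geno[take])
            need_ctrl -= take.size
    geno = np.concatenate(case_g + ctrl_g, axis=0)
    phen = np.zeros(n_total, np.int8)
    phen[:n_case] = 1
    out = _finalize(panel, geno, phen, causal)
    out.diagnostics = {"draws": drawn, "risk_scale": scale,
                       "clipped": n_clipped}
    return out


def _finalize(panel, geno, phen, causal_indices):
    causal_mask = np.zeros(panel.n_sites, bool)
    causal_mask[causal_indices] = True
    f = geno.mean(axis=0) / 2.0
    keep = (f > 0) & (f < 1)  # drop sample-monomorphic columns
    return CohortDataset(geno[:, keep], phen, panel.positions[keep],
                         panel.exonic[keep], causal_mask[keep])


def causal_fraction_filter(dataset, fraction, seed=None, rare_maf=0.01):
    """Remove non-causal rare sites at random so that causal:total among
    retained MAF<``rare_maf`` sites equals ``fraction`` (closest achievable
    integer count).  All causal sites are always retained.

    If too few neutral sites exist to *reach* the fraction from above the
    dataset is returned with all neutral rare sites removed; if the fraction
    would require keeping more neutral sites than exist, the achieved ratio
    is reported via the returned dataset itself (no failure).
    """
    if not 0 < fraction <= 1:
        raise ParameterError("fraction must be in (0, 1]")
    if dataset.causal_mask.size != dataset.n_sites:
        raise ParameterError("dataset lacks a causal mask")
    rng = np.random.default_rng(seed)
    maf = dataset.maf
    rare = maf < rare_maf
    causal = dataset.causal_mask
    n_causal_rare = int((rare & causal).sum())
    neutral_rare = np.flatnonzero(rare & ~causal)
    if n_causal_rare == 0:
        return dataset
    n_total_target = int(round(n_causal_rare / fraction))
    n_neutral_keep = min(max(n_total_target - n_causal_rare, 0),
                         neutral_rare.size)
    kept_neutral = rng.choice(neutral_rare, size=n_neutral_keep,
                              replace=False) if n_neutral_keep else np.array([], int)
    drop = np.setdiff1d(neutral_rare, kept_neutral)
    keep = np.setdiff1d(np.arange(dataset.n_sites), drop)
    return dataset.subset_sites(keep)
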