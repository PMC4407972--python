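"""Genetic architectures: joint frequency-effect-size maps, liability-scale
variance explained, and sampling of causal-variant sets at a locus.

Six bundled architectures span the regimes of interest for a common
dichotomous trait (modeled on type 2 diabetes, prevalence 8%):

====  ==========================  ====================  =========
id    direction of effects        causal frequencies    selection
====  ==========================  ====================  =========
ar1   all risk-increasing         full spectrum         strong
ar2   all risk-increasing         full spectrum         moderate
ar3   all risk-increasing         full spectrum         weak
ar4   all risk-increasing         MAF < 1% only         strong
ar5   all risk-increasing         MAF < 1% only         moderate
ar6   50% risk / 50% protective   full spectrum         moderate
====  ==========================  ====================  =========

"Selection" controls the coupling between a variant's frequency and its
relative risk: under strong coupling rare variants carry large effects
(sharply inverse frequency-RR relation); under weak coupling effects are
frequency-independent.  The bundled maps are qualitative parametric
stand-ins for distributions that would otherwise come from forward
population-genetic simulation, which is out of scope here; any custom map
can be supplied as a weight grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (ExhaustionError, InfeasibleEffectError, NoSupportError,
                     ParameterError)

__all__ = [
    "FreqRRMap",
    "ArchitectureModel",
    "DiseaseModel",
    "LocusEffects",
    "default_architecture",
    "sample_rr",
    "variance_explained",
    "locus_ve",
    "sample_locus_effects",
]


@dataclass(frozen=True)
class DiseaseModel:
    """Dichotomous disease under a liability-threshold model.

    prevalence : population risk K (default 0.08, modeling type 2 diabetes).
    Effects are per-allele relative risks with additive dosage coding
    (het RR, hom 2*RR - 1).
    """

    prevalence: float = 0.08

    def __post_init__(self):
        if not 0 < self.prevalence < 1:
            raise ParameterError("prevalence must be in (0, 1)")


class FreqRRMap:
    """Sampling weights on a (MAF bin x RR bin) grid.

    The conditional relative-risk distribution at a given MAF is the
    normalized row of weights for the MAF bin containing it; RR values are
    drawn log-uniformly within the selected RR bin.
    """

    def __init__(self, maf_edges, rr_edges, weights):
        maf_edges = np.asarray(maf_edges, float)
        rr_edges = np.asarray(rr_edges, float)
        weights = np.asarray(weights, float)
        if np.any(np.diff(maf_edges) <= 0) or np.any(np.diff(rr_edges) <= 0):
            raise ParameterError("bin edges must be strictly increasing")
        if np.any(rr_edges <= 1.0):
            raise ParameterError("RR bins describe risk effects and must exceed 1")
        if weights.shape != (maf_edges.size - 1, rr_edges.size - 1):
            raise ParameterError("weights shape must be (n_maf_bins, n_rr_bins)")
        if np.any(weights < 0):
            raise ParameterError("weights must be non-negative")
        self.maf_edges = maf_edges
        self.rr_edges = rr_edges
        self.weights = weights

    def maf_bin(self, maf):
        if not 0 < maf <= 0.5:
            raise ParameterError("maf must be in (0, 0.5]")
        b = int(np.digitize(maf, self.maf_edges, right=True)) - 1
        if maf <= self.maf_edges[0] and maf > 0:
            b = 0  # frequencies below the lowest edge use the rarest bin
        if b < 0 or b >= self.weights.shape[0]:
            return -1
        return b

    def has_support(self, maf):
        b = self.maf_bin(maf)
        return b >= 0 and self.weights[b].sum() > 0

    def conditional(self, maf):
        """Normalized RR-bin probabilities at ``maf``."""
        b = self.maf_bin(maf)
        if b < 0 or self.weights[b].sum() <= 0:
            raise NoSupportError(f"map has no support at MAF {maf:g}")
        w = self.weights[b]
        return w / w.sum()

    def restricted(self, max_maf):
        """Copy of the map with zero weight above ``max_maf``."""
        w = self.weights.copy()
        w[self.maf_edges[1:] > max_maf + 1e-12, :] = 0.0
        return FreqRRMap(self.maf_edges, self.rr_edges, w)


@dataclass(frozen=True)
class ArchitectureModel:
    """A frequency-RR map plus direction mixture and MAF restriction."""

    id: str
    map: FreqRRMap
    maf_restriction: float = 0.5      # causal variants must have MAF <= this
    direction_mix: float = 0.0        # fraction of protective draws
    selection: str = "moderate"

    def __post_init__(self):
        if not 0 <= self.direction_mix <= 1:
            raise ParameterError("direction_mix must be in [0, 1]")


def _parametric_map(coupling, amplitude, sigma=0.3, n_maf=24, n_rr=40,
                    maf_range=(2e-5, 0.5), rr_range=(1.02, 5.0)):
    """Log-normal RR distribution per MAF bin whose mode follows
    1 + amplitude * (maf / 0.005) ** -coupling (anchored so a MAF 0.5%
    variant has modal RR = 1 + amplitude)."""
    maf_edges = np.geomspace(maf_range[0], maf_range[1], n_maf + 1)
    rr_edges = 1 + np.geomspace(rr_range[0] - 1, rr_range[1] - 1, n_rr + 1)
    m_mid = np.sqrt(maf_edges[:-1] * maf_edges[1:])
    r_mid = 1 + np.sqrt((rr_edges[:-1] - 1) * (rr_edges[1:] - 1))
    mode = 1 + amplitude * (m_mid / 0.005) ** (-coupling)
    mode = np.clip(mode, rr_edges[0], rr_edges[-1])
    w = stats.norm.pdf(np.log(r_mid[None, :] - 1),
                       loc=np.log(mode[:, None] - 1), scale=sigma)
    return FreqRRMap(maf_edges, rr_edges, w)


_AR_PARAMS = {
    # id: (coupling, amplitude, maf restriction, protective fraction, label)
    # Amplitudes anchor the modal RR of a MAF 0.5% variant at 1 + amplitude;
    # coupling sets how fast effects shrink toward common frequencies, so
    # that common causal variants keep the modest relative risks seen for
    # complex-trait loci (RR ~ 1.1-1.3) and joint multiplicative risks stay
    # below 1.
    "ar1": (0.60, 2.0, 0.5, 0.0, "strong"),
    "ar2": (0.45, 1.2, 0.5, 0.0, "moderate"),
    "ar3": (0.00, 0.5, 0.5, 0.0, "weak"),
    "ar4": (0.60, 2.0, 0.01, 0.0, "strong"),
    "ar5": (0.45, 1.2, 0.01, 0.0, "moderate"),
    "ar6": (0.45, 1.2, 0.5, 0.5, "moderate"),
}


def default_architecture(arch_id):
    """One of the six bundled architecture models (``'ar1'``..``'ar6'``)."""
    key = arch_id.lower()
    if key not in _AR_PARAMS:
        raise ParameterError(f"unknown architecture {arch_id!r}")
    coupling, amp, maxmaf, mix, label = _AR_PARAMS[key]
    m = _parametric_map(coupling, amp)
    if maxmaf < 0.5:
        m = m.restricted(maxmaf)
    return ArchitectureModel(id=key, map=m, maf_restriction=maxmaf,
                             direction_mix=mix, selection=label)


def sample_rr(maf, arch, seed=None, rng=None):
    """Draw a per-allele relative risk at ``maf`` from the architecture's
    conditional distribution.  With probability ``direction_mix`` the effect
    is protective and the drawn RR is inverted (RR -> 1/RR)."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    if maf > arch.maf_restriction + 1e-12 or not arch.map.has_support(maf):
        raise NoSupportError(
            f"architecture {arch.id} has no support at MAF {maf:g}")
    probs = arch.map.conditional(maf)
    b = rng.choice(probs.size, p=probs)
    lo, hi = arch.map.rr_edges[b], arch.map.rr_edges[b + 1]
    rr = 1 + np.exp(rng.uniform(np.log(lo - 1), np.log(hi - 1)))
    if arch.direction_mix > 0 and rng.random() < arch.direction_mix:
        return 1.0 / rr
    return rr


def _penetrances(maf, rr, disease):
    """Genotype penetrances under HWE and additive RR coding, solved so the
    population risk equals the prevalence."""
    q = maf
    p0, p1, p2 = (1 - q) ** 2, 2 * q * (1 - q), q * q
    rr_hom = 2 * rr - 1
    denom = p0 + p1 * rr + p2 * rr_hom
    if denom <= 0:
        raise InfeasibleEffectError("no baseline risk solves the prevalence")
    f0 = disease.prevalence / denom
    f = np.array([f0, rr * f0, rr_hom * f0])
    if np.any(f <= 0) or np.any(f >= 1):
        raise InfeasibleEffectError(
            f"penetrances outside (0,1) for maf={maf:g}, rr={rr:g}")
    return np.array([p0, p1, p2]), f


def variance_explained(maf, rr, disease=DiseaseModel()):
    """Liability-scale variance explained by one biallelic variant.

    Each genotype class is assigned a unit-variance normal liability whose
    mean reproduces its penetrance against the population threshold at
    1 - K; the between-genotype variance Vg is reported as the fraction
    Vg / (1 + Vg) of total liability variance.
    """
    if not 0 < maf <= 0.5:
        raise ParameterError("maf must be in (0, 0.5]")
    if rr <= 0:
        raise ParameterError("rr must be positive")
    if rr == 1.0:
        return 0.0
    pg, f = _penetrances(maf, rr, disease)
    thr = stats.norm.isf(disease.prevalence)
    mu = thr - stats.norm.isf(f)
    mean = float(pg @ mu)
    vg = float(pg @ mu**2) - mean**2
    return vg / (1.0 + vg)


def locus_ve(effects, disease=DiseaseModel()):
    """Total liability-scale VE of a causal set, assuming independence
    between variants (sum of per-variant contributions)."""
    return float(sum(variance_explained(m, r, disease)
                     for m, r in zip(effects.mafs, effects.rrs)))


@dataclass
class LocusEffects:
    """An accepted causal-variant set for one locus."""

    site_indices: list
    rrs: list                 # per-allele RR; < 1 encodes a protective effect
    mafs: list                # panel MAF of each causal variant
    achieved_ve: float
    target_ve: float
    cap: int = 35

    @property
    def directions(self):
        return ["protective" if r < 1 else "risk" for r in self.rrs]

    def __len__(self):
        return len(self.site_indices)


def sample_locus_effects(panel, arch, target_ve, disease=DiseaseModel(),
                         seed=None, cap=35, window=(0.95, 1.05),
                         max_restarts=1000):
    """Sample causal effects at exonic panel variants until the cumulative
    liability-scale VE lands inside ``window`` times the target.

    The accept/reject loop: pick an exonic variant at random, draw its RR
    from the architecture map; while cumulative VE is below the window keep
    adding; when above, remove one introduced effect uniformly at random; on
    acceptance, restart from scratch if more than ``cap`` variants were
    introduced.  Raises :class:`ExhaustionError` after ``max_restarts``.
    """
    if target_ve <= 0:
        raise ParameterError("target_ve must be positive")
    rng = np.random.default_rng(seed)
    maf = panel.maf
    exonic_idx = np.flatnonzero(panel.exonic)
    candidates = [i for i in exonic_idx
                  if maf[i] <= arch.maf_restriction + 1e-12
                  and arch.map.has_support(maf[i])]
    if not candidates:
        raise NoSupportError("panel has no exonic variants inside the "
                             "architecture's support")
    lo, hi = window[0] * target_ve, window[1] * target_ve

    for _ in range(max_restarts):
        chosen: dict[int, tuple[float, float]] = {}  # index -> (rr, ve)
        total = 0.0
        stuck = 0
        steps = 0
        while True:
            steps += 1
            if steps > 10000:
                break  # add/remove cycle is not converging; restart
            if total < lo:
                if len(chosen) == len(candidates) or stuck > 200:
                    break  # cannot reach the target from here; restart
                i = int(candidates[rng.integers(len(candidates))])
                if i in chosen:
                    stuck += 1
                    continue
                try:
                    rr = sample_rr(maf[i], arch, rng=rng)
                    ve = variance_explained(maf[i], rr, disease)
                except InfeasibleEffectError:
                    stuck += 1
                    continue
                chosen[i] = (rr, ve)
                total += ve
                stuck = 0
            elif total > hi:
                drop = list(chosen)[rng.integers(len(chosen))]
                total -= chosen.pop(drop)[1]
            else:
                if len(chosen) > cap:
                    break  # quit and restart
                achieved = float(sum(v for _, v in chosen.values()))
                if not lo <= achieved <= hi:  # guard against drift of the
                    total = achieved          # running float total
                    continue
                idx = sorted(chosen)
                return LocusEffects(
                    site_indices=idx,
                    rrs=[chosen[i][0] for i in idx],
                    mafs=[float(maf[i]) for i in idx],
                    achieved_ve=achieved, target_ve=target_ve, cap=cap)
    raise ExhaustionError(
        f"no acceptable causal set within {max_restarts} restarts")
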