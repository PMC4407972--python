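"""Phased haplotype reference panels: simulation, Li & Stephens expansion,
site-frequency-spectrum calibration, and LD validation.

The panel is the substrate for every downstream simulation.  A base panel of a
few hundred individuals is produced by coalescent simulation (msprime), then
iteratively expanded to many thousands of individuals by sampling imperfect
mosaics of the existing haplotypes under a hidden-Markov copying model with
mutation parameter ``theta``.  Copying errors at currently-monomorphic exonic
positions introduce new singleton columns, producing the excess of rare
variation seen in large exome-sequencing samples; a final rejection-sampling
thinning step matches a target exome-like site frequency spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import msprime
import numpy as np
import pandas as pd

from .errors import InfeasibleSFSError, ParameterError

__all__ = [
    "VariantSite",
    "HaplotypePanel",
    "SFSTarget",
    "ExpansionParams",
    "simulate_base_panel",
    "mosaic_haplotype",
    "mosaic_haplotypes",
    "expand_panel",
    "thin_to_sfs",
    "sfs",
    "ld_profile",
    "subsample_individuals",
    "default_exome_sfs_target",
    "exome_calibrated_panel",
]


@dataclass(frozen=True)
class VariantSite:
    """One biallelic site in a panel.  Allele coding: 0 = major, 1 = minor
    (as of panel construction; drift during expansion may flip minority)."""

    index: int
    position: int
    exonic: bool
    panel_maf: float


@dataclass(frozen=True)
class ExpansionParams:
    """Parameters of the iterative Li & Stephens panel expansion.

    theta
        Population-scaled mutation parameter of the copying model (the
        HAPGEN2 convention); governs both per-site copy error and the rate at
        which new singleton columns appear at exonic positions.
    rho
        Per-bp recombination intensity of the copying model.
    increment
        Individuals added per iteration.
    target_n
        Final number of individuals in the expanded panel.
    """

    theta: float = 0.08
    rho: float = 1e-3
    increment: int = 300
    target_n: int = 12514

    def __post_init__(self):
        if self.theta <= 0:
            raise ParameterError("theta must be positive")
        if self.increment < 1:
            raise ParameterError("increment must be >= 1")
        if self.target_n < 1:
            raise ParameterError("target_n must be >= 1")


@dataclass(frozen=True)
class SFSTarget:
    """A binned minor-allele-frequency spectrum to thin a panel towards.

    ``edges`` are ascending MAF bin edges covering (edges[0], edges[-1]];
    ``proportions`` (one per bin) sum to 1.  ``total_per_kb`` optionally fixes
    the retained variant density (variants per kb of simulated region).
    """

    edges: tuple
    proportions: tuple
    total_per_kb: float | None = None

    def __post_init__(self):
        edges = np.asarray(self.edges, float)
        props = np.asarray(self.proportions, float)
        if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
            raise ParameterError("edges must be ascending with >= 2 values")
        if props.size != edges.size - 1:
            raise ParameterError("need one proportion per bin")
        if np.any(props < 0) or abs(props.sum() - 1.0) > 1e-9:
            raise ParameterError("proportions must be >= 0 and sum to 1")

    def bin_of(self, maf):
        """Bin index for each MAF (-1 if outside the covered range)."""
        maf = np.asarray(maf, float)
        idx = np.digitize(maf, self.edges, right=True) - 1
        idx[(maf <= self.edges[0]) | (maf > self.edges[-1])] = -1
        return idx


class HaplotypePanel:
    """Phased binary haplotypes over an ordered list of variant sites.

    haplotypes : uint8 array, rows = haplotypes (2 per individual), columns =
    sites.  Every column is polymorphic; positions are strictly increasing
    0-based bp on a synthetic contig of length ``region_length``.
    """

    def __init__(self, haplotypes, positions, exonic, region_length,
                 exon_intervals, provenance="base"):
        haplotypes = np.ascontiguousarray(haplotypes, dtype=np.uint8)
        positions = np.asarray(positions, dtype=np.int64)
        exonic = np.asarray(exonic, dtype=bool)
        if haplotypes.ndim != 2:
            raise ParameterError("haplotypes must be 2-D")
        if haplotypes.shape[0] % 2 != 0:
            raise ParameterError("haplotype row count must be even")
        if haplotypes.shape[1] != positions.size or positions.size != exonic.size:
            raise ParameterError("site annotation length mismatch")
        if positions.size > 1 and np.any(np.diff(positions) <= 0):
            raise ParameterError("positions must be strictly increasing")
        freq = haplotypes.mean(axis=0) if haplotypes.size else np.empty(0)
        if haplotypes.size and (np.any(freq == 0) or np.any(freq == 1)):
            raise ParameterError("monomorphic columns are not allowed")
        self.haplotypes = haplotypes
        self.positions = positions
        self.exonic = exonic
        self.region_length = int(region_length)
        self.exon_intervals = [(int(a), int(b)) for a, b in exon_intervals]
        self.provenance = provenance

    # -- basic accessors ---------------------------------------------------
    @property
    def n_haplotypes(self):
        return self.haplotypes.shape[0]

    @property
    def n_individuals(self):
        return self.haplotypes.shape[0] // 2

    @property
    def n_sites(self):
        return self.haplotypes.shape[1]

    @property
    def allele_freq(self):
        """Frequency of the 1-coded allele per column."""
        return self.haplotypes.mean(axis=0)

    @property
    def maf(self):
        f = self.allele_freq
        return np.minimum(f, 1.0 - f)

    @property
    def sites(self):
        maf = self.maf
        return [VariantSite(i, int(p), bool(e), float(m))
                for i, (p, e, m) in enumerate(zip(self.positions, self.exonic, maf))]

    def select_sites(self, keep, provenance=None):
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        keep = np.sort(keep)
        return HaplotypePanel(self.haplotypes[:, keep], self.positions[keep],
                              self.exonic[keep], self.region_length,
                              self.exon_intervals,
                              provenance or self.provenance)

    def _canonical(self):
        """Flip columns so the 1 allele is the minor allele (ties kept)."""
        flip = self.haplotypes.mean(axis=0) > 0.5
        if flip.any():
            self.haplotypes[:, flip] = 1 - self.haplotypes[:, flip]
        return self


def _exon_intervals(region_length, exon_fraction, n_blocks=3):
    """Evenly spaced contiguous exon blocks covering ``exon_fraction`` of the
    region, mimicking the exonic portion of an average coding gene."""
    if not (0 < exon_fraction <= 1):
        raise ParameterError("exon_fraction must be in (0, 1]")
    if exon_fraction == 1:
        return [(0, int(region_length))]
    n_blocks = max(1, min(n_blocks, int(region_length * exon_fraction // 50) or 1))
    block = region_length * exon_fraction / n_blocks
    gap = region_length * (1 - exon_fraction) / (n_blocks + 1)
    out = []
    for i in range(n_blocks):
        start = gap * (i + 1) + block * i
        out.append((int(round(start)), int(round(start + block))))
    return out


def _in_intervals(positions, intervals):
    positions = np.asarray(positions)
    mask = np.zeros(positions.shape, bool)
    for a, b in intervals:
        mask |= (positions >= a) & (positions < b)
    return mask


def simulate_base_panel(n_individuals=379, region_length_bp=3000,
                        exon_fraction=0.5, theta=2e-3, rho=1e-3, seed=None):
    """Simulate a phased base reference panel by neutral coalescent.

    ``theta`` and ``rho`` are population-scaled per-bp rates (4*Ne*mu and
    4*Ne*r).  The output has LD decaying with distance and a rare-skewed SFS;
    exonic flags mark contiguous blocks covering ``exon_fraction`` of the
    region.  Deterministic for a fixed seed.
    """
    if n_individuals < 2 or region_length_bp <= 0:
        raise ParameterError("need n_individuals >= 2 and a positive region length")
    if theta <= 0 or rho < 0:
        raise ParameterError("theta must be > 0 and rho >= 0")
    ne = 1e4
    if seed is None:
        seed = int(np.random.default_rng().integers(2**31 - 3))
    seed = int(seed) % (2**31 - 3)
    ts = msprime.sim_ancestry(
        samples=n_individuals, ploidy=2, population_size=ne,
        sequence_length=region_length_bp, recombination_rate=rho / (4 * ne),
        random_seed=seed + 1)
    ts = msprime.sim_mutations(ts, rate=theta / (4 * ne), random_seed=seed + 2)
    geno = []
    positions = []
    seen = set()
    for var in ts.variants():
        g = var.genotypes
        pos = int(var.site.position)
        if len(var.alleles) != 2 or pos in seen:
            continue  # keep the model biallelic on a discrete grid
        if g.min() == g.max():
            continue
        seen.add(pos)
        positions.append(pos)
        geno.append(g.astype(np.uint8))
    order = np.argsort(positions)
    haps = np.asarray(geno, dtype=np.uint8)[order].T
    positions = np.asarray(positions, dtype=np.int64)[order]
    intervals = _exon_intervals(region_length_bp, exon_fraction)
    exonic = _in_intervals(positions, intervals)
    panel = HaplotypePanel(haps, positions, exonic, region_length_bp,
                           intervals, provenance="base")
    return panel._canonical()


# -- Li & Stephens mosaic copying -----------------------------------------

def _mosaic_batch(haplotypes, positions, n_new, rho, theta, rng,
                  return_paths=False):
    """Simulate ``n_new`` haplotypes as hidden-Markov mosaics of the rows of
    ``haplotypes``.  Template switches occur between adjacent sites with
    probability 1 - exp(-rho * d / H); each site is copied with error
    probability theta/2 / (H + theta)."""
    H, S = haplotypes.shape
    if H == 0 or S == 0:
        raise ParameterError("cannot build mosaics from an empty panel")
    d = np.diff(positions)
    p_switch = -np.expm1(-rho * d / H)
    eps = 0.5 * theta / (H + theta)
    # Template index per (row, site): new uniform template at the start and at
    # every switch event, carried forward otherwise.
    switch = np.empty((n_new, S), dtype=bool)
    switch[:, 0] = True
    switch[:, 1:] = rng.random((n_new, S - 1)) < p_switch
    proposal = rng.integers(0, H, size=(n_new, S))
    cols = np.arange(S)
    last = np.where(switch, cols, 0)
    np.maximum.accumulate(last, axis=1, out=last)
    templates = np.take_along_axis(proposal, last, axis=1)
    out = haplotypes[templates, cols]
    if eps > 0:
        err = rng.random((n_new, S)) < eps
        out = out ^ err
    if return_paths:
        return out.astype(np.uint8), templates
    return out.astype(np.uint8)


def mosaic_haplotypes(panel, n, rho=None, theta=None, seed=None,
                      return_paths=False):
    """Batch of ``n`` mosaic haplotypes copied from ``panel`` (no new
    columns are introduced; see :func:`expand_panel` for that)."""
    rng = np.random.default_rng(seed)
    rho = ExpansionParams().rho if rho is None else rho
    theta = ExpansionParams().theta if theta is None else theta
    return _mosaic_batch(panel.haplotypes, panel.positions, n, rho, theta,
                         rng, return_paths=return_paths)


def mosaic_haplotype(panel, rho=None, theta=None, seed=None,
                     return_path=False):
    """One new haplotype built by the Li & Stephens copying model."""
    res = mosaic_haplotypes(panel, 1, rho=rho, theta=theta, seed=seed,
                            return_paths=return_path)
    if return_path:
        return res[0][0], res[1][0]
    return res[0]


def expand_panel(panel, params=None, seed=None):
    """Iteratively append mosaic haplotypes (``increment`` individuals per
    iteration) until the panel holds ``target_n`` individuals.

    No phenotype effects are involved.  New minor alleles arise at
    previously-monomorphic exonic positions: each candidate exonic bp mutates
    with the same per-site copy-error rate as segregating sites, creating new
    singleton columns whose frequency can then drift as later haplotypes copy
    them.
    """
    params = params or ExpansionParams()
    if params.target_n < panel.n_individuals:
        raise ParameterError("target_n is smaller than the current panel")
    rng = np.random.default_rng(seed)

    haps = panel.haplotypes
    positions = panel.positions.copy()
    exonic = panel.exonic.copy()
    exon_pos = np.concatenate([np.arange(a, b) for a, b in panel.exon_intervals])
    free = np.setdiff1d(exon_pos, positions, assume_unique=False)

    n_ind = panel.n_individuals
    while n_ind < params.target_n:
        add_ind = min(params.increment, params.target_n - n_ind)
        b = 2 * add_ind
        H = haps.shape[0]
        new = _mosaic_batch(haps, positions, b, params.rho, params.theta, rng)
        # new singleton mutations at free exonic positions
        eps = 0.5 * params.theta / (H + params.theta)
        lam = eps * free.size
        counts = rng.poisson(lam, b)
        total = int(min(counts.sum(), free.size))
        if total > 0:
            mut_pos = rng.choice(free, size=total, replace=False)
            owners = np.repeat(np.arange(b), counts)[:total]
            free = np.setdiff1d(free, mut_pos, assume_unique=False)
            old_cols = np.zeros((H, total), dtype=np.uint8)
            new_cols = np.zeros((b, total), dtype=np.uint8)
            new_cols[owners, np.arange(total)] = 1
            haps = np.concatenate([np.concatenate([haps, old_cols], axis=1),
                                   np.concatenate([new, new_cols], axis=1)],
                                  axis=0)
            positions = np.concatenate([positions, mut_pos])
            exonic = np.concatenate([exonic, np.ones(total, bool)])
            order = np.argsort(positions, kind="stable")
            haps = haps[:, order]
            positions = positions[order]
            exonic = exonic[order]
        else:
            haps = np.concatenate([haps, new], axis=0)
        n_ind += add_ind

    out = HaplotypePanel(haps, positions, exonic, panel.region_length,
                         panel.exon_intervals, provenance="expanded")
    return out._canonical()


# -- SFS calibration -------------------------------------------------------

def sfs(panel, bins, by="maf"):
    """Binned site frequency spectrum of a panel.

    ``bins`` are ascending edges on MAF (``by='maf'``, bins are
    (lo, hi]-open-low) or on minor allele count (``by='count'``, inclusive of
    the upper edge).  Returns a DataFrame with per-bin counts and proportions.
    """
    bins = np.asarray(bins, float)
    if bins.size < 2:
        raise ParameterError("need at least two bin edges")
    if panel.n_sites == 0:
        raise ParameterError("panel has no sites")
    if by == "maf":
        values = panel.maf
        idx = np.digitize(values, bins, right=True) - 1
        idx[(values <= bins[0]) | (values > bins[-1])] = -1
    elif by == "count":
        f = panel.allele_freq
        values = np.rint(np.minimum(f, 1 - f) * panel.n_haplotypes)
        idx = np.digitize(values, bins, right=False) - 1  # [lo, hi) bins
        idx[values == bins[-1]] = bins.size - 2
        idx[(values < bins[0]) | (values > bins[-1])] = -1
    else:
        raise ParameterError("by must be 'maf' or 'count'")
    counts = np.bincount(idx[idx >= 0], minlength=bins.size - 1)
    total = counts.sum()
    return pd.DataFrame({
        "lower": bins[:-1], "upper": bins[1:], "count": counts,
        "proportion": counts / total if total else np.zeros_like(counts, float),
    })


def default_exome_sfs_target(n_haplotypes, alpha=1.6, total_per_kb=27.0):
    """Bundled exome-like SFS target: a power-law spectrum on minor allele
    count (P(MAC=k) proportional to k**-alpha) binned into standard rare /
    low-frequency / common classes.

    The default density ``total_per_kb`` was calibrated once so that an
    average-coding-length locus (~1.5 kb exonic) yields a median of ~38
    segregating MAF<1% exonic variants in a 3,000-individual sample drawn
    from the thinned panel.
    """
    N = int(n_haplotypes)
    kmax = N // 2
    k = np.arange(1, kmax + 1)
    pk = k.astype(float) ** -alpha
    pk /= pk.sum()
    count_edges = np.array([1, 2, 3, 6, 11, max(12, int(0.001 * N)),
                            int(0.01 * N), int(0.05 * N), kmax])
    count_edges = np.unique(count_edges)
    props = []
    for lo, hi in zip(count_edges[:-1], count_edges[1:]):
        props.append(pk[(k >= lo) & (k < hi)].sum())
    props[-1] += pk[k == count_edges[-1]].sum()
    props = np.asarray(props)
    props /= props.sum()
    # convert count edges to MAF edges, half-open (lo, hi]
    maf_edges = np.concatenate([[0.25 / N], (count_edges[1:] - 0.5) / N])
    maf_edges[-1] = 0.5
    return SFSTarget(tuple(maf_edges), tuple(props), total_per_kb=total_per_kb)


def thin_to_sfs(panel, target, seed=None, strict=False):
    """Remove whole variant columns by rejection sampling so the retained
    spectrum matches ``target`` per-bin proportions.

    Never edits genotypes within retained columns.  With ``strict=True`` a
    target that would require *adding* variants to some bin (given its
    requested total density) raises :class:`InfeasibleSFSError`; otherwise the
    total is clipped to the feasible maximum.
    """
    rng = np.random.default_rng(seed)
    maf = panel.maf
    bin_idx = target.bin_of(maf)
    nbins = len(target.proportions)
    counts = np.bincount(bin_idx[bin_idx >= 0], minlength=nbins)
    props = np.asarray(target.proportions, float)

    # Largest total n such that every bin's (rounded) allocation fits in
    # its available count; bins whose target rounds to zero don't bind.
    with np.errstate(divide="ignore", invalid="ignore"):
        feas = np.where(props > 0, (counts + 0.5 - 1e-9) / props, np.inf)
    n_max = int(np.floor(feas.min())) if np.isfinite(feas.min()) else int(counts.sum())
    n_max = min(n_max, int(counts.sum()))
    if target.total_per_kb is not None:
        n_req = int(round(target.total_per_kb * panel.region_length / 1000.0))
        if n_req > n_max and strict:
            raise InfeasibleSFSError(
                f"target needs {n_req} variants but proportions only allow {n_max}")
        n_total = min(n_req, n_max)
    else:
        n_total = n_max
    if n_total <= 0:
        raise InfeasibleSFSError("no variant allocation satisfies the target")

    # largest-remainder apportionment of n_total across bins
    raw = props * n_total
    keep_n = np.floor(raw).astype(int)
    rem = raw - keep_n
    short = n_total - keep_n.sum()
    for b in np.argsort(-rem)[:short]:
        keep_n[b] += 1
    keep_n = np.minimum(keep_n, counts)

    keep = []
    for b in range(nbins):
        members = np.flatnonzero(bin_idx == b)
        if keep_n[b] >= members.size:
            keep.append(members)
        elif keep_n[b] > 0:
            keep.append(rng.choice(members, size=keep_n[b], replace=False))
    keep = np.sort(np.concatenate(keep)) if keep else np.array([], int)
    return panel.select_sites(keep, provenance="thinned")


# -- validation metrics ----------------------------------------------------

def ld_profile(panel, maf_bins=(0.0, 0.05, 0.5), distance_bins=None):
    """Mean pairwise r^2 within MAF strata, binned by inter-site distance.

    Returns a tidy DataFrame; cells with no pairs carry NaN.
    """
    maf_bins = np.asarray(maf_bins, float)
    if distance_bins is None:
        distance_bins = np.linspace(0, panel.region_length, 7)
    distance_bins = np.asarray(distance_bins, float)
    maf = panel.maf
    rows = []
    for mlo, mhi in zip(maf_bins[:-1], maf_bins[1:]):
        in_bin = np.flatnonzero((maf > mlo) & (maf <= mhi))
        if in_bin.size >= 2:
            sub = panel.haplotypes[:, in_bin].astype(float)
            r = np.corrcoef(sub.T)
            r2 = r ** 2
            pos = panel.positions[in_bin]
            iu = np.triu_indices(in_bin.size, k=1)
            dists = np.abs(pos[iu[0]] - pos[iu[1]])
            vals = r2[iu]
            ok = np.isfinite(vals)
            dists, vals = dists[ok], vals[ok]
        else:
            dists = np.array([]); vals = np.array([])
        which = np.digitize(dists, distance_bins, right=True) - 1
        for d in range(distance_bins.size - 1):
            sel = which == d
            rows.append({
                "maf_lo": mlo, "maf_hi": mhi,
                "dist_lo": distance_bins[d], "dist_hi": distance_bins[d + 1],
                "mean_r2": float(vals[sel].mean()) if sel.any() else np.nan,
                "n_pairs": int(sel.sum()),
            })
    return pd.DataFrame(rows)


def subsample_individuals(panel, n, seed=None):
    """Panel restricted to ``n`` individuals sampled without replacement;
    columns monomorphic in the subsample are dropped."""
    if n > panel.n_individuals:
        raise ParameterError("cannot subsample more individuals than present")
    rng = np.random.default_rng(seed)
    ind = rng.choice(panel.n_individuals, size=n, replace=False)
    rows = np.sort(np.concatenate([2 * ind, 2 * ind + 1]))
    haps = panel.haplotypes[rows]
    f = haps.mean(axis=0)
    keep = (f > 0) & (f < 1)
    out = HaplotypePanel(haps[:, keep], panel.positions[keep],
                         panel.exonic[keep], panel.region_length,
                         panel.exon_intervals, provenance=panel.provenance)
    return out._canonical()


def exome_calibrated_panel(seed=None, n_base=379, region_length_bp=3000,
                           exon_fraction=0.5, params=None, sfs_target=None):
    """Full panel pipeline: coalescent base panel -> Li & Stephens expansion
    (theta = 0.08, increments of 300 individuals) -> thinning to the bundled
    exome-like SFS target."""
    ss = np.random.SeedSequence(seed)
    s1, s2, s3 = ss.spawn(3)
    params = params or ExpansionParams()
    base = simulate_base_panel(n_base, region_length_bp, exon_fraction,
                               seed=int(s1.generate_state(1)[0] % (2**31 - 1)))
    big = expand_panel(base, params, seed=s2)
    if sfs_target is None:
        sfs_target = default_exome_sfs_target(big.n_haplotypes)
    return thin_to_sfs(big, sfs_target, seed=s3)
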