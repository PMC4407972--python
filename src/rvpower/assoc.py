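"""Gene-based rare-variant association tests and single-variant Fisher
association, behind a uniform interface.

Eleven gene-based tests are implemented from their published definitions:

* collapsing regression: CMC
* weighted / unweighted sums: VT, FRQWGT, WILCOX-WSS, KBAC
* summary count permutation tests: BURDEN, UNIQ
* variance-component tests: C-ALPHA, SKAT
* combined burden + variance-component tests: SKAT-O, MIST

plus two-sided Fisher's exact per single variant (locus summary = minimum
p).  All permutation tests exchange case/control labels, use the +1
small-sample correction, escalate adaptively, and switch to exhaustive
enumeration automatically when the label-assignment space is small.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy import stats

from .errors import NoQualifyingVariantsError, ParameterError
from .quadform import (liu_params, liu_quantile, moment_adjusted_sf,
                       permutation_quadform_moments)

__all__ = [
    "TestSpec",
    "TestResult",
    "TEST_NAMES",
    "maf_filter",
    "run_test",
    "run_test_battery",
]

TEST_NAMES = ("CMC", "VT", "FRQWGT", "WILCOX-WSS", "KBAC", "BURDEN", "UNIQ",
              "C-ALPHA", "SKAT", "SKAT-O", "MIST", "SINGLE-FISHER")

#: tests whose permutation statistic is one-sided towards case enrichment
ONE_SIDED = ("BURDEN", "UNIQ", "KBAC", "FRQWGT")


@dataclass(frozen=True)
class TestSpec:
    """Shared configuration of the test battery.

    maf_threshold : strict upper MAF bound for inclusion in gene-based
        tests (sample MAF from cases + controls combined).
    n_permutations : adaptive escalation cap.
    initial_permutations : first adaptive stage.
    beta_weights : Beta-density MAF weight parameters for SKAT-family tests;
        ``flat_weights`` replaces them with unit weights.
    rho_grid : SKAT-O burden/variance-component mixing grid.
    """

    maf_threshold: float = 0.01
    n_permutations: int = 1_000_000
    initial_permutations: int = 1000
    beta_weights: tuple = (1.0, 25.0)
    flat_weights: bool = False
    rho_grid: tuple = (0.0, 0.01, 0.04, 0.09, 0.16, 0.25, 1.0)

    __test__ = False  # not a pytest class, despite the name

    def __post_init__(self):
        if not 0 < self.maf_threshold <= 0.5:
            raise ParameterError("maf_threshold must be in (0, 0.5]")
        if self.n_permutations < 100:
            raise ParameterError("n_permutations must be >= 100")


@dataclass
class TestResult:
    """Outcome of one test on one dataset."""

    __test__ = False  # not a pytest class, despite the name

    test: str
    p_value: float
    statistic: float
    n_variants: int
    diagnostics: dict = field(default_factory=dict)


def maf_filter(dataset, threshold):
    """Indices of sites with sample MAF strictly below ``threshold``
    (computed from the full case + control sample)."""
    return np.flatnonzero(dataset.maf < threshold)


def _minor_dosage(dataset, idx):
    """Minor-allele dosage matrix (individuals x selected sites), float."""
    g = dataset.genotypes[:, idx].astype(np.float64)
    flip = ~dataset.minor_is_alt[idx]
    g[:, flip] = 2.0 - g[:, flip]
    return g


def _rare_matrix(dataset, spec):
    idx = maf_filter(dataset, spec.maf_threshold)
    if idx.size == 0:
        raise NoQualifyingVariantsError(
            f"no variant with MAF < {spec.maf_threshold}")
    return _minor_dosage(dataset, idx), idx


def _weights(maf, spec):
    if spec.flat_weights:
        return np.ones_like(maf)
    a, b = spec.beta_weights
    return stats.beta.pdf(maf, a, b)


# ---------------------------------------------------------------------------
# permutation engine
# ---------------------------------------------------------------------------

_EXHAUSTIVE_LIMIT = 5000


def _label_columns(y, assignments):
    n = y.size
    cols = np.zeros((n, len(assignments)), dtype=np.float64)
    for j, rows in enumerate(assignments):
        cols[list(rows), j] = 1.0
    return cols


def _perm_pvalue(stat_fn, observed, y, rng, spec, chunk=1000):
    """One-sided (greater) permutation p-value of ``observed``.

    ``stat_fn`` maps an (n x b) matrix of permuted 0/1 case labels to a
    length-b statistic vector.  Uses exhaustive enumeration of case
    assignments when feasible, otherwise adaptive Monte Carlo with the +1
    correction (p >= 1/(B+1))."""
    n, k = y.size, int(y.sum())
    tol = 1e-9 * max(1.0, abs(observed))
    if comb(n, k) <= _EXHAUSTIVE_LIMIT:
        assignments = list(itertools.combinations(range(n), k))
        vals = stat_fn(_label_columns(y, assignments))
        p = float(np.mean(vals >= observed - tol))
        return p, len(assignments), True

    done = 0
    count_ge = 0
    target = spec.initial_permutations
    while True:
        while done < target:
            b = min(chunk, target - done)
            keys = rng.random((b, n), dtype=np.float32)
            idx = np.argpartition(keys, k, axis=1)[:, :k]
            perm = np.zeros((b, n))
            np.put_along_axis(perm, idx, 1.0, axis=1)
            perm = perm.T
            vals = stat_fn(perm)
            count_ge += int(np.sum(vals >= observed - tol))
            done += b
        p = (1 + count_ge) / (done + 1)
        if done >= spec.n_permutations or p > 10.0 / done:
            break
        target = min(target * 10, spec.n_permutations)
    return float(p), done, False


# ---------------------------------------------------------------------------
# permutation-based tests
# ---------------------------------------------------------------------------

def _burden_stat_fn(G):
    s = G.sum(axis=1)
    return lambda Y: s @ Y


def test_burden(dataset, spec=TestSpec(), seed=None):
    """Total rare minor-allele count in cases; one-sided permutation p."""
    G, idx = _rare_matrix(dataset, spec)
    rng = np.random.default_rng(seed)
    y = dataset.phenotype.astype(np.float64)
    fn = _burden_stat_fn(G)
    obs = float(fn(y[:, None])[0])
    p, b, exact = _perm_pvalue(fn, obs, y, rng, spec)
    return TestResult("BURDEN", p, obs, idx.size,
                      {"permutations": b, "exhaustive": exact})


def _uniq_stat_fn(G):
    tot = G.sum(axis=0)[:, None]
    GT = G.T

    def fn(Y):
        A = GT @ Y
        return (A * (tot - A == 0)).sum(axis=0)
    return fn


def test_uniq(dataset, spec=TestSpec(), seed=None):
    """Count of minor-allele observations at case-unique sites;
    permutation p."""
    G, idx = _rare_matrix(dataset, spec)
    rng = np.random.default_rng(seed)
    y = dataset.phenotype.astype(np.float64)
    fn = _uniq_stat_fn(G)
    obs = float(fn(y[:, None])[0])
    p, b, exact = _perm_pvalue(fn, obs, y, rng, spec)
    return TestResult("UNIQ", p, obs, idx.size,
                      {"permutations": b, "exhaustive": exact})


def _frqwgt_stat_fn(G, n):
    tot = G.sum(axis=0)[:, None]
    GT = G.T

    def fn(Y):
        n_ctrl = n - Y.sum(axis=0)
        C = tot - GT @ Y
        q = (C + 1) / (2 * n_ctrl[None, :] + 2)
        w = 1.0 / np.sqrt(n * q * (1 - q))
        return (w * (tot - C)).sum(axis=0)
    return fn


def test_frqwgt(dataset, spec=TestSpec(), seed=None):
    """Inverse-frequency-weighted case allele count (weights estimated from
    controls and recomputed per permutation); one-sided permutation p."""
    G, idx = _rare_matrix(dataset, spec)
    rng = np.random.default_rng(seed)
    y = dataset.phenotype.astype(np.float64)
    fn = _frqwgt_stat_fn(G, y.size)
    obs = float(fn(y[:, None])[0])
    p, b, exact = _perm_pvalue(fn, obs, y, rng, spec)
    return TestResult("FRQWGT", p, obs, idx.size,
                      {"permutations": b, "exhaustive": exact})


def _calpha_stat_fn(G, p0):
    tot = G.sum(axis=0)[:, None]
    GT = G.T
    expected_var = tot * p0 * (1 - p0)

    def fn(Y):
        A = GT @ Y
        return ((A - tot * p0) ** 2 - expected_var).sum(axis=0)
    return fn


def test_calpha(dataset, spec=TestSpec(), seed=None):
    """C-alpha dispersion statistic: summed squared deviation of per-site
    case minor-allele counts from their binomial expectation; permutation
    p of the sum (sensitive to both risk and protective skews)."""
    G, idx = _rare_matrix(dataset, spec)
    rng = np.random.default_rng(seed)
    y = dataset.phenotype.astype(np.float64)
    p0 = y.mean()
    fn = _calpha_stat_fn(G, p0)
    obs = float(fn(y[:, None])[0])
    p, b, exact = _perm_pvalue(fn, obs, y, rng, spec)
    return TestResult("C-ALPHA", p, obs, idx.size,
                      {"permutations": b, "exhaustive": exact})


def _vt_stat_fn(G, mafs):
    order = np.argsort(mafs, kind="stable")
    Gs = G[:, order]
    uniq_maf = np.unique(mafs)
    # cumulative per-individual scores at each distinct MAF threshold
    cum = np.cumsum(Gs, axis=1)
    cuts = np.searchsorted(mafs[order], uniq_maf, side="right") - 1
    S = cum[:, cuts]                       # n x K
    centered = S - S.mean(axis=0, keepdims=True)
    denom = np.sqrt((centered ** 2).sum(axis=0))
    denom[denom == 0] = np.inf
    ST = S.T

    def fn(Y):
        k = Y.sum(axis=0)
        num = ST @ Y - np.outer(S.mean(axis=0), k)
        return (num / denom[:, None]).max(axis=0)
    return fn


def test_vt(dataset, spec=TestSpec(), seed=None):
    """Variable-threshold burden: the z-like statistic is maximized over all
    distinct observed MAF inclusion thresholds; permutation p of the
    maximum (thresholds re-scanned per permutation)."""
    G, idx = _rare_matrix(dataset, spec)
    rng = np.random.default_rng(seed)
    y = dataset.phenotype.astype(np.float64)
    mafs = dataset.maf[idx]
    fn = _vt_stat_fn(G, mafs)
    obs = float(fn(y[:, None])[0])
    p, b, exact = _perm_pvalue(fn, obs, y, rng, spec)
    return TestResult("VT", p, obs, idx.size,
                      {"permutations": b, "exhaustive": exact,
                       "n_thresholds": int(np.unique(mafs).size)})


def _kbac_stat_fn(G, y):
    n = G.shape[0]
    from scipy import sparse

    patterns, pat_id = np.unique(G, axis=0, return_inverse=True)
    nonzero = np.flatnonzero(patterns.sum(axis=1) > 0)
    remap = -np.ones(patterns.shape[0], int)
    remap[nonzero] = np.arange(nonzero.size)
    rows = remap[pat_id]
    carriers = np.flatnonzero(rows >= 0)
    member = sparse.csr_matrix(
        (np.ones(carriers.size), (rows[carriers], carriers)),
        shape=(nonzero.size, n))
    n_g = np.asarray(member.sum(axis=1)).ravel().astype(int)
    n_case = int(y.sum())
    n_ctrl = n - n_case
    # per-pattern hypergeometric CDF lookup tables for the adaptive
    # weights; patterns of equal size share a table
    width = int(n_g.max()) + 1 if n_g.size else 1
    W = np.zeros((nonzero.size, width))
    for ng in np.unique(n_g):
        table = stats.hypergeom.cdf(np.arange(ng + 1), n, ng, n_case)
        W[np.ix_(n_g == ng, np.arange(ng + 1))] = table

    def fn(Y):
        A = (member @ Y).astype(int)              # cases per pattern
        w = np.take_along_axis(W, A, axis=1)
        diff = A / n_case - (n_g[:, None] - A) / n_ctrl
        return (w * diff).sum(axis=0)
    return fn


def test_kbac(dataset, spec=TestSpec(), seed=None):
    """Kernel-based adaptive clustering: multi-site rare genotype patterns
    weighted by the hypergeometric tail probability of their observed case
    enrichment; one-sided permutation p."""
    G, idx = _rare_matrix(dataset, spec)
    rng = np.random.default_rng(seed)
    y = dataset.phenotype.astype(np.float64)
    fn = _kbac_stat_fn(G, y)
    obs = float(fn(y[:, None])[0])
    p, b, exact = _perm_pvalue(fn, obs, y, rng, spec)
    return TestResult("KBAC", p, obs, idx.size,
                      {"permutations": b, "exhaustive": exact})


# ---------------------------------------------------------------------------
# regression / asymptotic tests
# ---------------------------------------------------------------------------

def test_cmc(dataset, spec=TestSpec(), seed=None):
    """Collapse rare variants into a carrier indicator and test it against
    phenotype with the logistic-regression likelihood-ratio test (for a
    single binary predictor this is the 2x2 G-test).  Degenerate carrier
    status returns p = 1."""
    G, idx = _rare_matrix(dataset, spec)
    carrier = (G.sum(axis=1) > 0).astype(int)
    y = dataset.phenotype.astype(int)
    if carrier.min() == carrier.max():
        return TestResult("CMC", 1.0, 0.0, idx.size, {"degenerate": True})
    obs = np.zeros((2, 2))
    for ci in (0, 1):
        for yi in (0, 1):
            obs[ci, yi] = np.sum((carrier == ci) & (y == yi))
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    exp = row @ col / obs.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
    g2 = 2.0 * terms.sum()
    p = float(stats.chi2.sf(g2, 1))
    return TestResult("CMC", p, float(g2), idx.size,
                      {"carriers": int(carrier.sum())})


def test_wss(dataset, spec=TestSpec(), seed=None):
    """Madsen-Browning weighted-sum scores (weights from control allele
    frequencies) compared between cases and controls by the tie-corrected
    asymptotic Wilcoxon rank-sum test."""
    G, idx = _rare_matrix(dataset, spec)
    y = dataset.phenotype.astype(bool)
    n = y.size
    n_ctrl = int((~y).sum())
    ctrl_counts = G[~y].sum(axis=0)
    q = (ctrl_counts + 1) / (2 * n_ctrl + 2)
    w = 1.0 / np.sqrt(n * q * (1 - q))
    scores = G @ w
    if np.ptp(scores) == 0:
        return TestResult("WILCOX-WSS", 1.0, 0.0, idx.size,
                          {"degenerate": True})
    res = stats.mannwhitneyu(scores[y], scores[~y], alternative="two-sided",
                             method="asymptotic")
    return TestResult("WILCOX-WSS", float(res.pvalue), float(res.statistic),
                      idx.size, {})


def test_single_fisher(dataset, spec=TestSpec(), seed=None):
    """Two-sided Fisher's exact test on the 2x2 minor-allele count table at
    every site (no MAF filter); locus summary is the minimum p and the MAF
    of the site attaining it."""
    case, ctrl = dataset.minor_allele_counts()
    n_case, n_ctrl = dataset.n_case, dataset.n_control
    ps = np.empty(dataset.n_sites)
    for v in range(dataset.n_sites):
        table = [[case[v], 2 * n_case - case[v]],
                 [ctrl[v], 2 * n_ctrl - ctrl[v]]]
        ps[v] = stats.fisher_exact(table, alternative="two-sided")[1]
    best = int(np.argmin(ps))
    return TestResult("SINGLE-FISHER", float(ps[best]), float(ps[best]),
                      dataset.n_sites,
                      {"p_per_site": ps, "top_site": best,
                       "top_maf": float(dataset.maf[best])})


# ---------------------------------------------------------------------------
# SKAT family
# ---------------------------------------------------------------------------

def _skat_parts(dataset, spec):
    G, idx = _rare_matrix(dataset, spec)
    y = dataset.phenotype.astype(np.float64)
    mu = y.mean()
    sigma2 = mu * (1 - mu)
    if sigma2 == 0:
        raise ParameterError("phenotype has zero variance")
    w = _weights(dataset.maf[idx], spec)
    B = (G - G.mean(axis=0, keepdims=True)) * w[None, :]
    v = y - mu
    return B, v, sigma2, idx


def _skat_pvalue(B, v, sigma2):
    u = B.T @ v
    q = float(u @ u)
    lam = np.linalg.eigvalsh(B.T @ B) * sigma2
    lam = lam[lam > 1e-10 * max(lam.max(initial=0.0), 1e-300)]
    mean_q, var_q = permutation_quadform_moments(B, v)
    return moment_adjusted_sf(q, lam, mean_q, var_q), q, lam


def test_skat(dataset, spec=TestSpec(), seed=None):
    """Sequence kernel association test: score statistic
    Q = (y - mu)' G W^2 G' (y - mu) with Beta-density MAF weights; p from
    the chi-square-mixture null via exact-tail numeric inversion with
    moment-matching fallback."""
    B, v, sigma2, idx = _skat_parts(dataset, spec)
    p, q, lam = _skat_pvalue(B, v, sigma2)
    return TestResult("SKAT", p, q, idx.size, {"n_eigen": int(lam.size)})


def test_skato(dataset, spec=TestSpec(), seed=None):
    """SKAT-O: minimum p over Q_rho = (1 - rho) Q_SKAT + rho Q_burden on the
    rho grid, with the grid-search null accounted for by one-dimensional
    numeric integration."""
    B, v, sigma2, idx = _skat_parts(dataset, spec)
    grid = tuple(spec.rho_grid)
    m = B.shape[1]

    if m == 1 or len(grid) == 1 and grid[0] == 0.0:
        p, q, _ = _skat_pvalue(B, v, sigma2)
        return TestResult("SKAT-O", p, q, idx.size,
                          {"rho": 0.0 if m > 1 else 1.0, "degenerate": True})

    Z = B * np.sqrt(sigma2)
    vs = v / np.sqrt(sigma2)
    u = Z.sum(axis=1)                   # burden direction (n,)
    u2 = float(u @ u)
    score = Z.T @ vs                    # (m,)
    q_skat = float(score @ score)
    q_burden = float(score.sum() ** 2)

    ZZ = Z.T @ Z
    ones = np.ones(m)
    p_rhos, q_rhos, lam_rhos = [], [], []
    for rho in grid:
        q_rho = (1 - rho) * q_skat + rho * q_burden
        c1 = np.sqrt(1 - rho)
        c2 = np.sqrt((1 - rho) + m * rho)
        # R_rho^{1/2} = c1 (I - J/m) + c2 J/m applied on both sides
        Rh = c1 * np.eye(m) + (c2 - c1) / m * np.outer(ones, ones)
        lam = np.linalg.eigvalsh(Rh @ ZZ @ Rh)
        lam = lam[lam > 1e-10 * max(lam.max(initial=0.0), 1e-300)]
        mean_r, var_r = permutation_quadform_moments(Z @ Rh, vs)
        p_rhos.append(moment_adjusted_sf(q_rho, lam, mean_r, var_r))
        q_rhos.append(q_rho)
        lam_rhos.append(lam)
    T = min(p_rhos)
    rho_sel = grid[int(np.argmin(p_rhos))]
    if len(grid) == 1:
        return TestResult("SKAT-O", T, q_rhos[0], idx.size, {"rho": grid[0]})
    if u2 <= 1e-12:
        return TestResult("SKAT-O", T, q_rhos[0], idx.size,
                          {"rho": rho_sel, "degenerate": True})

    # null decomposition along / orthogonal to the burden direction
    Zp = np.outer(u / u2, u @ Z)
    Zq = Z - Zp
    lam_k = np.linalg.eigvalsh(Zq.T @ Zq)
    lam_k = lam_k[lam_k > 1e-10 * max(lam_k.max(initial=0.0), 1e-300)]
    mu_q = lam_k.sum()
    var_lam = 2 * (lam_k ** 2).sum()
    var_adj = 4 * float(np.sum((Zp.T @ Zq) ** 2))
    var_q = var_lam + var_adj
    zu = Z.T @ u
    taus = np.array([rho * u2 + (1 - rho) * float(zu @ zu) / u2
                     for rho in grid])

    # per-rho quantiles of Q_rho at upper-tail probability T
    qstars = []
    for rho, lam in zip(grid, lam_rhos):
        if rho == 1.0:
            qstars.append(u2 * stats.chi2.isf(T, 1))
        else:
            qstars.append(liu_quantile(T, lam))
    qstars = np.asarray(qstars)

    notone = np.array([r != 1.0 for r in grid])
    if (~notone).any():
        j = int(np.flatnonzero(~notone)[0])
        x_max = qstars[j] / taus[j]
    else:
        x_max = stats.chi2.isf(1e-14, 1)

    if lam_k.size:
        mu_k, sigma_k, df_k, ncp_k = liu_params(lam_k)
        mu_x = df_k + ncp_k
        sigma_x = np.sqrt(2 * (df_k + 2 * ncp_k))

    def kappa_cdf(t):
        """Moment-matched CDF of the non-burden component (with the
        cross-term variance adjustment)."""
        if t <= 0:
            return 0.0
        if lam_k.size == 0:
            return 1.0
        if var_adj > 0:
            t = (t - mu_q) * np.sqrt(var_lam / var_q) + mu_q
            if t <= 0:
                return 0.0
        tt = (t - mu_k) / sigma_k * sigma_x + mu_x
        return float(stats.ncx2.cdf(tt, df_k, ncp_k))

    from scipy import integrate

    def integrand(x):
        bound = np.min((qstars[notone] - taus[notone] * x) /
                       (1 - np.asarray(grid)[notone]))
        return kappa_cdf(bound) * stats.chi2.pdf(x, 1)

    prob_all, _ = integrate.quad(integrand, 0, x_max, limit=200,
                                 epsabs=1e-12, epsrel=1e-6)
    p = 1.0 - prob_all
    p = float(min(max(p, T), min(1.0, T * len(grid))))
    return TestResult("SKAT-O", p, float(min(q_rhos)), idx.size,
                      {"rho": rho_sel, "min_p": T})


def test_mist(dataset, spec=TestSpec(), seed=None):
    """Mixed-effects score test: a score test of the weighted-burden
    component (stage 1) and a variance-component score test of the residual
    per-variant heterogeneity orthogonal to it (stage 2), combined with
    Fisher's method (chi-square, 4 df)."""
    B, v, sigma2, idx = _skat_parts(dataset, spec)
    n = v.size
    s = B.sum(axis=1)                    # weighted burden score (centered)
    ss = float(s @ s)
    if ss <= 1e-12:
        p1 = 1.0
    else:
        z = float(s @ v) / np.sqrt(sigma2 * ss)
        p1 = float(2 * stats.norm.sf(abs(z)))
    # stage 2: project columns orthogonal to the burden score
    if ss > 1e-12:
        B2 = B - np.outer(s / ss, s @ B)
    else:
        B2 = B
    lam = np.linalg.eigvalsh(B2.T @ B2) * sigma2
    lam = lam[lam > 1e-10 * max(lam.max(initial=0.0), 1e-300)]
    if lam.size == 0:
        p2 = 1.0
    else:
        u2 = B2.T @ v
        q2 = float(u2 @ u2)
        mean2, var2 = permutation_quadform_moments(B2, v)
        p2 = moment_adjusted_sf(q2, lam, mean2, var2)
    fisher = -2.0 * (np.log(max(p1, 1e-300)) + np.log(max(p2, 1e-300)))
    p = float(stats.chi2.sf(fisher, 4))
    return TestResult("MIST", p, fisher, idx.size, {"p_burden": p1,
                                                    "p_heterogeneity": p2})


# ---------------------------------------------------------------------------
# battery
# ---------------------------------------------------------------------------

_DISPATCH = {
    "CMC": test_cmc,
    "VT": test_vt,
    "FRQWGT": test_frqwgt,
    "WILCOX-WSS": test_wss,
    "KBAC": test_kbac,
    "BURDEN": test_burden,
    "UNIQ": test_uniq,
    "C-ALPHA": test_calpha,
    "SKAT": test_skat,
    "SKAT-O": test_skato,
    "MIST": test_mist,
    "SINGLE-FISHER": test_single_fisher,
}


def run_test(name, dataset, spec=TestSpec(), seed=None):
    """Run a single named test."""
    key = name.upper()
    if key not in _DISPATCH:
        raise ParameterError(f"unknown test {name!r}")
    return _DISPATCH[key](dataset, spec, seed=seed)


def run_test_battery(dataset, specs=None, seed=None, tests=TEST_NAMES):
    """Run the requested tests on the identical filtered dataset.

    ``specs`` may be a single :class:`TestSpec` (shared) or a mapping from
    test name to spec.  Permutation streams are independently seeded per
    test from ``seed``.  Per-test errors become missing-with-reason rows.
    Returns a list of :class:`TestResult`.
    """
    if specs is None:
        specs = TestSpec()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(tests))
    out = []
    for name, child in zip(tests, children):
        spec = specs[name] if isinstance(specs, dict) else specs
        sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        try:
            out.append(run_test(name, dataset, spec, seed=sub_seed))
        except Exception as exc:  # noqa: BLE001 - recorded, not raised
            out.append(TestResult(name.upper(), np.nan, np.nan, 0,
                                  {"error": f"{type(exc).__name__}: {exc}"}))
    return out
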