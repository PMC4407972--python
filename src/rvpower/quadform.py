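"""Tail probabilities of positive quadratic forms in standard normals,
Q = sum_j lambda_j * chi^2_1j.

``chi2_mixture_sf`` evaluates the upper tail by numerical inversion of the
characteristic function (Imhof's method) with a moment-matched noncentral
chi-square fallback (Liu-Tang-Zhang) when the integral is unreliable.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import integrate, stats

__all__ = ["chi2_mixture_sf", "liu_params", "liu_sf", "liu_quantile"]


def _imhof_sf(q, lam):
    """Imhof inversion P(Q > q) = 1/2 + (1/pi) int sin(theta(u))/(u rho(u)) du
    with theta(u) = 0.5 sum arctan(lam u) - q u / 2.

    The integrand oscillates at frequency q/2; beyond the first half-period
    the sin/cos components are integrated as Fourier integrals (QAWF), which
    is stable even for widely spread eigenvalue mixtures."""
    lam = np.asarray(lam, float)
    scale = lam.max()
    lam = lam / scale
    q = q / scale
    w = 0.5 * q

    def phi(u):
        return 0.5 * np.sum(np.arctan(lam * u))

    def inv_urho(u):
        return np.exp(-np.log(u) - 0.25 * np.sum(np.log1p((lam * u) ** 2)))

    def integrand(u):
        return np.sin(phi(u) - w * u) * inv_urho(u)

    # truncation point where the envelope is negligible
    upper = 1.0
    while inv_urho(upper) > 1e-14 and upper < 1e14:
        upper *= 4.0

    a = min(np.pi / w, upper)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        head, err0 = integrate.quad(integrand, 0, a, limit=200,
                                    epsabs=1e-13, epsrel=1e-9)
        # sin(phi - wu) = sin(phi)cos(wu) - cos(phi)sin(wu)
        i1, err1 = integrate.quad(lambda u: np.sin(phi(u)) * inv_urho(u),
                                  a, np.inf, weight="cos", wvar=w, limit=400)
        i2, err2 = integrate.quad(lambda u: np.cos(phi(u)) * inv_urho(u),
                                  a, np.inf, weight="sin", wvar=w, limit=400)
    val = head + i1 - i2
    return 0.5 + val / np.pi, err0 + err1 + err2


def liu_params(lam):
    """Moment-matching parameters (Liu et al. 2009 modification): returns
    (mu_q, sigma_q, df, ncp) of the matched noncentral chi-square."""
    lam = np.asarray(lam, float)
    c1, c2, c3, c4 = (np.sum(lam), np.sum(lam**2), np.sum(lam**3),
                      np.sum(lam**4))
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1 / (s1 - np.sqrt(s1**2 - s2))
        ncp = s1 * a**3 - a**2
        df = a**2 - 2 * ncp
    else:
        ncp = 0.0
        df = 1 / s2 if s2 > 0 else 1.0
    mu_q = c1
    sigma_q = np.sqrt(2 * c2)
    return mu_q, sigma_q, max(df, 1e-8), max(ncp, 0.0)


def liu_sf(q, lam):
    mu_q, sigma_q, df, ncp = liu_params(lam)
    mu_x = df + ncp
    sigma_x = np.sqrt(2 * (df + 2 * ncp))
    t = (q - mu_q) / sigma_q * sigma_x + mu_x
    return float(stats.ncx2.sf(t, df, ncp))


def liu_quantile(p_upper, lam):
    """Value q with approximate upper-tail probability ``p_upper``."""
    mu_q, sigma_q, df, ncp = liu_params(lam)
    mu_x = df + ncp
    sigma_x = np.sqrt(2 * (df + 2 * ncp))
    t = stats.ncx2.isf(p_upper, df, ncp)
    return float((t - mu_x) / sigma_x * sigma_q + mu_q)


def permutation_quadform_moments(B, a):
    """Exact mean and variance of Q = v' B B' v when ``v`` is a uniformly
    random permutation of the fixed zero-sum vector ``a`` and the columns of
    ``B`` are centered (so the kernel has zero row sums)."""
    a = np.asarray(a, float)
    n = a.size
    S2 = float((a**2).sum())
    S4 = float((a**4).sum())
    d = (B**2).sum(axis=1)              # diagonal of BB'
    t1 = float(d.sum())
    T2 = float((d**2).sum())
    F = float(((B.T @ B) ** 2).sum())   # tr((BB')^2)
    e4 = S4 / n
    e22 = (S2**2 - S4) / (n * (n - 1))
    e31 = -S4 / (n * (n - 1))
    e211 = (2 * S4 - S2**2) / (n * (n - 1) * (n - 2))
    e1111 = (3 * S2**2 - 6 * S4) / (n * (n - 1) * (n - 2) * (n - 3))
    dd = t1**2 + 2 * F - 6 * T2
    mean_q = t1 * S2 / (n - 1)
    eq2 = (T2 * e4
           + (t1**2 - T2 + 2 * (F - T2)) * e22
           - 4 * T2 * e31
           + (2 * (2 * T2 - t1**2) + 4 * (2 * T2 - F)) * e211
           + dd * e1111)
    return mean_q, eq2 - mean_q**2


def moment_adjusted_sf(q, lam, mean_exact, var_exact):
    """Tail probability of the chi-square mixture after rescaling ``q`` so
    the mixture's mean and variance match the exact permutation moments."""
    lam = np.asarray(lam, float)
    mu = lam.sum()
    var = 2 * (lam**2).sum()
    if var_exact <= 0 or var <= 0:
        return chi2_mixture_sf(q, lam)
    q_adj = (q - mean_exact) * np.sqrt(var / var_exact) + mu
    return chi2_mixture_sf(q_adj, lam)


def chi2_mixture_sf(q, lam, min_lambda_frac=1e-10):
    """P(sum_j lam_j chi^2_1 > q), clipped to (0, 1].

    Eigenvalues below ``min_lambda_frac`` of the largest are discarded as
    numerical noise.
    """
    lam = np.asarray(lam, float)
    lam = lam[lam > min_lambda_frac * max(lam.max(initial=0.0), 0)]
    if lam.size == 0:
        return 1.0
    if q <= 0:
        return 1.0
    try:
        p, err = _imhof_sf(q, lam)
    except Exception:
        p, err = np.nan, np.inf
    # fall back to moment matching in the far tail / on integration failure
    if not np.isfinite(p) or p < 1e-10 or p > 1 or err > max(1e-6, 0.1 * abs(p)):
        p = liu_sf(q, lam)
    return float(min(max(p, 1e-300), 1.0))
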