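"""Tail probabilities for mixtures of chi-square variables.

Computes ``P(sum_k lambda_k * chi2_1k > q)`` — the null distribution of
variance-component (SKAT-type) statistics.  Methods, tried in order:

1. Ruben's series: the mixture CDF expanded as a positive mixture of
   central chi-square CDFs in steps of 2 degrees of freedom.  Terms are
   non-negative and sum to one, so the truncation error is rigorously
   bounded by the unassigned mass; when that bound reaches 1e-14 the result
   is effectively exact.  Converges fast unless the eigenvalue spread is
   extreme.
2. Imhof's characteristic-function inversion integral (adaptive
   quadrature) when Ruben does not converge in the term budget.
3. Kuonen's saddlepoint approximation for deep tails where the oscillatory
   integral degrades, with Liu's moment-matching chi-square approximation
   as the final fallback.

The method actually used is available via ``full_output=True``.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import integrate, optimize, stats

_RUBEN_MAX_TERMS = 6000
_RUBEN_TAIL_MASS = 1e-14


def _ruben(lambdas: np.ndarray, q: float) -> float | None:
    """Ruben's mixture-of-chi-squares expansion; None if not converged.

    With beta = min(lambda) the mixing weights a_k are non-negative and sum
    to 1, giving the truncation bound sum_{k>N} a_k <= 1 - sum_{k<=N} a_k.
    """
    m = lambdas.size
    beta = lambdas.min()
    b = 1.0 - beta / lambdas          # in [0, 1)
    a = np.empty(_RUBEN_MAX_TERMS)
    a[0] = np.exp(0.5 * np.sum(np.log(beta / lambdas)))
    if a[0] == 0.0:
        return None
    total = a[0]
    powers = np.ones_like(b)
    g = np.empty(_RUBEN_MAX_TERMS)
    n_terms = _RUBEN_MAX_TERMS
    for k in range(1, _RUBEN_MAX_TERMS):
        powers *= b
        g[k] = powers.sum()
        a[k] = 0.5 * np.dot(g[1:k + 1][::-1], a[:k]) / k
        total += a[k]
        if 1.0 - total < _RUBEN_TAIL_MASS:
            n_terms = k + 1
            break
    else:
        return None
    k_arr = np.arange(n_terms)
    sf_terms = stats.chi2.sf(q / beta, m + 2 * k_arr)
    return float(np.dot(a[:n_terms], sf_terms))


def _imhof(lambdas: np.ndarray, q: float) -> tuple[float, float]:
    """Imhof's inversion integral; returns (p, quadrature error estimate)."""

    def integrand(u):
        theta = 0.5 * np.sum(np.arctan(lambdas * u)) - 0.5 * q * u
        rho = np.exp(0.25 * np.sum(np.log1p((lambdas * u) ** 2)))
        return np.sin(theta) / (u * rho)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, err = integrate.quad(integrand, 0.0, np.inf,
                                  limit=500, epsabs=1e-14, epsrel=1e-12)
    return 0.5 + val / np.pi, err


def _saddlepoint(lambdas: np.ndarray, q: float) -> float:
    """Kuonen's saddlepoint approximation (Lugannani–Rice form)."""
    lmax = lambdas.max()
    mean = lambdas.sum()
    if abs(q - mean) < 1e-10 * mean:
        return 0.5

    def kprime(t):
        return np.sum(lambdas / (1.0 - 2.0 * t * lambdas))

    hi = 0.5 / lmax
    lo = -1e6 / lmax
    t_hat = optimize.brentq(lambda t: kprime(t) - q,
                            lo, hi * (1 - 1e-12), xtol=5e-16, maxiter=300)
    K = -0.5 * np.sum(np.log1p(-2.0 * t_hat * lambdas))
    Kpp = 2.0 * np.sum(lambdas ** 2 / (1.0 - 2.0 * t_hat * lambdas) ** 2)
    w = np.sign(t_hat) * np.sqrt(max(2.0 * (t_hat * q - K), 0.0))
    v = t_hat * np.sqrt(Kpp)
    if w == 0.0:
        return 0.5
    z = w + np.log(v / w) / w
    return float(stats.norm.sf(z))


def _liu(lambdas: np.ndarray, q: float) -> float:
    """Liu et al. moment-matched (non-central) chi-square approximation."""
    c1 = lambdas.sum()
    c2 = (lambdas ** 2).sum()
    c3 = (lambdas ** 3).sum()
    c4 = (lambdas ** 4).sum()
    s1 = c3 / c2 ** 1.5
    s2 = c4 / c2 ** 2
    if s1 ** 2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1 ** 2 - s2))
        delta = s1 * a ** 3 - a ** 2
        df = a ** 2 - 2 * delta
    else:
        delta = 0.0
        df = 1.0 / s2
    t_star = (q - c1) / np.sqrt(2 * c2)
    q_norm = t_star * np.sqrt(2 * (df + 2 * delta)) + df + delta
    return float(stats.ncx2.sf(q_norm, df, delta)) if delta > 0 \
        else float(stats.chi2.sf(q_norm, df))


def mixture_chisq_tail(eigenvalues, q: float, full_output: bool = False):
    """Upper-tail probability of a positively weighted chi-square mixture.

    Parameters
    ----------
    eigenvalues : array-like
        Non-negative mixture weights (eigenvalues of the projected,
        weighted genotype covariance); zeros are dropped.
    q : float
        Observed value of the quadratic form (``q >= 0``).
    full_output : bool
        If True, return ``(p, method)`` where method is one of
        "ruben", "imhof", "saddlepoint", "liu", "exact".
    """
    lam = np.asarray(eigenvalues, dtype=float).ravel()
    if np.any(lam < -1e-10 * max(1.0, abs(lam).max(initial=0.0))):
        raise ValueError("eigenvalues must be non-negative")
    lam = lam[lam > 0]
    if lam.size == 0:
        raise ValueError("at least one positive eigenvalue required")
    if q < 0:
        raise ValueError("q must be non-negative")
    if q == 0:
        return (1.0, "exact") if full_output else 1.0

    p = _ruben(lam, q)
    method = "ruben"
    if p is None:
        p, err = _imhof(lam, q)
        method = "imhof"
        if not (1e-8 <= p <= 1.0) or err > 1e-6:
            try:
                p = _saddlepoint(lam, q)
                method = "saddlepoint"
            except Exception:
                p = _liu(lam, q)
                method = "liu"
    p = float(min(max(p, 5e-324), 1.0))
    return (p, method) if full_output else p
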