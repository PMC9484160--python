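"""Likelihood building blocks: Beta density, zero-inflated Beta, Bernoulli.

The non-zero relative abundance of a taxon is modeled by a Beta density in
its mean/precision parameterization: for mean ``mu`` in (0, 1) and
overdispersion (precision) ``phi`` > 0 the shapes are ``(mu * phi,
(1 - mu) * phi)``.  A zero observation is handled by a separate presence
probability ``pi``, giving the two-part (zero-inflated Beta) likelihood
per sample:

    (1 - pi)              if y == 0
    pi * Beta(y; mu, phi) if y  > 0
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2

__all__ = [
    "beta_logpdf",
    "zib_subject_loglik",
    "disease_loglik",
    "wald_joint",
    "bh_adjust",
]


def beta_logpdf(y, mu, phi):
    """Log Beta density with mean ``mu`` and precision ``phi``.

    Shapes are ``mu * phi`` and ``(1 - mu) * phi``.  All arguments may be
    scalars or broadcastable arrays; ``y`` and ``mu`` must lie strictly in
    (0, 1) and ``phi`` must be positive.
    """
    y = np.asarray(y, float)
    mu = np.asarray(mu, float)
    phi = np.asarray(phi, float)
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("y must lie strictly in (0, 1)")
    if np.any((mu <= 0) | (mu >= 1)):
        raise ValueError("mu must lie strictly in (0, 1)")
    if np.any(phi <= 0):
        raise ValueError("phi must be positive")
    a = mu * phi
    b = (1.0 - mu) * phi
    out = (
        gammaln(phi)
        - gammaln(a)
        - gammaln(b)
        + (a - 1.0) * np.log(y)
        + (b - 1.0) * np.log1p(-y)
    )
    return out if out.ndim else float(out)


def zib_subject_loglik(y_series, mu_series, pi_series, phi):
    """Two-part log-likelihood of one subject's abundance series.

    Sums over time points: ``log(1 - pi_t)`` where ``y_t == 0`` and
    ``log(pi_t) + log Beta(y_t; mu_t, phi)`` where ``y_t > 0``.  ``y_t = 1``
    is outside the Beta support and raises.
    """
    y = np.asarray(y_series, float)
    mu = np.asarray(mu_series, float)
    pi = np.asarray(pi_series, float)
    if not (y.shape == mu.shape == pi.shape):
        raise ValueError("y, mu, pi series must have equal lengths")
    if np.any((y < 0) | (y >= 1)):
        raise ValueError("y must lie in [0, 1); y == 1 has no Beta density")
    if np.any((pi <= 0) | (pi >= 1)):
        raise ValueError("pi must lie strictly in (0, 1)")
    pos = y > 0
    total = float(np.log1p(-pi[~pos]).sum())
    if pos.any():
        total += float(np.log(pi[pos]).sum())
        total += float(np.sum(beta_logpdf(y[pos], mu[pos], phi)))
    return total


def disease_loglik(O, p):
    """Bernoulli log-likelihood of a binary disease outcome."""
    if O not in (0, 1):
        raise ValueError("O must be 0 or 1")
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly in (0, 1)")
    return float(np.log(p) if O == 1 else np.log1p(-p))


def wald_joint(lam_r, se_r, lam_p, se_p):
    """Joint Wald statistic for the two random-effect scaling parameters.

    ``W = lam_r^2 / se_r^2 + lam_p^2 / se_p^2`` referred to a chi-square
    distribution; the degrees of freedom equal the number of terms with a
    finite positive standard error (2 for the full two-part model, 1 when
    the presence part was dropped for a never-absent taxon).  Returns
    ``(W, p, df)``; ``(nan, nan, 0)`` when no term is testable.
    """
    w = 0.0
    df = 0
    for est, se in ((lam_r, se_r), (lam_p, se_p)):
        if se is not None and np.isfinite(se) and se > 0 and np.isfinite(est):
            w += (est / se) ** 2
            df += 1
    if df == 0:
        return float("nan"), float("nan"), 0
    return float(w), float(chi2.sf(w, df)), df


def bh_adjust(p_values):
    """Benjamini-Hochberg step-up adjusted p-values (monotone, in [0, 1]).

    NaN entries are passed through unadjusted and excluded from the ranking.
    """
    p = np.asarray(p_values, float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m:
        order = np.argsort(pv, kind="stable")
        ranked = pv[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(adj, 1.0)
        q[ok] = out
    return q
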