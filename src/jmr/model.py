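"""Joint model of matched disease outcomes and taxon trajectories.

The model links two processes through shared nested random effects
``a_sj ~ N(0, sigma_a^2)`` (subject within matched set) and
``b_s ~ N(0, sigma_b^2)`` (matched set):

    logit(p_sj)   = u_sj  alpha + a_sj + b_s
    logit(mu_sjt) = x1_sjt beta11 + z_sjt beta12 + zt_sjt (lam_r a_sj + gam_r b_s)
    logit(pi_sjt) = x2_sjt beta21 + z_sjt beta22 + zt_sjt (lam_p a_sj + gam_p b_s)

where ``p`` is the disease probability, ``mu`` the conditional (non-zero)
mean relative abundance of the target taxon, ``pi`` its presence
probability, ``x1``/``x2`` pre-selected covariate taxa, ``z`` longitudinal
covariates (intercept and scaled age first) and ``zt`` equals 1 for the
intercept test or scaled age for the slope test.  The scaling parameters
``lam_r, lam_p`` carry the taxon-disease association and are tested
jointly by a Wald statistic.

This module holds the model containers, the marginal set likelihood (a
plain-numpy reference of the compiled kernel) and the penalized objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit, gammaln

from . import _kernel
from .data import CovariateTaxaSet, LongitudinalTaxaTable, MatchedCohort
from .quadrature import gh_rule

__all__ = [
    "JMRSpec",
    "JMRParams",
    "JMRFit",
    "TaxonTestResult",
    "SubjectData",
    "set_marginal_loglik",
    "penalized_loglik",
]

VARIANTS = ("JMR", "JMR-NC", "JR-NC")
TEST_MODES = ("intercept", "slope")


@dataclass(frozen=True)
class JMRSpec:
    """Model configuration.

    ``variant`` selects the full model ("JMR", with covariate taxa), the
    model without covariate taxa ("JMR-NC"), or the latter additionally
    without the matched-set random effect ("JR-NC").  ``gh_nodes`` is the
    Gauss-Hermite node count per random-effect dimension and ``rho`` the
    ridge penalty on the penalized likelihood.
    """

    test_mode: str = "intercept"
    variant: str = "JMR"
    gh_nodes: int = 5
    rho: float = 0.1
    fix_re_variances: bool = True

    def __post_init__(self) -> None:
        if self.test_mode not in TEST_MODES:
            raise ValueError(f"test_mode must be one of {TEST_MODES}")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.gh_nodes < 3:
            raise ValueError("gh_nodes must be >= 3")
        if self.rho < 0:
            raise ValueError("rho must be >= 0")
        if not self.fix_re_variances:
            raise NotImplementedError(
                "free random-effect variances are not supported; sigma_a and "
                "sigma_b are fixed at 1 (scale is absorbed by lam/gam)"
            )

    @property
    def include_set_effect(self) -> bool:
        return self.variant != "JR-NC"

    @property
    def use_covariate_taxa(self) -> bool:
        return self.variant == "JMR"


@dataclass
class JMRParams:
    """Full parameter vector of the joint model.

    ``beta11``/``beta21`` act on the covariate-taxa columns (may be empty);
    ``beta12``/``beta22`` on the shared longitudinal design ``z`` whose
    first column is the intercept.  ``sigma_a``/``sigma_b`` are the
    random-effect SDs (fixed at 1 by default).
    """

    alpha: np.ndarray
    beta11: np.ndarray
    beta12: np.ndarray
    beta21: np.ndarray
    beta22: np.ndarray
    lam_r: float = 0.0
    lam_p: float = 0.0
    gam_r: float = 0.0
    gam_p: float = 0.0
    phi: float = 10.0
    sigma_a: float = 1.0
    sigma_b: float = 1.0

    def __post_init__(self) -> None:
        if self.phi <= 0:
            raise ValueError("phi must be positive")
        if self.sigma_a <= 0 or self.sigma_b <= 0:
            raise ValueError("random-effect SDs must be positive")
        for name in ("alpha", "beta11", "beta12", "beta21", "beta22"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), float)))


@dataclass
class JMRFit:
    """Result of one penalized maximum-likelihood fit."""

    taxon: str
    spec: JMRSpec
    params: JMRParams
    se: dict[str, float | np.ndarray]
    loglik: float
    penalized_loglik: float
    aic: float
    k: int
    converged: bool
    n_iter: int
    status: str = "ok"
    theta: np.ndarray | None = None
    theta_names: list[str] = field(default_factory=list)
    presence_part: bool = True


@dataclass
class TaxonTestResult:
    """Joint Wald test of the random-effect scaling parameters."""

    taxon: str
    W: float
    p: float
    df: int
    q: float = float("nan")
    status: str = "ok"


@dataclass
class SubjectData:
    """One subject's contribution to a matched set's likelihood.

    ``d1``/``d2`` are the full abundance/presence design matrices (covariate
    taxa columns followed by ``z`` columns) with one row per sample; a
    subject with no samples contributes only the disease part.
    """

    O: int
    u: np.ndarray
    y: np.ndarray
    d1: np.ndarray
    d2: np.ndarray
    zt: np.ndarray


def _subject_loglik_grid(subj: SubjectData, params: JMRParams, a: np.ndarray,
                         b: np.ndarray, include_b: bool, use_presence: bool) -> np.ndarray:
    """Conditional log-likelihood of one subject on an (a, b) node grid."""
    beta1 = np.concatenate([params.beta11, params.beta12])
    beta2 = np.concatenate([params.beta21, params.beta22])
    A = a[:, None]
    B = b[None, :]
    ll = np.zeros((a.size, b.size))
    gb = float(include_b)
    for t in range(subj.y.size):
        ztv = subj.zt[t]
        yv = subj.y[t]
        if yv > 0:
            emu = subj.d1[t] @ beta1 + ztv * (params.lam_r * A + gb * params.gam_r * B)
            emu = np.clip(emu, -30.0, 30.0)
            mu = expit(emu)
            sh1, sh2 = mu * params.phi, (1 - mu) * params.phi
            ll += (
                gammaln(params.phi) - gammaln(sh1) - gammaln(sh2)
                + (sh1 - 1) * np.log(yv) + (sh2 - 1) * np.log1p(-yv)
            )
            if use_presence:
                epi = subj.d2[t] @ beta2 + ztv * (params.lam_p * A + gb * params.gam_p * B)
                ll -= np.log1p(np.exp(-np.clip(epi, -700, 700)))
        elif use_presence:
            epi = subj.d2[t] @ beta2 + ztv * (params.lam_p * A + gb * params.gam_p * B)
            ll -= np.log1p(np.exp(np.clip(epi, -700, 700)))
    eta = float(subj.u @ params.alpha) + A + gb * B
    ll += subj.O * eta - np.log1p(np.exp(-np.abs(eta))) - np.maximum(eta, 0.0)
    return ll


def set_marginal_loglik(
    subjects: Sequence[SubjectData],
    params: JMRParams,
    spec: JMRSpec | None = None,
    gh_nodes: int | None = None,
) -> float:
    """Marginal log-likelihood of one matched set by nested Gauss-Hermite.

    Integrates the set-level effect ``b_s`` on the outer nodes; conditional
    on each ``b`` node the subject effects ``a_sj`` factorize, so the inner
    expectation is a per-subject one-dimensional sum.  This factorized
    product rule equals the full (J+1)-dimensional tensor rule for the
    product-form integrand, at O(Q^2) cost per subject.

    Random effects enter on the N(0,1) scale (``sigma_a = sigma_b = 1``
    by default); the variance scale of the longitudinal submodels is
    carried by ``lam``/``gam``.
    """
    spec = spec or JMRSpec(variant="JMR-NC")
    Q = gh_nodes or spec.gh_nodes
    nodes, w = gh_rule(Q)
    logw = np.log(w)
    include_b = spec.include_set_effect
    use_presence = True
    a_nodes = params.sigma_a * nodes
    b_nodes = params.sigma_b * nodes if include_b else np.zeros(1)
    logw_b = logw if include_b else np.zeros(1)
    # per-subject conditional loglik on the (a, b) grid
    inner = np.zeros(b_nodes.size)
    for subj in subjects:
        grid = _subject_loglik_grid(subj, params, a_nodes, b_nodes, include_b, use_presence)
        la = grid + logw[:, None]
        m = la.max(axis=0)
        inner += m + np.log(np.exp(la - m).sum(axis=0))
    lb = inner + logw_b
    m = lb.max()
    out = m + np.log(np.exp(lb - m).sum())
    if not np.isfinite(out):
        raise FloatingPointError("non-finite marginal likelihood contribution")
    return float(out)


def penalized_loglik(loglik: float, theta_penalized: np.ndarray, rho: float) -> float:
    """Ridge-penalized marginal log-likelihood ``loglik - rho * ||theta||^2``.

    ``theta_penalized`` holds only the penalized entries: by design the
    intercepts of ``alpha``, ``beta12``, ``beta22`` and the fixed
    random-effect SDs are excluded (penalizing intercepts would distort
    baseline prevalence), while all slopes, covariate-taxa coefficients,
    ``lam``/``gam`` scalings and ``log phi`` are included.
    """
    theta_penalized = np.asarray(theta_penalized, float)
    return float(loglik - rho * np.sum(theta_penalized**2))
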