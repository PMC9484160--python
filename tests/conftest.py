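"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.special import expit

from jmr import JMRParams, SubjectData
from jmr.density import beta_logpdf


def make_toy_subject(rng, T=2, k_z=2, with_samples=True):
    """Random small subject for quadrature tests (J z-columns: 1, age)."""
    T = T if with_samples else 0
    y = rng.uniform(0.05, 0.6, T)
    y[rng.random(T) < 0.4] = 0.0
    z = np.column_stack([np.ones(T), rng.uniform(0, 1, T)]) if T else np.empty((0, k_z))
    return SubjectData(
        O=int(rng.random() < 0.5),
        u=np.array([1.0, rng.random()]),
        y=y,
        d1=z,
        d2=z.copy(),
        zt=np.ones(T),
    )


def make_toy_params(rng):
    return JMRParams(
        alpha=rng.normal(0, 0.5, 2),
        beta11=np.empty(0),
        beta12=rng.normal(0, 0.5, 2) + [-1.5, 0],
        beta21=np.empty(0),
        beta22=rng.normal(0, 0.5, 2),
        lam_r=rng.uniform(-0.5, 0.5),
        lam_p=rng.uniform(-0.5, 0.5),
        gam_r=rng.uniform(-0.5, 0.5),
        gam_p=rng.uniform(-0.5, 0.5),
        # moderate overdispersion: the plain (non-adaptive) rule's accuracy
        # degrades as phi sharpens the integrand
        phi=rng.uniform(4, 12),
    )


def subject_loglik_at(subj: SubjectData, params: JMRParams, a: float, b: float,
                      include_b: bool = True) -> float:
    """Plain conditional log-likelihood of one subject at fixed (a, b)."""
    gb = 1.0 if include_b else 0.0
    beta1 = np.concatenate([params.beta11, params.beta12])
    beta2 = np.concatenate([params.beta21, params.beta22])
    ll = 0.0
    for t in range(subj.y.size):
        emu = float(subj.d1[t] @ beta1) + subj.zt[t] * (params.lam_r * a + gb * params.gam_r * b)
        epi = float(subj.d2[t] @ beta2) + subj.zt[t] * (params.lam_p * a + gb * params.gam_p * b)
        pi = expit(epi)
        if subj.y[t] == 0:
            ll += np.log1p(-pi)
        else:
            ll += np.log(pi) + beta_logpdf(subj.y[t], float(expit(emu)), params.phi)
    eta = float(subj.u @ params.alpha) + a + gb * b
    p = expit(eta)
    ll += np.log(p) if subj.O else np.log1p(-p)
    return float(ll)


def dense_grid_marginal_loglik(subjects, params: JMRParams, lim=8.0, n=535) -> float:
    """Trapezoid-rule oracle for the (J+1)-dimensional marginal integral.

    Evaluates each subject's conditional likelihood on an (a, b) grid over
    [-lim, lim]^2, multiplies by the N(0,1) densities and contracts the
    full (J+1)-dimensional tensor-product trapezoid sum (the contraction
    order exploits the product form; the sum is the same).
    """
    g = np.linspace(-lim, lim, n)
    w = np.full(n, g[1] - g[0])
    w[0] *= 0.5
    w[-1] *= 0.5
    phi_n = np.exp(-0.5 * g**2) / np.sqrt(2 * np.pi)
    A = g[:, None]
    B = g[None, :]
    total_b = np.ones(n)
    for subj in subjects:
        beta1 = np.concatenate([params.beta11, params.beta12])
        beta2 = np.concatenate([params.beta21, params.beta22])
        ll = np.zeros((n, n))  # (a, b)
        for t in range(subj.y.size):
            emu = float(subj.d1[t] @ beta1) + subj.zt[t] * (params.lam_r * A + params.gam_r * B)
            epi = float(subj.d2[t] @ beta2) + subj.zt[t] * (params.lam_p * A + params.gam_p * B)
            pi = expit(epi)
            if subj.y[t] == 0:
                ll += np.log1p(-pi)
            else:
                ll += np.log(pi) + beta_logpdf(
                    np.full((n, n), subj.y[t]), expit(emu), params.phi
                )
        eta = float(subj.u @ params.alpha) + A + B
        ll += subj.O * eta - np.logaddexp(0.0, eta)
        inner = (w * phi_n) @ np.exp(ll)  # integrate over a for each b
        total_b = total_b * inner
    val = float(np.sum(w * phi_n * total_b))
    return float(np.log(val))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_b1():
    """One small scenario-B1 dataset shared across tests."""
    from jmr.simulate import sim_scenario_b

    return sim_scenario_b(P=40, S=30, T=4, gamma=0.7, lam=0.7, seed=424242)
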