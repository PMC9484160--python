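"""Compiled marginal log-likelihood kernel.

Evaluates the matched-set marginal likelihood of the joint model: for each
set, a product Gauss-Hermite rule integrates the set-level random effect
``b_s`` (outer nodes) and, nested inside, the subject-level effects
``a_sj`` (inner nodes).  Because subjects are conditionally independent
given ``b_s``, the inner integral factorizes over subjects and the cost is
``O(Q^2 * J * sum(T))`` rather than ``O(Q^(J+1))``.

All per-sample linear-predictor offsets that do not involve the random
effects are precomputed by the caller; the kernel only adds the scaled
random-effect contributions, so one evaluation is a tight scalar loop.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_CLAMP = 30.0  # clamp on logits; expit(30) is 1 - 9.4e-14


@njit(cache=True)
def _log_sigmoid(x):
    # log expit(x), stable for large |x|
    if x > 0.0:
        return -math.log1p(math.exp(-x))
    return x - math.log1p(math.exp(x))


@njit(cache=True)
def marginal_loglik(
    off_p,      # (n_subj,) disease linear predictor without random effects
    O,          # (n_subj,) binary outcome as float
    set_ptr,    # (n_sets+1,) subject index ranges per set
    off_mu,     # (n_samp,) abundance logit offset
    off_pi,     # (n_samp,) presence logit offset
    y_pos,      # (n_samp,) 1.0 where y > 0
    logy,       # (n_samp,) log y   (0 where y == 0)
    log1my,     # (n_samp,) log(1-y)
    zt,         # (n_samp,) random-effect design (1 or scaled age)
    samp_ptr,   # (n_subj+1,) sample index ranges per subject
    lam_r, lam_p, gam_r, gam_p, phi,
    nodes_a, logw_a, nodes_b, logw_b,
    include_b,     # 1 -> set-level effect in all submodels, 0 -> dropped
    use_presence,  # 1 -> two-part likelihood, 0 -> Beta part only
):
    n_sets = set_ptr.shape[0] - 1
    qa = nodes_a.shape[0]
    qb = nodes_b.shape[0]
    lgam_phi = math.lgamma(phi)
    la = np.empty(qa)
    lb = np.empty(qb)
    total = 0.0
    for s in range(n_sets):
        for ib in range(qb):
            b = nodes_b[ib]
            sumj = logw_b[ib]
            for j in range(set_ptr[s], set_ptr[s + 1]):
                for ia in range(qa):
                    a = nodes_a[ia]
                    ra = lam_r * a + gam_r * b
                    pa = lam_p * a + gam_p * b
                    ll = 0.0
                    for t in range(samp_ptr[j], samp_ptr[j + 1]):
                        if y_pos[t] > 0.0:
                            emu = off_mu[t] + zt[t] * ra
                            if emu > _CLAMP:
                                emu = _CLAMP
                            elif emu < -_CLAMP:
                                emu = -_CLAMP
                            mu = 1.0 / (1.0 + math.exp(-emu))
                            sh1 = mu * phi
                            sh2 = (1.0 - mu) * phi
                            ll += (
                                lgam_phi
                                - math.lgamma(sh1)
                                - math.lgamma(sh2)
                                + (sh1 - 1.0) * logy[t]
                                + (sh2 - 1.0) * log1my[t]
                            )
                            if use_presence == 1:
                                epi = off_pi[t] + zt[t] * pa
                                ll += _log_sigmoid(epi)
                        elif use_presence == 1:
                            epi = off_pi[t] + zt[t] * pa
                            ll += _log_sigmoid(-epi)
                    eta = off_p[j] + a + include_b * b
                    ll += O[j] * eta + _log_sigmoid(-eta)
                    la[ia] = logw_a[ia] + ll
                # log-sum-exp over subject nodes
                m = la[0]
                for ia in range(1, qa):
                    if la[ia] > m:
                        m = la[ia]
                acc = 0.0
                for ia in range(qa):
                    acc += math.exp(la[ia] - m)
                sumj += m + math.log(acc)
            lb[ib] = sumj
        m = lb[0]
        for ib in range(1, qb):
            if lb[ib] > m:
                m = lb[ib]
        acc = 0.0
        for ib in range(qb):
            acc += math.exp(lb[ib] - m)
        total += m + math.log(acc)
    return total
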