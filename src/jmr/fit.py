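"""Penalized maximum-likelihood fitting and Wald testing.

Estimation maximizes the ridge-penalized marginal log-likelihood with a
quasi-Newton (L-BFGS-B) optimizer; the overdispersion is optimized on the
log scale.  Standard errors come from the inverse observed information of
the penalized objective (finite-difference Hessian at the optimum).  The
taxon-disease association is tested by the joint Wald statistic on the
two random-effect scaling parameters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from . import _kernel, _kernel_grad
from .data import CovariateTaxaSet, LongitudinalTaxaTable, MatchedCohort
from .density import bh_adjust, wald_joint
from .model import JMRFit, JMRParams, JMRSpec, TaxonTestResult
from .quadrature import gh_rule

__all__ = ["fit_jmr", "wald_test", "test_taxa"]

log = logging.getLogger(__name__)

_Y_HIGH_CLIP = 1.0 - 1e-6
_Y_LOW_CLIP = 1e-12
_RESTART_SEED = 20220919  # fixed: keeps refits bit-reproducible


@dataclass
class _Packed:
    """Arrays in the layout the compiled kernel consumes."""

    O: np.ndarray
    U: np.ndarray
    set_ptr: np.ndarray
    y: np.ndarray
    y_pos: np.ndarray
    logy: np.ndarray
    log1my: np.ndarray
    zt: np.ndarray
    samp_ptr: np.ndarray
    X1: np.ndarray
    X2: np.ndarray
    n_z: int
    n_x1: int
    n_x2: int


def _scaled_age(age: np.ndarray) -> np.ndarray:
    lo, hi = float(age.min()), float(age.max())
    if hi <= lo:
        return np.zeros_like(age)
    return (age - lo) / (hi - lo)


def pack_data(
    cohort: MatchedCohort,
    table: LongitudinalTaxaTable,
    taxon: str,
    spec: JMRSpec,
    covariates: CovariateTaxaSet | None = None,
) -> _Packed:
    """Arrange cohort and sample data into flat per-set / per-subject arrays.

    Subjects are grouped by matched set and samples by subject; ages are
    rescaled to [0, 1] across the study window for numeric stability.
    """
    subj = cohort.subjects.sort_values(["set_id", "subject_id"], kind="stable")
    subj = subj.reset_index(drop=True)
    set_codes = subj["set_id"].astype("category").cat.codes.to_numpy()
    # subjects already sorted by set -> set_ptr from run lengths
    change = np.flatnonzero(np.diff(set_codes)) + 1
    set_ptr = np.concatenate([[0], change, [len(subj)]]).astype(np.int64)
    O = subj["outcome"].to_numpy(float)
    n = len(subj)
    U = np.column_stack(
        [np.ones(n)] + [subj[c].to_numpy(float) for c in cohort.covariates]
    )

    smeta = table.samples.copy()
    pos_of_subject = {sid: i for i, sid in enumerate(subj["subject_id"])}
    unknown = set(smeta["subject_id"]) - set(pos_of_subject)
    if unknown:
        raise ValueError(f"samples reference unknown subjects: {sorted(unknown)[:5]}")
    smeta["_subj_pos"] = smeta["subject_id"].map(pos_of_subject)
    order = np.argsort(smeta["_subj_pos"].to_numpy(), kind="stable")
    smeta = smeta.iloc[order]
    samp_counts = np.bincount(smeta["_subj_pos"].to_numpy(), minlength=n)
    samp_ptr = np.concatenate([[0], np.cumsum(samp_counts)]).astype(np.int64)

    if taxon not in table.abundance.index:
        raise KeyError(f"taxon {taxon!r} not in table")
    y = table.abundance.loc[taxon].to_numpy(float)[order]
    if (y >= 1.0).any():
        warnings.warn(
            f"taxon {taxon}: {int((y >= 1).sum())} monodominant sample(s) with "
            f"y >= 1 clipped to {_Y_HIGH_CLIP}",
            stacklevel=2,
        )
        y = np.minimum(y, _Y_HIGH_CLIP)
    tiny = (y > 0) & (y < _Y_LOW_CLIP)
    if tiny.any():
        y = np.where(tiny, _Y_LOW_CLIP, y)

    age = _scaled_age(smeta["age"].to_numpy(float))
    zcols = [np.ones(len(smeta)), age]
    for c in table.covariates:
        zcols.append(smeta[c].to_numpy(float))
    Z = np.column_stack(zcols)
    zt = np.ones(len(smeta)) if spec.test_mode == "intercept" else age.copy()

    def _cov_matrix(names: list[str], as_presence: bool) -> np.ndarray:
        if not names:
            return np.empty((len(smeta), 0))
        block = table.abundance.loc[names].to_numpy(float).T[order]
        return (block > 0).astype(float) if as_presence else block

    if spec.use_covariate_taxa and covariates is not None:
        x1 = _cov_matrix(covariates.abundance_covariates, as_presence=False)
        x2 = _cov_matrix(covariates.presence_covariates, as_presence=True)
    else:
        x1 = np.empty((len(smeta), 0))
        x2 = np.empty((len(smeta), 0))

    ypos = (y > 0).astype(float)
    logy = np.where(y > 0, np.log(np.where(y > 0, y, 1.0)), 0.0)
    log1my = np.log1p(-y)
    return _Packed(
        O=O, U=U, set_ptr=set_ptr,
        y=y, y_pos=ypos, logy=logy, log1my=log1my,
        zt=zt, samp_ptr=samp_ptr,
        X1=np.ascontiguousarray(np.column_stack([x1, Z])),
        X2=np.ascontiguousarray(np.column_stack([x2, Z])),
        n_z=Z.shape[1], n_x1=x1.shape[1], n_x2=x2.shape[1],
    )


class _Layout:
    """Slices of the free parameter vector theta and the ridge penalty mask.

    theta = [alpha | beta1 (x1 then z cols) | beta2 (x2 then z cols)
             | lam_r | lam_p | (gam_r | gam_p) | log_phi]

    The presence block (beta2, lam_p, gam_p) is absent for never-absent
    taxa; the gam block is absent for the JR-NC variant.  The penalty
    mask excludes the intercepts of alpha, beta12 and beta22.
    """

    def __init__(self, packed: _Packed, spec: JMRSpec, use_presence: bool):
        self.use_presence = use_presence
        self.include_b = spec.include_set_effect
        ku = packed.U.shape[1]
        k1 = packed.X1.shape[1]
        k2 = packed.X2.shape[1] if use_presence else 0
        names: list[str] = [f"alpha{i}" for i in range(ku)]
        names += [f"beta11_{i}" for i in range(packed.n_x1)]
        names += [f"beta12_{i}" for i in range(packed.n_z)]
        if use_presence:
            names += [f"beta21_{i}" for i in range(packed.n_x2)]
            names += [f"beta22_{i}" for i in range(packed.n_z)]
        names.append("lam_r")
        if use_presence:
            names.append("lam_p")
        if self.include_b:
            names.append("gam_r")
            if use_presence:
                names.append("gam_p")
        names.append("log_phi")
        self.names = names
        self.n = len(names)
        self.sl_alpha = slice(0, ku)
        self.sl_beta1 = slice(ku, ku + k1)
        self.sl_beta2 = slice(ku + k1, ku + k1 + k2)
        self.i_rest = ku + k1 + k2
        mask = np.ones(self.n, bool)
        mask[0] = False                      # alpha intercept
        mask[ku + packed.n_x1] = False       # beta12 intercept
        if use_presence:
            mask[ku + k1 + packed.n_x2] = False  # beta22 intercept
        self.penalty_mask = mask
        self.n_x1 = packed.n_x1
        self.n_x2 = packed.n_x2
        self.n_z = packed.n_z
        # scalar positions for the gradient kernel (-1 when absent)
        i = self.i_rest
        self.i_lam_r = i; i += 1
        self.i_lam_p = i if use_presence else -1
        i += int(use_presence)
        if self.include_b:
            self.i_gam_r = i; i += 1
            self.i_gam_p = i if use_presence else -1
            i += int(use_presence)
        else:
            self.i_gam_r = self.i_gam_p = -1
        self.i_logphi = self.n - 1

    def unpack(self, theta: np.ndarray):
        alpha = theta[self.sl_alpha]
        beta1 = theta[self.sl_beta1]
        beta2 = theta[self.sl_beta2]
        i = self.i_rest
        lam_r = theta[i]; i += 1
        lam_p = theta[i] if self.use_presence else 0.0
        i += int(self.use_presence)
        if self.include_b:
            gam_r = theta[i]; i += 1
            gam_p = theta[i] if self.use_presence else 0.0
            i += int(self.use_presence)
        else:
            gam_r = gam_p = 0.0
        log_phi = theta[i]
        return alpha, beta1, beta2, float(lam_r), float(lam_p), float(gam_r), float(gam_p), float(log_phi)

    def to_params(self, theta: np.ndarray) -> JMRParams:
        alpha, beta1, beta2, lam_r, lam_p, gam_r, gam_p, log_phi = self.unpack(theta)
        return JMRParams(
            alpha=alpha,
            beta11=beta1[: self.n_x1],
            beta12=beta1[self.n_x1:],
            beta21=beta2[: self.n_x2] if self.use_presence else np.empty(0),
            beta22=beta2[self.n_x2:] if self.use_presence else np.empty(0),
            lam_r=lam_r, lam_p=lam_p, gam_r=gam_r, gam_p=gam_p,
            phi=float(np.exp(log_phi)),
        )


def _make_objective(packed: _Packed, layout: _Layout, spec: JMRSpec):
    nodes, w = gh_rule(spec.gh_nodes)
    logw = np.log(w)
    if layout.include_b:
        nodes_b, logw_b = nodes, logw
    else:
        nodes_b, logw_b = np.zeros(1), np.zeros(1)
    use_presence = 1 if layout.use_presence else 0
    include_b = 1 if layout.include_b else 0
    zero_pi = np.zeros(packed.X2.shape[0])

    def loglik(theta: np.ndarray) -> float:
        alpha, beta1, beta2, lam_r, lam_p, gam_r, gam_p, log_phi = layout.unpack(theta)
        off_p = packed.U @ alpha
        off_mu = packed.X1 @ beta1
        off_pi = packed.X2 @ beta2 if use_presence else zero_pi
        return _kernel.marginal_loglik(
            off_p, packed.O, packed.set_ptr,
            off_mu, off_pi, packed.y_pos, packed.logy, packed.log1my,
            packed.zt, packed.samp_ptr,
            lam_r, lam_p, gam_r, gam_p, float(np.exp(log_phi)),
            nodes, logw, nodes_b, logw_b,
            include_b, use_presence,
        )

    def objective(theta: np.ndarray) -> float:
        ll = loglik(theta)
        pen = spec.rho * float(np.sum(theta[layout.penalty_mask] ** 2))
        val = -(ll - pen)
        if not np.isfinite(val):
            return 1e12
        return val

    U = packed.U
    X1 = packed.X1
    X2 = packed.X2 if use_presence else packed.X2[:, :0]

    def objective_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
        alpha, beta1, beta2, lam_r, lam_p, gam_r, gam_p, log_phi = layout.unpack(theta)
        off_p = U @ alpha
        off_mu = X1 @ beta1
        off_pi = packed.X2 @ beta2 if use_presence else zero_pi
        grad = np.zeros(layout.n)
        ll = _kernel_grad.loglik_and_grad(
            off_p, packed.O, packed.set_ptr,
            off_mu, off_pi, packed.y_pos, packed.logy, packed.log1my,
            packed.zt, packed.samp_ptr,
            lam_r, lam_p, gam_r, gam_p, float(np.exp(log_phi)),
            nodes, logw, nodes_b, logw_b,
            include_b, use_presence,
            U, X1, X2,
            layout.i_lam_r, layout.i_lam_p, layout.i_gam_r, layout.i_gam_p,
            layout.i_logphi,
            grad,
        )
        pen_theta = np.where(layout.penalty_mask, theta, 0.0)
        f = -(ll - spec.rho * float(pen_theta @ pen_theta))
        g = -grad + 2.0 * spec.rho * pen_theta
        if not np.isfinite(f) or not np.all(np.isfinite(g)):
            return 1e12, np.zeros(layout.n)
        return f, g

    return loglik, objective, objective_grad


def _hessian_from_grad(grad_fn, theta: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Central finite differences of the analytic gradient, symmetrized."""
    n = theta.size
    H = np.empty((n, n))
    for k in range(n):
        h = rel_step * max(1.0, abs(theta[k]))
        tp = theta.copy(); tp[k] += h
        tm = theta.copy(); tm[k] -= h
        H[:, k] = (grad_fn(tp)[1] - grad_fn(tm)[1]) / (2.0 * h)
    return 0.5 * (H + H.T)


def _logit_fit(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Quick ridge-stabilized Newton logistic fit for initialization."""
    beta = np.zeros(X.shape[1])
    ybar = float(np.clip(y.mean(), 1e-3, 1 - 1e-3))
    beta[0] = logit(ybar)
    for _ in range(25):
        eta = np.clip(X @ beta, -30, 30)
        p = expit(eta)
        Wd = p * (1 - p) + 1e-6
        g = X.T @ (y - p) - 1e-4 * beta
        H = (X * Wd[:, None]).T @ X + 1e-4 * np.eye(X.shape[1])
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    return np.clip(beta, -10, 10)


def _initial_theta(packed: _Packed, layout: _Layout) -> np.ndarray:
    theta = np.zeros(layout.n)
    theta[layout.sl_alpha] = _logit_fit(packed.O, packed.U)
    pos = packed.y > 0
    if pos.sum() >= 2:
        X1p = packed.X1[pos]
        resp = logit(np.clip(packed.y[pos], 1e-10, 1 - 1e-10))
        b1, *_ = np.linalg.lstsq(
            X1p.T @ X1p + 1e-4 * np.eye(X1p.shape[1]), X1p.T @ resp, rcond=None
        )
        theta[layout.sl_beta1] = np.clip(b1, -15, 15)
        mu = expit(np.clip(X1p @ theta[layout.sl_beta1], -30, 30))
        resid = packed.y[pos] - mu
        v = float(np.var(resid)) + 1e-10
        phi0 = float(np.clip(np.mean(mu * (1 - mu)) / v - 1.0, 2.0, 200.0))
    else:
        theta[layout.sl_beta1][0] = logit(float(np.clip(packed.y[pos].mean() if pos.any() else 0.1, 1e-6, 1 - 1e-6)))
        phi0 = 10.0
    if layout.use_presence:
        theta[layout.sl_beta2] = _logit_fit(packed.y_pos, packed.X2)
    i = layout.i_rest
    n_lam = 1 + int(layout.use_presence)
    n_gam = (1 + int(layout.use_presence)) if layout.include_b else 0
    theta[i : i + n_lam + n_gam] = 0.1
    theta[-1] = np.log(phi0)
    return theta


def fit_jmr(
    cohort: MatchedCohort,
    table: LongitudinalTaxaTable,
    taxon: str,
    spec: JMRSpec | None = None,
    covariates: CovariateTaxaSet | None = None,
    maxiter: int = 300,
) -> JMRFit:
    """Fit the joint model for one target taxon.

    Returns a :class:`JMRFit` with estimates, standard errors from the
    inverse observed information of the penalized objective, the
    unpenalized marginal log-likelihood at the optimum, and
    ``aic = 2k - 2 loglik`` with ``k`` the number of free parameters.

    Degenerate taxa: an all-zero taxon is not fit (``status ==
    "no_presence"``); a never-zero taxon is fit without the presence part
    (``lam_p`` fixed at 0, Wald test reduces to one degree of freedom).
    """
    spec = spec or JMRSpec(variant="JMR-NC")
    packed = pack_data(cohort, table, taxon, spec, covariates)
    n_pos = int(packed.y_pos.sum())
    if n_pos == 0:
        empty = JMRParams(alpha=np.zeros(packed.U.shape[1]), beta11=np.empty(0),
                          beta12=np.zeros(packed.n_z), beta21=np.empty(0),
                          beta22=np.zeros(packed.n_z))
        return JMRFit(taxon=taxon, spec=spec, params=empty, se={},
                      loglik=float("nan"), penalized_loglik=float("nan"),
                      aic=float("nan"), k=0, converged=False, n_iter=0,
                      status="no_presence")
    use_presence = n_pos < packed.y.size
    if not use_presence:
        log.info("taxon %s never absent: presence part dropped (df=1 Wald)", taxon)
    layout = _Layout(packed, spec, use_presence)
    loglik_fn, objective, objective_grad = _make_objective(packed, layout, spec)
    theta0 = _initial_theta(packed, layout)
    obj0 = objective(theta0)

    best = None
    n_iter = 0
    rng = np.random.default_rng(_RESTART_SEED)
    for attempt in range(3):
        start = theta0 if attempt == 0 else theta0 + rng.normal(0.0, 0.2, layout.n)
        res = minimize(
            objective_grad, start, method="L-BFGS-B", jac=True,
            options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7},
        )
        n_iter += res.nit
        if best is None or res.fun < best.fun:
            best = res
        if res.success and res.fun <= obj0 + 1e-8:
            best = res if res.fun <= best.fun else best
            break
    converged = bool(best.success) and np.isfinite(best.fun)
    theta_hat = best.x

    H = _hessian_from_grad(objective_grad, theta_hat)
    se = np.full(layout.n, np.nan)
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        se = np.where(d > 0, np.sqrt(np.abs(d)), np.nan)
    except np.linalg.LinAlgError:
        try:
            cov = np.linalg.pinv(H)
            d = np.diag(cov)
            se = np.where(d > 0, np.sqrt(np.abs(d)), np.nan)
        except np.linalg.LinAlgError:
            pass

    ll_hat = loglik_fn(theta_hat)
    params = layout.to_params(theta_hat)
    se_map: dict[str, float] = dict(zip(layout.names, se))
    k = layout.n
    fit = JMRFit(
        taxon=taxon, spec=spec, params=params, se=se_map,
        loglik=float(ll_hat), penalized_loglik=float(-best.fun),
        aic=float(2 * k - 2 * ll_hat), k=k,
        converged=converged, n_iter=int(n_iter),
        status="ok" if converged else "not_converged",
        theta=theta_hat, theta_names=list(layout.names),
        presence_part=use_presence,
    )
    return fit


def wald_test(fit: JMRFit) -> TaxonTestResult:
    """Joint Wald test of ``lam_r`` (and ``lam_p`` when present).

    ``W = lam_r^2/SE^2 + lam_p^2/SE^2`` referred to chi-square with as many
    degrees of freedom as testable terms (no cross-covariance term).
    """
    if fit.status == "no_presence" or not fit.converged:
        return TaxonTestResult(fit.taxon, float("nan"), float("nan"), 0,
                               status=fit.status if fit.status != "ok" else "not_converged")
    se_r = fit.se.get("lam_r")
    se_p = fit.se.get("lam_p") if fit.presence_part else None
    lam_p = fit.params.lam_p if fit.presence_part else float("nan")
    W, p, df = wald_joint(fit.params.lam_r, se_r, lam_p, se_p)
    status = "ok" if np.isfinite(p) else "no_se"
    if status == "no_se":
        log.warning("taxon %s: missing/invalid SE, Wald test unavailable", fit.taxon)
    return TaxonTestResult(fit.taxon, W, p, df, status=status)


def test_taxa(
    cohort: MatchedCohort,
    table: LongitudinalTaxaTable,
    spec: JMRSpec | None = None,
    taxa: list[str] | None = None,
    covariate_sets: dict[str, CovariateTaxaSet] | None = None,
    maxiter: int = 300,
) -> pd.DataFrame:
    """Fit and Wald-test every requested taxon; BH-adjust across taxa.

    Returns one row per taxon with estimates, SEs, W, p, BH q, AIC and the
    convergence status.
    """
    spec = spec or JMRSpec(variant="JMR-NC")
    taxa = list(taxa) if taxa is not None else list(table.taxa)
    rows = []
    for tx in taxa:
        cov = (covariate_sets or {}).get(tx)
        fit = fit_jmr(cohort, table, tx, spec, covariates=cov, maxiter=maxiter)
        tr = wald_test(fit)
        rows.append({
            "taxon": tx,
            "lam_r": fit.params.lam_r, "se_lam_r": fit.se.get("lam_r", np.nan),
            "lam_p": fit.params.lam_p if fit.presence_part else np.nan,
            "se_lam_p": fit.se.get("lam_p", np.nan),
            "gam_r": fit.params.gam_r, "gam_p": fit.params.gam_p,
            "phi": fit.params.phi,
            "W": tr.W, "p": tr.p, "df": tr.df,
            "loglik": fit.loglik, "aic": fit.aic,
            "converged": fit.converged, "status": tr.status,
        })
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out
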