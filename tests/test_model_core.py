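"""Marginal set likelihood, penalized objective, fitting and Wald testing."""

import numpy as np
import pytest

from conftest import (
    dense_grid_marginal_loglik,
    make_toy_params,
    make_toy_subject,
    subject_loglik_at,
)
from jmr import (
    JMRParams,
    JMRSpec,
    SubjectData,
    fit_jmr,
    penalized_loglik,
    set_marginal_loglik,
    wald_test,
)
from jmr.fit import _Layout, _initial_theta, _make_objective, pack_data
from jmr.quadrature import gh_rule
from jmr.simulate import sim_joint_model


def _kernel_loglik(subjects, params, spec):
    """Drive the compiled kernel through the fitting pathway's packing."""
    from jmr import _kernel

    O = np.array([float(s.O) for s in subjects])
    U = np.vstack([s.u for s in subjects])
    set_ptr = np.array([0, len(subjects)], dtype=np.int64)
    y = np.concatenate([s.y for s in subjects])
    d1 = np.vstack([s.d1 for s in subjects])
    d2 = np.vstack([s.d2 for s in subjects])
    zt = np.concatenate([s.zt for s in subjects])
    counts = np.array([s.y.size for s in subjects])
    samp_ptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    beta1 = np.concatenate([params.beta11, params.beta12])
    beta2 = np.concatenate([params.beta21, params.beta22])
    nodes, w = gh_rule(spec.gh_nodes)
    logw = np.log(w)
    include_b = 1 if spec.include_set_effect else 0
    nodes_b = nodes if include_b else np.zeros(1)
    logw_b = logw if include_b else np.zeros(1)
    return _kernel.marginal_loglik(
        U @ params.alpha, O, set_ptr,
        d1 @ beta1, d2 @ beta2,
        (y > 0).astype(float),
        np.where(y > 0, np.log(np.where(y > 0, y, 1.0)), 0.0),
        np.log1p(-y), zt, samp_ptr,
        params.lam_r, params.lam_p, params.gam_r, params.gam_p, params.phi,
        nodes, logw, nodes_b, logw_b, include_b, 1,
    )


class TestSetMarginalLoglik:
    @pytest.mark.parametrize("variant", ["JMR-NC", "JR-NC"])
    def test_reference_matches_kernel(self, rng, variant):
        spec = JMRSpec(variant=variant, gh_nodes=7)
        for _ in range(5):
            subjects = [make_toy_subject(rng) for _ in range(2)]
            params = make_toy_params(rng)
            ref = set_marginal_loglik(subjects, params, spec)
            ker = _kernel_loglik(subjects, params, spec)
            assert ref == pytest.approx(ker, rel=1e-12, abs=1e-12)

    def test_point_mass_limit(self, rng):
        # lam = gam = 0 and vanishing RE scale: marginal equals the plug-in
        # likelihood at a = b = 0
        subjects = [make_toy_subject(rng) for _ in range(2)]
        params = make_toy_params(rng)
        params.lam_r = params.lam_p = params.gam_r = params.gam_p = 0.0
        params.sigma_a = params.sigma_b = 1e-10
        plug_in = sum(subject_loglik_at(s, params, 0.0, 0.0) for s in subjects)
        approx = set_marginal_loglik(subjects, params, JMRSpec(variant="JMR-NC", gh_nodes=9))
        assert approx == pytest.approx(plug_in, rel=1e-8)

    def test_logit_symmetry_single_subject(self):
        # J=1, no samples, alpha=0, O=1: P(O=1) = E[expit(a+b)] = 1/2
        subj = SubjectData(O=1, u=np.array([1.0, 0.0]), y=np.empty(0),
                           d1=np.empty((0, 2)), d2=np.empty((0, 2)), zt=np.empty(0))
        params = JMRParams(alpha=np.zeros(2), beta11=[], beta12=np.zeros(2),
                           beta21=[], beta22=np.zeros(2), phi=5.0)
        val = set_marginal_loglik([subj], params, JMRSpec(variant="JMR-NC", gh_nodes=20))
        assert val == pytest.approx(np.log(0.5), abs=1e-6)

    def test_matches_dense_grid_oracle(self, rng):
        spec = JMRSpec(variant="JMR-NC", gh_nodes=20)
        for _ in range(3):
            subjects = [make_toy_subject(rng, T=2) for _ in range(2)]
            params = make_toy_params(rng)
            gh = set_marginal_loglik(subjects, params, spec)
            oracle = dense_grid_marginal_loglik(subjects, params)
            assert abs(gh - oracle) / abs(oracle) < 1e-5

    def test_error_decreases_with_nodes(self, rng):
        subjects = [make_toy_subject(rng, T=2) for _ in range(2)]
        params = make_toy_params(rng)
        oracle = dense_grid_marginal_loglik(subjects, params)
        errs = [
            abs(set_marginal_loglik(subjects, params, JMRSpec(variant="JMR-NC", gh_nodes=q)) - oracle)
            for q in (3, 8, 20)
        ]
        assert errs[2] <= errs[0] + 1e-12 and errs[2] < 1e-6


class TestPenalizedLoglik:
    def test_zero_rho_is_identity(self):
        assert penalized_loglik(-12.5, np.array([1.0, 2.0]), 0.0) == -12.5

    def test_zero_theta_no_penalty(self):
        assert penalized_loglik(-3.0, np.zeros(5), 2.0) == -3.0

    def test_linear_in_rho(self):
        theta = np.array([0.5, -1.5])
        gap1 = -10.0 - penalized_loglik(-10.0, theta, 1.0)
        gap2 = -10.0 - penalized_loglik(-10.0, theta, 2.0)
        assert gap2 == pytest.approx(2 * gap1)

    def test_nonincreasing_in_rho(self):
        theta = np.array([0.3, 0.8])
        vals = [penalized_loglik(-5.0, theta, r) for r in (0.0, 0.1, 1.0, 10.0)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


@pytest.fixture(scope="module")
def joint_fit_case():
    sim = sim_joint_model(S=60, T=4, lam_r=0.8, seed=99)
    spec = JMRSpec(variant="JMR-NC", gh_nodes=5)
    fit = fit_jmr(sim.cohort, sim.table, "otu_jm", spec)
    return sim, spec, fit


class TestFitJMR:
    def test_converges_and_aic_identity(self, joint_fit_case):
        _, _, fit = joint_fit_case
        assert fit.converged
        assert fit.aic == 2 * fit.k - 2 * fit.loglik

    def test_fit_is_deterministic(self, joint_fit_case):
        sim, spec, fit = joint_fit_case
        refit = fit_jmr(sim.cohort, sim.table, "otu_jm", spec)
        assert np.array_equal(refit.theta, fit.theta)
        assert refit.loglik == fit.loglik

    def test_objective_improves_on_initialization(self, joint_fit_case):
        sim, spec, fit = joint_fit_case
        packed = pack_data(sim.cohort, sim.table, "otu_jm", spec)
        layout = _Layout(packed, spec, True)
        _, objective, _ = _make_objective(packed, layout, spec)
        assert -fit.penalized_loglik <= objective(_initial_theta(packed, layout)) + 1e-8

    def test_analytic_gradient_matches_finite_differences(self, joint_fit_case, rng):
        sim, spec, _ = joint_fit_case
        packed = pack_data(sim.cohort, sim.table, "otu_jm", spec)
        layout = _Layout(packed, spec, True)
        _, objective, objective_grad = _make_objective(packed, layout, spec)
        theta = _initial_theta(packed, layout) + rng.normal(0, 0.05, layout.n)
        _, g = objective_grad(theta)
        h = 1e-6
        for k in range(theta.size):
            tp, tm = theta.copy(), theta.copy()
            tp[k] += h
            tm[k] -= h
            fd = (objective(tp) - objective(tm)) / (2 * h)
            assert g[k] == pytest.approx(fd, rel=1e-4, abs=1e-6)

    def test_wald_statistic_definition(self, joint_fit_case):
        _, _, fit = joint_fit_case
        tr = wald_test(fit)
        expected = (fit.params.lam_r / fit.se["lam_r"]) ** 2 + (
            fit.params.lam_p / fit.se["lam_p"]
        ) ** 2
        assert tr.W == pytest.approx(expected, rel=1e-12)
        assert tr.df == 2 and 0 <= tr.p <= 1


class TestDegenerateTaxa:
    def test_all_zero_taxon_skipped(self):
        sim = sim_joint_model(S=20, T=3, seed=5)
        sim.table.abundance.loc["otu_jm"] = 0.0
        fit = fit_jmr(sim.cohort, sim.table, "otu_jm", JMRSpec(variant="JMR-NC"))
        assert fit.status == "no_presence" and not fit.converged
        assert np.isnan(wald_test(fit).p)

    def test_never_zero_taxon_drops_presence_part(self):
        sim = sim_joint_model(S=30, T=3, beta22=(8.0, 0.0), lam_p=0.0, gam_p=0.0, seed=6)
        y = sim.table.abundance.loc["otu_jm"].to_numpy()
        assert (y > 0).all(), "fixture must produce a never-absent taxon"
        fit = fit_jmr(sim.cohort, sim.table, "otu_jm", JMRSpec(variant="JMR-NC"))
        assert not fit.presence_part
        tr = wald_test(fit)
        assert tr.df == 1
        assert tr.W == pytest.approx((fit.params.lam_r / fit.se["lam_r"]) ** 2)
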