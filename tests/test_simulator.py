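"""Matched-cohort simulator: outcomes, Beta-Binomial counts, shifting, scenarios."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jmr.simulate import (
    max_shift,
    shift_composition,
    sim_joint_model,
    sim_scenario_a,
    sim_scenario_b,
    sim_scenario_c,
    stat_sim,
)


class TestStatSim:
    def test_median_split_is_exact_for_even_counts(self):
        cohort, labels = stat_sim(40, seed=0)
        assert labels.A.sum() == 40          # half of 80 subjects
        assert labels.B.sum() == 20          # half of 40 sets
        assert set(cohort.subjects["outcome"]).issubset({0, 1})

    def test_protective_genotype_lowers_risk(self):
        # alpha1 = -2: outcome rate must be lower for G = 1
        rates = {0: [], 1: []}
        cohort, _ = stat_sim(2000, seed=1)
        df = cohort.subjects
        for g in (0, 1):
            rates[g] = df.loc[df["G"] == g, "outcome"].mean()
        assert rates[1] < rates[0] - 0.2

    def test_subject_risk_label_is_null_when_alpha2_zero(self):
        # alpha2 = 0: A carries no information about O beyond (G, B)
        cohort, labels = stat_sim(3000, alpha=(0.5, -2.0, 0.0, 1.0), seed=2)
        df = cohort.subjects.assign(A=labels.A, B=np.repeat(labels.B, 2))
        gaps = []
        for g in (0, 1):
            for b in (0, 1):
                cell = df[(df["G"] == g) & (df["B"] == b)]
                gaps.append(abs(cell.loc[cell["A"] == 1, "outcome"].mean()
                                - cell.loc[cell["A"] == 0, "outcome"].mean()))
        assert np.nanmean(gaps) < 0.05

    def test_deterministic(self):
        c1, _ = stat_sim(10, seed=42)
        c2, _ = stat_sim(10, seed=42)
        assert c1.subjects.equals(c2.subjects)


class TestScenarioA:
    def test_counts_bounded_by_library_size(self):
        cohort, labels = stat_sim(20, seed=3)
        tab = sim_scenario_a(cohort, labels, T=4, seed=4)
        counts = tab.counts.to_numpy().ravel()
        assert (counts <= tab.library_sizes.to_numpy()).all()
        y = tab.abundance.to_numpy()
        assert ((y >= 0) & (y <= 1)).all()

    def test_mean_tracks_age_path(self):
        # with huge precisions the hierarchy collapses onto the mu path:
        # mean abundance rises by the configured age slope
        cohort, labels = stat_sim(200, seed=5)
        tab = sim_scenario_a(cohort, labels, T=4, mu0=0.05, phi0=1e6,
                             phi_t=1e6, phi_st=1e6, age_slope=0.5, seed=6)
        y = tab.abundance.to_numpy().ravel()
        ages = tab.samples["age"].to_numpy()
        first, last = y[ages == 1].mean(), y[ages == 4].mean()
        assert last / first == pytest.approx(1.5, rel=0.02)

    def test_subject_shift_raises_high_risk_mean(self):
        cohort, labels = stat_sim(150, seed=7)
        tab = sim_scenario_a(cohort, labels, T=3, delta_subject=0.02, seed=8)
        y = tab.abundance.to_numpy().ravel()
        A = np.repeat(labels.A, 1)
        subj_idx = tab.samples["subject_id"].map(
            {s: i for i, s in enumerate(cohort.subjects["subject_id"])}
        ).to_numpy()
        hi = y[labels.A[subj_idx] == 1].mean()
        lo = y[labels.A[subj_idx] == 0].mean()
        assert hi > lo

    def test_null_config_independent_of_risk_labels(self):
        # with both deltas zero, high- and low-risk subjects share the
        # same abundance distribution (two-sample KS over pooled samples)
        from scipy.stats import ks_2samp

        cohort, labels = stat_sim(300, seed=9)
        tab = sim_scenario_a(cohort, labels, T=2, delta_set=0.0,
                             delta_subject=0.0, seed=10)
        y = tab.abundance.to_numpy().ravel()
        subj_idx = tab.samples["subject_id"].map(
            {s: i for i, s in enumerate(cohort.subjects["subject_id"])}
        ).to_numpy()
        stat = ks_2samp(y[labels.A[subj_idx] == 1], y[labels.A[subj_idx] == 0])
        assert stat.pvalue > 0.01


class TestShiftComposition:
    def test_zero_shift_is_identity(self):
        eta = np.array([0.5, 0.3, 0.2])
        out = shift_composition(eta, [0], [np.array([1, 2])], 0.0)
        np.testing.assert_array_equal(out, eta)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_conservation_and_nonnegativity(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.integers(4, 30)
        eta = rng.dirichlet(np.full(P, 0.3))
        idx = rng.permutation(P)
        k = rng.integers(1, P - 2)
        inc, rest = idx[:k], idx[k:]
        half = rest.size // 2 or 1
        dec = [rest[:half], rest[half:]] if rest.size > 1 else [rest]
        w = [0.6, 0.4][: len(dec)]
        w = [x / sum(w) for x in w]
        delta = rng.uniform(0, 2.0)  # may exceed the feasible maximum
        out = shift_composition(eta, inc, dec, delta, w)
        assert out.min() >= 0
        assert out.sum() == pytest.approx(eta.sum(), abs=1e-10)

    def test_requested_shift_capped_at_maximum(self):
        eta = np.array([0.4, 0.1, 0.5])
        dec = [np.array([1])]
        cap = max_shift(eta, dec)
        assert cap == pytest.approx(0.1)
        out = shift_composition(eta, np.array([0]), dec, 5.0)
        assert out[1] == pytest.approx(0.0, abs=1e-15)
        assert out[0] == pytest.approx(0.5)

    def test_four_taxon_risk_set_sign_pattern(self):
        # schematic four-taxon community: A, D gain and B, C lose mass in
        # a high-risk set relative to its low-risk counterpart
        eta = np.array([0.4, 0.3, 0.2, 0.1])  # A, B, C, D
        out = shift_composition(eta, np.array([0, 3]), [np.array([1, 2])], 0.15)
        assert out[0] > eta[0] and out[3] > eta[3]
        assert out[1] < eta[1] and out[2] < eta[2]
        assert out.sum() == pytest.approx(1.0, abs=1e-12)

    def test_errors(self):
        eta = np.array([0.5, 0.5])
        with pytest.raises(ValueError):
            shift_composition(eta, np.array([], int), [np.array([1])], 0.1)
        with pytest.raises(ValueError):
            shift_composition(eta, np.array([0]), [np.array([0])], 0.1)
        with pytest.raises(ValueError):
            shift_composition(eta, np.array([0]), [np.array([1])], -0.5)


class TestScenarioB:
    def test_truth_partition_and_library_sizes(self, small_b1):
        truth, table = small_b1.truth, small_b1.table
        P = 40
        assert len(truth.M_plus) == len(truth.M_minus) == round(0.15 * P)
        groups = [truth.M_plus, truth.M_minus, truth.M_zero, truth.null]
        all_ids = [t for g in groups for t in g]
        assert len(all_ids) == len(set(all_ids)) == P
        libs = table.library_sizes.to_numpy()
        assert (libs >= 10_000).all()
        np.testing.assert_array_equal(
            table.counts.to_numpy().sum(axis=0), libs
        )

    def test_compositional_closure(self, small_b1):
        small_b1.table.check_compositional()

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            sim_scenario_b(P=3, S=5, T=2, seed=0)

    def test_null_effect_leaves_risk_groups_exchangeable(self):
        from scipy.stats import ks_2samp

        sim = sim_scenario_b(P=30, S=60, T=3, gamma=0.5, lam=0.0, seed=11)
        A = sim.labels.A
        subj_idx = sim.table.samples["subject_id"].map(
            {s: i for i, s in enumerate(sim.cohort.subjects["subject_id"])}
        ).to_numpy()
        tx = sim.truth.M_plus[0]
        y = sim.table.abundance.loc[tx].to_numpy()
        assert ks_2samp(y[A[subj_idx] == 1], y[A[subj_idx] == 0]).pvalue > 0.01

    def test_negative_cross_correlation_mplus_vs_m0(self):
        # compositional shifting induces anti-correlation between gaining
        # and losing subsets (directional, averaged over replicates)
        cors = []
        for seed in (21, 22, 23, 24):
            sim = sim_scenario_b(P=30, S=40, T=3, gamma=0.6, lam=0.8, d=0.3,
                                 seed=seed)
            rel = sim.table.abundance
            mp = rel.loc[sim.truth.M_plus].sum(axis=0).to_numpy()
            m0 = rel.loc[sim.truth.M_zero].sum(axis=0).to_numpy()
            cors.append(np.corrcoef(mp, m0)[0, 1])
        # a replicate where every M0 taxon fell below detection gives NaN
        assert np.nanmean(cors) < 0

    def test_zero_fraction_decreases_with_abundance(self, small_b1):
        rel = small_b1.table.abundance
        mean_ab = rel.mean(axis=1).to_numpy()
        zero_frac = (rel == 0).mean(axis=1).to_numpy()
        from scipy.stats import spearmanr

        assert spearmanr(mean_ab, zero_frac).statistic < -0.5

    def test_deterministic(self):
        s1 = sim_scenario_b(P=20, S=10, T=2, seed=33)
        s2 = sim_scenario_b(P=20, S=10, T=2, seed=33)
        assert s1.table.counts.equals(s2.table.counts)
        assert s1.truth.M_plus == s2.truth.M_plus


class TestScenarioC:
    def test_partition_fractions(self):
        sim = sim_scenario_c(P=40, S=10, T=2, seed=12)
        assert len(sim.truth.null) == 20
        assert len(sim.truth.M_plus) == 4
        assert len(sim.truth.M_minus) == 16
        assert sim.truth.M_zero == []

    def test_compositional_closure(self):
        sim = sim_scenario_c(P=30, S=8, T=2, seed=13)
        sim.table.check_compositional()


class TestSimJointModel:
    def test_zero_inflation_and_support(self):
        res = sim_joint_model(S=100, T=3, seed=14)
        y = res.table.abundance.to_numpy()
        assert ((y >= 0) & (y < 1)).all()
        assert 0.05 < (y == 0).mean() < 0.9

    def test_positive_lambda_links_taxon_to_outcome(self):
        # lam_r > 0: cases (whose 'a' tends higher) show higher abundance
        res = sim_joint_model(S=400, T=3, lam_r=1.5, seed=15)
        y = res.table.abundance.to_numpy().ravel()
        O = res.cohort.subjects.set_index("subject_id")["outcome"]
        o_sample = res.table.samples["subject_id"].map(O).to_numpy()
        assert y[o_sample == 1].mean() > y[o_sample == 0].mean()
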