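"""Bray-Curtis screening and elastic-net refinement of covariate taxa."""

import numpy as np
import pandas as pd
import pytest

from jmr.data import LongitudinalTaxaTable
from jmr.preselect import (
    bray_curtis,
    elastic_net_refine,
    preselect_covariates,
    screen_by_distance,
)


class TestBrayCurtis:
    def test_identical_profiles(self):
        assert bray_curtis([0.2, 0.8], [0.2, 0.8]) == 0.0

    def test_disjoint_supports(self):
        assert bray_curtis([1.0, 0.0], [0.0, 1.0]) == 1.0

    def test_worked_example(self):
        assert bray_curtis([0.7, 0.3], [0.3, 0.7]) == pytest.approx(0.4)

    def test_binary_profiles_equal_one_minus_dice(self):
        u = np.array([1, 1, 0, 1, 0], float)
        v = np.array([1, 0, 1, 1, 0], float)
        shared = np.sum((u > 0) & (v > 0))
        dice = 2 * shared / (u.sum() + v.sum())
        assert bray_curtis(u, v) == pytest.approx(1 - dice)

    def test_errors(self):
        with pytest.raises(ValueError):
            bray_curtis([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            bray_curtis([0.0, 0.0], [0.0, 0.0])
        with pytest.raises(ValueError):
            bray_curtis([-0.1, 1.0], [0.5, 0.5])


class TestScreenByDistance:
    @staticmethod
    def _profiles_at_distances(ds):
        # v = (1 - x, x) has Bray-Curtis distance exactly x to (1, 0)
        return {f"c{i}": np.array([1 - x, x]) for i, x in enumerate(ds)}

    def test_evenly_spaced_distances(self):
        # distances 0.0, 0.1, ..., 1.0; the 0.1 type-7 quantile is 0.1,
        # so only the candidate at distance 0.0 survives the strict cut
        target = np.array([1.0, 0.0])
        cands = self._profiles_at_distances(np.linspace(0, 1, 11))
        assert screen_by_distance(target, cands, q=0.1) == ["c0"]

    def test_identical_candidate_always_kept(self):
        target = np.array([1.0, 0.0])
        cands = self._profiles_at_distances(np.linspace(0, 1, 15))
        kept = screen_by_distance(target, cands, q=0.1)
        assert "c0" in kept

    def test_size_bound(self):
        rng = np.random.default_rng(3)
        target = np.array([1.0, 0.0])
        ds = rng.uniform(0, 1, 40)
        kept = screen_by_distance(target, self._profiles_at_distances(ds), q=0.1)
        assert len(kept) <= int(np.ceil(0.1 * 40)) + 1

    def test_few_candidates_keeps_nearest(self):
        target = np.array([1.0, 0.0])
        cands = self._profiles_at_distances([0.9, 0.2, 0.5])
        assert screen_by_distance(target, cands, q=0.1) == ["c1"]


class TestElasticNetRefine:
    def test_exact_copy_selected(self):
        rng = np.random.default_rng(0)
        y = rng.uniform(0.05, 0.6, 300)
        X = np.column_stack([y, rng.uniform(0, 1, (300, 3))])
        sel = elastic_net_refine(y, X, ["copy", "n1", "n2", "n3"], "abundance", seed=1)
        assert "copy" in sel

    def test_pure_noise_mostly_rejected(self):
        rng = np.random.default_rng(1)
        y = rng.uniform(0.05, 0.6, 500)
        X = rng.uniform(0, 1, (500, 5))
        sel = elastic_net_refine(y, X, [f"n{i}" for i in range(5)], "abundance", seed=1)
        assert len(sel) <= 1

    def test_presence_mode_selects_informative(self):
        rng = np.random.default_rng(2)
        pres = rng.integers(0, 2, 400).astype(float)
        X = np.column_stack([pres, rng.integers(0, 2, (400, 3)).astype(float)])
        sel = elastic_net_refine(pres, X, ["copy", "n1", "n2", "n3"], "presence", seed=1)
        assert "copy" in sel

    def test_constant_response_empty(self):
        X = np.random.default_rng(0).uniform(size=(50, 3))
        assert elastic_net_refine(np.ones(50), X, ["a", "b", "c"], "abundance") == []


class TestPreselectCovariates:
    def test_pipeline_containment_and_determinism(self, small_b1):
        table = small_b1.table
        target = table.taxa[0]
        res1 = preselect_covariates(table, target, seed=11)
        res2 = preselect_covariates(table, target, seed=11)
        assert res1.abundance_covariates == res2.abundance_covariates
        assert res1.presence_covariates == res2.presence_covariates
        assert target not in res1.abundance_covariates
        assert target not in res1.presence_covariates

    def test_covariate_set_excludes_target(self, small_b1):
        res = preselect_covariates(small_b1.table, small_b1.table.taxa[1], seed=4)
        cs = res.as_covariate_set()
        assert cs.target == small_b1.table.taxa[1]

    def test_selected_covariates_co_move_with_target(self):
        """The adjustment mechanism requires that a pseudo-biomarker's
        selected abundance covariates actually track its abundance: their
        |correlation| with the target should exceed the median |correlation|
        over all candidates (averaged over replicates)."""
        from jmr.io import filter_taxa
        from jmr.simulate import sim_scenario_b

        sel_cors, med_cors = [], []
        for seed in (101, 202, 303):
            sim = sim_scenario_b(P=80, S=40, T=4, gamma=0.7, lam=0.8, seed=seed)
            table = filter_taxa(sim.table)
            avail = table.taxa.tolist()
            m0 = [t for t in sim.truth.M_zero if t in avail]
            for t in m0:
                res = preselect_covariates(table, t, seed=7)
                if not res.abundance_covariates:
                    continue
                y = table.abundance.loc[t].to_numpy()
                cors = {
                    c: abs(np.corrcoef(y, table.abundance.loc[c].to_numpy())[0, 1])
                    for c in avail if c != t
                }
                sel_cors.append(np.mean([cors[c] for c in res.abundance_covariates]))
                med_cors.append(np.median(list(cors.values())))
        assert len(sel_cors) >= 3, "fixture produced too few refinable targets"
        assert np.mean(sel_cors) > np.mean(med_cors)
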