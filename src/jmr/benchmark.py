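"""Baseline method and evaluation metrics for simulation benchmarks.

The baseline is the standard field approach: a linear mixed model on
arcsin-square-root transformed relative abundance with a single subject
random intercept (LMM-S) or subject-within-set nested intercepts (LMM-N),
fixed effects for age, genotype, disease status and the genotype-disease
interaction; the intercept test is the Wald test on the disease main
effect and the slope test the Wald test on a disease-by-age interaction.

Metrics follow the matched-cohort simulation design: sensitivity on the
true biomarkers (M+ and M-), FPR/FDR on null taxa, and the false-or-pseudo
positive rate FPPR = positives outside M+ u M- divided by the number of
taxa outside M+ u M- (pseudo biomarkers M0 cannot be separated from false
positives in compositional data, hence the combined rate).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .data import LongitudinalTaxaTable, MatchedCohort
from .density import bh_adjust
from .fit import test_taxa
from .model import JMRSpec, TaxonTestResult
from .preselect import preselect_covariates
from .simulate import SimTruth, sim_scenario_b, sim_scenario_c

__all__ = [
    "asin_sqrt",
    "fit_lmm_baseline",
    "lmm_test_taxa",
    "evaluate_metrics",
    "run_benchmark",
    "BenchmarkGrid",
]

log = logging.getLogger(__name__)


def asin_sqrt(y):
    """Arcsin-square-root (angular) transform of relative abundance."""
    y = np.asarray(y, float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("y must lie in [0, 1]")
    out = np.arcsin(np.sqrt(y))
    return out if out.ndim else float(out)


def _lmm_frame(table: LongitudinalTaxaTable, cohort: MatchedCohort, taxon: str) -> pd.DataFrame:
    df = table.samples.copy()
    df["y"] = asin_sqrt(table.abundance.loc[taxon].to_numpy(float))
    subj = cohort.subjects.set_index("subject_id")
    df["disease"] = df["subject_id"].map(subj["outcome"]).astype(float)
    gcol = cohort.covariates[0] if cohort.covariates else None
    df["genotype"] = df["subject_id"].map(subj[gcol]).astype(float) if gcol else 0.0
    df["set_id"] = df["subject_id"].map(subj["set_id"])
    age = df["age"].to_numpy(float)
    lo, hi = age.min(), age.max()
    df["age_s"] = (age - lo) / (hi - lo) if hi > lo else 0.0
    return df


def fit_lmm_baseline(
    table: LongitudinalTaxaTable,
    cohort: MatchedCohort,
    taxon: str,
    nested: bool = True,
    test_mode: str = "intercept",
) -> TaxonTestResult:
    """Wald test of disease association from the transformed-LMM baseline.

    ``nested=True`` adds a matched-set random intercept above the subject
    intercept (LMM-N); ``nested=False`` is the single-random-effect LMM-S.
    A singular or failed fit yields an NA result.
    """
    df = _lmm_frame(table, cohort, taxon)
    if df["y"].var() == 0:
        return TaxonTestResult(taxon, float("nan"), float("nan"), 0, status="constant")
    fixed = "y ~ age_s + genotype + disease + genotype:disease"
    term = "disease"
    if test_mode == "slope":
        fixed += " + disease:age_s"
        term = "disease:age_s"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if nested:
                model = smf.mixedlm(fixed, df, groups=df["set_id"],
                                    re_formula="1",
                                    vc_formula={"subject": "0 + C(subject_id)"})
            else:
                model = smf.mixedlm(fixed, df, groups=df["subject_id"], re_formula="1")
            try:
                res = model.fit(reml=True, maxiter=200)
            except np.linalg.LinAlgError:
                res = model.fit(reml=True, method="powell", maxiter=500)
        z = res.params[term] / res.bse[term]
        W = float(z**2)
        from scipy.stats import chi2
        return TaxonTestResult(taxon, W, float(chi2.sf(W, 1)), 1)
    except Exception as err:  # singular fits, convergence failures
        log.warning("LMM fit failed for %s: %s", taxon, err)
        return TaxonTestResult(taxon, float("nan"), float("nan"), 0, status="failed")


def lmm_test_taxa(
    table: LongitudinalTaxaTable,
    cohort: MatchedCohort,
    nested: bool = True,
    test_mode: str = "intercept",
    taxa: list[str] | None = None,
) -> pd.DataFrame:
    taxa = list(taxa) if taxa is not None else list(table.taxa)
    rows = []
    for t in taxa:
        r = fit_lmm_baseline(table, cohort, t, nested=nested, test_mode=test_mode)
        rows.append({"taxon": t, "W": r.W, "p": r.p, "status": r.status})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def evaluate_metrics(
    results: pd.DataFrame,
    truth: SimTruth,
    p_cut: float = 0.05,
    q_cut: float | None = None,
) -> dict[str, float]:
    """Benchmark metrics against simulation ground truth.

    ``q_cut`` switches calling to the BH-adjusted q (used for the
    high-dimensional scenarios, cutoff 0.15 in the benchmark); otherwise
    raw p at ``p_cut``.  Metrics: sensitivity on M+ u M-, FPR and type I
    error on null taxa, FDR among calls (0 when nothing is called), and
    FPPR on the complement of M+ u M-.
    """
    res = results.set_index("taxon")
    if q_cut is not None:
        called = res["q"] < q_cut
    else:
        called = res["p"] < p_cut
    called = called.fillna(False)
    truth_lab = truth.label_of()
    missing = set(truth_lab) - set(res.index)
    if missing:
        raise ValueError(f"results missing taxa: {sorted(missing)[:5]}")
    true_set = set(truth.M_plus) | set(truth.M_minus)
    null_set = set(truth.null)
    outside = [t for t in truth_lab if t not in true_set]
    n_called = int(called.loc[list(truth_lab)].sum())
    tp = int(called.loc[[t for t in true_set]].sum()) if true_set else 0
    fp_null = int(called.loc[[t for t in null_set]].sum()) if null_set else 0
    fp_outside = int(called.loc[outside].sum()) if outside else 0
    return {
        "sensitivity": tp / len(true_set) if true_set else float("nan"),
        "fpr": fp_null / len(null_set) if null_set else float("nan"),
        "type_i_error": fp_null / len(null_set) if null_set else float("nan"),
        "fdr": (n_called - tp) / n_called if n_called else 0.0,
        "fppr": fp_outside / len(outside) if outside else float("nan"),
        "n_called": float(n_called),
    }


@dataclass
class BenchmarkGrid:
    metrics: pd.DataFrame            # long format: scenario, method, replicate, metric columns
    config: dict = field(default_factory=dict)
    replicate_seeds: list[int] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        cols = ["sensitivity", "fpr", "fdr", "fppr"]
        return self.metrics.groupby(["scenario", "method"])[cols].mean()


def _jmr_results(table: LongitudinalTaxaTable, cohort: MatchedCohort, spec: JMRSpec,
                 with_covariates: bool, seed: int, maxiter: int) -> pd.DataFrame:
    cov_sets = None
    if with_covariates:
        cov_sets = {}
        for t in table.taxa:
            cov_sets[t] = preselect_covariates(table, t, seed=seed).as_covariate_set()
    return test_taxa(cohort, table, spec, covariate_sets=cov_sets, maxiter=maxiter)


def _reindex_results(res: pd.DataFrame, all_taxa: list[str]) -> pd.DataFrame:
    """Add NaN rows for taxa removed by filtering (treated as not called)."""
    res = res.set_index("taxon").reindex(all_taxa)
    return res.reset_index().rename(columns={"index": "taxon"})


def run_benchmark(
    scenario: str = "B1",
    methods: tuple[str, ...] = ("JMR", "JMR-NC"),
    n_replicates: int = 10,
    P: int = 120,
    S: int = 100,
    T: int = 4,
    gamma: float = 0.7,
    lam: float = 0.7,
    q_cut: float = 0.15,
    test_mode: str | None = None,
    gh_nodes: int = 5,
    rho: float = 0.1,
    seed: int = 0,
    maxiter: int = 300,
) -> BenchmarkGrid:
    """Replicated scenario benchmark over the requested methods.

    Scenarios: "B1" (random intercept, pseudo biomarkers), "B2" (random
    slope), "C" (half null, no pseudo biomarkers).  Methods: "JMR",
    "JMR-NC", "JR-NC", "LMM-N", "LMM-S".  Replicate seeds are spawned
    deterministically from ``seed`` and recorded.
    """
    if scenario not in ("B1", "B2", "C"):
        raise ValueError("scenario must be B1, B2 or C")
    test_mode = test_mode or ("slope" if scenario == "B2" else "intercept")
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_replicates)]
    from .io import filter_taxa

    rows = []
    for rep, rs in enumerate(rep_seeds):
        if scenario == "C":
            sim = sim_scenario_c(P=P, S=S, T=T, gamma=gamma, lam=lam, seed=rs)
        else:
            sim = sim_scenario_b(P=P, S=S, T=T, gamma=gamma, lam=lam,
                                 slope_mode=(scenario == "B2"), seed=rs)
        all_taxa = list(sim.table.taxa)
        table = filter_taxa(sim.table)  # standard abundance/prevalence filter
        for method in methods:
            if method.startswith("LMM"):
                res = lmm_test_taxa(table, sim.cohort,
                                    nested=(method == "LMM-N"), test_mode=test_mode)
            else:
                spec = JMRSpec(test_mode=test_mode, variant=method,
                               gh_nodes=gh_nodes, rho=rho)
                res = _jmr_results(table, sim.cohort, spec, method == "JMR", rs, maxiter)
            m = evaluate_metrics(_reindex_results(res, all_taxa), sim.truth, q_cut=q_cut)
            m.update({"scenario": scenario, "method": method, "replicate": rep,
                      "seed": rs, "gamma": gamma, "lambda": lam, "N": 2 * S})
            rows.append(m)
    metrics = pd.DataFrame(rows)
    cfg = dict(scenario=scenario, methods=list(methods), n_replicates=n_replicates,
               P=P, S=S, T=T, gamma=gamma, lam=lam, q_cut=q_cut,
               test_mode=test_mode, gh_nodes=gh_nodes, rho=rho, seed=seed)
    return BenchmarkGrid(metrics=metrics, config=cfg, replicate_seeds=rep_seeds)
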