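"""Ridge-penalty selection by matched-set five-fold cross-validation.

A small panel of ``P0`` representative taxa is drawn across abundance
decades; matched sets (never individual subjects) are partitioned into
five folds; for every penalty on a log-spaced grid the model is fit on
four folds and scored by the negative penalized log-likelihood on the
held-out fold.  The selected penalty is the elbow of the mean loss curve:
the grid point maximizing the discrete second difference of the loss over
log-rho, falling back to the arg-min when the curve is monotone (no knee).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import LongitudinalTaxaTable, MatchedCohort
from .fit import _make_objective, _Layout, fit_jmr, pack_data
from .model import JMRSpec

__all__ = ["CVResult", "default_rho_grid", "select_representative_otus", "find_elbow", "cv_rho"]

log = logging.getLogger(__name__)


def default_rho_grid(n: int = 8) -> np.ndarray:
    """Log-spaced penalty grid in [1e-3, 10]."""
    return np.logspace(-3, 1, n)


@dataclass
class CVResult:
    rho_grid: np.ndarray
    mean_loss: np.ndarray               # S(rho), averaged over folds and taxa
    fold_losses: pd.DataFrame           # long format: rho, fold, taxon, loss
    selected_rho: float
    taxa: list[str] = field(default_factory=list)
    fold_of_set: dict = field(default_factory=dict)


def select_representative_otus(
    table: LongitudinalTaxaTable, P0: int = 12, seed: int = 0
) -> list[str]:
    """Stratified draw of ``P0`` taxa across relative-abundance decades.

    Taxa are binned by ``floor(-log10(mean relative abundance))`` into
    unit-width bins; the draw allocates round-robin across non-empty bins
    (so the panel spans the abundance range) and is seeded.
    """
    means = table.abundance.mean(axis=1)
    means = means[means > 0]
    if P0 > len(means):
        raise ValueError("P0 exceeds the number of non-empty taxa")
    rng = np.random.default_rng(seed)
    bins = np.floor(-np.log10(means.to_numpy())).astype(int)
    chosen: list[str] = []
    by_bin: dict[int, list[str]] = {}
    for t, b in zip(means.index, bins):
        by_bin.setdefault(b, []).append(t)
    # bin members sorted before shuffling: selection is invariant to the
    # taxon ordering of the input table
    pools = {b: list(rng.permutation(sorted(v))) for b, v in sorted(by_bin.items())}
    while len(chosen) < P0:
        progressed = False
        for b in sorted(pools):
            if pools[b] and len(chosen) < P0:
                chosen.append(pools[b].pop())
                progressed = True
        if not progressed:
            break
    return chosen


def find_elbow(rho_grid: np.ndarray, mean_loss: np.ndarray) -> float:
    """Elbow of a loss curve over a sorted log-spaced grid.

    Returns the rho maximizing the discrete second difference of the loss
    (the point of strongest convex bend); for grids shorter than 3 or a
    monotone second-difference-free curve, the arg-min of the loss.
    """
    rho = np.asarray(rho_grid, float)
    S = np.asarray(mean_loss, float)
    order = np.argsort(rho)
    rho, S = rho[order], S[order]
    if rho.size == 1:
        return float(rho[0])
    if rho.size < 3:
        return float(rho[int(np.argmin(S))])
    d2 = S[:-2] - 2 * S[1:-1] + S[2:]
    tol = 1e-9 * max(1.0, float(np.max(np.abs(S))))  # ignore float noise
    if np.all(d2 <= tol):  # no convex bend anywhere: monotone/concave curve
        return float(rho[int(np.argmin(S))])
    return float(rho[1 + int(np.argmax(d2))])


def _fold_assignment(set_ids: list, seed: int, n_folds: int = 5) -> dict:
    rng = np.random.default_rng(seed)
    ids = list(set_ids)
    perm = rng.permutation(len(ids))
    return {ids[p]: f % n_folds for f, p in enumerate(perm)}


def cv_rho(
    cohort: MatchedCohort,
    table: LongitudinalTaxaTable,
    rho_grid: np.ndarray | None = None,
    P0: int = 12,
    spec: JMRSpec | None = None,
    seed: int = 0,
    maxiter: int = 200,
) -> CVResult:
    """Five-fold matched-set cross-validation of the ridge penalty.

    For each fold and panel taxon, the model is fit on the training sets
    at every rho and scored by the negative penalized log-likelihood of
    the held-out sets (penalty recomputed at the training estimate).
    Non-converged fold fits are excluded with a warning; more than 20%
    exclusions abort.
    """
    spec = spec or JMRSpec(variant="JMR-NC")
    if cohort.n_sets < 5:
        raise ValueError("need at least 5 matched sets for 5-fold CV")
    rho_grid = np.sort(np.asarray(default_rho_grid() if rho_grid is None else rho_grid, float))
    taxa = select_representative_otus(table, P0=min(P0, len(table.taxa)), seed=seed)
    fold_of = _fold_assignment(sorted(cohort.subjects["set_id"].unique()), seed)

    records = []
    n_bad = 0
    n_total = 0
    for fold in range(5):
        train_sets = {s for s, f in fold_of.items() if f != fold}
        val_sets = {s for s, f in fold_of.items() if f == fold}
        if not val_sets:
            continue
        tr_cohort, tr_table = _subset(cohort, table, train_sets)
        va_cohort, va_table = _subset(cohort, table, val_sets)
        for taxon in taxa:
            for rho in rho_grid:
                rspec = JMRSpec(test_mode=spec.test_mode, variant=spec.variant,
                                gh_nodes=spec.gh_nodes, rho=float(rho))
                fit = fit_jmr(tr_cohort, tr_table, taxon, rspec, maxiter=maxiter)
                n_total += 1
                if not fit.converged or fit.theta is None:
                    n_bad += 1
                    log.warning("fold %d taxon %s rho %.3g: fit excluded (%s)",
                                fold, taxon, rho, fit.status)
                    continue
                loss = _validation_loss(va_cohort, va_table, taxon, rspec,
                                        fit.theta, fit.presence_part)
                records.append({"rho": float(rho), "fold": fold, "taxon": taxon,
                                "loss": loss})
    if n_total and n_bad / n_total > 0.2:
        raise RuntimeError(f"{n_bad}/{n_total} cross-validation fits failed to converge")
    df = pd.DataFrame(records)
    mean_loss = df.groupby("rho")["loss"].mean().reindex(rho_grid).to_numpy()
    sel = find_elbow(rho_grid, mean_loss)
    return CVResult(rho_grid=rho_grid, mean_loss=mean_loss, fold_losses=df,
                    selected_rho=sel, taxa=taxa, fold_of_set=fold_of)


def _subset(cohort: MatchedCohort, table: LongitudinalTaxaTable, sets) -> tuple:
    subj = cohort.subjects[cohort.subjects["set_id"].isin(sets)].reset_index(drop=True)
    sub_cohort = MatchedCohort(subj, covariates=list(cohort.covariates))
    keep = table.samples["subject_id"].isin(set(subj["subject_id"]))
    smeta = table.samples[keep].reset_index(drop=True)
    abund = table.abundance.loc[:, smeta["sample_id"]]
    sub_table = LongitudinalTaxaTable(abundance=abund, samples=smeta,
                                      covariates=list(table.covariates))
    return sub_cohort, sub_table


def _validation_loss(cohort, table, taxon, spec: JMRSpec, theta: np.ndarray,
                     use_presence: bool) -> float:
    """Negative penalized log-likelihood of held-out sets at a fixed theta.

    ``use_presence`` follows the training fit so the parameter layout
    matches even when the held-out fold is degenerate for the taxon.
    """
    packed = pack_data(cohort, table, taxon, spec)
    layout = _Layout(packed, spec, use_presence)
    if layout.n != theta.size:
        raise ValueError("parameter layout changed between folds (degenerate taxon)")
    _, objective, _ = _make_objective(packed, layout, spec)
    return float(objective(theta))
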