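"""Two-stage pre-selection of covariate taxa for a target taxon.

Stage 1 screens candidates by Bray-Curtis distance between across-sample
taxon profiles (relative abundance for the abundance part, 0/1 presence
for the presence part), keeping candidates strictly below the 0.1
empirical quantile of the distance-to-target vector.  All longitudinal
samples are treated as independent.  Stage 2 refines the screened set by
elastic-net regression (linear on non-zero abundance, logistic on
presence), keeping taxa with non-zero coefficients at the CV-selected
penalty.  On 0/1 vectors the Bray-Curtis formula equals one minus the
Sorensen-Dice overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNetCV, LogisticRegressionCV
from sklearn.model_selection import KFold

from .data import CovariateTaxaSet, LongitudinalTaxaTable

__all__ = [
    "PreselectionResult",
    "bray_curtis",
    "screen_by_distance",
    "elastic_net_refine",
    "preselect_covariates",
]

log = logging.getLogger(__name__)

_L1_RATIO = 0.5          # balanced elastic-net mixing
_MIN_CANDIDATES = 10     # below this, keep the single nearest candidate


@dataclass
class PreselectionResult:
    target: str
    abundance_covariates: list[str] = field(default_factory=list)
    presence_covariates: list[str] = field(default_factory=list)
    quantile: float = 0.1
    l1_ratio: float = _L1_RATIO

    def as_covariate_set(self) -> CovariateTaxaSet:
        return CovariateTaxaSet(
            target=self.target,
            abundance_covariates=list(self.abundance_covariates),
            presence_covariates=list(self.presence_covariates),
        )


def bray_curtis(u, v) -> float:
    """Bray-Curtis dissimilarity ``sum|u - v| / sum(u + v)`` in [0, 1]."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    if u.shape != v.shape:
        raise ValueError("profiles must have equal length")
    if np.any(u < 0) or np.any(v < 0):
        raise ValueError("profiles must be nonnegative")
    denom = float((u + v).sum())
    if denom == 0:
        raise ValueError("both profiles are all-zero")
    return float(np.abs(u - v).sum() / denom)


def screen_by_distance(
    target_profile: np.ndarray,
    candidate_profiles: dict[str, np.ndarray] | "pandas.DataFrame",
    q: float = 0.1,
) -> list[str]:
    """Keep candidates with Bray-Curtis distance to the target strictly
    below the ``q`` empirical quantile (type-7, linear interpolation) of
    the distance-to-target vector.

    With fewer than 10 candidates the quantile is unreliable and the
    single nearest candidate is kept instead.
    """
    try:
        items = list(candidate_profiles.items())  # dict-like
    except AttributeError:
        items = [(str(i), row) for i, row in enumerate(candidate_profiles)]
    if len(items) < 2:
        raise ValueError("need at least 2 candidates to screen")
    names = [k for k, _ in items]
    d = np.array([bray_curtis(target_profile, v) for _, v in items])
    if len(items) < _MIN_CANDIDATES:
        log.info("fewer than %d candidates: keeping single nearest", _MIN_CANDIDATES)
        return [names[int(np.argmin(d))]]
    cut = float(np.quantile(d, q))  # numpy default = type-7 linear
    return [n for n, di in zip(names, d) if di < cut]


def _seeded_folds(n: int, seed: int) -> KFold:
    return KFold(n_splits=5, shuffle=True, random_state=seed)


def elastic_net_refine(
    target_response: np.ndarray,
    candidate_matrix: np.ndarray,
    candidate_names: list[str],
    mode: str,
    seed: int = 0,
) -> list[str]:
    """Elastic-net refinement of a screened candidate set.

    ``mode="abundance"``: linear elastic net of the target's non-zero
    relative abundance on candidate relative abundances (rows restricted
    to samples with target > 0 by the caller).  ``mode="presence"``:
    logistic elastic net of the target's presence indicator on candidate
    presence indicators.  Returns names with non-zero coefficients at the
    five-fold CV-selected penalty.
    """
    X = np.asarray(candidate_matrix, float)
    y = np.asarray(target_response, float)
    if X.shape[1] == 0:
        return []
    if X.shape[0] != y.size:
        raise ValueError("response and candidate matrix are misaligned")
    if np.unique(y).size < 2:
        log.info("constant response in %s refinement: empty selection", mode)
        return []
    if mode == "abundance":
        model = ElasticNetCV(
            l1_ratio=_L1_RATIO, alphas=40, cv=_seeded_folds(y.size, seed),
            max_iter=2000, tol=1e-4,
        )
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore", ConvergenceWarning)
            model.fit(X, y)
        coefs = model.coef_
    elif mode == "presence":
        model = LogisticRegressionCV(
            solver="saga", l1_ratios=[_L1_RATIO],
            Cs=7, cv=_seeded_folds(y.size, seed), max_iter=300, tol=1e-3,
            scoring="neg_log_loss", random_state=seed,
        )
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore", ConvergenceWarning)
            model.fit(X, y.astype(int))
        coefs = model.coef_.ravel()
    else:
        raise ValueError("mode must be 'abundance' or 'presence'")
    return [n for n, c in zip(candidate_names, coefs) if c != 0.0]


def preselect_covariates(
    table: LongitudinalTaxaTable,
    target: str,
    q: float = 0.1,
    seed: int = 0,
    restrict_to: list[str] | None = None,
) -> PreselectionResult:
    """Run the two-stage pre-selection for one target taxon.

    ``restrict_to`` optionally limits candidates to a named sub-community.
    Deterministic given the data and ``seed`` (the CV fold seed).
    """
    if target not in table.abundance.index:
        raise KeyError(f"target {target!r} not in table")
    candidates = [t for t in table.taxa if t != target]
    if restrict_to is not None:
        allowed = set(restrict_to)
        candidates = [t for t in candidates if t in allowed]
    if len(candidates) < 2:
        return PreselectionResult(target=target, quantile=q)
    rel = table.abundance
    y = rel.loc[target].to_numpy(float)
    if y.sum() == 0:
        log.info("target %s never present: no covariates selected", target)
        return PreselectionResult(target=target, quantile=q)

    abund_profiles = {t: rel.loc[t].to_numpy(float)
                      for t in candidates if rel.loc[t].sum() > 0}
    kept_a = screen_by_distance(y, abund_profiles, q) if len(abund_profiles) >= 2 else []
    pres = (rel > 0).astype(float)
    ty = pres.loc[target].to_numpy()
    pres_profiles = {t: pres.loc[t].to_numpy() for t in abund_profiles}
    kept_p = screen_by_distance(ty, pres_profiles, q) if len(pres_profiles) >= 2 else []

    pos = y > 0
    sel_a: list[str] = []
    if kept_a and pos.sum() >= 10:
        Xa = np.column_stack([abund_profiles[t][pos] for t in kept_a])
        sel_a = elastic_net_refine(y[pos], Xa, kept_a, "abundance", seed)
    sel_p: list[str] = []
    if kept_p and 0 < ty.sum() < ty.size:
        Xp = np.column_stack([pres_profiles[t] for t in kept_p])
        sel_p = elastic_net_refine(ty, Xp, kept_p, "presence", seed)
    return PreselectionResult(
        target=target, abundance_covariates=sel_a, presence_covariates=sel_p,
        quantile=q,
    )
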