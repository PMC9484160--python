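"""Matched-cohort metagenome simulator.

Generates synthetic data emulating a prospective matched case-control
microbiome study (1:1 pairs, roughly monthly sampling, zero-inflated
compositional counts):

* ``stat_sim`` draws latent subject/set risk, binarizes it at the median,
  and produces binary disease outcomes from a logistic model.
* ``sim_scenario_a`` draws single-taxon counts through a Beta-Binomial
  hierarchy with optional set- and subject-level disease shifts.
* ``sim_scenario_b`` / ``sim_scenario_c`` draw a full taxa-by-sample count
  table through a Dirichlet hierarchy combined with a compositional
  shifting procedure that creates true biomarkers (M+ up, M- down in
  high-risk subjects) and -- via the sum-to-one constraint -- pseudo
  biomarkers (M0), plus null taxa.
* ``sim_joint_model`` draws data directly from the joint model itself
  (shared random effects, zero-inflated Beta observations), used for
  parameter-recovery checks.

Dirichlet draws with mean ``m`` and overdispersion ``xi`` use
concentration ``m * (1 - xi) / xi`` (so ``xi = 1 / (1 + sum(conc))``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import LongitudinalTaxaTable, MatchedCohort

__all__ = [
    "RiskLabels",
    "SimTruth",
    "ScenarioResult",
    "stat_sim",
    "sim_scenario_a",
    "shift_composition",
    "max_shift",
    "sim_scenario_b",
    "sim_scenario_c",
    "sim_joint_model",
]


@dataclass
class RiskLabels:
    """Latent risk draws and their median-binarized high-risk indicators."""

    a: np.ndarray  # per-subject latent N(0,1)
    b: np.ndarray  # per-set latent N(0,1)
    A: np.ndarray  # per-subject high-risk indicator
    B: np.ndarray  # per-set high-risk indicator
    G: np.ndarray  # per-subject genotype covariate


@dataclass
class SimTruth:
    """Ground-truth biomarker labels of a simulated count table."""

    M_plus: list[str]
    M_minus: list[str]
    M_zero: list[str]
    null: list[str]
    params: dict = field(default_factory=dict)

    def label_of(self) -> dict[str, str]:
        out = {t: "M+" for t in self.M_plus}
        out.update({t: "M-" for t in self.M_minus})
        out.update({t: "M0" for t in self.M_zero})
        out.update({t: "null" for t in self.null})
        return out


@dataclass
class ScenarioResult:
    cohort: MatchedCohort
    labels: RiskLabels
    table: LongitudinalTaxaTable
    truth: SimTruth | None = None


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def stat_sim(
    S: int,
    J: int = 2,
    alpha: tuple[float, float, float, float] = (0.5, -2.0, 1.0, 1.0),
    seed=None,
) -> tuple[MatchedCohort, RiskLabels]:
    """Simulate matched-set disease outcomes.

    Latent risks ``a_sj, b_s ~ N(0, 1)`` are binarized at their medians
    into high-risk indicators ``A, B``; a binary genotype ``G ~
    Bernoulli(0.5)`` is drawn per subject; outcomes follow
    ``logit(p) = a0 + a1 G + a2 A + a3 B`` with ``alpha = (a0, a1, a2, a3)``.
    """
    if S < 2:
        raise ValueError("need at least 2 matched sets")
    rng = _rng(seed)
    n = S * J
    a = rng.standard_normal(n)
    b = rng.standard_normal(S)
    A = (a > np.median(a)).astype(int)
    B = (b > np.median(b)).astype(int)
    G = rng.integers(0, 2, n)
    a0, a1, a2, a3 = alpha
    Bsub = np.repeat(B, J)
    p = expit(a0 + a1 * G + a2 * A + a3 * Bsub)
    O = rng.binomial(1, p)
    set_ids = [f"set{s:04d}" for s in range(S)]
    subjects = pd.DataFrame({
        "subject_id": [f"set{s:04d}_subj{j}" for s in range(S) for j in range(J)],
        "set_id": np.repeat(set_ids, J),
        "outcome": O,
        "G": G,
    })
    cohort = MatchedCohort(subjects, covariates=["G"])
    return cohort, RiskLabels(a=a, b=b, A=A, B=B, G=G)


def _beta_mp(rng, mean, precision, size=None):
    """Beta draw in the mean/precision parameterization, domain-guarded."""
    m = np.clip(mean, 1e-10, 1 - 1e-10)
    return rng.beta(m * precision, (1 - m) * precision, size=size)


def sim_scenario_a(
    cohort: MatchedCohort,
    labels: RiskLabels,
    *,
    T: int = 4,
    mu0: float = 0.005,
    phi0: float = 200.0,
    phi_t: float = 50.0,
    phi_st: float = 100.0,
    delta_set: float = 0.0,
    delta_subject: float = 0.0,
    age_slope: float = 0.5,
    set_shift_sign: int = 1,
    subject_shift_sign: int = 1,
    mean_libsize: float = 100_000.0,
    seed=None,
    taxon: str = "otu_a",
) -> LongitudinalTaxaTable:
    """Single-taxon Beta-Binomial counts with risk-label shifts.

    The taxon's study-level mean at the first time point is ``mu1 ~
    Beta(mu0, phi0)`` and increases linearly to ``mu1 * (1 + age_slope)``
    at the last time point.  Set-level means are ``Beta(mu_t, phi_t)``
    shifted by ``+/- delta_set`` for high-risk sets; subject-level means
    are ``Beta(mu_st, phi_st)`` shifted by ``+/- delta_subject`` for
    high-risk subjects.  Library sizes are Poisson(``mean_libsize``) and
    counts Binomial.  Setting both deltas to zero gives the null
    configuration (abundance independent of disease risk).
    """
    rng = _rng(seed)
    subj = cohort.subjects
    n = len(subj)
    S = cohort.n_sets
    J = n // S
    set_code = subj["set_id"].astype("category").cat.codes.to_numpy()
    mu1 = float(_beta_mp(rng, mu0, phi0))
    mu1 = float(np.clip(mu1, 1e-6, 0.9))
    counts = np.zeros((1, n * T))
    libsizes = np.zeros(n * T)
    sample_ids, subject_ids, ages = [], [], []
    eps = 1e-8
    col = 0
    for t in range(1, T + 1):
        frac = (t - 1) / max(T - 1, 1)
        mu_t = float(np.clip(mu1 * (1.0 + age_slope * frac), 1e-8, 1 - 1e-8))
        mu_st = np.clip(_beta_mp(rng, mu_t, phi_t, size=S), eps, 1 - eps)
        shift_s = set_shift_sign * delta_set * labels.B
        if delta_set > 0 and np.any(
            (mu_st + shift_s <= 0) | (mu_st + shift_s >= 1)
        ):
            warnings.warn("set-level shift truncated to keep the mean inside (0, 1)",
                          stacklevel=2)
        mu_st = np.clip(mu_st + shift_s, eps, 1 - eps)
        for i in range(n):
            m = mu_st[set_code[i]]
            mu_sjt = float(np.clip(_beta_mp(rng, m, phi_st), eps, 1 - eps))
            sh = subject_shift_sign * delta_subject * labels.A[i]
            if sh != 0 and not (0 < mu_sjt + sh < 1):
                warnings.warn("subject-level shift truncated to keep the mean inside (0, 1)",
                              stacklevel=2)
            mu_sjt = float(np.clip(mu_sjt + sh, eps, 1 - eps))
            N = max(int(rng.poisson(mean_libsize)), 1)
            counts[0, col] = rng.binomial(N, mu_sjt)
            libsizes[col] = N
            sid = subj["subject_id"].iloc[i]
            sample_ids.append(f"{sid}_t{t}")
            subject_ids.append(sid)
            ages.append(t)
            col += 1
    counts_df = pd.DataFrame(counts, index=[taxon], columns=sample_ids)
    samples = pd.DataFrame({"sample_id": sample_ids, "subject_id": subject_ids, "age": ages})
    return LongitudinalTaxaTable.from_counts(
        counts_df, samples, library_sizes=pd.Series(libsizes, index=sample_ids)
    )


def max_shift(eta: np.ndarray, decrease_sets, weights=None) -> float:
    """Largest total shift keeping all entries nonnegative.

    With removal allocated within each decrease set proportionally to
    current frequency and split across sets by ``weights``, entries reach
    zero only when a set's whole mass is removed, so the bound is
    ``min_k(mass_k / w_k)``.
    """
    decrease_sets = [np.asarray(ix, int) for ix in decrease_sets]
    if weights is None:
        weights = [1.0 / len(decrease_sets)] * len(decrease_sets)
    bound = np.inf
    for ix, w in zip(decrease_sets, weights):
        if w <= 0:
            continue
        bound = min(bound, float(eta[ix].sum()) / w)
    return bound


def shift_composition(
    eta: np.ndarray,
    increase_set,
    decrease_sets,
    delta: float,
    weights=None,
) -> np.ndarray:
    """Move total mass ``delta`` into ``increase_set`` out of ``decrease_sets``.

    ``decrease_sets`` is one index array or a sequence of them; ``weights``
    split ``delta`` across the decrease sets (default equal).  Mass is
    allocated within each set proportionally to current frequencies, the
    requested ``delta`` is capped at the sum-to-one maximum
    (:func:`max_shift`), and the result sums to the input sum exactly.
    """
    eta = np.asarray(eta, float)
    if delta < 0:
        raise ValueError("delta must be >= 0")
    inc = np.asarray(increase_set, int)
    if isinstance(decrease_sets, np.ndarray) or (
        len(decrease_sets) > 0 and np.isscalar(decrease_sets[0])
    ):
        decrease_sets = [decrease_sets]
    dec = [np.asarray(ix, int) for ix in decrease_sets]
    if delta > 0 and (inc.size == 0 or all(d.size == 0 for d in dec)):
        raise ValueError("empty increase or decrease set with delta > 0")
    flat = np.concatenate([inc] + dec)
    if flat.size != np.unique(flat).size:
        raise ValueError("increase and decrease sets must be disjoint")
    if weights is None:
        weights = [1.0 / len(dec)] * len(dec)
    weights = np.asarray(weights, float)
    if weights.size != len(dec) or np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("weights must be nonnegative and match decrease_sets")
    weights = weights / weights.sum()
    delta = min(delta, max_shift(eta, dec, weights))
    out = eta.copy()
    if delta == 0:
        return out
    removed = 0.0
    for ix, w in zip(dec, weights):
        mass = out[ix].sum()
        take = delta * w
        if mass > 0:
            # max(., 0): the capped shift can land a hair past zero in floats
            out[ix] *= max(1.0 - take / mass, 0.0)
            removed += take
    inc_mass = out[inc].sum()
    # proportional allocation is meaningless (and overflows) when the
    # increase set carries essentially no mass: fall back to uniform
    with np.errstate(over="ignore", invalid="ignore"):
        ratio = removed / inc_mass if inc_mass > 0 else np.inf
    if np.isfinite(ratio) and ratio < 1e12:
        out[inc] *= 1.0 + ratio
    else:
        out[inc] += removed / inc.size
    return out


def _truth_partition_b(P: int, m0_frac: float, rng) -> tuple[np.ndarray, ...]:
    n15 = round(0.15 * P)
    if n15 < 1 or 2 * n15 >= P:
        raise ValueError("P too small for the 15%/15%/70% biomarker split")
    perm = rng.permutation(P)
    mp, mm, rest = perm[:n15], perm[n15: 2 * n15], perm[2 * n15:]
    n0 = min(round(m0_frac * P), rest.size)
    m0 = rng.choice(rest, size=n0, replace=False)
    null = np.setdiff1d(rest, m0)
    return mp, mm, m0, null


def _truth_partition_c(P: int, rng) -> tuple[np.ndarray, ...]:
    perm = rng.permutation(P)
    n_null = round(0.5 * P)
    n_p = round(0.1 * P)
    n_m = round(0.4 * P)
    null, mp = perm[:n_null], perm[n_null: n_null + n_p]
    mm = perm[n_null + n_p: n_null + n_p + n_m]
    return mp, mm, np.empty(0, int), null


def _sim_counts_table(
    P, S, T, gamma, lam, d, slope_mode, seed, partition,
    m0_frac, alpha, age_effect, xi0, xi1, xi_last, xi_star,
    mean_libsize, min_libsize,
) -> ScenarioResult:
    rng = _rng(seed)
    cohort, labels = stat_sim(S, 2, alpha, seed=rng)
    subj = cohort.subjects
    n = len(subj)
    set_code = subj["set_id"].astype("category").cat.codes.to_numpy()

    # Step 1: baseline composition spanning ~6 orders of magnitude, then a
    # Dirichlet draw around it (synthetic stand-in for a cohort-estimated
    # baseline profile)
    eta0 = 10.0 ** (-rng.uniform(0.0, 6.0, P))
    eta0 /= eta0.sum()
    eta01 = rng.dirichlet(eta0 * (1 - xi0) / xi0)

    # Step 2 partitions: every taxon ages up or down
    base_perm = rng.permutation(P)
    mp_base, mm_base = base_perm[: P // 2], base_perm[P // 2:]

    if partition == "B":
        mp, mm, m0, null = _truth_partition_b(P, m0_frac, rng)
        dec_sets, dec_w = [mm, m0], [d, 1.0 - d]
        if m0.size == 0:
            dec_sets, dec_w = [mm], [1.0]
    else:
        mp, mm, m0, null = _truth_partition_c(P, rng)
        dec_sets, dec_w = [mm], [1.0]

    taxa = [f"otu{i:04d}" for i in range(P)]
    counts = np.zeros((P, n * T), dtype=np.int64)
    libsizes = np.zeros(n * T)
    sample_ids = [f"{sid}_t{t}" for t in range(1, T + 1) for sid in subj["subject_id"]]
    subject_ids = [sid for _ in range(T) for sid in subj["subject_id"]]
    ages = [t for t in range(1, T + 1) for _ in range(n)]

    col = 0
    for t in range(1, T + 1):
        frac = (t - 1) / max(T - 1, 1)
        # Step 2: age shift of the study-level mean
        delta_t = age_effect * frac * max_shift(eta01, [mm_base])
        eta0t = shift_composition(eta01, mp_base, [mm_base], delta_t)
        # Step 3: set-level heterogeneity with time-decreasing overdispersion
        xi_t = xi1 + (xi_last - xi1) * frac
        eta_st_all = np.empty((S, P))
        for s in range(S):
            eta_st = rng.dirichlet(eta0t * (1 - xi_t) / xi_t)
            if labels.B[s]:
                d0 = max_shift(eta_st, [mm_base])
                eta_st = shift_composition(eta_st, mp_base, [mm_base], gamma * d0)
            eta_st_all[s] = eta_st
        # Steps 4-5: subject-level composition, disease shift, counts
        for i in range(n):
            eta_sjt = rng.dirichlet(eta_st_all[set_code[i]] * (1 - xi_star) / xi_star)
            if labels.A[i]:
                scale = frac if slope_mode else 1.0
                d0 = max_shift(eta_sjt, dec_sets, dec_w)
                eta_sjt = shift_composition(eta_sjt, mp, dec_sets, lam * scale * d0, dec_w)
            N = int(rng.poisson(mean_libsize))
            while N < min_libsize:
                N = int(rng.poisson(mean_libsize))
            counts[:, col] = rng.multinomial(N, eta_sjt / eta_sjt.sum())
            libsizes[col] = N
            col += 1

    counts_df = pd.DataFrame(counts, index=taxa, columns=sample_ids)
    samples = pd.DataFrame({"sample_id": sample_ids, "subject_id": subject_ids, "age": ages})
    table = LongitudinalTaxaTable.from_counts(counts_df, samples)
    truth = SimTruth(
        M_plus=[taxa[i] for i in np.sort(mp)],
        M_minus=[taxa[i] for i in np.sort(mm)],
        M_zero=[taxa[i] for i in np.sort(m0)],
        null=[taxa[i] for i in np.sort(null)],
        params={"P": P, "S": S, "T": T, "gamma": gamma, "lambda": lam, "d": d,
                "slope_mode": slope_mode, "xi0": xi0, "xi1": xi1,
                "xi_last": xi_last, "xi_star": xi_star},
    )
    return ScenarioResult(cohort=cohort, labels=labels, table=table, truth=truth)


def sim_scenario_b(
    P: int = 1030,
    S: int = 100,
    T: int = 4,
    gamma: float = 0.7,
    lam: float = 0.7,
    d: float = 0.5,
    slope_mode: bool = False,
    seed=None,
    *,
    m0_frac: float = 0.15,
    alpha=(0.5, -2.0, 1.0, 1.0),
    age_effect: float = 0.3,
    xi0: float = 0.04,
    xi1: float = 0.05,
    xi_last: float = 0.03,
    xi_star: float = 0.03,
    mean_libsize: float = 100_000.0,
    min_libsize: int = 10_000,
) -> ScenarioResult:
    """High-dimensional count table with true and pseudo biomarkers.

    High-risk subjects gain a total ``lam * max`` shift into the 15% M+
    taxa, drawn ``d`` from the 15% M- taxa and ``1 - d`` from the pseudo
    biomarkers M0.  ``slope_mode`` ramps the subject shift linearly with
    age (random-slope signal) instead of applying it at every time point.
    """
    if not (0 <= gamma <= 1 and 0 <= lam <= 1):
        raise ValueError("gamma and lambda must lie in [0, 1]")
    if not 0 < d < 1:
        raise ValueError("d must lie in (0, 1)")
    return _sim_counts_table(
        P, S, T, gamma, lam, d, slope_mode, seed, "B",
        m0_frac, alpha, age_effect, xi0, xi1, xi_last, xi_star,
        mean_libsize, min_libsize,
    )


def sim_scenario_c(
    P: int = 1030,
    S: int = 100,
    T: int = 4,
    gamma: float = 0.7,
    lam: float = 0.7,
    seed=None,
    **kwargs,
) -> ScenarioResult:
    """Count table with half null taxa, 10% M+, 40% M- and no pseudo set."""
    if not (0 <= gamma <= 1 and 0 <= lam <= 1):
        raise ValueError("gamma and lambda must lie in [0, 1]")
    defaults = dict(m0_frac=0.0, alpha=(0.5, -2.0, 1.0, 1.0), age_effect=0.3,
                    xi0=0.04, xi1=0.05, xi_last=0.03, xi_star=0.03,
                    mean_libsize=100_000.0, min_libsize=10_000)
    defaults.update(kwargs)
    return _sim_counts_table(
        P, S, T, gamma, lam, 1.0, False, seed, "C", **defaults
    )


def sim_joint_model(
    S: int = 200,
    T: int = 4,
    alpha: tuple[float, float, float] = (0.5, -2.0, 1.0),
    beta12=(-2.0, 0.5),
    beta22=(1.0, 0.0),
    lam_r: float = 1.0,
    lam_p: float = 0.5,
    gam_r: float = 0.3,
    gam_p: float = 0.3,
    phi: float = 30.0,
    seed=None,
) -> ScenarioResult:
    """Draw data from the joint model itself (for parameter recovery).

    Disease: ``logit(p) = a0 + a1 G + a2 H + a + b`` with subject genotype
    ``G`` and an observed set-level binary covariate ``H`` (both
    Bernoulli(0.5)), ``a, b ~ N(0,1)``.  Trajectory: zero-inflated Beta
    with ``logit(mu) = beta12 . (1, age) + lam_r a + gam_r b`` and
    ``logit(pi) = beta22 . (1, age) + lam_p a + gam_p b`` on the [0, 1]
    age scale (intercept-mode association).
    """
    rng = _rng(seed)
    J = 2
    n = S * J
    a = rng.standard_normal(n)
    b = rng.standard_normal(S)
    G = rng.integers(0, 2, n)
    H = rng.integers(0, 2, S)
    Hsub = np.repeat(H, J)
    bsub = np.repeat(b, J)
    a0, a1, a2 = alpha
    O = rng.binomial(1, expit(a0 + a1 * G + a2 * Hsub + a + bsub))
    set_ids = [f"set{s:04d}" for s in range(S)]
    subjects = pd.DataFrame({
        "subject_id": [f"set{s:04d}_subj{j}" for s in range(S) for j in range(J)],
        "set_id": np.repeat(set_ids, J),
        "outcome": O,
        "G": G,
        "H": Hsub,
    })
    cohort = MatchedCohort(subjects, covariates=["G", "H"])

    ages01 = np.array([(t - 1) / max(T - 1, 1) for t in range(1, T + 1)])
    b12 = np.asarray(beta12, float)
    b22 = np.asarray(beta22, float)
    y = np.zeros((1, n * T))
    sample_ids, subject_ids, ages = [], [], []
    col = 0
    for t in range(1, T + 1):
        z = ages01[t - 1]
        mu = expit(b12[0] + b12[1] * z + lam_r * a + gam_r * bsub)
        pi = expit(b22[0] + b22[1] * z + lam_p * a + gam_p * bsub)
        present = rng.random(n) < pi
        draw = _beta_mp(rng, mu, phi, size=n)
        y[0, col: col + n] = np.where(present, np.clip(draw, 1e-10, 1 - 1e-9), 0.0)
        sid = subjects["subject_id"].tolist()
        sample_ids += [f"{s}_t{t}" for s in sid]
        subject_ids += sid
        ages += [t] * n
        col += n
    abundance = pd.DataFrame(y, index=["otu_jm"], columns=sample_ids)
    samples = pd.DataFrame({"sample_id": sample_ids, "subject_id": subject_ids, "age": ages})
    table = LongitudinalTaxaTable(abundance=abundance, samples=samples)
    labels = RiskLabels(a=a, b=b, A=(a > np.median(a)).astype(int),
                        B=(b > np.median(b)).astype(int), G=G)
    truth = SimTruth(M_plus=[], M_minus=[], M_zero=[], null=[],
                     params={"alpha": list(alpha), "lam_r": lam_r, "lam_p": lam_p,
                             "gam_r": gam_r, "gam_p": gam_p, "phi": phi})
    return ScenarioResult(cohort=cohort, labels=labels, table=table, truth=truth)
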