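"""Core data containers for matched-cohort longitudinal microbiome studies.

The study design modeled throughout this package is a matched case-control
cohort: participants are grouped into matched sets (typically 1:1 pairs
matched on confounding risk factors), each participant carries a binary
disease outcome, and each participant contributes a series of microbiome
samples (taxon counts or relative abundances) collected at different ages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MatchedCohort",
    "LongitudinalTaxaTable",
    "CovariateTaxaSet",
    "RELABUND_SUM_TOL",
]

#: tolerance for per-sample relative abundances summing to one
RELABUND_SUM_TOL = 1e-8


@dataclass
class MatchedCohort:
    """Subject-level design of a matched cohort.

    Parameters
    ----------
    subjects
        One row per subject with at least the columns ``subject_id``,
        ``set_id`` and ``outcome`` (binary disease status).  Additional
        columns may hold time-invariant disease covariates.
    covariates
        Names of the time-invariant disease covariate columns.  An intercept
        is always prepended internally; do not include one here.
    """

    subjects: pd.DataFrame
    covariates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"subject_id", "set_id", "outcome"}
        missing = required - set(self.subjects.columns)
        if missing:
            raise ValueError(f"subject table missing columns: {sorted(missing)}")
        if self.subjects["subject_id"].duplicated().any():
            raise ValueError("duplicate subject_id: a subject cannot belong to two sets")
        out = self.subjects["outcome"].to_numpy()
        if not np.isin(out, [0, 1]).all():
            raise ValueError("outcome must be binary 0/1")
        for c in self.covariates:
            if c not in self.subjects.columns:
                raise ValueError(f"covariate column {c!r} not in subject table")

    @property
    def n_sets(self) -> int:
        return self.subjects["set_id"].nunique()

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def design_matrix(self) -> np.ndarray:
        """Disease-submodel design ``u`` (intercept column first)."""
        n = len(self.subjects)
        cols = [np.ones(n)]
        for c in self.covariates:
            cols.append(self.subjects[c].to_numpy(float))
        return np.column_stack(cols)


@dataclass
class LongitudinalTaxaTable:
    """Longitudinal taxon-by-sample relative abundances with sample metadata.

    Parameters
    ----------
    abundance
        Taxa (rows) by samples (columns) relative abundances in [0, 1].
    samples
        One row per sample: ``sample_id``, ``subject_id``, ``age`` plus any
        longitudinal covariate columns.  Row order must match the columns of
        ``abundance``.
    covariates
        Names of longitudinal covariate columns beyond age.
    counts, library_sizes
        Optional raw counts and per-sample library sizes from which the
        relative abundances were derived.
    """

    abundance: pd.DataFrame
    samples: pd.DataFrame
    covariates: list[str] = field(default_factory=list)
    counts: pd.DataFrame | None = None
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        required = {"sample_id", "subject_id", "age"}
        missing = required - set(self.samples.columns)
        if missing:
            raise ValueError(f"sample table missing columns: {sorted(missing)}")
        if self.abundance.index.duplicated().any():
            raise ValueError("duplicate taxon ids in abundance table")
        if list(self.abundance.columns) != list(self.samples["sample_id"]):
            raise ValueError("abundance columns must match sample_id order")
        vals = self.abundance.to_numpy(float)
        if (vals < 0).any() or (vals > 1).any():
            raise ValueError("relative abundances must lie in [0, 1]")

    @classmethod
    def from_counts(
        cls,
        counts: pd.DataFrame,
        samples: pd.DataFrame,
        covariates: list[str] | None = None,
        library_sizes: pd.Series | None = None,
    ) -> "LongitudinalTaxaTable":
        """Build a table from raw counts, normalizing to relative abundance.

        When ``library_sizes`` is omitted, per-sample column sums are used
        (compositional closure: relative abundances then sum to one within
        each sample).  An explicit ``library_sizes`` supports single-taxon
        tables where the row sum is not the sequencing depth.
        """
        vals = counts.to_numpy(float)
        if (vals < 0).any():
            raise ValueError("negative counts")
        if library_sizes is None:
            depth = pd.Series(vals.sum(axis=0), index=counts.columns)
        else:
            depth = library_sizes.reindex(counts.columns)
            if depth.isna().any():
                raise ValueError("library_sizes missing entries for some samples")
        rel = counts.divide(depth.replace(0, np.nan), axis=1).fillna(0.0)
        return cls(
            abundance=rel,
            samples=samples,
            covariates=list(covariates or []),
            counts=counts,
            library_sizes=depth,
        )

    @property
    def taxa(self) -> pd.Index:
        return self.abundance.index

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[1]

    def presence(self) -> pd.DataFrame:
        """0/1 presence indicators I(y > 0), same shape as ``abundance``."""
        return (self.abundance > 0).astype(float)

    def check_compositional(self, tol: float = RELABUND_SUM_TOL) -> None:
        """Assert per-sample relative abundances sum to one (count-derived tables)."""
        sums = self.abundance.to_numpy(float).sum(axis=0)
        if np.abs(sums - 1.0).max() > tol:
            raise ValueError("per-sample relative abundances do not sum to 1")


@dataclass
class CovariateTaxaSet:
    """Pre-selected covariate taxa for one target taxon.

    ``abundance_covariates`` feed the non-zero abundance submodel as
    relative-abundance columns x(1); ``presence_covariates`` feed the
    presence submodel as 0/1 indicator columns x(2).  The target taxon is
    never a member of its own covariate set.
    """

    target: str
    abundance_covariates: list[str] = field(default_factory=list)
    presence_covariates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.target in self.abundance_covariates or self.target in self.presence_covariates:
            raise ValueError("target taxon cannot be its own covariate")
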