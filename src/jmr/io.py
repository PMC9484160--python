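"""Readers, writers, taxon filtering and run configuration.

Canonical interchange is UTF-8 tab-delimited text: a taxa-by-samples
count (or relative abundance) table, a sample metadata table
(sample_id, subject_id, age, longitudinal covariates) and a subject
metadata table (subject_id, set_id, outcome, time-invariant covariates).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import LongitudinalTaxaTable, MatchedCohort
from .simulate import ScenarioResult

__all__ = [
    "RunConfig",
    "read_taxa_table",
    "read_cohort",
    "filter_taxa",
    "write_results",
    "write_simulation",
]


@dataclasses.dataclass
class RunConfig:
    """Resolved run configuration; serializes round-trip to JSON."""

    variant: str = "JMR-NC"
    test_mode: str = "intercept"
    gh_nodes: int = 5
    rho: float | str = 0.1       # a number, or "tune"
    seed: int = 0
    min_abund: float = 1e-6
    min_prev: float = 0.05
    scenario: dict = dataclasses.field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RunConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls(**json.loads(text))

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def read_taxa_table(
    counts_path: str | Path,
    sample_meta_path: str | Path,
    covariates: list[str] | None = None,
    normalized: bool = False,
) -> LongitudinalTaxaTable:
    """Read a taxa-by-samples TSV plus sample metadata.

    Counts are normalized per sample to relative abundance unless
    ``normalized`` marks the table as already relative.  Sample ids must
    be unique, metadata must cover every column of the table, and counts
    must be nonnegative.
    """
    tab = pd.read_csv(counts_path, sep="\t", index_col=0)
    if tab.index.duplicated().any():
        dup = tab.index[tab.index.duplicated()].tolist()
        raise ValueError(f"duplicate taxon ids: {dup[:5]}")
    if tab.columns.duplicated().any():
        raise ValueError("duplicate sample ids in taxa table")
    meta = pd.read_csv(sample_meta_path, sep="\t")
    missing = set(tab.columns) - set(meta["sample_id"].astype(str))
    if missing:
        raise ValueError(f"samples absent from metadata: {sorted(missing)[:5]}")
    meta = meta.set_index("sample_id").loc[list(tab.columns)].reset_index()
    if (tab.to_numpy(float) < 0).any():
        raise ValueError("negative values in taxa table")
    if normalized:
        return LongitudinalTaxaTable(abundance=tab, samples=meta,
                                     covariates=list(covariates or []))
    return LongitudinalTaxaTable.from_counts(tab, meta, covariates=covariates)


def read_cohort(subject_meta_path: str | Path,
                covariates: list[str] | None = None) -> MatchedCohort:
    meta = pd.read_csv(subject_meta_path, sep="\t")
    return MatchedCohort(meta, covariates=list(covariates or []))


def filter_taxa(
    table: LongitudinalTaxaTable,
    min_abund: float = 1e-6,
    min_prev: float = 0.05,
) -> LongitudinalTaxaTable:
    """Keep taxa with mean relative abundance > ``min_abund`` and
    prevalence (fraction of samples present) > ``min_prev``; both strict.
    """
    rel = table.abundance
    keep = (rel.mean(axis=1) > min_abund) & ((rel > 0).mean(axis=1) > min_prev)
    return LongitudinalTaxaTable(
        abundance=rel.loc[keep],
        samples=table.samples,
        covariates=list(table.covariates),
        counts=table.counts.loc[keep] if table.counts is not None else None,
        library_sizes=table.library_sizes,
    )


def write_results(results: pd.DataFrame, path: str | Path,
                  config: RunConfig | None = None) -> None:
    """Write the per-taxon results TSV (with a config/seed provenance JSON)."""
    path = Path(path)
    results.to_csv(path, sep="\t", index=False, float_format="%.10g")
    if config is not None:
        config.to_json(path.with_suffix(".config.json"))


def write_simulation(sim: ScenarioResult, outdir: str | Path,
                     config: RunConfig | None = None) -> dict[str, Path]:
    """Write a simulated dataset: counts, metadata, truth labels, config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    src = sim.table.counts if sim.table.counts is not None else sim.table.abundance
    paths["counts"] = outdir / "counts.tsv"
    src.to_csv(paths["counts"], sep="\t", index_label="taxon")
    paths["samples"] = outdir / "samples.tsv"
    sim.table.samples.to_csv(paths["samples"], sep="\t", index=False)
    paths["subjects"] = outdir / "subjects.tsv"
    sim.cohort.subjects.to_csv(paths["subjects"], sep="\t", index=False)
    if sim.truth is not None:
        lab = sim.truth.label_of()
        truth_df = pd.DataFrame({"taxon": list(lab), "label": list(lab.values())})
        paths["truth"] = outdir / "truth.tsv"
        truth_df.to_csv(paths["truth"], sep="\t", index=False)
    if config is not None:
        paths["config"] = outdir / "config.json"
        config.to_json(paths["config"])
    return paths
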