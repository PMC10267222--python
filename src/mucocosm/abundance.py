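"""Strain x sample abundance tables and the detection/prevalence rules.

The central container pairs two strain-by-sample matrices — relative
abundance and horizontal genome coverage (fraction of genome positions
covered by at least one mapped read) — with per-sample design metadata
(condition, passage, biological and technical replicate).  Operations
implement the study-design bookkeeping: collapsing technical replicates to
their median, calling a strain detected when it exceeds both an abundance
and a coverage cutoff, per-sample richness, the prevalence filter that
defines the "top prevalent strains", and aggregation to a taxonomic rank.

Thresholds are stored as fractions throughout (0.0001% relative abundance
== 1e-6; 0.01% == 1e-4); :func:`parse_fraction` converts "%"-suffixed
strings for config files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "read_abundance_table",
    "write_abundance_table",
    "read_taxonomy",
    "collapse_technical",
    "detect",
    "richness",
    "prevalence_filter",
    "aggregate_taxon",
    "parse_fraction",
]

REQUIRED_COLUMNS = ("sample_id", "condition", "passage", "bio_rep",
                    "tech_rep", "strain_id", "rel_abundance", "h_coverage")

#: default detection cutoffs: 0.0001% relative abundance, 1% horizontal coverage
DETECT_MIN_ABUND = 1e-6
DETECT_MIN_COV = 0.01
#: default prevalence cutoffs: 0.01% abundance in >= 10% of passaged samples
PREVALENCE_MIN_ABUND = 1e-4
PREVALENCE_MIN_FRAC = 0.10


def parse_fraction(value) -> float:
    """Convert a config value to a fraction; only '%'-suffixed strings scale."""
    if isinstance(value, str):
        s = value.strip()
        if s.endswith("%"):
            return float(s[:-1]) / 100.0
        return float(s)
    return float(value)


@dataclass
class AbundanceTable:
    """Relative abundance + horizontal coverage with sample metadata.

    ``rel_abundance`` and ``h_coverage`` are strain x sample DataFrames with
    identical axes; ``samples`` is indexed by sample id and carries at least
    a ``condition`` column.  ``h_coverage`` may be None after taxonomic
    aggregation (coverage is undefined above the strain level).
    """

    rel_abundance: pd.DataFrame
    h_coverage: pd.DataFrame | None
    samples: pd.DataFrame
    #: tolerance on per-sample abundance sums above 1.  Raw per-library
    #: tables use 1e-6; median-collapsed tables relax this, because the
    #: element-wise median of unit-sum replicate vectors need not sum to 1
    #: (it is bounded by 1.5 for triplicates).
    sum_slack: float = 1e-6

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ra = self.rel_abundance
        if (ra.to_numpy() < 0).any():
            raise ValueError("negative relative abundance")
        sums = ra.sum(axis=0)
        if (sums > 1 + self.sum_slack).any():
            bad = sums[sums > 1 + self.sum_slack].index.tolist()
            raise ValueError(f"per-sample abundance sums exceed 1: {bad}")
        if self.h_coverage is not None:
            hc = self.h_coverage
            if not (ra.index.equals(hc.index) and ra.columns.equals(hc.columns)):
                raise ValueError("abundance and coverage matrices misaligned")
            vals = hc.to_numpy()
            if (vals < 0).any() or (vals > 1).any():
                raise ValueError("horizontal coverage outside [0, 1]")
        if not ra.columns.equals(self.samples.index):
            raise ValueError("sample metadata does not match matrix columns")
        if "condition" not in self.samples.columns:
            raise ValueError("sample metadata needs a 'condition' column")

    @property
    def strains(self) -> list[str]:
        return list(self.rel_abundance.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.rel_abundance.columns)

    def subset_samples(self, sample_ids: Sequence[str]) -> "AbundanceTable":
        ids = list(sample_ids)
        return AbundanceTable(
            self.rel_abundance[ids],
            None if self.h_coverage is None else self.h_coverage[ids],
            self.samples.loc[ids],
            sum_slack=self.sum_slack,
        )


def read_abundance_table(
    path,
    required_meta: Sequence[str] = ("condition", "passage", "bio_rep", "tech_rep"),
    sum_slack: float = 1e-6,
) -> AbundanceTable:
    """Read a long-format TSV (one row per sample x strain) into a table.

    Columns ``sample_id, strain_id, rel_abundance, h_coverage`` plus the
    metadata columns in *required_meta* must be present; extra metadata
    columns are carried along.  Errors name the offending row.  Pass a
    larger *sum_slack* when reading median-collapsed tables, whose
    per-sample sums may legitimately exceed 1.
    """
    df = pd.read_csv(path, sep="\t")
    needed = ["sample_id", "strain_id", "rel_abundance", "h_coverage",
              *required_meta]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns in {path}: {missing}")
    for col, lo, hi in (("rel_abundance", 0.0, 1.0), ("h_coverage", 0.0, 1.0)):
        bad = df.index[(df[col] < lo) | (df[col] > hi)]
        if len(bad):
            raise ValueError(
                f"{col} outside [{lo}, {hi}] at row {bad[0] + 2} of {path}"
            )
    if df.duplicated(["sample_id", "strain_id"]).any():
        row = df.index[df.duplicated(["sample_id", "strain_id"])][0]
        raise ValueError(f"duplicate (sample, strain) row at line {row + 2}")
    meta_cols = [c for c in df.columns
                 if c not in ("strain_id", "rel_abundance", "h_coverage")]
    samples = (df[meta_cols].drop_duplicates("sample_id")
               .set_index("sample_id"))
    ra = df.pivot(index="strain_id", columns="sample_id",
                  values="rel_abundance").fillna(0.0)
    hc = df.pivot(index="strain_id", columns="sample_id",
                  values="h_coverage").fillna(0.0)
    ra = ra[samples.index]
    hc = hc[samples.index]
    ra.index.name = hc.index.name = None
    ra.columns.name = hc.columns.name = None
    return AbundanceTable(ra, hc, samples, sum_slack=sum_slack)


def write_abundance_table(table: AbundanceTable, path) -> None:
    """Write the long-format TSV dialect read by :func:`read_abundance_table`."""
    if table.h_coverage is None:
        raise ValueError("cannot write a table without coverage")
    rows = []
    for sid in table.sample_ids:
        meta = table.samples.loc[sid]
        for strain in table.strains:
            rows.append({
                "sample_id": sid, **meta.to_dict(), "strain_id": strain,
                "rel_abundance": table.rel_abundance.at[strain, sid],
                "h_coverage": table.h_coverage.at[strain, sid],
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_taxonomy(path) -> pd.DataFrame:
    """Read strain taxonomy TSV: strain_id, phylum[, family, genus]."""
    tax = pd.read_csv(path, sep="\t")
    if "strain_id" not in tax.columns or "phylum" not in tax.columns:
        raise ValueError("taxonomy needs strain_id and phylum columns")
    return tax.set_index("strain_id")


def collapse_technical(table: AbundanceTable) -> AbundanceTable:
    """Median-collapse technical replicates within each culture tube.

    Samples sharing (condition, passage, bio_rep) are technical replicates of
    one tube; each strain's abundance and coverage become the median across
    them.  Biological replicates stay separate.  Singleton groups pass
    through unchanged (up to sample renaming).
    """
    keys = ["condition", "passage", "bio_rep"]
    for k in keys:
        if k not in table.samples.columns:
            raise ValueError(f"sample metadata lacks '{k}'")
    groups = table.samples.groupby(keys, dropna=False, sort=True)
    new_ids, ra_cols, hc_cols, meta_rows = [], [], [], []
    for key, members in groups:
        ids = list(members.index)
        cond, passage, bio = key
        new_id = f"{cond}|P{passage}|b{bio}"
        new_ids.append(new_id)
        ra_cols.append(table.rel_abundance[ids].median(axis=1))
        if table.h_coverage is not None:
            hc_cols.append(table.h_coverage[ids].median(axis=1))
        meta_rows.append({"condition": cond, "passage": passage,
                          "bio_rep": bio, "tech_rep": "median"})
    ra = pd.concat(ra_cols, axis=1)
    ra.columns = new_ids
    hc = None
    if table.h_coverage is not None:
        hc = pd.concat(hc_cols, axis=1)
        hc.columns = new_ids
    samples = pd.DataFrame(meta_rows, index=pd.Index(new_ids, name="sample_id"))
    return AbundanceTable(ra, hc, samples, sum_slack=0.5)


def detect(table: AbundanceTable,
           min_abund: float = DETECT_MIN_ABUND,
           min_cov: float = DETECT_MIN_COV) -> pd.DataFrame:
    """Boolean strain x sample detection calls.

    A strain is present when it strictly exceeds both the relative-abundance
    and horizontal-coverage cutoffs (defaults 0.0001% and 1%).
    """
    if not (0 <= min_abund <= 1 and 0 <= min_cov <= 1):
        raise ValueError("thresholds must be fractions in [0, 1]")
    if table.h_coverage is None:
        raise ValueError("detection needs horizontal coverage")
    return (table.rel_abundance > min_abund) & (table.h_coverage > min_cov)


def richness(presence: pd.DataFrame,
             groups: Mapping[str, str] | pd.Series | None = None):
    """Per-sample detected-strain counts; optional per-group medians.

    Returns the per-sample counts, or ``(counts, group_medians)`` when a
    sample -> group mapping is given.
    """
    counts = presence.sum(axis=0)
    if groups is None:
        return counts
    g = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    medians = counts.groupby(g.reindex(counts.index)).median()
    return counts, medians


def prevalence_filter(table: AbundanceTable,
                      min_abund: float = PREVALENCE_MIN_ABUND,
                      min_frac: float = PREVALENCE_MIN_FRAC) -> list[str]:
    """Strains abundant (> *min_abund*) in >= ceil(*min_frac* * n) samples.

    With the defaults this is the "top prevalent strains" rule: present
    above 0.01% relative abundance in at least 10% of the passaged samples
    (27 of 270 in the full passaging design).  Call on a table already
    restricted to passaged samples.  Strain order follows the table.
    """
    n = len(table.sample_ids)
    if n == 0:
        raise ValueError("empty table")
    required = math.ceil(min_frac * n)
    hits = (table.rel_abundance > min_abund).sum(axis=1)
    return [s for s in table.strains if hits[s] >= required]


def aggregate_taxon(table: AbundanceTable, taxonomy: pd.DataFrame,
                    rank: str = "phylum") -> AbundanceTable:
    """Sum strain abundances within each taxon at *rank*; coverage dropped."""
    if rank not in taxonomy.columns:
        raise ValueError(f"taxonomy lacks rank '{rank}'")
    labels = taxonomy[rank].reindex(table.strains)
    unmapped = labels.index[labels.isna()].tolist()
    if unmapped:
        raise KeyError(f"strains unmapped at rank {rank}: {unmapped}")
    ra = table.rel_abundance.groupby(labels).sum()
    ra.index.name = None
    return AbundanceTable(ra, None, table.samples)
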