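"""Gene-neighborhood enrichment test.

Given per-genome gene annotations (intervals with sets of KO labels), counts
how often every KO occurs within a window (default 10 kb) of genes carrying
an anchor KO, and compares the observed counts against a null distribution
built by shuffling the gene -> label-set assignment uniformly within each
genome (gene positions fixed, label sets move as units, so the per-genome
label multiset is preserved exactly).

Counting conventions: a gene is "within the window" of an anchor when its
interval intersects ``[anchor_start - w, anchor_end + w]`` on the same
contig; overlapping anchor windows are unioned per genome so a gene is
counted at most once per genome; anchor-labeled genes contribute their other
labels, and the anchor KO itself is excluded from the output.

The empirical p-value uses the raw permutation denominator,
``p = #{null >= observed} / n_perm``; a KO is a hit when the observed count
strictly exceeds the null in at least ``ceil(0.99 * n_perm)`` permutations
(the ">= 990 of 1000" rule — algebraically identical to ``p <= 0.01``).
An add-one-smoothed p is also reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "KOAnnotationRule",
    "annotate_genes",
    "observed_counts",
    "permutation_test",
]

ANNOT_COLUMNS = ("genome", "gene_id", "contig", "start", "end", "strand",
                 "labels")
HITS_COLUMNS = ("genome", "gene", "contig", "start", "end", "strand", "ko",
                "bitscore", "cov_frac", "ko_threshold")


@dataclass(frozen=True)
class KOAnnotationRule:
    """Thresholds for accepting a profile-HMM hit as a gene's KO label.

    A gene is labeled with a KO when the hit covers strictly more than
    *min_cov_frac* of the KO's pHMM and its bitscore strictly exceeds
    *min_bitscore_frac* of the KO-specific adaptive bitscore threshold.
    """

    min_cov_frac: float = 0.5
    min_bitscore_frac: float = 0.5

    def __post_init__(self) -> None:
        for v in (self.min_cov_frac, self.min_bitscore_frac):
            if not 0 < v <= 1:
                raise ValueError("rule fractions must lie in (0, 1]")


def annotate_genes(hits: pd.DataFrame,
                   rule: KOAnnotationRule = KOAnnotationRule()) -> pd.DataFrame:
    """Collapse a per-hit table into per-gene KO label sets.

    *hits* has one row per (gene, KO) candidate hit with columns
    ``genome, gene, contig, start, end, strand, ko, bitscore, cov_frac,
    ko_threshold`` (coordinates 1-based inclusive).  Every gene in the table
    appears in the output, with an empty label set if none of its hits pass
    the rule — unlabeled genes still take part in the permutation null.
    """
    missing = [c for c in HITS_COLUMNS if c not in hits.columns]
    if missing:
        raise ValueError(f"hits table missing columns: {missing}")
    if ((hits["cov_frac"] < 0) | (hits["cov_frac"] > 1)).any():
        raise ValueError("cov_frac outside [0, 1]")
    ok = ((hits["cov_frac"] > rule.min_cov_frac)
          & (hits["bitscore"] > rule.min_bitscore_frac * hits["ko_threshold"]))
    rows = []
    keys = ["genome", "gene", "contig", "start", "end", "strand"]
    for key, grp in hits.groupby(keys, sort=True):
        labels = frozenset(grp.loc[ok.reindex(grp.index), "ko"])
        genome, gene, contig, start, end, strand = key
        rows.append({"genome": genome, "gene_id": gene, "contig": contig,
                     "start": start, "end": end, "strand": strand,
                     "labels": labels})
    out = pd.DataFrame(rows, columns=list(ANNOT_COLUMNS))
    return out.sort_values(["genome", "contig", "start"], kind="stable",
                           ignore_index=True)


@dataclass
class _GenomeIndex:
    """Per-(genome, contig) arrays for fast window counting."""

    starts: np.ndarray
    ends: np.ndarray
    lo: np.ndarray          # first gene index with end >= start_i - w
    hi: np.ndarray          # one past last gene with start <= end_i + w
    set_ids: np.ndarray     # label-set id carried by each gene position
    has_anchor: np.ndarray  # per label-set id: contains the anchor KO
    set_codes: list[np.ndarray]  # per label-set id: sorted KO codes
    window_bp: int
    exact: bool             # nested genes: use the O(anchors x genes) path


def _validate_annotations(annotations: pd.DataFrame) -> None:
    missing = [c for c in ANNOT_COLUMNS if c not in annotations.columns]
    if missing:
        raise ValueError(f"annotations missing columns: {missing}")
    if (annotations["start"] >= annotations["end"]).any():
        raise ValueError("gene intervals must satisfy start < end")


def _build_indices(annotations: pd.DataFrame, anchor_ko: str, window_bp: int):
    """Per-genome indexing plus the global KO code book.

    Label sets are deduplicated per genome; each gene position carries a
    set id so permutations can move sets as units.
    """
    all_kos = sorted({ko for s in annotations["labels"] for ko in s})
    code = {ko: i for i, ko in enumerate(all_kos)}
    genomes: dict[str, list[_GenomeIndex]] = {}
    for genome, gdf in annotations.groupby("genome", sort=True):
        per_contig = []
        for _, cdf in gdf.groupby("contig", sort=True):
            cdf = cdf.sort_values("start", kind="stable")
            starts = cdf["start"].to_numpy(dtype=np.int64)
            ends = cdf["end"].to_numpy(dtype=np.int64)
            exact = not bool(np.all(np.diff(ends) >= 0))
            lo = np.searchsorted(ends, starts - window_bp, side="left")
            hi = np.searchsorted(starts, ends + window_bp, side="right")
            uniq: dict[frozenset, int] = {}
            set_ids = np.empty(len(cdf), dtype=np.int64)
            for i, s in enumerate(cdf["labels"]):
                sid = uniq.setdefault(s, len(uniq))
                set_ids[i] = sid
            sets = list(uniq)
            has_anchor = np.array([anchor_ko in s for s in sets], dtype=bool)
            set_codes = [np.array(sorted(code[k] for k in s), dtype=np.int64)
                         for s in sets]
            per_contig.append(_GenomeIndex(starts, ends, lo, hi, set_ids,
                                           has_anchor, set_codes, window_bp,
                                           exact))
        genomes[genome] = per_contig
    return genomes, all_kos


def _count_one(gi: _GenomeIndex, perm: np.ndarray | None,
               n_codes: int) -> np.ndarray:
    """KO counts in the anchor window union for one contig arrangement."""
    set_ids = gi.set_ids if perm is None else gi.set_ids[perm]
    anchors = np.flatnonzero(gi.has_anchor[set_ids])
    counts = np.zeros(n_codes, dtype=np.int64)
    if anchors.size == 0:
        return counts
    n = set_ids.size
    if gi.exact:
        w = gi.window_bp
        inside = np.logical_or.reduce(
            (gi.starts[None, :] <= gi.ends[anchors][:, None] + w)
            & (gi.ends[None, :] >= gi.starts[anchors][:, None] - w)
        )
    else:
        diff = np.zeros(n + 1, dtype=np.int64)
        np.add.at(diff, gi.lo[anchors], 1)
        np.add.at(diff, gi.hi[anchors], -1)
        inside = np.cumsum(diff[:-1]) > 0
    sel = set_ids[inside]
    sizes = np.fromiter((gi.set_codes[s].size for s in sel), dtype=np.int64,
                        count=sel.size)
    if sizes.sum() == 0:
        return counts
    if np.all(sizes <= 1):
        single = np.array([gi.set_codes[s][0] if gi.set_codes[s].size else -1
                           for s in sel], dtype=np.int64)
        single = single[single >= 0]
        counts = np.bincount(single, minlength=n_codes)
    else:
        flat = np.concatenate([gi.set_codes[s] for s in sel])
        counts = np.bincount(flat, minlength=n_codes)
    return counts


def observed_counts(annotations: pd.DataFrame, anchor_ko: str,
                    window_bp: int = 10_000) -> pd.Series:
    """Observed per-KO counts within *window_bp* of anchor-labeled genes.

    Counts are summed over genomes; within a genome each gene contributes
    each of its labels at most once (window-union rule).  The anchor KO is
    excluded from the result.
    """
    _validate_annotations(annotations)
    genomes, kos = _build_indices(annotations, anchor_ko, window_bp)
    if not any(gi.has_anchor.any() for per in genomes.values() for gi in per):
        raise ValueError(f"anchor KO {anchor_ko!r} absent from all genomes")
    total = np.zeros(len(kos), dtype=np.int64)
    for per_contig in genomes.values():
        for gi in per_contig:
            total += _count_one(gi, None, len(kos))
    out = pd.Series(total, index=pd.Index(kos, name="ko"), name="count")
    return out.drop(index=anchor_ko, errors="ignore")


def permutation_test(annotations: pd.DataFrame, anchor_ko: str,
                     window_bp: int = 10_000, n_perm: int = 1000,
                     seed: int = 0) -> pd.DataFrame:
    """Within-genome label-permutation null for anchor-window co-occurrence.

    Returns one row per KO with a nonzero observed count (anchor excluded):
    ``observed, p_raw, p_smoothed, hit``, where
    ``p_raw = #{null >= observed} / n_perm``,
    ``p_smoothed = (1 + #{null >= observed}) / (n_perm + 1)``, and ``hit``
    applies the "observed strictly greater in >= ceil(0.99 n_perm)
    permutations" rule.  Deterministic given *seed*.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    _validate_annotations(annotations)
    genomes, kos = _build_indices(annotations, anchor_ko, window_bp)
    if not any(gi.has_anchor.any() for per in genomes.values() for gi in per):
        raise ValueError(f"anchor KO {anchor_ko!r} absent from all genomes")
    n_codes = len(kos)
    observed = np.zeros(n_codes, dtype=np.int64)
    for per_contig in genomes.values():
        for gi in per_contig:
            observed += _count_one(gi, None, n_codes)

    rng = np.random.default_rng(seed)
    ge = np.zeros(n_codes, dtype=np.int64)   # #{null >= observed}
    lt = np.zeros(n_codes, dtype=np.int64)   # #{null < observed}
    for _ in range(n_perm):
        null = np.zeros(n_codes, dtype=np.int64)
        for per_contig in genomes.values():
            for gi in per_contig:
                perm = rng.permutation(gi.set_ids.size)
                null += _count_one(gi, perm, n_codes)
        ge += null >= observed
        lt += null < observed

    threshold = math.ceil(0.99 * n_perm)
    out = pd.DataFrame({
        "observed": observed,
        "p_raw": ge / n_perm,
        "p_smoothed": (1 + ge) / (n_perm + 1),
        "hit": lt >= threshold,
    }, index=pd.Index(kos, name="ko"))
    out = out.drop(index=anchor_ko, errors="ignore")
    return out[out["observed"] > 0]
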