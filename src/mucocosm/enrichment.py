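"""Compartment-enrichment scores from paired samples.

For every strain and every pair of samples drawn from the same culture tube
(carrier vs supernatant) or the same gut site (mucosa vs lumen), the
per-pair score is the log ratio of relative abundances, with zeros replaced
by half the smallest nonzero abundance of that sample before the log
transform.  A pair in which the strain is absent from both compartments
carries no signal and is left missing.  The per-strain aggregate is the mean
over standard deviation (n-1) of the non-missing pair scores — by default
the 12 late-passage pairs (passages 3-6 x 3 biological replicates).
Positive scores indicate carrier (or mucosal) preference.

The aggregate is invariant to the logarithm base, since mean/SD cancels the
conversion constant; per-pair scores default to natural log (nats).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .abundance import AbundanceTable

__all__ = [
    "paired_log_ratios",
    "aggregate_enrichment",
    "invivo_enrichment",
    "LATE_PASSAGES",
]

#: passages entering the aggregate score (culture considered stabilized)
LATE_PASSAGES = (3, 4, 5, 6)


def _half_min_nonzero(col: pd.Series) -> float:
    nz = col[col > 0]
    if nz.empty:
        return math.nan
    return 0.5 * float(nz.min())


def paired_log_ratios(
    table: AbundanceTable,
    num_condition: str,
    den_condition: str,
    pairing_keys: Sequence[str] = ("passage", "bio_rep"),
    base: float = math.e,
) -> pd.DataFrame:
    """Per-strain, per-pair log-ratio scores between two compartments.

    Samples are paired by *pairing_keys*; each key must have exactly one
    sample in each compartment (collapse technical replicates first).
    Returns strains x pairs, pair columns as a MultiIndex over the keys;
    double-zero pairs are NaN.
    """
    meta = table.samples
    for k in pairing_keys:
        if k not in meta.columns:
            raise ValueError(f"sample metadata lacks pairing key '{k}'")
    pairs: dict[tuple, tuple[str, str]] = {}
    sel = meta[meta["condition"].isin([num_condition, den_condition])]
    for key, members in sel.groupby(list(pairing_keys), dropna=False, sort=True):
        num = members.index[members["condition"] == num_condition]
        den = members.index[members["condition"] == den_condition]
        if len(num) != 1 or len(den) != 1:
            raise ValueError(
                f"pair {dict(zip(pairing_keys, key))} needs exactly one "
                f"{num_condition} and one {den_condition} sample "
                f"(got {len(num)}/{len(den)})"
            )
        pairs[key] = (num[0], den[0])
    if not pairs:
        raise ValueError(
            f"no {num_condition}/{den_condition} pairs under keys {pairing_keys}"
        )
    log = np.log if base == math.e else (lambda v: np.log(v) / math.log(base))
    cols = {}
    for key, (num_id, den_id) in pairs.items():
        a_num = table.rel_abundance[num_id]
        a_den = table.rel_abundance[den_id]
        num_fill = _half_min_nonzero(a_num)
        den_fill = _half_min_nonzero(a_den)
        both_zero = (a_num == 0) & (a_den == 0)
        num_adj = a_num.where(a_num > 0, num_fill)
        den_adj = a_den.where(a_den > 0, den_fill)
        score = log(num_adj / den_adj)
        score[both_zero] = np.nan
        cols[key] = score
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=list(pairing_keys))
    return out


def aggregate_enrichment(
    pair_scores: pd.DataFrame,
    include_pairs: Sequence | None = None,
) -> pd.DataFrame:
    """Mean/SD aggregate of per-pair scores for each strain.

    *include_pairs* selects pair columns (default: pairs whose first key is
    a late passage if the first pairing key is ``passage``, else all pairs).
    The aggregate is missing with a flag when fewer than 2 non-missing
    scores remain (``too_few``) or their sample SD is zero (``zero_sd``).
    """
    cols = pair_scores.columns
    if include_pairs is not None:
        sel = pair_scores[list(include_pairs)]
    elif cols.names and cols.names[0] == "passage":
        late = [c for c in cols if c[0] in LATE_PASSAGES]
        sel = pair_scores[late]
    else:
        sel = pair_scores
    mean = sel.mean(axis=1)
    sd = sel.std(axis=1, ddof=1)
    n_used = sel.notna().sum(axis=1)
    agg = mean / sd
    flag = pd.Series("ok", index=sel.index, dtype=object)
    flag[sd == 0] = "zero_sd"
    flag[n_used < 2] = "too_few"
    agg[flag != "ok"] = np.nan
    return pd.DataFrame({
        "aggregate": agg, "mean": mean, "sd": sd,
        "n_pairs_used": n_used, "flag": flag,
    })


def invivo_enrichment(
    table: AbundanceTable,
    num_condition: str = "mucosa",
    den_condition: str = "lumen",
    pairing_keys: Sequence[str] = ("individual", "site"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mucosal-vs-lumen enrichment paired over (individual, site).

    Identical statistic to the in vitro carrier score; with the study design
    of 13 individuals x 3 sites each species has up to 39 pair scores, all
    of which enter the aggregate.  Returns (pair_scores, aggregate).
    """
    pair_scores = paired_log_ratios(table, num_condition, den_condition,
                                    pairing_keys=pairing_keys)
    return pair_scores, aggregate_enrichment(pair_scores,
                                             include_pairs=list(pair_scores.columns))
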