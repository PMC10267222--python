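"""Biosynthetic gene cluster (BGC) grouping and association.

Downstream of BGC detection: each BGC is summarized by the set of KO gene
families its genes carry (same profile-HMM acceptance rule as gene
labeling), BGCs with fewer than 3 present KOs are dropped, and the
survivors are grouped by average-linkage hierarchical clustering of Jaccard
distances between binary KO profiles, cut into a fixed number of flat
groups.  Group presence per strain (any member BGC in the strain's genome)
then feeds the phylogenetic association scan.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from . import phyloreg

__all__ = [
    "bgc_ko_presence",
    "jaccard_distance",
    "filter_and_cluster",
    "group_presence",
    "bgc_association_scan",
]


def bgc_ko_presence(bgcs: pd.DataFrame,
                    annotations: pd.DataFrame) -> pd.Series:
    """KO-presence set per BGC: union of member genes' accepted labels.

    *bgcs* needs columns ``bgc_id, genome, gene_ids`` (gene_ids a list, or a
    comma-joined string as in the TSV dialect); *annotations* is the
    per-gene table produced by :func:`mucocosm.neighborhood.annotate_genes`.
    """
    lookup = annotations.set_index(["genome", "gene_id"])["labels"]
    out = {}
    for row in bgcs.itertuples(index=False):
        genes = row.gene_ids
        if isinstance(genes, str):
            genes = [g for g in genes.split(",") if g]
        kos: set[str] = set()
        for g in genes:
            try:
                kos |= set(lookup.loc[(row.genome, g)])
            except KeyError:
                raise KeyError(
                    f"gene {g!r} of BGC {row.bgc_id!r} not found in "
                    f"annotations for genome {row.genome!r}"
                ) from None
        out[row.bgc_id] = frozenset(kos)
    return pd.Series(out, name="ko_presence")


def jaccard_distance(a: frozenset, b: frozenset) -> float:
    """1 - |A n B| / |A u B|; distance 0 between two empty sets."""
    union = a | b
    if not union:
        return 0.0
    return 1.0 - len(a & b) / len(union)


def filter_and_cluster(
    ko_presence: Mapping[str, frozenset] | pd.Series,
    min_kos: int = 3,
    k_groups: int = 256,
) -> tuple[pd.Series, pd.DataFrame]:
    """Drop sparse BGCs and cut a Jaccard/average-linkage dendrogram.

    BGCs with fewer than *min_kos* present KOs are removed; the rest are
    clustered on binary KO profiles and the tree is cut into
    ``min(k_groups, n_surviving)`` flat groups.  Input order does not
    matter: BGC ids are sorted before clustering, making the grouping
    deterministic.

    Returns ``(membership, profiles)``: a BGC -> group-id Series and a
    group x KO frequency DataFrame (fraction of member BGCs carrying each
    KO).
    """
    pres = pd.Series(dict(ko_presence)) if not isinstance(ko_presence, pd.Series) \
        else ko_presence
    pres = pres[sorted(pres.index)]
    pres = pres[pres.map(len) >= min_kos]
    if pres.empty:
        raise ValueError(f"no BGC has >= {min_kos} present KOs")
    kos = sorted({k for s in pres for k in s})
    X = np.zeros((len(pres), len(kos)), dtype=bool)
    ko_idx = {k: j for j, k in enumerate(kos)}
    for i, s in enumerate(pres):
        for k in s:
            X[i, ko_idx[k]] = True
    k = min(k_groups, len(pres))
    if len(pres) == 1:
        labels = np.array([1])
    else:
        D = pdist(X, metric="jaccard")
        Z = linkage(D, method="average")
        labels = fcluster(Z, t=k, criterion="maxclust")
    membership = pd.Series(labels, index=pres.index, name="group")
    freq = pd.DataFrame(X, index=pres.index, columns=kos)
    profiles = freq.groupby(membership).mean()
    profiles.index.name = "group"
    return membership, profiles


def group_presence(
    membership: pd.Series,
    bgc_genomes: Mapping[str, str] | pd.Series,
    strains: Sequence[str],
    genome_to_strain: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Binary strain x group matrix: 1 iff the strain carries a member BGC.

    *bgc_genomes* maps BGC id -> genome id; *genome_to_strain* maps genome
    id -> strain id (identity if omitted).  Unmapped genomes are an error.
    """
    genomes = pd.Series(dict(bgc_genomes)) if not isinstance(bgc_genomes, pd.Series) \
        else bgc_genomes
    groups = sorted(membership.unique())
    out = pd.DataFrame(0, index=list(strains), columns=groups, dtype=int)
    for bgc, grp in membership.items():
        genome = genomes[bgc]
        strain = genome if genome_to_strain is None else genome_to_strain.get(genome)
        if strain is None:
            raise KeyError(f"genome {genome!r} has no strain mapping")
        if strain in out.index:
            out.at[strain, grp] = 1
    return out


def bgc_association_scan(
    presence: pd.DataFrame,
    phenotype: pd.Series,
    tree: dendropy.Tree,
    fdr: float = 0.01,
) -> pd.DataFrame:
    """PGLS scan of binary group-presence columns against the phenotype.

    Delegates to :func:`mucocosm.phyloreg.association_scan`; the 0/1 columns
    are used directly (t and p are invariant to affine rescaling of a single
    regressor, so standardization is unnecessary).
    """
    presence = presence.copy()
    presence.columns = [str(c) for c in presence.columns]
    return phyloreg.association_scan(presence, phenotype, tree, fdr=fdr,
                                     standardize=False)
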