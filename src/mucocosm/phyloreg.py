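"""Phylogenetic regression engine.

Implements the genotype-phenotype association machinery used throughout the
package: Newick parsing and validation, the Brownian-motion (BM) covariance a
rooted tree with branch lengths induces on its tips, phylogenetic generalized
least squares (PGLS) for a single regressor, a per-feature association scan
with Benjamini-Hochberg FDR control, per-clade scans, and a Fisher overlap
test between two hit lists.

The PGLS model is ``y = alpha + beta * x + eps`` with ``eps ~ N(0, sigma^2 C)``
where ``C[i, j]`` is the shared root-to-MRCA branch length of tips *i* and *j*
— the covariance of a trait evolving by Brownian motion along the tree.  The
fit whitens both sides with the Cholesky factor of ``C`` and solves ordinary
least squares on the whitened data, so on a star phylogeny (``C = I``) it
reduces exactly to OLS.  ``sigma^2`` is profiled out; the test statistic is
Student-t on ``n - 2`` degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from io import StringIO
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.stats.contingency import odds_ratio as _odds_ratio
from statsmodels.stats.multitest import multipletests

__all__ = [
    "parse_newick",
    "prune_tree",
    "bm_covariance",
    "RegressionResult",
    "pgls_fit",
    "association_scan",
    "bh_fdr",
    "clade_scan",
    "OverlapResult",
    "overlap_test",
    "FIRMICUTES_MERGE",
]

# Phyla collapsed into a single clade for the clade-restricted scans; GTDB
# splits Firmicutes into several phylum-level lineages that are treated as one
# biological clade here.
FIRMICUTES_MERGE = frozenset({"Firmicutes", "Firmicutes_A", "Firmicutes_C"})


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> dendropy.Tree:
    """Parse a rooted Newick string/stream into a validated dendropy tree.

    Every non-root edge must carry a branch length; leaf labels must be
    unique.  Polytomies are allowed.
    """
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", rooting="force-rooted",
            suppress_internal_node_taxa=True,
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate leaf labels in tree: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {x for x in labels if labels.count(x) > 1}
    if dupes:
        raise ValueError(f"duplicate leaf labels in tree: {sorted(dupes)}")
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            node.edge.length = 0.0
            continue
        if node.edge.length is None:
            raise ValueError(
                f"missing branch length on edge above {_node_name(node)}"
            )
        if node.edge.length < 0:
            raise ValueError(
                f"negative branch length on edge above {_node_name(node)}"
            )
    return tree


def _node_name(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return f"internal node {id(node)}"


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def prune_tree(tree: dendropy.Tree, strains: Sequence[str]) -> dendropy.Tree:
    """Non-destructively restrict *tree* to the given leaf set."""
    present = set(leaf_labels(tree))
    missing = [s for s in strains if s not in present]
    if missing:
        raise KeyError(f"strains not in tree: {missing}")
    pruned = tree.extract_tree_with_taxa_labels(labels=set(strains))
    pruned.seed_node.edge.length = 0.0
    return pruned


def bm_covariance(tree: dendropy.Tree, strains: Sequence[str]) -> pd.DataFrame:
    """Brownian-motion covariance of the tips listed in *strains*.

    ``C[i, j]`` is the total branch length from the root to the most recent
    common ancestor of *i* and *j*; the diagonal holds root-to-tip depths.
    The tree is pruned to *strains* first, so shared path lengths refer to
    the induced subtree.
    """
    strains = list(strains)
    if len(set(strains)) != len(strains):
        raise ValueError("duplicate strain ids requested")
    pruned = prune_tree(tree, strains)
    idx = {s: i for i, s in enumerate(strains)}
    n = len(strains)
    C = np.zeros((n, n))

    # node depths by preorder accumulation
    depth: dict[int, float] = {id(pruned.seed_node): 0.0}
    for node in pruned.preorder_node_iter():
        if node is pruned.seed_node:
            continue
        depth[id(node)] = depth[id(node.parent_node)] + node.edge.length

    # postorder: leaf index sets; cross pairs get the MRCA depth
    leafset: dict[int, list[int]] = {}
    for node in pruned.postorder_node_iter():
        if node.is_leaf():
            i = idx[node.taxon.label]
            C[i, i] = depth[id(node)]
            leafset[id(node)] = [i]
            continue
        child_sets = [leafset.pop(id(ch)) for ch in node.child_nodes()]
        d = depth[id(node)]
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                for i in child_sets[a]:
                    for j in child_sets[b]:
                        C[i, j] = C[j, i] = d
        leafset[id(node)] = [i for s in child_sets for i in s]
    return pd.DataFrame(C, index=strains, columns=strains)


# ---------------------------------------------------------------------------
# PGLS
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    feature: str
    beta: float
    se: float
    t: float
    p: float
    n: int
    q: float = float("nan")
    tested: bool = True


def _cholesky_with_jitter(C: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor; one diagonal jitter retry for near-singular C."""
    try:
        return linalg.cholesky(C, lower=True)
    except linalg.LinAlgError:
        jitter = 1e-10 * np.trace(C) / C.shape[0]
        try:
            return linalg.cholesky(C + jitter * np.eye(C.shape[0]), lower=True)
        except linalg.LinAlgError as exc:
            raise linalg.LinAlgError(
                "BM covariance is singular even after diagonal jitter"
            ) from exc


def _as_cov_array(C, order: Sequence[str] | None = None) -> np.ndarray:
    if isinstance(C, pd.DataFrame):
        if order is not None:
            C = C.loc[list(order), list(order)]
        return C.to_numpy(dtype=float)
    return np.asarray(C, dtype=float)


def pgls_fit(y, x, C, feature: str = "x") -> RegressionResult:
    """Fit ``y = alpha + beta x`` by GLS with residual covariance ``sigma^2 C``.

    Whitens with the Cholesky factor of ``C`` and solves OLS on the whitened
    design; ``sigma^2`` is estimated as whitened RSS / (n - 2) and the
    two-sided p-value comes from Student t with ``n - 2`` df.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = y.shape[0]
    if n < 3:
        raise ValueError("PGLS needs at least 3 taxa")
    if x.shape[0] != n:
        raise ValueError("y and x lengths differ")
    Ca = _as_cov_array(C)
    if Ca.shape != (n, n):
        raise ValueError("covariance shape does not match data")
    if np.ptp(x) == 0:
        raise ValueError("regressor has zero variance")
    L = _cholesky_with_jitter(Ca)
    X = np.column_stack([np.ones(n), x])
    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    beta_hat, rss, se = _ols2(Xw, yw)
    df = n - 2
    sigma2 = rss / df
    se_b = math.sqrt(sigma2 * se)
    if se_b == 0:  # perfect fit
        t = math.inf * (1 if beta_hat > 0 else -1) if beta_hat != 0 else 0.0
        p = 0.0 if beta_hat != 0 else 1.0
    else:
        t = beta_hat / se_b
        p = 2.0 * stats.t.sf(abs(t), df)
    return RegressionResult(feature=feature, beta=beta_hat, se=se_b, t=t,
                            p=p, n=n)


def _ols2(Xw: np.ndarray, yw: np.ndarray) -> tuple[float, float, float]:
    """Slope, RSS, and unit-sigma slope variance for a 2-column design."""
    s00 = Xw[:, 0] @ Xw[:, 0]
    s01 = Xw[:, 0] @ Xw[:, 1]
    s11 = Xw[:, 1] @ Xw[:, 1]
    s0y = Xw[:, 0] @ yw
    s1y = Xw[:, 1] @ yw
    det = s00 * s11 - s01 * s01
    if det <= 0:
        raise linalg.LinAlgError("whitened design is singular")
    beta = (s00 * s1y - s01 * s0y) / det
    alpha = (s11 * s0y - s01 * s1y) / det
    resid = yw - alpha * Xw[:, 0] - beta * Xw[:, 1]
    rss = float(resid @ resid)
    var_beta = s00 / det  # (X'X)^{-1}[1,1]
    return float(beta), rss, float(var_beta)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, clipped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def association_scan(
    genotypes: pd.DataFrame,
    phenotype: pd.Series,
    tree: dendropy.Tree,
    fdr: float = 0.01,
    standardize: bool = True,
) -> pd.DataFrame:
    """Per-feature PGLS scan of *genotypes* columns against *phenotype*.

    Strains with missing phenotype are dropped; each remaining genotype
    column is (optionally) standard-scaled over the scanned strains, fit by
    :func:`pgls_fit` against the BM covariance of the tree pruned to those
    strains, and BH-FDR is applied across the tested (non-constant) columns.

    Returns a DataFrame indexed by feature with columns
    ``beta, se, t, p, q, n, tested, significant``; positive ``beta`` means
    the feature tracks higher phenotype values (carrier enrichment under the
    default sign convention).
    """
    pheno = phenotype.dropna()
    strains = [s for s in genotypes.index if s in pheno.index]
    if len(strains) < 3:
        raise ValueError(
            f"need >= 3 strains with phenotype and genotype, got {len(strains)}"
        )
    y = pheno.loc[strains].to_numpy(dtype=float)
    G = genotypes.loc[strains]
    C = bm_covariance(tree, strains).to_numpy()
    L = _cholesky_with_jitter(C)
    n = len(strains)
    ones_w = linalg.solve_triangular(L, np.ones(n), lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)

    X = G.to_numpy(dtype=float)
    sd = X.std(axis=0)
    tested = sd > 0
    out = pd.DataFrame(
        index=G.columns,
        data={
            "beta": np.nan, "se": np.nan, "t": np.nan, "p": np.nan,
            "q": np.nan, "n": n, "tested": tested,
        },
    )
    if tested.any():
        Z = X[:, tested]
        if standardize:
            Z = (Z - Z.mean(axis=0)) / Z.std(axis=0)
        Zw = linalg.solve_triangular(L, Z, lower=True)
        s00 = ones_w @ ones_w
        s01 = ones_w @ Zw
        s11 = np.einsum("ij,ij->j", Zw, Zw)
        s0y = ones_w @ yw
        s1y = yw @ Zw
        det = s00 * s11 - s01 ** 2
        beta = (s00 * s1y - s01 * s0y) / det
        alpha = (s11 * s0y - s01 * s1y) / det
        resid = yw[:, None] - ones_w[:, None] * alpha[None, :] - Zw * beta[None, :]
        rss = np.einsum("ij,ij->j", resid, resid)
        df = n - 2
        se = np.sqrt(rss / df * s00 / det)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se > 0, beta / np.where(se > 0, se, 1.0),
                             np.inf * np.sign(beta))
        p = 2.0 * stats.t.sf(np.abs(tstat), df)
        out.loc[tested, "beta"] = beta
        out.loc[tested, "se"] = se
        out.loc[tested, "t"] = tstat
        out.loc[tested, "p"] = p
        out.loc[tested, "q"] = bh_fdr(p)
    out["significant"] = (out["q"] < fdr).fillna(False)
    return out


def clade_scan(
    genotypes: pd.DataFrame,
    phenotype: pd.Series,
    tree: dendropy.Tree,
    taxonomy: Mapping[str, str] | pd.Series,
    fdr: float = 0.01,
    merge: frozenset[str] = FIRMICUTES_MERGE,
    merged_name: str = "Firmicutes_merged",
    min_strains: int = 3,
) -> dict[str, pd.DataFrame]:
    """Run :func:`association_scan` within each phylum-level clade.

    Strains whose phylum is in *merge* form one combined clade.  Clades with
    fewer than *min_strains* phenotype-bearing strains are skipped.
    """
    tax = pd.Series(dict(taxonomy)) if not isinstance(taxonomy, pd.Series) else taxonomy
    clade_of = tax.map(lambda ph: merged_name if ph in merge else ph)
    results: dict[str, pd.DataFrame] = {}
    pheno = phenotype.dropna()
    for clade in sorted(clade_of.dropna().unique()):
        members = [s for s in genotypes.index
                   if clade_of.get(s) == clade and s in pheno.index]
        if len(members) < min_strains:
            continue
        results[clade] = association_scan(
            genotypes.loc[members], pheno.loc[members], tree, fdr=fdr
        )
    return results


# ---------------------------------------------------------------------------
# hit-list overlap
# ---------------------------------------------------------------------------

@dataclass
class OverlapResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    log_odds: float
    ci95: tuple[float, float]
    p: float
    sample_log_odds: float
    capped: bool = False


_LOG_ODDS_CAP = 50.0


def overlap_test(hits_a: Iterable[str], hits_b: Iterable[str],
                 universe: Iterable[str]) -> OverlapResult:
    """Two-sided Fisher exact test for overlap of two hit lists.

    The 2x2 table partitions *universe* by membership in each hit set.  The
    reported log-odds is the log of the conditional maximum-likelihood odds
    ratio with its exact 95% CI; the sample (cross-product) odds ratio is
    also reported.  Infinite odds ratios are capped and flagged.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    A, B = set(hits_a) & uni, set(hits_b) & uni
    if set(hits_a) - uni or set(hits_b) - uni:
        raise ValueError("hit lists must be subsets of the universe")
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = len(uni) - a - b - c
    table = [[a, b], [c, d]]
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    res = _odds_ratio(table, kind="conditional")
    ci = res.confidence_interval(0.95)
    capped = False

    def _log(v: float) -> float:
        nonlocal capped
        if v == 0:
            capped = True
            return -_LOG_ODDS_CAP
        if not math.isfinite(v):
            capped = True
            return _LOG_ODDS_CAP
        return math.log(v)

    log_or = _log(float(res.statistic))
    lo, hi = _log(float(ci.low)), _log(float(ci.high))
    if b * c == 0 or a * d == 0:
        capped = True
        sample = math.log((a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5)))
    else:
        sample = math.log(a * d / (b * c))
    return OverlapResult(table=((a, b), (c, d)), log_odds=log_or,
                         ci95=(lo, hi), p=p, sample_log_odds=sample,
                         capped=capped)
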