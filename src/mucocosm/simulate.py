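"""Synthetic-data generators for every input the pipeline consumes.

The generators emulate, at desk scale, the structure of a defined gut
community passaged on hydrogel carriers and profiled by strain-resolved
metagenomics:

* a pure-birth (Yule) phylogeny scaled to unit root-to-tip depth;
* a strain x KO bitscore genotype matrix whose presence patterns carry
  phylogenetic signal (a Brownian latent trait thresholded per KO);
* a per-strain spatial-preference trait generated exactly under the model
  the downstream regression assumes — Brownian motion on the tree plus
  additive effects of planted causal KOs plus i.i.d. noise;
* paired carrier/supernatant abundance tables whose per-pair log-ratio
  equals the trait in expectation (the trait enters the two compartments as
  ``exp(+trait/2)`` and ``exp(-trait/2)`` around a shared log-normal
  baseline), with a logistic horizontal-coverage model so the detection
  rule has both failure modes;
* per-genome gene annotations on a fixed geometry (1 kb genes, 200 bp
  gaps, one contig) with optional planted KO colocalization around an
  anchor KO;
* BGC KO-presence profiles with planted group structure.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from . import phyloreg
from .abundance import AbundanceTable

__all__ = [
    "SimConfig",
    "default_design",
    "simulate_tree",
    "GenotypeMatrix",
    "simulate_genotypes",
    "simulate_phenotype",
    "simulate_abundance",
    "simulate_annotations",
    "simulate_bgcs",
    "clade_labels",
]

GENE_LENGTH_BP = 1000
GENE_GAP_BP = 200
GENE_PITCH_BP = GENE_LENGTH_BP + GENE_GAP_BP

#: logistic horizontal-coverage model: h = 1 / (1 + (a / midpoint)^(-1/scale))
COVERAGE_MIDPOINT = 1e-4
COVERAGE_LOG_SCALE = 0.5


def default_design(
    conditions: Sequence[str] = ("mucin-carrier", "mucin-supernatant"),
    passages: Sequence[int] = (1, 2, 3, 4, 5, 6),
    bio_reps: Sequence[int] = (1, 2, 3),
    tech_reps: Sequence[int] = (1, 2, 3),
) -> list[tuple[str, int, int, int]]:
    """The passaging design: compartments x 6 passages x 3 bio x 3 tech reps."""
    return [(c, p, b, t) for c in conditions for p in passages
            for b in bio_reps for t in tech_reps]


@dataclass
class SimConfig:
    """Parameters of one synthetic community experiment.

    ``effect_beta`` is in phenotype units per standardized genotype unit;
    ``bm_sigma2`` is the Brownian rate on the unit-depth tree (so also the
    stationary trait variance); ``noise_sd`` is both the residual trait SD
    and the per-sample log-abundance noise SD; ``detection_floor`` zeroes
    relative abundances below it.
    """

    n_strains: int = 64
    n_kos: int = 2000
    n_causal: int = 1
    effect_beta: float = 2.0
    bm_sigma2: float = 1.0
    noise_sd: float = 0.1
    presence_rate: float = 0.5
    #: SD of per-strain log baseline abundance; ~2.5 spreads strains over
    #: several orders of magnitude, as in real defined communities, so the
    #: coverage/abundance detection rule sees both failure modes
    baseline_log_sd: float = 2.5
    detection_floor: float = 1e-6
    design: list[tuple[str, int, int, int]] = field(default_factory=default_design)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_causal > self.n_kos:
            raise ValueError("n_causal cannot exceed n_kos")
        for name in ("bm_sigma2", "noise_sd", "detection_floor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        cells = [tuple(c) for c in self.design]
        if len(set(cells)) != len(cells):
            raise ValueError("design cells must be unique")
        self.design = cells


# ---------------------------------------------------------------------------
# tree
# ---------------------------------------------------------------------------

def simulate_tree(n_leaves: int, seed: int) -> dendropy.Tree:
    """Yule (pure-birth) tree with unit root-to-tip depth.

    Lineages split at rate 1 each; after the n-th tip appears the clock runs
    one further exponential stretch so terminal edges are positive, then all
    branch lengths are rescaled so every root-to-tip path length is exactly
    1.  Leaves are labeled ``S0001``.. in creation order.
    """
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves for downstream regression")
    rng = np.random.default_rng(seed)
    parent: list[int | None] = [None]        # node 0 = root
    birth: list[float] = [0.0]
    children: dict[int, list[int]] = {0: [1, 2]}
    parent += [0, 0]
    birth += [0.0, 0.0]
    active = [1, 2]
    t = 0.0
    while len(active) < n_leaves:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        node = active.pop(i)
        a, b = len(parent), len(parent) + 1
        parent += [node, node]
        birth += [t, t]
        children[node] = [a, b]
        active += [a, b]
    t_end = t + rng.exponential(1.0 / n_leaves)

    labels = {node: f"S{k + 1:04d}"
              for k, node in enumerate(sorted(active))}

    def newick(node: int) -> str:
        end = birth[children[node][0]] if node in children else t_end
        length = (end - birth[node]) / t_end
        if node in children:
            inner = ",".join(newick(c) for c in children[node])
            return f"({inner}):{length:.12f}"
        return f"{labels[node]}:{length:.12f}"

    text = "(" + ",".join(newick(c) for c in children[0]) + ");"
    return phyloreg.parse_newick(text)


# ---------------------------------------------------------------------------
# genotypes and phenotype
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Strain x KO maximum-bitscore matrix with per-KO adaptive thresholds."""

    bitscores: pd.DataFrame
    thresholds: pd.Series

    def __post_init__(self) -> None:
        if not self.bitscores.columns.equals(self.thresholds.index):
            raise ValueError("thresholds misaligned with bitscore columns")
        if (self.thresholds <= 0).any():
            raise ValueError("KO thresholds must be positive")

    @property
    def strains(self) -> list[str]:
        return list(self.bitscores.index)

    @property
    def kos(self) -> list[str]:
        return list(self.bitscores.columns)

    def presence(self) -> pd.DataFrame:
        """Boolean calls: bitscore above the KO's adaptive threshold."""
        return self.bitscores.ge(self.thresholds, axis=1)

    def standardized(self) -> pd.DataFrame:
        """Standard-scaled bitscore columns ((x - mean) / sd, population sd)."""
        mu = self.bitscores.mean(axis=0)
        sd = self.bitscores.std(axis=0, ddof=0)
        return (self.bitscores - mu) / sd


def simulate_genotypes(tree: dendropy.Tree, n_kos: int,
                       presence_rate: float = 0.5,
                       seed: int = 0) -> GenotypeMatrix:
    """Genotypes with phylogenetic signal.

    Per KO, a Brownian latent trait on the tree is thresholded at its
    empirical ``1 - presence_rate`` quantile: strains above it are carriers.
    Carriers receive bitscore ``threshold * (1 + |N(0.5, 0.1)|)``; the rest
    draw uniformly below half the threshold, so presence calls at the
    adaptive threshold reproduce the latent split exactly.
    """
    if not 0 < presence_rate <= 1:
        raise ValueError("presence_rate must lie in (0, 1]")
    strains = phyloreg.leaf_labels(tree)
    if len(strains) < 3:
        raise ValueError("tree must have >= 3 leaves")
    C = phyloreg.bm_covariance(tree, strains).to_numpy()
    L = phyloreg._cholesky_with_jitter(C)
    rng = np.random.default_rng(seed)
    latent = L @ rng.standard_normal((len(strains), n_kos))
    cutoff = np.quantile(latent, 1.0 - presence_rate, axis=0)
    present = latent >= cutoff[None, :]
    kos = [f"K{j + 1:05d}" for j in range(n_kos)]
    thresholds = rng.uniform(60.0, 400.0, size=n_kos)
    hi = thresholds[None, :] * (1.0 + np.abs(rng.normal(0.5, 0.1,
                                                        size=present.shape)))
    lo = thresholds[None, :] * 0.5 * rng.uniform(0.0, 1.0, size=present.shape)
    scores = np.where(present, hi, lo)
    return GenotypeMatrix(
        bitscores=pd.DataFrame(scores, index=strains, columns=kos),
        thresholds=pd.Series(thresholds, index=kos),
    )


def simulate_phenotype(tree: dendropy.Tree, genotypes: GenotypeMatrix,
                       causal_kos: Sequence[str], beta: float,
                       bm_sigma2: float, noise_sd: float,
                       seed: int = 0) -> pd.Series:
    """Per-strain spatial-preference trait under the regression's own model.

    ``y = BM(0, bm_sigma2) + sum_k beta * z_k + N(0, noise_sd^2)`` where
    ``z_k`` is the standardized presence indicator of causal KO *k*.
    """
    unknown = [k for k in causal_kos if k not in genotypes.bitscores.columns]
    if unknown:
        raise KeyError(f"causal KOs not in genotype matrix: {unknown}")
    strains = phyloreg.leaf_labels(tree)
    rng = np.random.default_rng(seed)
    y = np.zeros(len(strains))
    if bm_sigma2 > 0:
        C = phyloreg.bm_covariance(tree, strains).to_numpy()
        L = phyloreg._cholesky_with_jitter(C)
        y = y + math.sqrt(bm_sigma2) * (L @ rng.standard_normal(len(strains)))
    presence = genotypes.presence().loc[strains]
    for ko in causal_kos:
        col = presence[ko].to_numpy(dtype=float)
        sd = col.std()
        if sd == 0:
            raise ValueError(f"causal KO {ko} has constant presence")
        y = y + beta * (col - col.mean()) / sd
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=len(strains))
    return pd.Series(y, index=strains, name="trait")


# ---------------------------------------------------------------------------
# abundance
# ---------------------------------------------------------------------------

def _coverage_from_abundance(a: np.ndarray) -> np.ndarray:
    """Logistic-in-log-abundance horizontal coverage, 0 where absent."""
    with np.errstate(divide="ignore"):
        z = (np.log(a) - math.log(COVERAGE_MIDPOINT)) / COVERAGE_LOG_SCALE
    h = 1.0 / (1.0 + np.exp(-z))
    return np.where(a > 0, h, 0.0)


def simulate_abundance(trait: pd.Series, config: SimConfig,
                       seed: int = 0) -> AbundanceTable:
    """Paired-compartment abundance tables realizing the trait.

    Each culture tube (condition prefix, passage, bio_rep) draws a shared
    log-normal baseline per strain; carrier samples multiply it by
    ``exp(+trait/2 + eps)`` and supernatant samples by ``exp(-trait/2 +
    eps')`` with ``eps ~ N(0, noise_sd^2)`` i.i.d. per strain and sample
    (technical replicates redraw eps only).  Samples are renormalized to
    sum 1, then abundances below ``detection_floor`` are zeroed.
    Conditions without a carrier/supernatant suffix (e.g. ``no-carrier``)
    get baseline noise only.  Every carrier cell must have its supernatant
    partner and vice versa.
    """
    strains = list(trait.index)
    n = len(strains)
    rng = np.random.default_rng(seed)

    def split(cond: str) -> tuple[str | None, str | None]:
        for suffix, role in (("-carrier", "carrier"),
                             ("-supernatant", "supernatant")):
            if cond.endswith(suffix):
                return cond[: -len(suffix)], role
        return None, None

    cells = sorted(set(config.design))
    paired = {}
    for cond, passage, bio, _tech in cells:
        prefix, role = split(cond)
        if role is not None:
            paired.setdefault((prefix, passage, bio), set()).add(role)
    for key, roles in paired.items():
        if roles != {"carrier", "supernatant"}:
            raise ValueError(
                f"unpaired design: tube {key} has only {sorted(roles)}"
            )

    t = trait.to_numpy(dtype=float)
    baselines: dict[tuple, np.ndarray] = {}
    ra_cols, hc_cols, meta = {}, {}, []
    for cond, passage, bio, tech in cells:
        prefix, role = split(cond)
        tube = (prefix if prefix is not None else cond, passage, bio)
        if tube not in baselines:
            baselines[tube] = np.exp(
                rng.normal(0.0, config.baseline_log_sd, size=n))
        shift = {"carrier": +0.5, "supernatant": -0.5}.get(role, 0.0)
        eps = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 \
            else np.zeros(n)
        raw = baselines[tube] * np.exp(shift * t + eps)
        a = raw / raw.sum()
        a = np.where(a < config.detection_floor, 0.0, a)
        sid = f"{cond}|P{passage}|b{bio}|t{tech}"
        ra_cols[sid] = a
        hc_cols[sid] = _coverage_from_abundance(a)
        meta.append({"sample_id": sid, "condition": cond, "passage": passage,
                     "bio_rep": bio, "tech_rep": tech})
    samples = pd.DataFrame(meta).set_index("sample_id")
    ra = pd.DataFrame(ra_cols, index=strains)
    hc = pd.DataFrame(hc_cols, index=strains)
    return AbundanceTable(ra, hc, samples)


# ---------------------------------------------------------------------------
# gene annotations
# ---------------------------------------------------------------------------

def simulate_annotations(
    n_genomes: int,
    genes_per_genome: int,
    ko_pool: int,
    anchor_ko: str,
    partner_kos: Sequence[str],
    colocal_prob: float,
    window: int = 10_000,
    seed: int = 0,
    anchors_per_genome: int = 1,
) -> pd.DataFrame:
    """Single-contig genomes with fixed gene geometry and planted colocalization.

    Genes are 1 kb long with 200 bp gaps.  Labels draw uniformly from a pool
    ``K00001..``; *anchors_per_genome* positions per genome are overwritten
    with *anchor_ko*, and with probability *colocal_prob* each anchor's
    immediately following genes are overwritten with *partner_kos* (all of
    which sit inside the anchor's window under this geometry).
    """
    if window < GENE_LENGTH_BP:
        raise ValueError("window smaller than the gene length")
    if anchor_ko in set(partner_kos):
        raise ValueError("partner KOs must be disjoint from the anchor")
    if len(partner_kos) * GENE_PITCH_BP > window + GENE_LENGTH_BP - 1:
        raise ValueError("too many partner KOs to fit inside the window")
    if anchors_per_genome * (1 + len(partner_kos)) > genes_per_genome:
        raise ValueError("genome too small for the requested anchors")
    rng = np.random.default_rng(seed)
    pool = [f"K{j + 1:05d}" for j in range(ko_pool)]
    rows = []
    starts = 1 + GENE_PITCH_BP * np.arange(genes_per_genome, dtype=np.int64)
    ends = starts + GENE_LENGTH_BP - 1
    for g in range(n_genomes):
        genome = f"G{g + 1:03d}"
        labels = [pool[j] for j in rng.integers(0, ko_pool,
                                                size=genes_per_genome)]
        anchor_pos = rng.choice(genes_per_genome, size=anchors_per_genome,
                                replace=False)
        for pos in np.sort(anchor_pos):
            labels[pos] = anchor_ko
        for pos in np.sort(anchor_pos):
            if partner_kos and rng.random() < colocal_prob:
                if pos + len(partner_kos) < genes_per_genome:
                    targets = range(pos + 1, pos + 1 + len(partner_kos))
                else:
                    targets = range(pos - len(partner_kos), pos)
                for k, j in zip(partner_kos, targets):
                    if labels[j] != anchor_ko:
                        labels[j] = k
        for i in range(genes_per_genome):
            rows.append({
                "genome": genome, "gene_id": f"{genome}_g{i + 1:05d}",
                "contig": "c1", "start": int(starts[i]), "end": int(ends[i]),
                "strand": "+", "labels": frozenset({labels[i]}),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# BGCs
# ---------------------------------------------------------------------------

def simulate_bgcs(
    strains: Sequence[str],
    n_groups: int,
    kos_per_group: int = 6,
    presence_prob: float = 0.5,
    seed: int = 0,
    dropout: float = 0.1,
    noise_prob: float = 0.2,
    noise_pool: int = 50,
) -> pd.DataFrame:
    """BGCs with planted group structure.

    Each group owns a disjoint signature of *kos_per_group* KOs; each strain
    carries each group's BGC independently with *presence_prob*.  A member
    BGC keeps at least 80% of its signature (random drops at rate *dropout*,
    capped) and with *noise_prob* gains one random KO from a shared noise
    pool.  Returns columns ``bgc_id, genome, contig, start, end,
    ko_presence, true_group``.
    """
    if kos_per_group < 3:
        raise ValueError("kos_per_group must be >= 3 (the presence filter "
                         "drops sparser BGCs)")
    if not 0 <= dropout <= 0.2:
        raise ValueError("dropout above 0.2 would break the 80% sharing rule")
    rng = np.random.default_rng(seed)
    signatures = [
        [f"K9{g:02d}{j:02d}" for j in range(kos_per_group)]
        for g in range(n_groups)
    ]
    noise_kos = [f"K8{j:04d}" for j in range(noise_pool)]
    max_drop = math.floor(0.2 * kos_per_group)
    rows = []
    counter = 0
    for strain in strains:
        for g in range(n_groups):
            if rng.random() >= presence_prob:
                continue
            counter += 1
            sig = list(signatures[g])
            n_drop = min(int(rng.binomial(kos_per_group, dropout)), max_drop)
            if n_drop:
                drop = rng.choice(kos_per_group, size=n_drop, replace=False)
                sig = [k for j, k in enumerate(sig) if j not in set(drop)]
            kos = set(sig)
            if noise_prob > 0 and rng.random() < noise_prob:
                kos.add(noise_kos[int(rng.integers(noise_pool))])
            start = 1 + 50_000 * g
            rows.append({
                "bgc_id": f"BGC{counter:05d}", "genome": strain,
                "contig": "c1", "start": start,
                "end": start + 40_000, "ko_presence": frozenset(kos),
                "true_group": g + 1,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# synthetic taxonomy
# ---------------------------------------------------------------------------

def clade_labels(tree: dendropy.Tree, n_clades: int = 4) -> pd.Series:
    """Phylum-like labels obtained by splitting the largest subtrees.

    Starts from the root's children and repeatedly splits the clade with the
    most leaves until *n_clades* clades exist (or no clade can split).
    """
    roots = list(tree.seed_node.child_nodes())
    while len(roots) < n_clades:
        sizes = [len(r.leaf_nodes()) for r in roots]
        order = int(np.argmax(sizes))
        node = roots[order]
        kids = node.child_nodes()
        if not kids or sizes[order] <= 1:
            break
        roots.pop(order)
        roots.extend(kids)
    out = {}
    for i, r in enumerate(sorted(roots, key=lambda n: min(
            leaf.taxon.label for leaf in n.leaf_iter()))):
        for leaf in r.leaf_iter():
            out[leaf.taxon.label] = f"Clade{i + 1:02d}"
    return pd.Series(out, name="phylum")
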