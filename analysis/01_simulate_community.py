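#!/usr/bin/env python
"""Generate the synthetic community dataset used by the downstream analyses.

Simulates a 64-strain community with a unit-depth Yule phylogeny, a
2000-KO bitscore genotype matrix with phylogenetic signal, a carrier-
preference trait driven by one causal KO (beta = 2) on top of Brownian
background, and the full passaging design (2 compartments x 6 passages x
3 biological x 3 technical replicates).  Also plants a gene-neighborhood
colocalization (3 partner KOs around an anchor) and 8 BGC groups.

Writes everything under results/demo/inputs/.
"""

import sys
from pathlib import Path

import pandas as pd

from mucocosm import abundance, phyloreg, simulate
from mucocosm.pipeline import child_seed
from mucocosm.simulate import SimConfig

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 7
OUT = Path("results/demo/inputs")
ANCHOR, PARTNERS = "K00441", ["K70001", "K70002", "K70003"]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=SEED)

    tree = simulate.simulate_tree(cfg.n_strains, child_seed(SEED, "tree"))
    genotypes = simulate.simulate_genotypes(tree, cfg.n_kos,
                                            cfg.presence_rate,
                                            child_seed(SEED, "genotypes"))
    causal = genotypes.kos[: cfg.n_causal]
    trait = simulate.simulate_phenotype(tree, genotypes, causal,
                                        cfg.effect_beta, cfg.bm_sigma2,
                                        cfg.noise_sd,
                                        child_seed(SEED, "phenotype"))
    table = simulate.simulate_abundance(trait, cfg,
                                        child_seed(SEED, "abundance"))
    annotations = simulate.simulate_annotations(
        n_genomes=20, genes_per_genome=300, ko_pool=400, anchor_ko=ANCHOR,
        partner_kos=PARTNERS, colocal_prob=0.9,
        seed=child_seed(SEED, "annotations"), anchors_per_genome=2)
    bgcs = simulate.simulate_bgcs(genotypes.strains, n_groups=8,
                                  seed=child_seed(SEED, "bgcs"))
    taxonomy = simulate.clade_labels(tree)

    (OUT / "tree.nwk").write_text(phyloreg.tree_to_newick(tree) + "\n")
    abundance.write_abundance_table(table, OUT / "abundance.tsv")
    genotypes.bitscores.to_csv(OUT / "genotypes.tsv", sep="\t",
                               index_label="strain_id", lineterminator="\n")
    genotypes.thresholds.rename("threshold").to_frame().to_csv(
        OUT / "ko_thresholds.tsv", sep="\t", index_label="ko",
        lineterminator="\n")
    trait.rename("true_trait").to_frame().to_csv(
        OUT / "true_trait.tsv", sep="\t", index_label="strain_id",
        lineterminator="\n")
    pd.DataFrame({"causal_ko": causal}).to_csv(
        OUT / "causal_kos.tsv", sep="\t", index=False, lineterminator="\n")
    ann = annotations.copy()
    ann["labels"] = ann["labels"].map(lambda s: ";".join(sorted(s)))
    ann.to_csv(OUT / "annotations.tsv", sep="\t", index=False,
               lineterminator="\n")
    b = bgcs.copy()
    b["ko_presence"] = b["ko_presence"].map(lambda s: ";".join(sorted(s)))
    b.to_csv(OUT / "bgcs.tsv", sep="\t", index=False, lineterminator="\n")
    taxonomy.rename("phylum").to_frame().to_csv(
        OUT / "taxonomy.tsv", sep="\t", index_label="strain_id",
        lineterminator="\n")

    print(f"seed {SEED}: simulated {cfg.n_strains} strains, "
          f"{cfg.n_kos} KOs ({len(causal)} causal: {causal}), "
          f"{table.rel_abundance.shape[1]} samples, "
          f"{len(annotations)} genes in {annotations['genome'].nunique()} "
          f"genomes, {len(bgcs)} BGCs in 8 planted groups")
    print(f"wrote inputs to {OUT}")


if __name__ == "__main__":
    main()
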