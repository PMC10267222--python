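"""End-to-end pipeline: simulate (or load) -> filter -> enrich -> scan ->
neighborhood -> BGC, from a single config, with a machine-readable manifest.

The run directory receives, per stage, plain TSV tables; a ``manifest.json``
records the config hash, seed, package version and per-output row counts.
Reruns with the same config and seed are byte-identical.  Stage randomness
uses child seeds derived from the global seed by stable hashing of the
stage name, so each stage is reproducible in isolation.

Percent-valued thresholds may be written with a ``%`` suffix in the config
("0.01%" -> 1e-4); bare numbers are fractions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, abundance, bgc, enrichment, phyloreg, simulate
from .abundance import AbundanceTable, parse_fraction
from .neighborhood import permutation_test

__all__ = ["RunConfig", "run_pipeline", "child_seed"]


def child_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31."""
    return (seed ^ zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class RunConfig:
    """One pipeline run: either a simulation block or input paths."""

    out_dir: str = "results/run"
    seed: int = 0
    # exactly one of the two input modes
    simulation: dict | None = None
    inputs: dict | None = None
    # thresholds
    detect_min_abund: float = abundance.DETECT_MIN_ABUND
    detect_min_cov: float = abundance.DETECT_MIN_COV
    prevalence_min_abund: float = abundance.PREVALENCE_MIN_ABUND
    prevalence_min_frac: float = abundance.PREVALENCE_MIN_FRAC
    fdr: float = 0.01
    window_bp: int = 10_000
    n_perm: int = 1000
    k_groups: int = 16
    min_kos: int = 3
    late_passages: tuple[int, ...] = enrichment.LATE_PASSAGES
    num_condition: str = "mucin-carrier"
    den_condition: str = "mucin-supernatant"

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError(
                "config must set exactly one of 'simulation' or 'inputs'"
            )
        for name in ("detect_min_abund", "detect_min_cov",
                     "prevalence_min_abund", "prevalence_min_frac", "fdr"):
            value = parse_fraction(getattr(self, name))
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must be a fraction in [0, 1]")
            setattr(self, name, value)
        self.late_passages = tuple(self.late_passages)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def canonical(self) -> str:
        """Canonical JSON of the analysis config (output location excluded)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        d["late_passages"] = list(d["late_passages"])
        return json.dumps(d, sort_keys=True, default=str)


def _write_tsv(df: pd.DataFrame, path: Path, index_label=None) -> int:
    df.to_csv(path, sep="\t", index=index_label is not None,
              index_label=index_label, lineterminator="\n")
    return len(df)


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and return the run directory.

    On stage failure, partial outputs are retained next to a ``FAILED``
    marker naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    stage = "setup"
    try:
        # ---- inputs ----------------------------------------------------
        stage = "simulate" if config.simulation is not None else "load"
        if config.simulation is not None:
            sim = dict(config.simulation)
            n_causal = int(sim.pop("n_causal", 1))
            cfg = simulate.SimConfig(seed=config.seed, n_causal=n_causal,
                                     **sim)
            tree = simulate.simulate_tree(cfg.n_strains,
                                          child_seed(config.seed, "tree"))
            genotypes = simulate.simulate_genotypes(
                tree, cfg.n_kos, cfg.presence_rate,
                child_seed(config.seed, "genotypes"))
            causal = genotypes.kos[: cfg.n_causal]
            trait = simulate.simulate_phenotype(
                tree, genotypes, causal, cfg.effect_beta, cfg.bm_sigma2,
                cfg.noise_sd, child_seed(config.seed, "phenotype"))
            table = simulate.simulate_abundance(
                trait, cfg, child_seed(config.seed, "abundance"))
            taxonomy = simulate.clade_labels(tree)
            (out / "tree.nwk").write_text(phyloreg.tree_to_newick(tree) + "\n")
            abundance.write_abundance_table(table, out / "abundance.tsv")
            trait.rename("true_trait").to_frame().to_csv(
                out / "true_trait.tsv", sep="\t", index_label="strain_id",
                lineterminator="\n")
            pd.DataFrame({"causal_ko": causal}).to_csv(
                out / "causal_kos.tsv", sep="\t", index=False,
                lineterminator="\n")
        else:
            paths = config.inputs
            table = abundance.read_abundance_table(paths["abundance"])
            tree = phyloreg.parse_newick(Path(paths["tree"]).read_text())
            geno_df = pd.read_csv(paths["genotypes"], sep="\t", index_col=0)
            thresholds = pd.read_csv(paths["ko_thresholds"], sep="\t",
                                     index_col=0).iloc[:, 0]
            genotypes = simulate.GenotypeMatrix(geno_df,
                                                thresholds[geno_df.columns])
            taxonomy = (abundance.read_taxonomy(paths["taxonomy"])["phylum"]
                        if "taxonomy" in paths else None)

        # ---- abundance stage -------------------------------------------
        stage = "abundance"
        collapsed = abundance.collapse_technical(table)
        abundance.write_abundance_table(collapsed, out / "abundance_collapsed.tsv")
        presence = abundance.detect(collapsed, config.detect_min_abund,
                                    config.detect_min_cov)
        rich = abundance.richness(presence)
        counts["richness"] = _write_tsv(
            rich.rename("n_detected").to_frame(), out / "richness.tsv",
            index_label="sample_id")
        prevalent = abundance.prevalence_filter(
            collapsed, config.prevalence_min_abund, config.prevalence_min_frac)
        (out / "prevalent_strains.txt").write_text(
            "".join(s + "\n" for s in prevalent))
        counts["prevalent_strains"] = len(prevalent)

        # ---- enrichment stage ------------------------------------------
        stage = "enrichment"
        pair_scores = enrichment.paired_log_ratios(
            collapsed, config.num_condition, config.den_condition)
        late = [c for c in pair_scores.columns if c[0] in config.late_passages]
        agg = enrichment.aggregate_enrichment(pair_scores, include_pairs=late)
        flat = pair_scores.copy()
        flat.columns = [f"P{p}_b{b}" for p, b in pair_scores.columns]
        counts["pair_scores"] = _write_tsv(flat, out / "enrichment_pairs.tsv",
                                           index_label="strain_id")
        counts["aggregate_scores"] = _write_tsv(
            agg, out / "enrichment_aggregate.tsv", index_label="strain_id")

        # ---- association scan ------------------------------------------
        stage = "association_scan"
        scan_strains = [s for s in prevalent if s in genotypes.bitscores.index]
        phenotype = agg.loc[scan_strains, "aggregate"]
        scan = phyloreg.association_scan(
            genotypes.bitscores.loc[scan_strains], phenotype, tree,
            fdr=config.fdr)
        counts["scan"] = _write_tsv(scan, out / "scan_global.tsv",
                                    index_label="ko")
        hits = scan.index[scan["significant"]].tolist()
        counts["scan_hits"] = len(hits)
        if taxonomy is not None:
            stage = "clade_scan"
            per_clade = phyloreg.clade_scan(
                genotypes.bitscores.loc[scan_strains], phenotype, tree,
                taxonomy, fdr=config.fdr)
            for clade, df in per_clade.items():
                counts[f"scan_{clade}"] = _write_tsv(
                    df, out / f"scan_clade_{clade}.tsv", index_label="ko")

        # ---- neighborhood stage ----------------------------------------
        stage = "neighborhood"
        anchor, partners = "K00441", ["K70001", "K70002", "K70003"]
        annotations = simulate.simulate_annotations(
            n_genomes=20, genes_per_genome=300, ko_pool=400,
            anchor_ko=anchor, partner_kos=partners, colocal_prob=0.9,
            window=config.window_bp,
            seed=child_seed(config.seed, "annotations"), anchors_per_genome=2)
        neigh = permutation_test(annotations, anchor,
                                 window_bp=config.window_bp,
                                 n_perm=config.n_perm,
                                 seed=child_seed(config.seed, "permutation"))
        counts["neighborhood"] = _write_tsv(
            neigh.sort_values(["p_raw", "observed"],
                              ascending=[True, False]),
            out / "neighborhood.tsv", index_label="ko")

        # ---- BGC stage --------------------------------------------------
        stage = "bgc"
        bgcs = simulate.simulate_bgcs(
            scan_strains, n_groups=config.k_groups,
            seed=child_seed(config.seed, "bgcs"))
        membership, profiles = bgc.filter_and_cluster(
            bgcs.set_index("bgc_id")["ko_presence"],
            min_kos=config.min_kos, k_groups=config.k_groups)
        presence_matrix = bgc.group_presence(
            membership, bgcs.set_index("bgc_id")["genome"], scan_strains)
        bgc_scan = bgc.bgc_association_scan(presence_matrix, phenotype, tree,
                                            fdr=config.fdr)
        counts["bgc_membership"] = _write_tsv(
            membership.to_frame(), out / "bgc_membership.tsv",
            index_label="bgc_id")
        counts["bgc_presence"] = _write_tsv(
            presence_matrix, out / "bgc_presence.tsv", index_label="strain_id")
        counts["bgc_scan"] = _write_tsv(bgc_scan, out / "bgc_scan.tsv",
                                        index_label="group")

        # ---- manifest ---------------------------------------------------
        stage = "manifest"
        manifest = {
            "config_sha256": hashlib.sha256(
                config.canonical().encode()).hexdigest(),
            "seed": config.seed,
            "mucocosm_version": __version__,
            "row_counts": counts,
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    failed = out / "FAILED"
    if failed.exists():
        failed.unlink()
    return out


def main(argv=None) -> int:
    import argparse

    parser = argparse.ArgumentParser(
        description="Run the carrier-enrichment analysis pipeline")
    parser.add_argument("config", help="YAML run configuration")
    args = parser.parse_args(argv)
    out = run_pipeline(RunConfig.from_yaml(args.config))
    print(f"run complete: {out}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
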