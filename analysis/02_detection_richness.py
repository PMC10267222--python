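#!/usr/bin/env python
"""Apply the detection and prevalence rules; report per-sample richness.

Collapses technical triplicates to their median, calls a strain detected
when it strictly exceeds 0.0001% relative abundance AND 1% horizontal
coverage, counts detected strains per library, and applies the stricter
prevalence rule (>0.01% abundance in >=10% of samples) that defines the
"top prevalent strains" used by the association scans.
"""

from pathlib import Path

from mucocosm import abundance

IN = Path("results/demo/inputs")
OUT = Path("results/demo/abundance")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table = abundance.read_abundance_table(IN / "abundance.tsv")
    collapsed = abundance.collapse_technical(table)
    abundance.write_abundance_table(collapsed, OUT / "abundance_collapsed.tsv")

    # richness per technical-replicate library, medians by condition
    presence = abundance.detect(table)
    counts, medians = abundance.richness(
        presence, table.samples["condition"].to_dict())
    counts.rename("n_detected").to_frame().to_csv(
        OUT / "richness_per_library.tsv", sep="\t", index_label="sample_id",
        lineterminator="\n")

    prevalent = abundance.prevalence_filter(collapsed)
    (OUT / "prevalent_strains.txt").write_text(
        "".join(s + "\n" for s in prevalent))

    print(f"{table.rel_abundance.shape[0]} strains x "
          f"{table.rel_abundance.shape[1]} libraries")
    print("median detected strains by condition:")
    for cond, med in medians.items():
        print(f"  {cond}: {med:.0f}")
    print(f"top prevalent strains (>0.01% in >=10% of samples): "
          f"{len(prevalent)} of {len(table.strains)}")


if __name__ == "__main__":
    main()
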