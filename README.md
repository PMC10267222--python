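# mucocosm

Strain-resolved analysis of **spatial organization in defined gut microbial
communities cultured on hydrogel carriers**, for microbiome researchers who
want to connect *where* a strain lives (attached to a mucin-mimicking
carrier vs. free-living in supernatant; mucosa vs. lumen in vivo) to *which
genes* it carries.

The package implements the full statistical pipeline over strain-resolved
metagenomic abundance tables, together with a synthetic-data generator that
reproduces the statistical structure of such an experiment so every stage is
testable end to end without sequencing data.

## The statistics at the core

**Carrier-enrichment score.** For strain *s* and paired samples (same
culture tube) at passage *p*, replicate *r*:

    e_{s,p,r} = ln( a_carrier / a_supernatant )

with zeros replaced by half the sample's minimum nonzero relative abundance
before the log. The per-strain aggregate is the mean over standard
deviation of the 12 late-passage scores (passages 3–6 × 3 biological
replicates); positive values indicate carrier preference. The same
statistic, paired over (individual, site), gives mucosal-enrichment scores
for in vivo data.

**Phylogenetic regression (PGLS).** Each KO gene family's genotype
(standard-scaled maximum profile-HMM bitscore across strains) is tested
against the enrichment phenotype under

    y = α + β x + ε,   ε ~ N(0, σ² C),   C_ij = shared root-to-MRCA branch length,

i.e. residuals covary by Brownian motion along the community phylogeny, so
gene–phenotype associations are not confounded by shared ancestry the way
ordinary least squares is. BH-FDR at q < 0.01 defines hits; scans are also
run within phylum-level clades.

**Gene-neighborhood permutation test.** KO counts within 10 kb of an
anchor KO's genes are compared against 1000 within-genome label
permutations; a KO is a hit when its observed count strictly beats the
null in ≥ 990 of 1000 permutations (p ≤ 0.01).

**BGC grouping.** Biosynthetic gene clusters are summarized by binary KO
profiles, filtered (≥ 3 KOs), grouped by average-linkage hierarchical
clustering of Jaccard distances, and group presence per strain is scanned
with the same PGLS machinery.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (seed 7 by default), writing tables under `results/demo/`:

```bash
python analysis/01_simulate_community.py
python analysis/02_detection_richness.py
python analysis/03_enrichment_scores.py
python analysis/04_phylo_association.py
python analysis/05_gene_neighborhood.py
python analysis/06_bgc_groups.py
```

Output of step 03 (enrichment scores):

```
18 carrier/supernatant pairs per strain; aggregate uses up to 12 late-passage scores
strains with defined aggregate: 64 of 64
Pearson r between true trait and recovered aggregate: 0.999
most carrier-enriched strains: S0031 (+3.57), S0002 (+2.87), S0032 (+2.87)
most supernatant-enriched strains: S0013 (-2.31), S0037 (-2.48), S0027 (-2.56)
```

The r = 0.999 line is the key check: the mean/SD aggregate computed from
simulated paired abundance tables recovers the spatial-preference trait
that generated them. Step 04 then finds the planted causal gene:

```
scanned 2000 testable KOs across 64 prevalent strains
73 KOs significant at q<0.01; planted causal KO(s) ['K00001'] recovered: [True]
  K00001: beta=+0.99, q=3.11e-09
```

The causal KO is the top hit by four orders of magnitude in q; the other
significant KOs reflect genuine correlation of phylogenetically structured
genotypes with the phenotype (see `docs/methods.md` on linkage). Step 05
recovers all three KOs planted within 10 kb of the anchor gene
(`observed=36, p_raw=0.000` each), and step 06 groups 262 synthetic BGCs
into the 8 planted groups exactly (adjusted Rand index 1.000).

A single-config version of the same pipeline is available as
`python -m mucocosm.pipeline config.yaml`; see `mucocosm.pipeline.RunConfig`
for the keys (thresholds accept percent strings such as `"0.01%"`).

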