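# Methods

This note documents the statistical models implemented in `mucocosm`, the
synthetic-data generator that stands in for sequencing-derived inputs, the
numerical choices made where conventions differ between packages, and the
limits of what the test suite demonstrates.

## 1. Abundance processing

Input is a long-format TSV of per-library strain measurements: relative
abundance `a_{s,j}` and horizontal genome coverage `h_{s,j}` (fraction of
genome positions covered by at least one read), with sample metadata
(condition, passage, biological and technical replicate). Processing rules:

- **Technical collapsing.** Libraries sharing (condition, passage,
  biological replicate) are technical replicates of one culture tube and
  are collapsed to their element-wise median. The element-wise median of
  unit-sum vectors need not sum to 1 (bounded by 1.5 for triplicates), so
  collapsed tables carry a relaxed sum check; raw tables are validated
  strictly (per-sample sums ≤ 1 + 1e-6).
- **Detection.** A strain is present in a library when it *strictly*
  exceeds both 0.0001% relative abundance (1e-6 as a fraction) and 1%
  horizontal coverage. Strict inequalities make boundary values absent.
- **Prevalence ("top prevalent strains").** Strains above 0.01% abundance
  in at least ceil(0.10 · n_samples) samples. `ceil` reproduces the
  27-of-270 count of the full passaging design and is monotone in the
  fraction. All thresholds are stored as fractions; config files may use
  percent strings ("0.01%" → 1e-4) to avoid the percent/fraction trap.
- **Richness** is counted per library (before collapsing), with group
  medians on request; both per-library and per-tube richness are exposed
  because the choice is a reporting convention, not a modeling one.

## 2. Enrichment scores

Per strain and carrier/supernatant pair: `e = ln(a_num′ / a_den′)` where a
zero abundance is replaced by half the minimum nonzero abundance *of that
sample* — the sample's own detection limit; per-strain or global
replacements would mix detection limits across sequencing depths. A pair
in which the strain is absent from both compartments carries no
information and is left missing rather than imputed to 0 (a ratio of two
pseudo-counts). The aggregate is mean/SD (sample SD, n−1) over the
non-missing late-passage scores (passages 3–6 × 3 biological replicates,
up to 12); it is reported missing, with a flag, when fewer than 2 scores
remain or their SD is 0 — never ±infinity.

Natural log is the default and per-pair scores are reported in nats; the
aggregate is invariant to the base because mean/SD cancels the conversion
constant (asserted to 1e-12 in the tests). Swapping numerator and
denominator compartments negates every score exactly. The same computation
paired over (individual, site) yields in vivo mucosal-enrichment scores
(13 individuals × 3 sites → up to 39 scores per species in the reference
design).

## 3. Phylogenetic regression

For tips `i, j` of a rooted tree with branch lengths, Brownian-motion
covariance is `C_ij` = total branch length from the root to the MRCA of
`i` and `j`; the diagonal holds root-to-tip depths. `pgls_fit` whitens
`y = α + βx` with the lower Cholesky factor of `C` and solves OLS on the
whitened design, so a star phylogeny reduces it exactly to OLS, and
rescaling `C` by any positive constant leaves β̂, t, and p unchanged (the
BM rate is profiled out).

Numerical choices:

- `σ̂² = RSS_whitened / (n − 2)`, two-sided p from Student t on n − 2 df
  (the common convention for a two-parameter model; implementations using
  ML variance differ slightly in p — correctness is established against a
  brute-force GLS oracle via explicit `C⁻¹` normal equations, not against
  any particular package).
- Near-singular `C`: one retry with diagonal jitter `1e-10 · tr(C)/n`,
  then a hard error. Perfect fits (RSS = 0) report p = 0 rather than 0/0.
- Genotype columns are standard-scaled over the scanned strains
  ((x − mean)/sd, population sd); zero-variance columns are excluded from
  the BH family entirely (they carry no test). Binary BGC-group columns
  are used unstandardized — t and p are invariant to affine rescaling of a
  single regressor.
- Strains with missing phenotype (flagged aggregates) are dropped per
  scan, never imputed; scans require ≥ 3 strains.
- BH-FDR is standard step-up (via statsmodels), stable in ties; hits are
  q < 0.01 by default. Positive β means carrier-enriched (the phenotype
  sign convention is carrier minus supernatant).
- Clade scans prune the tree to each phylum's strains; the
  Firmicutes/Firmicutes_A/Firmicutes_C phylum labels merge into a single
  clade, matching how that lineage is split at phylum rank in GTDB-style
  taxonomies. Clades under 3 phenotype-bearing strains are skipped.
- Hit-list overlap between two scans uses the two-sided Fisher exact test
  on the 2×2 partition of a stated KO universe, reporting the log
  conditional-MLE odds ratio with exact 95% CI (and the sample odds
  ratio); degenerate tables are capped and flagged.

**Known behavior: linkage and near-zero branches.** Two properties of
PGLS on genotype matrices are worth naming because the tests quantify
them. (i) Phylogenetically structured genotype columns are mutually
correlated, so a strong causal gene drags genuinely correlated "null"
genes over the significance line — those discoveries are statistically
correct marginal associations, and the pooled fraction of null genes
declared significant in the planted-effect simulations stays ≤ 5%
(measured ≈ 1.5% over 50 replicates; single replicates are heavy-tailed).
(ii) When the phenotype contains any non-heritable (iid) noise, a pair of
tips joined by a near-zero branch is strongly up-weighted by whitening;
rare tree draws therefore produce outlier scans. Under a pure Brownian
phenotype the scan is exactly calibrated (type-I error at α = 0.05 inside
the 99% binomial CI over 1000 simulated KOs; BH keeps the null
false-discovery proportion at the nominal level), while naive OLS on the
same data is strongly anticonservative.

## 4. Gene-neighborhood permutation test

A gene is labeled with a KO when the hit covers > 0.5 of the KO's
profile-HMM *and* its bitscore exceeds 0.5 × the KO's adaptive threshold
(both strict). A gene is "within 10 kb" of an anchor when its interval
intersects `[anchor_start − w, anchor_end + w]` on the same contig —
midpoint or start-to-start conventions are less inclusive and were not
adopted. Overlapping anchor windows are unioned per genome so a gene is
counted at most once per genome; anchor-labeled genes contribute their
other labels, and the anchor KO itself is dropped from the output.

The null shuffles the gene → label-set assignment uniformly within each
genome: positions stay fixed, label sets move as units (multi-label genes
stay internally consistent), and the per-genome label multiset is
preserved exactly. `p_raw = #{null ≥ observed}/N` with the raw N
denominator, mirroring the "≥ 990 of 1000" hit rule (the two are
algebraically identical); an add-one-smoothed p is also emitted for
downstream use. No multiple-testing correction is applied across KOs —
hits are reported at raw p ≤ 0.01. KOs never observed near an anchor are
skipped.

**Calibration regime.** Permutation p-values on small integer counts are
conservative: if a KO's null count is almost always 0, an observed count
of 1 can never reach the 99th percentile strictly. The calibration study
therefore uses a design where null window counts are approximately
continuous — 50 genomes × 2000 genes with 35 anchor genes per genome and
a 2000-KO pool gives per-KO null counts with mean ≈ 13.5 and SD ≈ 3.6, at
which point the discrete 990/1000 rule achieves close to its nominal 1%
level (measured hit fraction 0.0065, inside the 99% binomial CI around
0.01, with the p-value ECDF at 0.05 below 0.05). With sparse anchors the
test remains valid but conservative — that is a property of the
statistic, not an implementation artifact.

## 5. BGC grouping

Each BGC's KO profile is the union of its genes' accepted labels; BGCs
with fewer than 3 KOs are dropped. Grouping is hierarchical clustering of
pairwise Jaccard distances (`1 − |A∩B|/|A∪B|`) between binary profiles
with **average linkage**, cut into `min(K, n)` flat groups. Average
linkage is the common default for Jaccard profiles; it is a configuration
choice, as is K (the reference community's 1103 BGCs were cut into 256
groups; the synthetic demos use K = 8–16). BGC ids are sorted before
clustering, making group assignments invariant to input order (verified
by adjusted Rand index 1.0 across shuffles). Group presence per strain
(any member BGC in the strain's genome) feeds the PGLS scan unchanged.

## 6. The synthetic-data generator

The generator produces every input the pipeline consumes, with the
dependency structure the analysis assumes, at desk scale:

- **Tree**: pure-birth (Yule) process, splitting rate 1 per lineage, with
  a final Exp(n) stretch so terminal edges are positive, rescaled to unit
  root-to-tip depth. Leaves are `S0001…`.
- **Genotypes**: per KO, a latent Brownian trait on the tree thresholded
  at its empirical (1 − presence_rate) quantile; carriers score
  `threshold × (1 + |N(0.5, 0.1)|)`, non-carriers draw below half the
  threshold. This gives presence patterns phylogenetic signal and makes
  the adaptive-threshold presence call exact.
- **Phenotype**: `y = BM(0, σ²_BM) + Σ_k β z_k + N(0, σ²_noise)` with
  `z_k` the standardized presence of causal KO k — exactly the generative
  model the PGLS assumes, plus planted effects.
- **Abundance**: each culture tube draws per-strain log-normal baselines;
  carrier samples multiply by `exp(+trait/2 + ε)` and supernatant by
  `exp(−trait/2 + ε′)`, ε iid N(0, noise_sd²) per strain and library, so
  the per-pair log ratio equals the trait in expectation and recovery is
  exact in the noiseless limit. Samples renormalize to sum 1; values
  below the detection floor are zeroed. Horizontal coverage is logistic
  in log abundance (midpoint 1e-4, scale 0.5 in ln units), so the
  two-sided detection rule sees both failure modes.
- **Annotations**: single-contig genomes with fixed geometry (1 kb genes,
  200 bp gaps) so window arithmetic is hand-checkable; labels drawn
  uniformly from a KO pool; a configurable number of anchor genes per
  genome; with probability `colocal_prob` the genes immediately following
  an anchor are overwritten with the partner KOs (all inside the 10 kb
  window under this geometry).
- **BGCs**: disjoint KO signatures per group; each strain carries each
  group's BGC with `presence_prob`; members keep ≥ 80% of the signature
  (dropout capped at 20%) plus optional single-KO noise.

Key defaults (one synthetic experiment): 64 strains, 2000 KOs, 1 causal
KO with β = 2 phenotype units per genotype SD, Brownian variance 1 on the
unit-depth tree, residual/measurement noise SD 0.1, KO presence rate 0.5,
per-strain baseline log-abundance SD 2.5 (spreads strains over several
orders of magnitude, as in real defined communities, so detection
actually fails for rare strains), detection floor 1e-6, and the full
passaging design (2 compartments × 6 passages × 3 biological × 3
technical replicates). Every generator is bit-reproducible given its
seed; the pipeline derives per-stage child seeds from a global seed by
stable hashing of stage names.

**What the generator does not emulate**: read-level sampling noise
(abundances are exact up to the modeled log-normal noise), compositional
coupling beyond renormalization, gene gain/loss along specific branches
(presence comes from thresholded Brownian latents, which concentrates
patterns on deep clades more than a gain/loss process would), operonic
correlation between KOs, variable gene geometry, and multi-contig
assemblies (supported by the counting code, exercised only in unit
tests). Passing tests demonstrate the statistics are implemented
correctly under their own assumptions, not that those assumptions hold in
any particular real dataset.

## 7. Problem sizes used in the checks

Simulation sizes were chosen so the full suite and the acceptance script
each run in well under a minute of CPU apart from the permutation
calibration (~20 s): 200 random trees (n = 5–30) for the GLS oracle, 100
star-tree datasets, 10 × 100 KOs for null calibration (independent
replicates, so the binomial CI applies), 20 seeds × 501 KOs for planted
recovery, 50 seeds for the pooled null-significance fraction (the
per-seed statistic is heavy-tailed, see §3), the §4 design for
permutation calibration, and 262 BGCs in 8 planted groups for cluster
recovery.

## 8. Known limitations

- The PGLS variance convention (OLS-style n − 2) may differ in the last
  digits of p from ML-based implementations; effect estimates and the
  oracle agreement are unaffected.
- The permutation test's empirical p has resolution 1/N; N = 1000 is the
  default and the hit rule is only meaningful for N ≥ 100.
- `fcluster(criterion="maxclust")` can return fewer than K groups when
  ties collapse; with distinct profiles and K ≤ n this does not occur in
  practice and the group count is asserted in the demos.
- The in vivo comparison implements the enrichment statistic and the
  Fisher overlap test; species-level genotype construction from pangenome
  catalogs is out of scope and must be supplied as a genotype table.
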