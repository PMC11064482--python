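# microclade

Marker-gene clade classification and distance-based community statistics for
reciprocal-transplant litter metagenomics.

## The problem

*Sphingomonas* is the most abundant gram-negative genus in leaf-litter
communities along Southern California's climate gradient (desert, scrubland,
grassland, pine-oak, subalpine). Whether its **within-genus** composition —
12 phylogenetic clades defined by a core-gene genome tree — tracks the
destination climate or instead converges on the shared grassland litter
substrate is a question about microdiversity: do bacteria respond to
environmental change at fine phylogenetic scales the way whole communities
do? `microclade` implements the complete analysis chain for that question,
for anyone running (or simulating) a reciprocal-transplant metagenomics
study:

1. **Clade classification.** Metagenomic reads aligned against 23 marker
   core genes (BLAST/DIAMOND outfmt-6 tables) are filtered at percent
   identity ≥ 98 and E-value < 1e−20. A read goes to the single clade whose
   hits reach the globally highest identity; ties at the top identity define
   a *pseudo clade* named by the sorted tie set (hits of 100 % to clades 1
   and 2, plus 98 % to clade 3, give pseudo clade `1-2`). Pseudo clades with
   fewer than 10 reads dataset-wide collapse into a broad pseudo clade.
2. **Community matrices.** Counts are rarefied to depth 50 by a single
   multivariate-hypergeometric draw per sample (shallow samples dropped and
   reported), then converted to relative abundances.
3. **Ordination and inference.** Bray-Curtis dissimilarity
   `D(i,j) = Σ|xᵢ−xⱼ| / Σ(xᵢ+xⱼ)`, principal coordinate analysis via Gower
   centering `G = −½·J·D∘D·J`, and PERMANOVA with sequential (Type-I) sums
   of squares from the McArdle–Anderson identity
   `SS_k = tr(H_k G) − tr(H_{k−1} G)` for the term order
   `site, inoculum, site:inoculum`; pseudo-F is tested against free sample
   permutations with the +1 correction. PERMDISP tests homogeneity of
   dispersion using distances to group centroids in the full (real plus
   imaginary) embedding, exactly as `betadisper` defines them.
4. **Trait projection.** Clade abundances (restricted to the 12 main clades)
   are multiplied by a row-stochastic clade × trait matrix over eight
   genome-based Y-A-S categories (growth Yield, resource Acquisition, Stress
   tolerance), and the resulting functional profiles get Euclidean
   PERMANOVA and a PCA whose factor loadings are score–trait correlations.
5. **Convergence test.** Per (site, sample-type) centroids — per-axis
   medians on the first two ordination axes — yield two mean distances:
   transplant → same-site survey (climate hypothesis) and transplant →
   grassland survey (substrate hypothesis); the smaller mean wins.

A synthetic-data module simulates the whole study design (5 sites × 5
inocula × 4 replicates × 3 time points = 300 bags, with a missing replicate
giving 99 sequenced T3 transplants) under three scenarios — `climate`,
`substrate`, `null` — with known ground truth down to the individual
alignment hit, so every stage is testable offline.

## Worked example

```python
import microclade as mc

design = mc.build_design(missing_slots=[("grassland", "desert", "T3", "r1")])
print("deployed bags:", design.total_deployed)
print("T3 transplant metagenomes:", design.transplant_samples("T3"))

params = mc.ScenarioParams(scenario="climate", reads_per_sample=300, seed=1)
tables, truth, db = mc.simulate_hit_tables(design, params)
counts, diag = mc.classify_samples(tables, annotations=db)
counts = mc.collapse_rare_pseudo_clades(counts, min_hits=10)

rarefied, drops = mc.rarefy(counts, depth=50, seed=1)
abundance = mc.relative_abundance(rarefied)
md = design.metadata("T3").loc[abundance.index]
transplants = md.index[md["type"] == "transplant"]

result = mc.permanova(
    mc.bray_curtis(abundance.loc[transplants]), md,
    terms=("site", "inoculum", "site:inoculum"),
    n_permutations=999, seed=1,
)
print(result.to_frame().round(3))

ordination = mc.pcoa(mc.bray_curtis(abundance))
centroids = mc.group_centroids(ordination.coordinates, md)
summary = mc.convergence_distances(centroids)
print("supported hypothesis:", summary.supported_hypothesis)
```

prints

```
deployed bags: 300
T3 transplant metagenomes: 99
               Df      SS     R2       F      p
term
site            4  20.944  0.615  37.087  0.001
inoculum        4   0.601  0.018   1.063  0.366
site:inoculum  16   2.078  0.061   0.920  0.752
Residual       74  10.448  0.307    NaN    NaN
Total          98  34.071  1.000    NaN    NaN
supported hypothesis: climate
```

Under the site-driven scenario, site explains far more Bray-Curtis variance
(R² = 0.615, p = 0.001) than the inoculum origin (R² = 0.018), and the
transplant centroids sit near their own site's survey centroid (mean
same-site distance 0.035 versus 0.320 to the grassland survey) — the
signature of climate-driven assembly. A `substrate` simulation flips both
readouts.

The same chain is available from the shell:

```bash
microclade simulate --scenario climate --out sim/ --seed 1
microclade classify --hits sim/hits --annotations sim/annotations.tsv --out counts.tsv
microclade rarefy --counts counts.tsv --depth 50 --seed 1 --out rarefied.tsv --relative
microclade run --out results/   # full pipeline from one config
```

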