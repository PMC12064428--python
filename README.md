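# oakintro

Population-genetics pipeline for diploid nuclear and haploid chloroplast
microsatellite (SSR) data, built around the analysis of hybridizing white-oak
populations: Bayesian admixture inference, hybrid-category classification with
an introgression index, diversity/differentiation statistics, Monmonier
barrier detection, chloroplast haplotype networks, and beta regression of
introgression on environmental covariates. A synthetic-data module generates
datasets with known ground truth so every stage is testable without any
external downloads.

## Modules

| Module                  | Purpose |
| ----------------------- | ------- |
| `oakintro.simulate`     | Synthetic nSSR/cpSSR datasets: drift-correlated cluster allele frequencies, admixed genotypes, stepwise chloroplast haplotypes, environment-linked introgression targets, missing-data injection |
| `oakintro.genotype_io`  | STRUCTURE-format genotypes (one-row and two-row dialects), CSV/TSV population/environment/haplotype tables, q-matrix TSV, geographic-to-planar projection |
| `oakintro.admixture`    | Gibbs sampler for the admixture model (optional location prior and correlated-frequency prior), lnP(X\|K) estimation, exact label alignment across replicate runs, mode detection, population-assignment count metrics and the two-criterion K selection rule |
| `oakintro.classify`     | Species membership sums, pure/admixed/highly-admixed categories (0.875 / 0.625 thresholds), introgression index (n_had + 0.5 n_ad)/n |
| `oakintro.diversity`    | Ho/He/uHe, FIS, hypergeometric rarefied allelic richness, Nei FST and Jost's D with sample-size corrections, PCoA |
| `oakintro.barriers`     | Delaunay/Voronoi dual graph, Monmonier maximum-difference barrier tracing, iterative multi-barrier extraction, locus-bootstrap support |
| `oakintro.haplotypes`   | Haplotype calling, minimum spanning network with co-minimal ties, Pons–Petit hS/hT/GST with jackknife SEs, Mann–Whitney group comparison |
| `oakintro.envglm`       | Pearson correlation pre-filter, scaling/centring, VIF loop, beta regression (logit mean link), both-direction stepwise AIC, Cox–Snell generalized R² |
| `oakintro.pipeline` / `oakintro.cli` | End-to-end orchestration from a YAML config with manifests and seeds |

## CLI

```bash
oakintro simulate  --config sim.yaml --out-dir out --seed 1
oakintro admixture --genotypes out/genotypes.str --k-range 1:5 \
                   --replicates 10 --burnin 5000 --iters 10000 \
                   --seed 1 --out-dir adm
oakintro classify  --q adm/q_K3_run1.tsv --species-map map.yaml --out taxa.tsv
oakintro diversity --genotypes out/genotypes.str --rarefaction-individuals 8 \
                   --out-dir div
oakintro barriers  --genotypes out/genotypes.str --pops out/populations.csv \
                   --n-barriers 8 --bootstrap 100 --seed 1 --out-dir bar
oakintro haplotypes --cp out/haplotypes.csv --out-dir hap
oakintro glm       --env env.csv --response introgression_index --out-dir glm
oakintro run       --config pipeline.yaml
```

A pipeline config lists the enabled stages plus per-stage parameters; see
`tests/test_pipeline.py::base_config` for a complete example. Unknown keys
are rejected and every run writes a `manifest.json` with seeds and
parameters.

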