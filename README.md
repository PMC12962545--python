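# mycofeedback

Analysis pipeline for **phylosymbiosis and plant–soil feedback in
arbuscular mycorrhizal (AM) fungal communities**: from ASV count tables
and a host plant phylogeny, through compositional statistics and
phylogenetic mixed models, to meta-analytic growth benefits and pairwise
feedback interaction coefficients.

The package is aimed at microbiome and plant–soil ecologists asking two
linked questions about a "training" experiment in which many host plant
species condition a common AM fungal community:

1. **Phylosymbiosis** — do related host plants drive AM fungal species
   and within-species ("genetic", rDNA ASV-level) composition in similar
   directions, and how much of the among-host variance does the phylogeny
   explain?
2. **Feedback** — does that host-driven differentiation change how plants
   subsequently grow in each other's soils?

## Core statistics

- **Aitchison geometry.** Counts are centred-log-ratio transformed,
  CLR(x)ᵢ = ln(xᵢ + c) − mean ln(x + c), and compared by Euclidean
  (Aitchison) distance — at the species level (ASVs summed per fungus)
  and within each fungus (genetic dissimilarity).
- **PGLMM.** Per-sample responses follow a phylogenetic linear mixed
  model with covariance
  V = σ²ₐ Z C Zᵀ + σ²ₛ Z Zᵀ + σ²_b Z_b Z_bᵀ + σ²ₑ I, where C is the
  Brownian-motion covariance of the host tree. REML estimation, a
  boundary likelihood-ratio test for phylogenetic signal, and
  phylogenetic heritability **H² = σ̂²ₐ / (σ̂²ₐ + σ̂²ₛ)**.
- **PERMANOVA.** Multi-factor sequential (Type I) pseudo-F tests on
  Aitchison matrices with permutation p-values.
- **Meta-analysis.** Log response ratio **LRR = ln(x̄_inoc/x̄_ctrl)** with
  sampling variance σ² = SD²_inoc/(n x̄²_inoc) + SD²_ctrl/(n x̄²_ctrl),
  pooled by REML with crossed study/host random effects, moderators,
  Wald QM tests and marginal means.
- **Interaction coefficient.** Pairwise feedback
  **I = F_Aα − F_Aβ − F_Bα + F_Bβ** (biomass of hosts A, B in soils
  conditioned by A (α) and B (β)); positive I means plants do better in
  self-conditioned soil. Group tests, a type III life-history ANOVA, and
  regressions of I on phylogenetic distance and on compositional /
  genetic dissimilarity.

A synthetic-data generator reproduces the study's design (38 host species
on a tree, 7 fungal species with 2–15 ASVs each, phylogenetically
autocorrelated host effects, blocks, two years, overdispersed counts,
factorial feedback assays with prescribed I) so every estimator can be
checked for parameter recovery. See `docs/methods.md` for the full model
descriptions and design choices.

## Worked example

```python
from mycofeedback.datasets import PipelineConfig
from mycofeedback.simulate import SimulationConfig, generate_full_dataset
from mycofeedback import pipeline

dataset, truth = generate_full_dataset(SimulationConfig(seed=1))
config = PipelineConfig()

meta_out = pipeline.run_meta(dataset, config)
fb = pipeline.run_feedback(dataset, config, meta_out=meta_out)

print(fb["feedback_group_tests"].round(4).to_string(index=False))
print(fb["feedback_vs_dissimilarity"].round(4).to_string(index=False))
```

Output:

```
      group  n   mean      t  p_mean  median  p_median  degenerate
    overall 55 0.3688 2.8185  0.0067  0.1915    0.0208       False
early-early  9 0.5869 1.9374  0.0887  0.5980    0.0977       False
 early-late 37 0.3581 2.1204  0.0409  0.0704    0.1105       False
  late-late  9 0.1950 0.7015  0.5029  0.1182    0.6523       False

            predictor  n   slope     R2       F      p
species_dissimilarity 55  0.2157 0.1207  7.2764 0.0093
    genetic:A_spinosa 55  0.0525 0.0017  0.0917 0.7632
 genetic:Ce_pellucida 55 -0.3451 0.0085  0.4524 0.5041
genetic:Cl_claroideum 55  0.8920 0.0639  3.6199 0.0625
genetic:Cl_lamellosum 55  0.1174 0.0509  2.8446 0.0976
 genetic:E_infrequens 55  0.3044 0.6389 93.7805 0.0000
    genetic:F_mosseae 55 -0.0461 0.0015  0.0795 0.7791
    genetic:R_fulgida 55 -0.4782 0.0544  3.0509 0.0865
```

Reading it: across 55 factorial species pairs the mean feedback is
positive (Ī = 0.37 g, t = 2.82, p = 0.007) — plants grow better in
self-conditioned soil — and pairwise feedback strength is predicted by
the genetic dissimilarity of the most abundant fungus (*E. infrequens*,
R² = 0.64, p < 0.001), the structure this seeded dataset was generated
with (its generator prescribes I as a positive function of exactly that
dissimilarity).

## Command line

```sh
mycofeedback simulate --out data/ --seed 1
mycofeedback all --config data/config.yaml --out results/ --seed 1
```

Stages can be run individually (`composition`, `pglmm`, `permanova`,
`meta`, `feedback`); all outputs are TSV with a header recording the
config hash and seed, and runs are byte-reproducible for a fixed seed.

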