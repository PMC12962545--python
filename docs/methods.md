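# Methods

`mycofeedback` analyses how host-plant phylogeny and successional life
history structure arbuscular mycorrhizal (AM) fungal communities, and
whether that host-driven differentiation feeds back on plant performance.
This note documents the models, the synthetic data generator, the numeric
choices, and what the package's tests do and do not establish.

## Data model

One study consists of: an ASV count table (samples × ASVs, integer reads)
with a map from each ASV to one of the inoculated fungal species or to
`unassigned` (legacy DNA); per-sample metadata (host species, life history
∈ {early, late}, phylogenetic group, greenhouse block, year, replicate); a
rooted host phylogeny with branch lengths (Newick; underscores and spaces
in tip labels are interchangeable); a factorial feedback-experiment
biomass table (host species × soil-training species × replicate); and a
growth-assay summary table (per study × host × fungal isolate: inoculated
and control mean, SD, n). All tables are TSV with `#` comment lines.

## Compositional statistics

Counts are analysed on the centred log-ratio (CLR) scale,
CLR(x)_i = ln(x_i + c) − mean_j ln(x_j + c), with pseudocount c = 1 by
default (exact scale invariance holds at c = 0 on positive counts; the
zero-free oracle tests use c = 0). Aitchison distance is the Euclidean
distance between CLR rows. Species-level composition sums all ASVs of a
fungal species first; "genetic" (within-species) dissimilarity applies the
same transform to one species' ASVs only. Samples with zero reads for the
focal species are excluded from that species' genetic matrix rather than
imputed — a pseudocount-only composition carries no information and would
shrink distances toward an artifact. A fungus with a single ASV has a
degenerate (identically zero) genetic matrix and is reported as such.

Shannon diversity is computed in nats on rarefied counts (depth 100 by
default, matching typical practice for these read depths) and averaged
over 100 rarefaction draws; averaging stabilises the estimate, and the
draw count is configurable. Samples below the rarefaction depth are
flagged and excluded.

Fungal density is proxied by the proportion of reads assigned to
inoculated fungi. Its logit uses the empirical clamp
ε = 1/(2 · depth). The proxy is validated against spore counts with a
Poisson log-link GLM fitted by iteratively reweighted least squares,
reporting the Wald slope test and McFadden's pseudo-R²
(1 − ll_model/ll_null).

## Phylogenetic linear mixed model (PGLMM)

Per-sample responses y (per-species logit relative abundance, per-ASV
logit share within species, Shannon diversity, logit density; each year
separately) are modelled as

    y = Xβ + u_phylo + u_species + u_block + e,
    V = σ²_a Z C Zᵀ + σ²_s Z Zᵀ + σ²_b Z_b Z_bᵀ + σ²_e I,

where C is the Brownian-motion covariance (shared root-to-MRCA path
length, rescaled to mean diagonal 1 so σ²_a is expressed per unit
root-to-tip depth and comparable across trees). Fixed effects are an
intercept, life history (late vs. early), and log sequencing depth — a
continuous covariate cannot be a variance component, so depth enters the
mean model. Estimation is REML with analytic gradients on log-variances
(bounded L-BFGS-B, three randomised restarts beyond a moment start,
tolerance 1e-8). Variance components driven to the optimiser's lower
bound are reported as exact zeros. On a star phylogeny C = I and the
phylogenetic and species components are non-identifiable; numerically
proportional structure matrices are detected and collapsed into a summed
component with a joint label.

Phylogenetic signal is tested by a boundary likelihood-ratio test against
the model without the phylogenetic component: Λ = 2Δll floored at 0, with
p = 0.5 · P(χ²₁ ≥ Λ) (the 50:50 χ²₀/χ²₁ mixture appropriate for a
variance component on its boundary; slightly conservative in finite
samples, which the null-calibration tests confirm). Phylogenetic
heritability is H² = σ̂²_a / (σ̂²_a + σ̂²_s), the share of among-host-species
variance attributable to the phylogeny; it is undefined (NaN, with a
warning) when both components vanish. No multiple-testing correction is
applied across ASV-level responses, which are fitted in order of
decreasing overall abundance.

## PERMANOVA

Multi-factor PERMANOVA on Aitchison matrices uses the Gower-centred
inner-product matrix G = −½ J D² J, sequential (Type I) sums of squares
through cumulative projection matrices (life history, then phylogenetic
group, then their interaction), pseudo-F against the residual mean
square, and p-values by raw-label permutation,
p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm), with 999 permutations by
default. The Gower identity (total SS = Σ_{i<j} d²_ij / n) is asserted on
every run. Interaction terms that add no estimable contrasts (empty
cells) are dropped with a warning.

## Meta-analysis of mycorrhizal growth response

The effect size is the log response ratio LRR = ln(x̄_inoc/x̄_ctrl) with
sampling variance σ² = SD²_inoc/(n_inoc x̄²_inoc) +
SD²_ctrl/(n_ctrl x̄²_ctrl); this variance is invariant to rescaling the
biomass units. Effects are pooled in a multilevel random-effects
meta-regression with the sampling variances known, crossed random
intercepts for study and host species estimated by REML (the same engine
as the PGLMM, with V₀ = diag(σ²_i) fixed), and moderators (life history,
phylogenetic group, fungal isolate, and isolate × life-history /
isolate × group interactions) under treatment contrasts with grasses and
early-successional as baselines. Aliased moderator columns (isolate ×
group cells absent from the assays) are dropped and reported, not
penalised. Moderator subsets are tested with the Wald statistic
QM = b_sᵀ Cov(b_s)⁻¹ b_s against χ²_df. Marginal means average
predictions over a balanced reference grid of the non-focal factors, with
delta-method standard errors; cells touching dropped columns are returned
as missing.

Diversity-response effects compare a mixture inoculum to the mean single
inoculum or to the best single inoculum (ties broken by smallest sampling
variance). The reference's variance enters by the delta method:
Var(ln(x̄_multi/x̄_ref)) = SD²_multi/(n_multi x̄²_multi) + Var(x̄_ref)/x̄²_ref,
with Var(x̄_ref) the variance of a mean of means (or of the best single's
mean). The exact form of the reference variance is a documented choice;
only the delta-method analogue is defensible from the summary statistics
available.

## Pairwise feedback

The interaction coefficient for hosts A, B with conditioned soils α, β is
I = F_Aα − F_Aβ − F_Bα + F_Bβ (biomass as fitness). I is symmetric under
swapping both hosts and soils, and invariant to adding a constant to all
biomasses of one host (host main effects cancel); both are asserted in
tests. Per pair, I is estimated from cell means; its standard error pools
the within-cell variance over the four cells,
se = s_pooled √(Σ 1/n_cell), with a t test on the pooled residual df —
the canonical test of an interaction contrast in a 2 × 2 cell-means
model. Zero-variance (noise-free) designs are flagged degenerate rather
than assigned p = 0.

Downstream patterns: one-sample t (mean) and Wilcoxon signed-rank
(median) tests of I against zero, per life-history pair class and
overall; type III ANOVA of I on host and training life history under
sum-to-zero contrasts (via statsmodels); linear vs. quadratic OLS of I on
patristic distance with AIC comparison; OLS of I on species-level and
per-fungus genetic dissimilarity between the two year-2 conditioned
communities (host-level counts are summed over blocks before the
transform), with a Holm-corrected column emitted alongside the raw
per-fungus p-values. The year-2 choice reflects that year-2 soils were
the feedback inocula.

The predicted-feedback check correlates, across fungal species, the
difference in meta-analytic benefit (marginal-mean LRR, focal group minus
baseline) with the difference in fungal accumulation (mean CLR abundance
per host group), by weighted least squares with weights equal to each
fungus' grand-mean relative abundance. A positive slope predicts positive
feedback. With only seven fungal species these tests have little power;
the null-calibration test documents their type-I behaviour at n = 7.

## Synthetic data generator

The generator emulates the training-experiment design: 38 host species on
a pure-birth (Yule) tree made ultrametric and rescaled to unit depth (any
ultrametric tree suffices structurally; unit depth makes σ²_a
comparable); 7 fungal species with (2, 4, 8, 12, 9, 4, 15) ASVs; balanced
early/late life histories; six phylogenetically contiguous host groups;
four greenhouse blocks; two years.

Latent log relative fitness is E[h, f] = b_f + β_f·1[late] + u_f + e_f
with u_f ~ N(0, σ²_a C) (Brownian motion, default σ²_a = 1) and
e_f ~ N(0, σ²_s I) (default 0.25, so H² = 0.8). Life-history effects
default to +0.4 on the three fungi that accumulate on late-successional
hosts. Counts per sample are Dirichlet-multinomial (concentration 200)
around softmax(E + block + year effects), with lognormal depths (median
≈ 9,000 reads, spanning roughly 2,000–50,000) and 30% of reads on legacy
"unassigned" ASVs. Within-species ASV profiles are host-specific
Dirichlet draws around a per-fungus base profile; for the designated
"genetically responsive" fungi the base is tilted by a Brownian host
score, so genetic composition is phylogenetically autocorrelated. Year-2
samples redraw counts around E plus a year main effect; serial-passage
dynamics are not modelled.

Feedback biomass inverts the interaction coefficient: conspecific cells
at the base biomass μ, heterospecific cells at μ − I/2 (the symmetric
split; I constrains only the sum of the two conditioning deficits), with
Gaussian replicate noise truncated at a small positive floor. Default
targets make I a positive linear function of the standardized genetic
dissimilarity of the most abundant fungus between the two hosts' year-2
communities (intercept 0.5, slope 0.8) — the data-generating structure
the feedback regressions are meant to detect. Growth assays draw control
replicates around a baseline and inoculated replicates around
baseline · exp(LRR) for prescribed per-(fungus × group) LRRs plus a
late-successional bonus on the fungi that benefit late hosts, across
three emulated studies; mixture-inoculum records are added for the later
two studies. Ground-truth files (parameters, latent fitness, per-pair I
targets, true LRRs) are written next to the dataset for recovery tests.

What the generator does not emulate: real rDNA copy-number variation,
chimeras or ASV misassignment, spatial soil heterogeneity, multi-season
fungal evolution, or non-lognormal depth artifacts. Passing recovery
tests therefore show the estimators are correct under the assumed
generative structure, not that the real data satisfy it.

## Calibration of variance recovery

Recovery of σ²_a is assessed on CLR-transformed species abundances, where
the latent-effect geometry is preserved up to the CLR centring (a small,
bounded attenuation). The logit relative-abundance responses used in the
empirical suite carry an additional host-level variance contribution from
the log-sum-exp of the competing fungi, which inflates the apparent σ²_a
by roughly 30–50% under the default conditions; the heritability ratio H²
is insensitive to this common inflation and is well calibrated on either
scale. Under the default study conditions the package recovers σ²_a
within ±30% and H² within ±0.15 (medians over 20 replicate datasets),
verified in the test suite.

## Determinism and problem sizes

All randomised procedures take one master seed; per-stage streams are
derived by fixed offsets, and the full pipeline is byte-reproducible for
a fixed seed. Monte-Carlo tests use ≥3-standard-error tolerances with
fixed seeds. Null-calibration tests run 200 replicates each on small
balanced layouts (e.g. 20 species × 3 replicates for the boundary LRT,
24 samples for PERMANOVA uniformity); parameter-recovery tests use the
full 38-host × 4-block design with 20 replicate datasets — sizes chosen
so the entire suite runs in about a minute on one CPU while keeping
Monte-Carlo error well below the tested tolerances.

## Known limitations

- The PGLMM is Gaussian-only; binomial/Poisson links are out of scope,
  and logit-transformed proportions are treated as Gaussian.
- Wald z tests for fixed effects (no Satterthwaite/Kenward-Roger df);
  with ~150 samples the normal approximation is adequate and the
  null-calibration tests bound the realised type-I error.
- PERMANOVA uses raw-label permutations; restricted/strata permutations
  and dispersion (PERMDISP) tests are not implemented.
- The meta-regression treats sampling variances as known, as is standard;
  very small assay n makes that approximation rough.
- Host-level dissimilarities aggregate a year's blocks by summing counts,
  which weights blocks by depth; a mean-of-CLR alternative would weight
  blocks equally.
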