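# Methods

This note documents the statistical machinery in `msbat`: the estimators and
their conventions, the admixture model and its optimisation, the synthetic
data generator and what it does and does not emulate, the numerical choices,
and the design decisions that were genuinely open.

## Estimator conventions

**Gene diversity.** Per population and locus,
`H_S = n/(n−1) · (1 − Σp² − H_O/(2n))` with `n` the number of genotyped
individuals — the small-sample correction that removes the downward bias of
the plug-in `1 − Σp²`. Across populations the same correction uses the
harmonic mean `ñ` of per-population counts (the design is unbalanced,
n = 5–15 per colony), and total diversity is
`H_T = 1 − Σp̄² + H_S/(ñ·np) − H_O/(2ñ·np)` with `p̄` the unweighted mean
frequency over the `np` populations observed at the locus. Loci missing
entirely from a population contribute only to statistics over the populations
where they were observed; this keeps a high-missingness colony in the tables
rather than dropping it.

**Ratio-of-averages.** Every multi-locus F-statistic is a ratio of summed
components (summed numerators over summed denominators), never a mean of
per-locus ratios. Per-locus ratios are noisy and biased for weakly variable
loci; component sums are the standard estimator-family convention and the
bootstrap resamples the per-locus components accordingly.

**Population-specific F_ST (β).** Within-population allele matching
`M_w = Σ c_i(c_i−1)/(n(n−1))` against the mean between-population matching
`M_b = mean over pairs of Σ p_i q_i`; `β_p = (M_w^p − M_b)/(1 − M_b)`,
summed over loci before the ratio. A population drifting away from the pool
has high self-matching and hence high β, regardless of what the other
populations do — which is what makes β per-population where θ is global.

**Hierarchical F-statistics.** A fully nested method-of-moments ANOVA of
allele indicators over gamete < individual < population < country. With
exactly two gametes per individual the expected-mean-square coefficients for
the individual component are exactly 2 at every level; the unbalanced
population/country coefficients are

    k2  = (N − Σ_p n_p²/n_c(p)) / (P − C)
    k1p = (Σ_p n_p²/n_c(p) − Σ_p n_p²/N) / (C − 1)
    k1c = (N − Σ_c n_c²/N) / (C − 1)

in gamete counts. Solving top-down gives σ² per stratum; F_CT = σ²_C/σ²_tot,
F_SC = σ²_P/(σ²_tot − σ²_C). The identity
(1−F_SC)(1−F_CT) = 1−F_ST holds exactly on the component scale. At two
levels this construction *is* the Weir–Cockerham (1984) estimator — the test
suite checks pairwise θ against the collapsed hierarchy at 1e−9 and against
a scalar implementation of the published a/b/c formulas at 1e−12. A column
(locus-allele) contributes only where every stratum retains at least one
degree of freedom; when every population is its own country the empty
within-country stratum is dropped and the design collapses to two levels.

**Allelic richness.** Hypergeometric rarefaction
`A_R = Σ_i [1 − C(N−N_i, g)/C(N, g)]`, with `g` defaulting per locus to twice
the smallest number of complete genotypes over populations at that locus.
Computed in log-gamma space; a combination with `N−N_i < g` contributes 1
(the allele is certain to appear).

**H_S envelope.** The outlier-locus diagnostic band is
`2p(1−p)(1−f_IT) ± 2·sqrt(2p(1−p)(1+f_IT)/N)`, implemented exactly in this
form. The `(1+f_IT)` under the radical is kept as the primary form;
a `variance_form=True` switch substitutes `(1−f_IT)`, which is what a
binomial sampling-variance derivation yields — the two differ by a few
percent of the half-width at realistic f_IT and the switch makes the choice
auditable.

**Distances, trees, IBD.** Chord distance per locus is
`(2/π)·sqrt(2(1−Σ√(p_i q_i)))`, averaged over loci observed in both
populations (the per-locus-mean variant; pooled-cosine averaging is a known
alternative and deliberately not the default). Trees use BIONJ — neighbour
joining with variance-weighted reduction (λ chosen per merge to minimise the
variance of the new distances, clamped to [0,1]) — implemented in-package
because no installed library provides the variant; negative branch lengths
are clamped to 0. Geographic distances are haversine on a 6,371 km sphere.
The Mantel test permutes one matrix's labels jointly over rows and columns
with `p = (#{r* ≥ r}+1)/(n_perm+1)`, 999 permutations by default; IBD
linearises to `F_ST/(1−F_ST) ~ ln(km)` by default (`linearize=False` gives
the raw regression), flooring negative F_ST at 0 before the transform only.

**mAIc sex-bias test.** The assignment index is the log10 HWE probability of
an individual's multilocus genotype in its sampled population, with
leave-one-out allele frequencies (own alleles removed) floored at `1/(2n)`.
The floor matters: a migrant's private alleles would otherwise send AI to
−∞ and the centering would destroy exactly the signal sought. AIc centers AI
per population; the test is Welch's t on males vs females pooled across
populations, with a within-population sex-label permutation p as a
nonparametric companion.

## The admixture model

The one-hot genotype matrix `X (n × 3L)` is factorized as `X ≈ Q G` with
row-stochastic `Q (n × K)` and per-cluster, per-locus genotype-class
probability triplets `G`. The objective is masked penalized least squares:
`||W ⊙ (X − QG)||² + α||Q||²`, where `W` marks training entries (non-missing
and not blinded) and α defaults to 100.

*Optimisation.* Block projected-gradient descent. Before each block update
the unobserved entries are EM-filled with the current prediction, making the
filled objective an upper bound that touches the masked objective; any
descent step on the filled objective therefore cannot increase the masked
one (the monotonicity the test suite asserts at every iteration). Within a
block the Gram and cross products are constant, so 12 inner gradient steps
at the exact Lipschitz step size (`2(||GGᵀ||₂+α)` for Q, `2||QᵀQ||₂` for G)
cost almost nothing beyond the first. Projections onto the probability
simplex are exact Euclidean (sort-based generally; closed form for the
width-3 G triplets). Convergence: relative objective change < 1e−6, at most
500 iterations (the experiment entry points use 1e−5/200 — at those
problem sizes the cross-entropies agree to the third decimal at a third of
the cost). Initialisation: Dirichlet(1) rows for Q; G at the global class
frequencies perturbed by 10% lognormal-ish noise, per-repetition seeds
derived as `seed·1000 + repetition`.

*Masked cross-entropy.* Per repetition a uniform 10% of non-missing genotype
entries is blinded. After fitting, the predicted class probabilities
(`QG` triplets, exactly normalised by construction, floored at 1e−10) score
the held-out classes: `CE = −mean log p(observed class)`. K is selected by a
plateau rule: the smallest K whose median CE over repetitions is within one
median absolute deviation (of the best K's repetitions) of the minimum
median. Flat CE across K therefore yields K = 1.

*Ridge strength and crispness.* The α-ridge pulls ancestry rows toward the
simplex barycenter. On data with D effective informative one-hot columns the
shrinkage is O(α/D): with two fully fixed clusters and only 100 loci the
optimum is analytically `q* = 2L/(2L+α/…)` — concretely 0.75 at L = 100,
0.95 at L = 1000, 0.99 at L = 5000. At study-scale locus counts the default
α = 100 is negligible, which is why real assignments are crisp; degenerate
few-locus separation tests use α = 0.

*Concordance.* The subsampling experiment aligns cluster labels by Hungarian
assignment on the Q-column correlation matrix and reports the fraction of
individuals keeping their modal cluster — invariant to label switching by
construction.

## The synthetic-data generator

Frequencies follow a Balding–Nichols hierarchy: ancestral `p ~ U(0.05,
0.95)` per SNP, country `~ Beta(p(1−F_CT)/F_CT, (1−p)(1−F_CT)/F_CT)`,
population likewise around its country with F_SC, genotypes Binomial(2, p).
Microsatellites use the Dirichlet analogue with concentration `(1−F)/F` and
3–18 alleles per locus. F = 0 copies frequencies directly (no division).
The `paper_like_config` preset fixes the study conditions: 19 colonies in 7
countries with the published per-colony sample sizes (196 individuals) and
coordinates, 4,994 SNPs, 11 microsatellites, F_CT = 0.058, F_SC = 0.019,
and missingness concentrated in the small French colony (45%, vs 5%
elsewhere — mirroring the near-50% missingness that colony shows in the real
matrix).

Read depths are negative binomial (mean 20, dispersion 5 by default);
heterozygote reads split Binomial(depth, ½); sequencing errors flip reads at
rate 0.005. Depth simulation deliberately does not re-call genotypes — its
purpose is to exercise the filtering rules, and the preferential masking of
read-ratio-skewed heterozygotes at low coverage is by itself sufficient to
reproduce the missingness→H_O/F_IS distortion mechanism (the sensitivity
diagnostics test shows F_IS rising with per-population missingness and the
effect vanishing when the low-coverage colony is excluded).

Migratory hubs are emulated by `inject_migrants`: a fraction of a colony is
redrawn *pure* from another deme's latent frequencies — syntopy without
admixture — with optional forced sex for dispersal experiments. Sex-biased
dispersal in the base generator redraws a dispersing individual's genotype
from a random other deme at the per-sex rate. A one-dimensional
Balding–Nichols drift chain (`stepping_stone_dataset`) provides
distance-structured differentiation for IBD power tests.

**What the generator does not emulate** — and therefore what passing tests
do not show about real data: linkage between SNPs on a RAD locus, mutation
(microsatellite homoplasy, SNP ascertainment), demographic history
(bottlenecks, expansions, unequal N_e), spatially continuous gene flow, and
genotype-calling bias conditional on depth. Estimator consistency shown here
is consistency under the frequency-level model, not under a coalescent.

## Experiment problem sizes

The validation experiments fix: parameter recovery — 20 replicates of the
full 19-colony preset; resolution — 4 demes × 49 individuals (study-scale
total) at F = 0.06 with 5,000 SNPs, K = 1–7 × 3 repetitions over 5 seeded
replicates, concordance at 1,000 and 100 SNPs; Mantel null — 200 random
19-label matrices at 199 permutations; IBD null — 100 island-model datasets
with shuffled coordinates; bootstrap coverage — 200 two-deme datasets
(F = 0.05, 500 loci, 1,000 resamples); sex-bias power — 50 datasets with 10
demes × 20 individuals, 1,000 SNPs, 30% male dispersal. These sizes are the
package's reference conditions; rates quoted anywhere are computed by
`msbat.experiments` at run time.

## Degenerate inputs and numerical edges

Monomorphic data yield H = 0 and *missing* (never zero) F-statistics.
A locus unobserved in a population is flagged absent and skipped
pairwise-complete. Dosage missingness uses a reserved sentinel (−1), never
0. Negative pairwise F_ST is reported as computed, floored only for the IBD
transform. Bootstrap CIs are percentile 2.5/97.5 and bit-reproducible given
a seed. The filtering pipeline is idempotent and its ledger conserves locus
counts exactly; all rule boundaries are inclusive on the keep side (depth 8
passes, a 25% minor-read heterozygote passes, 70% call rate passes).

## Known limitations

The admixture surrogate pins one concrete objective (ridge on Q, masked
least squares, projected-gradient descent) out of the family the cited
algorithm sketch admits; cross-entropy *levels* are therefore not comparable
across implementations, only across K within one. β for populations with
very few genotyped individuals is noisy and the per-locus M_b uses only
populations observed at that locus. The per-locus F_IS used by the SNP
filter pools all individuals (one panmictic unit) unless metadata is
supplied — with real structure present, pooling inflates F_IS slightly
(Wahlund), so the filter is marginally more aggressive than a
per-population version. The mAIc test assumes HWE within colonies and
treats loci as independent.
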