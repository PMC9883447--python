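# msbat

**Microsatellite-vs-SNP population-structure analysis for weakly
differentiated, highly mobile species.**

Molecular ecologists studying long-distance dispersers — the motivating case
is a migratory cave bat sampled across 19 European colonies in 7 countries —
face a recurring problem: gene flow keeps range-wide differentiation so low
(F_ST well under 0.1) that a dozen microsatellites may fail to resolve any
structure at all, while a few thousand ddRAD-seq SNPs can. `msbat` packages
the complete analysis battery needed to make that comparison rigorously, plus
a hierarchical simulator so every stage is testable without touching real
data.

## What it computes

**Genotype handling.** Biallelic SNP dosage matrices (TSV or VCF with GT/AD)
and multiallelic microsatellite tables (`a/b` allele-size cells) share one
allele-count abstraction; sample metadata carries population, country, sex
and per-colony coordinates.

**ddRAD filtering** (`run_filter_pipeline`), with a per-step audit ledger:
drop RAD loci with more than 5 SNPs; mask genotypes under 8 reads; mask
heterozygotes whose rarer allele holds less than 25% of reads; mask annotated
tri-allelic genotypes; drop singletons; drop SNPs called in under 70% of
individuals; drop SNPs with per-locus F_IS outside [−0.2, 0.2].

**Diversity and differentiation.** Nei–Chesser small-sample gene diversity
(H_O, H_S, H_T, F_IS), hypergeometric-rarefaction allelic richness A_R,
allele-matching population-specific F_ST (β), Weir–Cockerham pairwise θ, and
a nested method-of-moments decomposition of allele-indicator variance over
gamete < individual < population < country, giving the hierarchical
F-statistics

    F_CT = σ²_C / σ²_tot,   F_SC = σ²_P / (σ²_tot − σ²_C),
    (1 − F_SC)(1 − F_CT) = 1 − F_ST   (identically).

Multi-locus F-statistics are ratios of locus-summed components; 95% CIs come
from locus-resampling bootstrap (1,000 replicates). Cavalli-Sforza chord
distances feed a BIONJ tree; Mantel permutation tests compare distance
matrices; isolation by distance uses the Rousset regression
F_ST/(1−F_ST) ~ ln(km) on haversine distances.

**Individual-level structure.** Genotype PCA (column-mean imputation) and a
regularized-NMF admixture model: the one-hot genotype matrix is factorized as
X ≈ Q·G with row-stochastic ancestries Q and per-cluster genotype-class
frequencies G, fitted by monotone block projected-gradient descent on a
masked least-squares objective with an α-ridge on Q (default α = 100, 10% of
entries blinded per repetition). K is chosen where the median masked
cross-entropy plateaus. A subsampling experiment measures how ancestry
recovery degrades from 3,000 down to 100 SNPs, and the mAIc assignment-index
test screens for sex-biased dispersal.

**The pipeline.** `MarkerComparison(snp, microsat, meta).fit(seed)` runs the
whole battery and returns a JSON-serializable `ComparisonResult` with
per-population tables, CIs, between-marker Pearson correlations, Mantel/IBD
results, hierarchical F-statistics, trees, sex-bias tests and missing-data
sensitivity diagnostics. A `msbat` command-line interface wraps each stage.

## Worked example

```python
from msbat import (paper_like_config, simulate_dataset,
                   hierarchical_fstats, pairwise_fst)
import numpy as np

cfg = paper_like_config()          # 19 colonies, 7 countries, 196 bats,
ds = simulate_dataset(cfg, seed=3) # 4,994 SNPs, F_CT=0.058, F_SC=0.019

h = hierarchical_fstats(ds.snp, ds.metadata)
print(h.summary())
pw = pairwise_fst(ds.snp, ds.metadata)
print("mean pairwise theta:", round(float(np.nanmean(pw.condensed())), 3))
```

prints (seed 3):

```
Hierarchical F-statistics
     country component:  53.0544
  population component:  15.7896
  individual component: -0.97635
      gamete component:  832.376
        F_ST:  0.0765
        F_SC:  0.0186
        F_CT:  0.0589
        F_IS: -0.0012
mean pairwise theta: 0.069
```

The country-level differentiation (F_CT ≈ 0.059) and within-country
substructure (F_SC ≈ 0.019) recover the generating parameters of the preset;
the mean pairwise θ of ≈ 0.069 is what a few-percent nested differentiation
looks like through the Weir–Cockerham lens at these sample sizes.

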