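# dimorph

Sex-dimorphic temporal transcriptomics: model-based clustering of male and
female gene-expression time courses, differential-expression signatures, and
compendium signature scans.

## The problem

Skeletal (and many other) tissues age differently in males and females, and
the difference is as much a matter of *timing* as of expression level.  Given
a bulk expression study with the design

* 2 sexes × ages {3, 6, 9, 12, 18} months × 4 replicates,

`dimorph` answers three questions:

1. **Which genes differ between the sexes overall?**  A pooled-variance
   two-sample *t* test per gene across all time points on unlogged values,
   with Benjamini–Hochberg FDR control, yields a signed **sex signature**
   (+1 = higher in males, −1 = higher in females).
2. **Which genes follow different temporal programs in the two sexes?**
   Each gene contributes two temporal profiles (one per sex), which are
   clustered *jointly* by an entropy-penalized EM (EPEM) fit of a mixture of
   polynomial mixed-effects models.  Cross-tabulating each gene's male and
   female cluster labels splits the transcriptome into **concordant**
   (same cluster, on-diagonal) and **discordant** (different cluster,
   off-diagonal) genes; gene-set overrepresentation in either side uses the
   one-sided hypergeometric ("modified Fisher exact") test.
3. **Where else does the sex signature act coordinately?**  An
   openSESAME-style scan scores every sample of every dataset in a
   compendium by the mean direction-signed z-score over signature genes
   (the **SA score**) and ranks datasets by a two-sided Fisher exact test
   for enrichment in strong-|SA| samples.

## The model

A profile `y_i ∈ R^T` (one gene in one sex, replicate-averaged,
standardized, ages mapped to s ∈ [−1, 1]) follows a K-component mixture

```
y_i | c_i = k  ~  N( X β_k ,  Z D_k Zᵀ + σ² I_T )
```

with `X = [1, s, s², s³]` the cubic fixed-effect basis (cluster mean curve)
and `Z = [1, s, s²]` the quadratic random-effect basis (per-gene deviation,
covariance `D_k`).  Fitting maximizes the entropy-penalized objective

```
J = Σ_i log Σ_k π_k f_k(y_i) + λ N Σ_k π_k log π_k
```

so superfluous components are driven to zero weight and pruned: the cluster
count is selected automatically from an over-specified `K_max`.  Everything
is testable offline because the package ships a generator that simulates
studies from exactly this model (plus a configurable fraction of
sex-discordant genes) and compendia with embedded signatures.

## Worked example

```python
from dimorph import (SimConfig, simulate_timecourse_study, collapse_replicates,
                     standardize_profiles, TemporalMixture, partition_genes,
                     cross_tabulate, summarize_crosstab)

cfg = SimConfig(n_genes=2000, K_true=4, discordant_fraction=0.3, seed=11)
matrix, annot, truth = simulate_timecourse_study(cfg)

profiles = standardize_profiles(collapse_replicates(matrix, annot), per="gene")
result = TemporalMixture(profiles, k_max=10, n_restarts=3, seed=12).fit()
print(result.K)                       # 5

male, female = result.label_maps()
summary = summarize_crosstab(cross_tabulate(male, female, result.K))
print(summary["diagonal_total"], summary["offdiagonal_total"])
# 1402 598
part = partition_genes(male, female)
acc = sum((m == f) == (not d) for (g, (m, f)), d in
          zip(sorted(part.labels.items()), truth.to_frame().sort_values(
              "gene_id")["discordant"])) / len(part.labels)
print(round(acc, 4))                  # 0.9985
```

2,000 simulated genes (30% of them given different temporal programs in the
two sexes) are collapsed to 4,000 profiles and clustered; the fit selects 5
clusters from a start at 10, the cross-tabulation places 598 discordant
genes on the off-diagonal, and 99.85% of genes are classified into the
correct concordant/discordant side of the partition.

The same stages are available from a shell:

```sh
dimorph simulate --n-genes 2000 --discordant-fraction 0.3 --seed 11 \
        --out-matrix m.tsv --out-annot a.tsv --out-truth t.tsv
dimorph de-screen --matrix m.tsv --annot a.tsv --q-threshold 0.1 \
        --out de.tsv --out-signature sig.tsv
dimorph cluster --matrix m.tsv --annot a.tsv --k-max 10 --seed 12 \
        --out-model model.json --out-labels labels.tsv
dimorph crosstab --labels labels.tsv --k 5 --out tab.tsv --out-partition part.tsv
dimorph run --config pipeline.yaml     # all of the above from one file
```

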