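# cohortdiversity

Quantifies the **molecular diversity within a cohort of tumor profiles** —
how dissimilar the members of a group are in gene expression (continuous)
or in mutation / copy-number profiles (categorical). Intertumor diversity
of this kind tracks the genomic heterogeneity of cancer subtypes and is
associated with resistance to therapy, but needs a well-calibrated
statistic to be compared across groups. This package is aimed at
computational biologists analyzing cohort-level transcriptomic and
genomic data.

## The statistics

For samples *i*, *j* with expression vectors over a gene panel:

* **Pearson distance** `d_ij = (1 − ρ_ij) / 2`, with ρ the Pearson
  correlation of the two profiles.
* **Cosine distance** `d_ij = arccos(cos θ_ij) / π`, the normalized angle.
* **Hamming distance** `d_ij = (1/L) Σ_k [x_ki ≠ x_kj]` for categorical
  profiles of length L (mutation indicators, del/none/amp copy-number
  states).
* **Dispersion distance** — the recommended summary. Any pairwise distance
  matrix *D* is embedded by principal coordinates analysis: Gower
  double-centering `G = J(−½ D∘D)J`, `J = I − 11ᵀ/n`, whose diagonal
  `G_ii` is the squared Euclidean distance of sample *i* to the cohort
  centroid in the full embedding (negative eigenvalues of a semimetric
  contribute "imaginary" axes with a minus sign; negative squared
  distances are clamped to zero and reported). The cohort's diversity is
  the mean (or median) of these per-sample centroid distances.

Inference uses **bootstrap resampling** (groups of 100 drawn with
replacement, 500 iterations by default) and a **permutation test** on the
difference in bootstrap means, `p = (1 + #(D > d)) / (1 + R)` with
R = 10⁵ permutations, so the smallest attainable p-value is 1/(1+R).

A built-in **hierarchical simulator** generates benchmark cohorts:
per-gene means `μ_g ~ Normal(μ₀, σ_g)`, per-gene between-sample SDs
`σ_P ~ InvGamma(α, β)` (defaults α = 15, β = 7, prior mean 0.5), log2
values `X ~ Normal(μ_g, σ_P)`, with latent subgroups produced by
independently redrawing the per-gene parameters. A **variance
decomposition** recovers σ_g (SD across genes of the per-gene means) and
σ_P (root mean per-gene across-sample variance) from any cohort.

Supporting machinery: hypergeometric gene-set overlap testing with
recursive reduction to minimally overlapping pathway collections (GMT in
and out), per-pathway bootstrap diversity tables, and gene-level
del/none/amp calls from segmented copy-number data (SEG + BED-like gene
models).

## Worked example

```python
from cohortdiversity import (
    SimulationConfig, simulate_cohort, pearson_distance_matrix,
    dispersion_distances, summarize_diversity, estimate_variances,
    bootstrap_diversity, permutation_test,
)

uniform = simulate_cohort(SimulationConfig(n_genes=50, n_samples=40, seed=1))
mixed = simulate_cohort(
    SimulationConfig(n_genes=50, n_samples=40, group_sizes=(10, 10, 10, 10), seed=1)
)

for name, cohort in [("uniform", uniform), ("4 subgroups", mixed)]:
    D = pearson_distance_matrix(cohort)
    disp = dispersion_distances(D)
    est = estimate_variances(cohort)
    print(f"{name:12s} mean dispersion = {summarize_diversity(disp):.3f}   "
          f"sigma_g_hat = {est.sigma_g_hat:.2f}   sigma_p_hat = {est.sigma_p_hat:.2f}")

boots_u = bootstrap_diversity(uniform, ["uniform"] * 40, metric="dispersion",
                              group_size=40, n_boot=500, seed=2)
boots_m = bootstrap_diversity(mixed, ["mixed"] * 40, metric="dispersion",
                              group_size=40, n_boot=500, seed=2)
p = permutation_test(boots_u["uniform"], boots_m["mixed"], n_perm=100_000, seed=3)
print(f"bootstrap means: uniform {boots_u['uniform'].mean:.3f}, "
      f"mixed {boots_m['mixed'].mean:.3f}, permutation p = {p:.2g}")
```

prints

```
uniform      mean dispersion = 0.035   sigma_g_hat = 1.48   sigma_p_hat = 0.50
4 subgroups  mean dispersion = 0.299   sigma_g_hat = 0.81   sigma_p_hat = 1.41
bootstrap means: uniform 0.035, mixed 0.293, permutation p = 1e-05
```

The homogeneous cohort shows low mean dispersion and near-unbiased
recovery of the generating parameters (σ_g = 1.5, σ_P prior mean 0.5).
The four-subgroup cohort is far more diverse; the latent structure
inflates the between-sample estimate and deflates the within-sample one,
and the permutation test bottoms out at its floor 1/(1+10⁵).

## Command line

```
cohortdiv simulate  --config cfg.yaml --out cohort.tsv
cohortdiv diversity --matrix cohort.tsv --metric dispersion --summary mean
cohortdiv compare   --matrix m.tsv --labels lab.tsv --group-a basal \
                    --group-b lumA --metric dispersion --n-boot 500 \
                    --group-size 100 --n-perm 100000 --seed 1
cohortdiv pathways-reduce --gmt kegg.gmt --alpha 0.05 --out reduced.gmt
cohortdiv pathway-diversity --matrix m.tsv --gmt reduced.gmt --labels lab.tsv \
                    --seed 1 --out pathway_table.tsv
cohortdiv cna-genes --seg tumors.seg --genes refseq.bed --out cna_calls.tsv
cohortdiv fixtures  --out-dir fixtures/ --seed 1
```

Every command writes a JSON manifest (config echo, seed, input digests)
next to its output.

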