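# mechanomics

Data-driven discovery and validation of gene markers of the cell
mechanical phenotype (and, more generally, of any two-class sample
phenotype measured alongside transcriptomes).

Given several gene-by-sample expression datasets ("views") whose
samples fall into two classes — e.g. *soft* vs *stiff* cell states —
the package:

1. infers a **conserved discriminative co-expression network** across
   the views (PC-corr),
2. compresses the strongest network module into a **combinatorial
   marker** (direction-aligned mean of the module genes),
3. validates markers across held-out datasets with a **joint multiview
   AUC-ROC** (the minimum across comparisons), and
4. tests how hard each marker is to beat by chance with the
   **joint-view trustworthiness (JVT)** resampling test.

A synthetic multi-view study generator with a planted, mutually
correlated, class-associated gene module makes every stage testable
without external data.

## The method

**PC-corr.** For one normalized dataset, PCA is run with genes as
features and the component separating the classes is chosen. Its raw
loadings V⁰ are log-compressed and rescaled onto [−1, 1],

&nbsp;&nbsp;V\*ᵢ = sgn(V⁰ᵢ)·log₁₀(1 + |V⁰ᵢ|/⟨|V⁰|⟩),&nbsp;&nbsp;
Vᵢ = sgn(V\*ᵢ)·(|V\*ᵢ| − min|V\*|)/(max|V\*| − min|V\*|),

so they are commensurate with Pearson correlations. Each gene pair is
then scored

&nbsp;&nbsp;PC-corrᵢⱼ = sgn(cᵢⱼ)·min(|Vᵢ|, |Vⱼ|, |cᵢⱼ|),

combining co-expression (cᵢⱼ) with each gene's discriminative weight.
Per-view matrices are merged across N views — magnitude by mean or
minimum, sign by consensus (pairs whose sign disagrees between views
are masked to zero) — and thresholding |PC-corr^comb| yields the
conserved network. The marker module is the network's largest clique.

**Combinatorial marker.** On the inference dataset a reference gene is
chosen (highest average correlation with the other module genes); genes
anticorrelated with it are flagged for alignment, g → 2ḡ − g
(reflection about the gene's mean on the dataset being scored), and the
per-sample marker score is the mean of the aligned, normalized module
genes. Alignment prevents anticorrelated genes from cancelling in the
mean.

**Multiview evaluation and JVT.** A marker's performance on a
hypothesis (a set of dataset comparisons) is the minimum rank-based
AUC-ROC across the comparisons — two-sided by default
(max(AUC, 1−AUC)), since a marker's direction may flip between
biological systems. JVT draws T random genes (or T random m-gene sets,
rebuilding the full marker each time) from the pool of Z genes common
to all datasets, and reports the empirical p value: the proportion of
null draws whose multiview score is at least the observed one. When the
number of distinct draws is ≤ T the null is enumerated exhaustively.

## Worked example

```
python analysis/01_simulate_study.py          # write the synthetic study
python analysis/02_infer_network.py           # PC-corr network + module
python analysis/03_validate_markers.py        # multiview AUC + JVT table
python analysis/04_operating_characteristics.py
```

On the reference study (two views, 500 genes, 6+6 samples per view,
planted 5-gene module `MOD001..MOD005` at effect d = 2 and correlation
ρ = 0.6, seed 0) this prints:

```
combined network (mean, cutoff 0.513): 105 nodes, 125 edges
marker module (6 genes): BG145, MOD001, MOD002, MOD003, MOD004, MOD005
planted genes recovered in module: 5/5

== stiff_vs_soft ==
measure      BG145  MOD001  MOD002  MOD003  MOD004  MOD005  comb
min AUC-ROC  0.83   0.81    1.00    0.94    0.92    0.97    0.92
JVT p value  0.01   0.02    0.00    0.01    0.01    0.00    0.00
```

The network cutoff is the 99.9th percentile of |PC-corr^comb|; the
module (largest clique) contains all five planted genes plus one
background passenger. Each module gene, and the combinatorial marker,
discriminates stiff from soft samples in *both* views (min AUC-ROC) far
better than random module draws do (JVT p ≪ 0.05, T = 1,000), while on
matched null studies (no class effect) the same module is not
significant:

```
module_recovery_>=4of5: 0.9500   (n=20)
jvt_power_p<=0.05: 0.9500        (n=20)
jvt_null_module_p<=0.05: 0.0000  (n=20)
```

The same pipeline runs on real expression matrices (TSV, genes as rows)
through a YAML config:

```
mechanomics run --config study.yaml --out results/
```

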