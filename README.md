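# igem

Geneset-embedded joint non-negative matrix factorization (iGEM) for
integrating gene expression and DNA methylation from a shared patient
cohort, together with the surrounding analysis pipeline: differential
feature selection, geneset merging, gene–CpG interaction graphs,
topic–phenotype association statistics, genotype QC and cis-QTL mapping,
and a synthetic multi-omic cohort generator with planted ground truth.

## Who this is for

Researchers analysing paired bulk expression and methylation profiles of a
clinical cohort (here, antidepressant treatment response in major
depression, labelled by the MADRS ≥ 50 % total-score reduction rule) who
want low-dimensional, pathway-interpretable "meta-phenotype" scores per
subject instead of thousands of marginal tests.

## The model

Two nonnegative views share a subject axis: expression `X1` (subjects ×
genes) and methylation beta values `X2` (subjects × CpGs). iGEM factorizes
them jointly,

    X1 ≈ W H1,   H1 = α ρ
    X2 ≈ W H2

where `W` (subjects × K topics) holds subject meta-phenotype scores, `ρ`
(genesets × genes) is a fixed, row-normalized geneset membership design, `α`
(topics × genesets) are geneset factor scores — so the gene basis
`H1 = αρ` is embedded in known genesets — and `H2` (topics × CpGs) is the
methylation basis. The loss is

    L = ‖X1 − W αρ‖²_F + ‖X2 − W H2‖²_F
        + λ_net Σ_{g,c} B[g,c] Σ_k (H1[k,g] − H2[k,c])²
        + λ_W ΣW + λ_α Σα + λ_H ΣH2

with `B` a sparse gene × CpG adjacency linking correlated proximal
(≤ 500 kb) gene–CpG pairs. Minimization is by multiplicative updates
(order W → α → H2), which preserve non-negativity and never increase `L`;
with all λ = 0 and `ρ = I` they reduce to the standard two-view Lee–Seung
rules. See `docs/methods.md` for assumptions, defaults and numerical
details.

The surrounding pipeline mirrors standard practice: Welch-test expression
gate at p ≤ 0.05 restricted to geneset members, |Δβ| ≥ 0.025 methylation
gate within 500 kb of a selected gene, recursive geneset merging, covariate
residualization + mean normalization + omic balancing (n2/(n1+n2) and
n1/(n1+n2)), Spearman/Pearson topic associations with Benjamini–Hochberg
control, exact Hardy–Weinberg QC (p ≥ 10⁻³, missing rate ≤ 0.01,
MAF ≥ 0.05), a per-SNP response scan (top set at p < 10⁻⁴), SNP–topic
regression under additive and major-allele-presence codings, and cis-QTL
mapping at BH FDR < 0.1.

## Worked example

Simulate a small cohort and run every stage:

```python
from igem.config import RunConfig
from igem.pipeline import run_all

cfg = RunConfig(workdir="demo", seed=7, n_topics=3, max_iter=300, n_restarts=2,
                sim=dict(n_subjects=60, n_topics=3, n_genes=80, n_cpgs=100,
                         n_snps=120, n_genesets=12, frac_differential=0.25))
res = run_all(cfg)
print(res["associate"]["topic_response"].round(4))
```

prints

```
           rho       p   p_adj  direction  significant
topic
topic1 -0.3696  0.0037  0.0055       -1.0         True
topic2 -0.1424  0.2776  0.2776       -1.0        False
topic3  0.7333  0.0000  0.0000        1.0         True
```

i.e. two of the three fitted topics correlate with treatment response after
BH correction (`rho` is the Spearman correlation of the topic's subject
scores with the binary responder label; `topic3` here is the fitted
counterpart of the planted response topic). The same run selected 51 genes,
53 CpGs and 55 interaction edges, reached relative reconstruction errors of
0.52 / 0.19 for the two views, and retained 106 / 120 SNPs after QC
(9 removed for missingness, 1 for MAF, 4 for Hardy–Weinberg violation).
All per-stage tables (`W.tsv`, `alpha.tsv`, `H1.tsv`, `H2.tsv`,
`topic_response.tsv`, `top_genes.tsv`, `eqtl.tsv`, …) are written to the
working directory, and `demo/manifest.json` records config, seed and input
checksums so any product can be regenerated.

The same stages are available from the shell:

```sh
igem --config run.yaml all
```

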