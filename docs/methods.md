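# Methods

## Model

iGEM is a two-view nonnegative factorization with a geneset embedding.
Subjects-by-features views `X1` (expression) and `X2` (methylation beta
values) share the subject loading matrix `W` (subjects × K). The gene basis
is never free: `H1 = α ρ`, where `ρ` (genesets × genes) is fixed ahead of
fitting — each row is a merged geneset's membership indicator divided by
its size over the selected gene universe — and `α` (topics × genesets)
carries the interpretable geneset factor scores. The methylation basis `H2`
(topics × CpGs) is free.

The objective is

    L = ‖X1 − W α ρ‖²_F + ‖X2 − W H2‖²_F
        + λ_net Σ_{g,c} B[g,c] Σ_k (H1[k,g] − H2[k,c])²
        + λ_W ΣW + λ_α Σα + λ_H ΣH2.

The graph penalty is the symmetric squared-difference form standard in
graph-regularized NMF: it pulls the basis values of a gene and a CpG
towards each other exactly when the pair is an edge of the interaction
adjacency `B` (correlated, proximal pairs). This form is bounded below and
admits monotone multiplicative updates; an inner-product coupling would
not. The L1 terms encourage sparse loadings. This objective is the
package's canonical definition of the model; its gradients are verified
against central finite differences in the test suite.

### Updates

One iteration applies, in the order W → α → H2 (ε = denominator floor,
`D_g`/`D_c` = row/column degree of `B`):

    W  ← W  ⊙ (X1 H1ᵀ + X2 H2ᵀ) ⊘ (W (H1 H1ᵀ + H2 H2ᵀ) + λ_W/2 + ε)
    α  ← α  ⊙ (Wᵀ X1 ρᵀ + λ_net H2 Bᵀ ρᵀ)
             ⊘ (WᵀW α ρρᵀ + λ_net (αρ D_g) ρᵀ + λ_α/2 + ε)
    H2 ← H2 ⊙ (Wᵀ X2 + λ_net H1 B) ⊘ (WᵀW H2 + λ_net H2 D_c + λ_H/2 + ε)

after which `H1 = αρ` is recomputed. Each rule is the ratio of the negative
to the positive part of that block's gradient (the L1 gradient λ enters the
denominator as λ/2 because the quadratic parts carry a factor 2), so
non-negativity is preserved and the loss is non-increasing; the suite
checks descent to 1e-9 relative over hundreds of iterations and penalty
settings, and checks that with λ = 0, ρ = I the step equals the plain
two-view Lee–Seung iteration to 1e-12.

### Defaults and numerical choices

| knob | default | why |
|---|---|---|
| K (topics) | 10 | operating point of the analysis this package supports |
| λ_net, λ_W, λ_α, λ_H | 1.0 | neutral starting point; not calibrated to any dataset |
| max_iter / rel_tol | 2000 / 1e-6 | relative-change stopping on the objective |
| n_restarts | 5 | multiplicative updates find local optima; best restart kept |
| ε guard | 1e-12 | division safety; below the descent tolerance |
| init | uniform(0.1, 1.1) × √(mean(X)/K) | strictly positive, reconstruction at the data's magnitude |

The α initialization carries an extra G/S factor because each row of ρ sums
to 1, which shrinks mean(αρ) by S/G. Taking the scale as √(mean/K) (rather
than mean/K) is what puts the initial reconstruction within an order of
magnitude of the data, which the suite asserts. An NNDSVD-style
deterministic start is available (`init="nndsvd"`); zeros are floored to a
small positive value since multiplicative updates cannot leave zero.
Restart r draws from `SeedSequence([seed, r])`, so fits are bit-reproducible.
Rank selection is by inspection of `rank_diagnostics` (objective, per-view
reconstruction error, restart dispersion per K); no automatic criterion is
imposed.

Degenerate inputs: K > min(N, G, C) is rejected; non-finite values
appearing in any block abort with the block named; constant features are
skipped (correlations) or dropped (zero-mean features in normalization),
always logged.

## Preprocessing

* **Expression gate** — Welch two-sample t-test per gene on log2
  expression between responders and non-responders; a gene passes at
  p ≤ 0.05 *and* membership in ≥ 1 geneset. The Welch test is the package's
  differential-expression stand-in: the pipeline ingests already-normalized
  matrices, downstream only the binary gate matters, and a precomputed
  p-value column can be supplied instead. Features with zero variance in
  both groups get p = 1 with a warning.
* **Methylation gate** — |mean(RES) − mean(NRES)| ≥ 0.025 on the beta scale
  (threshold inclusive) and distance ≤ 500 kb from a selected gene.
  A p-value gate is available but off by default; the Welch p is reported
  regardless.
* **Geneset merging** — pairs are merged (union) recursively until no pair
  qualifies. The qualifying rule is overlap ≥ 80 % of the smaller set and
  ≥ 50 % of the larger; the literal opposite reading (50 % of the smaller,
  80 % of the larger) is vacuous whenever the larger-set condition holds,
  so it is implemented only as an option (`rule="literal"`). Candidate
  pairs are scanned in lexicographic id order and the union keeps the
  smaller id, making the fixed point deterministic and order-independent;
  merging its own output is a no-op (tested).
* **ρ construction** — merged sets restricted to the selected gene
  universe, rows divided by their sums; empty rows dropped and logged.
* **Interaction graph B** — per gene, Pearson correlation against every
  selected CpG within 500 kb; at most the 10 smallest-p pairs with p < 0.05
  become edges. Edges are binary (weight 1) by default — the pairs are
  "valid interactions", no weighting is implied — with |r| weights behind a
  flag. Distance is the minimum gap between the CpG position and the
  0-based half-open gene interval (0 inside).
* **Input normalization** — per feature: optional OLS residualization on
  age + sex with the feature mean restored; clipping at 0 (the model takes
  only nonnegative input, and residualization can produce small negatives);
  division by the feature mean; omic balancing by n2/(n1+n2) for X1 and
  n1/(n1+n2) for X2 so neither view dominates the joint loss by feature
  count alone.
* **CpG → gene annotation** — gene body or ≤ 1500 bp upstream of the TSS,
  strand-aware; unknown strand falls back to body-only (logged).

## Association statistics

Topic–response uses Spearman correlation (labels are binary; ranks are the
honest scale), BH-corrected across the K topics, significant at FDR < 0.05.
Topic–MADRS and gene–MADRS use Pearson correlation against per-item change
ratios (week0 − week8)/week0 — positive = improvement — BH-corrected over
all pairs tested within the analysis; gene–item results are reported at
both the 0.05 and 0.1 tiers. Items with zero baseline are flagged missing
and handled pairwise-complete. BH adjustment delegates to statsmodels with
NaN exclusion/restoration; the test suite checks it against a literal
step-up implementation. Top features are ranked per topic by factor score
with relative scores (top = 1, ties broken by feature id); top CpGs are
substituted by their most |r|-correlated gene within 500 kb for
readability. Patient clustering is agglomerative with average linkage on
Euclidean distance (no method is canonical here; configurable), after
optional per-column min-max scaling to [0, 1]; the dendrogram is exported
as newick.

## Genetics

Dosages count the minor allele; input SNPs counted on the major allele are
flipped on load (MAF, HWE p and association |t| are invariant to the flip —
tested). The HWE test is the exact conditional test: given the allele
counts, heterozygote-count probabilities follow a hypergeometric-type law
computed by a stable ratio recurrence, and the p-value sums all
configurations no more probable than the observed one. QC removes SNPs by
missing rate > 0.01, then MAF < 0.05, then HWE p < 10⁻³ (first-failing
attribution, so the report's counts partition the input). Scans are OLS of
the outcome on dosage + age + sex with Wald p on the dosage term,
vectorized by Frisch–Waugh residualization for complete columns and
complete-case per SNP where dosages are missing. The response scan carries
no global multiple-testing correction by design (the top set is p < 10⁻⁴).
SNP–topic regression supports the additive (0/1/2) coding and the
major-allele-presence coding (minor homozygotes vs carriers), which target
additive and recessive architectures respectively. cis-QTL mapping tests
SNPs within 500 kb of the feature, BH within each feature's cis set, FDR
0.1; topics and MADRS ratios have no genomic position and are scanned
genome-wide (flag-controlled). No genotype principal components are
included by default; a PCA-covariate option exists.

## Synthetic cohorts

The generator emulates the structure every stage assumes, at desk scale
(defaults: 111 subjects, 10 topics, 300 genes, 400 CpGs, 500 SNPs, 40
genesets — a cohort-sized N with feature counts small enough for tests):

* **Expression** `= exp(W αρ + N(0, σ) + covariate/QTL/differential
  effects)`; log-normal noise keeps positivity and matches a log-scale
  analysis.
* **Methylation** beta `= logistic(standardized W H2 + noise + effects)`;
  per-CpG standardization keeps beta values spread over (0, 1). Planted
  differential CpGs get a group shift of 7 × (target Δβ) on the logit
  scale, the slope that realizes at least the target difference on the
  beta scale at typical baselines; they are placed within 300 kb of a
  planted differential gene so the proximity filter can see them (only as
  many as the geography allows).
* **Genotypes** are Binomial(2, MAF) under HWE, with a configurable set of
  violating SNPs drawn with inbreeding excess F = 0.6. Missingness is
  concentrated: only a fraction (10 %) of SNPs are missingness-prone at
  0.5 % per call, plus a few planted high-missingness SNPs — uniform
  per-call missingness would fail nearly half of all SNPs at the 0.01
  gate for cohort-sized N, which is not how array data behave.
* **Labels** come from a logistic link on the standardized response-topic
  column of W (slope 2.0, intercept 0.2 → roughly balanced groups, as in
  a responder/non-responder cohort), optionally plus per-allele effects of
  planted response SNPs.
* **MADRS items** distribute a total (uniform 20–40 at baseline, a
  moderate-to-severe depression range) across the 10 items by a multinomial
  draw capped at 6 per item; week-8 totals are drawn from the target change
  ratio and then forced onto the correct side of the 50 %-reduction rule,
  so responder labels and item scores are always mutually consistent. Item
  distributions are plausible placeholders, not calibrated to any cohort.
* Each modality draws from its own PRNG stream spawned from the master
  seed, so changing one modality's dimensions does not perturb another's
  draws; the same config and seed reproduce byte-identical files.

What passing tests on these cohorts do **not** show: robustness to batch
effects, count overdispersion, probe artefacts, cell-type composition,
population structure or relatedness — none of which the generator
emulates.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run planted-recovery fits at
N ≈ 60–111 subjects with tens-to-hundreds of features and K ≤ 10, null
calibrations over 100 seeds, and exact-oracle comparisons (BH step-up;
HWE enumeration over all genotype tables with n ≤ 30). These sizes were
chosen so the whole battery runs on a laptop in minutes while keeping every
statistical check adequately powered.

## Known limitations

* Two views only; the interfaces reserve the extension point but v1 does
  not fit three or more omics.
* λ defaults are uncalibrated; any real analysis should examine
  `rank_diagnostics` and sensitivity to λ_net.
* Multiplicative updates stall near zero entries; collapsed (all-zero)
  topics can occur under strong L1 and are reported as NA correlations
  downstream.
* The differential-expression gate is a Welch test on normalized values,
  not a count-model fit; supply precomputed p-values if a count model is
  required.
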