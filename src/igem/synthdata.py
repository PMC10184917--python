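"""Synthetic multi-omic cohort generator with planted ground truth.

Emulates the statistical structure the pipeline assumes: a latent topic
model behind both omics (expression = exp(W @ alpha @ rho + noise +
covariate and QTL effects), methylation beta = logistic of a per-CpG
standardized topic signal), genotypes drawn under Hardy-Weinberg equilibrium
except a configurable set of violating SNPs, a binary treatment-response
label drawn from a logistic link on one topic's subject scores, and MADRS
item scores at week 0 and week 8 constructed so responders satisfy the
>= 50% total-score reduction rule.

Each data modality draws from its own PRNG stream spawned from the master
seed, so e.g. adding SNPs does not perturb the expression draws.  The same
config and seed always reproduce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import json
import numpy as np
import pandas as pd

from .io import GenomeLayout, write_layout, write_matrix, write_gmt, write_plink_raw

__all__ = ["SimConfig", "CohortTruth", "Cohort", "generate_cohort",
           "planted_truth_report", "write_cohort", "null_config"]

_STREAMS = ("layout", "genesets", "factors", "expression", "methylation",
            "genotype", "phenotype", "qtl")

# per-allele shift on the logit scale producing roughly this multiple of the
# target beta-value difference at a standard-normal baseline logit
_LOGIT_SLOPE = 7.0


@dataclass
class SimConfig:
    """Cohort dimensions, noise levels and planted effect sizes.

    Defaults emulate the study conditions at desk scale: a 111-subject
    cohort with 10 latent topics, log-normal expression noise, logit-scale
    methylation noise, HWE genotypes at MAF in [0.05, 0.5], a logistic
    response link on one topic, and modest fractions of planted differential
    features and cis-QTLs.
    """

    n_subjects: int = 111
    n_topics: int = 10
    n_genes: int = 300
    n_cpgs: int = 400
    n_snps: int = 500
    n_genesets: int = 40

    n_chromosomes: int = 4
    chrom_length: int = 60_000_000

    noise_sd: float = 0.3            # log-expression Gaussian noise
    beta_noise_sd: float = 0.3       # logit-scale methylation noise
    age_effect_sd: float = 0.002     # per-year covariate coefficient spread
    sex_effect_sd: float = 0.05
    covariate_effects: bool = True

    frac_differential: float = 0.1   # fraction of genes/CpGs with group effects
    expr_effect: float = 0.6         # log-units between groups for planted genes
    beta_effect: float = 0.05        # target |delta beta| for planted CpGs

    maf_range: tuple[float, float] = (0.05, 0.5)
    frac_snps_with_missing: float = 0.1   # most SNPs assay cleanly
    missing_rate: float = 0.005           # per call, within that fraction
    n_high_missing_snps: int = 5          # planted QC failures
    high_missing_rate: float = 0.05
    n_hwe_violations: int = 5
    hwe_inbreeding: float = 0.6

    n_qtls: int = 10
    qtl_beta: float = 0.6            # per-allele effect (log / logit scale)

    response_topic_index: int = 0
    logistic_slope: float = 2.0      # on the standardized response-topic score
    logistic_intercept: float = 0.2
    n_response_snps: int = 2
    response_snp_beta: float = 2.0   # per-allele logit effect on response

    madrs_base_range: tuple[int, int] = (20, 40)

    def validate(self) -> None:
        for name in ("n_subjects", "n_topics", "n_genes", "n_cpgs", "n_snps",
                     "n_genesets", "n_chromosomes", "chrom_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_topics > min(self.n_subjects, self.n_genes, self.n_cpgs):
            raise ValueError("n_topics may not exceed min(n_subjects, n_genes, n_cpgs)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0 <= self.response_topic_index < self.n_topics):
            raise ValueError("response_topic_index must be < n_topics")


def null_config(**overrides) -> SimConfig:
    """A cohort with no planted structure: labels independent of everything."""
    base = dict(frac_differential=0.0, n_qtls=0, n_response_snps=0,
                logistic_slope=0.0, n_hwe_violations=0)
    base.update(overrides)
    return SimConfig(**base)


@dataclass
class CohortTruth:
    """Planted ground truth used by recovery and calibration tests."""

    W_true: np.ndarray               # subjects x topics
    alpha_true: np.ndarray           # topics x genesets
    H2_true: np.ndarray              # topics x CpGs
    rho_true: np.ndarray             # genesets x genes (row-normalized)
    genesets_true: list[tuple[str, list[str]]]
    response_topic_index: int
    differential_gene_ids: set[str] = field(default_factory=set)
    differential_cpg_ids: set[str] = field(default_factory=set)
    qtl_effects: list[tuple[str, str, float]] = field(default_factory=list)
    response_snp_effects: list[tuple[str, float]] = field(default_factory=list)
    labels: np.ndarray = None
    age: np.ndarray = None
    sex: np.ndarray = None


@dataclass
class Cohort:
    """Everything ``generate_cohort`` produces, ready to write or analyse."""

    expression: pd.DataFrame        # genes x subjects, strictly positive
    methylation: pd.DataFrame       # CpGs x subjects, beta values in (0, 1)
    genotypes: pd.DataFrame         # subjects x SNPs dosages, NaN = missing
    phenotypes: pd.DataFrame        # label, age, sex, MADRS items w0/w8
    layout: GenomeLayout
    genesets: list[tuple[str, list[str]]]
    truth: CohortTruth


# ---------------------------------------------------------------------------
# building blocks


def _make_layout(cfg: SimConfig, rng: np.random.Generator):
    chroms = {f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chromosomes)}
    names = list(chroms)
    g_chrom = rng.integers(0, cfg.n_chromosomes, size=cfg.n_genes)
    g_len = rng.integers(5_000, 100_000, size=cfg.n_genes)
    g_start = rng.integers(500_000, cfg.chrom_length - 600_000, size=cfg.n_genes)
    genes = pd.DataFrame({
        "gene_id": [f"G{i:04d}" for i in range(cfg.n_genes)],
        "chrom": [names[c] for c in g_chrom],
        "start": g_start,
        "end": g_start + g_len,
        "strand": rng.choice(["+", "-"], size=cfg.n_genes),
    })
    # CpGs anchored near genes so proximity filters have something to find
    anchor = rng.integers(0, cfg.n_genes, size=cfg.n_cpgs)
    offset = rng.integers(-200_000, 200_001, size=cfg.n_cpgs)
    cpos = np.clip(g_start[anchor] + offset, 0, cfg.chrom_length - 1)
    cpgs = pd.DataFrame({
        "cpg_id": [f"cg{i:05d}" for i in range(cfg.n_cpgs)],
        "chrom": [names[c] for c in g_chrom[anchor]],
        "pos": cpos,
    })
    s_anchor = rng.integers(0, cfg.n_genes, size=cfg.n_snps)
    s_offset = rng.integers(-400_000, 400_001, size=cfg.n_snps)
    spos = np.clip(g_start[s_anchor] + s_offset, 0, cfg.chrom_length - 1)
    alleles = np.array(["A", "C", "G", "T"])
    ref = rng.integers(0, 4, size=cfg.n_snps)
    alt = (ref + rng.integers(1, 4, size=cfg.n_snps)) % 4
    snps = pd.DataFrame({
        "snp_id": [f"rs{i:05d}" for i in range(cfg.n_snps)],
        "chrom": [names[c] for c in g_chrom[s_anchor]],
        "pos": spos,
        "ref": alleles[ref],
        "alt": alleles[alt],
    })
    layout = GenomeLayout(chromosomes=chroms, genes=genes, cpgs=cpgs, snps=snps)
    layout.validate()
    return layout, anchor


def _make_genesets(cfg: SimConfig, gene_ids: list[str], rng: np.random.Generator):
    """Random genesets covering every gene at least once."""
    sets: list[set[str]] = [set() for _ in range(cfg.n_genesets)]
    for g in gene_ids:
        for s in rng.choice(cfg.n_genesets, size=rng.integers(1, 4), replace=False):
            sets[s].add(g)
    for s in range(cfg.n_genesets):  # no empty sets
        if not sets[s]:
            sets[s].add(gene_ids[int(rng.integers(0, len(gene_ids)))])
    return [(f"GS{i:03d}", sorted(sets[i])) for i in range(cfg.n_genesets)]


def _rho_from_genesets(genesets, gene_ids: list[str]) -> np.ndarray:
    col = {g: j for j, g in enumerate(gene_ids)}
    rho = np.zeros((len(genesets), len(gene_ids)))
    for i, (_, genes) in enumerate(genesets):
        idx = [col[g] for g in genes]
        rho[i, idx] = 1.0 / len(idx)
    return rho


def _sparse_gamma(rng, shape, keep=0.3):
    x = rng.gamma(2.0, 1.0, size=shape)
    mask = rng.random(shape) < keep
    # every row keeps at least one entry
    for k in range(shape[0]):
        if not mask[k].any():
            mask[k, int(rng.integers(0, shape[1]))] = True
    return x * mask


def _distribute_items(total: int, rng: np.random.Generator) -> np.ndarray:
    """Split a MADRS total across 10 items, each clipped to 0..6."""
    total = int(min(total, 60))
    items = rng.multinomial(total, np.ones(10) / 10)
    while (items > 6).any():
        hi = int(np.argmax(items))
        lo = int(np.argmin(items))
        items[hi] -= 1
        items[lo] += 1
    return items


# ---------------------------------------------------------------------------
# main entry point


def generate_cohort(cfg: SimConfig, seed: int) -> Cohort:
    """Generate a complete synthetic cohort; deterministic given (cfg, seed)."""
    cfg.validate()
    streams = dict(zip(_STREAMS, (np.random.default_rng(c)
                                  for c in np.random.SeedSequence(seed).spawn(len(_STREAMS)))))
    n, k = cfg.n_subjects, cfg.n_topics
    subj = [f"S{i:03d}" for i in range(n)]

    layout, _ = _make_layout(cfg, streams["layout"])
    gene_ids = layout.genes["gene_id"].tolist()
    cpg_ids = layout.cpgs["cpg_id"].tolist()
    snp_ids = layout.snps["snp_id"].tolist()
    genesets = _make_genesets(cfg, gene_ids, streams["genesets"])
    rho = _rho_from_genesets(genesets, gene_ids)

    frng = streams["factors"]
    W = frng.gamma(2.0, 1.0, size=(n, k))
    alpha = _sparse_gamma(frng, (k, cfg.n_genesets))
    H2 = _sparse_gamma(frng, (k, cfg.n_cpgs))

    # covariates and response label (phenotype stream)
    prng = streams["phenotype"]
    age = prng.integers(18, 71, size=n).astype(float)
    sex = prng.integers(0, 2, size=n).astype(float)
    w_resp = W[:, cfg.response_topic_index]
    z = (w_resp - w_resp.mean()) / max(w_resp.std(), 1e-12)
    lin = cfg.logistic_intercept + cfg.logistic_slope * z

    # genotypes (genotype stream)
    grng = streams["genotype"]
    maf = grng.uniform(*cfg.maf_range, size=cfg.n_snps)
    dosage = grng.binomial(2, maf, size=(n, cfg.n_snps)).astype(float)
    hwe_violators = list(np.array(snp_ids)[
        grng.choice(cfg.n_snps, size=min(cfg.n_hwe_violations, cfg.n_snps),
                    replace=False)]) if cfg.n_hwe_violations else []
    for s in hwe_violators:
        j = snp_ids.index(s)
        p, q, F = maf[j], 1 - maf[j], cfg.hwe_inbreeding
        probs = np.array([q * q + F * p * q, 2 * p * q * (1 - F), p * p + F * p * q])
        dosage[:, j] = grng.choice(3, size=n, p=probs / probs.sum())

    # response-associated SNPs enter the logistic link before labels are drawn
    resp_snps: list[tuple[str, float]] = []
    if cfg.n_response_snps:
        picks = grng.choice(cfg.n_snps, size=min(cfg.n_response_snps, cfg.n_snps),
                            replace=False)
        for j in picks:
            resp_snps.append((snp_ids[int(j)], cfg.response_snp_beta))
            lin = lin + cfg.response_snp_beta * (dosage[:, j] - 2 * maf[j])
    labels = (prng.random(n) < 1.0 / (1.0 + np.exp(-lin))).astype(int)
    centered = labels - 0.5

    # planted differential features and QTLs
    qrng = streams["qtl"]
    n_dg = int(round(cfg.frac_differential * cfg.n_genes))
    n_dc = int(round(cfg.frac_differential * cfg.n_cpgs))
    diff_genes = sorted(qrng.choice(gene_ids, size=n_dg, replace=False)) if n_dg else []
    diff_cpg_pool = cpg_ids
    if diff_genes and n_dc:
        # keep planted CpGs within reach of a planted (hence selected) gene
        dg = layout.genes[layout.genes["gene_id"].isin(diff_genes)]
        from .preprocess import feature_gene_distances
        dist = feature_gene_distances(layout.cpgs["pos"].to_numpy(),
                                      layout.cpgs["chrom"].to_numpy(), dg)
        pool = list(layout.cpgs["cpg_id"][dist <= 300_000])
        if pool:  # plant only what the geography allows
            diff_cpg_pool = pool
    diff_cpgs = sorted(qrng.choice(diff_cpg_pool, size=min(n_dc, len(diff_cpg_pool)),
                                   replace=False)) if n_dc else []

    qtls: list[tuple[str, str, float]] = []
    if cfg.n_qtls:
        snp_pos = layout.snps.set_index("snp_id")
        for t in range(cfg.n_qtls):
            feat_is_gene = t % 2 == 0
            feats = layout.genes if feat_is_gene else layout.cpgs
            for _ in range(200):  # rejection-sample a cis pair
                fi = int(qrng.integers(0, len(feats)))
                frow = feats.iloc[fi]
                lo = frow["start"] if feat_is_gene else frow["pos"]
                hi = frow["end"] if feat_is_gene else frow["pos"] + 1
                same = snp_pos["chrom"] == frow["chrom"]
                gap = (np.maximum(lo - snp_pos["pos"], 0)
                       + np.maximum(snp_pos["pos"] - (hi - 1), 0))
                cis = snp_pos.index[same & (gap <= 400_000)].tolist()
                if cis:
                    snp = cis[int(qrng.integers(0, len(cis)))]
                    fid = frow["gene_id"] if feat_is_gene else frow["cpg_id"]
                    qtls.append((snp, fid, cfg.qtl_beta))
                    break

    # expression (expression stream)
    erng = streams["expression"]
    signal = W @ alpha @ rho  # subjects x genes
    log_expr = signal.copy()
    if cfg.noise_sd:
        log_expr = log_expr + erng.normal(0, cfg.noise_sd, size=signal.shape)
    if cfg.covariate_effects and (cfg.age_effect_sd or cfg.sex_effect_sd):
        a_coef = erng.normal(0, cfg.age_effect_sd, size=cfg.n_genes)
        s_coef = erng.normal(0, cfg.sex_effect_sd, size=cfg.n_genes)
        log_expr = log_expr + np.outer(age - age.mean(), a_coef) + np.outer(sex, s_coef)
    gidx = {g: j for j, g in enumerate(gene_ids)}
    for g in diff_genes:
        log_expr[:, gidx[g]] += cfg.expr_effect * centered
    for snp, feat, beta in qtls:
        if feat in gidx:
            log_expr[:, gidx[feat]] += beta * dosage[:, snp_ids.index(snp)]
    expression = pd.DataFrame(np.exp(log_expr).T, index=gene_ids, columns=subj)

    # methylation (methylation stream)
    mrng = streams["methylation"]
    msig = W @ H2  # subjects x CpGs
    sd = msig.std(axis=0)
    logit = (msig - msig.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    if cfg.beta_noise_sd:
        logit = logit + mrng.normal(0, cfg.beta_noise_sd, size=logit.shape)
    if cfg.covariate_effects and (cfg.age_effect_sd or cfg.sex_effect_sd):
        a_coef = mrng.normal(0, cfg.age_effect_sd, size=cfg.n_cpgs)
        s_coef = mrng.normal(0, cfg.sex_effect_sd, size=cfg.n_cpgs)
        logit = logit + np.outer(age - age.mean(), a_coef) + np.outer(sex, s_coef)
    cidx = {c: j for j, c in enumerate(cpg_ids)}
    for c in diff_cpgs:
        logit[:, cidx[c]] += _LOGIT_SLOPE * cfg.beta_effect * centered
    for snp, feat, beta in qtls:
        if feat in cidx:
            logit[:, cidx[feat]] += beta * dosage[:, snp_ids.index(snp)]
    beta_vals = 1.0 / (1.0 + np.exp(-logit))
    methylation = pd.DataFrame(beta_vals.T, index=cpg_ids, columns=subj)

    # genotype missingness (after all effects were planted)
    if cfg.missing_rate and cfg.frac_snps_with_missing:
        prone = grng.random(cfg.n_snps) < cfg.frac_snps_with_missing
        mask = (grng.random(dosage.shape) < cfg.missing_rate) & prone
        dosage[mask] = np.nan
    if cfg.n_high_missing_snps:
        picks = grng.choice(cfg.n_snps, size=min(cfg.n_high_missing_snps, cfg.n_snps),
                            replace=False)
        for j in picks:
            mask = grng.random(n) < cfg.high_missing_rate
            dosage[mask, j] = np.nan
    genotypes = pd.DataFrame(dosage, index=subj, columns=snp_ids)

    # MADRS items consistent with the response rule (phenotype stream)
    lo, hi = cfg.madrs_base_range
    t0 = prng.integers(lo, hi + 1, size=n)
    w0 = np.vstack([_distribute_items(t, prng) for t in t0])
    t8 = np.empty(n, dtype=int)
    for i in range(n):
        if labels[i]:
            ratio = prng.uniform(0.5, 0.95)
            t8[i] = min(int(np.floor(t0[i] * (1 - ratio))), t0[i] // 2)
        else:
            ratio = prng.uniform(-0.1, 0.45)
            t8[i] = max(int(np.ceil(t0[i] * (1 - ratio))), t0[i] // 2 + 1)
            t8[i] = min(t8[i], 60)
    w8 = np.vstack([_distribute_items(t, prng) for t in t8])

    phen = pd.DataFrame({"subject_id": subj, "response": labels,
                         "age": age.astype(int), "sex": sex.astype(int)})
    for j in range(10):
        phen[f"madrs{j + 1}_w0"] = w0[:, j]
    for j in range(10):
        phen[f"madrs{j + 1}_w8"] = w8[:, j]
    phen = phen.set_index("subject_id")

    truth = CohortTruth(
        W_true=W, alpha_true=alpha, H2_true=H2, rho_true=rho,
        genesets_true=genesets, response_topic_index=cfg.response_topic_index,
        differential_gene_ids=set(diff_genes), differential_cpg_ids=set(diff_cpgs),
        qtl_effects=qtls, response_snp_effects=resp_snps,
        labels=labels, age=age, sex=sex)
    return Cohort(expression=expression, methylation=methylation,
                  genotypes=genotypes, phenotypes=phen, layout=layout,
                  genesets=genesets, truth=truth)


# ---------------------------------------------------------------------------
# reporting and persistence


def planted_truth_report(truth: CohortTruth) -> pd.DataFrame:
    """Flat table of every planted effect, one row each."""
    rows = [{"kind": "qtl", "snp_id": s, "feature_id": f, "beta": b}
            for s, f, b in truth.qtl_effects]
    rows += [{"kind": "differential_gene", "snp_id": None, "feature_id": g,
              "beta": None} for g in sorted(truth.differential_gene_ids)]
    rows += [{"kind": "differential_cpg", "snp_id": None, "feature_id": c,
              "beta": None} for c in sorted(truth.differential_cpg_ids)]
    return pd.DataFrame(rows, columns=["kind", "snp_id", "feature_id", "beta"])


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix(cohort.expression, outdir / "expression.tsv")
    write_matrix(cohort.methylation, outdir / "methylation.tsv")
    alt = dict(zip(cohort.layout.snps["snp_id"], cohort.layout.snps["alt"]))
    write_plink_raw(cohort.genotypes, alt, outdir / "genotypes.raw",
                    sex=(cohort.phenotypes["sex"] + 1).tolist(),
                    phenotype=(cohort.phenotypes["response"] + 1).tolist())
    write_layout(cohort.layout, outdir / "layout")
    write_gmt(cohort.genesets, outdir / "genesets.gmt")
    cohort.phenotypes.to_csv(outdir / "phenotypes.tsv", sep="\t")
    truth = cohort.truth
    payload = {
        "W_true": truth.W_true.tolist(),
        "alpha_true": truth.alpha_true.tolist(),
        "H2_true": truth.H2_true.tolist(),
        "rho_true": truth.rho_true.tolist(),
        "genesets_true": [[i, list(g)] for i, g in truth.genesets_true],
        "response_topic_index": truth.response_topic_index,
        "differential_gene_ids": sorted(truth.differential_gene_ids),
        "differential_cpg_ids": sorted(truth.differential_cpg_ids),
        "qtl_effects": [[s, f, b] for s, f, b in truth.qtl_effects],
        "response_snp_effects": [[s, b] for s, b in truth.response_snp_effects],
        "labels": truth.labels.tolist(),
        "age": truth.age.tolist(),
        "sex": truth.sex.tolist(),
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(payload, fh)
        fh.write("\n")
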