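"""Stage runners chaining the library end-to-end over a working directory.

Each stage reads its inputs from, and writes its products to, the run's
working directory, so any product can be regenerated from the manifest
(config + seed + input checksums) alone.  All writers emit deterministic
column order and row sort.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import association as assoc
from . import genetics, preprocess, synthdata
from .config import RunConfig
from .io import (read_gmt, read_layout, read_matrix, read_plink_raw,
                 write_manifest, write_matrix)
from .model import Hyperparams, fit, reconstruction_errors

log = logging.getLogger("igem")

__all__ = ["run_simulate", "run_preprocess", "run_fit", "run_associate",
           "run_qtl", "run_all"]


def _wd(cfg: RunConfig) -> Path:
    wd = Path(cfg.workdir)
    wd.mkdir(parents=True, exist_ok=True)
    return wd


def run_simulate(cfg: RunConfig) -> Path:
    wd = _wd(cfg)
    sim = synthdata.SimConfig(**cfg.sim)
    cohort = synthdata.generate_cohort(sim, cfg.seed)
    synthdata.write_cohort(cohort, wd)
    write_manifest(wd / "manifest.json", inputs={}, config=cfg.to_dict(),
                   seed=cfg.seed)
    return wd


def _load_phenotypes(wd: Path, cfg: RunConfig) -> pd.DataFrame:
    return pd.read_csv(wd / cfg.phenotypes, sep="\t", index_col=0)


def run_preprocess(cfg: RunConfig) -> dict:
    wd = _wd(cfg)
    expr = read_matrix(wd / cfg.expression)          # genes x subjects, linear
    beta = read_matrix(wd / cfg.methylation)         # CpGs x subjects
    layout = read_layout(wd / cfg.layout_dir)
    genesets = read_gmt(wd / cfg.genesets)
    phen = _load_phenotypes(wd, cfg)
    labels = phen["response"].to_numpy()
    log_expr = np.log2(expr)

    de = preprocess.differential_expression(
        log_expr, labels, genesets, p_threshold=cfg.de_p_threshold)
    selected_genes = sorted(de.index[de["pass_flag"]])
    dm = preprocess.differential_methylation(
        beta, labels, selected_genes, layout,
        delta_threshold=cfg.dm_delta_beta, window=cfg.proximity_window,
        p_threshold=cfg.dm_p_threshold)
    selected_cpgs = sorted(dm.index[dm["pass_flag"]])
    log.info("selected %d genes, %d CpGs", len(selected_genes), len(selected_cpgs))

    merged, merge_log = preprocess.merge_genesets(
        genesets, small_frac=cfg.merge_small_frac,
        large_frac=cfg.merge_large_frac, rule=cfg.merge_rule)
    design = preprocess.build_rho(merged, selected_genes, merge_log)

    graph = preprocess.build_interaction_graph(
        log_expr.loc[selected_genes], beta.loc[selected_cpgs], layout,
        window=cfg.proximity_window, top_pairs=cfg.interaction_top_pairs,
        p_threshold=cfg.interaction_p_threshold,
        weighted=cfg.interaction_weighted)

    covars = phen[["age", "sex"]]
    X1, X2 = preprocess.normalize_inputs(
        log_expr.loc[selected_genes], beta.loc[selected_cpgs], covars,
        residualize=cfg.residualize_covariates)

    # re-align rho and B if normalization dropped zero-mean features
    if list(X1.columns) != design.gene_ids or list(X2.columns) != graph.cpg_ids:
        design = preprocess.build_rho(merged, list(X1.columns), merge_log)
        gi = [graph.gene_ids.index(g) for g in X1.columns]
        ci = [graph.cpg_ids.index(c) for c in X2.columns]
        graph.B = graph.B[gi][:, ci]
        graph.gene_ids, graph.cpg_ids = list(X1.columns), list(X2.columns)

    de.to_csv(wd / "differential_expression.tsv", sep="\t")
    dm.to_csv(wd / "differential_methylation.tsv", sep="\t")
    pd.Series(selected_genes).to_csv(wd / "selected_genes.txt", index=False, header=False)
    pd.Series(selected_cpgs).to_csv(wd / "selected_cpgs.txt", index=False, header=False)
    rho_df = pd.DataFrame(design.rho, index=design.geneset_ids, columns=design.gene_ids)
    write_matrix(rho_df, wd / "rho.tsv", orientation="genesets_by_genes")
    graph.edges.to_csv(wd / "interaction_edges.tsv", sep="\t", index=False)
    write_matrix(X1.T, wd / "X1.tsv")   # stored features x subjects
    write_matrix(X2.T, wd / "X2.tsv")
    return {"n_genes": len(X1.columns), "n_cpgs": len(X2.columns),
            "n_genesets": len(design.geneset_ids), "n_edges": len(graph.edges),
            "design": design, "graph": graph, "X1": X1, "X2": X2}


def _load_model_inputs(wd: Path):
    X1 = read_matrix(wd / "X1.tsv").T   # subjects x genes
    X2 = read_matrix(wd / "X2.tsv").T
    rho = read_matrix(wd / "rho.tsv")
    edges = pd.read_csv(wd / "interaction_edges.tsv", sep="\t")
    gi = {g: j for j, g in enumerate(X1.columns)}
    ci = {c: j for j, c in enumerate(X2.columns)}
    B = sp.csr_matrix(
        (edges["weight"],
         ([gi[g] for g in edges["gene_id"]], [ci[c] for c in edges["cpg_id"]])),
        shape=(X1.shape[1], X2.shape[1]))
    return X1, X2, rho, B


def run_fit(cfg: RunConfig) -> dict:
    wd = _wd(cfg)
    X1, X2, rho, B = _load_model_inputs(wd)
    hyper = Hyperparams(
        n_topics=cfg.n_topics, lambda_net=cfg.lambda_net, lambda_w=cfg.lambda_w,
        lambda_alpha=cfg.lambda_alpha, lambda_h=cfg.lambda_h,
        max_iter=cfg.max_iter, rel_tol=cfg.rel_tol, n_restarts=cfg.n_restarts,
        seed=cfg.seed, epsilon_guard=cfg.epsilon_guard, init=cfg.init)
    res = fit(X1.to_numpy(), X2.to_numpy(), rho.to_numpy(), B, hyper)
    topics = [f"topic{k + 1}" for k in range(hyper.n_topics)]
    write_matrix(pd.DataFrame(res.W, index=X1.index, columns=topics).T,
                 wd / "W.tsv", orientation="topics_by_subjects")
    write_matrix(pd.DataFrame(res.alpha, index=topics, columns=rho.index),
                 wd / "alpha.tsv", orientation="topics_by_genesets")
    write_matrix(pd.DataFrame(res.H1, index=topics, columns=X1.columns),
                 wd / "H1.tsv", orientation="topics_by_genes")
    write_matrix(pd.DataFrame(res.H2, index=topics, columns=X2.columns),
                 wd / "H2.tsv", orientation="topics_by_cpgs")
    pd.DataFrame({"iteration": range(len(res.objective_trajectory)),
                  "objective": res.objective_trajectory}).to_csv(
        wd / "objective.tsv", sep="\t", index=False)
    e1, e2 = reconstruction_errors(res, X1.to_numpy(), X2.to_numpy())
    log.info("fit: %d iters, converged=%s, recon err (%.3g, %.3g)",
             res.n_iter, res.converged, e1, e2)
    return {"fit": res, "recon_err": (e1, e2)}


def _madrs_tables(phen: pd.DataFrame):
    w0 = phen[[f"madrs{j}_w0" for j in range(1, 11)]]
    w8 = phen[[f"madrs{j}_w8" for j in range(1, 11)]]
    w0 = w0.rename(columns=lambda c: c.replace("_w0", ""))
    w8 = w8.rename(columns=lambda c: c.replace("_w8", ""))
    return assoc.madrs_change(w0, w8)


def run_associate(cfg: RunConfig) -> dict:
    wd = _wd(cfg)
    W = read_matrix(wd / "W.tsv").T           # subjects x topics
    H1 = read_matrix(wd / "H1.tsv")
    H2 = read_matrix(wd / "H2.tsv")
    phen = _load_phenotypes(wd, cfg)
    layout = read_layout(wd / cfg.layout_dir)
    expr = read_matrix(wd / cfg.expression)
    betam = read_matrix(wd / cfg.methylation)
    change = _madrs_tables(phen)

    topic_resp = assoc.topic_response_association(
        W, phen["response"], fdr=cfg.association_fdr)
    topic_madrs = assoc.topic_madrs_association(W, change, fdr=cfg.association_fdr)
    top_genes = assoc.top_features(H1, n=cfg.top_n_features)
    top_cpgs = assoc.top_features(H2, n=cfg.top_n_features)
    top_cpgs["proxy_gene"] = [
        assoc.map_cpg_to_correlated_gene(c, betam.T, np.log2(expr).T, layout,
                                         window=cfg.proximity_window)
        for c in top_cpgs["feature"]]
    gene_lists = {t: g["feature"].tolist()
                  for t, g in top_genes.groupby("topic")}
    gene_madrs = assoc.gene_madrs_association(gene_lists, np.log2(expr).T, change)
    sig = topic_resp.index[topic_resp["significant"]].tolist()
    cluster_cols = sig if sig else list(W.columns)
    leaves, Z, newick = assoc.cluster_patients(
        W[cluster_cols], normalize=True, method=cfg.cluster_method,
        metric=cfg.cluster_metric)

    topic_resp.to_csv(wd / "topic_response.tsv", sep="\t")
    topic_madrs.to_csv(wd / "topic_madrs.tsv", sep="\t", index=False)
    top_genes.to_csv(wd / "top_genes.tsv", sep="\t", index=False)
    top_cpgs.to_csv(wd / "top_cpgs.tsv", sep="\t", index=False)
    gene_madrs.to_csv(wd / "gene_madrs.tsv", sep="\t", index=False)
    with open(wd / "patient_tree.nwk", "w") as fh:
        fh.write(newick + "\n")
    pd.Series(leaves).to_csv(wd / "patient_leaf_order.txt", index=False, header=False)
    return {"topic_response": topic_resp, "topic_madrs": topic_madrs,
            "top_genes": top_genes, "top_cpgs": top_cpgs,
            "gene_madrs": gene_madrs, "significant_topics": sig}


def run_qtl(cfg: RunConfig) -> dict:
    wd = _wd(cfg)
    dosages, _counted = read_plink_raw(wd / cfg.genotypes)
    layout = read_layout(wd / cfg.layout_dir)
    phen = _load_phenotypes(wd, cfg)
    gt = genetics.GenotypeTable(dosages, layout.snps)
    gt, report = genetics.snp_qc(
        gt, hwe_p_threshold=cfg.hwe_p_threshold,
        missing_rate_threshold=cfg.missing_rate_threshold,
        maf_threshold=cfg.maf_threshold)
    covars = phen[["age", "sex"]]
    if cfg.genotype_n_pcs:
        covars = pd.concat(
            [covars, genetics.genotype_pcs(gt, cfg.genotype_n_pcs)], axis=1)

    scan = genetics.response_snp_scan(gt, phen["response"], covars,
                                      top_p=cfg.top_snp_p)
    top_snps = scan.index[scan["top"]].tolist()

    out: dict = {"qc_report": report, "scan": scan, "top_snps": top_snps}
    W = None
    if (wd / "W.tsv").exists():
        W = read_matrix(wd / "W.tsv").T
        for coding in ("additive", "major_presence"):
            out[f"snp_topic_{coding}"] = genetics.snp_topic_regression(
                gt, top_snps, W, covars, coding=coding)
            out[f"snp_topic_{coding}"].to_csv(
                wd / f"snp_topic_{coding}.tsv", sep="\t", index=False)

    # cis-QTL over the top features of the response-associated topics
    if (wd / "top_genes.tsv").exists():
        expr = read_matrix(wd / cfg.expression)
        betam = read_matrix(wd / cfg.methylation)
        top_genes = pd.read_csv(wd / "top_genes.tsv", sep="\t")
        top_cpgs = pd.read_csv(wd / "top_cpgs.tsv", sep="\t")
        genes = sorted(set(top_genes["feature"]))
        cpgs = sorted(set(top_cpgs["feature"]))
        gpos = layout.genes.rename(columns={"gene_id": "feature_id"})
        cpos = layout.cpgs.rename(columns={"cpg_id": "feature_id"})
        cpos = cpos.assign(start=cpos["pos"], end=cpos["pos"] + 1)
        eqtl = genetics.cis_qtl(np.log2(expr).T[genes], gt, gpos, covars,
                                window=cfg.qtl_window, fdr=cfg.qtl_fdr)
        mqtl = genetics.cis_qtl(betam.T[cpgs], gt, cpos, covars,
                                window=cfg.qtl_window, fdr=cfg.qtl_fdr)
        eqtl.to_csv(wd / "eqtl.tsv", sep="\t", index=False)
        mqtl.to_csv(wd / "mqtl.tsv", sep="\t", index=False)
        out["eqtl"], out["mqtl"] = eqtl, mqtl
    if W is not None and cfg.genomewide_topic_qtl:
        change = _madrs_tables(phen)
        tqtl = genetics.cis_qtl(W, gt, None, covars, window=None, fdr=cfg.qtl_fdr)
        madrs_feats = change.item_ratios.copy()
        madrs_feats["total"] = change.total_ratio
        mdqtl = genetics.cis_qtl(madrs_feats, gt, None, covars, window=None,
                                 fdr=cfg.qtl_fdr)
        tqtl.to_csv(wd / "topic_qtl.tsv", sep="\t", index=False)
        mdqtl.to_csv(wd / "madrs_qtl.tsv", sep="\t", index=False)
        out["topic_qtl"], out["madrs_qtl"] = tqtl, mdqtl

    scan.to_csv(wd / "response_snp_scan.tsv", sep="\t")
    with open(wd / "qc_report.json", "w") as fh:
        json.dump({k: v for k, v in report.items() if k != "removed"}, fh,
                  indent=2, sort_keys=True)
        fh.write("\n")
    return out


_STAGE_FUNCS = {"simulate": run_simulate, "preprocess": run_preprocess,
                "fit": run_fit, "associate": run_associate, "qtl": run_qtl}


def run_all(cfg: RunConfig) -> dict:
    results = {}
    for stage in cfg.stages:
        log.info("running stage %s", stage)
        results[stage] = _STAGE_FUNCS[stage](cfg)
    wd = _wd(cfg)
    inputs = {name: wd / getattr(cfg, attr) for name, attr in
              [("expression", "expression"), ("methylation", "methylation"),
               ("genotypes", "genotypes"), ("genesets", "genesets"),
               ("phenotypes", "phenotypes")]}
    write_manifest(wd / "manifest.json", inputs=inputs, config=cfg.to_dict(),
                   seed=cfg.seed)
    return results
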