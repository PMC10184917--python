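"""Topic-phenotype statistics downstream of the factorization.

Covers the MADRS change ratios and responder rule, Spearman topic-response
and Pearson topic-item / gene-item correlation scans with Benjamini-Hochberg
control, top-feature reporting with relative scores, CpG-to-gene substitution
by proximal correlation, and hierarchical patient clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .io import GenomeLayout

log = logging.getLogger("igem")

__all__ = ["MadrsChange", "madrs_change", "bh_adjust",
           "topic_response_association", "topic_madrs_association",
           "top_features", "map_cpg_to_correlated_gene",
           "gene_madrs_association", "cluster_patients"]


# ---------------------------------------------------------------------------
# MADRS change ratios


@dataclass
class MadrsChange:
    """Per-item and total change ratios (week0 - week8) / week0.

    Positive means improvement.  Items (or totals) with a zero baseline are
    NaN and flagged; the responder rule is total ratio >= 0.5.
    """

    item_ratios: pd.DataFrame  # subjects x items
    total_ratio: pd.Series
    responder: pd.Series  # boolean; NA where baseline total is 0
    flagged: list[str]


def madrs_change(week0: pd.DataFrame, week8: pd.DataFrame) -> MadrsChange:
    for df in (week0, week8):
        vals = df.to_numpy()
        if not np.isin(vals, range(7)).all():
            raise ValueError("MADRS items must be integers in 0..6")
    if list(week0.index) != list(week8.index) or list(week0.columns) != list(week8.columns):
        raise ValueError("week-0 and week-8 tables must align")
    w0 = week0.to_numpy(dtype=float)
    w8 = week8.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        items = np.where(w0 > 0, (w0 - w8) / w0, np.nan)
    t0 = w0.sum(axis=1)
    t8 = w8.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        total = np.where(t0 > 0, (t0 - t8) / t0, np.nan)
    flagged = [str(s) for s in week0.index[t0 == 0]]
    if flagged:
        log.warning("%d subjects have zero baseline MADRS total", len(flagged))
    responder = pd.Series(total >= 0.5, index=week0.index).where(t0 > 0)
    return MadrsChange(
        item_ratios=pd.DataFrame(items, index=week0.index, columns=week0.columns),
        total_ratio=pd.Series(total, index=week0.index, name="total_ratio"),
        responder=responder.rename("responder"),
        flagged=flagged)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def bh_adjust(p) -> np.ndarray:
    """BH step-up adjusted p-values; NaN entries are excluded and restored."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        if (p[ok] < 0).any() or (p[ok] > 1).any():
            raise ValueError("p-values must lie in [0, 1]")
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# topic associations


def topic_response_association(W: pd.DataFrame, labels,
                               fdr: float = 0.05) -> pd.DataFrame:
    """Spearman correlation of each topic's scores with the binary response;
    BH across the K topics."""
    y = np.asarray(labels, dtype=float)
    rows = []
    for topic in W.columns:
        x = W[topic].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append({"topic": topic, "rho": np.nan, "p": np.nan})
            continue
        rho, p = stats.spearmanr(x, y)
        rows.append({"topic": topic, "rho": rho, "p": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"])
    out["direction"] = np.sign(out["rho"])
    out["significant"] = out["p_adj"] < fdr
    return out.set_index("topic")


def _pearson_table(X: pd.DataFrame, Y: pd.DataFrame, xname: str, yname: str) -> pd.DataFrame:
    """All-pairs pairwise-complete Pearson correlations with p-values."""
    rows = []
    for xc in X.columns:
        for yc in Y.columns:
            x = X[xc].to_numpy(dtype=float)
            y = Y[yc].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                rows.append({xname: xc, yname: yc, "r": np.nan, "p": np.nan,
                             "n": int(ok.sum())})
                continue
            if ok.sum() < len(x):
                log.info("pair (%s, %s): %d incomplete subjects dropped",
                         xc, yc, int(len(x) - ok.sum()))
            r, p = stats.pearsonr(x[ok], y[ok])
            rows.append({xname: xc, yname: yc, "r": r, "p": p, "n": int(ok.sum())})
    return pd.DataFrame(rows)


def topic_madrs_association(W: pd.DataFrame, change: MadrsChange,
                            fdr: float = 0.05) -> pd.DataFrame:
    """Pearson correlation of topic scores with each MADRS item change ratio
    (and the total); BH over all tested pairs."""
    items = change.item_ratios.copy()
    items["total"] = change.total_ratio
    out = _pearson_table(W, items, "topic", "item")
    out["p_adj"] = bh_adjust(out["p"])
    out["significant"] = out["p_adj"] < fdr
    return out


def gene_madrs_association(top_genes: dict, expr: pd.DataFrame,
                           change: MadrsChange) -> pd.DataFrame:
    """Pearson correlation of each topic's top genes with MADRS item changes.

    ``top_genes`` maps topic -> gene list; ``expr`` is subjects-by-genes.
    BH over all tested (gene, item) pairs; reported at the 0.05 and 0.1 tiers.
    """
    frames = []
    for topic, genes in top_genes.items():
        genes = [g for g in genes if g in expr.columns]
        if not genes:
            continue
        tab = _pearson_table(expr[genes], change.item_ratios, "gene", "item")
        tab.insert(0, "topic", topic)
        frames.append(tab)
    if not frames:
        return pd.DataFrame(columns=["topic", "gene", "item", "r", "p", "n",
                                     "p_adj", "fdr_05", "fdr_10"])
    out = pd.concat(frames, ignore_index=True)
    out["p_adj"] = bh_adjust(out["p"])
    out["fdr_05"] = out["p_adj"] < 0.05
    out["fdr_10"] = out["p_adj"] < 0.10
    return out


# ---------------------------------------------------------------------------
# top features


def top_features(H: pd.DataFrame, n: int = 10) -> pd.DataFrame:
    """Per-topic top-``n`` features by factor score with relative scores.

    The relative score divides by the topic's maximum, so the top feature is
    1.  Ties are broken by feature id (logged).
    """
    rows = []
    for topic in H.index:
        s = H.loc[topic]
        if s.duplicated().any() and len(s) > 1:
            log.info("topic %s: tied factor scores broken by feature id", topic)
        order = sorted(s.index, key=lambda f: (-s[f], f))[:n]
        top = s[order[0]]
        for rank, feat in enumerate(order, 1):
            rel = float(s[feat] / top) if top > 0 else 0.0
            rows.append({"topic": topic, "rank": rank, "feature": feat,
                         "score": float(s[feat]), "rel_score": rel})
    return pd.DataFrame(rows)


def map_cpg_to_correlated_gene(cpg_id: str, beta: pd.DataFrame,
                               log_expr: pd.DataFrame, layout: GenomeLayout,
                               window: int = 500_000) -> str | None:
    """Most |Pearson|-correlated gene among genes within 500 kb of the CpG.

    ``beta`` and ``log_expr`` are subjects-by-features.  Returns None (with a
    log entry) when the CpG has no proximal gene.
    """
    cp = layout.cpgs.set_index("cpg_id").loc[cpg_id]
    genes = layout.genes[layout.genes["gene_id"].isin(log_expr.columns)]
    same = genes[genes["chrom"] == cp["chrom"]]
    gap = (np.maximum(same["start"] - cp["pos"], 0)
           + np.maximum(cp["pos"] - (same["end"] - 1), 0))
    prox = same.loc[gap <= window, "gene_id"].tolist()
    if not prox:
        log.info("CpG %s has no gene within %d bp", cpg_id, window)
        return None
    x = beta[cpg_id].to_numpy(dtype=float)
    best, best_r = None, -1.0
    for g in sorted(prox):
        y = log_expr[g].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            continue
        r = abs(float(stats.pearsonr(x, y)[0]))
        if r > best_r:
            best, best_r = g, r
    return best


# ---------------------------------------------------------------------------
# patient clustering


def cluster_patients(scores: pd.DataFrame, normalize: bool = True,
                     method: str = "average", metric: str = "euclidean"):
    """Agglomerative clustering of subjects on (optionally min-max scaled)
    topic scores.

    Returns (leaf order as subject ids, scipy linkage matrix, newick string).
    Constant columns map to 0 under normalization (logged).
    """
    X = scores.to_numpy(dtype=float)
    if normalize:
        lo = X.min(axis=0)
        rng = X.max(axis=0) - lo
        const = rng == 0
        if const.any():
            log.info("%d constant columns mapped to 0 under min-max", int(const.sum()))
        X = np.where(const, 0.0, (X - lo) / np.where(const, 1.0, rng))
    Z = hierarchy.linkage(pdist(X, metric=metric), method=method)
    leaves = hierarchy.leaves_list(Z)
    leaf_ids = [str(scores.index[i]) for i in leaves]
    newick = _linkage_to_newick(Z, [str(s) for s in scores.index])
    return leaf_ids, Z, newick


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(Z, labels)
    return str(tree).strip()
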