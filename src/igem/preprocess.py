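"""Feature selection and model-input construction.

Implements the differential filters (Welch t-test gate on expression at
p <= 0.05 restricted to geneset members; |delta beta| >= 0.025 within 500 kb
of a selected gene for methylation), recursive geneset merging with
row-normalization into the design matrix rho, the proximal-correlation
interaction graph B, and the covariate-corrected / mean-normalized /
omic-balanced inputs the factorization consumes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .io import GenomeLayout

log = logging.getLogger("igem")

__all__ = [
    "differential_expression", "differential_methylation", "merge_genesets",
    "GenesetDesign", "build_rho", "InteractionGraph", "build_interaction_graph",
    "normalize_inputs", "annotate_cpg_to_gene", "feature_gene_distances",
]


# ---------------------------------------------------------------------------
# differential filters


def _welch(x: np.ndarray, labels: np.ndarray):
    """Row-wise Welch t-test between label groups; returns (diff, p).

    diff is mean(group 1) - mean(group 0).  Features with zero variance in
    both groups get p = 1 with a warning (the test is undefined there).
    """
    g1 = x[:, labels == 1]
    g0 = x[:, labels == 0]
    if g1.shape[1] < 2 or g0.shape[1] < 2:
        raise ValueError("need at least 2 subjects per group")
    diff = g1.mean(axis=1) - g0.mean(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(g1, g0, axis=1, equal_var=False)
    degenerate = (g1.var(axis=1) == 0) & (g0.var(axis=1) == 0)
    if degenerate.any():
        log.warning("%d features have zero variance in both groups; p set to 1",
                    int(degenerate.sum()))
        p = np.where(degenerate, 1.0, p)
    return diff, np.nan_to_num(p, nan=1.0)


def differential_expression(log_expr: pd.DataFrame, labels,
                            genesets: list[tuple[str, list[str]]],
                            p_threshold: float = 0.05) -> pd.DataFrame:
    """Welch test per gene on log2 expression; a gene passes at p <= threshold
    only if it belongs to at least one geneset."""
    labels = np.asarray(labels)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if len(set(np.unique(labels))) < 2:
        raise ValueError("both groups must be present")
    diff, p = _welch(log_expr.to_numpy(dtype=float), labels)
    in_geneset = pd.Index(log_expr.index).isin(
        set().union(*[set(g) for _, g in genesets]) if genesets else set())
    return pd.DataFrame({
        "feature_id": log_expr.index,
        "diff": diff,
        "p_value": p,
        "in_geneset": in_geneset,
        "pass_flag": (p <= p_threshold) & in_geneset,
    }).set_index("feature_id")


def feature_gene_distances(positions: np.ndarray, chroms: np.ndarray,
                           genes: pd.DataFrame) -> np.ndarray:
    """Min gap (bp) from each point feature to any gene interval (0 inside).

    Intervals are 0-based half-open; returns +inf for features with no gene
    on their chromosome.
    """
    out = np.full(len(positions), np.inf)
    for chrom, gsub in genes.groupby("chrom"):
        mask = chroms == chrom
        if not mask.any():
            continue
        pos = positions[mask][:, None].astype(float)
        start = gsub["start"].to_numpy(dtype=float)[None, :]
        end = gsub["end"].to_numpy(dtype=float)[None, :]
        # gap to [start, end): 0 if start <= pos < end
        d = np.maximum(start - pos, 0) + np.maximum(pos - (end - 1), 0)
        out[mask] = d.min(axis=1)
    return out


def differential_methylation(beta: pd.DataFrame, labels, selected_genes,
                             layout: GenomeLayout,
                             delta_threshold: float = 0.025,
                             window: int = 500_000,
                             p_threshold: float | None = None) -> pd.DataFrame:
    """Mean beta-difference gate with a proximity requirement.

    A CpG passes when |mean(RES) - mean(NRES)| >= delta_threshold and it lies
    within ``window`` bp of at least one selected gene.  The Welch p-value is
    reported for downstream use; an extra p gate only applies if
    ``p_threshold`` is given.
    """
    arr = beta.to_numpy(dtype=float)
    if arr.min() < 0 or arr.max() > 1:
        raise ValueError("beta values must lie in [0, 1]")
    labels = np.asarray(labels)
    diff, p = _welch(arr, labels)
    genes = layout.genes[layout.genes["gene_id"].isin(set(selected_genes))]
    cp = layout.cpgs.set_index("cpg_id").loc[beta.index]
    dist = feature_gene_distances(cp["pos"].to_numpy(), cp["chrom"].to_numpy(), genes)
    passed = (np.abs(diff) >= delta_threshold) & (dist <= window)
    if p_threshold is not None:
        passed &= p <= p_threshold
    return pd.DataFrame({
        "feature_id": beta.index, "diff": diff, "p_value": p,
        "distance_bp": dist, "pass_flag": passed,
    }).set_index("feature_id")


# ---------------------------------------------------------------------------
# geneset merging and the rho design


def _qualifies(a: set, b: set, small_frac: float, large_frac: float,
               rule: str) -> bool:
    inter = len(a & b)
    small, large = sorted((len(a), len(b)))
    if small == 0:
        return False
    if rule == "swapped":
        # overlap covers >= 80% of the smaller set and >= 50% of the larger
        return inter / small >= small_frac and inter / large >= large_frac
    if rule == "literal":
        return inter / small >= 0.5 and inter / large >= 0.8
    raise ValueError(f"unknown merge rule {rule!r}")


def merge_genesets(genesets: list[tuple[str, list[str]]],
                   small_frac: float = 0.8, large_frac: float = 0.5,
                   rule: str = "swapped"):
    """Recursively merge overlapping genesets to a fixed point.

    Candidate pairs are scanned in lexicographic id order and the union keeps
    the lexicographically smaller id, so the result is deterministic and
    independent of input order.  Returns (merged sets, merge_log).
    """
    ids = [i for i, _ in genesets]
    if len(set(ids)) != len(ids):
        raise ValueError("geneset ids must be unique")
    current: dict[str, set] = {i: set(g) for i, g in genesets}
    merge_log: list[tuple[str, str]] = []
    changed = True
    while changed:
        changed = False
        names = sorted(current)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if _qualifies(current[a], current[b], small_frac, large_frac, rule):
                    current[a] = current[a] | current[b]
                    del current[b]
                    merge_log.append((b, a))  # absorbed, surviving
                    changed = True
                    break
            if changed:
                break
    merged = [(i, sorted(current[i])) for i in sorted(current)]
    return merged, merge_log


@dataclass
class GenesetDesign:
    """Fixed geneset-gene design: rho rows sum to 1 over selected genes."""

    rho: np.ndarray
    geneset_ids: list[str]
    gene_ids: list[str]
    merge_log: list[tuple[str, str]] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)


def build_rho(merged_genesets: list[tuple[str, list[str]]], selected_genes,
              merge_log: list[tuple[str, str]] | None = None) -> GenesetDesign:
    """Restrict genesets to the selected gene universe and row-normalize.

    Genesets left with zero selected genes are dropped (logged)."""
    gene_ids = sorted(set(selected_genes))
    col = {g: j for j, g in enumerate(gene_ids)}
    rows, kept, dropped = [], [], []
    for gs_id, genes in merged_genesets:
        hit = [col[g] for g in genes if g in col]
        if not hit:
            dropped.append(gs_id)
            continue
        row = np.zeros(len(gene_ids))
        row[hit] = 1.0 / len(hit)
        rows.append(row)
        kept.append(gs_id)
    if dropped:
        log.info("dropped %d genesets with no selected genes", len(dropped))
    rho = np.vstack(rows) if rows else np.zeros((0, len(gene_ids)))
    return GenesetDesign(rho=rho, geneset_ids=kept, gene_ids=gene_ids,
                         merge_log=list(merge_log or []), dropped=dropped)


# ---------------------------------------------------------------------------
# gene-CpG interaction graph


@dataclass
class InteractionGraph:
    """Sparse gene x CpG adjacency from correlated proximal pairs."""

    B: sp.csr_matrix
    gene_ids: list[str]
    cpg_ids: list[str]
    edges: pd.DataFrame  # gene_id, cpg_id, r, p, weight


def _pearson_p(r: np.ndarray, n: int) -> np.ndarray:
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def build_interaction_graph(log_expr: pd.DataFrame, beta: pd.DataFrame,
                            layout: GenomeLayout, window: int = 500_000,
                            top_pairs: int = 10, p_threshold: float = 0.05,
                            weighted: bool = False) -> InteractionGraph:
    """Correlate each gene with its proximal CpGs; keep the top pairs.

    For every gene, Pearson correlation against each CpG within ``window`` bp
    of the gene interval; at most the ``top_pairs`` smallest-p pairs with
    p < ``p_threshold`` become edges.  Edge weight is 1 unless ``weighted``
    (then |r|).  Constant features are skipped with a log entry.
    """
    if list(log_expr.columns) != list(beta.columns):
        raise ValueError("expression and methylation must share the subject axis")
    n = log_expr.shape[1]
    gene_ids = list(log_expr.index)
    cpg_ids = list(beta.index)
    cpg_pos = layout.cpgs.set_index("cpg_id").loc[cpg_ids]
    genes = layout.genes.set_index("gene_id").loc[gene_ids]

    E = log_expr.to_numpy(dtype=float)
    M = beta.to_numpy(dtype=float)
    Ec = E - E.mean(axis=1, keepdims=True)
    Mc = M - M.mean(axis=1, keepdims=True)
    Es = np.sqrt((Ec * Ec).sum(axis=1))
    Ms = np.sqrt((Mc * Mc).sum(axis=1))

    rows = []
    data, ri, ci = [], [], []
    for gi, gid in enumerate(gene_ids):
        grow = genes.loc[gid]
        if Es[gi] == 0:
            log.info("gene %s constant across subjects; skipped", gid)
            continue
        on_chrom = cpg_pos["chrom"].to_numpy() == grow["chrom"]
        pos = cpg_pos["pos"].to_numpy()
        gap = np.maximum(grow["start"] - pos, 0) + np.maximum(pos - (grow["end"] - 1), 0)
        prox = np.flatnonzero(on_chrom & (gap <= window))
        prox = prox[Ms[prox] > 0]
        if len(prox) < len(np.flatnonzero(on_chrom & (gap <= window))):
            log.info("constant CpGs near gene %s skipped", gid)
        if not len(prox):
            continue
        r = (Mc[prox] @ Ec[gi]) / (Ms[prox] * Es[gi])
        p = _pearson_p(r, n)
        ok = np.flatnonzero(p < p_threshold)
        if not len(ok):
            continue
        # smallest p first; ties broken by cpg id for determinism
        order = sorted(ok, key=lambda j: (p[j], cpg_ids[prox[j]]))[:top_pairs]
        for j in order:
            ci_idx = prox[j]
            w = abs(float(r[j])) if weighted else 1.0
            rows.append({"gene_id": gid, "cpg_id": cpg_ids[ci_idx],
                         "r": float(r[j]), "p": float(p[j]), "weight": w})
            data.append(w)
            ri.append(gi)
            ci.append(ci_idx)
    B = sp.csr_matrix((data, (ri, ci)), shape=(len(gene_ids), len(cpg_ids)))
    edges = pd.DataFrame(rows, columns=["gene_id", "cpg_id", "r", "p", "weight"])
    return InteractionGraph(B=B, gene_ids=gene_ids, cpg_ids=cpg_ids, edges=edges)


# ---------------------------------------------------------------------------
# model-input normalization


def _residualize(x: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Per-feature OLS on the covariate design; keep residual + feature mean."""
    coef, *_ = np.linalg.lstsq(design, x.T, rcond=None)
    resid = x.T - design @ coef
    return resid.T + x.mean(axis=1, keepdims=True)


def normalize_inputs(expr: pd.DataFrame, beta: pd.DataFrame,
                     covariates: pd.DataFrame | None = None,
                     residualize: bool = True):
    """Build the model-ready subject-by-feature views X1 and X2.

    Steps: (i) optional age+sex residualization per feature (mean restored);
    (ii) clip at 0 (the model takes only nonnegative input); (iii) divide
    each feature by its mean; (iv) balance the omics by scaling X1 by
    n2/(n1+n2) and X2 by n1/(n1+n2).  Zero-mean features are dropped.
    Returns (X1, X2) as subjects-by-features frames.
    """
    if list(expr.columns) != list(beta.columns):
        raise ValueError("views must share the subject axis")
    out = []
    for df in (expr, beta):
        x = df.to_numpy(dtype=float)
        if residualize and covariates is not None:
            design = np.column_stack([
                np.ones(len(covariates)),
                covariates["age"].to_numpy(dtype=float),
                covariates["sex"].to_numpy(dtype=float)])
            x = _residualize(x, design)
        x = np.clip(x, 0.0, None)
        mean = x.mean(axis=1)
        keep = mean > 0
        if not keep.all():
            log.info("dropping %d zero-mean features", int((~keep).sum()))
        x = x[keep] / mean[keep][:, None]
        out.append(pd.DataFrame(x, index=df.index[keep], columns=df.columns))
    e, b = out
    n1, n2 = len(e), len(b)
    total = n1 + n2
    X1 = (e * (n2 / total)).T
    X2 = (b * (n1 / total)).T
    return X1, X2


# ---------------------------------------------------------------------------
# CpG -> gene annotation


def annotate_cpg_to_gene(layout: GenomeLayout, upstream: int = 1500) -> dict[str, list[str]]:
    """Map each CpG to genes whose body or 1500 bp-upstream promoter covers it.

    Strand-aware: upstream extends the interval before the TSS (before
    ``start`` on +, after ``end`` on -).  Genes of unknown strand fall back
    to the body-only rule (logged).
    """
    mapping: dict[str, list[str]] = {c: [] for c in layout.cpgs["cpg_id"]}
    unknown = 0
    for _, g in layout.genes.iterrows():
        lo, hi = int(g["start"]), int(g["end"])
        if g["strand"] == "+":
            lo -= upstream
        elif g["strand"] == "-":
            hi += upstream
        else:
            unknown += 1
        sub = layout.cpgs[(layout.cpgs["chrom"] == g["chrom"])
                          & (layout.cpgs["pos"] >= lo) & (layout.cpgs["pos"] < hi)]
        for c in sub["cpg_id"]:
            mapping[c].append(g["gene_id"])
    if unknown:
        log.warning("%d genes with unknown strand: body-only annotation", unknown)
    return mapping
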