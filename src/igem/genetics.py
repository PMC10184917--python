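"""Genotype QC and SNP-level association analyses.

Dosages count the minor allele (0/1/2, NaN missing).  QC removes SNPs by
missing call rate (> 0.01), minor allele frequency (< 0.05) and the exact
Hardy-Weinberg test (p < 1e-3).  Downstream scans are ordinary least squares
of the outcome on dosage plus age and sex, with Wald p-values on the dosage
coefficient; cis-QTL mapping restricts candidate SNPs to a 500 kb window
around the feature and controls FDR per feature with Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association import bh_adjust
from .io import GenomeLayout

log = logging.getLogger("igem")

__all__ = ["GenotypeTable", "hwe_exact_test", "snp_qc", "response_snp_scan",
           "snp_topic_regression", "cis_qtl", "genotype_pcs"]


@dataclass
class GenotypeTable:
    """Subjects-by-SNPs minor-allele dosage matrix with coordinates.

    ``dosages`` entries are in {0, 1, 2, NaN}; ``snps`` carries (snp_id,
    chrom, pos, ref, alt).  ``orient_minor`` flips SNPs whose counted allele
    is the major one so that MAF <= 0.5 everywhere.
    """

    dosages: pd.DataFrame
    snps: pd.DataFrame
    flipped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        vals = self.dosages.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be in {0, 1, 2, NA}")

    def allele_freq(self) -> pd.Series:
        """Frequency of the counted allele from non-missing dosages."""
        return self.dosages.mean(axis=0, skipna=True) / 2.0

    def maf(self) -> pd.Series:
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    def missing_rate(self) -> pd.Series:
        return self.dosages.isna().mean(axis=0)

    def genotype_counts(self) -> pd.DataFrame:
        d = self.dosages
        return pd.DataFrame({
            "n_ref_hom": (d == 0).sum(axis=0),
            "n_het": (d == 1).sum(axis=0),
            "n_alt_hom": (d == 2).sum(axis=0),
        })

    def orient_minor(self) -> "GenotypeTable":
        f = self.allele_freq()
        flip = f.index[f > 0.5].tolist()
        if not flip:
            return self
        d = self.dosages.copy()
        d[flip] = 2.0 - d[flip]
        snps = self.snps.copy().set_index("snp_id")
        ref = snps.loc[flip, "ref"].copy()
        snps.loc[flip, "ref"] = snps.loc[flip, "alt"]
        snps.loc[flip, "alt"] = ref
        log.info("oriented %d SNPs to count the minor allele", len(flip))
        return GenotypeTable(d, snps.reset_index(), flipped=list(flip))


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg test, conditional on the allele counts.

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the probabilities no larger than the observed configuration's
    (computed by the stable ratio recurrence).  Symmetric in the two
    homozygote classes; monomorphic SNPs give p = 1.
    """
    for v in (n_hom1, n_het, n_hom2):
        if v < 0 or int(v) != v:
            raise ValueError("genotype counts must be nonnegative integers")
    n_hom1, n_het, n_hom2 = int(n_hom1), int(n_het), int(n_hom2)
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("at least one genotype required")
    rare = 2 * min(n_hom1, n_hom2) + n_het  # rare-allele count
    if rare == 0:
        return 1.0
    # unnormalized probabilities over het = rare, rare-2, ..., (rare mod 2)
    hets = list(range(rare % 2, rare + 1, 2))
    probs = np.zeros(len(hets))
    # start from the largest possible het count
    idx = {h: i for i, h in enumerate(hets)}
    probs[idx[rare]] = 1.0
    cur = 1.0
    for h in range(rare, 1, -2):
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        # P(h-2) / P(h) = h*(h-1) / (4*(hom_r+1)*(hom_c+1))
        cur *= h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        probs[idx[h - 2]] = cur
    probs /= probs.sum()
    p_obs = probs[idx[n_het]]
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# QC


def snp_qc(gt: GenotypeTable, hwe_p_threshold: float = 1e-3,
           missing_rate_threshold: float = 0.01,
           maf_threshold: float = 0.05):
    """Filter SNPs by missing rate, MAF and exact HWE, in that order.

    Attribution is first-failing: a SNP removed for missingness is not also
    counted under MAF or HWE.  Returns (filtered GenotypeTable, report dict).
    """
    gt = gt.orient_minor()
    miss = gt.missing_rate()
    maf = gt.maf()
    counts = gt.genotype_counts()
    removed = {"missing_rate": [], "maf": [], "hwe": []}
    keep = []
    for snp in gt.dosages.columns:
        if miss[snp] > missing_rate_threshold:
            removed["missing_rate"].append(snp)
        elif maf[snp] < maf_threshold:
            removed["maf"].append(snp)
        elif hwe_exact_test(counts.at[snp, "n_ref_hom"], counts.at[snp, "n_het"],
                            counts.at[snp, "n_alt_hom"]) < hwe_p_threshold:
            removed["hwe"].append(snp)
        else:
            keep.append(snp)
    report = {
        "n_input": gt.dosages.shape[1],
        "n_retained": len(keep),
        "n_removed_missing": len(removed["missing_rate"]),
        "n_removed_maf": len(removed["maf"]),
        "n_removed_hwe": len(removed["hwe"]),
        "removed": removed,
    }
    filtered = GenotypeTable(gt.dosages[keep],
                             gt.snps[gt.snps["snp_id"].isin(keep)].reset_index(drop=True),
                             flipped=gt.flipped)
    return filtered, report


# ---------------------------------------------------------------------------
# OLS scans


def _ols_dosage_scan(y: np.ndarray, G: np.ndarray, covariates: np.ndarray | None):
    """Per-column OLS of y on dosage + covariates; Wald stats on dosage.

    Uses Frisch-Waugh residualization for fully-observed columns and a
    per-SNP complete-case fallback where dosages are missing.  Returns
    (beta, t, p, n_used) arrays, NaN for degenerate columns.
    """
    n, m = G.shape
    Z = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), covariates])
    k = Z.shape[1] + 1  # + dosage
    beta = np.full(m, np.nan)
    tstat = np.full(m, np.nan)
    pval = np.full(m, np.nan)
    nuse = np.zeros(m, dtype=int)

    def _single(yv, gv, Zv):
        X = np.column_stack([Zv, gv])
        XtX = X.T @ X
        try:
            XtX_inv = np.linalg.inv(XtX)
        except np.linalg.LinAlgError:
            return np.nan, np.nan, np.nan
        b = XtX_inv @ (X.T @ yv)
        resid = yv - X @ b
        df = len(yv) - X.shape[1]
        if df <= 0:
            return np.nan, np.nan, np.nan
        s2 = float(resid @ resid) / df
        se = np.sqrt(s2 * XtX_inv[-1, -1])
        if se == 0:
            return float(b[-1]), np.nan, np.nan
        t = float(b[-1]) / se
        return float(b[-1]), t, 2.0 * stats.t.sf(abs(t), df)

    has_nan = np.isnan(G).any(axis=0)
    full = np.flatnonzero(~has_nan)
    if len(full):
        Q, _ = np.linalg.qr(Z)
        yr = y - Q @ (Q.T @ y)
        Gf = G[:, full]
        Gr = Gf - Q @ (Q.T @ Gf)
        gg = (Gr * Gr).sum(axis=0)
        nondeg = gg > 1e-12
        gy = Gr.T @ yr
        df = n - k
        with np.errstate(divide="ignore", invalid="ignore"):
            b = np.where(nondeg, gy / gg, np.nan)
            rss = (yr @ yr) - np.where(nondeg, gy * gy / gg, 0.0)
            s2 = rss / df
            se = np.sqrt(s2 / gg)
            t = np.where(nondeg & (se > 0), b / se, np.nan)
        beta[full] = np.where(nondeg, b, np.nan)
        tstat[full] = t
        pval[full] = np.where(np.isfinite(t), 2.0 * stats.t.sf(np.abs(t), df), np.nan)
        nuse[full] = n
    for j in np.flatnonzero(has_nan):
        ok = ~np.isnan(G[:, j])
        nuse[j] = int(ok.sum())
        if nuse[j] < k + 1 or np.nanstd(G[ok, j]) == 0:
            continue
        beta[j], tstat[j], pval[j] = _single(y[ok], G[ok, j], Z[ok])
    return beta, tstat, pval, nuse


def _covariate_matrix(covariates: pd.DataFrame | None) -> np.ndarray | None:
    """Every column of the frame enters the design (age, sex, PCs, ...)."""
    if covariates is None:
        return None
    return covariates.to_numpy(dtype=float)


def genotype_pcs(gt: GenotypeTable, n_pcs: int = 10) -> pd.DataFrame:
    """Principal components of the mean-imputed, standardized dosage matrix.

    Off by default in the scans (the analyses here do not correct for
    population structure); concatenate the returned frame onto the
    covariates to enable PC correction.
    """
    X = gt.dosages.to_numpy(dtype=float)
    mu = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), mu, X) - mu
    sd = X.std(axis=0)
    X = X[:, sd > 0] / sd[sd > 0]
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    k = min(n_pcs, len(s))
    return pd.DataFrame(U[:, :k] * s[:k], index=gt.dosages.index,
                        columns=[f"PC{i + 1}" for i in range(k)])


def response_snp_scan(gt: GenotypeTable, labels,
                      covariates: pd.DataFrame | None = None,
                      top_p: float = 1e-4) -> pd.DataFrame:
    """OLS of response on dosage + age + sex, per SNP; flag p < ``top_p``.

    No global multiple-testing correction is applied to this scan.
    """
    y = np.asarray(labels, dtype=float)
    G = gt.dosages.to_numpy(dtype=float)
    beta, t, p, nuse = _ols_dosage_scan(y, G, _covariate_matrix(covariates))
    res = pd.DataFrame({
        "snp_id": gt.dosages.columns, "beta": beta, "t": t, "p": p, "n": nuse,
    }).merge(gt.snps[["snp_id", "chrom", "pos"]], on="snp_id", how="left")
    res["top"] = res["p"] < top_p
    return res.set_index("snp_id")


def code_genotypes(dosages: pd.DataFrame, coding: str) -> pd.DataFrame:
    """``additive`` keeps the 0/1/2 dosage; ``major_presence`` codes minor
    homozygotes 1 against carriers of the major allele 0."""
    if coding == "additive":
        return dosages
    if coding == "major_presence":
        return (dosages == 2).astype(float).where(~dosages.isna())
    raise ValueError(f"unknown coding {coding!r}")


def snp_topic_regression(gt: GenotypeTable, snp_ids, W: pd.DataFrame,
                         covariates: pd.DataFrame | None = None,
                         coding: str = "additive") -> pd.DataFrame:
    """Per (SNP, topic) OLS of topic score on coded genotype + age + sex."""
    snp_ids = [s for s in snp_ids if s in gt.dosages.columns]
    coded = code_genotypes(gt.dosages[snp_ids], coding)
    G = coded.to_numpy(dtype=float)
    cov = _covariate_matrix(covariates)
    rows = []
    for topic in W.columns:
        y = W[topic].to_numpy(dtype=float)
        beta, t, p, nuse = _ols_dosage_scan(y, G, cov)
        for j, snp in enumerate(snp_ids):
            rows.append({"snp_id": snp, "topic": topic, "coding": coding,
                         "coef": beta[j], "t": t[j], "p": p[j], "n": nuse[j]})
    out = pd.DataFrame(rows, columns=["snp_id", "topic", "coding", "coef",
                                      "t", "p", "n"])
    degenerate = out["coef"].isna().sum()
    if degenerate:
        log.info("%d SNP-topic pairs degenerate under coding %s", degenerate, coding)
    return out


# ---------------------------------------------------------------------------
# cis-QTL


def cis_qtl(features: pd.DataFrame, gt: GenotypeTable,
            feature_positions: pd.DataFrame | None,
            covariates: pd.DataFrame | None = None,
            window: int | None = 500_000, fdr: float = 0.1) -> pd.DataFrame:
    """cis window scan of each feature against nearby SNPs, BH per feature.

    ``features`` is subjects-by-features (expression, beta values, topic
    scores or MADRS change ratios).  ``feature_positions`` gives (feature_id,
    chrom, start, end); pass None (or window=None) for positionless features
    such as topics, which are then tested genome-wide.
    """
    snp_pos = gt.snps.set_index("snp_id")
    cov = _covariate_matrix(covariates)
    pos_idx = None
    if feature_positions is not None:
        pos_idx = feature_positions.set_index("feature_id")
    out = []
    for feat in features.columns:
        if pos_idx is not None and window is not None:
            if feat not in pos_idx.index:
                log.info("feature %s has no position; skipped", feat)
                continue
            row = pos_idx.loc[feat]
            same = snp_pos["chrom"] == row["chrom"]
            gap = (np.maximum(row["start"] - snp_pos["pos"], 0)
                   + np.maximum(snp_pos["pos"] - (row["end"] - 1), 0))
            cis = snp_pos.index[same & (gap <= window)].tolist()
            dist = gap[cis].to_numpy()
        else:
            cis = list(gt.dosages.columns)
            dist = np.full(len(cis), np.nan)
        if not cis:
            log.info("feature %s has no cis SNPs", feat)
            continue
        y = features[feat].to_numpy(dtype=float)
        G = gt.dosages[cis].to_numpy(dtype=float)
        beta, t, p, nuse = _ols_dosage_scan(y, G, cov)
        p_adj = bh_adjust(p)
        for j, snp in enumerate(cis):
            out.append({"feature_id": feat, "snp_id": snp,
                        "distance_bp": dist[j], "beta": beta[j], "t": t[j],
                        "p": p[j], "p_adj": p_adj[j], "n": nuse[j],
                        "significant": bool(p_adj[j] < fdr) if np.isfinite(p_adj[j]) else False})
    cols = ["feature_id", "snp_id", "distance_bp", "beta", "t", "p", "p_adj",
            "n", "significant"]
    return pd.DataFrame(out, columns=cols)
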