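"""Differential filters, geneset merging, rho, B and input normalization."""

import numpy as np
import pandas as pd
import pytest

from igem.io import GenomeLayout
from igem.preprocess import (annotate_cpg_to_gene, build_interaction_graph,
                             build_rho, differential_expression,
                             differential_methylation, merge_genesets,
                             normalize_inputs)


def _layout(genes=None, cpgs=None):
    genes = genes if genes is not None else []
    cpgs = cpgs if cpgs is not None else []
    return GenomeLayout(
        chromosomes={"chr1": 10_000_000, "chr2": 10_000_000},
        genes=pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end", "strand"]),
        cpgs=pd.DataFrame(cpgs, columns=["cpg_id", "chrom", "pos"]),
        snps=pd.DataFrame(columns=["snp_id", "chrom", "pos", "ref", "alt"]))


# ---------------------------------------------------------------------------
# differential expression


def test_equal_group_means_fail_the_gate():
    rng = np.random.default_rng(0)
    x = pd.DataFrame(rng.normal(5, 1, (20, 200)),
                     index=[f"G{i}" for i in range(20)])
    labels = np.repeat([0, 1], 100)
    res = differential_expression(x, labels, [("S1", list(x.index))])
    assert (res["p_value"] > 0.2).mean() > 0.7
    assert res["pass_flag"].mean() < 0.2


def test_two_sd_shift_detected_with_high_power():
    rng = np.random.default_rng(1)
    n_genes = 300
    x = rng.normal(0, 1, (n_genes, 100))
    labels = np.repeat([0, 1], 50)
    x[:, labels == 1] += 2.0  # 2 SD planted shift in every gene
    df = pd.DataFrame(x, index=[f"G{i}" for i in range(n_genes)])
    res = differential_expression(df, labels, [("S1", list(df.index))])
    assert res["pass_flag"].mean() > 0.95


def test_gene_outside_genesets_never_passes():
    rng = np.random.default_rng(2)
    x = pd.DataFrame(rng.normal(0, 1, (2, 60)), index=["Gin", "Gout"])
    labels = np.repeat([0, 1], 30)
    x.loc["Gout", labels == 1] += 5  # hugely significant but not in any set
    x.loc["Gin", labels == 1] += 5
    res = differential_expression(x, labels, [("S1", ["Gin"])])
    assert res.loc["Gout", "p_value"] < 0.001
    assert not res.loc["Gout", "pass_flag"]
    assert res.loc["Gin", "pass_flag"]


def test_degenerate_zero_variance_rows_get_p_one():
    x = pd.DataFrame([[1.0] * 10, [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]],
                     index=["flat", "ok"])
    labels = np.repeat([0, 1], 5)
    res = differential_expression(x, labels, [("S1", ["flat", "ok"])])
    assert res.loc["flat", "p_value"] == 1.0


def test_single_group_rejected():
    x = pd.DataFrame(np.ones((3, 6)))
    with pytest.raises(ValueError):
        differential_expression(x, np.zeros(6, dtype=int), [])


# ---------------------------------------------------------------------------
# differential methylation


def _dm_layout():
    return _layout(
        genes=[("GA", "chr1", 1_000_000, 1_010_000, "+")],
        cpgs=[("cgNear", "chr1", 1_200_000), ("cgFar", "chr1", 1_650_000)])


def _beta_frame(delta_near, delta_far, n=100, seed=3):
    rng = np.random.default_rng(seed)
    labels = np.repeat([0, 1], n // 2)
    base = np.full((2, n), 0.5) + rng.normal(0, 0.001, (2, n))
    base[0, labels == 1] += delta_near
    base[1, labels == 1] += delta_far
    return pd.DataFrame(base, index=["cgNear", "cgFar"]), labels


def test_delta_beta_below_threshold_fails():
    beta, labels = _beta_frame(0.020, 0.020)
    res = differential_methylation(beta, labels, ["GA"], _dm_layout())
    assert not res["pass_flag"].any()


def test_large_delta_but_distal_cpg_fails_window():
    beta, labels = _beta_frame(0.10, 0.10)
    res = differential_methylation(beta, labels, ["GA"], _dm_layout(),
                                   window=400_000)
    assert res.loc["cgNear", "pass_flag"]          # 190 kb away
    assert not res.loc["cgFar", "pass_flag"]       # 640 kb away


def test_beta_outside_unit_interval_rejected():
    beta = pd.DataFrame([[1.2, 0.5, 0.1, 0.4]], index=["cgNear"])
    with pytest.raises(ValueError):
        differential_methylation(beta, np.array([0, 0, 1, 1]), ["GA"], _dm_layout())


def test_planted_generator_cpgs_mostly_pass(small_cohort):
    coh = small_cohort
    res = differential_methylation(
        coh.methylation, coh.truth.labels,
        sorted(coh.truth.differential_gene_ids), coh.layout)
    planted = sorted(coh.truth.differential_cpg_ids)
    assert res.loc[planted, "pass_flag"].mean() >= 0.9


def test_filter_order_independence(small_cohort):
    coh = small_cohort
    genes = sorted(coh.truth.differential_gene_ids)
    res = differential_methylation(coh.methylation, coh.truth.labels, genes,
                                   coh.layout)
    perm = coh.methylation.sample(frac=1, random_state=0)
    res_p = differential_methylation(perm, coh.truth.labels, genes, coh.layout)
    assert set(res.index[res["pass_flag"]]) == set(res_p.index[res_p["pass_flag"]])


# ---------------------------------------------------------------------------
# geneset merging


def _brute_force_closure(sets, qualifies):
    """Fixed-point oracle: merge any qualifying pair until none remains."""
    sets = {k: set(v) for k, v in sets}
    while True:
        names = sorted(sets)
        hit = None
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if qualifies(sets[a], sets[b]):
                    hit = (a, b)
                    break
            if hit:
                break
        if not hit:
            return {k: frozenset(v) for k, v in sets.items()}
        a, b = hit
        sets[a] |= sets.pop(b)


def _default_rule(a, b):
    inter = len(a & b)
    small, large = sorted((len(a), len(b)))
    return small > 0 and inter / small >= 0.8 and inter / large >= 0.5


def test_disjoint_sets_unchanged():
    merged, log = merge_genesets([("A", ["g1", "g2"]), ("B", ["g3", "g4"])])
    assert len(merged) == 2 and not log


def test_identical_sets_merge_once():
    merged, log = merge_genesets([("A", ["g1", "g2"]), ("B", ["g1", "g2"])])
    assert len(merged) == 1
    assert merged[0] == ("A", ["g1", "g2"])
    assert log == [("B", "A")]


def test_chain_collapses_to_single_set_matching_oracle():
    # A subset of B subset of C, built so every pair qualifies
    sets = [("A", [f"g{i}" for i in range(8)]),
            ("B", [f"g{i}" for i in range(10)]),
            ("C", [f"g{i}" for i in range(12)])]
    merged, _ = merge_genesets(sets)
    oracle = _brute_force_closure(sets, _default_rule)
    assert {frozenset(g) for _, g in merged} == set(oracle.values())
    assert len(merged) == 1


def test_random_collections_match_brute_force_oracle():
    rng = np.random.default_rng(4)
    for trial in range(10):
        sets = [(f"S{j}", sorted(rng.choice(30, size=rng.integers(3, 12),
                                            replace=False).astype(str)))
                for j in range(8)]
        merged, _ = merge_genesets(sets)
        oracle = _brute_force_closure(sets, _default_rule)
        assert {frozenset(g) for _, g in merged} == set(oracle.values())


def test_merge_idempotent():
    rng = np.random.default_rng(5)
    sets = [(f"S{j}", sorted(rng.choice(20, size=rng.integers(3, 10),
                                        replace=False).astype(str)))
            for j in range(6)]
    merged, _ = merge_genesets(sets)
    again, log = merge_genesets(merged)
    assert again == merged and not log


# ---------------------------------------------------------------------------
# rho


def test_rho_uniform_normalization():
    design = build_rho([("S1", ["g1", "g2", "g3", "g4"])], ["g1", "g2", "g3", "g4"])
    np.testing.assert_allclose(design.rho, 0.25)


def test_rho_restricted_to_selected_universe():
    design = build_rho([("S1", [f"g{i}" for i in range(10)])], ["g0", "g5"])
    np.testing.assert_allclose(design.rho, 0.5)
    assert design.gene_ids == ["g0", "g5"]


def test_rho_rows_sum_to_one_and_empty_rows_dropped():
    rng = np.random.default_rng(6)
    genes = [f"g{i}" for i in range(40)]
    sets = [(f"S{j}", sorted(rng.choice(genes, size=rng.integers(2, 15),
                                        replace=False))) for j in range(12)]
    sets.append(("Sempty", ["zz1", "zz2"]))  # no selected genes
    design = build_rho(sets, genes)
    assert design.dropped == ["Sempty"]
    np.testing.assert_allclose(design.rho.sum(axis=1), 1.0, atol=1e-9)
    assert ((design.rho >= 0) & (design.rho <= 1)).all()


# ---------------------------------------------------------------------------
# interaction graph


def test_gene_without_proximal_cpgs_has_no_edges():
    layout = _layout(genes=[("GA", "chr1", 1000, 2000, "+")],
                     cpgs=[("cg1", "chr2", 1500)])
    rng = np.random.default_rng(7)
    expr = pd.DataFrame(rng.normal(size=(1, 30)), index=["GA"])
    beta = pd.DataFrame(rng.uniform(size=(1, 30)), index=["cg1"])
    g = build_interaction_graph(expr, beta, layout)
    assert g.edges.empty and g.B.nnz == 0


def test_top_pairs_capped_at_ten():
    layout = _layout(
        genes=[("GA", "chr1", 1000, 2000, "+")],
        cpgs=[(f"cg{i}", "chr1", 3000 + i) for i in range(15)])
    rng = np.random.default_rng(8)
    base = rng.normal(size=30)
    expr = pd.DataFrame(base[None, :], index=["GA"])
    beta = pd.DataFrame(np.tile(base, (15, 1)) * 0.1 + 0.5,
                        index=[f"cg{i}" for i in range(15)])
    g = build_interaction_graph(expr, beta, layout)
    assert len(g.edges) == 10


def test_edges_match_exhaustive_all_pairs_oracle(small_cohort):
    from scipy import stats

    coh = small_cohort
    expr = np.log2(coh.expression.iloc[:20])
    beta = coh.methylation.iloc[:30]
    g = build_interaction_graph(expr, beta, coh.layout, window=500_000)

    genes = coh.layout.genes.set_index("gene_id")
    cpgs = coh.layout.cpgs.set_index("cpg_id")
    expected = set()
    for gid in expr.index:
        grow = genes.loc[gid]
        cands = []
        for cid in beta.index:
            crow = cpgs.loc[cid]
            if crow["chrom"] != grow["chrom"]:
                continue
            d = max(grow["start"] - crow["pos"], 0) + max(crow["pos"] - (grow["end"] - 1), 0)
            if d > 500_000:
                continue
            r, p = stats.pearsonr(expr.loc[gid], beta.loc[cid])
            if p < 0.05:
                cands.append((p, cid))
        for p, cid in sorted(cands)[:10]:
            expected.add((gid, cid))
    assert set(zip(g.edges["gene_id"], g.edges["cpg_id"])) == expected


def test_graph_invariant_to_cpg_order(small_cohort):
    coh = small_cohort
    expr = np.log2(coh.expression.iloc[:10])
    beta = coh.methylation.iloc[:30]
    g1 = build_interaction_graph(expr, beta, coh.layout)
    g2 = build_interaction_graph(expr, beta.iloc[::-1], coh.layout)
    assert (set(zip(g1.edges["gene_id"], g1.edges["cpg_id"]))
            == set(zip(g2.edges["gene_id"], g2.edges["cpg_id"])))


# ---------------------------------------------------------------------------
# normalization


def test_balance_factors_match_published_feature_counts():
    n1, n2 = 1572, 13900
    assert n2 / (n1 + n2) == pytest.approx(13900 / 15472)
    rng = np.random.default_rng(9)
    expr = pd.DataFrame(rng.uniform(1, 2, (n1 // 100, 10)))
    beta = pd.DataFrame(rng.uniform(0, 1, (n2 // 100, 10)))
    X1, X2 = normalize_inputs(expr, beta, None, residualize=False)
    f1 = X1.shape[1] and X2.shape[1]
    s1 = X2.shape[1] / (X1.shape[1] + X2.shape[1])
    np.testing.assert_allclose(X1.mean(axis=0), s1, atol=1e-12)


def test_scale_factors_sum_to_one_and_output_nonnegative():
    rng = np.random.default_rng(10)
    expr = pd.DataFrame(rng.uniform(1, 2, (6, 20)))
    beta = pd.DataFrame(rng.uniform(0.2, 0.8, (14, 20)))
    X1, X2 = normalize_inputs(expr, beta, None, residualize=False)
    s1 = X1.to_numpy().mean(axis=0).mean() * X1.shape[1] / X1.shape[1]
    assert (X1.to_numpy() >= 0).all() and (X2.to_numpy() >= 0).all()
    # per-feature means are exactly the two balance factors, summing to 1
    np.testing.assert_allclose(
        X1.mean(axis=0).iloc[0] + X2.mean(axis=0).iloc[0], 1.0, atol=1e-12)


def test_residualization_removes_covariate_trend():
    rng = np.random.default_rng(11)
    n = 200
    age = rng.uniform(20, 70, n)
    sex = rng.integers(0, 2, n).astype(float)
    x = 5.0 + 0.1 * age + 0.8 * sex + rng.normal(0, 0.01, n)
    expr = pd.DataFrame(x[None, :])
    beta = pd.DataFrame(rng.uniform(0.3, 0.7, (1, n)))
    cov = pd.DataFrame({"age": age, "sex": sex})
    X1, _ = normalize_inputs(expr, beta, cov, residualize=True)
    resid = X1.to_numpy().ravel()
    assert abs(np.corrcoef(resid, age)[0, 1]) < 0.05


# ---------------------------------------------------------------------------
# CpG annotation


def test_promoter_and_body_annotation_rules():
    layout = _layout(
        genes=[("Gplus", "chr1", 10_000, 20_000, "+"),
               ("Gminus", "chr2", 10_000, 20_000, "-")],
        cpgs=[("cg_up1000", "chr1", 9_000),     # 1000 bp upstream of + TSS
              ("cg_up1600", "chr1", 8_400),     # 1600 bp upstream: too far
              ("cg_body_minus", "chr2", 15_000),
              ("cg_minus_up", "chr2", 21_000)])  # 1000 bp upstream of - TSS
    m = annotate_cpg_to_gene(layout, upstream=1500)
    assert m["cg_up1000"] == ["Gplus"]
    assert m["cg_up1600"] == []
    assert m["cg_body_minus"] == ["Gminus"]
    assert m["cg_minus_up"] == ["Gminus"]
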