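"""Run configuration: every threshold and hyperparameter in one place.

Defaults are the pipeline's published operating point: expression gate
p <= 0.05, methylation gate |delta beta| >= 0.025, 500 kb proximity windows,
top-10 gene-CpG interaction pairs at p < 0.05, genotype QC at HWE p >= 1e-3 /
missing rate <= 0.01 / MAF >= 0.05, top response SNPs at p < 1e-4, QTL FDR
0.1, association FDR 0.05 and 10 latent topics.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

log = logging.getLogger("igem")

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    # paths
    workdir: str = "igem_run"
    expression: str = "expression.tsv"
    methylation: str = "methylation.tsv"
    genotypes: str = "genotypes.raw"
    genesets: str = "genesets.gmt"
    phenotypes: str = "phenotypes.tsv"
    layout_dir: str = "layout"

    # differential filters
    de_p_threshold: float = 0.05
    dm_delta_beta: float = 0.025
    dm_p_threshold: float | None = None  # optional extra p gate, off by default
    proximity_window: int = 500_000
    tss_upstream: int = 1500

    # geneset merging
    merge_small_frac: float = 0.8
    merge_large_frac: float = 0.5
    merge_rule: str = "swapped"  # or "literal"

    # interaction graph
    interaction_top_pairs: int = 10
    interaction_p_threshold: float = 0.05
    interaction_weighted: bool = False

    # normalization
    residualize_covariates: bool = True

    # factorization
    n_topics: int = 10
    lambda_net: float = 1.0
    lambda_w: float = 1.0
    lambda_alpha: float = 1.0
    lambda_h: float = 1.0
    max_iter: int = 2000
    rel_tol: float = 1e-6
    n_restarts: int = 5
    epsilon_guard: float = 1e-12
    init: str = "uniform"

    # genotype QC and scans
    hwe_p_threshold: float = 1e-3
    missing_rate_threshold: float = 0.01
    maf_threshold: float = 0.05
    genotype_n_pcs: int = 0   # PC covariates off by default
    top_snp_p: float = 1e-4
    qtl_fdr: float = 0.1
    qtl_window: int = 500_000
    genomewide_topic_qtl: bool = True  # topics/MADRS have no position

    # association
    association_fdr: float = 0.05
    gene_madrs_fdr: float = 0.1
    top_n_features: int = 10
    cluster_method: str = "average"
    cluster_metric: str = "euclidean"

    # global
    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "preprocess", "fit", "associate", "qtl")

    # simulation (forwarded to synthdata.SimConfig)
    sim: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML config; unknown keys are rejected with the offending name."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update(overrides)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(unknown)}")
    if "stages" in data:
        data["stages"] = tuple(data["stages"])
    return RunConfig(**data)
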