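"""Readers and writers for the plain-text formats the pipeline exchanges.

Matrices are stored features-by-subjects on disk (the expression-matrix
convention) with one header row of subject ids and one leading label column;
an optional ``#orientation=`` comment line records how the matrix is laid
out.  Genomic coordinates are 0-based half-open (BED convention).  Genotypes
travel in the PLINK ``.raw`` additive text dialect.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "read_matrix",
    "write_matrix",
    "read_gmt",
    "write_gmt",
    "read_layout",
    "write_layout",
    "read_plink_raw",
    "write_plink_raw",
    "file_checksum",
    "write_manifest",
]


# ---------------------------------------------------------------------------
# genome layout


@dataclass
class GenomeLayout:
    """Genomic coordinates for genes, CpG sites and SNPs.

    ``chromosomes`` maps chromosome name to length in bp.  ``genes`` has
    columns (gene_id, chrom, start, end, strand), 0-based half-open;
    ``cpgs`` has (cpg_id, chrom, pos); ``snps`` has (snp_id, chrom, pos,
    ref, alt).
    """

    chromosomes: dict[str, int] = field(default_factory=dict)
    genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    cpgs: pd.DataFrame = field(default_factory=pd.DataFrame)
    snps: pd.DataFrame = field(default_factory=pd.DataFrame)

    def validate(self) -> None:
        for name, df, idcol in (
            ("genes", self.genes, "gene_id"),
            ("cpgs", self.cpgs, "cpg_id"),
            ("snps", self.snps, "snp_id"),
        ):
            if df.empty:
                continue
            if df[idcol].duplicated().any():
                dup = df.loc[df[idcol].duplicated(), idcol].iloc[0]
                raise ValueError(f"duplicate id in layout.{name}: {dup!r}")
            for chrom, sub in df.groupby("chrom"):
                if chrom not in self.chromosomes:
                    raise ValueError(f"layout.{name}: unknown chromosome {chrom!r}")
                length = self.chromosomes[chrom]
                hi = sub["end"] if "end" in sub else sub["pos"] + 1
                lo = sub["start"] if "start" in sub else sub["pos"]
                if (lo < 0).any() or (hi > length).any():
                    raise ValueError(f"layout.{name}: interval outside {chrom}")
        if not self.genes.empty and "end" in self.genes:
            if (self.genes["end"] <= self.genes["start"]).any():
                raise ValueError("layout.genes: empty or inverted interval")


# ---------------------------------------------------------------------------
# labelled matrices


def read_matrix(path: str | Path, orientation: str = "features_by_subjects") -> pd.DataFrame:
    """Read a labelled TSV matrix; duplicate labels and non-numeric cells error."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    skip = 1 if first.startswith("#") else 0
    df = pd.read_csv(path, sep="\t", index_col=0, skiprows=skip)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate row label {dup!r}")
    if pd.Index(df.columns).has_duplicates:
        dup = df.columns[pd.Index(df.columns).duplicated()][0]
        raise ValueError(f"{path}: duplicate column label {dup!r}")
    if not df.empty:
        bad = df.columns[~df.apply(lambda c: pd.api.types.is_numeric_dtype(c))]
        if len(bad):
            col = bad[0]
            row = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise ValueError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_matrix(df: pd.DataFrame, path: str | Path,
                 orientation: str = "features_by_subjects") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#orientation={orientation}\n")
        df.to_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# GMT genesets


def read_gmt(path: str | Path) -> list[tuple[str, list[str]]]:
    """Read a GMT file into an ordered list of (set id, member gene ids).

    Duplicate genes within a set are dropped (first occurrence kept); a blank
    set name is an error.
    """
    sets: list[tuple[str, list[str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: GMT line needs name and description")
            name = parts[0].strip()
            if not name:
                raise ValueError(f"{path}:{lineno}: blank geneset name")
            genes = list(dict.fromkeys(g for g in parts[2:] if g))
            sets.append((name, genes))
    return sets


def write_gmt(sets: Iterable[tuple[str, Iterable[str]]], path: str | Path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets:
            fh.write("\t".join([name, description, *sorted(set(genes))]) + "\n")


# ---------------------------------------------------------------------------
# BED-like layout files


def write_layout(layout: GenomeLayout, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"chrom": list(layout.chromosomes), "length": list(layout.chromosomes.values())}
    ).to_csv(outdir / "chromosomes.tsv", sep="\t", index=False)
    layout.genes[["chrom", "start", "end", "gene_id", "strand"]].to_csv(
        outdir / "genes.bed", sep="\t", index=False, header=False)
    cp = layout.cpgs.assign(start=layout.cpgs["pos"], end=layout.cpgs["pos"] + 1)
    cp[["chrom", "start", "end", "cpg_id"]].to_csv(
        outdir / "cpgs.bed", sep="\t", index=False, header=False)
    sn = layout.snps.assign(start=layout.snps["pos"], end=layout.snps["pos"] + 1)
    sn[["chrom", "start", "end", "snp_id", "ref", "alt"]].to_csv(
        outdir / "snps.bed", sep="\t", index=False, header=False)


def read_layout(indir: str | Path) -> GenomeLayout:
    indir = Path(indir)
    chroms = pd.read_csv(indir / "chromosomes.tsv", sep="\t")
    genes = pd.read_csv(indir / "genes.bed", sep="\t",
                        names=["chrom", "start", "end", "gene_id", "strand"])
    cpgs = pd.read_csv(indir / "cpgs.bed", sep="\t",
                       names=["chrom", "start", "end", "cpg_id"])
    snps = pd.read_csv(indir / "snps.bed", sep="\t",
                       names=["chrom", "start", "end", "snp_id", "ref", "alt"])
    layout = GenomeLayout(
        chromosomes=dict(zip(chroms["chrom"].astype(str), chroms["length"])),
        genes=genes[["gene_id", "chrom", "start", "end", "strand"]],
        cpgs=cpgs.assign(pos=cpgs["start"])[["cpg_id", "chrom", "pos"]],
        snps=snps.assign(pos=snps["start"])[["snp_id", "chrom", "pos", "ref", "alt"]],
    )
    layout.validate()
    return layout


# ---------------------------------------------------------------------------
# PLINK .raw additive dialect


def write_plink_raw(dosages: pd.DataFrame, alt_alleles: dict[str, str],
                    path: str | Path, sex: Sequence[int] | None = None,
                    phenotype: Sequence[int] | None = None) -> None:
    """Write subjects-by-SNPs dosages as PLINK ``.raw`` (counted-allele columns)."""
    n = len(dosages)
    header = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    snp_cols = [f"{s}_{alt_alleles.get(s, 'A')}" for s in dosages.columns]
    sex = [0] * n if sex is None else list(sex)
    phen = [-9] * n if phenotype is None else list(phenotype)
    with open(path, "w") as fh:
        fh.write(" ".join(header + snp_cols) + "\n")
        for i, (iid, row) in enumerate(dosages.iterrows()):
            vals = ["NA" if pd.isna(v) else str(int(v)) for v in row]
            fh.write(" ".join([str(iid), str(iid), "0", "0",
                               str(sex[i]), str(phen[i]), *vals]) + "\n")


def read_plink_raw(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a PLINK ``.raw`` file -> (subjects-by-SNPs dosage frame, counted allele)."""
    df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
    meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    missing = [c for c in meta if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: not PLINK .raw, missing columns {missing}")
    snp_cols = [c for c in df.columns if c not in meta]
    counted = {}
    new_names = {}
    for c in snp_cols:
        snp, _, allele = c.rpartition("_")
        counted[snp] = allele
        new_names[c] = snp
    dos = df[snp_cols].rename(columns=new_names)
    dos.index = df["IID"].astype(str)
    dos.index.name = "IID"
    bad = ~(dos.isin([0, 1, 2]) | dos.isna())
    if bad.any().any():
        col = dos.columns[bad.any(axis=0)][0]
        raise ValueError(f"{path}: dosage outside {{0,1,2,NA}} in column {col!r}")
    return dos, counted


# ---------------------------------------------------------------------------
# manifest / checksums


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, *, inputs: dict[str, str | Path],
                   config: dict, seed: int | None) -> None:
    import igem

    manifest = {
        "igem_version": igem.__version__,
        "seed": seed,
        "config": config,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()).hexdigest(),
        "inputs": {k: {"path": str(v), "sha256": file_checksum(v)}
                   for k, v in inputs.items() if Path(v).exists()},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
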