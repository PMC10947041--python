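"""Readers and writers for the tabular formats the pipeline exchanges.

All tables are tab-separated UTF-8 text with a header row. Variants are
identified throughout by the string key ``chrom:pos:ref:alt`` with 1-based
positions and bare integer autosome labels (``1``..``22``, plus ``X``, ``Y``,
``MT``).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

GWAS_COLUMNS = [
    "chrom", "pos", "rsid", "ref", "alt",
    "effect_allele", "log_effect", "se", "p", "maf", "n",
]

SITE_COLUMNS = [
    "chrom", "pos", "ref", "alt", "allele",
    "mirna", "gene", "transcript", "targetscan", "miranda", "rnahybrid",
]

EQTL_COLUMNS = ["chrom", "pos", "ref", "alt", "gene", "tissue", "fdr", "n_samples_expressed"]

AUTOSOMES = frozenset(str(i) for i in range(1, 23))
VALID_CHROMS = AUTOSOMES | {"X", "Y", "MT"}


def variant_ids(df: pd.DataFrame) -> pd.Series:
    """Canonical ``chrom:pos:ref:alt`` key for a table with variant columns."""
    return (
        df["chrom"].astype(str) + ":" + df["pos"].astype(int).astype(str)
        + ":" + df["ref"].astype(str) + ":" + df["alt"].astype(str)
    )


def read_tsv(path: str | os.PathLike, columns: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if columns is not None:
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
    return df


def write_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gwas(path: str | os.PathLike) -> pd.DataFrame:
    df = read_tsv(path, GWAS_COLUMNS)
    df["pos"] = df["pos"].astype(int)
    return df


def read_site_scores(path: str | os.PathLike) -> pd.DataFrame:
    """Per-allele target predictions; empty score cells mean "not predicted"."""
    return read_tsv(path, SITE_COLUMNS)


def read_eqtls(path: str | os.PathLike) -> pd.DataFrame:
    return read_tsv(path, EQTL_COLUMNS)


def read_family_map(path: str | os.PathLike) -> pd.Series:
    """miRNA -> family mapping; every miRNA belongs to exactly one family."""
    df = read_tsv(path, ["mirna", "family"])
    dup = df["mirna"].duplicated()
    if dup.any():
        raise ValueError(f"{path}: miRNAs mapped to more than one family: "
                         f"{sorted(df.loc[dup, 'mirna'].unique())[:5]}")
    return df.set_index("mirna")["family"]


def read_expression(path: str | os.PathLike) -> pd.DataFrame:
    """Entity-by-sample matrix: first column entity id, remaining columns samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def read_library_sizes(path: str | os.PathLike) -> pd.Series:
    df = read_tsv(path, ["sample", "reads"])
    return df.set_index("sample")["reads"].astype(float)


def read_gmt(path: str | os.PathLike) -> dict[str, set[str]]:
    """GMT gene sets: name, description, then member genes, tab-separated."""
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[0]:
                continue
            sets[fields[0]] = set(f for f in fields[2:] if f)
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


@dataclass(frozen=True)
class RegionMask:
    """1-based inclusive genomic interval."""
    chrom: str
    start: int
    end: int
    build: str = "hg19"

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"mask start {self.start} > end {self.end}")

    def contains(self, chrom, pos) -> bool:
        return str(chrom) == self.chrom and self.start <= int(pos) <= self.end


#: MHC region on chromosome 6 (hg19), excluded from variant calling because of
#: its extreme LD and gene density.
MHC_HG19 = RegionMask("6", 28_477_797, 33_448_354)


def read_bed_masks(path: str | os.PathLike, build: str = "hg19") -> list[RegionMask]:
    """BED is 0-based half-open; convert to 1-based inclusive on read."""
    masks = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            chrom = chrom.removeprefix("chr")
            masks.append(RegionMask(chrom, int(start) + 1, int(end), build))
    return masks


def read_dosage_panel(path: str | os.PathLike) -> pd.DataFrame:
    """Dosage TSV: rows = variants (id in first column), columns = samples.

    Returns a samples-by-variants frame of dosages in {0, 1, 2}, preserving
    the variant order of the file.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    panel = df.T
    bad = ~panel.isin([0, 1, 2]).all(axis=None)
    if bad:
        raise ValueError(f"{path}: dosages must be 0, 1 or 2")
    return panel.astype(np.int8)


def write_dosage_panel(panel: pd.DataFrame, path: str | os.PathLike) -> None:
    panel.T.to_csv(path, sep="\t", index_label="variant")


def read_vcf_panel(path: str | os.PathLike) -> pd.DataFrame:
    """Read diploid GT genotypes from a VCF into a samples-by-variants dosage frame."""
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, rows = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue
        chrom = rec.CHROM.removeprefix("chr")
        ids.append(f"{chrom}:{rec.POS}:{rec.REF}:{rec.ALT[0]}")
        gts = np.asarray(rec.genotype.array())[:, :2]
        rows.append(np.clip(gts, 0, None).sum(axis=1))
    return pd.DataFrame(np.array(rows, dtype=np.int8).T, index=samples, columns=ids)
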