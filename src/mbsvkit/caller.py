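"""Calling miRNA binding site variants (MBSVs) from per-allele predictions.

A variant is an MBSV when multi-algorithm target predictions show that its
two alleles differ substantially in predicted miRNA binding. The caller works
from a long table of per-(variant, allele, miRNA, gene, transcript) records
carrying a primary context-style score (more negative = stronger predicted
repression) and flags for which secondary algorithms also predicted the site.

The difference score Δ of a variant-gene pair is the best (most negative)
alternate-allele score minus the best reference-allele score; a positive Δ
means the alternate allele loses binding affinity, a negative Δ means it
gains. A site predicted for only one allele contributes an implicit score of
0 for the missing allele (no predicted site, no repression).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import AUTOSOMES, MHC_HG19, RegionMask, variant_ids

SECONDARY_ALGORITHMS = ("miranda", "rnahybrid")


def consensus_filter(sites: pd.DataFrame, primary: str = "targetscan") -> pd.DataFrame:
    """Keep records supported by the primary algorithm plus >=1 secondary.

    Only the primary score column is carried forward; secondary algorithms
    act purely as a consensus vote for the same (allele, miRNA, gene) record.
    """
    has_primary = sites[primary].notna()
    has_secondary = pd.Series(False, index=sites.index)
    for alg in SECONDARY_ALGORITHMS:
        if alg in sites.columns:
            has_secondary |= sites[alg].notna()
    kept = sites.loc[has_primary & has_secondary].copy()
    if (kept[primary] > 0).any():
        raise ValueError("primary scores must be <= 0")
    kept = kept.drop(columns=[c for c in SECONDARY_ALGORITHMS if c in kept.columns])
    return kept


def best_allele_gene_score(sites: pd.DataFrame, primary: str = "targetscan") -> pd.DataFrame:
    """Best (most negative) primary score per (variant, allele, gene).

    Also records which miRNA attains the best score, for family assignment.
    Input must already be consensus-filtered.
    """
    if len(sites) == 0:
        return pd.DataFrame(columns=["variant_id", "allele", "gene", "score", "mirna"])
    df = sites.copy()
    if "variant_id" not in df.columns:
        df["variant_id"] = variant_ids(df)
    idx = df.groupby(["variant_id", "allele", "gene"], sort=True)[primary].idxmin()
    best = df.loc[idx, ["variant_id", "allele", "gene", primary, "mirna"]]
    return best.rename(columns={primary: "score"}).reset_index(drop=True)


def gene_difference_score(best_ref: float | None, best_alt: float | None) -> float:
    """Δ = best alternate score − best reference score, missing scores imputed as 0."""
    if best_ref is None and best_alt is None:
        raise ValueError("at least one allele must have a score")
    return (best_alt if best_alt is not None else 0.0) - (best_ref if best_ref is not None else 0.0)


def variant_difference_score(per_gene: dict[str, float]) -> tuple[float, str]:
    """Representative Δ for a variant hitting several genes: the largest |Δ|.

    Ties on |Δ| prefer the more negative Δ (a predicted gain of binding),
    then the lexicographically smallest gene id.
    """
    if not per_gene:
        raise ValueError("per_gene map must be non-empty")
    best_gene = min(per_gene, key=lambda g: (-abs(per_gene[g]), per_gene[g], g))
    return per_gene[best_gene], best_gene


def _per_gene_table(best: pd.DataFrame) -> pd.DataFrame:
    """Wide per-(variant, gene) frame with ref/alt best scores and Δ."""
    pivot = best.pivot_table(index=["variant_id", "gene"], columns="allele",
                             values="score", aggfunc="first")
    for allele in ("ref", "alt"):
        if allele not in pivot.columns:
            pivot[allele] = np.nan
    pivot = pivot.reset_index()
    pivot["delta"] = pivot["alt"].fillna(0.0) - pivot["ref"].fillna(0.0)
    return pivot


def call_mbsvs(
    sites: pd.DataFrame,
    expressed_genes: set[str],
    expressed_mirnas: set[str],
    threshold: float = 0.2,
    masks: list[RegionMask] = (MHC_HG19,),
    primary: str = "targetscan",
) -> pd.DataFrame:
    """Run the full calling cascade on consensus-filtered site records.

    Order of filters: drop non-autosomal variants; drop records whose gene or
    miRNA is not expressed in the reference tissue; reduce to per-gene and
    per-variant difference scores; drop |Δ| < threshold (inclusive >= keeps a
    variant at exactly the threshold); drop variants inside any region mask.

    Returns one row per called MBSV: variant key columns, representative
    ``delta``, ``best_gene``, the miRNA attaining the representative score,
    and the per-gene Δ map as ``genes``/``gene_deltas`` parallel lists.
    """
    df = sites.copy()
    if len(df) == 0:
        return _empty_calls()
    df["chrom"] = df["chrom"].astype(str)
    bad = ~df["chrom"].isin(AUTOSOMES | {"X", "Y", "MT"})
    if bad.any():
        raise ValueError(f"malformed chromosome labels: {sorted(df.loc[bad, 'chrom'].unique())}")
    df = df[df["chrom"].isin(AUTOSOMES)]
    df = df[df["gene"].isin(expressed_genes) & df["mirna"].isin(expressed_mirnas)]
    if len(df) == 0:
        return _empty_calls()
    df["variant_id"] = variant_ids(df)

    best = best_allele_gene_score(df, primary=primary)
    per_gene = _per_gene_table(best)

    keys = df.drop_duplicates("variant_id").set_index("variant_id")[["chrom", "pos", "ref", "alt"]]
    records = []
    for vid, sub in per_gene.groupby("variant_id", sort=True):
        deltas = dict(zip(sub["gene"], sub["delta"]))
        delta, best_gene = variant_difference_score(deltas)
        if abs(delta) < threshold:
            continue
        key = keys.loc[vid]
        if any(m.contains(key["chrom"], key["pos"]) for m in masks):
            continue
        row = sub.set_index("gene").loc[best_gene]
        # representative miRNA: the one attaining the more extreme allele score
        # of the representative gene
        cand = best[(best["variant_id"] == vid) & (best["gene"] == best_gene)]
        rep = cand.loc[cand["score"].idxmin()]
        records.append({
            "variant_id": vid, "chrom": key["chrom"], "pos": int(key["pos"]),
            "ref": key["ref"], "alt": key["alt"],
            "delta": float(delta), "best_gene": best_gene, "best_mirna": rep["mirna"],
            "genes": ";".join(sub["gene"]),
            "gene_deltas": ";".join(f"{d:.6g}" for d in sub["delta"]),
        })
    return pd.DataFrame(records) if records else _empty_calls()


def _empty_calls() -> pd.DataFrame:
    return pd.DataFrame(columns=[
        "variant_id", "chrom", "pos", "ref", "alt", "delta",
        "best_gene", "best_mirna", "genes", "gene_deltas",
    ])


def affected_genes(mbsvs: pd.DataFrame) -> pd.Series:
    """Per-variant set of all affected genes (from the per-gene Δ map)."""
    return mbsvs.set_index("variant_id")["genes"].map(lambda g: set(g.split(";")))


def filter_psychencode(raw: pd.DataFrame, max_fdr: float = 0.05,
                       min_samples: int = 150) -> pd.DataFrame:
    """Filter a cohort eQTL table: FDR strictly below 0.05 and the gene
    expressed (FPKM > 0.1) in at least 150 samples."""
    for col in ("fdr", "n_samples_expressed"):
        if col not in raw.columns:
            raise ValueError(f"eQTL table missing column {col!r}")
    return raw[(raw["fdr"] < max_fdr) & (raw["n_samples_expressed"] >= min_samples)].copy()


def annotate_eqtls(
    mbsvs: pd.DataFrame,
    gtex: pd.DataFrame,
    psychencode: pd.DataFrame,
    brain_tissues: set[str],
    match_on: str = "any",
) -> pd.DataFrame:
    """Flag MBSVs that are eQTLs for a gene they affect.

    ``gtex_any``: some GTEx record matches (variant, gene); ``gtex_brain``:
    the match is in a brain tissue; ``psychencode``: a match in the (already
    filtered) cohort table. ``match_on`` selects whether the gene match uses
    any affected gene ("any", default) or only the representative gene
    ("best").
    """
    if match_on not in ("any", "best"):
        raise ValueError("match_on must be 'any' or 'best'")
    out = mbsvs.copy()
    if len(out) == 0:
        for c in ("gtex_any", "gtex_brain", "psychencode"):
            out[c] = pd.Series(dtype=bool)
        return out

    if match_on == "any":
        genes = affected_genes(mbsvs)
    else:
        genes = mbsvs.set_index("variant_id")["best_gene"].map(lambda g: {g})

    def pairs(eqtl: pd.DataFrame, tissues: set[str] | None = None) -> set[tuple[str, str]]:
        if len(eqtl) == 0:
            return set()
        df = eqtl
        if tissues is not None:
            df = df[df["tissue"].isin(tissues)]
        return set(zip(variant_ids(df), df["gene"]))

    gtex_pairs = pairs(gtex)
    brain_pairs = pairs(gtex, brain_tissues)
    pe_pairs = pairs(psychencode)

    def flag(pairset):
        return [
            any((vid, g) in pairset for g in genes[vid])
            for vid in out["variant_id"]
        ]

    out["gtex_any"] = flag(gtex_pairs)
    out["gtex_brain"] = flag(brain_pairs)
    out["psychencode"] = flag(pe_pairs)
    return out


def mbsv_families(
    mbsvs: pd.DataFrame,
    sites: pd.DataFrame,
    family_map: pd.Series,
    expressed_genes: set[str],
    expressed_mirnas: set[str],
) -> pd.DataFrame:
    """Long (variant_id, family) table of every miRNA family a called MBSV affects.

    A variant contributes one row per family with at least one surviving
    consensus site record at that variant, so per-family aggregation sees it
    in every family it could perturb. ``sites`` must be consensus-filtered.
    """
    if len(mbsvs) == 0:
        return pd.DataFrame(columns=["variant_id", "family"])
    df = sites.copy()
    df["variant_id"] = variant_ids(df)
    df = df[df["variant_id"].isin(set(mbsvs["variant_id"]))]
    df = df[df["gene"].isin(expressed_genes) & df["mirna"].isin(expressed_mirnas)]
    unknown = set(df["mirna"]) - set(family_map.index)
    if unknown:
        raise ValueError(f"miRNAs without a family assignment: {sorted(unknown)[:5]}")
    df["family"] = df["mirna"].map(family_map)
    return df[["variant_id", "family"]].drop_duplicates().reset_index(drop=True)
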