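"""Synthetic pipeline inputs with known ground truth.

Every external resource the analysis consumes — GWAS summary statistics, a
per-allele multi-algorithm target-prediction table, gene and miRNA expression
matrices, eQTL annotations, a miRNA family map, gene sets and an LD reference
panel — is emulated here with explicit truth labels, so each downstream
filter and statistic can be validated against a known answer.

The association model generates per-variant z-scores (null: N(0,1);
signal-carrying MBSVs: N(delta, 1)) and derives two-sided p-values and
effect sizes from the same z, keeping p-values and effects mutually
consistent. Genotypes follow a block-equicorrelated latent-Gaussian model
thresholded at the allele frequency, giving tunable within-block LD and
independence across blocks. Non-MBSV "decoy" variants are constructed to
violate exactly one calling filter each (single-algorithm support, |Δ| below
threshold, MHC location, non-autosomal chromosome, unexpressed gene or
miRNA), which makes the caller's confusion matrix fully checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .expression import MISANNOTATED_TIER
from .io import MHC_HG19

BRAIN_TISSUES = {"cortex", "hippocampus", "cerebellum"}
OTHER_TISSUES = {"liver", "blood"}

DECOY_CLASSES = (
    "single_algorithm", "secondary_only", "sub_threshold",
    "mhc", "nonautosomal", "unexpressed_gene", "unexpressed_mirna",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic cohort.

    ``enrichment_shift`` is the mean shift delta of association z-scores for
    signal-carrying MBSVs; ``frac_enriched`` is the fraction of MBSVs that
    carry it. ``n_mhc`` / ``n_nonautosomal`` variants are placed inside the
    MHC region and on chromosome X to feed the corresponding decoy classes.
    """

    n_variants: int = 5_000
    n_samples_panel: int = 503
    n_mirnas: int = 150
    n_genes: int = 400
    frac_mbsv: float = 0.05
    enrichment_shift: float = 0.0
    frac_enriched: float = 0.0
    ld_block_size: int = 50
    ld_rho: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0
    n_gwas: int = 50_000
    n_mhc: int = 10
    n_nonautosomal: int = 10
    frac_decoy: float = 0.05
    n_expr_samples: int = 16

    def __post_init__(self):
        for name in ("frac_mbsv", "frac_enriched", "frac_decoy"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if min(self.n_variants, self.n_mirnas, self.n_genes) < 0:
            raise ValueError("counts must be non-negative")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be within (0, 0.5]")
        if not np.isfinite(self.enrichment_shift) or self.enrichment_shift < 0:
            raise ValueError("enrichment_shift must be a finite non-negative real")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must be in [0, 1)")
        if self.frac_enriched > 0 and self.frac_mbsv == 0:
            raise ValueError("frac_enriched > 0 requires frac_mbsv > 0")


@dataclass
class TruthLabels:
    """Ground truth: per-variant MBSV/signal flags, per-entity expression."""

    variants: pd.DataFrame  # index variant_id; is_mbsv, is_enriched, true_delta, decoy_class
    expressed_genes: set[str] = field(default_factory=set)
    expressed_mirnas: set[str] = field(default_factory=set)

    @property
    def mbsv_ids(self) -> list[str]:
        return list(self.variants.index[self.variants["is_mbsv"]])


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    """Named substream derived from the single config seed."""
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


_NUC = np.array(list("ACGT"))


def simulate_gwas(config: SimulationConfig) -> tuple[pd.DataFrame, TruthLabels]:
    """GWAS summary statistics plus truth labels.

    Variants live on autosomes 1-22 in position order, with ``n_mhc`` of the
    chromosome-6 variants placed inside the MHC and ``n_nonautosomal`` extra
    variants on X. Half the variants (seeded) are emitted reference-oriented
    to exercise effect standardization downstream.
    """
    n = config.n_variants
    if n == 0:
        empty = pd.DataFrame(columns=[
            "chrom", "pos", "rsid", "ref", "alt", "effect_allele",
            "log_effect", "se", "p", "maf", "n", "variant_id"])
        return empty, TruthLabels(pd.DataFrame(
            columns=["is_mbsv", "is_enriched", "true_delta", "decoy_class"]))
    rng = _rng(config, 1)

    n_auto = n
    chroms = [str(1 + (i * 22) // n_auto) for i in range(n_auto)]
    pos = np.empty(n_auto, dtype=int)
    mhc_flags = np.zeros(n_auto, dtype=bool)
    offset = {c: 0 for c in set(chroms)}
    n_mhc_placed = 0
    for i, c in enumerate(chroms):
        k = offset[c]
        if c == "6" and n_mhc_placed < config.n_mhc:
            pos[i] = MHC_HG19.start + 2_000 + k * 5_000
            mhc_flags[i] = True
            n_mhc_placed += 1
        elif c == "6":
            pos[i] = MHC_HG19.end + 1_000_000 + k * 5_000
        else:
            pos[i] = 1_000_000 + k * 5_000
        offset[c] = k + 1

    chroms = chroms + ["X"] * config.n_nonautosomal
    pos = np.concatenate([pos, 1_000_000 + 5_000 * np.arange(config.n_nonautosomal)])
    mhc_flags = np.concatenate([mhc_flags, np.zeros(config.n_nonautosomal, dtype=bool)])
    n_total = len(chroms)

    ref_idx = rng.integers(0, 4, size=n_total)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_total)) % 4
    ref, alt = _NUC[ref_idx], _NUC[alt_idx]
    vids = [f"{c}:{p}:{r}:{a}" for c, p, r, a in zip(chroms, pos, ref, alt)]

    maf = rng.uniform(*config.maf_range, size=n_total)

    # truth: MBSVs drawn from autosomal, non-MHC variants only
    eligible = np.flatnonzero(~mhc_flags & (np.array(chroms) != "X"))
    n_mbsv = int(round(config.frac_mbsv * n))
    mbsv_idx = rng.choice(eligible, size=min(n_mbsv, eligible.size), replace=False)
    is_mbsv = np.zeros(n_total, dtype=bool)
    is_mbsv[mbsv_idx] = True
    n_enriched = int(round(config.frac_enriched * is_mbsv.sum()))
    enr_idx = rng.choice(mbsv_idx, size=n_enriched, replace=False) if n_enriched else []
    is_enriched = np.zeros(n_total, dtype=bool)
    is_enriched[list(enr_idx)] = True

    true_delta = np.zeros(n_total)
    mags = rng.uniform(0.2, 0.7, size=is_mbsv.sum())
    signs = rng.choice([-1.0, 1.0], size=is_mbsv.sum())
    true_delta[is_mbsv] = mags * signs

    z = rng.standard_normal(n_total)
    z[is_enriched] += config.enrichment_shift
    p = 2 * stats.norm.sf(np.abs(z))
    se = 1.0 / np.sqrt(2 * maf * (1 - maf) * config.n_gwas)
    beta_alt = z * se
    ref_oriented = rng.random(n_total) < 0.5
    effect_allele = np.where(ref_oriented, ref, alt)
    log_effect = np.where(ref_oriented, -beta_alt, beta_alt)

    gwas = pd.DataFrame({
        "chrom": chroms, "pos": pos,
        "rsid": [f"rs{i + 1:07d}" for i in range(n_total)],
        "ref": ref, "alt": alt, "effect_allele": effect_allele,
        "log_effect": log_effect, "se": se, "p": p, "maf": maf,
        "n": config.n_gwas, "variant_id": vids,
    })
    labels = pd.DataFrame({
        "is_mbsv": is_mbsv, "is_enriched": is_enriched,
        "true_delta": true_delta, "decoy_class": "",
    }, index=pd.Index(vids, name="variant_id"))
    return gwas, TruthLabels(labels)


def simulate_genotypes(config: SimulationConfig, variants: pd.DataFrame) -> pd.DataFrame:
    """Samples-by-variants dosage panel with block-equicorrelated LD.

    Within each run of ``ld_block_size`` consecutive variants on a
    chromosome, the two latent haplotype Gaussians per sample share a common
    factor with loading sqrt(ld_rho); thresholding at Phi^-1(MAF) converts
    them to alleles. Blocks and chromosomes are independent.
    """
    if config.n_samples_panel < 2:
        raise ValueError("panel needs at least 2 samples")
    rng = _rng(config, 2)
    ns = config.n_samples_panel
    samples = [f"s{i + 1:04d}" for i in range(ns)]
    cols, mats = [], []
    for chrom, grp in variants.groupby("chrom", sort=False):
        vids = list(grp["variant_id"])
        maf = grp["maf"].to_numpy(dtype=float)
        for b0 in range(0, len(vids), config.ld_block_size):
            blk = slice(b0, b0 + config.ld_block_size)
            k = len(vids[blk])
            thr = stats.norm.ppf(maf[blk])
            dose = np.zeros((ns, k), dtype=np.int8)
            for _hap in range(2):
                shared = rng.standard_normal((ns, 1))
                noise = rng.standard_normal((ns, k))
                latent = np.sqrt(config.ld_rho) * shared + np.sqrt(1 - config.ld_rho) * noise
                dose += (latent < thr).astype(np.int8)
            cols.extend(vids[blk])
            mats.append(dose)
    if not mats:
        return pd.DataFrame(index=samples)
    return pd.DataFrame(np.hstack(mats), index=samples, columns=cols)


def simulate_expression(config: SimulationConfig):
    """Expression-side resources with known pass/fail entities.

    Returns ``(gene_rpkm, mirna_counts, library_sizes, tiers, family_map,
    gene_sets, truth_sets)`` where ``truth_sets`` is the pair of expressed
    gene and miRNA id sets under the standard filter rules (RPKM >= 1 in
    >= 75% of samples; CPM >= the smallest-library equivalent of 10 reads in
    >= 75%; confidently annotated miRNAs only).
    """
    rng = _rng(config, 3)
    ns = config.n_expr_samples
    samples = [f"b{i + 1:02d}" for i in range(ns)]

    genes = [f"gene{i + 1:04d}" for i in range(config.n_genes)]
    n_fail_g = config.n_genes // 4
    rpkm = rng.lognormal(mean=1.0, sigma=0.5, size=(config.n_genes, ns)) + 1.0
    fail_rows = rng.choice(config.n_genes, size=n_fail_g, replace=False)
    for r in fail_rows:
        off = rng.choice(ns, size=int(np.ceil(ns * 0.5)), replace=False)
        rpkm[r, off] = 0.0
    gene_rpkm = pd.DataFrame(rpkm, index=genes, columns=samples)

    mirnas = [f"mir{i + 1:03d}" for i in range(config.n_mirnas)]
    libs = pd.Series(rng.uniform(0.97e6, 2.0e6, size=ns), index=samples, name="reads")
    n_fail_m = config.n_mirnas // 4
    min_cpm = 10.0 / (libs.min() / 1e6)
    counts = rng.poisson(lam=200.0, size=(config.n_mirnas, ns)).astype(float)
    counts += np.ceil(min_cpm * libs.max() / 1e6)  # clear the CPM rule in every library
    fail_m = rng.choice(config.n_mirnas, size=n_fail_m, replace=False)
    for r in fail_m:
        off = rng.choice(ns, size=int(np.ceil(ns * 0.5)), replace=False)
        counts[r, off] = 0.0
    mirna_counts = pd.DataFrame(counts, index=mirnas, columns=samples)

    tiers = {m: "conserved" for m in mirnas}
    n_mis = max(1, config.n_mirnas // 20) if config.n_mirnas else 0
    passing = [m for i, m in enumerate(mirnas) if i not in set(fail_m)]
    for m in passing[:n_mis]:
        tiers[m] = MISANNOTATED_TIER

    family_map = pd.Series({m: f"fam{idx // 3 + 1:03d}" for idx, m in enumerate(mirnas)},
                           name="family")

    gene_sets = {}
    for s in range(10 if config.n_genes >= 20 else 0):
        members = rng.choice(genes, size=min(15, config.n_genes), replace=False)
        gene_sets[f"set{s + 1:02d}"] = set(members)

    cpm = counts / (libs.to_numpy() / 1e6)
    expressed_mirnas = {
        m for i, m in enumerate(mirnas)
        if (cpm[i] >= min_cpm).mean() >= 0.75 and tiers[m] != MISANNOTATED_TIER
    }
    expressed_genes = {
        g for i, g in enumerate(genes) if (rpkm[i] >= 1.0).mean() >= 0.75
    }
    return (gene_rpkm, mirna_counts, libs, tiers, family_map, gene_sets,
            (expressed_genes, expressed_mirnas))


def _site_rows(vrow, allele, mirna, gene, score, support):
    return {
        "chrom": vrow["chrom"], "pos": vrow["pos"], "ref": vrow["ref"],
        "alt": vrow["alt"], "allele": allele, "mirna": mirna, "gene": gene,
        "transcript": f"{gene}.t1", "targetscan": score,
        "miranda": -1.0 if "miranda" in support else np.nan,
        "rnahybrid": -1.0 if "rnahybrid" in support else np.nan,
    }


def simulate_site_scores(
    config: SimulationConfig,
    variants: pd.DataFrame,
    truth: TruthLabels,
) -> pd.DataFrame:
    """Per-allele prediction records realizing the truth labels.

    True MBSVs get consensus-supported records whose downstream difference
    score equals ``true_delta`` exactly. A seeded subset of non-MBSVs gets
    decoy records, each violating exactly one calling filter; the class is
    recorded in ``truth.variants['decoy_class']`` in place.
    """
    if not truth.expressed_genes or not truth.expressed_mirnas:
        raise ValueError("truth must carry expressed gene and miRNA sets")
    missing = truth.variants.index.difference(variants["variant_id"])
    if len(missing):
        raise ValueError(f"truth references variants absent from the table: {list(missing)[:5]}")
    rng = _rng(config, 4)
    vtab = variants.set_index("variant_id")
    exp_g = sorted(truth.expressed_genes)
    exp_m = sorted(truth.expressed_mirnas)
    unexp_g = sorted(set(f"gene{i + 1:04d}" for i in range(config.n_genes))
                     - truth.expressed_genes)
    unexp_m = sorted(set(f"mir{i + 1:03d}" for i in range(config.n_mirnas))
                     - truth.expressed_mirnas)

    rows = []
    tv = truth.variants

    def emit_pair(vrow, gene, mirna, delta, support=("miranda",)):
        """Records for one variant-gene pair with difference score delta."""
        if rng.random() < 0.5:
            base = -0.75
            rows.append(_site_rows(vrow, "ref", mirna, gene, base, support))
            rows.append(_site_rows(vrow, "alt", mirna, gene, base + delta, support))
            # a worse-scoring extra transcript must not change the best score
            extra = _site_rows(vrow, "ref", mirna, gene, base / 2, support)
            extra["transcript"] = f"{gene}.t2"
            rows.append(extra)
        elif delta > 0:
            rows.append(_site_rows(vrow, "ref", mirna, gene, -delta, support))
        else:
            rows.append(_site_rows(vrow, "alt", mirna, gene, delta, support))

    for vid in tv.index[tv["is_mbsv"]]:
        vrow = vtab.loc[vid]
        delta = tv.at[vid, "true_delta"]
        gene = exp_g[rng.integers(len(exp_g))]
        mirna = exp_m[rng.integers(len(exp_m))]
        support = ("miranda",) if rng.random() < 0.5 else ("miranda", "rnahybrid")
        emit_pair(vrow, gene, mirna, delta, support)
        if rng.random() < 0.3:  # second affected gene with a smaller |Δ|
            gene2 = exp_g[rng.integers(len(exp_g))]
            if gene2 != gene:
                emit_pair(vrow, gene2, exp_m[rng.integers(len(exp_m))], 0.8 * delta)

    # decoys: MHC and X variants are forced into their location classes;
    # other classes cycle over a seeded draw of the remaining non-MBSVs
    non_mbsv = tv.index[~tv["is_mbsv"]]
    located = {}
    for vid in non_mbsv:
        vrow = vtab.loc[vid]
        if vrow["chrom"] == "X":
            located[vid] = "nonautosomal"
        elif MHC_HG19.contains(vrow["chrom"], vrow["pos"]):
            located[vid] = "mhc"
    other_classes = [c for c in DECOY_CLASSES if c not in ("mhc", "nonautosomal")]
    free = [v for v in non_mbsv if v not in located]
    n_decoy = int(round(config.frac_decoy * len(free)))
    chosen = rng.choice(len(free), size=n_decoy, replace=False) if n_decoy else []
    for j, i in enumerate(sorted(chosen)):
        located[free[i]] = other_classes[j % len(other_classes)]

    for vid, cls in located.items():
        vrow = vtab.loc[vid]
        gene = exp_g[rng.integers(len(exp_g))]
        mirna = exp_m[rng.integers(len(exp_m))]
        delta = rng.choice([-0.4, 0.4])
        if cls == "single_algorithm":
            rows.append(_site_rows(vrow, "ref", mirna, gene, -abs(delta), ()))
        elif cls == "secondary_only":
            rows.append(_site_rows(vrow, "ref", mirna, gene, np.nan, ("miranda", "rnahybrid")))
        elif cls == "sub_threshold":
            emit_pair(vrow, gene, mirna, float(np.sign(delta)) * 0.1)
        elif cls in ("mhc", "nonautosomal"):
            emit_pair(vrow, gene, mirna, delta)
        elif cls == "unexpressed_gene" and unexp_g:
            emit_pair(vrow, unexp_g[rng.integers(len(unexp_g))], mirna, delta)
        elif cls == "unexpressed_mirna" and unexp_m:
            emit_pair(vrow, gene, unexp_m[rng.integers(len(unexp_m))], delta)
        truth.variants.at[vid, "decoy_class"] = cls

    df = pd.DataFrame(rows, columns=[
        "chrom", "pos", "ref", "alt", "allele", "mirna", "gene", "transcript",
        "targetscan", "miranda", "rnahybrid"])
    return df.reset_index(drop=True)


def simulate_eqtls(
    config: SimulationConfig,
    variants: pd.DataFrame,
    truth: TruthLabels,
    sites: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """GTEx-style and cohort-style eQTL tables wired to a subset of MBSVs.

    Roughly half the MBSVs get a GTEx record for an affected gene (half of
    those in a brain tissue) and a third get a cohort record, mixed with
    records that fail the FDR or sample-count filters and with decoy records
    for non-affected genes.
    """
    rng = _rng(config, 5)
    vtab = variants.set_index("variant_id")
    site_genes = sites.assign(variant_id=(
        sites["chrom"].astype(str) + ":" + sites["pos"].astype(str)
        + ":" + sites["ref"] + ":" + sites["alt"]))
    by_variant = site_genes.groupby("variant_id")["gene"].agg(set)

    brain = sorted(BRAIN_TISSUES)
    other = sorted(OTHER_TISSUES)
    gtex_rows, pe_rows = [], []
    for vid in truth.mbsv_ids:
        genes = sorted(by_variant.get(vid, set()))
        if not genes:
            continue
        vrow = vtab.loc[vid]
        key = dict(chrom=vrow["chrom"], pos=vrow["pos"], ref=vrow["ref"], alt=vrow["alt"])
        gene = genes[rng.integers(len(genes))]
        u = rng.random()
        if u < 0.25:
            gtex_rows.append({**key, "gene": gene, "tissue": brain[rng.integers(len(brain))],
                              "fdr": 0.01, "n_samples_expressed": 200})
        elif u < 0.5:
            gtex_rows.append({**key, "gene": gene, "tissue": other[rng.integers(len(other))],
                              "fdr": 0.01, "n_samples_expressed": 200})
        elif u < 0.6:  # decoy: eQTL for a gene the variant does not affect
            gtex_rows.append({**key, "gene": "geneXXXX", "tissue": brain[0],
                              "fdr": 0.01, "n_samples_expressed": 200})
        v = rng.random()
        if v < 0.33:
            pe_rows.append({**key, "gene": gene, "tissue": "cortex",
                            "fdr": 0.01, "n_samples_expressed": 200})
        elif v < 0.45:  # fails the FDR or expression filter
            fail = rng.random() < 0.5
            pe_rows.append({**key, "gene": gene, "tissue": "cortex",
                            "fdr": 0.5 if fail else 0.01,
                            "n_samples_expressed": 200 if fail else 100})
    cols = ["chrom", "pos", "ref", "alt", "gene", "tissue", "fdr", "n_samples_expressed"]
    return (pd.DataFrame(gtex_rows, columns=cols),
            pd.DataFrame(pe_rows, columns=cols))


@dataclass
class SyntheticDataset:
    """Everything one pipeline run consumes, plus the truth labels."""

    config: SimulationConfig
    gwas: pd.DataFrame
    truth: TruthLabels
    panel: pd.DataFrame
    sites: pd.DataFrame
    gene_rpkm: pd.DataFrame
    mirna_counts: pd.DataFrame
    library_sizes: pd.Series
    tiers: dict[str, str]
    family_map: pd.Series
    gene_sets: dict[str, set[str]]
    gtex_eqtls: pd.DataFrame
    psychencode_eqtls: pd.DataFrame


def simulate_all(config: SimulationConfig) -> SyntheticDataset:
    """Generate a complete, internally consistent synthetic study."""
    gwas, truth = simulate_gwas(config)
    (gene_rpkm, mirna_counts, libs, tiers, family_map, gene_sets,
     (exp_g, exp_m)) = simulate_expression(config)
    truth.expressed_genes = exp_g
    truth.expressed_mirnas = exp_m
    sites = simulate_site_scores(config, gwas, truth)
    panel = simulate_genotypes(config, gwas)
    gtex, pe = simulate_eqtls(config, gwas, truth, sites)
    return SyntheticDataset(
        config=config, gwas=gwas, truth=truth, panel=panel, sites=sites,
        gene_rpkm=gene_rpkm, mirna_counts=mirna_counts, library_sizes=libs,
        tiers=tiers, family_map=family_map, gene_sets=gene_sets,
        gtex_eqtls=gtex, psychencode_eqtls=pe,
    )
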