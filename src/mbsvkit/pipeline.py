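"""End-to-end orchestration: expression filter -> call -> prune -> stats.

The in-memory entry point is :func:`run`, which takes a
:class:`PipelineInputs` bundle (either loaded from files via
:func:`load_inputs` or produced directly by the synthetic generator) and
returns a :class:`PipelineResult` with every intermediate table plus a
manifest of per-stage input/output counts. :func:`run_pipeline` wraps it
with file I/O for the command line.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import aggregation, caller, effects, enrichment, io, pruning
from .expression import (ExpressionFilterRule, ExpressionMatrix, cpm_normalize,
                         filter_confident_mirnas, filter_expressed,
                         min_cpm_threshold)

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """All analysis thresholds in one place (documented defaults)."""

    delta_threshold: float = 0.2
    min_rpkm: float = 1.0
    min_fraction: float = 0.75
    min_count: int = 10
    maf_min: float = 0.01
    r2_max: float = 0.1
    window: int = 50
    step: int = 5
    p_thresholds: tuple[float, ...] = (5e-8, 1e-5)
    quantiles: tuple[float, ...] = (0.5, 0.9, 0.99, 0.999)
    n_boot: int = 200
    background: str = "utr"  # "utr": non-MBSV variants with 3'UTR site records; "all"
    brain_tissues: frozenset = frozenset({"cortex", "hippocampus", "cerebellum"})
    eqtl_match: str = "any"
    table_style: str = "totals"

    def validate(self):
        if self.delta_threshold < 0 or self.min_rpkm < 0:
            raise ValueError("thresholds must be non-negative")
        if self.background not in ("utr", "all"):
            raise ValueError("background must be 'utr' or 'all'")
        for t in self.p_thresholds:
            if not (0 < t < 1):
                raise ValueError("p thresholds must be in (0, 1)")
        for q in self.quantiles:
            if not (0 < q < 1):
                raise ValueError("quantiles must be in (0, 1)")


@dataclass
class PipelineInputs:
    gwas: pd.DataFrame
    sites: pd.DataFrame
    gene_expression: pd.DataFrame      # entity x sample, normalized units
    gene_units: str
    mirna_counts: pd.DataFrame         # raw counts
    library_sizes: pd.Series
    mirna_tiers: dict[str, str]
    family_map: pd.Series
    gtex_eqtls: pd.DataFrame
    psychencode_eqtls: pd.DataFrame
    panel: pd.DataFrame | None = None  # samples x variants dosages
    masks: list = field(default_factory=lambda: [io.MHC_HG19])
    gene_sets: dict = field(default_factory=dict)


@dataclass
class PipelineResult:
    expressed_genes: set
    expressed_mirnas: set
    mbsvs: pd.DataFrame
    families: pd.DataFrame
    kept_variants: list
    classified: pd.DataFrame
    enrichment_tests: pd.DataFrame
    acat_overall: dict
    acat_families: pd.DataFrame
    effect_delta: pd.DataFrame
    effect_sign: pd.DataFrame
    manifest: dict


def _filter_counts(manifest, stage, n_in, n_out, rule):
    manifest["stages"].append(
        {"stage": stage, "n_in": int(n_in), "n_out": int(n_out),
         "n_removed": int(n_in - n_out), "rule": rule})


def run(inputs: PipelineInputs, params: PipelineParams | None = None,
        seed: int = 0) -> PipelineResult:
    """Execute every stage in dependency order on in-memory tables."""
    params = params or PipelineParams()
    params.validate()
    manifest: dict = {"seed": seed, "stages": [], "params": {
        k: (sorted(v) if isinstance(v, frozenset) else list(v) if isinstance(v, tuple) else v)
        for k, v in asdict(params).items()}}

    # 1. expression universe
    gene_m = ExpressionMatrix(inputs.gene_expression, units=inputs.gene_units)
    expressed_genes = filter_expressed(
        gene_m, ExpressionFilterRule(params.min_rpkm, params.min_fraction, inputs.gene_units))
    _filter_counts(manifest, "gene_expression", len(gene_m.entities), len(expressed_genes),
                   f">={params.min_rpkm} {inputs.gene_units} in >={params.min_fraction:.0%} samples")

    mirna_m = cpm_normalize(ExpressionMatrix(
        inputs.mirna_counts, units="counts", library_sizes=inputs.library_sizes))
    cpm_min = min_cpm_threshold(params.min_count, inputs.library_sizes)
    expressed_mirnas = filter_expressed(
        mirna_m, ExpressionFilterRule(cpm_min, params.min_fraction, "CPM"))
    expressed_mirnas = filter_confident_mirnas(expressed_mirnas, inputs.mirna_tiers)
    _filter_counts(manifest, "mirna_expression", len(mirna_m.entities), len(expressed_mirnas),
                   f">={cpm_min:.4g} CPM in >={params.min_fraction:.0%} samples; confident tiers")

    # 2. MBSV calling
    consensus = caller.consensus_filter(inputs.sites)
    _filter_counts(manifest, "consensus", len(inputs.sites), len(consensus),
                   "primary algorithm + >=1 secondary")
    mbsvs = caller.call_mbsvs(consensus, expressed_genes, expressed_mirnas,
                              threshold=params.delta_threshold, masks=inputs.masks)
    n_consensus_variants = io.variant_ids(consensus).nunique() if len(consensus) else 0
    _filter_counts(manifest, "call_mbsvs", n_consensus_variants, len(mbsvs),
                   f"autosomal, expressed, |delta| >= {params.delta_threshold}, outside masks")

    pe = caller.filter_psychencode(inputs.psychencode_eqtls)
    mbsvs = caller.annotate_eqtls(mbsvs, inputs.gtex_eqtls, pe,
                                  set(params.brain_tissues), match_on=params.eqtl_match)
    families = caller.mbsv_families(mbsvs, consensus, inputs.family_map,
                                    expressed_genes, expressed_mirnas)

    # 3. classification and pruning
    gwas = inputs.gwas.copy()
    if "variant_id" not in gwas.columns:
        gwas["variant_id"] = io.variant_ids(gwas)
    mbsv_ids = set(mbsvs["variant_id"])
    utr_ids = set(io.variant_ids(inputs.sites)) if len(inputs.sites) else set()
    gwas["is_mbsv"] = gwas["variant_id"].isin(mbsv_ids)
    if params.background == "utr":
        background = gwas["variant_id"].isin(utr_ids) & ~gwas["is_mbsv"]
    else:
        background = ~gwas["is_mbsv"]
    classified = gwas[gwas["is_mbsv"] | background].copy()

    if inputs.panel is not None and len(inputs.panel.columns):
        shared = [v for v in inputs.panel.columns if v in set(classified["variant_id"])]
        panel = inputs.panel[shared]
        prio = pd.Series([v in mbsv_ids for v in panel.columns], index=panel.columns)
        kept = pruning.prune(panel, pruning.PruneParams(
            window=params.window, step=params.step,
            r2_max=params.r2_max, maf_min=params.maf_min), priority=prio)
        _filter_counts(manifest, "ld_prune", len(shared), len(kept),
                       f"window {params.window}/{params.step}, r2 <= {params.r2_max}, "
                       f"MAF >= {params.maf_min}, MBSVs prioritized")
        classified = classified[classified["variant_id"].isin(set(kept))]
    else:
        kept = list(classified["variant_id"])

    # 4. enrichment statistics
    tests = []
    p1 = classified.loc[classified["is_mbsv"], "p"].to_numpy()
    p0 = classified.loc[~classified["is_mbsv"], "p"].to_numpy()
    eff = effects.orient_effects(
        classified["log_effect"].to_numpy(),
        np.where(classified["effect_allele"] == classified["alt"], "alt", "ref"))
    classified = classified.assign(effect_alt=eff)
    y_p = enrichment.neglog10(classified["p"].to_numpy())
    y_b = np.abs(eff)
    x = classified["is_mbsv"].to_numpy()
    if len(p1) and len(p0):
        for name, y in (("neglog10_p", y_p), ("abs_log_effect", y_b)):
            d, kp = enrichment.ks_two_sample(y[x], y[~x])
            tests.append({"test": f"ks_{name}", "statistic": d, "p": kp})
            for tau in params.quantiles:
                qr = enrichment.quantile_regression_binary(
                    y, x, tau, n_boot=params.n_boot, seed=np.random.default_rng([seed, 7]))
                tests.append({"test": f"quantreg_{name}_q{tau}", "statistic": qr.coef,
                              "p": qr.p, "se": qr.se})
        for res in enrichment.threshold_enrichment(
                p1, p0, params.p_thresholds, table_style=params.table_style):
            tests.append({"test": f"fisher_p<{res.threshold:g}",
                          "statistic": res.fisher.odds_ratio, "p": res.fisher.p,
                          "hits_1": res.n_hits_1, "n_1": res.n_1,
                          "hits_0": res.n_hits_0, "n_0": res.n_0})
    enrichment_tests = pd.DataFrame(tests)
    if len(enrichment_tests):
        enrichment_tests["q"] = enrichment.bh_fdr(enrichment_tests["p"].to_numpy())

    # 5. aggregation
    mbsv_stats = mbsvs.merge(gwas[["variant_id", "p", "log_effect", "effect_allele"]],
                             on="variant_id", how="left")
    pruned_mbsvs = mbsv_stats[mbsv_stats["variant_id"].isin(set(kept))]
    acat_overall = aggregation.acat_overall(pruned_mbsvs) if len(pruned_mbsvs) else {}
    fam_pruned = families[families["variant_id"].isin(set(kept))]
    acat_families = aggregation.acat_by_family(pruned_mbsvs, fam_pruned) \
        if len(fam_pruned) else pd.DataFrame()

    # 6. effect regressions within ACAT-significant families
    sig = effects.significant_families(acat_families) if len(acat_families) else set()
    reg_in = fam_pruned.merge(pruned_mbsvs, on="variant_id")
    reg_in = reg_in[reg_in["family"].isin(sig)]
    if len(reg_in):
        reg_in = reg_in.assign(effect=effects.orient_effects(
            reg_in["log_effect"].to_numpy(),
            np.where(reg_in["effect_allele"] == reg_in["alt"], "alt", "ref")))
        effect_delta = effects.regress_effect_on_delta(reg_in)
        effect_sign = effects.regress_effect_on_sign(reg_in)
    else:
        effect_delta = pd.DataFrame()
        effect_sign = pd.DataFrame()

    manifest["counts"] = {
        "n_gwas_variants": int(len(gwas)),
        "n_expressed_genes": len(expressed_genes),
        "n_expressed_mirnas": len(expressed_mirnas),
        "n_mbsvs": int(len(mbsvs)),
        "n_pruned": int(len(kept)),
        "n_pruned_mbsvs": int(len(pruned_mbsvs)),
        "n_families": int(families["family"].nunique()) if len(families) else 0,
    }
    return PipelineResult(
        expressed_genes=expressed_genes, expressed_mirnas=expressed_mirnas,
        mbsvs=mbsvs, families=families, kept_variants=list(kept),
        classified=classified, enrichment_tests=enrichment_tests,
        acat_overall=acat_overall, acat_families=acat_families,
        effect_delta=effect_delta, effect_sign=effect_sign, manifest=manifest)


@dataclass
class RunConfig:
    """File-based run configuration for the CLI."""

    gwas: str
    sites: str
    gene_expression: str
    mirna_counts: str
    library_sizes: str
    mirna_tiers: str               # TSV: mirna, tier
    family_map: str
    gtex_eqtls: str
    psychencode_eqtls: str
    out_dir: str
    panel: str | None = None       # dosage TSV or .vcf
    masks_bed: str | None = None
    gene_units: str = "RPKM"
    seed: int = 0
    params: PipelineParams = field(default_factory=PipelineParams)


def validate_inputs(inputs: PipelineInputs) -> list[str]:
    """Report-only sanity checks on the loaded tables."""
    report = []
    gwas = inputs.gwas
    bad_p = ~gwas["p"].between(0, 1)
    for i in gwas.index[bad_p]:
        report.append(f"gwas row {i}: p={gwas.at[i, 'p']} outside [0, 1]")
    vids = io.variant_ids(gwas)
    for vid in vids[vids.duplicated()].unique():
        report.append(f"gwas: duplicated variant key {vid}")
    for col in ("ref", "alt"):
        bad = ~gwas[col].astype(str).str.fullmatch("[ACGT]+")
        for i in gwas.index[bad]:
            report.append(f"gwas row {i}: {col} allele {gwas.at[i, col]!r} not A/C/G/T")
    if (gwas["pos"] < 1).any():
        report.append("gwas: positions must be 1-based (>= 1)")
    same = gwas["ref"] == gwas["alt"]
    for i in gwas.index[same]:
        report.append(f"gwas row {i}: ref == alt")
    return report


def load_inputs(config: RunConfig) -> PipelineInputs:
    for name in ("gwas", "sites", "gene_expression", "mirna_counts", "library_sizes",
                 "mirna_tiers", "family_map", "gtex_eqtls", "psychencode_eqtls"):
        path = getattr(config, name)
        if not os.path.exists(path):
            raise FileNotFoundError(f"{name} file not found: {path}")
    tiers_df = io.read_tsv(config.mirna_tiers, ["mirna", "tier"])
    panel = None
    if config.panel:
        if not os.path.exists(config.panel):
            raise FileNotFoundError(f"panel file not found: {config.panel}")
        panel = (io.read_vcf_panel(config.panel) if config.panel.endswith(".vcf")
                 else io.read_dosage_panel(config.panel))
    masks = [io.MHC_HG19]
    if config.masks_bed:
        masks = io.read_bed_masks(config.masks_bed)
    return PipelineInputs(
        gwas=io.read_gwas(config.gwas),
        sites=io.read_site_scores(config.sites),
        gene_expression=io.read_expression(config.gene_expression),
        gene_units=config.gene_units,
        mirna_counts=io.read_expression(config.mirna_counts),
        library_sizes=io.read_library_sizes(config.library_sizes),
        mirna_tiers=dict(zip(tiers_df["mirna"], tiers_df["tier"])),
        family_map=io.read_family_map(config.family_map),
        gtex_eqtls=io.read_eqtls(config.gtex_eqtls),
        psychencode_eqtls=io.read_eqtls(config.psychencode_eqtls),
        panel=panel, masks=masks)


def run_pipeline(config: RunConfig) -> dict:
    """Load inputs, run all stages, write per-stage TSVs and a JSON manifest."""
    inputs = load_inputs(config)
    issues = validate_inputs(inputs)
    for msg in issues:
        logger.warning("input validation: %s", msg)
    result = run(inputs, config.params, seed=config.seed)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_tsv(result.mbsvs, out / "mbsvs.tsv")
    io.write_tsv(result.families, out / "mbsv_families.tsv")
    io.write_tsv(result.enrichment_tests, out / "enrichment_tests.tsv")
    io.write_tsv(result.acat_families, out / "acat_families.tsv")
    io.write_tsv(result.effect_delta, out / "effect_on_delta.tsv")
    io.write_tsv(result.effect_sign, out / "effect_on_sign.tsv")
    (out / "kept_variants.txt").write_text(
        "\n".join(result.kept_variants) + ("\n" if result.kept_variants else ""))
    overall = {
        cls: (None if res is None else
              {"t_acat": res.t_acat, "w_sum": res.w_sum, "p_acat": res.p_acat, "k": res.k})
        for cls, res in result.acat_overall.items()}
    manifest = dict(result.manifest)
    manifest["acat_overall"] = overall
    manifest["validation_issues"] = issues
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
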