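"""Aggregate p-value combination: weighted Cauchy (ACAT) and Stouffer's Z.

The Cauchy combination test turns each p-value into a Cauchy-tailed statistic
tan[(1/2 - p) * pi], averages the statistics with non-negative weights, and
maps the average back through the Cauchy CDF:

    T = sum_i w_i * tan[(1/2 - p_i) * pi]
    p_combined ~= 1/2 - arctan(T / sum_i w_i) / pi

Its tail is insensitive to dependence between the component p-values, which
is what makes it usable over LD-correlated variants without a correlation
model. Here the weights are the absolute difference scores |Δ| of the MBSVs,
so variants predicted to perturb binding more strongly count more.

Stouffer's weighted Z combines one-sided evidence across studies:

    Z_i = Phi^-1(1 - p_i),  Z_meta = sum_i w_i Z_i / sqrt(sum_i w_i^2)

with study sample sizes as weights, and p_meta = 1 - Phi(Z_meta).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_fdr

logger = logging.getLogger(__name__)

P_CLIP = 1e-15  # tan[(1/2 - p) pi] diverges at p = 0 and 1


@dataclass(frozen=True)
class AcatResult:
    t_acat: float
    w_sum: float
    p_acat: float
    k: int           # number of component p-values
    n_clipped: int = 0


@dataclass(frozen=True)
class MetaResult:
    z_meta: float
    p_meta: float
    k: int


def _clip_p(p: np.ndarray, eps: float) -> tuple[np.ndarray, int]:
    clipped = np.clip(p, eps, 1 - eps)
    n = int((clipped != p).sum())
    if n:
        logger.info("clipped %d p-values into [%.0e, 1-%.0e]", n, eps, eps)
    return clipped, n


def acat(p, weights=None, eps: float = P_CLIP) -> AcatResult:
    """Weighted Cauchy combination of p-values; equal weights when omitted."""
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any((p <= 0) | (p >= 1)):
        if np.any((p < 0) | (p > 1)):
            raise ValueError("p-values must lie in [0, 1]")
    w = np.ones_like(p) if weights is None else np.atleast_1d(np.asarray(weights, dtype=float))
    if w.shape != p.shape:
        raise ValueError("weights must match p-values in length")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    w_sum = float(w.sum())
    if w_sum == 0:
        raise ValueError("at least one weight must be positive")
    pc, n_clipped = _clip_p(p, eps)
    t = float(np.sum(w * np.tan((0.5 - pc) * np.pi)))
    p_acat = 0.5 - math.atan(t / w_sum) / math.pi
    return AcatResult(t_acat=t, w_sum=w_sum, p_acat=float(np.clip(p_acat, eps, 1 - eps)),
                      k=int(p.size), n_clipped=n_clipped)


#: The four variant classes tested per trait.
VARIANT_CLASSES = ("all", "gtex_any", "gtex_brain", "psychencode")


def acat_overall(mbsvs: pd.DataFrame) -> dict[str, AcatResult | None]:
    """One weighted ACAT per variant class (all MBSVs and each eQTL subset).

    ``mbsvs`` needs columns ``p`` (GWAS p-value), ``delta`` and the eQTL flag
    columns. Weights are |Δ|. An empty subset is reported as None (not
    testable).
    """
    if mbsvs["p"].isna().any():
        raise ValueError("every MBSV must carry a GWAS p-value")
    results: dict[str, AcatResult | None] = {}
    for cls in VARIANT_CLASSES:
        sub = mbsvs if cls == "all" else mbsvs[mbsvs[cls].astype(bool)]
        if len(sub) == 0:
            results[cls] = None
            continue
        results[cls] = acat(sub["p"].to_numpy(), np.abs(sub["delta"].to_numpy()))
    return results


def acat_by_family(
    mbsvs: pd.DataFrame,
    families: pd.DataFrame,
    m_tests: int | None = None,
) -> pd.DataFrame:
    """Weighted ACAT per (miRNA family, variant class), Bonferroni-adjusted.

    ``families`` is the long (variant_id, family) table; a variant belonging
    to several families contributes to each. ``m_tests`` is the Bonferroni
    denominator — the total number of ACAT tests across every trait and
    class in the run; it defaults to the number of tests performed here.
    Families with no members in a class are skipped (logged).
    """
    merged = families.merge(mbsvs, on="variant_id", how="left")
    if merged["p"].isna().any():
        missing = merged.loc[merged["p"].isna(), "variant_id"].unique()
        raise ValueError(f"family members missing from the MBSV table: {missing[:5]}")
    rows = []
    for family, grp in merged.groupby("family", sort=True):
        for cls in VARIANT_CLASSES:
            sub = grp if cls == "all" else grp[grp[cls].astype(bool)]
            if len(sub) == 0:
                logger.info("family %s has no members in class %s; skipped", family, cls)
                continue
            res = acat(sub["p"].to_numpy(), np.abs(sub["delta"].to_numpy()))
            rows.append({"family": family, "variant_class": cls, "k": res.k,
                         "t_acat": res.t_acat, "p_acat": res.p_acat})
    out = pd.DataFrame(rows)
    if len(out):
        m = m_tests if m_tests is not None else len(out)
        out["p_bonferroni"] = np.minimum(out["p_acat"] * m, 1.0)
        out["significant"] = out["p_bonferroni"] < 0.05
    return out


def stouffer_meta(p, weights) -> MetaResult:
    """Stouffer's weighted-Z meta-analysis of one-sided p-values.

    Weights are the study sample sizes; a single study returns its own p.
    """
    p = np.atleast_1d(np.asarray(p, dtype=float))
    w = np.atleast_1d(np.asarray(weights, dtype=float))
    if p.size == 0:
        raise ValueError("no studies to combine")
    if w.shape != p.shape:
        raise ValueError("weights must match p-values in length")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    pc, _ = _clip_p(p, P_CLIP)
    z = stats.norm.isf(pc)  # Phi^-1(1 - p)
    z_meta = float(np.sum(w * z) / math.sqrt(float(np.sum(w * w))))
    return MetaResult(z_meta=z_meta, p_meta=float(stats.norm.sf(z_meta)), k=int(p.size))


def meta_analyse_families(
    family_results: dict[str, pd.DataFrame],
    sample_sizes: dict[str, float],
) -> pd.DataFrame:
    """Stouffer meta-analysis of per-family ACAT p-values across traits.

    ``family_results`` maps trait -> the frame from :func:`acat_by_family`;
    ``sample_sizes`` maps trait -> GWAS N. Only (family, class) combinations
    present in every trait are combined.
    """
    traits = list(family_results)
    stacked = pd.concat(
        [df.assign(trait=t) for t, df in family_results.items()], ignore_index=True
    )
    rows = []
    for (family, cls), grp in stacked.groupby(["family", "variant_class"], sort=True):
        if set(grp["trait"]) != set(traits):
            continue
        grp = grp.set_index("trait").loc[traits]
        res = stouffer_meta(grp["p_acat"].to_numpy(),
                            [sample_sizes[t] for t in traits])
        rows.append({"family": family, "variant_class": cls,
                     "z_meta": res.z_meta, "p_meta": res.p_meta, "k": res.k})
    out = pd.DataFrame(rows)
    if len(out):
        out["q_meta"] = bh_fdr(out["p_meta"].to_numpy())
    return out


def bonferroni(p, m: int) -> np.ndarray:
    """Bonferroni adjustment: min(1, m * p)."""
    return np.minimum(np.asarray(p, dtype=float) * m, 1.0)
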