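"""Regression of GWAS effect sizes on MBSV difference scores.

Once a miRNA family shows an aggregate association, the natural follow-up is
whether the *direction* of the predicted binding change tracks the direction
of the trait effect. Effect sizes (log odds ratios or betas) are first
standardized to the alternate allele — the orientation in which difference
scores are defined — then regressed, within each family, on the difference
score Δ and separately on its sign.

Sign is coded -1/+1 so the intercept is the grand mean; the slope then equals
half the difference between the mean effect of loss-of-binding (Δ > 0) and
gain-of-binding (Δ < 0) variants. A negative sign-slope means a gain of
binding affinity for the alternate allele is associated with a more positive
(risk-increasing) effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .enrichment import bh_fdr

logger = logging.getLogger(__name__)


def orient_effects(effects, orientation) -> np.ndarray:
    """Standardize log-scale effects to the alternate allele.

    ``orientation`` holds "ref" or "alt" per entry: effects reported for the
    reference allele have their sign inverted; alt-oriented effects pass
    through unchanged.
    """
    effects = np.asarray(effects, dtype=float)
    orientation = np.asarray(orientation, dtype=object)
    bad = ~np.isin(orientation, ("ref", "alt"))
    if bad.any():
        raise ValueError(f"unknown orientation flags: {sorted(set(orientation[bad]))}")
    return np.where(orientation == "ref", -effects, effects)


@dataclass
class FamilyRegression:
    family: str
    n: int
    slope: float
    se: float
    p: float


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return float(model.params[1]), float(model.bse[1]), float(model.pvalues[1])


def regress_effect_on_delta(df: pd.DataFrame, min_members: int = 3) -> pd.DataFrame:
    """Per-family OLS of alt-oriented effect size on Δ, with BH FDR.

    ``df`` needs columns ``family``, ``delta`` and ``effect`` (alt-oriented).
    Families with fewer than ``min_members`` rows or without distinct Δ
    values are skipped (logged).
    """
    rows = []
    for family, grp in df.groupby("family", sort=True):
        if len(grp) < min_members:
            logger.info("family %s: only %d members; skipped", family, len(grp))
            continue
        deltas = grp["delta"].to_numpy(dtype=float)
        if np.all(deltas == deltas[0]):
            logger.info("family %s: constant difference score; skipped", family)
            continue
        slope, se, p = _ols_slope(deltas, grp["effect"].to_numpy(dtype=float))
        rows.append({"family": family, "n": len(grp), "slope": slope, "se": se, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def regress_effect_on_sign(df: pd.DataFrame, min_members: int = 3) -> pd.DataFrame:
    """Per-family OLS of alt-oriented effect size on sign(Δ) in {-1, +1}.

    Families whose members all share one sign of Δ are skipped; Δ = 0 cannot
    occur after the |Δ| >= 0.2 calling threshold.
    """
    rows = []
    for family, grp in df.groupby("family", sort=True):
        signs = np.sign(grp["delta"].to_numpy(dtype=float))
        if len(grp) < min_members or len(np.unique(signs)) < 2:
            logger.info("family %s: single-sign or too small; skipped", family)
            continue
        slope, se, p = _ols_slope(signs, grp["effect"].to_numpy(dtype=float))
        rows.append({"family": family, "n": len(grp), "slope": slope, "se": se, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def significant_families(family_acat: pd.DataFrame, variant_class: str = "all") -> set[str]:
    """Families eligible for effect regression: Bonferroni-significant ACAT."""
    if len(family_acat) == 0:
        return set()
    sub = family_acat[(family_acat["variant_class"] == variant_class)
                      & family_acat["significant"]]
    return set(sub["family"])
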