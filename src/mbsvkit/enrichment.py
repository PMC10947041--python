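"""Comparing MBSV association statistics against a background variant class.

The suite covers the distribution-level and threshold-level comparisons used
to ask whether MBSVs carry more GWAS signal than matched background variants:

* two-sample Kolmogorov-Smirnov tests on empirical CDFs,
* Fisher's exact test on 2x2 significance tables, with the conditional
  maximum-likelihood odds ratio,
* quantile regression of an outcome on the binary variant class, with
  bootstrap standard errors,
* Benjamini-Hochberg FDR across a battery of tests,
* a generic score-rank comparison (used for deleteriousness scores such as
  CADD, consumed as an external annotation table).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

P_FLOOR = 1e-300  # cap for -log10 transforms


def neglog10(p, floor: float = P_FLOOR) -> np.ndarray:
    """-log10(p) with p floored to avoid infinities at p = 0."""
    return -np.log10(np.maximum(np.asarray(p, dtype=float), floor))


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample K-S statistic D = sup|ECDF_x - ECDF_y| and asymptotic p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class FisherResult:
    p: float
    odds_ratio: float        # conditional MLE under the noncentral hypergeometric model
    sample_odds_ratio: float

    def __iter__(self):
        return iter((self.p, self.odds_ratio))


def fisher_exact(a: int, b: int, c: int, d: int,
                 with_odds_ratio: bool = True) -> FisherResult:
    """Two-sided Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    The two-sided p sums the probabilities of every table (with the observed
    margins) whose hypergeometric probability does not exceed the observed
    table's. Tie comparison is done in exact integer arithmetic, so the
    result matches the textbook definition with no floating-point fudge.
    The reported odds ratio is the conditional MLE (an iterative fit; skip it
    with ``with_odds_ratio=False`` when only p is needed); the sample
    cross-product ratio is carried alongside for transparency.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0 or c1 == 0 or c1 == n or r1 == 0 or r2 == 0:
        # a margin is empty: every admissible table is the observed one
        return FisherResult(1.0, math.nan, math.nan)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = [math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)]
    w_obs = weights[a - lo]
    total = math.comb(n, c1)
    p = float(Fraction(sum(w for w in weights if w <= w_obs), total))
    cmle = math.nan
    if with_odds_ratio:
        cmle = float(stats.contingency.odds_ratio(
            [[a, b], [c, d]], kind="conditional").statistic)
    sample = (a * d) / (b * c) if b * c > 0 else math.inf if a * d > 0 else math.nan
    return FisherResult(min(p, 1.0), cmle, float(sample))


@dataclass
class EnrichmentResult:
    threshold: float
    n_hits_1: int
    n_1: int
    n_hits_0: int
    n_0: int
    proportion_1: float
    proportion_0: float
    fisher: FisherResult


def threshold_enrichment(
    p_class1,
    p_class0,
    thresholds=(5e-8, 1e-5),
    table_style: str = "totals",
) -> list[EnrichmentResult]:
    """Fisher enrichment of small p-values in class 1 versus class 0.

    Significance is strict ``p < threshold``. ``table_style`` controls the
    second column of the 2x2 table handed to Fisher's test: ``"totals"``
    (default) tests hit counts against the full class sizes, the construction
    behind the published contingency statistics this package reproduces;
    ``"counts"`` uses the textbook hit/non-hit split.
    """
    if table_style not in ("totals", "counts"):
        raise ValueError("table_style must be 'totals' or 'counts'")
    p1 = np.asarray(p_class1, dtype=float)
    p0 = np.asarray(p_class0, dtype=float)
    out = []
    for t in thresholds:
        if not (0 < t < 1):
            raise ValueError(f"threshold {t} outside (0, 1)")
        a, c = int((p1 < t).sum()), int((p0 < t).sum())
        n1, n0 = p1.size, p0.size
        if table_style == "totals":
            fr = fisher_exact(a, n1, c, n0)
        else:
            fr = fisher_exact(a, n1 - a, c, n0 - c)
        out.append(EnrichmentResult(
            threshold=t, n_hits_1=a, n_1=n1, n_hits_0=c, n_0=n0,
            proportion_1=a / n1 if n1 else math.nan,
            proportion_0=c / n0 if n0 else math.nan,
            fisher=fr,
        ))
    return out


def _check_loss_quantile(v: np.ndarray, tau: float) -> float:
    """Sample tau-quantile as the smallest minimizer of the check loss.

    Equals the order statistic v_(ceil(n*tau)) (1-based); at integer n*tau the
    loss is flat on an interval and the lower endpoint is returned.
    """
    return float(np.quantile(v, tau, method="inverted_cdf"))


@dataclass
class QuantRegResult:
    tau: float
    coef: float
    se: float
    p: float
    n_boot: int
    n_redraws: int


def quantile_regression_binary(
    y,
    x,
    tau: float,
    n_boot: int = 200,
    seed: int | np.random.Generator = 0,
) -> QuantRegResult:
    """Quantile regression of ``y`` on a binary class indicator ``x``.

    With a single binary regressor the tau-quantile regression coefficient is
    the difference of within-group tau-quantiles, computed here directly as
    the check-loss minimizer. Standard errors come from ``n_boot`` paired
    bootstrap resamples of (y, x); a resample that loses one of the classes
    is redrawn (the count is reported). The p-value is a two-sided normal
    test of coef/se.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=bool)
    if not (0 < tau < 1):
        raise ValueError("tau must be in (0, 1)")
    if y.shape != x.shape:
        raise ValueError("y and x must be the same length")
    if not (x.any() and (~x).any()):
        raise ValueError("both classes must be represented")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    def coef_of(yy, xx):
        return _check_loss_quantile(yy[xx], tau) - _check_loss_quantile(yy[~xx], tau)

    coef = coef_of(y, x)
    n = y.size
    boots = np.empty(n_boot)
    redraws = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            xx = x[idx]
            if xx.any() and (~xx).any():
                break
            redraws += 1
        boots[b] = coef_of(y[idx], xx)
    se = float(boots.std(ddof=1))
    if se == 0:
        p = 1.0 if coef == 0 else 0.0
    else:
        p = float(2 * stats.norm.sf(abs(coef) / se))
    return QuantRegResult(tau=tau, coef=coef, se=se, p=p, n_boot=n_boot, n_redraws=redraws)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


@dataclass
class RankCompareResult:
    ranks: np.ndarray
    ks_d: float
    ks_p: float
    median_reg: QuantRegResult | None
    degenerate: bool = False


def rank_compare(scores, subset, n_boot: int = 200, seed=0) -> RankCompareResult:
    """Compare average ranks of an annotation score between a subset and the rest.

    Ranks are computed over the combined universe (average rank for ties),
    then passed to the K-S test and a median (tau = 0.5) regression on the
    subset indicator. If all scores are equal the comparison is degenerate
    and reported as null.
    """
    scores = np.asarray(scores, dtype=float)
    subset = np.asarray(subset, dtype=bool)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    ranks = stats.rankdata(scores, method="average")
    if np.all(scores == scores[0]):
        return RankCompareResult(ranks=ranks, ks_d=0.0, ks_p=1.0,
                                 median_reg=None, degenerate=True)
    d, p = ks_two_sample(ranks[subset], ranks[~subset])
    qr = quantile_regression_binary(ranks, subset, tau=0.5, n_boot=n_boot, seed=seed)
    return RankCompareResult(ranks=ranks, ks_d=d, ks_p=p, median_reg=qr)
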