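"""Expression normalization and tissue-expression filtering.

The MBSV pipeline restricts variants to genes and miRNAs that are actually
expressed in the reference tissue. Gene-level matrices arrive already
normalized (RPKM or NEV); miRNA matrices arrive as raw counts and are
converted to counts-per-million (CPM) against per-sample library sizes. An
entity counts as expressed when its value clears a minimum threshold in at
least a given fraction of samples (default three quarters).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: TargetScan annotation tiers treated as confidently annotated miRNAs.
CONFIDENT_MIRNA_TIERS = frozenset({
    "highly conserved",
    "conserved",
    "poorly conserved but confidently annotated",
})

#: The one tier that is excluded.
MISANNOTATED_TIER = "poorly conserved and possibly misannotated as a miRNA"

KNOWN_TIERS = CONFIDENT_MIRNA_TIERS | {MISANNOTATED_TIER}


@dataclass
class ExpressionMatrix:
    """Entity-by-sample expression values with a unit tag.

    ``library_sizes`` (total mapped reads per sample) is required only when
    ``units == "counts"``, where it enables CPM normalization.
    """

    values: pd.DataFrame
    units: str  # "counts", "CPM", "RPKM" or "NEV"
    library_sizes: pd.Series | None = None

    def __post_init__(self):
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.library_sizes is not None:
            missing = self.values.columns.difference(self.library_sizes.index)
            if len(missing):
                raise ValueError(f"samples without library sizes: {list(missing)[:5]}")

    @property
    def entities(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass(frozen=True)
class ExpressionFilterRule:
    """Expressed = value >= min_value in >= min_fraction of samples."""

    min_value: float
    min_fraction: float = 0.75
    unit: str = "RPKM"

    def __post_init__(self):
        if not (0 < self.min_fraction <= 1):
            raise ValueError("min_fraction must be in (0, 1]")
        if self.min_value < 0:
            raise ValueError("min_value must be >= 0")


def cpm_normalize(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Counts-per-million: each sample's counts divided by its library size in millions."""
    if counts.units != "counts":
        raise ValueError(f"cpm_normalize expects raw counts, got units={counts.units!r}")
    if counts.library_sizes is None:
        raise ValueError("cpm_normalize requires library sizes")
    libs = counts.library_sizes.reindex(counts.samples)
    if (libs <= 0).any() or libs.isna().any():
        raise ValueError("library sizes must be positive for every sample")
    cpm = counts.values / (libs / 1e6)
    return replace(counts, values=cpm, units="CPM", library_sizes=counts.library_sizes)


def min_cpm_threshold(min_count: float, library_sizes) -> float:
    """CPM threshold equivalent to ``min_count`` reads in the smallest library."""
    libs = np.asarray(library_sizes, dtype=float)
    if libs.size == 0:
        raise ValueError("library_sizes must be non-empty")
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    return float(min_count / (libs.min() / 1e6))


def filter_expressed(m: ExpressionMatrix, rule: ExpressionFilterRule,
                     sample_mask: pd.Index | list[str] | None = None) -> set[str]:
    """Entities expressed under ``rule``; both comparisons are inclusive (>=).

    ``sample_mask`` restricts the evaluation to a subset of samples, e.g. to
    apply an age cutoff decided upstream of this module.
    """
    if m.units != rule.unit:
        raise ValueError(f"unit mismatch: matrix is {m.units!r}, rule expects {rule.unit!r}")
    values = m.values if sample_mask is None else m.values.loc[:, list(sample_mask)]
    n = values.shape[1]
    if n == 0:
        raise ValueError("no samples to evaluate")
    frac_passing = (values >= rule.min_value).sum(axis=1) / n
    return set(values.index[frac_passing >= rule.min_fraction])


def filter_confident_mirnas(mirna_ids, annotation_tiers: dict[str, str]) -> set[str]:
    """Drop miRNAs whose annotation tier marks them as possibly misannotated."""
    kept = set()
    for mid in mirna_ids:
        tier = annotation_tiers.get(mid)
        if tier is None or tier not in KNOWN_TIERS:
            raise ValueError(f"unknown annotation tier for {mid!r}: {tier!r}")
        if tier in CONFIDENT_MIRNA_TIERS:
            kept.add(mid)
    return kept
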