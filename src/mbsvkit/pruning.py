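"""Windowed LD pruning with priority variants.

Reduces a set of variants to an approximately independent subset by removing
one member of every pair whose squared Pearson correlation of dosages (r²)
exceeds a threshold inside a sliding window of consecutive variants. Variants
flagged as priorities (here: called MBSVs) are preferentially retained, so a
priority variant is only ever removed in favour of another priority variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class PruneParams:
    """Pruning parameters: window/step in variant counts, r² and MAF cutoffs.

    Defaults correspond to a window of 50 variants advanced in steps of 5,
    r² > 0.1 triggering removal, and a MAF floor of 0.01.
    """

    window: int = 50
    step: int = 5
    r2_max: float = 0.1
    maf_min: float = 0.01
    unit: str = "variants"  # or "kb": window/step measured in kilobases

    def __post_init__(self):
        if self.step > self.window:
            raise ValueError("step must not exceed window")
        if not (0 < self.r2_max <= 1):
            raise ValueError("r2_max must be in (0, 1]")
        if not (0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must be in [0, 0.5)")
        if self.unit not in ("variants", "kb"):
            raise ValueError("unit must be 'variants' or 'kb'")


def allele_frequencies(panel: pd.DataFrame) -> pd.Series:
    """Minor allele frequency per variant from a samples-by-variants dosage frame."""
    af = panel.mean(axis=0) / 2.0
    return np.minimum(af, 1.0 - af)


def pairwise_r2(g_i, g_j) -> float:
    """Squared Pearson correlation of two dosage vectors.

    A constant vector has undefined correlation; it is treated as r² = 0
    (such variants carry no LD information) with a warning.
    """
    g_i = np.asarray(g_i, dtype=float)
    g_j = np.asarray(g_j, dtype=float)
    if g_i.shape != g_j.shape or g_i.ndim != 1 or g_i.size < 2:
        raise ValueError("dosage vectors must be 1-D, equal length >= 2")
    vi, vj = g_i.var(), g_j.var()
    if vi == 0 or vj == 0:
        warnings.warn("constant dosage vector: r^2 treated as 0", stacklevel=2)
        return 0.0
    cov = np.mean((g_i - g_i.mean()) * (g_j - g_j.mean()))
    return float(cov * cov / (vi * vj))


def _window_starts(n: int, window: int, step: int) -> range:
    if n <= window:
        return range(0, 1)
    return range(0, n - window + step, step)


def prune(
    panel: pd.DataFrame,
    params: PruneParams,
    priority: pd.Series | None = None,
    positions: pd.DataFrame | None = None,
) -> list[str]:
    """Greedy windowed pruning; returns the kept variant ids in panel order.

    ``panel`` is samples-by-variants with dosages in {0,1,2}, columns ordered
    by (chromosome, position). ``priority`` is a boolean Series over the same
    variants. ``positions`` (columns ``chrom``/``pos`` indexed by variant id)
    confines windows to single chromosomes and enables kb-unit windows; when
    omitted, chromosome/position are parsed from ``chrom:pos:ref:alt`` ids.

    Within each window, while any surviving pair exceeds ``r2_max``, the pair
    with the largest r² is resolved by removing the non-priority member; with
    equal priority the lower-MAF member goes, and on a MAF tie the later
    variant. After the pass, no two kept variants that ever shared a window
    have r² above the threshold.
    """
    variants = list(panel.columns)
    if priority is None:
        priority = pd.Series(False, index=panel.columns)
    if not priority.index.equals(panel.columns):
        raise ValueError("priority flags misaligned with panel variants")
    if positions is None:
        parts = [v.split(":") for v in variants]
        positions = pd.DataFrame(
            {"chrom": [p[0] for p in parts], "pos": [int(p[1]) for p in parts]},
            index=variants,
        )
    maf = allele_frequencies(panel)
    alive: dict[str, bool] = {v: maf[v] >= params.maf_min for v in variants}

    dos = panel.to_numpy(dtype=float)
    col = {v: i for i, v in enumerate(variants)}

    for chrom, group in positions.groupby("chrom", sort=False):
        chrom_variants = [v for v in group.index if v in col]
        if params.unit == "kb":
            windows = _kb_windows(group, chrom_variants, params)
        else:
            windows = [
                chrom_variants[s:s + params.window]
                for s in _window_starts(len(chrom_variants), params.window, params.step)
            ]
        for win in windows:
            _resolve_window(win, alive, dos, col, maf, priority, params.r2_max)

    return [v for v in variants if alive[v]]


def _kb_windows(group: pd.DataFrame, chrom_variants: list[str], params: PruneParams):
    pos = group["pos"]
    start = int(pos.min())
    stop = int(pos.max())
    w, s = int(params.window * 1000), int(params.step * 1000)
    out = []
    for lo in range(start, stop + 1, s):
        members = [v for v in chrom_variants if lo <= pos[v] < lo + w]
        if members:
            out.append(members)
    return out


def _resolve_window(win, alive, dos, col, maf, priority, r2_max):
    live = [v for v in win if alive[v]]
    if len(live) < 2:
        return
    idx = [col[v] for v in live]
    sub = dos[:, idx]
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(sub, rowvar=False)
    r2 = np.nan_to_num(r * r, nan=0.0)
    np.fill_diagonal(r2, 0.0)
    local_alive = np.ones(len(live), dtype=bool)
    while True:
        masked = np.where(np.outer(local_alive, local_alive), r2, 0.0)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= r2_max:
            break
        vi, vj = live[i], live[j]
        drop = _choose_removal(vi, vj, maf, priority)
        k = live.index(drop)
        local_alive[k] = False
        alive[drop] = False


def _choose_removal(vi: str, vj: str, maf, priority) -> str:
    pi, pj = bool(priority[vi]), bool(priority[vj])
    if pi != pj:
        return vj if pj is False else vi
    if maf[vi] != maf[vj]:
        return vi if maf[vi] < maf[vj] else vj
    return vj  # later position loses on a full tie
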