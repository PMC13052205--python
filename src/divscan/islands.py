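"""Empirical outlier windows, merged divergence regions and core islands.

A "genomic island of differentiation" here is a run of top-ranked windows:
the empirical top 1% of windows by a statistic is flagged, flagged windows
closer than a merge gap are unioned into regions, and windows flagged for BOTH
Fst and Dxy (intersected at the window level, then merged) form the core
islands — the conservative set robust to low within-population diversity
inflating Fst alone.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .formats import GeneRecord, GenomicInterval
from .windows import Window

logger = logging.getLogger(__name__)


@dataclass
class OutlierRegion:
    interval: GenomicInterval
    source: str  # "fst" | "dxy" | "core"
    members: list[int]  # window indices
    max_value: float
    mean_value: float
    genes: list[str] = field(default_factory=list)


def empirical_top_fraction(
    values, fraction: float = 0.01
) -> tuple[np.ndarray, float]:
    """Flag the ceil(fraction * W) highest defined values; boundary ties all in.

    Returns (flagged index array into ``values``, realized threshold). NaN
    values (undefined windows) are excluded before ranking.
    """
    if not (0 < fraction < 1):
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    values = np.asarray(values, dtype=float)
    defined = np.flatnonzero(np.isfinite(values))
    if defined.size == 0:
        raise ValueError("no defined values to rank")
    vals = values[defined]
    k = math.ceil(fraction * vals.size)
    threshold = float(np.sort(vals)[::-1][k - 1])
    if np.all(vals == vals[0]):
        logger.warning("all %d values equal (%g): flagging every window", vals.size, vals[0])
    flagged = defined[vals >= threshold]
    return flagged, threshold


def _merge_sorted(
    intervals: list[tuple[str, int, int, int]], max_gap: int
) -> list[tuple[str, int, int, list[int]]]:
    """Union intervals (chrom, start, end, id) whose gap is <= max_gap."""
    out: list[tuple[str, int, int, list[int]]] = []
    for chrom, start, end, wid in sorted(intervals, key=lambda t: (t[0], t[1], t[2])):
        if out and out[-1][0] == chrom and start - out[-1][2] <= max_gap:
            prev = out[-1]
            out[-1] = (chrom, prev[1], max(prev[2], end), prev[3] + [wid])
        else:
            out.append((chrom, start, end, [wid]))
    return out


def merge_outlier_windows(
    windows: list[Window],
    flagged: np.ndarray,
    values,
    max_gap: int = 10_000,
    source: str = "fst",
) -> list[OutlierRegion]:
    """Merge flagged windows whose inter-window gap is <= max_gap (overlap included).

    Output regions are disjoint and pairwise separated by more than max_gap;
    their union covers the union of the flagged windows. Input order does not
    matter. Empty input yields an empty list.
    """
    values = np.asarray(values, dtype=float)
    by_index = {w.index: w for w in windows}
    items = [
        (by_index[i].interval.chrom, by_index[i].interval.start, by_index[i].interval.end, int(i))
        for i in np.asarray(flagged, dtype=int)
    ]
    regions = []
    for chrom, start, end, members in _merge_sorted(items, max_gap):
        stat = values[members]
        regions.append(
            OutlierRegion(
                interval=GenomicInterval(chrom, start, end),
                source=source,
                members=sorted(members),
                max_value=float(np.nanmax(stat)),
                mean_value=float(np.nanmean(stat)),
            )
        )
    return regions


def core_islands(
    fst_flags: np.ndarray,
    dxy_flags: np.ndarray,
    windows: list[Window],
    values=None,
    max_gap: int = 10_000,
) -> list[OutlierRegion]:
    """Windows flagged in BOTH statistics, merged with the same gap rule.

    ``values`` (optional, per-window) annotates the merged regions; defaults
    to zeros. Both flag sets must index the same window list.
    """
    indices = {w.index for w in windows}
    for flags, name in ((fst_flags, "fst"), (dxy_flags, "dxy")):
        stray = set(np.asarray(flags, dtype=int)) - indices
        if stray:
            raise ValueError(f"{name} flags reference unknown windows {sorted(stray)}")
    core = np.array(sorted(set(map(int, fst_flags)) & set(map(int, dxy_flags))), dtype=int)
    if values is None:
        values = np.zeros(max(indices) + 1 if indices else 0)
    return merge_outlier_windows(windows, core, values, max_gap=max_gap, source="core")


def regions_cover_subset(inner: list[OutlierRegion], outer: list[OutlierRegion]) -> bool:
    """True iff the genomic cover of ``inner`` is contained in that of ``outer``."""
    tree: dict[str, IntervalTree] = {}
    for r in outer:
        tree.setdefault(r.interval.chrom, IntervalTree()).addi(
            r.interval.start, r.interval.end
        )
    for t in tree.values():
        t.merge_overlaps()
    for r in inner:
        t = tree.get(r.interval.chrom)
        if t is None:
            return False
        hits = sorted(t.overlap(r.interval.start, r.interval.end))
        covered = r.interval.start
        for h in hits:
            if h.begin > covered:
                return False
            covered = max(covered, h.end)
        if covered < r.interval.end:
            return False
    return True


def genes_in_regions(
    regions: list[OutlierRegion] | list[GenomicInterval],
    genes: list[GeneRecord],
) -> tuple[list[list[str]], list[str]]:
    """Assign genes overlapping each region by >= 1 bp (half-open semantics).

    Returns (per-region gene-id lists, deduplicated union preserving first-seen
    order). ``regions`` may be OutlierRegions (annotated in place) or bare
    intervals.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.interval.chrom, IntervalTree()).addi(
            g.interval.start, g.interval.end, g.gene_id
        )
    per_region: list[list[str]] = []
    union: list[str] = []
    seen: set[str] = set()
    for region in regions:
        interval = region.interval if isinstance(region, OutlierRegion) else region
        tree = trees.get(interval.chrom)
        hits = (
            sorted(tree.overlap(interval.start, interval.end), key=lambda h: (h.begin, h.data))
            if tree is not None
            else []
        )
        ids = [h.data for h in hits]
        per_region.append(ids)
        if isinstance(region, OutlierRegion):
            region.genes = ids
        for gid in ids:
            if gid not in seen:
                seen.add(gid)
                union.append(gid)
    return per_region, union


def regions_frame(regions: list[OutlierRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.interval.chrom for r in regions],
            "start": [r.interval.start for r in regions],
            "end": [r.interval.end for r in regions],
            "source": [r.source for r in regions],
            "n_windows": [len(r.members) for r in regions],
            "max_value": [r.max_value for r in regions],
            "mean_value": [r.mean_value for r in regions],
            "genes": [",".join(r.genes) for r in regions],
        }
    )
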