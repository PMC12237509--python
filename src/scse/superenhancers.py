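"""ROSE-style super-enhancer calling from cell-type-split fragments.

Candidate enhancers are stitched when their gap is at most the
species-specific stitch distance (12.5 kb human/mouse, 2 kb fly), each
stitched region's signal is the summed support count of the fragments
overlapping it, regions are ranked ascending by signal, and the cutoff
is the slope-1 tangent of the min-max-scaled rank curve (the point
minimising scaled_y - scaled_x).  Regions strictly above the cutoff
signal are true super-enhancers; only those intersecting a typical
enhancer are retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .intervals import FragmentIndex, overlaps_any
from .io import FragmentRecord, GenomicInterval

__all__ = ["StitchedRegion", "RankCurve", "SuperEnhancerCall",
           "STITCH_DISTANCES", "stitch", "region_signal", "rank_and_cutoff",
           "classify", "intersect_with_consensus", "call_superenhancers"]

#: Default stitch distances (bp) per species.
STITCH_DISTANCES = {"human": 12_500, "mouse": 12_500, "fly": 2_000}


@dataclass
class StitchedRegion:
    interval: GenomicInterval
    members: list[GenomicInterval]
    total_signal: float = 0.0


@dataclass
class RankCurve:
    signals: np.ndarray        # ascending
    scaled_x: np.ndarray
    scaled_y: np.ndarray
    cutoff_index: int          # 1-based rank of the tangent point
    cutoff_signal: float


@dataclass
class SuperEnhancerCall:
    region: StitchedRegion
    rank: int
    is_super: bool
    retained: bool = False


def stitch(candidates: Iterable[GenomicInterval], d: int
           ) -> list[StitchedRegion]:
    """Merge candidates whose gap (next.start - current.end) is <= d.

    Overlapping or abutting candidates (gap <= 0) always merge; a
    candidate with no neighbour within ``d`` becomes a singleton region.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in candidates:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    regions: list[StitchedRegion] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        members = [ivs[0]]
        cur_end = ivs[0].end
        for iv in ivs[1:]:
            if iv.start - cur_end <= d:
                members.append(iv)
                cur_end = max(cur_end, iv.end)
            else:
                span = GenomicInterval(chrom, members[0].start, cur_end)
                regions.append(StitchedRegion(span, members))
                members = [iv]
                cur_end = iv.end
        span = GenomicInterval(chrom, members[0].start, cur_end)
        regions.append(StitchedRegion(span, members))
    return regions


def region_signal(region: StitchedRegion | GenomicInterval,
                  fragments: Iterable[FragmentRecord] | FragmentIndex,
                  barcodes: set[str] | Sequence[str]) -> float:
    """Integrated signal: summed ``count`` of fragments from the given
    barcodes overlapping the region by >= 1 bp."""
    barcodes = set(barcodes)
    if not barcodes:
        raise ValueError("empty barcode set")
    iv = region.interval if isinstance(region, StitchedRegion) else region
    index = (fragments if isinstance(fragments, FragmentIndex)
             else FragmentIndex(fragments, sorted(barcodes)))
    per_cell = index.count_in_region(iv.chrom, iv.start, iv.end, per_cell=True)
    keep = np.array([b in barcodes for b in index.barcodes])
    return float(per_cell[keep].sum())


def rank_and_cutoff(signals: Sequence[float]) -> RankCurve:
    """Slope-1 tangent cutoff on the ascending min-max-scaled rank curve.

    ``cutoff_index`` is the 1-based rank minimising scaled_y - scaled_x
    (ties broken toward the largest index, the most stringent choice).
    A flat curve (all signals equal) degenerates to cutoff at the top:
    no region is classified super.
    """
    s = np.sort(np.asarray(signals, dtype=float))
    n = s.size
    if n < 2:
        raise ValueError("need at least two signals")
    if (s < 0).any():
        raise ValueError("signals must be nonnegative")
    x = np.arange(n, dtype=float) / (n - 1)
    rng = s[-1] - s[0]
    y = (s - s[0]) / rng if rng > 0 else np.zeros(n)
    diff = y - x
    # argmin with ties to the largest index
    cutoff_index = int(n - 1 - np.argmin(diff[::-1])) + 1
    return RankCurve(s, x, y, cutoff_index, float(s[cutoff_index - 1]))


def classify(regions: Sequence[StitchedRegion], curve: RankCurve
             ) -> list[SuperEnhancerCall]:
    """True super-enhancer iff total_signal strictly exceeds the cutoff."""
    order = np.argsort([r.total_signal for r in regions], kind="stable")
    ranks = np.empty(len(regions), dtype=int)
    ranks[order] = np.arange(1, len(regions) + 1)
    return [SuperEnhancerCall(r, int(ranks[i]),
                              r.total_signal > curve.cutoff_signal)
            for i, r in enumerate(regions)]


def intersect_with_consensus(calls: Sequence[SuperEnhancerCall],
                             typical_enhancers: Sequence[GenomicInterval]
                             ) -> list[SuperEnhancerCall]:
    """Retain only true SEs overlapping >= 1 bp with a typical enhancer."""
    spans = [c.region.interval for c in calls]
    hits = (overlaps_any(spans, typical_enhancers)
            if len(typical_enhancers) else np.zeros(len(calls), dtype=bool))
    for c, hit in zip(calls, hits):
        c.retained = bool(c.is_super and hit)
    return list(calls)


def call_superenhancers(candidates: Sequence[GenomicInterval],
                        fragments: Iterable[FragmentRecord] | FragmentIndex,
                        barcodes: Sequence[str],
                        stitch_distance: int = 12_500,
                        typical_enhancers: Sequence[GenomicInterval] = (),
                        tss_exclusion: Sequence[GenomicInterval] = (),
                        ) -> tuple[list[SuperEnhancerCall], RankCurve]:
    """Full SE pipeline on one cell type's candidates and fragments.

    ``tss_exclusion`` optionally removes candidates overlapping the given
    windows before stitching (off by default).
    """
    if tss_exclusion:
        keep = ~overlaps_any(candidates, tss_exclusion)
        candidates = [c for c, k in zip(candidates, keep) if k]
    regions = stitch(candidates, stitch_distance)
    index = (fragments if isinstance(fragments, FragmentIndex)
             else FragmentIndex(fragments, sorted(set(barcodes))))
    bc = set(barcodes)
    keep_mask = np.array([b in bc for b in index.barcodes])
    for r in regions:
        per_cell = index.count_in_region(r.interval.chrom, r.interval.start,
                                         r.interval.end, per_cell=True)
        r.total_signal = float(per_cell[keep_mask].sum())
    curve = rank_and_cutoff([r.total_signal for r in regions])
    calls = classify(regions, curve)
    return intersect_with_consensus(calls, typical_enhancers), curve
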