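"""Interval arithmetic shared across modules.

Everything operates on half-open ``[start, end)`` coordinates.  Fragment
overlap counting is done with sorted numpy arrays rather than per-record
Python loops so that shuffle-null replicates and per-region signal
integration stay cheap.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .io import FragmentRecord, GenomicInterval

__all__ = ["merge_intervals", "overlaps_any", "overlap_pairs", "FragmentIndex"]


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or abutting intervals into maximal regions."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


def overlaps_any(queries: Sequence[GenomicInterval],
                 regions: Iterable[GenomicInterval],
                 min_bp: int = 1) -> np.ndarray:
    """Boolean mask: does each query overlap any region by >= min_bp bp?

    Regions are merged internally, so the test is a binary search per query.
    ``min_bp`` > 1 is evaluated against the merged regions.
    """
    merged = merge_intervals(regions) if regions else []
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom in {m.chrom for m in merged}:
        chrom_ivs = [m for m in merged if m.chrom == chrom]
        starts[chrom] = np.array([m.start for m in chrom_ivs])
        ends[chrom] = np.array([m.end for m in chrom_ivs])
    mask = np.zeros(len(queries), dtype=bool)
    for i, q in enumerate(queries):
        if q.chrom not in starts:
            continue
        s, e = starts[q.chrom], ends[q.chrom]
        # candidate regions with start < q.end and end > q.start
        lo = int(np.searchsorted(e, q.start, side="right"))
        hi = int(np.searchsorted(s, q.end, side="left"))
        for j in range(lo, hi):
            if min(e[j], q.end) - max(s[j], q.start) >= min_bp:
                mask[i] = True
                break
    return mask


def overlap_pairs(query: Sequence[GenomicInterval],
                  reference: Sequence[GenomicInterval],
                  min_bp: int = 1) -> list[tuple[int, int]]:
    """All (query index, reference index) pairs overlapping by >= min_bp bp."""
    ref_by_chrom: dict[str, list[int]] = {}
    for j, r in enumerate(reference):
        ref_by_chrom.setdefault(r.chrom, []).append(j)
    pairs: list[tuple[int, int]] = []
    for chrom, idxs in ref_by_chrom.items():
        idxs = sorted(idxs, key=lambda j: reference[j].start)
        r_start = np.array([reference[j].start for j in idxs])
        r_end = np.array([reference[j].end for j in idxs])
        for i, q in enumerate(query):
            if q.chrom != chrom:
                continue
            hi = int(np.searchsorted(r_start, q.end, side="left"))
            for pos in range(hi):
                j = idxs[pos]
                if min(r_end[pos], q.end) - max(r_start[pos], q.start) >= min_bp:
                    pairs.append((i, j))
    pairs.sort()
    return pairs


class FragmentIndex:
    """Per-chromosome sorted arrays of fragments for fast overlap counting."""

    def __init__(self, fragments: Iterable[FragmentRecord],
                 barcodes: Sequence[str] | None = None) -> None:
        chroms: dict[str, list[tuple[int, int, int, int]]] = {}
        if barcodes is not None:
            bc_index = {b: i for i, b in enumerate(barcodes)}
        else:
            bc_index = {}
        self._dynamic = barcodes is None
        total = 0
        for fr in fragments:
            if fr.barcode not in bc_index:
                if not self._dynamic:
                    continue  # fragments from cells outside the matrix
                bc_index[fr.barcode] = len(bc_index)
            chroms.setdefault(fr.chrom, []).append(
                (fr.start, fr.end, bc_index[fr.barcode], fr.count))
            total += 1
        self.barcodes = [b for b, _ in sorted(bc_index.items(), key=lambda kv: kv[1])]
        self.n_cells = len(bc_index)
        self.n_fragments = total
        self._chrom: dict[str, tuple[np.ndarray, ...]] = {}
        self.max_length = 0
        for chrom, rows in chroms.items():
            arr = np.array(rows, dtype=np.int64)
            order = np.argsort(arr[:, 0], kind="stable")
            arr = arr[order]
            self._chrom[chrom] = (arr[:, 0].copy(), arr[:, 1].copy(),
                                  arr[:, 2].copy(), arr[:, 3].copy())
            if len(arr):
                self.max_length = max(self.max_length,
                                      int((arr[:, 1] - arr[:, 0]).max()))

    def count_in_region(self, chrom: str, start: int, end: int,
                        per_cell: bool = False):
        """Total (or per-cell) fragment ``count`` overlapping [start, end)."""
        if chrom not in self._chrom:
            return np.zeros(self.n_cells, dtype=np.int64) if per_cell else 0
        s, e, cell, cnt = self._chrom[chrom]
        lo = int(np.searchsorted(s, start - self.max_length, side="left"))
        hi = int(np.searchsorted(s, end, side="left"))
        sl = slice(lo, hi)
        keep = e[sl] > start
        if per_cell:
            out = np.zeros(self.n_cells, dtype=np.int64)
            np.add.at(out, cell[sl][keep], cnt[sl][keep])
            return out
        return int(cnt[sl][keep].sum())

    def count_matrix(self, intervals: Sequence[GenomicInterval]) -> np.ndarray:
        """Dense (len(intervals) x n_cells) overlap-count matrix."""
        out = np.zeros((len(intervals), self.n_cells), dtype=np.int64)
        for i, iv in enumerate(intervals):
            out[i] = self.count_in_region(iv.chrom, iv.start, iv.end,
                                          per_cell=True)
        return out
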