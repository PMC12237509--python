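"""Quality filters on the peak-by-cell matrix and cell-type splitting.

Filters are applied cells-first, then peaks; thresholds are strict
("fewer than"), so a cell with exactly ``min_peaks`` nonzero peaks
survives.  Splitting keeps only cell types with at least
``min_cells_per_type`` cells and drops all-zero peaks within each
sub-population.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import PeakByCellMatrix

__all__ = [
    "QCReport",
    "DEFAULT_UNCOMMON_CHROM_PATTERNS",
    "filter_cells_min_peaks",
    "filter_peaks",
    "split_by_cell_type",
    "preprocess_matrix",
]

#: Mitochondrial, scaffold, random, alt and unplaced contig name patterns.
DEFAULT_UNCOMMON_CHROM_PATTERNS = (
    r"^(chr)?M(T)?$",
    r"_random$",
    r"_alt$",
    r"^chrUn",
    r"scaffold",
    r"^GL\d",
    r"^KI\d",
)


class EmptyResultError(ValueError):
    """All cells / peaks / cell types were removed by a filter."""


@dataclass
class QCReport:
    n_cells_in: int = 0
    n_cells_out: int = 0
    n_peaks_in: int = 0
    n_peaks_out: int = 0
    n_cell_types_in: int = 0
    n_cell_types_out: int = 0
    removed: dict[str, int] = field(default_factory=dict)

    def record(self, filter_name: str, n_removed: int) -> None:
        self.removed[filter_name] = self.removed.get(filter_name, 0) + n_removed


def filter_cells_min_peaks(matrix: PeakByCellMatrix, min_peaks: int = 200,
                           report: QCReport | None = None) -> PeakByCellMatrix:
    """Drop cells with fewer than ``min_peaks`` peaks carrying signal."""
    per_cell = matrix.peaks_per_cell()
    keep = per_cell >= min_peaks
    if report is not None:
        report.record("cells_min_peaks", int((~keep).sum()))
    if not keep.any():
        raise EmptyResultError(
            f"all {matrix.n_cells} cells have fewer than {min_peaks} peaks"
        )
    if keep.all():
        return matrix
    return matrix.subset(cell_idx=np.flatnonzero(keep))


def filter_peaks(matrix: PeakByCellMatrix, min_cells: int = 10,
                 uncommon_chrom_patterns=DEFAULT_UNCOMMON_CHROM_PATTERNS,
                 report: QCReport | None = None) -> PeakByCellMatrix:
    """Drop peaks supported by fewer than ``min_cells`` cells and peaks on
    uncommon chromosomes (mitochondrial / scaffold / random / alt names)."""
    support = matrix.cells_per_peak()
    keep = support >= min_cells
    n_low = int((~keep).sum())
    regexes = [re.compile(p) for p in uncommon_chrom_patterns]
    uncommon = np.array(
        [any(rx.search(p.chrom) for rx in regexes) for p in matrix.peaks]
    )
    if report is not None:
        report.record("peaks_min_cells", n_low)
        report.record("peaks_uncommon_chrom", int((uncommon & keep).sum()))
    keep &= ~uncommon
    if not keep.any():
        warnings.warn("peak filter removed every peak")
    if keep.all():
        return matrix
    return matrix.subset(peak_idx=np.flatnonzero(keep))


def split_by_cell_type(matrix: PeakByCellMatrix,
                       min_cells_per_type: int = 100,
                       report: QCReport | None = None
                       ) -> dict[str, PeakByCellMatrix]:
    """One sub-matrix per cell type with >= ``min_cells_per_type`` cells.

    Within each sub-population, peaks with no signal across all its cells
    are dropped.  Unlabeled cells are excluded with a warning.
    """
    unlabeled = [b for b in matrix.barcodes if b not in matrix.labels]
    if unlabeled:
        warnings.warn(f"{len(unlabeled)} barcodes have no cell-type label; "
                      "excluded from the split")
    by_type: dict[str, list[int]] = {}
    for j, b in enumerate(matrix.barcodes):
        if b in matrix.labels:
            by_type.setdefault(matrix.labels[b], []).append(j)
    if report is not None:
        report.n_cell_types_in = len(by_type)
    out: dict[str, PeakByCellMatrix] = {}
    for ctype in sorted(by_type):
        idx = by_type[ctype]
        if len(idx) < min_cells_per_type:
            continue
        sub = matrix.subset(cell_idx=np.array(idx))
        nonzero = np.flatnonzero(sub.cells_per_peak() > 0)
        out[ctype] = sub.subset(peak_idx=nonzero)
    if report is not None:
        report.n_cell_types_out = len(out)
    if not out:
        raise EmptyResultError(
            f"no cell type has >= {min_cells_per_type} cells "
            f"(sizes: { {t: len(v) for t, v in by_type.items()} })"
        )
    return out


def preprocess_matrix(matrix: PeakByCellMatrix, min_peaks: int = 200,
                      min_cells_per_peak: int = 10,
                      min_cells_per_type: int = 100,
                      uncommon_chrom_patterns=DEFAULT_UNCOMMON_CHROM_PATTERNS,
                      ) -> tuple[dict[str, PeakByCellMatrix], QCReport]:
    """Full preprocessing: cell filter, peak filter, cell-type split."""
    report = QCReport(n_cells_in=matrix.n_cells, n_peaks_in=matrix.n_peaks)
    m = filter_cells_min_peaks(matrix, min_peaks, report)
    m = filter_peaks(m, min_cells_per_peak, uncommon_chrom_patterns, report)
    report.n_cells_out = m.n_cells
    report.n_peaks_out = m.n_peaks
    split = split_by_cell_type(m, min_cells_per_type, report)
    return split, report
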