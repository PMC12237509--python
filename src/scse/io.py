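"""Readers and writers for the external formats the pipeline touches.

All coordinates are 0-based half-open ``[start, end)`` throughout the
package.  GTF input (1-based inclusive) is converted on read and back on
write.  Chromosome names are used verbatim; no ``chr`` normalisation is
applied.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp

__all__ = [
    "GenomicInterval",
    "FragmentRecord",
    "PeakByCellMatrix",
    "GeneModel",
    "FormatError",
    "read_fragments",
    "write_fragments",
    "read_peak_matrix",
    "write_peak_matrix",
    "read_narrowpeak",
    "read_bed",
    "write_bed",
    "read_gene_models",
    "write_gene_models",
    "read_labels",
    "write_labels",
    "promoter_window",
]


class FormatError(ValueError):
    """Raised for malformed or inconsistent input files."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    name: str = ""
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def overlaps(self, other: "GenomicInterval", min_bp: int = 1) -> bool:
        if self.chrom != other.chrom:
            return False
        return min(self.end, other.end) - max(self.start, other.start) >= min_bp


@dataclass(frozen=True)
class FragmentRecord:
    """One sequenced Tn5 fragment with its cell barcode and support count."""

    chrom: str
    start: int
    end: int
    barcode: str
    count: int = 1

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted fragment {self.chrom}:{self.start}-{self.end}"
            )
        if self.count < 1:
            raise ValueError(f"fragment count must be >= 1, got {self.count}")


@dataclass
class GeneModel:
    """A gene with orientation-aware TSS/TES and exon structure.

    ``tss`` is the transcription start site in genome coordinates: for a
    ``+`` strand gene it is the smaller coordinate of the span, for a ``-``
    strand gene the larger one (upstream extends rightward).
    """

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    tss: int
    tes: int
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.strand == "+" and not self.tss < self.tes:
            raise ValueError(f"gene {self.gene_id}: + strand requires tss < tes")
        if self.strand == "-" and not self.tss > self.tes:
            raise ValueError(f"gene {self.gene_id}: - strand requires tss > tes")

    @property
    def span(self) -> GenomicInterval:
        lo, hi = min(self.tss, self.tes), max(self.tss, self.tes)
        return GenomicInterval(self.chrom, lo, hi, name=self.gene_id,
                               strand=self.strand)


def promoter_window(gene: GeneModel, upstream: int = 2000,
                    downstream: int = 100) -> GenomicInterval:
    """Strand-aware promoter window around the TSS.

    For a ``+`` strand gene this is ``[TSS - upstream, TSS + downstream)``;
    for a ``-`` strand gene the window mirrors rightward.
    """
    if gene.strand == "+":
        lo, hi = gene.tss - upstream, gene.tss + downstream
    else:
        lo, hi = gene.tss - downstream, gene.tss + upstream
    return GenomicInterval(gene.chrom, max(0, lo), hi, name=gene.gene_id,
                           strand=gene.strand)


class PeakByCellMatrix:
    """Sparse nonnegative fragment counts per peak per cell.

    Peaks are kept sorted by ``(chrom, start, end)``; the count matrix rows
    are permuted accordingly on construction.
    """

    def __init__(
        self,
        peaks: Sequence[GenomicInterval],
        barcodes: Sequence[str],
        counts,
        labels: dict[str, str] | None = None,
    ) -> None:
        counts = sp.csr_matrix(counts)
        if counts.shape != (len(peaks), len(barcodes)):
            raise FormatError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(peaks)} peaks x {len(barcodes)} barcodes"
            )
        if len(set(barcodes)) != len(barcodes):
            raise FormatError("barcodes are not unique")
        if counts.nnz and counts.data.min() < 0:
            raise FormatError("negative counts in matrix")
        order = sorted(range(len(peaks)),
                       key=lambda i: (peaks[i].chrom, peaks[i].start, peaks[i].end))
        if order != list(range(len(peaks))):
            peaks = [peaks[i] for i in order]
            counts = counts[order]
        self.peaks: list[GenomicInterval] = list(peaks)
        self.barcodes: list[str] = list(barcodes)
        self.counts: sp.csr_matrix = counts.astype(np.int64)
        self.labels: dict[str, str] = dict(labels or {})

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def subset(self, peak_idx=None, cell_idx=None) -> "PeakByCellMatrix":
        peak_idx = np.arange(self.n_peaks) if peak_idx is None else np.asarray(peak_idx)
        cell_idx = np.arange(self.n_cells) if cell_idx is None else np.asarray(cell_idx)
        peaks = [self.peaks[i] for i in peak_idx]
        barcodes = [self.barcodes[j] for j in cell_idx]
        counts = self.counts[peak_idx][:, cell_idx]
        labels = {b: self.labels[b] for b in barcodes if b in self.labels}
        return PeakByCellMatrix(peaks, barcodes, counts, labels)

    def cells_per_peak(self) -> np.ndarray:
        """Number of cells with a nonzero count, per peak."""
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()

    def peaks_per_cell(self) -> np.ndarray:
        """Number of peaks with a nonzero count, per cell."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()


def _open_text(path, mode: str = "rt") -> IO[str]:
    path = str(path)
    if path.endswith(".gz"):
        if "w" in mode:
            # mtime=0 keeps outputs byte-identical across runs
            import io as _io
            raw = open(path, "wb")
            gz = gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0)
            gz.myfileobj = raw  # GzipFile closes this on close()
            return _io.TextIOWrapper(gz) if "t" in mode else gz
        return gzip.open(path, mode)
    return open(path, mode)


def read_fragments(path) -> Iterator[FragmentRecord]:
    """Stream fragment records from a (optionally gzipped) fragments TSV.

    Columns: chrom, start, end, barcode[, count]; a missing count column
    defaults to 1.  Lines starting with ``#`` are skipped.
    """
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(
                    f"{path}: line {lineno}: expected >=4 tab-separated "
                    f"columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
                count = int(fields[4]) if len(fields) >= 5 and fields[4] else 1
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
            try:
                yield FragmentRecord(fields[0], start, end, fields[3], count)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None


def write_fragments(records: Iterable[FragmentRecord], path) -> None:
    with _open_text(path, "wt") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.barcode}\t{r.count}\n")


def _parse_peak_line(line: str, lineno: int, path) -> GenomicInterval:
    line = line.strip()
    try:
        if "\t" in line:
            f = line.split("\t")
            name = f[3] if len(f) > 3 else ""
            return GenomicInterval(f[0], int(f[1]), int(f[2]), name=name)
        # "chr:start-end" form
        chrom, rng = line.split(":")
        lo, hi = rng.replace(",", "").split("-")
        return GenomicInterval(chrom, int(lo), int(hi))
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}: line {lineno}: cannot parse peak "
                          f"{line!r} ({exc})") from None


def read_peak_matrix(mtx_path, peaks_path, barcodes_path,
                     labels: dict[str, str] | None = None) -> PeakByCellMatrix:
    """Read an MTX triplet (matrix, peak BED / region strings, barcodes)."""
    with _open_text(mtx_path, "rb" if str(mtx_path).endswith(".gz") else "r") as fh:
        counts = sp.csr_matrix(scipy.io.mmread(fh))
    peaks = []
    with _open_text(peaks_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                peaks.append(_parse_peak_line(line, lineno, peaks_path))
    with _open_text(barcodes_path) as fh:
        barcodes = [ln.strip().split("\t")[0] for ln in fh if ln.strip()]
    if counts.shape[0] != len(peaks) or counts.shape[1] != len(barcodes):
        raise FormatError(
            f"MTX declares {counts.shape[0]} x {counts.shape[1]} but peak "
            f"file has {len(peaks)} lines and barcode file {len(barcodes)}"
        )
    if counts.nnz and counts.data.min() < 0:
        raise FormatError(f"{mtx_path}: negative counts")
    return PeakByCellMatrix(peaks, barcodes, counts, labels)


def write_peak_matrix(matrix: PeakByCellMatrix, mtx_path, peaks_path,
                      barcodes_path) -> None:
    scipy.io.mmwrite(str(mtx_path), sp.coo_matrix(matrix.counts))
    write_bed(matrix.peaks, peaks_path)
    with _open_text(barcodes_path, "wt") as fh:
        for b in matrix.barcodes:
            fh.write(b + "\n")


def read_narrowpeak(path) -> list[GenomicInterval]:
    """Read ENCODE narrowPeak (10 columns) or plain BED (>=3 columns).

    narrowPeak ``signalValue`` (column 7) is stored as the interval score;
    for BED6 the score column is used.  Output is sorted by
    ``(chrom, start)``.
    """
    out: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >=3 columns")
            try:
                start, end = int(f[1]), int(f[2])
                name = f[3] if len(f) > 3 else ""
                strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "."
                score: float | None = None
                if len(f) >= 10:  # narrowPeak: signalValue in column 7
                    score = float(f[6])
                elif len(f) > 4 and f[4] not in (".", ""):
                    score = float(f[4])
                out.append(GenomicInterval(f[0], start, end, name=name,
                                           score=score, strand=strand))
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return out


read_bed = read_narrowpeak


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with _open_text(path, "wt") as fh:
        for iv in intervals:
            score = "." if iv.score is None else f"{iv.score:g}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t"
                     f"{score}\t{iv.strand}\n")


def _gtf_attributes(raw: str) -> dict[str, str]:
    attrs = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gene_models(gtf_path, warn=None) -> list[GeneModel]:
    """Parse gene and exon features from a GTF into :class:`GeneModel` s.

    GTF is 1-based inclusive; spans are converted to 0-based half-open.
    Genes without a strand are excluded with a warning.
    """
    import warnings

    genes: dict[str, dict] = {}
    with _open_text(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise FormatError(f"{gtf_path}: line {lineno}: expected 9 columns")
            chrom, _, feature, start1, end1, _, strand, _, attrs_raw = f[:9]
            if feature not in ("gene", "exon", "transcript"):
                continue
            attrs = _gtf_attributes(attrs_raw)
            gid = attrs.get("gene_id")
            if gid is None:
                raise FormatError(f"{gtf_path}: line {lineno}: missing gene_id")
            start, end = int(start1) - 1, int(end1)  # to 0-based half-open
            rec = genes.setdefault(gid, {"chrom": chrom, "strand": strand,
                                         "lo": start, "hi": end, "exons": [],
                                         "name": attrs.get("gene_name", gid)})
            rec["lo"] = min(rec["lo"], start)
            rec["hi"] = max(rec["hi"], end)
            if feature == "exon":
                rec["exons"].append(GenomicInterval(chrom, start, end, name=gid))

    models: list[GeneModel] = []
    for gid, rec in genes.items():
        if rec["strand"] not in ("+", "-"):
            warnings.warn(f"gene {gid} has no strand; excluded")
            continue
        if rec["strand"] == "+":
            tss, tes = rec["lo"], rec["hi"]
        else:
            tss, tes = rec["hi"], rec["lo"]
        models.append(GeneModel(gid, rec["name"], rec["chrom"], rec["strand"],
                                tss, tes, rec["exons"]))
    models.sort(key=lambda g: (g.chrom, min(g.tss, g.tes)))
    return models


def write_gene_models(genes: Iterable[GeneModel], path) -> None:
    """Write gene + exon GTF lines (converting back to 1-based inclusive)."""
    with _open_text(path, "wt") as fh:
        for g in genes:
            span = g.span
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}";'
            fh.write(f"{g.chrom}\tscse\tgene\t{span.start + 1}\t{span.end}\t."
                     f"\t{g.strand}\t.\t{attrs}\n")
            for ex in g.exons:
                fh.write(f"{g.chrom}\tscse\texon\t{ex.start + 1}\t{ex.end}\t."
                         f"\t{g.strand}\t.\t{attrs}\n")


def read_labels(path) -> dict[str, str]:
    """Read a barcode -> tissue/cell-type TSV (2 columns, optional header)."""
    labels: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 2:
                raise FormatError(f"{path}: line {lineno}: expected 2 columns")
            if lineno == 1 and f[0].lower() in ("barcode", "cell"):
                continue
            labels[f[0]] = f[1]
    return labels


def write_labels(labels: dict[str, str], path) -> None:
    with _open_text(path, "wt") as fh:
        for barcode, lab in labels.items():
            fh.write(f"{barcode}\t{lab}\n")
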