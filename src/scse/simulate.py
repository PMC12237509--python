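"""Synthetic scATAC datasets with planted regulatory structure.

The generator emulates the data model the pipeline assumes: a sparse
nonnegative-integer peak-by-cell count matrix with per-cell depth
variation, cell-type-specific accessible peaks, clustered high-signal
peak groups (planted super-enhancer clusters), promoter-proximal peaks
tied to planted marker genes, and a fragment file whose in-peak
fragments exactly account for the matrix counts.

Layout.  The genome is organised into well-separated "blocks" (>= 1.2 Mb
apart, alternating between two chromosomes) so that each co-accessibility
window sees a single planted structure:

* **enhancer blocks** (one per planted type-specific enhancer): a marker
  gene with an accessible promoter peak plus a distal enhancer peak
  ~20 kb from the TSS, both elevated in the owning type and co-varying
  through a shared per-cell latent factor;
* **SE blocks**: ``peaks_per_cluster`` peaks at ``intra_cluster_spacing``
  gaps (below the stitch distance), elevated in the owning type, with a
  co-varying marker-gene promoter 50 kb away;
* **housekeeping blocks**: a gene with a promoter peak (and in half the
  blocks an exonic peak) accessible uniformly in all types;
* **background blocks**: intergenic shared peaks, singly or as pairs
  ~200 kb apart (co-accessibility background), far from any gene.

Counts are Poisson draws whose rates mix a per-cell Gamma depth factor
with a per-(cell, block) Gamma latent factor, i.e. negative-binomial-like
overdispersed integers.  Peaks closed in a cell type receive a fragment
with probability ``noise_rate``.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (FragmentRecord, GeneModel, GenomicInterval, PeakByCellMatrix,
                 write_bed, write_fragments, write_gene_models, write_labels,
                 write_peak_matrix)

__all__ = ["SimulationConfig", "TruthTables", "SimulatedDataset",
           "simulate_dataset"]

PEAK_WIDTH = 500
GENE_BODY = 3000
BLOCK_GAP = 1_300_000
FRAG_MIN, FRAG_MAX = 50, 500


class PlacementError(ValueError):
    """The requested peaks do not fit into the configured genome."""


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe a two-type desk-scale experiment: 150 cells per
    type, 30 planted type-specific enhancers per type, signal multiplier
    8 over the accessible background, and 1% leak-through noise on
    closed peaks.
    """

    n_cell_types: int = 2
    cells_per_type: int = 150
    genome: dict[str, int] | None = None  # auto-sized when None
    n_shared_peaks: int = 40
    n_specific_peaks_per_type: int = 30
    n_se_clusters_per_type: int = 0
    peaks_per_cluster: int = 8
    intra_cluster_spacing: int = 1000
    signal_multiplier: float = 8.0
    n_genes: int = 80
    promoter_fraction_of_peaks: float = 0.3
    mean_fragments_per_cell: float = 800.0
    background_fragment_fraction: float = 0.05
    noise_rate: float = 0.01
    depth_shape: float = 8.0  # Gamma shape of the per-cell depth factor
    latent_shape: float = 2.0  # Gamma shape of the per-block latent factor
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cell_types", "cells_per_type", "n_shared_peaks",
                     "n_specific_peaks_per_type", "peaks_per_cluster",
                     "intra_cluster_spacing", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_se_clusters_per_type < 0:
            raise ValueError("n_se_clusters_per_type must be >= 0")
        if not 0 <= self.noise_rate < 1:
            raise ValueError("noise_rate must be in [0, 1)")
        if self.signal_multiplier <= 1:
            raise ValueError("signal_multiplier must exceed 1")


@dataclass
class TruthTables:
    """Planted structure, for recovery scoring against pipeline calls."""

    specific_enhancers: list[tuple[GenomicInterval, str]] = field(default_factory=list)
    se_clusters: list[tuple[GenomicInterval, str]] = field(default_factory=list)
    marker_genes: list[tuple[str, str]] = field(default_factory=list)
    coaccess_pairs: list[tuple[GenomicInterval, GenomicInterval, str]] = \
        field(default_factory=list)

    def enhancers_of(self, cell_type: str) -> list[GenomicInterval]:
        return [iv for iv, t in self.specific_enhancers if t == cell_type]

    def clusters_of(self, cell_type: str) -> list[GenomicInterval]:
        return [iv for iv, t in self.se_clusters if t == cell_type]

    def markers_of(self, cell_type: str) -> list[str]:
        return [g for g, t in self.marker_genes if t == cell_type]


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    fragments: list[FragmentRecord]
    matrix: PeakByCellMatrix
    labels: dict[str, str]
    genes: list[GeneModel]
    truth: TruthTables
    genome: dict[str, int]
    summary: dict[str, int]

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fragments(self.fragments, out / "fragments.tsv.gz")
        write_peak_matrix(self.matrix, out / "matrix.mtx",
                          out / "peaks.bed", out / "barcodes.txt")
        write_labels(self.labels, out / "labels.tsv")
        write_gene_models(self.genes, out / "genes.gtf")
        write_bed([iv for iv, _ in self.truth.specific_enhancers],
                  out / "truth_enhancers.bed")
        write_bed([iv for iv, _ in self.truth.se_clusters],
                  out / "truth_se_clusters.bed")
        with open(out / "truth_markers.tsv", "w") as fh:
            for gene, ctype in self.truth.marker_genes:
                fh.write(f"{gene}\t{ctype}\n")
        with open(out / "genome.tsv", "w") as fh:
            for chrom, size in self.genome.items():
                fh.write(f"{chrom}\t{size}\n")


def _type_names(n: int) -> list[str]:
    letters = string.ascii_uppercase
    return [f"type_{letters[i % 26]}{i // 26 if i >= 26 else ''}" for i in range(n)]


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a dataset; identical config (incl. seed) gives identical output."""
    rng = np.random.default_rng(config.seed)
    types = _type_names(config.n_cell_types)
    truth = TruthTables()

    # ------------------------------------------------------------------ layout
    peaks: list[GenomicInterval] = []
    # role per peak: (kind, owner index or -1, latent block id or -1)
    roles: list[tuple[str, int, int]] = []
    genes: list[GeneModel] = []
    bg_zones: list[GenomicInterval] = []  # guaranteed peak- and gene-free
    cursors = {"chr1": 500_000, "chr2": 500_000}
    chrom_cycle = ["chr1", "chr2"]
    n_block = 0
    n_latent = 0

    def place(chrom: str, span: int) -> int:
        start = cursors[chrom]
        cursors[chrom] = start + span + BLOCK_GAP
        mid = start + span + BLOCK_GAP // 2
        bg_zones.append(GenomicInterval(chrom, mid - 50_000, mid + 50_000))
        return start

    def next_chrom() -> str:
        nonlocal n_block
        chrom = chrom_cycle[n_block % len(chrom_cycle)]
        n_block += 1
        return chrom

    def add_peak(chrom: str, start: int, kind: str, owner: int,
                 latent: int, name: str) -> GenomicInterval:
        iv = GenomicInterval(chrom, start, start + PEAK_WIDTH, name=name)
        peaks.append(iv)
        roles.append((kind, owner, latent))
        return iv

    gene_serial = 0

    def add_gene(chrom: str, start: int, strand: str, prefix: str) -> GeneModel:
        nonlocal gene_serial
        gene_serial += 1
        gid = f"{prefix}{gene_serial:04d}"
        lo, hi = start, start + GENE_BODY
        tss, tes = (lo, hi) if strand == "+" else (hi, lo)
        g = GeneModel(gid, gid, chrom, strand, tss, tes,
                      exons=[GenomicInterval(chrom, lo, hi, name=gid)])
        genes.append(g)
        return g

    # enhancer blocks: gene + promoter peak + distal enhancer, per type
    for t_idx, ctype in enumerate(types):
        for j in range(config.n_specific_peaks_per_type):
            chrom = next_chrom()
            strand = "+" if j % 2 == 0 else "-"
            start = place(chrom, 30_000)
            gene = add_gene(chrom, start + 22_000, strand, f"MK{t_idx}_")
            lo = start + 22_000
            if strand == "+":
                prom_start = lo - 300          # overlaps [TSS-2000, TSS+100)
                enh_start = lo - 20_000
            else:
                prom_start = lo + GENE_BODY - 200   # overlaps [TSS-100, TSS+2000)
                enh_start = lo + GENE_BODY + 19_500
            enh = add_peak(chrom, enh_start, "specific", t_idx, n_latent,
                           f"enh_{ctype}_{j}")
            prom = add_peak(chrom, prom_start, "marker_promoter", t_idx,
                            n_latent, f"prom_{gene.gene_id}")
            truth.specific_enhancers.append((enh, ctype))
            truth.marker_genes.append((gene.gene_id, ctype))
            truth.coaccess_pairs.append((enh, prom, ctype))
            n_latent += 1

    # SE blocks: peak cluster + co-varying marker-gene promoter
    step = PEAK_WIDTH + config.intra_cluster_spacing
    for t_idx, ctype in enumerate(types):
        for j in range(config.n_se_clusters_per_type):
            chrom = next_chrom()
            cluster_span = config.peaks_per_cluster * step
            start = place(chrom, cluster_span + 60_000)
            members = [add_peak(chrom, start + k * step, "se", t_idx, n_latent,
                                f"se_{ctype}_{j}_{k}")
                       for k in range(config.peaks_per_cluster)]
            gene = add_gene(chrom, start + cluster_span + 50_000, "+",
                            f"SEMK{t_idx}_")
            add_peak(chrom, gene.span.start - 300, "marker_promoter", t_idx,
                     n_latent, f"prom_{gene.gene_id}")
            span = GenomicInterval(chrom, members[0].start, members[-1].end,
                                   name=f"se_cluster_{ctype}_{j}")
            truth.se_clusters.append((span, ctype))
            truth.marker_genes.append((gene.gene_id, ctype))
            n_latent += 1

    # shared peaks: promoter/exonic fraction on housekeeping genes, rest
    # intergenic (singles and window-sharing background pairs)
    n_markers = len(truth.marker_genes)
    n_hk_target = max(0, config.n_genes - n_markers)
    n_prom_shared = min(n_hk_target,
                        round(config.promoter_fraction_of_peaks
                              * config.n_shared_peaks))
    n_shared_left = config.n_shared_peaks
    for j in range(n_prom_shared):
        chrom = next_chrom()
        start = place(chrom, 10_000)
        gene = add_gene(chrom, start + 3_000, "+", "HK_")
        add_peak(chrom, gene.span.start - 300, "shared", -1, -1,
                 f"prom_{gene.gene_id}")
        n_shared_left -= 1
        if j % 2 == 0 and n_shared_left > 0:  # exonic shared peak
            add_peak(chrom, gene.span.start + 1250, "shared", -1, -1,
                     f"exonic_{gene.gene_id}")
            n_shared_left -= 1
    n_pairs = max(1, n_shared_left // 4)
    for j in range(n_pairs):
        if n_shared_left < 2:
            break
        chrom = next_chrom()
        start = place(chrom, 220_000)
        add_peak(chrom, start, "shared", -1, -1, f"bgpair_{j}_a")
        add_peak(chrom, start + 200_000, "shared", -1, -1, f"bgpair_{j}_b")
        n_shared_left -= 2
    for j in range(n_shared_left):
        chrom = next_chrom()
        start = place(chrom, 1_000)
        add_peak(chrom, start, "shared", -1, -1, f"bg_{j}")

    # genes beyond the peak-bearing ones (annotation-only housekeeping)
    for j in range(n_hk_target - n_prom_shared):
        chrom = next_chrom()
        start = place(chrom, 10_000)
        add_gene(chrom, start + 3_000, "+", "HK_")

    genome = {c: cursors[c] + 500_000 for c in chrom_cycle}
    if config.genome is not None:
        for chrom, needed in genome.items():
            if config.genome.get(chrom, 0) < needed:
                raise PlacementError(
                    f"genome too small: need {needed} bp on {chrom}, have "
                    f"{config.genome.get(chrom, 0)}"
                )
        genome = dict(config.genome)

    # sort peaks (and roles) the way PeakByCellMatrix stores them
    order = sorted(range(len(peaks)),
                   key=lambda i: (peaks[i].chrom, peaks[i].start))
    peaks = [peaks[i] for i in order]
    roles = [roles[i] for i in order]

    # ------------------------------------------------------------------ counts
    n_peaks = len(peaks)
    m = config.n_cell_types * config.cells_per_type
    barcodes = []
    cell_type_idx = np.empty(m, dtype=int)
    labels: dict[str, str] = {}
    for t_idx, ctype in enumerate(types):
        for c in range(config.cells_per_type):
            b = f"{ctype}-{c:04d}"
            barcodes.append(b)
            labels[b] = ctype
            cell_type_idx[t_idx * config.cells_per_type + c] = t_idx

    n_owned = (config.n_specific_peaks_per_type * 2
               + config.n_se_clusters_per_type * (config.peaks_per_cluster + 1))
    lam0 = config.mean_fragments_per_cell / (
        config.n_shared_peaks + config.signal_multiplier * n_owned)

    depth = rng.gamma(config.depth_shape, 1.0 / config.depth_shape, size=m)
    latent = (rng.gamma(config.latent_shape, 1.0 / config.latent_shape,
                        size=(max(n_latent, 1), m))
              if n_latent else np.ones((1, m)))
    noise_lam = -np.log1p(-config.noise_rate) if config.noise_rate > 0 else 0.0

    rates = np.zeros((n_peaks, m))
    for i, (kind, owner, lat) in enumerate(roles):
        if kind == "shared":
            rates[i] = lam0 * depth
        else:
            owned = cell_type_idx == owner
            rates[i, owned] = (lam0 * config.signal_multiplier
                               * depth[owned] * latent[lat, owned])
            rates[i, ~owned] = noise_lam
    counts = rng.poisson(rates)
    matrix = PeakByCellMatrix(peaks, barcodes, counts, labels)

    # realized-signal sanity: planted SE peaks vs accessible background,
    # within the owning type, to 3 standard errors
    if config.n_se_clusters_per_type:
        shared_idx = [i for i, r in enumerate(roles) if r[0] == "shared"]
        for t_idx in range(config.n_cell_types):
            cells = cell_type_idx == t_idx
            se_vals = counts[np.array([i for i, r in enumerate(roles)
                                       if r[0] == "se" and r[1] == t_idx])][:, cells]
            bg_vals = counts[np.array(shared_idx)][:, cells]
            se_mean = se_vals.mean()
            bg_mean = bg_vals.mean()
            # cells are the independent units (the latent factor is shared
            # across a cluster's peaks within a cell), so the standard error
            # comes from per-cell means
            se_cell = se_vals.mean(axis=0)
            bg_cell = bg_vals.mean(axis=0)
            se_sem = se_cell.std(ddof=1) / np.sqrt(se_cell.size)
            bg_sem = config.signal_multiplier * bg_cell.std(ddof=1) / \
                np.sqrt(bg_cell.size)
            slack = 3 * np.hypot(se_sem, bg_sem)
            if se_mean < config.signal_multiplier * bg_mean - slack:
                warnings.warn(
                    f"planted SE signal below target in {types[t_idx]}: "
                    f"{se_mean:.2f} vs {config.signal_multiplier} x {bg_mean:.2f}")

    # --------------------------------------------------------------- fragments
    fragments: list[FragmentRecord] = []
    counts_sorted = matrix.counts  # rows follow matrix.peaks order
    for i, peak in enumerate(matrix.peaks):
        row = counts_sorted.getrow(i)
        for j, c in zip(row.indices, row.data):
            width = len(peak)
            lens = rng.integers(FRAG_MIN, min(FRAG_MAX, width) + 1, size=c)
            starts = peak.start + (rng.random(c) * (width - lens + 1)).astype(int)
            for s, ln in zip(starts, lens):
                fragments.append(FragmentRecord(peak.chrom, int(s),
                                                int(s + ln),
                                                matrix.barcodes[j]))
    n_in_peak = len(fragments)
    n_bg_per_cell = rng.poisson(config.background_fragment_fraction
                                * config.mean_fragments_per_cell, size=m)
    for j, nbg in enumerate(n_bg_per_cell):
        zones = rng.integers(0, len(bg_zones), size=nbg)
        for z in zones:
            zone = bg_zones[z]
            ln = int(rng.integers(FRAG_MIN, FRAG_MAX + 1))
            s = int(zone.start + rng.integers(0, len(zone) - ln))
            fragments.append(FragmentRecord(zone.chrom, s, s + ln, barcodes[j]))
    fragments.sort(key=lambda f: (f.chrom, f.start, f.end, f.barcode))

    summary = {"n_fragments": len(fragments),
               "n_in_peak_fragments": n_in_peak,
               "n_background_fragments": len(fragments) - n_in_peak,
               "matrix_total": int(matrix.counts.sum())}
    return SimulatedDataset(config, fragments, matrix, labels, genes, truth,
                            genome, summary)
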