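"""End-to-end pipeline: preprocess, co-accessibility, consensus
enhancers, super-enhancers, gene markers and an optional overlap report.

Outputs are plain TSV/BED tables plus a JSON manifest recording the
package version, the seed, every parameter and per-stage counts, so a
run can be reproduced exactly.  One global seed fans out to per-stage
seeds through CRC32-tagged ``SeedSequence`` derivation, keeping stages
independent of each other's random draws.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .coaccess import (aggregate_metacells, coaccessibility_scores,
                       link_enhancer_promoter, lsi_embed, tfidf_transform)
from .consensus import (call_consensus_enhancers, cell_weights,
                        shuffle_null_threshold, tanimoto_matrix)
from .intervals import FragmentIndex
from .io import (PeakByCellMatrix, promoter_window, read_fragments,
                 read_gene_models, read_labels, read_narrowpeak,
                 read_peak_matrix, write_bed)
from .markers import find_markers, gene_activity, normalize_activity
from .overlap import overlap_report
from .preprocess import preprocess_matrix
from .superenhancers import STITCH_DISTANCES, call_superenhancers

__all__ = ["PipelineConfig", "run_all", "enhancer_stage", "derive_seed"]

SPECIES_PRESETS = {
    "human": {"stitch_distance": 12_500, "max_dist": 500_000},
    "mouse": {"stitch_distance": 12_500, "max_dist": 500_000},
    "fly": {"stitch_distance": 2_000, "max_dist": 100_000},
}


def derive_seed(seed: int, tag: str) -> int:
    """Per-stage seed: SeedSequence over (seed, crc32(tag))."""
    entropy = [int(seed), zlib.crc32(tag.encode())]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """All thresholds default to the published pipeline values."""

    # inputs
    matrix_mtx: str = ""
    peaks_bed: str = ""
    barcodes: str = ""
    labels: str = ""
    gtf: str = ""
    fragments: str = ""       # optional; SE calling + criterion iii need it
    genome_sizes: str = ""    # chrom<TAB>length; required with fragments
    candidates: str = ""      # optional narrowPeak; default: matrix peaks
    reference_bed: str = ""   # optional; enables the overlap report
    out_dir: str = "scse_out"
    # species presets
    species: str = "human"
    stitch_distance: int | None = None
    max_dist: int | None = None
    promoter_upstream: int = 2000
    promoter_downstream: int = 100
    # QC thresholds
    min_peaks_per_cell: int = 200
    min_cells_per_peak: int = 10
    min_cells_per_type: int = 100
    # consensus enhancers
    support_fraction: float = 1.0 / 3.0
    coaccess_cutoff: float = 0.1
    n_shuffles: int = 20
    shuffle_percentile: float = 95.0
    # co-accessibility
    lsi_components: int = 50
    metacell_k: int = 50
    metacell_max_overlap: float = 0.8
    penalty_scale: float = 1.0
    # markers
    marker_min_pct: float = 0.3
    marker_min_log2fc: float = 0.585
    marker_alpha: float = 1e-5
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        preset = SPECIES_PRESETS.get(self.species, SPECIES_PRESETS["human"])
        if self.stitch_distance is None:
            self.stitch_distance = preset["stitch_distance"]
        if self.max_dist is None:
            self.max_dist = preset["max_dist"]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extras = {k: v for k, v in raw.items() if k not in known}
        cfg = cls(**kwargs)
        cfg.extras = extras
        return cfg


def _fmt(x) -> str:
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def _write_tsv(path, header: list[str], rows) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def enhancer_stage(sub: PeakByCellMatrix, genes, frag_index, genome,
                   cfg: PipelineConfig, seed: int):
    """Co-accessibility + consensus enhancer calling for one cell type.

    Returns (enhancers, coaccess pairs, enhancer-promoter links,
    null threshold).
    """
    tf = tfidf_transform(sub)
    n_comp = min(cfg.lsi_components, min(tf.shape) - 1)
    coords = lsi_embed(tf, n_components=n_comp, seed=derive_seed(seed, "lsi"))
    # cap k so the overlap rule can still accept a handful of metacells
    # on small sub-populations (the glasso needs >= 5 observations)
    k_eff = min(cfg.metacell_k, max(5, sub.n_cells // 5))
    meta = aggregate_metacells(sub, coords, k=k_eff,
                               max_overlap=cfg.metacell_max_overlap,
                               seed=derive_seed(seed, "metacells"))
    pairs = coaccessibility_scores(meta, sub.peaks, max_dist=cfg.max_dist,
                                   penalty_scale=cfg.penalty_scale,
                                   seed=derive_seed(seed, "glasso"))
    promoters = [promoter_window(g, cfg.promoter_upstream,
                                 cfg.promoter_downstream) for g in genes]
    links = link_enhancer_promoter(pairs, promoters, cfg.coaccess_cutoff)

    T = tanimoto_matrix(sub)
    w = cell_weights(T)
    null = None
    if frag_index is not None and genome:
        null = shuffle_null_threshold(frag_index, sub.peaks, sub.barcodes, w,
                                      genome, n_shuffles=cfg.n_shuffles,
                                      percentile=cfg.shuffle_percentile,
                                      seed=derive_seed(seed, "shuffle"))
    enhancers = call_consensus_enhancers(
        sub, w, genes, null, pairs,
        support_fraction=cfg.support_fraction,
        coaccess_cutoff=cfg.coaccess_cutoff,
        promoter_upstream=cfg.promoter_upstream,
        promoter_downstream=cfg.promoter_downstream)
    return enhancers, pairs, links, null


def run_all(cfg: PipelineConfig) -> dict:
    """Run every stage and write the artifact directory; returns the manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    labels = read_labels(cfg.labels)
    matrix = read_peak_matrix(cfg.matrix_mtx, cfg.peaks_bed, cfg.barcodes,
                              labels=labels)
    missing = [b for b in matrix.barcodes if b not in labels]
    if missing:
        raise ValueError(f"barcode {missing[0]!r} present in the matrix but "
                         "missing from the label table")
    genes = read_gene_models(cfg.gtf)
    genome: dict[str, int] = {}
    if cfg.genome_sizes:
        with open(cfg.genome_sizes) as fh:
            for line in fh:
                if line.strip():
                    chrom, size = line.split("\t")[:2]
                    genome[chrom] = int(size)
    frag_index = None
    if cfg.fragments:
        frag_index = FragmentIndex(read_fragments(cfg.fragments),
                                   matrix.barcodes)
        if not genome:
            raise ValueError("fragments provided but genome_sizes missing "
                             "(needed by the shuffle null and SE calling)")

    manifest: dict = {"version": __version__, "seed": cfg.seed,
                      "parameters": {k: v for k, v in asdict(cfg).items()
                                     if k != "extras"},
                      "stages": {}}

    split, qc = preprocess_matrix(
        matrix, cfg.min_peaks_per_cell, cfg.min_cells_per_peak,
        cfg.min_cells_per_type)
    manifest["stages"]["preprocess"] = {
        "cells_in": qc.n_cells_in, "cells_out": qc.n_cells_out,
        "peaks_in": qc.n_peaks_in, "peaks_out": qc.n_peaks_out,
        "cell_types": sorted(split), "removed": qc.removed}
    _write_tsv(out / "qc_report.tsv", ["metric", "value"],
               [["n_cells_in", qc.n_cells_in], ["n_cells_out", qc.n_cells_out],
                ["n_peaks_in", qc.n_peaks_in], ["n_peaks_out", qc.n_peaks_out]]
               + [[f"removed_{k}", v] for k, v in sorted(qc.removed.items())])

    candidates_global = (read_narrowpeak(cfg.candidates)
                         if cfg.candidates else None)
    typical_by_type: dict[str, list] = {}
    for ctype, sub in sorted(split.items()):
        seed_t = derive_seed(cfg.seed, f"type:{ctype}")
        enhancers, pairs, links, null = enhancer_stage(
            sub, genes, frag_index, genome, cfg, seed_t)
        typical = [e.interval for e in enhancers if e.is_typical]
        typical_by_type[ctype] = typical
        _write_tsv(out / f"enhancers_{ctype}.tsv",
                   ["chrom", "start", "end", "name", "combined_score",
                    "support_fraction", "pass_support", "pass_annotation",
                    "pass_shuffle_null", "pass_coaccessibility",
                    "max_promoter_coaccess", "is_typical"],
                   [[e.interval.chrom, e.interval.start, e.interval.end,
                     e.interval.name, e.combined_score, e.support_fraction,
                     int(e.qc_flags["support"]), int(e.qc_flags["annotation"]),
                     int(e.qc_flags["shuffle_null"]),
                     int(e.qc_flags["coaccessibility"]),
                     e.max_promoter_coaccess, int(e.is_typical)]
                    for e in enhancers])
        write_bed(typical, out / f"enhancers_{ctype}.bed")
        _write_tsv(out / f"links_{ctype}.tsv",
                   ["chrom_enh", "start_enh", "end_enh", "chrom_prom",
                    "start_prom", "end_prom", "score", "gene"],
                   [[l.enhancer.chrom, l.enhancer.start, l.enhancer.end,
                     l.promoter_site.chrom, l.promoter_site.start,
                     l.promoter_site.end, l.score, l.gene] for l in links])
        stage = {"n_enhancers": len(typical), "n_links": len(links),
                 "n_coaccess_pairs": len(pairs),
                 "null_threshold": None if null is None else round(null, 6)}

        if frag_index is not None:
            cand = (candidates_global if candidates_global is not None
                    else sub.peaks)
            cand = [c for c in cand]
            if len(cand) >= 2:
                calls, curve = call_superenhancers(
                    cand, frag_index, sub.barcodes,
                    stitch_distance=cfg.stitch_distance,
                    typical_enhancers=typical)
                calls_sorted = sorted(calls, key=lambda c: c.rank)
                _write_tsv(out / f"superenhancers_{ctype}.tsv",
                           ["chrom", "start", "end", "n_members",
                            "total_signal", "rank", "is_super", "retained"],
                           [[c.region.interval.chrom, c.region.interval.start,
                             c.region.interval.end, len(c.region.members),
                             c.region.total_signal, c.rank, int(c.is_super),
                             int(c.retained)] for c in calls_sorted])
                _write_tsv(out / f"rank_curve_{ctype}.tsv",
                           ["rank", "signal", "scaled_x", "scaled_y"],
                           [[i + 1, curve.signals[i], curve.scaled_x[i],
                             curve.scaled_y[i]]
                            for i in range(len(curve.signals))])
                stage["n_superenhancers"] = sum(c.retained for c in calls)
        manifest["stages"][f"enhancers:{ctype}"] = stage

    if len(split) >= 3:
        filtered = matrix.subset(
            cell_idx=[matrix.barcodes.index(b) for sub in split.values()
                      for b in sub.barcodes])
        activity = gene_activity(filtered, genes,
                                 upstream_d=cfg.promoter_upstream)
        norm = normalize_activity(activity)
        res = find_markers(norm, labels, min_pct=cfg.marker_min_pct,
                           min_log2fc=cfg.marker_min_log2fc,
                           alpha_adj=cfg.marker_alpha)
        _write_tsv(out / "markers.tsv",
                   ["gene", "cell_type", "log2_fold_change", "pct_in",
                    "pct_out", "p_value", "p_adjusted", "is_marker"],
                   [[r.gene, r.cell_type, r.log2_fold_change, r.pct_in,
                     r.pct_out, r.p_value, r.p_adjusted,
                     int(r.is_marker(cfg.marker_alpha))] for r in res])
        manifest["stages"]["markers"] = {
            "n_tested": len(res),
            "n_markers": sum(r.is_marker(cfg.marker_alpha) for r in res)}
    else:
        warnings.warn("fewer than three cell types survived preprocessing; "
                      "marker stage skipped")
        manifest["stages"]["markers"] = {"skipped": "fewer than 3 cell types"}

    if cfg.reference_bed:
        reference = read_narrowpeak(cfg.reference_bed)
        all_typical = [iv for ivs in typical_by_type.values() for iv in ivs]
        res, jac = overlap_report(all_typical, reference)
        _write_tsv(out / "overlap_report.tsv",
                   ["N", "K", "n", "k", "percent_query", "percent_ref",
                    "p_point", "p_tail", "jaccard"],
                   [[res.N, res.K, res.n, res.k, res.percent_query,
                     res.percent_ref, res.p_point, res.p_tail, jac]])
        manifest["stages"]["overlap"] = {"k": res.k, "p_tail": res.p_tail}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
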