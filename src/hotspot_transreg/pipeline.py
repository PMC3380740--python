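"""End-to-end pipeline: scan -> enrich over coldspot replicates -> GO gap
ranking -> coverage clustering.

All stage parameters live in :class:`PipelineConfig`; the defaults are the
printed settings of the hotspot study this pipeline reproduces (scan
p-value threshold 3.73e-6, 20 coldspot replicates, 50 kb exclusion
distance, odds ratio > 1.20 with p < 0.05 for candidates, coverage-graph
edge threshold 0.16).  Every output TSV starts with a comment line carrying
a hash of the producing configuration, and a fixed seed makes the whole run
byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import enrichment as enr
from . import motif_io
from .coverage_graph import (
    CoverageSummary,
    build_graph,
    coverage_from_hits,
    coverage_summary,
    hierarchical_clusters,
    threshold_clusters,
)
from .go_semantic import (
    AnnotationMap,
    TermSimilarity,
    gene_to_reference_terms,
    parse_obo,
    rank_terms_by_gap,
)
from .motif_scan import (
    MotifMatrix,
    UNIFORM_BACKGROUND,
    attach_qvalues,
    estimate_background,
    hit_region_ids,
    make_scoring_matrix,
    n_scanned_positions,
    scan_regions,
    score_pvalue_function,
)
from .regions import RegionSet, extract_sequences, read_bed, sample_coldspots

logger = logging.getLogger("hotspot_transreg")

_SEED_MOD = 2**31 - 1


@dataclass
class PipelineConfig:
    genome: str = ""
    hotspots: str = ""
    motifs: str = ""
    motif_format: str | None = None
    obo: str = ""
    annotations: str = ""
    out_dir: str = "results"
    p_threshold: float = 3.73e-6
    q_max: float = 0.05
    filter_by_q: bool = False
    n_replicates: int = 20
    min_distance: int = 50_000
    or_min: float = 1.20
    p_max: float = 0.05
    w_t: float = 0.16
    top_k_terms: int = 15
    reference_terms: tuple[str, ...] = ("GO:0006310", "GO:0007127")
    background: str = "uniform"  # "uniform" | "regions" (0-order fit to scanned sequences)
    pseudocount: float = 0.1
    granularity: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold <= 1):
            raise ValueError("p_threshold must be in (0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        self.reference_terms = tuple(self.reference_terms)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def config_hash(self) -> str:
        # out_dir is excluded: the same analysis written elsewhere is the same run
        data = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(data, sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: PipelineConfig
    results: list[enr.EnrichmentResult]
    hg: list[enr.EnrichmentResult]
    gaps: list[tuple[str, float]]
    reference_scores: dict[str, float]
    clusters: list[list[str]]
    hier_clusters: list[list[str]]
    summary: CoverageSummary | None
    coverage: dict[str, set[str]]
    paths: dict[str, Path] = field(default_factory=dict)


def _replicate_seed(seed: int, r: int) -> int:
    return (seed * 1_000_003 + 97 * r + 1) % _SEED_MOD


def _load_genome(path: str):
    from pyfaidx import Fasta

    return Fasta(path, as_raw=True, sequence_always_upper=False)


def _scan_counts(
    motifs: Sequence[MotifMatrix],
    hot_seqs: Mapping[str, str],
    cold_seq_sets: Sequence[Mapping[str, str]],
    cfg: PipelineConfig,
    collect_hits: bool = True,
    p_threshold: float | None = None,
):
    """Scan all motifs over hotspots and every coldspot replicate.

    Returns (hot_hits_per_motif, hm_per_motif, cm_lists_per_motif).
    """
    p_thr = cfg.p_threshold if p_threshold is None else p_threshold
    bg = None
    if cfg.background == "regions":
        bg = estimate_background(hot_seqs.values())
    hot_hits: dict[str, list] = {}
    hm: dict[str, int] = {}
    cms: dict[str, list[int]] = {}
    for motif in motifs:
        sm = make_scoring_matrix(motif, bg, cfg.pseudocount)
        pv = score_pvalue_function(sm, granularity=cfg.granularity)
        hits = scan_regions(sm, hot_seqs, p_thr, pv=pv)
        attach_qvalues(hits, n_scanned_positions(hot_seqs, motif.width))
        if cfg.filter_by_q:
            hits = [h for h in hits if h.q_value is not None and h.q_value <= cfg.q_max]
        hot_hits[motif.name] = hits if collect_hits else []
        hm[motif.name] = len(hit_region_ids(hits))
        cms[motif.name] = []
        for cold_seqs in cold_seq_sets:
            chits = scan_regions(sm, cold_seqs, p_thr, pv=pv)
            cms[motif.name].append(len(hit_region_ids(chits)))
        logger.info(
            "scanned %s (w=%d): HM=%d, CM=%s",
            motif.name, motif.width, hm[motif.name], cms[motif.name],
        )
    return hot_hits, hm, cms


def _write_tsv(df: pd.DataFrame, path: Path, tag: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config: {tag}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute all stages and persist every intermediate under ``out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = cfg.config_hash()
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run_pipeline(cfg, out, tag)
    except Exception as exc:  # annotate the failing stage for the caller
        logger.error("pipeline aborted: %s", exc)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run_pipeline(cfg: PipelineConfig, out: Path, tag: str) -> PipelineResult:
    logger.info("stage inputs: loading genome, hotspots, motifs (config %s)", tag)
    genome = _load_genome(cfg.genome)
    chrom_sizes = {name: len(genome[name]) for name in genome.keys()}
    hotspots = read_bed(cfg.hotspots, chrom_sizes)
    motifs = motif_io.read_motifs(cfg.motifs, cfg.motif_format)
    logger.info("loaded %d hotspots, %d motifs", len(hotspots), len(motifs))

    hot_seqs = extract_sequences(hotspots, genome)

    logger.info("stage coldspots: %d replicates, min_distance=%d", cfg.n_replicates, cfg.min_distance)
    cold_seq_sets = []
    for r in range(cfg.n_replicates):
        cold = sample_coldspots(
            hotspots, chrom_sizes, cfg.min_distance, seed=_replicate_seed(cfg.seed, r)
        )
        cold_seq_sets.append(extract_sequences(cold, genome))

    logger.info("stage scan/enrich: p_threshold=%g", cfg.p_threshold)
    hot_hits, hm, cms = _scan_counts(motifs, hot_seqs, cold_seq_sets, cfg)
    n_hot = len(hotspots)
    results = []
    for motif in motifs:
        cm, _cn = enr.average_replicates(cms[motif.name], n_hot)
        table = enr.ContingencyTable(hm[motif.name], n_hot - hm[motif.name], cm, n_hot - cm)
        results.append(enr.evaluate(motif.name, table))
    hg = enr.select_candidates(results, cfg.or_min, cfg.p_max)
    hg_names = [r.gene for r in hg]
    logger.info("HG candidates: %s", hg_names)

    paths: dict[str, Path] = {}
    _write_tsv(enr.results_to_frame(results), out / "enrichment.tsv", tag)
    paths["enrichment"] = out / "enrichment.tsv"
    (out / "hg.txt").write_text("".join(f"{g}\n" for g in hg_names))
    paths["hg"] = out / "hg.txt"
    all_hits = [h for motif in motifs for h in hot_hits[motif.name]]
    motif_io.write_hits_tsv(all_hits, out / "hotspot_hits.tsv", f"config: {tag}")
    paths["hits"] = out / "hotspot_hits.tsv"

    # GO stage
    gaps: list[tuple[str, float]] = []
    ref_scores: dict[str, float] = {}
    if cfg.obo and cfg.annotations:
        logger.info("stage GO: ranking terms by gap score")
        dag = parse_obo(cfg.obo)
        reader = AnnotationMap.from_gaf if cfg.annotations.endswith(".gaf") else AnnotationMap.from_tsv
        ann = reader(cfg.annotations, dag)
        sim = TermSimilarity(dag)
        all_genes = sorted(set(m.name for m in motifs) | set(ann.mapping))
        if ann.annotated(hg_names) and ann.annotated(all_genes):
            gaps = rank_terms_by_gap(sim, None, hg_names, all_genes, ann, top_k=cfg.top_k_terms)
            df = pd.DataFrame(
                [(i + 1, t, dag.name(t), g) for i, (t, g) in enumerate(gaps)],
                columns=["rank", "term", "name", "gap"],
            )
            _write_tsv(df, out / "gaps.tsv", tag)
            paths["gaps"] = out / "gaps.tsv"
        if all(t in dag for t in cfg.reference_terms):
            for g in ann.annotated(hg_names):
                ref_scores[g] = gene_to_reference_terms(sim, g, cfg.reference_terms, ann)

    # coverage stage
    clusters: list[list[str]] = []
    hier: list[list[str]] = []
    summary = None
    coverage = {g: s for g, s in coverage_from_hits(all_hits, hg_names).items() if s}
    if coverage:
        logger.info("stage coverage: w_t=%g over %d genes", cfg.w_t, len(coverage))
        graph = build_graph(coverage)
        clusters = threshold_clusters(graph, cfg.w_t)
        hier = hierarchical_clusters(graph, k=len(clusters))
        summary = coverage_summary(clusters, coverage, n_hot)
        edges = [
            (graph.genes[i], graph.genes[j], graph.weights[i, j])
            for i in range(len(graph.genes))
            for j in range(i + 1, len(graph.genes))
        ]
        _write_tsv(pd.DataFrame(edges, columns=["gene_i", "gene_j", "weight"]),
                   out / "edges.tsv", tag)
        paths["edges"] = out / "edges.tsv"
        rows = [(g, ci) for ci, cl in enumerate(clusters) for g in cl]
        _write_tsv(pd.DataFrame(rows, columns=["gene", "cluster"]), out / "clusters.tsv", tag)
        paths["clusters"] = out / "clusters.tsv"
        srows = [
            (ci, summary.cluster_sizes[ci], summary.cluster_union_sizes[ci])
            for ci in range(len(clusters))
        ]
        sdf = pd.DataFrame(srows, columns=["cluster", "n_genes", "hotspots_covered"])
        sdf.loc[len(sdf)] = ["union", sum(summary.cluster_sizes), summary.total_covered]
        sdf.loc[len(sdf)] = ["uncovered", 0, summary.uncovered]
        _write_tsv(sdf, out / "coverage_summary.tsv", tag)
        paths["coverage_summary"] = out / "coverage_summary.tsv"

    logger.info("pipeline complete: %d candidates, %d clusters", len(hg_names), len(clusters))
    return PipelineResult(
        config=cfg,
        results=results,
        hg=hg,
        gaps=gaps,
        reference_scores=ref_scores,
        clusters=clusters,
        hier_clusters=hier,
        summary=summary,
        coverage=coverage,
        paths=paths,
    )


def sweep_thresholds(cfg: PipelineConfig, thresholds: Sequence[float]) -> pd.DataFrame:
    """Recompute the odds ratio of every motif across a p-threshold grid.

    Sequences are scanned once at the loosest threshold; tighter thresholds
    reuse the cached hits, so one scan pass serves the whole grid.
    """
    if not thresholds:
        raise ValueError("empty threshold list")
    thresholds = sorted(thresholds)
    if not all(0 < t <= 1 for t in thresholds):
        raise ValueError("thresholds must be in (0, 1]")
    genome = _load_genome(cfg.genome)
    chrom_sizes = {name: len(genome[name]) for name in genome.keys()}
    hotspots = read_bed(cfg.hotspots, chrom_sizes)
    motifs = motif_io.read_motifs(cfg.motifs, cfg.motif_format)
    hot_seqs = extract_sequences(hotspots, genome)
    cold_seq_sets = []
    for r in range(cfg.n_replicates):
        cold = sample_coldspots(
            hotspots, chrom_sizes, cfg.min_distance, seed=_replicate_seed(cfg.seed, r)
        )
        cold_seq_sets.append(extract_sequences(cold, genome))

    loosest = max(thresholds)
    bg = estimate_background(hot_seqs.values()) if cfg.background == "regions" else None
    rows = []
    n_hot = len(hotspots)
    for motif in motifs:
        sm = make_scoring_matrix(motif, bg, cfg.pseudocount)
        pv = score_pvalue_function(sm, granularity=cfg.granularity)
        hot_hits = scan_regions(sm, hot_seqs, loosest, pv=pv)
        cold_hits = [scan_regions(sm, cs, loosest, pv=pv) for cs in cold_seq_sets]
        for t in thresholds:
            hm = len({h.region_id for h in hot_hits if h.p_value <= t})
            cm_reps = [len({h.region_id for h in ch if h.p_value <= t}) for ch in cold_hits]
            cm, _ = enr.average_replicates(cm_reps, n_hot)
            table = enr.ContingencyTable(hm, n_hot - hm, cm, n_hot - cm)
            res = enr.evaluate(motif.name, table)
            rows.append((t, motif.name, hm, cm, res.o_hc.value, res.p_value))
    return pd.DataFrame(
        rows, columns=["p_threshold", "motif", "HM", "CM", "O_hc", "p_value"]
    )
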