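"""Self-contained synthetic fixtures with known ground truth.

The generator emulates the shape of a hotspot-enrichment study: uniform-
composition chromosomes, hotspot intervals spaced so that valid coldspots
exist (pairwise gaps of at least twice the coldspot exclusion distance),
exact consensus motif copies planted per hotspot with probability ``p_hot``
and per length-matched background window with probability ``p_cold``, and a
balanced toy GO tree in which a marked subtree is preferentially annotated
to the designated high-odds-ratio genes.  Every generator is a pure
function of (config, seed).

It deliberately omits GC heterogeneity, repeats and assembly gaps: passing
recovery tests shows the pipeline's statistics are correct under the
planting model, not that real genomes behave this way.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .go_semantic import AnnotationMap, GoDag
from .regions import COLDSPOT, HOTSPOT, GenomicInterval, RegionSet, RegionError, _merge

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class MotifSpec:
    """One planted motif: exact consensus copies at per-region rates."""

    name: str
    consensus: str
    p_hot: float
    p_cold: float

    def __post_init__(self) -> None:
        if not (0 <= self.p_cold <= self.p_hot <= 1):
            raise SyntheticError(
                f"{self.name}: need 0 <= p_cold <= p_hot <= 1, got {self.p_cold}, {self.p_hot}"
            )
        if not self.consensus or set(self.consensus.upper()) - set("ACGT"):
            raise SyntheticError(f"{self.name}: consensus must be non-empty ACGT")

    @property
    def enriched(self) -> bool:
        return self.p_hot > self.p_cold


@dataclass(frozen=True)
class GoSpec:
    """Balanced is_a tree of given depth/branching plus a round-robin
    annotation rule; ``marked_child_index=None`` disables HG enrichment."""

    depth: int = 3
    branching: int = 3
    n_background_genes: int = 40
    annotations_per_gene: int = 3
    marked_child_index: int | None = 0

    def __post_init__(self) -> None:
        if self.depth < 2 or self.branching < 2:
            raise SyntheticError("GO tree needs depth >= 2 and branching >= 2")


@dataclass(frozen=True)
class SyntheticConfig:
    n_chromosomes: int = 4
    chromosome_length: int = 4_000_000
    n_hotspots: int = 400
    hotspot_length: int | tuple[int, int] = 1000
    min_distance: int = 5_000
    motifs: tuple[MotifSpec, ...] = ()
    go: GoSpec = field(default_factory=GoSpec)
    seed: int = 0


def paper_like_config(seed: int = 0) -> SyntheticConfig:
    """A scaled-down study: a few hundred hotspots, a handful of motifs with
    enrichment strengths bracketing the odds-ratio regime seen in real
    hotspot data (roughly 1.2 to 4), and one unenriched control motif."""
    return SyntheticConfig(
        n_chromosomes=4,
        chromosome_length=4_000_000,
        n_hotspots=400,
        hotspot_length=1000,
        min_distance=5_000,
        motifs=(
            MotifSpec("TRANSREG_A", "ACGTAGCCGTAT", 0.60, 0.20),
            MotifSpec("TRANSREG_B", "TTGACCGGATCA", 0.50, 0.25),
            MotifSpec("TRANSREG_C", "GGCATATCGTTG", 0.40, 0.10),
            MotifSpec("NULL_TF", "CATGCGATACCA", 0.20, 0.20),
        ),
        go=GoSpec(),
        seed=seed,
    )


def recovery_config(p_hot: float = 0.25, p_cold: float = 0.20, seed: int = 0) -> SyntheticConfig:
    """Parameter-recovery study: 5000 hotspots of 500 bp with one motif
    planted at rates near the odds-ratio regime of real hotspot data
    (O_hc about 1.3).  Regions are short and sparse: background gaps
    between hotspot exclusion zones are long relative to the region length,
    so the planted-copy geometry a coldspot samples is well approximated by
    an unbroken window tiling (the model behind
    :func:`planting_odds_interval`)."""
    return SyntheticConfig(
        n_chromosomes=5,
        chromosome_length=10_000_000,
        n_hotspots=5000,
        hotspot_length=500,
        min_distance=1_000,
        motifs=(MotifSpec("PLANTED", "ACGTAGCCGTAT", p_hot, p_cold),),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Genome and hotspots


def _hotspot_lengths(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    if isinstance(cfg.hotspot_length, tuple):
        lo, hi = cfg.hotspot_length
        return rng.integers(lo, hi + 1, size=cfg.n_hotspots)
    return np.full(cfg.n_hotspots, cfg.hotspot_length, dtype=int)


def generate_genome_and_hotspots(
    cfg: SyntheticConfig,
) -> tuple[dict[str, np.ndarray], RegionSet, dict]:
    """Uniform-ACGT chromosomes (as code arrays) with slotted hotspots.

    Each chromosome is divided into equal slots, one hotspot per slot placed
    uniformly inside the slot's feasible region, which guarantees pairwise
    hotspot gaps of at least 2 * min_distance so a coldspot fits between any
    two hotspots.
    """
    rng = np.random.default_rng(cfg.seed)
    lengths = _hotspot_lengths(cfg, rng)
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_hotspots // cfg.n_chromosomes)
    per_chrom[: cfg.n_hotspots % cfg.n_chromosomes] += 1

    genome: dict[str, np.ndarray] = {}
    intervals: list[GenomicInterval] = []
    idx = 0
    for c in range(cfg.n_chromosomes):
        chrom = f"chr{c + 1}"
        genome[chrom] = rng.integers(0, 4, size=cfg.chromosome_length, dtype=np.uint8)
        n_c = int(per_chrom[c])
        if n_c == 0:
            continue
        slot = cfg.chromosome_length // n_c
        for s in range(n_c):
            length = int(lengths[idx])
            feas = slot - length - 2 * cfg.min_distance
            if feas <= 0:
                raise SyntheticError(
                    f"slot of {slot} bp on {chrom} cannot host a {length}-bp hotspot "
                    f"with {cfg.min_distance}-bp margins"
                )
            start = s * slot + cfg.min_distance + int(rng.integers(0, feas))
            intervals.append(GenomicInterval(chrom, start, start + length, f"hs{idx:05d}"))
            idx += 1
    hotspots = RegionSet(role=HOTSPOT, intervals=intervals, genome_id="synthetic")
    truth = {"seed": cfg.seed, "n_hotspots": len(intervals)}
    return genome, hotspots, truth


def _write_copy(chrom_codes: np.ndarray, pos: int, codes: np.ndarray, strand: str) -> None:
    if strand == "-":
        codes = (3 - codes)[::-1]
    chrom_codes[pos : pos + len(codes)] = codes


def plant_motifs(
    genome: dict[str, np.ndarray],
    hotspots: RegionSet,
    motifs: Sequence[MotifSpec],
    min_distance: int,
    seed: int,
    window_length: int | None = None,
) -> dict[str, list[dict]]:
    """Plant exact consensus copies in place; returns planted positions.

    Every hotspot independently receives one copy with probability p_hot at
    a uniform offset and strand.  The background — everything at least
    ``min_distance`` away from any hotspot, where coldspots can land — is
    tiled into windows of ``window_length`` (default: mean hotspot length),
    each receiving a copy with probability p_cold.
    """
    rng = np.random.default_rng(seed)
    win = int(window_length or round(hotspots.mean_length()))
    hot_by = hotspots.by_chrom()
    planted: dict[str, list[dict]] = {m.name: [] for m in motifs}

    for m in motifs:
        codes = np.array(["ACGT".index(c) for c in m.consensus.upper()], dtype=np.uint8)
        w = len(codes)
        if w > win or any(iv.length < w for iv in hotspots):
            raise SyntheticError(f"{m.name}: consensus longer than target regions")
        for iv in hotspots:
            if rng.random() < m.p_hot:
                off = int(rng.integers(0, iv.length - w + 1))
                strand = "+" if rng.random() < 0.5 else "-"
                _write_copy(genome[iv.chrom], iv.start + off, codes, strand)
                planted[m.name].append(
                    {"chrom": iv.chrom, "pos": iv.start + off, "strand": strand, "where": "hotspot"}
                )
        for chrom, arr in genome.items():
            zs, ze = _merge(
                [
                    (max(0, iv.start - min_distance), iv.end + min_distance)
                    for iv in hot_by.get(chrom, [])
                ]
            )
            # allowed background segments = complement of the exclusion zones
            bounds = [0] + [x for s, e in zip(zs, ze) for x in (s, e)] + [len(arr)]
            for seg_start, seg_end in zip(bounds[::2], bounds[1::2]):
                for wstart in range(seg_start, seg_end - win + 1, win):
                    if rng.random() < m.p_cold:
                        off = int(rng.integers(0, win - w + 1))
                        strand = "+" if rng.random() < 0.5 else "-"
                        _write_copy(arr, wstart + off, codes, strand)
                        planted[m.name].append(
                            {"chrom": chrom, "pos": wstart + off, "strand": strand,
                             "where": "background"}
                        )
    return planted


def codes_to_sequences(genome: Mapping[str, np.ndarray]) -> dict[str, str]:
    return {c: _BASES[arr].tobytes().decode("ascii") for c, arr in genome.items()}


@dataclass
class SyntheticWorld:
    config: SyntheticConfig
    genome: dict[str, str]
    chrom_sizes: dict[str, int]
    hotspots: RegionSet
    planted: dict[str, list[dict]]
    truth: dict


def generate_world(cfg: SyntheticConfig) -> SyntheticWorld:
    """Genome generation plus motif planting in one deterministic call."""
    codes, hotspots, truth = generate_genome_and_hotspots(cfg)
    planted = plant_motifs(
        codes, hotspots, cfg.motifs, cfg.min_distance, seed=cfg.seed + 1
    )
    genome = codes_to_sequences(codes)
    truth = dict(
        truth,
        motifs=[asdict(m) for m in cfg.motifs],
        planted_counts={k: len(v) for k, v in planted.items()},
    )
    return SyntheticWorld(
        config=cfg,
        genome=genome,
        chrom_sizes={c: len(s) for c, s in genome.items()},
        hotspots=hotspots,
        planted=planted,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Toy GO world


@dataclass
class GoWorld:
    dag: GoDag
    annotations: AnnotationMap
    obo_text: str
    marked_terms: set[str]
    hg_genes: list[str]
    background_genes: list[str]
    truth: dict

    @property
    def all_genes(self) -> list[str]:
        return self.hg_genes + self.background_genes


def _term_id(k: int) -> str:
    return f"GO:9{k:06d}"


def generate_go_world(cfg: SyntheticConfig) -> GoWorld:
    """Balanced is_a tree plus deterministic round-robin annotations.

    Genes named after the enriched motifs are annotated only to leaves of
    the marked subtree (the ``marked_child_index``-th child of the root);
    background genes cycle through all leaves uniformly.  The construction
    is deterministic, so every marked term's gap strictly exceeds every
    unmarked term's gap by design rather than in expectation.
    """
    go = cfg.go
    terms: dict[str, tuple[str, str]] = {_term_id(0): ("synthetic process root", "biological_process")}
    edges: list[tuple[str, str, str]] = []
    level = [0]
    counter = 1
    children: dict[int, list[int]] = {}
    for _ in range(go.depth):
        nxt = []
        for parent in level:
            kids = list(range(counter, counter + go.branching))
            counter += go.branching
            children[parent] = kids
            for k in kids:
                terms[_term_id(k)] = (f"synthetic process {k}", "biological_process")
                edges.append((_term_id(k), _term_id(parent), "is_a"))
            nxt.extend(kids)
        level = nxt
    dag = GoDag.from_edges(terms, edges)

    leaves = [_term_id(k) for k in level]
    hg_genes = sorted(m.name for m in cfg.motifs if m.enriched)
    background_genes = [f"gene{i:03d}" for i in range(go.n_background_genes)]

    if go.marked_child_index is not None:
        marked_root = _term_id(children[0][go.marked_child_index])
        marked_terms = dag.descendants(marked_root)
        marked_leaves = sorted(t for t in marked_terms if t in set(leaves))
    else:
        marked_terms, marked_leaves = set(), sorted(leaves)

    apg = go.annotations_per_gene
    pairs: list[tuple[str, str]] = []
    for i, g in enumerate(hg_genes):
        pool = marked_leaves
        pairs += [(g, pool[(i * apg + j) % len(pool)]) for j in range(apg)]
    for i, g in enumerate(background_genes):
        pairs += [(g, leaves[(i * apg + j) % len(leaves)]) for j in range(apg)]
    ann = AnnotationMap.from_pairs(pairs, dag)

    obo_lines = ["format-version: 1.2", "ontology: synthetic-go", ""]
    parent_of: dict[str, list[str]] = {}
    for child, parent, _ in edges:
        parent_of.setdefault(child, []).append(parent)
    for tid in sorted(terms):
        name, ns = terms[tid]
        obo_lines += [f"[Term]", f"id: {tid}", f"name: {name}", f"namespace: {ns}"]
        for p in parent_of.get(tid, []):
            obo_lines.append(f"is_a: {p} ! {terms[p][0]}")
        obo_lines.append("")
    truth = {
        "n_terms": len(terms),
        "marked_terms": sorted(marked_terms),
        "hg_genes": hg_genes,
    }
    return GoWorld(
        dag=dag,
        annotations=ann,
        obo_text="\n".join(obo_lines),
        marked_terms=marked_terms,
        hg_genes=hg_genes,
        background_genes=background_genes,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# File emission


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_annotations_tsv(ann: AnnotationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(ann.mapping):
            for term in sorted(ann.mapping[gene]):
                fh.write(f"{gene}\t{term}\n")


def write_world(world: SyntheticWorld, go_world: GoWorld, out_dir: str | Path) -> dict[str, Path]:
    """Emit FASTA, BED, chrom sizes, OBO, annotations and a JSON truth record."""
    from .regions import write_bed

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fa",
        "chrom_sizes": out / "genome.chrom.sizes",
        "hotspots": out / "hotspots.bed",
        "obo": out / "go.obo",
        "annotations": out / "annotations.tsv",
        "truth": out / "truth.json",
    }
    write_fasta(world.genome, paths["genome"])
    with open(paths["chrom_sizes"], "w") as fh:
        for c, n in world.chrom_sizes.items():
            fh.write(f"{c}\t{n}\n")
    write_bed(world.hotspots, paths["hotspots"])
    paths["obo"].write_text(go_world.obo_text)
    write_annotations_tsv(go_world.annotations, paths["annotations"])
    truth = {"world": world.truth, "go": go_world.truth, "planted": world.planted}
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return paths


# ---------------------------------------------------------------------------
# Independent Monte-Carlo oracle for planted-enrichment recovery


def planting_odds_interval(
    n_hot: int,
    n_cold: int,
    p_hot: float,
    p_cold: float,
    region_length: int,
    motif_width: int,
    p_threshold: float,
    n_replicates: int = 1,
    n_sims: int = 4000,
    seed: int = 12345,
) -> tuple[float, float, float]:
    """95% interval for the estimated odds ratio under the planting model.

    Simulated directly from the generative description, independently of the
    scanner and sampler: a hotspot shows a hit if it got a planted copy or a
    chance background match (per-window false-hit probability from the scan
    p-value threshold); a coldspot shows a hit if it fully contains a copy
    planted in the tiled background (containment probability simulated
    geometrically) or a chance match.  Returns (low, high, median).
    """
    rng = np.random.default_rng(seed)
    L, w = region_length, motif_width
    lam = 1.0 - (1.0 - p_threshold) ** (2 * max(0, L - w + 1))

    # geometric containment: a random L-window against the infinite L-tiling
    m = 200_000
    x = rng.integers(0, L, size=m)
    c0 = rng.random(m) < p_cold
    c1 = rng.random(m) < p_cold
    u0 = rng.integers(0, L - w + 1, size=m)
    u1 = rng.integers(0, L - w + 1, size=m)
    contain = (c0 & (u0 >= x)) | (c1 & (u1 <= x - w))
    p_contain = contain.mean()

    q_hot = 1.0 - (1.0 - p_hot) * (1.0 - lam)
    q_cold = 1.0 - (1.0 - p_contain) * (1.0 - lam)

    hm = rng.binomial(n_hot, q_hot, size=n_sims)
    cm = rng.binomial(n_cold, q_cold, size=(n_sims, n_replicates)).mean(axis=1)
    ok = (hm > 0) & (hm < n_hot) & (cm > 0) & (cm < n_cold)
    o = (hm[ok] / (n_hot - hm[ok])) / (cm[ok] / (n_cold - cm[ok]))
    lo, med, hi = np.percentile(o, [2.5, 50.0, 97.5])
    return float(lo), float(hi), float(med)
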