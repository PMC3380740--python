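"""GO semantic similarity and the gap enrichment statistic.

Term-to-term similarity is the Wang graph-based measure: each ancestor a of
a term t gets an S-value S_t(t) = 1, S_t(a) = max over children c (on paths
to t) of w_edge * S_t(c), with edge weights 0.8 for is_a and 0.6 for
part_of; the similarity of two terms is the sum of both S-values over their
common ancestors divided by the sum of all their S-values.  From this:

* S(t, g)  — mean similarity of t to the terms annotating gene g;
* S(t, G)  — mean of S(t, g) over a gene set;
* gap(t)   = (S(t, HG) - S(t, G)) / S(t, G), the relative excess of t's
  similarity to the candidate trans-regulators HG over the whole gene
  background G.  Large gaps mark functions enriched among high-odds-ratio
  genes.

Cross-namespace similarity is defined as 0.  Genes without annotations are
excluded from averages rather than scored 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet

DEFAULT_EDGE_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


class GoError(ValueError):
    pass


class GoDag:
    """A GO DAG: nodes are term ids, directed edges run child -> parent."""

    def __init__(self, graph: nx.DiGraph):
        if not nx.is_directed_acyclic_graph(graph):
            raise GoError("ontology graph contains a cycle")
        self.graph = graph

    @classmethod
    def from_edges(
        cls,
        terms: Mapping[str, tuple[str, str]],
        edges: Iterable[tuple[str, str, str]],
    ) -> "GoDag":
        """Build from {term: (name, namespace)} and (child, parent, relation) triples."""
        g = nx.DiGraph()
        for tid, (name, ns) in terms.items():
            g.add_node(tid, name=name, namespace=ns)
        for child, parent, rel in edges:
            if child not in g or parent not in g:
                raise GoError(f"edge references unknown term: {child} -> {parent}")
            g.add_edge(child, parent, relation=rel)
        return cls(g)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def __len__(self) -> int:
        return len(self.graph)

    @property
    def terms(self) -> list[str]:
        return list(self.graph.nodes)

    def name(self, term: str) -> str:
        return self.graph.nodes[term].get("name", term)

    def namespace(self, term: str) -> str:
        return self.graph.nodes[term].get("namespace", "")

    def roots(self) -> list[str]:
        return [t for t in self.graph if self.graph.out_degree(t) == 0]

    def ancestor_closure(self, term: str) -> set[str]:
        """The term itself plus all ancestors reachable over is_a/part_of."""
        if term not in self.graph:
            raise GoError(f"unknown term {term!r}")
        return {term} | nx.descendants(self.graph, term)

    def descendants(self, term: str) -> set[str]:
        """The term itself plus all terms below it."""
        if term not in self.graph:
            raise GoError(f"unknown term {term!r}")
        return {term} | nx.ancestors(self.graph, term)


def parse_obo(path: str | Path) -> GoDag:
    """Parse an OBO 1.2 ontology, keeping is_a and part_of edges.

    Obsolete terms are skipped; relationship types other than part_of are
    ignored.
    """
    multi = obonet.read_obo(str(path), ignore_obsolete=True)
    g = nx.DiGraph()
    for node, data in multi.nodes(data=True):
        g.add_node(node, name=data.get("name", node), namespace=data.get("namespace", ""))
    for child, parent, rel in multi.edges(keys=True):
        if rel in ("is_a", "part_of"):
            g.add_edge(child, parent, relation=rel)
    return GoDag(g)


@dataclass
class AnnotationMap:
    """gene -> T(g), the set of GO terms annotating the gene."""

    mapping: dict[str, frozenset[str]] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]], dag: GoDag) -> "AnnotationMap":
        acc: dict[str, set[str]] = {}
        dropped = 0
        for gene, term in pairs:
            if term not in dag:
                dropped += 1
                continue
            acc.setdefault(gene, set()).add(term)
        if dropped:
            warnings.warn(f"dropped {dropped} annotations to unknown terms", stacklevel=3)
        return cls({g: frozenset(ts) for g, ts in acc.items()})

    @classmethod
    def from_tsv(cls, path: str | Path, dag: GoDag) -> "AnnotationMap":
        """Two-column gene<TAB>term file; lines starting with # or ! skipped."""
        pairs = []
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith(("#", "!")):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise GoError(f"annotation line needs 2 columns: {line!r}")
            pairs.append((parts[0], parts[1]))
        return cls.from_pairs(pairs, dag)

    @classmethod
    def from_gaf(cls, path: str | Path, dag: GoDag) -> "AnnotationMap":
        """GAF 2.x: gene symbol from column 3, GO id from column 5."""
        pairs = []
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("!"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise GoError("GAF line with fewer than 5 columns")
            pairs.append((parts[2], parts[4]))
        return cls.from_pairs(pairs, dag)

    def terms_of(self, gene: str) -> frozenset[str]:
        return self.mapping.get(gene, frozenset())

    def annotated(self, genes: Iterable[str]) -> list[str]:
        return [g for g in genes if self.mapping.get(g)]

    def __contains__(self, gene: str) -> bool:
        return gene in self.mapping


@dataclass
class GeneSet:
    label: str
    genes: list[str]


class TermSimilarity:
    """Cached Wang-measure similarity over one DAG."""

    def __init__(
        self,
        dag: GoDag,
        w_isa: float = 0.8,
        w_partof: float = 0.6,
    ) -> None:
        self.dag = dag
        self.weights = {"is_a": w_isa, "part_of": w_partof}
        self._svals: dict[str, dict[str, float]] = {}
        self._cache: dict[tuple[str, str], float] = {}

    def s_values(self, term: str) -> dict[str, float]:
        """S_t(a) for every a in the ancestor closure of t (including t)."""
        cached = self._svals.get(term)
        if cached is not None:
            return cached
        closure = self.dag.ancestor_closure(term)
        sub = self.dag.graph.subgraph(closure)
        sv: dict[str, float] = {term: 1.0}
        for node in nx.topological_sort(sub):  # children before parents
            if node == term:
                continue
            sv[node] = max(
                self.weights.get(sub.edges[c, node]["relation"], 0.0) * sv[c]
                for c in sub.predecessors(node)
            )
        self._svals[term] = sv
        return sv

    def __call__(self, t1: str, t2: str) -> float:
        if t1 not in self.dag or t2 not in self.dag:
            raise GoError(f"unknown term in sim({t1!r}, {t2!r})")
        if self.dag.namespace(t1) != self.dag.namespace(t2):
            return 0.0
        if t1 == t2:
            return 1.0
        key = (t1, t2) if t1 <= t2 else (t2, t1)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        s1, s2 = self.s_values(t1), self.s_values(t2)
        common = s1.keys() & s2.keys()
        num = sum(s1[a] + s2[a] for a in common)
        sim = num / (sum(s1.values()) + sum(s2.values())) if common else 0.0
        self._cache[key] = sim
        return sim


def term_gene_similarity(sim: TermSimilarity, term: str, gene: str, ann: AnnotationMap) -> float:
    """S(t, g): mean of sim(t, t') over the terms t' annotating g."""
    tg = ann.terms_of(gene)
    if not tg:
        raise GoError(f"gene {gene!r} has no annotations")
    return sum(sim(term, t2) for t2 in tg) / len(tg)


def term_geneset_similarity(
    sim: TermSimilarity, term: str, genes: Sequence[str] | GeneSet, ann: AnnotationMap
) -> float:
    """S(t, G): mean of S(t, g) over the annotated genes of G."""
    if isinstance(genes, GeneSet):
        genes = genes.genes
    kept = ann.annotated(genes)
    if not kept:
        raise GoError("gene set has no annotated genes")
    return sum(term_gene_similarity(sim, term, g, ann) for g in kept) / len(kept)


def gap_score(
    sim: TermSimilarity,
    term: str,
    hg: Sequence[str] | GeneSet,
    background: Sequence[str] | GeneSet,
    ann: AnnotationMap,
) -> float:
    """gap(t) = (S(t, HG) - S(t, G)) / S(t, G); 0 with a warning when S(t, G) = 0."""
    s_bg = term_geneset_similarity(sim, term, background, ann)
    s_hg = term_geneset_similarity(sim, term, hg, ann)
    if s_bg == 0:
        warnings.warn(f"S(t, G) = 0 for {term}; gap set to 0", stacklevel=2)
        return 0.0
    return (s_hg - s_bg) / s_bg


def candidate_terms(dag: GoDag, ann: AnnotationMap, genes: Iterable[str]) -> set[str]:
    """All terms annotating at least one gene, plus their ancestors."""
    out: set[str] = set()
    for g in genes:
        for t in ann.terms_of(g):
            out |= dag.ancestor_closure(t)
    return out


def rank_terms_by_gap(
    sim: TermSimilarity,
    terms: Iterable[str] | None,
    hg: Sequence[str] | GeneSet,
    background: Sequence[str] | GeneSet,
    ann: AnnotationMap,
    top_k: int | None = None,
    namespace: str = "biological_process",
) -> list[tuple[str, float]]:
    """Rank candidate terms by descending gap, ties broken by term id.

    When ``terms`` is None the candidate universe is every term annotating a
    background gene plus ancestors, restricted to ``namespace``.
    """
    bg_genes = background.genes if isinstance(background, GeneSet) else background
    if terms is None:
        terms = candidate_terms(sim.dag, ann, bg_genes)
    pool = sorted(t for t in terms if not namespace or sim.dag.namespace(t) == namespace)
    if not pool:
        raise GoError("empty candidate term list")
    scored = [(t, gap_score(sim, t, hg, background, ann)) for t in pool]
    scored.sort(key=lambda x: (-x[1], x[0]))
    return scored[:top_k] if top_k else scored


def gene_to_reference_terms(
    sim: TermSimilarity, gene: str, reference_terms: Sequence[str], ann: AnnotationMap
) -> float:
    """Mean of S(t, g) over a list of reference terms (e.g. DNA recombination,
    meiosis) — a per-gene relevance score."""
    if not reference_terms:
        raise GoError("no reference terms given")
    return sum(term_gene_similarity(sim, t, gene, ann) for t in reference_terms) / len(
        reference_terms
    )
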