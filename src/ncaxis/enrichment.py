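"""Interactor expansion and GO over-representation analysis.

Retained genes are expanded with their first-degree BioGRID partners, then
tested for GO-term over-representation: a right-tailed hypergeometric test
per term, corrected by Holm's step-down procedure (the "Bonferroni
step-down" of ClueGO), significant at p_adjusted < alpha.

Annotations are restricted to experimental evidence codes by default and
propagated up the ontology (is_a and part_of), so a gene annotated to a term
is annotated to every ancestor of that term.  The background population
defaults to all annotated genes of the loaded GAF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import obonet
from scipy.stats import hypergeom

from ncaxis.io_tables import GeneSet, InteractionTable, identifier_key

__all__ = [
    "EXPERIMENTAL_EVIDENCE_CODES",
    "AnnotationSet",
    "EnrichmentResult",
    "Ontology",
    "enrich",
    "expand_interactors",
    "holm_adjust",
    "load_annotations",
    "load_ontology",
]

#: GO experimental evidence codes (the "All_Experimental" selection):
#: classic experimental codes plus their high-throughput counterparts.
EXPERIMENTAL_EVIDENCE_CODES = frozenset(
    {"EXP", "IDA", "IPI", "IMP", "IGI", "IEP", "HTP", "HDA", "HMP", "HGI", "HEP"}
)

_PROPAGATE_RELATIONS = ("is_a", "part_of")
GO_NAMESPACES = ("biological_process", "cellular_component", "molecular_function")


def expand_interactors(genes: GeneSet, biogrid: InteractionTable) -> GeneSet:
    """Expand *genes* with all first-degree interaction partners.

    Returns the union of the input genes and every partner of any input gene
    in *biogrid*; ``metadata["contributions"]`` records which input gene
    contributed which partners.  Self-pairs contribute nothing new.
    """
    adjacency: dict[str, set[str]] = {}
    display: dict[str, str] = {}
    for rec in biogrid:
        a, b = rec.nc_key, rec.target_key
        display.setdefault(a, rec.nc_name)
        display.setdefault(b, rec.target_name)
        adjacency.setdefault(a, set()).add(b)
        adjacency.setdefault(b, set()).add(a)

    members = set(genes.members)
    contributions: dict[str, list[str]] = {}
    for gene in genes:
        key = identifier_key(gene)
        partners = adjacency.get(key, set()) - {key}
        if partners:
            contributions[gene] = sorted(display[p] for p in partners)
            members.update(display[p] for p in partners)
    return GeneSet(
        members=members,
        role="interactor",
        label=genes.label,
        metadata={"contributions": contributions},
    )


@dataclass
class Ontology:
    """A GO-style ontology: terms, is_a/part_of parent links, obsolete flags."""

    graph: nx.MultiDiGraph  # obonet convention: edges point child -> parent
    obsolete: set[str] = field(default_factory=set)

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes) - self.obsolete

    def name(self, term: str) -> str:
        return self.graph.nodes[term].get("name", term)

    def namespace(self, term: str) -> str:
        return self.graph.nodes[term].get("namespace", "")

    def parents(self, term: str) -> set[str]:
        return {
            parent
            for _, parent, rel in self.graph.out_edges(term, keys=True)
            if rel in _PROPAGATE_RELATIONS
        }

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable via is_a/part_of, excluding *term* itself."""
        seen: set[str] = set()
        frontier = [term]
        while frontier:
            node = frontier.pop()
            for parent in self.parents(node):
                if parent not in seen:
                    seen.add(parent)
                    frontier.append(parent)
        return seen


def load_ontology(obo_path: str | Path) -> Ontology:
    """Load an OBO 1.2/1.4 ontology file.

    Raises if the is_a/part_of parent graph is cyclic.
    """
    graph = obonet.read_obo(obo_path, ignore_obsolete=False)
    obsolete = {
        n for n, d in graph.nodes(data=True) if str(d.get("is_obsolete", "")).lower() == "true"
    }
    parent_graph = nx.DiGraph(
        (u, v) for u, v, rel in graph.edges(keys=True) if rel in _PROPAGATE_RELATIONS
    )
    if not nx.is_directed_acyclic_graph(parent_graph):
        raise ValueError(f"{obo_path}: is_a/part_of parent graph contains a cycle")
    return Ontology(graph=graph, obsolete=obsolete)


@dataclass
class AnnotationSet:
    """Ancestor-propagated term -> gene mapping plus the background population."""

    term_to_genes: dict[str, set[str]]
    evidence_filter: set[str]
    population: set[str]
    n_skipped_unknown_term: int = 0
    n_filtered_evidence: int = 0
    n_skipped_qualifier: int = 0

    def genes_for(self, term: str) -> set[str]:
        return self.term_to_genes.get(term, set())


def load_annotations(
    gaf_path: str | Path,
    ontology: Ontology,
    evidence_codes: frozenset[str] | set[str] = EXPERIMENTAL_EVIDENCE_CODES,
) -> AnnotationSet:
    """Load GAF 2.x annotations, filter by evidence code, propagate ancestors.

    Annotations to unknown or obsolete terms are skipped and counted, as are
    rows excluded by the evidence filter or carrying a NOT qualifier.
    Obsolete terms carry no annotations after loading.
    """
    evidence_codes = set(evidence_codes)
    term_to_genes: dict[str, set[str]] = {}
    population: set[str] = set()
    n_unknown = n_evidence = n_qualifier = 0
    ancestor_cache: dict[str, set[str]] = {}
    with open(gaf_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 15:
                continue
            symbol, qualifier, term, evidence = cols[2].strip(), cols[3], cols[4].strip(), cols[6].strip()
            if not symbol or not term:
                continue
            if "NOT" in qualifier.split("|"):
                n_qualifier += 1
                continue
            if evidence not in evidence_codes:
                n_evidence += 1
                continue
            if term not in ontology.graph.nodes or term in ontology.obsolete:
                n_unknown += 1
                continue
            if term not in ancestor_cache:
                ancestor_cache[term] = {term} | (
                    ontology.ancestors(term) - ontology.obsolete
                )
            for t in ancestor_cache[term]:
                term_to_genes.setdefault(t, set()).add(symbol)
            population.add(symbol)
    return AnnotationSet(
        term_to_genes=term_to_genes,
        evidence_filter=evidence_codes,
        population=population,
        n_skipped_unknown_term=n_unknown,
        n_filtered_evidence=n_evidence,
        n_skipped_qualifier=n_qualifier,
    )


def holm_adjust(pvalues: list[float]) -> list[float]:
    """Holm (Bonferroni step-down) adjusted p-values, in input order.

    Sort raw p ascending; adjusted_i = max over j <= i of min(1, (m-j+1)*p_j)
    with 1-based rank j.  The running maximum enforces monotonicity.
    """
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order, start=1):
        running = max(running, min(1.0, (m - rank + 1) * pvalues[idx]))
        adjusted[idx] = running
    return adjusted


@dataclass
class EnrichmentResult:
    """Per-term over-representation test outcome."""

    term: str
    name: str
    namespace: str
    study_count: int
    study_size: int
    pop_count: int
    pop_size: int
    p_raw: float
    p_adjusted: float
    significant: bool
    study_genes: tuple[str, ...] = ()


def enrich(
    study: GeneSet,
    annotations: AnnotationSet,
    ontology: Ontology | None = None,
    alpha: float = 0.05,
    min_study_count: int = 2,
) -> list[EnrichmentResult]:
    """Right-tailed hypergeometric over-representation test with Holm correction.

    Study genes outside the annotation population are dropped with a warning
    count.  Terms with study_count below ``min_study_count`` are not tested.
    Results are sorted by adjusted p-value, then raw p, then term id;
    ``significant`` means p_adjusted < alpha.
    """
    pop_by_key = {identifier_key(g): g for g in annotations.population}
    study_genes = {pop_by_key[identifier_key(g)] for g in study if identifier_key(g) in pop_by_key}
    dropped = len(study) - len(study_genes)
    if dropped:
        warnings.warn(
            f"{dropped} study gene(s) absent from the annotation population were dropped",
            stacklevel=2,
        )
    if not study_genes:
        warnings.warn("empty study set after intersecting with population", stacklevel=2)
        return []

    pop_size = len(annotations.population)
    study_size = len(study_genes)
    tested: list[tuple[str, int, int, set[str]]] = []
    for term, genes in annotations.term_to_genes.items():
        hits = study_genes & genes
        if len(hits) < min_study_count:
            continue
        tested.append((term, len(hits), len(genes), hits))
    if not tested:
        return []

    p_raws = [
        float(hypergeom.sf(study_count - 1, pop_size, pop_count, study_size))
        for _, study_count, pop_count, _ in tested
    ]
    p_adjs = holm_adjust(p_raws)
    results = [
        EnrichmentResult(
            term=term,
            name=ontology.name(term) if ontology else term,
            namespace=ontology.namespace(term) if ontology else "",
            study_count=study_count,
            study_size=study_size,
            pop_count=pop_count,
            pop_size=pop_size,
            p_raw=p_raw,
            p_adjusted=p_adj,
            significant=p_adj < alpha,
            study_genes=tuple(sorted(hits)),
        )
        for (term, study_count, pop_count, hits), p_raw, p_adj in zip(tested, p_raws, p_adjs)
    ]
    results.sort(key=lambda r: (r.p_adjusted, r.p_raw, r.term))
    return results


def write_enrichment_tsv(results: list[EnrichmentResult], path: str | Path) -> None:
    """Write enrichment results as a TSV report."""
    with open(path, "w") as fh:
        fh.write(
            "term\tname\tnamespace\tstudy_count\tstudy_size\tpop_count\tpop_size\t"
            "p_raw\tp_adjusted\tsignificant\tstudy_genes\n"
        )
        for r in results:
            fh.write(
                f"{r.term}\t{r.name}\t{r.namespace}\t{r.study_count}\t{r.study_size}\t"
                f"{r.pop_count}\t{r.pop_size}\t{r.p_raw:.6g}\t{r.p_adjusted:.6g}\t"
                f"{str(r.significant).lower()}\t{','.join(r.study_genes)}\n"
            )
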