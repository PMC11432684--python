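"""Seed-anchored tripartite network construction, thresholding, and pruning.

The extraction protocol is two-step.  From a curated seed list (mRNA and
protein biomarkers are one "seed-matchable" class):

1. extract every primary ncRNA (miRNA by default) with at least one
   interaction to a seed;
2. extract every secondary ncRNA (lncRNA) with at least one interaction to a
   seed *and* at least one interaction to a miRNA — any miRNA, which is what
   lets seedless miRNA blocks enter the network through their governing
   lncRNAs;
3. the final miRNA layer is the union of step-1 miRNAs and the miRNA
   neighbors of step-2 lncRNAs.

Edges are the input rows among retained nodes, collapsed to unique pairs
carrying an ``evidence_count`` (number of supporting rows).  Only the three
tripartite pair types exist: seed-miRNA, seed-lncRNA, miRNA-lncRNA.

Two reduction operators follow: an occurrence threshold (markers occurring
fewer than *k* times are expunged) and single-interactor pruning (markers
with exactly one interactor are removed, retaining loop-capable elements).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx

from ncaxis.io_tables import GeneSet, InteractionTable, identifier_key

__all__ = [
    "TripartiteNetwork",
    "build_axis",
    "threshold_filter",
    "prune_single_interactors",
]

_ALLOWED_PAIRS = {
    frozenset({"seed", "miRNA"}),
    frozenset({"seed", "lncRNA"}),
    frozenset({"miRNA", "lncRNA"}),
}


@dataclass
class TripartiteNetwork:
    """Typed undirected graph over seed, miRNA, and lncRNA nodes.

    Nodes are display identifiers with a ``node_type`` attribute; edges carry
    ``evidence_count`` (>= 1 supporting interaction rows).
    """

    graph: nx.Graph
    seed_set: GeneSet
    threshold_applied: int = 0
    unmatched_seeds: set[str] = field(default_factory=set)

    def nodes_of_type(self, node_type: str) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["node_type"] == node_type}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_type(self, node: str) -> str:
        return self.graph.nodes[node]["node_type"]

    def validate(self) -> None:
        """Raise if structural invariants are violated."""
        for u, v, d in self.graph.edges(data=True):
            pair = frozenset({self.node_type(u), self.node_type(v)})
            if pair not in _ALLOWED_PAIRS:
                raise ValueError(f"forbidden edge type pair {set(pair)} on ({u}, {v})")
            if d.get("evidence_count", 0) < 1:
                raise ValueError(f"edge ({u}, {v}) has evidence_count < 1")

    def copy(self) -> "TripartiteNetwork":
        return TripartiteNetwork(
            graph=self.graph.copy(),
            seed_set=self.seed_set,
            threshold_applied=self.threshold_applied,
            unmatched_seeds=set(self.unmatched_seeds),
        )

    def summary(self) -> dict[str, int]:
        return {
            "seeds": len(self.nodes_of_type("seed")),
            "miRNA": len(self.nodes_of_type("miRNA")),
            "lncRNA": len(self.nodes_of_type("lncRNA")),
            "nodes": self.n_nodes,
            "edges": self.n_edges,
        }


def _classify_pairs(table: InteractionTable, seeds: GeneSet, primary: str, secondary: str):
    """Classify each row into one of the three tripartite pair categories.

    Returns (seed_primary, seed_secondary, primary_secondary) lists of
    key-pairs plus a display-name map.  mRNA and protein targets are a single
    seed-matchable class; rows involving "other" types, or targets not in the
    seed list, contribute nothing.
    """
    display: dict[str, str] = {}
    seed_primary: list[tuple[str, str]] = []
    seed_secondary: list[tuple[str, str]] = []
    primary_secondary: list[tuple[str, str]] = []

    for rec in table:
        ends = (
            (rec.nc_key, rec.nc_name, rec.nc_type),
            (rec.target_key, rec.target_name, rec.target_type),
        )
        for (ka, na, ta), (kb, nb, tb) in (ends, ends[::-1]):
            seed_side = tb in ("mRNA", "protein") and kb in seeds.keys
            if ta == primary and seed_side:
                seed_primary.append((kb, ka))
            elif ta == secondary and seed_side:
                seed_secondary.append((kb, ka))
            elif ta == primary and tb == secondary:
                primary_secondary.append((ka, kb))
            else:
                continue
            display.setdefault(ka, na)
            display.setdefault(kb, seeds.display(nb) if seed_side else nb)
    return seed_primary, seed_secondary, primary_secondary, display


def build_axis(
    table: InteractionTable,
    seeds: GeneSet,
    primary_nc: str = "miRNA",
    secondary_nc: str = "lncRNA",
) -> TripartiteNetwork:
    """Construct the seed-anchored tripartite network via two-step extraction.

    If no seed matches any row, an empty network is returned with a warning
    listing the unmatched seeds.
    """
    seed_primary, seed_secondary, primary_secondary, display = _classify_pairs(
        table, seeds, primary_nc, secondary_nc
    )

    # step 1: primary ncRNAs with >=1 seed interaction
    m0 = {m for _, m in seed_primary}
    # step 2: secondary ncRNAs with >=1 seed interaction and >=1 primary interaction
    sec_with_seed = {l for _, l in seed_secondary}
    sec_with_primary = {l for _, l in primary_secondary}
    lnc = sec_with_seed & sec_with_primary
    # step 3: final primary layer = step-1 set plus primary neighbors of step-2 set
    mirna = m0 | {m for m, l in primary_secondary if l in lnc}

    edges: Counter[tuple[str, str]] = Counter()
    matched_seeds: set[str] = set()
    for s, m in seed_primary:
        if m in mirna:
            edges[(s, m)] += 1
            matched_seeds.add(s)
    for s, l in seed_secondary:
        if l in lnc:
            edges[(s, l)] += 1
            matched_seeds.add(s)
    for m, l in primary_secondary:
        if m in mirna and l in lnc:
            edges[(m, l)] += 1

    g = nx.Graph()
    type_of = {}
    for s in matched_seeds:
        type_of[s] = "seed"
    for m in mirna:
        type_of[m] = "miRNA"
    for l in lnc:
        type_of[l] = "lncRNA"
    for key, node_type in type_of.items():
        g.add_node(display[key], node_type=node_type)
    for (a, b), count in edges.items():
        g.add_edge(display[a], display[b], evidence_count=count)
    # retained nodes must have >=1 edge; step sets are edge-defined already,
    # but guard against rows whose partner fell outside the retained sets
    g.remove_nodes_from([n for n in list(g.nodes) if g.degree(n) == 0])

    any_seed_row = any(
        identifier_key(n) in seeds.keys
        for rec in table
        for n, t in ((rec.nc_name, rec.nc_type), (rec.target_name, rec.target_type))
        if t in ("mRNA", "protein")
    )
    unmatched = {s for s in seeds.members if identifier_key(s) not in matched_seeds}
    if seeds.keys and not any_seed_row:
        warnings.warn(
            "no seed matches any interaction row; unmatched seeds: "
            + ", ".join(sorted(unmatched)),
            stacklevel=2,
        )
    return TripartiteNetwork(graph=g, seed_set=seeds, unmatched_seeds=unmatched)


def _scope_nodes(network: TripartiteNetwork, scope) -> set[str]:
    if scope in (None, "all", "all_nodes"):
        return set(network.graph.nodes)
    if scope == "ncRNA":
        scope = ("miRNA", "lncRNA")
    if scope == "seeds_only":
        scope = ("seed",)
    if isinstance(scope, str):
        scope = (scope,)
    wanted = set(scope)
    return {n for n in network.graph.nodes if network.node_type(n) in wanted}


def threshold_filter(
    network: TripartiteNetwork,
    k: int,
    mode: str = "degree",
    scope="ncRNA",
) -> TripartiteNetwork:
    """Expunge every node in *scope* occurring fewer than *k* times.

    Occurrence is the number of distinct neighbors (``mode="degree"``,
    default, robust to redundant database rows) or the total number of
    supporting rows (``mode="rows"``).  Applied as a single simultaneous
    pass; k=1 is the identity.
    """
    if k < 1:
        raise ValueError(f"threshold k must be >= 1, got {k}")
    if mode not in ("degree", "rows"):
        raise ValueError(f"mode must be 'degree' or 'rows', got {mode!r}")
    out = network.copy()
    g = out.graph
    doomed = []
    for n in _scope_nodes(network, scope):
        if mode == "degree":
            occ = g.degree(n)
        else:
            occ = sum(d["evidence_count"] for _, _, d in g.edges(n, data=True))
        if occ < k:
            doomed.append(n)
    g.remove_nodes_from(doomed)
    out.threshold_applied = k
    return out


def prune_single_interactors(
    network: TripartiteNetwork,
    scope: str = "seeds_only",
    fixed_point: bool = False,
) -> TripartiteNetwork:
    """Remove nodes in *scope* with exactly one interactor.

    One simultaneous pass removes every in-scope node of degree 1, then every
    node left with zero neighbors.  With ``fixed_point=True`` the pass
    repeats until no change (idempotent at the fixed point).
    """
    out = network.copy()
    g = out.graph
    while True:
        in_scope = _scope_nodes(out, scope)
        singles = [n for n in in_scope if g.degree(n) == 1]
        g.remove_nodes_from(singles)
        isolated = [n for n in g.nodes if g.degree(n) == 0]
        g.remove_nodes_from(isolated)
        if not fixed_point or (not singles and not isolated):
            break
    return out
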