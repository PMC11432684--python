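"""miRNA-block detection, governed-gene queries, and sponge-state propagation.

A *miRNA block* is a set of miRNAs with no interactions to any seed, held in
the network only through shared governing lncRNAs (the recurring
NEAT1/MALAT1 pattern).  Blocks are operationalized as connected components of
the bipartite subgraph on lncRNA nodes and seedless miRNA nodes.

The *governed genes* reverse query asks which mRNAs/proteins interact with an
lncRNA that itself binds at least ``min_links`` distinct block miRNAs.

State propagation encodes ceRNA (sponge) logic as binary states: an
*expressed* lncRNA sponges (inhibits) its neighbor miRNAs; a miRNA left
*active* (no expressed lncRNA neighbor) represses its neighbor seed genes.
Direct seed-lncRNA edges have no agreed propagation rule and are surfaced as
``unresolved_edges`` rather than guessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ncaxis.axis import TripartiteNetwork
from ncaxis.io_tables import GeneSet, InteractionTable, identifier_key

__all__ = [
    "MiRNABlock",
    "StateMap",
    "detect_mirna_blocks",
    "governed_genes",
    "propagate_states",
]


@dataclass
class MiRNABlock:
    """A maximal seedless miRNA set plus its lncRNA governors.

    ``governors`` maps each governing lncRNA to its degree into the block
    (number of member miRNAs it binds).
    """

    mirnas: set[str]
    governors: dict[str, int]
    source_network: TripartiteNetwork | None = None

    def __len__(self) -> int:
        return len(self.mirnas)

    def ranked_governors(self) -> list[tuple[str, int]]:
        """Governors ranked by within-block degree (descending), then name."""
        return sorted(self.governors.items(), key=lambda kv: (-kv[1], kv[0]))

    @property
    def mirna_keys(self) -> set[str]:
        return {identifier_key(m) for m in self.mirnas}


def seedless_mirnas(network: TripartiteNetwork) -> set[str]:
    """miRNA nodes with zero edges to seed nodes."""
    g = network.graph
    return {
        m
        for m in network.nodes_of_type("miRNA")
        if not any(network.node_type(nb) == "seed" for nb in g.neighbors(m))
    }


def detect_mirna_blocks(network: TripartiteNetwork, min_size: int = 5) -> list[MiRNABlock]:
    """Find lncRNA-governed miRNA blocks, largest first.

    Restricts to the bipartite subgraph on lncRNA nodes and seedless miRNAs;
    blocks are its connected components containing at least ``min_size``
    miRNAs.  Components with no lncRNA, or isolated lncRNAs, never qualify.
    """
    import networkx as nx

    if min_size < 1:
        raise ValueError(f"min_size must be >= 1, got {min_size}")
    g = network.graph
    free = seedless_mirnas(network)
    lnc = network.nodes_of_type("lncRNA")
    sub = g.subgraph(free | lnc)
    blocks: list[MiRNABlock] = []
    for comp in nx.connected_components(sub):
        members = comp & free
        if len(members) < min_size:
            continue
        governors = {
            l: sum(1 for nb in sub.neighbors(l) if nb in members)
            for l in comp & lnc
        }
        governors = {l: d for l, d in governors.items() if d > 0}
        if not governors:
            continue  # every block member must be held by >= 1 governor
        blocks.append(MiRNABlock(mirnas=set(members), governors=governors, source_network=network))
    blocks.sort(key=lambda b: (-len(b.mirnas), min(b.mirnas)))
    return blocks


def governed_genes(
    table: InteractionTable,
    block: MiRNABlock,
    min_links: int = 2,
) -> GeneSet:
    """mRNAs/proteins interacting with lncRNAs that bind >= min_links block miRNAs.

    Links are counted as *distinct* block miRNAs per lncRNA, not rows.  The
    qualifying lncRNAs are returned in ``metadata["qualifying_lncrnas"]``.
    """
    if min_links < 1:
        raise ValueError(f"min_links must be >= 1, got {min_links}")
    block_keys = block.mirna_keys
    if not block_keys:
        return GeneSet(members=set(), role="governed", label="governed")

    # distinct block miRNAs per lncRNA
    links: dict[str, set[str]] = {}
    display: dict[str, str] = {}
    for rec in table:
        ends = (
            (rec.nc_key, rec.nc_name, rec.nc_type),
            (rec.target_key, rec.target_name, rec.target_type),
        )
        for (ka, na, ta), (kb, _, tb) in (ends, ends[::-1]):
            if ta == "lncRNA" and tb == "miRNA" and kb in block_keys:
                links.setdefault(ka, set()).add(kb)
                display.setdefault(ka, na)
    qualifying = {l for l, ms in links.items() if len(ms) >= min_links}

    members: set[str] = set()
    for rec in table:
        ends = (
            (rec.nc_key, rec.nc_type, rec.nc_name),
            (rec.target_key, rec.target_type, rec.target_name),
        )
        for (ka, ta, _), (kb, tb, nb) in (ends, ends[::-1]):
            if ta == "lncRNA" and ka in qualifying and tb in ("mRNA", "protein"):
                members.add(nb)
    return GeneSet(
        members=members,
        role="governed",
        label="governed",
        metadata={"qualifying_lncrnas": sorted(display[l] for l in qualifying)},
    )


@dataclass
class StateMap:
    """Binary regulatory states after sponge-logic propagation."""

    lncrna_states: dict[str, str] = field(default_factory=dict)  # expressed | down
    mirna_states: dict[str, str] = field(default_factory=dict)  # active | sponged
    gene_states: dict[str, str] = field(default_factory=dict)  # repressed | uninhibited
    unresolved_edges: list[tuple[str, str]] = field(default_factory=list)


def propagate_states(
    network: TripartiteNetwork,
    assigned: dict[str, str] | None = None,
) -> StateMap:
    """Propagate an lncRNA expression hypothesis down the axis.

    Unassigned lncRNAs default to "expressed".  A miRNA is "sponged" iff any
    neighbor lncRNA is expressed, else "active" (including miRNAs with no
    lncRNA neighbor).  A seed gene is "repressed" iff any neighbor miRNA is
    active, else "uninhibited".  Seed-lncRNA edges are not propagated
    through; they are listed in ``unresolved_edges``.  The result is
    independent of node iteration order.
    """
    assigned = assigned or {}
    g = network.graph
    lnc_nodes = network.nodes_of_type("lncRNA")
    key_to_node = {identifier_key(n): n for n in lnc_nodes}
    resolved: dict[str, str] = {}
    for name, state in assigned.items():
        node = key_to_node.get(identifier_key(name))
        if node is None:
            raise KeyError(f"assigned state for {name!r}: not an lncRNA node of the network")
        if state not in ("expressed", "down"):
            raise ValueError(f"state for {name!r} must be 'expressed' or 'down', got {state!r}")
        resolved[node] = state

    lnc_states = {l: resolved.get(l, "expressed") for l in lnc_nodes}
    mirna_states = {}
    for m in network.nodes_of_type("miRNA"):
        sponged = any(
            network.node_type(nb) == "lncRNA" and lnc_states[nb] == "expressed"
            for nb in g.neighbors(m)
        )
        mirna_states[m] = "sponged" if sponged else "active"
    gene_states = {}
    for s in network.nodes_of_type("seed"):
        repressed = any(
            network.node_type(nb) == "miRNA" and mirna_states[nb] == "active"
            for nb in g.neighbors(s)
        )
        gene_states[s] = "repressed" if repressed else "uninhibited"
    unresolved = sorted(
        (u, v) if network.node_type(u) == "seed" else (v, u)
        for u, v in g.edges
        if {network.node_type(u), network.node_type(v)} == {"seed", "lncRNA"}
    )
    return StateMap(
        lncrna_states=lnc_states,
        mirna_states=mirna_states,
        gene_states=gene_states,
        unresolved_edges=unresolved,
    )
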