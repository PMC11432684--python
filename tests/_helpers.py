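"""Shared constructors for in-memory tables and networks used across tests."""

from __future__ import annotations

import networkx as nx

from ncaxis.axis import TripartiteNetwork
from ncaxis.io_tables import (
    GeneSet,
    InteractionRecord,
    InteractionTable,
    Provenance,
)


def make_table(rows, organism="Homo sapiens"):
    """Build an InteractionTable from (nc_name, nc_type, tar_name, tar_type) tuples."""
    records = [
        InteractionRecord(
            interaction_id=f"T{i:04d}",
            nc_name=a,
            nc_type=ta,
            target_name=b,
            target_type=tb,
            organism=organism,
        )
        for i, (a, ta, b, tb) in enumerate(rows, start=1)
    ]
    prov = Provenance(path="<memory>", read=len(records), kept=len(records))
    return InteractionTable(records=records, dialect="test", provenance=prov)


def make_network(node_types, edges, seeds=None):
    """Build a TripartiteNetwork from {node: type} and (u, v[, count]) edges."""
    g = nx.Graph()
    for n, t in node_types.items():
        g.add_node(n, node_type=t)
    for e in edges:
        u, v = e[0], e[1]
        count = e[2] if len(e) > 2 else 1
        g.add_edge(u, v, evidence_count=count)
    seed_names = seeds if seeds is not None else {
        n for n, t in node_types.items() if t == "seed"
    }
    return TripartiteNetwork(graph=g, seed_set=GeneSet(members=set(seed_names)))


def psoriasis_toy():
    """A 17-node toy axis network encoding the psoriasis expression hypothesis.

    Four lncRNAs (NEAT1, MAP3K1-2, AKAP13-AS1, RP11-473M20.16), seven miRNAs
    of which two are sponged only by NEAT1, and six seed genes of which three
    sit downstream of those two miRNAs.
    """
    node_types = {
        "NEAT1": "lncRNA",
        "MAP3K1-2": "lncRNA",
        "AKAP13-AS1": "lncRNA",
        "RP11-473M20.16": "lncRNA",
        "hsa-miR-485-3p": "miRNA",
        "hsa-miR-371a-3p": "miRNA",
        "hsa-miR-9-5p": "miRNA",
        "hsa-miR-22-3p": "miRNA",
        "hsa-miR-132-3p": "miRNA",
        "hsa-miR-326": "miRNA",
        "hsa-miR-429": "miRNA",
        "TNFAIP3": "seed",
        "SHOC2": "seed",
        "HTR2A": "seed",
        "MAP3K14": "seed",
        "ERAP1": "seed",
        "SPEN": "seed",
    }
    edges = [
        # the two miRNAs whose only sponge is NEAT1
        ("NEAT1", "hsa-miR-485-3p"),
        ("NEAT1", "hsa-miR-371a-3p"),
        # the remaining five miRNAs, each held by MAP3K1-2 or AKAP13-AS1
        ("MAP3K1-2", "hsa-miR-9-5p"),
        ("MAP3K1-2", "hsa-miR-22-3p"),
        ("MAP3K1-2", "hsa-miR-132-3p"),
        ("AKAP13-AS1", "hsa-miR-326"),
        ("AKAP13-AS1", "hsa-miR-429"),
        ("RP11-473M20.16", "hsa-miR-326"),
        # mRNA endpoints downstream of the NEAT1-only miRNAs
        ("TNFAIP3", "hsa-miR-485-3p"),
        ("SHOC2", "hsa-miR-371a-3p"),
        ("HTR2A", "hsa-miR-485-3p"),
        ("HTR2A", "hsa-miR-371a-3p"),
        # mRNAs reached only through sponged miRNAs
        ("MAP3K14", "hsa-miR-9-5p"),
        ("ERAP1", "hsa-miR-22-3p"),
        ("SPEN", "hsa-miR-132-3p"),
    ]
    return make_network(node_types, edges)
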