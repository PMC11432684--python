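"""Independent brute-force implementations of the network rules.

Each function restates its rule definition directly over plain tuples and
dicts, deliberately sharing no code with the package, so the package's
graph-based implementations can be checked against exhaustive enumeration
on small random instances.
"""

from __future__ import annotations

import random


def bf_build_axis(rows, seeds):
    """rows: (name_a, type_a, name_b, type_b) tuples with canonical types;
    seeds: set of seed names.  Returns (node_types, edge_counts) dicts.

    Rule: step 1, miRNAs with an interaction to a seed; step 2, lncRNAs with
    an interaction to a seed and an interaction to any miRNA; step 3, final
    miRNAs = step-1 set union miRNA partners of step-2 lncRNAs.  Edges are
    all rows among retained nodes of allowed type pairs, with row counts.
    """
    def undirected(rows):
        for a, ta, b, tb in rows:
            yield a, ta, b, tb
            yield b, tb, a, ta

    def is_seed(name, typ):
        return typ in ("mRNA", "protein") and name in seeds

    m0 = set()
    for a, ta, b, tb in undirected(rows):
        if ta == "miRNA" and is_seed(b, tb):
            m0.add(a)
    lnc = set()
    for a, ta, b, tb in undirected(rows):
        if ta != "lncRNA" or not is_seed(b, tb):
            continue
        has_mirna = any(
            (p == a and qt == "miRNA")
            for p, pt, q, qt in undirected(rows)
            if pt == "lncRNA"
        )
        if has_mirna:
            lnc.add(a)
    mirna = set(m0)
    for a, ta, b, tb in undirected(rows):
        if ta == "miRNA" and tb == "lncRNA" and b in lnc:
            mirna.add(a)

    edge_counts: dict[tuple[str, str], int] = {}
    node_types: dict[str, str] = {}

    def add_edge(x, tx, y, ty):
        key = tuple(sorted((x, y)))
        edge_counts[key] = edge_counts.get(key, 0) + 1
        node_types[x] = tx
        node_types[y] = ty

    for a, ta, b, tb in rows:
        for x, tx, y, ty in ((a, ta, b, tb), (b, tb, a, ta)):
            if tx == "miRNA" and x in mirna and is_seed(y, ty):
                add_edge(x, "miRNA", y, "seed")
                break
            if tx == "lncRNA" and x in lnc and is_seed(y, ty):
                add_edge(x, "lncRNA", y, "seed")
                break
            if tx == "miRNA" and x in mirna and ty == "lncRNA" and y in lnc:
                add_edge(x, "miRNA", y, "lncRNA")
                break
    return node_types, edge_counts


def bf_threshold(node_types, edge_counts, k, mode, scope_types):
    """Remove every node of a scoped type whose occurrence count < k."""
    survivors = set()
    for n, t in node_types.items():
        if t not in scope_types:
            survivors.add(n)
            continue
        if mode == "degree":
            occ = sum(1 for e in edge_counts if n in e)
        else:
            occ = sum(c for e, c in edge_counts.items() if n in e)
        if occ >= k:
            survivors.add(n)
    new_edges = {e: c for e, c in edge_counts.items()
                 if e[0] in survivors and e[1] in survivors}
    return {n: t for n, t in node_types.items() if n in survivors}, new_edges


def bf_prune(node_types, edge_counts, scope_seeds_only, fixed_point):
    """Simultaneously drop in-scope degree-1 nodes, then all isolated nodes."""
    nodes = dict(node_types)
    edges = dict(edge_counts)
    while True:
        def degree(n):
            return sum(1 for e in edges if n in e)

        doomed = {
            n for n, t in nodes.items()
            if (t == "seed" or not scope_seeds_only) and degree(n) == 1
        }
        edges = {e: c for e, c in edges.items()
                 if e[0] not in doomed and e[1] not in doomed}
        nodes = {n: t for n, t in nodes.items() if n not in doomed}
        isolated = {n for n in nodes if sum(1 for e in edges if n in e) == 0}
        nodes = {n: t for n, t in nodes.items() if n not in isolated}
        if not fixed_point or (not doomed and not isolated):
            break
    return nodes, edges


def bf_blocks(node_types, edge_counts, min_size):
    """Connected components over lncRNAs + seedless miRNAs, >= min_size miRNAs."""
    def neighbors(n, edges):
        out = set()
        for a, b in edges:
            if a == n:
                out.add(b)
            elif b == n:
                out.add(a)
        return out

    seedless = {
        n for n, t in node_types.items()
        if t == "miRNA"
        and not any(node_types[nb] == "seed" for nb in neighbors(n, edge_counts))
    }
    keep = seedless | {n for n, t in node_types.items() if t == "lncRNA"}
    sub_edges = {e for e in edge_counts if e[0] in keep and e[1] in keep}

    unvisited = set(keep)
    blocks = []
    while unvisited:
        start = unvisited.pop()
        comp = {start}
        frontier = [start]
        while frontier:
            n = frontier.pop()
            for nb in neighbors(n, sub_edges):
                if nb not in comp:
                    comp.add(nb)
                    unvisited.discard(nb)
                    frontier.append(nb)
        members = {n for n in comp if n in seedless}
        if len(members) >= min_size:
            governors = {}
            for l in comp:
                if node_types[l] != "lncRNA":
                    continue
                deg = sum(1 for m in members if tuple(sorted((l, m))) in sub_edges)
                if deg:
                    governors[l] = deg
            if governors:
                blocks.append((frozenset(members), governors))
    return blocks


def bf_governed(rows, block_mirnas, min_links):
    """Partners of lncRNAs binding >= min_links distinct block miRNAs."""
    per_lnc: dict[str, set[str]] = {}
    for a, ta, b, tb in rows:
        for x, tx, y, ty in ((a, ta, b, tb), (b, tb, a, ta)):
            if tx == "lncRNA" and ty == "miRNA" and y in block_mirnas:
                per_lnc.setdefault(x, set()).add(y)
    qualifying = {l for l, ms in per_lnc.items() if len(ms) >= min_links}
    out = set()
    for a, ta, b, tb in rows:
        for x, tx, y, ty in ((a, ta, b, tb), (b, tb, a, ta)):
            if tx == "lncRNA" and x in qualifying and ty in ("mRNA", "protein"):
                out.add(y)
    return out


# ---------------------------------------------------------------------------
# random instance generators
# ---------------------------------------------------------------------------

def random_rows(rng: random.Random, max_nodes: int = 20):
    """A random interaction-row list plus a random seed set (<= max_nodes names)."""
    n_seed = rng.randint(1, max(1, max_nodes // 3))
    n_mir = rng.randint(1, max(1, max_nodes // 3))
    n_lnc = rng.randint(1, max_nodes - n_seed - n_mir) if max_nodes > n_seed + n_mir else 1
    seeds = [f"G{i}" for i in range(n_seed)]
    mirs = [f"miR{i}" for i in range(n_mir)]
    lncs = [f"lnc{i}" for i in range(n_lnc)]
    others = ["circ0", "G_extra"]
    rows = []
    for _ in range(rng.randint(0, 40)):
        kind = rng.randrange(6)
        if kind == 0:
            rows.append((rng.choice(mirs), "miRNA", rng.choice(seeds + ["G_extra"]), "mRNA"))
        elif kind == 1:
            rows.append((rng.choice(lncs), "lncRNA", rng.choice(seeds + ["G_extra"]),
                         rng.choice(("mRNA", "protein"))))
        elif kind == 2:
            rows.append((rng.choice(mirs), "miRNA", rng.choice(lncs), "lncRNA"))
        elif kind == 3:
            rows.append((rng.choice(lncs), "lncRNA", rng.choice(mirs), "miRNA"))
        elif kind == 4:
            rows.append((rng.choice(others), "other", rng.choice(seeds), "mRNA"))
        else:
            # duplicate an earlier row to exercise evidence counting
            if rows:
                rows.append(rows[rng.randrange(len(rows))])
    return rows, set(seeds)


def random_network_dicts(rng: random.Random, max_nodes: int = 20):
    """A random typed node dict and edge-count dict over allowed pair types."""
    n = rng.randint(2, max_nodes)
    node_types = {}
    for i in range(n):
        node_types[f"N{i}"] = rng.choice(("seed", "miRNA", "lncRNA"))
    allowed = {frozenset(("seed", "miRNA")), frozenset(("seed", "lncRNA")),
               frozenset(("miRNA", "lncRNA"))}
    edge_counts = {}
    names = list(node_types)
    for _ in range(rng.randint(0, 3 * n)):
        u, v = rng.sample(names, 2)
        if frozenset((node_types[u], node_types[v])) in allowed:
            edge_counts[tuple(sorted((u, v)))] = rng.randint(1, 4)
    return node_types, edge_counts
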