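"""Readers and writers for interaction tables, gene lists, and network exports.

Supported inputs
----------------
* NPInter-dialect TSV — one experimentally validated ncRNA interaction per
  row.  The column mapping ("dialect") is configurable because header names
  drift between database releases; the default targets the NPInter V5.0
  experimental-interactions file.
* BioGRID tab3 TSV — gene-gene / protein-protein interactions keyed by
  official symbols, used for first-degree interactor expansion.
* Plain-text gene lists — one biomarker identifier per line; these are the
  "genes of interest" (seeds) anchoring network construction.
* Two-column expression-state TSV (identifier, ``expressed``/``down``).

Outputs are Cytoscape-importable: a SIF file plus node- and edge-attribute
tables; :func:`read_network` reconstructs the network from that file pair.

Identifier normalization: surrounding whitespace is stripped; comparison is
case-folded (so ``hsa-miR-21`` and ``hsa-mir-21`` unify) while the first-seen
casing is preserved for display.
"""

from __future__ import annotations

import csv
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import yaml

__all__ = [
    "DialectError",
    "GeneSet",
    "InteractionRecord",
    "InteractionTable",
    "NPInterDialect",
    "Provenance",
    "normalize_identifier",
    "identifier_key",
    "read_biogrid",
    "read_gene_list",
    "read_network",
    "read_npinter",
    "read_state_file",
    "write_network",
]

NC_TYPES = frozenset({"miRNA", "lncRNA", "other"})
TARGET_TYPES = frozenset({"mRNA", "protein", "miRNA", "lncRNA", "other"})

#: raw molecule-type labels (case-folded) mapped onto the canonical vocabulary;
#: anything else becomes "other" and is kept, never silently dropped.
_TYPE_CANON = {
    "mirna": "miRNA",
    "microrna": "miRNA",
    "lncrna": "lncRNA",
    "lincrna": "lncRNA",
    "mrna": "mRNA",
    "protein": "protein",
}


class DialectError(ValueError):
    """A required column is missing or a file does not match its dialect."""


def normalize_identifier(raw: str) -> str:
    """Strip surrounding whitespace; preserve casing for display."""
    return raw.strip()


def identifier_key(raw: str) -> str:
    """Case-folded comparison key for a molecule identifier."""
    return raw.strip().casefold()


def canonical_type(raw: str, *, allowed: frozenset[str]) -> str:
    mapped = _TYPE_CANON.get(raw.strip().casefold(), "other")
    return mapped if mapped in allowed else "other"


@dataclass(frozen=True)
class InteractionRecord:
    """One row of an ncRNA interaction database."""

    interaction_id: str
    nc_name: str
    nc_type: str  # miRNA | lncRNA | other
    target_name: str
    target_type: str  # mRNA | protein | miRNA | lncRNA | other
    organism: str = ""
    evidence_class: str = ""
    source: str = ""

    @property
    def nc_key(self) -> str:
        return identifier_key(self.nc_name)

    @property
    def target_key(self) -> str:
        return identifier_key(self.target_name)

    @property
    def is_self_interaction(self) -> bool:
        return self.nc_key == self.target_key


@dataclass
class Provenance:
    """Row accounting for a parsed table: read == kept + discarded."""

    path: str
    read: int = 0
    kept: int = 0
    discarded: int = 0
    discard_reasons: Counter = field(default_factory=Counter)

    def discard(self, reason: str) -> None:
        self.discarded += 1
        self.discard_reasons[reason] += 1


@dataclass
class InteractionTable:
    records: list[InteractionRecord]
    dialect: str
    provenance: Provenance

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[InteractionRecord]:
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionTable):
            return NotImplemented
        return self.records == other.records and self.dialect == other.dialect


@dataclass
class GeneSet:
    """A set of normalized identifiers with a role in the workflow.

    ``members`` holds display names; membership tests are case-folded.
    """

    members: set[str] = field(default_factory=set)
    role: str = "seed"  # seed | interactor | governed
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        by_key: dict[str, str] = {}
        for name in sorted(self.members):
            by_key.setdefault(identifier_key(name), normalize_identifier(name))
        self._by_key = by_key
        self.members = set(by_key.values())

    @property
    def keys(self) -> set[str]:
        return set(self._by_key)

    def __contains__(self, name: str) -> bool:
        return identifier_key(name) in self._by_key

    def __len__(self) -> int:
        return len(self._by_key)

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.members))

    def display(self, name: str) -> str:
        """First-seen casing for *name* (falls back to *name* itself)."""
        return self._by_key.get(identifier_key(name), normalize_identifier(name))


@dataclass(frozen=True)
class NPInterDialect:
    """Column mapping for an NPInter-style interaction TSV.

    ``columns`` maps record fields to header names.  Fields mapped to ``None``
    are optional and default to the empty string.
    """

    name: str
    columns: Mapping[str, str | None]

    REQUIRED = ("nc_name", "nc_type", "target_name", "target_type")

    @classmethod
    def default(cls) -> "NPInterDialect":
        return cls(
            name="npinter-v5",
            columns={
                "interaction_id": "interID",
                "nc_name": "ncName",
                "nc_type": "ncType",
                "target_name": "tarName",
                "target_type": "tarType",
                "organism": "organism",
                "evidence_class": "class",
                "source": "source",
            },
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NPInterDialect":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        if not isinstance(payload, dict) or "columns" not in payload:
            raise DialectError(f"dialect file {path} must define a 'columns' mapping")
        return cls(name=str(payload.get("name", Path(path).stem)), columns=payload["columns"])

    def column_index(self, header: list[str]) -> dict[str, int]:
        index: dict[str, int] = {}
        lookup = {h.strip(): i for i, h in enumerate(header)}
        for fld, col in self.columns.items():
            if col is None:
                continue
            if col not in lookup:
                if fld in self.REQUIRED:
                    raise DialectError(
                        f"dialect {self.name!r}: required column {col!r} "
                        f"(field {fld!r}) missing from header"
                    )
                continue
            index[fld] = lookup[col]
        for fld in self.REQUIRED:
            if fld not in index:
                raise DialectError(
                    f"dialect {self.name!r}: required field {fld!r} has no mapped column"
                )
        return index


def _organism_matches(value: str, wanted: str) -> bool:
    return value.strip().casefold() == wanted.strip().casefold()


def read_npinter(
    path: str | Path,
    dialect: NPInterDialect | None = None,
    organism_filter: str | None = "Homo sapiens",
    evidence_class_filter: Iterable[str] | None = None,
) -> InteractionTable:
    """Read an NPInter-dialect interaction TSV.

    Rows failing the (case-insensitive) organism filter, rows with empty
    molecule names, and structurally unreadable rows are counted as discarded
    with a reason — never a crash.  Unrecognized molecule-type labels map to
    ``"other"`` and are kept; downstream axis construction excludes them.
    """
    dialect = dialect or NPInterDialect.default()
    evidence_keep = (
        {e.strip().casefold() for e in evidence_class_filter}
        if evidence_class_filter is not None
        else None
    )
    prov = Provenance(path=str(path))
    records: list[InteractionRecord] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise DialectError(f"{path}: empty file, no header row")
        index = dialect.column_index(header)
        needed = max(index.values()) + 1
        for row in reader:
            if not row or (len(row) == 1 and not row[0].strip()):
                continue  # blank line, not a data row
            prov.read += 1
            if len(row) < needed:
                prov.discard("malformed: too few fields")
                continue
            get = lambda fld: row[index[fld]].strip() if fld in index else ""
            nc_name = normalize_identifier(get("nc_name"))
            target_name = normalize_identifier(get("target_name"))
            if not nc_name or not target_name:
                prov.discard("empty molecule name")
                continue
            organism = get("organism")
            if organism_filter is not None and not _organism_matches(organism, organism_filter):
                prov.discard("organism filter")
                continue
            evidence_class = get("evidence_class")
            if evidence_keep is not None and evidence_class.strip().casefold() not in evidence_keep:
                prov.discard("evidence class filter")
                continue
            records.append(
                InteractionRecord(
                    interaction_id=get("interaction_id"),
                    nc_name=nc_name,
                    nc_type=canonical_type(get("nc_type"), allowed=NC_TYPES),
                    target_name=target_name,
                    target_type=canonical_type(get("target_type"), allowed=TARGET_TYPES),
                    organism=organism,
                    evidence_class=evidence_class,
                    source=get("source"),
                )
            )
            prov.kept += 1
    return InteractionTable(records=records, dialect=dialect.name, provenance=prov)


def read_gene_list(path: str | Path, role: str = "seed", label: str | None = None) -> GeneSet:
    """Read a plain-text biomarker list (one identifier per line).

    Blank lines and ``#`` comments are ignored; duplicates collapse under
    case-folded comparison, first-seen casing wins.
    """
    members: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            members.append(line)
    if not members:
        warnings.warn(f"gene list {path} is empty", stacklevel=2)
    gs = GeneSet(role=role, label=label if label is not None else Path(path).stem)
    # insert in file order so first-seen casing is preserved
    for name in members:
        gs._by_key.setdefault(identifier_key(name), normalize_identifier(name))
    gs.members = set(gs._by_key.values())
    return gs


# BioGRID tab3 header names for the fields we use.
_BIOGRID_SYMBOL_A = "Official Symbol Interactor A"
_BIOGRID_SYMBOL_B = "Official Symbol Interactor B"
_BIOGRID_ORG_A = "Organism ID Interactor A"
_BIOGRID_ORG_B = "Organism ID Interactor B"
_BIOGRID_ORGNAME_A = "Organism Name Interactor A"
_BIOGRID_ORGNAME_B = "Organism Name Interactor B"
_BIOGRID_ID = "#BioGRID Interaction ID"
_BIOGRID_SYSTEM = "Experimental System"


def read_biogrid(path: str | Path, organism_filter: str | None = "9606") -> InteractionTable:
    """Read a BioGRID tab3 TSV into an InteractionTable of protein-protein rows.

    ``organism_filter`` accepts a taxonomy id ("9606") or an organism name
    ("Homo sapiens"); both interactors must match.  Self-pairs are retained
    (flagged via :attr:`InteractionRecord.is_self_interaction`).
    """
    prov = Provenance(path=str(path))
    records: list[InteractionRecord] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise DialectError(f"{path}: empty file, no header row")
        lookup = {h.strip(): i for i, h in enumerate(header)}
        for col in (_BIOGRID_SYMBOL_A, _BIOGRID_SYMBOL_B):
            if col not in lookup:
                raise DialectError(f"{path}: not a BioGRID tab3 file, missing column {col!r}")
        ia, ib = lookup[_BIOGRID_SYMBOL_A], lookup[_BIOGRID_SYMBOL_B]
        org_cols = [
            (lookup.get(_BIOGRID_ORG_A), lookup.get(_BIOGRID_ORG_B)),
            (lookup.get(_BIOGRID_ORGNAME_A), lookup.get(_BIOGRID_ORGNAME_B)),
        ]
        id_col = lookup.get(_BIOGRID_ID)
        sys_col = lookup.get(_BIOGRID_SYSTEM)
        needed = max(ia, ib) + 1
        for row in reader:
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            prov.read += 1
            if len(row) < needed:
                prov.discard("malformed: too few fields")
                continue
            sym_a = normalize_identifier(row[ia])
            sym_b = normalize_identifier(row[ib])
            if not sym_a or not sym_b or sym_a == "-" or sym_b == "-":
                prov.discard("empty molecule name")
                continue
            if organism_filter is not None:
                wanted = organism_filter.strip().casefold()
                ok = False
                for ca, cb in org_cols:
                    if ca is None or cb is None or len(row) <= max(ca, cb):
                        continue
                    if row[ca].strip().casefold() == wanted and row[cb].strip().casefold() == wanted:
                        ok = True
                        break
                if not ok:
                    prov.discard("organism filter")
                    continue
            records.append(
                InteractionRecord(
                    interaction_id=row[id_col].strip() if id_col is not None and len(row) > id_col else "",
                    nc_name=sym_a,
                    nc_type="other",
                    target_name=sym_b,
                    target_type="protein",
                    organism=organism_filter or "",
                    evidence_class=row[sys_col].strip() if sys_col is not None and len(row) > sys_col else "",
                    source="BioGRID",
                )
            )
            prov.kept += 1
    # BioGRID rows are symmetric gene/protein pairs; mark both sides protein.
    records = [
        InteractionRecord(
            interaction_id=r.interaction_id,
            nc_name=r.nc_name,
            nc_type="other",
            target_name=r.target_name,
            target_type="protein",
            organism=r.organism,
            evidence_class=r.evidence_class,
            source=r.source,
        )
        for r in records
    ]
    return InteractionTable(records=records, dialect="biogrid-tab3", provenance=prov)


def read_state_file(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV of (identifier, state in {expressed, down})."""
    states: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected two tab-separated columns")
            name, state = normalize_identifier(parts[0]), parts[1].strip().casefold()
            if state not in {"expressed", "down"}:
                raise ValueError(f"{path}:{ln}: state must be 'expressed' or 'down', got {state!r}")
            states[name] = state
    return states


# -- network export / import -------------------------------------------------

#: SIF relation label per unordered endpoint-type pair; seeds render as mRNA,
#: matching the three line styles of the standard tripartite legend.
_SIF_LABEL = {
    frozenset({"seed", "miRNA"}): "mRNA-miRNA",
    frozenset({"seed", "lncRNA"}): "mRNA-lncRNA",
    frozenset({"miRNA", "lncRNA"}): "miRNA-lncRNA",
}


def write_network(network, out_dir: str | Path, basename: str = "network") -> dict[str, Path]:
    """Export a tripartite network as SIF + node/edge attribute tables.

    Emits ``<basename>.sif``, ``<basename>.nodes.tsv`` (id, node_type, degree,
    is_seed), ``<basename>.edges.tsv`` (source, target, relation,
    evidence_count).  :func:`read_network` on the output reconstructs an
    isomorphic network.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    g = network.graph
    sif_path = out_dir / f"{basename}.sif"
    nodes_path = out_dir / f"{basename}.nodes.tsv"
    edges_path = out_dir / f"{basename}.edges.tsv"

    edges = sorted(
        (tuple(sorted((u, v))), g.nodes[u]["node_type"], g.nodes[v]["node_type"], d["evidence_count"])
        for u, v, d in g.edges(data=True)
    )
    with open(sif_path, "w") as fh:
        for (u, v), tu, tv, _ in edges:
            label = _SIF_LABEL.get(frozenset({tu, tv}), f"{tu}-{tv}")
            fh.write(f"{u}\t{label}\t{v}\n")
    with open(nodes_path, "w") as fh:
        fh.write("id\tnode_type\tdegree\tis_seed\n")
        for n in sorted(g.nodes):
            nt = g.nodes[n]["node_type"]
            fh.write(f"{n}\t{nt}\t{g.degree(n)}\t{str(nt == 'seed').lower()}\n")
    with open(edges_path, "w") as fh:
        fh.write("source\ttarget\trelation\tevidence_count\n")
        for (u, v), tu, tv, count in edges:
            label = _SIF_LABEL.get(frozenset({tu, tv}), f"{tu}-{tv}")
            fh.write(f"{u}\t{v}\t{label}\t{count}\n")
    return {"sif": sif_path, "nodes": nodes_path, "edges": edges_path}


def read_network(out_dir: str | Path, basename: str = "network"):
    """Rebuild a TripartiteNetwork from a :func:`write_network` file pair."""
    from ncaxis.axis import TripartiteNetwork
    import networkx as nx

    out_dir = Path(out_dir)
    g = nx.Graph()
    with open(out_dir / f"{basename}.nodes.tsv") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            g.add_node(row["id"], node_type=row["node_type"])
    with open(out_dir / f"{basename}.edges.tsv") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            g.add_edge(row["source"], row["target"], evidence_count=int(row["evidence_count"]))
    seeds = GeneSet(
        members={n for n, d in g.nodes(data=True) if d["node_type"] == "seed"},
        role="seed",
        label=basename,
    )
    return TripartiteNetwork(graph=g, seed_set=seeds)
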