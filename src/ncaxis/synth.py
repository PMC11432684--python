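"""Deterministic synthetic fixtures with planted structure.

Generates an NPInter-dialect interaction table, a seed gene list, a BioGRID
tab3 table, an OBO ontology, a GAF 2.2 annotation file, and an
expression-state file — all small plain text, all parsing cleanly through
the package's own readers — together with a machine-readable truth record.

Planted structure:

* *miRNA blocks*: each block's miRNAs interact only with the block's
  governor lncRNAs (never with seeds), so they are seedless by construction;
  each governor also receives one seed edge so it survives the two-step axis
  extraction.  Governor j of a block binds ``block_size - j`` member miRNAs,
  giving a strict within-block degree ranking.
* *governed genes*: extra mRNAs attached to governors, recoverable by the
  reverse governed-genes query.
* *enriched terms*: GO terms annotating study (seed) genes at a configured
  fold over the baseline annotation probability.
* *decoys*: wrong-organism rows (discarded by the readers in exactly their
  configured number) and unrecognized-molecule-type rows (kept as "other",
  excluded by axis construction).

Generation is a pure function of the config, including its RNG seed: the
same config yields byte-identical files.  Fixtures are structural mimics of
the real databases, not statistical ones.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

__all__ = ["ConfigError", "FixtureConfig", "FixtureTruth", "generate_fixture"]

_GO_ROOTS = {
    "biological_process": ("GO:0008150", "P"),
    "cellular_component": ("GO:0005575", "C"),
    "molecular_function": ("GO:0003674", "F"),
}
_OBSOLETE_TERM = "GO:7199999"


class ConfigError(ValueError):
    """Inconsistent fixture configuration."""


@dataclass
class FixtureConfig:
    """Study conditions for one synthetic fixture.

    Defaults emulate a mid-sized curated biomarker study: a few dozen seeds,
    one large lncRNA-governed miRNA block on two hubs, sparse background
    interactions, and one GO term planted at high fold enrichment.
    """

    n_seeds: int = 30
    n_mirna: int = 40
    n_lncrna: int = 15
    planted_blocks: list[tuple[int, int]] = field(default_factory=lambda: [(12, 2)])
    planted_hub_names: tuple[str, ...] = ("NEAT1", "MALAT1")
    n_governed_genes_per_block: int = 3
    edge_density: float = 0.08
    n_decoy_organism_rows: int = 5
    n_other_type_rows: int = 2
    planted_terms: list[tuple[str, float]] = field(default_factory=lambda: [("GO:7100001", 8.0)])
    n_go_terms: int = 30
    n_population_genes: int = 200
    baseline_annotation_prob: float = 0.05
    n_iea_decoy_annotations: int = 3
    organism: str = "Homo sapiens"
    decoy_organism: str = "Mus musculus"
    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("n_seeds", "n_mirna", "n_lncrna", "n_decoy_organism_rows",
                     "n_other_type_rows", "n_go_terms", "n_population_genes",
                     "n_governed_genes_per_block", "n_iea_decoy_annotations"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if not 0.0 <= self.edge_density <= 1.0:
            raise ConfigError("edge_density must be in [0, 1]")
        if not 0.0 <= self.baseline_annotation_prob <= 1.0:
            raise ConfigError("baseline_annotation_prob must be in [0, 1]")
        if sum(size for size, _ in self.planted_blocks) > self.n_mirna:
            raise ConfigError("planted block sizes exceed n_mirna")
        n_gov = sum(g for _, g in self.planted_blocks)
        if n_gov > self.n_lncrna:
            raise ConfigError("planted governors exceed n_lncrna")
        for size, governors in self.planted_blocks:
            if size < 1 or governors < 1:
                raise ConfigError("each planted block needs size >= 1 and >= 1 governor")
            if size - (governors - 1) < 2:
                raise ConfigError(
                    "block too small for its governor count: every governor "
                    "must bind at least two member miRNAs"
                )
        term_ids = set(_term_ids(self.n_go_terms))
        for term, fold in self.planted_terms:
            if term not in term_ids:
                raise ConfigError(f"planted term {term} not among the {self.n_go_terms} generated terms")
            if fold < 1.0:
                raise ConfigError("planted fold enrichment must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FixtureConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if "planted_blocks" in payload:
            payload["planted_blocks"] = [tuple(b) for b in payload["planted_blocks"]]
        if "planted_terms" in payload:
            payload["planted_terms"] = [tuple(t) for t in payload["planted_terms"]]
        if "planted_hub_names" in payload:
            payload["planted_hub_names"] = tuple(payload["planted_hub_names"])
        return cls(**payload)


@dataclass
class FixtureTruth:
    """Ground truth planted into a generated fixture."""

    seeds: list[str]
    blocks: list[dict]  # {"mirnas": [...], "governors": {name: degree}}
    governed_genes: list[list[str]]  # per block, for min_links=2
    enriched_terms: list[str]
    n_decoy_organism_rows: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def _term_ids(n: int) -> list[str]:
    return [f"GO:71{i:05d}" for i in range(1, n + 1)]


def _npinter_row(idx: int, nc_name: str, nc_type: str, tar_name: str, tar_type: str,
                 organism: str, klass: str = "binding") -> list[str]:
    return [f"NPI-sim-{idx:05d}", nc_name, nc_type, tar_name, tar_type, organism, klass, "synthetic"]


def generate_fixture(config: FixtureConfig, out_dir: str | Path) -> tuple[dict[str, Path], FixtureTruth]:
    """Write all fixture files into *out_dir*; return their paths and the truth."""
    config.validate()
    rng = random.Random(config.rng_seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    seeds = [f"GENE{i:04d}" for i in range(1, config.n_seeds + 1)]

    # --- name the planted and background molecules -------------------------
    blocks_members: list[list[str]] = []
    blocks_governors: list[list[str]] = []
    hub_pool = list(config.planted_hub_names)
    gov_counter = 0
    mirna_counter = 0
    for b, (size, n_gov) in enumerate(config.planted_blocks, start=1):
        blocks_members.append([f"hsa-miR-blk{b}-{i}" for i in range(1, size + 1)])
        mirna_counter += size
        govs = []
        for _ in range(n_gov):
            if hub_pool:
                govs.append(hub_pool.pop(0))
            else:
                gov_counter += 1
                govs.append(f"LNC-gov-{gov_counter}")
        blocks_governors.append(govs)
    n_bg_mirna = config.n_mirna - mirna_counter
    bg_mirnas = [f"hsa-miR-sim-{i}" for i in range(1, n_bg_mirna + 1)]
    n_bg_lnc = config.n_lncrna - sum(len(g) for g in blocks_governors)
    bg_lncs = [f"LNC-sim-{i}" for i in range(1, n_bg_lnc + 1)]

    # --- interaction rows ---------------------------------------------------
    rows: list[list[str]] = []
    idx = 0

    def add(nc, nct, tar, tart, organism=None, klass="binding"):
        nonlocal idx
        idx += 1
        rows.append(_npinter_row(idx, nc, nct, tar, tart, organism or config.organism, klass))

    truth_governed: list[list[str]] = []
    for b, (members, govs) in enumerate(zip(blocks_members, blocks_governors), start=1):
        governed: set[str] = set()
        for j, gov in enumerate(govs):
            # governor j binds the first (size - j) members: strict degree ranking
            for m in members[: len(members) - j]:
                # alternate row orientation to exercise symmetric parsing
                if (j + len(m)) % 2:
                    add(gov, "lncRNA", m, "miRNA")
                else:
                    add(m, "miRNA", gov, "lncRNA")
            seed_partner = rng.choice(seeds)
            add(gov, "lncRNA", seed_partner, "mRNA")
            governed.add(seed_partner)
            for i in range(1, config.n_governed_genes_per_block + 1):
                gene = f"GOVGENE-b{b}-{i}"
                add(gov, "lncRNA", gene, "mRNA" if i % 2 else "protein")
                governed.add(gene)
        truth_governed.append(sorted(governed))

    for m in bg_mirnas:
        add(m, "miRNA", rng.choice(seeds), "mRNA")  # guaranteed seed anchor
        for s in seeds:
            if rng.random() < config.edge_density:
                add(m, "miRNA", s, "mRNA")
    for l in bg_lncs:
        if rng.random() < 0.7:
            add(l, "lncRNA", rng.choice(seeds), "mRNA")
        for m in bg_mirnas:
            if rng.random() < config.edge_density:
                add(l, "lncRNA", m, "miRNA")

    for i in range(config.n_decoy_organism_rows):
        add(f"mmu-miR-sim-{i + 1}", "miRNA", rng.choice(seeds), "mRNA",
            organism=config.decoy_organism)
    for i in range(config.n_other_type_rows):
        add(f"CIRC-sim-{i + 1}", "circRNA", rng.choice(seeds), "mRNA")

    npinter_path = out_dir / "npinter.tsv"
    with open(npinter_path, "w") as fh:
        fh.write("interID\tncName\tncType\ttarName\ttarType\torganism\tclass\tsource\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")

    # --- seed list ----------------------------------------------------------
    seeds_path = out_dir / "seeds.txt"
    with open(seeds_path, "w") as fh:
        fh.write("# synthetic seed biomarker list\n")
        for s in seeds:
            fh.write(s + "\n")

    # --- BioGRID tab3 -------------------------------------------------------
    biogrid_path = out_dir / "biogrid.tab3.txt"
    header = ["#BioGRID Interaction ID", "Official Symbol Interactor A",
              "Official Symbol Interactor B", "Organism ID Interactor A",
              "Organism ID Interactor B", "Experimental System"]
    bg_idx = 0
    with open(biogrid_path, "w") as fh:
        fh.write("\t".join(header) + "\n")

        def bg_row(a, b, org="9606"):
            nonlocal bg_idx
            bg_idx += 1
            fh.write(f"{bg_idx}\t{a}\t{b}\t{org}\t{org}\tTwo-hybrid\n")

        part_idx = 0
        for s in seeds:
            if rng.random() < 0.6:
                for _ in range(rng.choice((1, 2))):
                    part_idx += 1
                    bg_row(s, f"BG-PART-{part_idx}")
        bg_row(seeds[0], seeds[0])  # self-pair, flagged not dropped
        for i in range(2):
            bg_row(f"Mm-gene-{i + 1}", f"Mm-gene-{i + 2}", org="10090")

    # --- ontology (OBO) -----------------------------------------------------
    term_ids = _term_ids(config.n_go_terms)
    namespaces = list(_GO_ROOTS)
    obo_path = out_dir / "ontology.obo"
    term_ns: dict[str, str] = {}
    with open(obo_path, "w") as fh:
        fh.write("format-version: 1.2\nontology: go-synthetic\n")
        for ns, (root, _) in _GO_ROOTS.items():
            fh.write(f"\n[Term]\nid: {root}\nname: {ns}\nnamespace: {ns}\n")
        planted_ids = {t for t, _ in config.planted_terms}
        for i, term in enumerate(term_ids):
            ns = namespaces[i % 3]
            term_ns[term] = ns
            fh.write(f"\n[Term]\nid: {term}\nname: synthetic term {i + 1}\nnamespace: {ns}\n")
            # planted terms stay leaves: a descendant's annotations would
            # propagate into them and dilute the configured fold contrast
            if i >= 3 and term_ids[i - 3] not in planted_ids and rng.random() < 0.5:
                parent = term_ids[i - 3]
                rel = "is_a" if rng.random() < 0.7 else "part_of"
                if rel == "is_a":
                    fh.write(f"is_a: {parent} ! synthetic term {i - 2}\n")
                else:
                    fh.write(f"relationship: part_of {parent} ! synthetic term {i - 2}\n")
            else:
                fh.write(f"is_a: {_GO_ROOTS[ns][0]} ! {ns}\n")
        fh.write(f"\n[Term]\nid: {_OBSOLETE_TERM}\nname: obsolete synthetic term\n"
                 f"namespace: biological_process\nis_obsolete: true\n")

    # --- annotations (GAF 2.2) ----------------------------------------------
    pop_genes = [f"POPGENE{i:04d}" for i in range(1, config.n_population_genes + 1)]
    planted = dict(config.planted_terms)
    # anchor terms keep every gene in the background population without
    # touching the planted terms' annotation counts
    anchor_terms = [t for t in term_ids if t not in planted] or term_ids
    gaf_path = out_dir / "annotations.gaf"

    def gaf_line(gene: str, term: str, evidence: str = "IDA") -> str:
        ns = term_ns.get(term, "biological_process")
        aspect = _GO_ROOTS[ns][1]
        return (f"ncaxis-sim\t{gene}\t{gene}\t\t{term}\tSIM:0000001\t{evidence}\t\t{aspect}\t"
                f"\t\tprotein\ttaxon:9606\t20240101\tncaxis-sim\t\t\n")

    with open(gaf_path, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for gene in pop_genes + seeds:
            is_study = gene in set(seeds)
            annotated_any = False
            for term in term_ids:
                p = config.baseline_annotation_prob
                if term in planted and is_study:
                    p = min(1.0, planted[term] * p)
                if rng.random() < p:
                    fh.write(gaf_line(gene, term))
                    annotated_any = True
            if not annotated_any:
                fh.write(gaf_line(gene, anchor_terms[(len(gene) + config.rng_seed) % len(anchor_terms)]))
        for i in range(config.n_iea_decoy_annotations):
            fh.write(gaf_line(pop_genes[i % len(pop_genes)], term_ids[i % len(term_ids)], "IEA"))
        fh.write(gaf_line(pop_genes[0], _OBSOLETE_TERM))  # skipped at load

    # --- expression states --------------------------------------------------
    states_path = out_dir / "states.tsv"
    with open(states_path, "w") as fh:
        all_govs = [g for govs in blocks_governors for g in govs]
        for i, gov in enumerate(all_govs):
            fh.write(f"{gov}\t{'down' if i == 0 else 'expressed'}\n")

    truth = FixtureTruth(
        seeds=seeds,
        blocks=[
            {
                "mirnas": sorted(members),
                "governors": {gov: len(members) - j for j, gov in enumerate(govs)},
            }
            for members, govs in zip(blocks_members, blocks_governors)
        ],
        governed_genes=truth_governed,
        enriched_terms=[t for t, _ in config.planted_terms],
        n_decoy_organism_rows=config.n_decoy_organism_rows,
    )
    truth_path = out_dir / "truth.json"
    truth.to_json(truth_path)

    paths = {
        "npinter": npinter_path,
        "seeds": seeds_path,
        "biogrid": biogrid_path,
        "obo": obo_path,
        "gaf": gaf_path,
        "states": states_path,
        "truth": truth_path,
    }
    return paths, truth
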