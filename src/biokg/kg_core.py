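"""Typed knowledge-graph data model, edge-list I/O and ontology propagation.

The graph schema (metagraph) declares entity types (metanodes, identified by a
three-letter abbreviation such as GEN or CLL) and typed relations between them
(metaedges, e.g. ``GEN-ppi-GEN`` for protein-protein interaction). Actual data
enter the graph as *datasets*: named binary edge lists, each mapped to exactly
one metaedge. Datasets are never merged at this level — keeping sources apart
lets downstream metapath construction embed them individually or combined.

Conventions
-----------
* Heterogeneous metaedges are stored in one canonical direction (``CLL-has-TIS``
  rather than ``TIS-has-CLL``); metapaths may traverse either way.
* A metaedge is *directed* only when it is homogeneous and has a single valid
  orientation (kinase→substrate phosphorylation, TF→target regulation).
* Node identifiers are opaque strings; no biological nomenclature is parsed.
* Edge lists are plain TSV (``source<TAB>target``), ``#`` lines ignored, UTF-8.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import yaml


class SchemaError(ValueError):
    """An entity type, relation or dataset violates the declared metagraph."""


class GrammarError(ValueError):
    """A metaedge/metapath label cannot be parsed under the label grammar."""


_METAEDGE_RE = re.compile(
    r"^(?P<src>[A-Z]{3})-(?P<lmark>_?)(?P<rel>[a-z]{3})(?P<rmark>_?)-(?P<tgt>[A-Z]{3})$"
)


@dataclass(frozen=True)
class MetaedgeSpec:
    """A typed relation between two metanodes.

    ``directed`` is only legal for homogeneous relations (source and target
    type identical), mirroring how one-way biological relations (e.g.
    ``GEN-pho-GEN``) are modelled.
    """

    source_type: str
    relation: str
    target_type: str
    directed: bool = False

    def __post_init__(self) -> None:
        if self.directed and self.source_type != self.target_type:
            raise SchemaError(
                f"directed metaedge must be homogeneous: {self.label}"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.source_type, self.relation, self.target_type)

    @property
    def homogeneous(self) -> bool:
        return self.source_type == self.target_type

    @property
    def label(self) -> str:
        return f"{self.source_type}-{self.relation}-{self.target_type}"


@dataclass(frozen=True)
class MetaedgeRef:
    """A metaedge as referenced in a label, with an optional direction role.

    For directed homogeneous relations the ``'_'`` mark in a label records on
    which side the *source* of the relation sits: ``GEN-_pho-GEN`` reads
    "kinase (left) phosphorylates substrate (right)" while ``GEN-pho_-GEN``
    traverses the same relation from the substrate side.
    """

    spec: MetaedgeSpec
    source_side: str | None = None  # 'left' | 'right' | None

    @property
    def label(self) -> str:
        lm = "_" if self.source_side == "left" else ""
        rm = "_" if self.source_side == "right" else ""
        s = self.spec
        return f"{s.source_type}-{lm}{s.relation}{rm}-{s.target_type}"


def parse_metaedge_label(label: str, metagraph: "Metagraph | None" = None) -> MetaedgeRef:
    """Parse a single ``SRC-rel-TGT`` label (with optional ``'_'`` mark).

    If a metagraph is supplied the abbreviations and the declared directedness
    are validated against it; otherwise directedness is inferred from the mark.
    """
    m = _METAEDGE_RE.match(label)
    if m is None:
        raise GrammarError(f"cannot parse metaedge label {label!r}")
    src, tgt, rel = m.group("src"), m.group("tgt"), m.group("rel")
    lmark, rmark = bool(m.group("lmark")), bool(m.group("rmark"))
    if lmark and rmark:
        raise GrammarError(f"both sides marked as source in {label!r}")
    marked = lmark or rmark
    if marked and src != tgt:
        raise GrammarError(
            f"'_' direction mark on heterogeneous metaedge {label!r}"
        )
    if metagraph is not None:
        if src not in metagraph.metanodes:
            raise SchemaError(f"unknown metanode abbreviation {src!r}")
        if tgt not in metagraph.metanodes:
            raise SchemaError(f"unknown metanode abbreviation {tgt!r}")
        spec = metagraph.get_metaedge(src, rel, tgt)
        if spec is None:
            raise SchemaError(f"metaedge {label!r} not declared in metagraph")
        if marked and not spec.directed:
            raise GrammarError(
                f"'_' mark on undirected metaedge {spec.label!r}"
            )
    else:
        spec = MetaedgeSpec(src, rel, tgt, directed=marked)
    source_side = None
    if spec.directed:
        source_side = "right" if rmark else "left"
    return MetaedgeRef(spec, source_side)


@dataclass
class Metagraph:
    """The knowledge-graph schema: declared metanodes and metaedges."""

    metanodes: dict[str, str] = field(default_factory=dict)  # abbr -> full name
    metaedges: dict[tuple[str, str, str], MetaedgeSpec] = field(default_factory=dict)

    def add_metanode(self, abbr: str, name: str | None = None) -> None:
        if not re.fullmatch(r"[A-Z]{3}", abbr):
            raise SchemaError(f"metanode abbreviation must be 3 capitals: {abbr!r}")
        if abbr in self.metanodes and self.metanodes[abbr] != (name or abbr):
            raise SchemaError(f"abbreviation {abbr!r} already declared")
        self.metanodes[abbr] = name or abbr

    def add_metaedge(self, spec: MetaedgeSpec) -> None:
        for t in (spec.source_type, spec.target_type):
            if t not in self.metanodes:
                raise SchemaError(f"metaedge {spec.label!r} references undeclared metanode {t!r}")
        self.metaedges[spec.key] = spec

    def get_metaedge(self, src: str, rel: str, tgt: str) -> MetaedgeSpec | None:
        """Look up a metaedge; heterogeneous ones match in either direction."""
        spec = self.metaedges.get((src, rel, tgt))
        if spec is None and src != tgt:
            spec = self.metaedges.get((tgt, rel, src))
        return spec


@dataclass
class DatasetNetwork:
    """One named binary edge set mapped to exactly one metaedge.

    Edges are unweighted pairs of node ids; any weights in the original source
    are deliberately not stored (they are treated as cutoffs upstream, never as
    traversal weights). Undirected homogeneous edges are canonicalized with the
    lexicographically smaller id first; self-loops are dropped.
    """

    name: str
    metaedge: MetaedgeSpec
    edges: set[tuple[str, str]] = field(default_factory=set)
    source_universe: set[str] = field(default_factory=set)
    target_universe: set[str] = field(default_factory=set)
    dropped_edges: int = 0

    @classmethod
    def from_edges(
        cls,
        name: str,
        metaedge: MetaedgeSpec,
        edges: Iterable[tuple[str, str]],
        source_universe: Iterable[str] | None = None,
        target_universe: Iterable[str] | None = None,
    ) -> "DatasetNetwork":
        """Build a dataset, deduplicating and rejecting out-of-universe ids.

        When a universe is not given it defaults to the ids observed on that
        side. Edges with an id outside the declared universe are dropped and
        counted in ``dropped_edges``.
        """
        raw = list(edges)
        src_uni = set(source_universe) if source_universe is not None else None
        tgt_uni = set(target_universe) if target_universe is not None else None
        if metaedge.homogeneous:
            if src_uni is None and tgt_uni is None:
                uni = {n for e in raw for n in e}
            else:
                uni = (src_uni or set()) | (tgt_uni or set())
            src_uni = tgt_uni = uni
        else:
            if src_uni is None:
                src_uni = {a for a, _ in raw}
            if tgt_uni is None:
                tgt_uni = {b for _, b in raw}
        kept: set[tuple[str, str]] = set()
        dropped = 0
        for a, b in raw:
            if a == b:
                dropped += 1
                continue
            if a not in src_uni or b not in tgt_uni:
                dropped += 1
                continue
            if metaedge.homogeneous and not metaedge.directed and a > b:
                a, b = b, a
            kept.add((a, b))
        return cls(name, metaedge, kept, src_uni, tgt_uni, dropped)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for a, b in sorted(self.edges):
                fh.write(f"{a}\t{b}\n")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        name: str,
        metaedge: MetaedgeSpec,
        source_universe: Iterable[str] | None = None,
        target_universe: Iterable[str] | None = None,
    ) -> "DatasetNetwork":
        edges = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"malformed edge line in {path}: {line!r}")
                edges.append((parts[0], parts[1]))
        return cls.from_edges(name, metaedge, edges, source_universe, target_universe)


@dataclass
class KnowledgeGraph:
    """A metagraph together with the datasets populating each metaedge."""

    metagraph: Metagraph
    datasets: dict[tuple[str, str, str], list[DatasetNetwork]] = field(default_factory=dict)

    def datasets_for(self, spec: MetaedgeSpec) -> list[DatasetNetwork]:
        return self.datasets.get(spec.key, [])

    def dataset(self, name: str) -> DatasetNetwork:
        for dss in self.datasets.values():
            for ds in dss:
                if ds.name == name:
                    return ds
        raise KeyError(f"no dataset named {name!r}")

    def summary(self) -> dict:
        return {
            "n_metaedges": len(self.datasets),
            "n_datasets": sum(len(v) for v in self.datasets.values()),
            "n_edges": sum(ds.n_edges for v in self.datasets.values() for ds in v),
            "dropped_edges": sum(
                ds.dropped_edges for v in self.datasets.values() for ds in v
            ),
        }


def assemble_graph(
    datasets: Iterable[DatasetNetwork], metagraph: Metagraph
) -> KnowledgeGraph:
    """Validate datasets against the metagraph and index them by metaedge."""
    kg = KnowledgeGraph(metagraph)
    names = Counter()
    for ds in datasets:
        if ds.metaedge.key not in metagraph.metaedges:
            raise SchemaError(
                f"dataset {ds.name!r} tagged with undeclared metaedge {ds.metaedge.label!r}"
            )
        names[ds.name] += 1
        if names[ds.name] > 1:
            raise SchemaError(f"duplicate dataset name {ds.name!r}")
        kg.datasets.setdefault(ds.metaedge.key, []).append(ds)
    return kg


class Ontology:
    """A term → parents DAG used to propagate annotations upward."""

    def __init__(self, parents: Mapping[str, Iterable[str]]):
        self.parents: dict[str, frozenset[str]] = {
            t: frozenset(p) for t, p in parents.items()
        }
        g = nx.DiGraph()
        g.add_nodes_from(self.parents)
        for t, ps in self.parents.items():
            for p in ps:
                g.add_edge(t, p)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ontology contains a cycle")
        self._graph = g
        self._anc_cache: dict[str, frozenset[str]] = {}

    @property
    def terms(self) -> set[str]:
        return set(self._graph.nodes)

    def ancestors(self, term: str) -> frozenset[str]:
        """All (strict) ancestors of ``term``; empty for unknown terms."""
        if term not in self._graph:
            return frozenset()
        if term not in self._anc_cache:
            self._anc_cache[term] = frozenset(nx.descendants(self._graph, term))
        return self._anc_cache[term]

    def roots(self) -> set[str]:
        return {t for t in self._graph.nodes if self._graph.out_degree(t) == 0}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Ontology":
        parents: dict[str, set[str]] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                child, parent = line.split("\t")[:2]
                parents.setdefault(child, set()).add(parent)
                parents.setdefault(parent, set())
        return cls(parents)


def propagate_ontology(
    dataset: DatasetNetwork, ontology: Ontology, side: str = "target"
) -> DatasetNetwork:
    """Propagate annotations through ontology parents on one side of a dataset.

    Every edge ``(x, term)`` (for ``side='target'``) gains ``(x, ancestor)`` for
    each ancestor of ``term``. Idempotent and monotone: the output edge set is a
    superset of the input, and re-propagating changes nothing.
    """
    if side not in ("source", "target"):
        raise ValueError("side must be 'source' or 'target'")
    new_edges = set(dataset.edges)
    for a, b in dataset.edges:
        if side == "target":
            for anc in ontology.ancestors(b):
                new_edges.add((a, anc))
        else:
            for anc in ontology.ancestors(a):
                new_edges.add((anc, b))
    src_uni = set(dataset.source_universe)
    tgt_uni = set(dataset.target_universe)
    if side == "target":
        tgt_uni |= ontology.terms
    else:
        src_uni |= ontology.terms
    return DatasetNetwork.from_edges(
        dataset.name, dataset.metaedge, new_edges, src_uni, tgt_uni
    )


# ---------------------------------------------------------------------------
# Manifest I/O


def load_manifest(path: str | Path) -> tuple[KnowledgeGraph, dict]:
    """Load a YAML manifest describing a knowledge graph on disk.

    Schema::

        metanodes: {GEN: "genes", CLL: "cell lines", ...}
        metaedges:
          - {label: GEN-ppi-GEN}            # directed: true for one-way edges
        universes: {GEN: genes.txt, ...}    # optional node lists per metanode
        datasets:
          - {name: ppi_db1, metaedge: GEN-ppi-GEN, file: ppi_db1.tsv}

    Relative file paths are resolved against the manifest's directory.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    base = path.parent
    mg = Metagraph()
    for abbr, name in (doc.get("metanodes") or {}).items():
        mg.add_metanode(abbr, name)
    for entry in doc.get("metaedges") or []:
        ref = parse_metaedge_label(entry["label"])
        spec = MetaedgeSpec(
            ref.spec.source_type,
            ref.spec.relation,
            ref.spec.target_type,
            directed=bool(entry.get("directed", ref.spec.directed)),
        )
        mg.add_metaedge(spec)
    universes: dict[str, set[str]] = {}
    for abbr, fname in (doc.get("universes") or {}).items():
        with open(base / fname, encoding="utf-8") as fh:
            universes[abbr] = {
                ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")
            }
    datasets = []
    for entry in doc.get("datasets") or []:
        ref = parse_metaedge_label(entry["metaedge"], mg)
        spec = ref.spec
        ds = DatasetNetwork.from_tsv(
            base / entry["file"],
            entry["name"],
            spec,
            universes.get(spec.source_type),
            universes.get(spec.target_type),
        )
        datasets.append(ds)
    kg = assemble_graph(datasets, mg)
    return kg, {"universes": {k: len(v) for k, v in universes.items()}}
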