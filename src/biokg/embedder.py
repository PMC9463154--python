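"""Weighted random-walk corpus generation and skip-gram node embedding.

The collapsed metapath network (homogeneous or bipartite) is explored by a
random walker whose next-step distribution at each node is the node's DWPC
weights rescaled to sum to 1 (uniform on unweighted L1 networks). With the
walk-bias parameters p = q = 1 the walker is first-order Markov, which allows
an O(1)-per-step alias-sampling implementation vectorized over all walkers;
the general second-order (p, q) walker is supported but off by default. The
retained trajectories are fed to a skip-gram model with negative sampling,
yielding one fixed-length vector per node.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import json
import numpy as np
import scipy.sparse as sp

from ._sgns import train_sgns
from .dwpc import DWPCConfig, DWPCMatrix, cap_edges, dwpc_matrix, filter_components
from .kg_core import KnowledgeGraph
from .metapath import MetapathSpec, parse_metapath


@dataclass
class EmbedConfig:
    """Random-walk and skip-gram hyperparameters.

    dimension: embedding vector length.
    walks_per_node / walk_length: corpus size — every non-isolated node anchors
        ``walks_per_node`` walks of ``walk_length`` visited nodes.
    p, q: return and in-out bias of the walker (1.0 = unbiased first-order).
    window / negative / epochs / alpha / min_alpha: skip-gram parameters
        (word2vec conventions).
    seed: master seed; walks and training derive their streams from it.
    """

    dimension: int = 128
    walks_per_node: int = 100
    walk_length: int = 100
    p: float = 1.0
    q: float = 1.0
    window: int = 5
    negative: int = 5
    epochs: int = 5
    alpha: float = 0.025
    min_alpha: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dimension < 2:
            raise ValueError("dimension must be >= 2")
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be positive")


@dataclass
class WalkCorpus:
    """A set of random-walk trajectories over an indexed node universe."""

    walks: np.ndarray  # (n_walks, walk_length) int32, -1 padding
    nodes: list[str]

    def to_token_lists(self) -> list[list[str]]:
        return [
            [self.nodes[i] for i in row if i >= 0] for row in self.walks
        ]


@dataclass
class EmbeddingSet:
    """node → fixed-length vector, with provenance metadata."""

    nodes: list[str]
    vectors: np.ndarray  # (n_nodes, dim) float32
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float32)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.nodes):
            raise ValueError("vectors must be (n_nodes, dim)")
        self._index = {n: i for i, n in enumerate(self.nodes)}

    def __contains__(self, node: str) -> bool:
        return node in self._index

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def dimension(self) -> int:
        return self.vectors.shape[1]

    def vector(self, node: str) -> np.ndarray:
        return self.vectors[self._index[node]]

    def indices(self, nodes: Iterable[str]) -> np.ndarray:
        return np.fromiter((self._index[n] for n in nodes), dtype=np.int64)

    def unit_vectors(self) -> np.ndarray:
        norms = np.linalg.norm(self.vectors, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return self.vectors / norms

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for n, v in zip(self.nodes, self.vectors):
                fh.write(n + "\t" + "\t".join(f"{x:.6g}" for x in v) + "\n")
        meta_path = Path(path).with_suffix(".json")
        with open(meta_path, "w", encoding="utf-8") as fh:
            json.dump(self.metadata, fh, indent=1, default=str)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EmbeddingSet":
        nodes, rows = [], []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                nodes.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        meta_path = Path(path).with_suffix(".json")
        meta = {}
        if meta_path.exists():
            with open(meta_path, encoding="utf-8") as fh:
                meta = json.load(fh)
        return cls(nodes, np.array(rows, dtype=np.float32), meta)


# ---------------------------------------------------------------------------
# Walk graph construction


def _walk_graph(network: DWPCMatrix | Iterable[tuple[str, str]]) -> tuple[
    list[str], sp.csr_matrix
]:
    """Build the (symmetric) weighted adjacency the walker explores.

    Homogeneous networks are symmetrized (an edge can be traversed both ways);
    bipartite networks become a block adjacency over the disjoint union of the
    two sides. Bipartite side universes must not share node ids.
    """
    if isinstance(network, DWPCMatrix):
        if network.homogeneous:
            M = network.matrix.maximum(network.matrix.T)
            return list(network.row_nodes), sp.csr_matrix(M)
        overlap = set(network.row_nodes) & set(network.col_nodes)
        if overlap:
            raise ValueError(
                f"bipartite sides share {len(overlap)} node id(s); ids must be "
                "globally unique across entity types"
            )
        nodes = list(network.row_nodes) + list(network.col_nodes)
        M = sp.bmat([[None, network.matrix], [network.matrix.T, None]])
        return nodes, sp.csr_matrix(M)
    edges = list(network)
    nodes = sorted({n for e in edges for n in e[:2]})
    idx = {n: i for i, n in enumerate(nodes)}
    r = np.fromiter((idx[a] for a, b, *_ in edges), dtype=np.int64)
    c = np.fromiter((idx[b] for a, b, *_ in edges), dtype=np.int64)
    w = np.array([e[2] if len(e) > 2 else 1.0 for e in edges])
    A = sp.coo_matrix((w, (r, c)), shape=(len(nodes), len(nodes))).tocsr()
    return nodes, sp.csr_matrix(A.maximum(A.T))


def transition_matrix(adj: sp.csr_matrix) -> sp.csr_matrix:
    """Row-normalize weights into next-step probabilities (rows sum to 1)."""
    deg = np.asarray(adj.sum(axis=1)).ravel()
    inv = np.where(deg > 0, 1.0 / np.where(deg > 0, deg, 1.0), 0.0)
    return sp.csr_matrix(sp.diags(inv) @ adj)


def _alias_tables(P: sp.csr_matrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-row alias tables (prob, alias) over the CSR neighbour slots."""
    prob = np.empty_like(P.data)
    alias = np.zeros(P.nnz, dtype=np.int64)
    indptr = P.indptr
    for i in range(P.shape[0]):
        lo, hi = indptr[i], indptr[i + 1]
        k = hi - lo
        if k == 0:
            continue
        p = P.data[lo:hi] * k
        small = [j for j in range(k) if p[j] < 1.0]
        large = [j for j in range(k) if p[j] >= 1.0]
        pr = p.copy()
        al = np.zeros(k, dtype=np.int64)
        while small and large:
            s = small.pop()
            l = large.pop()
            al[s] = l
            pr[l] = pr[l] - (1.0 - pr[s])
            (small if pr[l] < 1.0 else large).append(l)
        for j in large + small:
            pr[j] = 1.0
        prob[lo:hi] = pr
        alias[lo:hi] = al
    return prob, alias


def generate_walks(
    network: DWPCMatrix | Iterable[tuple[str, str]], cfg: EmbedConfig | None = None
) -> WalkCorpus:
    """Generate the weighted random-walk corpus of a network.

    Per-node DWPC weights are rescaled to sum to 1 and used as next-step
    probabilities. Every non-isolated node anchors ``walks_per_node`` walks of
    ``walk_length`` nodes; anchor order is reshuffled each repetition.
    Isolated nodes are skipped with a warning. Seeded and reproducible.
    """
    cfg = cfg or EmbedConfig()
    nodes, adj = _walk_graph(network)
    deg = np.asarray(adj.sum(axis=1)).ravel()
    active = np.flatnonzero(deg > 0)
    if len(active) < len(nodes):
        warnings.warn(
            f"skipping {len(nodes) - len(active)} isolated node(s) with no edges"
        )
    if len(active) == 0:
        raise ValueError("network has no edges")
    P = transition_matrix(adj)
    if cfg.p == 1.0 and cfg.q == 1.0:
        walks = _first_order_walks(P, active, cfg)
    else:
        walks = _second_order_walks(P, active, cfg)
    return WalkCorpus(walks, nodes)


def _first_order_walks(
    P: sp.csr_matrix, active: np.ndarray, cfg: EmbedConfig
) -> np.ndarray:
    rng = np.random.default_rng(cfg.seed)
    prob, alias = _alias_tables(P)
    indptr, indices = P.indptr, P.indices
    counts = np.diff(indptr)
    L = cfg.walk_length
    out = np.empty((cfg.walks_per_node * len(active), L), dtype=np.int32)
    row = 0
    for _ in range(cfg.walks_per_node):
        cur = active[rng.permutation(len(active))]
        block = out[row: row + len(cur)]
        block[:, 0] = cur
        pos = cur.astype(np.int64)
        for t in range(1, L):
            k = counts[pos]
            slot = indptr[pos] + (rng.random(len(pos)) * k).astype(np.int64)
            take_alias = rng.random(len(pos)) >= prob[slot]
            nxt_slot = np.where(take_alias, indptr[pos] + alias[slot], slot)
            pos = indices[nxt_slot].astype(np.int64)
            block[:, t] = pos
        row += len(cur)
    return out


def _second_order_walks(
    P: sp.csr_matrix, active: np.ndarray, cfg: EmbedConfig
) -> np.ndarray:
    """Reference (non-vectorized) node2vec walker for general p, q."""
    rng = np.random.default_rng(cfg.seed)
    indptr, indices, data = P.indptr, P.indices, P.data
    neigh = {int(i): set(indices[indptr[i]: indptr[i + 1]]) for i in range(P.shape[0])}
    L = cfg.walk_length
    out = np.empty((cfg.walks_per_node * len(active), L), dtype=np.int32)
    row = 0
    for _ in range(cfg.walks_per_node):
        for start in active[rng.permutation(len(active))]:
            walk = [int(start)]
            for _t in range(1, L):
                cur = walk[-1]
                lo, hi = indptr[cur], indptr[cur + 1]
                cand, w = indices[lo:hi], data[lo:hi].copy()
                if len(walk) > 1:
                    prev = walk[-2]
                    for j, x in enumerate(cand):
                        if x == prev:
                            w[j] /= cfg.p
                        elif x not in neigh[prev]:
                            w[j] /= cfg.q
                w = w / w.sum()
                walk.append(int(rng.choice(cand, p=w)))
            out[row] = walk
            row += 1
    return out


# ---------------------------------------------------------------------------
# Skip-gram training


def train_skipgram(corpus: WalkCorpus, cfg: EmbedConfig | None = None) -> EmbeddingSet:
    """Train skip-gram vectors on a walk corpus.

    Only nodes appearing in the corpus receive a vector. Training is
    single-threaded and deterministic for a fixed seed.
    """
    cfg = cfg or EmbedConfig()
    if corpus.walks.size == 0:
        raise ValueError("empty corpus")
    present = np.unique(corpus.walks[corpus.walks >= 0])
    if len(present) < 2:
        raise ValueError("vocabulary smaller than 2 nodes")
    # compact the vocabulary to nodes actually visited
    remap = -np.ones(len(corpus.nodes), dtype=np.int32)
    remap[present] = np.arange(len(present), dtype=np.int32)
    walks = np.where(corpus.walks >= 0, remap[corpus.walks], -1).astype(np.int32)
    vecs = train_sgns(
        walks,
        vocab_size=len(present),
        dim=cfg.dimension,
        window=cfg.window,
        negative=cfg.negative,
        epochs=cfg.epochs,
        alpha=cfg.alpha,
        min_alpha=cfg.min_alpha,
        seed=cfg.seed,
    )
    nodes = [corpus.nodes[i] for i in present]
    return EmbeddingSet(nodes, vecs, metadata={"config": vars(cfg).copy()})


def embed_network(
    network: DWPCMatrix | Iterable[tuple[str, str]], cfg: EmbedConfig | None = None
) -> EmbeddingSet:
    """generate_walks → train_skipgram on an already-filtered network."""
    cfg = cfg or EmbedConfig()
    corpus = generate_walks(network, cfg)
    emb = train_skipgram(corpus, cfg)
    if isinstance(network, DWPCMatrix):
        emb.metadata.update(
            {"metapath": network.metapath, "datasets": list(network.datasets)}
        )
    return emb


def embed_metapath(
    spec: MetapathSpec | str,
    kg: KnowledgeGraph,
    dwpc_cfg: DWPCConfig | None = None,
    embed_cfg: EmbedConfig | None = None,
) -> tuple[EmbeddingSet, dict]:
    """Full pipeline: DWPC collapse → edge cap → component filter → embed.

    Raises ``ValueError`` when component filtering flags the metapath as
    REJECTED (less than half the nodes survive in large-enough components).
    Returns the embedding and the retention report.
    """
    dwpc_cfg = dwpc_cfg or DWPCConfig()
    embed_cfg = embed_cfg or EmbedConfig()
    if isinstance(spec, str):
        spec = parse_metapath(spec, kg)
    dm = dwpc_matrix(spec, kg, dwpc_cfg)
    capped = cap_edges(dm, dwpc_cfg)
    filtered, report = filter_components(capped, dwpc_cfg)
    if report["rejected"]:
        raise ValueError(
            f"metapath {spec.label} REJECTED: retains "
            f"{report['retention']:.1%} of nodes (< {dwpc_cfg.node_retention_min:.0%})"
        )
    emb = embed_network(filtered, embed_cfg)
    return emb, report
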