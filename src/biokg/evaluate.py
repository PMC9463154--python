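"""Validate embeddings by network reconstruction; characterize against references.

The quality bar for an embedding is whether it can reassemble the network it
was trained on: true edges should join nodes with small cosine distance, while
random node pairs should not. For every network edge we draw a fixed number of
random "permuted" pairs (endpoints resampled within the correct entity side),
pool the cosine distances and compute the AUROC with edges as positives.
Embeddings below the retention threshold (0.8) are dropped from a resource.

Characterization reuses the same statistic against *orthogonal* reference
networks, reporting node coverage alongside the AUROC, and offers two ways to
turn a bipartite reference into per-side similarity networks (TF-IDF cosine
top-k, and shared-neighbour top-k).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction.text import TfidfTransformer
from sklearn.metrics import roc_auc_score
from sklearn.metrics.pairwise import cosine_similarity

from .dwpc import DWPCMatrix
from .embedder import EmbeddingSet
from .kg_core import DatasetNetwork


@dataclass
class EvalConfig:
    """Reconstruction-evaluation parameters.

    negatives_per_edge: random node-pair permutations drawn per network edge.
    auroc_retention_threshold: embeddings scoring below this are not retained.
    dwpc_subset_fractions: per-node closest-neighbour fractions (by DWPC
        weight) at which the reconstruction is re-evaluated for weighted
        networks.
    """

    negatives_per_edge: int = 100
    auroc_retention_threshold: float = 0.8
    dwpc_subset_fractions: tuple[float, ...] = (0.01, 0.25, 0.50)
    seed: int = 0


@dataclass
class EvaluationReport:
    auroc: float | None
    n_positives: int
    n_negatives: int
    retained: bool
    subset_aurocs: dict[float, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "auroc": self.auroc,
            "n_positives": self.n_positives,
            "n_negatives": self.n_negatives,
            "retained": self.retained,
            "subset_aurocs": {str(k): v for k, v in self.subset_aurocs.items()},
        }


def _network_edges(
    network: DWPCMatrix | DatasetNetwork | Iterable[tuple[str, str]],
) -> tuple[list[tuple[str, str]], list[str], list[str], DWPCMatrix | None]:
    """Edges plus the two side universes of any supported network form."""
    if isinstance(network, DWPCMatrix):
        coo = network.matrix.tocoo()
        edges = [
            (network.row_nodes[i], network.col_nodes[j])
            for i, j in zip(coo.row, coo.col)
        ]
        if network.homogeneous:
            edges = list({tuple(sorted(e)) for e in edges})
        return edges, list(network.row_nodes), list(network.col_nodes), network
    if isinstance(network, DatasetNetwork):
        return (
            sorted(network.edges),
            sorted(network.source_universe),
            sorted(network.target_universe),
            None,
        )
    edges = [tuple(e[:2]) for e in network]
    left = sorted({a for a, _ in edges})
    right = sorted({b for _, b in edges})
    return edges, left, right, None


def _pair_distances(
    emb: EmbeddingSet, a_idx: np.ndarray, b_idx: np.ndarray
) -> np.ndarray:
    U = emb.unit_vectors()
    return 1.0 - np.einsum("ij,ij->i", U[a_idx], U[b_idx])


def _auroc_for_edges(
    emb: EmbeddingSet,
    edges: Sequence[tuple[str, str]],
    left_pool: np.ndarray,
    right_pool: np.ndarray,
    homogeneous: bool,
    cfg: EvalConfig,
) -> tuple[float, int, int]:
    rng = np.random.default_rng(cfg.seed)
    true_set = set(edges)
    if homogeneous:
        true_set |= {(b, a) for a, b in edges}
    a_idx = emb.indices(e[0] for e in edges)
    b_idx = emb.indices(e[1] for e in edges)
    pos = _pair_distances(emb, a_idx, b_idx)
    n_neg = cfg.negatives_per_edge * len(edges)
    neg_a = np.empty(n_neg, dtype=np.int64)
    neg_b = np.empty(n_neg, dtype=np.int64)
    filled = 0
    node_arr = np.asarray(emb.nodes, dtype=object)
    while filled < n_neg:
        take = n_neg - filled
        ca = left_pool[rng.integers(0, len(left_pool), take)]
        cb = right_pool[rng.integers(0, len(right_pool), take)]
        ok = ca != cb
        # reject resampled pairs that are true edges
        pairs = zip(node_arr[ca], node_arr[cb])
        ok &= np.fromiter((p not in true_set for p in pairs), dtype=bool, count=take)
        ca, cb = ca[ok], cb[ok]
        neg_a[filled: filled + len(ca)] = ca
        neg_b[filled: filled + len(cb)] = cb
        filled += len(ca)
    neg = _pair_distances(emb, neg_a, neg_b)
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    scores = -np.concatenate([pos, neg])  # smaller distance ranks as positive
    return float(roc_auc_score(y, scores)), len(pos), len(neg)


def reconstruction_auroc(
    emb: EmbeddingSet,
    network: DWPCMatrix | DatasetNetwork | Iterable[tuple[str, str]],
    cfg: EvalConfig | None = None,
) -> EvaluationReport:
    """AUROC of separating network edges from random node-pair permutations.

    Per positive edge, ``negatives_per_edge`` random pairs are drawn by
    resampling both endpoints uniformly within the embedded universe of the
    correct entity side, rejecting self-pairs and true edges. Cosine distances
    are pooled and ranked (Mann-Whitney AUROC, ties mid-ranked). For weighted
    networks the evaluation is repeated on the per-node top 1% / 25% / 50%
    closest-neighbour subsets by DWPC weight.
    """
    cfg = cfg or EvalConfig()
    edges, left_uni, right_uni, dm = _network_edges(network)
    edges = [e for e in edges if e[0] in emb and e[1] in emb]
    if not edges:
        raise ValueError("no network edge has both endpoints embedded")
    left_pool = emb.indices(n for n in left_uni if n in emb)
    right_pool = emb.indices(n for n in right_uni if n in emb)
    homogeneous = dm.homogeneous if dm is not None else set(left_uni) == set(right_uni)
    auroc, n_pos, n_neg = _auroc_for_edges(
        emb, edges, left_pool, right_pool, homogeneous, cfg
    )
    report = EvaluationReport(
        auroc=auroc,
        n_positives=n_pos,
        n_negatives=n_neg,
        retained=auroc >= cfg.auroc_retention_threshold,
    )
    weighted = dm is not None and dm.matrix.nnz and not np.allclose(dm.matrix.data, 1.0)
    if weighted:
        for frac in cfg.dwpc_subset_fractions:
            sub = _dwpc_subset_edges(dm, frac)
            sub = [e for e in sub if e[0] in emb and e[1] in emb]
            if not sub:
                continue
            a, _, _ = _auroc_for_edges(emb, sub, left_pool, right_pool, homogeneous, cfg)
            report.subset_aurocs[frac] = a
    return report


def _dwpc_subset_edges(dm: DWPCMatrix, fraction: float) -> list[tuple[str, str]]:
    """Per node, the top ``fraction`` of its neighbours by DWPC weight."""
    out: set[tuple[str, str]] = set()
    M = dm.matrix
    for mat, transpose in ((M, False), (sp.csr_matrix(M.T), True)):
        indptr, indices, data = mat.indptr, mat.indices, mat.data
        for i in range(mat.shape[0]):
            lo, hi = indptr[i], indptr[i + 1]
            if lo == hi:
                continue
            cols, vals = indices[lo:hi], data[lo:hi]
            k = max(1, int(round(fraction * len(cols))))
            order = np.lexsort((cols, -vals))[:k]
            for j in cols[order]:
                e = (dm.row_nodes[j], dm.col_nodes[i]) if transpose else (
                    dm.row_nodes[i], dm.col_nodes[j]
                )
                if dm.homogeneous:
                    e = tuple(sorted(e))
                out.add(e)
    return sorted(out)


def recapitulation(
    emb: EmbeddingSet,
    reference: DatasetNetwork | Iterable[tuple[str, str]],
    cfg: EvalConfig | None = None,
) -> tuple[int, float | None]:
    """Coverage and AUROC of an embedding against an orthogonal reference.

    The reference network is restricted to nodes present in the embedding;
    coverage is the count of overlapping nodes. With fewer than two covered
    nodes on a side, or no covered edges, the AUROC is undefined and reported
    as ``None`` (never 0.5).
    """
    cfg = cfg or EvalConfig()
    edges, left_uni, right_uni, _ = _network_edges(reference)
    covered_nodes = {n for n in set(left_uni) | set(right_uni) if n in emb}
    coverage = len(covered_nodes)
    edges = [e for e in edges if e[0] in emb and e[1] in emb]
    left_pool = [n for n in left_uni if n in emb]
    right_pool = [n for n in right_uni if n in emb]
    if not edges or len(left_pool) < 2 or len(right_pool) < 2:
        return coverage, None
    auroc, _, _ = _auroc_for_edges(
        emb,
        edges,
        emb.indices(left_pool),
        emb.indices(right_pool),
        set(left_uni) == set(right_uni),
        cfg,
    )
    return coverage, auroc


# ---------------------------------------------------------------------------
# Reference-network derived similarity networks


def _incidence(
    edges: Sequence[tuple[str, str]], side: int
) -> tuple[list[str], list[str], sp.csr_matrix]:
    ents = sorted({e[side] for e in edges})
    feats = sorted({e[1 - side] for e in edges})
    ei = {n: i for i, n in enumerate(ents)}
    fi = {n: i for i, n in enumerate(feats)}
    r = np.fromiter((ei[e[side]] for e in edges), dtype=np.int64)
    c = np.fromiter((fi[e[1 - side]] for e in edges), dtype=np.int64)
    M = sp.coo_matrix(
        (np.ones(len(edges)), (r, c)), shape=(len(ents), len(feats))
    ).tocsr()
    M.data = np.ones_like(M.data)  # collapse duplicates
    return ents, feats, M


def _topk_sim_edges(
    ents: list[str], S: np.ndarray, top_k: int
) -> list[tuple[str, str, float]]:
    """Per entity, its top-k most similar partners (ties by partner id)."""
    out = []
    n = len(ents)
    for i in range(n):
        sims = S[i].copy()
        sims[i] = -np.inf  # exclude self
        order = np.lexsort((np.arange(n), -sims))[: min(top_k, n - 1)]
        for j in order:
            if np.isfinite(sims[j]) and sims[j] > 0:
                out.append((ents[i], ents[j], float(sims[j])))
    return out


def entity_similarity_network(
    reference: DatasetNetwork | Iterable[tuple[str, str]], top_k: int = 5
) -> dict[str, list[tuple[str, str, float]]]:
    """TF-IDF cosine similarity networks, one per side of a bipartite reference.

    Each entity is encoded by its binary neighbour-incidence profile, the
    profiles are TF-IDF transformed, and each entity is linked to its ``top_k``
    closest entities of the same type by cosine similarity. Entities with no
    annotations are excluded. Returns ``{'source': edges, 'target': edges}``.
    """
    edges, left_uni, right_uni, _ = _network_edges(reference)
    if not edges:
        raise ValueError("empty reference network")
    result: dict[str, list[tuple[str, str, float]]] = {}
    for key, side in (("source", 0), ("target", 1)):
        ents, _, M = _incidence(edges, side)
        tf = TfidfTransformer(smooth_idf=True, norm="l2").fit_transform(M)
        S = cosine_similarity(tf)
        result[key] = _topk_sim_edges(ents, S, top_k)
    return result


def shared_neighbor_network(
    reference: DatasetNetwork | Iterable[tuple[str, str]],
    top_k: int = 3,
    side: int = 0,
) -> list[tuple[str, str, int]]:
    """Link each node with the top-k partners sharing the most neighbours.

    Operates on one side of a bipartite network (``side=0`` = source
    entities); the similarity is the raw shared-neighbour count, ties broken
    by partner id. Pairs sharing no neighbour are never linked.
    """
    edges, *_ = _network_edges(reference)
    ents, _, M = _incidence(edges, side)
    counts = (M @ M.T).toarray()
    out = _topk_sim_edges(ents, counts.astype(float), top_k)
    return [(a, b, int(c)) for a, b, c in out]
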