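"""Embedding-space distance queries, co-rank empirical P values and null models.

Raw cosine distances are not comparable across embedding spaces or across
nodes of very different connectivity. Two normalizations fix this:

* **co-rank P value** — for a node pair (a, b), rank b in a's ascending
  cosine-distance list and a in b's, normalize each rank by the number of
  other covered nodes, and keep the geometric mean. This is an empirical
  quantile in (0, 1], *not* the significance of a statistical test; a small
  value means the two nodes are mutually among each other's closest points.
* **permutation null** — degree-preserving edge swaps of a query network give
  an ensemble of random networks with identical degree sequences; comparing
  real versus null edge recovery across a sweep of P-value cutoffs yields
  fold-change curves and an empirical FDR cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .embedder import EmbeddingSet


def default_cutoff_grid(n: int = 50, lo: float = 0.001, hi: float = 1.0) -> np.ndarray:
    """Log-spaced P-value cutoff sweep (ascending), 50 points in [0.001, 1]."""
    return np.logspace(np.log10(lo), np.log10(hi), n)


# ---------------------------------------------------------------------------
# Exact cosine nearest neighbours


def cosine_knn(
    emb: EmbeddingSet, queries: Iterable[str], k: int
) -> dict[str, list[tuple[str, float]]]:
    """Exact cosine-distance k-nearest-neighbour lists for query nodes.

    Ranking is exhaustive (no approximation); ties are ordered by node id so
    results are deterministic. The query itself appears at rank 0 with
    distance 0.
    """
    queries = list(queries)
    missing = [q for q in queries if q not in emb]
    if missing:
        raise KeyError(f"query nodes not embedded: {missing[:5]}")
    U = emb.unit_vectors()
    qi = emb.indices(queries)
    D = 1.0 - U[qi] @ U.T
    n = len(emb.nodes)
    id_order = np.arange(n)  # emb.nodes need not be sorted; use index as tiebreak
    name_rank = np.argsort(np.argsort(np.asarray(emb.nodes, dtype=object)))
    out: dict[str, list[tuple[str, float]]] = {}
    for q, row in zip(queries, D):
        order = np.lexsort((name_rank, row))[: min(k, n)]
        out[q] = [(emb.nodes[j], float(row[j])) for j in order]
    return out


# ---------------------------------------------------------------------------
# Co-rank empirical P values


@dataclass
class CoRankTable:
    """Empirical co-rank P values for node pairs in one embedding space."""

    pvalues: dict[tuple[str, str], float]
    n_covered: int
    uncovered: list[tuple[str, str]] = field(default_factory=list)

    def values(self) -> np.ndarray:
        return np.asarray(list(self.pvalues.values()))

    def __len__(self) -> int:
        return len(self.pvalues)


def corank_pvalue(
    emb: EmbeddingSet, pairs: Iterable[tuple[str, str]]
) -> CoRankTable:
    """Geometric mean of the two normalized co-ranks of each node pair.

    rank(a→b) is the 1-based position of b in a's ascending cosine-distance
    list over all covered nodes (self excluded, ties by distance then node
    id), normalized by the n−1 other covered nodes so that a mutual nearest
    neighbour scores 1/(n−1) per side and a mutually farthest pair scores
    exactly 1. P = sqrt(norm_rank(a→b) · norm_rank(b→a)) ∈ (0, 1]. Pairs with
    an unembedded endpoint are reported as uncovered.
    """
    pairs = list(pairs)
    n = len(emb)
    if n < 2:
        raise ValueError("need at least 2 embedded nodes")
    U = emb.unit_vectors()
    name_rank = np.argsort(np.argsort(np.asarray(emb.nodes, dtype=object)))
    covered = [p for p in pairs if p[0] in emb and p[1] in emb and p[0] != p[1]]
    covered_set = set(covered)
    uncovered = [p for p in pairs if p not in covered_set]

    # rank queries grouped by anchor so each distance row is computed once
    anchors = sorted({a for a, _ in covered} | {b for _, b in covered})
    need: dict[str, set[str]] = {a: set() for a in anchors}
    for a, b in covered:
        need[a].add(b)
        need[b].add(a)
    rank_of: dict[tuple[str, str], int] = {}
    idx = emb._index
    for a in anchors:
        row = 1.0 - U[idx[a]] @ U.T
        order = np.lexsort((name_rank, row))
        pos = np.empty(n, dtype=np.int64)
        pos[order] = np.arange(n)
        self_pos = pos[idx[a]]
        for b in need[a]:
            p = pos[idx[b]]
            rank_of[(a, b)] = int(p if p < self_pos else p - 1) + 1
    denom = n - 1
    pvals = {
        (a, b): float(np.sqrt(rank_of[(a, b)] * rank_of[(b, a)])) / denom
        for a, b in covered
    }
    return CoRankTable(pvals, n, uncovered)


# ---------------------------------------------------------------------------
# Degree-preserving network permutation


def permute_network(
    edges: Iterable[tuple[str, str]],
    swaps_per_edge: int = 10,
    seed: int = 0,
    bipartite: bool = False,
) -> list[tuple[str, str]]:
    """Randomize a network by degree-preserving double-edge swaps.

    Picks two edges (a,b), (c,d) and rewires them to (a,d), (c,b), rejecting
    swaps that would create self-loops or duplicate edges; each side of a
    bipartite network stays on its side. Performs ``swaps_per_edge × n_edges``
    successful swaps (or stops after 100× that many attempts on pathological
    inputs). The degree sequence is preserved exactly.
    """
    rng = np.random.default_rng(seed)
    if bipartite:
        elist = [tuple(e) for e in edges]
    else:
        elist = [tuple(sorted(e)) for e in edges]
    if len(set(elist)) != len(elist):
        elist = list(dict.fromkeys(elist))
    if len(elist) < 2:
        raise ValueError("need at least 2 edges to swap")
    eset = set(elist)
    target = swaps_per_edge * len(elist)
    done = attempts = 0
    max_attempts = 100 * target
    while done < target and attempts < max_attempts:
        attempts += 1
        i, j = rng.integers(0, len(elist), 2)
        if i == j:
            continue
        a, b = elist[i]
        c, d = elist[j]
        e1, e2 = (a, d), (c, b)
        if not bipartite:
            e1, e2 = tuple(sorted(e1)), tuple(sorted(e2))
            if a == d or c == b:
                continue
        if e1 in eset or e2 in eset or e1 == e2:
            continue
        eset.remove(elist[i])
        eset.remove(elist[j])
        eset.update((e1, e2))
        elist[i], elist[j] = e1, e2
        done += 1
    return elist


# ---------------------------------------------------------------------------
# Fold change and empirical FDR over a cutoff sweep


def _counts_at_cutoffs(values: np.ndarray, cutoffs: np.ndarray) -> np.ndarray:
    return np.searchsorted(np.sort(values), cutoffs, side="right")


def fold_change_curve(
    p_real: CoRankTable | Mapping[tuple, float],
    p_null: Sequence[CoRankTable | Mapping[tuple, float]],
    cutoffs: np.ndarray | None = None,
) -> list[dict]:
    """Real-over-null edge recovery fold change across P-value cutoffs.

    FC(c) = (# real edges with P ≤ c) / mean over permutations of (# null
    edges with P ≤ c); the null mean is floored at 1 edge to keep the ratio
    finite, with raw counts reported alongside.
    """
    cutoffs = default_cutoff_grid() if cutoffs is None else np.asarray(cutoffs)
    rv = p_real.values() if isinstance(p_real, CoRankTable) else np.asarray(
        list(p_real.values())
    )
    nulls = [
        t.values() if isinstance(t, CoRankTable) else np.asarray(list(t.values()))
        for t in p_null
    ]
    real_counts = _counts_at_cutoffs(rv, cutoffs)
    null_counts = np.vstack([_counts_at_cutoffs(v, cutoffs) for v in nulls])
    mean_null = null_counts.mean(axis=0)
    fc = real_counts / np.maximum(mean_null, 1.0)
    return [
        {
            "cutoff": float(c),
            "fold_change": float(f),
            "n_real": int(r),
            "mean_null": float(m),
        }
        for c, f, r, m in zip(cutoffs, fc, real_counts, mean_null)
    ]


def fdr_pvalue_cutoff(
    p_null: Sequence[CoRankTable | Mapping[tuple, float]],
    fdr: float = 0.05,
    cutoffs: np.ndarray | None = None,
    conservative: bool = False,
) -> float:
    """P-value cutoff at which null-edge coverage stays within ``fdr``.

    By default returns the *largest* grid cutoff whose mean fraction of
    covered permuted-network edges is ≤ ``fdr`` (step function over the grid,
    no interpolation), which gives the most permissive recall at the nominal
    rate. ``conservative=True`` returns the grid point below it, the other
    reading of "minimum P value needed to cover no more than fdr". Returns
    0.0 when no grid point qualifies.
    """
    cutoffs = default_cutoff_grid() if cutoffs is None else np.asarray(cutoffs)
    cutoffs = np.sort(cutoffs)
    nulls = [
        t.values() if isinstance(t, CoRankTable) else np.asarray(list(t.values()))
        for t in p_null
    ]
    fracs = np.vstack(
        [_counts_at_cutoffs(v, cutoffs) / max(len(v), 1) for v in nulls]
    ).mean(axis=0)
    ok = np.flatnonzero(fracs <= fdr)
    if len(ok) == 0:
        return 0.0
    i = ok[-1]
    if conservative and i > 0:
        i -= 1
    return float(cutoffs[i])


# ---------------------------------------------------------------------------
# Support categories for query edges

SUPPORT_LABELS = (
    "known and supported",
    "known",
    "supported",
    "potentially novel",
)


def support_categories(
    query_edges: Iterable[tuple[str, str]],
    p_tables: Mapping[str, CoRankTable | Mapping[tuple, float]],
    ppi_metapath_id: str,
    cutoff: float,
) -> dict[tuple[str, str], str]:
    """Classify query edges by which embedding spaces support them.

    An edge is *covered* by a metapath when its co-rank P value passes the
    cutoff there. Edges covered by the designated direct-interaction metapath
    and at least one other are "known and supported"; only by it, "known";
    only by others, "supported"; by none, "potentially novel". Pairs are
    matched irrespective of orientation.
    """
    if ppi_metapath_id not in p_tables:
        raise KeyError(f"{ppi_metapath_id!r} not among the supplied P tables")
    norm_tables: dict[str, dict[frozenset, float]] = {}
    for mp, table in p_tables.items():
        pv = table.pvalues if isinstance(table, CoRankTable) else dict(table)
        norm_tables[mp] = {frozenset(k): v for k, v in pv.items()}
    out: dict[tuple[str, str], str] = {}
    for edge in query_edges:
        key = frozenset(edge)
        passing = {
            mp for mp, pv in norm_tables.items() if pv.get(key, np.inf) <= cutoff
        }
        ppi = ppi_metapath_id in passing
        other = bool(passing - {ppi_metapath_id})
        if ppi and other:
            label = "known and supported"
        elif ppi:
            label = "known"
        elif other:
            label = "supported"
        else:
            label = "potentially novel"
        out[tuple(edge)] = label
    return out
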