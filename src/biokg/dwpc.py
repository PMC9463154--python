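"""Collapse metapaths into degree-weighted path-count (DWPC) networks.

A metapath of length L is collapsed into a single source × target matrix by
chaining the adjacency matrices of its datasets. To keep hub nodes from
dominating, every adjacency is degree-normalized before multiplication:

    W = D_row^w · A · D_col^w,     w = degree_exponent (default −0.5),

with degrees computed *within each dataset*. The product of the W matrices
along the chain equals, entrywise, the sum over all source→target paths of the
product of the traversed node degrees raised to w — the degree-weighted path
count. The resulting dense-ish weighted network is then edge-capped per node
and component-filtered before being handed to the random walker.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .kg_core import DatasetNetwork, KnowledgeGraph
from .metapath import MetapathSpec, MetapathStep, expand_variants


@dataclass
class DWPCConfig:
    """Degree-control knobs of the metapath-collapse stage.

    degree_exponent: exponent applied to within-dataset node degrees (−0.5
        damps hubs; 0 recovers raw path counts).
    cap_fraction / cap_min / cap_max: per-node edge budget — each node keeps
        its top ``clamp(round(cap_fraction · n_possible), cap_min, cap_max)``
        neighbours by weight.
    component_min_frac: connected components covering less than this fraction
        of the entities are dropped.
    node_retention_min: a metapath whose filtered network retains less than
        this fraction of nodes is flagged REJECTED.
    """

    degree_exponent: float = -0.5
    cap_fraction: float = 0.05
    cap_min: int = 3
    cap_max: int = 250
    component_min_frac: float = 0.05
    node_retention_min: float = 0.5

    def __post_init__(self) -> None:
        if self.cap_min > self.cap_max:
            raise ValueError("cap_min must be <= cap_max")
        for f in (self.cap_fraction, self.component_min_frac):
            if not (0 < f <= 1):
                raise ValueError("fractions must lie in (0, 1]")


@dataclass
class DWPCMatrix:
    """Sparse source × target matrix of DWPC weights with node indexes."""

    matrix: sp.csr_matrix
    row_nodes: list[str]
    col_nodes: list[str]
    metapath: str | None = None
    datasets: tuple[str, ...] = ()
    # per-node top-k selections recorded by cap_edges (row/column perspective)
    row_kept: sp.csr_matrix | None = None
    col_kept: sp.csr_matrix | None = None

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        self.matrix.eliminate_zeros()
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValueError("DWPC weights must be nonnegative")

    @property
    def homogeneous(self) -> bool:
        return self.row_nodes == self.col_nodes

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def to_tsv(self, path) -> None:
        coo = self.matrix.tocoo()
        order = np.lexsort((coo.col, coo.row))
        with open(path, "w", encoding="utf-8") as fh:
            for i, j, v in zip(coo.row[order], coo.col[order], coo.data[order]):
                fh.write(f"{self.row_nodes[i]}\t{self.col_nodes[j]}\t{v:.10g}\n")


# ---------------------------------------------------------------------------
# Step adjacency construction


def _oriented_edges(ds: DatasetNetwork, step: MetapathStep, which: int) -> tuple[
    list[tuple[str, str]], set[str], set[str], bool
]:
    """Edges of a dataset oriented along the traversal of ``step``.

    Returns (edges, left_universe, right_universe, symmetrize) where
    ``symmetrize`` marks undirected homogeneous datasets whose adjacency must
    count both directions.
    """
    me = ds.metaedge
    if me.homogeneous:
        if not me.directed:
            return list(ds.edges), set(ds.source_universe), set(ds.source_universe), True
        if step.source_side == "right":
            return (
                [(b, a) for a, b in ds.edges],
                set(ds.source_universe),
                set(ds.source_universe),
                False,
            )
        return list(ds.edges), set(ds.source_universe), set(ds.source_universe), False
    if step.reversed[which]:
        return (
            [(b, a) for a, b in ds.edges],
            set(ds.target_universe),
            set(ds.source_universe),
            False,
        )
    return list(ds.edges), set(ds.source_universe), set(ds.target_universe), False


def _step_matrix(
    ds: DatasetNetwork, step: MetapathStep, which: int, exponent: float
) -> tuple[np.ndarray, np.ndarray, sp.csr_matrix]:
    """Degree-normalized adjacency of one dataset along the traversal."""
    edges, left_uni, right_uni, symmetrize = _oriented_edges(ds, step, which)
    rows = np.array(sorted(left_uni))
    cols = np.array(sorted(right_uni))
    ridx = {n: i for i, n in enumerate(rows)}
    cidx = {n: i for i, n in enumerate(cols)}
    if edges:
        r = np.fromiter((ridx[a] for a, b in edges), dtype=np.int64)
        c = np.fromiter((cidx[b] for a, b in edges), dtype=np.int64)
        A = sp.coo_matrix(
            (np.ones(len(edges)), (r, c)), shape=(len(rows), len(cols))
        ).tocsr()
        if symmetrize:
            A = A.maximum(A.T)
    else:
        A = sp.csr_matrix((len(rows), len(cols)))
    # degrees within this dataset, on the oriented adjacency
    rdeg = np.asarray(A.sum(axis=1)).ravel()
    cdeg = np.asarray(A.sum(axis=0)).ravel()
    with np.errstate(divide="ignore"):
        rw = np.where(rdeg > 0, rdeg**exponent, 0.0)
        cw = np.where(cdeg > 0, cdeg**exponent, 0.0)
    W = sp.diags(rw) @ A @ sp.diags(cw)
    return rows, cols, sp.csr_matrix(W)


def _chain(
    mats: Sequence[tuple[np.ndarray, np.ndarray, sp.csr_matrix]]
) -> tuple[np.ndarray, np.ndarray, sp.csr_matrix]:
    """Chain step matrices, aligning the shared node universe between steps."""
    rows, cols, M = mats[0]
    for nrows, ncols, W in mats[1:]:
        shared = np.array(sorted(set(cols) & set(nrows)))
        if shared.size == 0:
            raise ValueError("disconnected metapath: empty intermediate universe")
        lidx = {n: i for i, n in enumerate(cols)}
        ridx = {n: i for i, n in enumerate(nrows)}
        li = np.fromiter((lidx[n] for n in shared), dtype=np.int64)
        ri = np.fromiter((ridx[n] for n in shared), dtype=np.int64)
        M = sp.csr_matrix(M[:, li] @ W[ri, :])
        cols = ncols
    return rows, cols, M


def dwpc_matrix(
    spec: MetapathSpec, kg: KnowledgeGraph, cfg: DWPCConfig | None = None
) -> DWPCMatrix:
    """Collapse a metapath into a DWPC source × target matrix.

    '+'-combined relations expand into zipped variants; every step may bind
    several datasets, in which case one network is computed per dataset
    combination. Length-1 metapaths are returned as the binary union of their
    dataset edges (no weights); longer metapaths sum the DWPC values of all
    variant/combination networks.
    """
    cfg = cfg or DWPCConfig()
    variants = expand_variants(spec)
    used: list[str] = []
    parts: list[DWPCMatrix] = []
    for var in variants:
        for step in var.steps:
            if not step.datasets or not step.datasets[0]:
                raise ValueError(
                    f"no dataset bound for step {step.left_type}-"
                    f"{step.relations[0]}-{step.right_type}"
                )
        choices = [step.datasets[0] for step in var.steps]
        for combo in product(*choices):
            mats = []
            for step, ds_name in zip(var.steps, combo):
                ds = kg.dataset(ds_name)
                mats.append(_step_matrix(ds, step, 0, cfg.degree_exponent))
            rows, cols, M = _chain(mats)
            used.extend(combo)
            parts.append(
                DWPCMatrix(
                    M, [str(n) for n in rows], [str(n) for n in cols],
                    var.label, tuple(combo),
                )
            )
    mode = "union" if len(spec) == 1 else "sum"
    out = merge_networks(parts, mode=mode)
    out.metapath = spec.label
    out.datasets = tuple(dict.fromkeys(used))
    return out


def merge_networks(parts: Sequence[DWPCMatrix], mode: str = "sum") -> DWPCMatrix:
    """Merge networks over the union of their node universes.

    ``mode='sum'`` adds DWPC values elementwise (>L1 metapaths);
    ``mode='union'`` takes the binary union of the edges (L1 metapaths).
    """
    if mode not in ("sum", "union"):
        raise ValueError("mode must be 'sum' or 'union'")
    if not parts:
        raise ValueError("nothing to merge")
    if len(parts) == 1 and mode == "sum":
        p = parts[0]
        return DWPCMatrix(p.matrix.copy(), list(p.row_nodes), list(p.col_nodes),
                          p.metapath, p.datasets)
    homog = all(p.homogeneous for p in parts)
    rows = sorted(set().union(*(p.row_nodes for p in parts)))
    cols = rows if homog else sorted(set().union(*(p.col_nodes for p in parts)))
    ridx = {n: i for i, n in enumerate(rows)}
    cidx = {n: i for i, n in enumerate(cols)}
    acc = sp.csr_matrix((len(rows), len(cols)))
    for p in parts:
        ri = np.fromiter((ridx[n] for n in p.row_nodes), dtype=np.int64)
        ci = np.fromiter((cidx[n] for n in p.col_nodes), dtype=np.int64)
        coo = p.matrix.tocoo()
        m = sp.coo_matrix(
            (coo.data, (ri[coo.row], ci[coo.col])), shape=(len(rows), len(cols))
        ).tocsr()
        acc = acc + m
    if mode == "union":
        acc = sp.csr_matrix(acc)
        acc.data = np.ones_like(acc.data)
    return DWPCMatrix(sp.csr_matrix(acc), rows, cols)


# ---------------------------------------------------------------------------
# Edge capping and component filtering


def _cap_k(n_possible: int, cfg: DWPCConfig) -> int:
    k = math.floor(cfg.cap_fraction * n_possible + 0.5)  # round half up
    return int(min(max(k, cfg.cap_min), cfg.cap_max))


def _topk_rows(M: sp.csr_matrix, k: int) -> sp.csr_matrix:
    """Per-row top-k entries by (weight desc, column index asc)."""
    M = sp.csr_matrix(M)
    keep_rows, keep_cols, keep_data = [], [], []
    indptr, indices, data = M.indptr, M.indices, M.data
    for i in range(M.shape[0]):
        lo, hi = indptr[i], indptr[i + 1]
        cols = indices[lo:hi]
        vals = data[lo:hi]
        if len(cols) > k:
            order = np.lexsort((cols, -vals))[:k]
            cols, vals = cols[order], vals[order]
        keep_rows.append(np.full(len(cols), i))
        keep_cols.append(cols)
        keep_data.append(vals)
    if not keep_rows:
        return sp.csr_matrix(M.shape)
    return sp.coo_matrix(
        (np.concatenate(keep_data), (np.concatenate(keep_rows), np.concatenate(keep_cols))),
        shape=M.shape,
    ).tocsr()


def cap_edges(dm: DWPCMatrix, cfg: DWPCConfig | None = None) -> DWPCMatrix:
    """Limit each node's edges to its top-k neighbours by DWPC weight.

    k is ``clamp(round(cap_fraction · n_possible), cap_min, cap_max)`` with
    ``n_possible`` the size of the opposite-side universe. The cap is applied
    from both the row and the column perspective and an edge survives when
    either endpoint keeps it (dropping the intersection could disconnect
    low-degree nodes). The per-side selections are retained on the result as
    ``row_kept``/``col_kept``. Weights of surviving edges are unchanged, so
    the operation is idempotent.
    """
    cfg = cfg or DWPCConfig()
    n_rows, n_cols = dm.shape
    k_row = _cap_k(n_cols, cfg)
    k_col = _cap_k(n_rows, cfg)
    row_kept = _topk_rows(dm.matrix, k_row)
    col_kept = _topk_rows(sp.csr_matrix(dm.matrix.T), k_col).T
    mask = (row_kept != 0).maximum(col_kept != 0)
    union = dm.matrix.multiply(mask)
    return DWPCMatrix(
        sp.csr_matrix(union),
        list(dm.row_nodes),
        list(dm.col_nodes),
        dm.metapath,
        dm.datasets,
        row_kept=sp.csr_matrix(row_kept),
        col_kept=sp.csr_matrix(col_kept),
    )


def filter_components(
    dm: DWPCMatrix, cfg: DWPCConfig | None = None
) -> tuple[DWPCMatrix, dict]:
    """Drop small connected components and report node retention.

    Components covering less than ``component_min_frac`` of the entities are
    removed. The report flags the metapath as REJECTED when the retained
    nodes fall below ``node_retention_min`` of the universe (such embeddings
    would describe only a fragment of the entity space).
    """
    cfg = cfg or DWPCConfig()
    M = dm.matrix
    if dm.homogeneous:
        n = len(dm.row_nodes)
        g = M.maximum(M.T)
        n_comp, labels = connected_components(g, directed=False)
        total = n
        sizes = np.bincount(labels, minlength=n_comp)
        keep_comp = np.flatnonzero(sizes / total >= cfg.component_min_frac)
        keep = np.isin(labels, keep_comp)
        new = DWPCMatrix(
            sp.csr_matrix(M[np.ix_(keep, keep)]),
            [n_ for n_, k in zip(dm.row_nodes, keep) if k],
            [n_ for n_, k in zip(dm.col_nodes, keep) if k],
            dm.metapath,
            dm.datasets,
        )
        retained = int(keep.sum())
    else:
        n, m = M.shape
        g = sp.bmat([[None, M], [M.T, None]])
        n_comp, labels = connected_components(g, directed=False)
        total = n + m
        sizes = np.bincount(labels, minlength=n_comp)
        keep_comp = np.flatnonzero(sizes / total >= cfg.component_min_frac)
        keep = np.isin(labels, keep_comp)
        rkeep, ckeep = keep[:n], keep[n:]
        new = DWPCMatrix(
            sp.csr_matrix(M[np.ix_(rkeep, ckeep)]),
            [n_ for n_, k in zip(dm.row_nodes, rkeep) if k],
            [n_ for n_, k in zip(dm.col_nodes, ckeep) if k],
            dm.metapath,
            dm.datasets,
        )
        retained = int(keep.sum())
    retention = retained / total if total else 0.0
    report = {
        "metapath": dm.metapath,
        "total_nodes": int(total),
        "retained_nodes": retained,
        "retention": retention,
        "n_components": int(n_comp),
        "n_components_kept": int(len(keep_comp)),
        "rejected": retention < cfg.node_retention_min,
    }
    return new, report
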