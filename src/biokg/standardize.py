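"""Convert continuous omics data into binary edge sets and harmonize vocabularies.

Continuous measurements cannot enter a binary knowledge graph directly; this
module implements the standard binarization recipes used to populate it:

* expression/proteomics matrices → per-sample top-k up/down-regulated gene sets
  (log2 → quantile normalization → per-gene robust scaling → top-k selection);
* drug-response AUC profiles → sensitive cell-line sets via the waterfall
  (elbow) method with sanity clips;
* perturbation experiments → reified perturbagen (PGN) nodes;
* ontology term universes → information-content pruning of uninformative terms;
* cross-reference vocabularies → TF-IDF cosine mapping;
* pathway gene sets → SuperPath clustering by overlap, Jaccard similarity edges.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.feature_extraction.text import TfidfTransformer
from sklearn.metrics.pairwise import cosine_similarity

from .kg_core import DatasetNetwork, MetaedgeSpec, Ontology


@dataclass
class StandardizeConfig:
    """Constants of the binarization and harmonization recipes.

    top_k_genes: genes selected per sample on each tail of the scaled profile.
    waterfall_min_frac/max_frac: bounds on the sensitive fraction per drug.
    waterfall_auc_cut: AUC ceiling for a cell line to count as sensitive.
    tfidf_cosine_cut: minimum cosine for a cross-reference mapping.
    pathway_overlap_cut / pathway_min_genes / pathway_jaccard_cut: SuperPath
    clustering parameters.
    ic_prune_quantile: fraction of lowest-information-content terms removed.
    """

    top_k_genes: int = 250
    waterfall_min_frac: float = 0.01
    waterfall_max_frac: float = 0.20
    waterfall_auc_cut: float = 0.9
    tfidf_cosine_cut: float = 0.5
    pathway_overlap_cut: float = 0.9
    pathway_min_genes: int = 20
    pathway_jaccard_cut: float = 0.7
    ic_prune_quantile: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.waterfall_min_frac <= self.waterfall_max_frac <= 1):
            raise ValueError("require 0 < min_frac <= max_frac <= 1")


@dataclass
class ExpressionMatrix:
    """A genes × samples matrix of expression-like values (any monotone scale)."""

    values: pd.DataFrame  # index = gene ids, columns = sample ids

    def __post_init__(self) -> None:
        df = self.values
        if not np.issubdtype(df.to_numpy().dtype, np.number):
            raise ValueError("expression values must be numeric")
        # duplicate genes/samples collapsed by their mean value
        if df.index.has_duplicates:
            df = df.groupby(level=0).mean()
        if df.columns.has_duplicates:
            df = df.T.groupby(level=0).mean().T
        self.values = df

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns so every sample shares one distribution.

    Each column's values are replaced by the mean of the sorted columns at the
    corresponding rank; ties receive the average of their rank positions.
    """
    n = values.shape[0]
    mean_sorted = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values, dtype=float)
    for j in range(values.shape[1]):
        col = values[:, j]
        # average ranks (1-based) handle ties deterministically
        order = np.argsort(col, kind="mergesort")
        ranks = np.empty(n)
        ranks[order] = np.arange(n)
        # average tied ranks
        s = pd.Series(col).rank(method="average").to_numpy() - 1.0
        out[:, j] = np.interp(s, np.arange(n), mean_sorted)
    return out


def binarize_expression(
    matrix: ExpressionMatrix,
    cfg: StandardizeConfig | None = None,
    log_transform: bool = True,
    sample_type: str = "CLL",
    gene_type: str = "GEN",
    dataset_prefix: str = "expression",
) -> tuple[DatasetNetwork, DatasetNetwork]:
    """Binarize an expression matrix into up- and down-regulated gene sets.

    Pipeline: mean-collapse duplicates → log2 (skipped when the data are
    already on a log scale) → quantile-normalize samples → per-gene robust
    scaling (subtract median, divide by interquartile range) → per-sample
    selection of the ``top_k_genes`` most positive (upregulated) and most
    negative (downregulated) genes. Rank ties at the boundary are broken by
    gene id so the output is deterministic.
    """
    cfg = cfg or StandardizeConfig()
    df = matrix.values
    n_genes = df.shape[0]
    if n_genes < 2 * cfg.top_k_genes:
        raise ValueError(
            f"need >= {2 * cfg.top_k_genes} genes for disjoint top-{cfg.top_k_genes} "
            f"tails, got {n_genes}"
        )
    X = df.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("expression matrix contains non-finite values")
    shifted = False
    if log_transform:
        lo = X.min()
        if lo <= 0:
            X = X + (1.0 - lo)
            shifted = True
        X = np.log2(X)
    X = quantile_normalize(X)
    med = np.median(X, axis=1, keepdims=True)
    q75, q25 = np.percentile(X, [75, 25], axis=1)
    iqr = (q75 - q25)[:, None]
    flat = iqr[:, 0] == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant gene(s): IQR set to 1")
        iqr[flat] = 1.0
    Z = (X - med) / iqr

    genes = np.asarray(df.index)
    k = cfg.top_k_genes
    upr_edges: list[tuple[str, str]] = []
    dwr_edges: list[tuple[str, str]] = []
    gene_order = np.argsort(genes, kind="mergesort")
    for j, sample in enumerate(df.columns):
        col = Z[:, j]
        # stable sort over gene-id-sorted values -> lexicographic tie-break
        by_id = col[gene_order]
        desc = gene_order[np.argsort(-by_id, kind="mergesort")]
        asc = gene_order[np.argsort(by_id, kind="mergesort")]
        upr_edges.extend((sample, g) for g in genes[desc[:k]])
        dwr_edges.extend((sample, g) for g in genes[asc[:k]])

    samples = set(df.columns)
    gene_uni = set(genes)
    upr = DatasetNetwork.from_edges(
        f"{dataset_prefix}_upr",
        MetaedgeSpec(sample_type, "upr", gene_type),
        upr_edges,
        samples,
        gene_uni,
    )
    dwr = DatasetNetwork.from_edges(
        f"{dataset_prefix}_dwr",
        MetaedgeSpec(sample_type, "dwr", gene_type),
        dwr_edges,
        samples,
        gene_uni,
    )
    for ds in (upr, dwr):
        ds.__dict__.setdefault("meta", {})
    upr.__dict__["meta"] = {"log2_shift_applied": shifted}
    dwr.__dict__["meta"] = {"log2_shift_applied": shifted}
    return upr, dwr


def waterfall_binarize(
    profile: Mapping[str, float] | pd.Series, cfg: StandardizeConfig | None = None
) -> set[str]:
    """Binarize one drug's AUC profile into a sensitive cell-line set.

    Cell lines are ranked by ascending AUC (area under the growth-inhibition
    curve; low = sensitive). Only lines meeting the sensitivity requirement
    AUC < ``waterfall_auc_cut`` are eligible; the elbow of the eligible ranked
    curve — the point of maximal height above the chord joining its endpoints,
    i.e. where the resistant plateau begins — defines the raw sensitive count.
    Treating the AUC ceiling as an eligibility criterion (rather than a
    post-filter) keeps the sparse lower tail of the resistant mode from
    dragging the elbow past the true boundary. The count is finally clipped to
    keep at least ``waterfall_min_frac`` but no more than
    ``waterfall_max_frac`` of all profiled lines, so a profile of uniformly
    resistant lines yields an empty set.
    """
    cfg = cfg or StandardizeConfig()
    s = pd.Series(dict(profile)) if not isinstance(profile, pd.Series) else profile
    s = s.dropna()
    n_total = len(s)
    if n_total < 10:
        raise ValueError("need at least 10 cell lines with finite AUC")
    # deterministic order: AUC ascending, ties by cell id
    s = s.iloc[np.lexsort((np.asarray(s.index), s.to_numpy()))]
    eligible = s[s < cfg.waterfall_auc_cut]
    n = len(eligible)
    if n == 0:
        return set()
    v = eligible.to_numpy(dtype=float)
    if n == 1:
        k_elbow = 1
    else:
        i = np.arange(n)
        chord = v[0] + (v[-1] - v[0]) * i / (n - 1)
        # cells strictly before the point of maximal height above the chord
        k_elbow = int(np.argmax(v - chord))
    k_min = max(1, math.ceil(cfg.waterfall_min_frac * n_total))
    k_max = max(k_min, math.floor(cfg.waterfall_max_frac * n_total))
    k = min(int(np.clip(k_elbow, k_min, k_max)), n)
    return set(eligible.index[:k])


# ---------------------------------------------------------------------------
# Perturbagen reification

#: perturbation kinds mapped to the relation between the perturbagen node and
#: its perturbed gene: loss-of-function kinds push the gene down (pdw),
#: gain-of-function kinds push it up (pup).
PERTURBATION_KINDS: dict[str, str] = {
    "shrna": "pdw",
    "shrna-silence": "pdw",
    "sirna": "pdw",
    "crispr": "pdw",
    "crispr-ko": "pdw",
    "knockdown": "pdw",
    "silence": "pdw",
    "overexpression": "pup",
    "oe": "pup",
    "cdna": "pup",
}


def reify_perturbagens(
    records: Iterable[tuple[str, str, str, str, str]],
) -> tuple[dict[str, set[tuple[str, str]]], dict[str, set[tuple[str, str]]]]:
    """Reify perturbation experiments into perturbagen (PGN) nodes.

    Each record ``(perturbation_id, kind, perturbed_gene, outcome_relation,
    outcome_node)`` yields (a) a PGN→perturbed-gene edge whose relation
    (``pdw``/``pup``) encodes the perturbation kind, and (b) a PGN→outcome
    edge under ``outcome_relation``. The two-step statement "perturbagen that
    silences gene A upregulates gene B" thus becomes PGN-pdw-A plus PGN-upr-B.

    Returns two dicts keyed by relation tag, each holding edge sets.
    """
    gene_edges: dict[str, set[tuple[str, str]]] = {}
    outcome_edges: dict[str, set[tuple[str, str]]] = {}
    seen: set[str] = set()
    for pid, kind, gene, out_rel, out_node in records:
        rel = PERTURBATION_KINDS.get(kind.lower())
        if rel is None:
            raise ValueError(f"unknown perturbation kind {kind!r}")
        seen.add(pid)
        gene_edges.setdefault(rel, set()).add((pid, gene))
        outcome_edges.setdefault(out_rel, set()).add((pid, out_node))
    return gene_edges, outcome_edges


# ---------------------------------------------------------------------------
# Ontology information content and pruning


def information_content(
    ontology: Ontology, annotations: Mapping[str, Iterable[str]]
) -> dict[str, float]:
    """Information content in bits of each ontology term.

    ``annotations`` must already be propagated to ancestors (every entity
    annotated to a term also counts for all its parents). With the annotation
    corpus E (the union over all terms),

        IC(t) = -log2(|entities(t)| / |E|)

    so the root scores 0 and rarer, more specific terms score higher. Terms
    with no propagated annotations carry no information and are excluded.
    """
    sets = {t: set(v) for t, v in annotations.items()}
    corpus: set[str] = set()
    for v in sets.values():
        corpus |= v
    if not corpus:
        raise ValueError("no annotated entities")
    ic: dict[str, float] = {}
    for term, ents in sets.items():
        if not ents:
            continue
        ic[term] = -math.log2(len(ents) / len(corpus))
    return ic


def prune_uninformative_terms(
    ic_table: Mapping[str, float], cfg: StandardizeConfig | None = None
) -> tuple[set[str], set[str]]:
    """Remove the least informative (most general) terms of an ontology.

    Terms whose IC falls strictly below the ``ic_prune_quantile`` quantile of
    the IC distribution are removed. Returns ``(kept, removed)``.
    """
    cfg = cfg or StandardizeConfig()
    if not ic_table:
        raise ValueError("empty IC table")
    values = np.asarray(list(ic_table.values()))
    cut = float(np.quantile(values, cfg.ic_prune_quantile))
    removed = {t for t, v in ic_table.items() if v < cut}
    kept = set(ic_table) - removed
    if not kept:
        raise ValueError("pruning cutoff would remove every term")
    return kept, removed


# ---------------------------------------------------------------------------
# TF-IDF cross-reference mapping


def tfidf_crossref_map(
    source_terms: Mapping[str, Iterable[str]],
    target_terms: Mapping[str, Iterable[str]],
    cfg: StandardizeConfig | None = None,
) -> list[tuple[str, str, float]]:
    """Map terms of one vocabulary onto another via shared cross-references.

    Each term is encoded as a binary vector over the union of cross-reference
    ids, the stacked matrix is TF-IDF transformed (smoothed idf
    ln((1+N)/(1+df))+1, L2-normalized rows), and source-target cosine
    similarities at or above ``tfidf_cosine_cut`` are returned sorted
    best-match-first (cosine descending, then term ids).
    """
    cfg = cfg or StandardizeConfig()
    src = {t: set(v) for t, v in source_terms.items()}
    tgt = {t: set(v) for t, v in target_terms.items()}
    universe = sorted(set().union(*src.values(), *tgt.values()) if (src or tgt) else set())
    if not universe:
        raise ValueError("empty shared cross-reference universe")
    col = {x: j for j, x in enumerate(universe)}
    src_ids = sorted(src)
    tgt_ids = sorted(tgt)
    M = np.zeros((len(src_ids) + len(tgt_ids), len(universe)))
    for i, t in enumerate(src_ids):
        for x in src[t]:
            M[i, col[x]] = 1.0
    for i, t in enumerate(tgt_ids):
        for x in tgt[t]:
            M[len(src_ids) + i, col[x]] = 1.0
    tf = TfidfTransformer(smooth_idf=True, norm="l2").fit_transform(M)
    S = cosine_similarity(tf[: len(src_ids)], tf[len(src_ids):])
    out = [
        (s, t, float(S[i, j]))
        for i, s in enumerate(src_ids)
        for j, t in enumerate(tgt_ids)
        if S[i, j] >= cfg.tfidf_cosine_cut
    ]
    out.sort(key=lambda r: (-r[2], r[0], r[1]))
    return out


# ---------------------------------------------------------------------------
# Pathway clustering (SuperPaths)


def _overlap_coefficient(a: set, b: set) -> float:
    if not a or not b:
        return 0.0
    return len(a & b) / min(len(a), len(b))


def _jaccard(a: set, b: set) -> float:
    u = len(a | b)
    return len(a & b) / u if u else 0.0


def cluster_pathways(
    pathway_gene_sets: Mapping[str, Iterable[str]],
    cfg: StandardizeConfig | None = None,
) -> tuple[dict[str, set[str]], list[tuple[str, str, float]]]:
    """Cluster pathways into SuperPaths and emit pathway-similarity edges.

    Pathways with fewer than ``pathway_min_genes`` genes are excluded. Pathways
    whose gene-set overlap coefficient reaches ``pathway_overlap_cut`` are
    merged (transitively) into a SuperPath, named after its lexicographically
    first member. SuperPath pairs whose merged gene sets reach a Jaccard
    similarity of ``pathway_jaccard_cut`` become similarity edges.

    Returns ``(superpaths, similarity_edges)`` where ``superpaths`` maps a
    SuperPath id to its member pathway ids and edges are ``(sp_a, sp_b,
    jaccard)`` with ``sp_a < sp_b``.
    """
    cfg = cfg or StandardizeConfig()
    sets = {
        p: set(g)
        for p, g in pathway_gene_sets.items()
        if len(set(g)) >= cfg.pathway_min_genes
    }
    ids = sorted(sets)
    # union-find over the overlap graph
    parent = {p: p for p in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if _overlap_coefficient(sets[a], sets[b]) >= cfg.pathway_overlap_cut:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    clusters: dict[str, set[str]] = {}
    for p in ids:
        clusters.setdefault(find(p), set()).add(p)
    superpaths = {f"SP:{root}": members for root, members in clusters.items()}
    sp_genes = {
        sp: set().union(*(sets[m] for m in members))
        for sp, members in superpaths.items()
    }
    sp_ids = sorted(superpaths)
    edges = []
    for i, a in enumerate(sp_ids):
        for b in sp_ids[i + 1:]:
            j = _jaccard(sp_genes[a], sp_genes[b])
            if j >= cfg.pathway_jaccard_cut:
                edges.append((a, b, j))
    return superpaths, edges
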