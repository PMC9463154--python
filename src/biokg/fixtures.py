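"""Seeded synthetic-data generators exercising every stage of the pipeline.

Real biomedical source databases are large, licence-encumbered and slow to
obtain; these generators produce small inputs with the *structure* each stage
assumes, so the whole pipeline (knowledge graph → DWPC → walks → skip-gram →
evaluation → distance statistics) runs end to end in minutes with no
download:

* homogeneous/bipartite networks with planted community (stochastic block)
  structure, returned with their ground-truth labels;
* expression matrices with correlated sample groups and known marker genes;
* per-drug response profiles with a planted sensitive tail.

All generators are pure functions of their arguments: the same seed yields
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kg_core import (
    DatasetNetwork,
    KnowledgeGraph,
    Metagraph,
    MetaedgeSpec,
    assemble_graph,
)
from .standardize import ExpressionMatrix


@dataclass
class FixtureSpec:
    """Parameters of the synthetic knowledge-graph fixture.

    The block structure is shared across layers: genes, compounds, diseases
    and pathways are each partitioned into ``n_blocks`` communities, and
    within-block edge probabilities exceed cross-block ones in every layer, so
    multi-step metapaths carry recoverable signal.
    """

    seed: int = 0
    n_blocks: int = 4
    p_in: float = 0.25
    p_out: float = 0.01
    sizes: dict[str, int] = field(
        default_factory=lambda: {"GEN": 200, "CPD": 80, "DIS": 60, "PWY": 40}
    )

    def __post_init__(self) -> None:
        for p in (self.p_in, self.p_out):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")
        if any(s < 2 for s in self.sizes.values()):
            raise ValueError("every entity type needs at least 2 nodes")


def _block_labels(n: int, k: int) -> np.ndarray:
    """Round-robin block assignment: node i belongs to block i mod k."""
    return np.arange(n) % k


def planted_partition_network(
    n: int,
    k_blocks: int,
    p_in: float,
    p_out: float,
    seed: int = 0,
    node_prefix: str = "g",
    metaedge: MetaedgeSpec | None = None,
    name: str = "planted_partition",
) -> tuple[DatasetNetwork, dict[str, int]]:
    """Stochastic block model: dense within blocks, sparse across.

    Returns the homogeneous dataset and the true block label of every node
    (for silhouette / AUROC ground truth). ``p_in=1, p_out=0`` gives disjoint
    cliques.
    """
    rng = np.random.default_rng(seed)
    labels = _block_labels(n, k_blocks)
    nodes = [f"{node_prefix}{i}" for i in range(n)]
    same = labels[:, None] == labels[None, :]
    P = np.where(same, p_in, p_out)
    draw = rng.random((n, n))
    iu = np.triu_indices(n, k=1)
    hits = draw[iu] < P[iu]
    edges = [(nodes[i], nodes[j]) for i, j in zip(iu[0][hits], iu[1][hits])]
    me = metaedge or MetaedgeSpec("GEN", "ppi", "GEN")
    ds = DatasetNetwork.from_edges(name, me, edges, set(nodes), set(nodes))
    return ds, dict(zip(nodes, labels.tolist()))


def _bipartite_block_network(
    rng: np.random.Generator,
    src_nodes: list[str],
    src_labels: np.ndarray,
    tgt_nodes: list[str],
    tgt_labels: np.ndarray,
    p_in: float,
    p_out: float,
    metaedge: MetaedgeSpec,
    name: str,
) -> DatasetNetwork:
    same = src_labels[:, None] == tgt_labels[None, :]
    P = np.where(same, p_in, p_out)
    hits = rng.random(P.shape) < P
    r, c = np.nonzero(hits)
    edges = [(src_nodes[i], tgt_nodes[j]) for i, j in zip(r, c)]
    return DatasetNetwork.from_edges(
        name, metaedge, edges, set(src_nodes), set(tgt_nodes)
    )


def synthetic_kg(
    fixture: FixtureSpec | None = None,
) -> tuple[KnowledgeGraph, dict[str, dict[str, int]]]:
    """A small knowledge graph whose layers share planted block structure.

    Metagraph: GEN, CPD, DIS, PWY with GEN-ppi-GEN (homogeneous),
    CPD-int-GEN, DIS-ass-GEN and GEN-ass-PWY (bipartite). Because all layers
    use the same community assignment, 2-step metapaths such as
    ``CPD-int-GEN-ass-DIS`` connect same-block endpoints far more strongly
    than cross-block ones. Returns the graph and per-type true block labels.
    """
    fx = fixture or FixtureSpec()
    rng = np.random.default_rng(fx.seed)
    mg = Metagraph()
    for abbr, full in [
        ("GEN", "genes"),
        ("CPD", "compounds"),
        ("DIS", "diseases"),
        ("PWY", "pathways"),
    ]:
        mg.add_metanode(abbr, full)
    for spec in [
        MetaedgeSpec("GEN", "ppi", "GEN"),
        MetaedgeSpec("CPD", "int", "GEN"),
        MetaedgeSpec("DIS", "ass", "GEN"),
        MetaedgeSpec("GEN", "ass", "PWY"),
    ]:
        mg.add_metaedge(spec)

    prefixes = {"GEN": "g", "CPD": "c", "DIS": "d", "PWY": "p"}
    nodes: dict[str, list[str]] = {}
    labels: dict[str, np.ndarray] = {}
    for t, size in fx.sizes.items():
        nodes[t] = [f"{prefixes[t]}{i}" for i in range(size)]
        labels[t] = _block_labels(size, fx.n_blocks)

    ppi, _ = planted_partition_network(
        fx.sizes["GEN"],
        fx.n_blocks,
        fx.p_in,
        fx.p_out,
        seed=int(rng.integers(2**31)),
        node_prefix="g",
        name="ppi_synth",
    )
    datasets = [ppi]
    for src, rel, tgt, name in [
        ("CPD", "int", "GEN", "targets_synth"),
        ("DIS", "ass", "GEN", "disgene_synth"),
        ("GEN", "ass", "PWY", "pathways_synth"),
    ]:
        datasets.append(
            _bipartite_block_network(
                np.random.default_rng(int(rng.integers(2**31))),
                nodes[src],
                labels[src],
                nodes[tgt],
                labels[tgt],
                fx.p_in,
                fx.p_out,
                MetaedgeSpec(src, rel, tgt),
                name,
            )
        )
    kg = assemble_graph(datasets, mg)
    true_blocks = {
        t: dict(zip(nodes[t], labels[t].tolist())) for t in fx.sizes
    }
    return kg, true_blocks


def synthetic_expression(
    n_genes: int = 15000,
    n_samples: int = 50,
    n_groups: int = 5,
    effect: float = 2.0,
    seed: int = 0,
    n_markers_per_group: int = 300,
) -> tuple[ExpressionMatrix, dict[int, list[str]], dict[str, int]]:
    """Expression matrix with group-specific upregulated marker genes.

    Baseline is log-normal (per-gene mean ~N(7, 1) on log2 scale, sample noise
    sd 0.5); each sample group has ``n_markers_per_group`` marker genes
    shifted up by ``effect`` log2 units in its samples. Returns the matrix
    (linear scale), the marker list per group and the sample → group map.
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{i}" for i in range(n_samples)]
    group_of = {s: i % n_groups for i, s in enumerate(samples)}
    base = rng.normal(7.0, 1.0, size=(n_genes, 1))
    log2x = base + rng.normal(0.0, 0.5, size=(n_genes, n_samples))
    marker_ids = rng.permutation(n_genes)[: n_markers_per_group * n_groups]
    markers: dict[int, list[str]] = {}
    for g in range(n_groups):
        ids = marker_ids[g * n_markers_per_group: (g + 1) * n_markers_per_group]
        markers[g] = [genes[i] for i in ids]
        cols = [j for j, s in enumerate(samples) if group_of[s] == g]
        log2x[np.ix_(ids, cols)] += effect
    values = pd.DataFrame(2.0**log2x, index=genes, columns=samples)
    return ExpressionMatrix(values), markers, group_of


def synthetic_drug_response(
    n_drugs: int = 50,
    n_cells: int = 500,
    sens_frac: float = 0.05,
    seed: int = 0,
    sens_mean: float = 0.3,
    sens_sd: float = 0.05,
    res_mean: float = 0.92,
    res_sd: float = 0.03,
) -> dict[str, tuple[pd.Series, set[str]]]:
    """Bimodal per-drug AUC profiles with a planted sensitive tail.

    Each cell line is sensitive to a drug with probability ``sens_frac``;
    sensitive AUCs ~N(0.3, 0.05), resistant ~N(0.92, 0.03), clipped to [0, 1].
    Returns per drug the AUC profile and the planted sensitive set.
    """
    rng = np.random.default_rng(seed)
    cells = [f"cl{i}" for i in range(n_cells)]
    out: dict[str, tuple[pd.Series, set[str]]] = {}
    for d in range(n_drugs):
        sens = rng.random(n_cells) < sens_frac
        auc = np.where(
            sens,
            rng.normal(sens_mean, sens_sd, n_cells),
            rng.normal(res_mean, res_sd, n_cells),
        )
        auc = np.clip(auc, 0.0, 1.0)
        profile = pd.Series(auc, index=cells, name=f"drug{d}")
        out[f"drug{d}"] = (profile, {c for c, s in zip(cells, sens) if s})
    return out
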