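"""Metapath grammar: parsing, dataset binding and composition-rule checks.

A metapath is an ordered chain of metaedges describing a semantic route
between a source and a target entity type, written as alternating metanode
abbreviations and relation tags, e.g. ``CPD-int-GEN-ass-DIS``. Two extensions
of the single-metaedge grammar appear at this level:

* ``'+'``-combined relations (``CLL-dwr+upr-GEN-dwr+upr-CLL``): alternatives
  are *zipped positionally* across the steps that carry them, so the example
  expands to the two "mimicking" variants (dwr,dwr) and (upr,upr) — while
  ``CLL-upr+dwr-GEN-dwr+upr-CLL`` expands to the "reversion" variants
  (upr,dwr) and (dwr,upr). Variant networks are computed independently and
  merged downstream.
* ``'_'`` direction marks on directed homogeneous relations:
  ``GEN-_pho-GEN-ass-PWY`` walks from kinases to the pathways of their
  substrates, ``GEN-pho_-GEN-ass-PWY`` from substrates to the pathways of
  their kinases.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .kg_core import (
    GrammarError,
    KnowledgeGraph,
    Metagraph,
    MetaedgeSpec,
    SchemaError,
)

import re

_REL_TOKEN_RE = re.compile(r"^(_?)([a-z]{3}(?:\+[a-z]{3})*)(_?)$")
_NODE_TOKEN_RE = re.compile(r"^[A-Z]{3}$")


@dataclass(frozen=True)
class MetapathStep:
    """One traversal step of a metapath.

    ``relations`` holds the '+'-joined alternatives in written order;
    ``reversed`` flags traversal against the canonically stored direction of a
    heterogeneous metaedge; ``source_side`` records the '_' mark of a directed
    homogeneous relation ('left'/'right' relative to the written step).
    ``datasets`` maps each relation to the bound dataset names.
    """

    left_type: str
    right_type: str
    relations: tuple[str, ...]
    specs: tuple[MetaedgeSpec, ...]
    reversed: tuple[bool, ...]
    source_side: str | None = None
    datasets: tuple[tuple[str, ...], ...] = ()


@dataclass(frozen=True)
class MetapathSpec:
    """A parsed metapath: node types plus one step per metaedge."""

    node_types: tuple[str, ...]
    steps: tuple[MetapathStep, ...]

    @property
    def source_type(self) -> str:
        return self.node_types[0]

    @property
    def target_type(self) -> str:
        return self.node_types[-1]

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def label(self) -> str:
        parts = [self.node_types[0]]
        for step, nt in zip(self.steps, self.node_types[1:]):
            rel = "+".join(step.relations)
            if step.source_side == "left":
                rel = "_" + rel
            elif step.source_side == "right":
                rel = rel + "_"
            parts.extend([rel, nt])
        return "-".join(parts)


def parse_metapath(
    expr: str,
    kg: KnowledgeGraph | Metagraph,
    datasets: list[list[str] | dict[str, list[str]] | None] | None = None,
) -> MetapathSpec:
    """Parse a metapath expression and bind datasets to every step.

    ``datasets`` optionally gives, per step, either a flat list of dataset
    names (single-relation steps) or a mapping relation → names. When omitted,
    every dataset of the knowledge graph registered under the step's metaedge
    is bound (none, if only a bare metagraph is supplied).
    """
    mg = kg.metagraph if isinstance(kg, KnowledgeGraph) else kg
    tokens = expr.split("-")
    if len(tokens) < 3 or len(tokens) % 2 == 0:
        raise GrammarError(f"malformed metapath expression {expr!r}")
    node_types = tuple(tokens[0::2])
    rel_tokens = tokens[1::2]
    for nt in node_types:
        if not _NODE_TOKEN_RE.match(nt):
            raise GrammarError(f"bad metanode token {nt!r} in {expr!r}")
        if nt not in mg.metanodes:
            raise SchemaError(f"unknown metanode abbreviation {nt!r}")

    steps: list[MetapathStep] = []
    plus_arity: set[int] = set()
    for i, tok in enumerate(rel_tokens):
        m = _REL_TOKEN_RE.match(tok)
        if m is None:
            raise GrammarError(f"bad relation token {tok!r} in {expr!r}")
        lmark, rels_s, rmark = bool(m.group(1)), m.group(2), bool(m.group(3))
        if lmark and rmark:
            raise GrammarError(f"both sides marked in {tok!r}")
        left, right = node_types[i], node_types[i + 1]
        if (lmark or rmark) and left != right:
            raise GrammarError(f"'_' mark on heterogeneous step {tok!r}")
        rels = tuple(rels_s.split("+"))
        if len(rels) > 1:
            plus_arity.add(len(rels))
        specs: list[MetaedgeSpec] = []
        revs: list[bool] = []
        for rel in rels:
            spec = mg.get_metaedge(left, rel, right)
            if spec is None:
                raise SchemaError(
                    f"{left}-{rel}-{right} is not a declared metaedge"
                )
            specs.append(spec)
            # reversed traversal of a heterogeneous metaedge stored canonically
            revs.append(spec.key != (left, rel, right) and not spec.homogeneous)
        if len({(s.source_type, s.target_type) for s in specs}) > 1:
            raise GrammarError(
                f"'+' joins relations with different endpoint types in {tok!r}"
            )
        source_side = None
        if any(s.directed for s in specs):
            source_side = "right" if rmark else "left"
        elif lmark or rmark:
            raise GrammarError(f"'_' mark on undirected relation {tok!r}")
        bound: tuple[tuple[str, ...], ...]
        if datasets is not None and datasets[i] is not None:
            d = datasets[i]
            if isinstance(d, dict):
                bound = tuple(tuple(d.get(r, ())) for r in rels)
            else:
                if len(rels) > 1:
                    raise GrammarError(
                        "flat dataset list ambiguous for a '+' step; pass a mapping"
                    )
                bound = (tuple(d),)
        elif isinstance(kg, KnowledgeGraph):
            bound = tuple(
                tuple(ds.name for ds in kg.datasets_for(s)) for s in specs
            )
        else:
            bound = tuple(() for _ in rels)
        steps.append(
            MetapathStep(
                left, right, rels, tuple(specs), tuple(revs), source_side, bound
            )
        )
    if len(plus_arity) > 1:
        raise GrammarError(
            f"'+' groups of different arity cannot be zipped: {sorted(plus_arity)}"
        )
    return MetapathSpec(node_types, tuple(steps))


def expand_variants(spec: MetapathSpec) -> list[MetapathSpec]:
    """Expand '+'-combined steps into single-relation metapath variants.

    Alternatives are zipped positionally: every multi-relation step must carry
    the same number of alternatives and the v-th variant takes the v-th
    relation of each such step; single-relation steps broadcast.
    """
    arities = {len(s.relations) for s in spec.steps if len(s.relations) > 1}
    if not arities:
        return [spec]
    (k,) = arities
    variants = []
    for v in range(k):
        steps = []
        for s in spec.steps:
            j = v if len(s.relations) > 1 else 0
            steps.append(
                replace(
                    s,
                    relations=(s.relations[j],),
                    specs=(s.specs[j],),
                    reversed=(s.reversed[j],),
                    datasets=(s.datasets[j],) if s.datasets else (),
                )
            )
        variants.append(MetapathSpec(spec.node_types, tuple(steps)))
    return variants


# ---------------------------------------------------------------------------
# Composition-rule validation (advisory)

#: relations allowed between cells and genes inside a metapath
_CLL_GEN_ALLOWED = {"upr", "dwr", "mut"}
#: L1 relations that are never embedded standalone (cross-references,
#: ontological hierarchy, computed similarities, perturbagen mappings)
_L1_EXCLUDED = {"xrf", "hsp", "sim"}


def validate_metapath_rules(spec: MetapathSpec) -> list[str]:
    """Check the composition constraints of the embedding-selection grammar.

    Violations are advisory (the pipeline still runs): a curated resource
    limits itself to chemically sensible chains, but custom graphs may differ.
    Checks: (i) standalone length-1 metapaths must not be cross-reference,
    ontology, similarity or perturbagen relations; (ii) CLL and TIS connect
    only through ``has``; (iii) cells and genes link only via
    upr/dwr/mut; (iv) a gene reached from a perturbagen (PGN-pup/pdw-GEN)
    continues through heterogeneous or *directed* homogeneous associations,
    never an undirected homogeneous one.
    """
    issues: list[str] = []
    if len(spec) == 1:
        step = spec.steps[0]
        for rel in step.relations:
            if rel in _L1_EXCLUDED:
                issues.append(
                    f"L1 metapath uses excluded relation {rel!r} "
                    "(similarity/ontology/cross-reference edges are derived, "
                    "not embedded standalone)"
                )
        if "PGN" in (step.left_type, step.right_type):
            issues.append("perturbagen associations are not embedded as L1 metapaths")
    for i, step in enumerate(spec.steps):
        pair = {step.left_type, step.right_type}
        if pair == {"CLL", "TIS"} and any(r != "has" for r in step.relations):
            issues.append(
                f"step {i}: CLL and TIS must be connected through 'has'"
            )
        if pair == {"CLL", "GEN"}:
            for r in step.relations:
                if r not in _CLL_GEN_ALLOWED:
                    issues.append(
                        f"step {i}: CLL-GEN linked via {r!r}; only "
                        f"{sorted(_CLL_GEN_ALLOWED)} allowed"
                    )
    for i, step in enumerate(spec.steps[:-1]):
        nxt = spec.steps[i + 1]
        reaches_gene_from_pgn = (
            "PGN" in (step.left_type, step.right_type)
            and any(r in ("pup", "pdw") for r in step.relations)
            and "GEN" in (step.left_type, step.right_type)
        )
        if reaches_gene_from_pgn:
            undirected_homog = (
                nxt.left_type == nxt.right_type
                and not any(s.directed for s in nxt.specs)
            )
            if undirected_homog:
                issues.append(
                    f"step {i + 1}: gene mapped from a perturbagen must continue "
                    "through heterogeneous or directed homogeneous associations"
                )
    return issues
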