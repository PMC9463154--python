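"""Metapath grammar, DWPC collapse (vs brute-force oracle), capping, filtering."""

import itertools

import numpy as np
import pytest
import scipy.sparse as sp

import biokg as bk
from biokg.kg_core import GrammarError, SchemaError


@pytest.fixture()
def toy_kg(toy_metagraph):
    mg = toy_metagraph
    d = [
        bk.DatasetNetwork.from_edges(
            "ppi1", mg.metaedges[("GEN", "ppi", "GEN")], [("g1", "g2"), ("g2", "g3")]
        ),
        bk.DatasetNetwork.from_edges(
            "targets", mg.metaedges[("CPD", "int", "GEN")],
            [("c1", "g1"), ("c1", "g2"), ("c2", "g3")],
        ),
        bk.DatasetNetwork.from_edges(
            "disgene", mg.metaedges[("DIS", "ass", "GEN")],
            [("d1", "g2"), ("d2", "g3")],
        ),
        bk.DatasetNetwork.from_edges(
            "kinase", mg.metaedges[("GEN", "pho", "GEN")], [("g1", "g2")]
        ),
        bk.DatasetNetwork.from_edges(
            "pwy", mg.metaedges[("GEN", "ass", "PWY")], [("g2", "p1")]
        ),
    ]
    return bk.assemble_graph(d, mg)


class TestParseMetapath:
    def test_two_step_chain(self, toy_kg):
        spec = bk.parse_metapath("CPD-int-GEN-ass-DIS", toy_kg)
        assert len(spec) == 2
        assert spec.source_type == "CPD" and spec.target_type == "DIS"
        # DIS-ass-GEN is stored canonically; traversal here is reversed
        assert spec.steps[1].reversed == (True,)
        assert spec.steps[0].datasets == (("targets",),)

    def test_direction_marks_select_traversal(self, toy_kg):
        left = bk.parse_metapath("GEN-_pho-GEN-ass-PWY", toy_kg)
        right = bk.parse_metapath("GEN-pho_-GEN-ass-PWY", toy_kg)
        assert left.steps[0].source_side == "left"
        assert right.steps[0].source_side == "right"

    def test_undeclared_metaedge_rejected(self, toy_kg):
        with pytest.raises(SchemaError):
            bk.parse_metapath("CPD-int-GEN-has-CLL", toy_kg)

    def test_endpoint_mismatch_rejected(self, toy_kg):
        with pytest.raises((GrammarError, SchemaError)):
            bk.parse_metapath("CPD-int-DIS", toy_kg)

    def test_plus_zip_expansion(self, toy_metagraph):
        spec = bk.parse_metapath("CLL-dwr+upr-GEN-dwr+upr-CLL", toy_metagraph)
        variants = [v.label for v in bk.expand_variants(spec)]
        assert variants == ["CLL-dwr-GEN-dwr-CLL", "CLL-upr-GEN-upr-CLL"]
        rev = bk.parse_metapath("CLL-upr+dwr-GEN-dwr+upr-CLL", toy_metagraph)
        assert [v.label for v in bk.expand_variants(rev)] == [
            "CLL-upr-GEN-dwr-CLL",
            "CLL-dwr-GEN-upr-CLL",
        ]

    def test_label_round_trip(self, toy_kg):
        for expr in ("CPD-int-GEN-ass-DIS", "GEN-pho_-GEN-ass-PWY"):
            assert bk.parse_metapath(expr, toy_kg).label == expr


class TestCompositionRules:
    def _mg(self):
        mg = bk.Metagraph()
        for t in ("GEN", "PGN", "CLL", "TIS", "CPD"):
            mg.add_metanode(t)
        for spec in [
            bk.MetaedgeSpec("PGN", "pup", "GEN"),
            bk.MetaedgeSpec("GEN", "ppi", "GEN"),
            bk.MetaedgeSpec("GEN", "pho", "GEN", directed=True),
            bk.MetaedgeSpec("CLL", "has", "TIS"),
            bk.MetaedgeSpec("CLL", "ass", "TIS"),
            bk.MetaedgeSpec("CLL", "upr", "GEN"),
            bk.MetaedgeSpec("CLL", "exp", "GEN"),
            bk.MetaedgeSpec("CPD", "sim", "CPD"),
        ]:
            mg.add_metaedge(spec)
        return mg

    def test_pgn_gene_followed_by_undirected_homogeneous_flagged(self):
        mg = self._mg()
        bad = bk.parse_metapath("PGN-pup-GEN-ppi-GEN", mg)
        assert bk.validate_metapath_rules(bad)
        ok = bk.parse_metapath("PGN-pup-GEN-_pho-GEN", mg)
        assert not bk.validate_metapath_rules(ok)

    def test_similarity_edge_not_standalone(self):
        mg = self._mg()
        assert bk.validate_metapath_rules(bk.parse_metapath("CPD-sim-CPD", mg))

    def test_cll_tis_only_via_has(self):
        mg = self._mg()
        assert bk.validate_metapath_rules(bk.parse_metapath("CLL-ass-TIS", mg))
        assert not bk.validate_metapath_rules(bk.parse_metapath("CLL-has-TIS", mg))

    def test_cll_gen_restricted_relations(self):
        mg = self._mg()
        assert bk.validate_metapath_rules(
            bk.parse_metapath("CLL-exp-GEN-_pho-GEN", mg)
        )
        assert not bk.validate_metapath_rules(
            bk.parse_metapath("CLL-upr-GEN-_pho-GEN", mg)
        )


# ---------------------------------------------------------------------------
# DWPC vs brute-force path enumeration


def _dwpc_oracle(step_edge_lists, exponent):
    """Enumerate every path; each dataset crossing multiplies both endpoint
    degrees (within that dataset) raised to the exponent."""
    degs = []
    for edges in step_edge_lists:
        d_src, d_tgt = {}, {}
        for a, b in edges:
            d_src[a] = d_src.get(a, 0) + 1
            d_tgt[b] = d_tgt.get(b, 0) + 1
        degs.append((d_src, d_tgt))
    out = {}
    frontier = {}
    for a, b in step_edge_lists[0]:
        ds, dt = degs[0]
        w = (ds[a] ** exponent) * (dt[b] ** exponent)
        frontier.setdefault((a, b), 0.0)
        frontier[(a, b)] += w
    for k in range(1, len(step_edge_lists)):
        ds, dt = degs[k]
        nxt = {}
        for (src, mid), w in frontier.items():
            for a, b in step_edge_lists[k]:
                if a == mid:
                    nxt.setdefault((src, b), 0.0)
                    nxt[(src, b)] = nxt[(src, b)] + w * (ds[a] ** exponent) * (
                        dt[b] ** exponent
                    )
        frontier = nxt
    return frontier


def _random_bipartite_kg(rng, n_a, n_b, n_c, p):
    mg = bk.Metagraph()
    for t in ("AAA", "BBB", "CCC"):
        mg.add_metanode(t)
    mg.add_metaedge(bk.MetaedgeSpec("AAA", "rel", "BBB"))
    mg.add_metaedge(bk.MetaedgeSpec("BBB", "rel", "CCC"))
    e1 = [
        (f"a{i}", f"b{j}")
        for i in range(n_a)
        for j in range(n_b)
        if rng.random() < p
    ]
    e2 = [
        (f"b{i}", f"c{j}")
        for i in range(n_b)
        for j in range(n_c)
        if rng.random() < p
    ]
    if not e1 or not e2:
        return None, None
    d1 = bk.DatasetNetwork.from_edges("d1", mg.metaedges[("AAA", "rel", "BBB")], e1)
    d2 = bk.DatasetNetwork.from_edges("d2", mg.metaedges[("BBB", "rel", "CCC")], e2)
    kg = bk.assemble_graph([d1, d2], mg)
    return kg, (e1, e2)


class TestDWPC:
    def test_unit_chain_gives_one(self):
        rng = np.random.default_rng(0)
        mg = bk.Metagraph()
        for t in ("AAA", "BBB", "CCC"):
            mg.add_metanode(t)
        mg.add_metaedge(bk.MetaedgeSpec("AAA", "rel", "BBB"))
        mg.add_metaedge(bk.MetaedgeSpec("BBB", "rel", "CCC"))
        d1 = bk.DatasetNetwork.from_edges(
            "d1", mg.metaedges[("AAA", "rel", "BBB")], [("a1", "b1")]
        )
        d2 = bk.DatasetNetwork.from_edges(
            "d2", mg.metaedges[("BBB", "rel", "CCC")], [("b1", "c1")]
        )
        kg = bk.assemble_graph([d1, d2], mg)
        dm = bk.dwpc_matrix(bk.parse_metapath("AAA-rel-BBB-rel-CCC", kg), kg)
        np.testing.assert_allclose(dm.matrix.toarray(), [[1.0]])

    def test_hand_computed_branching_example(self):
        # a1->{b1,b2}; b1->c1; b2->{c1,c2}
        mg = bk.Metagraph()
        for t in ("AAA", "BBB", "CCC"):
            mg.add_metanode(t)
        mg.add_metaedge(bk.MetaedgeSpec("AAA", "rel", "BBB"))
        mg.add_metaedge(bk.MetaedgeSpec("BBB", "rel", "CCC"))
        d1 = bk.DatasetNetwork.from_edges(
            "d1", mg.metaedges[("AAA", "rel", "BBB")], [("a1", "b1"), ("a1", "b2")]
        )
        d2 = bk.DatasetNetwork.from_edges(
            "d2",
            mg.metaedges[("BBB", "rel", "CCC")],
            [("b1", "c1"), ("b2", "c1"), ("b2", "c2")],
        )
        kg = bk.assemble_graph([d1, d2], mg)
        dm = bk.dwpc_matrix(bk.parse_metapath("AAA-rel-BBB-rel-CCC", kg), kg)
        s = 2**-0.5
        expect = {
            ("a1", "c1"): s * s + s * (s * s),
            ("a1", "c2"): s * s,
        }
        arr = dm.matrix.toarray()
        for (a, c), v in expect.items():
            i, j = dm.row_nodes.index(a), dm.col_nodes.index(c)
            assert arr[i, j] == pytest.approx(v, abs=1e-12)

    @pytest.mark.parametrize("exponent", [-0.5, 0.0])
    def test_random_graphs_match_enumeration_oracle(self, exponent):
        rng = np.random.default_rng(123)
        checked = 0
        while checked < 30:
            kg, edges = _random_bipartite_kg(
                rng, int(rng.integers(2, 10)), int(rng.integers(2, 10)),
                int(rng.integers(2, 10)), 0.3,
            )
            if kg is None:
                continue
            spec = bk.parse_metapath("AAA-rel-BBB-rel-CCC", kg)
            try:
                dm = bk.dwpc_matrix(spec, kg, bk.DWPCConfig(degree_exponent=exponent))
            except ValueError:  # no shared middle universe: no paths exist
                continue
            oracle = _dwpc_oracle(edges, exponent)
            arr = dm.matrix.toarray()
            for (a, c), v in oracle.items():
                i, j = dm.row_nodes.index(a), dm.col_nodes.index(c)
                assert arr[i, j] == pytest.approx(v, abs=1e-9)
            assert np.count_nonzero(arr) == len(
                [1 for v in oracle.values() if v > 0]
            )
            checked += 1

    def test_symmetric_stack_gives_symmetric_matrix(self, toy_metagraph):
        rng = np.random.default_rng(5)
        mg = toy_metagraph
        edges = [
            (f"x{i}", f"g{j}")
            for i in range(8)
            for j in range(10)
            if rng.random() < 0.4
        ]
        ds = bk.DatasetNetwork.from_edges(
            "expr", mg.metaedges[("CLL", "upr", "GEN")], edges
        )
        kg = bk.assemble_graph([ds], mg)
        dm = bk.dwpc_matrix(bk.parse_metapath("CLL-upr-GEN-upr-CLL", kg), kg)
        assert dm.homogeneous
        np.testing.assert_allclose(
            dm.matrix.toarray(), dm.matrix.toarray().T, atol=1e-12
        )

    def test_disconnected_metapath_rejected(self, toy_metagraph):
        mg = toy_metagraph
        d1 = bk.DatasetNetwork.from_edges(
            "t", mg.metaedges[("CPD", "int", "GEN")], [("c1", "g1")]
        )
        d2 = bk.DatasetNetwork.from_edges(
            "d", mg.metaedges[("DIS", "ass", "GEN")], [("d1", "g2")]
        )
        kg = bk.assemble_graph([d1, d2], mg)
        with pytest.raises(ValueError, match="disconnected"):
            bk.dwpc_matrix(bk.parse_metapath("CPD-int-GEN-ass-DIS", kg), kg)


class TestCapEdges:
    def _uniform(self, n, m):
        return bk.DWPCMatrix(
            sp.csr_matrix(np.ones((n, m))),
            [f"r{i:04d}" for i in range(n)],
            [f"c{j:04d}" for j in range(m)],
        )

    def test_max_clamp_on_complete_bipartite(self):
        dm = self._uniform(20, 6000)
        capped = bk.cap_edges(dm)
        # 5% of 6000 = 300 -> clamped to the 250 maximum, per source node
        row_degrees = np.diff(capped.row_kept.indptr)
        assert (row_degrees == 250).all()

    def test_min_clamp_on_small_neighborhood(self):
        dm = self._uniform(50, 20)
        capped = bk.cap_edges(dm)
        # 5% of 20 = 1 -> clamped to the minimum of 3
        assert (np.diff(capped.row_kept.indptr) == 3).all()

    def test_sparse_rows_unchanged(self):
        M = sp.csr_matrix(
            np.array([[0.5, 0.2, 0, 0], [0, 0, 0.9, 0], [0.1, 0, 0, 0.3]])
        )
        dm = bk.DWPCMatrix(M, ["a", "b", "c"], ["w", "x", "y", "z"])
        capped = bk.cap_edges(dm)
        np.testing.assert_allclose(capped.matrix.toarray(), M.toarray())

    def test_idempotent_and_weights_preserved(self):
        rng = np.random.default_rng(9)
        M = sp.random(60, 80, density=0.4, random_state=3, format="csr")
        dm = bk.DWPCMatrix(
            M, [f"r{i:03d}" for i in range(60)], [f"c{j:03d}" for j in range(80)]
        )
        once = bk.cap_edges(dm)
        twice = bk.cap_edges(once)
        assert (once.matrix != twice.matrix).nnz == 0
        # surviving weights are original weights
        diff = dm.matrix.multiply(once.matrix != 0) - once.matrix
        assert abs(diff).max() < 1e-15


class TestMergeAndFilter:
    def test_merge_sum_commutative_associative(self):
        rng = np.random.default_rng(4)
        mats = []
        for _ in range(3):
            M = sp.random(10, 12, density=0.3, random_state=int(rng.integers(99)))
            mats.append(
                bk.DWPCMatrix(
                    M.tocsr(),
                    [f"r{i}" for i in range(10)],
                    [f"c{j}" for j in range(12)],
                )
            )
        a = bk.merge_networks(mats, mode="sum")
        b = bk.merge_networks(list(reversed(mats)), mode="sum")
        c = bk.merge_networks(
            [bk.merge_networks(mats[:2], mode="sum"), mats[2]], mode="sum"
        )
        np.testing.assert_allclose(a.matrix.toarray(), b.matrix.toarray(), atol=1e-12)
        np.testing.assert_allclose(a.matrix.toarray(), c.matrix.toarray(), atol=1e-12)

    def test_merge_union_binary_disjoint_sizes_add(self):
        m1 = bk.DWPCMatrix(sp.csr_matrix(np.eye(3)), list("abc"), list("xyz"))
        m2 = bk.DWPCMatrix(sp.csr_matrix(np.eye(3)), list("def"), list("uvw"))
        merged = bk.merge_networks([m1, m2], mode="union")
        assert merged.matrix.nnz == 6
        assert set(merged.matrix.data) == {1.0}

    def test_overlapping_weights_sum_to_hand_computation(self):
        m1 = bk.DWPCMatrix(sp.csr_matrix(np.array([[1.0, 2.0]])), ["a"], ["x", "y"])
        m2 = bk.DWPCMatrix(sp.csr_matrix(np.array([[0.5, 0.0]])), ["a"], ["x", "y"])
        merged = bk.merge_networks([m1, m2], mode="sum")
        np.testing.assert_allclose(merged.matrix.toarray(), [[1.5, 2.0]])

    def test_small_component_dropped(self):
        # 96-node component + 4-node component on 100 nodes
        big = [(f"n{i:03d}", f"n{i + 1:03d}") for i in range(95)]
        small = [(f"m{i}", f"m{i + 1}") for i in range(3)]
        nodes = sorted({x for e in big + small for x in e})
        idx = {n: i for i, n in enumerate(nodes)}
        M = sp.lil_matrix((len(nodes), len(nodes)))
        for a, b in big + small:
            M[idx[a], idx[b]] = 1.0
            M[idx[b], idx[a]] = 1.0
        dm = bk.DWPCMatrix(M.tocsr(), nodes, nodes)
        filt, report = bk.filter_components(dm)
        assert report["retained_nodes"] == 96
        assert not report["rejected"]
        assert all(n.startswith("n") for n in filt.row_nodes)

    def test_fragmented_network_rejected(self):
        # 50 isolated pairs: every component is 2/100 = 2% < 5%
        edges = [(f"a{i:02d}", f"b{i:02d}") for i in range(50)]
        nodes = sorted({x for e in edges for x in e})
        idx = {n: i for i, n in enumerate(nodes)}
        M = sp.lil_matrix((100, 100))
        for a, b in edges:
            M[idx[a], idx[b]] = 1.0
            M[idx[b], idx[a]] = 1.0
        dm = bk.DWPCMatrix(M.tocsr(), nodes, nodes)
        _, report = bk.filter_components(dm)
        assert report["rejected"]
        assert report["retained_nodes"] == 0

    def test_single_giant_component_untouched(self, two_clique_network):
        net, _ = two_clique_network
        mg = bk.Metagraph()
        mg.add_metanode("GEN")
        mg.add_metaedge(bk.MetaedgeSpec("GEN", "ppi", "GEN"))
        kg = bk.assemble_graph([net], mg)
        dm = bk.dwpc_matrix(bk.parse_metapath("GEN-ppi-GEN", kg), kg)
        filt, report = bk.filter_components(dm)
        assert report["retention"] == 1.0
        assert filt.matrix.nnz == dm.matrix.nnz
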