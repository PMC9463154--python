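import numpy as np
import pytest

import biokg as bk


@pytest.fixture(scope="session")
def toy_metagraph() -> bk.Metagraph:
    """The small schema used across the suite (gene-centric, 6 entity types)."""
    mg = bk.Metagraph()
    for abbr, name in [
        ("GEN", "genes"),
        ("CPD", "compounds"),
        ("DIS", "diseases"),
        ("PWY", "pathways"),
        ("CLL", "cell lines"),
        ("TIS", "tissues"),
    ]:
        mg.add_metanode(abbr, name)
    for spec in [
        bk.MetaedgeSpec("GEN", "ppi", "GEN"),
        bk.MetaedgeSpec("GEN", "pho", "GEN", directed=True),
        bk.MetaedgeSpec("GEN", "ass", "PWY"),
        bk.MetaedgeSpec("CPD", "int", "GEN"),
        bk.MetaedgeSpec("CPD", "sim", "CPD"),
        bk.MetaedgeSpec("DIS", "ass", "GEN"),
        bk.MetaedgeSpec("CLL", "has", "TIS"),
        bk.MetaedgeSpec("CLL", "upr", "GEN"),
        bk.MetaedgeSpec("CLL", "dwr", "GEN"),
        bk.MetaedgeSpec("CLL", "gex", "GEN"),
    ]:
        mg.add_metaedge(spec)
    return mg


@pytest.fixture(scope="session")
def two_clique_network() -> tuple[bk.DatasetNetwork, dict[str, int]]:
    """Two disjoint 8-cliques: the sharpest possible community structure."""
    return bk.planted_partition_network(
        16, 2, p_in=1.0, p_out=0.0, seed=7, name="cliques"
    )


@pytest.fixture(scope="session")
def small_embedding() -> bk.EmbeddingSet:
    """A seeded random-vector embedding used by distance-statistic tests."""
    rng = np.random.default_rng(42)
    n = 200
    return bk.EmbeddingSet(
        [f"n{i:03d}" for i in range(n)],
        rng.normal(size=(n, 64)).astype(np.float32),
    )
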