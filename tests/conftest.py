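import dendropy
import numpy as np
import pandas as pd
import pytest

from bdtt import OccurrenceTable, SiteTable, UltrametricTree
from bdtt.phylo_io import CLIMATE_COLUMNS
from bdtt.synthetic_data import simulate_tree

THREE_TIP_NEWICK = "((A:1,B:1):1,C:2);"


@pytest.fixture
def three_tip_tree() -> UltrametricTree:
    """((A:1,B:1):1,C:2); — root age 2, cherry at age 1."""
    return UltrametricTree.from_newick_string(THREE_TIP_NEWICK)


@pytest.fixture
def three_tip_occ() -> OccurrenceTable:
    """site1 = {A, B}, site2 = {A, C}."""
    return OccurrenceTable(
        pd.DataFrame(
            [[1, 1, 0], [1, 0, 1]], index=["site1", "site2"], columns=["A", "B", "C"]
        )
    )


def make_sites(n: int, spacing: float = 100.0, seed: int = 0) -> SiteTable:
    """Simple transect site table with monotone-plus-noise climate."""
    rng = np.random.default_rng(seed)
    grad = np.linspace(1.0, -1.0, n)
    df = pd.DataFrame({"site_id": [f"s{k}" for k in range(n)]})
    df["x_km"] = np.arange(n) * spacing
    df["y_km"] = 0.0
    for j, col in enumerate(CLIMATE_COLUMNS):
        df[col] = (j + 1) * 10.0 * grad + rng.normal(0, 1.0, n)
    return SiteTable(df.set_index("site_id"))


def random_occurrence(taxa, n_sites: int, seed: int = 0) -> OccurrenceTable:
    """Random 0/1 table guaranteed to have no empty site or taxon."""
    rng = np.random.default_rng(seed)
    while True:
        m = (rng.random((n_sites, len(taxa))) < 0.5).astype(np.int8)
        if (m.sum(axis=0) > 0).all() and (m.sum(axis=1) > 0).all():
            return OccurrenceTable(
                pd.DataFrame(m, index=[f"s{k}" for k in range(n_sites)], columns=list(taxa))
            )


@pytest.fixture
def yule_tree_factory():
    return simulate_tree


def dendropy_mrca_age(tree: UltrametricTree, label_u: str, label_v: str) -> float:
    """Independent MRCA age via dendropy bipartition machinery."""
    dmat = tree.tree.phylogenetic_distance_matrix()
    tu = tree.tree.taxon_namespace.get_taxon(label_u)
    tv = tree.tree.taxon_namespace.get_taxon(label_v)
    return dmat.patristic_distance(tu, tv) / 2.0
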