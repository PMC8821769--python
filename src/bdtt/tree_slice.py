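"""Slice an ultrametric tree at an evolutionary depth t.

A slice at depth t (Myr before present) truncates the phylogeny: every
branch segment younger than t is discarded and each branch crossing age
t becomes a *lineage* — a tip of the sliced tree whose geographic
distribution is the union of the distributions of its descendant tips.
At t = 0 the lineages are exactly the original tips.

Tie rule: a node whose age equals t exactly is collapsed into the
lineage below its crossing branch, i.e. two tips share a lineage iff
the age of their MRCA is <= t.  This keeps t = 0 the identity slice
(for trees with positive internal branch lengths) and makes the number
of lineages right-continuous in t.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import ValidationError
from .phylo_io import LineageOccurrenceTable, OccurrenceTable, UltrametricTree


def node_ages(tree: UltrametricTree) -> dict[dendropy.Node, float]:
    """Age (Myr before present) of every node; tips 0, root ``root_age``.

    Internal ages are ``root_age`` minus the path length from the root;
    leaf ages are pinned to exactly 0 (they differ from it only by the
    ultrametricity tolerance).
    """
    ages: dict[dendropy.Node, float] = {}
    depth: dict[dendropy.Node, float] = {}
    for nd in tree.tree.preorder_node_iter():
        if nd.parent_node is None:
            depth[nd] = 0.0
        else:
            depth[nd] = depth[nd.parent_node] + nd.edge.length
        ages[nd] = 0.0 if nd.is_leaf() else tree.root_age - depth[nd]
    return ages


def _format_slice_time(t: float) -> str:
    return f"{t:g}"


@dataclass
class SlicedLineageSet:
    """Product of slicing a tree at depth ``t``.

    Lineages partition the original tip set.  The lineage tree keeps the
    original topology above age t; each crossing branch becomes a tip
    branch of length (parent age - t), internal branches keep their
    original lengths.  ``edge_lengths``/``edge_below`` enumerate every
    branch of the lineage tree (no root stem) together with the set of
    lineages descending from it — the currency of branch-length
    beta-diversity.  ``mrca_ages`` holds pairwise MRCA ages between
    lineages on the original time scale (diagonal = t so that patristic
    distances have zero diagonal).
    """

    t: float
    root_age: float
    lineage_ids: list[str]
    tip_sets: list[frozenset[str]]
    tip_to_lineage: dict[str, str]
    edge_lengths: np.ndarray  # (E,) Myr
    edge_below: np.ndarray  # (E, L) bool: lineage j below edge e
    mrca_ages: np.ndarray  # (L, L) Myr
    newick: str = field(repr=False, default="")

    @property
    def n_lineages(self) -> int:
        return len(self.lineage_ids)

    def membership(self, taxon_ids: list[str]) -> np.ndarray:
        """0/1 matrix (taxa x lineages) mapping original taxa to lineages."""
        index = {lid: k for k, lid in enumerate(self.lineage_ids)}
        m = np.zeros((len(taxon_ids), self.n_lineages), dtype=np.int8)
        for i, taxon in enumerate(taxon_ids):
            m[i, index[self.tip_to_lineage[taxon]]] = 1
        return m


def slice_tree(tree: UltrametricTree, t: float) -> SlicedLineageSet:
    """Truncate ``tree`` at depth ``t`` and return its lineage set."""
    if t < 0:
        raise ValidationError(f"slice time must be >= 0, got {t}")
    if t >= tree.root_age:
        raise ValidationError(
            f"slice above root: t={t} >= root_age={tree.root_age}"
        )
    ages = node_ages(tree)
    prefix = f"t{_format_slice_time(t)}|"

    # crossing branch: child age <= t < parent age
    def is_crossing(nd: dendropy.Node) -> bool:
        return (
            nd.parent_node is not None
            and ages[nd] <= t
            and ages[nd.parent_node] > t
        )

    lineage_ids: list[str] = []
    tip_sets: list[frozenset[str]] = []
    tip_to_lineage: dict[str, str] = {}
    edge_lengths: list[float] = []
    edge_below: list[np.ndarray] = []

    # postorder pass: for kept nodes (age > t) record which lineages lie
    # below; crossing branches spawn lineages.
    below: dict[dendropy.Node, list[int]] = {}
    n_l = 0
    order: dict[dendropy.Node, int] = {}
    for nd in tree.tree.postorder_node_iter():
        if is_crossing(nd):
            tips = frozenset(
                lf.taxon.label for lf in nd.leaf_iter()
            )
            lid = prefix + min(tips)
            order[nd] = n_l
            lineage_ids.append(lid)
            tip_sets.append(tips)
            for label in tips:
                tip_to_lineage[label] = lid
            below[nd] = [n_l]
            n_l += 1
        elif ages[nd] > t:
            children = [c for c in nd.child_nodes() if c in below]
            below[nd] = [k for c in children for k in below[c]]

    L = n_l
    # pairwise MRCA ages between lineages: for each kept internal node,
    # lineage pairs split across its children coalesce exactly there.
    mrca = np.full((L, L), np.nan)
    np.fill_diagonal(mrca, t)
    for nd in tree.tree.postorder_node_iter():
        if nd in below and not is_crossing(nd):
            children = [c for c in nd.child_nodes() if c in below]
            for ii in range(len(children)):
                for jj in range(ii + 1, len(children)):
                    a = np.array(below[children[ii]])
                    b = np.array(below[children[jj]])
                    mrca[np.ix_(a, b)] = ages[nd]
                    mrca[np.ix_(b, a)] = ages[nd]

    # branches of the lineage tree: crossing branches (truncated) plus
    # kept internal branches; the root stem is never included.
    newick = _build_newick(tree, ages, t, below, order, lineage_ids)
    for nd in tree.tree.postorder_node_iter():
        if is_crossing(nd):
            mask = np.zeros(L, dtype=bool)
            mask[order[nd]] = True
            edge_lengths.append(ages[nd.parent_node] - t)
            edge_below.append(mask)
        elif nd in below and nd.parent_node is not None:
            mask = np.zeros(L, dtype=bool)
            mask[below[nd]] = True
            edge_lengths.append(nd.edge.length)
            edge_below.append(mask)

    return SlicedLineageSet(
        t=t,
        root_age=tree.root_age,
        lineage_ids=lineage_ids,
        tip_sets=tip_sets,
        tip_to_lineage=tip_to_lineage,
        edge_lengths=np.asarray(edge_lengths, dtype=float),
        edge_below=np.vstack(edge_below),
        mrca_ages=mrca,
        newick=newick,
    )


def _build_newick(
    tree: UltrametricTree,
    ages: dict[dendropy.Node, float],
    t: float,
    below: dict[dendropy.Node, list[int]],
    order: dict[dendropy.Node, int],
    lineage_ids: list[str],
) -> str:
    def render(nd: dendropy.Node) -> str:
        if nd in order:  # crossing branch -> lineage tip
            length = ages[nd.parent_node] - t
            return f"{lineage_ids[order[nd]]}:{length:.10g}"
        children = [c for c in nd.child_nodes() if c in below or c in order]
        inner = ",".join(render(c) for c in children)
        if nd.parent_node is None:
            return f"({inner})"
        return f"({inner}):{nd.edge.length:.10g}"

    root = tree.tree.seed_node
    return render(root) + ";"


def lineage_occurrence(
    sliced: SlicedLineageSet, occ: OccurrenceTable
) -> LineageOccurrenceTable:
    """Map site occurrences onto slice lineages (union of descendants).

    A lineage is present at a site iff at least one of its descendant
    tips is present there.
    """
    import pandas as pd

    missing = [tx for tx in occ.taxon_ids if tx not in sliced.tip_to_lineage]
    if missing:
        raise ValidationError(f"occurrence taxa absent from tree: {missing[:5]}")
    m = sliced.membership(occ.taxon_ids)
    values = (occ.presence() @ m > 0).astype(np.int8)
    df = pd.DataFrame(values, index=occ.data.index, columns=sliced.lineage_ids)
    return LineageOccurrenceTable(df)


def lineage_pairwise_distances(
    sliced: SlicedLineageSet, subtract_slice: bool = True
) -> np.ndarray:
    """Patristic distances between lineages on the sliced tree (Myr).

    d(Li, Lj) = 2 x (MRCA age - t); zero diagonal.  With
    ``subtract_slice=False`` distances are measured on the original time
    scale (2 x MRCA age, same-lineage pairs still 0), for the variant in
    which deep-slice mean pairwise distances keep species-level depth.
    """
    offset = sliced.t if subtract_slice else 0.0
    d = 2.0 * (sliced.mrca_ages - offset)
    np.fill_diagonal(d, 0.0)
    return d
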