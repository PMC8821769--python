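"""Read, validate, and write the three standard inputs.

The pipeline consumes a rooted ultrametric phylogeny (Newick, branch
lengths in Myr), a binary site-by-taxon occurrence table, and a site
table with projected midpoint coordinates (km) and six bioclimatic
variables.  All validation happens at read time; downstream modules can
assume the invariants hold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: relative tolerance (fraction of root age) for the ultrametricity check
ULTRAMETRIC_RTOL = 1e-6

CLIMATE_COLUMNS = ["bio1", "bio12", "bio6", "bio14", "bio4", "bio15"]
SITE_COLUMNS = ["site_id", "x_km", "y_km"] + CLIMATE_COLUMNS


@dataclass
class UltrametricTree:
    """Rooted ultrametric tree with branch lengths in Myr.

    Wraps a :class:`dendropy.Tree`; ``root_age`` is the maximum
    root-to-tip path length and every root-to-tip path must equal it
    within ``ULTRAMETRIC_RTOL`` (relative).  Tips sit at age 0.
    """

    tree: dendropy.Tree
    root_age: float = field(init=False)
    tip_labels: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.tree.is_rooted = True
        leaves = self.tree.leaf_nodes()
        if len(leaves) < 2:
            raise ValidationError(f"tree must have >= 2 tips, got {len(leaves)}")
        labels = [lf.taxon.label if lf.taxon is not None else None for lf in leaves]
        if any(lbl is None or lbl == "" for lbl in labels):
            raise ValidationError("every tip must carry a non-empty label")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValidationError(f"duplicate tip labels: {dupes}")
        for nd in self.tree.preorder_node_iter():
            if nd.parent_node is not None and nd.edge.length is None:
                raise ValidationError("every non-root branch needs a length")
            if nd.parent_node is not None and nd.edge.length < 0:
                raise ValidationError("negative branch length")
        depths = self._leaf_depths()
        root_age = max(depths.values())
        worst_label, worst_depth = min(depths.items(), key=lambda kv: kv[1])
        if root_age - worst_depth > ULTRAMETRIC_RTOL * max(root_age, 1e-300):
            raise ValidationError(
                f"tree is not ultrametric: tip {worst_label!r} at depth "
                f"{worst_depth:.6g} vs root age {root_age:.6g}"
            )
        self.root_age = root_age
        self.tip_labels = labels

    def _leaf_depths(self) -> dict[str, float]:
        depth: dict[dendropy.Node, float] = {}
        out: dict[str, float] = {}
        for nd in self.tree.preorder_node_iter():
            if nd.parent_node is None:
                depth[nd] = 0.0
            else:
                depth[nd] = depth[nd.parent_node] + nd.edge.length
            if nd.is_leaf():
                out[nd.taxon.label] = depth[nd]
        return out

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @classmethod
    def from_newick_string(cls, newick: str) -> "UltrametricTree":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises assorted error classes
            raise FormatError(f"could not parse Newick: {exc}") from exc
        return cls(tree)

    def as_newick_string(self) -> str:
        return (
            self.tree.as_string(
                schema="newick",
                suppress_rooting=True,
                real_value_format_specifier=".17g",
            ).strip()
            + "\n"
        )


@dataclass
class OccurrenceTable:
    """Binary site x taxon presence table.

    ``data`` is indexed by site_id with one 0/1 column per taxon.  At
    deeper slices the "taxa" are lineages; the container is the same.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise ValidationError(f"duplicate site ids: {sorted(df.index[df.index.duplicated()])}")
        if df.columns.has_duplicates:
            raise ValidationError(
                f"duplicate taxon ids: {sorted(df.columns[df.columns.duplicated()])}"
            )
        values = df.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise FormatError("occurrence cells must be 0 or 1")
        self.data = df.astype(np.int8)
        empty_sites = df.index[values.sum(axis=1) == 0].tolist()
        if empty_sites:
            raise ValidationError(f"sites with no taxa: {empty_sites}")
        empty_taxa = df.columns[values.sum(axis=0) == 0].tolist()
        if empty_taxa:
            raise ValidationError(f"taxa present in no site: {empty_taxa}")

    @property
    def site_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_sites(self) -> int:
        return len(self.data.index)

    def presence(self) -> np.ndarray:
        """0/1 matrix, sites x taxa."""
        return self.data.to_numpy(dtype=np.int8)


#: alias used where columns are slice lineages rather than species
LineageOccurrenceTable = OccurrenceTable


@dataclass
class SiteTable:
    """One row per site: projected midpoint (km) plus six climate columns."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in SITE_COLUMNS if c not in df.columns and c != "site_id"]
        if df.index.name != "site_id" and "site_id" in df.columns:
            df = df.set_index("site_id")
        if missing:
            raise FormatError(f"site table missing columns: {missing}")
        if df.index.has_duplicates:
            raise ValidationError(
                f"duplicate site ids: {sorted(df.index[df.index.duplicated()])}"
            )
        numeric = df[["x_km", "y_km"] + CLIMATE_COLUMNS].to_numpy(dtype=float)
        if not np.isfinite(numeric).all():
            raise ValidationError("site table contains non-finite values")
        self.data = df

    @property
    def site_ids(self) -> list[str]:
        return list(self.data.index)

    def coordinates(self) -> np.ndarray:
        return self.data[["x_km", "y_km"]].to_numpy(dtype=float)

    def climate(self) -> pd.DataFrame:
        return self.data[CLIMATE_COLUMNS].astype(float)


def _sniff_sep(path: str) -> str:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_newick(path: str) -> UltrametricTree:
    """Parse a rooted ultrametric Newick file and validate it."""
    try:
        tree = dendropy.Tree.get(
            path=path, schema="newick", preserve_underscores=True
        )
    except (dendropy.utility.error.DataParseError, ValueError) as exc:
        raise FormatError(f"could not parse Newick file {path}: {exc}") from exc
    return UltrametricTree(tree)


def write_newick(tree: UltrametricTree, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(tree.as_newick_string())


def read_occurrence(path: str) -> OccurrenceTable:
    """Read a delimited site x taxon 0/1 table (first column ``site_id``)."""
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0, encoding="utf-8")
    df.index = df.index.astype(str)
    df.index.name = "site_id"
    non_numeric = df.columns[
        [not np.issubdtype(dt, np.number) for dt in df.dtypes]
    ].tolist()
    if non_numeric:
        raise FormatError(f"non-numeric occurrence columns: {non_numeric}")
    return OccurrenceTable(df)


def write_occurrence(occ: OccurrenceTable, path: str, sep: str = ",") -> None:
    occ.data.to_csv(path, sep=sep, encoding="utf-8")


def read_sites(path: str) -> SiteTable:
    """Read the site table (site_id, x_km, y_km, six bioclim columns)."""
    df = pd.read_csv(path, sep=_sniff_sep(path), encoding="utf-8")
    if "site_id" not in df.columns:
        raise FormatError("site table must have a 'site_id' column")
    df["site_id"] = df["site_id"].astype(str)
    return SiteTable(df.set_index("site_id"))


def write_sites(sites: SiteTable, path: str, sep: str = ",") -> None:
    sites.data.to_csv(path, sep=sep, encoding="utf-8")


def align_inputs(
    tree: UltrametricTree, occ: OccurrenceTable, sites: SiteTable
) -> tuple[UltrametricTree, OccurrenceTable, SiteTable]:
    """Restrict all three inputs to their common taxa and sites.

    Taxa are restricted to the intersection of tree tips and occurrence
    columns (the tree is pruned, extra occurrence columns dropped; both
    logged with counts).  Sites are restricted to the intersection of
    the occurrence and site tables.  Output ordering is deterministic:
    sites in SiteTable order, taxa in (pruned) tree tip order.
    Idempotent on already-aligned inputs.
    """
    tree_taxa = set(tree.tip_labels)
    occ_taxa = set(occ.taxon_ids)
    common_taxa = tree_taxa & occ_taxa
    if not common_taxa:
        raise ValidationError("no taxa shared between tree and occurrence table")
    occ_sites = set(occ.site_ids)
    site_sites = set(sites.site_ids)
    common_sites = occ_sites & site_sites
    if not common_sites:
        raise ValidationError("no sites shared between occurrence and site tables")

    dropped_tips = len(tree_taxa) - len(common_taxa)
    if dropped_tips:
        logger.warning("dropped %d tree tip(s) absent from occurrence table", dropped_tips)
        pruned = tree.tree.extract_tree_with_taxa_labels(
            labels=common_taxa, suppress_unifurcations=True
        )
        tree = UltrametricTree(pruned)
    dropped_cols = len(occ_taxa) - len(common_taxa)
    if dropped_cols:
        logger.warning("dropped %d occurrence column(s) absent from tree", dropped_cols)
    dropped_sites = (len(occ_sites) - len(common_sites)) + (
        len(site_sites) - len(common_sites)
    )
    if dropped_sites:
        logger.warning("dropped %d site row(s) not shared by both tables", dropped_sites)

    site_order = [s for s in sites.site_ids if s in common_sites]
    taxon_order = [t for t in tree.tip_labels if t in common_taxa]
    occ_aligned = OccurrenceTable(occ.data.loc[site_order, taxon_order])
    sites_aligned = SiteTable(sites.data.loc[site_order])
    return tree, occ_aligned, sites_aligned
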