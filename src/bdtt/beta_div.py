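"""Turnover metrics between site pairs at a given slice.

Three metrics, all on presence/absence data:

* ``sim_tax`` — Simpson taxonomic turnover,
  beta_sim = min(b, c) / (a + min(b, c)), where a is the number of taxa
  shared by the two sites and b, c the numbers unique to each.  The
  index is insensitive to richness differences (nested assemblages
  score 0).
* ``sim_phy`` — the same formula with shared/unique *branch lengths* of
  the sliced tree in place of taxon counts (tip-weighted phylogenetic
  turnover).
* ``dpw`` — mean pairwise patristic distance (Myr) over all
  cross-assemblage lineage pairs (basal-weighted turnover).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform

from .errors import ValidationError
from .phylo_io import LineageOccurrenceTable
from .tree_slice import SlicedLineageSet, lineage_pairwise_distances

METRICS = ("sim_tax", "sim_phy", "dpw")


@dataclass(frozen=True)
class BetaComponents:
    """Shared (a) and unique (b, c) amounts in some currency (counts or Myr)."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) < 0:
            raise ValidationError("components must be non-negative")
        if self.a + self.b <= 0 or self.a + self.c <= 0:
            raise ValidationError("each site must be non-empty in the metric's currency")


def beta_sim(comp: BetaComponents) -> float:
    """Simpson turnover min(b,c)/(a+min(b,c)); 0 for identical/nested pairs."""
    m = min(comp.b, comp.c)
    denom = comp.a + m
    if denom == 0:
        raise ValidationError("a + min(b, c) = 0: both assemblages empty")
    return m / denom


@dataclass(frozen=True)
class PairDistanceVector:
    """Condensed vector over unordered site pairs in (i < j) order.

    Pair order matches :func:`scipy.spatial.distance.squareform`:
    (0,1), (0,2), ..., (0,n-1), (1,2), ...
    """

    site_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.site_ids)
        expected = n * (n - 1) // 2
        if len(self.values) != expected:
            raise ValidationError(
                f"expected {expected} pair values for {n} sites, got {len(self.values)}"
            )
        if not np.isfinite(self.values).all():
            raise ValidationError("non-finite pair values")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_pairs(self) -> int:
        return len(self.values)

    def pairs(self):
        """Iterate (site_i, site_j, value) in canonical order."""
        k = 0
        for i in range(self.n_sites):
            for j in range(i + 1, self.n_sites):
                yield self.site_ids[i], self.site_ids[j], self.values[k]
                k += 1

    def to_square(self) -> np.ndarray:
        return squareform(self.values)


def _site_vector(occ: LineageOccurrenceTable, site):
    try:
        return occ.data.loc[site].to_numpy(dtype=bool)
    except KeyError as exc:
        raise ValidationError(f"unknown site {site!r}") from exc


def tax_components(occ: LineageOccurrenceTable, site_i, site_j) -> BetaComponents:
    """Counts of shared and unique taxa between two sites."""
    vi, vj = _site_vector(occ, site_i), _site_vector(occ, site_j)
    return BetaComponents(
        a=float(np.sum(vi & vj)),
        b=float(np.sum(vi & ~vj)),
        c=float(np.sum(~vi & vj)),
    )


def phylo_components(
    sliced: SlicedLineageSet, occ: LineageOccurrenceTable, site_i, site_j
) -> BetaComponents:
    """Shared and unique branch lengths (Myr) between two sites.

    A branch of the lineage tree is present at a site iff at least one
    lineage below it (inclusive) occurs there; the root stem is never
    counted.  Branches present at neither site are ignored.
    """
    _check_columns(sliced, occ)
    vi, vj = _site_vector(occ, site_i), _site_vector(occ, site_j)
    pi = sliced.edge_below @ vi > 0
    pj = sliced.edge_below @ vj > 0
    w = sliced.edge_lengths
    return BetaComponents(
        a=float(w[pi & pj].sum()),
        b=float(w[pi & ~pj].sum()),
        c=float(w[~pi & pj].sum()),
    )


def d_pw(
    distmat: np.ndarray,
    occ: LineageOccurrenceTable,
    site_i,
    site_j,
    include_shared: bool = True,
) -> float:
    """Mean pairwise patristic distance (Myr) across two assemblages.

    Averages d(x, y) over all cross pairs x in site_i, y in site_j.
    Shared lineages contribute zero-distance pairs by default
    (``include_shared=False`` drops same-lineage pairs from the mean).
    """
    vi, vj = _site_vector(occ, site_i), _site_vector(occ, site_j)
    ni, nj = int(vi.sum()), int(vj.sum())
    if ni == 0 or nj == 0:
        raise ValidationError("both sites must be non-empty")
    total = float(vi @ distmat @ vj)
    n_pairs = ni * nj
    if not include_shared:
        n_pairs -= int(np.sum(vi & vj))
        if n_pairs == 0:
            return 0.0
    return total / n_pairs


def _check_columns(sliced: SlicedLineageSet, occ: LineageOccurrenceTable) -> None:
    if list(occ.data.columns) != sliced.lineage_ids:
        raise ValidationError("occurrence columns do not match slice lineage ids")


def pairwise_beta(
    metric: str,
    sliced: SlicedLineageSet,
    occ: LineageOccurrenceTable,
    dpw_subtract_slice: bool = True,
    dpw_include_shared: bool = True,
) -> PairDistanceVector:
    """One value per unordered site pair, vectorised over all pairs."""
    if metric not in METRICS:
        raise ValidationError(f"unknown metric {metric!r}; choose from {METRICS}")
    _check_columns(sliced, occ)
    S = occ.presence().astype(float)  # sites x lineages
    n = S.shape[0]
    iu = np.triu_indices(n, k=1)

    if metric == "sim_tax":
        shared = S @ S.T
        richness = S.sum(axis=1)
        a = shared[iu]
        b = richness[iu[0]] - a
        c = richness[iu[1]] - a
        m = np.minimum(b, c)
        values = m / (a + m)
    elif metric == "sim_phy":
        P = (sliced.edge_below.astype(float) @ S.T) > 0  # edges x sites
        w = sliced.edge_lengths
        shared = (w[:, None] * P).T @ P  # sites x sites shared branch length
        total = w @ P  # per-site branch length
        a = shared[iu]
        b = total[iu[0]] - a
        c = total[iu[1]] - a
        m = np.minimum(b, c)
        values = m / (a + m)
    else:  # dpw
        D = lineage_pairwise_distances(sliced, subtract_slice=dpw_subtract_slice)
        cross = S @ D @ S.T
        counts = S.sum(axis=1)
        n_pairs = np.outer(counts, counts)
        if not dpw_include_shared:
            n_pairs = n_pairs - (S @ S.T)
            n_pairs[n_pairs == 0] = 1  # identical single-lineage sites -> mean 0
        values = (cross / n_pairs)[iu]

    # guard against float round-off pushing turnover a hair outside [0, 1]
    if metric in ("sim_tax", "sim_phy"):
        values = np.clip(values, 0.0, 1.0)
    return PairDistanceVector(tuple(occ.site_ids), np.asarray(values, dtype=float))
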