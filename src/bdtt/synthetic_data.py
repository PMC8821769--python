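"""Synthetic phylogenies, transects, climates, and assemblages.

The generator reproduces the statistical structure the sweep assumes —
not any real flora.  A pure-birth tree supplies the phylogeny; niche
optima evolve by Brownian motion along its branches (with a Pagel-style
lambda dial for phylogenetic signal); sites lie on a linear transect
whose latent climate axis decreases monotonically and drives six
mutually correlated bioclim-style columns; species occupy sites by
Gaussian environmental filtering around their optima.  An optional
deep-pool bias pushes the two basal clades toward opposite transect
ends, emulating assemblages drawn from distinct ancestral species
pools.

All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import dendropy
import numpy as np
import pandas as pd

from .errors import ValidationError
from .phylo_io import CLIMATE_COLUMNS, OccurrenceTable, SiteTable, UltrametricTree
from .tree_slice import node_ages, slice_tree


@dataclass(frozen=True)
class ScenarioConfig:
    """Knobs of one simulated gradient study.

    Geometry follows the rectangular-site transect design: contiguous
    100 km x 300 km sites on a line, ~3400-3500 km end to end.  The
    latent climate axis is in niche units (niche optima have sd ~1 at
    the tips under full Brownian motion); ``filtering_sd`` is the niche
    breadth on that axis.
    """

    n_species: int = 300
    root_age: float = 140.0  # Myr, crown age of the simulated clade
    n_sites: int = 36
    site_spacing_km: float = 100.0
    transect_width_km: float = 300.0
    niche_conservatism: float = 1.0  # Pagel-style lambda in [0, 1]
    filtering_sd: float = 0.5  # niche breadth sigma, climate-axis units
    deep_pool_bias: float = 0.0  # 0 = one pool; 1 = basal clades fully segregated
    climate_amplitude: float = 2.0  # latent-axis half-range, climate-axis units
    climate_noise: float = 0.1  # sd of column noise as fraction of its gradient
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 3:
            raise ValidationError("need at least 3 species")
        if self.n_sites < 2:
            raise ValidationError("need at least 2 sites")
        for name in ("niche_conservatism", "deep_pool_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        for name in (
            "root_age",
            "site_spacing_km",
            "transect_width_km",
            "filtering_sd",
            "climate_amplitude",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


def _child_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent 31-bit child seeds from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def simulate_tree(n_species: int, root_age: float = 140.0, seed: int = 0) -> UltrametricTree:
    """Pure-birth (Yule) tree rescaled so the crown age equals ``root_age``.

    Exponential waiting times between speciation events, a uniformly
    random lineage splitting at each event; after the last split the
    tree grows one further exponential stretch before "the present",
    then all node times are rescaled.
    """
    if n_species < 3:
        raise ValidationError("need at least 3 species")
    rng = np.random.default_rng(seed)
    # crown tree: the root splits at depth 0 into two active lineages
    children: dict[int, list[int]] = {0: [1, 2]}
    split_depth: dict[int, float] = {0: 0.0}
    active = [1, 2]
    next_id = 3
    depth = 0.0
    while len(active) < n_species:
        depth += rng.exponential(1.0 / len(active))
        node = active.pop(int(rng.integers(len(active))))
        split_depth[node] = depth
        children[node] = [next_id, next_id + 1]
        active.extend([next_id, next_id + 1])
        next_id += 2
    # final stretch from the last split to the present
    depth += rng.exponential(1.0 / n_species)
    scale = root_age / depth

    taxon_namespace = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    width = len(str(n_species))
    tip_counter = [0]

    def build(node_id: int, node: dendropy.Node, node_depth: float) -> None:
        for ch in children[node_id]:
            child = dendropy.Node()
            node.add_child(child)
            if ch in children:
                child_depth = split_depth[ch] * scale
                child.edge.length = child_depth - node_depth
                build(ch, child, child_depth)
            else:  # leaf: extends to the present
                tip_counter[0] += 1
                child.taxon = taxon_namespace.new_taxon(f"s{tip_counter[0]:0{width}d}")
                child.edge.length = root_age - node_depth

    tree.seed_node.edge.length = None
    build(0, tree.seed_node, 0.0)
    return UltrametricTree(tree)


def simulate_niches(
    tree: UltrametricTree, niche_conservatism: float = 1.0, seed: int = 0
) -> dict[str, float]:
    """Brownian niche optima at the tips, with a Pagel-style signal dial.

    Under full conservatism (lambda = 1) optima follow Brownian motion
    along the tree, rate 1/root_age so tip optima have unit variance.
    Lambda scales the *shared* part of every tip pair's covariance, so
    lambda = 0 yields i.i.d. optima while total tip variance stays 1.
    """
    lam = niche_conservatism
    rng = np.random.default_rng(seed)
    sliced = slice_tree(tree, 0.0)  # tip-level MRCA table
    labels = [lid.split("|", 1)[1] for lid in sliced.lineage_ids]
    shared_time = tree.root_age - sliced.mrca_ages  # shared path from root
    np.fill_diagonal(shared_time, tree.root_age)
    rate = 1.0 / tree.root_age
    cov = lam * rate * shared_time
    np.fill_diagonal(cov, rate * tree.root_age)
    # covariance is PSD by construction; jitter guards the factorisation
    jitter = 1e-10 * np.eye(len(labels))
    chol = np.linalg.cholesky(cov + jitter)
    optima = chol @ rng.standard_normal(len(labels))
    return dict(zip(labels, optima.tolist()))


def latent_axis(config: ScenarioConfig) -> np.ndarray:
    """Noise-free latent climate value per site, decreasing along the transect."""
    n = config.n_sites
    return config.climate_amplitude * (1.0 - 2.0 * np.arange(n) / (n - 1))


#: affine maps latent -> bioclim-style columns (intercept, slope per latent unit).
#: Signs make temperature and precipitation fall together along the transect
#: while seasonality rises, as on real continental gradients.
_BIOCLIM_MAPS = {
    "bio1": (10.0, 6.0),  # degC, mean annual temperature
    "bio12": (1100.0, 450.0),  # mm, annual precipitation
    "bio6": (-4.0, 9.0),  # degC, min temperature of coldest month
    "bio14": (18.0, 11.0),  # mm, precipitation of driest month
    "bio4": (850.0, -250.0),  # temperature seasonality (sd x 100)
    "bio15": (75.0, -20.0),  # precipitation seasonality (CV)
}


def simulate_transect(config: ScenarioConfig, seed: int | None = None) -> SiteTable:
    """Collinear transect sites with six correlated climate columns.

    Midpoints sit ``site_spacing_km`` apart on the x axis.  Each bioclim
    column is an affine image of the latent axis plus seeded Gaussian
    noise (sd = ``climate_noise`` x the column's gradient amplitude), so
    the six columns are mutually correlated like real bioclim variables.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_sites
    axis = latent_axis(config)
    width = len(str(n))
    df = pd.DataFrame(
        {
            "site_id": [f"site{k + 1:0{width}d}" for k in range(n)],
            "x_km": np.arange(n) * config.site_spacing_km,
            "y_km": np.zeros(n),
        }
    )
    for col, (intercept, slope) in _BIOCLIM_MAPS.items():
        amplitude = abs(slope) * config.climate_amplitude
        noise = rng.normal(0.0, config.climate_noise * amplitude, size=n)
        df[col] = intercept + slope * axis + noise
    return SiteTable(df.set_index("site_id")[["x_km", "y_km"] + CLIMATE_COLUMNS])


def _basal_clades(tree: UltrametricTree) -> tuple[set[str], set[str]]:
    """Tip sets of the two sides of the root split (polytomies: first child vs rest)."""
    root_children = tree.tree.seed_node.child_nodes()
    first = {lf.taxon.label for lf in root_children[0].leaf_iter()}
    rest = set(tree.tip_labels) - first
    return first, rest


def occupancy_probabilities(
    tree: UltrametricTree,
    niches: dict[str, float],
    config: ScenarioConfig,
) -> np.ndarray:
    """P(species s occupies site k): Gaussian filtering x deep-pool weight.

    Optima are clamped to the latent-axis range before filtering:
    a species whose optimum lies beyond the sampled gradient responds
    like a species optimal at the nearest transect end, so every
    species has at least one climatically suitable site.
    """
    axis = latent_axis(config)
    opt = np.array([niches[lbl] for lbl in tree.tip_labels])
    opt = np.clip(opt, axis.min(), axis.max())
    p = np.exp(-((opt[:, None] - axis[None, :]) ** 2) / (2.0 * config.filtering_sd**2))
    b = config.deep_pool_bias
    if b > 0:
        clade_a, _ = _basal_clades(tree)
        pos = np.arange(config.n_sites) / (config.n_sites - 1)  # 0..1 along transect
        in_a = np.array([lbl in clade_a for lbl in tree.tip_labels])
        w_a = (1.0 - b) + b * (1.0 - pos)  # clade A favoured at the x=0 end
        w_b = (1.0 - b) + b * pos
        p = p * np.where(in_a[:, None], w_a[None, :], w_b[None, :])
    return p


def simulate_occurrence(
    tree: UltrametricTree,
    niches: dict[str, float],
    sites: SiteTable,
    config: ScenarioConfig,
    seed: int | None = None,
    max_retries: int = 100,
) -> OccurrenceTable:
    """Bernoulli occupancy draws; empty species and sites are redrawn.

    Empty species' rows and empty sites' columns are redrawn in
    alternating passes (up to ``max_retries``), which amounts to
    conditioning the table on every species and site being recorded at
    least once — an occurrence compilation, like a real one, only
    contains species and sites with at least one record.  Persistent
    failure (a site climatically out of reach of every species in this
    realisation) suggests a larger niche breadth ``filtering_sd``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    p = occupancy_probabilities(tree, niches, config)
    if p.shape[1] != len(sites.site_ids):
        raise ValidationError("site table does not match config.n_sites")
    draw = (rng.random(p.shape) < p).astype(np.int8)
    for _ in range(max_retries):
        empty_rows = np.flatnonzero(draw.sum(axis=1) == 0)
        for s in empty_rows:
            draw[s] = (rng.random(p.shape[1]) < p[s]).astype(np.int8)
        empty_cols = np.flatnonzero(draw.sum(axis=0) == 0)
        for k in empty_cols:
            draw[:, k] = (rng.random(p.shape[0]) < p[:, k]).astype(np.int8)
        if (draw.sum(axis=1) > 0).all() and (draw.sum(axis=0) > 0).all():
            df = pd.DataFrame(
                draw.T, index=pd.Index(sites.site_ids, name="site_id"),
                columns=tree.tip_labels,
            )
            return OccurrenceTable(df)
    still_empty = [tree.tip_labels[s] for s in np.flatnonzero(draw.sum(axis=1) == 0)]
    still_empty += [sites.site_ids[k] for k in np.flatnonzero(draw.sum(axis=0) == 0)]
    raise ValidationError(
        f"empty species/sites persist after {max_retries} redraw passes "
        f"({still_empty[:5]}); consider a larger filtering_sd (now {config.filtering_sd})"
    )


PRESETS = {
    # single species pool, strong niche conservatism, 36 sites
    "latitudinal-like": ScenarioConfig(n_sites=36, niche_conservatism=1.0, deep_pool_bias=0.0),
    # two basal pools biased to opposite ends, 34 sites
    "longitudinal-like": ScenarioConfig(n_sites=34, niche_conservatism=1.0, deep_pool_bias=0.8),
}


def make_scenario(
    preset: str, seed: int = 0, **overrides
) -> tuple[UltrametricTree, OccurrenceTable, SiteTable, ScenarioConfig]:
    """Deterministic (tree, occurrence, sites) bundle for a named preset."""
    if preset not in PRESETS:
        raise ValidationError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    config = replace(PRESETS[preset], seed=seed, **overrides)
    s_tree, s_niche, s_trans, s_occ = _child_seeds(seed, 4)
    tree = simulate_tree(config.n_species, config.root_age, seed=s_tree)
    niches = simulate_niches(tree, config.niche_conservatism, seed=s_niche)
    sites = simulate_transect(config, seed=s_trans)
    occ = simulate_occurrence(tree, niches, sites, config, seed=s_occ)
    return tree, occ, sites, config
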