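"""Geographic and climatic distances between sites.

Geographic distance is the planar Euclidean distance (km) between site
midpoints (coordinates are assumed already projected).  Climatic
distance is the Euclidean distance over the six bioclimatic variables,
by default after per-column standardisation (z-scores) so that
precipitation's large numeric range does not dominate; a flag restores
raw-scale distances.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.spatial.distance import pdist

from .errors import ValidationError
from .beta_div import PairDistanceVector
from .phylo_io import CLIMATE_COLUMNS, SiteTable

logger = logging.getLogger(__name__)


def geographic_distance(sites: SiteTable) -> PairDistanceVector:
    """Euclidean distance (km) between site midpoints, condensed form."""
    xy = sites.coordinates()
    values = pdist(xy, metric="euclidean")
    if np.any(values == 0):
        logger.warning("some site pairs have identical midpoints (distance 0)")
    return PairDistanceVector(tuple(sites.site_ids), values)


def climate_distance(sites: SiteTable, standardize: bool = True) -> PairDistanceVector:
    """Euclidean distance over the six climate variables per site pair."""
    clim = sites.climate().to_numpy(dtype=float)
    if clim.shape[1] != len(CLIMATE_COLUMNS):
        raise ValidationError(f"expected {len(CLIMATE_COLUMNS)} climate columns")
    if standardize:
        sd = clim.std(axis=0, ddof=1)
        dead = [CLIMATE_COLUMNS[k] for k in np.flatnonzero(sd == 0)]
        if dead:
            raise ValidationError(f"zero-variance climate column(s): {dead}")
        clim = (clim - clim.mean(axis=0)) / sd
    values = pdist(clim, metric="euclidean")
    return PairDistanceVector(tuple(sites.site_ids), values)


def rescale01(v: PairDistanceVector) -> PairDistanceVector:
    """Min-max rescale to [0, 1]; rank statistics are unaffected."""
    lo, hi = float(v.values.min()), float(v.values.max())
    if hi == lo:
        raise ValidationError("cannot rescale a constant distance vector")
    return PairDistanceVector(v.site_ids, (v.values - lo) / (hi - lo))
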