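"""Alpha diversity, Bray-Curtis dissimilarity, geographic distance and
distance-decay relationships.

Shannon entropy is reported in nats; Chao1 uses the bias-corrected
estimator so it is defined when no doubletons are observed.  The
distance-decay relationship (DDR) is the ordinary least-squares slope of
community similarity (1 - Bray-Curtis) against between-site geographic
distance, with a Mantel-style permutation p-value alongside the
parametric one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy import stats

__all__ = [
    "shannon",
    "chao1",
    "alpha_diversity",
    "bray_curtis",
    "haversine_km",
    "geographic_distance_matrix",
    "distance_decay",
    "DdrResult",
]

EARTH_RADIUS_KM = 6371.0


def shannon(counts) -> float:
    """Shannon entropy H = -sum(p ln p) over nonzero proportions, in nats."""
    c = np.asarray(counts, dtype=float)
    if c.sum() <= 0:
        raise ValueError("empty sample")
    p = c[c > 0] / c.sum()
    return float(-(p * np.log(p)).sum())


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1) / (2 (F2+1))."""
    c = np.asarray(counts)
    if not np.issubdtype(c.dtype, np.integer):
        if not np.allclose(c, np.round(c)):
            raise ValueError("chao1 requires integer counts")
        c = np.round(c).astype(np.int64)
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def alpha_diversity(table) -> pd.DataFrame:
    """Per-sample Shannon (nats) and Chao1 estimates."""
    counts = table.counts if hasattr(table, "counts") else pd.DataFrame(table)
    return pd.DataFrame(
        {
            "shannon": [shannon(row) for _, row in counts.iterrows()],
            "chao1": [chao1(row.to_numpy()) for _, row in counts.iterrows()],
        },
        index=counts.index,
    )


def bray_curtis(table) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities between samples.

    Accepts an OtuTable, relative-abundance DataFrame or array; returns
    a labeled symmetric matrix with zero diagonal.
    """
    counts = table.counts if hasattr(table, "counts") else pd.DataFrame(table)
    if counts.shape[0] < 2:
        raise ValueError("need at least two samples")
    d = squareform(pdist(counts.to_numpy(dtype=float), metric="braycurtis"))
    return pd.DataFrame(d, index=counts.index, columns=counts.index)


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km (spherical Earth, radius 6371 km)."""
    for lat in (lat1, lat2):
        if not -90 <= lat <= 90:
            raise ValueError("latitude outside [-90, 90]")
    for lon in (lon1, lon2):
        if not -180 <= lon <= 180:
            raise ValueError("longitude outside [-180, 180]")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def geographic_distance_matrix(metadata: pd.DataFrame) -> pd.DataFrame:
    """Pairwise haversine distances (km) from latitude/longitude columns."""
    lat = metadata["latitude"].to_numpy(dtype=float)
    lon = metadata["longitude"].to_numpy(dtype=float)
    n = len(lat)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = haversine_km(lat[i], lon[i], lat[j], lon[j])
    return pd.DataFrame(d, index=metadata.index, columns=metadata.index)


@dataclass
class DdrResult:
    """Distance-decay regression of similarity on geographic distance."""

    slope: float
    intercept: float
    r_squared: float
    p_parametric: float
    p_permutation: float
    n_pairs: int


def distance_decay(
    similarity: pd.DataFrame,
    geo: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = 0,
) -> DdrResult:
    """OLS of pairwise community similarity against geographic distance.

    ``similarity`` is typically 1 - Bray-Curtis.  The permutation
    p-value shuffles sample labels of the similarity matrix jointly
    (Mantel-style), two-sided on the slope.
    """
    if similarity.shape[0] < 3:
        raise ValueError("need at least three samples")
    sim = similarity.loc[geo.index, geo.index].to_numpy(dtype=float)
    g = geo.to_numpy(dtype=float)
    iu = np.triu_indices(len(g), k=1)
    x, y = g[iu], sim[iu]
    res = stats.linregress(x, y)
    slope_obs = res.slope
    rng = np.random.default_rng(seed)
    n = len(g)
    exceed = 0
    denom = np.sum((x - x.mean()) ** 2)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = sim[np.ix_(perm, perm)][iu]
        b = np.sum((x - x.mean()) * (yp - yp.mean())) / denom
        if abs(b) >= abs(slope_obs):
            exceed += 1
    p_perm = (1 + exceed) / (1 + n_perm)
    return DdrResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_parametric=float(res.pvalue),
        p_permutation=float(p_perm),
        n_pairs=len(x),
    )
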