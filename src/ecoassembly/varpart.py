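"""Spatial eigenvectors, distance-based RDA and variation partitioning.

PCNM (principal coordinates of neighbor matrices) turns the between-site
geographic distance matrix into orthogonal spatial predictors: distances
beyond the truncation threshold t (the longest edge of the minimum
spanning tree) are replaced by 4t, the truncated matrix is
double-centered and eigen-decomposed, and the positive-eigenvalue axes
(scaled by sqrt(eigenvalue)) describe spatial structure from broad to
fine scale.

dbRDA regresses the principal coordinates of a community dissimilarity
matrix on explanatory variables; the fraction of total inertia captured
is adjusted with Ezekiel's formula, 1 - (1 - R^2)(n - 1)/(n - p - 1).
Negative PCoA eigenvalues are discarded (no Lingoes/Cailliez
correction).

Variation partitioning decomposes community variation among three
predictor sets (typically soil chemistry, climate, and PCNM spatial
axes) into seven fractions by inclusion-exclusion on the adjusted R^2
of the seven subset models; pure fractions may be slightly negative and
are reported as-is (interpret as zero).

NMDS with environmental vector fitting mirrors the usual ordination
workflow: non-metric MDS on the dissimilarity matrix, then per-variable
squared multiple correlation with the site scores and a permutation
p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import minimum_spanning_tree
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import MDS

__all__ = [
    "PcnmBasis",
    "pcnm",
    "dbrda_adjusted_r2",
    "dbrda_permutation_p",
    "forward_select",
    "VarPartResult",
    "variation_partition",
    "OrdinationFit",
    "nmds_envfit",
]


# ---------------------------------------------------------------------------
# PCNM


@dataclass
class PcnmBasis:
    vectors: pd.DataFrame  # sites x positive axes, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray
    truncation: float


def pcnm(geo: pd.DataFrame, eps: float = 1e-9) -> PcnmBasis:
    """Positive spatial eigenvectors of the truncated distance matrix."""
    D = geo.to_numpy(dtype=float)
    n = D.shape[0]
    if n < 3:
        raise ValueError("need at least 3 sites")
    mst = minimum_spanning_tree(D).toarray()
    t = float(mst.max())
    if t <= 0:
        raise ValueError("duplicate coordinates: truncation distance is 0")
    Dt = np.where(D > t, 4.0 * t, D)
    np.fill_diagonal(Dt, 0.0)
    A = -0.5 * Dt**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > eps * vals.max()
    vals, vecs = vals[pos], vecs[:, pos]
    axes = vecs * np.sqrt(vals)
    cols = [f"pcnm{i+1}" for i in range(axes.shape[1])]
    return PcnmBasis(
        vectors=pd.DataFrame(axes, index=geo.index, columns=cols),
        eigenvalues=vals,
        truncation=t,
    )


# ---------------------------------------------------------------------------
# dbRDA


def _pcoa_coords(dist: pd.DataFrame, eps: float = 1e-9) -> np.ndarray:
    D = dist.to_numpy(dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > eps * max(vals.max(), 1.0)
    return vecs[:, pos] * np.sqrt(vals[pos])


def _r2_from_coords(Y: np.ndarray, X: np.ndarray) -> float:
    """Constrained / total inertia of centered site scores on predictors."""
    Yc = Y - Y.mean(axis=0)
    total = float((Yc**2).sum())
    if X.shape[1] == 0 or total == 0:
        return 0.0
    Xc = np.column_stack([np.ones(len(Y)), X])
    beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    fitted = Xc @ beta
    return float((fitted**2).sum() / total)


def _ezekiel(r2: float, n: int, p: int) -> float:
    if p == 0:
        return 0.0
    if n - p - 1 <= 0:
        raise ValueError("too few samples for the number of predictors")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def dbrda_adjusted_r2(response_dist: pd.DataFrame, predictors: pd.DataFrame | None):
    """Ezekiel-adjusted R^2 of a dbRDA of the dissimilarity matrix.

    Returns ``(adjusted R^2, raw R^2, n_predictors)``.  ``predictors``
    with zero columns (or None) give R^2 = 0.
    """
    Y = _pcoa_coords(response_dist)
    if predictors is None or predictors.shape[1] == 0:
        return 0.0, 0.0, 0
    X = predictors.loc[response_dist.index].to_numpy(dtype=float)
    p = int(np.linalg.matrix_rank(X - X.mean(axis=0)))
    if p < X.shape[1]:
        raise ValueError("rank-deficient predictor set")
    r2 = _r2_from_coords(Y, X)
    return _ezekiel(r2, len(Y), p), r2, p


def dbrda_permutation_p(
    response_dist: pd.DataFrame,
    predictors: pd.DataFrame,
    n_perm: int = 199,
    seed: int = 0,
    condition: pd.DataFrame | None = None,
) -> float:
    """Permutation p-value for the (partial) dbRDA R^2.

    Permutes sample rows of ``predictors``; when ``condition`` is given
    the statistic is the R^2 gain over the conditioned model.
    """
    Y = _pcoa_coords(response_dist)
    X = predictors.loc[response_dist.index].to_numpy(dtype=float)
    if condition is not None and condition.shape[1] > 0:
        C = condition.loc[response_dist.index].to_numpy(dtype=float)
        base = _r2_from_coords(Y, C)
        stat = _r2_from_coords(Y, np.column_stack([C, X])) - base
    else:
        C = None
        stat = _r2_from_coords(Y, X)
    rng = np.random.default_rng(seed)
    exceed = 0
    n = len(Y)
    for _ in range(n_perm):
        Xp = X[rng.permutation(n)]
        if C is not None:
            s = _r2_from_coords(Y, np.column_stack([C, Xp])) - _r2_from_coords(Y, C)
        else:
            s = _r2_from_coords(Y, Xp)
        exceed += s >= stat
    return (1 + exceed) / (1 + n_perm)


def forward_select(
    response_dist: pd.DataFrame,
    candidates: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 199,
    seed: int = 0,
) -> list[str]:
    """Greedy forward selection with the double stopping criterion.

    At each step the candidate giving the largest adjusted-R^2 gain is
    tested by permutation; selection stops when that candidate's p is
    not below ``alpha`` or when the cumulative adjusted R^2 would
    exceed the full model's adjusted R^2.
    """
    if candidates.shape[1] == 0:
        raise ValueError("no candidate variables")
    cand = candidates.loc[response_dist.index]
    try:
        r2_full, _, _ = dbrda_adjusted_r2(response_dist, cand)
    except ValueError:  # collinear full set: bound by best achievable
        r2_full = np.inf
    selected: list[str] = []
    remaining = list(cand.columns)
    rng = np.random.default_rng(seed)
    current_adj = 0.0
    while remaining:
        best, best_adj = None, current_adj
        for v in remaining:
            cols = selected + [v]
            try:
                adj, _, _ = dbrda_adjusted_r2(response_dist, cand[cols])
            except ValueError:
                continue
            if adj > best_adj:
                best, best_adj = v, adj
        if best is None:
            break
        # the full-model bound guards against accumulation of spurious
        # gains; it is not applied to the first variable, where sampling
        # noise in the Ezekiel penalty can put a single strong predictor
        # above the noise-diluted full model
        if selected and best_adj > r2_full + 1e-12:
            break
        cond = cand[selected] if selected else None
        p = dbrda_permutation_p(
            response_dist,
            cand[[best]],
            n_perm=n_perm,
            seed=int(rng.integers(2**31 - 1)),
            condition=cond,
        )
        if p >= alpha:
            break
        selected.append(best)
        remaining.remove(best)
        current_adj = best_adj
    return selected


# ---------------------------------------------------------------------------
# variation partitioning


@dataclass
class VarPartResult:
    """Seven variation fractions for three predictor sets plus residual.

    Keys of ``fractions``: pure_<name> for each set, shared_<a>_<b> for
    pairwise overlaps (excluding the third), shared_all, residual.
    ``totals`` holds the adjusted R^2 of each single set and the full
    model.
    """

    fractions: dict[str, float]
    totals: dict[str, float]
    set_names: tuple[str, str, str]

    def pure(self, name: str) -> float:
        return self.fractions[f"pure_{name}"]


def variation_partition(
    response_dist: pd.DataFrame,
    sets: dict[str, pd.DataFrame],
) -> VarPartResult:
    """Partition community variation among three predictor sets.

    Each value of ``sets`` is a DataFrame of (already forward-selected)
    predictors; an empty DataFrame contributes zero with a warning.
    Fractions are derived by inclusion-exclusion from the adjusted R^2
    of the seven subset models and reconstruct each set's total
    exactly.
    """
    if len(sets) != 3:
        raise ValueError("variation_partition expects exactly three predictor sets")
    names = tuple(sets)
    frames = {}
    for k, df in sets.items():
        if df is None or df.shape[1] == 0:
            warnings.warn(f"predictor set {k!r} is empty; contributes 0")
            frames[k] = pd.DataFrame(index=response_dist.index)
        else:
            frames[k] = df.loc[response_dist.index]

    def adj(keys) -> float:
        X = pd.concat([frames[k] for k in keys], axis=1)
        if X.shape[1] == 0:
            return 0.0
        # sets may overlap (shared or duplicated variables): keep a
        # maximal linearly independent column subset
        arr = X.to_numpy(dtype=float)
        arr = arr - arr.mean(axis=0)
        keep = []
        for j in range(arr.shape[1]):
            cand = arr[:, keep + [j]]
            if np.linalg.matrix_rank(cand) == len(keep) + 1:
                keep.append(j)
        return dbrda_adjusted_r2(response_dist, X.iloc[:, keep])[0]

    A, B, C = names
    rA, rB, rC = adj([A]), adj([B]), adj([C])
    rAB, rAC, rBC = adj([A, B]), adj([A, C]), adj([B, C])
    rABC = adj([A, B, C])
    a = rABC - rBC
    b = rABC - rAC
    c = rABC - rAB
    g = rA + rB + rC - rAB - rAC - rBC + rABC
    df_sum = rA - a - g  # d + f
    de_sum = rB - b - g  # d + e
    ef_sum = rC - c - g  # e + f
    d = (df_sum + de_sum - ef_sum) / 2
    e = de_sum - d
    f = df_sum - d
    fractions = {
        f"pure_{A}": a,
        f"pure_{B}": b,
        f"pure_{C}": c,
        f"shared_{A}_{B}": d,
        f"shared_{B}_{C}": e,
        f"shared_{A}_{C}": f,
        "shared_all": g,
        "residual": 1.0 - rABC,
    }
    totals = {A: rA, B: rB, C: rC, "full": rABC}
    return VarPartResult(fractions=fractions, totals=totals, set_names=names)


# ---------------------------------------------------------------------------
# NMDS + envfit


@dataclass
class OrdinationFit:
    coordinates: pd.DataFrame
    stress: float  # Kruskal stress-1
    envfit: pd.DataFrame = field(default=None)  # variable, r2, p, key


def _stress1(dissim: np.ndarray, emb: np.ndarray) -> float:
    iu = np.triu_indices(len(emb), k=1)
    d_obs = dissim[iu]
    e = np.sqrt(((emb[:, None, :] - emb[None, :, :]) ** 2).sum(axis=2))[iu]
    iso = IsotonicRegression()
    dhat = iso.fit_transform(d_obs, e)
    denom = float((e**2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((e - dhat) ** 2).sum() / denom))


def nmds_envfit(
    response_dist: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    variables=None,
    k: int = 2,
    n_restarts: int = 20,
    n_perm: int = 999,
    seed: int = 0,
    r2_key: float = 0.2,
    p_key: float = 0.01,
    collinearity_rho: float = 0.7,
) -> OrdinationFit:
    """Non-metric MDS with environmental vector fitting.

    Variables with pairwise |Spearman rho| above ``collinearity_rho``
    are pre-filtered (first kept wins).  Per retained variable, R^2 is
    the squared multiple correlation with the site scores; p permutes
    the variable's values.  ``key`` flags variables with R^2 > 0.2 and
    p < 0.01.
    """
    n = response_dist.shape[0]
    if n < k + 2:
        raise ValueError("too few samples for the requested dimensionality")
    D = response_dist.to_numpy(dtype=float)
    mds = MDS(
        n_components=k,
        metric=False,
        dissimilarity="precomputed",
        n_init=n_restarts,
        max_iter=300,
        eps=1e-6,
        random_state=seed,
        normalized_stress=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        emb = mds.fit_transform(D)
    coords = pd.DataFrame(
        emb, index=response_dist.index, columns=[f"nmds{i+1}" for i in range(k)]
    )
    stress = _stress1(D, emb)
    fit = OrdinationFit(coordinates=coords, stress=stress)
    if metadata is None:
        return fit
    variables = list(variables) if variables is not None else list(metadata.columns)
    md = metadata.loc[response_dist.index, variables].astype(float)
    # collinearity pre-filter
    kept: list[str] = []
    for v in variables:
        if all(
            abs(stats.spearmanr(md[v], md[w]).statistic) <= collinearity_rho for w in kept
        ):
            kept.append(v)
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), emb])
    rows = []
    for v in kept:
        y = md[v].to_numpy()
        ss_tot = ((y - y.mean()) ** 2).sum()
        if ss_tot == 0:
            continue
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r2 = 1 - (((y - X @ beta) ** 2).sum() / ss_tot)
        exceed = 0
        for _ in range(n_perm):
            yp = y[rng.permutation(n)]
            bp, *_ = np.linalg.lstsq(X, yp, rcond=None)
            exceed += (1 - ((yp - X @ bp) ** 2).sum() / ss_tot) >= r2
        p = (1 + exceed) / (1 + n_perm)
        rows.append({"variable": v, "r2": float(r2), "p": float(p)})
    env = pd.DataFrame(rows)
    if len(env):
        env["key"] = (env["r2"] > r2_key) & (env["p"] < p_key)
    fit.envfit = env
    return fit
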