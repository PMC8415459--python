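"""Distance-matrix statistics: Mantel, partial Mantel, Mantel
correlograms and multiple regression on distance matrices (MRM).

All tests operate on labeled symmetric matrices (pandas DataFrames) and
draw permutation inference by shuffling sample labels jointly on rows
and columns, which respects the dependence structure among the n(n-1)/2
pairwise entries.  Permutation p-values use the add-one convention
p = (1 + #exceedances) / (1 + n_perm), so p is never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MantelResult",
    "CorrelogramClass",
    "MrmResult",
    "mantel",
    "partial_mantel",
    "mantel_correlogram",
    "mrm",
    "mrm_two_stage",
]


def _aligned_square(mats):
    """Align matrices on the first one's labels; return float arrays."""
    ref = mats[0]
    labels = list(ref.index)
    out = []
    for m in mats:
        m = m.loc[labels, labels]
        out.append(m.to_numpy(dtype=float))
    return out, labels


def _condensed(a: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(a.shape[0], k=1)
    return a[iu]


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("correlation undefined for constant matrix")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    method: str = "pearson"


def mantel(
    dA: pd.DataFrame,
    dB: pd.DataFrame,
    n_perm: int = 999,
    method: str = "pearson",
    seed: int | None = 0,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel test of matrix correlation between two distance matrices.

    The observed statistic is the correlation of the unfolded upper
    triangles; the null permutes rows and columns of ``dB`` jointly.
    ``alternative='greater'`` is the classical one-sided test.
    """
    (a, b), _ = _aligned_square([dA, dB])
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)
    xa = a[iu]
    r_obs = _corr(xa, b[iu], method)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = _corr(xa, b[np.ix_(perm, perm)][iu], method)
        if alternative == "greater":
            exceed += r_p >= r_obs
        elif alternative == "two-sided":
            exceed += abs(r_p) >= abs(r_obs)
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
    return MantelResult(r=r_obs, p=(1 + exceed) / (1 + n_perm), n_perm=n_perm, method=method)


def _residualize(y: np.ndarray, controls: np.ndarray) -> np.ndarray:
    """Residuals of y after OLS on controls (with intercept)."""
    X = np.column_stack([np.ones(len(y)), controls])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def partial_mantel(
    dA: pd.DataFrame,
    dB: pd.DataFrame,
    *controls: pd.DataFrame,
    n_perm: int = 999,
    method: str = "pearson",
    seed: int | None = 0,
) -> MantelResult:
    """Partial Mantel correlation of dA and dB controlling for one or
    more further distance matrices.

    Both dA and dB are residualized on the controls; the permutation
    null shuffles dB's labels and re-residualizes.
    """
    if not controls:
        raise ValueError("partial Mantel needs at least one control matrix")
    mats, _ = _aligned_square([dA, dB, *controls])
    a, b = mats[0], mats[1]
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)
    C = np.column_stack([m[iu] for m in mats[2:]])
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(C)), C])) < C.shape[1] + 1:
        raise ValueError("collinear control matrices")
    if method == "spearman":
        ra = stats.rankdata(a[iu])
        Cr = np.column_stack([stats.rankdata(c) for c in C.T])
    else:
        ra, Cr = a[iu], C
    res_a = _residualize(ra, Cr)

    def partial_r(bmat):
        xb = b_tri = bmat[iu]
        if method == "spearman":
            xb = stats.rankdata(b_tri)
        res_b = _residualize(xb, Cr)
        if res_a.std() == 0 or res_b.std() == 0:
            raise ValueError("partial correlation undefined (constant residuals)")
        return float(np.corrcoef(res_a, res_b)[0, 1])

    r_obs = partial_r(b)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        exceed += partial_r(b[np.ix_(perm, perm)]) >= r_obs
    return MantelResult(r=r_obs, p=(1 + exceed) / (1 + n_perm), n_perm=n_perm, method=method)


@dataclass
class CorrelogramClass:
    lower: float
    upper: float
    midpoint: float
    n_pairs: int
    r: float
    p: float
    p_holm: float
    significant: bool


def mantel_correlogram(
    dA: pd.DataFrame,
    dB: pd.DataFrame,
    n_classes: int | None = None,
    n_perm: int = 999,
    seed: int | None = 0,
    alpha: float = 0.05,
    convention: str = "association",
) -> list[CorrelogramClass]:
    """Mantel correlogram of dA across distance classes of dB.

    Classes partition [min, max] of dB's off-diagonal values into
    equal-width bins (Sturges' rule when ``n_classes`` is None).  The
    per-class statistic is the Mantel correlation between dA and the
    binary membership-indicator matrix of the class.  Two sign
    conventions are in use in the field: ``association`` (default)
    reports the correlation directly, so a positive r means dA is
    elevated among pairs in that class; ``autocorrelation`` negates it,
    so that small dA within a class (similar values, as in
    phylogenetic-signal tests) reads as positive, like an
    autocorrelation function.  Holm correction is applied across
    classes.
    """
    if convention not in ("association", "autocorrelation"):
        raise ValueError(f"unknown convention {convention!r}")
    flip = -1.0 if convention == "autocorrelation" else 1.0
    (a, b), _ = _aligned_square([dA, dB])
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)
    xa, xb = a[iu], b[iu]
    n_pairs = len(xb)
    if n_classes is None:
        n_classes = int(np.ceil(1 + np.log2(n_pairs)))
    edges = np.linspace(xb.min(), xb.max(), n_classes + 1)
    rng = np.random.default_rng(seed)
    results = []
    for k in range(n_classes):
        lo, hi = edges[k], edges[k + 1]
        if k < n_classes - 1:
            member = (b >= lo) & (b < hi)
        else:
            member = (b >= lo) & (b <= hi)
        np.fill_diagonal(member, False)
        m_tri = member[iu].astype(float)
        npairs = int(m_tri.sum())
        if npairs < 2:
            raise ValueError(f"distance class {k} has fewer than 2 pairs")
        r_obs = flip * _corr(xa, m_tri, "pearson")
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            m_p = member[np.ix_(perm, perm)][iu].astype(float)
            exceed += flip * _corr(xa, m_p, "pearson") >= r_obs
        p = (1 + exceed) / (1 + n_perm)
        results.append(
            CorrelogramClass(
                lower=float(lo),
                upper=float(hi),
                midpoint=float((lo + hi) / 2),
                n_pairs=npairs,
                r=r_obs,
                p=p,
                p_holm=np.nan,
                significant=False,
            )
        )
    # Holm step-down across classes
    ps = np.array([c.p for c in results])
    order = np.argsort(ps)
    m = len(ps)
    holm = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        adj = (m - rank) * ps[idx]
        running = max(running, adj)
        holm[idx] = min(1.0, running)
    for c, ph in zip(results, holm):
        c.p_holm = float(ph)
        c.significant = bool(ph < alpha)
    return results


@dataclass
class MrmResult:
    coefficients: dict[str, float]
    coefficient_p: dict[str, float]
    r_squared: float
    f_p: float
    n_perm: int
    predictors: list[str] = field(default_factory=list)


def mrm(
    response: pd.DataFrame,
    predictors: dict[str, pd.DataFrame],
    n_perm: int = 999,
    seed: int | None = 0,
) -> MrmResult:
    """Multiple regression on distance matrices.

    OLS of the unfolded response triangle on the predictor triangles;
    p-values by jointly permuting the response matrix's rows/columns,
    two-sided on |coefficient| and one-sided on R^2.
    """
    names = list(predictors)
    mats, _ = _aligned_square([response, *predictors.values()])
    y_sq, preds = mats[0], mats[1:]
    n = y_sq.shape[0]
    iu = np.triu_indices(n, k=1)
    X = np.column_stack([np.ones(len(iu[0]))] + [p[iu] for p in preds])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("perfectly collinear predictor matrices")

    XtX_inv_Xt = np.linalg.pinv(X)

    def fit(yvec):
        beta = XtX_inv_Xt @ yvec
        resid = yvec - X @ beta
        ss_tot = np.sum((yvec - yvec.mean()) ** 2)
        r2 = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else 0.0
        return beta, r2

    y = y_sq[iu]
    beta_obs, r2_obs = fit(y)
    rng = np.random.default_rng(seed)
    exceed_b = np.zeros(len(beta_obs))
    exceed_r2 = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        beta_p, r2_p = fit(y_sq[np.ix_(perm, perm)][iu])
        exceed_b += np.abs(beta_p) >= np.abs(beta_obs)
        exceed_r2 += r2_p >= r2_obs
    p_b = (1 + exceed_b) / (1 + n_perm)
    return MrmResult(
        coefficients=dict(zip(names, beta_obs[1:])),
        coefficient_p=dict(zip(names, p_b[1:])),
        r_squared=float(r2_obs),
        f_p=float((1 + exceed_r2) / (1 + n_perm)),
        n_perm=n_perm,
        predictors=names,
    )


def mrm_two_stage(
    response: pd.DataFrame,
    predictors: dict[str, pd.DataFrame],
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int | None = 0,
) -> tuple[MrmResult, MrmResult | None]:
    """MRM on all predictors, then refit keeping only those with p < alpha.

    Returns (stage-1 result, stage-2 result); stage 2 is None when no
    predictor survives.
    """
    stage1 = mrm(response, predictors, n_perm=n_perm, seed=seed)
    kept = {k: predictors[k] for k, p in stage1.coefficient_p.items() if p < alpha}
    if not kept:
        return stage1, None
    stage2 = mrm(response, kept, n_perm=n_perm, seed=seed)
    return stage1, stage2
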