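"""Threshold indicator taxa analysis (TITAN).

For every taxon, candidate change points along an environmental
gradient split the samples into a low and a high group; the indicator
value (IndVal) of each group is the product of group-equalized relative
abundance and relative frequency, scaled to 100.  The taxon's change
point is the candidate maximizing IndVal, its direction z- (decreaser,
indicator of the low side) or z+ (increaser) the side achieving that
maximum.  A permutation null (shuffling the gradient) standardizes the
observed IndVal into a z-score, and bootstrap resampling of samples
yields purity (fraction of bootstraps agreeing in direction) and
reliability (fraction with permutation p <= 0.05).  Taxa passing purity
and reliability filters (default 0.95 each) are summed: the community
sum(z-) and sum(z+) curves across candidates peak at the lower and
upper community-level thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "candidate_change_points",
    "TitanTaxonResult",
    "taxon_titan",
    "titan_all_taxa",
    "TitanCommunityResult",
    "community_thresholds",
]


def candidate_change_points(gradient, min_side: int = 5) -> np.ndarray:
    """Unique sorted gradient values leaving >= min_side samples on
    each side (left group is x <= candidate, right group is x > candidate)."""
    x = np.asarray(gradient, dtype=float)
    if len(x) < 2 * min_side:
        raise ValueError("too few samples for the requested min_side")
    out = []
    for v in np.unique(x):
        if (x <= v).sum() >= min_side and (x > v).sum() >= min_side:
            out.append(v)
    return np.asarray(out)


def _indval_maxima(A: np.ndarray, x_sorted: np.ndarray, boundaries: np.ndarray):
    """IndVal maxima over candidates for both directions, vectorized.

    A: (B, n) abundance rows already arranged in gradient-sorted order.
    boundaries: left-group sizes per candidate (1..n-1).
    Returns (max_left, max_right, argmax_left, argmax_right) each (B,).
    """
    n = A.shape[1]
    csum = np.cumsum(A, axis=1)
    cpres = np.cumsum(A > 0, axis=1)
    tot = csum[:, -1][:, None]
    totp = cpres[:, -1][:, None]
    nl = boundaries[None, :].astype(float)
    nr = n - nl
    sl = csum[:, boundaries - 1]
    pl = cpres[:, boundaries - 1]
    mean_l = sl / nl
    mean_r = (tot - sl) / nr
    denom = mean_l + mean_r
    with np.errstate(divide="ignore", invalid="ignore"):
        ra_l = np.where(denom > 0, mean_l / denom, 0.0)
        ra_r = np.where(denom > 0, mean_r / denom, 0.0)
    freq_l = pl / nl
    freq_r = (totp - pl) / nr
    iv_l = 100.0 * ra_l * freq_l
    iv_r = 100.0 * ra_r * freq_r
    return (
        iv_l.max(axis=1),
        iv_r.max(axis=1),
        iv_l.argmax(axis=1),
        iv_r.argmax(axis=1),
    )


def _prepare_sorted(abundance: np.ndarray, gradient: np.ndarray, min_side: int):
    order = np.argsort(gradient, kind="stable")
    x_sorted = gradient[order]
    a_sorted = abundance[order]
    cands = candidate_change_points(gradient, min_side=min_side)
    # left-group size for each candidate (ties included on the left)
    boundaries = np.searchsorted(x_sorted, cands, side="right")
    return a_sorted, x_sorted, cands, boundaries


@dataclass
class TitanTaxonResult:
    taxon: str
    direction: str  # 'z-' decreaser or 'z+' increaser
    change_point: float
    indval: float  # observed IndVal in [0, 100]
    z: float
    p: float
    purity: float
    reliability: float
    filtered: bool


def taxon_titan(
    abundance,
    gradient,
    n_perm: int = 250,
    n_boot: int = 500,
    seed: int = 0,
    min_side: int = 5,
    purity_min: float = 0.95,
    reliability_min: float = 0.95,
    boot_alpha: float = 0.05,
    taxon: str = "",
) -> TitanTaxonResult | None:
    """Change point, z-score, purity and reliability for one taxon.

    Returns None (with a warning) when the permutation null has zero
    spread and the z-score is undefined.
    """
    a = np.asarray(abundance, dtype=float)
    x = np.asarray(gradient, dtype=float)
    if (a > 0).sum() < 3:
        raise ValueError("taxon present in fewer than 3 samples")
    rng = np.random.default_rng(seed)
    a_sorted, x_sorted, cands, bounds = _prepare_sorted(a, x, min_side)

    ml, mr, al, ar = _indval_maxima(a_sorted[None, :], x_sorted, bounds)
    decreaser = ml[0] >= mr[0]
    obs = float(ml[0] if decreaser else mr[0])
    cp = float(cands[al[0] if decreaser else ar[0]])

    perm_idx = np.array([rng.permutation(len(a)) for _ in range(n_perm)])
    ml_p, mr_p, *_ = _indval_maxima(a_sorted[perm_idx], x_sorted, bounds)
    null = ml_p if decreaser else mr_p
    sd = null.std(ddof=1)
    if sd == 0:
        warnings.warn(f"taxon {taxon or '?'}: permutation null has zero spread; excluded")
        return None
    z = (obs - null.mean()) / sd
    # the observed statistic is a maximum over both directions, so the
    # p-value must use the direction-free maximum as the null statistic
    # (a per-direction null would be anticonservative)
    null_free = np.maximum(ml_p, mr_p)
    obs_free = max(float(ml[0]), float(mr[0]))
    p = (1 + (null_free >= obs_free).sum()) / (1 + n_perm)

    same_dir = 0
    reliable = 0
    n = len(a)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        xb, ab = x[idx], a[idx]
        try:
            ab_s, xb_s, cands_b, bounds_b = _prepare_sorted(ab, xb, min_side)
        except ValueError:  # too few distinct values on one side
            continue
        mlb, mrb, albb, arbb = _indval_maxima(ab_s[None, :], xb_s, bounds_b)
        dec_b = mlb[0] >= mrb[0]
        same_dir += dec_b == decreaser
        obs_b = max(float(mlb[0]), float(mrb[0]))
        pb_idx = np.array([rng.permutation(n) for _ in range(n_perm)])
        mlbp, mrbp, *_ = _indval_maxima(ab_s[pb_idx], xb_s, bounds_b)
        null_b = np.maximum(mlbp, mrbp)
        p_b = (1 + (null_b >= obs_b).sum()) / (1 + n_perm)
        reliable += p_b <= boot_alpha
    purity = same_dir / n_boot
    reliability = reliable / n_boot
    return TitanTaxonResult(
        taxon=taxon,
        direction="z-" if decreaser else "z+",
        change_point=cp,
        indval=obs,
        z=float(z),
        p=float(p),
        purity=float(purity),
        reliability=float(reliability),
        filtered=bool(purity >= purity_min and reliability >= reliability_min),
    )


def titan_all_taxa(
    table,
    gradient,
    n_perm: int = 250,
    n_boot: int = 500,
    seed: int = 0,
    min_side: int = 5,
    min_occurrence: int = 3,
    **kwargs,
) -> list[TitanTaxonResult]:
    """Run TITAN for every sufficiently occurring taxon in a table."""
    counts = table.counts if hasattr(table, "counts") else pd.DataFrame(table)
    x = np.asarray(gradient, dtype=float)
    rng = np.random.default_rng(seed)
    results = []
    for name in counts.columns:
        a = counts[name].to_numpy(dtype=float)
        if (a > 0).sum() < min_occurrence:
            continue
        res = taxon_titan(
            a,
            x,
            n_perm=n_perm,
            n_boot=n_boot,
            seed=int(rng.integers(2**31 - 1)),
            min_side=min_side,
            taxon=str(name),
            **kwargs,
        )
        if res is not None:
            results.append(res)
    return results


@dataclass
class TitanCommunityResult:
    candidates: np.ndarray
    sum_z_minus: np.ndarray
    sum_z_plus: np.ndarray
    cp_counts_minus: np.ndarray
    cp_counts_plus: np.ndarray
    lower_threshold: float | None  # argmax of sum(z-)
    upper_threshold: float | None  # argmax of sum(z+)


def community_thresholds(
    taxon_results: list[TitanTaxonResult], candidates
) -> TitanCommunityResult:
    """Community-level sum(z-) / sum(z+) curves and their peaks.

    z-scores of filtered taxa are tallied at each taxon's observed
    change point (mapped to the nearest candidate); the lower and upper
    community thresholds are the candidates maximizing sum(z-) and
    sum(z+).
    """
    cands = np.asarray(candidates, dtype=float)
    filtered = [r for r in taxon_results if r.filtered]
    if not filtered:
        warnings.warn("no taxa passed the purity/reliability filters")
        return TitanCommunityResult(
            candidates=cands,
            sum_z_minus=np.zeros(len(cands)),
            sum_z_plus=np.zeros(len(cands)),
            cp_counts_minus=np.zeros(len(cands), dtype=int),
            cp_counts_plus=np.zeros(len(cands), dtype=int),
            lower_threshold=None,
            upper_threshold=None,
        )
    zm = np.zeros(len(cands))
    zp = np.zeros(len(cands))
    cm = np.zeros(len(cands), dtype=int)
    cp_ = np.zeros(len(cands), dtype=int)
    for r in filtered:
        k = int(np.argmin(np.abs(cands - r.change_point)))
        if r.direction == "z-":
            zm[k] += r.z
            cm[k] += 1
        else:
            zp[k] += r.z
            cp_[k] += 1
    lower = float(cands[int(np.argmax(zm))]) if zm.max() > 0 else None
    upper = float(cands[int(np.argmax(zp))]) if zp.max() > 0 else None
    return TitanCommunityResult(
        candidates=cands,
        sum_z_minus=zm,
        sum_z_plus=zp,
        cp_counts_minus=cm,
        cp_counts_plus=cp_,
        lower_threshold=lower,
        upper_threshold=upper,
    )
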