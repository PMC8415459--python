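"""Sloan neutral community model and niche-breadth / dispersal metrics.

The Sloan model predicts the frequency with which a taxon occurs across
local communities from its mean relative abundance in the
metacommunity, with a single free parameter: the migration rate ``m``,
the probability that a death in a local community is replaced by an
immigrant from the metacommunity rather than by local reproduction.
Occurrence frequency is predicted as

    f_pred(p) = 1 - BetaCDF(d; N m p, N m (1 - p))

with N the (mean) number of reads per sample and d the detection limit.
The fit minimizes the sum of squared deviations between observed and
predicted occurrence frequencies; goodness of fit is the generalized
R^2 = 1 - SS_err / SS_total.  A binomial model — local communities as
random N-read subsets of the metacommunity, no free parameters — serves
as the null for AIC comparison: lower AIC for the neutral model implies
dispersal limitation matters.

Niche metrics: Levins niche breadth B = 1 / sum_i P_i^2 (P_i the share
of a taxon's reads found in sample i), its per-sample community mean
Bcom, and a relative community-level dispersal ability D based on the
pairwise shared proportion of reads belonging to taxa common to both
samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .tables import to_relative_abundance

__all__ = [
    "NeutralFit",
    "fit_sloan",
    "fit_sloan_curve",
    "binomial_null_fit",
    "sloan_occurrence",
    "levins_b",
    "niche_breadth_table",
    "community_niche_breadth",
    "dispersal_ability",
]


def _prepare(table, d: float | None):
    rel = to_relative_abundance(table) if hasattr(table, "counts") else pd.DataFrame(table)
    counts = table.counts if hasattr(table, "counts") else rel
    N = float(counts.sum(axis=1).mean())
    if d is None:
        d = 1.0 / N
    p_mean = rel.mean(axis=0)
    f_obs = (counts > 0).mean(axis=0)
    keep = p_mean > 0
    return p_mean[keep].to_numpy(), f_obs[keep].to_numpy(), p_mean.index[keep], N, d


def sloan_occurrence(p_mean: np.ndarray, m: float, N: float, d: float) -> np.ndarray:
    """Predicted occurrence frequency under the neutral model."""
    a = N * m * p_mean
    b = N * m * (1.0 - p_mean)
    return 1.0 - stats.beta.cdf(d, a, b)


def _aic_ls(ss_err: float, n: int, k: int) -> float:
    # least-squares AIC, comparable across models fitted to the same data
    return n * np.log(ss_err / n) + 2 * k


@dataclass
class NeutralFit:
    m: float
    N: float
    d: float
    r_squared: float
    aic_neutral: float
    aic_binomial: float
    per_taxon: pd.DataFrame  # p_mean, f_obs, f_pred_neutral, f_pred_binomial

    @property
    def neutral_preferred(self) -> bool:
        return self.aic_neutral < self.aic_binomial


def binomial_null_fit(table, d: float | None = None):
    """Occurrence prediction for random binomial N-read subsampling.

    f_pred = P(X >= ceil(d N)) for X ~ Binomial(N, p_mean); no free
    parameters (k = 0 in the AIC).
    """
    p_mean, f_obs, taxa, N, d = _prepare(table, d)
    thresh = int(np.ceil(d * N))
    f_pred = 1.0 - stats.binom.cdf(thresh - 1, int(round(N)), p_mean)
    ss_err = float(np.sum((f_obs - f_pred) ** 2))
    aic = _aic_ls(ss_err, len(f_obs), k=0)
    return pd.Series(f_pred, index=taxa), aic


def fit_sloan_curve(p_mean, f_obs, N: float, d: float, m_bounds=(1e-6, 1.0)):
    """Least-squares fit of m on (mean abundance, occurrence) pairs.

    Returns ``(m, generalized R^2, SS_err)``.  Exposed separately so the
    curve inversion can be validated against exactly model-generated
    occurrence frequencies.
    """
    p_mean = np.asarray(p_mean, dtype=float)
    f_obs = np.asarray(f_obs, dtype=float)

    def sse(m):
        return np.sum((f_obs - sloan_occurrence(p_mean, m, N, d)) ** 2)

    res = optimize.minimize_scalar(sse, bounds=m_bounds, method="bounded")
    if not res.success:
        raise RuntimeError(f"Sloan fit did not converge: {res.message}")
    m_hat = float(res.x)
    ss_err = float(sse(m_hat))
    ss_tot = float(np.sum((f_obs - f_obs.mean()) ** 2))
    return m_hat, 1.0 - ss_err / ss_tot, ss_err


def fit_sloan(table, d: float | None = None, m_bounds=(1e-6, 1.0)) -> NeutralFit:
    """Fit the Sloan neutral model by least squares over m.

    ``d`` defaults to 1/N (one read at mean depth).  Raises if fewer
    than 10 taxa have nonzero mean abundance.
    """
    p_mean, f_obs, taxa, N, d = _prepare(table, d)
    if len(p_mean) < 10:
        raise ValueError("need at least 10 taxa with nonzero mean abundance")
    m_hat, r2, ss_err = fit_sloan_curve(p_mean, f_obs, N, d, m_bounds)
    f_pred = sloan_occurrence(p_mean, m_hat, N, d)
    f_binom, aic_binom = binomial_null_fit(table, d=d)
    per_taxon = pd.DataFrame(
        {
            "p_mean": p_mean,
            "f_obs": f_obs,
            "f_pred_neutral": f_pred,
            "f_pred_binomial": f_binom.reindex(taxa).to_numpy(),
        },
        index=taxa,
    )
    return NeutralFit(
        m=m_hat,
        N=N,
        d=d,
        r_squared=r2,
        aic_neutral=_aic_ls(ss_err, len(f_obs), k=1),
        aic_binomial=aic_binom,
        per_taxon=per_taxon,
    )


# ---------------------------------------------------------------------------
# niche breadth and dispersal ability


def levins_b(taxon_counts) -> float:
    """Levins niche breadth B = 1 / sum_i P_i^2 across samples."""
    c = np.asarray(taxon_counts, dtype=float)
    tot = c.sum()
    if tot <= 0:
        raise ValueError("taxon absent from all samples")
    p = c / tot
    return float(1.0 / np.sum(p**2))


def niche_breadth_table(table) -> pd.Series:
    """Levins B for every taxon (zero-total taxa excluded)."""
    counts = table.counts if hasattr(table, "counts") else pd.DataFrame(table)
    totals = counts.sum(axis=0)
    nz = totals.index[totals > 0]
    p = counts[nz] / totals[nz]
    return 1.0 / (p**2).sum(axis=0)


def community_niche_breadth(table, weighted: bool = False) -> pd.Series:
    """Per-sample community niche breadth Bcom.

    Default is the unweighted mean of Levins B over taxa present in the
    sample; ``weighted=True`` weights by the sample's relative
    abundances.
    """
    counts = table.counts if hasattr(table, "counts") else pd.DataFrame(table)
    B = niche_breadth_table(table)
    out = {}
    for s, row in counts.iterrows():
        present = row.index[(row > 0) & row.index.isin(B.index)]
        if len(present) == 0:
            raise ValueError(f"sample {s!r} is empty")
        if weighted:
            w = row[present] / row[present].sum()
            out[s] = float((B[present] * w).sum())
        else:
            out[s] = float(B[present].mean())
    return pd.Series(out, name="bcom")


def dispersal_ability(table, convention: str = "mean"):
    """Community-level relative dispersal ability D.

    For each sample pair, the shared proportion is the fraction of each
    sample's reads belonging to taxa present in BOTH samples;
    ``convention='mean'`` averages the two sides (``'min'`` takes the
    smaller, as a sensitivity variant).  D is the mean over all pairs.

    Returns ``(pairwise DataFrame, D)``.
    """
    counts = table.counts if hasattr(table, "counts") else pd.DataFrame(table)
    if counts.shape[0] < 2:
        raise ValueError("need at least two samples")
    rel = counts.div(counts.sum(axis=1), axis=0).to_numpy(dtype=float)
    if np.isnan(rel).any():
        raise ValueError("empty sample")
    pres = rel > 0
    n = rel.shape[0]
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = pres[i] & pres[j]
            si = rel[i, shared].sum()
            sj = rel[j, shared].sum()
            S[i, j] = S[j, i] = 0.5 * (si + sj) if convention == "mean" else min(si, sj)
    iu = np.triu_indices(n, k=1)
    D = float(S[iu].mean())
    return pd.DataFrame(S, index=counts.index, columns=counts.index), D
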