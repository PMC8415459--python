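"""Null-model partitioning of community assembly processes.

Implements the phylogenetic + taxonomic null-model framework that
classifies every pair of communities into one of five assembly
processes:

* beta-mean-nearest-taxon distance (betaMNTD): the abundance-weighted
  mean phylogenetic distance from each taxon in one community to its
  nearest relative in the other.
* betaNTI: the z-score of observed betaMNTD against a null distribution
  obtained by shuffling taxon labels across the tips of the phylogeny.
  betaNTI > +2 indicates variable selection, betaNTI < -2 homogeneous
  selection.
* Raup-Crick on Bray-Curtis (RC_Bray): for pairs without a significant
  phylogenetic signal (|betaNTI| <= 2), the observed Bray-Curtis is
  compared to a null that preserves each sample's richness and total
  abundance while drawing species by metacommunity occurrence
  frequency.  RC > 0.95 indicates dispersal limitation, RC < -0.95
  homogenizing dispersal; the rest is undominated.

The ratio of selection to dispersal-limitation fractions (SDER) is the
summary used for cross-system comparison.

A phylogenetic-signal pretest (correlation between taxon niche
differences and phylogenetic distance at short distances) is provided,
because betaNTI is only interpretable when close relatives share
environmental preferences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .distance_tests import (
    CorrelogramClass,
    MantelResult,
    mantel,
    mantel_correlogram,
    partial_mantel,
)

__all__ = [
    "beta_mntd",
    "beta_mntd_matrix",
    "bnti",
    "raup_crick_bray",
    "classify_pair",
    "pair_table",
    "process_summary",
    "ProcessSummary",
    "phylo_signal",
    "bnti_env_drivers",
    "EnvDriverResult",
    "PROCESS_LABELS",
]

PROCESS_LABELS = (
    "variable_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)


# ---------------------------------------------------------------------------
# betaMNTD / betaNTI


def _min_to_other(D: np.ndarray, present: np.ndarray) -> np.ndarray:
    """For every taxon k, min distance to any taxon in the `present` set."""
    return D[:, present].min(axis=1)


def beta_mntd(rel_i, rel_j, taxon_distances: pd.DataFrame) -> float:
    """Abundance-weighted betaMNTD between two communities.

    ``rel_i`` / ``rel_j`` are relative-abundance Series indexed by taxon
    id; ``taxon_distances`` is the cophenetic matrix.  A taxon present
    in both communities contributes zero to its own nearest-taxon term.
    """
    rel_i = pd.Series(rel_i)
    rel_j = pd.Series(rel_j)
    taxa = taxon_distances.index
    missing = (set(rel_i[rel_i > 0].index) | set(rel_j[rel_j > 0].index)) - set(taxa)
    if missing:
        raise KeyError(f"taxa missing from distance matrix: {sorted(missing)[:5]}")
    fi = rel_i.reindex(taxa).fillna(0.0).to_numpy(dtype=float)
    fj = rel_j.reindex(taxa).fillna(0.0).to_numpy(dtype=float)
    if fi.sum() == 0 or fj.sum() == 0:
        raise ValueError("empty community")
    fi, fj = fi / fi.sum(), fj / fj.sum()
    D = taxon_distances.to_numpy(dtype=float)
    si, sj = np.flatnonzero(fi > 0), np.flatnonzero(fj > 0)
    term_i = fi[si] @ _min_to_other(D, sj)[si]
    term_j = fj[sj] @ _min_to_other(D, si)[sj]
    return float(0.5 * (term_i + term_j))


def _bmntd_all_pairs(F: np.ndarray, masks: list[np.ndarray], D: np.ndarray) -> np.ndarray:
    """betaMNTD for all sample pairs at once.

    F is the (n_samples, n_taxa) relative-abundance array; masks hold the
    present-taxon indices per sample.  Returns the symmetric matrix
    0.5 * (P + P.T) with P[i, j] = sum_k F[i, k] * min_{l in S_j} D[k, l].
    """
    n = F.shape[0]
    mind = np.empty((n, D.shape[0]))
    for j in range(n):
        mind[j] = D[:, masks[j]].min(axis=1)
    P = F @ mind.T
    return 0.5 * (P + P.T)


def beta_mntd_matrix(table, tree_distances: pd.DataFrame) -> pd.DataFrame:
    """Observed betaMNTD for every pair of samples in a table."""
    counts = table.counts if hasattr(table, "counts") else pd.DataFrame(table)
    taxa = [t for t in counts.columns]
    missing = set(taxa) - set(tree_distances.index)
    if missing:
        raise KeyError(f"taxa missing from tree: {sorted(missing)[:5]}")
    D = tree_distances.loc[taxa, taxa].to_numpy(dtype=float)
    F = counts.to_numpy(dtype=float)
    F = F / F.sum(axis=1, keepdims=True)
    masks = [np.flatnonzero(F[i] > 0) for i in range(F.shape[0])]
    bm = _bmntd_all_pairs(F, masks, D)
    np.fill_diagonal(bm, 0.0)
    return pd.DataFrame(bm, index=counts.index, columns=counts.index)


def bnti(
    table,
    tree_distances: pd.DataFrame,
    n_null: int = 999,
    seed: int = 0,
    degenerate_sd: float = 1e-12,
):
    """Per-pair betaNTI with a taxa-label-shuffling null.

    Returns ``(bnti_df, bmntd_df, degenerate_df)``.  The null shuffles
    taxon labels across all tips of the tree (equivalently, applies a
    random permutation to the cophenetic matrix) and recomputes
    betaMNTD; betaNTI is the z-score of the observation.  Pairs whose
    null standard deviation collapses (identical communities, or a tree
    whose distances are label-invariant) are flagged degenerate and
    reported as NaN.
    """
    if n_null < 2:
        raise ValueError("need at least 2 null draws")
    counts = table.counts if hasattr(table, "counts") else pd.DataFrame(table)
    taxa = list(counts.columns)
    D = tree_distances.loc[taxa, taxa].to_numpy(dtype=float)
    F = counts.to_numpy(dtype=float)
    F = F / F.sum(axis=1, keepdims=True)
    masks = [np.flatnonzero(F[i] > 0) for i in range(F.shape[0])]
    obs = _bmntd_all_pairs(F, masks, D)
    rng = np.random.default_rng(seed)
    n_taxa = len(taxa)
    mean = np.zeros_like(obs)
    m2 = np.zeros_like(obs)
    for t in range(n_null):
        perm = rng.permutation(n_taxa)
        Dp = D[np.ix_(perm, perm)]
        null = _bmntd_all_pairs(F, masks, Dp)
        delta = null - mean
        mean += delta / (t + 1)
        m2 += delta * (null - mean)
    sd = np.sqrt(m2 / (n_null - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - mean) / sd
    degenerate = sd < degenerate_sd
    z[degenerate] = np.nan
    idx = counts.index
    return (
        pd.DataFrame(z, index=idx, columns=idx),
        pd.DataFrame(obs, index=idx, columns=idx),
        pd.DataFrame(degenerate, index=idx, columns=idx),
    )


# ---------------------------------------------------------------------------
# Raup-Crick on Bray-Curtis


def raup_crick_bray(table, n_null: int = 999, seed: int = 0) -> pd.DataFrame:
    """Per-pair Raup-Crick metric on Bray-Curtis, rescaled to [-1, 1].

    Null communities preserve each sample's observed richness and total
    read count: species are drawn without replacement with probability
    proportional to their metacommunity occurrence frequency, each
    drawn species receives one individual, and the remaining reads are
    assigned multinomially in proportion to metacommunity relative
    abundance among the drawn species.  RC for a pair is
    ``2 * (fraction of nulls below observed + half the ties) - 1``.
    """
    counts = table.counts if hasattr(table, "counts") else pd.DataFrame(table)
    X = counts.to_numpy(dtype=float)
    n, T = X.shape
    if n < 2:
        raise ValueError("need at least two samples")
    occ = (X > 0).sum(axis=0).astype(float)  # occurrence frequency
    gamma = X.sum(axis=0)
    gamma = gamma / gamma.sum()  # metacommunity relative abundance
    richness = (X > 0).sum(axis=1)
    totals = X.sum(axis=1).astype(int)
    pool = np.flatnonzero(occ > 0)
    if (richness > len(pool)).any():
        raise ValueError("sample richness exceeds metacommunity richness")
    p_occ = occ[pool] / occ[pool].sum()

    obs_bc = squareform(pdist(X, metric="braycurtis"))
    rng = np.random.default_rng(seed)
    less = np.zeros((n, n))
    ties = np.zeros((n, n))
    null = np.zeros((n, T))
    for _ in range(n_null):
        null[:] = 0.0
        for i in range(n):
            chosen = rng.choice(pool, size=richness[i], replace=False, p=p_occ)
            null[i, chosen] = 1.0
            extra = totals[i] - richness[i]
            if extra > 0:
                pa = gamma[chosen]
                pa = pa / pa.sum()
                null[i, chosen] += rng.multinomial(extra, pa)
        null_bc = squareform(pdist(null, metric="braycurtis"))
        less += null_bc < obs_bc
        ties += null_bc == obs_bc
    rc = 2.0 * (less + 0.5 * ties) / n_null - 1.0
    np.fill_diagonal(rc, 0.0)
    return pd.DataFrame(rc, index=counts.index, columns=counts.index)


# ---------------------------------------------------------------------------
# classification and summary


def classify_pair(bnti_value: float, rc_value: float | None, degenerate: bool = False) -> str:
    """Five-way assembly-process label for one community pair.

    Selection is decided from betaNTI alone; pairs with |betaNTI| <= 2
    (or a degenerate null) fall through to the RC_Bray rules.
    """
    if not degenerate and bnti_value is not None and not np.isnan(bnti_value):
        if bnti_value > 2:
            return "variable_selection"
        if bnti_value < -2:
            return "homogeneous_selection"
    if rc_value is None or (isinstance(rc_value, float) and np.isnan(rc_value)):
        raise ValueError("RC_Bray required when |betaNTI| <= 2 or the null is degenerate")
    if rc_value > 0.95:
        return "dispersal_limitation"
    if rc_value < -0.95:
        return "homogenizing_dispersal"
    return "undominated"


def pair_table(
    bnti_df: pd.DataFrame,
    bmntd_df: pd.DataFrame,
    rc_df: pd.DataFrame,
    degenerate_df: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per unordered sample pair with metrics and process label."""
    samples = list(bnti_df.index)
    rows = []
    for a in range(len(samples)):
        for b in range(a + 1, len(samples)):
            i, j = samples[a], samples[b]
            deg = bool(degenerate_df.loc[i, j]) if degenerate_df is not None else False
            z = bnti_df.loc[i, j]
            rc = rc_df.loc[i, j]
            rows.append(
                {
                    "sample_i": i,
                    "sample_j": j,
                    "bmntd": bmntd_df.loc[i, j],
                    "bnti": z,
                    "rc_bray": rc,
                    "degenerate": deg,
                    "process": classify_pair(z, rc, deg),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ProcessSummary:
    """Fractions of the five assembly processes plus derived ratios."""

    fractions: dict[str, float]
    sder_null: float  # selection fraction / dispersal-limitation fraction
    sder_infinite: bool
    stochastic_fraction_rc: float | None = None
    sder_vpa: float | None = None

    @property
    def selection_fraction(self) -> float:
        return self.fractions["variable_selection"] + self.fractions["homogeneous_selection"]

    @property
    def dispersal_fraction(self) -> float:
        return self.fractions["dispersal_limitation"]


def process_summary(
    labels,
    rc_df: pd.DataFrame | None = None,
    vpa_pure_env: float | None = None,
    vpa_pure_space: float | None = None,
) -> ProcessSummary:
    """Summarize per-pair process labels into fractions and SDER.

    SDER_null = (variable + homogeneous selection) / dispersal
    limitation; a zero denominator is flagged infinite.  When an RC
    matrix is given, the RC-only stochasticity estimate (fraction of
    pairs with |RC| > 0.95) is included; when pure VPA fractions are
    given, SDER_vpa = pure-environment / pure-space adjusted R^2.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("no classified pairs")
    n = len(labels)
    fracs = {lab: labels.count(lab) / n for lab in PROCESS_LABELS}
    sel = fracs["variable_selection"] + fracs["homogeneous_selection"]
    disp = fracs["dispersal_limitation"]
    if disp > 0:
        sder, inf = sel / disp, False
    else:
        sder, inf = np.inf, True
    stoch = None
    if rc_df is not None:
        iu = np.triu_indices(rc_df.shape[0], k=1)
        rc = rc_df.to_numpy()[iu]
        stoch = float((np.abs(rc) > 0.95).mean())
    sder_vpa = None
    if vpa_pure_env is not None and vpa_pure_space is not None:
        sder_vpa = vpa_pure_env / vpa_pure_space if vpa_pure_space > 0 else np.inf
    return ProcessSummary(
        fractions=fracs,
        sder_null=float(sder),
        sder_infinite=inf,
        stochastic_fraction_rc=stoch,
        sder_vpa=sder_vpa,
    )


# ---------------------------------------------------------------------------
# phylogenetic signal pretest and environmental drivers of betaNTI


def taxon_niche_values(table, metadata: pd.DataFrame, variables) -> pd.DataFrame:
    """Abundance-weighted mean of each standardized variable per taxon."""
    counts = table.counts if hasattr(table, "counts") else pd.DataFrame(table)
    counts = counts.loc[:, counts.sum(axis=0) > 0]  # absent taxa have no niche
    md = metadata.loc[counts.index, list(variables)].astype(float)
    std = md.std(axis=0, ddof=1)
    if (std == 0).any():
        bad = std.index[std == 0][0]
        raise ValueError(f"variable {bad!r} is constant across samples")
    z = (md - md.mean(axis=0)) / std
    W = counts.to_numpy(dtype=float)
    W = W / W.sum(axis=0, keepdims=True)  # weights per taxon across samples
    niche = W.T @ z.to_numpy()
    return pd.DataFrame(niche, index=counts.columns, columns=list(variables))


def phylo_signal(
    table,
    tree_distances: pd.DataFrame,
    metadata: pd.DataFrame,
    variables,
    n_classes: int | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> list[CorrelogramClass]:
    """Mantel correlogram of taxon niche distance vs phylogenetic distance.

    A positive, significant correlation in the shortest phylogenetic
    distance classes indicates that close relatives have similar niches
    — the premise required for betaNTI to reflect selection.
    """
    niche = taxon_niche_values(table, metadata, variables)
    taxa = list(niche.index)
    missing = set(taxa) - set(tree_distances.index)
    if missing:
        raise KeyError(f"taxa absent from tree: {sorted(missing)[:5]}")
    nd = squareform(pdist(niche.to_numpy(), metric="euclidean"))
    niche_d = pd.DataFrame(nd, index=taxa, columns=taxa)
    phylo_d = tree_distances.loc[taxa, taxa]
    return mantel_correlogram(
        niche_d,
        phylo_d,
        n_classes=n_classes,
        n_perm=n_perm,
        seed=seed,
        convention="autocorrelation",
    )


@dataclass
class EnvDriverResult:
    per_variable: pd.DataFrame  # variable, mantel r, p
    best_variable: str | None
    partial: MantelResult | None
    correlogram: list[CorrelogramClass] = field(default_factory=list)


def _euclid_1d(values: pd.Series) -> pd.DataFrame:
    v = values.to_numpy(dtype=float)[:, None]
    d = np.abs(v - v.T)
    return pd.DataFrame(d, index=values.index, columns=values.index)


def bnti_env_drivers(
    bnti_df: pd.DataFrame,
    metadata: pd.DataFrame,
    geo: pd.DataFrame,
    variables,
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
) -> EnvDriverResult:
    """Rank environmental variables by their Mantel association with betaNTI.

    Uses |betaNTI| as a distance-like matrix; samples involved in
    degenerate (NaN) pairs are excluded listwise.  The top-ranked
    variable is re-tested with a partial Mantel controlling for
    geographic distance and the remaining variables, and a Mantel
    correlogram of betaNTI against that variable's distance classes is
    returned.
    """
    z = bnti_df.copy()
    # listwise removal: greedily drop the sample with most NaN pairs
    zz = z.to_numpy(dtype=float)
    np.fill_diagonal(zz, 0.0)
    keep = list(range(len(z)))
    while np.isnan(zz[np.ix_(keep, keep)]).any():
        sub = zz[np.ix_(keep, keep)]
        worst = keep[int(np.nanargmax(np.isnan(sub).sum(axis=1)))]
        keep.remove(worst)
    samples = [z.index[i] for i in keep]
    if len(samples) < 4:
        raise ValueError("too few non-degenerate pairs for Mantel analysis")
    bmat = z.loc[samples, samples].abs()
    if np.allclose(bmat.to_numpy()[np.triu_indices(len(samples), 1)].std(), 0):
        raise ValueError("betaNTI constant; Mantel r undefined")
    rows = []
    var_d = {}
    for v in variables:
        dv = _euclid_1d(metadata.loc[samples, v].astype(float))
        var_d[v] = dv
        res = mantel(bmat, dv, n_perm=n_perm, seed=seed)
        rows.append({"variable": v, "r": res.r, "p": res.p})
    per_var = pd.DataFrame(rows).sort_values("r", ascending=False, key=np.abs).reset_index(drop=True)
    sig = per_var[per_var["p"] < alpha]
    best = sig.iloc[0]["variable"] if len(sig) else per_var.iloc[0]["variable"]
    controls = [geo.loc[samples, samples]] + [var_d[v] for v in variables if v != best]
    partial = None
    try:
        partial = partial_mantel(bmat, var_d[best], *controls, n_perm=n_perm, seed=seed)
    except (ValueError, np.linalg.LinAlgError) as exc:  # collinear controls
        warnings.warn(f"partial Mantel failed: {exc}")
    corr = mantel_correlogram(bmat, var_d[best], n_perm=n_perm, seed=seed)
    return EnvDriverResult(
        per_variable=per_var,
        best_variable=str(best),
        partial=partial,
        correlogram=corr,
    )
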