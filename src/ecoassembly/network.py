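"""Co-occurrence network inference and topology.

Association between taxa is scored two ways — Spearman rank correlation
and Bray-Curtis similarity of the two abundance profiles — and each
score receives a ReBoot-style significance: the score's null value is
obtained by permuting one taxon's reads across samples with
renormalization of each sample's composition (easing the
compositionality artifact), and its sampling distribution by
bootstrapping samples; the p-value is the two-sided Gaussian tail of
the null mean under the bootstrap distribution.  The two p-values are
combined with Brown's method (a scaled chi-square matching the first
two moments of -2 sum ln p under dependence, with the covariance
estimated empirically across candidate edges) and corrected by
Benjamini-Hochberg.

Edges passing the q-value filter and a correlation-magnitude threshold
— chosen by random-matrix theory as the point where the adjacency
spectrum's nearest-neighbor spacing statistics turn from GOE (Wigner)
to Poisson — form an undirected signed graph.  Modules are detected by
fast-greedy (CNM) modularity maximization on the positive-edge
subgraph; module eigengenes (PC1 of the standardized member profiles)
summarize each dominant module's abundance pattern across samples.
Per-sample "local" networks are induced subgraphs on the taxa present
in a sample, summarized by standard topological features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .distance_tests import mrm_two_stage

__all__ = [
    "pairwise_scores",
    "reboot_pvalues",
    "browns_combine",
    "bh_adjust",
    "rmt_threshold",
    "infer_edges",
    "build_network",
    "fast_greedy_modules",
    "dominant_modules",
    "module_eigengene",
    "local_network_features",
    "local_network_distance",
    "topology_vs_space",
]


# ---------------------------------------------------------------------------
# association scores


def pairwise_scores(rel: pd.DataFrame):
    """Spearman rho and Bray-Curtis similarity between all taxon pairs.

    ``rel`` holds per-sample relative abundances (samples x taxa).
    Constant taxa yield NaN rho (flagged downstream).
    """
    if rel.shape[0] < 4:
        raise ValueError("need at least 4 samples")
    X = rel.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(X).statistic
    if np.isscalar(rho):  # two taxa
        rho = np.array([[1.0, rho], [rho, 1.0]])
    bc = 1.0 - squareform(pdist(X.T, metric="braycurtis"))
    np.fill_diagonal(bc, 1.0)
    taxa = rel.columns
    return (
        pd.DataFrame(rho, index=taxa, columns=taxa),
        pd.DataFrame(bc, index=taxa, columns=taxa),
    )


def _pair_scores(ra: np.ndarray, rb: np.ndarray):
    """Spearman and BC similarity for batches of profile pairs (B, n)."""
    n = ra.shape[1]
    rka = stats.rankdata(ra, axis=1)
    rkb = stats.rankdata(rb, axis=1)
    rka = rka - rka.mean(axis=1, keepdims=True)
    rkb = rkb - rkb.mean(axis=1, keepdims=True)
    denom = np.sqrt((rka**2).sum(axis=1) * (rkb**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (rka * rkb).sum(axis=1) / denom
    tot = np.abs(ra) + np.abs(rb)
    with np.errstate(divide="ignore", invalid="ignore"):
        bc = 1.0 - np.abs(ra - rb).sum(axis=1) / tot.sum(axis=1)
    return rho, bc


@dataclass
class RebootResult:
    rho: float
    bc_sim: float
    p_spearman: float
    p_bray: float
    degenerate: bool


def reboot_pvalues(
    counts: pd.DataFrame,
    pair: tuple[str, str],
    n_perm: int = 1000,
    n_boot: int = 1000,
    seed: int = 0,
) -> RebootResult:
    """ReBoot p-values for one taxon pair.

    ``counts`` is the full samples x taxa count table (all taxa are
    needed for the compositional renormalization).  The permutation
    shuffles taxon a's counts across samples and renormalizes each
    sample total before recomputing the scores; the bootstrap resamples
    samples with replacement.  p is the two-sided Gaussian tail of the
    mean null score under N(bootstrap mean, bootstrap sd).
    """
    a_name, b_name = pair
    X = counts.to_numpy(dtype=float)
    ia = counts.columns.get_loc(a_name)
    ib = counts.columns.get_loc(b_name)
    totals = X.sum(axis=1)
    a, b = X[:, ia], X[:, ib]
    rel_a, rel_b = a / totals, b / totals
    rho_obs, bc_obs = _pair_scores(rel_a[None, :], rel_b[None, :])
    rng = np.random.default_rng(seed)
    n = len(a)

    # permutation null with renormalization
    perm_idx = np.array([rng.permutation(n) for _ in range(n_perm)])
    a_perm = a[perm_idx]
    new_tot = totals[None, :] - a[None, :] + a_perm
    ra = a_perm / new_tot
    rb = np.broadcast_to(b, a_perm.shape) / new_tot
    rho_null, bc_null = _pair_scores(ra, rb)

    # bootstrap confidence distribution
    boot_idx = rng.integers(0, n, size=(n_boot, n))
    rho_boot, bc_boot = _pair_scores(rel_a[boot_idx], rel_b[boot_idx])

    def tail(null_vals, boot_vals):
        null_vals = null_vals[np.isfinite(null_vals)]
        boot_vals = boot_vals[np.isfinite(boot_vals)]
        if len(boot_vals) == 0 or len(null_vals) == 0:
            return 1.0, True
        mu, sd = boot_vals.mean(), boot_vals.std(ddof=1)
        if sd == 0:
            return 1.0, True
        z = (null_vals.mean() - mu) / sd
        return float(2 * stats.norm.sf(abs(z))), False

    p_s, deg_s = tail(rho_null, rho_boot)
    p_b, deg_b = tail(bc_null, bc_boot)
    return RebootResult(
        rho=float(rho_obs[0]) if np.isfinite(rho_obs[0]) else np.nan,
        bc_sim=float(bc_obs[0]),
        p_spearman=p_s,
        p_bray=p_b,
        degenerate=deg_s or deg_b,
    )


# ---------------------------------------------------------------------------
# p-value combination and correction


def browns_combine(p1, p2, cov_estimate: float | None = None):
    """Brown's combination of two dependent p-values.

    X = -2 (ln p1 + ln p2) is modeled as c * chi2(2f) with
    c = Var(X) / (2 E[X]) and f = 2 E[X]^2 / Var(X), where E[X] = 4 and
    Var(X) = 8 + 2 cov(-2 ln p1, -2 ln p2).  The covariance is
    estimated empirically across the supplied arrays unless given.
    With zero covariance the method reduces to Fisher's.
    """
    p1 = np.atleast_1d(np.asarray(p1, dtype=float))
    p2 = np.atleast_1d(np.asarray(p2, dtype=float))
    if (p1 <= 0).any() or (p2 <= 0).any():
        raise ValueError("p-values must be in (0, 1]")
    l1, l2 = -2 * np.log(p1), -2 * np.log(p2)
    if cov_estimate is None:
        if len(p1) < 3:
            raise ValueError("need >= 3 edges to estimate the covariance empirically")
        cov_estimate = float(np.cov(l1, l2)[0, 1])
    e_x = 4.0
    var_x = 8.0 + 2.0 * max(min(cov_estimate, 4.0), -4.0)  # |cov| bounded by sd1*sd2 = 4
    c = var_x / (2 * e_x)
    df = 2 * e_x**2 / var_x  # X / c ~ chi2(df); cov=0 gives df=4 (Fisher)
    x = l1 + l2
    out = stats.chi2.sf(x / c, df)
    return out if out.size > 1 else float(out[0])


def bh_adjust(p_values):
    """Benjamini-Hochberg step-up q-values with monotonicity enforced."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# random-matrix-theory threshold


def _nnsd_poisson_chi2(eigvals: np.ndarray, n_bins: int = 20, s_max: float = 3.0):
    """Chi-square p for Poisson NNSD of an unfolded spectrum."""
    lam = np.sort(eigvals)
    n = len(lam)
    if n < 20:
        return None
    # unfold via Gaussian-smoothed empirical CDF (Silverman bandwidth)
    sd = lam.std(ddof=1)
    iqr = np.subtract(*np.percentile(lam, [75, 25]))
    h = 0.9 * min(sd, iqr / 1.34 if iqr > 0 else sd) * n ** (-0.2)
    if h <= 0:
        return None
    F = stats.norm.cdf((lam[:, None] - lam[None, :]) / h).mean(axis=1)
    unfolded = n * F
    s = np.diff(np.sort(unfolded))
    s = s / s.mean()
    edges = np.linspace(0, s_max, n_bins + 1)
    obs, _ = np.histogram(s, bins=edges)
    # expected Poisson (exponential) spacing counts
    probs = np.exp(-edges[:-1]) - np.exp(-edges[1:])
    probs[-1] += np.exp(-s_max)  # fold the tail into the last bin
    exp = probs * len(s)
    mask = exp > 0
    chi2 = float(((obs[mask] - exp[mask]) ** 2 / exp[mask]).sum())
    return stats.chi2.sf(chi2, mask.sum() - 1)


def rmt_threshold(
    rho: pd.DataFrame,
    scan: tuple[float, float, float] = (0.50, 0.95, 0.01),
    alpha: float = 0.05,
    min_component: int = 20,
    default: float = 0.74,
) -> float:
    """Correlation threshold by the Poisson transition of NNSD.

    Scans |rho| thresholds from low to high, builds the thresholded
    adjacency's largest connected component, and returns the lowest
    threshold at which the nearest-neighbor spacing distribution of the
    unfolded eigenvalues is consistent with Poisson statistics
    (chi-square p > alpha) and remains so at all higher thresholds.
    Falls back to ``default`` with a warning when no threshold yields a
    component of at least ``min_component`` nodes.
    """
    if rho.shape[0] < 30:
        raise ValueError("need at least 30 taxa for spectrum statistics")
    R = np.abs(rho.to_numpy(dtype=float))
    np.fill_diagonal(R, 0.0)
    lo, hi, step = scan
    thresholds = np.arange(lo, hi + step / 2, step)
    fits = []
    for t in thresholds:
        A = (R >= t).astype(float)
        g = nx.from_numpy_array(A)
        comps = list(nx.connected_components(g))
        if not comps:
            fits.append(None)
            continue
        comp = max(comps, key=len)
        if len(comp) < min_component:
            fits.append(None)
            continue
        sub = A[np.ix_(sorted(comp), sorted(comp))]
        p = _nnsd_poisson_chi2(np.linalg.eigvalsh(sub))
        fits.append(p)
    usable = [(t, p) for t, p in zip(thresholds, fits) if p is not None]
    if not usable:
        warnings.warn("no threshold yields a large enough component; using default")
        return default
    for i, (t, p) in enumerate(usable):
        if p > alpha and all(q > alpha for _, q in usable[i:]):
            return float(t)
    # never transitions to Poisson within the scan: keep the most
    # conservative (highest) scanned threshold that was usable
    return float(usable[-1][0])


# ---------------------------------------------------------------------------
# edge inference and graph construction


def infer_edges(
    counts: pd.DataFrame,
    n_perm: int = 1000,
    n_boot: int = 1000,
    seed: int = 0,
    candidate_min_abs_rho: float = 0.0,
) -> pd.DataFrame:
    """ReBoot + Brown + BH edge table for all candidate taxon pairs.

    ``candidate_min_abs_rho`` can prefilter pairs by |Spearman rho|
    before the (costly) resampling step; q-values are computed over the
    retained candidate set.
    """
    totals = counts.sum(axis=1)
    rel = counts.div(totals, axis=0)
    rho_m, bc_m = pairwise_scores(rel)
    taxa = list(counts.columns)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            r = rho_m.iloc[i, j]
            if not np.isfinite(r) or abs(r) < candidate_min_abs_rho:
                continue
            res = reboot_pvalues(
                counts,
                (taxa[i], taxa[j]),
                n_perm=n_perm,
                n_boot=n_boot,
                seed=int(rng.integers(2**31 - 1)),
            )
            rows.append(
                {
                    "taxon_a": taxa[i],
                    "taxon_b": taxa[j],
                    "rho": res.rho,
                    "bc_sim": res.bc_sim,
                    "p_spearman": res.p_spearman,
                    "p_bray": res.p_bray,
                    "degenerate": res.degenerate,
                    "sign": "+" if res.rho >= 0 else "-",
                }
            )
    edges = pd.DataFrame(rows)
    if len(edges) == 0:
        return edges
    p1 = edges["p_spearman"].clip(lower=1e-300)
    p2 = edges["p_bray"].clip(lower=1e-300)
    if len(edges) >= 3:
        edges["brown_p"] = browns_combine(p1, p2)
    else:
        edges["brown_p"] = browns_combine(p1, p2, cov_estimate=0.0)
    edges["q"] = bh_adjust(edges["brown_p"])
    return edges


def build_network(
    edges: pd.DataFrame,
    q_max: float = 0.05,
    rho_min: float = 0.74,
    domain: pd.Series | None = None,
) -> nx.Graph:
    """Signed undirected graph of edges with q <= q_max and |rho| >= rho_min."""
    kept = edges[(edges["q"] <= q_max) & (edges["rho"].abs() >= rho_min)]
    if len(kept) == 0:
        raise ValueError("no edges pass the filters")
    g = nx.Graph()
    for _, row in kept.iterrows():
        g.add_edge(
            row["taxon_a"],
            row["taxon_b"],
            rho=float(row["rho"]),
            sign=row["sign"],
            weight=abs(float(row["rho"])),
        )
    if domain is not None:
        nx.set_node_attributes(g, {n: domain.get(n, "unknown") for n in g}, "domain")
    return g


def domain_subgraph(graph: nx.Graph, domain_tag: str) -> nx.Graph:
    """Subgraph on nodes of one domain (edges with both endpoints in it)."""
    nodes = [n for n, d in graph.nodes(data=True) if d.get("domain") == domain_tag]
    return graph.subgraph(nodes).copy()


# ---------------------------------------------------------------------------
# modules and eigengenes


def fast_greedy_modules(graph: nx.Graph, weighted: bool = False):
    """CNM fast-greedy modularity maximization.

    Negative-sign edges are excluded from clustering (modularity needs
    non-negative weights); their nodes remain and may end up as
    singletons.  Returns ``(module id per node, Q)`` where Q is the
    modularity of the returned partition on the positive-edge graph.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    pos = nx.Graph()
    pos.add_nodes_from(graph.nodes(data=True))
    for u, v, d in graph.edges(data=True):
        if d.get("sign", "+") == "+":
            pos.add_edge(u, v, weight=d.get("weight", 1.0))
    weight = "weight" if weighted else None
    if pos.number_of_edges() == 0:
        communities = [{n} for n in pos.nodes]
    else:
        communities = list(
            nx.community.greedy_modularity_communities(pos, weight=weight)
        )
    q = nx.community.modularity(pos, communities, weight=weight)
    assignment = {}
    for mid, comm in enumerate(communities, start=1):
        for node in comm:
            assignment[node] = mid
    return pd.Series(assignment, name="module"), float(q)


def dominant_modules(assignment: pd.Series, min_fraction: float = 0.10) -> list[int]:
    """Module ids holding more than ``min_fraction`` of the nodes."""
    counts = assignment.value_counts()
    return [int(m) for m, c in counts.items() if c / len(assignment) > min_fraction]


def module_eigengene(rel: pd.DataFrame, members) -> tuple[pd.Series, float]:
    """PC1 of the standardized member-abundance matrix across samples.

    Returns ``(eigengene per sample, fraction of variance explained)``;
    the sign is fixed so the eigengene correlates positively with the
    mean member abundance profile.
    """
    members = [m for m in members if m in rel.columns]
    if len(members) < 3:
        raise ValueError("module must have at least 3 member taxa")
    X = rel[members].to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    U, S, Vt = np.linalg.svd(Z - Z.mean(axis=0), full_matrices=False)
    pc1 = U[:, 0] * S[0]
    var_explained = float(S[0] ** 2 / (S**2).sum())
    mean_profile = X.mean(axis=1)
    if np.std(mean_profile) > 0 and np.corrcoef(pc1, mean_profile)[0, 1] < 0:
        pc1 = -pc1
    return pd.Series(pc1, index=rel.index, name="eigengene"), var_explained


def eigengene_env_correlation(eigengene: pd.Series, metadata: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation of a module eigengene with each variable."""
    rows = []
    for v in metadata.columns:
        r = stats.spearmanr(eigengene, metadata.loc[eigengene.index, v])
        rows.append({"variable": v, "rho": float(r.statistic), "p": float(r.pvalue)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# local networks


FEATURES = [
    "density",
    "clustering",
    "mean_degree_centrality",
    "mean_closeness",
    "mean_eigenvector_centrality",
    "modularity",
    "diameter",
    "avg_path_length",
    "n_nodes",
    "n_edges",
]


def local_network_features(graph: nx.Graph, table) -> pd.DataFrame:
    """Topological features of each sample's induced local network.

    The local network of a sample is the metacommunity graph restricted
    to taxa with nonzero count in that sample.  Path-based features are
    computed on the largest connected component.
    """
    counts = table.counts if hasattr(table, "counts") else pd.DataFrame(table)
    rows = {}
    for s, row in counts.iterrows():
        present = [t for t in graph.nodes if row.get(t, 0) > 0]
        sub = graph.subgraph(present)
        if sub.number_of_nodes() < 2:
            raise ValueError(f"sample {s!r} retains fewer than 2 network nodes")
        feats = {
            "density": nx.density(sub),
            "clustering": nx.average_clustering(sub),
            "mean_degree_centrality": float(np.mean(list(nx.degree_centrality(sub).values()))),
            "n_nodes": sub.number_of_nodes(),
            "n_edges": sub.number_of_edges(),
        }
        comp = sub.subgraph(max(nx.connected_components(sub), key=len))
        feats["mean_closeness"] = float(np.mean(list(nx.closeness_centrality(sub).values())))
        try:
            ev = nx.eigenvector_centrality(comp, max_iter=1000)
            feats["mean_eigenvector_centrality"] = float(np.mean(list(ev.values())))
        except nx.PowerIterationFailedConvergence:
            feats["mean_eigenvector_centrality"] = np.nan
        if sub.number_of_edges() > 0:
            _, q = fast_greedy_modules(sub)
        else:
            q = 0.0
        feats["modularity"] = q
        if comp.number_of_nodes() > 1:
            feats["diameter"] = nx.diameter(comp)
            feats["avg_path_length"] = nx.average_shortest_path_length(comp)
        else:
            feats["diameter"] = 0
            feats["avg_path_length"] = 0.0
        rows[s] = feats
    return pd.DataFrame(rows).T[FEATURES].astype(float)


def local_network_distance(
    features: pd.DataFrame, collinearity_rho: float = 0.7
) -> tuple[pd.DataFrame, list[str]]:
    """Euclidean distance among samples on decorrelated, standardized features.

    Features with pairwise |Spearman rho| above the cutoff are dropped
    (first kept wins); retained features are z-scored.  Returns the
    distance matrix and the retained feature names.
    """
    kept: list[str] = []
    for f in features.columns:
        col = features[f]
        if col.std() == 0 or col.isna().any():
            continue
        if all(
            abs(stats.spearmanr(col, features[g]).statistic) <= collinearity_rho
            for g in kept
        ):
            kept.append(f)
    if not kept:
        raise ValueError("no features retained after collinearity filter")
    Z = (features[kept] - features[kept].mean()) / features[kept].std(ddof=1)
    d = squareform(pdist(Z.to_numpy(), metric="euclidean"))
    return pd.DataFrame(d, index=features.index, columns=features.index), kept


def topology_vs_space(
    feature_dist: pd.DataFrame,
    geo_dist: pd.DataFrame,
    env_dists: dict[str, pd.DataFrame] | None = None,
    n_perm: int = 999,
    seed: int = 0,
):
    """Spatial variation rate of network topology, plus a two-stage MRM.

    Returns ``(OLS slope of feature distance on geographic distance,
    stage-1 MRM result, stage-2 MRM result or None)``; MRM predictors
    are the geographic distance plus any supplied environmental
    distance matrices.
    """
    g = geo_dist.loc[feature_dist.index, feature_dist.index]
    iu = np.triu_indices(len(g), k=1)
    x = g.to_numpy()[iu]
    y = feature_dist.to_numpy()[iu]
    slope = float(stats.linregress(x, y).slope)
    predictors = {"geographic": g}
    if env_dists:
        predictors.update(env_dists)
    stage1, stage2 = mrm_two_stage(feature_dist, predictors, n_perm=n_perm, seed=seed)
    return slope, stage1, stage2
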