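"""Synthetic metacommunities with known assembly regime.

Every downstream analysis in this package is exercised against
communities whose generating process is known.  The generator produces:

* a pure-birth (Yule) phylogeny, ultrametric with total depth 1;
* spatially arranged sites with environmental variables that can be
  spatially autocorrelated (Gaussian-process draw on site coordinates)
  or independent of space;
* per-taxon environmental optima evolved by Brownian motion on the
  tree, blended with independent noise by a conservatism parameter
  ``lambda`` (1 = fully phylogenetically conserved niches);
* local communities assembled under one of four regimes:

  - ``neutral``: migration-drift balance.  Each site's composition is
    drawn from the stationary law of the Hubbell death-replacement
    process with migration probability ``m`` — a Dirichlet(N m gamma)
    pool (whose marginals are exactly the Sloan beta distribution) —
    and reads are a multinomial draw from that pool.  A finite Moran
    chain (``sample_neutral_community``) is exposed separately for
    studying the transient dynamics.
  - ``selection``: the regional pool is re-weighted at each site by a
    Gaussian niche filter exp(-(env - optimum)^2 / (2 sigma^2)) before
    sampling; sigma -> infinity recovers the neutral ``m = 1`` limit.
  - ``dispersal_limited``: sites first drift apart under low migration,
    then each site's sampling pool is a distance-kernel mixture
    exp(-kappa * d_ij / d_scale) of the drifted local pools; large
    ``kappa`` isolates sites and steepens the distance-decay curve.
  - ``mixed``: selection filtering followed by the dispersal mixture.

Two special-purpose generators support the threshold and network
analyses: taxa with logistic step responses at known gradient change
points (negative-binomial read noise), and block-correlated log-normal
abundance profiles with known module membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from skbio import TreeNode

from .tables import OtuTable

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_tree",
    "simulate_sites",
    "assign_conserved_traits",
    "sample_neutral_community",
    "simulate_regime",
    "simulate_gradient_taxa",
    "simulate_correlated_blocks",
]

KM_PER_DEGREE = 111.19493  # 2 pi * 6371 / 360

REGIMES = ("neutral", "selection", "dispersal_limited", "mixed")


@dataclass
class SimulationConfig:
    """Knobs of the metacommunity generator.

    ``m`` is the migration probability per death-replacement event,
    ``niche_strength`` the Gaussian filter width sigma (smaller =
    stronger selection), ``trait_conservatism`` the Brownian blend
    lambda, ``dispersal_decay`` the kernel decay kappa.
    """

    n_sites: int = 40
    n_taxa: int = 300
    reads_per_sample: int = 2000
    regime: str = "neutral"
    m: float = 0.25
    niche_strength: float = 1.0
    trait_conservatism: float = 1.0
    dispersal_decay: float = 8.0
    seed: int = 0
    sweeps: int = 10
    n_env: int = 4
    extent_km: float = 650.0
    spatial_autocorr: float = 0.0
    selection_vars: tuple[str, ...] = ("env1",)

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if not 0 < self.m <= 1:
            raise ValueError("m must be in (0, 1]")
        if self.niche_strength < 0 or self.dispersal_decay < 0:
            raise ValueError("niche_strength and dispersal_decay must be >= 0")
        if not 0 <= self.trait_conservatism <= 1:
            raise ValueError("trait_conservatism must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth emitted with every simulated table."""

    gamma: pd.Series  # regional relative abundances, sums to 1
    optima: pd.DataFrame  # taxa x environmental variables
    coordinates: pd.DataFrame  # site latitude/longitude
    regime: str
    config: SimulationConfig = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# phylogeny


def simulate_tree(n_taxa: int, seed: int = 0) -> TreeNode:
    """Pure-birth ultrametric tree with total depth 1, tips t1..tn."""
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = np.random.default_rng(seed)
    root = TreeNode()
    left, right = TreeNode(), TreeNode()
    root.extend([left, right])
    active = [(left, 0.0), (right, 0.0)]
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        idx = rng.integers(len(active))
        node, born = active.pop(idx)
        node.length = t - born
        a, b = TreeNode(), TreeNode()
        node.extend([a, b])
        active.append((a, t))
        active.append((b, t))
    t_end = t + rng.exponential(1.0 / n_taxa)
    for node, born in active:
        node.length = t_end - born
    root.length = 0.0
    # scale to depth 1 and label tips in traversal order
    for node in root.traverse(include_self=False):
        node.length = node.length / t_end
    for i, tip in enumerate(root.tips(), start=1):
        tip.name = f"t{i}"
    return root


# ---------------------------------------------------------------------------
# sites and environment


def simulate_sites(
    n_sites: int,
    extent_km: float = 650.0,
    n_env: int = 4,
    spatial_autocorr: float = 0.0,
    seed: int = 0,
    center: tuple[float, float] = (24.0, 104.0),
) -> pd.DataFrame:
    """Random sites in a square of side ``extent_km`` with environment.

    ``spatial_autocorr`` is the Gaussian-kernel correlation length in
    km: 0 gives environment independent of space; a length comparable
    to the extent makes environmental and geographic distance strongly
    confounded.  Environmental variables are named env1..envK and are
    standard normal marginally.
    """
    if n_sites < 3:
        raise ValueError("need at least 3 sites")
    rng = np.random.default_rng(seed)
    xy = rng.uniform(0, extent_km, size=(n_sites, 2))
    lat0, lon0 = center
    lat = lat0 + xy[:, 1] / KM_PER_DEGREE
    lon = lon0 + xy[:, 0] / (KM_PER_DEGREE * np.cos(np.radians(lat0)))
    md = pd.DataFrame(
        {"latitude": lat, "longitude": lon},
        index=[f"s{i+1}" for i in range(n_sites)],
    )
    if spatial_autocorr > 0:
        d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
        cov = np.exp(-d2 / (2 * spatial_autocorr**2)) + 1e-8 * np.eye(n_sites)
        L = np.linalg.cholesky(cov)
        env = L @ rng.standard_normal((n_sites, n_env))
    else:
        env = rng.standard_normal((n_sites, n_env))
    for k in range(n_env):
        md[f"env{k+1}"] = env[:, k]
    return md


def assign_conserved_traits(
    tree: TreeNode, lam: float, seed: int = 0, n_traits: int = 1
) -> pd.DataFrame:
    """Per-taxon niche optima with tunable phylogenetic conservatism.

    Traits evolve by Brownian motion along the tree (variance equal to
    branch length) and are blended with iid noise:
    trait = sqrt(lambda) * BM + sqrt(1 - lambda) * noise, both sides
    standardized, so lambda = 1 gives fully conserved niches and
    lambda = 0 destroys any phylogenetic signal.
    """
    if not 0 <= lam <= 1:
        raise ValueError("lambda must be in [0, 1]")
    rng = np.random.default_rng(seed)
    tips = [t.name for t in tree.tips()]
    out = np.empty((len(tips), n_traits))
    for j in range(n_traits):
        values: dict[int, float] = {id(tree): 0.0}
        for node in tree.preorder(include_self=False):
            step = rng.normal(0.0, np.sqrt(max(node.length or 0.0, 0.0)))
            values[id(node)] = values[id(node.parent)] + step
        bm = np.array([values[id(t)] for t in tree.tips()])
        if bm.std() > 0:
            bm = (bm - bm.mean()) / bm.std()
        noise = rng.standard_normal(len(tips))
        out[:, j] = np.sqrt(lam) * bm + np.sqrt(1 - lam) * noise
    return pd.DataFrame(out, index=tips, columns=[f"env{j+1}" for j in range(n_traits)])


# ---------------------------------------------------------------------------
# neutral drift


@njit(cache=True)
def _moran_events(counts, gamma_cum, m, n_events, seed):  # pragma: no cover
    np.random.seed(seed)
    T = counts.shape[0]
    total = 0
    for k in range(T):
        total += counts[k]
    for _ in range(n_events):
        r = np.random.random() * total
        acc = 0.0
        dead = T - 1
        for k in range(T):
            acc += counts[k]
            if r < acc:
                dead = k
                break
        counts[dead] -= 1
        if np.random.random() < m:
            born = np.searchsorted(gamma_cum, np.random.random())
        else:
            r = np.random.random() * (total - 1)
            acc = 0.0
            born = T - 1
            for k in range(T):
                acc += counts[k]
                if r < acc:
                    born = k
                    break
        counts[born] += 1
    return counts


def sample_neutral_community(
    gamma, reads: int, m: float, seed: int = 0, sweeps: int = 10
) -> np.ndarray:
    """One local community under Hubbell-type drift with migration m.

    Initializes as multinomial(reads, gamma) and runs ``sweeps * reads``
    death-replacement events; the replacement is drawn from the regional
    pool with probability m, from the local community otherwise.  With
    m = 1 the stationary law is exactly multinomial(gamma) and is drawn
    directly.
    """
    g = np.asarray(gamma, dtype=float)
    if not 0 < m <= 1:
        raise ValueError("m must be in (0, 1]")
    g = g / g.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(reads, g)
    if m >= 1.0 or sweeps == 0:
        return counts
    gamma_cum = np.cumsum(g)
    gamma_cum[-1] = 1.0
    sub = int(rng.integers(0, 2**31 - 1))
    return np.asarray(
        _moran_events(counts.astype(np.int64), gamma_cum, m, sweeps * reads, sub)
    )


# ---------------------------------------------------------------------------
# regimes


def _regional_pool(n_taxa: int, rng) -> np.ndarray:
    ab = rng.lognormal(mean=0.0, sigma=1.5, size=n_taxa)
    return ab / ab.sum()


def _site_distances_km(md: pd.DataFrame) -> np.ndarray:
    lat = md["latitude"].to_numpy()
    lon = md["longitude"].to_numpy()
    y = lat * KM_PER_DEGREE
    x = lon * KM_PER_DEGREE * np.cos(np.radians(lat.mean()))
    return np.sqrt((x[:, None] - x[None, :]) ** 2 + (y[:, None] - y[None, :]) ** 2)


def _stationary_pools(gamma: np.ndarray, reads: int, m: float, n: int, rng) -> np.ndarray:
    """Site pools from the stationary migration-drift law Dirichlet(N m gamma)."""
    alpha = np.maximum(reads * m * gamma, 1e-12)
    return rng.dirichlet(alpha, size=n)


def simulate_regime(
    config: SimulationConfig,
    tree: TreeNode | None = None,
    sites: pd.DataFrame | None = None,
) -> tuple[OtuTable, SyntheticTruth]:
    """Simulate an OTU table under the configured assembly regime."""
    rng = np.random.default_rng(config.seed)
    if tree is None:
        tree = simulate_tree(config.n_taxa, seed=config.seed)
    taxa = [t.name for t in tree.tips()]
    if sites is None:
        sites = simulate_sites(
            config.n_sites,
            extent_km=config.extent_km,
            n_env=config.n_env,
            spatial_autocorr=config.spatial_autocorr,
            seed=config.seed,
        )
    gamma = pd.Series(_regional_pool(len(taxa), rng), index=taxa)
    optima = assign_conserved_traits(
        tree, config.trait_conservatism, seed=config.seed, n_traits=config.n_env
    )

    n = len(sites)
    g = gamma.to_numpy()
    pools = np.tile(g, (n, 1))

    if config.regime in ("selection", "mixed"):
        sigma = config.niche_strength
        for v in config.selection_vars:
            env = sites[v].to_numpy()[:, None]
            opt = optima[v].reindex(taxa).to_numpy()[None, :]
            if np.isfinite(sigma) and sigma > 0:
                pools = pools * np.exp(-((env - opt) ** 2) / (2 * sigma**2))
        pools = pools / pools.sum(axis=1, keepdims=True)

    if config.regime in ("dispersal_limited", "mixed"):
        # drift local pools apart (stationary Dirichlet), then mix by kernel
        drifted = np.empty_like(pools)
        for i in range(n):
            drifted[i] = _stationary_pools(
                pools[i], config.reads_per_sample, config.m, 1, rng
            )[0]
        d = _site_distances_km(sites)
        scale = d[np.triu_indices(n, 1)].mean()
        K = np.exp(-config.dispersal_decay * d / scale)
        pools = K @ drifted
        pools = pools / pools.sum(axis=1, keepdims=True)

    if config.regime == "neutral":
        pools = _stationary_pools(g, config.reads_per_sample, config.m, n, rng)
    counts = np.empty((n, len(taxa)), dtype=np.int64)
    for i in range(n):
        counts[i] = rng.multinomial(config.reads_per_sample, pools[i])
    table = OtuTable(pd.DataFrame(counts, index=sites.index, columns=taxa))
    truth = SyntheticTruth(
        gamma=gamma,
        optima=optima,
        coordinates=sites[["latitude", "longitude"]].copy(),
        regime=config.regime,
        config=config,
    )
    return table, truth


# ---------------------------------------------------------------------------
# special-purpose generators


def simulate_gradient_taxa(
    n_taxa: int,
    gradient,
    change_points,
    directions,
    noise: float = 0.0,
    seed: int = 0,
    amplitude: float = 50.0,
    width: float | None = None,
) -> OtuTable:
    """Taxa with step responses along an environmental gradient.

    ``directions`` holds +1 (increaser, abundant above its change
    point) or -1 (decreaser) per taxon.  With ``noise = 0`` the response
    is a hard step and counts are deterministic; otherwise the mean
    follows a logistic step and reads are drawn negative-binomially
    (dispersion size 1) with a uniform background rate of ``noise``
    reads, mimicking overdispersed amplicon counts.
    """
    x = np.asarray(gradient, dtype=float)
    cps = np.broadcast_to(np.asarray(change_points, dtype=float), (n_taxa,))
    dirs = np.broadcast_to(np.asarray(directions), (n_taxa,))
    if (cps < x.min()).any() or (cps > x.max()).any():
        raise ValueError("change points outside gradient range")
    rng = np.random.default_rng(seed)
    if width is None:
        width = (x.max() - x.min()) / 100.0
    counts = np.zeros((len(x), n_taxa), dtype=np.int64)
    for k in range(n_taxa):
        s = dirs[k] * (x - cps[k])
        if noise == 0:
            mean = np.where(s > 0, amplitude, 0.0)
            counts[:, k] = np.round(mean).astype(np.int64)
        else:
            mean = noise + amplitude / (1.0 + np.exp(-s / width))
            p = 1.0 / (1.0 + mean)  # NB with size 1
            counts[:, k] = rng.negative_binomial(1, p)
    return OtuTable(
        pd.DataFrame(
            counts,
            index=[f"s{i+1}" for i in range(len(x))],
            columns=[f"g{k+1}" for k in range(n_taxa)],
        )
    )


def simulate_correlated_blocks(
    n_blocks: int,
    taxa_per_block: int,
    rho: float,
    n_samples: int,
    seed: int = 0,
    depth_scale: float = 50.0,
) -> tuple[OtuTable, pd.Series]:
    """Log-normal abundances with block-structured correlation.

    Taxa within a block share a latent factor with loading sqrt(rho);
    between-block correlation is zero.  Counts are Poisson draws from
    the log-normal rates.  Returns the table and the true block id per
    taxon.
    """
    if not 0 <= rho < 1:
        raise ValueError("rho must be in [0, 1)")
    rng = np.random.default_rng(seed)
    taxa, blocks, cols = [], [], []
    counts = np.zeros((n_samples, n_blocks * taxa_per_block), dtype=np.int64)
    z = rng.standard_normal((n_samples, n_blocks))
    k = 0
    for b in range(n_blocks):
        for t in range(taxa_per_block):
            latent = np.sqrt(rho) * z[:, b] + np.sqrt(1 - rho) * rng.standard_normal(n_samples)
            lam = np.exp(np.log(depth_scale) + latent)
            counts[:, k] = rng.poisson(lam)
            cols.append(f"b{b+1}_t{t+1}")
            blocks.append(b + 1)
            k += 1
    table = OtuTable(
        pd.DataFrame(counts, index=[f"s{i+1}" for i in range(n_samples)], columns=cols)
    )
    return table, pd.Series(blocks, index=cols, name="block")
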