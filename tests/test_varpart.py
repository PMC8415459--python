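"""PCNM, dbRDA, forward selection, variation partitioning, NMDS+envfit."""

import numpy as np
import pandas as pd
import pytest

from ecoassembly.diversity import bray_curtis, geographic_distance_matrix
from ecoassembly.simulate import SimulationConfig, simulate_regime, simulate_sites
from ecoassembly.varpart import (
    dbrda_adjusted_r2,
    forward_select,
    nmds_envfit,
    pcnm,
    variation_partition,
)


def _line_geo(n=10, step=1.0):
    idx = [f"s{i}" for i in range(n)]
    x = np.arange(n) * step
    d = np.abs(x[:, None] - x[None, :])
    return pd.DataFrame(d, index=idx, columns=idx)


class TestPcnm:
    def test_orthogonality(self):
        sites = simulate_sites(20, seed=1)
        basis = pcnm(geographic_distance_matrix(sites))
        V = basis.vectors.to_numpy()
        G = V.T @ V
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(G)).max()

    def test_line_sites_match_direct_eigendecomposition(self):
        # equidistant sites on a line: compare against an independent
        # eigen-decomposition of the truncated, double-centered matrix
        geo = _line_geo(12)
        basis = pcnm(geo)
        D = geo.to_numpy().copy()
        t = 1.0  # MST edge on the line
        D2 = np.where(D > t, 4 * t, D) ** 2
        n = len(D)
        J = np.eye(n) - 1 / n
        B = -0.5 * J @ D2 @ J
        vals = np.sort(np.linalg.eigvalsh(B))[::-1]
        pos = vals[vals > 1e-9 * vals.max()]
        assert basis.truncation == pytest.approx(1.0)
        assert len(basis.eigenvalues) == len(pos)
        assert np.allclose(np.sort(basis.eigenvalues)[::-1], pos)

    def test_scale_invariance_of_patterns(self):
        geo = _line_geo(10)
        b1 = pcnm(geo)
        b2 = pcnm(geo * 7.5)
        assert b2.truncation == pytest.approx(7.5 * b1.truncation)
        # eigenvector patterns identical up to sign and scaling
        v1 = b1.vectors.to_numpy()
        v2 = b2.vectors.to_numpy()
        for k in range(min(3, v1.shape[1])):
            c = abs(np.corrcoef(v1[:, k], v2[:, k])[0, 1])
            assert c > 0.999

    def test_duplicate_coordinates_rejected(self):
        d = pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("abc"))
        with pytest.raises(ValueError, match="truncation"):
            pcnm(d)


class TestDbrda:
    def test_zero_predictors_r2_zero(self, rng):
        sites = simulate_sites(15, seed=2)
        bc = geographic_distance_matrix(sites) / 1000.0
        adj, raw, p = dbrda_adjusted_r2(bc, pd.DataFrame(index=bc.index))
        assert raw == 0.0 and adj == 0.0

    def test_permuted_predictors_near_zero(self):
        cfg = SimulationConfig(
            n_sites=25, n_taxa=80, reads_per_sample=800, regime="selection",
            niche_strength=0.5, seed=3,
        )
        sites = simulate_sites(25, seed=3)
        table, _ = simulate_regime(cfg, sites=sites)
        bc = bray_curtis(table)
        rng = np.random.default_rng(0)
        shuffled = sites[["env1"]].sample(frac=1.0, random_state=1).set_axis(sites.index)
        adj, _, _ = dbrda_adjusted_r2(bc, shuffled)
        assert adj < 0.15

    def test_constructed_response_high_r2(self):
        # distances built directly from the predictor
        idx = [f"s{i}" for i in range(20)]
        rng = np.random.default_rng(5)
        x = rng.normal(size=20)
        d = pd.DataFrame(
            np.abs(x[:, None] - x[None, :]), index=idx, columns=idx
        )
        adj, raw, _ = dbrda_adjusted_r2(d, pd.DataFrame({"x": x}, index=idx))
        assert adj > 0.9

    def test_matches_classic_rda_on_euclidean_distances(self):
        # dbRDA on Euclidean distances of raw data equals RDA on the data
        rng = np.random.default_rng(7)
        n = 15
        idx = [f"s{i}" for i in range(n)]
        Y = rng.normal(size=(n, 4))
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)}, index=idx)
        from scipy.spatial.distance import pdist, squareform

        d = pd.DataFrame(squareform(pdist(Y)), index=idx, columns=idx)
        _, r2_db, _ = dbrda_adjusted_r2(d, X)
        # classic RDA R^2
        Yc = Y - Y.mean(axis=0)
        Xd = np.column_stack([np.ones(n), X.to_numpy()])
        fitted = Xd @ np.linalg.lstsq(Xd, Yc, rcond=None)[0]
        r2_rda = (fitted**2).sum() / (Yc**2).sum()
        assert r2_db == pytest.approx(r2_rda, abs=1e-8)

    def test_rank_deficient_rejected(self):
        idx = [f"s{i}" for i in range(8)]
        x = np.arange(8.0)
        d = pd.DataFrame(np.abs(x[:, None] - x[None, :]), index=idx, columns=idx)
        X = pd.DataFrame({"a": x, "b": 2 * x}, index=idx)
        with pytest.raises(ValueError, match="rank"):
            dbrda_adjusted_r2(d, X)


class TestForwardSelect:
    def _selection_setup(self, seed):
        sites = simulate_sites(40, seed=seed, spatial_autocorr=0)
        cfg = SimulationConfig(
            n_sites=40, n_taxa=100, reads_per_sample=1000, regime="selection",
            niche_strength=0.5, seed=seed,
        )
        table, _ = simulate_regime(cfg, sites=sites)
        return bray_curtis(table), sites

    def test_true_driver_found(self):
        bc, sites = self._selection_setup(seed=1)
        sel = forward_select(bc, sites[["env1", "env2", "env3", "env4"]], seed=1)
        assert sel and sel[0] == "env1"

    def test_deterministic_under_seed(self):
        bc, sites = self._selection_setup(seed=2)
        cand = sites[["env1", "env2", "env3", "env4"]]
        assert forward_select(bc, cand, seed=5) == forward_select(bc, cand, seed=5)

    def test_never_exceeds_full_model(self):
        bc, sites = self._selection_setup(seed=3)
        cand = sites[["env1", "env2", "env3", "env4"]]
        sel = forward_select(bc, cand, seed=3)
        if len(sel) > 1:
            adj_sel, _, _ = dbrda_adjusted_r2(bc, cand[sel])
            adj_full, _, _ = dbrda_adjusted_r2(bc, cand)
            assert adj_sel <= adj_full + 1e-9


class TestVariationPartition:
    def test_inclusion_exclusion_identity(self):
        sites = simulate_sites(30, seed=4)
        cfg = SimulationConfig(
            n_sites=30, n_taxa=80, reads_per_sample=800, regime="selection",
            niche_strength=0.7, seed=4,
        )
        table, _ = simulate_regime(cfg, sites=sites)
        bc = bray_curtis(table)
        geo = geographic_distance_matrix(sites)
        basis = pcnm(geo)
        res = variation_partition(
            bc,
            {
                "soil": sites[["env1", "env2"]],
                "climate": sites[["env3"]],
                "space": basis.vectors.iloc[:, :4],
            },
        )
        total = sum(v for k, v in res.fractions.items() if k != "residual")
        assert total == pytest.approx(res.totals["full"], abs=1e-9)
        assert res.fractions["residual"] == pytest.approx(1 - res.totals["full"], abs=1e-9)
        # each single set's total reconstructs from its four regions
        f = res.fractions
        recon = (
            f["pure_soil"] + f["shared_soil_climate"] + f["shared_soil_space"]
            + f["shared_all"]
        )
        assert recon == pytest.approx(res.totals["soil"], abs=1e-9)

    def test_duplicated_partition_moves_signal_to_shared(self):
        sites = simulate_sites(30, seed=5)
        cfg = SimulationConfig(
            n_sites=30, n_taxa=80, reads_per_sample=800, regime="selection",
            niche_strength=0.5, seed=5,
        )
        table, _ = simulate_regime(cfg, sites=sites)
        bc = bray_curtis(table)
        basis = pcnm(geographic_distance_matrix(sites))
        res = variation_partition(
            bc,
            {
                "soil": sites[["env1"]],
                "climate": sites[["env1_copy"]].set_axis(["env1"], axis=1)
                if False
                else sites[["env1"]].rename(columns={"env1": "env1b"}),
                "space": basis.vectors.iloc[:, :3],
            },
        )
        assert abs(res.fractions["pure_soil"]) < 0.02
        assert abs(res.fractions["pure_climate"]) < 0.02
        assert res.fractions["shared_soil_climate"] > 0.2

    def test_spacefree_generator_pure_space_near_zero(self):
        sites = simulate_sites(30, seed=6, spatial_autocorr=0.0)
        cfg = SimulationConfig(
            n_sites=30, n_taxa=80, reads_per_sample=800, regime="selection",
            niche_strength=0.5, seed=6,
        )
        table, _ = simulate_regime(cfg, sites=sites)
        bc = bray_curtis(table)
        basis = pcnm(geographic_distance_matrix(sites))
        res = variation_partition(
            bc,
            {
                "soil": sites[["env1"]],
                "climate": sites[["env2"]],
                "space": basis.vectors.iloc[:, :3],
            },
        )
        assert res.fractions["pure_space"] < 0.05

    def test_empty_set_warns(self):
        sites = simulate_sites(12, seed=7)
        geo = geographic_distance_matrix(sites)
        bc = geo / geo.values.max()
        with pytest.warns(UserWarning, match="empty"):
            variation_partition(
                bc,
                {
                    "soil": sites[["env1"]],
                    "climate": pd.DataFrame(index=sites.index),
                    "space": sites[["env2"]],
                },
            )


class TestNmdsEnvfit:
    def test_one_dimensional_gradient(self):
        idx = [f"s{i}" for i in range(16)]
        x = np.linspace(0, 1, 16)
        d = pd.DataFrame(np.abs(x[:, None] - x[None, :]), index=idx, columns=idx)
        md = pd.DataFrame({"grad": x, "noise": np.cos(17 * x)}, index=idx)
        fit = nmds_envfit(d, md, k=2, n_perm=199, seed=0)
        assert fit.stress < 0.05
        r2 = dict(zip(fit.envfit["variable"], fit.envfit["r2"]))
        assert r2["grad"] > 0.9

    def test_permuted_variable_not_significant(self, rng):
        idx = [f"s{i}" for i in range(18)]
        x = rng.normal(size=18)
        d = pd.DataFrame(np.abs(x[:, None] - x[None, :]), index=idx, columns=idx)
        md = pd.DataFrame({"x": x, "perm": rng.permutation(x)}, index=idx)
        fit = nmds_envfit(d, md, n_perm=199, seed=1, collinearity_rho=1.01)
        p = dict(zip(fit.envfit["variable"], fit.envfit["p"]))
        assert p["perm"] > 0.05

    def test_collinear_variable_prefiltered(self, rng):
        idx = [f"s{i}" for i in range(14)]
        x = rng.normal(size=14)
        d = pd.DataFrame(np.abs(x[:, None] - x[None, :]), index=idx, columns=idx)
        md = pd.DataFrame({"x": x, "x_dup": 2 * x + 0.001 * rng.normal(size=14)}, index=idx)
        fit = nmds_envfit(d, md, n_perm=49, seed=0)
        assert list(fit.envfit["variable"]) == ["x"]

    def test_too_few_samples(self):
        idx = ["a", "b", "c"]
        d = pd.DataFrame(np.ones((3, 3)) - np.eye(3), index=idx, columns=idx)
        with pytest.raises(ValueError):
            nmds_envfit(d, k=2)
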