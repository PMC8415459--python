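"""betaMNTD/betaNTI, Raup-Crick, process classification and phylo signal."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ecoassembly.assembly import (
    beta_mntd,
    beta_mntd_matrix,
    bnti,
    classify_pair,
    pair_table,
    process_summary,
    phylo_signal,
    raup_crick_bray,
)
from ecoassembly.tables import OtuTable
from ecoassembly.trees import cophenetic_matrix, parse_newick


def _dm3():
    return pd.DataFrame(
        [[0, 1, 3], [1, 0, 2], [3, 2, 0]],
        index=["t1", "t2", "t3"],
        columns=["t1", "t2", "t3"],
        dtype=float,
    )


class TestBetaMntd:
    def test_identical_communities_zero(self):
        rel = pd.Series({"t1": 0.4, "t2": 0.6})
        assert beta_mntd(rel, rel, _dm3()) == 0.0

    def test_single_taxon_pair(self):
        d = pd.DataFrame([[0, 2], [2, 0]], index=["t1", "t2"], columns=["t1", "t2"], dtype=float)
        assert beta_mntd(pd.Series({"t1": 1.0}), pd.Series({"t2": 1.0}), d) == 2.0

    def test_hand_evaluation(self):
        # 0.5 * [1*1 + (0.5*1 + 0.5*3)] = 1.5
        a = pd.Series({"t1": 1.0})
        b = pd.Series({"t2": 0.5, "t3": 0.5})
        assert beta_mntd(a, b, _dm3()) == pytest.approx(1.5)

    def test_symmetry(self, rng):
        d = _dm3()
        a = pd.Series(rng.dirichlet([1, 1, 1]), index=d.index)
        b = pd.Series(rng.dirichlet([1, 1, 1]), index=d.index)
        assert beta_mntd(a, b, d) == pytest.approx(beta_mntd(b, a, d))

    def test_matrix_agrees_with_pairwise(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 20, size=(4, 3)) + np.eye(4, 3, dtype=int),
            index=list("abcd"),
            columns=["t1", "t2", "t3"],
        )
        table = OtuTable(counts)
        bm = beta_mntd_matrix(table, _dm3())
        rel = counts.div(counts.sum(axis=1), axis=0)
        for i, j in itertools.combinations(counts.index, 2):
            assert bm.loc[i, j] == pytest.approx(beta_mntd(rel.loc[i], rel.loc[j], _dm3()))

    def test_missing_taxon_errors(self):
        with pytest.raises(KeyError):
            beta_mntd(pd.Series({"zz": 1.0}), pd.Series({"t1": 1.0}), _dm3())


class TestBnti:
    def _exhaustive_null(self, counts, D):
        """Brute-force betaMNTD null over all tip-label permutations."""
        rel = counts.div(counts.sum(axis=1), axis=0)
        taxa = list(D.index)
        vals = {pair: [] for pair in itertools.combinations(counts.index, 2)}
        for perm in itertools.permutations(range(len(taxa))):
            Dp = pd.DataFrame(
                D.to_numpy()[np.ix_(perm, perm)], index=taxa, columns=taxa
            )
            for i, j in vals:
                vals[(i, j)].append(beta_mntd(rel.loc[i], rel.loc[j], Dp))
        return vals

    def test_null_matches_exhaustive_on_4_tips(self):
        tree = parse_newick("((t1:1,t2:1):2,(t3:1.5,t4:0.5):1);")
        D = cophenetic_matrix(tree)
        counts = pd.DataFrame(
            [[10, 5, 0, 0], [0, 0, 8, 7], [3, 0, 9, 0]],
            index=["a", "b", "c"],
            columns=["t1", "t2", "t3", "t4"],
        )
        table = OtuTable(counts)
        z, bm, deg = bnti(table, D, n_null=999, seed=5)
        exact = self._exhaustive_null(counts, D)
        for (i, j), nulls in exact.items():
            nulls = np.asarray(nulls)
            mean_e, sd_e = nulls.mean(), nulls.std(ddof=1)
            z_exact = (bm.loc[i, j] - mean_e) / sd_e
            # 999 sampled permutations of only 24 distinct values: MC error
            assert z.loc[i, j] == pytest.approx(z_exact, abs=0.35)

    def test_star_tree_degenerate(self):
        tree = parse_newick("(t1:1,t2:1,t3:1);")
        D = cophenetic_matrix(tree)
        counts = pd.DataFrame(
            [[5, 0, 0], [0, 5, 0]], index=["a", "b"], columns=["t1", "t2", "t3"]
        )
        z, bm, deg = bnti(OtuTable(counts), D, n_null=99, seed=0)
        assert deg.loc["a", "b"]
        assert np.isnan(z.loc["a", "b"])

    def test_identical_communities_degenerate(self):
        tree = parse_newick("((t1:1,t2:1):1,t3:2);")
        D = cophenetic_matrix(tree)
        counts = pd.DataFrame(
            [[5, 5, 0], [5, 5, 0]], index=["a", "b"], columns=["t1", "t2", "t3"]
        )
        z, bm, deg = bnti(OtuTable(counts), D, n_null=99, seed=0)
        assert bm.loc["a", "b"] == 0.0
        assert deg.loc["a", "b"]

    def test_too_few_nulls_rejected(self, random_table):
        with pytest.raises(ValueError):
            bnti(random_table, pd.DataFrame(), n_null=1)


class TestRaupCrick:
    def test_bounds(self, random_table):
        rc = raup_crick_bray(random_table, n_null=99, seed=0)
        iu = np.triu_indices(rc.shape[0], 1)
        assert ((rc.to_numpy()[iu] >= -1) & (rc.to_numpy()[iu] <= 1)).all()

    def test_one_taxon_metacommunity_all_ties(self):
        counts = pd.DataFrame([[10], [7]], index=["a", "b"], columns=["t1"])
        rc = raup_crick_bray(OtuTable(counts), n_null=99, seed=0)
        assert rc.loc["a", "b"] == pytest.approx(0.0)

    def test_identical_pair_in_diverse_metacommunity(self, rng):
        # two identical samples among divergent ones: nulls almost surely
        # exceed the observed dissimilarity of 0
        base = rng.integers(1, 30, size=12)
        rows = [base, base]
        for k in range(6):
            rows.append(np.roll(base, k + 1) * rng.integers(1, 4, size=12))
        counts = pd.DataFrame(
            np.array(rows), index=[f"s{i}" for i in range(8)],
            columns=[f"t{j}" for j in range(12)],
        )
        rc = raup_crick_bray(OtuTable(counts), n_null=199, seed=1)
        assert rc.loc["s0", "s1"] <= -0.9


class TestClassification:
    @pytest.mark.parametrize(
        "z, rc, expected",
        [
            (2.5, None, "variable_selection"),
            (-2.5, None, "homogeneous_selection"),
            (1.0, 0.97, "dispersal_limitation"),
            (1.0, -0.97, "homogenizing_dispersal"),
            (0.0, 0.0, "undominated"),
            (2.0, 0.5, "undominated"),  # |bNTI| <= 2 falls through to RC
        ],
    )
    def test_five_way_rules(self, z, rc, expected):
        assert classify_pair(z, rc) == expected

    def test_degenerate_falls_through_to_rc(self):
        assert classify_pair(np.nan, 0.99, degenerate=True) == "dispersal_limitation"

    def test_missing_rc_when_required(self):
        with pytest.raises(ValueError):
            classify_pair(1.0, None)

    def test_fractions_sum_to_one_and_sder(self):
        labels = (
            ["variable_selection"] * 5
            + ["homogeneous_selection"] * 1
            + ["dispersal_limitation"] * 2
            + ["undominated"] * 2
        )
        s = process_summary(labels)
        assert sum(s.fractions.values()) == pytest.approx(1.0)
        assert s.sder_null == pytest.approx((0.5 + 0.1) / 0.2)

    def test_sder_infinite_flag(self):
        s = process_summary(["undominated"] * 4)
        assert s.sder_infinite

    def test_pair_table_row_per_unordered_pair(self, rng):
        n = 5
        idx = [f"s{i}" for i in range(n)]
        z = pd.DataFrame(rng.normal(size=(n, n)), index=idx, columns=idx)
        z = (z + z.T) / 2
        rc = pd.DataFrame(np.zeros((n, n)), index=idx, columns=idx)
        deg = pd.DataFrame(False, index=idx, columns=idx)
        pt = pair_table(z, z.abs(), rc, deg)
        assert len(pt) == n * (n - 1) // 2


class TestPhyloSignal:
    def _setup(self, lam, seed=0):
        from ecoassembly.simulate import (
            SimulationConfig,
            simulate_regime,
            simulate_sites,
            simulate_tree,
        )

        tree = simulate_tree(100, seed=seed)
        sites = simulate_sites(30, seed=seed, n_env=4)
        cfg = SimulationConfig(
            n_sites=30, n_taxa=100, reads_per_sample=1500, regime="selection",
            niche_strength=0.5, trait_conservatism=lam, seed=seed, n_env=4,
            selection_vars=("env1", "env2", "env3"),
        )
        table, _ = simulate_regime(cfg, tree=tree, sites=sites)
        return table, cophenetic_matrix(tree), sites

    def test_conserved_traits_give_short_class_signal(self):
        table, D, sites = self._setup(lam=1.0, seed=2)
        classes = phylo_signal(
            table, D, sites, ["env1", "env2", "env3"], n_classes=6, n_perm=199, seed=0
        )
        # autocorrelation convention: similar niches among close relatives
        # read as positive r in the shortest phylogenetic distance class
        assert classes[0].r > 0
        assert classes[0].p < 0.05

    def test_unconserved_traits_no_short_class_signal(self):
        table, D, sites = self._setup(lam=0.0, seed=2)
        classes = phylo_signal(
            table, D, sites, ["env1", "env2", "env3"], n_classes=6, n_perm=199, seed=0
        )
        assert abs(classes[0].r) < 0.15

    def test_constant_variable_rejected(self):
        table, D, sites = self._setup(lam=1.0, seed=3)
        sites = sites.copy()
        sites["flat"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            phylo_signal(table, D, sites, ["flat"], n_perm=19)
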