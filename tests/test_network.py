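import warnings

import numpy as np
import pandas as pd
import pytest

import tissuexpr as tx


def random_adjacency(seed: int, n: int = 30) -> np.ndarray:
    rng = np.random.default_rng(seed)
    a = rng.uniform(0, 1, (n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    return a


def brute_force_tom(a: np.ndarray) -> np.ndarray:
    """Triple-loop evaluation of the unsigned TOM formula."""
    n = a.shape[0]
    k = a.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n))
            tom[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


class TestFilterForNetwork:
    def test_default_keeps_one_good_tissue(self, toy_matrix):
        # g4 > 1 in all samples of tissues A and C, < 1 in B
        out = tx.filter_for_network(toy_matrix, min_genes=1)
        assert "g4" in out.gene_ids and "g1" in out.gene_ids
        assert "g3" not in out.gene_ids

    def test_strict_requires_every_tissue(self, toy_matrix):
        out = tx.filter_for_network(toy_matrix, mode="strict", min_genes=1)
        assert out.gene_ids == ["g1"]

    def test_strict_subset_of_default(self, synth_default):
        matrix, _ = synth_default
        default = set(tx.filter_for_network(matrix).gene_ids)
        strict = set(tx.filter_for_network(matrix, mode="strict",
                                           min_genes=1).gene_ids)
        assert strict <= default

    def test_too_few_genes_is_hard_error(self, toy_matrix):
        with pytest.raises(ValueError, match="filter"):
            tx.filter_for_network(toy_matrix, min_genes=10)


class TestScaleFreeFit:
    def test_power_law_degrees_score_high(self):
        # frequencies exactly proportional to k^-2 over a decade
        ks = np.arange(1, 11, dtype=float)
        counts = np.round(10000 * ks**-2.0).astype(int)
        degrees = np.repeat(ks, counts)
        fit = tx.scale_free_fit_index(degrees, n_bins=10)
        assert fit >= 0.9

    def test_fit_bounded_by_one(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            fit = tx.scale_free_fit_index(rng.uniform(0.1, 5, 200))
            assert fit <= 1.0

    def test_increasing_distribution_scores_negative(self):
        ks = np.arange(1, 11, dtype=float)
        counts = np.round(100 * ks**2).astype(int)
        assert tx.scale_free_fit_index(np.repeat(ks, counts)) < 0

    def test_degenerate_single_bin_errors(self):
        with pytest.raises(ValueError):
            tx.scale_free_fit_index(np.array([2.0, 2.0]), n_bins=10)


class TestPickSoftThreshold:
    def test_returns_smallest_qualifying_beta(self):
        # two anti/correlated blocks give a hub-like connectivity profile;
        # just verify the contract: either fit > target at the returned beta,
        # or the returned beta maximizes the fit table.
        rng = np.random.default_rng(4)
        latent = rng.normal(0, 1, 40)
        expr = pd.DataFrame(
            np.outer(rng.uniform(0.5, 1, 60), latent)
            + rng.normal(0, 0.8, (60, 40)),
            index=[f"g{i}" for i in range(60)],
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            beta, rsq, table = tx.pick_soft_threshold(expr)
        qualifying = table[table.fit_index > 0.8]
        if len(qualifying):
            assert beta == int(qualifying.iloc[0].beta)
        else:
            assert rsq == pytest.approx(table.fit_index.max())

    def test_tiny_input_rejected(self):
        expr = pd.DataFrame(np.ones((1, 5)))
        with pytest.raises(ValueError):
            tx.pick_soft_threshold(expr)


class TestTopologicalOverlap:
    def test_two_gene_hand_value(self):
        a = np.array([[0.0, 0.4], [0.4, 0.0]])
        tom = tx.topological_overlap(a)
        # L = 0, k = 0.4 each: TOM = 0.4 / (0.4 + 1 - 0.4) = 0.4
        assert tom[0, 1] == pytest.approx(0.4)
        assert tom[0, 0] == 1.0

    def test_three_gene_saturated_clique(self):
        a = np.ones((3, 3)) - np.eye(3)
        tom = tx.topological_overlap(a)
        # L_ij = 1, k = 2: TOM = (1 + 1) / (2 + 1 - 1) = 1
        assert np.allclose(tom[~np.eye(3, dtype=bool)], 1.0)

    def test_zero_adjacency_gives_zero_overlap(self):
        tom = tx.topological_overlap(np.zeros((4, 4)))
        assert np.allclose(tom, np.eye(4))

    def test_matches_brute_force(self):
        for seed in range(3):
            a = random_adjacency(seed, n=15)
            np.testing.assert_allclose(
                tx.topological_overlap(a), brute_force_tom(a), atol=1e-10
            )

    def test_symmetric_unit_interval(self):
        for seed in range(5):
            tom = tx.topological_overlap(random_adjacency(seed))
            assert np.allclose(tom, tom.T)
            assert tom.min() >= 0 and tom.max() <= 1

    def test_asymmetric_input_rejected(self):
        a = random_adjacency(0)
        a[0, 1] += 0.2
        with pytest.raises(ValueError, match="symmetric"):
            tx.topological_overlap(a)

    def test_dataframe_round_trip(self):
        a = random_adjacency(1, n=5)
        genes = list("abcde")
        frame = pd.DataFrame(a, index=genes, columns=genes)
        tom = tx.topological_overlap(frame)
        assert list(tom.index) == genes


def two_block_tom(n_per_block=60, within=0.8, seed=0):
    rng = np.random.default_rng(seed)
    n = 2 * n_per_block
    a = rng.uniform(0, 0.02, (n, n))
    a[:n_per_block, :n_per_block] = rng.uniform(within - 0.1, within,
                                                (n_per_block, n_per_block))
    a[n_per_block:, n_per_block:] = rng.uniform(within - 0.1, within,
                                                (n_per_block, n_per_block))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    genes = [f"g{i}" for i in range(n)]
    return pd.DataFrame(tx.topological_overlap(a), index=genes, columns=genes)


class TestDetectModules:
    def test_two_planted_blocks_recovered_exactly(self):
        tom = two_block_tom()
        modules = tx.detect_modules(tom)
        assert len(modules.modules) == 2
        sizes = sorted(len(g) for g in modules.modules.values())
        assert sizes == [60, 60]
        first = set(modules.modules["M1"])
        assert first == {f"g{i}" for i in range(60)} or \
            first == {f"g{i}" for i in range(60, 120)}

    def test_min_size_larger_than_input_unassigns_everything(self):
        tom = two_block_tom(n_per_block=20)
        with pytest.warns(UserWarning, match="unassigned"):
            modules = tx.detect_modules(
                tom, tx.NetworkConfig(min_module_size=100)
            )
        assert not modules.modules
        assert len(modules.unassigned) == 40

    def test_modules_partition_assigned_genes(self, network_default):
        modules = network_default.modules
        all_assigned = [g for genes in modules.modules.values() for g in genes]
        assert len(all_assigned) == len(set(all_assigned))
        assert set(all_assigned).isdisjoint(modules.unassigned)


class TestModuleEigengene:
    def test_shared_profile_is_recovered(self):
        rng = np.random.default_rng(5)
        profile = rng.normal(0, 1, 25)
        expr = pd.DataFrame(
            [3 * profile + 1, 5 * profile - 2, 0.5 * profile],
            index=["a", "b", "c"],
        )
        eig, var = tx.module_eigengene(expr)
        z = (profile - profile.mean()) / profile.std()
        expected = z / np.linalg.norm(z)
        np.testing.assert_allclose(eig.to_numpy(), expected, atol=1e-8)
        assert var == pytest.approx(1.0)

    def test_sign_convention_positive_mean_correlation(self, network_default):
        modules = network_default.modules
        expr = network_default.expr
        for mid, genes in list(modules.modules.items())[:3]:
            eig = modules.eigengenes[mid].to_numpy()
            cors = [np.corrcoef(expr.loc[g], eig)[0, 1] for g in genes[:20]]
            assert np.mean(cors) >= 0

    def test_variance_explained_in_unit_interval(self, network_default):
        for v in network_default.modules.var_explained.values():
            assert 0 < v <= 1

    def test_zero_variance_gene_dropped_with_warning(self):
        rng = np.random.default_rng(6)
        profile = rng.normal(0, 1, 10)
        expr = pd.DataFrame([profile, 2 * profile, np.zeros(10)],
                            index=["a", "b", "flat"])
        with pytest.warns(UserWarning, match="zero-variance"):
            eig, _ = tx.module_eigengene(expr)
        assert np.isfinite(eig.to_numpy()).all()


class TestMergeCloseModules:
    def test_identical_eigengene_modules_merge(self):
        rng = np.random.default_rng(7)
        profile = rng.normal(0, 1, 30)
        expr = pd.DataFrame(
            np.vstack([np.outer(rng.uniform(1, 2, 6), profile)
                       + rng.normal(0, 0.01, (6, 30))]),
            index=[f"g{i}" for i in range(6)],
        )
        start = tx.ModuleSet(modules={"M1": ["g0", "g1", "g2"],
                                      "M2": ["g3", "g4", "g5"]},
                             unassigned=[])
        merged = tx.merge_close_modules(start, expr)
        assert len(merged.modules) == 1
        assert len(merged.modules["M1"]) == 6

    def test_distant_modules_stay_apart(self):
        rng = np.random.default_rng(8)
        p1, p2 = rng.normal(0, 1, (2, 30))
        expr = pd.DataFrame(
            np.vstack([np.outer(np.ones(3), p1), np.outer(np.ones(3), p2)])
            + rng.normal(0, 0.01, (6, 30)),
            index=[f"g{i}" for i in range(6)],
        )
        start = tx.ModuleSet(modules={"M1": ["g0", "g1", "g2"],
                                      "M2": ["g3", "g4", "g5"]},
                             unassigned=[])
        merged = tx.merge_close_modules(start, expr)
        assert len(merged.modules) == 2

    def test_module_count_never_increases(self, network_default):
        # merging the final module set again changes nothing
        modules = network_default.modules
        again = tx.merge_close_modules(modules, network_default.expr)
        assert len(again.modules) <= len(modules.modules)
        assert len(again.modules) == len(modules.modules)  # already a fixpoint


class TestModuleTraitAssociation:
    @staticmethod
    def _modules_from_eigengenes(eigs: pd.DataFrame) -> tx.ModuleSet:
        return tx.ModuleSet(modules={m: [f"{m}_gene"] for m in eigs.columns},
                            unassigned=[], eigengenes=eigs)

    def test_indicator_eigengene_has_r_one(self):
        samples = [f"s{i}" for i in range(12)]
        design = pd.Series(["A"] * 4 + ["B"] * 4 + ["C"] * 4, index=samples)
        ind = (design == "A").astype(float)
        eigs = pd.DataFrame({"M1": (ind - ind.mean())}, index=samples)
        table = tx.module_trait_association(
            self._modules_from_eigengenes(eigs), design)
        row = table[(table.module_id == "M1") & (table.tissue == "A")].iloc[0]
        assert row.r == pytest.approx(1.0)
        assert row.is_tissue_specific

    def test_orthogonal_eigengene_p_matches_t_oracle(self):
        from scipy import stats
        samples = [f"s{i}" for i in range(10)]
        design = pd.Series(["A"] * 5 + ["B"] * 5, index=samples)
        # orthogonal to the A-indicator: zero-sum within each tissue
        e = np.array([1.0, -1, 2, -2, 0, 3, -3, 1, -1, 0])
        eigs = pd.DataFrame({"M1": e}, index=samples)
        table = tx.module_trait_association(
            self._modules_from_eigengenes(eigs), design)
        row = table[(table.module_id == "M1") & (table.tissue == "A")].iloc[0]
        assert row.r == pytest.approx(0.0, abs=1e-12)
        # closed-form: t = 0 at r = 0, two-sided p = 1
        assert row.p == pytest.approx(2 * stats.t.sf(0, df=8)) == 1.0

    def test_r_values_bounded(self, network_default):
        t = network_default.trait_table
        assert t.r.abs().max() <= 1.0
        assert ((t.p > 0) | (t.p == 0)).all() and (t.p <= 1).all()


class TestCallHubGenes:
    def test_eigengene_like_gene_is_hub(self):
        samples = [f"s{i}" for i in range(20)]
        design = pd.Series(["A"] * 5 + ["B"] * 15, index=samples)
        rng = np.random.default_rng(9)
        ind = (design == "A").to_numpy(float)
        expr = pd.DataFrame(
            np.outer(np.ones(4), ind) + rng.normal(0, 0.05, (4, 20)),
            index=["g0", "g1", "g2", "g3"], columns=samples,
        )
        modules = tx.ModuleSet(modules={"M1": list(expr.index)}, unassigned=[])
        modules = tx.merge_close_modules(modules, expr)
        trait = tx.module_trait_association(modules, design)
        hubs = tx.call_hub_genes(modules, expr, design, trait)
        assert hubs.is_hub.all()
        assert hubs.mm.min() > 0.9 and hubs.gs.min() > 0.9

    def test_noise_genes_rarely_pass_membership_threshold(self):
        # 200 seeded noise genes appended to a tight module: the noise
        # genes' |MM| should fail the 0.8 cut almost always.
        rng = np.random.default_rng(10)
        samples = [f"s{i}" for i in range(30)]
        design = pd.Series(["A"] * 6 + ["B"] * 24, index=samples)
        ind = (design == "A").to_numpy(float)
        core = np.outer(np.ones(10), ind) + rng.normal(0, 0.05, (10, 30))
        noise = rng.normal(0, 1, (200, 30))
        expr = pd.DataFrame(np.vstack([core, noise]),
                            index=[f"g{i}" for i in range(210)],
                            columns=samples)
        modules = tx.ModuleSet(modules={"M1": list(expr.index)}, unassigned=[])
        modules = tx.merge_close_modules(modules, expr)
        trait = tx.module_trait_association(modules, design)
        hubs = tx.call_hub_genes(modules, expr, design, trait).set_index("gene_id")
        noise_ids = [f"g{i}" for i in range(10, 210)]
        non_hub_fraction = (~hubs.loc[noise_ids, "is_hub"]).mean()
        assert non_hub_fraction >= 0.95

    def test_no_tissue_specific_module_gives_empty_table(self):
        samples = [f"s{i}" for i in range(8)]
        design = pd.Series(["A"] * 4 + ["B"] * 4, index=samples)
        rng = np.random.default_rng(11)
        expr = pd.DataFrame(rng.normal(0, 1, (4, 8)),
                            index=list("wxyz"), columns=samples)
        modules = tx.merge_close_modules(
            tx.ModuleSet(modules={"M1": list("wxyz")}, unassigned=[]), expr)
        trait = tx.module_trait_association(modules, design)
        trait["is_tissue_specific"] = False
        with pytest.warns(UserWarning, match="no tissue-specific"):
            hubs = tx.call_hub_genes(modules, expr, design, trait)
        assert hubs.empty

    def test_hub_set_confined_to_tissue_specific_modules(self, network_default):
        hubs = network_default.hub_table
        spec = network_default.trait_table
        allowed = set(spec.loc[spec.is_tissue_specific, "module_id"])
        assert set(hubs.module_id) <= allowed
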