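"""Signed network construction, TOM, module detection, eigenproteins, traits."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from endoprot import (
    SimConfig,
    detect_modules,
    module_eigenproteins,
    module_trait_correlation,
    pick_soft_power,
    signed_adjacency,
    simulate_cohort,
    tom_similarity,
    zscale,
)
from endoprot.wgcna import ModuleAssignment, scale_free_fit


def frame(arr, prefix="P"):
    return pd.DataFrame(arr, columns=[f"{prefix}{j}" for j in range(arr.shape[1])])


@pytest.fixture(scope="module")
def planted_network(default_cohort):
    npx, clinical, truth = default_cohort
    scaled = zscale(npx)
    adj = signed_adjacency(scaled.values, 9)
    tom = tom_similarity(adj)
    modules = detect_modules(tom, scaled.values)
    return scaled, clinical, truth, adj, tom, modules


class TestAdjacency:
    def test_closed_forms(self, rng):
        n = 50
        base = rng.normal(size=n)
        X = frame(np.column_stack([base, base, -base, rng.normal(size=n)]))
        adj = signed_adjacency(X, power=9)
        assert adj.iloc[0, 1] == pytest.approx(1.0)  # cor +1
        assert adj.iloc[0, 2] == pytest.approx(0.0, abs=1e-12)  # cor -1
        assert np.diag(adj).tolist() == [1.0] * 4

    def test_zero_correlation_value_at_power_nine(self):
        # analytic value for cor = 0: 0.5^9
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        adj = signed_adjacency(frame(np.column_stack([x, y])), power=9)
        assert adj.iloc[0, 1] == pytest.approx(0.5 ** 9)
        assert 0.5 ** 9 == pytest.approx(0.001953125)

    def test_permutation_invariance(self, rng):
        X = frame(rng.normal(size=(30, 8)))
        perm = list(rng.permutation(X.columns))
        a = signed_adjacency(X, 5)
        b = signed_adjacency(X[perm], 5)
        pd.testing.assert_frame_equal(a.loc[perm, perm], b)

    def test_bounds_and_symmetry(self, rng):
        X = frame(rng.normal(size=(25, 12)))
        adj = signed_adjacency(X, 7)
        a = adj.to_numpy()
        assert ((a >= 0) & (a <= 1)).all()
        np.testing.assert_allclose(a, a.T)


class TestTOM:
    def test_complete_graph_is_all_ones(self):
        adj = pd.DataFrame(np.ones((3, 3)), index=list("abc"), columns=list("abc"))
        tom = tom_similarity(adj)
        np.testing.assert_allclose(tom, 1.0)

    def test_disconnected_blocks_have_zero_overlap(self):
        adj = np.eye(6)
        adj[:3, :3] = 1.0
        adj[3:, 3:] = 1.0
        tom = tom_similarity(pd.DataFrame(adj))
        assert (tom.to_numpy()[:3, 3:] == 0).all()

    def test_matches_triple_loop_oracle(self, rng):
        p = 10
        cor = np.corrcoef(rng.normal(size=(20, p)), rowvar=False)
        A = ((1 + cor) / 2) ** 3
        np.fill_diagonal(A, 1.0)
        tom = tom_similarity(pd.DataFrame(A)).to_numpy()
        # independent brute-force walk over the definition
        k = A.sum(axis=0) - 1.0
        expected = np.eye(p)
        for i in range(p):
            for j in range(p):
                if i == j:
                    continue
                l_ij = sum(A[i, u] * A[u, j] for u in range(p) if u not in (i, j))
                expected[i, j] = (l_ij + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
        np.testing.assert_allclose(tom, expected, atol=1e-12)


class TestSoftPower:
    def test_hub_structured_data_reaches_target(self, rng):
        """Preferential-attachment-like loadings (a few dominant hubs, heavy
        tailed connectivity) produce a scale-free fit above 0.9."""
        n, p = 60, 300
        # lognormal hub strengths: a few dominant proteins, heavy-tailed
        # connectivity, the signature of scale-free co-expression
        lam = np.clip(rng.lognormal(-1.5, 1.0, p), 0.0, 1.0)
        f = rng.normal(size=n)
        X = np.outer(f, lam) + rng.normal(size=(n, p)) * 0.6
        power, fit = pick_soft_power(frame(X), r2_target=0.9)
        assert fit["r_squared"].max() >= 0.9
        assert power == int(fit[fit["r_squared"] >= 0.9]["power"].iloc[0])

    def test_pure_noise_takes_fallback_with_warning(self, rng):
        X = frame(rng.normal(size=(30, 60)))
        with pytest.warns(UserWarning, match="no power reached"):
            power, fit = pick_soft_power(X, r2_target=0.9)
        assert 1 <= power <= 20
        assert len(fit) == 20  # one row per candidate power

    def test_positive_slope_scores_zero(self):
        # frequency increasing with connectivity: anti-scale-free, R^2 forced to 0
        k = np.repeat(np.arange(1.0, 11.0), np.arange(1, 11))
        r2, slope = scale_free_fit(k)
        assert slope > 0 and r2 == 0.0


class TestModuleDetection:
    def test_planted_modules_recovered(self, planted_network):
        _, _, truth, _, _, modules = planted_network
        n_planted = truth.module_label[truth.module_label != "background"].nunique()
        n_found = len(modules.modules())
        assert abs(n_found - n_planted) <= 1
        nz = modules.labels[modules.labels != "grey"]
        tl = truth.module_label.loc[nz.index]
        mask = tl != "background"
        assert adjusted_rand_score(tl[mask], nz[mask]) > 0.8

    def test_module_names_follow_color_order(self, planted_network):
        *_, modules = planted_network
        sizes = modules.sizes().drop("grey", errors="ignore")
        assert sizes.index[0] == "turquoise"
        assert (sizes.sort_values(ascending=False).index == sizes.index).all()

    def test_perfectly_correlated_modules_merge(self, rng):
        n = 40
        f = rng.normal(size=n)
        X = np.column_stack(
            [np.outer(f, np.ones(25)) + rng.normal(size=(n, 25)) * 0.05,
             np.outer(f, np.ones(25)) + rng.normal(size=(n, 25)) * 0.05]
        )
        Xf = frame(X)
        adj = signed_adjacency(Xf, 6)
        tom = tom_similarity(adj)
        modules = detect_modules(tom, Xf, min_module_size=10)
        assert len(modules.modules()) == 1

    def test_min_size_above_any_block_gives_all_grey(self, rng):
        X = frame(rng.normal(size=(20, 30)))
        adj = signed_adjacency(X, 6)
        tom = tom_similarity(adj)
        with pytest.warns(UserWarning):
            modules = detect_modules(tom, X, min_module_size=40)
        assert (modules.labels == "grey").all()

    def test_order_invariance_up_to_names(self, rng):
        f1, f2 = rng.normal(size=(2, 50))
        X = np.column_stack(
            [np.outer(f1, rng.uniform(0.7, 1, 30)) + rng.normal(size=(50, 30)) * 0.3,
             np.outer(f2, rng.uniform(0.7, 1, 25)) + rng.normal(size=(50, 25)) * 0.3]
        )
        Xf = frame(X)
        tom = tom_similarity(signed_adjacency(Xf, 6))
        mods = detect_modules(tom, Xf, min_module_size=10)
        perm = list(rng.permutation(Xf.columns))
        Xp = Xf[perm]
        tom_p = tom_similarity(signed_adjacency(Xp, 6))
        mods_p = detect_modules(tom_p, Xp, min_module_size=10)
        assert adjusted_rand_score(
            mods.labels.loc[perm], mods_p.labels.loc[perm]
        ) == pytest.approx(1.0)


class TestEigenproteins:
    def test_identical_proteins_give_unit_kme(self, rng):
        base = rng.normal(size=40)
        X = frame(np.column_stack([base] * 5 + [rng.normal(size=40)]))
        modules = ModuleAssignment(
            pd.Series(["turquoise"] * 5 + ["grey"], index=X.columns)
        )
        eig = module_eigenproteins(X, modules)
        np.testing.assert_allclose(
            eig.kme.loc[X.columns[:5], "turquoise"], 1.0, atol=1e-10
        )
        # ME tracks the common profile up to scale
        r = np.corrcoef(eig.me["turquoise"], base)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_me_explains_at_least_any_single_member(self, rng):
        f = rng.normal(size=60)
        X = frame(np.outer(f, rng.uniform(0.4, 1, 12)) + rng.normal(size=(60, 12)))
        modules = ModuleAssignment(pd.Series("turquoise", index=X.columns))
        eig = module_eigenproteins(X, modules)
        Xz = (X - X.mean()) / X.std(ddof=1)
        total = (Xz ** 2).to_numpy().sum()
        for col in X.columns:
            v = Xz[col].to_numpy()
            proj = (Xz.to_numpy().T @ v / np.linalg.norm(v)) ** 2
            assert eig.variance_explained["turquoise"] >= proj.sum() / total - 1e-9

    def test_rank_one_noiseless_block_reproduces_factor(self, rng):
        f = rng.normal(size=30)
        X = frame(np.outer(f, rng.uniform(0.5, 1.5, 8)))
        modules = ModuleAssignment(pd.Series("turquoise", index=X.columns))
        eig = module_eigenproteins(X, modules)
        assert abs(np.corrcoef(eig.me["turquoise"], f)[0, 1]) >= 0.999

    def test_hub_is_top_loading_protein(self, planted_network):
        scaled, _, truth, _, _, modules = planted_network
        eig = module_eigenproteins(scaled.values, modules)
        for mod, hub in eig.hubs.items():
            members = modules.members(mod)
            assert hub in set(members)
            assert eig.kme.loc[members, mod].max() == eig.kme.loc[hub, mod]


class TestModuleTrait:
    def test_self_correlation_is_one(self, planted_network):
        scaled, clinical, _, _, _, modules = planted_network
        eig = module_eigenproteins(scaled.values, modules)
        traits = pd.DataFrame({"self": eig.me["turquoise"]})
        mt = module_trait_correlation(eig, traits)
        assert mt.r.loc["turquoise", "self"] == pytest.approx(1.0)

    def test_disease_module_correlates_with_planted_severity(self, planted_network):
        scaled, clinical, truth, _, _, modules = planted_network
        eig = module_eigenproteins(scaled.values, modules)
        patients = scaled.sample_ids[scaled.group == "AD"]
        mt = module_trait_correlation(eig, clinical, samples=patients)
        # the disease module hosts the stepwise proteins; find it by overlap
        stepwise = set(truth.stepwise_set)
        disease_mod = max(
            modules.modules(), key=lambda m: len(stepwise & set(modules.members(m)))
        )
        assert mt.r.loc[disease_mod, "EASI"] > 0.3
        assert mt.p_adj.loc[disease_mod, "EASI"] < 0.05

    def test_permuted_trait_is_null(self, planted_network, rng):
        scaled, clinical, _, _, _, modules = planted_network
        eig = module_eigenproteins(scaled.values, modules)
        rs = []
        for _ in range(20):
            perm = pd.DataFrame(
                {"perm": rng.permutation(clinical.data["EASI"].to_numpy())},
                index=clinical.data.index,
            )
            mt = module_trait_correlation(eig, perm)
            rs.append(abs(mt.r.loc["turquoise", "perm"]))
        assert np.median(rs) < 0.25

    def test_constant_trait_reported_missing(self, planted_network):
        scaled, _, _, _, _, modules = planted_network
        eig = module_eigenproteins(scaled.values, modules)
        traits = pd.DataFrame({"const": 1.0}, index=eig.me.index)
        mt = module_trait_correlation(eig, traits)
        assert mt.r["const"].isna().all()
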