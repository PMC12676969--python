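"""Linear models, empirical-Bayes moderation, BH, thresholds, Venn groups."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from endoprot import (
    bh_adjust,
    build_design,
    ebayes_moderate,
    fit_linear_models,
    threshold_de,
    venn_trichotomy,
    volcano_table,
)
from endoprot.diffexp import DEResult, estimate_variance_prior

from conftest import make_npx


def two_group_fits(rng, n1=8, n2=8, p=30, delta=0.0):
    y = rng.normal(size=(n1 + n2, p))
    y[:n1, :] += delta
    npx = make_npx(y)
    contrast = pd.Series([1.0] * n1 + [0.0] * n2, index=npx.sample_ids)
    design = build_design(None, contrast)
    return npx, design, fit_linear_models(npx, design)


class TestLinearModels:
    def test_two_group_coef_is_mean_difference(self, rng):
        npx, _, fits = two_group_fits(rng, delta=1.3)
        diff = npx.values.iloc[:8].mean() - npx.values.iloc[8:].mean()
        np.testing.assert_allclose(fits["coef"], diff, atol=1e-10)

    def test_orthogonal_covariate_leaves_coef_unchanged(self, rng):
        y = rng.normal(size=(12, 10))
        npx = make_npx(y)
        contrast = pd.Series([1.0] * 6 + [0.0] * 6, index=npx.sample_ids)
        base = fit_linear_models(npx, build_design(None, contrast))
        # covariate orthogonal to both intercept and contrast
        cov = pd.Series([1, -1, 1, -1, 1, -1] * 2, index=npx.sample_ids, dtype=float)
        design = build_design(None, contrast)
        design["extra"] = cov
        with_cov = fit_linear_models(npx, design)
        np.testing.assert_allclose(base["coef"], with_cov["coef"], atol=1e-10)

    def test_noiseless_planted_shift_recovered_exactly(self):
        y = np.zeros((10, 3))
        y[:5, 1] = 2.5  # planted shift on protein 2 only, no noise
        npx = make_npx(y + 1.0)
        contrast = pd.Series([1.0] * 5 + [0.0] * 5, index=npx.sample_ids)
        fits = fit_linear_models(npx, build_design(None, contrast))
        np.testing.assert_allclose(fits["coef"], [0.0, 2.5, 0.0], atol=1e-12)

    def test_rank_deficient_design_rejected(self, rng):
        npx = make_npx(rng.normal(size=(8, 4)))
        contrast = pd.Series([1.0] * 4 + [0.0] * 4, index=npx.sample_ids)
        design = build_design(None, contrast)
        design["copy"] = design["contrast"]
        with pytest.raises(ValueError, match="rank"):
            fit_linear_models(npx, design)


class TestEbayes:
    def test_d0_zero_reduces_to_ordinary_t(self, rng):
        npx, design, fits = two_group_fits(rng, p=40)
        de = ebayes_moderate(fits, d0_override=0.0)
        ordinary_t = fits["coef"] / (np.sqrt(fits["s2"]) * fits["stdev_unscaled"])
        np.testing.assert_allclose(de.table["t_mod"], ordinary_t, atol=1e-10)

    def test_d0_infinite_pools_all_variances(self, rng):
        _, _, fits = two_group_fits(rng, p=40)
        de = ebayes_moderate(fits, d0_override=np.inf)
        assert de.table["s2_post"].nunique() == 1
        assert de.table["s2_post"].iloc[0] == pytest.approx(de.s0_sq)

    def test_prior_df_recovery_from_hierarchical_draws(self):
        """Variances drawn from the scaled-chi-square hierarchy with known
        (d0 = 4, s0^2 = 1) are recovered within 25% at G = 2,000."""
        rng = np.random.default_rng(42)
        d0_true, s0_sq, d, G = 4.0, 1.0, 14.0, 2000
        sigma2 = d0_true * s0_sq / rng.chisquare(d0_true, G)
        s2 = sigma2 * rng.chisquare(d, G) / d
        d0_hat, s0_hat = estimate_variance_prior(s2, np.full(G, d))
        assert abs(d0_hat - d0_true) / d0_true < 0.25
        assert abs(s0_hat - s0_sq) < 0.25

    def test_identical_variances_take_pooling_path(self):
        fits = pd.DataFrame(
            {"coef": [1.0, 2.0, 3.0], "stdev_unscaled": 0.5,
             "s2": [2.0, 2.0, 2.0], "df_resid": 10.0}
        )
        de = ebayes_moderate(fits)
        assert np.isinf(de.d0)

    def test_matches_limma_reference(self, rng, tmp_path):
        """Moderated statistics agree with the Bioconductor limma reference
        on a small two-group fixture with an age covariate."""
        n, p = 20, 50
        # heterogeneous true variances so the prior df is finite and the
        # moment estimator is exercised end to end
        sigma = np.sqrt(5.0 / rng.chisquare(5.0, p))
        y = rng.normal(size=(n, p)) * sigma
        y[:10, :5] += 1.5
        age = rng.normal(40, 10, n).round(1)
        npx = make_npx(y)
        contrast = pd.Series([1.0] * 10 + [0.0] * 10, index=npx.sample_ids)
        clin = pd.DataFrame({"Age": age}, index=npx.sample_ids)
        design = build_design(clin, contrast)
        fits = fit_linear_models(npx, design)
        de = ebayes_moderate(fits)

        ypath, dpath, opath = (tmp_path / f for f in ("y.csv", "design.csv", "out.csv"))
        pd.DataFrame(y.T).to_csv(ypath, index=False)
        design.to_csv(dpath, index=False)
        rscript = textwrap.dedent(f"""
            suppressMessages(library(limma))
            y <- as.matrix(read.csv("{ypath}"))
            design <- as.matrix(read.csv("{dpath}"))
            fit <- eBayes(lmFit(y, design))
            out <- data.frame(t = fit$t[, "contrast"], p = fit$p.value[, "contrast"],
                              d0 = fit$df.prior, s0 = fit$s2.prior)
            write.csv(out, "{opath}", row.names = FALSE)
        """)
        subprocess.run(["Rscript", "-e", rscript], check=True, capture_output=True)
        ref = pd.read_csv(opath)
        np.testing.assert_allclose(de.table["t_mod"], ref["t"], atol=1e-6)
        np.testing.assert_allclose(de.table["p_raw"], ref["p"], atol=1e-6)
        assert de.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-4)
        assert de.s0_sq == pytest.approx(ref["s0"].iloc[0], rel=1e-4)


class TestBH:
    def test_hand_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_single_value_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50)
    )
    @settings(deadline=None, max_examples=50)
    def test_dominates_raw_and_capped(self, p):
        adj = bh_adjust(p)
        assert (adj >= np.asarray(p) - 1e-12).all()
        assert (adj <= 1.0).all()


def _de_result(coefs, p_adjs):
    table = pd.DataFrame(
        {"coef": coefs, "p_adj": p_adjs},
        index=[f"P{i}" for i in range(len(coefs))],
    )
    return DEResult(table=table, d0=1.0, s0_sq=1.0)


class TestThresholdAndVenn:
    def test_fold_change_cutoff_is_strict(self):
        de = _de_result([1.19, 2.0, 1.21], [0.001, 0.06, 0.01])
        assert threshold_de(de, 1.2, 0.05, "up") == {"P2"}

    def test_down_direction(self):
        de = _de_result([-1.5, -1.0, 1.5], [0.01, 0.01, 0.01])
        assert threshold_de(de, 1.2, 0.05, "down") == {"P0"}

    def test_published_venn_counts(self):
        """169 AD-up and 56 cluster-up proteins overlapping in 40 split into
        129 upregulated-AD, 40 stepwise and 16 unique."""
        up_all = {f"A{i}" for i in range(129)} | {f"S{i}" for i in range(40)}
        up_c1 = {f"S{i}" for i in range(40)} | {f"U{i}" for i in range(16)}
        groups = venn_trichotomy(up_all, up_c1)
        assert len(groups.upregulated_ad) == 129
        assert len(groups.stepwise) == 40
        assert len(groups.unique) == 16
        assert len(groups.stepwise) + len(groups.unique) == len(up_c1)

    def test_identical_sets_all_stepwise(self):
        s = {"a", "b"}
        g = venn_trichotomy(s, s)
        assert g.stepwise == s and not g.unique and not g.upregulated_ad

    def test_disjoint_sets_all_unique(self):
        g = venn_trichotomy({"a"}, {"b", "c"})
        assert g.unique == {"b", "c"} and g.stepwise == set()

    @given(
        st.sets(st.integers(0, 30)), st.sets(st.integers(0, 30))
    )
    @settings(deadline=None, max_examples=100)
    def test_partition_property(self, up_all, up_c1):
        g = venn_trichotomy(up_all, up_c1)
        parts = [g.upregulated_ad, g.stepwise, g.unique]
        assert g.upregulated_ad | g.stepwise | g.unique == up_all | up_c1
        for i in range(3):
            for j in range(i + 1, 3):
                assert not parts[i] & parts[j]
        assert len(g.stepwise) + len(g.unique) == len(up_c1)


class TestVolcano:
    def test_p_one_maps_to_zero(self):
        de = _de_result([0.5], [1.0])
        assert volcano_table(de)["neg_log10_p_adj"].iloc[0] == 0.0

    def test_p_zero_clipped_before_log(self):
        de = _de_result([0.5], [0.0])
        y = volcano_table(de)["neg_log10_p_adj"].iloc[0]
        assert np.isfinite(y) and y > 300

    def test_coef_sign_preserved(self):
        de = _de_result([-2.0, 3.0], [0.01, 0.01])
        assert list(volcano_table(de)["coef"]) == [-2.0, 3.0]
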