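"""REML mixed model: oracles, Satterthwaite df, reporting helpers."""

import numpy as np
import pandas as pd
import pytest
from numpy.testing import assert_allclose

from leafspec.indices import index_table
from leafspec.mixed import TreatmentLMM, fit_all_indices, fit_lmm, fit_pcs


def _hierarchical_frame(seed=42, effect=0.02, sd_tree=0.012, sd_cell=0.015,
                        sd_leaf=0.043, n_leaves=6):
    """Two treatments x 4 trees x 4 dates x n_leaves, Gaussian hierarchy."""
    rng = np.random.default_rng(seed)
    rows = []
    trees = ([("aCO2", f"A{a+1}-T{t+1}") for a in range(2) for t in range(2)]
             + [("eCO2", f"E{a+1}-T{t+1}") for a in range(2) for t in range(2)])
    for trt, tree in trees:
        b_t = rng.normal(0, sd_tree)
        for d in ("d1", "d2", "d3", "d4"):
            b_td = rng.normal(0, sd_cell)
            for leaf in range(n_leaves):
                y = ((effect if trt == "eCO2" else 0.0) + b_t + b_td
                     + rng.normal(0, sd_leaf))
                rows.append((trt, tree, d, leaf + 1, y))
    return pd.DataFrame(
        rows, columns=["treatment", "tree_id", "date", "leaf_index", "y"])


def _no_random_effect_frame(effect=0.5):
    """Tree and cell means exactly equal within treatment: both variance
    components sit on the zero boundary by construction."""
    pattern = np.array([-1.5, -0.5, 0.5, 1.5]) * 0.2
    rows = []
    for i, trt in enumerate(["aCO2"] * 3 + ["eCO2"] * 3):
        for d in ("d1", "d2"):
            for e in pattern:
                rows.append((trt, f"T{i}", d,
                             (effect if trt == "eCO2" else 0.0) + e))
    return pd.DataFrame(rows, columns=["treatment", "tree_id", "date", "y"])


@pytest.fixture(scope="module")
def reference_fit():
    return fit_lmm(_hierarchical_frame(seed=42), "y")


class TestAgainstReferenceImplementation:
    """Frozen oracle values computed once with lme4/lmerTest (REML,
    Satterthwaite) on the deterministically regenerated fixture."""

    ORACLE = {
        "intercept": -0.00433050426954,
        "intercept_se": 0.00661023858864,
        "effect": 0.02214028218400,
        "effect_se": 0.00934828906257,
        "effect_df": 5.99997828791,
        "effect_p": 0.0556439259416,
        "var_tree": 7.45592709469e-05,
        "var_tree_date": 1.43249051871e-04,
        "var_residual": 1.54582758913e-03,
        "reml_loglik": 332.395626018,
    }

    def test_fixed_effects(self, reference_fit):
        fit = reference_fit
        assert fit.params[0] == pytest.approx(self.ORACLE["intercept"],
                                              abs=1e-8)
        assert fit.params[1] == pytest.approx(self.ORACLE["effect"], abs=1e-8)
        assert fit.bse[0] == pytest.approx(self.ORACLE["intercept_se"],
                                           rel=1e-4)
        assert fit.bse[1] == pytest.approx(self.ORACLE["effect_se"], rel=1e-4)

    def test_variance_components(self, reference_fit):
        fit = reference_fit
        assert fit.vcomp["tree"] == pytest.approx(self.ORACLE["var_tree"],
                                                  rel=1e-3)
        assert fit.vcomp["tree_date"] == pytest.approx(
            self.ORACLE["var_tree_date"], rel=1e-3)
        assert fit.vcomp["residual"] == pytest.approx(
            self.ORACLE["var_residual"], rel=1e-4)

    def test_reml_loglik(self, reference_fit):
        fit = reference_fit
        assert fit.llf == pytest.approx(self.ORACLE["reml_loglik"], abs=1e-6)

    def test_satterthwaite_df_and_p(self, reference_fit):
        fit = reference_fit
        df, p = fit.satterthwaite([0.0, 1.0])
        assert df == pytest.approx(self.ORACLE["effect_df"], abs=0.01)
        assert p == pytest.approx(self.ORACLE["effect_p"], rel=1e-3)


class TestClosedFormOracles:
    def test_balanced_one_way_matches_anova_estimators(self):
        # one-way layout (no date level): REML equals the classical ANOVA
        # estimators sigma2_e = MSW, sigma2_tree = (MSB - MSW) / n_per
        rng = np.random.default_rng(7)
        n_per = 10
        rows = []
        for i, trt in enumerate(["aCO2"] * 3 + ["eCO2"] * 3):
            mu = rng.normal(0, 1)
            for _ in range(n_per):
                rows.append((trt, f"T{i}", mu + rng.normal(0, 0.5)))
        df = pd.DataFrame(rows, columns=["treatment", "tree_id", "y"])
        res = TreatmentLMM(df["y"].to_numpy(), df["treatment"].to_numpy(),
                           df["tree_id"].to_numpy(),
                           include_tree_date=False).fit()
        gm = df.groupby("tree_id")["y"].mean()
        tm = df.groupby("treatment")["y"].mean()
        ssw = sum(((df[df.tree_id == t].y - gm[t]) ** 2).sum()
                  for t in gm.index)
        msw = ssw / (len(df) - len(gm))
        ssb = sum(n_per * (gm[t] - tm[df[df.tree_id == t].treatment.iloc[0]]) ** 2
                  for t in gm.index)
        msb = ssb / (len(gm) - 2)
        assert res.vcomp["residual"] == pytest.approx(msw, rel=1e-5)
        assert res.vcomp["tree"] == pytest.approx((msb - msw) / n_per, rel=1e-4)

    def test_zero_variance_limit_recovers_ols(self):
        df = _hierarchical_frame(seed=3, sd_tree=0.0, sd_cell=0.0)
        res = fit_lmm(df, "y")
        X = np.column_stack([np.ones(len(df)),
                             (df["treatment"] == "eCO2").astype(float)])
        beta_ols = np.linalg.lstsq(X, df["y"].to_numpy(), rcond=None)[0]
        assert_allclose(res.params, beta_ols, atol=1e-6)
        assert res.vcomp["tree"] < 1e-4 * res.vcomp["residual"]

    def test_no_random_effect_limit_gives_classical_df(self):
        df = _no_random_effect_frame()
        res = fit_lmm(df, "y")
        d, _ = res.satterthwaite([0.0, 1.0])
        assert d == pytest.approx(len(df) - 2, abs=0.1)

    def test_df_invariant_to_response_rescaling(self):
        df = _no_random_effect_frame()
        d1 = fit_lmm(df, "y").satterthwaite([0, 1])[0]
        df10 = df.assign(y=df["y"] * 10)
        d2 = fit_lmm(df10, "y").satterthwaite([0, 1])[0]
        assert d2 == pytest.approx(d1, rel=1e-3)
        dfh = _hierarchical_frame(seed=9)
        d3 = fit_lmm(dfh, "y").satterthwaite([0, 1])[0]
        d4 = fit_lmm(dfh.assign(y=dfh["y"] * 100), "y").satterthwaite([0, 1])[0]
        assert d4 == pytest.approx(d3, rel=1e-3)


class TestModelProperties:
    def test_study_shaped_design_gives_tree_limited_df(self, study_campaign):
        psri = index_table(study_campaign, names=("PSRI",))
        res = fit_lmm(psri, "value")
        d, _ = res.satterthwaite([0, 1])
        # treatment replication is 8 trees, so df sits near 6
        assert 4.0 < d < 8.0

    def test_shift_equivariance(self):
        df = _hierarchical_frame(seed=21)
        r1 = fit_lmm(df, "y")
        r2 = fit_lmm(df.assign(y=df["y"] + 5.0), "y")
        assert r2.params[1] == pytest.approx(r1.params[1], abs=1e-9)
        assert r2.params[0] == pytest.approx(r1.params[0] + 5.0, abs=1e-9)
        assert r2.bse[1] == pytest.approx(r1.bse[1], rel=1e-4)

    def test_reml_criterion_locally_optimal(self):
        df = _hierarchical_frame(seed=33)
        res = fit_lmm(df, "y")
        v_hat = res.variances
        ll_hat = res.model.restricted_loglike(v_hat)
        for j in (0, 1, 2):
            for factor in (0.7, 1.3):
                v = v_hat.copy()
                v[j] = max(v[j] * factor, 1e-12)
                assert res.model.restricted_loglike(v) <= ll_hat + 1e-8

    def test_constant_response_degenerates_gracefully(self):
        df = _hierarchical_frame(seed=1).assign(y=3.14)
        res = fit_lmm(df, "y")
        assert res.params[1] == 0.0
        assert all(v == 0.0 for v in res.vcomp.values())
        _, p = res.satterthwaite([0, 1])
        assert p == 1.0

    def test_single_observation_cells_stay_numerically_stable(self):
        # one leaf per tree:date cell: cell and residual variance are only
        # weakly identified; the fit must still converge (boundary allowed)
        df = _hierarchical_frame(seed=13, n_leaves=1)
        res = fit_lmm(df, "y")
        assert res.converged
        assert np.isfinite(res.llf)
        assert all(np.isfinite(v) for v in res.vcomp.values())

    def test_treatment_varying_within_tree_rejected(self):
        df = _hierarchical_frame(seed=2)
        df.loc[0, "treatment"] = "eCO2"
        with pytest.raises(ValueError, match="varies within tree"):
            fit_lmm(df, "y")

    def test_non_nested_array_rejected(self):
        df = _hierarchical_frame(seed=2)
        array = np.where(np.arange(len(df)) % 2 == 0, "A1", "A2")
        with pytest.raises(ValueError, match="not nested"):
            TreatmentLMM(df["y"].to_numpy(), df["treatment"].to_numpy(),
                         df["tree_id"].to_numpy(), df["date"].to_numpy(),
                         array=array)

    def test_optional_array_level_fits(self):
        df = _hierarchical_frame(seed=4)
        df["array_id"] = df["tree_id"].str[:2]
        res = TreatmentLMM.from_dataframe(df, "y", array_col="array_id").fit()
        assert set(res.vcomp) == {"array", "tree", "tree_date", "residual"}
        assert res.converged

    def test_summary_mentions_model_and_components(self):
        res = fit_lmm(_hierarchical_frame(seed=6), "y")
        text = res.summary()
        assert "REML" in text and "tree_date" in text and "eCO2" in text


class TestReports:
    def test_fit_all_indices_one_row_per_index(self, tiny_campaign):
        idx = index_table(tiny_campaign)
        table = fit_all_indices(idx)
        assert list(table["index"]) == [
            "NDVI", "MCARI", "PRI", "PSRI", "NDNI", "NDLI", "NDWI", "NPQI"]
        assert table["p_value"].between(0, 1).all()
        assert table["residual_variance"].gt(0).all()

    def test_all_undefined_index_skipped(self, tiny_campaign, caplog):
        idx = index_table(tiny_campaign, names=("NDVI", "PSRI"))
        idx.loc[idx["index_name"] == "PSRI", "defined"] = False
        with caplog.at_level("WARNING"):
            table = fit_all_indices(idx)
        assert list(table["index"]) == ["NDVI"]
        assert any("skipped" in r.message for r in caplog.records)

    def test_fit_pcs_identical_scores_pool_to_same_effect(self, tiny_campaign):
        meta = tiny_campaign.meta_frame()
        rng = np.random.default_rng(0)
        col = rng.normal(size=len(meta))
        scores = pd.DataFrame({f"PC{k}": col for k in range(1, 5)})
        out = fit_pcs(scores, meta, n_pcs=4)
        effects = [r.params[1] for r in out["per_pc"].values()]
        assert np.ptp(effects) < 1e-10
        assert out["pooled"].params[1] == pytest.approx(effects[0], abs=1e-8)
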