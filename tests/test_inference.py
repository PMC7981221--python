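"""Model selection machinery: dredge, nesting rule, averaging, R², VIF, AUC."""

import numpy as np
import pandas as pd
import pytest

from reefgap.glmm import DEFAULT_GLOBAL_TERMS, FittedModel
from reefgap.inference import (
    ModelSet,
    crossval_auc,
    dredge,
    enumerate_term_sets,
    nakagawa_r2,
    remove_nested,
    residual_diagnostics,
    select_or_average,
    vif,
)

from conftest import make_model_table


def dummy_model(terms, loglik, k=3, n=500, coef=None):
    """Minimal FittedModel for selection-rule unit tests."""
    if coef is None:
        coef = pd.DataFrame(
            {"Estimate": [0.0], "SE": [1.0], "ci_lo": [-2.0], "ci_hi": [2.0],
             "z": [0.0], "p": [1.0]}, index=["Intercept"])
    return FittedModel(
        terms=tuple(terms), design=None, coef=coef, factors=(), sigma2={},
        cond_modes={}, loglik=loglik, k=k, n=n, converged=True,
    )


class TestEnumeration:
    def test_full_global_count(self):
        # 4 non-species terms: absent without species (2^4) or in one of
        # three states with species (3^4)
        sets = enumerate_term_sets(DEFAULT_GLOBAL_TERMS)
        assert len(sets) == 2**4 + 3**4 == 97

    def test_reduced_count_and_intercept_only(self):
        sets = enumerate_term_sets(("species", "diel", "species:diel"))
        assert len(sets) == 5
        assert () in sets

    def test_marginality_respected(self):
        for s in enumerate_term_sets(DEFAULT_GLOBAL_TERMS):
            for t in s:
                if ":" in t:
                    assert set(t.split(":")) <= set(s)


@pytest.fixture(scope="module")
def model_set():
    tb = make_model_table(20, n_tags=40, per_tag=30)
    return dredge(tb, ("species", "diel", "species:diel"))


class TestDredge:
    def test_all_candidates_fitted_and_ranked(self, model_set):
        assert len(model_set.models) == 5
        assert model_set.table["AICc"].is_monotonic_increasing

    def test_weights_sum_to_one(self, model_set):
        assert model_set.table["weight"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_nested_removal_property(self, model_set):
        pruned = remove_nested(model_set)
        for i, mi in enumerate(pruned.models):
            for j, mj in enumerate(pruned.models):
                if set(mj.terms) < set(mi.terms):
                    assert pruned.table["AICc"].iloc[j] >= pruned.table["AICc"].iloc[i]
        assert pruned.table["weight"].sum() == pytest.approx(1.0, abs=1e-9)


class TestNestedRule:
    def test_simpler_better_drops_complex(self):
        # same fit, one extra parameter: the complex model ranks worse
        ms = ModelSet.from_models(
            [dummy_model(("diel",), loglik=-100, k=3),
             dummy_model(("diel", "season"), loglik=-100, k=4)]
        )
        pruned = remove_nested(ms)
        assert [m.terms for m in pruned.models] == [("diel",)]

    def test_complex_better_keeps_both(self):
        ms = ModelSet.from_models(
            [dummy_model(("diel",), loglik=-120), dummy_model(("diel", "season"), loglik=-100)]
        )
        assert len(remove_nested(ms).models) == 2


class TestSelection:
    def test_single_survivor_reported(self):
        ms = ModelSet.from_models([dummy_model(("diel",), -100)])
        sel = select_or_average(ms)
        assert sel.kind == "single" and sel.model.terms == ("diel",)

    def test_dominant_weight_reports_best(self):
        # delta AICc of 12 gives best weight ~0.9975
        ms = ModelSet.from_models(
            [dummy_model(("diel",), -100), dummy_model(("season",), -106)]
        )
        sel = select_or_average(ms)
        assert sel.kind == "best" and sel.model.terms == ("diel",)

    def test_close_weights_full_averaging(self):
        c1 = pd.DataFrame(
            {"Estimate": [1.0, 0.5], "SE": [0.2, 0.1], "ci_lo": 0, "ci_hi": 0,
             "z": 0, "p": 0}, index=["Intercept", "diel[night]"])
        c2 = pd.DataFrame(
            {"Estimate": [0.8], "SE": [0.25], "ci_lo": 0, "ci_hi": 0, "z": 0, "p": 0},
            index=["Intercept"])
        ms = ModelSet.from_models(
            [dummy_model(("diel",), -100.0, coef=c1), dummy_model((), -100.5, coef=c2)]
        )
        sel = select_or_average(ms)
        assert sel.kind == "averaged"
        w = ms.table["weight"].to_numpy()
        # full averaging substitutes zero where a term is absent
        exp_diel = w[0] * 0.5
        assert sel.coef.at["diel[night]", "Estimate"] == pytest.approx(exp_diel)
        exp_se = np.sqrt(w[0] * (0.1**2 + (0.5 - exp_diel) ** 2) + w[1] * (0 + exp_diel**2))
        assert sel.coef.at["diel[night]", "SE"] == pytest.approx(exp_se)


class TestFormulas:
    def test_nakagawa_example(self):
        m = dummy_model((), -100)
        m.var_fixed = 1.0
        m.sigma2 = {"tag_id": 1.2, "receiver_id": 0.8}
        r2m, r2c = nakagawa_r2(m)
        assert r2m == pytest.approx(1 / (3 + np.pi**2 / 3), abs=1e-9)
        assert r2c == pytest.approx(3 / (3 + np.pi**2 / 3), abs=1e-9)
        assert r2c >= r2m

    def test_null_fixed_effects(self):
        m = dummy_model((), -100)
        m.var_fixed = 0.0
        m.sigma2 = {"tag_id": 0.5}
        assert nakagawa_r2(m)[0] == 0.0


class TestVif:
    def test_orthogonal_predictors(self):
        rng = np.random.default_rng(0)
        n = 4000
        tb = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)})
        out = vif(tb, ("x1", "x2"))
        assert np.allclose(out["vif"], 1.0, atol=0.01)
        assert not out["gate"].any()

    def test_two_predictor_closed_form(self):
        rng = np.random.default_rng(1)
        n = 20000
        x1 = rng.normal(size=n)
        x2 = 0.9 * x1 + np.sqrt(1 - 0.81) * rng.normal(size=n)
        out = vif(pd.DataFrame({"x1": x1, "x2": x2}), ("x1", "x2"))
        r = np.corrcoef(x1, x2)[0, 1]
        assert np.allclose(out["vif"], 1 / (1 - r**2), rtol=1e-9)
        assert out["vif"].iloc[0] == pytest.approx(5.263, abs=0.35)
        assert out["gate"].all()

    def test_perfect_collinearity_infinite(self):
        x = np.arange(100.0)
        out = vif(pd.DataFrame({"x1": x, "x2": 2 * x}), ("x1", "x2"))
        assert np.isinf(out["vif"]).all()
        assert out["gate"].all()

    def test_study_predictors_pass_gate(self, classified_small):
        out = vif(classified_small["table"])
        assert (out["vif"] < 5.0).all()


class TestCrossval:
    def test_perfectly_separable(self):
        tb = make_model_table(30, n_tags=30, per_tag=30)
        tb["label"] = (tb["diel"] == "night").astype(int)
        auc = crossval_auc(tb, ("diel",), seed=0)
        assert auc == 1.0

    def test_single_class_test_split_errors(self):
        tb = make_model_table(31, n_tags=10, per_tag=10)
        tb["label"] = 0
        tb.loc[:1, "label"] = 1
        with pytest.raises(ValueError, match="both classes"):
            crossval_auc(tb, ("diel",), seed=1)

    def test_seeded_split_reproducible(self):
        tb = make_model_table(32, n_tags=30, per_tag=20)
        a1 = crossval_auc(tb, ("species", "diel"), seed=5)
        a2 = crossval_auc(tb, ("species", "diel"), seed=5)
        assert a1 == a2


class TestResidualDiagnostics:
    def test_iid_residuals_white(self):
        from reefgap.glmm import fit_glmm

        tb = make_model_table(40, n_tags=40, per_tag=50)
        fit = fit_glmm(tb, ("species", "diel", "season"))
        rep = residual_diagnostics(fit)
        assert rep["frac_acf_within_band"] >= 0.9
        assert rep["spread_ratio"] < 2.0

    def test_ar1_injected_flagged(self):
        rng = np.random.default_rng(2)
        n = 4000
        z = np.empty(n)
        z[0] = rng.normal()
        for i in range(1, n):
            z[i] = 0.8 * z[i - 1] + np.sqrt(1 - 0.64) * rng.normal()
        m = dummy_model((), -100)
        m.y = (z > 0).astype(float)
        m.fitted_prob = np.full(n, 0.5)
        rep = residual_diagnostics(m)
        assert rep["lag1_acf"] > 0.5

    def test_deterministic_given_fit(self):
        m = dummy_model((), -100)
        rng = np.random.default_rng(3)
        m.y = (rng.random(500) < 0.4).astype(float)
        m.fitted_prob = np.full(500, 0.4)
        r1 = residual_diagnostics(m)
        r2 = residual_diagnostics(m)
        assert np.allclose(r1["acf"], r2["acf"])
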