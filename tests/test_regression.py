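"""Standardized OLS stage: design building, AICc simplification, VIF."""

import numpy as np
import pandas as pd
import pytest

from trophicweb import InputError, fit_index_model, simplify_by_aicc, standardize_predictors, vif
from trophicweb.regression import ALT_MODEL_TERMS, FULL_MODEL_TERMS, build_design


def _raw_covariates(n=40, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "site": rng.choice(["A", "B"], n),
            "tree_species_richness": rng.choice([1, 2, 4, 8, 16, 24], n),
            "canopy_cover": rng.uniform(0.1, 0.9, n),
            "elevation": rng.normal(250, 40, n),
            "slope": rng.uniform(5, 40, n),
            "eastness": rng.uniform(-1, 1, n),
            "northness": rng.uniform(-1, 1, n),
            "tree_mpd": rng.uniform(1, 6, n),
            "tree_raoq": rng.uniform(0, 2, n),
        },
        index=[f"plot{i}" for i in range(n)],
    )


class TestStandardize:
    def test_log2_richness_z_scores(self):
        cov = pd.DataFrame(
            {"tree_species_richness": [1, 2, 4, 8]}, index=list("abcd")
        )
        out = standardize_predictors(cov)
        expected = np.array([-1.161895, -0.387298, 0.387298, 1.161895])
        assert np.allclose(out["log2_richness"], expected, atol=1e-6)

    def test_constant_column_dropped_with_warning(self):
        cov = _raw_covariates()
        cov["canopy_cover"] = 0.5
        with pytest.warns(UserWarning, match="canopy_cover"):
            out = standardize_predictors(cov)
        assert "canopy_cover" not in out.columns

    def test_idempotent_on_standardized_input(self):
        cov = _raw_covariates()
        once = standardize_predictors(cov)
        relabeled = pd.DataFrame({"elevation": once["log2_richness"].to_numpy()},
                                 index=once.index)
        again = standardize_predictors(relabeled)
        assert np.allclose(once["log2_richness"], again["elevation"], atol=1e-12)


class TestOLS:
    def test_matches_normal_equations_on_random_designs(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n, p = 30, 4
            x = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            design = pd.DataFrame(x, columns=[f"x{k}" for k in range(p)])
            fit = fit_index_model(pd.Series(y, name="y"), design, list(design.columns))
            xc = np.column_stack([np.ones(n), x])
            beta = np.linalg.solve(xc.T @ xc, xc.T @ y)
            assert np.allclose(fit.coefficients["estimate"].to_numpy(), beta, atol=1e-8)

    def test_near_exact_fit_limit(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=60)
        y = 2.0 * x + rng.normal(scale=1e-8, size=60)
        fit = fit_index_model(pd.Series(y), pd.DataFrame({"x": x}), ["x"])
        assert fit.coefficients.loc["x", "estimate"] == pytest.approx(2.0, abs=1e-6)
        assert fit.coefficients.loc["x", "p"] < 1e-12

    def test_hand_five_point_dataset(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 1.5, 3.5, 3.0])
        fit = fit_index_model(pd.Series(y), pd.DataFrame({"x": x}), ["x"])
        # closed-form slope and intercept
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        intercept = y.mean() - slope * x.mean()
        assert fit.coefficients.loc["x", "estimate"] == pytest.approx(slope, abs=1e-10)
        assert fit.coefficients.loc["intercept", "estimate"] == pytest.approx(intercept, abs=1e-10)

    def test_rank_deficiency_rejected(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=20)
        design = pd.DataFrame({"x": x, "x2": 2 * x})
        with pytest.raises(InputError, match="rank-deficient"):
            fit_index_model(pd.Series(rng.normal(size=20)), design, ["x", "x2"])


class TestDesignProtocol:
    def test_richness_and_mpd_never_share_a_model(self):
        cov = standardize_predictors(_raw_covariates())
        with pytest.raises(InputError, match="may not"):
            build_design(cov, ["log2_richness", "tree_mpd"])

    def test_protocol_term_lists_respect_exclusivity(self):
        flat_primary = {p for t in FULL_MODEL_TERMS for p in t.split(":")}
        flat_alt = {p for t in ALT_MODEL_TERMS for p in t.split(":")}
        assert "tree_mpd" not in flat_primary
        assert "log2_richness" not in flat_alt

    def test_site_interaction_columns_built(self):
        cov = standardize_predictors(_raw_covariates())
        x = build_design(cov, ["site", "log2_richness", "site:log2_richness"])
        assert any(":" in c for c in x.columns)


class TestSimplification:
    def test_already_minimal_model_is_fixed_point(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=85)
        y = pd.Series(1.5 * x + rng.normal(scale=0.5, size=85))
        design = pd.DataFrame({"x": x})
        fit = simplify_by_aicc(y, design, ["x"])
        assert fit.terms == ("x",)

    def test_strong_predictor_retained_among_noise(self):
        kept = 0
        for s in range(20):
            rng = np.random.default_rng(s)
            design = pd.DataFrame(
                {"signal": rng.normal(size=85), "n1": rng.normal(size=85), "n2": rng.normal(size=85)}
            )
            y = pd.Series(0.8 * design["signal"] + rng.normal(size=85))
            fit = simplify_by_aicc(y, design, list(design.columns))
            kept += "signal" in fit.terms
        assert kept >= 19

    def test_final_aicc_never_exceeds_full_model(self):
        for s in range(10):
            rng = np.random.default_rng(100 + s)
            design = pd.DataFrame({f"x{k}": rng.normal(size=60) for k in range(4)})
            y = pd.Series(rng.normal(size=60))
            full = fit_index_model(y, design, list(design.columns))
            final = simplify_by_aicc(y, design, list(design.columns))
            assert final.aicc <= full.aicc + 1e-9

    def test_marginality_protects_main_effects(self):
        rng = np.random.default_rng(5)
        cov = _raw_covariates(n=85, seed=5)
        design = standardize_predictors(cov)
        # response driven only by the interaction
        site_b = (cov["site"] == "B").astype(float)
        y = pd.Series(
            2.0 * site_b * design["log2_richness"].to_numpy() + rng.normal(size=85)
        )
        fit = simplify_by_aicc(y, design, ["site", "log2_richness", "site:log2_richness"])
        assert "site:log2_richness" in fit.terms
        assert "site" in fit.terms and "log2_richness" in fit.terms


class TestVIF:
    def test_orthogonal_predictors_have_unit_vif(self):
        rng = np.random.default_rng(0)
        raw = rng.normal(size=(30, 3))
        raw -= raw.mean(axis=0)
        q, _ = np.linalg.qr(raw)  # centered orthogonal columns
        q -= q.mean(axis=0)
        q, _ = np.linalg.qr(q)
        v = vif(pd.DataFrame(q, columns=["a", "b", "c"]))
        for val in v.values():
            assert val == pytest.approx(1.0, abs=1e-6)

    def test_duplicated_predictor_is_infinite(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=25)
        v = vif(pd.DataFrame({"a": x, "b": x}))
        assert np.isinf(v["a"]) and np.isinf(v["b"])

    def test_known_correlation_gives_closed_form(self):
        # construct two predictors with exact sample correlation 0.74
        rng = np.random.default_rng(7)
        n = 400
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        a = (a - a.mean()) / a.std()
        b -= b.mean()
        b -= a * (a @ b) / (a @ a)  # residualize: exactly orthogonal
        b /= b.std()
        r = 0.74
        c = r * a + np.sqrt(1 - r**2) * b
        v = vif(pd.DataFrame({"a": a, "c": c}))
        assert v["a"] == pytest.approx(1.0 / (1.0 - 0.74**2), rel=1e-9)
        assert v["c"] == pytest.approx(1.0 / (1.0 - 0.74**2), rel=1e-9)
        assert v["a"] == pytest.approx(2.2104, abs=1e-4)
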