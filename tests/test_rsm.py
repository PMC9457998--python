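"""Response-surface OLS fitting, ANOVA, fit statistics and diagnostics.

The Box-Behnken contrast identities provide an independent oracle for the
linear and interaction coefficients: on a 3-factor BBD the OLS estimate of a
linear term equals (sum y at x=+1 minus sum y at x=-1)/8 and an interaction
equals the four-point contrast (y++ + y-- - y+- - y-+)/4, regardless of which
quadratic terms are in the model.
"""

import numpy as np
import pytest

from biorsm import (
    FULL_QUADRATIC,
    LINEAR_INTERACTION,
    ModelSpec,
    SimulationConfig,
    anova,
    build_model_matrix,
    coded_to_actual,
    fit_ols,
    fit_stats,
    make_bbd,
    predict,
    reduce_model,
    residual_diagnostics,
    simulate_bbd_responses,
)
from biorsm.errors import ConfigurationError, SingularModelError

ENRO_TERMS = ("1", "A", "B", "C", "AB", "AC", "BC", "A2", "B2")


def bbd_contrasts(design, response):
    """Closed-form BBD estimates for linear and interaction terms."""
    X = design.coded_matrix()
    y = design.response(response)
    out = {}
    for j, letter in enumerate("ABC"):
        out[letter] = (y[X[:, j] == 1].sum() - y[X[:, j] == -1].sum()) / 8
    for (i, j), name in zip([(0, 1), (0, 2), (1, 2)], ["AB", "AC", "BC"]):
        pp = y[(X[:, i] == 1) & (X[:, j] == 1)].sum()
        mm = y[(X[:, i] == -1) & (X[:, j] == -1)].sum()
        pm = y[(X[:, i] == 1) & (X[:, j] == -1)].sum()
        mp = y[(X[:, i] == -1) & (X[:, j] == 1)].sum()
        out[name] = (pp + mm - pm - mp) / 4
    return out


# ---------------------------------------------------------------- model matrix

def test_model_matrix_shape_and_columns(design):
    X = build_model_matrix(design, FULL_QUADRATIC)
    assert X.shape == (15, 10)
    a_col = X[:, 1]
    assert (np.abs(a_col) == 1).sum() == 8 and (a_col == 0).sum() == 7
    # interaction column is the elementwise product
    assert np.array_equal(X[:, 4], X[:, 1] * X[:, 2])
    assert np.array_equal(X[:, 7], X[:, 1] ** 2)


def test_model_matrix_unknown_term(design):
    with pytest.raises(ConfigurationError):
        build_model_matrix(design, ("1", "A", "D"))


# ------------------------------------------------------------------- OLS fits

def test_cip_fit_matches_published_coefficients(design):
    model = fit_ols(design, "CIP", FULL_QUADRATIC)
    assert model.coef_coded["1"] == pytest.approx(77.67, abs=0.005)
    assert model.coef_coded["A"] == pytest.approx(-1.00, abs=1e-9)
    assert model.coef_coded["C"] == pytest.approx(7.25, abs=1e-9)
    assert model.p == 10 and model.n == 15


def test_enro_fit_matches_published_table(design):
    """Every published ENRO coefficient cell agrees with the 9-term OLS fit."""
    model = fit_ols(design, "ENRO", ENRO_TERMS)
    published = {"1": 74.54, "A": 1.63, "B": 0.0, "C": 9.13, "AB": 3.25,
                 "AC": -1.50, "BC": 0.25, "A2": 1.81, "B2": 1.56}
    for term, value in published.items():
        assert model.coef_coded[term] == pytest.approx(value, abs=0.005), term


@pytest.mark.parametrize("response", ["CIP", "ENRO", "COD"])
@pytest.mark.parametrize("terms", [FULL_QUADRATIC, LINEAR_INTERACTION, ENRO_TERMS])
def test_contrast_oracle_all_responses(design, response, terms):
    """Linear/interaction estimates equal the closed-form BBD contrasts."""
    model = fit_ols(design, response, terms)
    oracle = bbd_contrasts(design, response)
    for term in ("A", "B", "C", "AB", "AC", "BC"):
        assert model.coef_coded[term] == pytest.approx(oracle[term], abs=1e-9), term


def test_residuals_sum_to_zero(design):
    model = fit_ols(design, "COD", FULL_QUADRATIC)
    assert abs(model.residuals.sum()) < 1e-9


def test_zero_noise_recovery(factors):
    beta = {"1": 70.0, "A": 2.0, "B": -1.5, "C": 5.0, "AB": 0.7, "AC": -0.3,
            "BC": 0.1, "A2": -2.0, "B2": 0.4, "C2": -1.1}
    table = simulate_bbd_responses(SimulationConfig(beta, noise_sd=0.0, seed=1), factors)
    model = fit_ols(table, "Y", FULL_QUADRATIC)
    for term, value in beta.items():
        assert model.coef_coded[term] == pytest.approx(value, abs=1e-9)


def test_singular_matrix_names_terms(design):
    # duplicate quadratic columns on centre-heavy data are fine; force
    # singularity by exceeding run support instead: A and A2 collinear on a
    # two-level sub-design
    sub = design.data[design.data["coded_pH"] != 0].reset_index(drop=True)
    from biorsm.doe import DesignTable

    two_level = DesignTable(design.factors, sub, responses=["CIP"])
    with pytest.raises(SingularModelError) as err:
        fit_ols(two_level, "CIP", ("1", "A", "B", "A2", "B2"))
    assert err.value.terms  # names at least one collinear term


def test_too_few_runs_raises(factors):
    table = make_bbd(factors, n_center=1)
    rng = np.random.default_rng(0)
    table.data["Y"] = rng.normal(size=table.n_runs)
    table.responses = ["Y"]
    # 13 runs cannot fit 13 terms plus error; 10-term full quadratic is fine
    fit_ols(table, "Y", FULL_QUADRATIC)
    with pytest.raises(ConfigurationError):
        too_big = ModelSpec(FULL_QUADRATIC)
        fit_ols(table.__class__(table.factors, table.data.iloc[:9].copy(),
                                responses=["Y"]), "Y", too_big)


# --------------------------------------------------------- actual-unit models

def test_cip_actual_equation_matches_published(design):
    """Actual-unit expansion reproduces the published CIP equation."""
    actual = coded_to_actual(fit_ols(design, "CIP", FULL_QUADRATIC))
    expected = {"1": -9.81, "A": 21.056, "B": 0.583, "C": 0.425, "AB": 0.125,
                "AC": -0.0389, "BC": 8.33e-3, "A2": -1.4583, "B2": -0.2396,
                "C2": -2.263e-4}
    for term, value in expected.items():
        assert actual[term] == pytest.approx(value, rel=5e-3, abs=5e-4), term


def test_cod_actual_quadratic_coefficient(design):
    """COD actual C^2 ~ -5.144e-4 corresponds to coded C^2 ~ -1.04 (x 45^2)."""
    model = fit_ols(design, "COD", FULL_QUADRATIC)
    actual = coded_to_actual(model)
    assert actual["C2"] == pytest.approx(-5.144e-4, rel=2e-2)
    assert model.coef_coded["C2"] == pytest.approx(actual["C2"] * 45**2, abs=1e-9)


def test_identity_coding_leaves_coefficients_unchanged():
    from biorsm.doe import FactorSpec

    unit = [FactorSpec(n, -1, 1) for n in "xyz"]
    beta = {"1": 1.0, "A": 2.0, "B": -0.5, "AB": 0.25, "C2": 3.0}
    table = simulate_bbd_responses(SimulationConfig(beta, seed=0), unit)
    model = fit_ols(table, "Y", tuple(beta))
    actual = coded_to_actual(model)
    for term, value in beta.items():
        assert actual[term] == pytest.approx(value, abs=1e-9)


@pytest.mark.parametrize("response,terms", [
    ("CIP", FULL_QUADRATIC), ("ENRO", ENRO_TERMS), ("COD", FULL_QUADRATIC)])
def test_coded_and_actual_predict_identically(design, response, terms):
    model = fit_ols(design, response, terms)
    actual_coef = coded_to_actual(model)
    rng = np.random.default_rng(42)
    coded_pts = rng.uniform(-1, 1, size=(1000, 3))
    actual_pts = np.column_stack(
        [f.decode(coded_pts[:, i]) for i, f in enumerate(model.factors)])
    y_coded = predict(model, coded_pts, units="coded")
    # evaluate the actual-unit polynomial directly
    A, B, C = actual_pts.T
    mono = {"1": 1.0, "A": A, "B": B, "C": C, "AB": A * B, "AC": A * C,
            "BC": B * C, "A2": A**2, "B2": B**2, "C2": C**2}
    y_actual = sum(actual_coef[t] * mono[t] for t in actual_coef.index)
    assert np.allclose(y_coded, y_actual, atol=1e-9)


# ------------------------------------------------------------------ predict

def test_predict_published_points(design):
    model = fit_ols(design, "CIP", FULL_QUADRATIC)
    at_run1 = predict(model, [[7, 2, 10]], units="actual")[0]
    assert at_run1 == pytest.approx(69.75, abs=0.01)
    assert round(at_run1) == 70
    at_opt, extrap = predict(model, [[6, 2, 75]], units="actual",
                             return_extrapolation=True)
    assert at_opt[0] == pytest.approx(80.08, abs=0.01)
    assert not extrap[0]
    at_center = predict(model, [[7, 4, 55]], units="actual")[0]
    assert at_center == pytest.approx(model.coef_coded["1"], abs=1e-9)


def test_predict_flags_extrapolation(design):
    model = fit_ols(design, "CIP", FULL_QUADRATIC)
    _, extrap = predict(model, [[0, 0, 0], [0, 0, 1.2]], return_extrapolation=True)
    assert list(extrap) == [False, True]


def test_prediction_columns_reproduced_within_one_point(design):
    """Published per-run predictions agree within +/-1 for all 45 cells."""
    from biorsm.datasets import PREDICTION_TERM_SETS

    close = 0
    for resp, terms in PREDICTION_TERM_SETS.items():
        model = fit_ols(design, resp, terms)
        published = design.data[f"{resp}_pred"].to_numpy(dtype=float)
        close += int(np.sum(np.abs(model.fitted - published) <= 1.0))
    assert close >= 40
    assert close == 45


# ------------------------------------------------------------- model reduction

def test_reduce_model_keeps_true_linear_term(factors):
    """Backward elimination always keeps the generating linear effect.

    Null terms survive at roughly the test level, so across seeds the
    reduction must (a) never drop the true effect and (b) usually collapse
    to exactly the generating model.
    """
    beta = {"1": 50.0, "A": 5.0, "B": 0.0, "C": 0.0, "AB": 0.0, "AC": 0.0,
            "BC": 0.0, "A2": 0.0, "B2": 0.0, "C2": 0.0}
    exact = 0
    for seed in range(20):
        table = simulate_bbd_responses(
            SimulationConfig(beta, noise_sd=0.01, seed=seed), factors)
        spec = reduce_model(table, "Y", alpha=0.05)
        assert "A" in spec.terms
        assert not spec.hierarchy_violations()
        exact += spec.terms == ("1", "A")
    assert exact >= 8


def test_reduce_model_alpha_one_keeps_everything(design):
    spec = reduce_model(design, "CIP", alpha=1.0)
    assert spec.terms == tuple(FULL_QUADRATIC)


def test_reduce_model_enro_keeps_concentration(design):
    spec = reduce_model(design, "ENRO", alpha=0.05)
    assert "C" in spec.terms


def test_reduce_model_preserves_hierarchy(design):
    spec = reduce_model(design, "COD", alpha=0.05)
    assert not spec.hierarchy_violations()


# ----------------------------------------------------------------- ANOVA

def test_anova_decomposition(design):
    tab = anova(design, "CIP", FULL_QUADRATIC).table.set_index("source")
    assert tab.loc["Model", "ss"] + tab.loc["Residual", "ss"] == pytest.approx(
        tab.loc["Cor Total", "ss"], rel=1e-9)
    assert (tab.loc["Lack of Fit", "ss"] + tab.loc["Pure Error", "ss"]
            == pytest.approx(tab.loc["Residual", "ss"], rel=1e-9))
    assert tab.loc["Pure Error", "df"] == 2  # three centre replicates
    assert tab.loc["Model", "df"] + tab.loc["Residual", "df"] == tab.loc["Cor Total", "df"]
    assert tab.loc["Lack of Fit", "df"] + tab.loc["Pure Error", "df"] == tab.loc["Residual", "df"]


@pytest.mark.parametrize("response", ["CIP", "ENRO", "COD"])
def test_anova_concentration_term_highly_significant(design, response):
    terms = ENRO_TERMS if response == "ENRO" else FULL_QUADRATIC
    tab = anova(design, response, terms).table.set_index("source")
    assert tab.loc["C", "p"] < 1e-4


def test_anova_without_replicates(factors):
    beta = {"1": 50.0, "A": 5.0}
    table = simulate_bbd_responses(
        SimulationConfig(beta, noise_sd=1.0, seed=3, n_center=1), factors)
    result = anova(table, "Y", LINEAR_INTERACTION)
    assert not result.lack_of_fit_available
    assert "Lack of Fit" not in set(result.table["source"])


def test_anova_sequential_sums_to_model_ss(design):
    tab = anova(design, "ENRO", ENRO_TERMS, ss_type="sequential").table
    t = tab.set_index("source")
    term_ss = t.drop(["Model", "Residual", "Lack of Fit", "Pure Error", "Cor Total"])["ss"]
    assert term_ss.sum() == pytest.approx(t.loc["Model", "ss"], rel=1e-9)


# -------------------------------------------------------------- fit statistics

def test_cip_fit_statistics_match_published(design):
    st = fit_stats(design, "CIP", FULL_QUADRATIC)
    assert st.r2 == pytest.approx(0.9834, abs=5e-5)
    assert st.cv_percent == pytest.approx(1.63, abs=5e-3)
    assert st.mean == pytest.approx(76.13, abs=5e-3)
    assert st.std_dev == pytest.approx(1.24, abs=5e-3)
    assert st.adeq_precision == pytest.approx(17.8033, abs=5e-3)


def test_fit_stats_orderings(design):
    for resp in ("CIP", "ENRO", "COD"):
        st = fit_stats(design, resp, FULL_QUADRATIC)
        assert 0 <= st.r2 <= 1
        assert st.adj_r2 <= st.r2
        assert st.pred_r2 <= st.r2
        assert st.press >= 0


def test_full_model_r2_dominates_submodels(design):
    full = fit_stats(design, "ENRO", FULL_QUADRATIC).r2
    for terms in (LINEAR_INTERACTION, ENRO_TERMS, ("1", "A", "B", "C")):
        assert fit_stats(design, "ENRO", terms).r2 <= full + 1e-12


def test_press_leverage_identity_equals_explicit_loo(design):
    """PRESS via the hat-diagonal identity equals n refits leaving one out."""
    from biorsm.doe import DesignTable

    st = fit_stats(design, "CIP", FULL_QUADRATIC)
    explicit = 0.0
    for i in range(design.n_runs):
        rest = DesignTable(
            design.factors,
            design.data.drop(index=i).reset_index(drop=True),
            responses=["CIP"],
        )
        model = fit_ols(rest, "CIP", FULL_QUADRATIC)
        pred = predict(model, design.coded_matrix()[i][None, :])[0]
        explicit += (design.response("CIP")[i] - pred) ** 2
    assert st.press == pytest.approx(explicit, abs=1e-6)


def test_parameter_recovery_within_standard_error_bands(factors):
    """Simulated full-quadratic responses land inside 4*SE in >=95% of fits."""
    beta = {"1": 75.0, "A": -1.0, "B": 0.6, "C": 7.0, "AB": 1.0, "AC": -1.7,
            "BC": 0.7, "A2": -1.5, "B2": -1.0, "C2": -0.5}
    sigma = 1.2
    inside = total = 0
    for rep in range(500):
        table = simulate_bbd_responses(
            SimulationConfig(beta, noise_sd=sigma, seed=10_000 + rep), factors)
        model = fit_ols(table, "Y", FULL_QUADRATIC)
        for term, value in beta.items():
            total += 1
            inside += abs(model.coef_coded[term] - value) <= 4 * model.se_coded[term]
    assert inside / total >= 0.95


# ----------------------------------------------------------------- diagnostics

def test_diagnostics_quantiles_monotone(design):
    model = fit_ols(design, "CIP", FULL_QUADRATIC)
    diag = residual_diagnostics(model)
    assert len(diag) == 15
    assert np.all(np.diff(diag["normal_quantile"]) > 0)
    assert np.all(np.diff(diag["studentized_residual"]) >= 0)
    assert np.max(np.abs(model.residuals)) <= 2.0  # published Exp-Pred gap


def test_diagnostics_zero_noise(factors):
    table = simulate_bbd_responses(
        SimulationConfig({"1": 10.0, "A": 1.0}, noise_sd=0.0, seed=0), factors)
    model = fit_ols(table, "Y", ("1", "A"))
    diag = residual_diagnostics(model)
    assert np.allclose(diag["studentized_residual"], 0.0)
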