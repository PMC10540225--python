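"""Mixed models, likelihood-ratio ANOVA, associations, demographics."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from eegnps.longitudinal import (fit_lme_univariate, fit_mlme, compare_models,
                                 association_regression, demographics_tests,
                                 two_sample_t_from_summary, chi2_2x2)
from conftest import simulate_lme_cohort, simulate_mlme_data


# -- demographics ----------------------------------------------------------

def test_pooled_t_from_printed_summaries():
    """Published childhood-age summaries reproduce t = 0.81."""
    res = two_sample_t_from_summary(66, 8.10, 1.83, 83, 7.85, 1.89)
    assert round(res["t"], 2) == 0.81
    assert res["df"] == 147


def test_chi2_sex_and_handedness_counts():
    assert round(chi2_2x2([[38, 28], [50, 33]])["chi2"], 2) == 0.11
    assert round(chi2_2x2([[4, 62], [3, 80]])["chi2"], 2) == 0.49
    # Yates variant is smaller for small counts
    plain = chi2_2x2([[35, 10], [28, 25]])["chi2"]
    yates = chi2_2x2([[35, 10], [28, 25]], yates=True)["chi2"]
    assert yates < plain


def test_identical_groups_null_statistics():
    res = two_sample_t_from_summary(50, 1.0, 0.5, 50, 1.0, 0.5)
    assert res["t"] == 0.0 and res["p"] == pytest.approx(1.0)
    res = chi2_2x2([[20, 30], [20, 30]])
    assert res["chi2"] == 0.0 and res["p"] == pytest.approx(1.0)


def test_demographics_table(rng):
    from eegnps.simulate import SimulationConfig, generate_cohort
    cohort = generate_cohort(SimulationConfig(n_per_group=40, seed=3))
    tab = demographics_tests(cohort)
    assert set(tab["test"]) == {"t", "chi2"}
    eco = tab[tab["variable"].str.contains("standard of living")]
    assert eco["p"].iloc[0] < 0.05   # planted disadvantage detected
    with pytest.raises(ValueError):
        demographics_tests(cohort[cohort["group"] == "PEM"])


# -- univariate mixed model ------------------------------------------------

def test_lme_recovers_generative_effects(rng):
    df = simulate_lme_cohort(rng, n_subjects=150, n_evaluators=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_lme_univariate(df)
    tab = fit.fe_table
    assert abs(tab.loc["group[PEM]", "estimate"] + 0.7) < 3 * tab.loc["group[PEM]", "se"]
    assert abs(tab.loc["age", "estimate"] - 0.01) < 3 * tab.loc["age", "se"]
    assert fit.vc["subject"] > 0.3
    # CI convention
    np.testing.assert_allclose(
        tab["ci_high"] - tab["estimate"], 1.96 * tab["se"], rtol=1e-10)


def test_lme_zero_subject_variance_matches_ols(rng):
    df = simulate_lme_cohort(rng, n_subjects=120, subject_sd=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_lme_univariate(df)
    assert fit.vc["subject"] < 0.01
    from eegnps.longitudinal import build_design
    X = build_design(df)
    ols = sm.OLS(df["sqnps"], X).fit()
    assert np.abs(fit.fe_table["estimate"].to_numpy() - ols.params.to_numpy()).max() < 1e-2


def test_lme_identical_evaluators_prefer_simple_model(rng):
    """With no true evaluator effect the ANOVA p is ~1 (no improvement)."""
    df = simulate_lme_cohort(rng, n_subjects=60, n_evaluators=1)
    dup = df.copy()
    dup["evaluator"] = 2
    both = pd.concat([df, dup], ignore_index=True)   # evaluators truly identical
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f1 = fit_lme_univariate(both, random_spec="subject")
        f2 = fit_lme_univariate(both, random_spec="subject+evaluator")
    cmp = compare_models(f1, f2)
    assert f2.vc["evaluator"] < 1e-4
    assert cmp.p > 0.9


def test_lme_no_repeats_falls_back_to_ols(rng):
    df = simulate_lme_cohort(rng, n_subjects=80).groupby("subject_id").head(1)
    with pytest.warns(UserWarning, match="OLS"):
        fit = fit_lme_univariate(df)
    assert fit.vc["subject"] == 0.0


def test_lme_collinear_fixed_effects_rejected(rng):
    df = simulate_lme_cohort(rng, n_subjects=30)
    df["ecology"] = 2.0 * (df["group"] == "PEM")   # collinear with group
    with pytest.raises(ValueError, match="collinear"):
        fit_lme_univariate(df)


# -- multivariate mixed model ---------------------------------------------

@pytest.fixture(scope="module")
def mlme_fits():
    rng = np.random.default_rng(77)
    df = simulate_mlme_data(rng, n_subjects=50, sqnps_null=False,
                            sqnps_group=0.5)
    return {c: fit_mlme(df, constraint=c)
            for c in ("qnps_only", "sqnps_only", "both")}


def test_mlme_nesting_inequality(mlme_fits):
    assert mlme_fits["both"].loglik >= mlme_fits["qnps_only"].loglik - 1e-6
    assert mlme_fits["both"].loglik >= mlme_fits["sqnps_only"].loglik - 1e-6


def test_mlme_reports_structure(mlme_fits):
    both = mlme_fits["both"]
    assert both.psi.shape == (2, 2)
    assert both.n_free_params - mlme_fits["qnps_only"].n_free_params == 5
    assert set(both.resid_sd) == {"qnps", "sqnps"}
    cmp = compare_models(mlme_fits["qnps_only"], mlme_fits["both"])
    assert cmp.df == 5 and cmp.l_ratio >= 0


def test_mlme_duplicate_outcome_boundary(rng):
    df = simulate_mlme_data(rng, n_subjects=40)
    dup = df[df["modality"] == "qnps"].copy()
    dup["modality"] = "sqnps"
    f = fit_mlme(pd.concat([df[df["modality"] == "qnps"], dup],
                           ignore_index=True))
    assert f.subject_corr >= 0.99


def test_mlme_invalid_inputs(rng):
    df = simulate_mlme_data(rng, n_subjects=10)
    with pytest.raises(ValueError):
        fit_mlme(df, constraint="nope")
    solo = df[df["modality"] == "qnps"]
    with pytest.raises(ValueError, match="both outcomes"):
        fit_mlme(solo)


def test_mlme_agrees_with_statsmodels_on_equal_variances():
    """Equal-residual special case cross-checked against MixedLM."""
    rng = np.random.default_rng(5)
    df = simulate_mlme_data(rng, n_subjects=60, sqnps_null=False,
                            sqnps_group=0.6, resid=(0.5, 0.5))
    ours = fit_mlme(df, constraint="both")
    frame = df.copy()
    frame["qind"] = (frame["modality"] == "qnps").astype(float)
    frame["sind"] = 1.0 - frame["qind"]
    frame["grp"] = (frame["group"] == "PEM").astype(float)
    frame["sexM"] = (frame["sex"] == "M").astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sm_fit = sm.MixedLM.from_formula(
            "y ~ 0 + qind + sind + qind:grp + sind:grp + qind:age + sind:age"
            " + qind:age:grp + sind:age:grp + qind:sexM + sind:sexM"
            " + qind:ecology + sind:ecology",
            groups="subject_id", re_formula="0 + qind + sind",
            data=frame).fit(reml=False)
    # our model nests the common-variance one: loglik at least as high,
    # and close since the truth has equal residual variances
    assert ours.loglik >= sm_fit.llf - 1e-4
    assert ours.loglik - sm_fit.llf < 3.0
    est = ours.fe_table.loc["qnps:group[PEM]", "estimate"]
    assert abs(est - sm_fit.params["qind:grp"]) < 0.05


# -- model comparison ------------------------------------------------------

def test_compare_identical_fits(mlme_fits):
    cmp = compare_models(mlme_fits["both"], mlme_fits["both"])
    assert cmp.l_ratio == 0.0 and cmp.p == 1.0


def test_l_ratio_is_twice_loglik_difference():
    class F:
        def __init__(self, ll, k, n):
            self.loglik, self.n_free_params, self.n_obs = ll, k, n
            self.label = "f"
    cmp = compare_models(F(-506.91, 12, 300), F(-479.7, 17, 300))
    assert cmp.l_ratio == pytest.approx(2 * (506.91 - 479.7))
    assert cmp.l_ratio == pytest.approx(54.42, abs=1e-6)
    with pytest.raises(ValueError, match="different rows"):
        compare_models(F(-10, 3, 100), F(-9, 4, 99))


# -- associations ----------------------------------------------------------

def _assoc_data(rng, beta=-0.25, n=200):
    sqnps = rng.standard_normal(n)
    df = pd.DataFrame({
        "sqnps": sqnps,
        "ecology": rng.standard_normal(n),
        "sex": np.where(rng.uniform(size=n) < 0.5, "M", "F"),
        "age": rng.uniform(45, 51, n),
    })
    df["mf"] = beta * sqnps + rng.normal(0, np.sqrt(1 - beta ** 2), n)
    return df


def test_association_recovers_standardized_beta(rng):
    df = _assoc_data(rng)
    tab = association_regression(df)
    est, se = tab.loc["sqnps", ["estimate", "se"]]
    assert abs(est - (-0.25)) < 3 * se
    # rescaling the predictor leaves the standardized beta unchanged
    tab2 = association_regression(df.assign(sqnps=df["sqnps"] * 10))
    assert tab2.loc["sqnps", "estimate"] == pytest.approx(est)


def test_association_null_predictor(rng):
    hits = 0
    for seed in range(20):
        df = _assoc_data(np.random.default_rng(seed), beta=0.0, n=150)
        tab = association_regression(df)
        hits += abs(tab.loc["sqnps", "estimate"]) < 3 * tab.loc["sqnps", "se"]
    assert hits >= 19


def test_association_too_few_rows(rng):
    df = _assoc_data(rng).head(4)
    with pytest.raises(ValueError):
        association_regression(df)
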