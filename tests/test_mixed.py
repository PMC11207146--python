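"""Mixed-model fits against closed-form and statsmodels oracles."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from remiforest.mixed import (
    MixedModelFit,
    SeparationError,
    bootstrap_margin_distribution,
    fit_mixed_linear,
    fit_mixed_logit,
    marginal_effects,
    model_compare,
)

AMOUNT_FIXED = ["payment_cum_kyuan", "education_years", "outside_province"]
LOGIT_FIXED = [
    "payment_cum_kyuan",
    "gender",
    "age_years",
    "education_years",
    "outside_province",
]


@pytest.fixture(scope="module")
def migrants(tables_bundle):
    return tables_bundle.migrants


@pytest.fixture(scope="module")
def senders(tables_bundle):
    s = tables_bundle.migrants.query("sent_remittance == 1").copy()
    s["log10_amount"] = np.log10(s["remittance_amount_yuan"])
    return s


@pytest.fixture(scope="module")
def logit_fit(migrants):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_mixed_logit(
            migrants, "sent_remittance", LOGIT_FIXED, "group_id",
            weights="sampling_weight",
        )


@pytest.fixture(scope="module")
def linear_fit(senders):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_mixed_linear(
            senders, "log10_amount", AMOUNT_FIXED, "group_id",
            weights="sampling_weight",
        )


# --- zero-variance limits vs statsmodels oracles ---------------------------

def test_logit_zero_variance_matches_weighted_glm(migrants):
    ours = fit_mixed_logit(
        migrants, "sent_remittance", LOGIT_FIXED, "group_id",
        weights="sampling_weight", fix_sigma_u=0.0,
    )
    glm = sm.GLM(
        migrants["sent_remittance"],
        sm.add_constant(migrants[LOGIT_FIXED]),
        family=sm.families.Binomial(),
        freq_weights=migrants["sampling_weight"],
    ).fit()
    np.testing.assert_allclose(
        ours.params.to_numpy(), glm.params.to_numpy(), atol=1e-3
    )


def test_linear_zero_variance_matches_wls(senders):
    ours = fit_mixed_linear(
        senders, "log10_amount", AMOUNT_FIXED, "group_id",
        weights="sampling_weight", fix_sigma_u=0.0,
    )
    wls = sm.WLS(
        senders["log10_amount"],
        sm.add_constant(senders[AMOUNT_FIXED]),
        weights=senders["sampling_weight"],
    ).fit()
    np.testing.assert_allclose(
        ours.params.to_numpy(), wls.params.to_numpy(), atol=1e-6
    )


def test_unweighted_linear_cross_checks_statsmodels_mixedlm(senders):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ours = fit_mixed_linear(
            senders, "log10_amount", AMOUNT_FIXED, "group_id"
        )
        sm_fit = sm.MixedLM.from_formula(
            "log10_amount ~ " + " + ".join(AMOUNT_FIXED),
            groups="group_id",
            data=senders,
        ).fit(reml=False)
    np.testing.assert_allclose(
        ours.params.to_numpy(), sm_fit.fe_params.to_numpy(), atol=1e-5
    )
    assert ours.sigma_u**2 == pytest.approx(
        float(sm_fit.cov_re.iloc[0, 0]), abs=1e-4
    )


# --- fit structure and errors ----------------------------------------------

def test_logit_recovers_planted_effect_and_group_variance(logit_fit, tables_bundle):
    truth = tables_bundle.config
    est = logit_fit.params["payment_cum_kyuan"]
    se = logit_fit.se["payment_cum_kyuan"]
    assert abs(est - truth.beta_ccfp_logit) < 2 * se
    assert 0.2 < logit_fit.sigma_u < 1.0
    assert 0.0 <= logit_fit.icc < 1.0


def test_constant_response_raises_separation(migrants):
    flat = migrants.copy()
    flat["sent_remittance"] = 0
    with pytest.raises(SeparationError):
        fit_mixed_logit(flat, "sent_remittance", LOGIT_FIXED, "group_id")


def test_collinear_design_raises(senders):
    dup = senders.copy()
    dup["pay_copy"] = dup["payment_cum_kyuan"]
    with pytest.raises(ValueError, match="rank"):
        fit_mixed_linear(
            dup, "log10_amount", ["payment_cum_kyuan", "pay_copy"], "group_id"
        )


def test_more_parameters_than_observations_raises(senders):
    tiny = senders.head(3)
    with pytest.raises(ValueError):
        fit_mixed_linear(tiny, "log10_amount", AMOUNT_FIXED, "group_id")


def test_information_criteria_formulas(linear_fit):
    assert linear_fit.aic == pytest.approx(
        -2 * linear_fit.loglik + 2 * linear_fit.k
    )
    assert linear_fit.bic == pytest.approx(
        -2 * linear_fit.loglik + linear_fit.k * np.log(linear_fit.n)
    )
    # hand arithmetic: ll=-100, k=5, n=100 -> BIC = 200 + 5 ln 100 = 223.03
    f = MixedModelFit(
        family="linear", response="y", columns=[], params=pd.Series(dtype=float),
        se=pd.Series(dtype=float), sigma_u=0, sigma_e=1, icc=0, loglik=-100.0,
        n=100, k=5, converged=True, group="g",
    )
    assert f.bic == pytest.approx(223.03, abs=0.005)


def test_icc_is_monotone_in_group_variance(senders):
    fits = []
    for s in (0.05, 0.15, 0.4):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fits.append(
                fit_mixed_linear(
                    senders, "log10_amount", AMOUNT_FIXED, "group_id",
                    fix_sigma_u=s,
                )
            )
    iccs = [f.icc for f in fits]
    assert iccs == sorted(iccs)
    assert all(0 <= v < 1 for v in iccs)


# --- marginal effects ------------------------------------------------------

def test_linear_marginal_effect_equals_coefficient(linear_fit, senders):
    me = marginal_effects(linear_fit, senders[AMOUNT_FIXED].mean())
    eff = me.effects.set_index("variable")["effect"]
    for v in AMOUNT_FIXED:
        assert eff[v] == linear_fit.params[v]


def test_zero_coefficient_gives_exactly_zero_effect(logit_fit, migrants):
    clone = MixedModelFit(**{**logit_fit.__dict__})
    params = clone.params.copy()
    params["gender"] = 0.0
    clone.params = params
    me = marginal_effects(clone, migrants[LOGIT_FIXED].mean())
    assert (
        me.effects.set_index("variable").loc["gender", "effect"] == 0.0
    )


def test_logistic_effect_matches_finite_difference_oracle(logit_fit, migrants):
    """dP/dx from the quadrature formula equals a numeric derivative of the
    population-averaged probability."""
    from remiforest.mixed import _pa_probability

    at = migrants[LOGIT_FIXED].mean()
    me = marginal_effects(logit_fit, at)
    x = np.array([1.0] + [at[c] for c in LOGIT_FIXED])
    j = logit_fit.columns.index("payment_cum_kyuan")
    h = 1e-6
    xp, xm = x.copy(), x.copy()
    xp[j] += h
    xm[j] -= h
    numeric = (
        _pa_probability(logit_fit, xp)[0] - _pa_probability(logit_fit, xm)[0]
    ) / (2 * h)
    got = me.effects.set_index("variable").loc["payment_cum_kyuan", "effect"]
    assert got == pytest.approx(numeric, abs=1e-6)


def test_fixed_effects_logistic_effect_is_beta_p_one_minus_p(migrants):
    """With no random intercept and P=0.5 the effect reduces to beta/4."""
    f0 = fit_mixed_logit(
        migrants, "sent_remittance", LOGIT_FIXED, "group_id", fix_sigma_u=0.0
    )
    beta = f0.params
    # find an 'at' with linear predictor exactly 0 => P = 0.5
    at = migrants[LOGIT_FIXED].mean()
    eta_rest = beta["const"] + sum(
        beta[c] * at[c] for c in LOGIT_FIXED if c != "payment_cum_kyuan"
    )
    at["payment_cum_kyuan"] = -eta_rest / beta["payment_cum_kyuan"]
    me = marginal_effects(f0, at)
    eff = me.effects.set_index("variable")["effect"]
    assert eff["payment_cum_kyuan"] == pytest.approx(
        beta["payment_cum_kyuan"] / 4, rel=1e-6
    )


def test_marginal_effects_missing_column_raises(logit_fit):
    with pytest.raises(KeyError, match="missing"):
        marginal_effects(logit_fit, {"gender": 1.0})


def test_predictive_margins_increase_with_payment(logit_fit, migrants):
    me = marginal_effects(
        logit_fit,
        migrants[LOGIT_FIXED].mean(),
        grid_var="payment_cum_kyuan",
        grid=np.linspace(0, 12, 7),
    )
    m = me.margins["margin"].to_numpy()
    assert np.all(np.diff(m) > 0)
    assert 0.1 < m[0] < 0.5 and m[-1] < 0.9


# --- bootstrap margins -----------------------------------------------------

def test_bootstrap_margins_seeded_and_equal_weights_match():
    rng = np.random.default_rng(42)
    n_hh = 60
    hh = np.repeat(np.arange(n_hh), 2)
    grp = hh % 6
    x = rng.normal(0, 1, n_hh * 2)
    eta = -0.3 + 0.8 * x + rng.normal(0, 0.3, n_hh * 2)[grp * 0]
    y = (rng.random(n_hh * 2) < 1 / (1 + np.exp(-eta))).astype(int)
    df = pd.DataFrame(
        {
            "household_id": hh,
            "group_id": grp,
            "x": x,
            "y": y,
            "w_equal": 1.0,
            "w_scaled": 2.0,
        }
    )
    kwargs = dict(
        response="y", fixed=["x"], group="group_id", focal="x",
        family="logit", n_reps=100,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = bootstrap_margin_distribution(df, weights="w_equal", seed=5, **kwargs)
        b = bootstrap_margin_distribution(df, weights="w_scaled", seed=5, **kwargs)
        c = bootstrap_margin_distribution(df, weights="w_equal", seed=5, **kwargs)
    # uniform weights (any scale) give the ordinary bootstrap distribution
    np.testing.assert_allclose(a["samples"], b["samples"])
    np.testing.assert_allclose(a["samples"], c["samples"])
    assert a["ci95"][0] < 0.8 / 4 * 1.5  # interval is in a sane range


def test_bootstrap_interval_covers_zero_for_null_effect():
    """Degenerate zero-effect data: the response is orthogonalised against
    the predictor, so the planted (and sample) slope is exactly zero."""
    rng = np.random.default_rng(1)
    n = 150
    x = rng.normal(0, 1, n)
    y0 = rng.normal(0, 1, n)
    y = y0 - np.polyfit(x, y0, 1)[0] * x  # regress the slope out
    df = pd.DataFrame(
        {
            "household_id": np.arange(n),
            "group_id": np.arange(n) % 8,
            "x": x,
            "y": y,
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = bootstrap_margin_distribution(
            df, response="y", fixed=["x"], group="group_id", focal="x",
            family="linear", n_reps=120, seed=9,
        )
    lo, hi = res["ci95"]
    assert lo < 0 < hi


def test_bootstrap_requires_hundred_reps():
    with pytest.raises(ValueError, match="100"):
        bootstrap_margin_distribution(
            pd.DataFrame({"household_id": [1]}), response="y", fixed=[],
            group="g", focal="x", n_reps=10,
        )


# --- model comparison ------------------------------------------------------

def test_model_compare_identical_fits_no_favourite(linear_fit):
    tab = model_compare({"m1": linear_fit, "m2": linear_fit})
    assert tab["delta_bic"].max() == 0.0
    assert not tab["favoured"].any()


def test_model_compare_prefers_true_model(senders):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        small = fit_mixed_linear(
            senders, "log10_amount", ["gender"], "group_id"
        )
        full = fit_mixed_linear(
            senders, "log10_amount", AMOUNT_FIXED, "group_id"
        )
    tab = model_compare({"payment_free": small, "full": full})
    assert tab.loc["full", "favoured"]
    assert tab.loc["full", "bic"] < tab.loc["payment_free", "bic"] - 10


def test_model_compare_rejects_mismatched_samples(linear_fit, senders):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        other = fit_mixed_linear(
            senders.head(100), "log10_amount", AMOUNT_FIXED, "group_id"
        )
    with pytest.raises(ValueError, match="same"):
        model_compare({"a": linear_fit, "b": other})
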