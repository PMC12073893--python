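"""Association battery: closed forms, likelihood-grid oracles, enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from epimetab.assoc import (
    enrich,
    mlm_age,
    outcome_assoc,
    risk_factor_assoc,
    top_k_cpgs,
)
from epimetab.errors import ValidationError

# ---------------------------------------------------------------------------
# mlm_age


def _phen(n=300, seed=0):
    rng = np.random.default_rng(seed)
    idx = [f"S{i}" for i in range(n)]
    age = pd.Series(rng.uniform(21, 65, n), index=idx, name="age")
    sex = pd.Series(rng.integers(0, 2, n), index=idx, name="sex")
    return rng, age, sex


def test_mlm_standardised_age_feature_has_closed_form_slope():
    rng, age, sex = _phen()
    feat = pd.DataFrame({"agez": (age - age.mean()) / age.std(ddof=0)})
    out = mlm_age(feat, age, sex)
    assert out["effect_per_year"].iloc[0] == pytest.approx(1.0 / age.std(ddof=0), rel=1e-9)
    assert out["p"].iloc[0] < 1e-200


def test_mlm_sex_only_feature_has_null_age_slope():
    rng, age, sex = _phen(seed=1)
    feat = pd.DataFrame({"sexz": (sex - sex.mean()) / sex.std(ddof=0)})
    out = mlm_age(feat, age, sex)
    assert abs(out["effect_per_year"].iloc[0]) < 1e-12  # sex fully absorbed by covariate


def test_mlm_null_features_bonferroni_calibration():
    """1,000 independent features: Bonferroni finds nothing in >= 19/20 seeds."""
    hits = 0
    for seed in range(20):
        rng, age, sex = _phen(n=200, seed=seed)
        feat = pd.DataFrame(
            rng.normal(size=(200, 1000)), index=age.index,
            columns=[f"f{j}" for j in range(1000)],
        )
        out = mlm_age(feat, age, sex)
        hits += int(out["significant"].any())
    assert hits <= 1


def test_mlm_constant_sex_dropped_with_warning():
    rng, age, _ = _phen(n=60, seed=2)
    sex = pd.Series(1, index=age.index)
    feat = pd.DataFrame({"f": rng.normal(size=60)}, index=age.index)
    with pytest.warns(UserWarning, match="constant"):
        out = mlm_age(feat, age, sex)
    assert len(out) == 1


def test_mlm_matches_statsmodels_per_feature():
    import statsmodels.api as sm

    rng, age, sex = _phen(n=150, seed=3)
    feat = pd.DataFrame({"f": 0.02 * age + rng.normal(0, 1, 150)}, index=age.index)
    out = mlm_age(feat, age, sex)
    X = sm.add_constant(pd.DataFrame({"age": age, "sex": sex}))
    ref = sm.OLS(feat["f"], X).fit()
    assert out["effect_per_year"].iloc[0] == pytest.approx(ref.params["age"], rel=1e-10)
    assert out["p"].iloc[0] == pytest.approx(ref.pvalues["age"], rel=1e-8)


# ---------------------------------------------------------------------------
# risk factors


def _accel_fixture(n=500, effect=0.4, seed=0):
    rng = np.random.default_rng(seed)
    idx = [f"S{i}" for i in range(n)]
    alcohol = pd.Series(
        pd.Categorical.from_codes(rng.choice(3, n, p=[0.07, 0.86, 0.07]),
                                  ["none", "moderate", "heavy"]),
        index=idx, name="alcohol",
    )
    accel = pd.Series(rng.normal(size=n) + effect * (alcohol == "heavy"), index=idx,
                      name="accel")
    cov = pd.DataFrame(
        {
            "age": rng.uniform(21, 65, n),
            "sex": rng.integers(0, 2, n),
            "ethnicity": pd.Categorical(rng.choice(["white", "nonwhite"], n, p=[0.97, 0.03])),
        },
        index=idx,
    )
    return accel, alcohol, cov


def test_risk_factor_recovers_planted_effect():
    accel, alcohol, cov = _accel_fixture(effect=0.4, seed=5)
    results = risk_factor_assoc(accel, alcohol, cov)
    by_level = {r.exposure: r for r in results}
    heavy = by_level["alcohol[heavy]"]
    assert heavy.reference_level == "none"
    assert heavy.ci_low < 0.4 < heavy.ci_high
    assert heavy.ci_low < heavy.effect < heavy.ci_high


def test_risk_factor_age_reentered_is_null():
    """Acceleration is orthogonal to age, so age as an exposure has ~zero
    effect."""
    accel, alcohol, cov = _accel_fixture(effect=0.0, seed=6)
    # make accel exactly orthogonal to age
    age = cov["age"]
    resid = accel - np.polyval(np.polyfit(age, accel, 1), age)
    resid = (resid - resid.mean()) / resid.std(ddof=0)
    resid.name = "accel"
    (res,) = risk_factor_assoc(resid, age.rename("age_factor"), cov[["sex", "ethnicity"]])
    assert abs(res.effect) < 0.1
    assert res.p > 0.05


def test_risk_factor_single_level_errors():
    accel, alcohol, cov = _accel_fixture()
    const = pd.Series(pd.Categorical(["x"] * len(accel)), index=accel.index, name="c")
    with pytest.raises(ValidationError, match="single level"):
        risk_factor_assoc(accel, const, cov)


def test_risk_factor_small_level_warns():
    accel, alcohol, cov = _accel_fixture(n=60, seed=8)
    lv = pd.Series(pd.Categorical(["a"] * 57 + ["b"] * 3), index=accel.index, name="f")
    with pytest.warns(UserWarning, match="< 5"):
        risk_factor_assoc(accel, lv, cov)


def test_risk_factor_sensitivity_covariates_accepted():
    accel, alcohol, cov = _accel_fixture(seed=9)
    rng = np.random.default_rng(1)
    extra = pd.DataFrame(
        {"bmi": rng.normal(27, 4, len(accel)),
         "smoking": pd.Categorical(rng.choice(["never", "former", "current"], len(accel)))},
        index=accel.index,
    )
    res = risk_factor_assoc(accel, alcohol, cov, extra_covariates=extra)
    assert {r.exposure for r in res} == {"alcohol[moderate]", "alcohol[heavy]"}
    assert all("bmi" in r.covariates for r in res)


# ---------------------------------------------------------------------------
# outcome models


def test_logistic_two_by_two_closed_form():
    """Binary exposure on the 2x2 table (a,b,c,d) = (20,10,10,20): the
    log-odds ratio is ln(ad/bc) = ln 4."""
    y = np.array([1] * 20 + [0] * 10 + [1] * 10 + [0] * 20)
    x = np.array([1] * 30 + [0] * 30)
    accel = pd.Series(x.astype(float), name="exposure")
    res = outcome_assoc(accel, pd.Series(y), "logistic", standardize_exposure=False)
    assert res.effect == pytest.approx(np.log(4.0), rel=1e-6)
    assert res.ci_low < res.effect < res.ci_high


def test_cox_two_group_exponential_recovers_hazard_ratio():
    """True HR = 2 between two groups with exponential survival, n = 2,000."""
    rng = np.random.default_rng(12)
    n = 2000
    g = rng.integers(0, 2, n)
    t = rng.exponential(1.0 / np.exp(np.log(2.0) * g))
    c = np.minimum(t, 3.0)
    e = (t <= 3.0).astype(int)
    accel = pd.Series(g.astype(float), name="group")
    res = outcome_assoc(accel, (pd.Series(c), pd.Series(e)), "cox",
                        standardize_exposure=False)
    assert np.exp(res.effect) == pytest.approx(2.0, abs=0.15)


def test_cox_zero_events_errors():
    accel = pd.Series(np.arange(20, dtype=float))
    with pytest.raises(ValidationError, match="events"):
        outcome_assoc(accel, (pd.Series(np.ones(20)), pd.Series(np.zeros(20))), "cox")


def test_negbin_on_poisson_data_matches_poisson_fit():
    """With no overdispersion the NB2 rate ratio converges to the Poisson
    estimate (within 2%)."""
    import statsmodels.api as sm

    rng = np.random.default_rng(13)
    n = 1500
    x = rng.normal(size=n)
    y = rng.poisson(np.exp(0.5 + 0.3 * x))
    accel = pd.Series(x, name="exposure")
    res = outcome_assoc(accel, pd.Series(y), "negative_binomial", standardize_exposure=False)
    pois = sm.GLM(y, sm.add_constant(x), family=sm.families.Poisson()).fit()
    assert res.effect == pytest.approx(pois.params[1], rel=0.02)


def test_negbin_rejects_non_integer_counts():
    accel = pd.Series(np.arange(30, dtype=float))
    with pytest.raises(ValidationError, match="integer"):
        outcome_assoc(accel, pd.Series(np.linspace(0.5, 3, 30)), "negative_binomial")


def test_unknown_family_rejected():
    accel = pd.Series(np.arange(10, dtype=float))
    with pytest.raises(ValidationError, match="family"):
        outcome_assoc(accel, pd.Series(np.zeros(10)), "probit")


# --- likelihood oracles ----------------------------------------------------


def test_logistic_matches_likelihood_oracle():
    """The logistic estimate maximises an independently coded Bernoulli
    log-likelihood (agreement to 1e-3)."""
    rng = np.random.default_rng(20)
    n = 90
    x = rng.normal(size=n)
    y = (rng.random(n) < 1 / (1 + np.exp(-(-0.3 + 0.8 * x)))).astype(float)
    res = outcome_assoc(pd.Series(x, name="x"), pd.Series(y), "logistic",
                        standardize_exposure=False)

    def nll(b):
        eta = b[0] + b[1] * x
        return -(y * eta - np.log1p(np.exp(eta))).sum()

    opt = optimize.minimize(nll, [0.0, 0.0], method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10})
    assert res.effect == pytest.approx(opt.x[1], abs=1e-3)


def test_cox_matches_partial_likelihood_oracle():
    """The Cox estimate maximises an independently coded partial likelihood
    (no ties, so Efron = Breslow), agreement to 1e-3."""
    rng = np.random.default_rng(21)
    n = 80
    x = rng.normal(size=n)
    t = rng.exponential(1.0 / np.exp(0.6 * x))
    e = (t <= np.quantile(t, 0.8)).astype(int)
    tt = np.minimum(t, np.quantile(t, 0.8))
    res = outcome_assoc(pd.Series(x, name="x"), (pd.Series(tt), pd.Series(e)), "cox",
                        standardize_exposure=False)

    order = np.argsort(tt)
    ts, es, xs = tt[order], e[order], x[order]

    def npl(b):
        eta = b * xs
        # risk set of subject i: all j with t_j >= t_i
        log_risk = np.log(np.cumsum(np.exp(eta)[::-1])[::-1])
        return -((eta - log_risk) * es).sum()

    opt = optimize.minimize_scalar(npl, bounds=(-3, 3), method="bounded",
                                   options={"xatol": 1e-10})
    assert res.effect == pytest.approx(opt.x, abs=1e-3)


def test_negbin_matches_likelihood_oracle():
    """The NB2 estimate maximises an independently coded negative-binomial
    log-likelihood with free dispersion (agreement to 1e-3)."""
    from scipy.special import gammaln

    rng = np.random.default_rng(22)
    n = 100
    x = rng.normal(size=n)
    mu = np.exp(0.8 + 0.4 * x)
    theta = 3.0
    y = rng.poisson(rng.gamma(theta, mu / theta)).astype(float)
    res = outcome_assoc(pd.Series(x, name="x"), pd.Series(y), "negative_binomial",
                        standardize_exposure=False)

    def nll(par):
        b0, b1, log_a = par
        a = np.exp(log_a)            # statsmodels NB2 alpha = 1/theta
        m = np.exp(b0 + b1 * x)
        size = 1.0 / a
        ll = (
            gammaln(y + size) - gammaln(size) - gammaln(y + 1)
            + size * np.log(size / (size + m)) + y * np.log(m / (size + m))
        )
        return -ll.sum()

    opt = optimize.minimize(nll, [0.0, 0.0, 0.0], method="Nelder-Mead",
                            options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 5000})
    assert res.effect == pytest.approx(opt.x[1], abs=1e-3)


# ---------------------------------------------------------------------------
# enrichment


def _annotation(bg, mapping):
    rows = [{"probe_id": p, "trait": t} for t, probes in mapping.items() for p in probes]
    return pd.DataFrame(rows)


def test_enrich_matches_hypergeometric_tail():
    """(10 in-set annotated, 90 in-set not, 100 out annotated, 800 out not):
    the one-sided Fisher p equals the hypergeometric tail sum."""
    bg = [f"cg{i}" for i in range(1000)]
    cset = bg[:100]
    trait_probes = bg[:10] + bg[100:200]      # 10 overlap + 100 outside
    ann = _annotation(bg, {"traitX": trait_probes})
    out = enrich(cset, ann, bg)
    p_hyper = stats.hypergeom.sf(10 - 1, 1000, 110, 100)
    assert out.loc[0, "p"] == pytest.approx(p_hyper, rel=1e-10)
    assert out.loc[0, "overlap"] == 10


def test_enrich_identical_set_is_minimal_p_infinite_or():
    bg = [f"cg{i}" for i in range(200)]
    cset = bg[:30]
    ann = _annotation(bg, {"self": list(cset), "other": bg[50:80]})
    out = enrich(cset, ann, bg).set_index("trait")
    assert np.isinf(out.loc["self", "odds_ratio"])
    assert out.loc["self", "p"] < 1e-30
    assert out.loc["self", "p_fdr"] >= out.loc["self", "p"]


def test_enrich_zero_overlap_p_one():
    bg = [f"cg{i}" for i in range(100)]
    ann = _annotation(bg, {"t": bg[50:60]})
    out = enrich(bg[:10], ann, bg)
    assert out.loc[0, "overlap"] == 0
    assert out.loc[0, "p"] == pytest.approx(1.0)


def test_enrich_set_outside_background_errors():
    bg = [f"cg{i}" for i in range(50)]
    ann = _annotation(bg, {"t": bg[:5]})
    with pytest.raises(ValidationError, match="background"):
        enrich(["cgX"], ann, bg)


def test_top_k_cpgs_by_absolute_coefficient():
    coefs = pd.Series({"a": 0.1, "b": -0.9, "c": 0.5, "d": -0.2})
    assert top_k_cpgs(coefs, k=2) == ["b", "c"]


@given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=40))
@settings(max_examples=50, deadline=None)
def test_bh_and_bonferroni_monotone_in_raw_p(pvals):
    """Adjusted p-values are monotone transforms of the raw p-values."""
    p = np.array(pvals)
    bh = multipletests(p, method="fdr_bh")[1]
    bonf = np.minimum(1.0, p * len(p))
    order = np.argsort(p)
    assert np.all(np.diff(bh[order]) >= -1e-12)
    assert np.all(np.diff(bonf[order]) >= -1e-12)
    assert np.all(bh >= p - 1e-12)
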