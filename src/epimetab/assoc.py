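"""Association battery for surrogates, clocks and age acceleration.

Four analysis families:

* :func:`mlm_age` — per-feature sex-adjusted linear regression on
  chronological age, with Bonferroni control; effects are the change in
  feature standard deviations per year of age.
* :func:`risk_factor_assoc` — linear regression of scaled age acceleration
  on a (categorical or continuous) risk factor, adjusted for age, sex and
  ethnicity, optionally plus sensitivity covariates (e.g. BMI, smoking).
* :func:`outcome_assoc` — regression of a health outcome on scaled age
  acceleration: Cox proportional hazards for time-to-event (Efron ties),
  logistic for binary, ordinary least squares for continuous and NB2
  negative binomial for overdispersed counts.  Effects are per SD of the
  exposure.
* :func:`enrich` — one-sided Fisher's exact enrichment of a CpG set against
  a local probe→trait annotation table, with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

__all__ = [
    "AssociationResult",
    "EnrichmentResult",
    "mlm_age",
    "risk_factor_assoc",
    "outcome_assoc",
    "enrich",
    "top_k_cpgs",
    "clock_cpg_coefficients",
    "results_table",
]

_FAMILIES = ("linear", "logistic", "cox", "negative_binomial")


@dataclass
class AssociationResult:
    exposure: str
    outcome: str
    family: str                  # linear | logistic | cox | negative_binomial
    effect: float                # slope | log-odds | log-hazard | log-rate, per SD of exposure
    ci_low: float
    ci_high: float
    p: float
    covariates: tuple[str, ...]
    n: int
    reference_level: str | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValidationError(f"family must be one of {_FAMILIES}")

    @property
    def ratio(self) -> float:
        """Exponentiated effect (HR / OR / rate ratio); slope for linear."""
        return float(np.exp(self.effect)) if self.family != "linear" else self.effect


@dataclass
class EnrichmentResult:
    trait: str
    overlap: int
    set_size: int
    trait_size: int
    background_size: int
    odds_ratio: float
    p: float
    p_fdr: float


def results_table(results: list[AssociationResult]) -> pd.DataFrame:
    """Forest-plot-ready tidy table of association results."""
    return pd.DataFrame(
        [
            {
                "exposure": r.exposure,
                "outcome": r.outcome,
                "family": r.family,
                "effect": r.effect,
                "lo95": r.ci_low,
                "hi95": r.ci_high,
                "p": r.p,
                "n": r.n,
                "covariates": "+".join(r.covariates),
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# per-feature age associations


def mlm_age(
    features: pd.DataFrame, age: pd.Series, sex: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Sex-adjusted linear regression of every feature on chronological age.

    Each (standardised) feature is regressed on age + sex in one closed-form
    pass; the reported effect is the change in feature SD per year of age.
    Bonferroni correction runs over the number of features.  A constant sex
    column is dropped with a warning.
    """
    idx = features.index
    a = age.reindex(idx).to_numpy(dtype=float)
    s = sex.reindex(idx).to_numpy(dtype=float)
    cols = [np.ones_like(a), a]
    names = ["intercept", "age"]
    if np.ptp(s) == 0:
        warnings.warn("sex is constant; dropping it from the adjustment set", stacklevel=2)
    else:
        cols.append(s)
        names.append("sex")
    X = np.column_stack(cols)
    Y = features.to_numpy(dtype=float)
    n, k = X.shape
    coef, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    dof = n - rank
    sigma2 = (resid ** 2).sum(axis=0) / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    se_age = np.sqrt(sigma2 * xtx_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se_age > 0, coef[1] / se_age, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    tcrit = stats.t.ppf(0.975, dof)
    m = features.shape[1]
    out = pd.DataFrame(
        {
            "feature_id": features.columns,
            "effect_per_year": coef[1],
            "se": se_age,
            "lo95": coef[1] - tcrit * se_age,
            "hi95": coef[1] + tcrit * se_age,
            "p": p,
            "p_bonferroni": np.minimum(1.0, p * m),
        }
    )
    out["significant"] = out["p_bonferroni"] < alpha
    return out


# ---------------------------------------------------------------------------
# risk-factor regressions on age acceleration


def risk_factor_assoc(
    acceleration: pd.Series,
    factor: pd.Series,
    covariates: pd.DataFrame,
    extra_covariates: pd.DataFrame | None = None,
    min_level_n: int = 5,
) -> list[AssociationResult]:
    """Linear regression of scaled age acceleration on one risk factor.

    Categorical factors are dummy-coded against their first level (the
    explicit reference); one result per non-reference level, in SD units of
    acceleration.  Continuous factors give a single per-SD result.  The
    adjustment set is ``covariates`` (age, sex, ethnicity) plus any
    ``extra_covariates`` (the BMI/smoking sensitivity set).
    """
    idx = acceleration.index
    fac = factor.reindex(idx)
    cov = covariates.reindex(idx)
    if extra_covariates is not None:
        cov = pd.concat([cov, extra_covariates.reindex(idx)], axis=1)
    cov_num = _encode_covariates(cov)

    categorical = isinstance(fac.dtype, pd.CategoricalDtype) or fac.dtype == object
    y = acceleration.to_numpy(dtype=float)
    results = []
    if categorical:
        fac = fac.astype("category")
        levels = list(fac.cat.categories)
        if len(levels) < 2:
            raise ValidationError(f"factor {factor.name!r} has a single level")
        counts = fac.value_counts()
        small = [lv for lv in levels if counts.get(lv, 0) < min_level_n]
        if small:
            warnings.warn(f"factor levels with < {min_level_n} samples: {small}", stacklevel=2)
        dummies = pd.get_dummies(fac, drop_first=True).astype(float)
        X = pd.concat([dummies, cov_num], axis=1)
        X = sm.add_constant(X)
        fit = sm.OLS(y, X.to_numpy(), missing="drop").fit()
        param_names = list(X.columns)
        for level in levels[1:]:
            j = param_names.index(level)
            ci = fit.conf_int()[j]
            results.append(
                AssociationResult(
                    exposure=f"{factor.name}[{level}]",
                    outcome=str(acceleration.name or "age_acceleration"),
                    family="linear",
                    effect=float(fit.params[j]),
                    ci_low=float(ci[0]),
                    ci_high=float(ci[1]),
                    p=float(fit.pvalues[j]),
                    covariates=tuple(cov.columns),
                    n=int(fit.nobs),
                    reference_level=str(levels[0]),
                )
            )
    else:
        x = fac.to_numpy(dtype=float)
        sd = x.std(ddof=0)
        if sd == 0:
            raise ValidationError(f"factor {factor.name!r} is constant")
        xz = (x - x.mean()) / sd
        X = pd.concat([pd.Series(xz, index=idx, name="exposure"), cov_num], axis=1)
        X = sm.add_constant(X)
        fit = sm.OLS(y, X.to_numpy(), missing="drop").fit()
        j = list(X.columns).index("exposure")
        ci = fit.conf_int()[j]
        results.append(
            AssociationResult(
                exposure=str(factor.name),
                outcome=str(acceleration.name or "age_acceleration"),
                family="linear",
                effect=float(fit.params[j]),
                ci_low=float(ci[0]),
                ci_high=float(ci[1]),
                p=float(fit.pvalues[j]),
                covariates=tuple(cov.columns),
                n=int(fit.nobs),
            )
        )
    return results


def _encode_covariates(cov: pd.DataFrame) -> pd.DataFrame:
    """Dummy-code categorical covariates; pass numeric ones through."""
    parts = []
    for name in cov.columns:
        col = cov[name]
        if isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == object:
            d = pd.get_dummies(col.astype("category"), prefix=name, drop_first=True).astype(float)
            parts.append(d)
        else:
            col = col.astype(float)
            if col.std(ddof=0) == 0:
                warnings.warn(f"covariate {name!r} is constant; dropped", stacklevel=3)
                continue
            parts.append(col)
    return pd.concat(parts, axis=1) if parts else pd.DataFrame(index=cov.index)


# ---------------------------------------------------------------------------
# outcome models


def outcome_assoc(
    acceleration: pd.Series,
    outcome,
    family: str,
    covariates: pd.DataFrame | None = None,
    outcome_name: str | None = None,
    standardize_exposure: bool = True,
) -> AssociationResult:
    """Regression of one health outcome on scaled age acceleration.

    ``family`` selects the model: ``"cox"`` (pass ``outcome=(time, event)``),
    ``"logistic"`` (binary), ``"linear"`` (continuous) or
    ``"negative_binomial"`` (integer counts, NB2 with ML dispersion).
    The exposure is standardised so the effect is per SD of acceleration:
    log hazard ratio, log odds ratio, slope, or log rate ratio.
    """
    if family not in _FAMILIES:
        raise ValidationError(f"family must be one of {_FAMILIES}, got {family!r}")
    idx = acceleration.index
    x = acceleration.to_numpy(dtype=float)
    if standardize_exposure:
        sd = x.std(ddof=0)
        if sd == 0:
            raise ValidationError("acceleration is constant")
        x = (x - x.mean()) / sd
    cov_num = (
        _encode_covariates(covariates.reindex(idx)) if covariates is not None else pd.DataFrame(index=idx)
    )
    cov_names = tuple(covariates.columns) if covariates is not None else ()

    if family == "cox":
        time, event = outcome
        time = pd.Series(time).reindex(idx).to_numpy(dtype=float)
        event = pd.Series(event).reindex(idx).to_numpy(dtype=float)
        if event.sum() == 0:
            raise ValidationError("no events observed; Cox model is undefined")
        df = pd.DataFrame({"time": time, "event": event, "accel": x}, index=idx)
        for c in cov_num.columns:
            df[c] = cov_num[c]
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")  # Efron tie handling
        row = cph.summary.loc["accel"]
        return AssociationResult(
            exposure=str(acceleration.name or "age_acceleration"),
            outcome=outcome_name or "time_to_event",
            family="cox",
            effect=float(row["coef"]),
            ci_low=float(row["coef lower 95%"]),
            ci_high=float(row["coef upper 95%"]),
            p=float(row["p"]),
            covariates=cov_names,
            n=len(df),
        )

    y = pd.Series(outcome).reindex(idx).to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(x), x] + [cov_num[c].to_numpy(dtype=float) for c in cov_num.columns])
    oname = outcome_name or str(getattr(outcome, "name", None) or "outcome")

    if family == "linear":
        fit = sm.OLS(y, X).fit()
    elif family == "logistic":
        uniq = np.unique(y[~np.isnan(y)])
        if not np.all(np.isin(uniq, [0.0, 1.0])):
            raise ValidationError(f"logistic outcome must be binary 0/1, saw values {uniq[:4]}")
        # IRLS is robust to quasi-separation in sparse covariate dummies,
        # where Newton's method can hit a singular Hessian
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    else:  # negative binomial, NB2 with ML-estimated dispersion
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ValidationError("negative_binomial outcome must be non-negative integer counts")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.NegativeBinomial(y, X, loglike_method="nb2").fit(disp=0, maxiter=200)
    ci = fit.conf_int()[1]
    return AssociationResult(
        exposure=str(acceleration.name or "age_acceleration"),
        outcome=oname,
        family=family,
        effect=float(fit.params[1]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p=float(fit.pvalues[1]),
        covariates=cov_names,
        n=int(fit.nobs),
    )


# ---------------------------------------------------------------------------
# enrichment


def clock_cpg_coefficients(clock, surrogate_models) -> pd.Series:
    """Per-CpG composite coefficient of a surrogate-space clock.

    Chains the clock's weight on each surrogate through that surrogate's CpG
    coefficients: contribution(probe) = sum_m clock_coef[m] * surr_coef[m][probe].
    For a cpg-space clock the clock coefficients are returned directly.
    """
    if clock.feature_space == "cpg":
        return pd.Series(clock.coef, dtype=float)
    by_id = {m.metabolite_id: m for m in surrogate_models}
    agg: dict[str, float] = {}
    for met, w in clock.coef.items():
        model = by_id.get(met)
        if model is None:
            raise ValidationError(f"no surrogate model for clock feature {met!r}")
        for probe, c in model.coef.items():
            agg[probe] = agg.get(probe, 0.0) + w * c
    return pd.Series(agg, dtype=float)


def top_k_cpgs(cpg_coefficients: pd.Series, k: int = 5000) -> list[str]:
    """The k CpGs with the largest absolute composite coefficient."""
    return list(cpg_coefficients.abs().sort_values(ascending=False, kind="mergesort").head(k).index)


def enrich(
    cpg_set,
    annotation: pd.DataFrame,
    background,
    probe_col: str = "probe_id",
    trait_col: str = "trait",
) -> pd.DataFrame:
    """One-sided Fisher enrichment of a CpG set against trait annotations.

    ``annotation`` maps probes to trait labels (long format, one row per
    probe-trait link); ``background`` is every probe surviving QC.  For each
    trait the 2x2 overlap table is tested with Fisher's exact test
    (alternative: enrichment), then Benjamini-Hochberg FDR across traits.
    """
    bg = set(background)
    cset = set(cpg_set)
    outside = cset - bg
    if outside:
        raise ValidationError(
            f"cpg_set must be a subset of the background; offending: {sorted(outside)[:5]}"
        )
    ann = annotation[annotation[probe_col].isin(bg)]
    rows = []
    for trait, grp in ann.groupby(trait_col, sort=True):
        trait_probes = set(grp[probe_col])
        a = len(cset & trait_probes)                  # in set, annotated
        b = len(cset) - a                             # in set, not annotated
        c = len(trait_probes) - a                     # out of set, annotated
        d = len(bg) - len(cset) - c                   # out of set, not annotated
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append(
            {
                "trait": trait,
                "overlap": a,
                "set_size": len(cset),
                "trait_size": len(trait_probes),
                "background_size": len(bg),
                "odds_ratio": float(odds),
                "p": float(p),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["p_fdr"] = pd.Series(dtype=float)
    return out
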