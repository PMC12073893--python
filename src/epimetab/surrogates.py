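"""Methylation surrogates for circulating metabolites.

One surrogate per metabolite, built in four steps on a train/test split:

1. **EWAS screen** — per-probe simple linear regression of the metabolite on
   each probe's standardised M-values in the training set; the top fraction
   (default 1%) of probes by p-value feeds the penalised fit.
2. **Lasso fit** — L1-penalised regression of the metabolite on the screened
   probes, penalty chosen by k-fold cross-validation (minimum mean CV error
   by default, one-standard-error rule optional).
3. **Bimodality filter** — surrogates whose predicted values are multimodal
   are flagged: a multi-modal surrogate is the signature of a single
   polymorphism (SNP) driving its CpGs rather than the metabolite.  The flag
   combines Hartigan's dip test with a kernel-density mode count.
4. **Test-set validation** — Pearson correlation between surrogate
   predictions and the measured metabolite in the held-out test set, with
   Bonferroni control over the surrogate family.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

from ._dip import dip_test
from .errors import LeakageError, SchemaError, ValidationError

__all__ = [
    "EwasScreenResult",
    "SurrogateModel",
    "SurrogateValidation",
    "BimodalityResult",
    "split_cohort",
    "ewas_screen",
    "train_surrogate",
    "predict_surrogate",
    "bimodality_flag",
    "validate_surrogates",
    "min_significant_r",
    "write_surrogates",
    "read_surrogates",
]


# ---------------------------------------------------------------------------
# cohort split


def split_cohort(sample_ids, train_fraction: float = 0.8, seed: int = 0):
    """Seeded disjoint, exhaustive train/test partition (default 4:1).

    Train size is ``round(train_fraction * n)``.
    """
    ids = pd.Index(sample_ids)
    n = len(ids)
    if n < 10:
        raise ValidationError(f"split_cohort needs at least 10 samples, got {n}")
    if not (0.0 < train_fraction < 1.0):
        raise ValidationError(f"train_fraction must be in (0, 1), got {train_fraction}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    train = ids[np.sort(perm[:n_train])]
    test = ids[np.sort(perm[n_train:])]
    return train, test


# ---------------------------------------------------------------------------
# EWAS screen


@dataclass
class EwasScreenResult:
    metabolite_id: str
    table: pd.DataFrame          # probe_id, slope, se, p (all probes)
    top_probes: list[str]        # ceil(top_fraction * n_probes), ranked
    top_fraction: float


def ewas_screen(
    metabolite: pd.Series,
    m_matrix: pd.DataFrame,
    top_fraction: float = 0.01,
    metabolite_id: str | None = None,
) -> EwasScreenResult:
    """Per-probe simple regression of one metabolite on methylation.

    For each probe, an unadjusted linear regression of the (standardised)
    metabolite on the probe's (standardised) M-values; the two-sided p-value
    comes from the t statistic of the slope.  Probes with zero variance get
    p = 1 and are never ranked.  Ranking is by ascending p with ties broken
    by descending |slope| then probe id, and the top ``ceil(top_fraction *
    n_probes)`` probes are returned.
    """
    if not (0.0 < top_fraction <= 1.0):
        raise ValidationError(f"top_fraction must be in (0, 1], got {top_fraction}")
    y = metabolite.reindex(m_matrix.index).to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValidationError("metabolite values missing for some samples in the screen")
    X = m_matrix.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 4:
        raise ValidationError("ewas_screen needs at least 4 samples")

    xm = X.mean(axis=0)
    xc = X - xm
    yc = y - y.mean()
    sxx = (xc ** 2).sum(axis=0)
    zero_var = sxx == 0
    sxx_safe = np.where(zero_var, 1.0, sxx)
    slope = (xc * yc[:, None]).sum(axis=0) / sxx_safe
    # residual variance of y on each probe
    syy = (yc ** 2).sum()
    rss = syy - slope ** 2 * sxx_safe
    rss = np.maximum(rss, 0.0)
    dof = n - 2
    se = np.sqrt(rss / dof / sxx_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, slope / se, np.inf * np.sign(slope))
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p = np.where(zero_var, 1.0, p)
    slope = np.where(zero_var, 0.0, slope)
    se = np.where(zero_var, np.nan, se)

    table = pd.DataFrame(
        {"probe_id": m_matrix.columns, "slope": slope, "se": se, "p": p}
    )
    k = math.ceil(top_fraction * m_matrix.shape[1])
    rankable = table[~zero_var].sort_values(
        by=["p", "slope", "probe_id"],
        key=lambda s: -s.abs() if s.name == "slope" else s,
        kind="mergesort",
    )
    top = rankable["probe_id"].head(k).tolist()
    return EwasScreenResult(
        metabolite_id=metabolite_id or str(metabolite.name),
        table=table,
        top_probes=top,
        top_fraction=top_fraction,
    )


# ---------------------------------------------------------------------------
# lasso surrogate


@dataclass
class SurrogateModel:
    metabolite_id: str
    coef: dict[str, float]               # nonzero coefficients only
    intercept: float
    lam: float                           # L1 penalty actually used
    n_cpgs_selected: int
    screened_probes: list[str] = field(default_factory=list)
    cv_lambdas: np.ndarray | None = None
    cv_mse: np.ndarray | None = None     # mean CV error along the path
    seed: int | None = None

    def predict(self, m_matrix: pd.DataFrame) -> pd.Series:
        missing = [p for p in self.coef if p not in m_matrix.columns]
        if missing:
            raise ValidationError(f"matrix lacks surrogate probes: {missing[:5]}")
        pred = np.full(len(m_matrix), self.intercept)
        for probe, w in self.coef.items():
            pred = pred + w * m_matrix[probe].to_numpy(dtype=float)
        return pd.Series(pred, index=m_matrix.index, name=self.metabolite_id)


def train_surrogate(
    metabolite: pd.Series,
    m_matrix: pd.DataFrame,
    screened_probes: list[str] | None = None,
    folds: int = 10,
    seed: int = 0,
    rule: str = "min",
    lam: float | None = None,
) -> SurrogateModel:
    """Lasso fit of one metabolite on its screened probes.

    The penalty is chosen by ``folds``-fold cross-validation: the minimum
    mean squared CV error by default (``rule="min"``), or the largest penalty
    within one standard error of it (``rule="1se"``).  Passing ``lam`` skips
    cross-validation and fits at that fixed penalty.  Coefficients are on the
    scale of the (standardised) inputs.
    """
    probes = list(screened_probes) if screened_probes is not None else list(m_matrix.columns)
    if not probes:
        raise ValidationError("screened probe list is empty")
    X = m_matrix[probes].to_numpy(dtype=float)
    y = metabolite.reindex(m_matrix.index).to_numpy(dtype=float)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValidationError("train_surrogate requires complete inputs")
    n = len(y)
    cv_lambdas = cv_mse = None
    if lam is None:
        if n // folds < 3:
            raise ValidationError(
                f"cross-validation degenerate: {n} samples over {folds} folds leaves folds with < 3 samples"
            )
        cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = LassoCV(cv=cv, alphas=100, max_iter=50000).fit(X, y)
        cv_lambdas = fit.alphas_
        cv_mse = fit.mse_path_.mean(axis=1)
        if rule == "min":
            lam = float(fit.alpha_)
        elif rule == "1se":
            se = fit.mse_path_.std(axis=1, ddof=1) / math.sqrt(folds)
            imin = int(np.argmin(cv_mse))
            ok = cv_mse <= cv_mse[imin] + se[imin]
            lam = float(cv_lambdas[ok].max())
        else:
            raise ValidationError(f"rule must be 'min' or '1se', got {rule!r}")
    if lam < 0:
        raise ValidationError("penalty must be non-negative")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = Lasso(alpha=lam, max_iter=50000).fit(X, y)
    coef = {p: float(w) for p, w in zip(probes, model.coef_) if w != 0.0}
    return SurrogateModel(
        metabolite_id=str(metabolite.name),
        coef=coef,
        intercept=float(model.intercept_),
        lam=float(lam),
        n_cpgs_selected=len(coef),
        screened_probes=probes,
        cv_lambdas=cv_lambdas,
        cv_mse=cv_mse,
        seed=seed,
    )


def predict_surrogate(model: SurrogateModel, m_matrix: pd.DataFrame) -> pd.Series:
    return model.predict(m_matrix)


# ---------------------------------------------------------------------------
# bimodality flag


@dataclass
class BimodalityResult:
    flag: bool
    dip: float
    p: float
    n_modes: int


def _count_modes(values: np.ndarray, rel_height: float = 0.1) -> int:
    """Modes of a Gaussian KDE: local maxima above rel_height of the peak."""
    if np.ptp(values) == 0:
        return 1
    kde = stats.gaussian_kde(values)
    lo, hi = values.min(), values.max()
    pad = 0.1 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, 512)
    dens = kde(grid)
    peaks = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:]) & (dens[1:-1] > rel_height * dens.max())
    return max(int(peaks.sum()), 1)


def bimodality_flag(
    predictions, alpha: float = 0.05, n_boot: int = 1000
) -> BimodalityResult:
    """Flag multimodal surrogate predictions (SNP-confounding signature).

    The flag is raised when Hartigan's dip test rejects unimodality at
    ``alpha`` *and* a kernel-density mode count sees at least two modes — a
    conjunctive, reproducible stand-in for flagging by eye.  Constant
    predictions warn and return an unflagged result.
    """
    x = np.asarray(predictions, dtype=float)
    if x.size < 50:
        raise ValidationError(f"bimodality_flag needs >= 50 predictions, got {x.size}")
    if np.ptp(x) == 0:
        warnings.warn("constant predictions; bimodality flag set to False", stacklevel=2)
        return BimodalityResult(flag=False, dip=0.0, p=1.0, n_modes=1)
    d, p = dip_test(x, n_boot=n_boot)
    modes = _count_modes(x)
    return BimodalityResult(flag=bool(p < alpha and modes >= 2), dip=d, p=p, n_modes=modes)


# ---------------------------------------------------------------------------
# test-set validation


@dataclass
class SurrogateValidation:
    metabolite_id: str
    r: float
    p: float
    p_adjusted: float
    bimodal: bool
    dip: float
    n_test: int
    verdict: str                 # kept | dropped_bimodal | dropped_correlation
    negative_r: bool = False     # kept with r < 0 is allowed but flagged


def validate_surrogates(
    models: list[SurrogateModel],
    m_test: pd.DataFrame,
    metabolites_test: pd.DataFrame,
    bimodality: dict[str, BimodalityResult] | None = None,
    n_tests: int | None = None,
    alpha: float = 0.05,
    train_ids=None,
) -> list[SurrogateValidation]:
    """Pearson-correlation validation of surrogates in the held-out test set.

    Bimodal surrogates are dropped first; the Bonferroni denominator
    ``n_tests`` defaults to the number of surviving (non-bimodal) models.
    A validation is ``kept`` when not bimodal and the adjusted two-sided p
    is below ``alpha``.  Raises :class:`LeakageError` if the test partition
    intersects ``train_ids``.
    """
    if train_ids is not None:
        overlap = pd.Index(train_ids).intersection(m_test.index)
        if len(overlap):
            raise LeakageError(f"test partition overlaps training ids: {list(overlap[:5])}")
    bimodality = bimodality or {}
    n_nonbimodal = sum(
        0 if (bm := bimodality.get(m.metabolite_id)) is not None and bm.flag else 1 for m in models
    )
    denom = n_tests if n_tests is not None else max(n_nonbimodal, 1)
    out = []
    for model in models:
        bm = bimodality.get(model.metabolite_id)
        is_bimodal = bool(bm.flag) if bm is not None else False
        pred = model.predict(m_test)
        obs = metabolites_test[model.metabolite_id].reindex(m_test.index)
        if pred.std() == 0 or obs.std() == 0:
            r, p = 0.0, 1.0
        else:
            r, p = stats.pearsonr(pred.to_numpy(), obs.to_numpy(dtype=float))
        p_adj = min(1.0, float(p) * denom)
        if is_bimodal:
            verdict = "dropped_bimodal"
        elif p_adj < alpha:
            verdict = "kept"
        else:
            verdict = "dropped_correlation"
        out.append(
            SurrogateValidation(
                metabolite_id=model.metabolite_id,
                r=float(r),
                p=float(p),
                p_adjusted=p_adj,
                bimodal=is_bimodal,
                dip=bm.dip if bm is not None else np.nan,
                n_test=len(m_test),
                verdict=verdict,
                negative_r=bool(r < 0 and verdict == "kept"),
            )
        )
    return out


def min_significant_r(n: int, alpha: float = 1e-4, precision: int = 2) -> float:
    """Smallest correlation (at ``precision`` decimals) reaching two-sided
    significance ``alpha`` for sample size ``n``.

    Uses the exact t transform t = r sqrt(n-2) / sqrt(1-r^2) with n-2
    degrees of freedom, scanning the rounded-r grid from below.
    """
    if n < 4:
        raise ValidationError("min_significant_r needs n >= 4")
    dof = n - 2
    step = 10.0 ** (-precision)
    for k in range(1, int(round(1.0 / step))):
        r = k * step
        t = r * math.sqrt(dof) / math.sqrt(1.0 - r * r)
        p = 2.0 * stats.t.sf(t, dof)
        if p < alpha:
            return round(r, precision)
    return 1.0


# ---------------------------------------------------------------------------
# persistence (long coefficient table, one intercept row per metabolite)

_INTERCEPT = "(Intercept)"


def write_surrogates(models: list[SurrogateModel], path, sep: str = "\t") -> None:
    rows = []
    for m in models:
        rows.append({"metabolite_id": m.metabolite_id, "probe_id": _INTERCEPT, "coefficient": m.intercept})
        for probe, w in sorted(m.coef.items()):
            rows.append({"metabolite_id": m.metabolite_id, "probe_id": probe, "coefficient": w})
    pd.DataFrame(rows, columns=["metabolite_id", "probe_id", "coefficient"]).to_csv(path, sep=sep, index=False)


def read_surrogates(path, sep: str = "\t") -> list[SurrogateModel]:
    df = pd.read_csv(path, sep=sep)
    required = {"metabolite_id", "probe_id", "coefficient"}
    if not required.issubset(df.columns):
        raise SchemaError(f"surrogate table must have columns {sorted(required)}")
    models = []
    for met, grp in df.groupby("metabolite_id", sort=False):
        if grp["probe_id"].duplicated().any():
            dup = grp["probe_id"][grp["probe_id"].duplicated()].iloc[0]
            raise SchemaError(f"duplicated probe {dup!r} for metabolite {met!r}")
        inter = grp.loc[grp["probe_id"] == _INTERCEPT, "coefficient"]
        if len(inter) != 1:
            raise SchemaError(f"metabolite {met!r} needs exactly one intercept row")
        coef = {
            r.probe_id: float(r.coefficient)
            for r in grp.itertuples()
            if r.probe_id != _INTERCEPT and r.coefficient != 0.0
        }
        models.append(
            SurrogateModel(
                metabolite_id=str(met),
                coef=coef,
                intercept=float(inter.iloc[0]),
                lam=float("nan"),
                n_cpgs_selected=len(coef),
            )
        )
    return models
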