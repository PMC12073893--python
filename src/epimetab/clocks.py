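"""Ageing clocks: elastic-net age prediction, acceleration, and transfer.

A clock is a sparse linear predictor of chronological age built from one of
three feature spaces: surrogate predictions ("surrogate"), measured
metabolite levels ("metabolite"), or CpG M-values ("cpg").  The elastic-net
mixing weight and penalty are tuned jointly by k-fold cross-validation.

A trained clock carries the training-set median of every feature so it can
be transferred to an external matrix in which some features were lost to
quality control: absent features are filled with the stored training
medians, never recomputed from the target cohort.

Age acceleration is the residual from regressing clock-predicted age on
chronological age, scaled to unit variance within the cohort it is computed
in; positive values mean "older than expected".  By construction it is
orthogonal to chronological age.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

from .errors import SchemaError, ValidationError

__all__ = [
    "ClockModel",
    "AgeAcceleration",
    "PredictionResult",
    "build_clock",
    "predict_age",
    "age_acceleration",
    "write_clock",
    "read_clock",
]

_FORMAT_VERSION = "1"
_INTERCEPT = "(Intercept)"
_FEATURE_SPACES = ("surrogate", "metabolite", "cpg")
DEFAULT_ALPHA_GRID = (0.1, 0.25, 0.5, 0.75, 0.9, 1.0)


@dataclass
class ClockModel:
    feature_space: str
    coef: dict[str, float]            # nonzero coefficients
    intercept: float
    alpha: float                      # L1 mixing weight in [0, 1]
    lam: float                        # penalty strength
    medians: dict[str, float]         # training medians for transfer imputation
    n_train: int
    age_range: tuple[float, float]
    seed: int | None = None
    extra_columns: pd.DataFrame | None = None   # unknown file columns, preserved

    def __post_init__(self) -> None:
        if self.feature_space not in _FEATURE_SPACES:
            raise ValidationError(f"feature_space must be one of {_FEATURE_SPACES}")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValidationError("alpha must be in [0, 1]")
        if self.lam < 0:
            raise ValidationError("lam must be >= 0")
        missing = [f for f in self.coef if f not in self.medians]
        if missing:
            raise ValidationError(f"coefficient features lack training medians: {missing[:5]}")

    @property
    def features(self) -> list[str]:
        return list(self.coef)


@dataclass
class PredictionResult:
    predicted: pd.Series
    fraction_imputed: float
    imputed_features: list[str] = field(default_factory=list)


@dataclass
class AgeAcceleration:
    sample_ids: pd.Index
    predicted: pd.Series
    chronological: pd.Series
    residual: pd.Series          # years
    scaled: pd.Series            # unit variance


def build_clock(
    features: pd.DataFrame,
    age: pd.Series,
    feature_space: str,
    folds: int = 10,
    alpha_grid=DEFAULT_ALPHA_GRID,
    seed: int = 0,
) -> ClockModel:
    """Elastic-net regression of chronological age on a feature matrix.

    (alpha, lambda) are chosen by minimum mean cross-validated squared error
    over ``alpha_grid`` x the automatic penalty path.  The response stays in
    years; features are expected standardised (or at least commensurate).
    """
    if features.isna().any().any():
        raise ValidationError("build_clock requires a complete feature matrix")
    y = age.reindex(features.index).to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValidationError("age missing for some samples")
    n = len(y)
    if n < 50:
        raise ValidationError(f"build_clock needs n >= 50, got {n}")
    if np.ptp(y) == 0:
        raise ValidationError("chronological age is constant; cannot train a clock")
    X = features.to_numpy(dtype=float)
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = ElasticNetCV(
            l1_ratio=list(alpha_grid), cv=cv, alphas=100, max_iter=50000
        ).fit(X, y)
    coef = {f: float(w) for f, w in zip(features.columns, fit.coef_) if w != 0.0}
    medians = {f: float(features[f].median()) for f in features.columns}
    return ClockModel(
        feature_space=feature_space,
        coef=coef,
        intercept=float(fit.intercept_),
        alpha=float(fit.l1_ratio_),
        lam=float(fit.alpha_),
        medians=medians,
        n_train=n,
        age_range=(float(y.min()), float(y.max())),
        seed=seed,
    )


def fit_clock_at(
    features: pd.DataFrame, age: pd.Series, feature_space: str, alpha: float, lam: float
) -> ClockModel:
    """Elastic-net fit at fixed (alpha, lambda); no cross-validation."""
    y = age.reindex(features.index).to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = ElasticNet(alpha=lam, l1_ratio=alpha, max_iter=50000).fit(
            features.to_numpy(dtype=float), y
        )
    coef = {f: float(w) for f, w in zip(features.columns, fit.coef_) if w != 0.0}
    return ClockModel(
        feature_space=feature_space,
        coef=coef,
        intercept=float(fit.intercept_),
        alpha=float(alpha),
        lam=float(lam),
        medians={f: float(features[f].median()) for f in features.columns},
        n_train=len(features),
        age_range=(float(np.min(y)), float(np.max(y))),
    )


def predict_age(
    clock: ClockModel, features: pd.DataFrame, min_present: float = 0.5, warn_below: float = 0.9
) -> PredictionResult:
    """Apply a frozen clock to a (possibly feature-incomplete) matrix.

    Clock features absent from the matrix — or individual missing entries —
    are filled with the clock's stored training medians.  Errors when fewer
    than ``min_present`` of the clock features are present; warns below
    ``warn_below``.
    """
    feats = clock.features
    if not feats:
        return PredictionResult(
            predicted=pd.Series(clock.intercept, index=features.index, name="predicted_age"),
            fraction_imputed=0.0,
        )
    present = [f for f in feats if f in features.columns]
    frac_present = len(present) / len(feats)
    if frac_present < min_present:
        raise ValidationError(
            f"only {frac_present:.0%} of clock features present (< {min_present:.0%}); refusing to predict"
        )
    if frac_present < warn_below:
        warnings.warn(
            f"{1 - frac_present:.1%} of clock features absent; imputing training medians", stacklevel=2
        )
    absent = [f for f in feats if f not in features.columns]
    pred = np.full(len(features), clock.intercept, dtype=float)
    for f in present:
        col = features[f].to_numpy(dtype=float)
        col = np.where(np.isnan(col), clock.medians[f], col)
        pred += clock.coef[f] * col
    for f in absent:
        pred += clock.coef[f] * clock.medians[f]
    if absent and frac_present >= warn_below:
        warnings.warn(f"{len(absent)} clock features imputed at training medians", stacklevel=2)
    return PredictionResult(
        predicted=pd.Series(pred, index=features.index, name="predicted_age"),
        fraction_imputed=1.0 - frac_present,
        imputed_features=absent,
    )


def age_acceleration(predicted: pd.Series, chronological: pd.Series) -> AgeAcceleration:
    """Residuals of clock-predicted age on chronological age, unit-scaled.

    The scaling is cohort-specific: recompute it within every cohort the
    clock is applied to.
    """
    idx = predicted.index
    chron = chronological.reindex(idx)
    y = predicted.to_numpy(dtype=float)
    x = chron.to_numpy(dtype=float)
    if len(y) < 3:
        raise ValidationError("age_acceleration needs at least 3 samples")
    if np.ptp(x) == 0:
        raise ValidationError("chronological age is constant")
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sd = resid.std(ddof=0)
    if sd < 1e-12:
        raise ValidationError(
            "residual variance is zero (prediction is an exact affine function of age); "
            "acceleration is undefined for a perfect fit"
        )
    scaled = (resid - resid.mean()) / sd
    return AgeAcceleration(
        sample_ids=idx,
        predicted=predicted,
        chronological=chron,
        residual=pd.Series(resid, index=idx, name="acceleration_years"),
        scaled=pd.Series(scaled, index=idx, name="acceleration_scaled"),
    )


# ---------------------------------------------------------------------------
# persistence


def write_clock(clock: ClockModel, path, sep: str = "\t") -> None:
    """Clock file: '#'-prefixed header metadata plus a coefficient table.

    Columns (feature_id, coefficient, training_median) with one intercept
    row; any extra columns carried by the model are written back unchanged.
    """
    header = [
        f"# clock_format_version={_FORMAT_VERSION}",
        f"# feature_space={clock.feature_space}",
        f"# alpha={clock.alpha!r}",
        f"# lambda={clock.lam!r}",
        f"# n_train={clock.n_train}",
        f"# age_range={clock.age_range[0]!r},{clock.age_range[1]!r}",
        f"# seed={clock.seed}",
    ]
    rows = [{"feature_id": _INTERCEPT, "coefficient": clock.intercept, "training_median": np.nan}]
    for f in sorted(clock.coef):
        rows.append({"feature_id": f, "coefficient": clock.coef[f], "training_median": clock.medians[f]})
    table = pd.DataFrame(rows)
    if clock.extra_columns is not None:
        table = table.merge(clock.extra_columns, on="feature_id", how="left")
    buf = io.StringIO()
    table.to_csv(buf, sep=sep, index=False, float_format="%.17g")
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n" + buf.getvalue())


def read_clock(path, sep: str = "\t") -> ClockModel:
    meta: dict[str, str] = {}
    body_lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
            else:
                body_lines.append(line)
    if meta.get("clock_format_version") != _FORMAT_VERSION:
        raise SchemaError(
            f"unsupported clock file version {meta.get('clock_format_version')!r} (expected {_FORMAT_VERSION})"
        )
    table = pd.read_csv(io.StringIO("".join(body_lines)), sep=sep)
    required = {"feature_id", "coefficient", "training_median"}
    if not required.issubset(table.columns):
        raise SchemaError(f"clock table must have columns {sorted(required)}")
    if table["feature_id"].duplicated().any():
        dup = table["feature_id"][table["feature_id"].duplicated()].iloc[0]
        raise SchemaError(f"duplicated feature_id {dup!r} in clock file")
    inter = table.loc[table["feature_id"] == _INTERCEPT]
    if len(inter) != 1:
        raise SchemaError("clock file needs exactly one intercept row")
    coef_rows = table.loc[table["feature_id"] != _INTERCEPT]
    no_median = coef_rows["feature_id"][coef_rows["training_median"].isna()]
    if len(no_median):
        raise SchemaError(f"coefficient row(s) without training median: {list(no_median[:5])}")
    extra_cols = [c for c in table.columns if c not in required]
    extra = table[["feature_id"] + extra_cols].copy() if extra_cols else None
    lo, hi = (float(v) for v in meta.get("age_range", "nan,nan").split(","))
    seed_str = meta.get("seed", "None")
    return ClockModel(
        feature_space=meta.get("feature_space", "cpg"),
        coef={r.feature_id: float(r.coefficient) for r in coef_rows.itertuples()},
        intercept=float(inter["coefficient"].iloc[0]),
        alpha=float(meta.get("alpha", "nan")),
        lam=float(meta.get("lambda", "nan")),
        medians={r.feature_id: float(r.training_median) for r in coef_rows.itertuples()},
        n_train=int(meta.get("n_train", "0")),
        age_range=(lo, hi),
        seed=None if seed_str == "None" else int(seed_str),
        extra_columns=extra,
    )
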