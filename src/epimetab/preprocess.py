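"""Quality control and transformation of methylation and metabolite matrices.

Methylation side: probe-level missingness filtering, k-nearest-neighbour
imputation and the beta-to-M logit transform (M = log2(beta/(1-beta))), the
variance-stabilised scale used for differential methylation work.

Metabolite side: exclusion of features with excess missing-or-zero values,
of drug-linked metabolites and of the weaker member of each cross-platform
duplicate pair; participant-level missingness filtering; platform-aware
imputation (left-censored tail draws for NMR, which truncates at its
detection limit; kNN for MS); then natural-log transform and per-feature
standardisation.

Scaling statistics can be fitted on one partition and frozen for application
to another, so that a train/test split never leaks test information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.impute import KNNImputer

from .errors import ValidationError

__all__ = [
    "MethylationMatrix",
    "MetaboliteMatrix",
    "ExclusionReport",
    "Scaler",
    "beta_to_m",
    "m_to_beta",
    "filter_probes",
    "filter_samples",
    "knn_impute",
    "censored_impute",
    "impute_metabolites",
    "metabolite_qc",
    "log_standardize",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class MethylationMatrix:
    """Samples x probes methylation values; NaN marks missing entries.

    ``scale`` is ``"beta"`` (values in (0,1)) or ``"M"`` (finite reals).
    """

    values: pd.DataFrame
    scale: str = "beta"

    def __post_init__(self) -> None:
        if self.scale not in ("beta", "M"):
            raise ValidationError(f"scale must be 'beta' or 'M', got {self.scale!r}")
        if not self.values.columns.is_unique:
            raise ValidationError("probe_ids must be unique")
        if not self.values.index.is_unique:
            raise ValidationError("sample_ids must be unique")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    def validate_values(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        obs = arr[~np.isnan(arr)]
        if self.scale == "beta":
            if obs.size and (obs.min() <= 0.0 or obs.max() >= 1.0):
                raise ValidationError("beta values must lie strictly inside (0, 1)")
        else:
            if obs.size and not np.all(np.isfinite(obs)):
                raise ValidationError("M values must be finite")


@dataclass
class MetaboliteMatrix:
    """Samples x metabolites abundances with per-feature platform labels.

    ``platform`` maps each metabolite to ``"NMR"`` or ``"MS"``.
    ``duplicate_pairs`` links metabolites measured on both platforms.
    ``scale`` progresses raw -> log -> standardized only.
    """

    values: pd.DataFrame
    platform: pd.Series
    drug_linked: pd.Series | None = None
    duplicate_pairs: list[tuple[str, str]] = field(default_factory=list)
    scale: str = "raw"

    _SCALES = ("raw", "log", "standardized")

    def __post_init__(self) -> None:
        if self.scale not in self._SCALES:
            raise ValidationError(f"scale must be one of {self._SCALES}, got {self.scale!r}")
        if not self.values.columns.is_unique:
            raise ValidationError("metabolite ids must be unique")
        self.platform = self.platform.reindex(self.values.columns)
        bad = ~self.platform.isin(["NMR", "MS"])
        if bad.any():
            raise ValidationError(
                f"platform labels must be 'NMR' or 'MS'; offending: {list(self.platform.index[bad])[:5]}"
            )
        if self.drug_linked is None:
            self.drug_linked = pd.Series(False, index=self.values.columns)
        else:
            self.drug_linked = self.drug_linked.reindex(self.values.columns).fillna(False).astype(bool)
        for a, b in self.duplicate_pairs:
            if a in self.platform.index and b in self.platform.index:
                if self.platform[a] == self.platform[b]:
                    raise ValidationError(f"duplicate pair ({a}, {b}) must be cross-platform")

    @property
    def metabolite_ids(self) -> pd.Index:
        return self.values.columns

    def _advance_scale(self, new: str) -> None:
        if self._SCALES.index(new) <= self._SCALES.index(self.scale):
            raise ValidationError(f"scale may only advance raw->log->standardized, not {self.scale}->{new}")


@dataclass
class ExclusionReport:
    """Tidy record of removed features: (feature_id, reason, statistic)."""

    table: pd.DataFrame
    n_input: int

    @property
    def n_excluded(self) -> int:
        return len(self.table)

    @property
    def pct_excluded(self) -> float:
        return 100.0 * self.n_excluded / self.n_input

    @property
    def pct_retained(self) -> float:
        return 100.0 - self.pct_excluded

    @classmethod
    def build(cls, rows: list[tuple[str, str, float]], n_input: int) -> "ExclusionReport":
        table = pd.DataFrame(rows, columns=["feature_id", "reason", "statistic"])
        return cls(table=table, n_input=n_input)


# ---------------------------------------------------------------------------
# methylation operations


def beta_to_m(
    matrix: MethylationMatrix,
    on_boundary: str = "clamp",
    eps: float = 1e-6,
    standardize: bool = False,
    scaler: "Scaler | None" = None,
) -> MethylationMatrix | tuple[MethylationMatrix, "Scaler"]:
    """Transform beta values to M-values: M = log2(beta / (1 - beta)).

    Missing entries stay missing.  Values at exactly 0 or 1 have no finite M;
    ``on_boundary="clamp"`` clips them into [eps, 1-eps] with a warning and
    ``"error"`` raises.  With ``standardize=True`` each probe column is
    mean-centred and unit-scaled afterwards and the fitted :class:`Scaler` is
    returned alongside (or ``scaler`` is applied if given, for frozen
    train-set statistics).
    """
    if matrix.scale != "beta":
        raise ValidationError("beta_to_m requires a beta-scale matrix")
    vals = matrix.values.to_numpy(dtype=float, copy=True)
    boundary = (vals <= 0.0) | (vals >= 1.0)
    boundary &= ~np.isnan(vals)
    if boundary.any():
        if on_boundary == "error":
            raise ValidationError("beta values at 0 or 1 encountered (on_boundary='error')")
        if on_boundary != "clamp":
            raise ValidationError(f"on_boundary must be 'clamp' or 'error', got {on_boundary!r}")
        warnings.warn(
            f"{int(boundary.sum())} beta values at the (0,1) boundary clamped to [{eps}, {1 - eps}]",
            stacklevel=2,
        )
        vals = np.clip(vals, eps, 1.0 - eps)
    m = np.log2(vals / (1.0 - vals))
    out = MethylationMatrix(pd.DataFrame(m, index=matrix.values.index, columns=matrix.values.columns), scale="M")
    if scaler is not None:
        return scaler.transform_matrix(out), scaler
    if standardize:
        sc = Scaler.fit(out.values)
        return sc.transform_matrix(out), sc
    return out


def m_to_beta(matrix: MethylationMatrix) -> MethylationMatrix:
    """Inverse of :func:`beta_to_m` (unstandardised M-values only)."""
    if matrix.scale != "M":
        raise ValidationError("m_to_beta requires an M-scale matrix")
    m = matrix.values.to_numpy(dtype=float)
    beta = 1.0 / (1.0 + np.power(2.0, -m))
    return MethylationMatrix(
        pd.DataFrame(beta, index=matrix.values.index, columns=matrix.values.columns), scale="beta"
    )


def filter_probes(
    matrix: MethylationMatrix, max_missing_rate: float = 0.01
) -> tuple[MethylationMatrix, ExclusionReport]:
    """Drop probes whose missing fraction is strictly greater than the cutoff.

    The default removes probes with > 1% missing entries.  The report lists
    each excluded probe with its missing rate; its ``pct_excluded`` gives the
    headline exclusion percentage.
    """
    if matrix.values.shape[1] == 0 or matrix.values.shape[0] == 0:
        raise ValidationError("filter_probes: empty matrix")
    miss = matrix.values.isna().mean(axis=0)
    drop = miss.index[miss > max_missing_rate]
    rows = [(p, "missing_rate", float(miss[p])) for p in drop]
    report = ExclusionReport.build(rows, n_input=matrix.values.shape[1])
    kept = replace(matrix, values=matrix.values.drop(columns=drop))
    return kept, report


def filter_samples(
    matrix: MetaboliteMatrix, max_missing_rate: float = 0.05
) -> tuple[MetaboliteMatrix, ExclusionReport]:
    """Drop samples with a missing-metabolite fraction strictly above cutoff."""
    miss = matrix.values.isna().mean(axis=1)
    drop = miss.index[miss > max_missing_rate]
    rows = [(s, "sample_missing_rate", float(miss[s])) for s in drop]
    report = ExclusionReport.build(rows, n_input=matrix.values.shape[0])
    return replace(matrix, values=matrix.values.drop(index=drop)), report


def _knn_impute_frame(values: pd.DataFrame, k: int, axis: str) -> pd.DataFrame:
    fully_missing = values.isna().all(axis=0)
    if fully_missing.any():
        raise ValidationError(
            f"features with no observed values cannot be imputed; run the missingness filter first: "
            f"{list(values.columns[fully_missing])[:5]}"
        )
    if not values.isna().any().any():
        return values.copy()
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    if axis == "features":
        # neighbours are features (probes/metabolites), matching the
        # convention of expression-array kNN imputation
        arr = imputer.fit_transform(values.to_numpy(dtype=float).T).T
    elif axis == "samples":
        arr = imputer.fit_transform(values.to_numpy(dtype=float))
    else:
        raise ValidationError(f"axis must be 'features' or 'samples', got {axis!r}")
    return pd.DataFrame(arr, index=values.index, columns=values.columns)


def knn_impute(matrix, k: int = 10, axis: str = "features"):
    """k-nearest-neighbour imputation; observed values are untouched.

    Accepts a :class:`MethylationMatrix` or :class:`MetaboliteMatrix` (or a
    bare DataFrame) and returns the same type, complete.  Neighbours are
    found among features by default (Euclidean distance over co-observed
    entries, averaged over the k nearest), mirroring expression-style
    imputation; set ``axis="samples"`` for the transposed convention.
    """
    if isinstance(matrix, MethylationMatrix):
        return replace(matrix, values=_knn_impute_frame(matrix.values, k, axis))
    if isinstance(matrix, MetaboliteMatrix):
        return replace(matrix, values=_knn_impute_frame(matrix.values, k, axis))
    return _knn_impute_frame(matrix, k, axis)


# ---------------------------------------------------------------------------
# metabolite operations


def _qrilc_feature(col: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Impute left-censored NaNs of one feature from a truncated-normal tail.

    The uncensored distribution is assumed normal (apply after log transform
    for lognormal abundances); its mean and SD are recovered by regressing the
    observed order statistics on their theoretical normal quantiles, accounting
    for the fact that the missing values occupy the lowest ranks.  Draws are
    taken below the observed minimum (the empirical detection limit).
    """
    out = col.copy()
    missing = np.isnan(col)
    n_mis = int(missing.sum())
    if n_mis == 0:
        return out
    obs = col[~missing]
    n = col.size
    if obs.size < 10:
        warnings.warn(
            f"feature has only {obs.size} observed values; falling back to half-minimum substitution",
            stacklevel=3,
        )
        out[missing] = obs.min() / 2.0 if obs.min() > 0 else obs.min() - abs(obs.min()) * 0.5 - 1e-12
        return out
    order = np.sort(obs)
    # overall plotting positions: censored values occupy ranks 1..n_mis
    pp = (n_mis + np.arange(1, obs.size + 1) - 0.5) / n
    z = stats.norm.ppf(pp)
    slope, intercept = np.polyfit(z, order, 1)
    mu, sigma = intercept, max(slope, 1e-12)
    limit = order[0]
    # inverse-CDF draws restricted to the tail below the detection limit
    p_lim = stats.norm.cdf((limit - mu) / sigma)
    p_lim = max(p_lim, 1e-12)
    u = rng.random(n_mis) * p_lim
    out[missing] = mu + sigma * stats.norm.ppf(u)
    return out


def censored_impute(matrix: MetaboliteMatrix, seed: int = 0, log_first: bool = True) -> MetaboliteMatrix:
    """Left-censored imputation for NMR-labelled metabolites (QRILC-style).

    Missing NMR entries are treated as below-detection-limit censoring and
    drawn from the fitted low tail of each feature, strictly below the
    feature's observed minimum.  MS-labelled columns are left untouched (use
    :func:`knn_impute` for those).  Deterministic given ``seed``.

    ``log_first`` fits the tail model on the log scale (appropriate for raw,
    strictly positive abundances) and back-transforms the draws.
    """
    rng = np.random.default_rng(seed)
    vals = matrix.values.copy()
    for name in vals.columns:
        if matrix.platform[name] != "NMR":
            continue
        col = vals[name].to_numpy(dtype=float)
        if not np.isnan(col).any():
            continue
        obs = col[~np.isnan(col)]
        if obs.size < 10:
            # too few points to fit a tail model; half-minimum on the raw scale
            warnings.warn(
                f"feature {name!r} has only {obs.size} observed values; "
                "falling back to half-minimum substitution",
                stacklevel=2,
            )
            col[np.isnan(col)] = obs.min() / 2.0
            vals[name] = col
            continue
        if log_first and matrix.scale == "raw":
            obs = col[~np.isnan(col)]
            if np.any(obs <= 0):
                raise ValidationError(f"censored_impute: non-positive raw values in {name!r}")
            filled = _qrilc_feature(np.log(col), rng)
            vals[name] = np.exp(filled)
        else:
            vals[name] = _qrilc_feature(col, rng)
    return replace(matrix, values=vals)


def impute_metabolites(matrix: MetaboliteMatrix, k: int = 10, seed: int = 0) -> MetaboliteMatrix:
    """Platform-aware imputation: censored tail draws for NMR, kNN for MS."""
    out = censored_impute(matrix, seed=seed)
    ms_cols = out.metabolite_ids[out.platform == "MS"]
    if len(ms_cols) and out.values[ms_cols].isna().any().any():
        imputed_ms = _knn_impute_frame(out.values[ms_cols], k, axis="features")
        vals = out.values.copy()
        vals[ms_cols] = imputed_ms
        out = replace(out, values=vals)
    return out


def _age_association_p(col: pd.Series, age: pd.Series, sex: pd.Series) -> float:
    """Two-sided p of the age slope in a sex-adjusted linear model."""
    df = pd.DataFrame({"y": col, "age": age, "sex": sex}).dropna()
    n = len(df)
    if n < 4:
        return 1.0
    X = np.column_stack([np.ones(n), df["age"], df["sex"]])
    y = df["y"].to_numpy(dtype=float)
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = n - rank
    if dof <= 0:
        return 1.0
    sigma2 = resid @ resid / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    if se == 0:
        return 0.0
    t = coef[1] / se
    return float(2.0 * stats.t.sf(abs(t), dof))


def metabolite_qc(
    matrix: MetaboliteMatrix,
    age: pd.Series,
    sex: pd.Series,
    max_missing_or_zero: float = 0.20,
    drug_list: tuple[str, ...] = (),
) -> tuple[MetaboliteMatrix, ExclusionReport]:
    """Metabolite-level exclusions, applied in order:

    1. metabolites whose missing-or-zero fraction is strictly above
       ``max_missing_or_zero`` (default 20%);
    2. drug-linked metabolites (named in ``drug_list`` or flagged in the
       matrix), which would confound lifestyle associations of the clocks;
    3. for each cross-platform duplicate pair, the member with the weaker
       (larger p) sex-adjusted age association.

    Unknown ``drug_list`` names warn rather than error.  Idempotent.
    """
    vals = matrix.values
    rows: list[tuple[str, str, float]] = []
    dropped: set[str] = set()

    frac_bad = ((vals.isna()) | (vals == 0)).mean(axis=0)
    for name in vals.columns:
        if frac_bad[name] > max_missing_or_zero:
            rows.append((name, "missing_or_zero", float(frac_bad[name])))
            dropped.add(name)

    drug_flagged = set(matrix.metabolite_ids[matrix.drug_linked])
    for name in drug_list:
        if name not in vals.columns:
            warnings.warn(f"drug_list name {name!r} not found among metabolites", stacklevel=2)
        else:
            drug_flagged.add(name)
    for name in sorted(drug_flagged):
        if name not in dropped:
            rows.append((name, "drug_linked", np.nan))
            dropped.add(name)

    for a, b in matrix.duplicate_pairs:
        if a in dropped or b in dropped or a not in vals.columns or b not in vals.columns:
            continue
        pa = _age_association_p(vals[a], age, sex)
        pb = _age_association_p(vals[b], age, sex)
        loser, p = (a, pa) if pa > pb else (b, pb)
        rows.append((loser, "duplicate_weaker_age_association", float(p)))
        dropped.add(loser)

    report = ExclusionReport.build(rows, n_input=vals.shape[1])
    kept_pairs = [(a, b) for a, b in matrix.duplicate_pairs if a not in dropped and b not in dropped]
    kept = replace(
        matrix,
        values=vals.drop(columns=sorted(dropped)),
        platform=matrix.platform.drop(index=sorted(dropped)),
        drug_linked=matrix.drug_linked.drop(index=sorted(dropped)),
        duplicate_pairs=kept_pairs,
    )
    return kept, report


# ---------------------------------------------------------------------------
# scaling


@dataclass(frozen=True)
class Scaler:
    """Frozen per-feature centring/scaling statistics.

    Fit on the training partition and reuse on any other partition so that
    standardisation never sees test data.
    """

    means: pd.Series
    sds: pd.Series

    @classmethod
    def fit(cls, values: pd.DataFrame) -> "Scaler":
        means = values.mean(axis=0)
        sds = values.std(axis=0, ddof=0)
        zero = sds[sds == 0]
        if len(zero):
            raise ValidationError(f"zero-variance feature(s): {list(zero.index)[:5]}")
        return cls(means=means, sds=sds)

    def transform(self, values: pd.DataFrame) -> pd.DataFrame:
        return (values - self.means[values.columns]) / self.sds[values.columns]

    def transform_matrix(self, matrix: MethylationMatrix) -> MethylationMatrix:
        return replace(matrix, values=self.transform(matrix.values))


def log_standardize(
    matrix: MetaboliteMatrix, scaler: Scaler | None = None
) -> tuple[MetaboliteMatrix, Scaler]:
    """Natural-log transform then per-feature standardisation to mean 0, SD 1.

    Requires strictly positive, complete, raw-scale values.  Pass a fitted
    ``scaler`` to apply frozen training-partition statistics to the log
    values instead of refitting.
    """
    matrix._advance_scale("standardized")
    if matrix.scale != "raw":
        raise ValidationError("log_standardize expects raw-scale values")
    vals = matrix.values
    if vals.isna().any().any():
        raise ValidationError("log_standardize requires a complete matrix (impute first)")
    nonpos = (vals <= 0).any(axis=0)
    if nonpos.any():
        raise ValidationError(f"non-positive values in feature(s): {list(vals.columns[nonpos])[:5]}")
    logged = np.log(vals)
    if scaler is None:
        scaler = Scaler.fit(logged)
    std = scaler.transform(logged)
    return replace(matrix, values=std, scale="standardized"), scaler
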