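"""QC and transform operations: logit transform, filters, imputation, scaling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epimetab.errors import ValidationError
from epimetab.preprocess import (
    MethylationMatrix,
    MetaboliteMatrix,
    Scaler,
    beta_to_m,
    censored_impute,
    filter_probes,
    filter_samples,
    knn_impute,
    log_standardize,
    m_to_beta,
    metabolite_qc,
)


def _meth(arr, probes=None, samples=None, scale="beta"):
    arr = np.asarray(arr, dtype=float)
    probes = probes or [f"cg{j:03d}" for j in range(arr.shape[1])]
    samples = samples or [f"S{i:03d}" for i in range(arr.shape[0])]
    return MethylationMatrix(pd.DataFrame(arr, index=samples, columns=probes), scale=scale)


def _metab(arr, platform=None, **kw):
    arr = np.asarray(arr, dtype=float)
    cols = kw.pop("cols", [f"met{j:03d}" for j in range(arr.shape[1])])
    samples = [f"S{i:03d}" for i in range(arr.shape[0])]
    platform = platform or ["NMR" if j % 2 == 0 else "MS" for j in range(arr.shape[1])]
    return MetaboliteMatrix(
        values=pd.DataFrame(arr, index=samples, columns=cols),
        platform=pd.Series(platform, index=cols),
        **kw,
    )


# ---------------------------------------------------------------------------
# beta <-> M


@pytest.mark.parametrize("beta,m", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)])
def test_beta_to_m_exact_values(beta, m):
    out = beta_to_m(_meth([[beta]]))
    assert out.scale == "M"
    assert out.values.iloc[0, 0] == pytest.approx(m, abs=1e-12)


def test_beta_to_m_antisymmetry():
    b = np.array([[0.1, 0.3, 0.47]])
    m1 = beta_to_m(_meth(b)).values.to_numpy()
    m2 = beta_to_m(_meth(1 - b)).values.to_numpy()
    np.testing.assert_allclose(m1, -m2, atol=1e-12)


@given(
    st.lists(st.floats(min_value=1e-6, max_value=1 - 1e-6), min_size=1, max_size=30)
)
@settings(max_examples=50, deadline=None)
def test_beta_m_round_trip_and_monotone(betas):
    mat = _meth([betas])
    m = beta_to_m(mat)
    back = m_to_beta(m)
    np.testing.assert_allclose(back.values.to_numpy(), mat.values.to_numpy(), atol=1e-12)
    order = np.argsort(betas)
    m_sorted = m.values.to_numpy()[0][order]
    assert np.all(np.diff(m_sorted) >= 0)


def test_beta_to_m_missing_stays_missing():
    out = beta_to_m(_meth([[0.5, np.nan], [0.25, 0.75]]))
    assert np.isnan(out.values.iloc[0, 1])
    assert out.values.notna().sum().sum() == 3


def test_beta_to_m_boundary_clamp_and_error():
    with pytest.warns(UserWarning, match="clamp"):
        out = beta_to_m(_meth([[0.0, 1.0]]), eps=1e-6)
    assert np.isfinite(out.values.to_numpy()).all()
    with pytest.raises(ValidationError):
        beta_to_m(_meth([[0.0]]), on_boundary="error")


def test_beta_to_m_standardize_freezes_train_statistics():
    rng = np.random.default_rng(0)
    train = _meth(rng.uniform(0.2, 0.8, (50, 4)))
    test = _meth(rng.uniform(0.2, 0.8, (20, 4)))
    m_train, scaler = beta_to_m(train, standardize=True)
    assert np.allclose(m_train.values.mean(), 0, atol=1e-10)
    assert np.allclose(m_train.values.std(ddof=0), 1, atol=1e-10)
    m_test, _ = beta_to_m(test, scaler=scaler)
    # test columns are scaled by train statistics, so not exactly standard
    assert not np.allclose(m_test.values.mean(), 0, atol=1e-3)


# ---------------------------------------------------------------------------
# probe / sample filters


def test_filter_probes_strict_threshold():
    arr = np.full((200, 3), 0.5)
    arr[:0, 0] = np.nan          # probe 0: 0%
    arr[:4, 1] = np.nan          # probe 1: 2%
    arr[:1, 2] = np.nan          # probe 2: 0.5%
    kept, report = filter_probes(_meth(arr), max_missing_rate=0.01)
    assert list(kept.probe_ids) == ["cg000", "cg002"]
    assert report.n_excluded == 1
    assert report.table.iloc[0]["feature_id"] == "cg001"


def test_filter_probes_headline_percentage():
    """127,344 of 834,012 probes above the 1% missingness cutoff reports a
    15.3% exclusion rate."""
    n_probes, n_bad = 834_012, 127_344
    arr = np.full((3, n_probes), 0.5, dtype=np.float32)
    arr[0, :n_bad] = np.nan  # 1/3 missing > 1%
    mat = MethylationMatrix(
        pd.DataFrame(arr, index=["a", "b", "c"], columns=[f"cg{j:07d}" for j in range(n_probes)])
    )
    kept, report = filter_probes(mat, max_missing_rate=0.01)
    assert report.n_excluded == n_bad
    assert round(report.pct_excluded, 1) == 15.3
    assert kept.values.shape[1] == n_probes - n_bad


def test_filter_probes_complete_matrix_unchanged():
    mat = _meth(np.full((5, 4), 0.4))
    kept, report = filter_probes(mat)
    assert report.n_excluded == 0
    pd.testing.assert_frame_equal(kept.values, mat.values)


def test_filter_probes_empty_errors():
    with pytest.raises(ValidationError):
        filter_probes(_meth(np.empty((0, 0))))


def test_filter_samples_threshold():
    arr = np.ones((4, 20))
    arr[0, :3] = np.nan   # 15% missing -> dropped at 5%
    arr[1, :1] = np.nan   # 5% -> kept (strict >)
    kept, report = filter_samples(_metab(arr), max_missing_rate=0.05)
    assert report.n_excluded == 1
    assert "S000" not in kept.values.index


# ---------------------------------------------------------------------------
# kNN imputation


def test_knn_no_missing_is_identity(cohort):
    sub = MethylationMatrix(cohort.methylation.values.iloc[:, :20].dropna(axis=0))
    out = knn_impute(sub, k=5)
    pd.testing.assert_frame_equal(out.values, sub.values)


def test_knn_duplicate_neighbour_exact():
    # one missing cell; an exact-duplicate sample row at k=1 donates its value
    base = np.array([[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0], [9.0, 8.0, 7.0, 6.0]])
    arr = base.copy()
    arr[0, 2] = np.nan
    out = knn_impute(pd.DataFrame(arr), k=1, axis="samples")
    assert out.iloc[0, 2] == pytest.approx(3.0)


def test_knn_fully_missing_feature_errors():
    arr = np.ones((5, 3))
    arr[:, 1] = np.nan
    with pytest.raises(ValidationError, match="filter"):
        knn_impute(pd.DataFrame(arr), k=2)


def test_knn_mcar_rmse_below_feature_sd():
    """Planted 1% MCAR missingness on strongly correlated probes (shared age
    signal, low probe noise): imputation error is under the per-feature SD."""
    from epimetab.simdata import SimConfig, generate_cohort

    cfg = SimConfig(n_samples=150, n_probes=80, n_age_probes=80, age_effect_sd=0.05,
                    probe_noise_sd=0.05, n_metabolites=2, cpgs_per_metabolite=2,
                    n_snp_probes=0, seed=17)
    truth_vals = generate_cohort(cfg).methylation.values
    rng = np.random.default_rng(1)
    arr = truth_vals.to_numpy().copy()
    mask = rng.random(arr.shape) < 0.01
    arr[mask] = np.nan
    out = knn_impute(pd.DataFrame(arr, index=truth_vals.index, columns=truth_vals.columns), k=10)
    err = out.to_numpy()[mask] - truth_vals.to_numpy()[mask]
    rmse = np.sqrt((err**2).mean())
    pooled_sd = truth_vals.to_numpy().std(axis=0).mean()
    assert rmse < pooled_sd


# ---------------------------------------------------------------------------
# left-censored imputation


def test_censored_impute_no_missing_unchanged():
    rng = np.random.default_rng(0)
    mat = _metab(np.exp(rng.normal(size=(60, 2))), platform=["NMR", "NMR"])
    out = censored_impute(mat, seed=1)
    pd.testing.assert_frame_equal(out.values, mat.values)


def test_censored_impute_draws_below_detection_limit():
    """A standard-normal feature censored at its 10th percentile is refilled
    from the low tail: all draws below the observed minimum, and the imputed
    mean within half an SD of it."""
    rng = np.random.default_rng(2)
    x = rng.normal(size=400)
    cut = np.quantile(x, 0.10)
    col = np.where(x < cut, np.nan, x)
    mat = _metab(col[:, None], platform=["NMR"])
    out = censored_impute(mat, seed=3, log_first=False)
    imputed = out.values.to_numpy()[np.isnan(col), 0]
    obs_min = np.nanmin(col)
    assert (imputed < obs_min).mean() >= 0.95
    assert imputed.mean() < obs_min + 0.5 * np.nanstd(col)


def test_censored_impute_seeded_determinism():
    rng = np.random.default_rng(4)
    x = np.exp(rng.normal(size=100))
    x[x < np.quantile(x, 0.15)] = np.nan
    mat = _metab(x[:, None], platform=["NMR"])
    a = censored_impute(mat, seed=5)
    b = censored_impute(mat, seed=5)
    pd.testing.assert_frame_equal(a.values, b.values)
    c = censored_impute(mat, seed=6)
    assert not a.values.equals(c.values)


def test_censored_impute_few_observed_half_minimum():
    col = np.array([np.nan] * 6 + [2.0, 4.0, 8.0, 16.0])
    mat = _metab(col[:, None], platform=["NMR"])
    with pytest.warns(UserWarning, match="half-minimum"):
        out = censored_impute(mat, seed=0)
    assert np.allclose(out.values.iloc[:6, 0], 1.0)


# ---------------------------------------------------------------------------
# metabolite QC


def _qc_fixture():
    """634 metabolites: 22 high-missing, 8 drug-linked, 10 cross-platform
    duplicate pairs -> 594 retained."""
    rng = np.random.default_rng(8)
    n = 80
    total = 634
    age = pd.Series(rng.uniform(20, 65, n), index=[f"S{i:03d}" for i in range(n)])
    sex = pd.Series(rng.integers(0, 2, n), index=age.index)
    cols, data, platform = [], [], []
    drug = []
    # 10 duplicate pairs: member A tracks age, member B is noise
    pairs = []
    for j in range(10):
        a, b = f"dupA{j:02d}", f"dupB{j:02d}"
        pairs.append((a, b))
        cols += [a, b]
        platform += ["NMR", "MS"]
        data.append(np.exp(0.05 * age.to_numpy() + rng.normal(0, 0.1, n)))
        data.append(np.exp(rng.normal(0, 1, n)))
    # 22 with >20% zeros
    for j in range(22):
        cols.append(f"bad{j:02d}")
        platform.append("MS")
        col = np.exp(rng.normal(0, 1, n))
        col[: int(0.3 * n)] = 0.0
        data.append(col)
    # 8 drug-linked
    for j in range(8):
        name = f"drug{j}"
        cols.append(name)
        drug.append(name)
        platform.append("MS")
        data.append(np.exp(rng.normal(0, 1, n)))
    while len(cols) < total:
        cols.append(f"met{len(cols):04d}")
        platform.append("NMR" if len(cols) % 2 else "MS")
        data.append(np.exp(rng.normal(0, 1, n)))
    mat = MetaboliteMatrix(
        values=pd.DataFrame(np.column_stack(data), index=age.index, columns=cols),
        platform=pd.Series(platform, index=cols),
        duplicate_pairs=pairs,
    )
    return mat, age, sex, tuple(drug)


def test_metabolite_qc_headline_counts():
    mat, age, sex, drug = _qc_fixture()
    kept, report = metabolite_qc(mat, age, sex, drug_list=drug)
    assert report.n_input == 634
    assert report.n_excluded == 40
    assert kept.values.shape[1] == 594
    assert round(report.pct_retained, 1) == 93.7
    reasons = report.table["reason"].value_counts()
    assert reasons["missing_or_zero"] == 22
    assert reasons["drug_linked"] == 8
    assert reasons["duplicate_weaker_age_association"] == 10
    # the weaker (noise) member of each pair loses
    losers = set(report.table.loc[report.table["reason"].str.startswith("dup"), "feature_id"])
    assert losers == {f"dupB{j:02d}" for j in range(10)}


def test_metabolite_qc_idempotent():
    mat, age, sex, drug = _qc_fixture()
    once, _ = metabolite_qc(mat, age, sex, drug_list=drug)
    twice, rep2 = metabolite_qc(once, age, sex, drug_list=())
    assert rep2.n_excluded == 0
    pd.testing.assert_frame_equal(once.values, twice.values)


def test_metabolite_qc_unknown_drug_warns():
    mat, age, sex, _ = _qc_fixture()
    with pytest.warns(UserWarning, match="not found"):
        metabolite_qc(mat, age, sex, drug_list=("nonexistent_compound",))


def test_metabolite_qc_no_failures_identity():
    rng = np.random.default_rng(3)
    mat = _metab(np.exp(rng.normal(size=(40, 6))))
    age = pd.Series(rng.uniform(20, 60, 40), index=mat.values.index)
    sex = pd.Series(rng.integers(0, 2, 40), index=mat.values.index)
    kept, report = metabolite_qc(mat, age, sex)
    assert report.n_excluded == 0
    pd.testing.assert_frame_equal(kept.values, mat.values)


# ---------------------------------------------------------------------------
# log-standardise


def test_log_standardize_moments_and_skew():
    rng = np.random.default_rng(5)
    mat = _metab(np.exp(rng.normal(size=(10_000, 2))))
    out, _ = log_standardize(mat)
    assert out.scale == "standardized"
    np.testing.assert_allclose(out.values.mean(), 0.0, atol=1e-10)
    np.testing.assert_allclose(out.values.std(ddof=0), 1.0, atol=1e-10)
    from scipy.stats import skew

    assert np.all(np.abs(skew(out.values, axis=0)) < 0.1)


def test_log_standardize_rejects_nonpositive_and_constant():
    mat = _metab(np.array([[1.0, -1.0], [2.0, 3.0]]))
    with pytest.raises(ValidationError, match="non-positive"):
        log_standardize(mat)
    const = _metab(np.array([[2.0], [2.0], [2.0]]))
    with pytest.raises(ValidationError, match="zero-variance"):
        log_standardize(const)


def test_log_standardize_frozen_scaler():
    rng = np.random.default_rng(6)
    train = _metab(np.exp(rng.normal(size=(50, 3))))
    test = _metab(np.exp(rng.normal(0.5, 1, size=(30, 3))))
    _, scaler = log_standardize(train)
    out, _ = log_standardize(test, scaler=scaler)
    # shifted test distribution keeps its offset under frozen train statistics
    assert out.values.mean().mean() > 0.2


def test_scaler_rejects_zero_variance():
    with pytest.raises(ValidationError):
        Scaler.fit(pd.DataFrame({"a": [1.0, 1.0, 1.0]}))
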