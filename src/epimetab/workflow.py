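"""In-memory convenience workflow over the module API.

Mirrors the file-based pipeline stages for interactive and programmatic use:
prepare a cohort bundle (QC, imputation, transforms, train/test split with
train-frozen scaling), train one surrogate per metabolite, and filter them.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import preprocess, surrogates
from .simdata import CohortBundle

__all__ = ["PreparedCohort", "prepare_cohort", "build_surrogates", "filter_surrogates"]


@dataclass
class PreparedCohort:
    m_std: pd.DataFrame            # standardised M-values, all samples
    met_std: pd.DataFrame          # standardised log metabolites, QC-passed samples
    train_ids: pd.Index
    test_ids: pd.Index
    phenotypes: pd.DataFrame

    @property
    def met_train_ids(self) -> pd.Index:
        return self.met_std.index.intersection(self.train_ids)

    @property
    def met_test_ids(self) -> pd.Index:
        return self.met_std.index.intersection(self.test_ids)


def prepare_cohort(
    bundle: CohortBundle,
    train_fraction: float = 0.8,
    seed: int = 0,
    max_probe_missing_rate: float = 0.01,
    max_metabolite_missing_or_zero: float = 0.20,
    max_sample_missing_rate: float = 0.05,
    knn_k: int = 10,
    drug_list: tuple[str, ...] = (),
) -> PreparedCohort:
    """QC and transform a cohort bundle; scaling statistics come from the
    training partition only."""
    train_ids, test_ids = surrogates.split_cohort(
        bundle.methylation.sample_ids, train_fraction, seed
    )
    meth, _ = preprocess.filter_probes(bundle.methylation, max_probe_missing_rate)
    if meth.values.isna().any().any():
        meth = preprocess.knn_impute(meth, k=knn_k)
    m_mat = preprocess.beta_to_m(meth)
    scaler = preprocess.Scaler.fit(m_mat.values.loc[train_ids])
    m_std = scaler.transform(m_mat.values)

    met, _ = preprocess.metabolite_qc(
        bundle.metabolites,
        bundle.phenotypes["age"],
        bundle.phenotypes["sex"],
        max_metabolite_missing_or_zero,
        drug_list,
    )
    met, _ = preprocess.filter_samples(met, max_sample_missing_rate)
    met = preprocess.impute_metabolites(met, k=knn_k, seed=seed)
    met_train = met.values.index.intersection(train_ids)
    train_matrix = preprocess.MetaboliteMatrix(
        values=met.values.loc[met_train],
        platform=met.platform,
        drug_linked=met.drug_linked,
        duplicate_pairs=met.duplicate_pairs,
    )
    _, met_scaler = preprocess.log_standardize(train_matrix)
    met_std, _ = preprocess.log_standardize(met, scaler=met_scaler)
    return PreparedCohort(
        m_std=m_std,
        met_std=met_std.values,
        train_ids=train_ids,
        test_ids=test_ids,
        phenotypes=bundle.phenotypes,
    )


def build_surrogates(
    prepared: PreparedCohort,
    top_fraction: float = 0.01,
    folds: int = 10,
    seed: int = 0,
    rule: str = "min",
) -> list[surrogates.SurrogateModel]:
    """EWAS screen + cross-validated lasso, one surrogate per metabolite."""
    train = prepared.met_train_ids
    models = []
    for j, met_id in enumerate(prepared.met_std.columns):
        y = prepared.met_std[met_id].loc[train]
        screen = surrogates.ewas_screen(
            y, prepared.m_std.loc[train], top_fraction, metabolite_id=met_id
        )
        models.append(
            surrogates.train_surrogate(
                y, prepared.m_std.loc[train], screen.top_probes,
                folds=folds, seed=seed + j, rule=rule,
            )
        )
    return models


def filter_surrogates(
    models: list[surrogates.SurrogateModel],
    prepared: PreparedCohort,
    alpha: float = 0.05,
    n_boot: int = 1000,
):
    """Bimodality flags (full-cohort predictions) then test-set validation.

    Returns ``(validations, kept_models)``.
    """
    bimod = {
        m.metabolite_id: surrogates.bimodality_flag(
            m.predict(prepared.m_std), alpha=alpha, n_boot=n_boot
        )
        for m in models
    }
    test = prepared.met_test_ids
    validations = surrogates.validate_surrogates(
        models,
        prepared.m_std.loc[test],
        prepared.met_std.loc[test],
        bimodality=bimod,
        alpha=alpha,
        train_ids=prepared.train_ids,
    )
    kept = [m for m, v in zip(models, validations) if v.verdict == "kept"]
    return validations, kept
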