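"""Stage orchestration: simulate -> preprocess -> surrogates -> clock -> associations.

Each stage reads delimited-text artifacts from the run directory, writes its
outputs there, and records a manifest (parameters, forked seed, SHA-256 of
every input and output).  Before running, a stage verifies that its inputs
still hash to what the producing stage recorded, refusing to run on tampered
or stale intermediates unless forced.  Re-running a stage with the same
configuration and seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, clocks, preprocess, simdata, surrogates
from .config import RunConfig
from .errors import StaleInputError, ValidationError

__all__ = ["STAGES", "run_stage", "run_all", "stage_seed"]

log = logging.getLogger("epimetab")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministically fork a per-stage seed from the master seed."""
    idx = list(STAGES).index(stage)
    ss = np.random.SeedSequence([int(master_seed), idx])
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _manifest_path(out: Path, stage: str) -> Path:
    return out / f"{stage}.manifest.json"


def _write_manifest(out: Path, stage: str, seed: int, params: dict, inputs: list[Path], outputs: list[Path]):
    manifest = {
        "stage": stage,
        "seed": seed,
        "params": params,
        "inputs": {p.name: _sha256(p) for p in inputs},
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    _manifest_path(out, stage).write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")


def _recorded_output_hashes(out: Path) -> dict[str, str]:
    recorded: dict[str, str] = {}
    for mf in sorted(out.glob("*.manifest.json")):
        data = json.loads(mf.read_text())
        recorded.update(data.get("outputs", {}))
    return recorded


def _check_inputs(out: Path, inputs: list[Path], force: bool) -> None:
    for p in inputs:
        if not p.exists():
            raise ValidationError(f"required upstream artifact missing: {p}")
    recorded = _recorded_output_hashes(out)
    for p in inputs:
        want = recorded.get(p.name)
        if want is None:
            continue
        have = _sha256(p)
        if have != want:
            msg = (
                f"{p.name} does not match the hash recorded by its producing stage "
                f"(expected {want[:12]}..., found {have[:12]}...); rerun upstream or pass force"
            )
            if force:
                log.warning("FORCED past stale input: %s", msg)
            else:
                raise StaleInputError(msg)


def _read_df(path: Path, sep: str) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, index_col=0)


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(cfg: RunConfig, out: Path, seed: int, force: bool) -> list[Path]:
    import dataclasses

    sim = dataclasses.replace(cfg.simulate, seed=seed)
    bundle = simdata.generate_cohort(sim)
    paths = simdata.write_cohort(bundle, out, sep=cfg.delimiter)
    return list(paths.values())


def _stage_preprocess(cfg: RunConfig, out: Path, seed: int, force: bool) -> list[Path]:
    sep = cfg.delimiter
    ext = {"\t": "tsv", ",": "csv"}.get(sep, "txt")
    inputs = [out / f"methylation.{ext}", out / f"metabolites.{ext}",
              out / f"metabolite_meta.{ext}", out / f"phenotypes.{ext}"]
    _check_inputs(out, inputs, force)
    meth = preprocess.MethylationMatrix(_read_df(inputs[0], sep), scale="beta")
    met_vals = _read_df(inputs[1], sep)
    meta = _read_df(inputs[2], sep)
    phen = _read_df(inputs[3], sep)
    truth_file = out / "truth.json"
    dup_pairs = []
    if truth_file.exists():
        dup_pairs = [tuple(p) for p in json.loads(truth_file.read_text()).get("duplicate_pairs", [])]
    met = preprocess.MetaboliteMatrix(
        values=met_vals,
        platform=meta["platform"],
        drug_linked=meta["drug_linked"].astype(bool),
        duplicate_pairs=dup_pairs,
    )

    train_ids, test_ids = surrogates.split_cohort(meth.sample_ids, cfg.train_fraction, seed)

    meth, probe_report = preprocess.filter_probes(meth, cfg.max_probe_missing_rate)
    meth = preprocess.knn_impute(meth, k=cfg.knn_k)
    m_mat = preprocess.beta_to_m(meth)
    scaler = preprocess.Scaler.fit(m_mat.values.loc[train_ids])
    m_std = scaler.transform(m_mat.values)

    met, met_report = preprocess.metabolite_qc(
        met, phen["age"], phen["sex"], cfg.max_metabolite_missing_or_zero, cfg.drug_list
    )
    met, sample_report = preprocess.filter_samples(met, cfg.max_sample_missing_rate)
    met = preprocess.impute_metabolites(met, k=cfg.knn_k, seed=seed)
    met_train_ids = met.values.index.intersection(train_ids)
    met_raw_train = preprocess.MetaboliteMatrix(
        values=met.values.loc[met_train_ids], platform=met.platform,
        drug_linked=met.drug_linked, duplicate_pairs=met.duplicate_pairs,
    )
    _, met_scaler = preprocess.log_standardize(met_raw_train)
    met_std, _ = preprocess.log_standardize(met, scaler=met_scaler)

    outputs = {
        "m_values_std": out / f"m_values_std.{ext}",
        "metabolites_std": out / f"metabolites_std.{ext}",
        "split": out / "split.json",
        "probe_exclusions": out / f"probe_exclusions.{ext}",
        "metabolite_exclusions": out / f"metabolite_exclusions.{ext}",
        "sample_exclusions": out / f"sample_exclusions.{ext}",
    }
    m_std.to_csv(outputs["m_values_std"], sep=sep)
    met_std.values.to_csv(outputs["metabolites_std"], sep=sep)
    outputs["split"].write_text(
        json.dumps({"train": list(train_ids), "test": list(test_ids)}, indent=1) + "\n"
    )
    probe_report.table.to_csv(outputs["probe_exclusions"], sep=sep, index=False)
    met_report.table.to_csv(outputs["metabolite_exclusions"], sep=sep, index=False)
    sample_report.table.to_csv(outputs["sample_exclusions"], sep=sep, index=False)
    return list(outputs.values())


def _load_preprocessed(cfg: RunConfig, out: Path):
    sep = cfg.delimiter
    ext = {"\t": "tsv", ",": "csv"}.get(sep, "txt")
    m_std = _read_df(out / f"m_values_std.{ext}", sep)
    met_std = _read_df(out / f"metabolites_std.{ext}", sep)
    split = json.loads((out / "split.json").read_text())
    return m_std, met_std, split


def _stage_train_surrogates(cfg: RunConfig, out: Path, seed: int, force: bool) -> list[Path]:
    sep = cfg.delimiter
    ext = {"\t": "tsv", ",": "csv"}.get(sep, "txt")
    inputs = [out / f"m_values_std.{ext}", out / f"metabolites_std.{ext}", out / "split.json"]
    _check_inputs(out, inputs, force)
    m_std, met_std, split = _load_preprocessed(cfg, out)
    train = [s for s in split["train"] if s in met_std.index]
    models = []
    for j, met_id in enumerate(met_std.columns):
        y = met_std[met_id].loc[train]
        screen = surrogates.ewas_screen(y, m_std.loc[train], cfg.top_fraction, metabolite_id=met_id)
        model = surrogates.train_surrogate(
            y, m_std.loc[train], screen.top_probes, folds=cfg.folds,
            seed=seed + j, rule=cfg.lambda_rule,
        )
        models.append(model)
        log.info("surrogate %s: %d CpGs, lambda=%.4g", met_id, model.n_cpgs_selected, model.lam)
    path = out / f"surrogate_coefficients.{ext}"
    surrogates.write_surrogates(models, path, sep=sep)
    return [path]


def _stage_filter_surrogates(cfg: RunConfig, out: Path, seed: int, force: bool) -> list[Path]:
    sep = cfg.delimiter
    ext = {"\t": "tsv", ",": "csv"}.get(sep, "txt")
    inputs = [out / f"surrogate_coefficients.{ext}", out / f"m_values_std.{ext}",
              out / f"metabolites_std.{ext}", out / "split.json"]
    _check_inputs(out, inputs, force)
    m_std, met_std, split = _load_preprocessed(cfg, out)
    models = surrogates.read_surrogates(inputs[0], sep=sep)
    bimod = {}
    for model in models:
        preds = model.predict(m_std)  # full cohort, the default inspection set
        bimod[model.metabolite_id] = surrogates.bimodality_flag(preds, alpha=cfg.bonferroni_alpha)
    test = [s for s in split["test"] if s in met_std.index]
    validations = surrogates.validate_surrogates(
        models, m_std.loc[test], met_std.loc[test], bimodality=bimod,
        alpha=cfg.bonferroni_alpha, train_ids=split["train"],
    )
    table = pd.DataFrame(
        [
            {
                "metabolite_id": v.metabolite_id, "r": v.r, "p": v.p, "p_adjusted": v.p_adjusted,
                "bimodal": v.bimodal, "dip": v.dip, "n_test": v.n_test, "verdict": v.verdict,
            }
            for v in validations
        ]
    )
    vpath = out / f"surrogate_validation.{ext}"
    table.to_csv(vpath, sep=sep, index=False)
    kept = [m for m, v in zip(models, validations) if v.verdict == "kept"]
    kpath = out / f"surrogate_coefficients_kept.{ext}"
    surrogates.write_surrogates(kept, kpath, sep=sep)
    return [vpath, kpath]


def _surrogate_features(models, m_std: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame({m.metabolite_id: m.predict(m_std) for m in models}, index=m_std.index)


def _stage_build_clock(cfg: RunConfig, out: Path, seed: int, force: bool) -> list[Path]:
    sep = cfg.delimiter
    ext = {"\t": "tsv", ",": "csv"}.get(sep, "txt")
    inputs = [out / f"m_values_std.{ext}", out / f"metabolites_std.{ext}", out / "split.json",
              out / f"phenotypes.{ext}"]
    if cfg.clock_feature_space == "surrogate":
        inputs.append(out / f"surrogate_coefficients_kept.{ext}")
    _check_inputs(out, inputs, force)
    m_std, met_std, split = _load_preprocessed(cfg, out)
    phen = _read_df(out / f"phenotypes.{ext}", sep)
    if cfg.clock_feature_space == "surrogate":
        models = surrogates.read_surrogates(out / f"surrogate_coefficients_kept.{ext}", sep=sep)
        feats = _surrogate_features(models, m_std)
        train = [s for s in split["train"] if s in feats.index]
    else:
        feats = met_std
        train = [s for s in split["train"] if s in feats.index]
    clock = clocks.build_clock(
        feats.loc[train], phen["age"], feature_space=cfg.clock_feature_space,
        folds=cfg.folds, alpha_grid=cfg.alpha_grid, seed=seed,
    )
    cpath = out / f"clock.{ext}"
    clocks.write_clock(clock, cpath, sep=sep)
    log.info("clock: %d features, alpha=%.2f lambda=%.4g", len(clock.coef), clock.alpha, clock.lam)
    return [cpath]


def _clock_features(cfg: RunConfig, out: Path) -> pd.DataFrame:
    sep = cfg.delimiter
    ext = {"\t": "tsv", ",": "csv"}.get(sep, "txt")
    m_std, met_std, _ = _load_preprocessed(cfg, out)
    if cfg.clock_feature_space == "surrogate":
        models = surrogates.read_surrogates(out / f"surrogate_coefficients_kept.{ext}", sep=sep)
        return _surrogate_features(models, m_std)
    return met_std


def _stage_predict(cfg: RunConfig, out: Path, seed: int, force: bool) -> list[Path]:
    sep = cfg.delimiter
    ext = {"\t": "tsv", ",": "csv"}.get(sep, "txt")
    inputs = [out / f"clock.{ext}"]
    _check_inputs(out, inputs, force)
    clock = clocks.read_clock(inputs[0], sep=sep)
    feats = _clock_features(cfg, out)
    result = clocks.predict_age(clock, feats)
    path = out / f"predicted_age.{ext}"
    result.predicted.to_frame().to_csv(path, sep=sep)
    return [path]


def _stage_accelerate(cfg: RunConfig, out: Path, seed: int, force: bool) -> list[Path]:
    sep = cfg.delimiter
    ext = {"\t": "tsv", ",": "csv"}.get(sep, "txt")
    inputs = [out / f"predicted_age.{ext}", out / f"phenotypes.{ext}"]
    _check_inputs(out, inputs, force)
    pred = _read_df(inputs[0], sep)["predicted_age"]
    phen = _read_df(inputs[1], sep)
    accel = clocks.age_acceleration(pred, phen["age"])
    path = out / f"age_acceleration.{ext}"
    pd.DataFrame(
        {
            "predicted_age": accel.predicted,
            "age": accel.chronological,
            "residual_years": accel.residual,
            "acceleration_scaled": accel.scaled,
        }
    ).to_csv(path, sep=sep)
    return [path]


_RISK_FACTORS = ("sex", "bmi_cat", "alcohol", "smoking")
_OUTCOMES = (
    ("diabetes", "logistic"),
    ("cvd", "logistic"),
    ("disability", "logistic"),
    ("frailty", "linear"),
    ("gait_speed", "linear"),
    ("grip_strength", "linear"),
    ("cognitive_errors", "negative_binomial"),
)


def _stage_associate(cfg: RunConfig, out: Path, seed: int, force: bool) -> list[Path]:
    sep = cfg.delimiter
    ext = {"\t": "tsv", ",": "csv"}.get(sep, "txt")
    inputs = [out / f"age_acceleration.{ext}", out / f"phenotypes.{ext}"]
    _check_inputs(out, inputs, force)
    accel = _read_df(inputs[0], sep)["acceleration_scaled"]
    phen = _read_df(inputs[1], sep).loc[accel.index]
    cov = phen[["age", "sex", "ethnicity"]]
    results = []
    for fac in _RISK_FACTORS:
        if fac == "sex":
            series = phen["sex"].map({0: "female", 1: "male"}).astype("category")
            series.name = "sex"
            cov_f = phen[["age", "ethnicity"]]
        else:
            series = phen[fac].astype("category")
            cov_f = cov
        results.extend(assoc.risk_factor_assoc(accel, series, cov_f))
    for name, family in _OUTCOMES:
        results.append(
            assoc.outcome_assoc(accel, phen[name], family, covariates=cov, outcome_name=name)
        )
    if phen["event"].sum() > 0:
        results.append(
            assoc.outcome_assoc(
                accel, (phen["time"], phen["event"]), "cox", covariates=cov, outcome_name="mortality"
            )
        )
    path = out / f"associations.{ext}"
    assoc.results_table(results).to_csv(path, sep=sep, index=False)
    return [path]


def _stage_enrich(cfg: RunConfig, out: Path, seed: int, force: bool) -> list[Path]:
    sep = cfg.delimiter
    ext = {"\t": "tsv", ",": "csv"}.get(sep, "txt")
    if cfg.annotation_path is None:
        raise ValidationError("enrich stage needs annotation_path in the run config")
    inputs = [out / f"clock.{ext}", out / f"m_values_std.{ext}"]
    if cfg.clock_feature_space == "surrogate":
        inputs.append(out / f"surrogate_coefficients_kept.{ext}")
    _check_inputs(out, inputs, force)
    clock = clocks.read_clock(out / f"clock.{ext}", sep=sep)
    if cfg.clock_feature_space == "surrogate":
        models = surrogates.read_surrogates(out / f"surrogate_coefficients_kept.{ext}", sep=sep)
    else:
        raise ValidationError("enrichment requires a CpG-backed clock (surrogate feature space)")
    coefs = assoc.clock_cpg_coefficients(clock, models)
    m_std, _, _ = _load_preprocessed(cfg, out)
    background = list(m_std.columns)
    top = assoc.top_k_cpgs(coefs, k=cfg.top_k_cpgs)
    top = [p for p in top if p in set(background)]
    annotation = pd.read_csv(cfg.annotation_path, sep=None, engine="python")
    table = assoc.enrich(top, annotation, background)
    path = out / f"enrichment.{ext}"
    table.to_csv(path, sep=sep, index=False)
    return [path]


STAGES = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "train-surrogates": _stage_train_surrogates,
    "filter-surrogates": _stage_filter_surrogates,
    "build-clock": _stage_build_clock,
    "predict": _stage_predict,
    "accelerate": _stage_accelerate,
    "associate": _stage_associate,
    "enrich": _stage_enrich,
}


def run_stage(stage: str, cfg: RunConfig, force: bool = False) -> list[Path]:
    """Run one pipeline stage; writes artifacts plus a manifest."""
    if stage not in STAGES:
        raise ValidationError(f"unknown stage {stage!r}; choose from {list(STAGES)}")
    cfg.validate()
    out = cfg.out
    out.mkdir(parents=True, exist_ok=True)
    seed = stage_seed(cfg.seed, stage)
    log.info("stage %s (seed %d) -> %s", stage, seed, out)
    import dataclasses

    params = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in dataclasses.asdict(cfg).items()
        if not isinstance(v, dict)
    }
    outputs = STAGES[stage](cfg, out, seed, force)
    ext = {"\t": "tsv", ",": "csv"}.get(cfg.delimiter, "txt")
    known_inputs = []
    if stage != "simulate":
        recorded = _recorded_output_hashes(out)
        known_inputs = [out / name for name in recorded if (out / name).exists()
                        and name not in {p.name for p in outputs}]
    _write_manifest(out, stage, seed, params, known_inputs, outputs)
    return outputs


def run_all(cfg: RunConfig, force: bool = False, skip_enrich_without_annotation: bool = True):
    """Run every stage in order; 'enrich' is skipped when no annotation is set."""
    done = {}
    for stage in STAGES:
        if stage == "enrich" and cfg.annotation_path is None and skip_enrich_without_annotation:
            log.info("skipping enrich: no annotation_path configured")
            continue
        done[stage] = run_stage(stage, cfg, force=force)
    return done
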