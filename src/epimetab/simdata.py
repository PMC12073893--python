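"""Seeded synthetic cohorts with coupled epigenome-metabolome-phenotype structure.

The generator emulates the statistical features the surrogate/clock pipeline
assumes in real cohort data, with full ground truth for recovery tests:

* **Age-associated CpGs** — probe methylation is generated on the logit
  scale (so back-transformed beta values are strictly inside (0,1) with no
  clipping) with a per-year drift on a configurable probe subset.  Drift is
  driven by a latent *biological age* = chronological age + an ageing-rate
  deviation, so that accelerated agers are literally "older" at their age
  probes.
* **Sparse CpG-metabolite dependence** — each metabolite is a weighted sum
  of a small support set of probes' standardised M-values plus independent
  noise, exponentiated to a positive abundance.
* **SNP-confounded probes** — a subset of probes clusters at beta ~
  0.05/0.5/0.95 according to Hardy-Weinberg genotype frequencies; these are
  the probes the downstream bimodality filter exists to catch.
* **Platform-specific missingness** — NMR metabolites are left-censored
  below a per-feature quantile (detection limit); MS metabolites are missing
  completely at random.
* **Age-dependent outcomes** — survival times from an exponential hazard
  scaled by age (and optionally by the latent ageing rate), plus binary,
  continuous and count outcomes all fed by the same latent deviation, giving
  the association suite a known positive-control direction.

All randomness flows from ``SimConfig.seed``; identical configs produce
byte-identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import ValidationError
from .preprocess import MethylationMatrix, MetaboliteMatrix

__all__ = ["SimConfig", "SimTruth", "CohortBundle", "generate_cohort", "truth_report", "write_cohort"]

_LN2 = np.log(2.0)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort generator.

    Dimensions default to a desk-scale cohort (500 samples, 5,000 probes, 40
    metabolites) — large enough to exercise every pipeline contract, far
    below array scale.  Effects are on the logit(beta) scale; one logit unit
    is ln2 M-value units.
    """

    n_samples: int = 500
    n_probes: int = 5000
    n_metabolites: int = 40
    n_age_probes: int = 100
    age_effect_sd: float = 0.02      # logit units per year of biological age
    cpgs_per_metabolite: int = 5
    metabolite_noise_sd: float = 0.5  # relative to unit-SD planted signal
    n_snp_probes: int = 10
    allele_freq: float = 0.3
    nmr_censor_quantile: float = 0.05
    ms_missing_rate: float = 0.02
    age_range: tuple[float, float] = (21.0, 65.0)
    mortality_base_hazard: float = 0.01   # per year, at mid age-range
    mortality_age_loghr: float = 0.08     # log hazard ratio per year of age
    hazard_accel_loghr: float = 0.2       # log HR per SD of latent ageing deviation
    seed: int = 0

    # secondary knobs
    probe_noise_sd: float = 0.3       # logit-scale measurement noise
    bioage_sd: float = 3.0            # years of latent ageing deviation per SD
    n_sex_probes: int = 0
    sex_effect: float = 0.5           # logit shift in males on sex probes
    support_from_age_probes: bool = True
    probe_missing_rate: float = 0.0
    n_bad_probes: int = 0
    bad_probe_missing_rate: float = 0.05
    n_duplicate_pairs: int = 0
    n_drug_metabolites: int = 0
    followup_years: float = 15.0
    outcome_accel_effect: float = 0.3  # shared latent effect on non-survival outcomes
    risk_effects: dict = field(default_factory=dict)
    # e.g. {"alcohol": {"heavy": 0.4}}: shift (in SD of the latent ageing
    # deviation) added to samples at that factor level

    def validate(self) -> None:
        counts = {
            "n_samples": self.n_samples,
            "n_probes": self.n_probes,
            "n_metabolites": self.n_metabolites,
            "n_age_probes": self.n_age_probes,
            "cpgs_per_metabolite": self.cpgs_per_metabolite,
            "n_snp_probes": self.n_snp_probes,
            "n_sex_probes": self.n_sex_probes,
            "n_duplicate_pairs": self.n_duplicate_pairs,
            "n_drug_metabolites": self.n_drug_metabolites,
        }
        for name, v in counts.items():
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n_age_probes > self.n_probes:
            raise ValidationError("n_age_probes must not exceed n_probes")
        if self.cpgs_per_metabolite > self.n_probes:
            raise ValidationError("cpgs_per_metabolite must not exceed n_probes")
        if self.n_snp_probes + self.n_age_probes + self.n_sex_probes > self.n_probes:
            raise ValidationError("n_age_probes + n_snp_probes + n_sex_probes must not exceed n_probes")
        for name in ("allele_freq", "nmr_censor_quantile", "ms_missing_rate", "probe_missing_rate",
                     "bad_probe_missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v!r}")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValidationError(f"age_range must satisfy lo < hi, got {self.age_range!r}")
        for name in ("age_effect_sd", "metabolite_noise_sd", "probe_noise_sd", "bioage_sd",
                     "mortality_base_hazard", "followup_years"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.n_drug_metabolites + 2 * self.n_duplicate_pairs > self.n_metabolites:
            raise ValidationError("n_drug_metabolites + 2*n_duplicate_pairs must not exceed n_metabolites")


@dataclass
class SimTruth:
    """Ground-truth record of everything the generator planted."""

    age_probe_ids: list[str]
    age_effects: dict[str, float]            # logit units per year
    snp_probe_ids: list[str]
    genotypes: pd.DataFrame                  # samples x snp probes, values 0/1/2
    sex_probe_ids: list[str]
    support: dict[str, dict[str, float]]     # metabolite -> {probe: weight}
    accel: pd.Series                         # latent ageing deviation, SD units
    bioage: pd.Series                        # years
    outcome_coefs: dict[str, dict[str, float]]


@dataclass
class CohortBundle:
    methylation: MethylationMatrix
    metabolites: MetaboliteMatrix
    phenotypes: pd.DataFrame
    truth: SimTruth
    config: SimConfig


def _sample_categorical(rng, n, levels, probs):
    idx = rng.choice(len(levels), size=n, p=probs)
    return pd.Categorical.from_codes(idx, categories=levels)


def generate_cohort(config: SimConfig) -> CohortBundle:
    """Generate one synthetic cohort; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    p = config.n_probes
    lo, hi = config.age_range
    mid = 0.5 * (lo + hi)

    sample_ids = pd.Index([f"S{i:05d}" for i in range(n)], name="sample_id")
    probe_ids = pd.Index([f"cg{i:08d}" for i in range(p)], name="probe_id")

    # --- phenotype scaffolding -------------------------------------------
    age = rng.uniform(lo, hi, size=n)
    sex = rng.integers(0, 2, size=n)           # 0 female, 1 male
    ethnicity = _sample_categorical(rng, n, ["white", "nonwhite"], [0.976, 0.024])
    alcohol = _sample_categorical(rng, n, ["none", "moderate", "heavy"], [0.07, 0.86, 0.07])
    smoking = _sample_categorical(rng, n, ["never", "former", "current"], [0.66, 0.24, 0.10])
    bmi_cat = _sample_categorical(rng, n, ["normal", "overweight", "obese"], [0.32, 0.47, 0.21])
    factors = {"alcohol": alcohol, "smoking": smoking, "bmi_cat": bmi_cat}

    # latent ageing-rate deviation (SD units) with planted risk-factor shifts
    accel = rng.normal(0.0, 1.0, size=n)
    for fac, shifts in config.risk_effects.items():
        if fac not in factors:
            raise ValidationError(f"risk_effects factor {fac!r} unknown (use {sorted(factors)})")
        codes = np.asarray(factors[fac])
        for level, shift in shifts.items():
            accel = accel + shift * (codes == level)
    bioage = age + config.bioage_sd * accel

    # --- methylation ------------------------------------------------------
    # probe roles: [age probes][snp probes][sex probes][background]
    a, s, x = config.n_age_probes, config.n_snp_probes, config.n_sex_probes
    age_ids = list(probe_ids[:a])
    snp_ids = list(probe_ids[a:a + s])
    sex_ids = list(probe_ids[a + s:a + s + x])

    base = rng.normal(0.0, 1.5, size=p)
    age_slopes = rng.normal(0.0, config.age_effect_sd, size=a)
    logit_vals = np.tile(base, (n, 1))
    if a:
        logit_vals[:, :a] += np.outer(bioage - mid, age_slopes)
    if x:
        sex_slopes = np.full(x, config.sex_effect)
        logit_vals[:, a + s:a + s + x] += np.outer(sex, sex_slopes)
    # SNP probes: three beta clusters ~0.05 / 0.5 / 0.95 by HWE genotype
    geno = np.empty((n, s), dtype=np.int64)
    if s:
        q = config.allele_freq
        geno = rng.choice(3, size=(n, s), p=[(1 - q) ** 2, 2 * q * (1 - q), q ** 2])
        centers = np.array([logit(0.05), 0.0, logit(0.95)])
        logit_vals[:, a:a + s] = centers[geno]
    logit_vals += rng.normal(0.0, config.probe_noise_sd, size=(n, p))
    beta = expit(logit_vals)

    # --- metabolites from probe supports ---------------------------------
    m = config.n_metabolites
    met_ids = pd.Index([f"met{i:04d}" for i in range(m)], name="metabolite_id")
    m_vals = logit_vals / _LN2                           # exact M-values of the noise-free beta
    m_std = (m_vals - m_vals.mean(axis=0)) / np.where(m_vals.std(axis=0) == 0, 1.0, m_vals.std(axis=0))
    support: dict[str, dict[str, float]] = {}
    met_latent = np.empty((n, m))
    k = config.cpgs_per_metabolite
    pool = np.arange(a) if (config.support_from_age_probes and a >= k and k > 0) else np.arange(p)
    for j in range(m):
        if k == 0:
            support[met_ids[j]] = {}
            signal = np.zeros(n)
        else:
            sel = rng.choice(pool, size=k, replace=False)
            # magnitudes bounded away from zero: a support probe with ~0
            # weight is unrecoverable in principle, so every planted member
            # carries real signal
            w = rng.choice([-1.0, 1.0], size=k) * rng.uniform(0.5, 1.5, size=k)
            raw_sig = m_std[:, sel] @ w
            sd = raw_sig.std()
            scale = 1.0 / sd if sd > 0 else 1.0
            w = w * scale
            signal = raw_sig * scale
            support[met_ids[j]] = {probe_ids[i]: float(wi) for i, wi in zip(sel, w)}
        met_latent[:, j] = signal + rng.normal(0.0, config.metabolite_noise_sd, size=n)
    met_raw = np.exp(met_latent)

    platform = pd.Series(
        ["NMR" if j % 2 == 0 else "MS" for j in range(m)], index=met_ids, name="platform"
    )
    # duplicate pairs: re-measure the first n_duplicate_pairs metabolites on
    # the other platform with independent noise
    dup_pairs: list[tuple[str, str]] = []
    dup_cols = {}
    for j in range(config.n_duplicate_pairs):
        src = met_ids[j]
        twin = f"{src}_dup"
        noisy = np.log(met_raw[:, j]) + rng.normal(0.0, config.metabolite_noise_sd, size=n)
        dup_cols[twin] = np.exp(noisy)
        dup_pairs.append((src, twin))
    met_values = pd.DataFrame(met_raw, index=sample_ids, columns=met_ids)
    for twin, col in dup_cols.items():
        met_values[twin] = col
        src = twin[:-4]
        platform[twin] = "MS" if platform[src] == "NMR" else "NMR"
    drug_linked = pd.Series(False, index=met_values.columns)
    if config.n_drug_metabolites > 0:
        drug_linked.iloc[m - config.n_drug_metabolites:m] = True

    # platform-specific missingness
    for name in met_values.columns:
        col = met_values[name].to_numpy(copy=True)
        if platform[name] == "NMR" and config.nmr_censor_quantile > 0:
            cut = np.quantile(col, config.nmr_censor_quantile)
            col[col < cut] = np.nan
        elif platform[name] == "MS" and config.ms_missing_rate > 0:
            col[rng.random(n) < config.ms_missing_rate] = np.nan
        met_values[name] = col

    # probe missingness (MCAR background + a block of high-missing probes)
    beta_df = pd.DataFrame(beta, index=sample_ids, columns=probe_ids)
    if config.probe_missing_rate > 0:
        mask = rng.random((n, p)) < config.probe_missing_rate
        beta_df = beta_df.mask(pd.DataFrame(mask, index=sample_ids, columns=probe_ids))
    if config.n_bad_probes > 0:
        bad = probe_ids[p - config.n_bad_probes:]
        mask = rng.random((n, config.n_bad_probes)) < config.bad_probe_missing_rate
        sub = beta_df[bad].mask(pd.DataFrame(mask, index=sample_ids, columns=bad))
        beta_df[bad] = sub

    # --- outcomes ---------------------------------------------------------
    oc = config.outcome_accel_effect
    coefs = {
        "survival": {"base_hazard": config.mortality_base_hazard,
                     "age_loghr": config.mortality_age_loghr,
                     "accel_loghr": config.hazard_accel_loghr},
        "diabetes": {"intercept": -3.0, "age": 0.05, "accel": oc},
        "cvd": {"intercept": -3.5, "age": 0.07, "accel": oc},
        "disability": {"intercept": -2.5, "age": 0.04, "accel": oc},
        "frailty": {"intercept": 0.15, "age": 0.004, "accel": 0.03, "noise_sd": 0.05},
        "gait_speed": {"intercept": 130.0, "age": -0.5, "accel": -2.0 * oc / 0.3, "noise_sd": 10.0},
        "grip_strength": {"intercept": 35.0, "age": -0.2, "accel": -1.0 * oc / 0.3, "noise_sd": 5.0},
        "cognitive_errors": {"intercept": 0.5, "age": 0.03, "accel": 0.5 * oc, "theta": 5.0},
    }
    age_c = age - mid
    hazard = config.mortality_base_hazard * np.exp(
        config.mortality_age_loghr * age_c + config.hazard_accel_loghr * accel
    )
    t_death = rng.exponential(1.0 / hazard)
    event = (t_death <= config.followup_years).astype(int)
    time_obs = np.minimum(t_death, config.followup_years)
    time_obs = np.maximum(time_obs, 1e-8)

    def _binary(c):
        lp = c["intercept"] + c["age"] * age_c + c["accel"] * accel
        return (rng.random(n) < expit(lp)).astype(int)

    def _linear(c):
        return c["intercept"] + c["age"] * age_c + c["accel"] * accel + rng.normal(0, c["noise_sd"], n)

    mu = np.exp(coefs["cognitive_errors"]["intercept"]
                + coefs["cognitive_errors"]["age"] * age_c
                + coefs["cognitive_errors"]["accel"] * accel)
    theta = coefs["cognitive_errors"]["theta"]
    cog = rng.poisson(rng.gamma(theta, mu / theta))

    phenotypes = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "ethnicity": ethnicity,
            "alcohol": alcohol,
            "smoking": smoking,
            "bmi_cat": bmi_cat,
            "diabetes": _binary(coefs["diabetes"]),
            "cvd": _binary(coefs["cvd"]),
            "disability": _binary(coefs["disability"]),
            "frailty": _linear(coefs["frailty"]),
            "gait_speed": _linear(coefs["gait_speed"]),
            "grip_strength": _linear(coefs["grip_strength"]),
            "cognitive_errors": cog,
            "event": event,
            "time": time_obs,
            "accel_true": accel,
        },
        index=sample_ids,
    )

    truth = SimTruth(
        age_probe_ids=age_ids,
        age_effects={pid: float(sl) for pid, sl in zip(age_ids, age_slopes)},
        snp_probe_ids=snp_ids,
        genotypes=pd.DataFrame(geno, index=sample_ids, columns=snp_ids),
        sex_probe_ids=sex_ids,
        support=support,
        accel=pd.Series(accel, index=sample_ids, name="accel"),
        bioage=pd.Series(bioage, index=sample_ids, name="bioage"),
        outcome_coefs=coefs,
    )
    return CohortBundle(
        methylation=MethylationMatrix(beta_df, scale="beta"),
        metabolites=MetaboliteMatrix(
            values=met_values, platform=platform, drug_linked=drug_linked, duplicate_pairs=dup_pairs
        ),
        phenotypes=phenotypes,
        truth=truth,
        config=config,
    )


def truth_report(bundle: CohortBundle) -> pd.DataFrame:
    """Per-metabolite summary of the planted structure, for recovery tests.

    One row per metabolite (support size, platform) with cohort-level truth
    (genotype fractions, age-probe count, mean |age effect|) repeated as
    columns for convenience.
    """
    truth = bundle.truth
    geno = truth.genotypes.to_numpy()
    if geno.size:
        fr = [float((geno == g).mean()) for g in (0, 1, 2)]
    else:
        fr = [np.nan, np.nan, np.nan]
    eff = np.array(list(truth.age_effects.values()))
    rows = []
    for met in bundle.metabolites.metabolite_ids:
        sup = truth.support.get(met, {})
        rows.append(
            {
                "metabolite_id": met,
                "support_size": len(sup),
                "platform": bundle.metabolites.platform[met],
                "n_age_probes": len(truth.age_probe_ids),
                "mean_abs_age_effect": float(np.abs(eff).mean()) if eff.size else 0.0,
                "hom_ref_fraction": fr[0],
                "het_fraction": fr[1],
                "hom_alt_fraction": fr[2],
            }
        )
    return pd.DataFrame(rows).set_index("metabolite_id")


def write_cohort(bundle: CohortBundle, outdir, sep: str = "\t") -> dict[str, Path]:
    """Write the three tables plus a JSON truth file; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = {"\t": "tsv", ",": "csv"}.get(sep, "txt")
    paths = {
        "methylation": outdir / f"methylation.{ext}",
        "metabolites": outdir / f"metabolites.{ext}",
        "metabolite_meta": outdir / f"metabolite_meta.{ext}",
        "phenotypes": outdir / f"phenotypes.{ext}",
        "truth": outdir / "truth.json",
    }
    bundle.methylation.values.to_csv(paths["methylation"], sep=sep)
    bundle.metabolites.values.to_csv(paths["metabolites"], sep=sep)
    meta = pd.DataFrame(
        {
            "platform": bundle.metabolites.platform,
            "drug_linked": bundle.metabolites.drug_linked,
        }
    )
    meta.index.name = "metabolite_id"
    meta.to_csv(paths["metabolite_meta"], sep=sep)
    bundle.phenotypes.to_csv(paths["phenotypes"], sep=sep)
    truth = bundle.truth
    payload = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(bundle.config).items()},
        "age_probe_ids": truth.age_probe_ids,
        "age_effects": truth.age_effects,
        "snp_probe_ids": truth.snp_probe_ids,
        "sex_probe_ids": truth.sex_probe_ids,
        "support": truth.support,
        "genotypes": {c: truth.genotypes[c].tolist() for c in truth.genotypes.columns},
        "accel": truth.accel.tolist(),
        "bioage": truth.bioage.tolist(),
        "outcome_coefs": truth.outcome_coefs,
        "duplicate_pairs": bundle.metabolites.duplicate_pairs,
    }
    paths["truth"].write_text(json.dumps(payload, indent=1, sort_keys=True))
    return paths
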