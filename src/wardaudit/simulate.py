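"""Forward simulation of three-level admission cohorts with known truth.

The generator runs the analysis model forwards: hospitals of three types get
Gaussian random intercepts on the logit scale, wards nested inside them get a
second set, and each admission's 30-day death is Bernoulli with
``expit(x'beta + u_h + u_w)``.  Defaults emulate the structure of the Swedish
heart-failure audit cohort: 71 hospitals (41 municipal, 21 provincial, 9
regional), ~565 wards, ~37,000 patients, ~9% outcome prevalence, hospital and
ward variances 0.013 and 0.170, and covariate effects of the magnitudes seen
in such register studies.

``raw`` mode additionally plants admissions that the exclusion cascade is
meant to remove (prior heart-failure history, nursing-home facilities,
out-of-age-window patients, undersized hospitals) and records the intended
removal count of each cascade step in the truth bundle.

Randomness: one ``numpy.random.default_rng(seed)`` drives everything, in a
fixed stream order (ward counts -> patient counts -> raw-mode class labels ->
u_h -> u_w -> age -> sex/ethnicity -> comorbidity flags -> outcome), so a
seed pins the full cohort byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import math

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .cohort import (
    CohortTable,
    DEFAULT_COMORBIDITIES,
    COMORBIDITY_PREFIX,
)


class ConfigError(ValueError):
    """A simulation configuration is internally inconsistent."""


def _default_hospitals():
    return {"municipal": 41, "provincial": 21, "regional": 9}


def _default_wards_mean():
    # ~565 wards over 71 hospitals, allocated per the audit's Table-1 pattern
    return {"municipal": 4.0, "provincial": 9.4, "regional": 22.7}


def _default_patients_mean():
    # patient shares ~29% / 42.5% / 28.5% of ~37k admissions
    return {"municipal": 66.0, "provincial": 79.0, "regional": 52.0}


def _default_sex_eth_probs():
    return {
        "swedish_male": 0.512,
        "swedish_female": 0.341,
        "nonswedish_male": 0.082,
        "nonswedish_female": 0.065,
    }


def _default_sex_eth_beta():
    return {
        "swedish_female": 0.0,
        "swedish_male": math.log(1.11),
        "nonswedish_male": math.log(1.01),
        "nonswedish_female": math.log(0.78),
    }


def _default_comorbidities():
    """(prevalence, log-odds effect) per history flag.

    Prevalences and effects are plausible for an elderly first-heart-failure
    population; jointly with age they give a patient-mix linear predictor
    with SD ~1.1, i.e. a fitted top-vs-bottom risk-decile odds ratio in the
    low twenties and a case-mix AUC near 0.72 — the magnitudes the audit's
    association table reports.
    """
    return {
        "cerebral_arteries": (0.08, 0.50),
        "arrhythmia": (0.25, 0.35),
        "hypertension": (0.35, 0.21),
        "ischemic_heart": (0.25, 0.42),
        "varicose": (0.03, 0.07),
        "peripheral_vascular": (0.05, 0.42),
        "acute_mi": (0.12, 0.56),
        "other_heart": (0.20, 0.42),
        "respiratory": (0.20, 0.63),
        "digestive": (0.15, 0.42),
        "diabetes": (0.20, 0.35),
        "infectious": (0.08, 0.56),
        "cancer": (0.12, 1.26),
        "lung_cancer": (0.015, 1.54),
        "chronic_lower_respiratory": (0.10, 0.63),
        "immunity": (0.04, 0.42),
        "mental": (0.10, 0.49),
        "injury": (0.10, 0.35),
    }


def _default_volume_beta():
    return {1: 0.0, 2: math.log(0.81), 3: math.log(0.60)}


def _default_type_beta():
    return {"regional": 0.0, "municipal": math.log(0.89), "provincial": math.log(1.26)}


@dataclasses.dataclass
class SimulationConfig:
    """Complete description of one synthetic world.

    ``intercept`` is calibrated so the default world has ~9% 30-day
    mortality.  Variances are on the logit (latent) scale.  ``raw`` -mode
    rates are fractions of admissions planted for the exclusion cascade; they
    are mutually exclusive classes and must sum below 1.
    """

    n_hospitals: dict = dataclasses.field(default_factory=_default_hospitals)
    wards_per_hospital_mean: dict = dataclasses.field(default_factory=_default_wards_mean)
    patients_per_ward_mean: dict = dataclasses.field(default_factory=_default_patients_mean)
    sigma2_h: float = 0.013
    sigma2_w: float = 0.170
    intercept: float = -3.51  # calibrated via calibrate_intercept to ~9% mortality
    beta_age: float = 0.10  # per year, centred at age 71
    sex_eth_probs: dict = dataclasses.field(default_factory=_default_sex_eth_probs)
    sex_eth_beta: dict = dataclasses.field(default_factory=_default_sex_eth_beta)
    comorbidities: dict = dataclasses.field(default_factory=_default_comorbidities)
    ward_volume_beta: dict = dataclasses.field(default_factory=_default_volume_beta)
    hospital_type_beta: dict = dataclasses.field(default_factory=_default_type_beta)
    age_mean: float = 71.0
    age_sd: float = 8.0
    age_range: tuple = (45, 80)
    # raw-mode knobs
    prior_hf_rate: float = 0.0
    nursing_home_rate: float = 0.0
    out_of_age_rate: float = 0.0
    n_tiny_hospitals: int = 0
    tiny_hospital_size: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.sigma2_h < 0 or self.sigma2_w < 0:
            raise ConfigError("variances must be non-negative")
        if any(v < 1 for v in self.n_hospitals.values()):
            raise ConfigError("need at least one hospital per configured type")
        if any(m < 1 for m in self.wards_per_hospital_mean.values()):
            raise ConfigError("mean wards per hospital must be >= 1")
        if any(m < 1 for m in self.patients_per_ward_mean.values()):
            raise ConfigError("mean patients per ward must be >= 1")
        rates = (self.prior_hf_rate, self.nursing_home_rate, self.out_of_age_rate)
        if any(r < 0 or r > 1 for r in rates):
            raise ConfigError("raw-mode rates must lie in [0, 1]")
        if sum(rates) > 1:
            raise ConfigError("raw-mode rates must sum to at most 1")
        for name, (p, _) in self.comorbidities.items():
            if not 0 <= p <= 1:
                raise ConfigError(f"comorbidity prevalence out of [0,1]: {name}")
        p = sum(self.sex_eth_probs.values())
        if abs(p - 1) > 1e-6:
            raise ConfigError("sex_eth_probs must sum to 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["age_range"] = list(d["age_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        if "ward_volume_beta" in d:
            d["ward_volume_beta"] = {int(k): v for k, v in d["ward_volume_beta"].items()}
        return cls(**d)


@dataclasses.dataclass
class TruthBundle:
    """What the generator actually did: realized random effects and rates."""

    u_h: pd.Series  # hospital random intercepts, indexed by hospital_id
    u_w: pd.Series  # ward random intercepts, indexed by ward_id
    prevalence: float  # realized outcome prevalence (analysis-eligible rows)
    config: SimulationConfig
    exclusion_counts: dict = dataclasses.field(default_factory=dict)

    def to_json(self, path) -> None:
        out = {
            "u_h": self.u_h.to_dict(),
            "u_w": self.u_w.to_dict(),
            "prevalence": self.prevalence,
            "exclusion_counts": self.exclusion_counts,
            "config": self.config.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(out, fh, indent=2)


def simulate_cohort(config: SimulationConfig) -> tuple[CohortTable, TruthBundle]:
    """Generate an analysis-ready cohort (no exclusion work to do)."""
    return _simulate(config, raw=False)


def simulate_raw_cohort(config: SimulationConfig) -> tuple[CohortTable, TruthBundle]:
    """Generate a raw cohort carrying admissions the cascade should remove."""
    return _simulate(config, raw=True)


def _simulate(config: SimulationConfig, raw: bool) -> tuple[CohortTable, TruthBundle]:
    rng = np.random.default_rng(config.seed)

    # --- structure: hospitals, wards, patient counts --------------------
    hosp_ids, hosp_types = [], []
    for htype in ("municipal", "provincial", "regional"):
        for k in range(config.n_hospitals.get(htype, 0)):
            hosp_ids.append(f"H_{htype[:3]}_{k + 1:03d}")
            hosp_types.append(htype)
    if raw and config.n_tiny_hospitals > 0:
        for k in range(config.n_tiny_hospitals):
            hosp_ids.append(f"H_tiny_{k + 1:03d}")
            hosp_types.append("municipal")
    H = len(hosp_ids)

    wards_mean = np.array(
        [config.wards_per_hospital_mean[t] for t in hosp_types]
    )
    n_wards = 1 + rng.poisson(wards_mean - 1.0)
    tiny = np.array([h.startswith("H_tiny_") for h in hosp_ids])
    n_wards[tiny] = 1

    ward_hosp = np.repeat(np.arange(H), n_wards)  # hospital index per ward
    W = ward_hosp.size
    ward_ids = np.array(
        [f"{hosp_ids[h]}_W{j + 1:02d}" for h, j in zip(ward_hosp, _within_counter(ward_hosp))]
    )

    pat_mean = np.array(
        [config.patients_per_ward_mean[hosp_types[h]] for h in ward_hosp]
    )
    n_pat = 1 + rng.poisson(pat_mean - 1.0)
    if raw and config.n_tiny_hospitals > 0:
        n_pat[tiny[ward_hosp]] = config.tiny_hospital_size

    pat_ward = np.repeat(np.arange(W), n_pat)  # ward index per admission
    n = pat_ward.size
    pat_hosp = ward_hosp[pat_ward]

    # --- raw-mode class labels ------------------------------------------
    rates = (config.prior_hf_rate, config.nursing_home_rate, config.out_of_age_rate)
    if raw and sum(rates) > 0:
        u = rng.random(n)
        prior_hf = (u < rates[0]).astype(int)
        nursing = (u >= rates[0]) & (u < rates[0] + rates[1])
        out_age = (u >= rates[0] + rates[1]) & (u < sum(rates))
    else:
        prior_hf = np.zeros(n, dtype=int)
        nursing = np.zeros(n, dtype=bool)
        out_age = np.zeros(n, dtype=bool)

    # --- random effects --------------------------------------------------
    u_h = rng.normal(0.0, math.sqrt(config.sigma2_h), H)
    u_w = rng.normal(0.0, math.sqrt(config.sigma2_w), W)

    # --- patient covariates ----------------------------------------------
    lo, hi = config.age_range
    a, b = (lo - config.age_mean) / config.age_sd, (hi - config.age_mean) / config.age_sd
    age = truncnorm.rvs(
        a, b, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
    )
    age = np.round(age).clip(lo, hi).astype(int)
    if out_age.any():
        # planted out-of-window admissions: older than the audit window
        age[out_age] = rng.integers(hi + 1, hi + 13, size=int(out_age.sum()))

    levels = list(config.sex_eth_probs)
    sex_eth = rng.choice(levels, size=n, p=[config.sex_eth_probs[l] for l in levels])

    flags = {}
    for name, (prev, _beta) in config.comorbidities.items():
        flags[name] = (rng.random(n) < prev).astype(int)

    # --- linear predictor and outcome ------------------------------------
    ward_sizes = np.bincount(pat_ward, minlength=W)
    tert = _tertiles(ward_sizes)
    vol_beta = np.array([config.ward_volume_beta[t] for t in (1, 2, 3)])
    type_beta = np.array([config.hospital_type_beta[hosp_types[h]] for h in range(H)])

    lp = (
        config.intercept
        + config.beta_age * (age - config.age_mean)
        + np.array([config.sex_eth_beta[s] for s in sex_eth])
        + vol_beta[tert[pat_ward] - 1]
        + type_beta[pat_hosp]
        + u_h[pat_hosp]
        + u_w[pat_ward]
    )
    for name, (_prev, beta) in config.comorbidities.items():
        lp += beta * flags[name]

    death = (rng.random(n) < expit(lp)).astype(int)

    # --- assemble table ---------------------------------------------------
    df = pd.DataFrame(
        {
            "patient_id": [f"P{k + 1:06d}" for k in range(n)],
            "death30": death,
            "age": age,
            "sex_eth": sex_eth,
            "ward_id": ward_ids[pat_ward],
            "hospital_id": np.array(hosp_ids)[pat_hosp],
            "hospital_type": np.array(hosp_types)[pat_hosp],
        }
    )
    for name in config.comorbidities:
        df[COMORBIDITY_PREFIX + name] = flags[name]

    exclusion_counts = {}
    if raw:
        df["prior_hf"] = prior_hf
        df["facility_kind"] = "hospital"
        if nursing.any():
            # nursing-home admissions move to their own small facilities
            idx = np.flatnonzero(nursing)
            fac = idx // 30  # ~30 admissions per nursing home
            df.loc[idx, "facility_kind"] = "nursing_home"
            df.loc[idx, "hospital_id"] = [f"NH_{f + 1:03d}" for f in fac]
            df.loc[idx, "ward_id"] = [f"NH_{f + 1:03d}_W01" for f in fac]
        # intended cascade counts, in cascade order
        in_age = df["age"].between(lo, hi).to_numpy()
        step1 = ~in_age
        step2 = in_age & (df["prior_hf"].to_numpy() == 1)
        left = in_age & (df["prior_hf"].to_numpy() == 0)
        step3 = left & (df["facility_kind"] == "nursing_home").to_numpy()
        left = left & (df["facility_kind"] == "hospital").to_numpy()
        remaining = df.loc[left].groupby("hospital_id")["patient_id"].size()
        small = set(remaining.index[remaining < 50])
        step4 = left & df["hospital_id"].isin(small).to_numpy()
        exclusion_counts = {
            "age_window": int(step1.sum()),
            "prior_hf": int(step2.sum()),
            "nursing_home": int(step3.sum()),
            "small_hospital": int(step4.sum()),
        }
        eligible = left & ~df["hospital_id"].isin(small).to_numpy()
        prevalence = float(df.loc[eligible, "death30"].mean()) if eligible.any() else float("nan")
    else:
        prevalence = float(df["death30"].mean())

    truth = TruthBundle(
        u_h=pd.Series(u_h, index=hosp_ids, name="u_h"),
        u_w=pd.Series(u_w, index=ward_ids, name="u_w"),
        prevalence=prevalence,
        config=config,
        exclusion_counts=exclusion_counts,
    )
    return CohortTable(df), truth


def calibrate_intercept(
    config: SimulationConfig, target: float = 0.09, seed: int = 12345
) -> float:
    """Intercept value giving expected prevalence ``target`` under ``config``.

    Simulates one cohort's linear predictor with the intercept zeroed and
    root-finds the constant ``c`` with mean expit(lp + c) = target.  Used
    once, off-line, to fix the default; not called on the simulation path.
    """
    from scipy.optimize import brentq

    cfg = dataclasses.replace(config, intercept=0.0, seed=seed)
    table, _ = simulate_cohort(cfg)
    lp = _linear_predictor_of(table, cfg)
    return float(brentq(lambda c: expit(lp + c).mean() - target, -15, 15))


def _linear_predictor_of(table: CohortTable, config: SimulationConfig) -> np.ndarray:
    """Reconstruct the no-noise part of the generator's linear predictor."""
    df = table.data
    sizes = df.groupby("ward_id")["patient_id"].size()
    tert = pd.Series(_tertiles(sizes.to_numpy()), index=sizes.index)
    lp = (
        config.intercept
        + config.beta_age * (df["age"].to_numpy() - config.age_mean)
        + df["sex_eth"].map(config.sex_eth_beta).to_numpy()
        + df["ward_id"].map(tert).map(lambda t: config.ward_volume_beta[t]).to_numpy()
        + df["hospital_type"].map(config.hospital_type_beta).to_numpy()
    )
    for name, (_p, beta) in config.comorbidities.items():
        lp = lp + beta * df[COMORBIDITY_PREFIX + name].to_numpy()
    return lp


def _tertiles(sizes: np.ndarray) -> np.ndarray:
    """Tertile code (1..3) of each entry within the realized distribution."""
    order = np.argsort(sizes, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(sizes.size)
    return 1 + np.minimum(2, (3 * ranks) // max(1, sizes.size))


def _within_counter(group: np.ndarray) -> np.ndarray:
    """0-based running index within consecutive runs of equal values."""
    out = np.zeros(group.size, dtype=int)
    for i in range(1, group.size):
        out[i] = out[i - 1] + 1 if group[i] == group[i - 1] else 0
    return out
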