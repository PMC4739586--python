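"""Stepwise four-model pipeline, summary tables and league tables.

``run_stepwise`` reproduces the audit sequence on an analysis cohort:

1. **Model 1** — single-level logistic on risk-score deciles (case mix).
2. **Model 2** — model 1 + the combined sex-by-ethnicity category.
3. **Model 3** — model 2 + nested random intercepts for hospitals and wards.
4. **Model 4** — model 3 + ward-volume tertile and hospital type.

The risk score is fitted once on the cohort and reused.  Every model's OR
table, AUC (for model 3 also with either cluster level excluded), variance
components, ICC/MOR/PCV/POOR block and information criterion are collected
in a :class:`StepwiseReport`; the formatter only reads numbers off the
stored fit objects, never recomputes them.

``league_table`` ranks the clusters of one level by shrunken residual with
95% intervals and a flag for whether each interval excludes zero — the
classic caterpillar-plot ranking, exportable as CSV (the figure itself is an
optional extra via ``plot_caterpillar``).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time

import numpy as np
import pandas as pd

from .cohort import CohortTable, ward_volume_tertiles
from .discrimination import DiscriminationResult, auc_increment, roc_auc
from .measures import ContextualMeasures
from .multilevel import DicUnavailableError, MultilevelLogit, MultilevelResults
from .riskscore import fit_risk_score

logger = logging.getLogger("wardaudit")

#: reference levels of the adjustment covariates
REF_LEVELS = {
    "rs_decile": 1,
    "sex_eth": "swedish_female",
    "ward_volume_tertile": 1,
    "hospital_type": "regional",
}

MODEL_SEQUENCE = ("model1", "model2", "model3", "model4")


@dataclasses.dataclass
class StepwiseConfig:
    """Pipeline settings: stepwise threshold, estimation backend, chains."""

    alpha_remove: float = 0.05
    estimation: str = "laplace"  # 'laplace' (deterministic) or 'mcmc'
    mcmc_iter: int = 5000
    mcmc_burn: int = 1000
    mcmc_thin: int = 1
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclasses.dataclass
class StepwiseReport:
    """Everything the four-model audit produces, traceable to its fits."""

    risk_score: object
    fits: dict  # model name -> MultilevelResults
    auc: dict  # equation name -> DiscriminationResult
    auc_differences: dict  # equation name -> (diff vs model2, ci)
    measures: dict  # 'model3'/'model4' -> ContextualMeasures
    fit_stats: dict  # model name -> {'dic': ...} or {'aic': ...}
    provenance: dict
    config: StepwiseConfig
    timings: dict = dataclasses.field(default_factory=dict)

    # -- formatted tables -------------------------------------------------
    def table_associations(self) -> pd.DataFrame:
        """OR (95% CI) per fixed effect per model — the association table."""
        cols = {}
        for name in MODEL_SEQUENCE:
            ors = self.fits[name].odds_ratios()
            cols[name] = pd.Series(
                [f"{r.OR:.2f} ({r.lo:.2f}-{r.hi:.2f})" for r in ors.itertuples()],
                index=ors.index,
            )
        return pd.DataFrame(cols)

    def table_variance(self) -> pd.DataFrame:
        """AUC, variance, PCV, ICC, MOR and fit-criterion block per model."""
        rows = {}

        def put(row, model, value):
            rows.setdefault(row, {})[model] = value

        for name in MODEL_SEQUENCE:
            eq = name if name in self.auc else None
            if eq:
                r = self.auc[eq]
                put("auc", name, round(r.auc, 3))
                put("auc_lo", name, round(r.ci95[0], 3))
                put("auc_hi", name, round(r.ci95[1], 3))
            if name in self.auc_differences:
                put("auc_diff_vs_model2", name, round(self.auc_differences[name][0], 3))
            fit = self.fits[name]
            if "hospital" in fit.sigma2:
                put("sigma2_hospital", name, round(fit.sigma2["hospital"].estimate, 3))
                put("sigma2_ward", name, round(fit.sigma2["ward"].estimate, 3))
            if name in self.measures:
                m = self.measures[name].rounded()
                put("icc_hospital", name, m["icc_h"])
                put("icc_ward", name, m["icc_w"])
                put("mor_hospital", name, m["mor_h"])
                put("mor_ward", name, m["mor_w"])
                for level, v in m["pcv_by_level"].items():
                    put(f"pcv_{level}", name, v)
            for crit, value in self.fit_stats.get(name, {}).items():
                put(crit, name, round(value, 3))
        return pd.DataFrame(rows).T[list(MODEL_SEQUENCE)]

    def to_json(self, path=None):
        payload = {
            "config": self.config.to_dict(),
            "config_digest": self.config.digest,
            "provenance": self.provenance,
            "risk_score": {
                "retained": self.risk_score.retained,
                "params": self.risk_score.params.to_dict(),
                "decile_cuts": list(self.risk_score.decile_cuts),
                "trace": self.risk_score.trace,
            },
            "models": {
                name: {
                    "method": fit.method,
                    "params": fit.params.to_dict(),
                    "odds_ratios": fit.odds_ratios().round(6).to_dict(orient="index"),
                    "sigma2": {
                        lv: {
                            "estimate": vc.estimate,
                            "ci95": list(vc.ci95) if vc.ci95 else None,
                            "boundary": vc.boundary,
                        }
                        for lv, vc in fit.sigma2.items()
                    },
                }
                for name, fit in self.fits.items()
            },
            "auc": {
                name: {"auc": r.auc, "ci95": list(r.ci95)}
                for name, r in self.auc.items()
            },
            "auc_differences": {
                name: {"diff": d, "ci95": list(ci)}
                for name, (d, ci) in self.auc_differences.items()
            },
            "measures": {
                name: dataclasses.asdict(m) for name, m in self.measures.items()
            },
            "fit_stats": self.fit_stats,
            "timings": self.timings,
        }
        text = json.dumps(payload, indent=2, default=float)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text + "\n")


class StageError(RuntimeError):
    """A pipeline stage failed; names the stage and carries the cause."""

    def __init__(self, stage, cause):
        super().__init__(f"stepwise pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


def run_stepwise(cohort: CohortTable, config: StepwiseConfig | None = None) -> StepwiseReport:
    """Run the full four-model audit on an analysis cohort."""
    config = config or StepwiseConfig()
    df = cohort.data.copy()
    timings = {}
    t0 = time.perf_counter()

    def tick(stage):
        timings[stage] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s done at %.1fs (config %s)", stage, timings[stage], config.digest)

    def guarded(stage, fn, *args, **kw):
        try:
            out = fn(*args, **kw)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(stage, exc) from exc
        tick(stage)
        return out

    rs = guarded(
        "risk_score", fit_risk_score, cohort, alpha_remove=config.alpha_remove
    )
    df["rs_decile"] = rs.assign_deciles(df)
    df["ward_volume_tertile"] = ward_volume_tertiles(cohort).to_numpy()

    # adapt the nominal term list to the realized cohort: a covariate that is
    # constant (e.g. hospital type in a single-type world) is dropped, and a
    # configured reference level absent from the data falls back to the first
    # observed level
    ref_levels = {}
    for term, ref in REF_LEVELS.items():
        levels = sorted(pd.unique(df[term])) if term in df.columns else []
        if ref in levels:
            ref_levels[term] = ref
        elif levels:
            ref_levels[term] = levels[0]

    def usable(term):
        return term in df.columns and df[term].nunique() > 1

    terms = {
        "model1": ["rs_decile"],
        "model2": ["rs_decile", "sex_eth"],
        "model3": ["rs_decile", "sex_eth"],
        "model4": ["rs_decile", "sex_eth", "ward_volume_tertile", "hospital_type"],
    }
    terms = {name: [t for t in tl if usable(t)] for name, tl in terms.items()}

    fits: dict[str, MultilevelResults] = {}
    for name in ("model1", "model2"):
        model = MultilevelLogit.from_dataframe(
            df, "death30", terms[name], ref_levels=ref_levels
        )
        fits[name] = guarded(name, model.fit)
    for name in ("model3", "model4"):
        model = MultilevelLogit.from_dataframe(
            df,
            "death30",
            terms[name],
            ward="ward_id",
            hospital="hospital_id",
            ref_levels=ref_levels,
        )
        if config.estimation == "mcmc":
            fits[name] = guarded(
                name,
                model.fit_mcmc,
                n_iter=config.mcmc_iter,
                burn=config.mcmc_burn,
                thin=config.mcmc_thin,
                seed=config.seed,
            )
        else:
            fits[name] = guarded(name, model.fit)

    # --- discriminatory accuracy -----------------------------------------
    y = df["death30"].to_numpy(float)
    auc: dict[str, DiscriminationResult] = {}

    def add_auc(name, fit, levels):
        auc[name] = roc_auc(fit.linear_predictor(include_levels=levels), y, label=name)

    guarded("auc", lambda: [
        add_auc("model1", fits["model1"], ()),
        add_auc("model2", fits["model2"], ()),
        add_auc("model3", fits["model3"], ("hospital", "ward")),
        add_auc("model3_fixed_only", fits["model3"], ()),
        add_auc("model3_no_hospital", fits["model3"], ("ward",)),
        add_auc("model3_no_ward", fits["model3"], ("hospital",)),
        add_auc("model4", fits["model4"], ("hospital", "ward")),
    ])
    auc_diffs = {
        name: auc_increment(auc[name], auc["model2"])
        for name in auc
        if name != "model2"
    }

    # --- contextual measures ----------------------------------------------
    def _measures():
        cluster_terms = {}
        for term in fits["model4"].params.index:
            if term.startswith("ward_volume_tertile["):
                cluster_terms[term] = "ward"
            elif term.startswith("hospital_type["):
                cluster_terms[term] = "hospital"
        return {
            "model3": ContextualMeasures.from_fit(fits["model3"]),
            "model4": ContextualMeasures.from_fit(
                fits["model4"], prev_fit=fits["model3"], cluster_terms=cluster_terms
            ),
        }

    measures = guarded("measures", _measures)

    # --- fit criteria -------------------------------------------------------
    def _fit_stats():
        stats = {}
        if config.estimation == "mcmc":
            for name in ("model1", "model2"):
                mc = MultilevelLogit.from_dataframe(
                    df, "death30", terms[name], ref_levels=ref_levels
                ).fit_mcmc(
                    n_iter=config.mcmc_iter,
                    burn=config.mcmc_burn,
                    thin=config.mcmc_thin,
                    seed=config.seed,
                )
                stats[name] = {"dic": mc.dic, "p_d": mc.p_d}
            for name in ("model3", "model4"):
                stats[name] = {"dic": fits[name].dic, "p_d": fits[name].p_d}
        else:
            for name in MODEL_SEQUENCE:
                try:
                    stats[name] = {"aic": fits[name].aic}
                except DicUnavailableError:
                    pass
        return stats

    fit_stats = guarded("fit_criteria", _fit_stats)

    return StepwiseReport(
        risk_score=rs,
        fits=fits,
        auc=auc,
        auc_differences=auc_diffs,
        measures=measures,
        fit_stats=fit_stats,
        provenance=dict(cohort.provenance),
        config=config,
        timings=timings,
    )


# ---------------------------------------------------------------------------
# league tables
# ---------------------------------------------------------------------------

def league_table(fit: MultilevelResults, level: str) -> pd.DataFrame:
    """Rank clusters by shrunken residual with 95% intervals and flags.

    Ascending residual = lowest adjusted mortality first.  Ties are broken
    by cluster id (deterministic).  ``flag`` says whether a cluster's
    interval sits wholly above or below zero ('above'/'below') or straddles
    it ('indistinguishable').
    """
    tab = fit.random_effects(level).copy()
    tab.index.name = "cluster"
    tab = tab.reset_index()
    tab["cluster"] = tab["cluster"].astype(str)
    tab = tab.sort_values(["u", "cluster"], kind="stable").reset_index(drop=True)
    tab.insert(0, "rank", np.arange(1, len(tab) + 1))
    tab["flag"] = np.where(
        tab["lo"] > 0, "above", np.where(tab["hi"] < 0, "below", "indistinguishable")
    )
    return tab


def plot_caterpillar(league: pd.DataFrame, ax=None, title: str | None = None):
    """Caterpillar plot of a league table (optional visual; CSV is canonical)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, len(league) / 20), 4))
    x = league["rank"].to_numpy()
    ax.vlines(x, league["lo"], league["hi"], color="0.6", lw=0.8)
    ax.plot(x, league["u"], "o", ms=2.5, color="0.1")
    ax.axhline(0.0, color="red", lw=0.8)
    ax.set_xlabel("rank")
    ax.set_ylabel("shrunken residual (log-odds)")
    if title:
        ax.set_title(title)
    return ax
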