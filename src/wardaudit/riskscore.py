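"""Patient-mix risk score: stepwise backward logistic regression + deciles.

The risk score (RS) condenses age and the comorbidity-history flags into one
predicted 30-day mortality probability per admission, fitted by backward
elimination from the full single-level logistic model: at each step the
candidate with the largest Wald p-value is dropped while that p-value
exceeds ``alpha_remove`` (default 0.05).  The RS is then cut into decile
groups on the fitting cohort, and the decile labels — not the continuous
score — enter the downstream adjustment models.

The fitted score is an internal case-mix adjustment for the cohort at hand,
not a transportable clinical prediction rule.
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning


class SeparationError(RuntimeError):
    """A candidate predictor perfectly separates the outcome."""

    def __init__(self, message, predictor=None):
        super().__init__(message)
        self.predictor = predictor


class StepwiseConvergenceError(RuntimeError):
    """A stepwise refit failed to converge; carries iteration diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


def _find_separating_predictor(df, candidates, outcome):
    """Best-effort finger-pointing: a binary candidate with an empty 2x2 cell."""
    y = df[outcome]
    for cand in candidates:
        col = df[cand]
        if set(pd.unique(col)) <= {0, 1}:
            tab = pd.crosstab(col, y)
            if (tab.to_numpy() == 0).any():
                return cand
    return None


class RiskScore:
    """Stepwise-backward logistic risk-score model (fit with :meth:`fit`).

    Parameters
    ----------
    data : CohortTable or DataFrame with the outcome and candidate columns.
    candidates : predictor column names entering the full model.
    outcome : binary outcome column, default ``death30``.
    """

    def __init__(self, data, candidates, outcome: str = "death30"):
        df = getattr(data, "data", data)
        missing = [c for c in candidates if c not in df.columns]
        if missing:
            raise KeyError(f"candidate column(s) not in data: {missing}")
        y = df[outcome]
        if y.nunique() < 2:
            raise ValueError("outcome must have both classes present")
        self.df = df
        self.candidates = list(candidates)
        self.outcome = outcome

    def fit(self, alpha_remove: float = 0.05) -> "RiskScoreResults":
        """Backward elimination: drop the least significant predictor while
        its Wald p-value exceeds ``alpha_remove``."""
        retained = list(self.candidates)
        trace = []
        y = self.df[self.outcome].to_numpy(float)
        res = None
        while True:
            X = sm.add_constant(self.df[retained].to_numpy(float)) if retained else np.ones(
                (len(y), 1)
            )
            names = ["intercept"] + retained
            with warnings.catch_warnings():
                warnings.simplefilter("error", PerfectSeparationWarning)
                try:
                    res = sm.Logit(y, X).fit(disp=0, maxiter=200)
                except (PerfectSeparationError, PerfectSeparationWarning):
                    culprit = _find_separating_predictor(
                        self.df, retained, self.outcome
                    )
                    raise SeparationError(
                        "perfect separation during stepwise fit"
                        + (f"; offending predictor: {culprit!r}" if culprit else ""),
                        predictor=culprit,
                    )
            if not res.mle_retvals.get("converged", True):
                raise StepwiseConvergenceError(
                    "stepwise refit did not converge", diagnostics=res.mle_retvals
                )
            if not retained:
                break
            pvals = pd.Series(res.pvalues[1:], index=retained)
            worst = pvals.idxmax()
            if pvals[worst] <= alpha_remove:
                break
            trace.append({"dropped": worst, "p_value": float(pvals[worst])})
            retained.remove(worst)

        params = pd.Series(res.params, index=["intercept"] + retained)
        scores = self._predict_with(params, self.df)
        cuts = _decile_cuts(scores)
        if len(np.unique(scores)) == 1:
            warnings.warn("all risk scores identical; every record falls in decile 1")
        return RiskScoreResults(
            model=self,
            params=params,
            retained=retained,
            trace=trace,
            decile_cuts=cuts,
            alpha_remove=alpha_remove,
        )

    @staticmethod
    def _predict_with(params: pd.Series, df: pd.DataFrame) -> np.ndarray:
        from scipy.special import expit

        eta = np.full(len(df), params["intercept"], float)
        for name in params.index:
            if name == "intercept":
                continue
            eta = eta + params[name] * df[name].to_numpy(float)
        return expit(eta)


def _decile_cuts(scores: np.ndarray) -> np.ndarray:
    return np.quantile(scores, np.arange(1, 10) / 10.0)


@dataclasses.dataclass
class RiskScoreResults:
    """Fitted risk score: retained predictors, coefficients, decile cuts."""

    model: RiskScore
    params: pd.Series
    retained: list
    trace: list
    decile_cuts: np.ndarray
    alpha_remove: float

    def __post_init__(self):
        if np.any(np.diff(self.decile_cuts) < 0):
            raise ValueError("decile cut points must be non-decreasing")

    def predict(self, data) -> np.ndarray:
        """Predicted 30-day mortality probability (the risk score) per row."""
        df = getattr(data, "data", data)
        missing = [c for c in self.retained if c not in df.columns]
        if missing:
            raise KeyError(f"predictor column(s) missing from data: {missing}")
        return RiskScore._predict_with(self.params, df)

    def assign_deciles(self, data) -> pd.Series:
        """Decile-group label (1..10) per row; ties at a cut go to the lower
        group.  Cut points come from the fitting cohort and are reusable on
        new data."""
        df = getattr(data, "data", data)
        p = self.predict(df)
        labels = 1 + np.searchsorted(self.decile_cuts, p, side="left")
        return pd.Series(labels.astype(int), index=df.index, name="rs_decile")

    # -- serialization ----------------------------------------------------
    def to_json(self, path=None):
        payload = {
            "outcome": self.model.outcome,
            "candidates": self.model.candidates,
            "retained": self.retained,
            "params": self.params.to_dict(),
            "decile_cuts": self.decile_cuts.tolist(),
            "trace": self.trace,
            "alpha_remove": self.alpha_remove,
        }
        if path is None:
            return json.dumps(payload, indent=2)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, source) -> "RiskScoreResults":
        """Rehydrate a serialized score for reuse on new cohorts."""
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        dummy = RiskScore.__new__(RiskScore)
        dummy.df = None
        dummy.candidates = payload["candidates"]
        dummy.outcome = payload["outcome"]
        return cls(
            model=dummy,
            params=pd.Series(payload["params"]),
            retained=payload["retained"],
            trace=payload["trace"],
            decile_cuts=np.asarray(payload["decile_cuts"], float),
            alpha_remove=payload["alpha_remove"],
        )


def fit_risk_score(
    cohort, candidates=None, alpha_remove: float = 0.05, outcome: str = "death30"
) -> RiskScoreResults:
    """Fit the RS on a cohort; default candidates are age + comorbidity flags."""
    df = getattr(cohort, "data", cohort)
    if candidates is None:
        comorb = getattr(cohort, "comorbidity_cols", None) or [
            c for c in df.columns if c.startswith("cm_")
        ]
        candidates = ["age"] + list(comorb)
    return RiskScore(df, candidates, outcome=outcome).fit(alpha_remove=alpha_remove)


def assign_deciles(results: RiskScoreResults, cohort) -> pd.Series:
    """Module-level alias for :meth:`RiskScoreResults.assign_deciles`."""
    return results.assign_deciles(getattr(cohort, "data", cohort))
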