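"""ROC discriminatory accuracy of prediction equations with cluster residuals.

A fitted multilevel model yields a family of prediction equations: the fixed
part alone, or the fixed part plus the shrunken residuals of either or both
cluster levels.  Comparing their AUCs measures how much knowing the ward or
hospital improves patient-level discrimination — the general contextual
effect on the AUC scale.

AUC is the Mann-Whitney concordance probability with ties counted half; its
standard error and the paired-difference covariance use DeLong's placement
method (no closed-form implementation ships with the installed stack, so it
is written out here).  ROC curve points come from scikit-learn.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.metrics import roc_curve


def linear_predictor(fit, cohort=None, included_levels=("hospital", "ward")):
    """Per-record eta from a fit, adding the residuals of the named levels.

    Convenience alias for ``fit.linear_predictor``; excluding a level zeroes
    its residual contribution, and an unknown cluster raises.
    """
    return fit.linear_predictor(cohort, include_levels=included_levels)


@dataclasses.dataclass
class DiscriminationResult:
    """AUC with 95% CI, the ROC polyline, and the scores behind them."""

    auc: float
    ci95: tuple
    roc_points: pd.DataFrame  # columns fpr, tpr, from (0,0) to (1,1)
    scores: np.ndarray
    outcome: np.ndarray
    label: str = ""

    @property
    def n_pos(self) -> int:
        return int(self.outcome.sum())

    @property
    def n_neg(self) -> int:
        return int(len(self.outcome) - self.outcome.sum())


def _placements(scores: np.ndarray, outcome: np.ndarray):
    """DeLong placement values V10 (per case) and V01 (per non-case)."""
    pos = scores[outcome == 1]
    neg = scores[outcome == 0]
    m, n = len(pos), len(neg)
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n  # P(neg < pos) with half ties
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return v10, v01


def roc_auc(eta, outcome, label: str = "") -> DiscriminationResult:
    """Rank-based AUC of scores ``eta`` against a binary outcome.

    Ties get half credit (Mann-Whitney convention); the 95% CI is the DeLong
    asymptotic normal interval, clipped to [0, 1].
    """
    eta = np.asarray(eta, float)
    outcome = np.asarray(outcome, float)
    if eta.shape != outcome.shape:
        raise ValueError("scores and outcome must have equal length")
    if not np.isfinite(eta).all():
        raise ValueError("scores must be finite")
    if not np.isin(outcome, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    if outcome.min() == outcome.max():
        raise ValueError("both outcome classes must be present")

    v10, v01 = _placements(eta, outcome)
    auc = float(v10.mean())
    var = (
        v10.var(ddof=1) / len(v10) + v01.var(ddof=1) / len(v01)
        if len(v10) > 1 and len(v01) > 1
        else 0.0
    )
    half = 1.96 * np.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))

    fpr, tpr, _ = roc_curve(outcome, eta, drop_intermediate=False)
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    return DiscriminationResult(
        auc=auc, ci95=ci, roc_points=points, scores=eta, outcome=outcome, label=label
    )


def auc_increment(result_a: DiscriminationResult, result_b: DiscriminationResult):
    """Paired AUC difference ``a - b`` with a DeLong 95% CI.

    Both results must score the same records (same outcome vector); the CI
    accounts for the correlation between the two score sets.
    """
    if len(result_a.outcome) != len(result_b.outcome):
        raise ValueError("results score different numbers of records")
    if not np.array_equal(result_a.outcome, result_b.outcome):
        raise ValueError("results must share one outcome vector")
    va10, va01 = _placements(result_a.scores, result_a.outcome)
    vb10, vb01 = _placements(result_b.scores, result_b.outcome)
    m, n = len(va10), len(va01)
    diff = result_a.auc - result_b.auc
    var = (
        np.var(va10 - vb10, ddof=1) / m + np.var(va01 - vb01, ddof=1) / n
        if m > 1 and n > 1
        else 0.0
    )
    half = 1.96 * float(np.sqrt(var))
    return diff, (diff - half, diff + half)


def auc_pvalue(result_a: DiscriminationResult, result_b: DiscriminationResult) -> float:
    """Two-sided DeLong test p-value for equal AUCs of paired equations."""
    diff, (lo, hi) = auc_increment(result_a, result_b)
    se = (hi - lo) / (2 * 1.96)
    if se == 0:
        return 1.0 if diff == 0 else 0.0
    return float(2 * norm.sf(abs(diff) / se))
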