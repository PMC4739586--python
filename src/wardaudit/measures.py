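"""Derived contextual measures: ICC, MOR, PCV and POOR.

These closed forms turn the variance components of a multilevel logistic fit
into the quantities an institutional-performance audit reports:

* ``icc_latent`` — intraclass correlation under the latent-variable
  formulation, with logistic residual variance pi^2/3 at the patient level.
  The ward ICC's numerator includes the hospital variance: two patients on
  the same ward share both the ward and the hospital intercept.
* ``mor`` — median odds ratio, exp(sqrt(2 sigma2) * Phi^-1(0.75)).  The
  hospital MOR uses sigma2_h alone; the ward MOR uses sigma2_h + sigma2_w
  (comparing two random wards changes both intercepts).
* ``pcv`` — proportional change in a variance component between two nested
  models, signed so that a reduction is negative.
* ``poor`` — proportion of opposed odds ratios for a cluster-level
  covariate: the probability that the cluster-pair-specific OR points the
  opposite way from the average OR, 100 * Phi(-|beta| / sqrt(2 sigma2)),
  where sigma2 is the residual variance at the covariate's own level.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.stats import norm

#: latent-scale residual variance of the standard logistic distribution
LOGISTIC_RESIDUAL_VARIANCE = math.pi**2 / 3  # ~3.289868

#: 75th percentile of the standard normal, the MOR's constant
PHI_INV_075 = float(norm.ppf(0.75))  # ~0.674490


class UndefinedPCVError(ZeroDivisionError):
    """PCV is undefined when the reference variance is zero."""


def _check_variance(sigma2: float, name: str = "sigma2") -> float:
    sigma2 = float(sigma2)
    if not np.isfinite(sigma2) or sigma2 < 0:
        raise ValueError(f"{name} must be a finite non-negative variance, got {sigma2}")
    return sigma2


def icc_latent(sigma2_h: float, sigma2_w: float, ward_includes_hospital: bool = True):
    """Hospital- and ward-level intraclass correlations (proportions).

    ``ward_includes_hospital=False`` switches the ward numerator to
    sigma2_w alone; that convention answers a different question (the share
    unique to wards) and does not reproduce the audit's summary tables.
    """
    s2h = _check_variance(sigma2_h, "sigma2_h")
    s2w = _check_variance(sigma2_w, "sigma2_w")
    denom = s2h + s2w + LOGISTIC_RESIDUAL_VARIANCE
    icc_h = s2h / denom
    icc_w = (s2h + s2w) / denom if ward_includes_hospital else s2w / denom
    if not ward_includes_hospital:
        import warnings

        warnings.warn(
            "ward ICC computed from the ward variance alone; this is not the "
            "cumulative convention used in the reference tables"
        )
    return icc_h, icc_w


def mor(sigma2: float) -> float:
    """Median odds ratio for a cluster variance on the logit scale (>= 1)."""
    s2 = _check_variance(sigma2)
    return math.exp(math.sqrt(2.0 * s2) * PHI_INV_075)


def pcv(sigma2_prev: float, sigma2_new: float) -> float:
    """Signed percentage change in a variance component between models.

    Negative when covariates added in the newer model explain variance.
    """
    prev = _check_variance(sigma2_prev, "sigma2_prev")
    new = _check_variance(sigma2_new, "sigma2_new")
    if prev == 0:
        raise UndefinedPCVError("PCV undefined: reference variance is zero")
    return 100.0 * (new - prev) / prev


def poor(beta: float, sigma2_level: float) -> float:
    """Proportion of opposed odds ratios, in percent (0..50).

    ``beta`` is the log-odds coefficient of a cluster-level covariate;
    ``sigma2_level`` the residual variance at that covariate's level.  For a
    random pair of clusters differing in the covariate, the pair-specific OR
    is exp(beta + u_1 - u_0); the POOR is the chance its sign opposes beta's.
    A zero variance pins every pair to the average OR (POOR = 0 unless the
    average effect itself is null, where sign is a coin flip by symmetry).
    """
    beta = float(beta)
    s2 = _check_variance(sigma2_level, "sigma2_level")
    if s2 == 0:
        return 0.0 if beta != 0 else 50.0
    return 100.0 * float(norm.cdf(-abs(beta) / math.sqrt(2.0 * s2)))


@dataclasses.dataclass
class ContextualMeasures:
    """The audit's derived-measure block for one adjusted multilevel fit."""

    icc_h: float
    icc_w: float
    mor_h: float
    mor_w: float
    pcv_by_level: dict = dataclasses.field(default_factory=dict)
    poor_by_term: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_variances(
        cls,
        sigma2_h: float,
        sigma2_w: float,
        sigma2_prev: tuple | None = None,
        cluster_terms: dict | None = None,
    ) -> "ContextualMeasures":
        """Build the block from variance components.

        ``sigma2_prev`` is the (hospital, ward) pair of the previous model in
        the stepwise sequence, enabling PCV; ``cluster_terms`` maps a term
        name to ``(beta, level)`` with level 'hospital' or 'ward' for POOR.
        """
        ih, iw = icc_latent(sigma2_h, sigma2_w)
        out = cls(
            icc_h=ih,
            icc_w=iw,
            mor_h=mor(sigma2_h),
            mor_w=mor(sigma2_h + sigma2_w),
        )
        if sigma2_prev is not None:
            prev_h, prev_w = sigma2_prev
            out.pcv_by_level = {
                "hospital": pcv(prev_h, sigma2_h),
                "ward": pcv(prev_w, sigma2_w),
            }
        for name, (beta, level) in (cluster_terms or {}).items():
            s2 = sigma2_h if level == "hospital" else sigma2_w
            out.poor_by_term[name] = poor(beta, s2)
        return out

    @classmethod
    def from_fit(cls, fit, prev_fit=None, cluster_terms=None) -> "ContextualMeasures":
        """Derive the block from :class:`~wardaudit.multilevel.MultilevelResults`.

        ``cluster_terms`` maps fixed-effect names (as in ``fit.params``) to
        their level; coefficients are read off the fit.
        """
        s2h = fit.sigma2["hospital"].estimate
        s2w = fit.sigma2["ward"].estimate
        prev = None
        if prev_fit is not None:
            prev = (
                prev_fit.sigma2["hospital"].estimate,
                prev_fit.sigma2["ward"].estimate,
            )
        terms = None
        if cluster_terms:
            terms = {
                name: (float(fit.params[name]), level)
                for name, level in cluster_terms.items()
            }
        return cls.from_variances(s2h, s2w, sigma2_prev=prev, cluster_terms=terms)

    def rounded(self) -> dict:
        """Summary-table rounding: ICC 3 dp, MOR 2 dp, PCV 2 dp, POOR whole %."""
        return {
            "icc_h": round(self.icc_h, 3),
            "icc_w": round(self.icc_w, 3),
            "mor_h": round(self.mor_h, 2),
            "mor_w": round(self.mor_w, 2),
            "pcv_by_level": {k: round(v, 2) for k, v in self.pcv_by_level.items()},
            "poor_by_term": {k: round(v) for k, v in self.poor_by_term.items()},
        }
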