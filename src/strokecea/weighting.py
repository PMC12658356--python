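"""Stabilized inverse probability of treatment weighting (sIPTW).

The two treatment arms come from different trials, so their baseline
covariate distributions differ.  A main-effects logistic propensity model
over the 13 baseline covariates (subtype entering as three indicator
contrasts against large-artery atherosclerosis) yields stabilized weights
targeting either the combined population (ATE, the base case) or the
injection-treated population (ATT).  Balance is judged by standardized mean
differences, with |SMD| < 0.1 the conventional threshold for negligible
imbalance; weighted outcome distributions are compared by a Pearson
chi-square test on counts rescaled to each arm's Kish effective sample size.

The weighted day-90 mRS distributions produced here are the sole clinical
input of the downstream decision model.  Missing outcomes are redistributed
proportionally over the observed weighted distribution, i.e. the observed
distribution is renormalized to one.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .synthetic_cohorts import BALANCE_COVARIATES, SUBTYPES, covariate_matrix

N_MRS_LEVELS = 7  # mRS 0..6


class Estimand(str, Enum):
    ATE = "ATE"
    ATT = "ATT"


class EstimationError(RuntimeError):
    """Propensity or outcome estimation failed on degenerate input."""


class DiagnosticsError(RuntimeError):
    """Balance diagnostics undefined (e.g. zero total weight in an arm)."""


class WeightOverflowError(RuntimeError):
    """A propensity score of numerically 0 or 1 makes a weight explode."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

#: propensity design columns: drop large_artery as the subtype reference
PROPENSITY_COLUMNS = tuple(
    c for c in BALANCE_COVARIATES if c != "subtype_large_artery"
)


@dataclass(frozen=True)
class PropensityFit:
    """Fitted logistic propensity model for assignment to the EDSL arm."""

    coefficients: dict
    intercept: float
    fitted_scores: np.ndarray  # e(x), strictly inside (0, 1)
    marginal_treated: float  # P(T=1), the sample share in the EDSL arm

    def __post_init__(self):
        e = np.asarray(self.fitted_scores, dtype=float)
        if np.any(e <= 0.0) or np.any(e >= 1.0):
            raise WeightOverflowError(
                "fitted propensity scores must lie strictly in (0, 1)"
            )
        object.__setattr__(self, "fitted_scores", e)


@dataclass(frozen=True)
class WeightVector:
    estimand: Estimand
    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if np.any(~np.isfinite(w)) or np.any(w < 0):
            raise ValueError("weights must be finite and non-negative")
        object.__setattr__(self, "weights", w)


@dataclass(frozen=True)
class MRSDistribution:
    """Probability vector over mRS 0-6; the currency passed from the
    weighting stage into the decision model."""

    p: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        if p.shape != (N_MRS_LEVELS,):
            raise ValueError("an mRS distribution has exactly 7 entries")
        if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("mRS probabilities must be >= 0 and sum to 1")
        object.__setattr__(self, "p", np.clip(p, 0.0, None))

    def cumulative(self, k: int) -> float:
        """P(mRS <= k)."""
        return float(self.p[: k + 1].sum())


@dataclass(frozen=True)
class BalanceReport:
    smd_before: dict
    smd_after: dict
    balanced_after: dict  # |SMD| < 0.1 flag per covariate
    chisq_statistic: float
    chisq_pvalue: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "covariate": c,
                "smd_before": self.smd_before[c],
                "smd_after": self.smd_after[c],
                "balanced": self.balanced_after[c],
            }
            for c in self.smd_before
        ]
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# propensity model
# --------------------------------------------------------------------------

def treatment_indicator(ipd: pd.DataFrame) -> np.ndarray:
    return (ipd["arm"].to_numpy() == "EDSL").astype(float)


def exclude_missing_covariates(ipd: pd.DataFrame) -> pd.DataFrame:
    """Drop records with any missing baseline covariate (outcome may be
    missing; that is handled later by proportional redistribution)."""
    baseline = [c for c in ipd.columns if c not in ("id", "mrs90")]
    return ipd.dropna(subset=baseline).reset_index(drop=True)


def fit_propensity(ipd: pd.DataFrame) -> PropensityFit:
    """Maximum-likelihood logistic regression of arm on the 13 covariates.

    Raises :class:`EstimationError` for single-arm input, non-convergence,
    or (quasi-)perfect separation.
    """
    t = treatment_indicator(ipd)
    if len(ipd) == 0 or t.min() == t.max():
        raise EstimationError("both treatment arms must be present")

    x = covariate_matrix(ipd)[list(PROPENSITY_COLUMNS)]
    design = sm.add_constant(x.to_numpy(dtype=float), has_constant="add")
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(t, design).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises on perfect separation
        raise EstimationError(f"propensity fit failed: {exc}") from exc

    score = res.model.score(res.params)
    if not np.isfinite(res.params).all() or np.linalg.norm(score) > 1e-6:
        raise EstimationError(
            "propensity fit did not converge (gradient norm "
            f"{np.linalg.norm(score):.3g}); check for separation"
        )
    e = res.predict(design)
    eps = np.finfo(float).tiny
    if np.any(e <= eps) or np.any(e >= 1 - 1e-15):
        raise EstimationError("fitted scores at the boundary: separation")

    coeffs = dict(zip(PROPENSITY_COLUMNS, res.params[1:]))
    return PropensityFit(
        coefficients=coeffs,
        intercept=float(res.params[0]),
        fitted_scores=np.asarray(e, dtype=float),
        marginal_treated=float(t.mean()),
    )


def compute_weights(
    fit: PropensityFit,
    estimand: Estimand | str,
    treated: np.ndarray,
    truncate_percentile: float | None = None,
) -> WeightVector:
    """Stabilized weights for the requested estimand.

    ATE: treated ``P(T=1)/e(x)``, control ``P(T=0)/(1-e(x))``.
    ATT: treated 1, control ``e(x)/(1-e(x)) * P(T=0)/P(T=1)`` -- the treated
    sample stays unweighted under this convention.

    ``truncate_percentile``, if given (e.g. 99), symmetrically caps weights
    at that percentile and its complement; off by default.
    """
    estimand = Estimand(estimand)
    e = fit.fitted_scores
    t = np.asarray(treated, dtype=float)
    if e.shape != t.shape:
        raise ValueError("treated indicator must align with fitted scores")
    pt = fit.marginal_treated

    bad = (e <= 0.0) | (e >= 1.0)
    if np.any(bad):
        raise WeightOverflowError(
            f"propensity score numerically 0 or 1 for record(s) "
            f"{np.flatnonzero(bad)[:5].tolist()}"
        )

    if estimand is Estimand.ATE:
        w = np.where(t == 1.0, pt / e, (1.0 - pt) / (1.0 - e))
    else:
        odds = e / (1.0 - e)
        w = np.where(t == 1.0, 1.0, odds * (1.0 - pt) / pt)

    if truncate_percentile is not None:
        lo, hi = np.percentile(
            w, [100.0 - truncate_percentile, truncate_percentile]
        )
        w = np.clip(w, lo, hi)
    return WeightVector(estimand=estimand, weights=w)


# --------------------------------------------------------------------------
# balance diagnostics
# --------------------------------------------------------------------------

def _weighted_moments(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    sw = w.sum()
    if sw <= 0:
        raise DiagnosticsError("zero total weight in one arm")
    m = float(np.sum(w * x) / sw)
    v = float(np.sum(w * (x - m) ** 2) / sw)
    return m, v


def weighted_smd(
    ipd: pd.DataFrame, weights: WeightVector | np.ndarray, covariate: str
) -> float:
    """Weighted standardized mean difference (EDSL minus EDCSI).

    Binary covariates use the pooled proportion variance
    ``sqrt[(p1(1-p1)+p0(1-p0))/2]``; continuous ones the pooled weighted
    variance.  Returns 0 when the pooled spread vanishes but the means
    agree.
    """
    w = weights.weights if isinstance(weights, WeightVector) else np.asarray(weights)
    x = covariate_matrix(ipd)
    if covariate not in x.columns:
        raise KeyError(f"unknown covariate {covariate!r}")
    v = x[covariate].to_numpy(dtype=float)
    t = treatment_indicator(ipd).astype(bool)

    m1, s1 = _weighted_moments(v[t], w[t])
    m0, s0 = _weighted_moments(v[~t], w[~t])
    if covariate == "nihss":
        denom = np.sqrt((s1 + s0) / 2.0)
    else:
        denom = np.sqrt((m1 * (1 - m1) + m0 * (1 - m0)) / 2.0)
    if denom == 0.0:
        return 0.0
    return (m1 - m0) / denom


def balance_report(
    ipd: pd.DataFrame, weights: WeightVector, threshold: float = 0.1
) -> BalanceReport:
    """SMDs for all 13 covariates before (unit weights) and after
    weighting, plus the weighted chi-square test on the full mRS table."""
    unit = np.ones(len(ipd))
    before = {c: weighted_smd(ipd, unit, c) for c in BALANCE_COVARIATES}
    after = {
        c: weighted_smd(ipd, weights, c) for c in BALANCE_COVARIATES
    }
    flags = {c: abs(after[c]) < threshold for c in BALANCE_COVARIATES}

    counts = {}
    ess = {}
    arm_label = ipd["arm"].to_numpy()
    observed = pd.notna(ipd["mrs90"].to_numpy(dtype=object))
    for arm in ("EDSL", "EDCSI"):
        counts[arm] = weighted_mrs_counts(ipd, weights, arm)
        ess[arm] = kish_ess(weights.weights[(arm_label == arm) & observed])
    stat, p = weighted_chisq_test(
        counts["EDSL"], counts["EDCSI"], ess["EDSL"], ess["EDCSI"]
    )
    return BalanceReport(
        smd_before=before,
        smd_after=after,
        balanced_after=flags,
        chisq_statistic=stat,
        chisq_pvalue=p,
    )


# --------------------------------------------------------------------------
# weighted outcome distributions
# --------------------------------------------------------------------------

def weighted_mrs_counts(
    ipd: pd.DataFrame, weights: WeightVector | np.ndarray, arm: str
) -> np.ndarray:
    """Weighted counts over mRS 0-6 among observed outcomes in one arm,
    paired with the arm's weights (index 7 of the return is NOT used; the
    vector has exactly 7 entries)."""
    w = weights.weights if isinstance(weights, WeightVector) else np.asarray(weights)
    in_arm = ipd["arm"].to_numpy() == arm
    if not in_arm.any():
        raise EstimationError(f"arm {arm!r} not present")
    mrs = ipd["mrs90"].to_numpy(dtype=object)
    observed = in_arm & pd.notna(mrs)
    counts = np.zeros(N_MRS_LEVELS)
    np.add.at(counts, mrs[observed].astype(int), w[observed])
    return counts


def weighted_mrs_distribution(
    ipd: pd.DataFrame, weights: WeightVector | np.ndarray, arm: str
) -> MRSDistribution:
    """Weighted day-90 mRS distribution for one arm.

    Missing outcomes are redistributed proportionally over the observed
    weighted distribution, which is exactly renormalizing the observed
    distribution to one.
    """
    counts = weighted_mrs_counts(ipd, weights, arm)
    total = counts.sum()
    if total <= 0:
        raise EstimationError(f"all outcomes missing in arm {arm!r}")
    return MRSDistribution(p=counts / total)


def kish_ess(w: np.ndarray) -> float:
    """Kish effective sample size (sum w)^2 / sum w^2."""
    w = np.asarray(w, dtype=float)
    denom = np.sum(w**2)
    return float(np.sum(w) ** 2 / denom) if denom > 0 else 0.0


def weighted_chisq_test(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    ess_a: float | None = None,
    ess_b: float | None = None,
) -> tuple[float, float]:
    """Pearson chi-square on weighted category counts.

    ``ess_a``/``ess_b`` carry each arm's Kish effective sample size
    computed from its patient weights; each arm's counts are rescaled to
    that total so the statistic reflects the precision actually present in
    the weighted sample.  With no ESS given the counts are used at their
    own total, which for unit weights is the classical Pearson test.  No
    continuity correction is applied.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("count vectors must have equal length")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("weighted counts must be non-negative")
    if a.sum() <= 0 or b.sum() <= 0:
        raise ValueError("each arm needs positive total weighted count")

    a_scaled = a / a.sum() * (a.sum() if ess_a is None else ess_a)
    b_scaled = b / b.sum() * (b.sum() if ess_b is None else ess_b)
    table = np.vstack([a_scaled, b_scaled])
    keep = table.sum(axis=0) > 0  # empty categories carry no information
    table = table[:, keep]
    if table.shape[1] < 2 or np.allclose(
        table[0] / table[0].sum(), table[1] / table[1].sum(), atol=1e-14
    ):
        return 0.0, 1.0
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


# --------------------------------------------------------------------------
# one-call pipeline stage
# --------------------------------------------------------------------------

def weighted_day90_distributions(
    ipd: pd.DataFrame, estimand: Estimand | str = Estimand.ATE
) -> tuple[MRSDistribution, MRSDistribution, BalanceReport]:
    """Full weighting stage: exclusion, propensity fit, stabilized weights,
    balance report, and the two weighted day-90 mRS distributions
    (EDSL first)."""
    clean = exclude_missing_covariates(ipd)
    fit = fit_propensity(clean)
    wv = compute_weights(fit, estimand, treatment_indicator(clean))
    report = balance_report(clean, wv)
    dist_edsl = weighted_mrs_distribution(clean, wv, "EDSL")
    dist_edcsi = weighted_mrs_distribution(clean, wv, "EDCSI")
    return dist_edsl, dist_edcsi, report
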