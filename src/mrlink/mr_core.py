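"""Causal-effect estimators for harmonized two-sample MR instrument sets.

Given J harmonized instruments with exposure effects ``beta_x`` (SE
``se_x``) and outcome effects ``beta_y`` (SE ``se_y``), the per-variant
Wald ratio is ``theta_j = beta_y_j / beta_x_j`` with first-order standard
error ``se_y_j / |beta_x_j|`` (exposure-side uncertainty ignored, the
convention that makes IVW coincide with weighted least squares of the
outcome betas on the exposure betas through the origin).

Estimators
----------
- :func:`ivw` — inverse-variance weighted mean of the Wald ratios, with
  fixed-effect or multiplicative random-effects (MRE) standard errors.
- :func:`weighted_median` — weighted 50th percentile of the ordered
  ratios; consistent when at least half the instrument weight is valid.
  SE by seeded parametric bootstrap.
- :func:`egger` — weighted regression of ``beta_y`` on ``beta_x`` with a
  free intercept: the intercept estimates average directional pleiotropy
  and the slope is a pleiotropy-adjusted causal estimate.
- :func:`cochran_q` — Cochran's Q and I² heterogeneity of the ratios.

All betas are per exposure unit (per SD for continuous exposures, per
unit log-odds for binary ones); ``exp(beta)`` is the odds ratio for a
binary outcome.  Confidence intervals use the fixed multiplier 1.96 so
OR-scale intervals round-trip from printed tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .gwas_summary import HarmonizedInstrument

__all__ = [
    "RatioEstimate",
    "MREstimate",
    "EstimatorError",
    "wald_ratio",
    "ivw",
    "weighted_median",
    "egger",
    "cochran_q",
]

Z95 = 1.96  # fixed so printed OR/CI pairs reconstruct exactly


class EstimatorError(ValueError):
    """Too few or degenerate instruments for the requested estimator."""


@dataclass(frozen=True)
class RatioEstimate:
    """Single-variant Wald ratio estimate with inverse-variance weight."""

    variant_id: str
    theta: float
    se_theta: float
    weight: float


@dataclass(frozen=True)
class MREstimate:
    """A causal estimate on the log scale with its OR-scale derivations.

    ``q_stat``, ``i2`` and ``q_pvalue`` are attached by estimators that
    compute heterogeneity and are ``None`` otherwise.
    """

    method: str
    beta: float
    se: float
    pvalue: float
    n_snp: int
    q_stat: float | None = None
    i2: float | None = None
    q_pvalue: float | None = None

    @property
    def ci_low(self) -> float:
        return self.beta - Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.beta + Z95 * self.se

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))


def _arrays(hs: Sequence[HarmonizedInstrument]):
    bx = np.array([h.beta_x for h in hs], dtype=float)
    sx = np.array([h.se_x for h in hs], dtype=float)
    by = np.array([h.beta_y for h in hs], dtype=float)
    sy = np.array([h.se_y for h in hs], dtype=float)
    return bx, sx, by, sy


def wald_ratio(h: HarmonizedInstrument) -> RatioEstimate:
    """Per-variant causal estimate: outcome beta over exposure beta.

    Uses the first-order standard error ``se_y / |beta_x|``; the exposure
    estimate is treated as fixed.
    """
    if h.beta_x == 0:
        raise EstimatorError(f"{h.variant_id}: beta_x = 0, Wald ratio undefined")
    theta = h.beta_y / h.beta_x
    se = h.se_y / abs(h.beta_x)
    return RatioEstimate(h.variant_id, theta, se, 1.0 / se**2)


def _ratio_arrays(hs: Sequence[HarmonizedInstrument]):
    est = [wald_ratio(h) for h in hs]
    theta = np.array([e.theta for e in est])
    w = np.array([e.weight for e in est])
    return theta, w


def ivw(hs: Sequence[HarmonizedInstrument], model: str = "mre") -> MREstimate:
    """Inverse-variance weighted estimate over the Wald ratios.

    ``beta = sum(w_j * theta_j) / sum(w_j)`` with ``w_j = 1/se_theta_j^2``.
    The fixed-effect SE is ``(sum w_j)^{-1/2}``; under multiplicative
    random effects (``model="mre"``) it is inflated by
    ``max(1, sqrt(Q/(J-1)))`` so over-dispersion widens the interval but
    under-dispersion never shrinks it below the fixed-effect SE.  The
    point estimate is identical under both models.
    """
    if model not in ("fixed", "mre"):
        raise ValueError(f"unknown IVW model {model!r}")
    n = len(hs)
    if n < 1 or (model == "mre" and n < 2):
        raise EstimatorError(f"ivw[{model}] needs >= {2 if model == 'mre' else 1} instruments, got {n}")
    theta, w = _ratio_arrays(hs)
    beta = float(np.sum(w * theta) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    q = i2 = qp = None
    if n >= 2:
        q, i2, qp = cochran_q(hs)
        if model == "mre":
            se *= max(1.0, np.sqrt(q / (n - 1)))
    p = float(2 * stats.norm.sf(abs(beta) / se))
    return MREstimate(f"ivw_{'fe' if model == 'fixed' else 'mre'}",
                      beta, se, p, n, q, i2, qp)


def _weighted_median_point(theta: np.ndarray, w: np.ndarray) -> float:
    # cumulative standardized weights; linear interpolation at the 0.5 crossing
    order = np.argsort(theta, kind="stable")
    th = theta[order]
    ww = w[order]
    s = (np.cumsum(ww) - 0.5 * ww) / np.sum(ww)
    return float(np.interp(0.5, s, th))


def weighted_median(
    hs: Sequence[HarmonizedInstrument],
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    The point estimate is the weighted 50th percentile of the ordered Wald
    ratios (cumulative standardized weights ``s_j = (sum_{i<=j} w_i -
    w_j/2)/sum(w_i)``, linear interpolation at ``s = 0.5``).  It is a
    consistent causal estimate when instruments carrying at least 50% of
    the weight are valid.  The SE is the standard deviation of the point
    estimate over ``n_boot`` parametric resamples of ``(beta_x, beta_y)``
    from their normal sampling distributions; ``seed`` makes it
    reproducible.
    """
    n = len(hs)
    if n < 3:
        raise EstimatorError(f"weighted median needs >= 3 instruments, got {n}")
    theta, w = _ratio_arrays(hs)
    beta = _weighted_median_point(theta, w)

    bx, sx, by, sy = _arrays(hs)
    rng = np.random.default_rng(seed)
    bxs = rng.normal(bx, sx, size=(n_boot, n))
    bys = rng.normal(by, sy, size=(n_boot, n))
    boots = np.empty(n_boot)
    for k in range(n_boot):
        th = bys[k] / bxs[k]
        wk = (bxs[k] / sy) ** 2
        boots[k] = _weighted_median_point(th, wk)
    se = float(np.std(boots, ddof=1))
    p = float(2 * stats.norm.sf(abs(beta) / se)) if se > 0 else (1.0 if beta == 0 else 0.0)
    return MREstimate("weighted_median", beta, se, p, n)


def egger(
    hs: Sequence[HarmonizedInstrument], model: str = "mre"
) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression: slope (causal) and intercept (pleiotropy).

    Weighted linear regression of ``beta_y`` on ``beta_x`` with a free
    intercept and weights ``1/se_y^2``.  Requires the exposure-increasing
    orientation enforced by harmonization (all ``beta_x >= 0``).  Under
    ``model="mre"`` both SEs are scaled by ``max(1,
    sqrt(RSS_w/(J-2)))``; p-values use the t distribution with J-2
    degrees of freedom.
    """
    if model not in ("fixed", "mre"):
        raise ValueError(f"unknown Egger model {model!r}")
    n = len(hs)
    if n < 3:
        raise EstimatorError(f"MR-Egger needs >= 3 instruments, got {n}")
    bx, sx, by, sy = _arrays(hs)
    if np.ptp(bx) == 0:
        raise EstimatorError("MR-Egger undefined: zero spread in exposure betas")
    w = 1.0 / sy**2
    # closed-form weighted least squares with intercept
    W = np.sum(w)
    mx = np.sum(w * bx) / W
    my = np.sum(w * by) / W
    sxx = np.sum(w * (bx - mx) ** 2)
    sxy = np.sum(w * (bx - mx) * (by - my))
    slope = sxy / sxx
    intercept = my - slope * mx
    resid = by - intercept - slope * bx
    rss_w = np.sum(w * resid**2)
    scale = max(1.0, np.sqrt(rss_w / (n - 2))) if model == "mre" else 1.0
    se_slope = scale / np.sqrt(sxx)
    se_int = scale * np.sqrt(1.0 / W + mx**2 / sxx)
    df = n - 2
    p_slope = float(2 * stats.t.sf(abs(slope) / se_slope, df))
    p_int = float(2 * stats.t.sf(abs(intercept) / se_int, df))
    return (
        MREstimate("egger_slope", float(slope), float(se_slope), p_slope, n),
        MREstimate("egger_intercept", float(intercept), float(se_int), p_int, n),
    )


def cochran_q(hs: Sequence[HarmonizedInstrument]) -> tuple[float, float, float]:
    """Cochran's Q, I² (percent) and the chi-square heterogeneity p-value.

    ``Q = sum w_j (theta_j - theta_IVW)^2`` about the fixed-effect IVW
    mean; ``I² = max(0, (Q - (J-1))/Q) * 100``; p from chi-square with
    J-1 degrees of freedom.  Returns ``(nan, nan, nan)``-free values only
    for J >= 2; callers with a single instrument should not ask.
    """
    n = len(hs)
    if n < 2:
        raise EstimatorError("heterogeneity needs >= 2 instruments")
    theta, w = _ratio_arrays(hs)
    mean = np.sum(w * theta) / np.sum(w)
    q = float(np.sum(w * (theta - mean) ** 2))
    i2 = float(max(0.0, (q - (n - 1)) / q) * 100) if q > 0 else 0.0
    p = float(stats.chi2.sf(q, n - 1))
    return q, i2, p
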