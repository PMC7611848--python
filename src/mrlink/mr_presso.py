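"""MR-PRESSO: pleiotropy residual sum and outlier test.

Horizontal pleiotropy inflates the residuals of outcome effects about the
causal line.  MR-PRESSO quantifies this with a leave-one-out residual sum
of squares (RSS) compared against a parametric null:

- **global test** (:func:`presso_global`): for each instrument j the
  leave-one-out fixed-effect IVW slope ``theta_{-j}`` predicts
  ``beta_y_j``; the observed RSS of the standardized residuals is compared
  to ``n_sim`` simulated datasets drawn under no pleiotropy, giving an
  empirical p-value with add-one smoothing (so p is never 0 and is floored
  at ``1/(n_sim+1)``).
- **outlier test** (:func:`presso_outliers`): each instrument's observed
  squared residual is compared against its own simulated residuals;
  Bonferroni-adjusted p-values below ``alpha`` flag outliers, but only
  when the global test itself rejects.
- **corrected estimate** (:func:`presso_corrected`): IVW re-run on the
  non-outlier instruments.
- **distortion test** (:func:`presso_distortion`): the percent change of
  the all-instrument estimate relative to the corrected one, with an
  empirical null built from random outlier sets of the same size.

All randomness is driven by an explicit seed; a rerun with the same seed
and inputs is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .gwas_summary import HarmonizedInstrument
from .mr_core import EstimatorError, MREstimate, ivw

__all__ = [
    "PressoNotApplicable",
    "PressoNull",
    "PressoResult",
    "presso_global",
    "presso_outliers",
    "presso_corrected",
    "presso_distortion",
    "run_presso",
]


class PressoNotApplicable(ValueError):
    """Raised when fewer than 4 instruments are available; callers skip."""


@dataclass
class PressoNull:
    """The simulated null machinery shared by the global and outlier tests."""

    rss_obs: float
    global_pvalue: float
    rss_sim: np.ndarray          # (n_sim,)
    resid_obs_sq: np.ndarray     # (J,) standardized squared residuals
    resid_sim_sq: np.ndarray     # (n_sim, J)
    n_sim: int
    seed: int


@dataclass
class PressoResult:
    """Full MR-PRESSO output for one instrument set."""

    global_pvalue: float
    rss_obs: float
    outlier_pvalues: np.ndarray  # Bonferroni-adjusted, capped at 1
    outlier_ids: list[str]
    corrected: MREstimate | None
    distortion_coef: float | None
    distortion_pvalue: float | None
    n_sim: int
    seed: int


def _loo_slopes(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effect IVW slopes, vectorized.

    The fixed-effect IVW estimate equals weighted least squares of the
    outcome betas on the exposure betas through the origin with weights
    1/se_y^2, so each LOO slope is a ratio of rank-one-downdated sums.
    """
    w = 1.0 / sy**2
    s_xy = np.sum(w * bx * by)
    s_xx = np.sum(w * bx**2)
    return (s_xy - w * bx * by) / (s_xx - w * bx**2)


def _rss_and_residuals(bx, by, sy):
    theta_loo = _loo_slopes(bx, by, sy)
    resid = by - theta_loo * bx
    resid_sq = resid**2 / sy**2
    return float(np.sum(resid_sq)), resid_sq, theta_loo


def presso_global(
    hs: Sequence[HarmonizedInstrument],
    n_sim: int = 1000,
    seed: int = 0,
) -> PressoNull:
    """Global heterogeneity test: observed vs simulated leave-one-out RSS.

    Simulated datasets redraw ``beta_x* ~ N(beta_x_j, se_x_j^2)`` and
    ``beta_y* ~ N(theta_{-j} * beta_x_j, se_y_j^2)`` — the no-pleiotropy
    expectation — and the RSS is recomputed identically (including the
    leave-one-out slopes) on each.  ``global_pvalue = (1 + #{RSS* >=
    RSS_obs}) / (n_sim + 1)``.
    """
    n = len(hs)
    if n < 4:
        raise PressoNotApplicable(f"MR-PRESSO needs >= 4 instruments, got {n}")
    bx = np.array([h.beta_x for h in hs])
    sx = np.array([h.se_x for h in hs])
    by = np.array([h.beta_y for h in hs])
    sy = np.array([h.se_y for h in hs])

    rss_obs, resid_obs_sq, theta_loo = _rss_and_residuals(bx, by, sy)

    rng = np.random.default_rng(seed)
    bxs = rng.normal(bx, sx, size=(n_sim, n))
    bys = rng.normal(theta_loo * bx, sy, size=(n_sim, n))

    w = 1.0 / sy**2
    s_xy = np.sum(w * bxs * bys, axis=1, keepdims=True)
    s_xx = np.sum(w * bxs**2, axis=1, keepdims=True)
    theta_loo_sim = (s_xy - w * bxs * bys) / (s_xx - w * bxs**2)
    resid_sim_sq = (bys - theta_loo_sim * bxs) ** 2 / sy**2
    rss_sim = np.sum(resid_sim_sq, axis=1)

    p = (1 + int(np.sum(rss_sim >= rss_obs))) / (n_sim + 1)
    return PressoNull(rss_obs, p, rss_sim, resid_obs_sq, resid_sim_sq, n_sim, seed)


def presso_outliers(
    hs: Sequence[HarmonizedInstrument],
    null: PressoNull,
    alpha: float = 0.05,
) -> tuple[np.ndarray, list[str]]:
    """Per-instrument outlier test using the global test's null sample.

    Each instrument's p-value is the add-one-smoothed fraction of its own
    simulated squared residuals at or above the observed one, multiplied
    by J (Bonferroni) and capped at 1.  Outliers are declared only when
    the global test rejects at 0.05 — under homogeneity no instrument is
    removed regardless of its marginal p-value.
    """
    n = len(hs)
    exceed = np.sum(null.resid_sim_sq >= null.resid_obs_sq, axis=0)
    p_raw = (1 + exceed) / (null.n_sim + 1)
    p_adj = np.minimum(1.0, p_raw * n)
    if null.global_pvalue >= 0.05:
        return p_adj, []
    ids = [hs[j].variant_id for j in range(n) if p_adj[j] < alpha]
    return p_adj, ids


def presso_corrected(
    hs: Sequence[HarmonizedInstrument],
    outlier_ids: Sequence[str],
    model: str = "mre",
) -> MREstimate:
    """IVW on the non-outlier subset, tagged ``presso_corrected``."""
    keep = [h for h in hs if h.variant_id not in set(outlier_ids)]
    if len(keep) < 2:
        raise EstimatorError(
            f"only {len(keep)} instruments remain after outlier removal")
    est = ivw(keep, model=model)
    return MREstimate("presso_corrected", est.beta, est.se, est.pvalue,
                      est.n_snp, est.q_stat, est.i2, est.q_pvalue)


def presso_distortion(
    beta_all: float,
    beta_corrected: float,
    hs: Sequence[HarmonizedInstrument],
    outlier_ids: Sequence[str],
    n_boot: int = 1000,
    seed: int = 0,
    model: str = "mre",
) -> tuple[float, float]:
    """Distortion test: does outlier removal change the estimate?

    The coefficient is ``100 * (beta_all - beta_corrected) /
    |beta_corrected|`` (percent).  Its null distribution is built by
    removing ``len(outlier_ids)`` instruments at random ``n_boot`` times
    and recomputing the coefficient; the two-sided empirical p-value is
    add-one smoothed.
    """
    if not outlier_ids:
        raise ValueError("distortion test requires a non-empty outlier set")
    if beta_corrected == 0:
        raise ZeroDivisionError("distortion coefficient undefined: corrected beta is 0")
    coef = 100.0 * (beta_all - beta_corrected) / abs(beta_corrected)

    n = len(hs)
    k = len(outlier_ids)
    if n - k < 2:
        raise EstimatorError("too few instruments for the distortion null")
    rng = np.random.default_rng(seed)
    null_coefs = np.empty(n_boot)
    idx = np.arange(n)
    for b in range(n_boot):
        drop = set(rng.choice(idx, size=k, replace=False).tolist())
        sub = [hs[j] for j in range(n) if j not in drop]
        beta_sub = ivw(sub, model=model).beta
        if beta_sub == 0:
            null_coefs[b] = np.inf
        else:
            null_coefs[b] = 100.0 * (beta_all - beta_sub) / abs(beta_sub)
    p = (1 + int(np.sum(np.abs(null_coefs) >= abs(coef)))) / (n_boot + 1)
    return float(coef), float(p)


def run_presso(
    hs: Sequence[HarmonizedInstrument],
    n_sim: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    model: str = "mre",
    distortion: bool = True,
) -> PressoResult:
    """Full MR-PRESSO pass: global test, outliers, corrected estimate,
    distortion test.  ``corrected`` and the distortion statistics are
    ``None`` when no outlier is flagged."""
    null = presso_global(hs, n_sim=n_sim, seed=seed)
    p_adj, outlier_ids = presso_outliers(hs, null, alpha=alpha)
    corrected = None
    dist_coef = dist_p = None
    if outlier_ids:
        corrected = presso_corrected(hs, outlier_ids, model=model)
        beta_all = ivw(hs, model=model).beta
        if distortion and corrected.beta != 0:
            dist_coef, dist_p = presso_distortion(
                beta_all, corrected.beta, hs, outlier_ids,
                seed=seed + 1, model=model)
    return PressoResult(null.global_pvalue, null.rss_obs, p_adj, outlier_ids,
                        corrected, dist_coef, dist_p, n_sim, seed)
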