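"""Heterogeneity, pleiotropy, influence, and outlier diagnostics.

Cochran's Q against the fixed-effect pooled Wald ratio, the MR-Egger
intercept test for directional pleiotropy, leave-one-out influence
re-estimation, and the MR-PRESSO global/outlier test (simulation-based
residual-sum-of-squares comparison with leave-one-out slopes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import (
    EstimatorError,
    bonferroni_threshold,
    egger_fit,
    ivw_fit,
    significance_label,
    wald_ratio_arrays,
)
from .harmonization import HarmonizedSet

logger = logging.getLogger("mrkit")


@dataclass
class SensitivityReport:
    """Per-outcome sensitivity summary (heterogeneity, pleiotropy, influence)."""

    q: float
    q_df: int
    q_pval: float
    egger_intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None
    loo: pd.DataFrame | None = None
    loo_stable: bool | None = None
    presso_global_pval: float | None = None
    presso_outliers: list[str] = field(default_factory=list)

    @property
    def heterogeneous(self) -> bool:
        """Considerable heterogeneity: Q-derived p < 0.05."""
        return self.q_pval < 0.05


def cochran_q(h: HarmonizedSet) -> tuple[float, int, float]:
    """Cochran's Q over Wald ratios with fixed-effect inverse-variance weights."""
    if len(h) < 2:
        raise EstimatorError("Cochran's Q requires >= 2 instruments")
    bx, sx, by, sy = h.arrays()
    theta, se = wald_ratio_arrays(bx, sx, by, sy)
    w = 1.0 / se**2
    theta_fe = (w * theta).sum() / w.sum()
    q = float((w * (theta - theta_fe) ** 2).sum())
    df = theta.size - 1
    pval = float(stats.chi2.sf(q, df))
    return q, df, pval


def egger_intercept_test(h: HarmonizedSet) -> tuple[float, float, float]:
    """(intercept, se, p) from the MR-Egger fit; p < 0.05 flags pleiotropy."""
    bx, sx, by, sy = h.arrays()
    fit = egger_fit(bx, sx, by, sy)
    return fit.extra["intercept"], fit.extra["intercept_se"], fit.extra["intercept_pval"]


def leave_one_out(
    h: HarmonizedSet, alpha: float = 0.05, m: int = 1
) -> tuple[pd.DataFrame, bool]:
    """IVW re-estimated dropping each SNP in turn, with a stability verdict.

    The verdict is "stable" iff every leave-one-out estimate keeps both the
    direction and the significance class (significant / nominally
    significant / ns at the alpha/m and alpha lines) of the full-set IVW.
    """
    if len(h) < 3:
        raise EstimatorError("leave-one-out requires >= 3 instruments")
    bx, sx, by, sy = h.arrays()
    full = ivw_fit(bx, sx, by, sy)
    full_sign = np.sign(full.beta)
    full_class = significance_label(full.pval, alpha, m)
    rows, stable = [], True
    for i, rsid in enumerate(h.rsids):
        keep = np.arange(bx.size) != i
        fit = ivw_fit(bx[keep], sx[keep], by[keep], sy[keep])
        rows.append({"snp": rsid, "beta": fit.beta, "se": fit.se, "pval": fit.pval})
        if np.sign(fit.beta) != full_sign or significance_label(fit.pval, alpha, m) != full_class:
            stable = False
    return pd.DataFrame(rows), stable


def _loo_slopes(bx, by, w):
    """Leave-one-out fixed-effect slopes of by on bx through the origin.

    Vectorized over leading axes: bx/by may be (n_sim, L).
    """
    sxy = (w * bx * by).sum(axis=-1, keepdims=True)
    sxx = (w * bx * bx).sum(axis=-1, keepdims=True)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def mr_presso(
    h: HarmonizedSet,
    n_sim: int = 1000,
    seed: int | None = None,
    outlier_alpha: float = 0.05,
) -> tuple[float, list[str]]:
    """MR-PRESSO global test and outlier detection.

    The observed statistic is the weighted residual sum of squares
    sum_j w_j (beta_Yj - theta_(-j) beta_Xj)^2 with w_j = 1/sigma_Yj^2 and
    theta_(-j) the leave-one-out IVW slope.  Its null distribution comes
    from ``n_sim`` parametric draws beta*_Xj ~ N(beta_Xj, sigma_Xj),
    beta*_Yj ~ N(theta_(-j) beta_Xj, sigma_Yj) with the statistic (and its
    leave-one-out slopes) recomputed on each draw.  The global p is the
    fraction of simulated statistics >= observed; per-SNP outlier p-values
    are the analogous per-SNP fractions, Bonferroni-corrected by L, flagged
    below ``outlier_alpha``.
    """
    if len(h) < 4:
        raise EstimatorError("insufficient instruments for MR-PRESSO (need >= 4)")
    if seed is None:
        raise EstimatorError("MR-PRESSO requires an explicit seed")
    bx, sx, by, sy = h.arrays()
    global_pval, idx = mr_presso_arrays(bx, sx, by, sy, n_sim, seed, outlier_alpha)
    outliers = [h.rsids[i] for i in idx]
    if outliers:
        logger.info("MR-PRESSO outliers: %s", ", ".join(outliers))
    return global_pval, outliers


def mr_presso_arrays(
    bx, sx, by, sy, n_sim: int, seed, outlier_alpha: float = 0.05
) -> tuple[float, np.ndarray]:
    """Array-level MR-PRESSO; returns (global p, outlier indices).

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    bx, sx = np.asarray(bx, float), np.asarray(sx, float)
    by, sy = np.asarray(by, float), np.asarray(sy, float)
    L = bx.size
    w = 1.0 / sy**2

    theta_loo = _loo_slopes(bx[None, :], by[None, :], w)[0]
    obs_terms = w * (by - theta_loo * bx) ** 2
    obs_rss = float(obs_terms.sum())

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bx_s = rng.normal(bx, sx, size=(n_sim, L))
    by_s = rng.normal(theta_loo * bx, sy, size=(n_sim, L))
    loo_s = _loo_slopes(bx_s, by_s, w)
    terms_s = w * (by_s - loo_s * bx_s) ** 2
    rss_s = terms_s.sum(axis=1)

    global_pval = float(np.mean(rss_s >= obs_rss))
    p_snp = np.mean(terms_s >= obs_terms, axis=0)
    p_corr = np.minimum(1.0, p_snp * L)
    return global_pval, np.where(p_corr < outlier_alpha)[0]


def run_sensitivity(
    h: HarmonizedSet,
    seed: int,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    alpha: float = 0.05,
    m: int = 1,
) -> SensitivityReport:
    """Full sensitivity suite on one harmonized set."""
    q, df, q_p = cochran_q(h)
    report = SensitivityReport(q=q, q_df=df, q_pval=q_p)
    if len(h) >= 3:
        report.egger_intercept, report.intercept_se, report.intercept_pval = (
            egger_intercept_test(h)
        )
        report.loo, report.loo_stable = leave_one_out(h, alpha=alpha, m=m)
    if len(h) >= 4:
        report.presso_global_pval, report.presso_outliers = mr_presso(
            h, n_sim=n_sim, seed=seed, outlier_alpha=outlier_alpha
        )
    return report
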