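"""Causal-effect estimators for two-sample MR on harmonized summary data.

Five complementary estimators of the causal log-odds ratio theta from
per-SNP effects (beta_Xj, sigma_Xj) on the exposure and (beta_Yj, sigma_Yj)
on the outcome:

* **IVW** — inverse-variance-weighted mean of Wald ratios
  theta_j = beta_Yj / beta_Xj, equivalently weighted regression of beta_Y
  on beta_X through the origin; the multiplicative random-effects standard
  error inflates the fixed-effect one by max(1, sqrt(Q/(L-1))), never
  narrowing it.
* **MR-Egger** — weighted regression with a free intercept after orienting
  all SNPs to beta_X > 0; the intercept estimates directional pleiotropy,
  the slope the causal effect (consistent under InSIDE).
* **Weighted median** — interpolated 0.5-quantile of the Wald ratios under
  inverse-variance weights; consistent when >= 50% of weight is on valid
  instruments.  Standard error by parametric bootstrap.
* **Maximum likelihood** — profile likelihood of the bivariate normal
  measurement model beta_Xj ~ N(gamma_j, sigma_Xj²),
  beta_Yj ~ N(theta·gamma_j, sigma_Yj²), nuisance means profiled out.
* **RAPS** — profile likelihood with an overdispersion component tau² >= 0
  absorbing balanced pleiotropy, robust to many weak instruments.

Each returns an :class:`MREstimate` carrying beta/se/p plus the odds-ratio
scale (OR = exp(beta), 95% CI = exp(beta ± 1.959964·se)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import optimize, stats

from .harmonization import HarmonizedSet

Z95 = 1.959964  # two-sided 95% normal quantile


class EstimatorError(Exception):
    pass


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate with odds-ratio-scale reporting."""

    method: str
    beta: float
    se: float
    pval: float
    or_: float
    ci_low: float
    ci_high: float
    n_snps: int
    extra: dict = field(default_factory=dict)


class FitResult(NamedTuple):
    beta: float
    se: float
    pval: float
    extra: dict


def to_odds_ratio(beta: float, se: float) -> tuple[float, float, float]:
    """(OR, CI low, CI high) from a log-odds estimate and its standard error."""
    if se < 0:
        raise EstimatorError("se must be non-negative")
    return float(np.exp(beta)), float(np.exp(beta - Z95 * se)), float(np.exp(beta + Z95 * se))


def bonferroni_threshold(alpha: float = 0.05, m: int = 1) -> float:
    """Family-wise significance threshold alpha/m."""
    if m < 1:
        raise EstimatorError("number of tests m must be >= 1")
    return alpha / m


def significance_label(pval: float, alpha: float = 0.05, m: int = 1) -> str:
    """'significant' below alpha/m, 'nominally significant' below alpha, else 'ns'."""
    thresh = bonferroni_threshold(alpha, m)
    if pval < thresh:
        return "significant"
    if pval < alpha:
        return "nominally significant"
    return "ns"


def _estimate(method: str, fit: FitResult, n_snps: int) -> MREstimate:
    or_, lo, hi = to_odds_ratio(fit.beta, fit.se)
    return MREstimate(
        method=method, beta=float(fit.beta), se=float(fit.se), pval=float(fit.pval),
        or_=or_, ci_low=lo, ci_high=hi, n_snps=n_snps, extra=fit.extra,
    )


# ---------------------------------------------------------------------------
# array-level fits (fast path shared by the simulation studies)
# ---------------------------------------------------------------------------

def wald_ratio_arrays(bx, sx, by, sy) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP ratio estimates theta_j = by/bx, se_j = sy/|bx| (delta method)."""
    bx = np.asarray(bx, float)
    if np.any(bx == 0):
        raise EstimatorError("beta_X = 0: Wald ratio undefined")
    return np.asarray(by, float) / bx, np.asarray(sy, float) / np.abs(bx)


def ivw_fit(bx, sx, by, sy) -> FitResult:
    theta, se_j = wald_ratio_arrays(bx, sx, by, sy)
    w = 1.0 / se_j**2
    sw = w.sum()
    beta = float((w * theta).sum() / sw)
    L = theta.size
    q = float((w * (theta - beta) ** 2).sum())
    scale = max(1.0, np.sqrt(q / (L - 1))) if L > 1 else 1.0
    se = float(np.sqrt(1.0 / sw) * scale)
    pval = float(2 * stats.norm.sf(abs(beta) / se)) if se > 0 else 0.0
    return FitResult(beta, se, pval, {"q": q, "q_df": L - 1, "scale": scale})


def egger_fit(bx, sx, by, sy) -> FitResult:
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    sy = np.asarray(sy, float)
    L = bx.size
    if L < 3:
        raise EstimatorError("Egger requires >= 3 instruments")
    # orient so every SNP's exposure effect is positive
    s = np.sign(bx)
    if np.any(s == 0):
        raise EstimatorError("beta_X = 0: cannot orient for Egger")
    x, y, w = np.abs(bx), s * by, 1.0 / sy**2
    sw, swx, swxx = w.sum(), (w * x).sum(), (w * x * x).sum()
    swy, swxy = (w * y).sum(), (w * x * y).sum()
    det = sw * swxx - swx**2
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    resid = y - intercept - slope * x
    df = L - 2
    phi = float((w * resid**2).sum() / df)
    scale = max(1.0, np.sqrt(phi))
    se_slope = float(np.sqrt(sw / det) * scale)
    se_int = float(np.sqrt(swxx / det) * scale)
    p_slope = float(2 * stats.t.sf(abs(slope) / se_slope, df))
    p_int = float(2 * stats.t.sf(abs(intercept) / se_int, df))
    return FitResult(
        float(slope), se_slope, p_slope,
        {
            "intercept": float(intercept), "intercept_se": se_int,
            "intercept_pval": p_int, "residual_scale": scale, "df": df,
        },
    )


def _weighted_median_rows(thetas: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Interpolated weighted median of each row of ``thetas`` with shared weights."""
    thetas = np.atleast_2d(thetas)
    order = np.argsort(thetas, axis=1)
    b = np.take_along_axis(thetas, order, axis=1)
    ww = np.broadcast_to(w, thetas.shape)
    ww = np.take_along_axis(ww, order, axis=1)
    p = (np.cumsum(ww, axis=1) - 0.5 * ww) / ww.sum(axis=1, keepdims=True)
    out = np.empty(thetas.shape[0])
    for i in range(thetas.shape[0]):
        out[i] = np.interp(0.5, p[i], b[i])
    return out


def weighted_median_fit(bx, sx, by, sy, n_boot: int = 1000, seed: int | None = None) -> FitResult:
    theta, se_j = wald_ratio_arrays(bx, sx, by, sy)
    if theta.size < 3:
        raise EstimatorError("weighted median requires >=3 instruments")
    if seed is None:
        raise EstimatorError("weighted median bootstrap requires an explicit seed")
    w = 1.0 / se_j**2
    beta = float(_weighted_median_rows(theta, w)[0])
    rng = np.random.default_rng(seed)
    draws = rng.normal(theta, se_j, size=(n_boot, theta.size))
    boots = _weighted_median_rows(draws, w)
    se = float(boots.std(ddof=1))
    pval = float(2 * stats.norm.sf(abs(beta) / se)) if se > 0 else 0.0
    return FitResult(beta, se, pval, {"n_boot": n_boot})


def _profile_nll(t, bx, sx, by, sy, tau2=0.0):
    v = sy**2 + t * t * sx**2 + tau2
    return 0.5 * np.sum((by - t * bx) ** 2 / v)


def _curvature_se(f, x0: float) -> float:
    h = 1e-5 * (1.0 + abs(x0))
    d2 = (f(x0 + h) - 2.0 * f(x0) + f(x0 - h)) / h**2
    if d2 <= 0:
        raise EstimatorError("non-positive curvature at optimum")
    return float(1.0 / np.sqrt(d2))


def max_likelihood_fit(bx, sx, by, sy, xtol: float = 1e-10, maxiter: int = 10_000) -> FitResult:
    """Profile-likelihood MLE with per-SNP nuisance means profiled out.

    Profiling gamma_j gives l(theta) = -1/2 sum (by - theta·bx)² /
    (sy² + theta²·sx²); the standard error comes from the numeric curvature
    at the optimum.
    """
    bx, sx = np.asarray(bx, float), np.asarray(sx, float)
    by, sy = np.asarray(by, float), np.asarray(sy, float)
    t0 = ivw_fit(bx, sx, by, sy).beta
    res = optimize.minimize_scalar(
        _profile_nll, args=(bx, sx, by, sy),
        bracket=(t0 - 0.5, t0 + 0.5),
        method="brent", options={"xtol": xtol, "maxiter": maxiter},
    )
    if not res.success:
        raise EstimatorError(f"ML optimizer failed: {res}")
    beta = float(res.x)
    se = _curvature_se(lambda t: _profile_nll(t, bx, sx, by, sy), beta)
    pval = float(2 * stats.norm.sf(abs(beta) / se))
    return FitResult(beta, se, pval, {"nll": float(res.fun)})


def raps_fit(
    bx, sx, by, sy,
    overdispersion: bool = True,
    seed: int | None = None,
    tol: float = 1e-10,
    maxiter: int = 10_000,
) -> FitResult:
    """Robust-adjusted-profile-score estimate with optional overdispersion.

    Maximizes the profile likelihood of the model beta_Yj ~ N(theta·gamma_j,
    sigma_Yj² + tau²), beta_Xj ~ N(gamma_j, sigma_Xj²) after profiling the
    gamma_j:

        l(theta, tau²) = -1/2 sum [ (by - theta·bx)² / (sy² + tau² + theta²·sx²)
                                    + log(sy² + tau²) ]

    tau² >= 0 absorbs balanced horizontal pleiotropy; a boundary solution
    tau² = 0 is reported, not an error.  ``seed`` is accepted for interface
    symmetry with the bootstrap estimators; the fit itself is deterministic.
    """
    bx, sx = np.asarray(bx, float), np.asarray(sx, float)
    by, sy = np.asarray(by, float), np.asarray(sy, float)
    if bx.size < 3:
        raise EstimatorError("RAPS requires >=3 instruments")
    t0 = ivw_fit(bx, sx, by, sy).beta

    if not overdispersion:
        res = optimize.minimize_scalar(
            _profile_nll, args=(bx, sx, by, sy),
            bracket=(t0 - 0.5, t0 + 0.5),
            method="brent", options={"xtol": tol, "maxiter": maxiter},
        )
        beta = float(res.x)
        se = _curvature_se(lambda t: _profile_nll(t, bx, sx, by, sy), beta)
        return FitResult(beta, se, float(2 * stats.norm.sf(abs(beta) / se)), {"tau2": 0.0})

    # overdispersion expressed in units of the mean outcome variance so both
    # optimizer coordinates live on comparable scales
    sbar2 = float(np.mean(sy**2))

    def nll(params):
        t, u = params
        tau2 = max(u, 0.0) * sbar2
        v = sy**2 + tau2 + t * t * sx**2
        return 0.5 * np.sum((by - t * bx) ** 2 / v + np.log(sy**2 + tau2))

    r0 = by - t0 * bx
    tau2_0 = max(0.0, float(np.mean(r0**2 - sy**2 - t0**2 * sx**2)))
    x0 = np.array([t0, tau2_0 / sbar2])
    res = optimize.minimize(
        nll, x0=x0, method="L-BFGS-B",
        bounds=[(None, None), (0.0, None)],
        options={"maxiter": maxiter, "ftol": tol},
    )
    if not res.success:
        res = optimize.minimize(
            nll, x0=x0, method="Nelder-Mead",
            bounds=[(None, None), (0.0, None)],
            options={"maxiter": maxiter, "xatol": 1e-10, "fatol": tol},
        )
    if not res.success:
        raise EstimatorError(f"RAPS optimizer failed: {res.message}")
    beta, tau2 = float(res.x[0]), float(res.x[1]) * sbar2

    # observed information; fall back to the theta-profile curvature when
    # tau2 sits at the boundary (the joint Hessian is ill-posed there)
    se = None
    if tau2 > 1e-6 * sbar2:
        h_t = 1e-5 * (1.0 + abs(beta))
        h_s = min(1e-5 * (sbar2 + tau2), 0.5 * tau2)

        def f(a, b):
            v = sy**2 + b + a * a * sx**2
            return 0.5 * np.sum((by - a * bx) ** 2 / v + np.log(sy**2 + b))
        d_tt = (f(beta + h_t, tau2) - 2 * f(beta, tau2) + f(beta - h_t, tau2)) / h_t**2
        d_ss = (f(beta, tau2 + h_s) - 2 * f(beta, tau2) + f(beta, tau2 - h_s)) / h_s**2
        d_ts = (
            f(beta + h_t, tau2 + h_s) - f(beta + h_t, tau2 - h_s)
            - f(beta - h_t, tau2 + h_s) + f(beta - h_t, tau2 - h_s)
        ) / (4 * h_t * h_s)
        H = np.array([[d_tt, d_ts], [d_ts, d_ss]])
        try:
            cov = np.linalg.inv(H)
            if cov[0, 0] > 0:
                se = float(np.sqrt(cov[0, 0]))
        except np.linalg.LinAlgError:
            se = None
    if se is None:
        se = _curvature_se(lambda t: _profile_nll(t, bx, sx, by, sy, tau2), beta)
    pval = float(2 * stats.norm.sf(abs(beta) / se))
    return FitResult(beta, se, pval, {"tau2": tau2})


# ---------------------------------------------------------------------------
# HarmonizedSet-facing surface
# ---------------------------------------------------------------------------

def wald_ratios(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-SNP (theta_j, se_j) for every retained SNP with beta_X != 0.

    SNPs with beta_X = 0 are excluded with a warning and returned in the
    third element.
    """
    bx, sx, by, sy = h.arrays()
    bad = np.where(bx == 0)[0]
    excluded = [h.records[i].rsid for i in bad]
    if excluded:
        warnings.warn(f"Wald ratio undefined (beta_X = 0), excluding: {excluded}")
        keep = bx != 0
        bx, sx, by, sy = bx[keep], sx[keep], by[keep], sy[keep]
    theta, se = wald_ratio_arrays(bx, sx, by, sy)
    return theta, se, excluded


def _require(h: HarmonizedSet, minimum: int, method: str) -> tuple:
    if len(h) < minimum:
        raise EstimatorError(f"{method} requires >= {minimum} instruments, got {len(h)}")
    return h.arrays()


def ivw(h: HarmonizedSet) -> MREstimate:
    """Random-effects inverse-variance-weighted estimate (the primary method)."""
    bx, sx, by, sy = _require(h, 1, "IVW")
    if len(h) == 1:
        warnings.warn("single instrument: IVW degrades to the Wald ratio")
    return _estimate("IVW", ivw_fit(bx, sx, by, sy), len(h))


def egger(h: HarmonizedSet) -> MREstimate:
    """MR-Egger slope; the intercept and its test live in ``extra``."""
    bx, sx, by, sy = _require(h, 3, "Egger")
    return _estimate("Egger", egger_fit(bx, sx, by, sy), len(h))


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed: int | None = None) -> MREstimate:
    bx, sx, by, sy = _require(h, 3, "weighted median")
    return _estimate("WeightedMedian", weighted_median_fit(bx, sx, by, sy, n_boot, seed), len(h))


def max_likelihood(h: HarmonizedSet) -> MREstimate:
    bx, sx, by, sy = _require(h, 1, "maximum likelihood")
    return _estimate("MaxLikelihood", max_likelihood_fit(bx, sx, by, sy), len(h))


def raps(h: HarmonizedSet, overdispersion: bool = True, seed: int | None = None) -> MREstimate:
    bx, sx, by, sy = _require(h, 3, "RAPS")
    return _estimate("RAPS", raps_fit(bx, sx, by, sy, overdispersion, seed), len(h))


#: method key -> callable(h, **kwargs)
METHODS = {
    "ivw": ivw,
    "egger": egger,
    "wmedian": weighted_median,
    "ml": max_likelihood,
    "raps": raps,
}
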