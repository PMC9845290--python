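"""Replicate simulation studies: calibration, recovery, robustness, detection.

Each study draws independent synthetic summary-statistic replicates from
:mod:`mrkit.synthetic` (via its fast numeric core), applies the estimators
or diagnostics under test, and aggregates. The module defines the preset
study conditions used throughout the package's validation; all randomness
flows from a single integer seed through ``numpy.random.SeedSequence``
children, one per replicate.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .estimators import (
    Z95,
    _weighted_median_rows,
    egger_fit,
    ivw_fit,
    max_likelihood_fit,
    raps_fit,
    wald_ratio_arrays,
)
from .sensitivity import mr_presso_arrays
from .synthetic import SimulationConfig, simulate_effect_arrays

#: valid-instrument recovery conditions: 75 strong instruments from a 600k
#: exposure GWAS against a 460k outcome GWAS, causal effect 0.1, no pleiotropy
RECOVERY_CONFIG = SimulationConfig(
    n_snps=75, true_theta=0.1, n_exposure=600_000, n_outcome=460_000,
    gamma_sd=0.03, pleiotropy_mode="none",
)

#: balanced pleiotropy on every SNP (tau = 1e-3, about half the typical
#: outcome se), used for type-I calibration of the Egger intercept test
BALANCED_CONFIG = replace(
    RECOVERY_CONFIG, pleiotropy_mode="balanced", prop_invalid=1.0,
    pleiotropy_sd=1e-3, n_snps=100,
)

#: directional pleiotropy on 30% of instruments, strong enough to bias IVW
#: by roughly a third of the causal effect while the majority stays valid
DIRECTIONAL_CONFIG = replace(
    RECOVERY_CONFIG, gamma_sd=0.04, pleiotropy_mode="directional",
    prop_invalid=0.3, pleiotropy_mean=4e-3, pleiotropy_sd=5e-4,
)

#: one gross outlier (pleiotropic offset 10 x sigma_Y) among 50 instruments
OUTLIER_CONFIG = replace(
    RECOVERY_CONFIG, n_snps=50, n_outliers=1, outlier_offset=10.0,
)

#: the same 50-instrument conditions with no outlier (PRESSO null)
CLEAN_CONFIG = replace(RECOVERY_CONFIG, n_snps=50)


def _child_rngs(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def estimator_recovery_study(
    n_reps: int = 500,
    cfg: SimulationConfig = RECOVERY_CONFIG,
    seed: int = 0,
) -> dict:
    """Bias and IVW coverage of IVW / weighted median / ML / RAPS.

    Returns mean bias per method (point estimators; the weighted median is
    evaluated at its point estimate), the IVW 95% CI coverage of the true
    effect, and the Monte-Carlo standard error of the IVW bias.
    """
    rngs = _child_rngs(seed, n_reps)
    bias = {"ivw": [], "wmedian": [], "ml": [], "raps": []}
    covered = []
    for rng in rngs:
        bx, sx, by, sy, *_ = simulate_effect_arrays(cfg, rng)
        fit = ivw_fit(bx, sx, by, sy)
        bias["ivw"].append(fit.beta - cfg.true_theta)
        covered.append(
            fit.beta - Z95 * fit.se <= cfg.true_theta <= fit.beta + Z95 * fit.se
        )
        theta, se_j = wald_ratio_arrays(bx, sx, by, sy)
        wm = float(_weighted_median_rows(theta, 1.0 / se_j**2)[0])
        bias["wmedian"].append(wm - cfg.true_theta)
        bias["ml"].append(max_likelihood_fit(bx, sx, by, sy).beta - cfg.true_theta)
        bias["raps"].append(raps_fit(bx, sx, by, sy).beta - cfg.true_theta)
    out = {f"{k}_mean_bias": float(np.mean(v)) for k, v in bias.items()}
    out["ivw_coverage"] = float(np.mean(covered))
    out["ivw_bias_mc_se"] = float(np.std(bias["ivw"], ddof=1) / np.sqrt(n_reps))
    out["n_reps"] = n_reps
    return out


def q_type1_study(
    n_reps: int = 2000,
    cfg: SimulationConfig = RECOVERY_CONFIG,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Cochran's Q rejection rate under homogeneity (no pleiotropy)."""
    from scipy import stats

    rejections = 0
    for rng in _child_rngs(seed, n_reps):
        bx, sx, by, sy, *_ = simulate_effect_arrays(cfg, rng)
        fit = ivw_fit(bx, sx, by, sy)
        pval = stats.chi2.sf(fit.extra["q"], fit.extra["q_df"])
        rejections += pval < alpha
    return {"rejection_rate": rejections / n_reps, "n_reps": n_reps}


def egger_type1_study(
    n_reps: int = 1000,
    cfg: SimulationConfig = BALANCED_CONFIG,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Egger intercept-test rejection rate under balanced pleiotropy."""
    rejections = 0
    for rng in _child_rngs(seed, n_reps):
        bx, sx, by, sy, *_ = simulate_effect_arrays(cfg, rng)
        fit = egger_fit(bx, sx, by, sy)
        rejections += fit.extra["intercept_pval"] < alpha
    return {"rejection_rate": rejections / n_reps, "n_reps": n_reps}


def egger_power_study(
    n_reps: int = 200,
    seed: int = 0,
    mu_alpha: float = 2e-3,
    alpha: float = 0.05,
) -> dict:
    """Egger intercept-test power under directional pleiotropy on all SNPs."""
    cfg = replace(
        RECOVERY_CONFIG, n_snps=100, pleiotropy_mode="directional",
        prop_invalid=1.0, pleiotropy_mean=mu_alpha, pleiotropy_sd=2e-4,
    )
    rejections = 0
    for rng in _child_rngs(seed, n_reps):
        bx, sx, by, sy, *_ = simulate_effect_arrays(cfg, rng)
        rejections += egger_fit(bx, sx, by, sy).extra["intercept_pval"] < alpha
    return {"rejection_rate": rejections / n_reps, "n_reps": n_reps}


def robustness_study(
    n_reps: int = 500,
    cfg: SimulationConfig = DIRECTIONAL_CONFIG,
    seed: int = 0,
) -> dict:
    """IVW vs weighted-median bias with 30% directionally pleiotropic SNPs."""
    ivw_b, wm_b, egger_b = [], [], []
    for rng in _child_rngs(seed, n_reps):
        bx, sx, by, sy, *_ = simulate_effect_arrays(cfg, rng)
        ivw_b.append(ivw_fit(bx, sx, by, sy).beta - cfg.true_theta)
        theta, se_j = wald_ratio_arrays(bx, sx, by, sy)
        wm_b.append(float(_weighted_median_rows(theta, 1.0 / se_j**2)[0]) - cfg.true_theta)
        egger_b.append(egger_fit(bx, sx, by, sy).beta - cfg.true_theta)
    return {
        "ivw_mean_bias": float(np.mean(ivw_b)),
        "wmedian_mean_bias": float(np.mean(wm_b)),
        "egger_mean_bias": float(np.mean(egger_b)),
        "true_theta": cfg.true_theta,
        "n_reps": n_reps,
    }


def presso_study(
    n_reps: int = 200,
    seed: int = 0,
    n_sim: int = 500,
    outlier_cfg: SimulationConfig = OUTLIER_CONFIG,
    clean_cfg: SimulationConfig = CLEAN_CONFIG,
) -> dict:
    """MR-PRESSO outlier-detection rate and clean-data global-test behaviour."""
    detected = 0
    for rng in _child_rngs(seed, n_reps):
        bx, sx, by, sy, _, _, outlier_mask, _ = simulate_effect_arrays(outlier_cfg, rng)
        _, idx = mr_presso_arrays(bx, sx, by, sy, n_sim, rng)
        planted = set(np.where(outlier_mask)[0])
        detected += planted <= set(idx.tolist())
    clean_ok = 0
    for rng in _child_rngs(seed + 1, n_reps):
        bx, sx, by, sy, *_ = simulate_effect_arrays(clean_cfg, rng)
        gp, _ = mr_presso_arrays(bx, sx, by, sy, n_sim, rng)
        clean_ok += gp > 0.05
    return {
        "detection_rate": detected / n_reps,
        "clean_global_rate": clean_ok / n_reps,
        "n_reps": n_reps,
        "n_sim": n_sim,
    }
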