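"""Synthetic GWAS summary-statistic pairs with known ground truth.

Generates an exposure/outcome dataset pair (plus an LD side file and a
PhenoScanner-style confounder-annotation table) under the standard
two-sample MR measurement model on a standardized-trait scale:

    EAF_j ~ Uniform(eaf_range)
    gamma_j ~ Normal(0, gamma_sd^2)                 true SNP-exposure effect
    sigma_Xj = 1/sqrt(2 EAF_j (1-EAF_j) N_X)        exact 1/sqrt(N) scaling
    sigma_Yj = 1/sqrt(2 EAF_j (1-EAF_j) N_Y)
    beta_Xj ~ Normal(gamma_j, sigma_Xj^2)
    beta_Yj ~ Normal(theta gamma_j + alpha_j, sigma_Yj^2)

alpha_j is the horizontal-pleiotropy component: zero for valid SNPs;
Normal(0, tau^2) under balanced pleiotropy; under directional pleiotropy it
is applied in the orientation of the exposure-increasing allele,
sign(gamma_j) * Normal(mu_alpha, tau^2), so that its mean survives the
beta_X > 0 orientation instead of cancelling across the arbitrary allele
labelling (instrument strength stays independent of the direct effect, so
the InSIDE condition holds).  Planted gross outliers add
outlier_offset * sigma_Yj on top.

A configurable fraction of SNPs gets palindromic (A/T or C/G) alleles, a
fraction gets confounder-trait annotations, and a fraction of outcome rows
is written on the opposite allele so harmonization is exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import ConfounderAnnotation, LDInfo
from .summary_io import SNPAssociation, SummaryDataset, write_summary_stats

CONFOUNDER_TRAIT_POOL = (
    "smoking status",
    "alcohol intake frequency",
    "acidic beverage consumption",
    "vitamin c levels",
    "vitamin d levels",
)
BENIGN_TRAIT_POOL = ("standing height", "hair colour", "heel bone mineral density")

_NONPALINDROMIC_PAIRS = (
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
)
_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic exposure/outcome pair."""

    n_snps: int = 80
    true_theta: float = 0.1
    n_exposure: int = 600_000
    n_outcome: int = 460_000
    gamma_sd: float = 0.02
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    prop_invalid: float = 0.0
    n_outliers: int = 0
    outlier_offset: float = 0.0
    prop_palindromic: float = 0.0
    prop_confounder_annotated: float = 0.0
    prop_outcome_flipped: float = 0.3
    n_ld_duplicates: int = 0
    eaf_range: tuple = (0.1, 0.9)
    ensure_qc_hits: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_snps < 1:
            raise ConfigError("n_snps must be >= 1")
        for name in (
            "prop_invalid", "prop_palindromic",
            "prop_confounder_annotated", "prop_outcome_flipped",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.gamma_sd < 0 or self.pleiotropy_sd < 0:
            raise ConfigError("standard deviations must be >= 0")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ConfigError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.n_outliers < 0 or self.n_outliers + self.n_ld_duplicates + 2 > self.n_snps:
            raise ConfigError("n_outliers/n_ld_duplicates too large for n_snps")
        lo, hi = self.eaf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigError("eaf_range must satisfy 0 < lo <= hi < 1")

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["eaf_range"] = list(self.eaf_range)
        return d


@dataclass
class GroundTruth:
    """Latent per-SNP quantities behind a generated pair."""

    theta: float
    gamma: np.ndarray
    alpha: np.ndarray
    outlier: np.ndarray       # bool
    palindromic: np.ndarray   # bool
    confounder: np.ndarray    # bool
    ld_parent: np.ndarray     # parent index for LD duplicates, -1 otherwise
    rsids: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp": self.rsids,
                "gamma": self.gamma,
                "alpha": self.alpha,
                "outlier": self.outlier.astype(int),
                "palindromic": self.palindromic.astype(int),
                "confounder": self.confounder.astype(int),
                "ld_parent": self.ld_parent,
            }
        )


@dataclass
class SimulatedStudy:
    exposure: SummaryDataset
    outcome: SummaryDataset
    ld: LDInfo
    annotation: ConfounderAnnotation
    truth: GroundTruth


def _draw_alpha(cfg: SimulationConfig, rng, gamma: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(alpha, invalid mask) under the configured pleiotropy mode."""
    L = gamma.size
    alpha = np.zeros(L)
    invalid = np.zeros(L, bool)
    if cfg.pleiotropy_mode != "none" and cfg.prop_invalid > 0:
        invalid = rng.random(L) < cfg.prop_invalid
        if cfg.pleiotropy_mode == "balanced":
            draws = rng.normal(0.0, cfg.pleiotropy_sd, L)
            alpha[invalid] = draws[invalid]
        else:  # directional, oriented along the exposure-increasing allele
            draws = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, L)
            alpha[invalid] = np.sign(gamma[invalid]) * draws[invalid]
    return alpha, invalid


def simulate_effect_arrays(cfg: SimulationConfig, rng=None):
    """Fast numeric core: harmonized-scale effect arrays plus latent truth.

    Returns (bx, sx, by, sy, gamma, alpha, outlier_mask, eaf).  This is the
    path the replicate studies use; :func:`generate` adds alleles, rsids,
    p-values and file-format dressing on top of the same draws.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    L = cfg.n_snps
    eaf = rng.uniform(cfg.eaf_range[0], cfg.eaf_range[1], L)
    sx = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * cfg.n_exposure)
    sy = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * cfg.n_outcome)
    gamma = rng.normal(0.0, cfg.gamma_sd, L)

    forced = []
    if cfg.ensure_qc_hits:
        # reserve disjoint roles: 0 = confounder-annotated, 1 = palindromic
        # with intermediate EAF, then outliers, then LD-duplicate parents;
        # all forced genome-wide significant so each filter sees work
        forced = list(range(2 + cfg.n_outliers + cfg.n_ld_duplicates))
        if cfg.prop_palindromic > 0:
            eaf[1] = 0.5
            sx[1] = 1.0 / np.sqrt(0.5 * cfg.n_exposure)
            sy[1] = 1.0 / np.sqrt(0.5 * cfg.n_outcome)
        for i in forced:
            sign = 1.0 if gamma[i] >= 0 else -1.0
            gamma[i] = sign * (8.0 + 3.0 * rng.random()) * sx[i]

    # LD duplicates copy their parent's latent effect and frequency
    ld_parent = np.full(L, -1, dtype=int)
    for d in range(cfg.n_ld_duplicates):
        dup = L - 1 - d
        parent = 2 + cfg.n_outliers + d
        ld_parent[dup] = parent
        eaf[dup] = eaf[parent]
        sx[dup], sy[dup] = sx[parent], sy[parent]
        gamma[dup] = gamma[parent]

    alpha, invalid = _draw_alpha(cfg, rng, gamma)

    outlier = np.zeros(L, bool)
    if cfg.n_outliers > 0:
        if cfg.ensure_qc_hits:
            idx = np.arange(2, 2 + cfg.n_outliers)
        else:
            idx = rng.choice(L, size=cfg.n_outliers, replace=False)
        outlier[idx] = True
        alpha[idx] += cfg.outlier_offset * sy[idx]

    bx = rng.normal(gamma, sx)
    by = rng.normal(cfg.true_theta * gamma + alpha, sy)
    return bx, sx, by, sy, gamma, alpha, outlier, eaf


def generate(cfg: SimulationConfig) -> SimulatedStudy:
    """Full synthetic study: datasets, LD and annotation side tables, truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    L = cfg.n_snps
    bx, sx, by, sy, gamma, alpha, outlier, eaf = simulate_effect_arrays(cfg, rng)
    ld_parent = np.full(L, -1, dtype=int)
    for d in range(cfg.n_ld_duplicates):
        ld_parent[L - 1 - d] = 2 + cfg.n_outliers + d

    rsids = [f"rs{j + 1:06d}" for j in range(L)]
    palindromic = rng.random(L) < cfg.prop_palindromic
    confounder = rng.random(L) < cfg.prop_confounder_annotated
    if cfg.ensure_qc_hits:
        if cfg.prop_confounder_annotated > 0:
            confounder[0] = True
            palindromic[0] = False
        if cfg.prop_palindromic > 0:
            palindromic[1] = True
            confounder[1] = False
        # the planted outliers and LD pairs must survive the earlier filters
        palindromic[2:2 + cfg.n_outliers] = False
        confounder[2:2 + cfg.n_outliers] = False
        for d in range(cfg.n_ld_duplicates):
            for i in (2 + cfg.n_outliers + d, L - 1 - d):
                palindromic[i] = False
                confounder[i] = False

    alleles = []
    for j in range(L):
        pool = _PALINDROMIC_PAIRS if palindromic[j] else _NONPALINDROMIC_PAIRS
        alleles.append(pool[rng.integers(len(pool))])
    for d in range(cfg.n_ld_duplicates):  # duplicates share parent alleles
        alleles[L - 1 - d] = alleles[ld_parent[L - 1 - d]]

    pval_x = 2.0 * stats.norm.sf(np.abs(bx) / sx)
    pval_y = 2.0 * stats.norm.sf(np.abs(by) / sy)
    tiny = np.nextafter(0.0, 1.0)
    pval_x = np.clip(pval_x, tiny, 1.0)
    pval_y = np.clip(pval_y, tiny, 1.0)

    chrom = [(j % 22) + 1 for j in range(L)]
    pos = [1_000_000 + (j // 22) * 20_000_000 for j in range(L)]
    for d in range(cfg.n_ld_duplicates):  # duplicates sit 50 kb from parents
        p = ld_parent[L - 1 - d]
        chrom[L - 1 - d] = chrom[p]
        pos[L - 1 - d] = pos[p] + 50_000

    flip_out = rng.random(L) < cfg.prop_outcome_flipped

    exp_snps, out_snps = {}, {}
    for j in range(L):
        ea, oa = alleles[j]
        exp_snps[rsids[j]] = SNPAssociation(
            rsid=rsids[j], effect_allele=ea, other_allele=oa, eaf=float(eaf[j]),
            beta=float(bx[j]), se=float(sx[j]), pval=float(pval_x[j]),
            n=cfg.n_exposure, chrom=str(chrom[j]), pos=pos[j],
        )
        if flip_out[j]:
            o_ea, o_oa, o_beta, o_eaf = oa, ea, -by[j], 1.0 - eaf[j]
        else:
            o_ea, o_oa, o_beta, o_eaf = ea, oa, by[j], eaf[j]
        out_snps[rsids[j]] = SNPAssociation(
            rsid=rsids[j], effect_allele=o_ea, other_allele=o_oa, eaf=float(o_eaf),
            beta=float(o_beta), se=float(sy[j]), pval=float(pval_y[j]),
            n=cfg.n_outcome, chrom=str(chrom[j]), pos=pos[j],
        )

    ld = LDInfo()
    for d in range(cfg.n_ld_duplicates):
        dup, parent = L - 1 - d, ld_parent[L - 1 - d]
        ld.set(rsids[parent], rsids[dup], 0.95)

    ann = ConfounderAnnotation()
    for j in range(L):
        if confounder[j]:
            ann.add(rsids[j], CONFOUNDER_TRAIT_POOL[rng.integers(len(CONFOUNDER_TRAIT_POOL))],
                    float(10 ** -rng.uniform(5, 12)))
        elif rng.random() < 0.1:  # benign annotations exercise non-removal
            ann.add(rsids[j], BENIGN_TRAIT_POOL[rng.integers(len(BENIGN_TRAIT_POOL))],
                    float(10 ** -rng.uniform(5, 12)))

    truth = GroundTruth(
        theta=cfg.true_theta, gamma=gamma, alpha=alpha, outlier=outlier,
        palindromic=palindromic, confounder=confounder, ld_parent=ld_parent,
        rsids=rsids,
    )
    exposure = SummaryDataset(trait_label="synthetic exposure", role="exposure", snps=exp_snps)
    outcome = SummaryDataset(trait_label="synthetic outcome", role="outcome", snps=out_snps)
    return SimulatedStudy(exposure=exposure, outcome=outcome, ld=ld, annotation=ann, truth=truth)


def paper_like_config(seed: int = 0) -> SimulationConfig:
    """Study-shaped conditions: 80 candidate instruments from a 602,604-sample
    exposure GWAS against a ~460k outcome GWAS, a small causal effect on the
    log-odds scale, and enough palindromic / confounder-annotated / outlier /
    LD-duplicate SNPs that every quality-control rung removes something."""
    return SimulationConfig(
        n_snps=80,
        true_theta=0.008,
        n_exposure=602_604,
        n_outcome=460_000,
        gamma_sd=0.02,
        pleiotropy_mode="none",
        n_outliers=3,
        outlier_offset=4.5,
        prop_palindromic=0.10,
        prop_confounder_annotated=0.05,
        prop_outcome_flipped=0.3,
        n_ld_duplicates=2,
        eaf_range=(0.1, 0.9),
        ensure_qc_hits=True,
        seed=seed,
    )


def write_study(study: SimulatedStudy, outdir) -> dict:
    """Write the study through the package's own writers; returns the paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "exposure": outdir / "exposure.tsv",
        "outcome": outdir / "outcome.tsv",
        "ld": outdir / "ld.tsv",
        "confounders": outdir / "confounders.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_summary_stats(study.exposure, paths["exposure"])
    write_summary_stats(study.outcome, paths["outcome"])
    ld_rows = [
        {"snp_a": sorted(k)[0], "snp_b": sorted(k)[1], "r2": v}
        for k, v in study.ld._r2.items()
    ]
    pd.DataFrame(ld_rows, columns=["snp_a", "snp_b", "r2"]).to_csv(
        paths["ld"], sep="\t", index=False
    )
    ann_rows = [
        {"snp": rsid, "trait": trait, "pval": p}
        for rsid, lst in study.annotation.traits.items()
        for trait, p in lst
    ]
    pd.DataFrame(ann_rows, columns=["snp", "trait", "pval"]).to_csv(
        paths["confounders"], sep="\t", index=False
    )
    study.truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    return paths
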