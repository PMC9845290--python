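"""End-to-end orchestration: QC ladder -> harmonization -> estimators -> diagnostics.

Stage order for each outcome (matching the instrument-selection ladder):

1. genome-wide-significance filter on the exposure (p < 5e-8)
2. LD clumping (r² < 0.001 within 10,000 kb)
3. confounder screen against the annotation table
4. intersection with the outcome; removal of outcome-significant SNPs
5. allele harmonization (palindromic / incompatible drops)
6. MR-PRESSO global test and outlier removal
7. R²/F instrument-strength screen (F >= 10)
8. the five estimators + sensitivity suite, Bonferroni-labelled with
   m = number of outcomes.

Every removal is logged with rsid, stage and reason; the audit trail
conserves candidates (each candidate SNP is either a survivor or appears in
exactly one removal row per outcome).  All stochastic stages derive their
seeds from the single analysis seed, so a re-run is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .estimators import METHODS, MREstimate, significance_label
from .harmonization import HarmonizedSet, harmonize
from .instruments import (
    DEFAULT_CONFOUNDERS,
    ConfounderAnnotation,
    LDInfo,
    clump,
    filter_weak,
    instrument_strength,
    remove_outcome_associated,
    screen_confounders,
    select_significant,
)
from .sensitivity import SensitivityReport, cochran_q, mr_presso, run_sensitivity
from .summary_io import SummaryDataset, intersect, read_summary_stats

logger = logging.getLogger("mrkit")


@dataclass
class AnalysisConfig:
    p_exposure: float = 5e-8
    clump_r2: float = 0.001
    clump_kb: float = 10_000.0
    confounders: tuple = tuple(sorted(DEFAULT_CONFOUNDERS))
    p_outcome: float = 5e-8
    palindrome_eaf_window: tuple = (0.42, 0.58)
    f_min: float = 10.0
    methods: tuple = ("ivw", "egger", "wmedian", "ml", "raps")
    n_boot: int = 1000
    presso_nsim: int = 1000
    presso_alpha: float = 0.05
    alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if not self.methods:
            raise ValueError("at least one method required")
        for name in ("p_exposure", "p_outcome", "clump_r2", "clump_kb", "f_min", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown method(s): {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["confounders"] = list(self.confounders)
        d["palindrome_eaf_window"] = list(self.palindrome_eaf_window)
        d["methods"] = list(self.methods)
        return d


@dataclass
class OutcomeResult:
    outcome_label: str
    n_candidates: int = 0
    n_instruments: int = 0
    estimates: list = field(default_factory=list)
    sensitivity: SensitivityReport | None = None
    total_r2: float | None = None
    overall_f: float | None = None
    presso_global_pval: float | None = None  # pre-removal global test
    presso_outliers: list = field(default_factory=list)
    q_pre_presso: float | None = None
    labels: dict = field(default_factory=dict)
    error: str | None = None


@dataclass
class AnalysisReport:
    exposure_label: str
    outcomes: dict  # label -> OutcomeResult
    removals: list  # dicts: outcome, snp, stage, reason
    config: AnalysisConfig
    n_candidates: int
    m: int


def _seed_for(base_seed: int, outcome_index: int, tag: int) -> int:
    """Deterministic per-(outcome, stage) child seed below 2^31."""
    ss = np.random.SeedSequence((base_seed, outcome_index, tag))
    return int(ss.generate_state(1)[0] % (2**31))


def _log_removals(removals, outcome, before: set, after: set, stage: str, reason_fn=None):
    for rsid in sorted(before - after):
        reason = reason_fn(rsid) if reason_fn else stage
        removals.append({"outcome": outcome, "snp": rsid, "stage": stage, "reason": reason})


def run_analysis(
    exposure_path,
    outcome_paths,
    ann_path=None,
    ld_path=None,
    cfg: AnalysisConfig | None = None,
) -> AnalysisReport:
    """Run the full analysis of one exposure against one or more outcomes."""
    cfg = cfg or AnalysisConfig()
    cfg.validate()
    exposure = read_summary_stats(exposure_path, trait_label=Path(exposure_path).stem, role="exposure")
    ld = LDInfo.from_file(ld_path) if ld_path else LDInfo()
    ann = ConfounderAnnotation.from_file(ann_path) if ann_path else ConfounderAnnotation()

    removals: list[dict] = []
    n_candidates = len(exposure)

    sig = select_significant(exposure, cfg.p_exposure)
    _log_removals(removals, "shared", set(exposure.rsids), set(sig.rsids),
                  "significance", lambda r: f"exposure p >= {cfg.p_exposure:g}")
    clumped = clump(sig, ld, cfg.clump_r2, cfg.clump_kb)
    _log_removals(removals, "shared", set(sig.rsids), set(clumped.rsids),
                  "clump", lambda r: "in LD with a better instrument")
    screened = screen_confounders(clumped, ann, cfg.confounders)
    _log_removals(removals, "shared", set(clumped.rsids), set(screened.rsids),
                  "confounder", lambda r: "annotated to a confounder trait")

    outcomes: dict[str, OutcomeResult] = {}
    m = len(outcome_paths)
    for i, path in enumerate(outcome_paths):
        label = Path(path).stem
        res = OutcomeResult(outcome_label=label, n_candidates=n_candidates)
        outcomes[label] = res
        try:
            out_ds = read_summary_stats(path, trait_label=label, role="outcome")
            pairs = intersect(screened, out_ds)
            for rsid in sorted(pairs.unmatched):
                removals.append({"outcome": label, "snp": rsid,
                                 "stage": "intersect", "reason": "absent from outcome GWAS"})
            out_p = {e.rsid: o.pval for e, o in pairs.pairs}
            kept = remove_outcome_associated(pairs, cfg.p_outcome)
            _log_removals(removals, label, set(pairs.rsids), set(kept.rsids),
                          "outcome_association",
                          lambda r: f"outcome p = {out_p[r]:.3g}")
            h = harmonize(kept, cfg.palindrome_eaf_window,
                          exposure_label=exposure.trait_label, outcome_label=label)
            for rec in h.dropped:
                removals.append({"outcome": label, "snp": rec.rsid,
                                 "stage": "harmonization", "reason": rec.status})

            if len(h) >= 4:
                res.q_pre_presso = cochran_q(h)[0]
                gp, outliers = mr_presso(
                    h, n_sim=cfg.presso_nsim, seed=_seed_for(cfg.seed, i, 0),
                    outlier_alpha=cfg.presso_alpha,
                )
                res.presso_global_pval, res.presso_outliers = gp, outliers
                if outliers:
                    h = h.drop(outliers, "dropped_presso_outlier")
                    for rsid in outliers:
                        removals.append({"outcome": label, "snp": rsid,
                                         "stage": "mr_presso", "reason": "global-test outlier"})

            exp_sub = screened.subset(h.rsids)
            diag = instrument_strength(exp_sub)
            strong = filter_weak(exp_sub, diag, cfg.f_min)
            weak = set(h.rsids) - set(strong.rsids)
            if weak:
                h = h.drop(sorted(weak), "dropped_weak")
                for rsid in sorted(weak):
                    removals.append({"outcome": label, "snp": rsid, "stage": "weak_instrument",
                                     "reason": f"F = {diag.f[rsid]:.2f} < {cfg.f_min:g}"})
            diag = instrument_strength(screened.subset(h.rsids))
            res.total_r2, res.overall_f = diag.total_r2, diag.overall_f
            res.n_instruments = len(h)

            for j, mname in enumerate(cfg.methods):
                kwargs = {}
                if mname == "wmedian":
                    kwargs = {"n_boot": cfg.n_boot, "seed": _seed_for(cfg.seed, i, 1)}
                elif mname == "raps":
                    kwargs = {"seed": _seed_for(cfg.seed, i, 2)}
                est: MREstimate = METHODS[mname](h, **kwargs)
                res.estimates.append(est)
                res.labels[est.method] = significance_label(est.pval, cfg.alpha, m)

            res.sensitivity = run_sensitivity(
                h, seed=_seed_for(cfg.seed, i, 3), n_sim=cfg.presso_nsim,
                outlier_alpha=cfg.presso_alpha, alpha=cfg.alpha, m=m,
            )
        except Exception as exc:  # per-outcome failure must not sink the run
            logger.error("outcome %s failed: %s", label, exc)
            res.error = str(exc)
    return AnalysisReport(
        exposure_label=exposure.trait_label, outcomes=outcomes,
        removals=removals, config=cfg, n_candidates=n_candidates, m=m,
    )


def render_report(report: AnalysisReport, out_dir) -> dict:
    """Write estimates.tsv, sensitivity.tsv, removals.tsv and run.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    est_rows, sens_rows = [], []
    for label, res in report.outcomes.items():
        if res.error is not None:
            est_rows.append({"outcome": label, "method": "ERROR", "n_snp": 0,
                             "beta": "", "se": "", "pval": "", "or": "",
                             "ci_low": "", "ci_high": "", "significance": res.error})
            continue
        for est in res.estimates:
            est_rows.append({
                "outcome": label, "method": est.method, "n_snp": est.n_snps,
                "beta": f"{est.beta:.10g}", "se": f"{est.se:.10g}",
                "pval": f"{est.pval:.10g}", "or": f"{est.or_:.10g}",
                "ci_low": f"{est.ci_low:.10g}", "ci_high": f"{est.ci_high:.10g}",
                "significance": report.outcomes[label].labels.get(est.method, ""),
            })
        s = res.sensitivity
        if s is not None:
            sens_rows.append({
                "outcome": label,
                "q": f"{s.q:.10g}", "q_df": s.q_df, "q_pval": f"{s.q_pval:.10g}",
                "intercept": "" if s.egger_intercept is None else f"{s.egger_intercept:.10g}",
                "intercept_pval": "" if s.intercept_pval is None else f"{s.intercept_pval:.10g}",
                "presso_global_pval": "" if s.presso_global_pval is None else f"{s.presso_global_pval:.10g}",
                "presso_outliers": ",".join(s.presso_outliers),
                "loo_stable": "" if s.loo_stable is None else str(bool(s.loo_stable)),
            })

    paths = {
        "estimates": out_dir / "estimates.tsv",
        "sensitivity": out_dir / "sensitivity.tsv",
        "removals": out_dir / "removals.tsv",
        "run": out_dir / "run.json",
    }
    pd.DataFrame(est_rows, columns=["outcome", "method", "n_snp", "beta", "se", "pval",
                                    "or", "ci_low", "ci_high", "significance"]
                 ).to_csv(paths["estimates"], sep="\t", index=False)
    pd.DataFrame(sens_rows, columns=["outcome", "q", "q_df", "q_pval", "intercept",
                                     "intercept_pval", "presso_global_pval",
                                     "presso_outliers", "loo_stable"]
                 ).to_csv(paths["sensitivity"], sep="\t", index=False)
    pd.DataFrame(report.removals, columns=["outcome", "snp", "stage", "reason"]
                 ).to_csv(paths["removals"], sep="\t", index=False)
    run_info = {
        "mrkit_version": __version__,
        "seed": report.config.seed,
        "config": report.config.to_dict(),
        "exposure": report.exposure_label,
        "n_candidates": report.n_candidates,
        "n_outcomes": report.m,
        "instruments": {lbl: r.n_instruments for lbl, r in report.outcomes.items()},
    }
    paths["run"].write_text(json.dumps(run_info, indent=2, sort_keys=True) + "\n")
    return paths
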