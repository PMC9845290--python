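"""Align exposure and outcome effects onto a shared effect allele.

Outcome records reported on the opposite allele (directly or after strand
complementation) have their beta negated and EAF reflected.  Palindromic
SNPs (A/T or C/G) carry no strand information in their alleles; they are
resolved by effect-allele-frequency agreement when the exposure EAF is far
from 0.5 and dropped when it lies in the ambiguity window (default
[0.42, 0.58]) or when the outcome EAF is missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .summary_io import IntersectResult, SNPAssociation

logger = logging.getLogger("mrkit")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

STATUS_ALIGNED = "aligned"
STATUS_FLIPPED = "flipped"
STATUS_DROPPED_PALINDROMIC = "dropped_palindromic"
STATUS_DROPPED_INCOMPATIBLE = "dropped_incompatible"


class HarmonizationError(Exception):
    pass


def is_palindromic(snp: SNPAssociation) -> bool:
    """True iff the allele pair is its own reverse complement ({A,T} or {C,G})."""
    pair = {snp.effect_allele, snp.other_allele}
    return pair == {"A", "T"} or pair == {"C", "G"}


@dataclass(frozen=True)
class HarmonizedRecord:
    """Exposure and outcome effects of one SNP on a common effect allele."""

    rsid: str
    effect_allele: str
    other_allele: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf_exposure: float | None
    eaf_outcome: float | None
    status: str


@dataclass
class HarmonizedSet:
    """Retained harmonized records plus an audit list of dropped ones."""

    records: list[HarmonizedRecord]
    exposure_label: str = ""
    outcome_label: str = ""
    dropped: list[HarmonizedRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def rsids(self) -> list[str]:
        return [r.rsid for r in self.records]

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_X, se_X, beta_Y, se_Y) as float arrays, estimator substrate."""
        bx = np.array([r.beta_exposure for r in self.records])
        sx = np.array([r.se_exposure for r in self.records])
        by = np.array([r.beta_outcome for r in self.records])
        sy = np.array([r.se_outcome for r in self.records])
        return bx, sx, by, sy

    def drop(self, rsids, status: str) -> "HarmonizedSet":
        """New set with ``rsids`` moved to the audit list under ``status``."""
        gone = set(rsids)
        kept = [r for r in self.records if r.rsid not in gone]
        removed = [
            HarmonizedRecord(**{**r.__dict__, "status": status})
            for r in self.records
            if r.rsid in gone
        ]
        return HarmonizedSet(
            records=kept,
            exposure_label=self.exposure_label,
            outcome_label=self.outcome_label,
            dropped=self.dropped + removed,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "snp": r.rsid,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "beta_exp": r.beta_exposure,
                "se_exp": r.se_exposure,
                "beta_out": r.beta_outcome,
                "se_out": r.se_outcome,
                "eaf_exp": r.eaf_exposure,
                "eaf_out": r.eaf_outcome,
                "status": r.status,
            }
            for r in list(self.records) + list(self.dropped)
        ]
        return pd.DataFrame(rows)


def _flip(out: SNPAssociation) -> tuple[float, float | None]:
    """Outcome beta and EAF re-expressed on the opposite allele."""
    eaf = None if out.eaf is None else 1.0 - out.eaf
    return -out.beta, eaf


def harmonize(
    pairs: IntersectResult | list,
    palindrome_eaf_window: tuple[float, float] = (0.42, 0.58),
    exposure_label: str = "",
    outcome_label: str = "",
) -> HarmonizedSet:
    """Harmonize intersected exposure/outcome pairs onto the exposure's alleles.

    For each pair: same-orientation alleles are kept as-is; swapped alleles
    (directly or via strand complement for non-palindromic SNPs) flip the
    outcome beta and EAF; palindromic SNPs with exposure EAF inside
    ``palindrome_eaf_window`` — or with missing outcome EAF — are dropped as
    strand-ambiguous, while those outside the window are orientation-resolved
    so that minor alleles correspond; irreconcilable allele sets are dropped
    as incompatible.  Every input pair lands in exactly one of retained or
    dropped.
    """
    if isinstance(pairs, IntersectResult):
        pairs = pairs.pairs
    lo, hi = palindrome_eaf_window
    records: list[HarmonizedRecord] = []
    dropped: list[HarmonizedRecord] = []

    for exp, out in pairs:
        ea, oa = exp.effect_allele, exp.other_allele
        cea, coa = _COMPLEMENT[out.effect_allele], _COMPLEMENT[out.other_allele]
        palindromic = is_palindromic(exp)

        if (out.effect_allele, out.other_allele) == (ea, oa):
            by, eaf_out, status = out.beta, out.eaf, STATUS_ALIGNED
        elif (out.effect_allele, out.other_allele) == (oa, ea):
            (by, eaf_out), status = _flip(out), STATUS_FLIPPED
        elif not palindromic and (cea, coa) == (ea, oa):
            by, eaf_out, status = out.beta, out.eaf, STATUS_ALIGNED
        elif not palindromic and (cea, coa) == (oa, ea):
            (by, eaf_out), status = _flip(out), STATUS_FLIPPED
        else:
            dropped.append(
                HarmonizedRecord(
                    exp.rsid, ea, oa, exp.beta, exp.se, out.beta, out.se,
                    exp.eaf, out.eaf, STATUS_DROPPED_INCOMPATIBLE,
                )
            )
            logger.info("harmonize: %s dropped (incompatible alleles)", exp.rsid)
            continue

        if palindromic:
            ambiguous = (
                exp.eaf is None
                or lo <= exp.eaf <= hi
                or eaf_out is None
            )
            if ambiguous:
                dropped.append(
                    HarmonizedRecord(
                        exp.rsid, ea, oa, exp.beta, exp.se, out.beta, out.se,
                        exp.eaf, out.eaf, STATUS_DROPPED_PALINDROMIC,
                    )
                )
                logger.info(
                    "harmonize: %s dropped (palindromic, intermediate or missing EAF)",
                    exp.rsid,
                )
                continue
            # allele labels carry no strand info for palindromes: trust EAF
            if (exp.eaf - 0.5) * (eaf_out - 0.5) < 0:
                by = -by
                eaf_out = 1.0 - eaf_out
                status = STATUS_FLIPPED if status == STATUS_ALIGNED else STATUS_ALIGNED

        records.append(
            HarmonizedRecord(
                exp.rsid, ea, oa, exp.beta, exp.se, by, out.se,
                exp.eaf, eaf_out, status,
            )
        )

    if pairs and not records:
        raise HarmonizationError("no harmonizable instruments")
    return HarmonizedSet(
        records=records,
        exposure_label=exposure_label,
        outcome_label=outcome_label,
        dropped=dropped,
    )


def write_harmonized(h: HarmonizedSet, path) -> None:
    h.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")
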