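"""GWAS summary-statistic data model and delimited-text I/O.

The exchange format is a tab-separated table with the canonical header

    snp  effect_allele  other_allele  eaf  beta  se  pval  n  chrom  pos

(``chrom``/``pos`` optional).  A ``column_map`` lets IEU-style or Neale-style
exports load without editing the file.  Only biallelic single-nucleotide
variants are retained; rows violating the per-field invariants are dropped
and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("mrkit")

VALID_BASES = frozenset("ACGT")

#: logical field -> canonical column name
CANONICAL_COLUMNS = {
    "rsid": "snp",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "n",
    "chrom": "chrom",
    "pos": "pos",
}

MANDATORY_FIELDS = ("rsid", "effect_allele", "other_allele", "beta", "se", "pval")


class SummaryStatsError(Exception):
    """Malformed summary-statistic input (missing columns, duplicate rsids...)."""


@dataclass(frozen=True)
class SNPAssociation:
    """One SNP's marginal association in one GWAS.

    ``beta`` is the per-allele effect of ``effect_allele`` (log-odds for a
    binary trait, linear otherwise); ``eaf`` is the effect-allele frequency
    and may be ``None`` on the outcome side (such SNPs cannot be
    strand-resolved if palindromic and are dropped at harmonization).
    """

    rsid: str
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: int | None = None
    chrom: str | None = None
    pos: int | None = None

    def problems(self) -> list[str]:
        """Invariant violations, empty if the record is valid."""
        out = []
        if self.effect_allele not in VALID_BASES or self.other_allele not in VALID_BASES:
            out.append("alleles must be single bases A/C/G/T")
        elif self.effect_allele == self.other_allele:
            out.append("effect and other allele identical")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            out.append("eaf outside [0, 1]")
        if not (self.se > 0):
            out.append("se must be > 0")
        if not (0.0 < self.pval <= 1.0):
            out.append("pval outside (0, 1]")
        if self.n is not None and self.n <= 0:
            out.append("n must be positive")
        return out


@dataclass
class SummaryDataset:
    """A trait's SNP associations keyed by rsid, plus trait metadata."""

    trait_label: str
    role: str  # "exposure" | "outcome"
    snps: dict[str, SNPAssociation] = field(default_factory=dict)
    n_cases: int | None = None
    n_controls: int | None = None

    def __len__(self) -> int:
        return len(self.snps)

    def __iter__(self):
        return iter(self.snps.values())

    def __contains__(self, rsid: str) -> bool:
        return rsid in self.snps

    @property
    def rsids(self) -> list[str]:
        return list(self.snps)

    def subset(self, rsids) -> "SummaryDataset":
        """New dataset restricted to ``rsids`` (input order preserved)."""
        keep = set(rsids)
        return replace(
            self, snps={r: s for r, s in self.snps.items() if r in keep}
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "snp": s.rsid,
                "effect_allele": s.effect_allele,
                "other_allele": s.other_allele,
                "eaf": s.eaf,
                "beta": s.beta,
                "se": s.se,
                "pval": s.pval,
                "n": s.n,
                "chrom": s.chrom,
                "pos": s.pos,
            }
            for s in self
        ]
        return pd.DataFrame(
            rows, columns=list(CANONICAL_COLUMNS.values())
        )


@dataclass
class IntersectResult:
    """Exposure/outcome record pairs for shared rsids, plus the unmatched rsids."""

    pairs: list[tuple[SNPAssociation, SNPAssociation]]
    unmatched: list[str]

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def rsids(self) -> list[str]:
        return [e.rsid for e, _ in self.pairs]


def _parse_row(row: dict, has_eaf: bool, has_n: bool, has_pos: bool) -> SNPAssociation | None:
    ea = str(row["effect_allele"]).strip().upper()
    oa = str(row["other_allele"]).strip().upper()
    eaf = None
    if has_eaf and pd.notna(row["eaf"]):
        eaf = float(row["eaf"])
    pval = float(row["pval"])
    if pval == 0.0:
        # p-values truncated to 0 upstream: clamp to the smallest positive float
        pval = np.nextafter(0.0, 1.0)
        logger.warning("rsid %s: pval of 0 clamped to %.3g", row["rsid"], pval)
    n = int(row["n"]) if has_n and pd.notna(row["n"]) else None
    chrom = pos = None
    if has_pos and pd.notna(row.get("chrom")) and pd.notna(row.get("pos")):
        chrom, pos = str(row["chrom"]), int(row["pos"])
    return SNPAssociation(
        rsid=str(row["rsid"]),
        effect_allele=ea,
        other_allele=oa,
        eaf=eaf,
        beta=float(row["beta"]),
        se=float(row["se"]),
        pval=pval,
        n=n,
        chrom=chrom,
        pos=pos,
    )


def read_summary_stats(
    path,
    column_map: dict[str, str] | None = None,
    trait_label: str = "",
    role: str = "exposure",
    n_cases: int | None = None,
    n_controls: int | None = None,
    sep: str = "\t",
) -> SummaryDataset:
    """Read a delimited summary-statistic table into a :class:`SummaryDataset`.

    ``column_map`` maps logical field names (``rsid``, ``effect_allele``, ...)
    to the column names actually present; it defaults to the canonical header.
    Rows failing the record invariants (indels, se <= 0, EAF outside [0,1],
    p outside (0,1]) are dropped with a logged count.  Duplicate rsids raise.
    """
    cmap = dict(CANONICAL_COLUMNS)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=sep, dtype={cmap.get("chrom", "chrom"): str})
    missing = [cmap[f] for f in MANDATORY_FIELDS if cmap[f] not in df.columns]
    if missing:
        raise SummaryStatsError(
            f"{path}: missing mandatory column(s): {', '.join(missing)}"
        )
    has_eaf = cmap["eaf"] in df.columns
    has_n = cmap["n"] in df.columns
    has_pos = cmap["chrom"] in df.columns and cmap["pos"] in df.columns

    snps: dict[str, SNPAssociation] = {}
    duplicates, n_dropped = [], 0
    for _, raw in df.iterrows():
        row = {f: raw.get(c) for f, c in cmap.items() if c in df.columns}
        try:
            snp = _parse_row(row, has_eaf, has_n, has_pos)
        except (TypeError, ValueError):
            n_dropped += 1
            continue
        probs = snp.problems()
        if probs:
            n_dropped += 1
            logger.info("dropping %s: %s", snp.rsid, "; ".join(probs))
            continue
        if snp.rsid in snps:
            duplicates.append(snp.rsid)
            continue
        snps[snp.rsid] = snp
    if duplicates:
        raise SummaryStatsError(f"{path}: duplicate rsid(s): {', '.join(sorted(set(duplicates)))}")
    if n_dropped:
        logger.warning("%s: dropped %d invalid row(s)", path, n_dropped)
    ds = SummaryDataset(
        trait_label=trait_label, role=role, snps=snps,
        n_cases=n_cases, n_controls=n_controls,
    )
    ds.n_dropped = n_dropped  # type: ignore[attr-defined]  # audit count
    return ds


def write_summary_stats(ds: SummaryDataset, path) -> None:
    """Write ``ds`` as a canonical tab-separated table (round-trip safe)."""
    df = ds.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def intersect(exposure: SummaryDataset, outcome: SummaryDataset) -> IntersectResult:
    """Pair exposure SNPs with the same rsid in the outcome dataset.

    Exposure rsids absent from the outcome are reported as unmatched (no
    proxy search).  Zero overlap warns rather than raising.
    """
    pairs, unmatched = [], []
    for rsid, exp in exposure.snps.items():
        out = outcome.snps.get(rsid)
        if out is None:
            unmatched.append(rsid)
        else:
            pairs.append((exp, out))
    if not pairs:
        logger.warning(
            "no overlapping rsids between %s and %s",
            exposure.trait_label, outcome.trait_label,
        )
    if unmatched:
        logger.info("%d exposure SNP(s) not found in outcome (dropped, no proxies)", len(unmatched))
    return IntersectResult(pairs=pairs, unmatched=unmatched)
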