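"""Instrument selection and validation for the exposure GWAS.

The quality-control ladder: genome-wide-significance filter (p < 5e-8),
greedy LD clumping (r² < 0.001 within 10,000 kb), confounder screen against
a PhenoScanner-style annotation table, removal of SNPs significantly
associated with the outcome, and the variance-explained / F-statistic
weak-instrument screen (F >= 10):

    R²_j = 2 · EAF_j · (1 − EAF_j) · β_j²
    F    = R²/(1 − R²) · (N − k − 1)/k

with k = 1 per SNP and k = number of instruments overall.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd

from .summary_io import IntersectResult, SummaryDataset

logger = logging.getLogger("mrkit")


class InstrumentError(Exception):
    """Unusable instrument inputs (missing positions, malformed R²...)."""


@dataclass
class LDInfo:
    """Sparse pairwise r² between rsids; an absent pair means r² = 0."""

    _r2: dict[frozenset, float] = field(default_factory=dict)

    def set(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise InstrumentError(f"r² for ({a}, {b}) outside [0, 1]: {r2}")
        self._r2[frozenset((a, b))] = r2

    def get(self, a: str, b: str) -> float:
        return self._r2.get(frozenset((a, b)), 0.0)

    def __len__(self) -> int:
        return len(self._r2)

    @classmethod
    def from_file(cls, path) -> "LDInfo":
        """Read a 3-column TSV ``snp_a  snp_b  r2``."""
        df = pd.read_csv(path, sep="\t")
        ld = cls()
        for a, b, r2 in zip(df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2]):
            ld.set(str(a), str(b), float(r2))
        return ld


@dataclass
class ConfounderAnnotation:
    """rsid -> associated trait labels, emulating a PhenoScanner extract.

    Trait labels are case-folded on entry; each association may carry a
    p-value (used only when a cutoff is requested).
    """

    traits: dict[str, list[tuple[str, float | None]]] = field(default_factory=dict)

    def add(self, rsid: str, trait: str, pval: float | None = None) -> None:
        self.traits.setdefault(rsid, []).append((trait.casefold().strip(), pval))

    def for_snp(self, rsid: str) -> list[tuple[str, float | None]]:
        return self.traits.get(rsid, [])

    @classmethod
    def from_file(cls, path) -> "ConfounderAnnotation":
        """Read a TSV ``snp  trait  pval`` (pval column optional)."""
        df = pd.read_csv(path, sep="\t")
        ann = cls()
        has_p = df.shape[1] >= 3
        for _, row in df.iterrows():
            p = float(row.iloc[2]) if has_p and pd.notna(row.iloc[2]) else None
            ann.add(str(row.iloc[0]), str(row.iloc[1]), p)
        return ann


@dataclass
class InstrumentDiagnostics:
    """Per-SNP and aggregate instrument-strength measures."""

    r2: dict[str, float]           # per-SNP variance explained
    f: dict[str, float]            # per-SNP F (k = 1)
    total_r2: float                # sum of per-SNP r2
    overall_f: float               # F with k = number of instruments
    k: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"snp": list(self.r2), "r2": list(self.r2.values()), "f": list(self.f.values())}
        )


DEFAULT_CONFOUNDERS = frozenset(
    {"smoking", "alcohol", "acidic beverage", "vitamin c", "vitamin d"}
)


def select_significant(ds: SummaryDataset, p_threshold: float = 5e-8) -> SummaryDataset:
    """Keep SNPs with p strictly below the genome-wide threshold."""
    keep = {r: s for r, s in ds.snps.items() if s.pval < p_threshold}
    if not keep:
        logger.warning("%s: no SNP passes p < %g", ds.trait_label, p_threshold)
    return replace(ds, snps=keep)


def clump(
    ds: SummaryDataset,
    ld: LDInfo | None = None,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000,
) -> SummaryDataset:
    """Greedy LD clumping: keep the best SNP of each correlated cluster.

    SNPs are visited by ascending p (ties broken by rsid, so the result is
    independent of input order); a SNP is accepted iff its r² with every
    already-accepted SNP on the same chromosome within ``window_kb`` is
    below ``r2_threshold``.  With an empty ``ld`` all SNPs are treated as
    independent.
    """
    if ld is None or len(ld) == 0:
        return replace(ds, snps=dict(ds.snps))
    snps = sorted(ds.snps.values(), key=lambda s: (s.pval, s.rsid))
    missing_pos = [s.rsid for s in snps if s.chrom is None or s.pos is None]
    if missing_pos:
        raise InstrumentError(
            "clumping needs chrom/pos for every SNP when LD is supplied "
            f"(missing: {', '.join(missing_pos[:5])}...); provide positions "
            "or pass an empty LDInfo to declare all SNPs independent"
        )
    accepted = []
    for s in snps:
        ok = True
        for a in accepted:
            if a.chrom != s.chrom:
                continue
            if abs(a.pos - s.pos) > window_kb * 1000:
                continue
            if ld.get(a.rsid, s.rsid) >= r2_threshold:
                ok = False
                logger.info("clump: %s removed (r² with %s)", s.rsid, a.rsid)
                break
        if ok:
            accepted.append(s)
    kept = {r: s for r, s in ds.snps.items() if r in {a.rsid for a in accepted}}
    return replace(ds, snps=kept)


def screen_confounders(
    ds: SummaryDataset,
    ann: ConfounderAnnotation,
    confounder_traits=DEFAULT_CONFOUNDERS,
    p_cutoff: float | None = None,
) -> SummaryDataset:
    """Remove SNPs annotated to a confounder trait.

    Matching is case-folded substring containment: a SNP annotated
    "Smoking status" is removed by the confounder term "smoking".  With
    ``p_cutoff`` set, only annotations at p below the cutoff count;
    annotations without a p-value always count.
    """
    terms = [t.casefold() for t in confounder_traits]
    keep = {}
    for rsid, snp in ds.snps.items():
        hit = None
        for trait, pval in ann.for_snp(rsid):
            if p_cutoff is not None and pval is not None and pval >= p_cutoff:
                continue
            if any(term in trait for term in terms):
                hit = trait
                break
        if hit is None:
            keep[rsid] = snp
        else:
            logger.info("confounder screen: %s removed (annotated '%s')", rsid, hit)
    return replace(ds, snps=keep)


def remove_outcome_associated(
    pairs: IntersectResult, p_threshold: float = 5e-8
) -> IntersectResult:
    """Discard pairs whose *outcome* association is genome-wide significant."""
    kept, unmatched = [], list(pairs.unmatched)
    for exp, out in pairs.pairs:
        if out.pval < p_threshold:
            logger.info(
                "outcome-association filter: %s removed (outcome p = %.3g)",
                exp.rsid, out.pval,
            )
        else:
            kept.append((exp, out))
    return IntersectResult(pairs=kept, unmatched=unmatched)


def instrument_strength(ds: SummaryDataset) -> InstrumentDiagnostics:
    """Variance explained and F-statistics, per SNP and overall.

    Per-SNP F uses k = 1; the overall F uses the summed R² with k equal to
    the instrument count and N the exposure GWAS sample size (the maximum
    per-SNP N when they differ).
    """
    r2, f = {}, {}
    n_max = 0
    for snp in ds:
        if snp.eaf is None or snp.n is None:
            raise InstrumentError(f"{snp.rsid}: eaf and n required for strength")
        r2_j = 2.0 * snp.eaf * (1.0 - snp.eaf) * snp.beta**2
        if r2_j >= 1.0:
            raise InstrumentError(f"{snp.rsid}: R² >= 1, malformed input")
        if snp.eaf in (0.0, 1.0):
            logger.warning("%s: monomorphic EAF, R² and F set to 0", snp.rsid)
            r2_j = 0.0
        r2[snp.rsid] = r2_j
        f[snp.rsid] = r2_j / (1.0 - r2_j) * (snp.n - 2) if r2_j > 0 else 0.0
        n_max = max(n_max, snp.n)
    k = len(r2)
    total_r2 = sum(r2.values())
    if k and total_r2 < 1.0:
        overall_f = total_r2 / (1.0 - total_r2) * (n_max - k - 1) / k
    else:
        overall_f = float("nan") if k else 0.0
    return InstrumentDiagnostics(r2=r2, f=f, total_r2=total_r2, overall_f=overall_f, k=k)


def filter_weak(
    ds: SummaryDataset, diag: InstrumentDiagnostics, f_min: float = 10.0
) -> SummaryDataset:
    """Keep SNPs whose per-SNP F is at least ``f_min`` (>=, not >)."""
    keep = {}
    for rsid, snp in ds.snps.items():
        if diag.f.get(rsid, 0.0) >= f_min:
            keep[rsid] = snp
        else:
            logger.info("weak-instrument filter: %s removed (F = %.2f)", rsid, diag.f.get(rsid, 0.0))
    return replace(ds, snps=keep)
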