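"""Instrument QC ladder: significance, clumping, confounders, strength."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_dataset, make_snp
from mrkit.instruments import (
    ConfounderAnnotation,
    InstrumentError,
    LDInfo,
    clump,
    filter_weak,
    instrument_strength,
    remove_outcome_associated,
    screen_confounders,
    select_significant,
)
from mrkit.summary_io import intersect


class TestSelectSignificant:
    @pytest.mark.parametrize(
        "pvals, expected",
        [
            ({"rs1": 1e-9, "rs2": 1e-7}, {"rs1"}),
            ({"rs1": 5e-8}, set()),          # boundary excluded: strict <
            ({}, set()),
        ],
    )
    def test_strict_threshold(self, pvals, expected):
        ds = make_dataset([make_snp(r, pval=p) for r, p in pvals.items()])
        assert set(select_significant(ds).rsids) == expected

    def test_idempotent(self):
        ds = make_dataset([make_snp("rs1", pval=1e-9), make_snp("rs2", pval=1e-3)])
        once = select_significant(ds)
        assert select_significant(once).rsids == once.rsids


def brute_force_clump(snps, ld, r2_threshold, window_kb):
    """Independent oracle: explicit greedy pass over (pval, rsid)-sorted SNPs."""
    kept = []
    for s in sorted(snps, key=lambda s: (s.pval, s.rsid)):
        if all(
            a.chrom != s.chrom
            or abs(a.pos - s.pos) > window_kb * 1000
            or ld.get(a.rsid, s.rsid) < r2_threshold
            for a in kept
        ):
            kept.append(s)
    return {s.rsid for s in kept}


class TestClump:
    def two_snp_case(self, r2, dist_kb, p1=1e-20, p2=1e-10):
        s1 = make_snp("rs1", pval=p1, chrom="1", pos=1_000_000)
        s2 = make_snp("rs2", pval=p2, chrom="1", pos=1_000_000 + int(dist_kb * 1000))
        ld = LDInfo()
        ld.set("rs1", "rs2", r2)
        return make_dataset([s1, s2]), ld

    def test_correlated_pair_keeps_best_pvalue(self):
        ds, ld = self.two_snp_case(r2=0.5, dist_kb=5000)
        assert clump(ds, ld).rsids == ["rs1"]

    def test_low_r2_pair_both_kept(self):
        ds, ld = self.two_snp_case(r2=0.0005, dist_kb=5000)
        assert set(clump(ds, ld).rsids) == {"rs1", "rs2"}

    def test_outside_window_both_kept(self):
        ds, ld = self.two_snp_case(r2=0.9, dist_kb=20_000)
        assert set(clump(ds, ld).rsids) == {"rs1", "rs2"}

    def test_empty_ld_means_independent(self):
        ds = make_dataset([make_snp("rs1"), make_snp("rs2")])
        assert set(clump(ds, LDInfo()).rsids) == {"rs1", "rs2"}

    def test_missing_positions_with_ld_raises(self):
        ld = LDInfo()
        ld.set("rs1", "rs2", 0.5)
        ds = make_dataset([make_snp("rs1"), make_snp("rs2")])
        with pytest.raises(InstrumentError, match="chrom/pos"):
            clump(ds, ld)

    def test_equal_pvalues_tie_break_lexicographic(self):
        ds, ld = self.two_snp_case(r2=0.9, dist_kb=100, p1=1e-10, p2=1e-10)
        assert clump(ds, ld).rsids == ["rs1"]

    @given(st.data())
    def test_matches_brute_force_oracle_and_permutation_invariant(self, data):
        n = data.draw(st.integers(3, 8))
        rs = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        snps = [
            make_snp(
                f"rs{i}", pval=float(rs.uniform(1e-12, 1e-8)),
                chrom=str(rs.integers(1, 3)),
                pos=int(rs.integers(0, 3) * 4_000_000),
            )
            for i in range(n)
        ]
        ld = LDInfo()
        for a, b in itertools.combinations(range(n), 2):
            if rs.random() < 0.4:
                ld.set(f"rs{a}", f"rs{b}", float(rs.random()))
        expected = brute_force_clump(snps, ld, 0.001, 10_000)
        assert set(clump(make_dataset(snps), ld).rsids) == expected
        perm = list(rs.permutation(n))
        shuffled = make_dataset([snps[i] for i in perm])
        assert set(clump(shuffled, ld).rsids) == expected


class TestConfounderScreen:
    def annotated(self, trait):
        ann = ConfounderAnnotation()
        ann.add("rs1", trait)
        return ann

    def test_substring_match_removes(self):
        ds = make_dataset([make_snp("rs1")])
        out = screen_confounders(ds, self.annotated("Smoking status"), {"smoking"})
        assert len(out) == 0

    def test_benign_trait_retained(self):
        ds = make_dataset([make_snp("rs1")])
        out = screen_confounders(ds, self.annotated("standing height"), {"smoking"})
        assert out.rsids == ["rs1"]

    def test_empty_annotation_is_noop(self):
        ds = make_dataset([make_snp("rs1"), make_snp("rs2")])
        assert screen_confounders(ds, ConfounderAnnotation()).rsids == ds.rsids

    def test_p_cutoff_spares_weak_associations(self):
        ann = ConfounderAnnotation()
        ann.add("rs1", "smoking status", 0.04)
        ds = make_dataset([make_snp("rs1")])
        assert len(screen_confounders(ds, ann, {"smoking"}, p_cutoff=1e-5)) == 1
        assert len(screen_confounders(ds, ann, {"smoking"})) == 0


class TestOutcomeAssociated:
    def paired(self, outcome_pval):
        exp = make_dataset([make_snp("rs1")])
        out = make_dataset([make_snp("rs1", pval=outcome_pval)], role="outcome")
        return intersect(exp, out)

    def test_genomewide_outcome_hit_removed(self):
        assert len(remove_outcome_associated(self.paired(6.5e-13))) == 0

    def test_modest_outcome_association_retained(self):
        assert len(remove_outcome_associated(self.paired(1e-3))) == 1

    def test_empty_pairs(self):
        exp = make_dataset([make_snp("rs1")])
        out = make_dataset([make_snp("rs9")], role="outcome")
        assert len(remove_outcome_associated(intersect(exp, out))) == 0


class TestInstrumentStrength:
    def test_printed_formula_worked_example(self):
        ds = make_dataset([make_snp("rs1", eaf=0.5, beta=0.1, n=602_604)])
        diag = instrument_strength(ds)
        assert diag.r2["rs1"] == pytest.approx(0.005, abs=1e-12)
        assert diag.f["rs1"] == pytest.approx(3028.2, abs=0.1)
        assert diag.overall_f == pytest.approx(diag.f["rs1"])

    def test_zero_effect_gives_zero_strength(self):
        ds = make_dataset([make_snp("rs1", eaf=0.5, beta=0.0)])
        diag = instrument_strength(ds)
        assert diag.r2["rs1"] == 0.0 and diag.f["rs1"] == 0.0

    def test_total_r2_is_additive(self):
        ds = make_dataset([make_snp("rs1", eaf=0.4, beta=0.1),
                           make_snp("rs2", eaf=0.4, beta=0.1)])
        diag = instrument_strength(ds)
        assert diag.total_r2 == pytest.approx(2 * diag.r2["rs1"])
        assert diag.k == 2

    def test_r2_invariant_under_allele_relabeling(self):
        a = make_dataset([make_snp("rs1", eaf=0.2, beta=0.1)])
        b = make_dataset([make_snp("rs1", eaf=0.8, beta=-0.1)])
        assert instrument_strength(a).r2["rs1"] == pytest.approx(
            instrument_strength(b).r2["rs1"]
        )

    def test_monomorphic_snp_warned_zeroed(self):
        ds = make_dataset([make_snp("rs1", eaf=1.0, beta=0.1)])
        diag = instrument_strength(ds)
        assert diag.f["rs1"] == 0.0

    def test_malformed_r2_raises(self):
        ds = make_dataset([make_snp("rs1", eaf=0.5, beta=2.0)])
        with pytest.raises(InstrumentError, match="R"):
            instrument_strength(ds)


class TestFilterWeak:
    @pytest.mark.parametrize("beta, kept", [(0.0057, False), (0.0058, True)])
    def test_f_threshold_is_inclusive(self, beta, kept):
        # with EAF 0.5 and n 602604, beta 0.0058 puts F just above 10
        ds = make_dataset([make_snp("rs1", eaf=0.5, beta=beta, n=602_604)])
        diag = instrument_strength(ds)
        assert (len(filter_weak(ds, diag)) == 1) == kept

    def test_exact_boundary_retained(self):
        ds = make_dataset([make_snp("rs1", eaf=0.5, beta=0.1, n=602_604)])
        diag = instrument_strength(ds)
        diag.f["rs1"] = 10.0
        assert filter_weak(ds, diag).rsids == ["rs1"]

    def test_all_strong_unchanged_and_idempotent(self):
        ds = make_dataset([make_snp("rs1", eaf=0.5, beta=0.1, n=602_604),
                           make_snp("rs2", eaf=0.3, beta=0.08, n=602_604)])
        diag = instrument_strength(ds)
        once = filter_weak(ds, diag)
        assert once.rsids == ds.rsids
        assert filter_weak(once, diag).rsids == once.rsids
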