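"""Pileup tallies, the 90%/70% classifier, update policy, mini-contigs."""

import numpy as np
import pytest
from scipy import stats

from asmeval import base_validation as bv
from asmeval import simulate as sim
from asmeval.formats import DEL, INS, SNV, FormatError, VariantSite


def read(start, seq, ops, mapq=60, name="r", flag=0x1 | 0x40):
    return sim.SimulatedRead(name, flag, "ctg", start, mapq, ops, seq)


REF = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"  # 40 bp toy contig


class TestPileupTally:
    def test_mapq_filter_drops_low_quality_alt(self):
        site = VariantSite("ctg", 10, REF[10], "A", "s1", SNV)
        reads = [read(0, REF[0:30], [(0, 30)], name=f"r{i}") for i in range(30)]
        alt_seq = REF[0:10] + "A" + REF[11:30]
        reads.append(read(0, alt_seq, [(0, 30)], mapq=10, name="low"))
        (tally,) = bv.pileup_tally(reads, [site])
        assert tally.counts == {REF[10]: 30}
        assert tally.depth == 30

    def test_no_reads_gives_depth_zero(self):
        site = VariantSite("ctg", 10, REF[10], "A", "s1", SNV)
        (tally,) = bv.pileup_tally([], [site])
        assert tally.depth == 0
        assert bv.classify_site(tally).call == bv.NO_DATA

    def test_spanning_deletion_counted_as_del_allele(self):
        site = VariantSite("ctg", 10, REF[10], "A", "s1", SNV)
        rec = read(0, REF[0:8] + REF[14:30], [(0, 8), (2, 6), (0, 16)])
        (tally,) = bv.pileup_tally([rec], [site])
        assert tally.counts == {bv.DEL_ALLELE: 1}
        assert "unexpected_allele" in tally.flags

    def test_insertion_alleles(self):
        site = VariantSite("ctg", 9, REF[9], REF[9] + "TT", "s1", INS)
        with_ins = read(0, REF[0:10] + "TT" + REF[10:28], [(0, 10), (1, 2), (0, 18)])
        without = read(0, REF[0:30], [(0, 30)])
        (tally,) = bv.pileup_tally([with_ins, without], [site])
        assert tally.counts == {"alt": 1, "ref": 1}

    def test_deletion_requires_spanning_reads(self):
        site = VariantSite("ctg", 9, REF[9:12], REF[9], "s1", DEL)
        with_del = read(0, REF[0:10] + REF[12:32], [(0, 10), (2, 2), (0, 20)])
        spanning_ref = read(0, REF[0:30], [(0, 30)])
        ends_at_anchor = read(0, REF[0:10], [(0, 10)])
        (tally,) = bv.pileup_tally([with_del, spanning_ref, ends_at_anchor], [site])
        assert tally.counts == {"alt": 1, "ref": 1}  # short read not assessable

    def test_ref_allele_checked_against_reference(self):
        site = VariantSite("ctg", 10, "X", "A", "s1", SNV)
        with pytest.raises(FormatError, match="ref allele"):
            bv.pileup_tally([], [site], reference={"ctg": REF})

    def test_site_beyond_contig_rejected(self):
        site = VariantSite("ctg", 99, "A", "C", "s1", SNV)
        with pytest.raises(FormatError, match="beyond"):
            bv.pileup_tally([], [site], reference={"ctg": REF})

    def test_sam_file_path_input(self, tmp_path):
        site = VariantSite("ctg", 10, REF[10], "A", "s1", SNV)
        reads = [read(0, REF[0:30], [(0, 30)], name=f"r{i}") for i in range(5)]
        path = str(tmp_path / "reads.sam")
        sim.write_sam(reads, [("ctg", len(REF))], path)
        (tally,) = bv.pileup_tally(path, [site])
        assert tally.depth == 5


def snv_tally(counts, ref="C", alt="A"):
    site = VariantSite("ctg", 10, ref, alt, "s", SNV)
    t = bv.AlleleTally(site, counts)
    expected = {ref, alt}
    if len(counts) > 2:
        t.flags.add("multi_allelic")
    if any(a not in expected for a in counts):
        t.flags.add("unexpected_allele")
    return t


class TestClassifySite:
    def test_ninety_percent_cutoff_hom_ref(self):
        cls = bv.classify_site(snv_tally({"C": 28, "A": 2}))
        assert cls.call == bv.HOM_REF
        assert cls.majority_fraction == pytest.approx(28 / 30)

    def test_balanced_alleles_het(self):
        assert bv.classify_site(snv_tally({"C": 15, "A": 15})).call == bv.HET

    def test_three_alleles_review(self):
        cls = bv.classify_site(snv_tally({"C": 10, "A": 10, "G": 5}))
        assert cls.call == bv.REVIEW

    def test_boundary_fraction_counts_as_homozygous(self):
        assert bv.classify_site(snv_tally({"A": 27, "C": 3})).call == bv.HOM_ALT
        assert bv.classify_site(snv_tally({"A": 26, "C": 4})).call == bv.HET

    def test_indel_cutoff_seventy_percent(self):
        site = VariantSite("ctg", 10, "C", "CT", "s", INS)
        t = bv.AlleleTally(site, {"alt": 7, "ref": 3})
        assert bv.classify_site(t).call == bv.HOM_ALT
        t2 = bv.AlleleTally(site, {"alt": 6, "ref": 4})
        assert bv.classify_site(t2).call == bv.HET


class TestDecideUpdate:
    SNV_SITE = VariantSite("ctg", 10, "C", "A", "s", SNV)
    INS_SITE = VariantSite("ctg", 10, "C", "CT", "s", INS)

    @pytest.mark.parametrize(
        "site,call,in_source,expected",
        [
            ("SNV_SITE", bv.HOM_ALT, False, bv.APPLY_UPDATE),
            ("SNV_SITE", bv.HOM_REF, False, bv.RETAIN_REFERENCE),
            ("SNV_SITE", bv.HET, True, bv.RETAIN_REFERENCE),
            ("SNV_SITE", bv.HET, False, bv.MANUAL_REVIEW),
            ("SNV_SITE", bv.REVIEW, True, bv.MANUAL_REVIEW),
            ("SNV_SITE", bv.NO_DATA, True, bv.MANUAL_REVIEW),
            ("INS_SITE", bv.HET, True, bv.MANUAL_REVIEW),
            ("INS_SITE", bv.HOM_ALT, False, bv.APPLY_UPDATE),
        ],
    )
    def test_policy(self, site, call, in_source, expected):
        decision = bv.decide_update(
            getattr(self, site), bv.SiteClassification(call, 0.8), in_source
        )
        assert decision.decision == expected

    def test_pure_function(self):
        cls = bv.SiteClassification(bv.HET, 0.6)
        d1 = bv.decide_update(self.SNV_SITE, cls, True)
        d2 = bv.decide_update(self.SNV_SITE, cls, True)
        assert (d1.decision, d1.reason) == (d2.decision, d2.reason)


class TestHetRecovery:
    def test_het_rate_tracks_binomial_at_small_panel(self):
        """Depth-30 HET SNV panel: observed HET rate near the closed-form
        P(4 <= Binomial(30, 1/2) <= 26) (full-scale check in acceptance)."""
        n = 400
        name, ref, sites, genos = sim.site_panel(n, seed=21)
        reads = sim.simulate_site_reads(name, ref, sites, genos, depth=30, seed=21)
        tallies = bv.pileup_tally(reads, sites)
        calls = [bv.classify_site(t).call for t in tallies]
        het_rate = calls.count(bv.HET) / n
        p = stats.binom.cdf(26, 30, 0.5) - stats.binom.cdf(3, 30, 0.5)
        assert abs(het_rate - p) < 4 * np.sqrt(p * (1 - p) / n)


WINDOW = (
    "TTGACCAGTAGGCATCAGGTCCAGAACTTAT"
    "GCACAGGTTCAATCGATCAGGCATCAGGTA"
)  # 61-base toy window


class TestMiniContig:
    def test_expected_substitution_passes(self):
        site = VariantSite("w", 30, WINDOW[30], "G", "s", SNV)
        contig = WINDOW[:30] + "G" + WINDOW[31:]
        result = bv.validate_minicontig(contig, WINDOW, site, 0)
        assert result.passed
        assert result.differences == [("sub", 30, WINDOW[30], "G")]

    def test_extra_mismatch_fails_with_both_reported(self):
        site = VariantSite("w", 30, WINDOW[30], "G", "s", SNV)
        contig = WINDOW[:30] + "G" + WINDOW[31:]
        contig = contig[:10] + ("A" if contig[10] != "A" else "C") + contig[11:]
        result = bv.validate_minicontig(contig, WINDOW, site, 0)
        assert not result.passed
        assert len(result.differences) == 2

    def test_single_base_deletion_hand_checked(self):
        # deleting window base 31 leaves one 1-base deletion at the site
        site = VariantSite("w", 30, WINDOW[30:32], WINDOW[30], "s", DEL)
        contig = WINDOW[:31] + WINDOW[32:]
        result = bv.validate_minicontig(contig, WINDOW, site, 0)
        assert result.passed
        assert result.differences[0][0] == "del"

    def test_insertion_passes(self):
        site = VariantSite("w", 30, WINDOW[30], WINDOW[30] + "AC", "s", INS)
        contig = WINDOW[:31] + "AC" + WINDOW[31:]
        result = bv.validate_minicontig(contig, WINDOW, site, 0)
        assert result.passed

    def test_unalignable_contig_rejected(self):
        site = VariantSite("w", 30, WINDOW[30], "G", "s", SNV)
        contig = "T" * 60
        with pytest.raises(bv.MiniContigError):
            bv.validate_minicontig(contig, WINDOW, site, 0)

    def test_window_offset_coordinates(self):
        # site at assembly position 1030 inside a window starting at 1000
        site = VariantSite("w", 1030, WINDOW[30], "G", "s", SNV)
        contig = WINDOW[:30] + "G" + WINDOW[31:]
        result = bv.validate_minicontig(contig, WINDOW, site, 1000)
        assert result.passed
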