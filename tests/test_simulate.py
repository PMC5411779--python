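"""Simulator: determinism, donor composition, event semantics, read truth."""

import numpy as np
import pytest
from scipy import stats

from asmeval import simulate as sim
from asmeval.formats import GenomicInterval, Unprojectable, project_coordinate


class TestDonor:
    def test_same_seed_identical_output(self, small_config):
        d1 = sim.build_donor(small_config)
        d2 = sim.build_donor(small_config)
        assert d1.sequences == d2.sequences

    def test_satellite_array_length(self, small_donor, small_config):
        for iv in small_donor.satellites.values():
            assert len(iv) == (
                small_config.satellite_monomer_length
                * small_config.satellite_copy_count
            )

    def test_gc_fraction_within_binomial_tolerance(self):
        # at n = 1 Mb, 3 binomial SD on the GC fraction is ~0.0015 << 0.02
        cfg = sim.SimConfig(
            n_chromosomes=1, chromosome_length=1_000_000, segdup_count=1, seed=3
        )
        donor = sim.build_donor(cfg)
        seq = donor.sequences["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - cfg.gc_fraction) < 0.02

    def test_segdup_copies_high_identity(self, small_donor):
        for a, b in small_donor.segdup_pairs:
            s1 = small_donor.sequences[a.seq_id][a.start : a.end]
            s2 = small_donor.sequences[b.seq_id][b.start : b.end]
            identity = sum(x == y for x, y in zip(s1, s2)) / len(s1)
            assert identity >= 0.95

    def test_oversized_features_rejected(self):
        cfg = sim.SimConfig(chromosome_length=30_000, segdup_length=20_000)
        with pytest.raises(sim.SimConfigError):
            sim.build_donor(cfg)


class TestDeriveAssemblyPair:
    def test_no_events_identical_assemblies_single_blocks(self, small_donor):
        pair = sim.derive_assembly_pair(small_donor, [])
        assert pair.A.sequences == pair.B.sequences
        assert len(pair.truth.blocks) == len(small_donor.sequences)
        assert all(b.pass_class == "RECIPROCAL" for b in pair.truth.blocks)

    def test_gap_closure_lengths(self, small_donor, small_config):
        loc = GenomicInterval("chr1", 40_000, 46_000)
        pair = sim.derive_assembly_pair(small_donor, [sim.gap_closure(loc)])
        assert "N" * small_config.default_gap_length in pair.A.sequences["chr1"]
        a_ungapped = len(pair.A.sequences["chr1"]) - pair.A.sequences["chr1"].count("N")
        b_ungapped = len(pair.B.sequences["chr1"]) - pair.B.sequences["chr1"].count("N")
        # the default 50-kb gap in A stands in for only 6 kb of real sequence
        assert b_ungapped - a_ungapped == 6_000
        assert pair.truth.new_sequence_bed[0].end - pair.truth.new_sequence_bed[0].start == 6_000

    def test_false_duplication_truth_labels(self, small_donor):
        loc = GenomicInterval("chr1", 40_000, 60_000)
        ev = sim.false_duplication(loc, "chr1", 100_000, applies_to="A")
        pair = sim.derive_assembly_pair(small_donor, [ev])
        assert pair.truth.label_length("A", sim.EXPANDED) == 20_000
        assert pair.truth.label_length("B", sim.COLLAPSED) == 20_000

    def test_overlapping_events_rejected(self, small_donor):
        ev1 = sim.gap_closure(GenomicInterval("chr1", 40_000, 46_000))
        ev2 = sim.inversion(GenomicInterval("chr1", 43_000, 48_000))
        with pytest.raises(sim.SimEventError, match="overlapping"):
            sim.derive_assembly_pair(small_donor, [ev1, ev2])

    def test_event_past_chromosome_end_rejected(self, small_donor):
        ev = sim.gap_closure(GenomicInterval("chr1", 295_000, 305_000))
        with pytest.raises(sim.SimEventError, match="past"):
            sim.derive_assembly_pair(small_donor, [ev])

    def test_alt_locus_only_in_full_assembly(self, small_donor):
        ev = sim.alt_locus(GenomicInterval("chr2", 40_000, 44_000))
        pair = sim.derive_assembly_pair(small_donor, [ev])
        assert not set(pair.B.sequences) & set(pair.B.alt_sequences)
        assert pair.B.roles["alt1"] == "alternate"
        assert len(pair.B.alt_sequences["alt1"]) == 4_000

    def test_retile_changes_component_not_sequence(self, small_donor):
        loc = GenomicInterval("chr2", 40_000, 50_000)
        pair = sim.derive_assembly_pair(small_donor, [sim.retile(loc)])
        assert pair.A.sequences == pair.B.sequences
        comps_a = {r.component_id for r in pair.A.agp if r.kind == "component"}
        comps_b = {r.component_id for r in pair.B.agp if r.kind == "component"}
        assert len(comps_a ^ comps_b) == 2  # exactly the swapped tiling path

    def test_truth_unique_round_trip_identity(self, small_pair):
        """Projecting a truth-UNIQUE base of A through truth blocks and back
        is the identity (label/alignment mutual consistency)."""
        from asmeval.formats import invert_block

        recip = [b for b in small_pair.truth.blocks if b.is_reciprocal]
        inv = [invert_block(b) for b in recip]
        checked = 0
        for seq_id, runs in small_pair.truth.labels["A"].items():
            for s, e, lab in runs:
                if lab != sim.UNIQUE:
                    continue
                for pos in range(s, e, max(1, (e - s) // 10)):
                    for b, bi in zip(recip, inv):
                        if b.query.seq_id == seq_id and b.query.contains(pos):
                            back = project_coordinate(bi, project_coordinate(b, pos))
                            assert back == pos
                            checked += 1
        assert checked > 50

    def test_expanded_collapsed_totals_per_side(self, small_pair):
        events = small_pair.truth.events
        dup_a = sum(
            len(e.donor_locus)
            for e in events
            if e.kind == sim.FALSE_DUPLICATION and e.applies_to == "A"
        )
        dup_b = sum(
            len(e.donor_locus)
            for e in events
            if e.kind == sim.FALSE_DUPLICATION and e.applies_to == "B"
        )
        col = sum(len(e.donor_locus) for e in events if e.kind == sim.COLLAPSE)
        assert small_pair.truth.label_length("A", sim.EXPANDED) == dup_a
        assert small_pair.truth.label_length("B", sim.EXPANDED) == dup_b + col
        assert small_pair.truth.label_length("A", sim.COLLAPSED) == dup_b + col
        assert small_pair.truth.label_length("B", sim.COLLAPSED) == dup_a


class TestReads:
    def test_error_free_reads_match_source(self, small_pair, small_config):
        reads = sim.simulate_reads(small_pair, None, small_config)
        sources = {s.name: s for s in sim.build_sample(small_pair)}
        for rid, r1, r2 in reads.fastq[:200]:
            name = rid.rsplit("p", 1)[0]
            assert r1 in sources[name].seq
            assert sim.revcomp(r2) in sources[name].seq

    def test_pair_count_poisson_tolerance(self):
        cfg = sim.SimConfig(
            n_chromosomes=1, chromosome_length=1_000_000, segdup_count=1,
            depth=30.0, seed=5,
        )
        donor = sim.build_donor(cfg)
        pair = sim.derive_assembly_pair(donor, [])
        reads = sim.simulate_reads(pair, None, cfg)
        lam = 30 * 1_000_000 / (2 * 150)
        assert abs(reads.n_pairs() - lam) < 3 * np.sqrt(lam)

    def test_gap_closure_reads_unmapped_a_mapped_b(self, small_donor, small_config):
        loc = GenomicInterval("chr1", 40_000, 46_000)
        pair = sim.derive_assembly_pair(small_donor, [sim.gap_closure(loc)])
        reads = sim.simulate_reads(pair, None, small_config)
        status = {}
        for target in ("A", "B"):
            for rec in reads.sam[target]:
                status.setdefault((rec.query_name, rec.is_read2), {})[target] = rec
        inside = 0
        for key, recs in status.items():
            b = recs["B"]
            if b.is_unmapped or b.reference_name != "chr1":
                continue
            if not (40_000 <= b.reference_start and b.reference_end <= 46_000):
                continue
            inside += 1
            assert recs["A"].is_unmapped
        assert inside > 50

    def test_determinism(self, small_pair, small_config):
        r1 = sim.simulate_reads(small_pair, None, small_config)
        r2 = sim.simulate_reads(small_pair, None, small_config)
        assert r1.fastq == r2.fastq
        assert [x.to_sam() for x in r1.sam["A"]] == [x.to_sam() for x in r2.sam["A"]]


@pytest.fixture(scope="module")
def planted(small_pair):
    return sim.plant_candidate_sites(
        small_pair,
        n_sites=30,
        type_mix={"SNV": 0.5, "INS": 0.25, "DEL": 0.25},
        genotype_mix={"HOM_REF": 0.2, "HET": 0.5, "HOM_ALT": 0.3},
    )


class TestCandidateSites:

    def test_mix_counts_exact(self, planted):
        from collections import Counter

        # 30 * {0.5, 0.25, 0.25} with the largest-remainder tie going to the
        # alphabetically first type
        assert Counter(s.site_type for s in planted.sites) == {
            "SNV": 15, "DEL": 8, "INS": 7,
        }
        assert Counter(planted.genotypes.values()) == {
            "HET": 15, "HOM_ALT": 9, "HOM_REF": 6,
        }

    def test_minicontig_single_difference(self, planted, small_pair):
        for sid, contig, window in planted.minicontigs:
            site = next(s for s in planted.sites if s.site_id == sid)
            ref_win = small_pair.A.sequences[window.seq_id][window.start : window.end]
            n_diff = sum(a != b for a, b in zip(contig, ref_win))
            if site.site_type == "SNV":
                assert n_diff == 1
            else:
                assert contig != ref_win
                assert len(contig) - len(ref_win) == (
                    len(site.alt_allele) - len(site.ref_allele)
                )

    def test_hom_alt_sites_alt_on_both_haplotypes(self, planted, small_pair):
        def donor_pos(site):
            for en in small_pair._maps["A"][site.seq_id]:
                if (
                    en.kind == "run"
                    and en.seq_id == site.seq_id
                    and en.asm_start <= site.pos < en.asm_start + (en.donor_end - en.donor_start)
                ):
                    return en.donor_start + (site.pos - en.asm_start)
            raise AssertionError("site not on an unchanged run")

        for sid, geno in planted.genotypes.items():
            site = next(s for s in planted.sites if s.site_id == sid)
            dpos = donor_pos(site)
            edits = [
                e
                for hap in (1, 2)
                for e in planted.hap_edits[hap].get(site.seq_id, [])
                if e.donor_pos == dpos
            ]
            assert len(edits) == {"HOM_REF": 0, "HET": 1, "HOM_ALT": 2}[geno]

    def test_too_many_sites_rejected(self, small_pair):
        with pytest.raises(sim.SimEventError, match="cannot plant"):
            sim.plant_candidate_sites(small_pair, n_sites=100_000)

    def test_het_pileup_alt_fraction(self):
        """Simulated HET pileups at depth 40 keep the alternate fraction
        within 3 binomial SD of one half."""
        name, ref, sites, genos = sim.site_panel(40, seed=9)
        reads = sim.simulate_site_reads(name, ref, sites, genos, depth=40, seed=9)
        from asmeval.base_validation import pileup_tally

        tallies = pileup_tally(reads, sites)
        sd3 = 3 * np.sqrt(0.25 / 40)
        for t in tallies:
            assert t.depth == 40
            alt = t.counts.get(t.site.alt_allele, 0)
            # per-site fractions fluctuate; check the mean over the panel
        mean_alt = np.mean(
            [t.counts.get(t.site.alt_allele, 0) / t.depth for t in tallies]
        )
        assert abs(mean_alt - 0.5) < 3 * np.sqrt(0.25 / (40 * len(tallies)))
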