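"""Read movement: unchanged regions, eligibility, detection, taxonomy, rescue."""

import pytest

from asmeval import read_movement as rm
from asmeval.formats import FormatError, GenomicInterval, ReadPlacement, parse_agp


def agp(text):
    return parse_agp(text)


def placement(rid, mate, sid="chr1", pos=1000, mapq=60, mapped=True, primary=True,
              length=150):
    span = GenomicInterval(sid, pos, pos + length) if mapped else None
    return ReadPlacement(rid, mate, sid if mapped else None,
                         pos if mapped else None, mapq, mapped, primary, span)


class TestUnchangedRegions:
    def test_identical_rows_full_pair(self):
        rows = "chr1\t1\t1000\t1\tW\tC1.1\t1\t1000\t+\n"
        (pair,) = rm.unchanged_regions(agp(rows), agp(rows))
        assert (pair.interval_on_a.start, pair.interval_on_a.end) == (0, 1000)
        assert pair.interval_on_a == pair.interval_on_b
        assert pair.component_id == "C1.1"

    def test_orientation_mismatch_excluded(self):
        a = agp("chr1\t1\t1000\t1\tW\tC1.1\t1\t1000\t+\n")
        b = agp("chr1\t1\t1000\t1\tW\tC1.1\t1\t1000\t-\n")
        assert rm.unchanged_regions(a, b) == []

    def test_partial_component_overlap_brute_force(self):
        # component bases 0..100k in A at offset 0; bases 50k..150k in B at 0.
        # brute-force per-base map: shared component bases are 50k..100k,
        # sitting at A offsets 50k..100k and B offsets 0..50k.
        a = agp("chr1\t1\t100000\t1\tW\tC1.1\t1\t100000\t+\n")
        b = agp("chr1\t1\t100000\t1\tW\tC1.1\t50001\t150000\t+\n")
        (pair,) = rm.unchanged_regions(a, b)
        assert (pair.interval_on_a.start, pair.interval_on_a.end) == (50_000, 100_000)
        assert (pair.interval_on_b.start, pair.interval_on_b.end) == (0, 50_000)

    def test_duplicate_component_span_rejected(self):
        a = agp(
            "chr1\t1\t1000\t1\tW\tC1.1\t1\t1000\t+\n"
            "chr2\t1\t1000\t1\tW\tC1.1\t1\t1000\t+\n"
        )
        b = agp("chr1\t1\t1000\t1\tW\tC1.1\t1\t1000\t+\n")
        with pytest.raises(FormatError, match="placed twice"):
            rm.unchanged_regions(a, b)


REGIONS = [
    rm.UnchangedRegionPair(
        GenomicInterval("chr1", 0, 10_000),
        GenomicInterval("chr1", 0, 10_000),
        "C1.1",
        "+",
    )
]


class TestSelectUniquePairs:
    def test_high_mapq_contained_pair_eligible(self):
        pls = {("r1", 1): placement("r1", 1, pos=100),
               ("r1", 2): placement("r1", 2, pos=400)}
        assert rm.select_unique_pairs(pls, rm.MovementConfig(), REGIONS) == {"r1"}

    def test_low_mapq_mate_excluded(self):
        pls = {("r1", 1): placement("r1", 1, mapq=5),
               ("r1", 2): placement("r1", 2)}
        assert rm.select_unique_pairs(pls, rm.MovementConfig(), REGIONS) == set()

    def test_pair_straddling_region_boundary_excluded(self):
        # containment oracle over the region list: any mate crossing an edge
        # disqualifies the pair
        pls = {("r1", 1): placement("r1", 1, pos=9_900),
               ("r1", 2): placement("r1", 2, pos=5_000)}
        assert rm.select_unique_pairs(pls, rm.MovementConfig(), REGIONS) == set()


AGP_A = (
    "chr1\t1\t10000\t1\tW\tC1.1\t1\t10000\t+\n"
    "chr1\t10001\t20000\t2\tW\tC2.1\t1\t10000\t+\n"
)
AGP_B = (
    "chr1\t1\t10000\t1\tW\tC1.1\t1\t10000\t+\n"
    "chr1\t10001\t20000\t2\tW\tC9.1\t1\t10000\t+\n"
)


class TestDetectMovedPairs:
    def test_same_component_not_moved(self):
        pa = {("r1", 1): placement("r1", 1, pos=100),
              ("r1", 2): placement("r1", 2, pos=400)}
        pb = {("r1", 1): placement("r1", 1, pos=100),
              ("r1", 2): placement("r1", 2, pos=400)}
        records, stats = rm.detect_moved_pairs(
            {"r1"}, pa, pb, agp(AGP_A), agp(AGP_B))
        assert records == [] and stats.n_moved == 0
        assert stats.fraction_moved == 0.0

    def test_component_change_detected_and_version_bump_counts(self):
        pa = {("r1", 1): placement("r1", 1, pos=100),
              ("r1", 2): placement("r1", 2, pos=400)}
        pb = {("r1", 1): placement("r1", 1, pos=12_000),  # lands on C9.1
              ("r1", 2): placement("r1", 2, pos=400)}
        records, stats = rm.detect_moved_pairs(
            {"r1"}, pa, pb, agp(AGP_A), agp(AGP_B))
        assert stats.n_moved == 1 and len(records) == 1
        assert records[0].component_a == "C1.1"
        assert records[0].component_b == "C9.1"
        # a version bump alone is a different component
        agp_b2 = agp(AGP_B.replace("C1.1", "C1.2"))
        records2, stats2 = rm.detect_moved_pairs(
            {"r1"}, pa, {("r1", 1): placement("r1", 1, pos=100),
                         ("r1", 2): placement("r1", 2, pos=400)},
            agp(AGP_A), agp_b2)
        assert stats2.n_moved == 1

    def test_missing_b_record_error_lists_reads(self):
        pa = {("r1", 1): placement("r1", 1), ("r1", 2): placement("r1", 2)}
        with pytest.raises(FormatError, match="r1"):
            rm.detect_moved_pairs({"r1"}, pa, {}, agp(AGP_A), agp(AGP_B))

    def test_fraction_invariant_under_input_order(self):
        import itertools

        pa, pb = {}, {}
        for i, moved in enumerate([True, False, True, False, False]):
            rid = f"r{i}"
            for mate, pos in ((1, 100 + i * 500), (2, 400 + i * 500)):
                pa[(rid, mate)] = placement(rid, mate, pos=pos)
                pb[(rid, mate)] = placement(
                    rid, mate, pos=12_000 if (moved and mate == 1) else pos)
        base = rm.detect_moved_pairs(set(pa and {f"r{i}" for i in range(5)}),
                                     pa, pb, agp(AGP_A), agp(AGP_B))[1]
        for perm in itertools.islice(itertools.permutations(pa.items()), 3):
            shuffled = dict(perm)
            stats = rm.detect_moved_pairs({f"r{i}" for i in range(5)},
                                          shuffled, pb, agp(AGP_A), agp(AGP_B))[1]
            assert stats.fraction_moved == base.fraction_moved == 0.4


class TestClassifyMovement:
    CEN = [GenomicInterval("chr1", 5_000, 6_000), GenomicInterval("scafC", 0, 1_000)]
    ROLES = {"chr1": "chromosome", "chr2": "chromosome",
             "scafU": "unplaced", "scafC": "unplaced"}

    def _record(self, dest_sid, dest_pos):
        return rm.MovementRecord(
            "r1", 1,
            placement("r1", 1, sid="chr1", pos=100),
            placement("r1", 1, sid=dest_sid, pos=dest_pos),
            "C1.1", "CX.1",
        )

    @pytest.mark.parametrize(
        "dest,pos,expected",
        [
            ("chr1", 5_200, rm.ONCEN),   # same chromosome, centromere overlap
            ("chr1", 8_000, rm.ON),      # same chromosome, arm
            ("chr2", 5_200, rm.OFF),     # different chromosome, no centromere
            ("scafU", 100, rm.TOSCAF),   # plain unplaced scaffold
            ("scafC", 5_000, rm.UNCEN),  # centromere-associated scaffold
        ],
    )
    def test_destination_taxonomy(self, dest, pos, expected):
        config = rm.MovementConfig(centromere_bed=self.CEN, roles=self.ROLES)
        assert rm.classify_movement(self._record(dest, pos), config) == expected

    def test_off_chromosome_centromere(self):
        cen = self.CEN + [GenomicInterval("chr2", 5_000, 6_000)]
        config = rm.MovementConfig(centromere_bed=cen, roles=self.ROLES)
        assert rm.classify_movement(self._record("chr2", 5_100), config) == rm.OFFCEN

    def test_destination_without_role_rejected(self):
        config = rm.MovementConfig(centromere_bed=self.CEN, roles={"chr1": "chromosome"})
        with pytest.raises(FormatError, match="role"):
            rm.classify_movement(self._record("chrX", 0), config)


class TestRescueStats:
    def test_zero_denominators_undefined_not_zero(self):
        pls = {("r1", 1): placement("r1", 1), ("r1", 2): placement("r1", 2)}
        stats = rm.rescue_stats(pls, pls, pls, [])
        assert stats.fraction_a_unmapped_rescued is None
        assert stats.fraction_b_unmapped_rescued_full is None

    def test_read_level_fractions(self):
        new_seq = [GenomicInterval("chr1", 0, 5_000)]
        pa = {("r1", 1): placement("r1", 1, mapped=False),
              ("r1", 2): placement("r1", 2),
              ("r2", 1): placement("r2", 1, mapped=False),
              ("r2", 2): placement("r2", 2)}
        pb = {("r1", 1): placement("r1", 1, pos=1_000),
              ("r1", 2): placement("r1", 2),
              ("r2", 1): placement("r2", 1, mapped=False),
              ("r2", 2): placement("r2", 2)}
        pbf = {k: (placement(*k, pos=9_000) if k == ("r2", 1) else v)
               for k, v in pb.items()}
        stats = rm.rescue_stats(pa, pb, pbf, new_seq)
        assert stats.fraction_a_unmapped_rescued == 0.5
        assert stats.fraction_rescued_in_new_sequence == 1.0
        assert stats.fraction_b_unmapped_rescued_full == 1.0

    def test_inconsistent_universes_rejected(self):
        pa = {("r1", 1): placement("r1", 1)}
        with pytest.raises(FormatError, match="universe"):
            rm.rescue_stats(pa, {}, {}, [])


class TestComponentPairings:
    def test_counts_sum_and_ordering(self):
        records = []
        for i in range(3):
            records.append(rm.MovementRecord(
                f"r{i}", 1, placement(f"r{i}", 1), placement(f"r{i}", 1, pos=12_000),
                "C1.1", "C9.1"))
        records.append(rm.MovementRecord(
            "r3", 1, placement("r3", 1), placement("r3", 1, pos=12_000),
            "C0.1", "C9.1"))
        pairings = rm.component_pairings(records)
        assert pairings == [("C1.1", "C9.1", 3), ("C0.1", "C9.1", 1)]
        assert sum(n for _, _, n in pairings) == len(records)

    def test_equal_counts_lexicographic(self):
        records = [
            rm.MovementRecord("r1", 1, placement("r1", 1),
                              placement("r1", 1, pos=12_000), "B.1", "X.1"),
            rm.MovementRecord("r2", 1, placement("r2", 1),
                              placement("r2", 1, pos=12_000), "A.1", "X.1"),
        ]
        assert [p[:2] for p in rm.component_pairings(records)] == [
            ("A.1", "X.1"), ("B.1", "X.1")]
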