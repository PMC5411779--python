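"""Format boundaries: AGP, the PAF+rc dialect, and coordinate projection."""

import pytest
from hypothesis import given, settings, strategies as st

from asmeval.formats import (
    AGPError,
    AlignmentBlock,
    GenomicInterval,
    PAFError,
    Segment,
    Unprojectable,
    invert_block,
    parse_agp,
    parse_alignment_table,
    project_coordinate,
    write_agp,
    write_alignment_table,
)

AGP_TEXT = """\
chr1\t1\t1000\t1\tW\tCMP1.1\t1\t1000\t+
chr1\t1001\t51000\t2\tN\t50000\tcontig\tno\tna
chr1\t51001\t52000\t3\tW\tCMP2.1\t1\t1000\t-
"""


class TestAGP:
    def test_component_and_gap_rows(self):
        rows = parse_agp(AGP_TEXT)
        comp, gap, rev = rows
        assert comp.kind == "component"
        assert (comp.object_start, comp.object_end) == (0, 1000)
        assert (comp.component_start, comp.component_end) == (0, 1000)
        assert comp.orientation == "+"
        assert gap.kind == "gap" and gap.gap_length == 50_000
        assert gap.gap_kind == "unspanned"
        assert rev.orientation == "-"

    def test_overlapping_rows_rejected(self):
        bad = (
            "chr1\t1\t600\t1\tW\tC1.1\t1\t600\t+\n"
            "chr1\t500\t700\t2\tW\tC2.1\t1\t201\t+\n"
        )
        with pytest.raises(AGPError, match="chr1 part 2"):
            parse_agp(bad)

    def test_length_mismatch_rejected(self):
        with pytest.raises(AGPError, match="span"):
            parse_agp("chr1\t1\t1000\t1\tW\tC1.1\t1\t900\t+\n")

    def test_round_trip_identity(self):
        rows = parse_agp(AGP_TEXT)
        again = parse_agp(write_agp(rows))
        assert again == rows

    @given(
        st.lists(
            st.tuples(st.booleans(), st.integers(1, 5_000), st.sampled_from("+-")),
            min_size=1,
            max_size=8,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_round_trip_on_random_objects(self, parts):
        lines, pos, comp_idx = [], 0, 0
        for is_gap, length, orient in parts:
            part_no = len(lines) + 1
            if is_gap:
                lines.append(
                    f"obj\t{pos + 1}\t{pos + length}\t{part_no}\tN\t{length}\tcontig\tno\tna"
                )
            else:
                comp_idx += 1
                lines.append(
                    f"obj\t{pos + 1}\t{pos + length}\t{part_no}\tW\tC{comp_idx}.1\t1\t{length}\t{orient}"
                )
            pos += length
        rows = parse_agp("\n".join(lines) + "\n")
        assert parse_agp(write_agp(rows)) == rows


PAF_BASE = "q\t1000\t{qs}\t{qe}\t{strand}\tt\t1000\t{ts}\t{te}\t90\t100\t60"


class TestAlignmentTable:
    def test_reciprocal_block_without_cigar(self):
        line = PAF_BASE.format(qs=0, qe=100, strand="+", ts=50, te=150) + "\trc:A:R\n"
        (block,) = parse_alignment_table(line)
        assert block.pass_class == "RECIPROCAL"
        assert len(block.segments) == 1
        assert block.segments[0] == Segment(0, 50, 100)

    def test_nonreciprocal_tag(self):
        line = PAF_BASE.format(qs=0, qe=100, strand="+", ts=50, te=150) + "\trc:A:N\n"
        (block,) = parse_alignment_table(line)
        assert block.pass_class == "NONRECIPROCAL"

    def test_missing_or_unknown_tag_rejected(self):
        line = PAF_BASE.format(qs=0, qe=100, strand="+", ts=50, te=150)
        with pytest.raises(PAFError, match="missing rc"):
            parse_alignment_table(line + "\n")
        with pytest.raises(PAFError, match="unknown reciprocity"):
            parse_alignment_table(line + "\trc:A:X\n")

    def test_cigar_insertion_splits_segments(self):
        # 50=10I40=: hand expansion gives target-side segments
        # query [0,50)->target [200,250) and query [60,100)->target [250,290)
        line = (
            "q\t1000\t0\t100\t+\tt\t1000\t200\t290\t90\t100\t60"
            "\trc:A:R\tcg:Z:50=10I40=\n"
        )
        (block,) = parse_alignment_table(line)
        assert block.segments == [Segment(0, 200, 50), Segment(60, 250, 40)]

    def test_inconsistent_cigar_rejected(self):
        line = (
            "q\t1000\t0\t100\t+\tt\t1000\t200\t290\t90\t100\t60"
            "\trc:A:R\tcg:Z:50=40=\n"
        )
        with pytest.raises(PAFError, match="inconsistent"):
            parse_alignment_table(line)

    def test_write_read_round_trip_with_gaps(self):
        line = (
            "q\t1000\t0\t100\t-\tt\t1000\t200\t295\t90\t100\t60"
            "\trc:A:N\tcg:Z:50=5D10I40=\n"
        )
        blocks = parse_alignment_table(line)
        again = parse_alignment_table(write_alignment_table(blocks))
        assert again[0].segments == blocks[0].segments
        assert again[0].pass_class == blocks[0].pass_class
        assert again[0].strand == blocks[0].strand


def _block(qs, qe, ts, te, strand="+", segments=None):
    return AlignmentBlock(
        GenomicInterval("q", qs, qe),
        GenomicInterval("t", ts, te),
        strand,
        "RECIPROCAL",
        segments or [],
    )


class TestProjection:
    def test_identity_offset_forward(self):
        block = _block(0, 100, 200, 300)
        assert project_coordinate(block, 0) == 200
        assert project_coordinate(block, 99) == 299

    def test_reverse_strand_brute_force(self):
        # enumerate all 100 positions: monotone reversal of the offset
        block = _block(0, 100, 200, 300, strand="-")
        expected = {p: 299 - p for p in range(100)}
        assert {p: project_coordinate(block, p) for p in range(100)} == expected

    def test_insertion_region_unprojectable(self):
        block = _block(
            0, 100, 200, 290, segments=[Segment(0, 200, 50), Segment(60, 250, 40)]
        )
        assert project_coordinate(block, 49) == 249
        assert project_coordinate(block, 60) == 250
        for pos in (50, 55, 59):
            with pytest.raises(Unprojectable):
                project_coordinate(block, pos)
        with pytest.raises(Unprojectable):
            project_coordinate(block, 100)
        with pytest.raises(ValueError):
            project_coordinate(block, -1)

    @given(
        qs=st.integers(0, 500),
        ts=st.integers(0, 500),
        strand=st.sampled_from("+-"),
        ops=st.lists(
            st.tuples(st.sampled_from("=ID"), st.integers(1, 30)),
            min_size=1,
            max_size=6,
        ).filter(lambda ops: any(op == "=" for op, _ in ops)),
    )
    @settings(max_examples=100, deadline=None)
    def test_projection_bijective_and_invertible(self, qs, ts, strand, ops):
        """Composing a block with its inverse is identity on every aligned
        base, and the aligned-position map is a bijection."""
        # normalize: trim leading/trailing indels, build via PAF text
        while ops and ops[0][0] != "=":
            ops.pop(0)
        while ops and ops[-1][0] != "=":
            ops.pop()
        cigar = "".join(f"{n}{op}" for op, n in ops)
        qlen = sum(n for op, n in ops if op in "=I")
        tlen = sum(n for op, n in ops if op in "=D")
        line = (
            f"q\t10000\t{qs}\t{qs + qlen}\t{strand}\tt\t10000\t{ts}\t{ts + tlen}"
            f"\t{qlen}\t{qlen}\t60\trc:A:R\tcg:Z:{cigar}\n"
        )
        (block,) = parse_alignment_table(line)
        inverse = invert_block(block)
        images = {}
        for pos in range(qs, qs + qlen):
            try:
                tpos = project_coordinate(block, pos)
            except Unprojectable:
                continue
            images[pos] = tpos
            assert project_coordinate(inverse, tpos) == pos
        assert len(set(images.values())) == len(images)  # injective
        aligned = sum(n for op, n in ops if op == "=")
        assert len(images) == aligned
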