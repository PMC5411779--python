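"""Core domain types and file-format boundaries.

All coordinates are 0-based half-open internally.  AGP (1-based inclusive)
and VCF (1-based, left-anchored indels) values are converted at the parser
boundary and converted back on write, so the rest of the package works in a
single arithmetic convention.

The assembly-assembly alignment interchange format is PAF with one extra
typed tag, ``rc:A:R`` / ``rc:A:N``, carrying the best-hit reciprocity class
of each block (reciprocal best hits versus second-pass, nonreciprocal best
hits).  An optional ``cg:Z:`` CIGAR tag refines a block into co-linear
ungapped segments; blocks without a CIGAR are single ungapped segments.
"""

from __future__ import annotations

import io
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pysam

RECIPROCAL = "RECIPROCAL"
NONRECIPROCAL = "NONRECIPROCAL"

_PASS_CLASSES = {RECIPROCAL, NONRECIPROCAL}
_RC_CODES = {"R": RECIPROCAL, "N": NONRECIPROCAL}
_RC_CODES_INV = {v: k for k, v in _RC_CODES.items()}


class FormatError(ValueError):
    """Malformed input in one of the supported text formats."""


class AGPError(FormatError):
    pass


class PAFError(FormatError):
    pass


class Unprojectable(Exception):
    """A position has no image under an alignment block.

    Raised when a query offset falls in a query-only (insertion) region of a
    block, or outside the block entirely.  Distinct from :class:`FormatError`
    so that callers can treat "no image" as data, not as corruption.
    """


# ---------------------------------------------------------------------------
# Intervals
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval on a named sequence; strand '.' means unset."""

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end}) on {self.seq_id}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )


# ---------------------------------------------------------------------------
# AGP
# ---------------------------------------------------------------------------

_COMPONENT_TYPES = set("WFADOPG")
_GAP_TYPES = set("NU")


@dataclass
class AGPRow:
    """One component or gap line of an assembly's component map.

    ``object_start``/``object_end`` and ``component_start``/``component_end``
    are 0-based half-open here; the on-disk AGP v2.0 representation is
    1-based inclusive.
    """

    object_id: str
    object_start: int
    object_end: int
    part_number: int
    kind: str  # "component" | "gap"
    component_id: str | None = None
    component_start: int | None = None
    component_end: int | None = None
    orientation: str | None = None
    gap_length: int | None = None
    gap_kind: str | None = None  # "spanned" | "unspanned"

    @property
    def length(self) -> int:
        return self.object_end - self.object_start


def parse_agp(stream: Iterable[str] | str) -> list[AGPRow]:
    """Parse an AGP v2.0 stream into validated, ordered rows.

    Rows are returned in file order; rows of one object must be contiguous,
    non-overlapping and ordered by part_number, and component rows must have
    equal object-span and component-span lengths.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    rows: list[AGPRow] = []
    expected: dict[str, tuple[int, int]] = {}  # object -> (next part, next start)
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) == 1:
            f = line.split()
        if len(f) < 8:
            raise AGPError(f"line {lineno}: expected >=8 AGP columns, got {len(f)}")
        obj, ob, oe, part, ctype = f[0], int(f[1]), int(f[2]), int(f[3]), f[4]
        ob0, oe0 = ob - 1, oe  # to 0-based half-open
        if ctype in _COMPONENT_TYPES:
            if len(f) < 9:
                raise AGPError(f"line {lineno}: component row needs 9 columns")
            cb0, ce0 = int(f[6]) - 1, int(f[7])
            orient = f[8]
            if orient in ("?", "0", "na"):
                orient = "+"
            if orient not in ("+", "-"):
                raise AGPError(f"line {lineno}: bad orientation {f[8]!r}")
            if oe0 - ob0 != ce0 - cb0:
                raise AGPError(
                    f"object {obj} part {part}: object span {oe0 - ob0} != "
                    f"component span {ce0 - cb0}"
                )
            row = AGPRow(obj, ob0, oe0, part, "component", f[5], cb0, ce0, orient)
        elif ctype in _GAP_TYPES:
            gap_len = int(f[5])
            if gap_len < 1:
                raise AGPError(f"object {obj} part {part}: gap_length {gap_len} < 1")
            if oe0 - ob0 != gap_len:
                raise AGPError(
                    f"object {obj} part {part}: object span {oe0 - ob0} != "
                    f"gap_length {gap_len}"
                )
            linkage = f[7] if len(f) > 7 else "no"
            gap_kind = "spanned" if linkage == "yes" else "unspanned"
            row = AGPRow(obj, ob0, oe0, part, "gap", gap_length=gap_len, gap_kind=gap_kind)
        else:
            raise AGPError(f"line {lineno}: unknown component type {ctype!r}")
        nxt_part, nxt_start = expected.get(obj, (1, 0))
        if part != nxt_part:
            raise AGPError(f"object {obj} part {part}: expected part_number {nxt_part}")
        if ob0 != nxt_start:
            raise AGPError(
                f"object {obj} part {part}: starts at {ob0}, expected {nxt_start} "
                "(rows must be contiguous and non-overlapping)"
            )
        if oe0 <= ob0:
            raise AGPError(f"object {obj} part {part}: empty or inverted span")
        expected[obj] = (part + 1, oe0)
        rows.append(row)
    return rows


def write_agp(rows: Sequence[AGPRow]) -> str:
    """Render rows back to AGP v2.0 text (inverse of :func:`parse_agp`)."""
    out = []
    for r in rows:
        if r.kind == "component":
            out.append(
                "\t".join(
                    [
                        r.object_id,
                        str(r.object_start + 1),
                        str(r.object_end),
                        str(r.part_number),
                        "W",
                        r.component_id,
                        str(r.component_start + 1),
                        str(r.component_end),
                        r.orientation,
                    ]
                )
            )
        else:
            linkage = "yes" if r.gap_kind == "spanned" else "no"
            gap_type = "scaffold" if r.gap_kind == "spanned" else "contig"
            out.append(
                "\t".join(
                    [
                        r.object_id,
                        str(r.object_start + 1),
                        str(r.object_end),
                        str(r.part_number),
                        "N",
                        str(r.gap_length),
                        gap_type,
                        linkage,
                        "na",
                    ]
                )
            )
    return "\n".join(out) + "\n"


def agp_by_object(rows: Iterable[AGPRow]) -> dict[str, list[AGPRow]]:
    grouped: dict[str, list[AGPRow]] = {}
    for r in rows:
        grouped.setdefault(r.object_id, []).append(r)
    for obj in grouped:
        grouped[obj].sort(key=lambda r: r.part_number)
    return grouped


# ---------------------------------------------------------------------------
# Alignment blocks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Segment:
    """Ungapped sub-block: equal-length query/target spans."""

    query_start: int
    target_start: int
    length: int


@dataclass
class AlignmentBlock:
    """One best-hit alignment block between two assemblies.

    ``segments`` are sorted by query_start and tile the query monotonically;
    on '-' blocks the target offset decreases as the query offset increases.
    """

    query: GenomicInterval
    target: GenomicInterval
    strand: str
    pass_class: str
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.pass_class not in _PASS_CLASSES:
            raise ValueError(f"bad pass_class {self.pass_class!r}")
        if not self.segments:
            if len(self.query) != len(self.target):
                raise ValueError("ungapped block requires equal query/target lengths")
            tstart = self.target.start
            self.segments = [Segment(self.query.start, tstart, len(self.query))]
        self._validate_segments()

    def _validate_segments(self) -> None:
        prev_q = self.query.start
        prev_t = self.target.end if self.strand == "-" else self.target.start
        for seg in self.segments:
            if seg.length <= 0:
                raise ValueError("zero-length segment")
            if seg.query_start < prev_q:
                raise ValueError("segments not monotone on query")
            if seg.query_start + seg.length > self.query.end:
                raise ValueError("segment exceeds query interval")
            if self.strand == "+":
                if seg.target_start < prev_t:
                    raise ValueError("segments not monotone on target")
                prev_t = seg.target_start + seg.length
            else:
                if seg.target_start + seg.length > prev_t:
                    raise ValueError("segments not reverse-monotone on target")
                prev_t = seg.target_start
            if seg.target_start < self.target.start or (
                seg.target_start + seg.length > self.target.end
            ):
                raise ValueError("segment exceeds target interval")
            prev_q = seg.query_start + seg.length

    @property
    def is_reciprocal(self) -> bool:
        return self.pass_class == RECIPROCAL


def project_coordinate(block: AlignmentBlock, pos: int) -> int:
    """Project a 0-based query offset through a block onto the target.

    Strand-aware linear projection within the containing segment.  Raises
    :class:`Unprojectable` for positions in query-only (insertion) regions or
    outside the block; raises ``ValueError`` for malformed input.
    """
    if not isinstance(pos, int) or isinstance(pos, bool):
        raise ValueError(f"position must be an int, got {pos!r}")
    if pos < 0:
        raise ValueError(f"negative position {pos}")
    starts = [s.query_start for s in block.segments]
    i = bisect_right(starts, pos) - 1
    if i >= 0:
        seg = block.segments[i]
        off = pos - seg.query_start
        if off < seg.length:
            if block.strand == "+":
                return seg.target_start + off
            return seg.target_start + seg.length - 1 - off
    raise Unprojectable(
        f"{block.query.seq_id}:{pos} has no image on {block.target.seq_id}"
    )


def invert_block(block: AlignmentBlock) -> AlignmentBlock:
    """Swap query and target; the per-base map becomes its inverse."""
    segs = [Segment(s.target_start, s.query_start, s.length) for s in block.segments]
    segs.sort(key=lambda s: s.query_start)
    return AlignmentBlock(
        query=block.target,
        target=block.query,
        strand=block.strand,
        pass_class=block.pass_class,
        segments=segs,
    )


def _cigar_to_segments(
    cigar: str, qstart: int, qend: int, tstart: int, tend: int, strand: str
) -> list[Segment]:
    ops: list[tuple[int, str]] = []
    n = ""
    for ch in cigar:
        if ch.isdigit():
            n += ch
        else:
            if not n or ch not in "M=XID":
                raise PAFError(f"bad CIGAR {cigar!r}")
            ops.append((int(n), ch))
            n = ""
    if n:
        raise PAFError(f"bad CIGAR {cigar!r}")
    segs: list[Segment] = []
    t = tstart
    q = qstart if strand == "+" else qend
    for length, op in ops:
        if op in "M=X":
            if strand == "+":
                segs.append(Segment(q, t, length))
                q += length
            else:
                q -= length
                segs.append(Segment(q, t, length))
            t += length
        elif op == "I":  # query-only
            q = q + length if strand == "+" else q - length
        elif op == "D":  # target-only
            t += length
    q_ok = q == (qend if strand == "+" else qstart)
    if not q_ok or t != tend:
        raise PAFError(
            f"CIGAR {cigar!r} inconsistent with intervals "
            f"(query [{qstart},{qend}), target [{tstart},{tend}))"
        )
    if strand == "-":
        segs.reverse()
    return segs


def parse_alignment_table(stream: Iterable[str] | str) -> list[AlignmentBlock]:
    """Parse PAF records carrying the ``rc`` reciprocity tag into blocks.

    Records lacking the tag, or with an unknown reciprocity value, are
    rejected with :class:`PAFError`.  A ``cg:Z:`` tag yields gapped segments;
    otherwise the block is a single ungapped segment.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    blocks: list[AlignmentBlock] = []
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 12:
            raise PAFError(f"line {lineno}: expected >=12 PAF columns")
        qname, qstart, qend = f[0], int(f[2]), int(f[3])
        strand = f[4]
        tname, tstart, tend = f[5], int(f[7]), int(f[8])
        tags = {}
        for tag in f[12:]:
            parts = tag.split(":", 2)
            if len(parts) == 3:
                tags[parts[0]] = (parts[1], parts[2])
        if "rc" not in tags:
            raise PAFError(f"line {lineno}: record rejected, missing rc tag")
        rc_val = tags["rc"][1]
        if rc_val not in _RC_CODES:
            raise PAFError(f"line {lineno}: unknown reciprocity value {rc_val!r}")
        pass_class = _RC_CODES[rc_val]
        query = GenomicInterval(qname, qstart, qend)
        target = GenomicInterval(tname, tstart, tend)
        if "cg" in tags:
            segs = _cigar_to_segments(tags["cg"][1], qstart, qend, tstart, tend, strand)
        else:
            if qend - qstart != tend - tstart:
                raise PAFError(
                    f"line {lineno}: CIGAR-less block with unequal query/target spans"
                )
            segs = []
        blocks.append(AlignmentBlock(query, target, strand, pass_class, segs))
    return blocks


def _segments_to_cigar(block: AlignmentBlock) -> str:
    """Rebuild a target-ordered CIGAR from a block's segments."""
    segs = block.segments if block.strand == "+" else list(reversed(block.segments))
    ops: list[str] = []
    t = block.target.start
    q = block.query.start if block.strand == "+" else block.query.end
    for seg in segs:
        if block.strand == "+":
            if seg.query_start > q:
                ops.append(f"{seg.query_start - q}I")
            q = seg.query_start + seg.length
        else:
            q_hi = seg.query_start + seg.length
            if q > q_hi:
                ops.append(f"{q - q_hi}I")
            q = seg.query_start
        if seg.target_start > t:
            ops.append(f"{seg.target_start - t}D")
        ops.append(f"{seg.length}=")
        t = seg.target_start + seg.length
    return "".join(ops)


def write_alignment_table(
    blocks: Sequence[AlignmentBlock],
    seq_lengths: dict[str, int] | None = None,
) -> str:
    """Render blocks to PAF text with the ``rc`` tag (and ``cg`` when gapped)."""
    seq_lengths = seq_lengths or {}
    lines = []
    for b in blocks:
        aligned = sum(s.length for s in b.segments)
        cols = [
            b.query.seq_id,
            str(seq_lengths.get(b.query.seq_id, b.query.end)),
            str(b.query.start),
            str(b.query.end),
            b.strand,
            b.target.seq_id,
            str(seq_lengths.get(b.target.seq_id, b.target.end)),
            str(b.target.start),
            str(b.target.end),
            str(aligned),
            str(aligned),
            "60",
            f"rc:A:{_RC_CODES_INV[b.pass_class]}",
        ]
        if len(b.segments) > 1 or aligned != len(b.query) or aligned != len(b.target):
            cols.append(f"cg:Z:{_segments_to_cigar(b)}")
        lines.append("\t".join(cols))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Read placements (SAM/BAM boundary)
# ---------------------------------------------------------------------------


@dataclass
class ReadPlacement:
    """The per-mate alignment facts the pipeline consumes from SAM/BAM."""

    read_id: str
    mate: int
    seq_id: str | None
    pos: int | None
    mapq: int
    mapped: bool
    primary: bool
    aligned_span: GenomicInterval | None

    @property
    def midpoint(self) -> int:
        span = self.aligned_span
        return (span.start + span.end - 1) // 2


def iter_placements(path: str) -> Iterator[ReadPlacement]:
    """Yield one ReadPlacement per SAM/BAM record (all records, in order)."""
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for rec in fh:
            mate = 2 if rec.is_read2 else 1
            if rec.is_unmapped:
                yield ReadPlacement(rec.query_name, mate, None, None, 0, False, True, None)
            else:
                span = GenomicInterval(
                    rec.reference_name,
                    rec.reference_start,
                    rec.reference_end,
                    "-" if rec.is_reverse else "+",
                )
                yield ReadPlacement(
                    rec.query_name,
                    mate,
                    rec.reference_name,
                    rec.reference_start,
                    rec.mapping_quality,
                    True,
                    not (rec.is_secondary or rec.is_supplementary),
                    span,
                )


def load_primary_placements(path: str) -> dict[tuple[str, int], ReadPlacement]:
    """Primary placement per (read_id, mate); duplicates are an input error."""
    out: dict[tuple[str, int], ReadPlacement] = {}
    for p in iter_placements(path):
        if not p.primary:
            continue
        key = (p.read_id, p.mate)
        if key in out:
            raise FormatError(f"two primary placements for read {p.read_id}/{p.mate}")
        out[key] = p
    return out


# ---------------------------------------------------------------------------
# Variant sites (VCF boundary)
# ---------------------------------------------------------------------------

SNV = "SNV"
INS = "INS"
DEL = "DEL"


@dataclass
class VariantSite:
    """A candidate site; ``pos`` is the 0-based anchor base.

    For indels the anchor is the base preceding the event (VCF left-anchored
    convention): an INS alt is ref + inserted bases, a DEL ref spans the
    anchor plus the deleted bases.
    """

    seq_id: str
    pos: int
    ref_allele: str
    alt_allele: str
    site_id: str
    site_type: str

    @staticmethod
    def classify_alleles(ref: str, alt: str) -> str:
        if len(ref) == 1 and len(alt) == 1:
            return SNV
        if len(alt) > len(ref) == 1:
            return INS
        if len(ref) > len(alt) == 1:
            return DEL
        raise FormatError(f"unsupported allele pair {ref}>{alt}")


def parse_vcf_sites(path: str) -> list[VariantSite]:
    sites: list[VariantSite] = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            alt = rec.alts[0] if rec.alts else rec.ref
            sites.append(
                VariantSite(
                    rec.chrom,
                    rec.pos - 1,
                    rec.ref,
                    alt,
                    rec.id or f"{rec.chrom}_{rec.pos}",
                    VariantSite.classify_alleles(rec.ref, alt),
                )
            )
    return sites


def write_vcf_sites(
    sites: Sequence[VariantSite],
    contig_lengths: dict[str, int],
    path: str,
    extra_info: dict[str, dict[str, str]] | None = None,
) -> None:
    """Write sites as a minimal uncompressed VCF 4.2 file."""
    lines = ["##fileformat=VCFv4.2"]
    for name, length in contig_lengths.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    info_keys = sorted({k for d in (extra_info or {}).values() for k in d})
    for k in info_keys:
        lines.append(f'##INFO=<ID={k},Number=1,Type=String,Description="{k}">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for s in sites:
        info = "."
        if extra_info and s.site_id in extra_info:
            info = ";".join(f"{k}={v}" for k, v in sorted(extra_info[s.site_id].items()))
        lines.append(
            f"{s.seq_id}\t{s.pos + 1}\t{s.site_id}\t{s.ref_allele}\t"
            f"{s.alt_allele}\t.\tPASS\t{info}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BED and small table helpers
# ---------------------------------------------------------------------------


def read_bed(path: str) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            strand = f[5] if len(f) > 5 and f[5] in "+-" else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str, names: Sequence[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            cols = [iv.seq_id, str(iv.start), str(iv.end)]
            if names is not None:
                cols.append(names[i])
            fh.write("\t".join(cols) + "\n")


def read_role_table(path: str) -> dict[str, str]:
    """seq_id -> role, one of chromosome/unlocalized/unplaced/alternate."""
    roles = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            seq_id, role = line.split("\t")[:2]
            if role not in ("chromosome", "unlocalized", "unplaced", "alternate"):
                raise FormatError(f"unknown sequence role {role!r} for {seq_id}")
            roles[seq_id] = role
    return roles


def write_role_table(roles: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for seq_id in sorted(roles):
            fh.write(f"{seq_id}\t{roles[seq_id]}\n")
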