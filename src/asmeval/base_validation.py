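"""Validation of candidate reference-error sites from read pileups.

For each candidate site, alleles are tallied from primary alignments with
MAPQ >= 20 (default).  A site is called homozygous when the majority-allele
fraction reaches 90% for SNVs or 70% for indels (boundary counts as
homozygous), heterozygous otherwise; SNV sites with more than two alleles,
or with alleles outside the expected ref/alt pair, are flagged for manual
review.  Heterozygous candidates inside a component derived from the read
sample's own source library are retained — the "error" is a real allele of
that haplotype — while homozygous-alternate calls support applying the
update.  Nonhomozygous-alternate indel calls always go to manual review.

Replacement mini-contigs are accepted only when an end-free affine
alignment against the reference window shows exactly one difference: the
expected alternate allele at the target site.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import pysam
from Bio import Align

from .formats import DEL, INS, SNV, FormatError, VariantSite

HOM_REF = "HOM_REF"
HET = "HET"
HOM_ALT = "HOM_ALT"
REVIEW = "REVIEW"
NO_DATA = "NO_DATA"

APPLY_UPDATE = "APPLY_UPDATE"
RETAIN_REFERENCE = "RETAIN_REFERENCE"
MANUAL_REVIEW = "MANUAL_REVIEW"

DEL_ALLELE = "del"  # spanning deletion observed at an SNV site


class MiniContigError(ValueError):
    """Contig could not be aligned confidently to its reference window."""


@dataclass
class ClassifierParams:
    snv_cutoff: float = 0.90
    indel_cutoff: float = 0.70
    min_mapq: int = 20
    min_depth: int = 1

    def __post_init__(self) -> None:
        for name in ("snv_cutoff", "indel_cutoff"):
            v = getattr(self, name)
            if not (0.5 < v < 1.0):
                raise ValueError(f"{name} must be in (0.5, 1)")

    def cutoff(self, site_type: str) -> float:
        return self.snv_cutoff if site_type == SNV else self.indel_cutoff


@dataclass
class AlleleTally:
    site: VariantSite
    counts: dict[str, int] = field(default_factory=dict)
    flags: set[str] = field(default_factory=set)

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


@dataclass
class SiteClassification:
    call: str  # HOM_REF | HET | HOM_ALT | REVIEW | NO_DATA
    majority_fraction: float | None


@dataclass
class UpdateDecision:
    decision: str  # APPLY_UPDATE | RETAIN_REFERENCE | MANUAL_REVIEW
    reason: str


# ---------------------------------------------------------------------------
# Pileup tallies
# ---------------------------------------------------------------------------


def _site_allele(read, site: VariantSite) -> str | None:
    """Observed allele of one read at one site, or None if not assessable.

    SNV: the base aligned to the site position ('del' for a spanning
    deletion).  INS/DEL: presence ('alt') or absence ('ref') of the
    left-anchored event right after the anchor base; the read must align
    through the whole junction to be counted.
    """
    p = site.pos
    ops = read.cigartuples or []
    r = read.reference_start
    q = 0
    seq = read.query_sequence
    if site.site_type == SNV:
        for op, ln in ops:
            if op in (0, 7, 8):  # M/=/X
                if r <= p < r + ln:
                    return seq[q + (p - r)]
                r += ln
                q += ln
            elif op == 2:  # D
                if r <= p < r + ln:
                    return DEL_ALLELE
                r += ln
            elif op in (1, 4):  # I/S
                q += ln
            elif op == 3:  # N
                r += ln
        return None
    # indels: locate the anchor within a match op
    k_ins = len(site.alt_allele) - 1
    k_del = len(site.ref_allele) - 1
    for i, (op, ln) in enumerate(ops):
        if op in (0, 7, 8):
            if r <= p < r + ln:
                off = p - r
                if off < ln - 1:
                    # read aligns through the junction without an event
                    return _indel_ref_or_none(site, ops, i, r, ln, k_del, p)
                nxt = ops[i + 1] if i + 1 < len(ops) else None
                if nxt is None:
                    return None  # read ends at the anchor
                if site.site_type == INS:
                    if nxt[0] == 1:
                        ins_seq = seq[q + ln : q + ln + nxt[1]]
                        return "alt" if ins_seq == site.alt_allele[1:] else "other"
                    if nxt[0] == 2:
                        return "other"
                    return None  # soft clip: junction not assessable
                # DEL site
                if nxt[0] == 2:
                    return "alt" if nxt[1] == k_del else "other"
                if nxt[0] == 1:
                    return "other"
                return None
            r += ln
            q += ln
        elif op == 2:
            if r <= p < r + ln:
                return None  # anchor itself deleted; not assessable
            r += ln
        elif op in (1, 4):
            q += ln
        elif op == 3:
            r += ln
    return None


def _indel_ref_or_none(site, ops, i, r, ln, k_del, p) -> str | None:
    """For a DEL site, 'ref' only if the read aligns across the whole
    would-be deleted span; INS sites just need the junction."""
    if site.site_type == INS:
        return "ref"
    end_needed = p + 1 + k_del
    # walk forward from op i accumulating matched reference
    ref_end = r + ln
    j = i + 1
    while ref_end < end_needed and j < len(ops):
        op2, ln2 = ops[j]
        if op2 in (0, 7, 8):
            ref_end += ln2
        elif op2 == 2:
            return "other"  # a differently placed deletion over the span
        else:
            break
        j += 1
    return "ref" if ref_end >= end_needed else None


def pileup_tally(
    alignments: str | Iterable,
    sites: list[VariantSite],
    params: ClassifierParams | None = None,
    reference: dict[str, str] | None = None,
) -> list[AlleleTally]:
    """MAPQ-filtered allele tallies at candidate sites.

    ``alignments`` is a SAM/BAM path or an iterable of aligned-segment-like
    records; secondary and supplementary alignments are excluded.  When a
    reference is supplied, each site's ref allele is checked against it.
    """
    params = params or ClassifierParams()
    if reference is not None:
        for s in sites:
            if s.pos + len(s.ref_allele) > len(reference.get(s.seq_id, "")):
                raise FormatError(f"site {s.site_id} beyond end of {s.seq_id}")
            have = reference[s.seq_id][s.pos : s.pos + len(s.ref_allele)]
            if have != s.ref_allele:
                raise FormatError(
                    f"site {s.site_id}: ref allele {s.ref_allele} != assembly {have}"
                )
    by_contig: dict[str, tuple[list[int], list[AlleleTally]]] = {}
    tallies = [AlleleTally(s) for s in sites]
    order: dict[str, list[tuple[int, AlleleTally]]] = {}
    for t in tallies:
        order.setdefault(t.site.seq_id, []).append((t.site.pos, t))
    for contig, items in order.items():
        items.sort(key=lambda x: x[0])
        by_contig[contig] = ([p for p, _ in items], [t for _, t in items])

    if isinstance(alignments, str):
        handle = pysam.AlignmentFile(alignments, check_sq=False)
        records: Iterable = handle
    else:
        handle = None
        records = alignments
    try:
        for read in records:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < params.min_mapq:
                continue
            contig = read.reference_name
            if contig not in by_contig:
                continue
            positions, contig_tallies = by_contig[contig]
            lo = bisect_left(positions, read.reference_start)
            hi = bisect_right(positions, read.reference_end - 1)
            for idx in range(lo, hi):
                t = contig_tallies[idx]
                allele = _site_allele(read, t.site)
                if allele is None:
                    continue
                t.counts[allele] = t.counts.get(allele, 0) + 1
    finally:
        if handle is not None:
            handle.close()

    for t in tallies:
        expected = (
            {t.site.ref_allele, t.site.alt_allele}
            if t.site.site_type == SNV
            else {"ref", "alt"}
        )
        if len(t.counts) > 2:
            t.flags.add("multi_allelic")
        if any(a not in expected for a in t.counts):
            t.flags.add("unexpected_allele")
    return tallies


# ---------------------------------------------------------------------------
# Genotype classification and update decisions
# ---------------------------------------------------------------------------


def classify_site(
    tally: AlleleTally, params: ClassifierParams | None = None
) -> SiteClassification:
    params = params or ClassifierParams()
    if tally.depth < params.min_depth:
        return SiteClassification(NO_DATA, None)
    majority, count = max(tally.counts.items(), key=lambda kv: (kv[1], kv[0]))
    fraction = count / tally.depth
    if tally.flags:
        return SiteClassification(REVIEW, fraction)
    if fraction >= params.cutoff(tally.site.site_type):
        ref_key = tally.site.ref_allele if tally.site.site_type == SNV else "ref"
        call = HOM_REF if majority == ref_key else HOM_ALT
        return SiteClassification(call, fraction)
    return SiteClassification(HET, fraction)


def decide_update(
    site: VariantSite,
    classification: SiteClassification,
    in_source_library_component: bool,
) -> UpdateDecision:
    """Deterministic update policy for one classified candidate site."""
    call = classification.call
    if call in (REVIEW, NO_DATA):
        return UpdateDecision(MANUAL_REVIEW, f"classification_{call.lower()}")
    if site.site_type != SNV and call != HOM_ALT:
        return UpdateDecision(MANUAL_REVIEW, "nonhomozygous_alt_indel")
    if call == HOM_ALT:
        return UpdateDecision(APPLY_UPDATE, "homozygous_alternate")
    if call == HOM_REF:
        return UpdateDecision(RETAIN_REFERENCE, "candidate_refuted")
    # heterozygous SNV
    if in_source_library_component:
        return UpdateDecision(RETAIN_REFERENCE, "heterozygous_in_source_library")
    return UpdateDecision(MANUAL_REVIEW, "heterozygous_outside_source_library")


# ---------------------------------------------------------------------------
# Mini-contig validation
# ---------------------------------------------------------------------------


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    # end gaps free on both sequences: overlap-style alignment
    end_gap_attrs = (
        ("open_end_insertion_score", "target_end_open_gap_score"),
        ("extend_end_insertion_score", "target_end_extend_gap_score"),
        ("open_end_deletion_score", "query_end_open_gap_score"),
        ("extend_end_deletion_score", "query_end_extend_gap_score"),
    )
    for new, old in end_gap_attrs:
        setattr(aligner, new if hasattr(aligner, new) else old, 0)
    return aligner


def _left_normalize_del(window: str, pos: int, length: int) -> int:
    while pos > 0 and window[pos - 1] == window[pos + length - 1]:
        pos -= 1
    return pos


def _left_normalize_ins(window: str, pos: int, seq: str) -> tuple[int, str]:
    while pos > 0 and seq and seq[-1] == window[pos - 1]:
        seq = seq[-1] + seq[:-1]
        pos -= 1
    return pos, seq


@dataclass
class MiniContigResult:
    passed: bool
    differences: list[tuple]  # ("sub", pos, window_base, contig_base) etc.
    expected: tuple


def validate_minicontig(
    contig: str,
    window: str,
    site: VariantSite,
    window_start: int,
    min_aligned_fraction: float = 0.8,
) -> MiniContigResult:
    """Check that a replacement contig differs from its reference window only
    at the target site, by the expected alternate allele.

    Differences are reported in window coordinates.  Indel differences are
    left-normalized before comparison so homopolymer placement ambiguity in
    the alignment cannot produce spurious failures.
    """
    aligner = _make_aligner()
    aln = aligner.align(window, contig)[0]
    t_blocks, q_blocks = aln.aligned
    aligned_len = sum(int(e - s) for s, e in q_blocks)
    if aligned_len < min_aligned_fraction * len(contig):
        raise MiniContigError(
            f"contig aligns with only {aligned_len}/{len(contig)} bases in window"
        )
    diffs: list[tuple] = []
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        for i in range(int(te - ts)):
            wb, cb = window[ts + i], contig[qs + i]
            if wb != cb:
                diffs.append(("sub", int(ts + i), wb, cb))
    for j in range(len(t_blocks) - 1):
        t_gap = int(t_blocks[j + 1][0] - t_blocks[j][1])
        q_gap = int(q_blocks[j + 1][0] - q_blocks[j][1])
        if t_gap > 0:  # window bases absent from contig: deletion
            pos = _left_normalize_del(window, int(t_blocks[j][1]), t_gap)
            diffs.append(("del", pos, t_gap))
        if q_gap > 0:  # contig-only bases: insertion
            ins = contig[int(q_blocks[j][1]) : int(q_blocks[j + 1][0])]
            pos, ins = _left_normalize_ins(window, int(t_blocks[j][1]), ins)
            diffs.append(("ins", pos, ins))

    wp = site.pos - window_start
    if site.site_type == SNV:
        expected = ("sub", wp, site.ref_allele, site.alt_allele)
    elif site.site_type == INS:
        pos, ins = _left_normalize_ins(window, wp + 1, site.alt_allele[1:])
        expected = ("ins", pos, ins)
    else:
        k = len(site.ref_allele) - 1
        expected = ("del", _left_normalize_del(window, wp + 1, k), k)
    diffs.sort(key=lambda d: d[1])
    return MiniContigResult(diffs == [expected], diffs, expected)
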