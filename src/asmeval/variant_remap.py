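"""Variant-site coverage and cross-assembly remapping.

A site is COVERED when at least one primary alignment with MAPQ >= 20
(default) overlaps its position.  Sites are remapped between assemblies by
projecting their anchor base through every alignment block containing it;
a site is *ambiguous* when it acquires two or more distinct placements on
primary-assembly sequences (alternate-loci placements are reported but do
not count toward ambiguity).  Comparing coverage before and after
remapping yields the gained/lost transition report, with nearby sites
merged into region groups by single-linkage within a distance threshold.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

import numpy as np

from .formats import (
    RECIPROCAL as RECIPROCAL_,
    AlignmentBlock,
    FormatError,
    GenomicInterval,
    ReadPlacement,
    Unprojectable,
    VariantSite,
    project_coordinate,
)

COVERED = "COVERED"
ZERO = "ZERO"


@dataclass
class CoverageStatus:
    site: VariantSite
    depth: int

    @property
    def status(self) -> str:
        return COVERED if self.depth >= 1 else ZERO


@dataclass
class RemapResult:
    site: VariantSite
    placements: list[tuple[str, int, str, str]]  # (seq, pos, strand, pass_class)
    ambiguous: bool
    unmapped: bool
    # unique reciprocal-best placement on a primary sequence, when one exists:
    # the default-remap behavior the coverage-transition protocol follows
    best: tuple[str, int, str] | None = None
    best_status: str = "unmapped"  # "unique" | "ambiguous" | "unmapped"


@dataclass
class TransitionReport:
    gained: list[VariantSite]
    lost: list[VariantSite]
    gained_groups: list[list[VariantSite]]
    lost_groups: list[list[VariantSite]]
    n_ambiguous_skipped: int
    n_unmapped_skipped: int


def site_coverage(
    placements: dict[tuple[str, int], ReadPlacement] | list[ReadPlacement],
    sites: list[VariantSite],
    min_mapq: int = 20,
) -> list[CoverageStatus]:
    """Depth of MAPQ-filtered primary alignments overlapping each site."""
    if isinstance(placements, dict):
        placements = list(placements.values())
    by_seq: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    spans: dict[str, list[tuple[int, int]]] = {}
    for p in placements:
        if not (p.mapped and p.primary and p.mapq >= min_mapq):
            continue
        spans.setdefault(p.seq_id, []).append((p.aligned_span.start, p.aligned_span.end))
    for sid, pairs in spans.items():
        starts = np.sort(np.array([s for s, _ in pairs], dtype=np.int64))
        ends = np.sort(np.array([e for _, e in pairs], dtype=np.int64))
        by_seq[sid] = (starts, ends)
    out: list[CoverageStatus] = []
    for site in sites:
        if site.seq_id in by_seq:
            starts, ends = by_seq[site.seq_id]
            depth = int(
                np.searchsorted(starts, site.pos, side="right")
                - np.searchsorted(ends, site.pos, side="right")
            )
        else:
            depth = 0
        out.append(CoverageStatus(site, depth))
    return out


class _BlockIndex:
    """Sorted-start lookup of blocks covering a query position."""

    def __init__(self, blocks: list[AlignmentBlock]):
        self._by_seq: dict[str, list[AlignmentBlock]] = {}
        for b in blocks:
            self._by_seq.setdefault(b.query.seq_id, []).append(b)
        for lst in self._by_seq.values():
            lst.sort(key=lambda b: b.query.start)

    def covering(self, seq_id: str, pos: int) -> list[AlignmentBlock]:
        return [
            b
            for b in self._by_seq.get(seq_id, [])
            if b.query.start <= pos < b.query.end
        ]


def remap_sites(
    sites: list[VariantSite],
    blocks: list[AlignmentBlock],
    roles: dict[str, str] | None = None,
) -> list[RemapResult]:
    """Project each site's anchor base through every containing block.

    Placements are deduplicated at exact (seq, pos, strand); ambiguity is
    evaluated against primary-assembly sequences only.  Unprojectable sites
    are reported unmapped, not errored; indel sites remap by their anchor.
    """
    roles = roles or {}
    index = _BlockIndex(blocks)
    results: list[RemapResult] = []
    for site in sites:
        placements: list[tuple[str, int, str, str]] = []
        seen: set[tuple[str, int, str]] = set()
        for b in index.covering(site.seq_id, site.pos):
            try:
                tpos = project_coordinate(b, site.pos)
            except Unprojectable:
                continue
            key = (b.target.seq_id, tpos, b.strand)
            if key in seen:
                continue
            seen.add(key)
            placements.append((b.target.seq_id, tpos, b.strand, b.pass_class))
        primary = [
            p for p in placements if roles.get(p[0], "chromosome") != "alternate"
        ]
        recip = sorted({(p[0], p[1], p[2]) for p in primary if p[3] == RECIPROCAL_})
        if len(recip) == 1:
            best, best_status = recip[0], "unique"
        elif recip:
            best, best_status = None, "ambiguous"
        else:
            best, best_status = None, "unmapped"
        results.append(
            RemapResult(
                site,
                sorted(placements),
                ambiguous=len({(p[0], p[1], p[2]) for p in primary}) >= 2,
                unmapped=not placements,
                best=best,
                best_status=best_status,
            )
        )
    return results


def _single_linkage_groups(
    sites: list[VariantSite], merge_distance: int
) -> list[list[VariantSite]]:
    groups: list[list[VariantSite]] = []
    for site in sorted(sites, key=lambda s: (s.seq_id, s.pos)):
        if (
            groups
            and groups[-1][-1].seq_id == site.seq_id
            and site.pos - groups[-1][-1].pos <= merge_distance
        ):
            groups[-1].append(site)
        else:
            groups.append([site])
    return groups


def coverage_transition(
    status_a: list[CoverageStatus],
    remaps: list[RemapResult],
    status_b: list[CoverageStatus] | dict[tuple[str, int], CoverageStatus],
    merge_distance: int = 100_000,
) -> TransitionReport:
    """Coverage gains and losses across the assembly transition.

    ``status_b`` must hold coverage at the remapped positions of the input
    sites.  Remapping follows each site's unique reciprocal-best placement
    (the default-remap behavior); sites whose reciprocal placement is
    ambiguous or absent are excluded and counted.  A remapped site
    contributes to *gained* when ZERO on A and COVERED on B, and to *lost*
    when COVERED on A and ZERO on B.  Region groups merge sites within
    ``merge_distance`` on the same source sequence.
    """
    remap_by_id = {r.site.site_id: r for r in remaps}
    if isinstance(status_b, list):
        status_b = {(c.site.seq_id, c.site.pos): c for c in status_b}
    gained: list[VariantSite] = []
    lost: list[VariantSite] = []
    n_ambiguous = n_unmapped = 0
    for cov_a in status_a:
        site = cov_a.site
        r = remap_by_id.get(site.site_id)
        if r is None:
            raise FormatError(f"no remap result for site {site.site_id}")
        if r.best_status == "unmapped":
            n_unmapped += 1
            continue
        if r.best_status == "ambiguous":
            n_ambiguous += 1
            continue
        seq_b, pos_b = r.best[0], r.best[1]
        cov_b = status_b.get((seq_b, pos_b))
        if cov_b is None:
            raise FormatError(
                f"no B coverage at remapped position {seq_b}:{pos_b} "
                f"for site {site.site_id}"
            )
        if cov_a.status == ZERO and cov_b.status == COVERED:
            gained.append(site)
        elif cov_a.status == COVERED and cov_b.status == ZERO:
            lost.append(site)
    gained.sort(key=lambda s: (s.seq_id, s.pos))
    lost.sort(key=lambda s: (s.seq_id, s.pos))
    return TransitionReport(
        gained,
        lost,
        _single_linkage_groups(gained, merge_distance),
        _single_linkage_groups(lost, merge_distance),
        n_ambiguous,
        n_unmapped,
    )
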