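"""Read-pair movement between two assembly versions.

The analysis restricts to *unchanged regions* — spans whose underlying
assembly component (accession.version) is identical in both versions, with
overlapping component coordinates and equal orientation.  Read pairs that
map uniquely inside unchanged regions of assembly A are then checked
against their placements on assembly B: a pair has *moved* when at least
one mate's primary B placement midpoint lies on a different component than
its A placement.  Each moved read is classified into the six-way
destination taxonomy:

ON      same chromosome, noncentromeric sequence
ONCEN   same chromosome, centromeric sequence
OFF     different chromosome, noncentromeric
OFFCEN  different chromosome, centromeric
TOSCAF  unlocalized/unplaced scaffold, noncentromeric
UNCEN   unplaced scaffold carrying centromere-associated sequence

"Uniquely mapped" is operationalized as primary alignment with MAPQ >= 20
(configurable), matching the MAPQ filter used elsewhere in the pipeline.
"""

from __future__ import annotations

from bisect import bisect_right
from collections import Counter
from dataclasses import dataclass, field

from .formats import (
    AGPRow,
    FormatError,
    GenomicInterval,
    ReadPlacement,
    agp_by_object,
)

ON = "ON"
ONCEN = "ONCEN"
OFF = "OFF"
OFFCEN = "OFFCEN"
TOSCAF = "TOSCAF"
UNCEN = "UNCEN"
CATEGORIES = (ON, ONCEN, OFF, OFFCEN, TOSCAF, UNCEN)


@dataclass
class MovementConfig:
    min_mapq: int = 20
    primary_only: bool = True
    centromere_bed: list[GenomicInterval] = field(default_factory=list)
    roles: dict[str, str] = field(default_factory=dict)


@dataclass
class UnchangedRegionPair:
    """Equal-length spans of A and B built from the same component bases."""

    interval_on_a: GenomicInterval
    interval_on_b: GenomicInterval
    component_id: str
    orientation: str

    def __post_init__(self) -> None:
        if len(self.interval_on_a) != len(self.interval_on_b):
            raise ValueError("unchanged-region pair with unequal spans")


@dataclass
class MovementRecord:
    read_id: str
    mate: int
    placement_a: ReadPlacement
    placement_b: ReadPlacement
    component_a: str | None
    component_b: str | None
    category: str | None = None


@dataclass
class MovementStats:
    n_eligible: int
    n_moved: int
    n_moved_unique_b: int

    @property
    def fraction_moved(self) -> float | None:
        return self.n_moved / self.n_eligible if self.n_eligible else None

    @property
    def fraction_moved_also_unique_in_b(self) -> float | None:
        return self.n_moved_unique_b / self.n_moved if self.n_moved else None


def unchanged_regions(
    agp_a: list[AGPRow], agp_b: list[AGPRow]
) -> list[UnchangedRegionPair]:
    """Component-provenance intersection of two AGPs.

    For every component accession.version present in both assemblies, the
    intersection of its component-coordinate placements is mapped into both
    object coordinate systems.  Orientation mismatches are excluded; a
    duplicated placement of one component span within one assembly is an
    error (ambiguous provenance).
    """

    def index(rows: list[AGPRow], label: str) -> dict[str, list[AGPRow]]:
        by_comp: dict[str, list[AGPRow]] = {}
        for r in rows:
            if r.kind == "component":
                by_comp.setdefault(r.component_id, []).append(r)
        for comp, placements in by_comp.items():
            placements.sort(key=lambda r: r.component_start)
            for prev, cur in zip(placements, placements[1:]):
                if cur.component_start < prev.component_end:
                    raise FormatError(
                        f"component {comp} placed twice over the same span in "
                        f"assembly {label}"
                    )
        return by_comp

    comps_a = index(agp_a, "A")
    comps_b = index(agp_b, "B")
    pairs: list[UnchangedRegionPair] = []
    for comp in comps_a.keys() & comps_b.keys():
        for ra in comps_a[comp]:
            for rb in comps_b[comp]:
                if ra.orientation != rb.orientation:
                    continue
                lo = max(ra.component_start, rb.component_start)
                hi = min(ra.component_end, rb.component_end)
                if lo >= hi:
                    continue

                def to_object(row: AGPRow) -> tuple[int, int]:
                    if row.orientation == "+":
                        return (
                            row.object_start + (lo - row.component_start),
                            row.object_start + (hi - row.component_start),
                        )
                    return (
                        row.object_start + (row.component_end - hi),
                        row.object_start + (row.component_end - lo),
                    )

                a_s, a_e = to_object(ra)
                b_s, b_e = to_object(rb)
                pairs.append(
                    UnchangedRegionPair(
                        GenomicInterval(ra.object_id, a_s, a_e),
                        GenomicInterval(rb.object_id, b_s, b_e),
                        comp,
                        ra.orientation,
                    )
                )
    pairs.sort(key=lambda p: (p.interval_on_a.seq_id, p.interval_on_a.start))
    return pairs


def _merged_spans(pairs: list[UnchangedRegionPair]) -> dict[str, list[tuple[int, int]]]:
    by_seq: dict[str, list[tuple[int, int]]] = {}
    for p in pairs:
        iv = p.interval_on_a
        by_seq.setdefault(iv.seq_id, []).append((iv.start, iv.end))
    merged: dict[str, list[tuple[int, int]]] = {}
    for sid, spans in by_seq.items():
        spans.sort()
        out = [list(spans[0])]
        for s, e in spans[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[sid] = [(s, e) for s, e in out]
    return merged


def _contained(merged: dict[str, list[tuple[int, int]]], span: GenomicInterval) -> bool:
    spans = merged.get(span.seq_id, [])
    starts = [s for s, _ in spans]
    i = bisect_right(starts, span.start) - 1
    return i >= 0 and spans[i][0] <= span.start and span.end <= spans[i][1]


def select_unique_pairs(
    placements_a: dict[tuple[str, int], ReadPlacement],
    config: MovementConfig,
    regions: list[UnchangedRegionPair],
) -> set[str]:
    """Read ids of pairs with both mates uniquely mapped inside unchanged
    regions of A (mapped, primary, MAPQ >= threshold, span fully contained)."""
    merged = _merged_spans(regions)
    by_read: dict[str, dict[int, ReadPlacement]] = {}
    for (rid, mate), p in placements_a.items():
        by_read.setdefault(rid, {})[mate] = p
    eligible: set[str] = set()
    for rid, mates in by_read.items():
        if set(mates) != {1, 2}:
            continue
        ok = True
        for p in mates.values():
            if not (p.mapped and p.primary and p.mapq >= config.min_mapq):
                ok = False
                break
            if not _contained(merged, p.aligned_span):
                ok = False
                break
        if ok:
            eligible.add(rid)
    return eligible


class ComponentLocator:
    """Binary-search lookup of the AGP component under an object position."""

    def __init__(self, agp: list[AGPRow]):
        self._by_obj: dict[str, tuple[list[int], list[AGPRow]]] = {}
        for obj, rows in agp_by_object(agp).items():
            starts = [r.object_start for r in rows]
            self._by_obj[obj] = (starts, rows)

    def component_at(self, seq_id: str, pos: int) -> str | None:
        if seq_id not in self._by_obj:
            return None
        starts, rows = self._by_obj[seq_id]
        i = bisect_right(starts, pos) - 1
        if i < 0 or pos >= rows[i].object_end:
            return None
        return rows[i].component_id if rows[i].kind == "component" else None


def detect_moved_pairs(
    eligible: set[str],
    placements_a: dict[tuple[str, int], ReadPlacement],
    placements_b: dict[tuple[str, int], ReadPlacement],
    agp_a: list[AGPRow],
    agp_b: list[AGPRow],
    config: MovementConfig | None = None,
) -> tuple[list[MovementRecord], MovementStats]:
    """Moved pairs among the eligible set, plus movement statistics.

    A pair moves iff at least one mate's primary B placement midpoint lies
    on a component accession.version different from its A component (a
    version bump counts as changed).  Returns one MovementRecord per moved
    read (mate whose own component changed, with a mapped B placement).
    """
    config = config or MovementConfig()
    loc_a = ComponentLocator(agp_a)
    loc_b = ComponentLocator(agp_b)
    missing = [
        rid
        for rid in sorted(eligible)
        for mate in (1, 2)
        if (rid, mate) not in placements_b
    ]
    if missing:
        raise FormatError(
            f"missing B placements for eligible reads: {', '.join(missing[:10])}"
            + ("..." if len(missing) > 10 else "")
        )
    records: list[MovementRecord] = []
    n_moved = 0
    n_moved_unique_b = 0
    for rid in sorted(eligible):
        moved = False
        pair_records: list[MovementRecord] = []
        unique_b = True
        for mate in (1, 2):
            pa = placements_a[(rid, mate)]
            pb = placements_b[(rid, mate)]
            comp_a = loc_a.component_at(pa.seq_id, pa.midpoint)
            if not (pb.mapped and pb.primary and pb.mapq >= config.min_mapq):
                unique_b = False
            if not pb.mapped:
                continue
            comp_b = loc_b.component_at(pb.seq_id, pb.midpoint)
            if comp_a != comp_b:
                moved = True
                pair_records.append(
                    MovementRecord(rid, mate, pa, pb, comp_a, comp_b)
                )
        if moved:
            n_moved += 1
            if unique_b:
                n_moved_unique_b += 1
            records.extend(pair_records)
    return records, MovementStats(len(eligible), n_moved, n_moved_unique_b)


def classify_movement(record: MovementRecord, config: MovementConfig) -> str:
    """Six-way destination category of one moved read.

    Destination role decides the scaffold branch (TOSCAF/UNCEN); otherwise
    same-versus-different chromosome and centromere overlap (any overlap of
    the aligned span with a centromere interval) decide the rest.
    """
    pb = record.placement_b
    dest = pb.seq_id
    if dest not in config.roles:
        raise FormatError(f"destination sequence {dest!r} has no assigned role")
    role = config.roles[dest]
    cen = any(
        iv.seq_id == dest and pb.aligned_span.overlaps(iv)
        for iv in config.centromere_bed
    )
    if role in ("unlocalized", "unplaced"):
        scaffold_cen = any(iv.seq_id == dest for iv in config.centromere_bed)
        category = UNCEN if scaffold_cen else TOSCAF
    elif role == "chromosome":
        same = dest == record.placement_a.seq_id
        if same:
            category = ONCEN if cen else ON
        else:
            category = OFFCEN if cen else OFF
    else:
        raise FormatError(f"unsupported destination role {role!r} for {dest}")
    record.category = category
    return category


@dataclass
class RescueStats:
    """Read-level rescue fractions; None marks an undefined (0/0) fraction."""

    n_unmapped_a: int
    n_rescued_b_primary: int
    n_rescued_in_new_sequence: int
    n_unmapped_b_primary: int
    n_rescued_b_full: int

    @property
    def fraction_a_unmapped_rescued(self) -> float | None:
        return (
            self.n_rescued_b_primary / self.n_unmapped_a if self.n_unmapped_a else None
        )

    @property
    def fraction_rescued_in_new_sequence(self) -> float | None:
        return (
            self.n_rescued_in_new_sequence / self.n_rescued_b_primary
            if self.n_rescued_b_primary
            else None
        )

    @property
    def fraction_b_unmapped_rescued_full(self) -> float | None:
        return (
            self.n_rescued_b_full / self.n_unmapped_b_primary
            if self.n_unmapped_b_primary
            else None
        )


def rescue_stats(
    placements_a: dict[tuple[str, int], ReadPlacement],
    placements_b_primary: dict[tuple[str, int], ReadPlacement],
    placements_b_full: dict[tuple[str, int], ReadPlacement],
    new_sequence_bed: list[GenomicInterval],
) -> RescueStats:
    """Unmapped-read rescue between assembly versions, at read level.

    First fraction: reads unmapped on A that map on B's primary assembly
    (and, of those, the share landing in annotated new-sequence intervals).
    Second: reads still unmapped on B-primary that map on B's full
    assembly (alternate loci included).
    """
    universe = set(placements_a)
    if set(placements_b_primary) != universe or set(placements_b_full) != universe:
        raise FormatError("the three alignment sets cover different read universes")
    n_unmapped_a = n_rescued = n_in_new = 0
    n_unmapped_bp = n_rescued_full = 0
    for key in universe:
        pa = placements_a[key]
        pbp = placements_b_primary[key]
        pbf = placements_b_full[key]
        if not pa.mapped:
            n_unmapped_a += 1
            if pbp.mapped:
                n_rescued += 1
                if any(pbp.aligned_span.overlaps(iv) for iv in new_sequence_bed):
                    n_in_new += 1
        if not pbp.mapped:
            n_unmapped_bp += 1
            if pbf.mapped:
                n_rescued_full += 1
    return RescueStats(n_unmapped_a, n_rescued, n_in_new, n_unmapped_bp, n_rescued_full)


def component_pairings(records: list[MovementRecord]) -> list[tuple[str, str, int]]:
    """(source component, destination component) contingency counts for moved
    reads with a mapped B placement, sorted descending, ties lexicographic."""
    counts = Counter(
        (r.component_a or ".", r.component_b or ".")
        for r in records
        if r.placement_b.mapped
    )
    return sorted(
        ((a, b, n) for (a, b), n in counts.items()),
        key=lambda t: (-t[2], t[0], t[1]),
    )
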