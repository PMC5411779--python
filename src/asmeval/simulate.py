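"""Two-version assembly-pair simulator with complete ground truth.

The simulator emulates the situation an assembly-curation effort leaves
behind: a *donor* genome (the underlying biological truth), an older
assembly ``A`` and a newer assembly ``B`` derived from it by implanted
curation events, paired reads from the donor sample with truth placements
against both assemblies, and candidate reference-error sites with truth
genotypes.  Every downstream analysis stage can therefore be checked
against exact expectations.

Event vocabulary
----------------
FALSE_DUPLICATION   an extra, near-identical copy of a donor window is
                    present in one assembly only (the classic expansion).
COLLAPSE            one copy of a donor segmental-duplication pair is
                    missing from assembly A (the classic collapse).
GAP_CLOSURE         A carries a default-length N gap where B carries the
                    actual (much shorter) sequence.
INVERSION           B places the component in the opposite orientation.
BASE_ERROR          A carries a single erroneous base; B carries the donor
                    base under a bumped component version.
RETILE              the region's tiling path was replaced: same sequence
                    (up to a stated edit budget) under new component
                    accessions on both sides.
CENTROMERE_MODEL    B carries the satellite array as a modeled centromere
                    where A has an N gap.
ALT_LOCUS           B's full assembly gains an extra (alternate-locus)
                    scaffold carrying a diverged haplotype of a donor window.

Aligner model
-------------
Truth placements use a deliberately minimal aligner model: MAPQ is 60 for
a uniquely resolvable placement and 0 for a read whose span lies inside a
window that has a zero-divergence duplicate copy elsewhere in the same
assembly; such ambiguous reads are deterministically placed at the
duplicate copy.  This realizes, exactly and reproducibly, the two
mechanisms the evaluation method is about: loss of MAPQ-filtered coverage
over duplicated sequence, and movement of uniquely-A-mapped read pairs to
new components in B.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

from .formats import (
    AGPRow,
    AlignmentBlock,
    GenomicInterval,
    INS,
    NONRECIPROCAL,
    RECIPROCAL,
    SNV,
    DEL,
    Segment,
    VariantSite,
    write_agp,
    write_alignment_table,
    write_bed,
    write_role_table,
    write_vcf_sites,
)

# event kinds
FALSE_DUPLICATION = "FALSE_DUPLICATION"
COLLAPSE = "COLLAPSE"
GAP_CLOSURE = "GAP_CLOSURE"
INVERSION = "INVERSION"
BASE_ERROR = "BASE_ERROR"
RETILE = "RETILE"
CENTROMERE_MODEL = "CENTROMERE_MODEL"
ALT_LOCUS = "ALT_LOCUS"

# truth labels (shared with collapse_expand)
COLLAPSED = "COLLAPSED"
EXPANDED = "EXPANDED"
UNIQUE = "UNIQUE"
UNALIGNED = "UNALIGNED"

HOM_REF = "HOM_REF"
HET = "HET"
HOM_ALT = "HOM_ALT"

_BASES = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class SimConfigError(ValueError):
    pass


class SimEventError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Simulation parameters.

    ``default_gap_length`` follows the reference-assembly convention of
    writing unsized gaps at 50 kbp, which deliberately overestimates the
    missing sequence; ``satellite_divergence`` of 5% per monomer copy keeps
    per-copy alignment nontrivial while the array as a whole is a distinct
    read sink.
    """

    n_chromosomes: int = 2
    chromosome_length: int = 500_000
    gc_fraction: float = 0.41
    segdup_count: int = 2
    segdup_length: int = 20_000
    segdup_divergence: float = 0.02
    satellite_monomer_length: int = 171
    satellite_copy_count: int = 100
    satellite_divergence: float = 0.05
    default_gap_length: int = 50_000
    read_length: int = 150
    insert_mean: int = 400
    insert_sd: int = 50
    per_base_error_rate: float = 0.0
    depth: float = 30.0
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_chromosomes",
            "chromosome_length",
            "segdup_length",
            "satellite_monomer_length",
            "satellite_copy_count",
            "default_gap_length",
            "read_length",
            "insert_mean",
            "insert_sd",
        ):
            if getattr(self, name) <= 0:
                raise SimConfigError(f"{name} must be positive")
        if not (0.0 <= self.per_base_error_rate < 0.1):
            raise SimConfigError("per_base_error_rate must be in [0, 0.1)")
        if not (0.0 < self.gc_fraction < 1.0):
            raise SimConfigError("gc_fraction must be in (0, 1)")
        if self.depth <= 0:
            raise SimConfigError("depth must be positive")
        if self.insert_mean < self.read_length:
            raise SimConfigError("insert_mean must be >= read_length")


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    at, gcw = (1.0 - gc) / 2.0, gc / 2.0
    codes = rng.choice(np.frombuffer(b"ACGT", np.uint8), size=n, p=[at, gcw, gcw, at])
    return codes.tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitution-only divergence; length is preserved."""
    if rate <= 0.0:
        return seq
    arr = bytearray(seq.encode("ascii"))
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    shifts = rng.integers(1, 4, size=hits.size)
    for i, sh in zip(hits.tolist(), shifts.tolist()):
        base = chr(arr[i])
        if base in _BASES:
            arr[i] = ord(_BASES[(_BASES.index(base) + sh) % 4])
    return arr.decode("ascii")


# ---------------------------------------------------------------------------
# Donor genome
# ---------------------------------------------------------------------------


@dataclass
class Donor:
    sequences: dict[str, str]
    segdup_pairs: list[tuple[GenomicInterval, GenomicInterval]]
    satellites: dict[str, GenomicInterval]
    config: SimConfig

    @property
    def chromosomes(self) -> list[str]:
        return list(self.sequences)


def build_donor(config: SimConfig) -> Donor:
    """Deterministic donor genome with a satellite array per chromosome and
    evenly laid-out segmental-duplication pairs (copies in opposite arms)."""
    config.validate()
    rng = np.random.default_rng([config.seed, 101])
    L = config.chromosome_length
    sat_len = config.satellite_monomer_length * config.satellite_copy_count
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    sat_start = (L - sat_len) // 2
    if sat_start < L // 20:
        raise SimConfigError("satellite array does not fit on the chromosome")

    # assign segdup pairs round-robin to chromosomes
    per_chrom: dict[str, int] = {c: 0 for c in chroms}
    for i in range(config.segdup_count):
        per_chrom[chroms[i % len(chroms)]] += 1

    sequences: dict[str, str] = {}
    satellites: dict[str, GenomicInterval] = {}
    segdup_pairs: list[tuple[GenomicInterval, GenomicInterval]] = []
    for c in chroms:
        seq = bytearray(_random_seq(rng, L, config.gc_fraction).encode("ascii"))
        # satellite array: tandem monomers, each diverged from the consensus
        monomer = _random_seq(rng, config.satellite_monomer_length, config.gc_fraction)
        array = "".join(
            _mutate(rng, monomer, config.satellite_divergence)
            for _ in range(config.satellite_copy_count)
        )
        seq[sat_start : sat_start + sat_len] = array.encode("ascii")
        satellites[c] = GenomicInterval(c, sat_start, sat_start + sat_len)

        n_pairs = per_chrom[c]
        if n_pairs:
            sd = config.segdup_length
            arm_margin = max(L // 50, config.read_length * 4)
            left_lo, left_hi = arm_margin, sat_start - arm_margin
            right_lo, right_hi = sat_start + sat_len + arm_margin, L - arm_margin
            need = n_pairs * sd + (n_pairs - 1) * sd // 2
            if need > (left_hi - left_lo) or need > (right_hi - right_lo):
                raise SimConfigError("segmental duplications do not fit in the arms")
            for j in range(n_pairs):
                s1 = left_lo + j * (sd + sd // 2)
                s2 = right_lo + j * (sd + sd // 2)
                src = _random_seq(rng, sd, config.gc_fraction)
                copy2 = _mutate(rng, src, config.segdup_divergence)
                seq[s1 : s1 + sd] = src.encode("ascii")
                seq[s2 : s2 + sd] = copy2.encode("ascii")
                segdup_pairs.append(
                    (GenomicInterval(c, s1, s1 + sd), GenomicInterval(c, s2, s2 + sd))
                )
        sequences[c] = seq.decode("ascii")
    return Donor(sequences, segdup_pairs, satellites, config)


# ---------------------------------------------------------------------------
# Events
# ---------------------------------------------------------------------------


@dataclass
class SimEvent:
    kind: str
    donor_locus: GenomicInterval
    applies_to: str = "A"  # "A" | "B" | "both"
    parameters: dict = field(default_factory=dict)


def false_duplication(
    locus: GenomicInterval,
    insert_on: str,
    insert_pos: int,
    applies_to: str = "A",
    divergence: float = 0.01,
) -> SimEvent:
    """Extra near-identical copy of ``locus`` in one assembly.

    ``insert_pos`` is a donor coordinate when ``insert_on`` is a chromosome,
    a scaffold-local coordinate otherwise.  ``divergence`` 0 makes the two
    copies indistinguishable to the aligner model (reads become MAPQ-0 and
    are drawn to the new copy), which is how read-movement attractors and
    coverage-loss loci are built.
    """
    return SimEvent(
        FALSE_DUPLICATION,
        locus,
        applies_to,
        {"insert_on": insert_on, "insert_pos": insert_pos, "divergence": divergence},
    )


def collapse(locus: GenomicInterval) -> SimEvent:
    """Remove one copy of a donor segdup pair from assembly A only."""
    return SimEvent(COLLAPSE, locus, "A")


def gap_closure(locus: GenomicInterval) -> SimEvent:
    return SimEvent(GAP_CLOSURE, locus, "A")


def inversion(locus: GenomicInterval) -> SimEvent:
    return SimEvent(INVERSION, locus, "B")


def base_error(chrom: str, pos: int, alt: str) -> SimEvent:
    return SimEvent(
        BASE_ERROR, GenomicInterval(chrom, pos, pos + 1), "A", {"alt": alt}
    )


def retile(locus: GenomicInterval, edits: int = 0) -> SimEvent:
    return SimEvent(RETILE, locus, "both", {"edits": edits})


def centromere_model(donor: Donor, chrom: str) -> SimEvent:
    return SimEvent(CENTROMERE_MODEL, donor.satellites[chrom], "A")


def alt_locus(locus: GenomicInterval, divergence: float = 0.03) -> SimEvent:
    return SimEvent(ALT_LOCUS, locus, "B", {"divergence": divergence})


@dataclass
class ScaffoldSpec:
    """An unlocalized/unplaced scaffold present in assembly B."""

    name: str
    length: int
    centromere_associated: bool = False


# ---------------------------------------------------------------------------
# Assembly construction
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class _Piece:
    kind: str  # "seq" | "gap"
    seq: str = ""
    seq_id: str = ""  # assembly sequence this piece ends up on; set on finalization
    gap_length: int = 0
    component_id: str = ""
    component_start: int = 0
    orientation: str = "+"
    donor_chrom: str | None = None
    donor_start: int = 0
    donor_end: int = 0
    source: tuple[str, int, int] | None = None  # donor span this sequence copies
    is_duplicate: bool = False
    divergence: float = 0.0
    tag: str = "unchanged"
    event_index: int | None = None
    start: int = 0  # assembly offset, set on finalization

    @property
    def length(self) -> int:
        return len(self.seq) if self.kind == "seq" else self.gap_length


@dataclass
class Assembly:
    name: str
    sequences: dict[str, str]
    agp: list[AGPRow]
    roles: dict[str, str]
    alt_sequences: dict[str, str] = field(default_factory=dict)
    alt_agp: list[AGPRow] = field(default_factory=list)

    @property
    def full_sequences(self) -> dict[str, str]:
        return {**self.sequences, **self.alt_sequences}

    @property
    def full_agp(self) -> list[AGPRow]:
        return self.agp + self.alt_agp


@dataclass
class TruthBundle:
    """Ground truth tying events, alignments, labels, reads and genotypes."""

    events: list[SimEvent]
    blocks: list[AlignmentBlock]  # A as query, B as target
    labels: dict[str, dict[str, list[tuple[int, int, str]]]]  # side -> seq -> runs
    centromere_bed: list[GenomicInterval]  # on B
    new_sequence_bed: list[GenomicInterval]  # on B
    genotypes: dict[str, str] = field(default_factory=dict)
    moved_pair_categories: dict[str, str] = field(default_factory=dict)
    moved_read_categories: dict[tuple[str, int], str] = field(default_factory=dict)
    transitions: dict[str, str] = field(default_factory=dict)  # site -> GAINED/LOST/NONE

    def label_length(self, side: str, label: str) -> int:
        return sum(
            e - s
            for runs in self.labels[side].values()
            for s, e, lab in runs
            if lab == label
        )


@dataclass
class _ResolveEntry:
    """One donor-span -> assembly-span mapping rule."""

    donor_start: int
    donor_end: int
    seq_id: str
    asm_start: int
    orientation: str
    mapq: int
    kind: str  # "run" | "redirect" | "homology"
    category: str | None = None
    shift_to: tuple[str, int, int] | None = None  # homology: donor span of kept copy


@dataclass
class Placement:
    """A resolved truth placement: assembly coordinates plus model MAPQ."""

    seq_id: str
    pos: int
    orientation: str
    mapq: int
    category: str | None  # movement destination category, when redirected
    via: str = "run"  # "run" | "redirect" | "homology"


@dataclass
class AssemblyPair:
    donor: Donor
    A: Assembly
    B: Assembly
    truth: TruthBundle
    # donor-chrom -> entries, per side; resolution order redirect > run > homology
    _maps: dict[str, dict[str, list[_ResolveEntry]]] = field(default_factory=dict)

    def _resolve_runs(self, side: str, chrom: str, start: int, end: int):
        for en in self._maps[side].get(chrom, []):
            if en.kind == "run" and en.donor_start <= start and end <= en.donor_end:
                if en.orientation == "+":
                    return en.seq_id, en.asm_start + (start - en.donor_start), "+"
                return en.seq_id, en.asm_start + (en.donor_end - end), "-"
        return None

    def resolve(self, side: str, chrom: str, start: int, end: int) -> Placement | None:
        """Map a donor span to an assembly placement under the aligner model.

        Resolution order: zero-divergence duplicate redirects (MAPQ 0 at the
        copy), then contiguous primary runs (MAPQ 60), then collapse
        homology (reads from a removed segdup copy pile onto the kept copy).
        """
        entries = self._maps[side].get(chrom, [])
        for kind in ("redirect", "run", "homology"):
            for en in entries:
                if en.kind != kind:
                    continue
                if not (en.donor_start <= start and end <= en.donor_end):
                    continue
                if kind == "homology":
                    kc, ks, _ = en.shift_to
                    off = ks - en.donor_start
                    sub = self._resolve_runs(side, kc, start + off, end + off)
                    if sub is None:
                        return None
                    return Placement(sub[0], sub[1], sub[2], en.mapq, None, "homology")
                if en.orientation == "+":
                    pos = en.asm_start + (start - en.donor_start)
                else:
                    pos = en.asm_start + (en.donor_end - end)
                return Placement(
                    en.seq_id, pos, en.orientation, en.mapq, en.category, kind
                )
        return None


def _event_component(ev_idx: int, side: str, chrom: str, kind: str) -> str:
    return f"{chrom.upper()}E{ev_idx:02d}{kind[:3]}{side}.1"


def derive_assembly_pair(
    donor: Donor,
    events: list[SimEvent],
    extra_scaffolds: list[ScaffoldSpec] | None = None,
) -> AssemblyPair:
    """Build assemblies A and B plus the complete TruthBundle."""
    config = donor.config
    rng = np.random.default_rng([config.seed, 202])
    _validate_events(donor, events)

    pieces: dict[str, dict[str, list[_Piece]]] = {"A": {}, "B": {}}
    roles: dict[str, str] = {}

    for chrom, dseq in donor.sequences.items():
        roles[chrom] = "chromosome"
        ch_events = sorted(
            (
                (i, ev)
                for i, ev in enumerate(events)
                if ev.donor_locus.seq_id == chrom
                and ev.kind in (COLLAPSE, GAP_CLOSURE, INVERSION, BASE_ERROR, RETILE, CENTROMERE_MODEL)
            ),
            key=lambda t: t[1].donor_locus.start,
        )
        piecesA: list[_Piece] = []
        piecesB: list[_Piece] = []
        cursor = 0
        useg = 0

        def emit_unchanged(lo: int, hi: int) -> None:
            nonlocal useg
            if hi <= lo:
                return
            comp = f"{chrom.upper()}U{useg:03d}.1"
            useg += 1
            for plist in (piecesA, piecesB):
                plist.append(
                    _Piece(
                        "seq",
                        seq=dseq[lo:hi],
                        component_id=comp,
                        donor_chrom=chrom,
                        donor_start=lo,
                        donor_end=hi,
                        source=(chrom, lo, hi),
                    )
                )

        for ev_idx, ev in ch_events:
            lo, hi = ev.donor_locus.start, ev.donor_locus.end
            emit_unchanged(cursor, lo)
            span = dseq[lo:hi]
            common = dict(donor_chrom=chrom, donor_start=lo, donor_end=hi,
                          source=(chrom, lo, hi), tag=ev.kind, event_index=ev_idx)
            if ev.kind == COLLAPSE:
                # A omits the copy entirely; B keeps it under its own accession
                piecesB.append(
                    _Piece("seq", seq=span,
                           component_id=_event_component(ev_idx, "B", chrom, ev.kind),
                           **common)
                )
            elif ev.kind in (GAP_CLOSURE, CENTROMERE_MODEL):
                piecesA.append(
                    _Piece("gap", gap_length=config.default_gap_length,
                           donor_chrom=chrom, donor_start=lo, donor_end=hi,
                           tag=ev.kind, event_index=ev_idx)
                )
                piecesB.append(
                    _Piece("seq", seq=span,
                           component_id=_event_component(ev_idx, "B", chrom, ev.kind),
                           **common)
                )
            elif ev.kind == INVERSION:
                comp = _event_component(ev_idx, "S", chrom, ev.kind)
                piecesA.append(_Piece("seq", seq=span, component_id=comp, **common))
                piecesB.append(
                    _Piece("seq", seq=revcomp(span), component_id=comp,
                           orientation="-", **common)
                )
            elif ev.kind == BASE_ERROR:
                alt = ev.parameters["alt"]
                root = _event_component(ev_idx, "V", chrom, ev.kind).rsplit(".", 1)[0]
                piecesA.append(
                    _Piece("seq", seq=alt, component_id=f"{root}.1", **common)
                )
                piecesB.append(
                    _Piece("seq", seq=span, component_id=f"{root}.2", **common)
                )
            elif ev.kind == RETILE:
                edits = ev.parameters.get("edits", 0)
                b_span = span
                if edits:
                    idx = rng.integers(0, len(span), size=edits)
                    arr = bytearray(span.encode())
                    for i in idx.tolist():
                        arr[i] = ord(_BASES[(_BASES.index(chr(arr[i])) + 1) % 4])
                    b_span = arr.decode()
                piecesA.append(
                    _Piece("seq", seq=span,
                           component_id=_event_component(ev_idx, "A", chrom, ev.kind),
                           **common)
                )
                piecesB.append(
                    _Piece("seq", seq=b_span,
                           component_id=_event_component(ev_idx, "B", chrom, ev.kind),
                           **common)
                )
            cursor = hi
        emit_unchanged(cursor, len(dseq))
        pieces["A"][chrom] = piecesA
        pieces["B"][chrom] = piecesB

    # extra scaffolds on B
    scaffold_cen: set[str] = set()
    for spec in extra_scaffolds or []:
        seq = _random_seq(rng, spec.length, config.gc_fraction)
        pieces["B"][spec.name] = [
            _Piece("seq", seq=seq, component_id=f"{spec.name.upper()}.1", tag="scaffold")
        ]
        roles[spec.name] = "unplaced"
        if spec.centromere_associated:
            scaffold_cen.add(spec.name)

    # false-duplication insertions (including movement attractors)
    alt_scaffolds: dict[str, _Piece] = {}
    for ev_idx, ev in enumerate(events):
        if ev.kind == ALT_LOCUS:
            lo, hi = ev.donor_locus.start, ev.donor_locus.end
            span = donor.sequences[ev.donor_locus.seq_id][lo:hi]
            name = f"alt{len(alt_scaffolds) + 1}"
            alt_scaffolds[name] = _Piece(
                "seq",
                seq=_mutate(rng, span, ev.parameters.get("divergence", 0.03)),
                component_id=f"{name.upper()}.1",
                source=(ev.donor_locus.seq_id, lo, hi),
                tag=ev.kind,
                event_index=ev_idx,
            )
            roles[name] = "alternate"
            continue
        if ev.kind != FALSE_DUPLICATION:
            continue
        sides = ["A", "B"] if ev.applies_to == "both" else [ev.applies_to]
        src_chrom = ev.donor_locus.seq_id
        lo, hi = ev.donor_locus.start, ev.donor_locus.end
        span = donor.sequences[src_chrom][lo:hi]
        div = ev.parameters.get("divergence", 0.01)
        dup_seq = _mutate(rng, span, div)
        insert_on = ev.parameters["insert_on"]
        insert_pos = ev.parameters["insert_pos"]
        for side in sides:
            dup = _Piece(
                "seq",
                seq=dup_seq,
                component_id=_event_component(ev_idx, side, insert_on, ev.kind),
                source=(src_chrom, lo, hi),
                is_duplicate=True,
                divergence=div,
                tag=ev.kind,
                event_index=ev_idx,
            )
            _insert_piece(pieces[side], insert_on, insert_pos, dup)

    assemblies: dict[str, Assembly] = {}
    for side in ("A", "B"):
        sequences: dict[str, str] = {}
        agp: list[AGPRow] = []
        for seq_id, plist in pieces[side].items():
            offset = 0
            part = 1
            comp_cursor: dict[str, int] = {}
            chunks: list[str] = []
            for p in plist:
                p.start = offset
                p.seq_id = seq_id
                if p.kind == "gap":
                    chunks.append("N" * p.gap_length)
                    agp.append(
                        AGPRow(seq_id, offset, offset + p.gap_length, part, "gap",
                               gap_length=p.gap_length, gap_kind="unspanned")
                    )
                else:
                    chunks.append(p.seq)
                    cstart = comp_cursor.get(p.component_id, 0)
                    p.component_start = cstart
                    comp_cursor[p.component_id] = cstart + len(p.seq)
                    agp.append(
                        AGPRow(seq_id, offset, offset + len(p.seq), part, "component",
                               p.component_id, cstart, cstart + len(p.seq),
                               p.orientation)
                    )
                offset += p.length
                part += 1
            sequences[seq_id] = "".join(chunks)
        side_roles = {s: roles[s] for s in sequences}
        assemblies[side] = Assembly(side, sequences, agp, side_roles)

    # alternate-locus scaffolds attach to B's full assembly
    for name, p in alt_scaffolds.items():
        assemblies["B"].alt_sequences[name] = p.seq
        assemblies["B"].alt_agp.append(
            AGPRow(name, 0, len(p.seq), 1, "component", p.component_id, 0, len(p.seq), "+")
        )
        assemblies["B"].roles[name] = "alternate"

    for name, p in alt_scaffolds.items():
        p.seq_id = name
    truth = _build_truth(donor, events, pieces, assemblies, scaffold_cen)
    maps = _build_maps(donor, events, pieces, scaffold_cen)
    return AssemblyPair(donor, assemblies["A"], assemblies["B"], truth, maps)


def _validate_events(donor: Donor, events: list[SimEvent]) -> None:
    loci: list[GenomicInterval] = []
    for ev in events:
        loc = ev.donor_locus
        if loc.seq_id not in donor.sequences:
            raise SimEventError(f"{ev.kind}: unknown donor chromosome {loc.seq_id}")
        if loc.end > len(donor.sequences[loc.seq_id]):
            raise SimEventError(f"{ev.kind}: locus extends past chromosome end")
        for other in loci:
            if loc.overlaps(other):
                raise SimEventError(f"{ev.kind}: overlapping event loci at {loc}")
        loci.append(loc)
        if ev.kind == COLLAPSE:
            copies = [iv for pair in donor.segdup_pairs for iv in pair]
            if not any(iv == GenomicInterval(loc.seq_id, loc.start, loc.end, iv.strand)
                       or (iv.seq_id, iv.start, iv.end) == (loc.seq_id, loc.start, loc.end)
                       for iv in copies):
                raise SimEventError("COLLAPSE locus must be a donor segdup copy")
        if ev.kind == CENTROMERE_MODEL:
            sat = donor.satellites[loc.seq_id]
            if (loc.start, loc.end) != (sat.start, sat.end):
                raise SimEventError("CENTROMERE_MODEL locus must be the satellite array")
        if ev.kind == BASE_ERROR:
            alt = ev.parameters.get("alt", "")
            ref = donor.sequences[loc.seq_id][loc.start:loc.end]
            if len(alt) != 1 or len(ref) != 1 or alt == ref:
                raise SimEventError("BASE_ERROR needs exactly one ref and one alt allele")


def _insert_piece(
    side_pieces: dict[str, list[_Piece]], seq_id: str, pos: int, dup: _Piece
) -> None:
    if seq_id not in side_pieces:
        raise SimEventError(f"insertion target {seq_id} absent from assembly")
    plist = side_pieces[seq_id]
    is_chrom = seq_id.startswith("chr")
    offset = 0
    for i, p in enumerate(plist):
        if is_chrom:
            inside = (
                p.kind == "seq"
                and p.donor_chrom is not None
                and p.donor_start < pos < p.donor_end
            )
            at_edge = p.kind == "seq" and p.donor_chrom is not None and pos == p.donor_start
            local = pos - p.donor_start if (inside or at_edge) else None
        else:
            inside = p.kind == "seq" and offset < pos < offset + p.length
            at_edge = p.kind == "seq" and pos == offset
            local = pos - offset if (inside or at_edge) else None
        if at_edge:
            plist.insert(i, dup)
            return
        if inside:
            left = dataclasses.replace(p)
            right = dataclasses.replace(p)
            left.seq, right.seq = p.seq[:local], p.seq[local:]
            if p.donor_chrom is not None:
                left.donor_end = p.donor_start + local
                right.donor_start = p.donor_start + local
                if p.source:
                    sc, ss, se = p.source
                    left.source = (sc, ss, ss + local)
                    right.source = (sc, ss + local, se)
            plist[i : i + 1] = [left, dup, right]
            return
        offset += p.length
    raise SimEventError(f"insertion position {seq_id}:{pos} not inside a sequence piece")


def _piece_asm_span(p: _Piece) -> tuple[int, int]:
    return p.start, p.start + p.length


def _map_source_to_asm(p: _Piece, s: int, e: int) -> tuple[int, int]:
    """Map donor sub-span [s, e) of p.source into assembly coordinates."""
    _, ss, _ = p.source
    if p.orientation == "+":
        return p.start + (s - ss), p.start + (e - ss)
    length = p.length
    return p.start + length - (e - ss), p.start + length - (s - ss)


def _primary_pieces(plist: list[_Piece]) -> list[_Piece]:
    """Pieces representing their own donor span with a counterpart on the
    other side — the join set for reciprocal truth blocks."""
    return [
        p for p in plist
        if p.kind == "seq" and p.source is not None and not p.is_duplicate
        and p.tag not in (GAP_CLOSURE, CENTROMERE_MODEL, ALT_LOCUS, COLLAPSE)
    ]


def _mappable_pieces(plist: list[_Piece]) -> list[_Piece]:
    """Donor-backed pieces reads can be placed on (includes new sequence)."""
    return [
        p for p in plist
        if p.kind == "seq" and p.donor_chrom is not None and not p.is_duplicate
    ]


def _build_truth(
    donor: Donor,
    events: list[SimEvent],
    pieces: dict[str, dict[str, list[_Piece]]],
    assemblies: dict[str, Assembly],
    scaffold_cen: set[str],
) -> TruthBundle:
    blocks: list[AlignmentBlock] = []

    def make_block(pa: _Piece, pb: _Piece, s: int, e: int, pass_class: str) -> None:
        qa_s, qa_e = _map_source_to_asm(pa, s, e)
        tb_s, tb_e = _map_source_to_asm(pb, s, e)
        strand = "+" if pa.orientation == pb.orientation else "-"
        blocks.append(
            AlignmentBlock(
                GenomicInterval(pa.seq_id, qa_s, qa_e),
                GenomicInterval(pb.seq_id, tb_s, tb_e),
                strand,
                pass_class,
            )
        )

    # reciprocal blocks over donor spans primary in both assemblies
    for chrom in donor.sequences:
        primA = _primary_pieces(pieces["A"].get(chrom, []))
        # primary B pieces for this donor chromosome can sit on chrom only
        primB = _primary_pieces(pieces["B"].get(chrom, []))
        for pa in primA:
            for pb in primB:
                s = max(pa.source[1], pb.source[1])
                e = min(pa.source[2], pb.source[2])
                if s < e:
                    make_block(pa, pb, s, e, RECIPROCAL)

    # nonreciprocal blocks: duplicates vs the other side's primary copy
    for side, other in (("A", "B"), ("B", "A")):
        for seq_id, plist in pieces[side].items():
            for p in plist:
                if not (p.kind == "seq" and p.is_duplicate):
                    continue
                sc, ss, se = p.source
                for q in _primary_pieces(pieces[other].get(sc, [])):
                    s = max(ss, q.source[1])
                    e = min(se, q.source[2])
                    if s >= e:
                        continue
                    if side == "A":
                        make_block(p, q, s, e, NONRECIPROCAL)
                    else:
                        make_block(q, p, s, e, NONRECIPROCAL)

    # nonreciprocal blocks from collapse events: B's retained copy of the
    # removed segdup aligns to A's kept partner copy
    for ev in events:
        if ev.kind != COLLAPSE:
            continue
        removed = ev.donor_locus
        kept = _segdup_partner(donor, removed)
        shift = kept.start - removed.start
        for pb in pieces["B"][removed.seq_id]:
            if pb.tag != COLLAPSE or pb.kind != "seq":
                continue
            if (pb.source[1], pb.source[2]) != (removed.start, removed.end):
                continue
            for pa in _primary_pieces(pieces["A"].get(kept.seq_id, [])):
                s = max(kept.start, pa.source[1])
                e = min(kept.end, pa.source[2])
                if s >= e:
                    continue
                qa_s, qa_e = _map_source_to_asm(pa, s, e)
                tb_s, tb_e = _map_source_to_asm(pb, s - shift, e - shift)
                blocks.append(
                    AlignmentBlock(
                        GenomicInterval(removed.seq_id, qa_s, qa_e),
                        GenomicInterval(removed.seq_id, tb_s, tb_e),
                        "+",
                        NONRECIPROCAL,
                    )
                )

    # truth labels by painting
    labels: dict[str, dict[str, list[tuple[int, int, str]]]] = {"A": {}, "B": {}}
    code = {UNALIGNED: 0, UNIQUE: 1, COLLAPSED: 2, EXPANDED: 3}
    name = {v: k for k, v in code.items()}
    paint: dict[str, dict[str, np.ndarray]] = {"A": {}, "B": {}}
    for side in ("A", "B"):
        for seq_id, seq in assemblies[side].full_sequences.items():
            arr = np.zeros(len(seq), dtype=np.uint8)
            paint[side][seq_id] = arr
        for seq_id, plist in pieces[side].items():
            arr = paint[side][seq_id]
            for p in plist:
                s, e = _piece_asm_span(p)
                if p.kind == "gap":
                    arr[s:e] = code[UNALIGNED]
                elif p.is_duplicate:
                    arr[s:e] = code[EXPANDED]
                elif p.tag in (GAP_CLOSURE, CENTROMERE_MODEL) or p.source is None:
                    arr[s:e] = code[UNALIGNED]
                elif p.tag == COLLAPSE:
                    arr[s:e] = code[EXPANDED]  # B-only retained segdup copy
                else:
                    arr[s:e] = code[UNIQUE]

    # collapse: the kept copy on A is collapsed
    for ev in events:
        if ev.kind != COLLAPSE:
            continue
        kept = _segdup_partner(donor, ev.donor_locus)
        for pa in _primary_pieces(pieces["A"].get(kept.seq_id, [])):
            s = max(kept.start, pa.source[1])
            e = min(kept.end, pa.source[2])
            if s < e:
                a_s, a_e = _map_source_to_asm(pa, s, e)
                paint["A"][kept.seq_id][a_s:a_e] = code[COLLAPSED]
    # duplicates: the copied span on the other side is collapsed
    for side, other in (("A", "B"), ("B", "A")):
        for plist in pieces[side].values():
            for p in plist:
                if not (p.kind == "seq" and p.is_duplicate):
                    continue
                sc, ss, se = p.source
                for q in _primary_pieces(pieces[other].get(sc, [])):
                    s, e = max(ss, q.source[1]), min(se, q.source[2])
                    if s < e:
                        o_s, o_e = _map_source_to_asm(q, s, e)
                        paint[other][sc][o_s:o_e] = code[COLLAPSED]

    for side in ("A", "B"):
        for seq_id, arr in paint[side].items():
            runs: list[tuple[int, int, str]] = []
            if arr.size:
                change = np.flatnonzero(np.diff(arr)) + 1
                bounds = np.concatenate(([0], change, [arr.size]))
                for s, e in zip(bounds[:-1], bounds[1:]):
                    runs.append((int(s), int(e), name[int(arr[s])]))
            labels[side][seq_id] = runs

    # annotation BEDs on B
    cen_bed: list[GenomicInterval] = []
    new_bed: list[GenomicInterval] = []
    for seq_id, plist in pieces["B"].items():
        cen_pieces = [p for p in plist if p.tag == CENTROMERE_MODEL]
        if cen_pieces:
            lo = min(p.start for p in cen_pieces)
            hi = max(p.start + p.length for p in cen_pieces)
            cen_bed.append(GenomicInterval(seq_id, lo, hi))
        if seq_id in scaffold_cen:
            total = sum(p.length for p in plist)
            cen_bed.append(GenomicInterval(seq_id, 0, total))
        for p in plist:
            # sequence B carries that A lacks entirely: closed gaps, modeled
            # centromeres, and segdup copies restored after a collapse
            if p.tag in (GAP_CLOSURE, CENTROMERE_MODEL, COLLAPSE) and p.kind == "seq":
                new_bed.append(GenomicInterval(seq_id, p.start, p.start + p.length))

    return TruthBundle(events, blocks, labels, cen_bed, new_bed)


def _segdup_partner(donor: Donor, locus: GenomicInterval) -> GenomicInterval:
    for a, b in donor.segdup_pairs:
        if (a.seq_id, a.start, a.end) == (locus.seq_id, locus.start, locus.end):
            return b
        if (b.seq_id, b.start, b.end) == (locus.seq_id, locus.start, locus.end):
            return a
    raise SimEventError(f"no segdup partner for {locus}")


def _build_maps(
    donor: Donor,
    events: list[SimEvent],
    pieces: dict[str, dict[str, list[_Piece]]],
    scaffold_cen: set[str],
) -> dict[str, dict[str, list[_ResolveEntry]]]:
    maps: dict[str, dict[str, list[_ResolveEntry]]] = {"A": {}, "B": {}}
    for side in ("A", "B"):
        by_chrom: dict[str, list[_ResolveEntry]] = {}
        for seq_id, plist in pieces[side].items():
            # runs: maximal chains of donor-backed pieces contiguous in both
            # donor and assembly coordinates, '+' orientation
            prim = _mappable_pieces(plist)
            prim.sort(key=lambda p: p.donor_start)
            i = 0
            while i < len(prim):
                p = prim[i]
                if p.orientation == "-":
                    by_chrom.setdefault(p.donor_chrom, []).append(
                        _ResolveEntry(p.donor_start, p.donor_end, seq_id, p.start,
                                      "-", 60, "run")
                    )
                    i += 1
                    continue
                j = i
                while (
                    j + 1 < len(prim)
                    and prim[j + 1].orientation == "+"
                    and prim[j + 1].donor_start == prim[j].donor_end
                    and prim[j + 1].start == prim[j].start + prim[j].length
                ):
                    j += 1
                by_chrom.setdefault(p.donor_chrom, []).append(
                    _ResolveEntry(p.donor_start, prim[j].donor_end, seq_id, p.start,
                                  "+", 60, "run")
                )
                i = j + 1
            # redirects: zero-divergence duplicates capture fully-contained reads
            for p in plist:
                if p.kind == "seq" and p.is_duplicate and p.divergence == 0.0:
                    sc, ss, se = p.source
                    ev = events[p.event_index]
                    cat = _truth_category(events, ev, seq_id, scaffold_cen)
                    by_chrom.setdefault(sc, []).append(
                        _ResolveEntry(ss, se, seq_id, p.start, "+", 0, "redirect",
                                      category=cat)
                    )
        # homology entries for collapse events (A side lacks the removed copy)
        if side == "A":
            for ev in events:
                if ev.kind != COLLAPSE:
                    continue
                removed = ev.donor_locus
                kept = _segdup_partner(donor, removed)
                by_chrom.setdefault(removed.seq_id, []).append(
                    _ResolveEntry(removed.start, removed.end, "", 0, "+", 60,
                                  "homology",
                                  shift_to=(kept.seq_id, kept.start, kept.end))
                )
        maps[side] = by_chrom
    return maps


def _truth_category(
    events: list[SimEvent],
    ev: SimEvent,
    dest_seq: str,
    scaffold_cen: set[str],
) -> str | None:
    """Six-way destination category of a movement attractor, from construction
    facts (declared scaffold flags and centromere-model spans), independently
    of the pipeline's BED/role-based classifier."""
    if ev.applies_to != "B" or ev.kind != FALSE_DUPLICATION:
        return None
    src_chrom = ev.donor_locus.seq_id
    if not dest_seq.startswith("chr"):
        return "UNCEN" if dest_seq in scaffold_cen else "TOSCAF"
    in_cen = False
    for other_ev in events:
        if other_ev.kind == CENTROMERE_MODEL and other_ev.donor_locus.seq_id == dest_seq:
            loc = other_ev.donor_locus
            pos = ev.parameters["insert_pos"]
            if loc.start <= pos <= loc.end:
                in_cen = True
    if dest_seq == src_chrom:
        return "ONCEN" if in_cen else "ON"
    return "OFFCEN" if in_cen else "OFF"


# ---------------------------------------------------------------------------
# Sample haplotypes and read simulation
# ---------------------------------------------------------------------------


@dataclass
class Edit:
    """A VCF-style, left-anchored sample edit relative to the donor."""

    donor_pos: int
    ref: str
    alt: str


def _build_haplotype(
    dseq: str, edits: list[Edit]
) -> tuple[str, list[tuple[int, int, int]], list[tuple[int, int]]]:
    """Apply edits to a donor sequence.

    Returns (sequence, match segments, insertion segments) where match
    segments are (hap_start, donor_start, length) and insertion segments are
    (hap_start, length).  SNVs change sequence only; indels break segments.
    """
    base = bytearray(dseq.encode("ascii"))
    indels: list[Edit] = []
    for e in edits:
        if len(e.ref) == 1 == len(e.alt):
            base[e.donor_pos] = ord(e.alt)
        else:
            indels.append(e)
    indels.sort(key=lambda e: e.donor_pos)
    parts: list[str] = []
    segs: list[tuple[int, int, int]] = []
    inss: list[tuple[int, int]] = []
    h = d = 0
    for e in indels:
        upto = e.donor_pos + 1  # include the anchor base
        seg_len = upto - d
        parts.append(base[d:upto].decode("ascii"))
        segs.append((h, d, seg_len))
        h += seg_len
        d = upto
        if len(e.alt) > len(e.ref):  # insertion
            ins_seq = e.alt[1:]
            parts.append(ins_seq)
            inss.append((h, len(ins_seq)))
            h += len(ins_seq)
        else:  # deletion
            d += len(e.ref) - 1
    parts.append(base[d:].decode("ascii"))
    segs.append((h, d, len(base) - d))
    return "".join(parts), segs, inss


def _hap_span_to_donor(
    segs: list[tuple[int, int, int]],
    inss: list[tuple[int, int]],
    s: int,
    e: int,
) -> tuple[int, int, list[tuple[int, int]]] | None:
    """Map a haplotype span to a donor span plus CIGAR-like ops.

    Op codes follow pysam: 0=M, 1=I, 2=D, 4=S.  Leading/trailing insertions
    become soft clips.  Returns None when the span has no donor-backed base.
    """
    elems: list[tuple[int, int, int | None]] = [
        (hs, ln, ds) for hs, ds, ln in segs
    ] + [(hs, ln, None) for hs, ln in inss]
    elems.sort(key=lambda t: t[0])
    ops: list[tuple[int, int]] = []
    donor_start = None
    donor_end = None
    for hs, ln, ds in elems:
        ov_s, ov_e = max(s, hs), min(e, hs + ln)
        if ov_s >= ov_e:
            continue
        if ds is None:
            ops.append((1, ov_e - ov_s))
        else:
            dstart = ds + (ov_s - hs)
            if donor_start is None:
                donor_start = dstart
            elif dstart > donor_end:
                ops.append((2, dstart - donor_end))
            ops.append((0, ov_e - ov_s))
            donor_end = dstart + (ov_e - ov_s)
    if donor_start is None:
        return None
    if ops and ops[0][0] == 1:
        ops[0] = (4, ops[0][1])
    if ops and ops[-1][0] == 1:
        ops[-1] = (4, ops[-1][1])
    return donor_start, donor_end, ops


@dataclass
class ReadSource:
    """One sequence the sample sheds reads from.

    ``hap`` sources are donor haplotypes (depth/2 each); ``alt`` sources are
    alternate-locus haplotypes truth-mapped only on B's full assembly;
    ``novel`` sources represent sample sequence absent from both assemblies.
    """

    name: str
    kind: str  # "hap" | "alt" | "novel"
    seq: str
    chrom: str | None = None
    segs: list[tuple[int, int, int]] = field(default_factory=list)
    inss: list[tuple[int, int]] = field(default_factory=list)
    alt_seq_id: str | None = None


def build_sample(
    pair: AssemblyPair,
    hap_edits: dict[int, dict[str, list[Edit]]] | None = None,
    novel_length: int = 0,
) -> list[ReadSource]:
    """Assemble the read sources for the simulated sample.

    Two haplotypes per donor chromosome (differing at planted candidate
    sites), one source per alternate-locus scaffold, and optionally a novel
    sequence unrepresented in either assembly.
    """
    hap_edits = hap_edits or {}
    sources: list[ReadSource] = []
    for chrom, dseq in pair.donor.sequences.items():
        for hap in (1, 2):
            edits = hap_edits.get(hap, {}).get(chrom, [])
            seq, segs, inss = _build_haplotype(dseq, edits)
            sources.append(ReadSource(f"{chrom}h{hap}", "hap", seq, chrom, segs, inss))
    for name in sorted(pair.B.alt_sequences):
        sources.append(
            ReadSource(f"{name}hap", "alt", pair.B.alt_sequences[name], alt_seq_id=name)
        )
    if novel_length > 0:
        rng = np.random.default_rng([pair.donor.config.seed, 404])
        sources.append(
            ReadSource(
                "novel", "novel",
                _random_seq(rng, novel_length, pair.donor.config.gc_fraction),
            )
        )
    return sources


_CIGAR_OPS = "MIDNSHP=X"


def _cigar_string(tuples: list[tuple[int, int]]) -> str:
    merged: list[tuple[int, int]] = []
    for op, ln in tuples:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + ln)
        else:
            merged.append((op, ln))
    return "".join(f"{ln}{_CIGAR_OPS[op]}" for op, ln in merged)


@dataclass
class SimulatedRead:
    """Duck-typed stand-in for a mapped/unmapped pysam.AlignedSegment."""

    query_name: str
    flag: int
    reference_name: str | None
    reference_start: int
    mapping_quality: int
    cigartuples: list[tuple[int, int]] | None
    query_sequence: str

    is_secondary: bool = False
    is_supplementary: bool = False

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & 0x4)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & 0x10)

    @property
    def is_read2(self) -> bool:
        return bool(self.flag & 0x80)

    @property
    def reference_end(self) -> int:
        ref_len = sum(ln for op, ln in self.cigartuples or [] if op in (0, 2))
        return self.reference_start + ref_len

    def to_sam(self) -> str:
        if self.is_unmapped:
            rname, pos, mapq, cigar = "*", 0, 0, "*"
        else:
            rname = self.reference_name
            pos = self.reference_start + 1
            mapq = self.mapping_quality
            cigar = _cigar_string(self.cigartuples)
        seq = self.query_sequence
        return "\t".join(
            [
                self.query_name,
                str(self.flag),
                rname,
                str(pos),
                str(mapq),
                cigar,
                "*",
                "0",
                "0",
                seq,
                "I" * len(seq),
            ]
        )


@dataclass
class ReadSet:
    """Simulated paired reads plus truth alignments against both assemblies."""

    fastq: list[tuple[str, str, str]]  # (pair name, read1, read2)
    sam: dict[str, list[SimulatedRead]]  # "A" | "B" | "B_full"
    headers: dict[str, list[tuple[str, int]]]
    moved_read_categories: dict[tuple[str, int], str]
    moved_pairs: set[str]

    def n_pairs(self) -> int:
        return len(self.fastq)


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0.0:
        return seq
    return _mutate(rng, seq, rate)


def simulate_reads(
    pair: AssemblyPair,
    sources: list[ReadSource] | None = None,
    config: SimConfig | None = None,
) -> ReadSet:
    """Draw paired-end reads from the sample and emit truth placements.

    Pair counts per source are Poisson with mean length*depth/(2*read_length)
    at half depth per haplotype-like source; inserts are normal, truncated at
    read_length.  Placements follow :meth:`AssemblyPair.resolve`; reads whose
    donor span is absent from an assembly are truth-unmapped there.
    """
    config = config or pair.donor.config
    config.validate()
    rng = np.random.default_rng([config.seed, 303])
    if sources is None:
        sources = build_sample(pair)
    rl = config.read_length

    fastq: list[tuple[str, str, str]] = []
    sam: dict[str, list[SimulatedRead]] = {"A": [], "B": [], "B_full": []}
    moved_read_categories: dict[tuple[str, int], str] = {}
    moved_pairs: set[str] = set()

    for source in sources:
        L = len(source.seq)
        lam = L * config.depth / 2.0 / (2.0 * rl)
        n_pairs = int(rng.poisson(lam))
        inserts = np.maximum(
            rl, np.rint(rng.normal(config.insert_mean, config.insert_sd, n_pairs))
        ).astype(int)
        inserts = np.minimum(inserts, L)
        starts = rng.integers(0, np.maximum(1, L - inserts + 1))
        for i in range(n_pairs):
            ins, start = int(inserts[i]), int(starts[i])
            rid = f"{source.name}p{i:07d}"
            spans = [(start, start + rl), (start + ins - rl, start + ins)]
            sub1 = source.seq[spans[0][0] : spans[0][1]]
            sub2 = source.seq[spans[1][0] : spans[1][1]]
            read1 = _apply_errors(rng, sub1, config.per_base_error_rate)
            read2 = _apply_errors(
                rng, revcomp(sub2), config.per_base_error_rate
            )
            fastq.append((rid, read1, read2))
            forward_subs = [read1, revcomp(read2)]  # source-forward, with errors
            for mate in (1, 2):
                hs, he = spans[mate - 1]
                fwd = forward_subs[mate - 1]
                placements = _truth_placements(pair, source, hs, he)
                for target in ("A", "B", "B_full"):
                    sam[target].append(
                        _make_record(rid, mate, fwd, placements[target])
                    )
                plc = placements["B"]
                if plc is not None and plc[4] is not None:
                    moved_read_categories[(rid, mate)] = plc[4]
                    moved_pairs.add(rid)

    headers = {
        "A": [(s, len(q)) for s, q in pair.A.sequences.items()],
        "B": [(s, len(q)) for s, q in pair.B.sequences.items()],
        "B_full": [(s, len(q)) for s, q in pair.B.full_sequences.items()],
    }
    for records in sam.values():
        records.sort(
            key=lambda r: (r.is_unmapped, r.reference_name or "~", r.reference_start)
        )
    pair.truth.moved_read_categories.update(moved_read_categories)
    return ReadSet(fastq, sam, headers, moved_read_categories, moved_pairs)


def _truth_placements(
    pair: AssemblyPair, source: ReadSource, hs: int, he: int
) -> dict[str, tuple | None]:
    """Per-target (seq_id, pos, orientation, ops, category, mapq) or None."""
    out: dict[str, tuple | None] = {"A": None, "B": None, "B_full": None}
    if source.kind == "novel":
        return out
    if source.kind == "alt":
        ops = [(0, he - hs)]
        out["B_full"] = (source.alt_seq_id, hs, "+", ops, None, 60)
        return out
    mapped = _hap_span_to_donor(source.segs, source.inss, hs, he)
    if mapped is None:
        return out
    ds, de, ops = mapped
    resolved: dict[str, "Placement | None"] = {}
    for side, targets in (("A", ("A",)), ("B", ("B", "B_full"))):
        plc = pair.resolve(side, source.chrom, ds, de)
        resolved[side] = plc
        if plc is None:
            continue
        for t in targets:
            out[t] = (plc.seq_id, plc.pos, plc.orientation, ops, plc.category, plc.mapq)
    # a read homology-mapped on A (collapsed copy) that maps onto the restored
    # copy in B has changed assembly component: a true movement, ON/OFF by
    # chromosome (segdup copies sit on chromosome arms, never in satellite)
    pa, pb = resolved["A"], resolved["B"]
    if pa is not None and pb is not None and pa.via == "homology" and pb.category is None:
        cat = "ON" if pb.seq_id == pa.seq_id else "OFF"
        for t in ("B", "B_full"):
            if out[t] is not None:
                o = out[t]
                out[t] = (o[0], o[1], o[2], o[3], cat, o[5])
    return out


def _make_record(rid: str, mate: int, fwd: str, placement) -> SimulatedRead:
    flag = 0x1 | (0x40 if mate == 1 else 0x80)
    if placement is None:
        return SimulatedRead(rid, flag | 0x4, None, 0, 0, None, fwd)
    seq_id, pos, orientation, ops, _cat, mapq = placement
    # mate 2 was sequenced reverse-complement of the source-forward strand
    seq_reverse = (mate == 2) if orientation == "+" else (mate == 1)
    if orientation == "-":
        ops = list(reversed(ops))
        seq = revcomp(fwd)
    else:
        seq = fwd
    if seq_reverse:
        flag |= 0x10
    return SimulatedRead(rid, flag, seq_id, pos, mapq, ops, seq)


# ---------------------------------------------------------------------------
# Candidate reference-error sites
# ---------------------------------------------------------------------------


@dataclass
class PlantResult:
    sites: list[VariantSite]
    genotypes: dict[str, str]
    hap_edits: dict[int, dict[str, list[Edit]]]
    in_source_library: dict[str, bool]
    minicontigs: list[tuple[str, str, GenomicInterval]]  # (site_id, contig, window)


def _exact_counts(mix: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n among mix keys."""
    keys = sorted(mix)
    raw = {k: mix[k] * n for k in keys}
    counts = {k: int(math.floor(raw[k])) for k in keys}
    rem = n - sum(counts.values())
    for k in sorted(keys, key=lambda k: (-(raw[k] - counts[k]), k)):
        if rem <= 0:
            break
        counts[k] += 1
        rem -= 1
    return counts


def plant_candidate_sites(
    pair: AssemblyPair,
    n_sites: int,
    type_mix: dict[str, float] | None = None,
    genotype_mix: dict[str, float] | None = None,
    seed: int | None = None,
    flank: int = 200,
    spacing: int | None = None,
    indel_length: int = 1,
    source_library_fraction: float = 0.5,
) -> PlantResult:
    """Plant candidate reference-error sites on assembly A.

    Sites go on unchanged, donor-backed, '+'-orientation A sequence, away
    from event loci and ambiguous windows, spaced so their read pileups do
    not interact.  The sample's haplotypes receive the alternate allele
    according to the truth genotype; each site also gets a mini-contig (the
    reference window with exactly the alternate allele substituted).
    """
    config = pair.donor.config
    type_mix = type_mix or {"SNV": 1.0}
    genotype_mix = genotype_mix or {"HET": 1.0}
    rng = np.random.default_rng([config.seed if seed is None else seed, 505])
    spacing = spacing or (2 * config.read_length + 10)
    margin = flank + 2 * config.read_length

    # exclusion zones in donor coordinates: all event loci plus redirects
    excluded: dict[str, list[tuple[int, int]]] = {}
    for ev in pair.truth.events:
        loc = ev.donor_locus
        excluded.setdefault(loc.seq_id, []).append((loc.start, loc.end))
    for side in ("A", "B"):
        for chrom, entries in pair._maps[side].items():
            for en in entries:
                if en.kind == "redirect":
                    excluded.setdefault(chrom, []).append((en.donor_start, en.donor_end))
    for a, b in pair.donor.segdup_pairs:
        excluded.setdefault(a.seq_id, []).append((a.start, a.end))
        excluded.setdefault(b.seq_id, []).append((b.start, b.end))
    for c, sat in pair.donor.satellites.items():
        excluded.setdefault(c, []).append((sat.start, sat.end))

    candidates: list[tuple[str, int, int]] = []  # (A seq, A pos, donor pos)
    # walk A's unchanged pieces via the map runs (donor-backed '+' spans)
    for chrom, entries in sorted(pair._maps["A"].items()):
        exc = sorted(excluded.get(chrom, []))
        for en in entries:
            if en.kind != "run" or en.orientation != "+":
                continue
            lo, hi = en.donor_start + margin, en.donor_end - margin
            pos = lo
            while pos < hi:
                blocked = any(s - margin <= pos < e + margin for s, e in exc)
                if not blocked:
                    a_pos = en.asm_start + (pos - en.donor_start)
                    candidates.append((en.seq_id, a_pos, pos))
                pos += spacing
    if len(candidates) < n_sites:
        raise SimEventError(
            f"cannot plant {n_sites} sites; only {len(candidates)} positions available"
        )
    order = rng.permutation(len(candidates))[:n_sites]
    chosen = sorted(candidates[i] for i in order)

    types = _exact_counts(type_mix, n_sites)
    genos = _exact_counts(genotype_mix, n_sites)
    type_list = [t for t in sorted(types) for _ in range(types[t])]
    geno_list = [g for g in sorted(genos) for _ in range(genos[g])]
    type_list = [type_list[i] for i in rng.permutation(n_sites)]
    geno_list = [geno_list[i] for i in rng.permutation(n_sites)]

    sites: list[VariantSite] = []
    genotypes: dict[str, str] = {}
    hap_edits: dict[int, dict[str, list[Edit]]] = {1: {}, 2: {}}
    in_source: dict[str, bool] = {}
    minicontigs: list[tuple[str, str, GenomicInterval]] = []

    for idx, ((seq_id, a_pos, d_pos), stype, geno) in enumerate(
        zip(chosen, type_list, geno_list)
    ):
        aseq = pair.A.sequences[seq_id]
        chrom = seq_id  # A chromosomes carry donor chromosome names
        ref_base = aseq[a_pos]
        if stype == "SNV":
            alt = _BASES[(_BASES.index(ref_base) + int(rng.integers(1, 4))) % 4]
            ref, alt_allele = ref_base, alt
        elif stype == "INS":
            ins = "".join(
                _BASES[int(b)] for b in rng.integers(0, 4, size=indel_length)
            )
            ref, alt_allele = ref_base, ref_base + ins
        else:  # DEL
            ref = aseq[a_pos : a_pos + 1 + indel_length]
            alt_allele = ref_base
        site_id = f"site{idx:05d}"
        site = VariantSite(seq_id, a_pos, ref, alt_allele, site_id, stype)
        sites.append(site)
        genotypes[site_id] = geno
        in_source[site_id] = bool(rng.random() < source_library_fraction)
        edit = Edit(d_pos, ref, alt_allele)
        if geno == HET:
            hap = 1 + int(rng.integers(0, 2))
            hap_edits[hap].setdefault(chrom, []).append(edit)
        elif geno == HOM_ALT:
            hap_edits[1].setdefault(chrom, []).append(edit)
            hap_edits[2].setdefault(chrom, []).append(edit)
        ws, we = a_pos - flank, a_pos + len(ref) + flank
        window = GenomicInterval(seq_id, ws, we)
        contig = aseq[ws:a_pos] + alt_allele + aseq[a_pos + len(ref) : we]
        minicontigs.append((site_id, contig, window))
    return PlantResult(sites, genotypes, hap_edits, in_source, minicontigs)


def plant_transition_sites(
    pair: AssemblyPair, per_window: int = 3, n_controls: int = 4
) -> tuple[list[VariantSite], dict[str, str]]:
    """Probe sites for the coverage-transition analysis.

    Probes go inside every zero-divergence duplication source window, at
    least a read length from its edges, so their MAPQ-filtered coverage is
    fully governed by the duplication: windows duplicated in A only regain
    coverage in B (GAINED), windows duplicated in B only lose it (LOST).
    Control probes on plain unchanged sequence transition neither way.
    """
    config = pair.donor.config
    rl = config.read_length
    sites: list[VariantSite] = []
    truth: dict[str, str] = {}
    idx = 0

    def add_site(seq_id: str, apos: int, expected: str) -> None:
        nonlocal idx
        ref = pair.A.sequences[seq_id][apos]
        if ref not in _BASES:
            return
        alt = _BASES[(_BASES.index(ref) + 1) % 4]
        sid = f"t{idx:04d}"
        idx += 1
        sites.append(VariantSite(seq_id, apos, ref, alt, sid, SNV))
        truth[sid] = expected

    for side, expected in (("A", "GAINED"), ("B", "LOST")):
        for chrom in sorted(pair._maps[side]):
            for en in pair._maps[side][chrom]:
                if en.kind != "redirect":
                    continue
                lo, hi = en.donor_start + rl, en.donor_end - rl
                if hi - lo <= per_window:
                    continue
                step = (hi - lo) // (per_window + 1)
                for j in range(per_window):
                    sub = pair._resolve_runs("A", chrom, lo + (j + 1) * step,
                                             lo + (j + 1) * step + 1)
                    if sub is None or sub[2] != "+":
                        continue
                    add_site(sub[0], sub[1], expected)
    # controls: positions well clear of every event locus and feature
    blocked: dict[str, list[tuple[int, int]]] = {}
    margin = 4 * rl
    for ev in pair.truth.events:
        loc = ev.donor_locus
        blocked.setdefault(loc.seq_id, []).append((loc.start - margin, loc.end + margin))
    for side in ("A", "B"):
        for chrom, entries in pair._maps[side].items():
            for en in entries:
                if en.kind == "redirect":
                    blocked.setdefault(chrom, []).append(
                        (en.donor_start - margin, en.donor_end + margin)
                    )
    for a, b in pair.donor.segdup_pairs:
        blocked.setdefault(a.seq_id, []).append((a.start - margin, a.end + margin))
        blocked.setdefault(b.seq_id, []).append((b.start - margin, b.end + margin))
    for c, sat in pair.donor.satellites.items():
        blocked.setdefault(c, []).append((sat.start - margin, sat.end + margin))
    placed = 0
    for chrom in sorted(pair._maps["A"]):
        for en in pair._maps["A"][chrom]:
            if en.kind != "run" or en.orientation != "+":
                continue
            pos = en.donor_start + margin
            while pos < en.donor_end - margin and placed < n_controls:
                if not any(s <= pos < e for s, e in blocked.get(chrom, [])):
                    sub = pair._resolve_runs("A", chrom, pos, pos + 1)
                    if sub is not None and sub[2] == "+":
                        add_site(sub[0], sub[1], "NONE")
                        placed += 1
                pos += 5 * rl
    pair.truth.transitions.update(truth)
    return sites, truth


# ---------------------------------------------------------------------------
# Targeted site-pileup simulation (exact per-site depth)
# ---------------------------------------------------------------------------


def site_panel(
    n_sites: int,
    site_type: str = "SNV",
    genotype: str = "HET",
    read_length: int = 150,
    seed: int = 0,
    indel_length: int = 1,
    gc: float = 0.41,
) -> tuple[str, str, list[VariantSite], dict[str, str]]:
    """A reference contig carrying n equally spaced candidate sites.

    Used for calibration experiments where the quantity of interest is the
    per-site allele distribution at an exact depth, not genome structure.
    """
    rng = np.random.default_rng([seed, 606])
    spacing = 2 * read_length + 20
    length = (n_sites + 1) * spacing
    ref = _random_seq(rng, length, gc)
    name = "panel"
    sites: list[VariantSite] = []
    genotypes: dict[str, str] = {}
    for i in range(n_sites):
        pos = (i + 1) * spacing
        ref_base = ref[pos]
        if site_type == "SNV":
            alt = _BASES[(_BASES.index(ref_base) + int(rng.integers(1, 4))) % 4]
            ra, aa = ref_base, alt
        elif site_type == "INS":
            ins = "".join(_BASES[int(b)] for b in rng.integers(0, 4, size=indel_length))
            ra, aa = ref_base, ref_base + ins
        else:
            ra, aa = ref[pos : pos + 1 + indel_length], ref_base
        sid = f"p{i:05d}"
        sites.append(VariantSite(name, pos, ra, aa, sid, site_type))
        genotypes[sid] = genotype
    return name, ref, sites, genotypes


def simulate_site_reads(
    ref_name: str,
    ref_seq: str,
    sites: list[VariantSite],
    genotypes: dict[str, str],
    depth: int,
    read_length: int = 150,
    seed: int = 0,
    error_rate: float = 0.0,
) -> list[SimulatedRead]:
    """Exactly ``depth`` reads over each site, alleles drawn per genotype.

    Each read picks one of the sample's two haplotypes uniformly, so a HET
    site's alternate-allele count is Binomial(depth, 1/2) exactly.
    """
    rng = np.random.default_rng([seed, 707])
    alt_p = {HOM_REF: 0.0, HET: 0.5, HOM_ALT: 1.0}
    reads: list[SimulatedRead] = []
    for s_idx, site in enumerate(sites):
        p_alt = alt_p[genotypes[site.site_id]]
        pos = site.pos
        k = len(site.ref_allele) - 1  # deleted bases for DEL, else 0
        lo = max(0, pos - read_length + k + 2)
        hi = min(pos, len(ref_seq) - read_length)
        for r in range(depth):
            start = int(rng.integers(lo, hi + 1))
            use_alt = bool(rng.random() < p_alt)
            if site.site_type == SNV:
                seq = ref_seq[start : start + read_length]
                if use_alt:
                    i = pos - start
                    seq = seq[:i] + site.alt_allele + seq[i + 1 :]
                ops = [(0, read_length)]
            elif site.site_type == INS:
                if use_alt:
                    a = pos - start + 1
                    ins = site.alt_allele[1:]
                    body = ref_seq[start : start + a] + ins
                    rest = read_length - len(body)
                    seq = body + ref_seq[start + a : start + a + rest]
                    ops = [(0, a), (1, len(ins)), (0, rest)]
                else:
                    seq = ref_seq[start : start + read_length]
                    ops = [(0, read_length)]
            else:  # DEL
                if use_alt:
                    a = pos - start + 1
                    rest = read_length - a
                    seq = ref_seq[start : start + a] + ref_seq[
                        start + a + k : start + a + k + rest
                    ]
                    ops = [(0, a), (2, k), (0, rest)]
                else:
                    seq = ref_seq[start : start + read_length]
                    ops = [(0, read_length)]
            if error_rate > 0.0:
                seq = _mutate(rng, seq, error_rate)
            flag = 0x1 | (0x40 if r % 2 == 0 else 0x80)
            reads.append(
                SimulatedRead(f"s{s_idx:05d}r{r:03d}", flag, ref_name, start, 60, ops, seq)
            )
    reads.sort(key=lambda r: r.reference_start)
    return reads


# ---------------------------------------------------------------------------
# On-disk fixture bundle
# ---------------------------------------------------------------------------


def _write_fasta(sequences: dict[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_sam(
    records: list[SimulatedRead], header: list[tuple[str, int]], path: str
) -> None:
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for name, length in header:
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for rec in records:
            fh.write(rec.to_sam() + "\n")


def write_pair(pair: AssemblyPair, outdir: str) -> dict[str, str]:
    """Write the assembly pair and its truth annotation; returns path map."""
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}

    def p(key: str, name: str) -> str:
        paths[key] = os.path.join(outdir, name)
        return paths[key]

    _write_fasta(pair.A.sequences, p("fasta_a", "assemblyA.fa"))
    _write_fasta(pair.B.sequences, p("fasta_b", "assemblyB.fa"))
    _write_fasta(pair.B.full_sequences, p("fasta_b_full", "assemblyB.full.fa"))
    with open(p("agp_a", "assemblyA.agp"), "w") as fh:
        fh.write(write_agp(pair.A.agp))
    with open(p("agp_b", "assemblyB.agp"), "w") as fh:
        fh.write(write_agp(pair.B.agp))
    with open(p("agp_b_full", "assemblyB.full.agp"), "w") as fh:
        fh.write(write_agp(pair.B.full_agp))
    lengths = {
        **{s: len(q) for s, q in pair.A.sequences.items()},
        **{s: len(q) for s, q in pair.B.full_sequences.items()},
    }
    with open(p("alignments", "truth_alignments.paf"), "w") as fh:
        fh.write(write_alignment_table(pair.truth.blocks, lengths))
    for side in ("A", "B"):
        ivs, names = [], []
        for seq_id, runs in sorted(pair.truth.labels[side].items()):
            for s, e, lab in runs:
                ivs.append(GenomicInterval(seq_id, s, e))
                names.append(lab)
        write_bed(ivs, p(f"labels_{side.lower()}", f"truth_labels.{side}.bed"), names)
    write_bed(pair.truth.centromere_bed, p("centromere_bed", "centromere.B.bed"))
    write_bed(pair.truth.new_sequence_bed, p("new_sequence_bed", "new_sequence.B.bed"))
    roles = dict(pair.A.roles)
    roles.update(pair.B.roles)
    write_role_table(roles, p("roles", "roles.tsv"))

    manifest = {
        "config": dataclasses.asdict(pair.donor.config),
        "events": [
            {
                "kind": ev.kind,
                "donor_locus": [ev.donor_locus.seq_id, ev.donor_locus.start, ev.donor_locus.end],
                "applies_to": ev.applies_to,
                "parameters": {k: ev.parameters[k] for k in sorted(ev.parameters)},
            }
            for ev in pair.truth.events
        ],
        "note": (
            "Synthetic fixture: all distributional choices are fixture design, "
            "not estimates from data."
        ),
        "truth_label_lengths": {
            side: {
                lab: pair.truth.label_length(side, lab)
                for lab in (COLLAPSED, EXPANDED, UNIQUE, UNALIGNED)
            }
            for side in ("A", "B")
        },
        "genotypes": dict(sorted(pair.truth.genotypes.items())),
        "moved_read_categories": {
            f"{rid}/{mate}": cat
            for (rid, mate), cat in sorted(pair.truth.moved_read_categories.items())
        },
        "truth_transitions": dict(sorted(pair.truth.transitions.items())),
    }
    with open(p("manifest", "truth_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


def write_reads(readset: ReadSet, outdir: str) -> dict[str, str]:
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}
    fq1 = os.path.join(outdir, "reads_1.fastq")
    fq2 = os.path.join(outdir, "reads_2.fastq")
    with open(fq1, "w") as f1, open(fq2, "w") as f2:
        for rid, r1, r2 in readset.fastq:
            f1.write(f"@{rid}/1\n{r1}\n+\n{'I' * len(r1)}\n")
            f2.write(f"@{rid}/2\n{r2}\n+\n{'I' * len(r2)}\n")
    paths["fastq_1"], paths["fastq_2"] = fq1, fq2
    for target, fname in (
        ("A", "reads.A.sam"),
        ("B", "reads.B.sam"),
        ("B_full", "reads.B_full.sam"),
    ):
        path = os.path.join(outdir, fname)
        write_sam(readset.sam[target], readset.headers[target], path)
        paths[f"sam_{target.lower()}"] = path
    return paths


def write_sites(plant: PlantResult, pair: AssemblyPair, outdir: str) -> dict[str, str]:
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}
    vcf = os.path.join(outdir, "candidate_sites.vcf")
    info = {
        s.site_id: {
            "SRC": "1" if plant.in_source_library[s.site_id] else "0",
            "STYPE": s.site_type,
        }
        for s in plant.sites
    }
    write_vcf_sites(
        plant.sites, {s: len(q) for s, q in pair.A.sequences.items()}, vcf, info
    )
    paths["vcf"] = vcf
    contigs = {sid: contig for sid, contig, _w in plant.minicontigs}
    fa = os.path.join(outdir, "minicontigs.fa")
    _write_fasta(contigs, fa)
    paths["minicontigs"] = fa
    windows = os.path.join(outdir, "minicontig_windows.bed")
    write_bed(
        [w for _sid, _c, w in plant.minicontigs],
        windows,
        [sid for sid, _c, _w in plant.minicontigs],
    )
    paths["windows"] = windows
    truth = os.path.join(outdir, "truth_genotypes.json")
    with open(truth, "w") as fh:
        json.dump(dict(sorted(plant.genotypes.items())), fh, indent=1, sort_keys=True)
        fh.write("\n")
    paths["truth_genotypes"] = truth
    pair.truth.genotypes.update(plant.genotypes)
    return paths


# ---------------------------------------------------------------------------
# Standard event suite
# ---------------------------------------------------------------------------


class _Allocator:
    """Deterministic placement of event loci in feature-free donor windows."""

    def __init__(self, donor: Donor, pad: int = 3_000):
        self.pad = pad
        self.occupied: dict[str, list[tuple[int, int]]] = {
            c: [] for c in donor.chromosomes
        }
        self.lengths = {c: len(s) for c, s in donor.sequences.items()}
        for c, sat in donor.satellites.items():
            self.occupied[c].append((sat.start - pad, sat.end + pad))
        for a, b in donor.segdup_pairs:
            self.occupied[a.seq_id].append((a.start - pad, a.end + pad))
            self.occupied[b.seq_id].append((b.start - pad, b.end + pad))

    def alloc(self, chrom: str, length: int) -> GenomicInterval:
        occ = sorted(self.occupied[chrom])
        cursor = self.pad
        for s, e in occ + [(self.lengths[chrom] - self.pad, self.lengths[chrom])]:
            if s - cursor >= length + 2 * self.pad:
                lo = cursor + self.pad
                self.occupied[chrom].append((lo - self.pad, lo + length + self.pad))
                return GenomicInterval(chrom, lo, lo + length)
            cursor = max(cursor, e)
        raise SimConfigError(f"no free window of {length} bases on {chrom}")

    def point(self, chrom: str) -> int:
        return self.alloc(chrom, 10).start


@dataclass
class StandardSuite:
    events: list[SimEvent]
    scaffolds: list[ScaffoldSpec]
    gap_closure_length: int
    alt_locus_length: int


def standard_event_suite(
    donor: Donor,
    gap_closure_length: int = 6_000,
    dup_length: int = 8_000,
    attractor_length: int = 2_000,
    alt_length: int = 8_000,
    scaffold_length: int = 30_000,
) -> StandardSuite:
    """One event of every kind plus the six movement-attractor destinations.

    Needs at least two chromosomes and one segdup pair on chr1.  The layout
    is fully deterministic given the donor.
    """
    if len(donor.chromosomes) < 2:
        raise SimConfigError("standard suite needs at least two chromosomes")
    chr1, chr2 = donor.chromosomes[0], donor.chromosomes[1]
    pair1 = next(
        ((a, b) for a, b in donor.segdup_pairs if a.seq_id == chr1), None
    )
    if pair1 is None:
        raise SimConfigError("standard suite needs a segdup pair on the first chromosome")
    alloc = _Allocator(donor)
    events: list[SimEvent] = []

    # centromere models everywhere; chr1/chr2 satellites also host attractors
    for c in donor.chromosomes:
        events.append(centromere_model(donor, c))
    sat1 = donor.satellites[chr1]
    sat2 = donor.satellites[chr2]

    events.append(gap_closure(alloc.alloc(chr1, gap_closure_length)))
    events.append(collapse(pair1[1]))
    events.append(inversion(alloc.alloc(chr2, 5_000)))
    be = alloc.alloc(chr1, 1)
    ref = donor.sequences[chr1][be.start]
    events.append(base_error(chr1, be.start, _BASES[(_BASES.index(ref) + 1) % 4]))
    events.append(retile(alloc.alloc(chr2, 10_000)))
    events.append(alt_locus(alloc.alloc(chr2, alt_length)))

    # coverage-loss mechanisms: a false duplication present only in A
    # (its sites regain coverage in B) and one present only in B (lost in B)
    events.append(
        false_duplication(
            alloc.alloc(chr2, dup_length), chr2, alloc.point(chr2),
            applies_to="A", divergence=0.0,
        )
    )
    events.append(
        false_duplication(
            alloc.alloc(chr1, dup_length), chr1, alloc.point(chr1),
            applies_to="B", divergence=0.0,
        )
    )

    # movement attractors, one per destination category
    scaffolds = [
        ScaffoldSpec("scafU", scaffold_length, centromere_associated=False),
        ScaffoldSpec("scafC", scaffold_length, centromere_associated=True),
    ]
    mid1 = (sat1.start + sat1.end) // 2
    mid2 = (sat2.start + sat2.end) // 2
    attractors = [
        (chr1, chr1, alloc.point(chr1)),        # ON
        (chr1, chr1, mid1),                     # ONCEN
        (chr1, chr2, alloc.point(chr2)),        # OFF
        (chr2, chr1, mid1 + 500),               # OFFCEN
        (chr2, "scafU", scaffold_length // 2),  # TOSCAF
        (chr1, "scafC", scaffold_length // 2),  # UNCEN
    ]
    for src_chrom, dest, pos in attractors:
        events.append(
            false_duplication(
                alloc.alloc(src_chrom, attractor_length), dest, pos,
                applies_to="B", divergence=0.0,
            )
        )
    return StandardSuite(events, scaffolds, gap_closure_length, alt_length)
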