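"""Collapse/expansion classification of an assembly pair.

Given best-hit alignment blocks between two assemblies, each base of the
focal assembly is classified by the kinds of alignments covering it:

* covered by both reciprocal and nonreciprocal best hits -> COLLAPSED
  (the other assembly carries an extra, duplicated representation);
* covered only by nonreciprocal best hits -> EXPANDED (this assembly
  carries the extra copy);
* covered only by reciprocal best hits -> UNIQUE;
* covered by nothing -> UNALIGNED.

Lengths are summarized over "ungapped regions": maximal inter-gap segments
that are more than 50% non-N by default.  Coverage is counted at segment
(post-CIGAR) resolution, not block envelopes, so indels inside a block do
not inflate labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats import AGPRow, AlignmentBlock, FormatError, GenomicInterval

COLLAPSED = "COLLAPSED"
EXPANDED = "EXPANDED"
UNIQUE = "UNIQUE"
UNALIGNED = "UNALIGNED"
LABELS = (COLLAPSED, EXPANDED, UNIQUE, UNALIGNED)

_CODE = {UNALIGNED: 0, UNIQUE: 1, EXPANDED: 2, COLLAPSED: 3}
_NAME = {v: k for k, v in _CODE.items()}


@dataclass
class RegionFilterParams:
    """Keep an inter-gap region iff its non-N fraction strictly exceeds
    ``min_non_n_fraction`` (default: more than 50% non-N)."""

    min_non_n_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_non_n_fraction < 1.0):
            raise ValueError("min_non_n_fraction must be in [0, 1)")


@dataclass
class RegionLabelTrack:
    """Run-length encoded per-base labels tiling one sequence exactly."""

    seq_id: str
    length: int
    runs: list[tuple[int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        pos = 0
        for s, e, lab in self.runs:
            if s != pos or e <= s:
                raise ValueError(f"runs do not tile {self.seq_id} at {s}")
            if lab not in LABELS:
                raise ValueError(f"unknown label {lab!r}")
            pos = e
        if pos != self.length:
            raise ValueError(f"runs cover {pos} of {self.length} bases")

    @classmethod
    def from_array(cls, seq_id: str, codes: np.ndarray) -> "RegionLabelTrack":
        runs: list[tuple[int, int, str]] = []
        if codes.size:
            change = np.flatnonzero(np.diff(codes)) + 1
            bounds = np.concatenate(([0], change, [codes.size]))
            runs = [
                (int(s), int(e), _NAME[int(codes[s])])
                for s, e in zip(bounds[:-1], bounds[1:])
            ]
        return cls(seq_id, int(codes.size), runs)

    def to_array(self) -> np.ndarray:
        codes = np.zeros(self.length, dtype=np.uint8)
        for s, e, lab in self.runs:
            codes[s:e] = _CODE[lab]
        return codes

    def intervals(self, label: str) -> list[GenomicInterval]:
        return [
            GenomicInterval(self.seq_id, s, e) for s, e, lab in self.runs if lab == label
        ]


def ungapped_regions(
    sequence: str,
    gap_rows: list[AGPRow] | None = None,
    params: RegionFilterParams | None = None,
    seq_id: str = "",
    fallback_gap_min: int = 10,
) -> list[GenomicInterval]:
    """Maximal inter-gap segments passing the non-N fraction filter.

    AGP gap rows are the separators when available; otherwise N runs of at
    least ``fallback_gap_min`` bases are used.  A kept region may still
    contain short N runs; it survives iff its non-N fraction strictly
    exceeds the threshold.
    """
    params = params or RegionFilterParams()
    n = len(sequence)
    separators: list[tuple[int, int]] = []
    if gap_rows:
        total = max(r.object_end for r in gap_rows)
        if total > n:
            raise FormatError(
                f"AGP describes {total} bases but sequence {seq_id or '?'} has {n}"
            )
        separators = [
            (r.object_start, r.object_end) for r in gap_rows if r.kind == "gap"
        ]
    else:
        arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
        is_n = np.concatenate(((arr == ord("N")), [False]))
        run_start = None
        for i in range(n + 1):
            if is_n[i] and run_start is None:
                run_start = i
            elif not is_n[i] and run_start is not None:
                if i - run_start >= fallback_gap_min:
                    separators.append((run_start, i))
                run_start = None
    separators.sort()
    regions: list[GenomicInterval] = []
    cursor = 0
    for s, e in separators + [(n, n)]:
        if s > cursor:
            seg = sequence[cursor:s]
            non_n = len(seg) - seg.count("N")
            if len(seg) > 0 and non_n / len(seg) > params.min_non_n_fraction:
                regions.append(GenomicInterval(seq_id, cursor, s))
        cursor = max(cursor, e)
    return regions


def label_bases(
    blocks: list[AlignmentBlock],
    seq_lengths: dict[str, int],
) -> dict[str, RegionLabelTrack]:
    """Per-base classification of the focal (query-side) assembly.

    Blocks must be oriented with the focal assembly as query.  Coverage is
    accumulated per alignment segment via difference arrays, then combined:
    both classes -> COLLAPSED, nonreciprocal only -> EXPANDED, reciprocal
    only -> UNIQUE, none -> UNALIGNED.
    """
    diffs: dict[str, dict[str, np.ndarray]] = {}
    for b in blocks:
        sid = b.query.seq_id
        if sid not in seq_lengths:
            raise FormatError(f"alignment block references unknown sequence {sid!r}")
        if b.query.end > seq_lengths[sid]:
            raise FormatError(f"block exceeds length of {sid}")
        if sid not in diffs:
            n = seq_lengths[sid]
            diffs[sid] = {
                "rec": np.zeros(n + 1, dtype=np.int32),
                "non": np.zeros(n + 1, dtype=np.int32),
            }
        key = "rec" if b.is_reciprocal else "non"
        d = diffs[sid][key]
        for seg in b.segments:
            d[seg.query_start] += 1
            d[seg.query_start + seg.length] -= 1
    tracks: dict[str, RegionLabelTrack] = {}
    for sid, n in seq_lengths.items():
        if sid in diffs:
            rec = np.cumsum(diffs[sid]["rec"][:-1]) > 0
            non = np.cumsum(diffs[sid]["non"][:-1]) > 0
        else:
            rec = np.zeros(n, dtype=bool)
            non = np.zeros(n, dtype=bool)
        codes = np.zeros(n, dtype=np.uint8)
        codes[rec & ~non] = _CODE[UNIQUE]
        codes[non & ~rec] = _CODE[EXPANDED]
        codes[rec & non] = _CODE[COLLAPSED]
        tracks[sid] = RegionLabelTrack.from_array(sid, codes)
    return tracks


def summarize(
    tracks: dict[str, RegionLabelTrack],
    regions: dict[str, list[GenomicInterval]],
    k: int = 10,
) -> tuple[pd.DataFrame, dict[str, list[GenomicInterval]]]:
    """Per-sequence label lengths inside kept regions plus top-k intervals.

    Returns a tidy table (seq_id, label, bases) and, per label, the k
    largest labeled intervals clipped to kept regions, sorted by length with
    ties broken by (seq_id, start).
    """
    rows: list[tuple[str, str, int]] = []
    top: dict[str, list[GenomicInterval]] = {lab: [] for lab in LABELS}
    for sid in sorted(tracks):
        track = tracks[sid]
        kept = sorted(
            (iv.start, iv.end) for iv in regions.get(sid, [])
        )
        lengths = {lab: 0 for lab in LABELS}
        for s, e, lab in track.runs:
            for ks, ke in kept:
                lo, hi = max(s, ks), min(e, ke)
                if lo < hi:
                    lengths[lab] += hi - lo
                    top[lab].append(GenomicInterval(sid, lo, hi))
        for lab in LABELS:
            rows.append((sid, lab, lengths[lab]))
    table = pd.DataFrame(rows, columns=["seq_id", "label", "bases"])
    for lab in LABELS:
        top[lab].sort(key=lambda iv: (-len(iv), iv.seq_id, iv.start))
        top[lab] = top[lab][:k]
    return table, top


def label_lengths(table: pd.DataFrame) -> dict[str, int]:
    """Genome-wide total bases per label from a summarize() table."""
    return table.groupby("label")["bases"].sum().to_dict()
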