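"""Domain types and plain-text readers/writers for interval tracks.

Coordinate convention: all internal coordinates are 0-based half-open
``[start, end)``.  GFF input is treated as 1-based inclusive and converted
on read; BED input/output is 0-based half-open and passes through
unchanged.  Strand is ignored everywhere.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

FIVE_COLOR_STATES = ("RED", "YELLOW", "BLUE", "GREEN", "BLACK")
NINE_STATES = tuple(str(i) for i in range(1, 10))

STATE_SCHEMES = {
    "five_color": FIVE_COLOR_STATES,
    "nine_state": NINE_STATES,
}


class ParseError(ValueError):
    """Raised when an input file cannot be parsed; carries the line number."""


# ---------------------------------------------------------------------------
# core types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A half-open genomic interval, optionally score-bearing."""

    chrom: str
    start: int
    end: int
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ValueError(
                f"empty/inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Nonzero shared bp; touching at a boundary is not overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GenomeBuild:
    """Named chromosome arms with their lengths in bp."""

    arms: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [name for name, _ in self.arms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate arm names in genome build")
        for name, length in self.arms:
            if length <= 0:
                raise ValueError(f"arm {name} has non-positive length {length}")

    @property
    def arm_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.arms)

    def length_of(self, arm: str) -> int:
        for name, length in self.arms:
            if name == arm:
                return length
        raise KeyError(f"unknown arm {arm!r}")

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.arms)

    def __contains__(self, arm: str) -> bool:
        return arm in self.arm_names


def merge_intervals(
    intervals: Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    """Union of base pairs as sorted, non-overlapping, score-free intervals."""
    by_key = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in by_key:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            prev = merged[-1]
            if iv.end > prev.end:
                merged[-1] = GenomicInterval(prev.chrom, prev.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


class IntervalIndex:
    """Per-arm sorted merged intervals supporting vectorized overlap queries."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for iv in merge_intervals(intervals):
            self._starts.setdefault(iv.chrom, []).append(iv.start)  # type: ignore[union-attr]
            self._ends.setdefault(iv.chrom, []).append(iv.end)  # type: ignore[union-attr]
        for chrom in self._starts:
            self._starts[chrom] = np.asarray(self._starts[chrom], dtype=np.int64)
            self._ends[chrom] = np.asarray(self._ends[chrom], dtype=np.int64)

    def any_overlap(self, chrom: str, start: int, end: int) -> bool:
        starts = self._starts.get(chrom)
        if starts is None:
            return False
        ends = self._ends[chrom]
        i = int(np.searchsorted(ends, start, side="right"))
        return i < len(starts) and starts[i] < end

    def any_overlap_many(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray
    ) -> np.ndarray:
        """Boolean mask: query i overlaps >=1 indexed interval on `chrom`."""
        idx_starts = self._starts.get(chrom)
        if idx_starts is None:
            return np.zeros(len(starts), dtype=bool)
        idx_ends = self._ends[chrom]
        i = np.searchsorted(idx_ends, starts, side="right")
        ok = i < len(idx_starts)
        out = np.zeros(len(starts), dtype=bool)
        out[ok] = idx_starts[i[ok]] < ends[ok]
        return out

    def overlap_bp(self, chrom: str, start: int, end: int) -> int:
        """Total covered bp of [start, end) by the indexed union."""
        starts = self._starts.get(chrom)
        if starts is None:
            return 0
        ends = self._ends[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if lo >= hi:
            return 0
        s = np.maximum(starts[lo:hi], start)
        e = np.minimum(ends[lo:hi], end)
        return int(np.sum(e - s))


@dataclass(frozen=True)
class BindingTrack:
    """A named protein's score-bearing binding fragments, kept sorted.

    Raw (possibly overlapping) fragments are the default view; a merged
    union index is built lazily for overlap queries.
    """

    protein: str
    intervals: tuple[GenomicInterval, ...]
    _index: IntervalIndex | None = field(
        default=None, repr=False, compare=False, hash=False
    )

    @classmethod
    def from_intervals(
        cls, protein: str, intervals: Iterable[GenomicInterval]
    ) -> "BindingTrack":
        ordered = tuple(
            sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        )
        return cls(protein, ordered)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    @property
    def index(self) -> IntervalIndex:
        if self._index is None:
            object.__setattr__(self, "_index", IntervalIndex(self.intervals))
        return self._index  # type: ignore[return-value]

    def merged(self) -> list[GenomicInterval]:
        return merge_intervals(self.intervals)

    def covered_bp(self) -> int:
        return sum(iv.length for iv in self.merged())

    def with_intervals(self, intervals: Iterable[GenomicInterval]) -> "BindingTrack":
        return BindingTrack.from_intervals(self.protein, intervals)


def filter_positive(track: BindingTrack) -> BindingTrack:
    """Keep fragments whose score is present and strictly positive."""
    return track.with_intervals(
        iv for iv in track.intervals if iv.score is not None and iv.score > 0
    )


def filter_max_length(
    track: BindingTrack, max_len_bp: int | None = None
) -> BindingTrack:
    """Keep fragments strictly shorter than ``max_len_bp`` (None = keep all)."""
    if max_len_bp is None:
        return track
    if max_len_bp <= 0:
        raise ValueError("max_len_bp must be positive")
    return track.with_intervals(
        iv for iv in track.intervals if iv.length < max_len_bp
    )


@dataclass(frozen=True, slots=True)
class Anchor:
    region_name: str
    chrom: str
    position: int
    note: str = ""


@dataclass(frozen=True)
class AnchorSet:
    """Reference positions that define the centers of window analyses."""

    anchors: tuple[Anchor, ...]

    def __len__(self) -> int:
        return len(self.anchors)

    def __iter__(self) -> Iterator[Anchor]:
        return iter(self.anchors)

    def per_arm_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for a in self.anchors:
            counts[a.chrom] = counts.get(a.chrom, 0) + 1
        return counts

    def validate_against(self, genome: GenomeBuild) -> None:
        for a in self.anchors:
            if a.chrom not in genome:
                raise ValueError(f"anchor {a.region_name}: unknown arm {a.chrom}")
            if not 0 <= a.position < genome.length_of(a.chrom):
                raise ValueError(
                    f"anchor {a.region_name}: position {a.position} outside "
                    f"{a.chrom} (length {genome.length_of(a.chrom)})"
                )


@dataclass(frozen=True, slots=True)
class StateSegment:
    chrom: str
    start: int
    end: int
    state: str


@dataclass(frozen=True)
class ChromatinStateMap:
    """A labeled partition of the genome into chromatin states."""

    scheme: str
    segments: tuple[StateSegment, ...]

    def __post_init__(self) -> None:
        alphabet = STATE_SCHEMES.get(self.scheme)
        if alphabet is None:
            raise ValueError(f"unknown state scheme {self.scheme!r}")
        ordered = sorted(self.segments, key=lambda s: (s.chrom, s.start))
        for seg in ordered:
            if seg.state not in alphabet:
                raise ValueError(
                    f"state {seg.state!r} not in scheme {self.scheme!r}"
                )
            if seg.end <= seg.start:
                raise ValueError(
                    f"empty state segment {seg.chrom}:{seg.start}-{seg.end}"
                )
        for a, b in zip(ordered, ordered[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise ValueError(
                    f"overlapping state segments on {a.chrom} at {b.start}"
                )
        object.__setattr__(self, "segments", tuple(ordered))

    @property
    def states(self) -> tuple[str, ...]:
        return STATE_SCHEMES[self.scheme]

    def window_state_bp(self, chrom: str, start: int, end: int) -> dict[str, int]:
        """bp of each state inside [start, end); uncovered bp keyed 'unassigned'."""
        out = {state: 0 for state in self.states}
        covered = 0
        starts = [s.start for s in self.segments if s.chrom == chrom]
        segs = [s for s in self.segments if s.chrom == chrom]
        lo = bisect.bisect_right(starts, start) - 1
        lo = max(lo, 0)
        for seg in segs[lo:]:
            if seg.start >= end:
                break
            ov = min(seg.end, end) - max(seg.start, start)
            if ov > 0:
                out[seg.state] += ov
                covered += ov
        out["unassigned"] = (end - start) - covered
        return out


# ---------------------------------------------------------------------------
# readers / writers (all plain text)
# ---------------------------------------------------------------------------


def _parse_score(token: str) -> float | None:
    if token in (".", ""):
        return None
    return float(token)


def read_track_gff(
    path: str | Path,
    protein_name: str,
    genome: GenomeBuild | None = None,
    on_unknown_chrom: str = "skip",
) -> BindingTrack:
    """Read a GFF2/GFF3 file (1-based inclusive) into a sorted track.

    ``on_unknown_chrom`` is only consulted when a ``genome`` is given:
    ``"skip"`` drops features on unlisted arms with a warning, ``"fail"``
    raises.
    """
    if on_unknown_chrom not in ("skip", "fail"):
        raise ValueError("on_unknown_chrom must be 'skip' or 'fail'")
    intervals: list[GenomicInterval] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(
                    f"{path}:{lineno}: expected >=6 tab-separated GFF fields, "
                    f"got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start1 = int(fields[3])
                end1 = int(fields[4])
                score = _parse_score(fields[5])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if start1 < 1 or end1 < start1:
                raise ParseError(
                    f"{path}:{lineno}: bad GFF coordinates {start1}..{end1}"
                )
            if genome is not None and chrom not in genome:
                if on_unknown_chrom == "fail":
                    raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                skipped += 1
                continue
            intervals.append(GenomicInterval(chrom, start1 - 1, end1, score))
    if skipped:
        logger.warning(
            "%s: skipped %d features on chromosomes absent from the genome build",
            path,
            skipped,
        )
    return BindingTrack.from_intervals(protein_name, intervals)


def read_track_bed(
    path: str | Path,
    protein_name: str,
    genome: GenomeBuild | None = None,
    on_unknown_chrom: str = "skip",
) -> BindingTrack:
    """Read BED3/BED4/BED5 (0-based half-open); score from column 5 if present."""
    intervals: list[GenomicInterval] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected >=3 BED fields, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start = int(fields[1])
                end = int(fields[2])
                if len(fields) >= 5:
                    score = _parse_score(fields[4])
                elif len(fields) == 4:
                    try:
                        score = _parse_score(fields[3])
                    except ValueError:
                        score = None  # column 4 was a name
                else:
                    score = None
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if genome is not None and chrom not in genome:
                if on_unknown_chrom == "fail":
                    raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                skipped += 1
                continue
            intervals.append(GenomicInterval(chrom, start, end, score))
    if skipped:
        logger.warning("%s: skipped %d features on unknown chromosomes", path, skipped)
    return BindingTrack.from_intervals(protein_name, intervals)


def write_bed(
    track_or_intervals: BindingTrack | Sequence[GenomicInterval],
    path: str | Path,
    name: str | None = None,
) -> None:
    """Write intervals as BED5 (name column = track protein or index)."""
    if isinstance(track_or_intervals, BindingTrack):
        intervals = track_or_intervals.intervals
        name = name or track_or_intervals.protein
    else:
        intervals = tuple(track_or_intervals)
        name = name or "region"
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            score = "." if iv.score is None else format(iv.score, "g")
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}_{i}\t{score}\n")


def read_genome_table(path: str | Path) -> GenomeBuild:
    arms: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected arm<TAB>length")
            arms.append((fields[0], int(fields[1])))
    return GenomeBuild(tuple(arms))


def write_genome_table(genome: GenomeBuild, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in genome.arms:
            fh.write(f"{name}\t{length}\n")


def read_anchor_table(
    path: str | Path, genome: GenomeBuild | None = None
) -> AnchorSet:
    """TSV columns: name, chrom, position[, note]."""
    anchors: list[Anchor] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected name<TAB>chrom<TAB>position"
                )
            note = fields[3] if len(fields) > 3 else ""
            anchors.append(Anchor(fields[0], fields[1], int(fields[2]), note))
    aset = AnchorSet(tuple(anchors))
    if genome is not None:
        aset.validate_against(genome)
    return aset


def write_anchor_table(anchors: AnchorSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in anchors:
            fh.write(f"{a.region_name}\t{a.chrom}\t{a.position}\t{a.note}\n")


def read_state_map(path: str | Path, scheme: str) -> ChromatinStateMap:
    """BED-like TSV: chrom, start, end, state label."""
    segments: list[StateSegment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(
                    f"{path}:{lineno}: expected chrom<TAB>start<TAB>end<TAB>state"
                )
            segments.append(
                StateSegment(fields[0], int(fields[1]), int(fields[2]), fields[3])
            )
    return ChromatinStateMap(scheme, tuple(segments))


def write_state_map(state_map: ChromatinStateMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for seg in state_map.segments:
            fh.write(f"{seg.chrom}\t{seg.start}\t{seg.end}\t{seg.state}\n")
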