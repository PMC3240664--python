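"""Anchored window analysis: bound fractions, segment heat-maps, class
profiles and chromatin-state composition around reference positions."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import (
    AnchorSet,
    BindingTrack,
    ChromatinStateMap,
    GenomeBuild,
    filter_positive,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowSpec:
    """A centered window [pos - half_width, pos + half_width) cut into
    fixed-size segments (20 segments for the 10 kb / 0.5 kb reference)."""

    half_width_bp: int = 5000
    segment_bp: int = 500

    def __post_init__(self) -> None:
        if self.half_width_bp <= 0 or self.segment_bp <= 0:
            raise ValueError("window dimensions must be positive")
        if self.half_width_bp % self.segment_bp:
            raise ValueError("half_width_bp must be a multiple of segment_bp")

    @property
    def n_segments(self) -> int:
        return 2 * self.half_width_bp // self.segment_bp

    def window_of(self, position: int) -> tuple[int, int]:
        return position - self.half_width_bp, position + self.half_width_bp

    def segment_bounds(self, position: int) -> list[tuple[int, int]]:
        left = position - self.half_width_bp
        return [
            (left + s * self.segment_bp, left + (s + 1) * self.segment_bp)
            for s in range(self.n_segments)
        ]


def _clip(start: int, end: int, genome: GenomeBuild | None, chrom: str) -> tuple[int, int]:
    lo, hi = start, end
    if lo < 0:
        lo = 0
    if genome is not None and chrom in genome:
        hi = min(hi, genome.length_of(chrom))
    if (lo, hi) != (start, end):
        logger.warning("window %s:%d-%d truncated to %d-%d", chrom, start, end, lo, hi)
    return lo, hi


def bound_fraction(
    track: BindingTrack,
    anchors: AnchorSet,
    window: WindowSpec | int,
    genome: GenomeBuild | None = None,
    positive_only: bool = True,
) -> float:
    """Percent of anchors whose window overlaps >=1 positive fragment."""
    if len(anchors) == 0:
        raise ValueError("anchor set is empty")
    half = window.half_width_bp if isinstance(window, WindowSpec) else window // 2
    use = filter_positive(track) if positive_only else track
    index = use.index
    bound = 0
    for a in anchors:
        lo, hi = _clip(a.position - half, a.position + half, genome, a.chrom)
        if hi > lo and index.any_overlap(a.chrom, lo, hi):
            bound += 1
    return 100.0 * bound / len(anchors)


def segment_profile(
    track: BindingTrack,
    anchor,
    window: WindowSpec,
    positive_only: bool = True,
) -> np.ndarray:
    """Boolean per-segment bound calls for one anchor."""
    use = filter_positive(track) if positive_only else track
    index = use.index
    out = np.zeros(window.n_segments, dtype=bool)
    for s, (lo, hi) in enumerate(window.segment_bounds(anchor.position)):
        lo = max(lo, 0)
        if hi > lo:
            out[s] = index.any_overlap(anchor.chrom, lo, hi)
    return out


def heatmap(
    tracks: list[BindingTrack],
    anchors: AnchorSet,
    window: WindowSpec,
    positive_only: bool = True,
) -> pd.DataFrame:
    """Proteins x segments matrix: percent of anchors with the segment bound."""
    if len(anchors) == 0:
        raise ValueError("anchor set is empty")
    # column labels are segment start offsets relative to the anchor
    labels = [str(lo) for lo, _ in window.segment_bounds(0)]
    rows = {}
    for track in tracks:
        profiles = np.stack(
            [segment_profile(track, a, window, positive_only) for a in anchors]
        )
        rows[track.protein] = 100.0 * profiles.mean(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=labels)


def class_profile(
    tracks: list[BindingTrack],
    class_map: dict[str, str],
    anchors: AnchorSet,
    window: WindowSpec,
    positive_only: bool = True,
) -> dict[str, pd.DataFrame]:
    """Per class: anchors x segments matrix of percent-of-class-proteins bound."""
    for track in tracks:
        if track.protein not in class_map:
            raise KeyError(f"protein {track.protein!r} missing from class map")
    classes: dict[str, list[BindingTrack]] = {}
    for track in tracks:
        classes.setdefault(class_map[track.protein], []).append(track)
    for cls, members in classes.items():
        if not members:
            raise ValueError(f"class {cls!r} is empty")
    out: dict[str, pd.DataFrame] = {}
    labels = [str(lo) for lo, _ in window.segment_bounds(0)]
    for cls, members in classes.items():
        mat = np.zeros((len(anchors), window.n_segments))
        for track in members:
            for ai, a in enumerate(anchors):
                mat[ai] += segment_profile(track, a, window, positive_only)
        out[cls] = pd.DataFrame(
            100.0 * mat / len(members),
            index=[a.region_name for a in anchors],
            columns=labels,
        )
    return out


def state_composition(
    state_map: ChromatinStateMap,
    anchors: AnchorSet,
    widths_bp: list[int],
    genome: GenomeBuild | None = None,
    min_bp: int = 1,
) -> pd.DataFrame:
    """Per window width and state: anchor counts and pooled bp percentages.

    ``n_regions`` counts anchors whose centered window contains >= min_bp
    of the state; ``bp_percent`` is the state's share of all window bp
    pooled over anchors (including an 'unassigned' share for uncovered bp).
    """
    if len(anchors) == 0:
        raise ValueError("anchor set is empty")
    rows = []
    state_names = list(state_map.states) + ["unassigned"]
    for width in widths_bp:
        half = width // 2
        totals = {s: 0 for s in state_names}
        n_regions = {s: 0 for s in state_names}
        window_bp = 0
        for a in anchors:
            lo, hi = _clip(a.position - half, a.position + half, genome, a.chrom)
            if hi <= lo:
                continue
            window_bp += hi - lo
            shares = state_map.window_state_bp(a.chrom, lo, hi)
            for s in state_names:
                totals[s] += shares[s]
                if shares[s] >= min_bp:
                    n_regions[s] += 1
        for s in state_names:
            rows.append(
                {
                    "width_bp": width,
                    "state": s,
                    "n_regions": n_regions[s],
                    "bp_percent": 100.0 * totals[s] / window_bp if window_bp else 0.0,
                }
            )
    return pd.DataFrame(rows)


def state_enrichment_ratio(
    state_map: ChromatinStateMap,
    anchors: AnchorSet,
    width_bp: int,
    state_a: str,
    state_b: str,
    genome: GenomeBuild | None = None,
) -> float:
    """Ratio of pooled bp-shares share(a)/share(b); NaN if share(b) is zero."""
    comp = state_composition(state_map, anchors, [width_bp], genome=genome)
    share = comp.set_index("state")["bp_percent"]
    if state_a not in share.index or state_b not in share.index:
        raise KeyError("state label not in scheme")
    if share[state_b] == 0:
        return float("nan")
    return float(share[state_a] / share[state_b])


def border_run(
    tracks: list[BindingTrack],
    anchor,
    window: WindowSpec,
    quorum: float = 0.5,
) -> tuple[int, int] | None:
    """Heuristic interband border: the maximal run of segments where at
    least a quorum fraction of the given tracks are bound.  Returns
    (first_segment, last_segment) inclusive, or None if no segment
    reaches quorum."""
    if not tracks:
        raise ValueError("no tracks given")
    counts = np.zeros(window.n_segments)
    for track in tracks:
        counts += segment_profile(track, anchor, window)
    ok = counts / len(tracks) >= quorum
    best: tuple[int, int] | None = None
    run_start = None
    for s, flag in enumerate(list(ok) + [False]):
        if flag and run_start is None:
            run_start = s
        elif not flag and run_start is not None:
            if best is None or (s - run_start) > (best[1] - best[0] + 1):
                best = (run_start, s - 1)
            run_start = None
    return best
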