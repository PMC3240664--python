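"""Genome-wide fragment length-class tabulation (counts and row percentages)."""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .io_core import BindingTrack, GenomicInterval

CLASS_LABELS = ("1-3", "4-6", "7-9", "10-11")
EXCLUDED_SHORT = "excluded-short"
EXCLUDED_LONG = "excluded-long"

_CLASS_OF_KB = {1: "1-3", 2: "1-3", 3: "1-3", 4: "4-6", 5: "4-6", 6: "4-6",
                7: "7-9", 8: "7-9", 9: "7-9", 10: "10-11", 11: "10-11"}


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal rounding with ties away from zero (not banker's)."""
    scale = 10**decimals
    return math.floor(x * scale + 0.5) / scale


def length_class(
    interval_or_bp: GenomicInterval | int, mode: str = "round"
) -> str:
    """Map a fragment length to a kb length class.

    ``mode="round"`` (default): length rounded to the nearest whole kb
    (half-up); rounded 0 -> excluded-short, >11 -> excluded-long.
    ``mode="truncate"``: whole kb by integer division instead.
    """
    bp = (
        interval_or_bp.length
        if isinstance(interval_or_bp, GenomicInterval)
        else int(interval_or_bp)
    )
    if bp <= 0:
        raise ValueError("fragment length must be positive")
    if mode == "round":
        kb = int(round_half_up(bp / 1000))
    elif mode == "truncate":
        kb = bp // 1000
    else:
        raise ValueError("mode must be 'round' or 'truncate'")
    if kb < 1:
        return EXCLUDED_SHORT
    if kb > 11:
        return EXCLUDED_LONG
    return _CLASS_OF_KB[kb]


def percent_row(counts: dict[str, int] | list[int] | tuple[int, ...]) -> dict[str, float]:
    """Row percentages (one decimal, half-up) from per-class counts."""
    if not isinstance(counts, dict):
        if len(counts) != len(CLASS_LABELS):
            raise ValueError(f"expected {len(CLASS_LABELS)} counts")
        counts = dict(zip(CLASS_LABELS, counts))
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("all-zero count row")
    if any(c < 0 for c in counts.values()):
        raise ValueError("negative count")
    return {
        label: round_half_up(100.0 * counts.get(label, 0) / total, 1)
        for label in CLASS_LABELS
    }


@dataclass(frozen=True)
class LengthClassTable:
    protein: str
    counts: dict[str, int]
    excluded_short: int
    excluded_long: int

    @property
    def percents(self) -> dict[str, float]:
        return percent_row(self.counts)

    @property
    def n_classified(self) -> int:
        return sum(self.counts.values())


def table_for(track: BindingTrack, mode: str = "round") -> LengthClassTable:
    counts = {label: 0 for label in CLASS_LABELS}
    short = long = 0
    for iv in track.intervals:
        cls = length_class(iv, mode=mode)
        if cls == EXCLUDED_SHORT:
            short += 1
        elif cls == EXCLUDED_LONG:
            long += 1
        else:
            counts[cls] += 1
    return LengthClassTable(track.protein, counts, short, long)


def length_table(tracks: list[BindingTrack], mode: str = "round") -> pd.DataFrame:
    """One row per track: per-class counts, percentages and exclusions."""
    rows = []
    for track in tracks:
        tab = table_for(track, mode=mode)
        row: dict[str, object] = {"protein": tab.protein}
        if tab.n_classified > 0:
            pct = tab.percents
        else:
            pct = {label: float("nan") for label in CLASS_LABELS}
        for label in CLASS_LABELS:
            row[f"count_{label}"] = tab.counts[label]
            row[f"pct_{label}"] = pct[label]
        row["excluded_short"] = tab.excluded_short
        row["excluded_long"] = tab.excluded_long
        rows.append(row)
    return pd.DataFrame(rows)
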