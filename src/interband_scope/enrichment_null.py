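"""Weighted-resampling null model and exact binomial enrichment test.

The test asks whether a set of anchored windows (reference regions) is
bound by a protein's fragments more (or less) often than same-sized
regions drawn at random from the genome, with arms weighted like the
anchors' arm-of-origin distribution.  The per-region null frequency p is
estimated empirically from the samplings; the P-value is a binomial tail
sum with a direction-dependent tail choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import (
    AnchorSet,
    BindingTrack,
    GenomeBuild,
    GenomicInterval,
    filter_positive,
)

#: Reference arm weights: one anchor on chr2R, 3 on chr3L, 4 on chr3R, 5 on chrX.
DEFAULT_ARM_WEIGHTS = {"chr2R": 1, "chr3L": 3, "chr3R": 4, "chrX": 5}

#: Molecularly mapped band controls (release-5.18 coordinates).
BAND_CONTROLS = {
    "10A1-2": GenomicInterval("chrX", 10_800_000, 10_980_000),
    "75C1": GenomicInterval("chr3L", 18_170_000, 18_370_000),
    "75C2": GenomicInterval("chr3L", 18_450_000, 18_610_000),
}

STAR_BINS = ((1e-6, "***"), (1e-3, "**"), (1e-2, "*"))


@dataclass(frozen=True)
class SamplingPlan:
    """How to draw random background regions."""

    n_samples: int = 13000
    region_size_bp: int = 10000
    arm_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ARM_WEIGHTS)
    )
    seed: int = 0
    restriction: tuple[GenomicInterval, ...] | None = None
    non_overlapping: bool = False

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if self.region_size_bp <= 0:
            raise ValueError("region_size_bp must be positive")
        if any(w < 0 for w in self.arm_weights.values()):
            raise ValueError("arm weights must be nonnegative")
        if not any(w > 0 for w in self.arm_weights.values()):
            raise ValueError("at least one arm weight must be positive")


@dataclass(frozen=True)
class OverlapFrequency:
    p: float
    null_mean: float
    null_sd: float
    n_regions: int


@dataclass(frozen=True)
class EnrichmentResult:
    protein: str
    m: int
    n13: int
    p: float
    P_raw: float
    P_final: float
    direction: str
    stars: str
    null_mean: float
    null_sd: float


def sample_regions(
    genome: GenomeBuild,
    plan: SamplingPlan,
    rng: np.random.Generator | None = None,
) -> list[GenomicInterval]:
    """Draw ``plan.n_samples`` fixed-size regions, arm chosen by weight.

    With a restriction set, regions are drawn from within the restriction
    intervals (weighted by feasible placement length) instead of whole arms.
    Sampling is with replacement; ``non_overlapping=True`` switches to
    rejection sampling of mutually disjoint regions.
    """
    if rng is None:
        rng = np.random.default_rng(plan.seed)
    size = plan.region_size_bp

    if plan.restriction is not None:
        pools = [(iv.chrom, iv.start, iv.end) for iv in plan.restriction]
        for chrom, start, end in pools:
            if end - start < size:
                raise ValueError(
                    f"restriction interval {chrom}:{start}-{end} shorter than "
                    f"region size {size}"
                )
        weights = np.array([end - start - size + 1 for _, start, end in pools], float)
    else:
        for arm in plan.arm_weights:
            if arm not in genome:
                raise ValueError(f"weight given for unknown arm {arm!r}")
        pools = [
            (arm, 0, genome.length_of(arm))
            for arm in genome.arm_names
            if plan.arm_weights.get(arm, 0) > 0
        ]
        for chrom, _, end in pools:
            if end < size:
                raise ValueError(f"arm {chrom} shorter than region size {size}")
        weights = np.array([plan.arm_weights[chrom] for chrom, _, _ in pools], float)

    weights = weights / weights.sum()
    chosen = rng.choice(len(pools), size=plan.n_samples, p=weights)
    regions: list[GenomicInterval] = []
    taken: list[tuple[str, int, int]] = []
    for idx in chosen:
        chrom, lo, hi = pools[idx]
        for _ in range(10000):
            start = int(rng.integers(lo, hi - size + 1))
            if not plan.non_overlapping:
                break
            if all(
                c != chrom or start >= e or start + size <= s for c, s, e in taken
            ):
                break
        else:
            raise RuntimeError("could not place non-overlapping region")
        if plan.non_overlapping:
            taken.append((chrom, start, start + size))
        regions.append(GenomicInterval(chrom, start, start + size))
    return regions


def count_bound_regions(
    track: BindingTrack, regions: list[GenomicInterval]
) -> int:
    """Regions overlapped by >=1 fragment (single hits per region)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for i, r in enumerate(regions):
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    total = 0
    index = track.index
    for chrom, spans in by_chrom.items():
        starts = np.array([s for s, _ in spans], dtype=np.int64)
        ends = np.array([e for _, e in spans], dtype=np.int64)
        total += int(index.any_overlap_many(chrom, starts, ends).sum())
    return total


def overlap_frequency(
    track: BindingTrack,
    regions: list[GenomicInterval],
    n13: int = 13,
) -> OverlapFrequency:
    """Empirical per-region overlap frequency p and the implied null mean/sd."""
    if not regions:
        raise ValueError("no regions sampled")
    hits = count_bound_regions(track, regions)
    p = hits / len(regions)
    return OverlapFrequency(
        p=p,
        null_mean=n13 * p,
        null_sd=float(np.sqrt(n13 * p * (1.0 - p))),
        n_regions=len(regions),
    )


def binomial_tail(p: float, m: int, n13: int = 13) -> tuple[float, float, str]:
    """Lower binomial tail sum and the direction-adjusted final P.

    P_raw = sum_{i=0..m} C(n13,i) p^i (1-p)^(n13-i).  If the observed count
    exceeds the null mean (m > n13*p) the complementary tail 1 - P_raw is
    reported instead (direction "enriched"); otherwise P_raw is used
    (direction "depleted").
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if not 0 <= m <= n13:
        raise ValueError(f"m must be an integer in [0, {n13}]")
    P_raw = float(stats.binom.cdf(m, n13, p))
    if m > n13 * p:
        return P_raw, float(stats.binom.sf(m, n13, p)), "enriched"
    return P_raw, P_raw, "depleted"


def stars(P_final: float) -> str:
    """Significance label: '' >=1e-2, '*' [1e-3,1e-2), '**' [1e-6,1e-3), '***' <1e-6."""
    if not 0.0 <= P_final <= 1.0:
        raise ValueError("P must be in [0, 1]")
    for cutoff, label in STAR_BINS:
        if P_final < cutoff:
            return label
    return ""


def count_bound_anchors(
    track: BindingTrack, anchors: AnchorSet, window_bp: int
) -> int:
    """Anchors whose centered window of total width window_bp is bound."""
    half = window_bp // 2
    regions = [
        GenomicInterval(a.chrom, max(0, a.position - half), a.position + half)
        for a in anchors
    ]
    return count_bound_regions(track, regions)


def evaluate_track(
    track: BindingTrack,
    anchors: AnchorSet,
    regions: list[GenomicInterval],
    window_bp: int,
) -> EnrichmentResult:
    n13 = len(anchors)
    m = count_bound_anchors(track, anchors, window_bp)
    freq = overlap_frequency(track, regions, n13=n13)
    P_raw, P_final, direction = binomial_tail(freq.p, m, n13)
    return EnrichmentResult(
        protein=track.protein,
        m=m,
        n13=n13,
        p=freq.p,
        P_raw=P_raw,
        P_final=P_final,
        direction=direction,
        stars=stars(P_final),
        null_mean=freq.null_mean,
        null_sd=freq.null_sd,
    )


def enrichment_report(
    tracks: list[BindingTrack],
    anchors: AnchorSet,
    genome: GenomeBuild,
    plans: dict[str, SamplingPlan],
    positive_only: bool = True,
) -> pd.DataFrame:
    """One row per protein x sampling plan (window size / background).

    Plans are keyed by a background label (e.g. "genome-10kb",
    "band-4kb"); each plan's region size doubles as the anchor window
    width.  A Benjamini-Hochberg column is emitted for convenience but no
    correction is applied to P_final itself.
    """
    if len(anchors) == 0:
        raise ValueError("anchor set is empty")
    rows = []
    for label, plan in plans.items():
        rng = np.random.default_rng(plan.seed)
        regions = sample_regions(genome, plan, rng=rng)
        for track in tracks:
            use = filter_positive(track) if positive_only else track
            res = evaluate_track(use, anchors, regions, plan.region_size_bp)
            rows.append(
                {
                    "protein": res.protein,
                    "background": label,
                    "window_bp": plan.region_size_bp,
                    "m": res.m,
                    "n_anchors": res.n13,
                    "percent_bound": round(100.0 * res.m / res.n13, 1),
                    "p": res.p,
                    "null_mean": res.null_mean,
                    "null_sd": res.null_sd,
                    "P_raw": res.P_raw,
                    "P_final": res.P_final,
                    "direction": res.direction,
                    "stars": res.stars,
                }
            )
    df = pd.DataFrame(rows)
    df["P_bh"] = _benjamini_hochberg(df["P_final"].to_numpy())
    return df


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    n = len(pvals)
    order = np.argsort(pvals)
    ranked = pvals[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out
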