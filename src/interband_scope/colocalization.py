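"""Pairwise co-localization statistics for binding tracks.

Two complementary measures are provided:

* a similarity rate r = k / min(m', n'), where k counts one-to-one
  overlapping fragment pairs after mutual redundancy removal (fragments
  that bind a counterpart fragment already claimed by another are
  dropped), and m', n' are the reduced track sizes;
* a 2x2 chi-square test over a tiling of the genome into fixed-size
  blocks (3 kb by default), comparing observed co-occupied blocks with
  the independence expectation en = l*m/n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import (
    BindingTrack,
    GenomeBuild,
    GenomicInterval,
    filter_max_length,
    filter_positive,
)

MAX_FRAGMENT_BP = 10000  # co-localization considers fragments shorter than this


@dataclass(frozen=True)
class SimilarityResult:
    protein_i: str
    protein_j: str
    m_prime: int
    n_prime: int
    k: int
    r: float
    degenerate: bool = False  # min(m', n') == 0; r reported as 0


@dataclass(frozen=True)
class SimilarityMatrix:
    proteins: tuple[str, ...]
    values: np.ndarray  # symmetric, diagonal 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.proteins, columns=self.proteins)


@dataclass(frozen=True)
class ContingencyResult:
    protein_i: str
    protein_j: str
    l: int  # blocks positive for protein i
    m: int  # blocks positive for protein j
    n: int  # total blocks
    a: int  # both positive
    b: int  # i only
    c: int  # j only
    d: int  # neither
    en: float  # expected co-occupied blocks l*m/n
    chi2: float
    p_value: float
    defined: bool


# ---------------------------------------------------------------------------
# similarity rate
# ---------------------------------------------------------------------------


def _greedy_overlap_matching(
    ivs_i: list[GenomicInterval], ivs_j: list[GenomicInterval]
) -> list[tuple[int, int]]:
    """Maximum one-to-one pairing of overlapping fragments.

    Earliest-end greedy: process i-fragments in order of end coordinate;
    each takes the unmatched overlapping j-fragment with the smallest end.
    For interval overlap graphs this greedy is maximum (exchange
    argument), which makes the pair count insensitive to which redundant
    fragment is kept.
    """
    pairs: list[tuple[int, int]] = []
    order_j = sorted(range(len(ivs_j)), key=lambda t: (ivs_j[t].start, ivs_j[t].end))
    starts_j = np.array([ivs_j[t].start for t in order_j], dtype=np.int64)
    ends_j = np.array([ivs_j[t].end for t in order_j], dtype=np.int64)
    unmatched = np.ones(len(order_j), dtype=bool)
    for idx_i in sorted(
        range(len(ivs_i)), key=lambda t: (ivs_i[t].end, ivs_i[t].start)
    ):
        a = ivs_i[idx_i]
        hi = int(np.searchsorted(starts_j, a.end, side="left"))
        if hi == 0:
            continue
        cand = unmatched[:hi] & (ends_j[:hi] > a.start)
        if not cand.any():
            continue
        masked_ends = np.where(cand, ends_j[:hi], np.iinfo(np.int64).max)
        pick = int(np.argmin(masked_ends))
        unmatched[pick] = False
        pairs.append((idx_i, order_j[pick]))
    return pairs


def _split_by_chrom(
    track: BindingTrack,
) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = {}
    for iv in track.intervals:
        out.setdefault(iv.chrom, []).append(iv)
    return out


def reduce_redundancy(
    track_i: BindingTrack, track_j: BindingTrack
) -> tuple[BindingTrack, BindingTrack]:
    """Drop fragments that bind a counterpart fragment already claimed.

    A fragment survives if it is part of the one-to-one overlap pairing or
    if it overlaps nothing in the counterpart track; redundant fragments
    (overlapping only already-claimed counterparts) are removed from both
    tracks symmetrically.
    """
    keep_i: list[GenomicInterval] = []
    keep_j: list[GenomicInterval] = []
    by_i = _split_by_chrom(track_i)
    by_j = _split_by_chrom(track_j)
    for chrom in sorted(set(by_i) | set(by_j)):
        ivs_i = by_i.get(chrom, [])
        ivs_j = by_j.get(chrom, [])
        pairs = _greedy_overlap_matching(ivs_i, ivs_j)
        matched_i = {a for a, _ in pairs}
        matched_j = {b for _, b in pairs}
        for t, iv in enumerate(ivs_i):
            if t in matched_i or not any(
                iv.start < jv.end and jv.start < iv.end for jv in ivs_j
            ):
                keep_i.append(iv)
        for t, jv in enumerate(ivs_j):
            if t in matched_j or not any(
                jv.start < av.end and av.start < jv.end for av in ivs_i
            ):
                keep_j.append(jv)
    return track_i.with_intervals(keep_i), track_j.with_intervals(keep_j)


def similarity(track_i: BindingTrack, track_j: BindingTrack) -> SimilarityResult:
    """Similarity rate r = k / min(m', n') after mutual redundancy removal.

    Tracks are expected to be pre-filtered (positive scores, fragments
    shorter than 10 kb); see :func:`prepare_track`.
    """
    red_i, red_j = reduce_redundancy(track_i, track_j)
    m_prime, n_prime = len(red_i), len(red_j)
    index_j = red_j.index
    k = sum(
        1 for iv in red_i.intervals if index_j.any_overlap(iv.chrom, iv.start, iv.end)
    )
    denom = min(m_prime, n_prime)
    if denom == 0:
        return SimilarityResult(
            track_i.protein, track_j.protein, m_prime, n_prime, k, 0.0, True
        )
    return SimilarityResult(
        track_i.protein, track_j.protein, m_prime, n_prime, k, k / denom
    )


def prepare_track(
    track: BindingTrack, max_len_bp: int | None = MAX_FRAGMENT_BP
) -> BindingTrack:
    """Apply the co-localization inclusion rule: positive score, short fragment."""
    return filter_max_length(filter_positive(track), max_len_bp)


def similarity_matrix(
    tracks: list[BindingTrack], prefilter: bool = True
) -> SimilarityMatrix:
    if len(tracks) < 2:
        raise ValueError("need at least two tracks")
    use = [prepare_track(t) if prefilter else t for t in tracks]
    n = len(use)
    values = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = similarity(use[i], use[j]).r
            values[i, j] = values[j, i] = r
    return SimilarityMatrix(tuple(t.protein for t in tracks), values)


def to_dissimilarity(matrix: SimilarityMatrix) -> np.ndarray:
    """d = 1 - r with an exact zero diagonal."""
    d = 1.0 - matrix.values
    np.fill_diagonal(d, 0.0)
    return d


# ---------------------------------------------------------------------------
# block contingency test
# ---------------------------------------------------------------------------


def block_partition(genome: GenomeBuild, block_bp: int = 3000) -> list[GenomicInterval]:
    """Tile each arm left-to-right with fixed-size blocks; last partial kept."""
    if block_bp <= 0:
        raise ValueError("block_bp must be positive")
    blocks: list[GenomicInterval] = []
    for arm, length in genome.arms:
        for start in range(0, length, block_bp):
            blocks.append(GenomicInterval(arm, start, min(start + block_bp, length)))
    return blocks


def _positive_blocks(track: BindingTrack, blocks: list[GenomicInterval]) -> np.ndarray:
    by_chrom: dict[str, list[int]] = {}
    for idx, blk in enumerate(blocks):
        by_chrom.setdefault(blk.chrom, []).append(idx)
    out = np.zeros(len(blocks), dtype=bool)
    index = track.index
    for chrom, idxs in by_chrom.items():
        starts = np.array([blocks[i].start for i in idxs], dtype=np.int64)
        ends = np.array([blocks[i].end for i in idxs], dtype=np.int64)
        out[np.array(idxs)] = index.any_overlap_many(chrom, starts, ends)
    return out


def block_test(
    track_i: BindingTrack,
    track_j: BindingTrack,
    blocks: list[GenomicInterval],
    continuity_correction: bool = False,
) -> ContingencyResult:
    """2x2 chi-square for block co-occupancy of two tracks.

    chi2 = sum over the 4 cells of (obs - exp)^2 / exp, expectations from
    the marginals; p from the chi-square distribution with 1 df.  With a
    degenerate margin (a track hitting no block or every block) the test
    is undefined and flagged rather than raised.
    """
    pos_i = _positive_blocks(track_i, blocks)
    pos_j = _positive_blocks(track_j, blocks)
    n = len(blocks)
    a = int(np.sum(pos_i & pos_j))
    b = int(np.sum(pos_i & ~pos_j))
    c = int(np.sum(~pos_i & pos_j))
    d = n - a - b - c
    l, m = a + b, a + c
    en = l * m / n
    if l == 0 or m == 0 or l == n or m == n:
        return ContingencyResult(
            track_i.protein, track_j.protein, l, m, n, a, b, c, d, en,
            float("nan"), float("nan"), False,
        )
    obs = np.array([a, b, c, d], dtype=float)
    exp = np.array(
        [l * m, l * (n - m), (n - l) * m, (n - l) * (n - m)], dtype=float
    ) / n
    dev = np.abs(obs - exp)
    if continuity_correction:
        dev = np.maximum(dev - 0.5, 0.0)
    chi2 = float(np.sum(dev**2 / exp))
    p = float(stats.chi2.sf(chi2, df=1))
    return ContingencyResult(
        track_i.protein, track_j.protein, l, m, n, a, b, c, d, en, chi2, p, True
    )


def pairwise_tables(
    tracks: list[BindingTrack],
    genome: GenomeBuild,
    block_bp: int = 3000,
    prefilter: bool = True,
) -> tuple[pd.DataFrame, SimilarityMatrix, pd.DataFrame]:
    """All-pairs overlap counts, similarity matrix and block-test p-values."""
    use = [prepare_track(t) if prefilter else t for t in tracks]
    blocks = block_partition(genome, block_bp)
    sim_rows, chi_rows = [], []
    n = len(use)
    values = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = similarity(use[i], use[j])
            values[i, j] = values[j, i] = s.r
            sim_rows.append(
                {
                    "protein_i": s.protein_i,
                    "protein_j": s.protein_j,
                    "m_prime": s.m_prime,
                    "n_prime": s.n_prime,
                    "k": s.k,
                    "r": s.r,
                }
            )
            c = block_test(use[i], use[j], blocks)
            chi_rows.append(
                {
                    "protein_i": c.protein_i,
                    "protein_j": c.protein_j,
                    "l": c.l,
                    "m": c.m,
                    "n": c.n,
                    "observed_both": c.a,
                    "expected_both": c.en,
                    "chi2": c.chi2,
                    "p_value": c.p_value,
                }
            )
    matrix = SimilarityMatrix(tuple(t.protein for t in tracks), values)
    return pd.DataFrame(sim_rows), matrix, pd.DataFrame(chi_rows)
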