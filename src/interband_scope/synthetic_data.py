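"""Synthetic worlds: genomes with planted interband-like loci, protein
tracks with controlled group co-localization, anchors and state maps.

The default world is a ~12 Mb four-arm genome (a tenth of the reference
120 Mb euchromatin) carrying a few hundred planted loci.  "Active"
proteins drop a fragment on every active locus with their detection
probability; two "silent" groups co-localize on a separate pool of loci;
background fragments are placed away from all loci so the planted
structure stays separable.  Fragment lengths are log-normal, truncated
to [0.2 kb, 11 kb] and tuned so the 1-3 kb length class dominates.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .io_core import (
    Anchor,
    AnchorSet,
    BindingTrack,
    ChromatinStateMap,
    GenomeBuild,
    GenomicInterval,
    StateSegment,
    STATE_SCHEMES,
)

DEFAULT_ARMS = (
    ("chr2R", 2_500_000),
    ("chr3L", 3_000_000),
    ("chr3R", 3_000_000),
    ("chrX", 3_500_000),
)

ACTIVE = "active"
SILENT_PCG = "silent_pcg"
SILENT_INSULATOR = "silent_insulator"


@dataclass(frozen=True)
class ProteinSpec:
    name: str
    detection_prob: float = 0.95
    length_median_bp: float = 1800.0
    length_sigma: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.detection_prob <= 1.0:
            raise ValueError("detection_prob must be in [0, 1]")


def _default_actives() -> tuple[ProteinSpec, ...]:
    return tuple(ProteinSpec(f"act{i}") for i in range(1, 7))


def _default_pcg() -> tuple[ProteinSpec, ...]:
    return tuple(ProteinSpec(f"pcg{i}") for i in range(1, 4))


def _default_insulators() -> tuple[ProteinSpec, ...]:
    return tuple(ProteinSpec(f"ins{i}") for i in range(1, 4))


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    arms: tuple[tuple[str, int], ...] = DEFAULT_ARMS
    n_loci: int = 250  # planted "active" interband-like loci
    n_silent_loci: int = 100  # separate pool shared by the silent groups
    active_proteins: tuple[ProteinSpec, ...] = field(default_factory=_default_actives)
    silent_pcg_proteins: tuple[ProteinSpec, ...] = field(default_factory=_default_pcg)
    silent_insulator_proteins: tuple[ProteinSpec, ...] = field(
        default_factory=_default_insulators
    )
    background_per_mb: float = 10.0
    background_avoids_loci: bool = True
    anchor_jitter_bp: int = 500
    n_anchors: int = 13
    locus_pitch_bp: int = 15000  # candidate-slot spacing; keeps loci separable
    locus_jitter_bp: int = 1000
    locus_window_bp: int = 3000  # painted/planted width of each locus
    silent_membership_prob: float = 0.8  # per silent locus, per silent group
    state_scheme: str = "five_color"

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.n_anchors > self.n_loci:
            raise ValueError("cannot place more anchors than loci")
        if self.state_scheme not in STATE_SCHEMES:
            raise ValueError(f"unknown state scheme {self.state_scheme!r}")

    @property
    def genome(self) -> GenomeBuild:
        return GenomeBuild(self.arms)

    @property
    def all_proteins(self) -> tuple[ProteinSpec, ...]:
        return (
            self.active_proteins
            + self.silent_pcg_proteins
            + self.silent_insulator_proteins
        )


@dataclass(frozen=True)
class GroundTruth:
    loci: tuple[GenomicInterval, ...]  # active loci (anchor candidates)
    silent_loci: tuple[GenomicInterval, ...]
    protein_group: dict[str, str]
    roster: dict[int, tuple[str, ...]]  # active locus index -> bound proteins
    n_fragments: dict[str, int]  # bookkeeping: fragments emitted per track


class World(NamedTuple):
    genome: GenomeBuild
    truth: GroundTruth
    tracks: list[BindingTrack]
    anchors: AnchorSet
    states: ChromatinStateMap


def _track_rng(seed: int, name: str) -> np.random.Generator:
    digest = hashlib.sha256(name.encode()).digest()
    key = int.from_bytes(digest[:8], "big")
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


def _draw_lengths(rng: np.random.Generator, spec: ProteinSpec, n: int) -> np.ndarray:
    """Truncated log-normal fragment lengths in [200, 11000] bp."""
    out = np.empty(n)
    need = np.ones(n, dtype=bool)
    while need.any():
        draw = rng.lognormal(np.log(spec.length_median_bp), spec.length_sigma,
                             int(need.sum()))
        out[need] = draw
        need = (out < 200) | (out > 11000)
    return np.round(out).astype(np.int64)


def _locus_slots(config: SimulationConfig) -> list[tuple[str, int]]:
    """Candidate locus centers on a fixed pitch, clear of arm edges."""
    margin = config.locus_pitch_bp
    slots: list[tuple[str, int]] = []
    for arm, length in config.arms:
        pos = margin
        while pos <= length - margin:
            slots.append((arm, pos))
            pos += config.locus_pitch_bp
    return slots


def _place_loci(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[list[tuple[str, int]], list[tuple[str, int]]]:
    slots = _locus_slots(config)
    n_total = config.n_loci + config.n_silent_loci
    if n_total > len(slots):
        raise ValueError(
            f"infeasible packing: {n_total} loci requested but only "
            f"{len(slots)} candidate slots at pitch {config.locus_pitch_bp} bp"
        )
    chosen = rng.choice(len(slots), size=n_total, replace=False)
    centers = [
        (slots[i][0], slots[i][1] + int(rng.integers(-config.locus_jitter_bp,
                                                     config.locus_jitter_bp + 1)))
        for i in chosen
    ]
    return centers[: config.n_loci], centers[config.n_loci:]


def _locus_interval(
    config: SimulationConfig, genome: GenomeBuild, chrom: str, center: int
) -> GenomicInterval:
    half = config.locus_window_bp // 2
    return GenomicInterval(
        chrom,
        max(0, center - half),
        min(genome.length_of(chrom), center + half),
    )


def _background_fragments(
    config: SimulationConfig,
    genome: GenomeBuild,
    spec: ProteinSpec,
    rng: np.random.Generator,
    forbidden: "np.ndarray | None",
    forbidden_chroms: list[str],
) -> list[GenomicInterval]:
    n = rng.poisson(config.background_per_mb * genome.total_length / 1e6)
    arms = genome.arm_names
    arm_lens = np.array([genome.length_of(a) for a in arms], dtype=float)
    probs = arm_lens / arm_lens.sum()
    out: list[GenomicInterval] = []
    lengths = _draw_lengths(rng, spec, n)
    exclusion = config.locus_pitch_bp // 2
    for length in lengths:
        for _ in range(1000):
            ai = int(rng.choice(len(arms), p=probs))
            arm = arms[ai]
            arm_len = int(arm_lens[ai])
            if arm_len <= length:
                continue
            start = int(rng.integers(0, arm_len - length))
            center = start + length // 2
            if config.background_avoids_loci and forbidden is not None:
                # reject fragments whose center falls inside a locus buffer
                ci = forbidden_chroms.index(arm) if arm in forbidden_chroms else -1
                if ci >= 0:
                    centers = forbidden[ci]
                    if centers.size and np.min(np.abs(centers - center)) < exclusion:
                        continue
            out.append(
                GenomicInterval(
                    arm, start, start + int(length), float(rng.uniform(1.0, 10.0))
                )
            )
            break
    return out


def _forbidden_centers(
    genome: GenomeBuild, loci: list[tuple[str, int]]
) -> tuple[list[str], list[np.ndarray]]:
    chroms = list(genome.arm_names)
    arrays = [
        np.array(sorted(p for c, p in loci if c == chrom), dtype=np.int64)
        for chrom in chroms
    ]
    return chroms, arrays


def _planted_fragment(
    config: SimulationConfig,
    genome: GenomeBuild,
    spec: ProteinSpec,
    rng: np.random.Generator,
    chrom: str,
    center: int,
) -> GenomicInterval:
    jitter = int(rng.integers(-config.anchor_jitter_bp, config.anchor_jitter_bp + 1))
    length = int(_draw_lengths(rng, spec, 1)[0])
    mid = center + jitter
    start = max(0, mid - length // 2)
    end = min(genome.length_of(chrom), start + length)
    return GenomicInterval(chrom, start, end, float(rng.uniform(1.0, 10.0)))


def _paint_states(
    config: SimulationConfig,
    genome: GenomeBuild,
    active_loci: list[tuple[str, int]],
    silent_loci: list[tuple[str, int]],
    rng: np.random.Generator,
) -> ChromatinStateMap:
    """RED-analog over active loci, BLUE-analog over silent loci, the rest
    chopped into random segments of the remaining states."""
    states = STATE_SCHEMES[config.state_scheme]
    if config.state_scheme == "five_color":
        active_state, silent_state = "RED", "BLUE"
        filler = [s for s in states if s not in (active_state, silent_state)]
        filler_weights = np.array([0.25, 0.15, 0.60])  # YELLOW, GREEN, BLACK
    else:
        active_state, silent_state = "1", "6"
        filler = [s for s in states if s not in (active_state, silent_state)]
        filler_weights = np.full(len(filler), 1.0 / len(filler))
    segments: list[StateSegment] = []
    for arm, length in genome.arms:
        marks = sorted(
            [(p, active_state) for c, p in active_loci if c == arm]
            + [(p, silent_state) for c, p in silent_loci if c == arm]
        )
        cursor = 0
        half = config.locus_window_bp // 2
        for pos, state in marks:
            lo, hi = max(0, pos - half), min(length, pos + half)
            if lo > cursor:
                segments.extend(
                    _fill_gap(arm, cursor, lo, filler, filler_weights, rng)
                )
            segments.append(StateSegment(arm, max(cursor, lo), hi, state))
            cursor = hi
        if cursor < length:
            segments.extend(
                _fill_gap(arm, cursor, length, filler, filler_weights, rng)
            )
    return ChromatinStateMap(config.state_scheme, tuple(segments))


def _fill_gap(
    arm: str,
    start: int,
    end: int,
    filler: list[str],
    weights: np.ndarray,
    rng: np.random.Generator,
) -> list[StateSegment]:
    out = []
    cursor = start
    while cursor < end:
        seg_len = int(rng.integers(5000, 50001))
        seg_end = min(cursor + seg_len, end)
        state = filler[int(rng.choice(len(filler), p=weights))]
        out.append(StateSegment(arm, cursor, seg_end, state))
        cursor = seg_end
    return out


def generate_world(config: SimulationConfig) -> World:
    """Deterministic world with planted co-localization structure."""
    genome = config.genome
    world_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    active_loci, silent_loci = _place_loci(config, world_rng)
    all_loci = active_loci + silent_loci
    forb_chroms, forb_centers = _forbidden_centers(genome, all_loci)

    # fixed per-group membership of silent loci (shared within a group)
    member_pcg = world_rng.random(len(silent_loci)) < config.silent_membership_prob
    member_ins = world_rng.random(len(silent_loci)) < config.silent_membership_prob

    protein_group: dict[str, str] = {}
    roster: dict[int, list[str]] = {i: [] for i in range(len(active_loci))}
    n_fragments: dict[str, int] = {}
    tracks: list[BindingTrack] = []

    group_specs = [
        (ACTIVE, config.active_proteins, None),
        (SILENT_PCG, config.silent_pcg_proteins, member_pcg),
        (SILENT_INSULATOR, config.silent_insulator_proteins, member_ins),
    ]
    for group, specs, membership in group_specs:
        for spec in specs:
            protein_group[spec.name] = group
            rng = _track_rng(config.seed, spec.name)
            intervals: list[GenomicInterval] = []
            if group == ACTIVE:
                for li, (chrom, center) in enumerate(active_loci):
                    if rng.random() < spec.detection_prob:
                        intervals.append(
                            _planted_fragment(config, genome, spec, rng, chrom, center)
                        )
                        roster[li].append(spec.name)
            else:
                for si, (chrom, center) in enumerate(silent_loci):
                    if membership[si] and rng.random() < spec.detection_prob:
                        intervals.append(
                            _planted_fragment(config, genome, spec, rng, chrom, center)
                        )
            intervals.extend(
                _background_fragments(
                    config, genome, spec, rng, forb_centers, forb_chroms
                )
            )
            n_fragments[spec.name] = len(intervals)
            tracks.append(BindingTrack.from_intervals(spec.name, intervals))

    anchor_idx = sorted(
        world_rng.choice(len(active_loci), size=config.n_anchors, replace=False)
    )
    anchors = AnchorSet(
        tuple(
            Anchor(
                f"R{i + 1}",
                active_loci[li][0],
                active_loci[li][1]
                + int(
                    world_rng.integers(
                        -config.anchor_jitter_bp, config.anchor_jitter_bp + 1
                    )
                ),
                note=f"locus_{li}",
            )
            for i, li in enumerate(anchor_idx)
        )
    )
    states = _paint_states(config, genome, active_loci, silent_loci, world_rng)
    truth = GroundTruth(
        loci=tuple(
            _locus_interval(config, genome, c, p) for c, p in active_loci
        ),
        silent_loci=tuple(
            _locus_interval(config, genome, c, p) for c, p in silent_loci
        ),
        protein_group=protein_group,
        roster={i: tuple(v) for i, v in roster.items()},
        n_fragments=n_fragments,
    )
    return World(genome, truth, tracks, anchors, states)


def null_world(config: SimulationConfig) -> World:
    """Same shape of outputs with no planted structure: every track's
    fragments and every anchor placed uniformly at random."""
    genome = config.genome
    world_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    arms = genome.arm_names
    arm_lens = np.array([genome.length_of(a) for a in arms], dtype=float)
    probs = arm_lens / arm_lens.sum()

    tracks: list[BindingTrack] = []
    protein_group: dict[str, str] = {}
    n_fragments: dict[str, int] = {}
    for group, specs in (
        (ACTIVE, config.active_proteins),
        (SILENT_PCG, config.silent_pcg_proteins),
        (SILENT_INSULATOR, config.silent_insulator_proteins),
    ):
        for spec in specs:
            protein_group[spec.name] = group
            rng = _track_rng(config.seed + 1_000_003, spec.name)
            # match the structured world's expected fragment count
            n = round(config.n_loci * spec.detection_prob) + rng.poisson(
                config.background_per_mb * genome.total_length / 1e6
            )
            lengths = _draw_lengths(rng, spec, n)
            intervals = []
            for length in lengths:
                ai = int(rng.choice(len(arms), p=probs))
                arm_len = int(arm_lens[ai])
                if arm_len <= length:
                    continue
                start = int(rng.integers(0, arm_len - length))
                intervals.append(
                    GenomicInterval(
                        arms[ai], start, start + int(length),
                        float(rng.uniform(1.0, 10.0)),
                    )
                )
            n_fragments[spec.name] = len(intervals)
            tracks.append(BindingTrack.from_intervals(spec.name, intervals))

    margin = 10000
    anchor_list = []
    for i in range(config.n_anchors):
        ai = int(world_rng.choice(len(arms), p=probs))
        pos = int(world_rng.integers(margin, int(arm_lens[ai]) - margin))
        anchor_list.append(Anchor(f"R{i + 1}", arms[ai], pos, note="uniform"))
    anchors = AnchorSet(tuple(anchor_list))

    states = _paint_states(config, genome, [], [], world_rng)
    truth = GroundTruth(
        loci=(),
        silent_loci=(),
        protein_group=protein_group,
        roster={},
        n_fragments=n_fragments,
    )
    return World(genome, truth, tracks, anchors, states)
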