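import numpy as np
import pytest

from conftest import make_track, random_track
from oracles import covered_basepairs
from interband_scope.io_core import (
    Anchor,
    AnchorSet,
    ChromatinStateMap,
    GenomeBuild,
    StateSegment,
)
from interband_scope.window_profiles import (
    WindowSpec,
    border_run,
    bound_fraction,
    class_profile,
    heatmap,
    segment_profile,
    state_composition,
    state_enrichment_ratio,
)
from interband_scope.synthetic_data import SimulationConfig, generate_world


@pytest.fixture
def big_genome():
    return GenomeBuild((("chrA", 1_000_000),))


@pytest.fixture
def anchors13_one_arm():
    return AnchorSet(
        tuple(Anchor(f"R{i + 1}", "chrA", 50_000 + 60_000 * i) for i in range(13))
    )


class TestWindowSpec:
    def test_reference_spec_has_20_segments(self):
        assert WindowSpec(5000, 500).n_segments == 20
        assert WindowSpec(2000, 500).n_segments == 8

    def test_half_width_must_divide(self):
        with pytest.raises(ValueError):
            WindowSpec(5100, 500)

    def test_segment_bounds_tile_window(self):
        spec = WindowSpec(5000, 500)
        bounds = spec.segment_bounds(100_000)
        assert bounds[0] == (95_000, 95_500)
        assert bounds[-1] == (104_500, 105_000)
        for (_, e1), (s2, _) in zip(bounds, bounds[1:]):
            assert e1 == s2


class TestBoundFraction:
    def test_genome_spanning_track_is_100(self, big_genome, anchors13_one_arm):
        track = make_track("p", [("chrA", 0, 1_000_000, 1.0)])
        assert bound_fraction(track, anchors13_one_arm, 10000) == 100.0

    def test_empty_track_is_0(self, anchors13_one_arm):
        track = make_track("p", [])
        assert bound_fraction(track, anchors13_one_arm, 10000) == 0.0

    def test_nine_of_thirteen(self, anchors13_one_arm):
        planted = [
            ("chrA", a.position - 100, a.position + 100, 1.0)
            for a in list(anchors13_one_arm)[:9]
        ]
        track = make_track("p", planted)
        got = bound_fraction(track, anchors13_one_arm, 10000)
        assert got == pytest.approx(100 * 9 / 13)
        assert round(got, 1) == 69.2

    def test_matches_per_bp_brute_force(self, rng):
        anchors = AnchorSet(
            tuple(Anchor(f"R{i}", "chrA", 2000 + 1500 * i) for i in range(5))
        )
        track = random_track(rng, n=15, arm_len=10_000, max_len=400, scored=False)
        got = bound_fraction(track, anchors, 1000)
        union = covered_basepairs(track.intervals, "chrA", 10_000)
        bound = sum(
            1
            for a in anchors
            if union & set(range(a.position - 500, a.position + 500))
        )
        assert got == pytest.approx(100 * bound / 5)

    def test_window_monotonicity(self, rng, anchors13_one_arm):
        for _ in range(10):
            track = random_track(rng, n=30, arm_len=1_000_000, max_len=3000)
            wide = bound_fraction(track, anchors13_one_arm, 10000)
            narrow = bound_fraction(track, anchors13_one_arm, 4000)
            assert wide >= narrow

    def test_nonpositive_fragments_ignored(self, anchors13_one_arm):
        a = list(anchors13_one_arm)[0]
        track = make_track("p", [("chrA", a.position - 10, a.position + 10, -5.0)])
        assert bound_fraction(track, anchors13_one_arm, 10000) == 0.0

    def test_empty_anchor_set_rejected(self):
        with pytest.raises(ValueError):
            bound_fraction(make_track("p", []), AnchorSet(()), 10000)


class TestSegmentHeatmap:
    def test_single_fragment_on_segment_10(self, anchors13_one_arm):
        spec = WindowSpec(5000, 500)
        a0 = list(anchors13_one_arm)[0]
        lo, hi = spec.segment_bounds(a0.position)[10]
        track = make_track("p", [("chrA", lo, hi, 1.0)])
        hm = heatmap([track], anchors13_one_arm, spec)
        row = hm.loc["p"].to_numpy()
        assert row[10] == pytest.approx(100 / 13)
        assert round(row[10], 1) == 7.7
        assert (np.delete(row, 10) == 0).all()

    def test_fragment_spanning_whole_window(self, anchors13_one_arm):
        spec = WindowSpec(5000, 500)
        a0 = list(anchors13_one_arm)[0]
        track = make_track(
            "p", [("chrA", a0.position - 6000, a0.position + 6000, 1.0)]
        )
        profile = segment_profile(track, a0, spec)
        assert profile.all()

    def test_cells_equal_segmentwise_bound_fraction(self, rng, anchors13_one_arm):
        spec = WindowSpec(5000, 500)
        track = random_track(rng, n=40, arm_len=1_000_000, max_len=2000)
        hm = heatmap([track], anchors13_one_arm, spec)
        for s, (lo, _) in enumerate(spec.segment_bounds(0)):
            shifted = AnchorSet(
                tuple(
                    Anchor(a.region_name, a.chrom, a.position + lo + spec.segment_bp // 2)
                    for a in anchors13_one_arm
                )
            )
            expected = bound_fraction(track, shifted, spec.segment_bp)
            assert hm.loc[track.protein].iloc[s] == pytest.approx(expected)

    def test_planted_active_track_peaks_centrally(self):
        anchors = AnchorSet((Anchor("R1", "chrA", 500_000),))
        track = make_track("p", [("chrA", 499_000, 501_000, 1.0)])
        spec = WindowSpec(5000, 500)
        hm = heatmap([track], anchors, spec)
        row = hm.loc["p"].to_numpy()
        assert (row[8:12] == 100.0).all()
        assert (row[:8] == 0.0).all() and (row[12:] == 0.0).all()


class TestClassProfile:
    def test_half_of_class_bound(self):
        anchors = AnchorSet((Anchor("R1", "chrA", 10_000),))
        spec = WindowSpec(2000, 500)
        bound = [("chrA", 9_900, 10_100, 1.0)]
        tracks = [
            make_track("a", bound),
            make_track("b", bound),
            make_track("c", [("chrA", 50_000, 50_100, 1.0)]),
            make_track("d", [("chrA", 60_000, 60_100, 1.0)]),
        ]
        classes = {p: "open" for p in "abcd"}
        prof = class_profile(tracks, classes, anchors, spec)["open"]
        center = prof.loc["R1"].iloc[3]  # segment [-500, 0)
        assert center == 50.0

    def test_missing_protein_rejected(self):
        anchors = AnchorSet((Anchor("R1", "chrA", 10_000),))
        tracks = [make_track("a", [("chrA", 0, 10, 1.0)])]
        with pytest.raises(KeyError, match="'a'"):
            class_profile(tracks, {}, anchors, WindowSpec(2000, 500))

    def test_matches_brute_force_recount(self, rng):
        anchors = AnchorSet(
            tuple(Anchor(f"R{i}", "chrA", 20_000 + 15_000 * i) for i in range(4))
        )
        spec = WindowSpec(2000, 500)
        tracks = [
            random_track(rng, protein=f"t{i}", n=25, arm_len=100_000, max_len=900)
            for i in range(3)
        ]
        classes = {f"t{i}": "cls" for i in range(3)}
        prof = class_profile(tracks, classes, anchors, spec)["cls"]
        from interband_scope.io_core import filter_positive

        for a in anchors:
            for s, (lo, hi) in enumerate(spec.segment_bounds(a.position)):
                n_bound = sum(
                    any(
                        iv.start < hi and lo < iv.end
                        for iv in filter_positive(t).intervals
                    )
                    for t in tracks
                )
                assert prof.loc[a.region_name].iloc[s] == pytest.approx(
                    100 * n_bound / 3
                )


def paint_all(chrom, length, state, scheme="five_color"):
    return ChromatinStateMap(scheme, (StateSegment(chrom, 0, length, state),))


class TestStateComposition:
    def test_all_red_map(self, big_genome, anchors13_one_arm):
        smap = paint_all("chrA", 1_000_000, "RED")
        comp = state_composition(smap, anchors13_one_arm, [2000, 10000])
        red = comp[comp.state == "RED"]
        assert (red.n_regions == 13).all()
        assert (red.bp_percent == 100.0).all()

    def test_half_red_half_yellow_window(self):
        smap = ChromatinStateMap(
            "five_color",
            (
                StateSegment("chrA", 0, 10_000, "RED"),
                StateSegment("chrA", 10_000, 20_000, "YELLOW"),
            ),
        )
        anchors = AnchorSet((Anchor("R1", "chrA", 10_000),))
        comp = state_composition(smap, anchors, [4000]).set_index("state")
        assert comp.loc["RED", "bp_percent"] == 50.0
        assert comp.loc["YELLOW", "bp_percent"] == 50.0

    def test_shares_sum_to_100_including_unassigned(self, rng):
        smap = ChromatinStateMap(
            "five_color",
            (
                StateSegment("chrA", 0, 5_000, "RED"),
                StateSegment("chrA", 8_000, 30_000, "BLACK"),
            ),
        )
        anchors = AnchorSet(
            tuple(Anchor(f"R{i}", "chrA", 6_000 + 4_000 * i) for i in range(3))
        )
        for width in (1000, 4000, 10000):
            comp = state_composition(smap, anchors, [width])
            assert comp.bp_percent.sum() == pytest.approx(100.0)

    def test_synthetic_world_matches_brute_force_tally(self):
        world = generate_world(SimulationConfig(seed=2))
        comp = state_composition(
            world.states, world.anchors, [4000], world.genome
        ).set_index("state")
        width = 4000
        tallies = {s: 0 for s in world.states.states}
        total = 0
        for a in world.anchors:
            lo = a.position - width // 2
            hi = a.position + width // 2
            total += hi - lo
            for seg in world.states.segments:
                if seg.chrom == a.chrom:
                    ov = min(seg.end, hi) - max(seg.start, lo)
                    if ov > 0:
                        tallies[seg.state] += ov
        for s, bp in tallies.items():
            assert comp.loc[s, "bp_percent"] == pytest.approx(100 * bp / total)


class TestStateEnrichmentRatio:
    def test_equal_shares_ratio_one(self):
        smap = ChromatinStateMap(
            "five_color",
            (
                StateSegment("chrA", 0, 10_000, "RED"),
                StateSegment("chrA", 10_000, 20_000, "YELLOW"),
            ),
        )
        anchors = AnchorSet((Anchor("R1", "chrA", 10_000),))
        assert state_enrichment_ratio(smap, anchors, 4000, "RED", "YELLOW") == 1.0

    def test_three_to_one(self):
        smap = ChromatinStateMap(
            "five_color",
            (
                StateSegment("chrA", 0, 6_000, "RED"),
                StateSegment("chrA", 6_000, 8_000, "YELLOW"),
                StateSegment("chrA", 8_000, 10_000, "BLUE"),
            ),
        )
        anchors = AnchorSet((Anchor("R1", "chrA", 5_000),))
        got = state_enrichment_ratio(smap, anchors, 10_000, "RED", "YELLOW")
        assert got == pytest.approx(3.0)

    def test_zero_denominator_is_nan(self, big_genome, anchors13_one_arm):
        smap = paint_all("chrA", 1_000_000, "RED")
        got = state_enrichment_ratio(smap, anchors13_one_arm, 4000, "RED", "GREEN")
        assert np.isnan(got)

    def test_planted_world_ratio_grows_toward_anchor(self):
        world = generate_world(SimulationConfig(seed=4))
        near = state_enrichment_ratio(
            world.states, world.anchors, 4000, "RED", "BLACK", world.genome
        )
        far = state_enrichment_ratio(
            world.states, world.anchors, 10000, "RED", "BLACK", world.genome
        )
        assert near > far


class TestBorderRun:
    def test_central_run_detected(self):
        anchors = AnchorSet((Anchor("R1", "chrA", 500_000),))
        spec = WindowSpec(5000, 500)
        bound = [("chrA", 499_000, 501_000, 1.0)]
        tracks = [make_track(p, bound) for p in "abc"]
        run = border_run(tracks, list(anchors)[0], spec)
        assert run == (8, 11)

    def test_no_quorum_returns_none(self):
        anchors = AnchorSet((Anchor("R1", "chrA", 500_000),))
        spec = WindowSpec(5000, 500)
        tracks = [
            make_track("a", [("chrA", 499_000, 501_000, 1.0)]),
            make_track("b", [("chrA", 10, 20, 1.0)]),
            make_track("c", [("chrA", 10, 20, 1.0)]),
        ]
        assert border_run(tracks, list(anchors)[0], spec) is None
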