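"""Quantization, translational pattern covers, compression ratio, rhythmic simplicity."""

import math
import random
from functools import lru_cache

import pytest

from improvsync.pattern_features import (
    QuantizedPointSet,
    candidate_classes,
    cr_dur,
    discover_cover,
    quantize,
    rhythmic_simplicity,
    rs,
    tc_o,
)
from improvsync.segmentation import make_eighth_grid

from conftest import make_beats, participant_note


def make_grid(n_beats=24, dt=0.75):
    return make_eighth_grid(make_beats(n_beats // 3, n_beats // 3, n_beats // 3, dt=dt))


def point_set(points):
    pts = {tuple(p) if isinstance(p, (tuple, list)) else (p,) for p in points}
    dim = len(next(iter(pts)))
    return QuantizedPointSet(points=frozenset(pts), dimensions=dim)


def exhaustive_optimal_cost(points):
    """Minimum encoding cost over all sequences of TEC selections (no ratio cutoff).

    Independent of the greedy path: memoized recursion over the remaining set,
    allowing any candidate class or leaving all points as residual.
    """

    @lru_cache(maxsize=None)
    def rec(rem):
        best = len(rem)
        if len(rem) >= 2:
            for cls in candidate_classes(rem):
                best = min(best, cls.cost + rec(rem - cls.covered))
        return best

    return rec(frozenset(points))


class TestQuantize:
    def test_ontime_is_nearest_grid_index(self):
        grid = make_grid()
        ps = quantize([participant_note(0.01), participant_note(0.74)], grid, with_duration=False)
        assert ps.points == {(0,), (2,)}

    def test_same_cell_collapses_to_one_point(self):
        grid = make_grid()
        notes = [participant_note(0.0, duration=0.375, pitch=72),
                 participant_note(0.0, duration=0.375, pitch=76)]
        ps = quantize(notes, grid)
        assert len(ps) == 1

    def test_duration_floors_at_one_unit(self):
        grid = make_grid()
        ps = quantize([participant_note(0.0, duration=0.01)], grid)
        assert ps.points == {(0, 1)}

    def test_metronomic_fixture_has_unit_iois(self):
        grid = make_grid()
        notes = [participant_note(0.375 * i) for i in range(10)]
        profile = rhythmic_simplicity(notes, grid)
        assert set(profile.iois) == {1}


class TestPatternCover:
    def test_repeated_four_point_rhythm_compresses_to_cr_1_6(self):
        # 4-point rhythm at ontimes {0,1,3,4}, repeated at offset +8:
        # encoding = pattern(4 points) + 2 translators - 1 = 5, CR = 8/5.
        # Exhaustive search over all TECs of this set confirms cost 5 is optimal.
        pts = [0, 1, 3, 4, 8, 9, 11, 12]
        cover = discover_cover(point_set(pts))
        assert exhaustive_optimal_cost({(p,) for p in pts}) == 5
        assert cover.encoding_cost == 5
        assert cover.compression_ratio == pytest.approx(1.6)

    def test_all_unique_difference_set_is_incompressible(self):
        # a Sidon set: every pairwise difference occurs once
        cover = discover_cover(point_set([0, 1, 3, 7]))
        assert cover.classes == []
        assert cover.compression_ratio == 1.0

    def test_empty_and_singleton_sets_have_cr_one(self):
        assert discover_cover(point_set([5])).compression_ratio == 1.0

    def test_cover_reconstruction_equals_input(self, rng):
        for _ in range(30):
            pts = {(int(a), int(b)) for a, b in
                   zip(rng.integers(0, 12, 12), rng.integers(1, 5, 12))}
            cover = discover_cover(QuantizedPointSet(frozenset(pts), 2))
            rebuilt = set(cover.residual)
            for cls in cover.classes:
                for t in cls.translators:
                    rebuilt |= {tuple(p + d for p, d in zip(pt, t)) for pt in cls.pattern}
            assert rebuilt == pts

    def test_cr_at_least_one_and_bounded_by_exhaustive_optimum(self):
        rnd = random.Random(424242)
        for _ in range(60):
            n = rnd.randint(2, 6)
            pts = set()
            while len(pts) < n:
                pts.add((rnd.randint(0, 7),))
            cover = discover_cover(QuantizedPointSet(frozenset(pts), 1))
            opt = exhaustive_optimal_cost(pts)
            assert cover.encoding_cost >= opt  # greedy can't beat the optimum
            assert 1.0 <= cover.compression_ratio <= len(pts) / opt

    def test_cr_strictly_above_one_iff_a_class_was_selected(self, rng):
        for _ in range(20):
            pts = {(int(a),) for a in rng.integers(0, 15, 8)}
            cover = discover_cover(QuantizedPointSet(frozenset(pts), 1))
            assert (cover.compression_ratio > 1.0) == bool(cover.classes)


class TestVariableLevel:
    def test_periodic_ontimes_fully_covered(self):
        grid = make_grid(n_beats=30)
        notes = [participant_note(0.75 * i) for i in range(12)]  # period 2 units
        assert tc_o(notes, grid) == pytest.approx(1.0)

    def test_unique_difference_ontimes_give_tc_zero(self):
        grid = make_grid(n_beats=30)
        notes = [participant_note(0.375 * k) for k in (0, 1, 3, 7)]
        assert tc_o(notes, grid) == 0.0

    def test_translation_leaves_cr_and_tc_unchanged(self):
        grid = make_grid(n_beats=45)
        base = [participant_note(0.375 * k, duration=0.4) for k in (0, 1, 4, 5, 8, 9)]
        moved = [participant_note(0.375 * (k + 5), duration=0.4) for k in (0, 1, 4, 5, 8, 9)]
        assert cr_dur(base, grid) == pytest.approx(cr_dur(moved, grid))
        assert tc_o(base, grid) == pytest.approx(tc_o(moved, grid))

    def test_pitch_permutation_leaves_timing_variables_unchanged(self, rng):
        grid = make_grid(n_beats=30)
        onsets = sorted(rng.choice(24, size=10, replace=False))
        a = [participant_note(0.375 * k, pitch=72) for k in onsets]
        b = [participant_note(0.375 * k, pitch=int(p)) for k, p in
             zip(onsets, rng.integers(67, 84, 10))]
        assert cr_dur(a, grid) == cr_dur(b, grid)
        assert rs(a, grid) == rs(b, grid)

    def test_fewer_than_two_notes_is_missing(self):
        grid = make_grid()
        assert math.isnan(cr_dur([participant_note(0.0)], grid))
        assert math.isnan(tc_o([], grid))
        assert math.isnan(rs([participant_note(0.0)], grid))


class TestRhythmicSimplicity:
    def test_isochronous_notes_give_rs_one(self):
        grid = make_grid(n_beats=30)
        notes = [participant_note(0.375 * i) for i in range(16)]
        assert rs(notes, grid) == 1.0

    def test_all_distinct_iois_give_rs_one_over_count(self):
        grid = make_grid(n_beats=60)
        ontimes = [0, 1, 3, 6, 10, 15]  # gaps 1,2,3,4,5 all distinct
        notes = [participant_note(0.375 * k) for k in ontimes]
        assert rs(notes, grid) == pytest.approx(1 / 5)

    def test_modal_proportion(self):
        grid = make_grid(n_beats=30)
        notes = [participant_note(0.375 * k) for k in (0, 1, 2, 4)]  # IOIs 1,1,2
        assert rs(notes, grid) == pytest.approx(2 / 3)

    def test_mode_tie_breaks_to_smaller_ioi(self):
        grid = make_grid(n_beats=30)
        notes = [participant_note(0.375 * k) for k in (0, 1, 3, 5, 6)]  # IOIs 1,2,2,1
        profile = rhythmic_simplicity(notes, grid)
        assert profile.modal_ioi == 1

    def test_chord_collapses_to_single_onset(self):
        grid = make_grid(n_beats=30)
        notes = [participant_note(0.0, pitch=72), participant_note(0.0, pitch=76),
                 participant_note(0.375), participant_note(0.75)]
        profile = rhythmic_simplicity(notes, grid)
        assert profile.iois == [1, 1]
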