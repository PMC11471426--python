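"""Range-change accounting: pixel bookkeeping, classification, centroids,
richness stacking, and the published reference table arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from climniche import (
    RangeChangeSummary,
    centroid,
    centroid_shift,
    classify_change,
    compare_ranges,
    export_table,
    load_published_range_changes,
    richness,
    richness_change,
)
from climniche.projection import BinaryNicheMap


def _bmap(mask, species="s", scenario="recent", cell_size=1.0, origin=(0.0, 0.0)):
    return BinaryNicheMap(species, scenario, np.asarray(mask, bool), 0.5,
                          cell_size=cell_size, origin=origin)


def _rand_mask(rng, shape=(12, 12), p=0.4):
    return rng.uniform(size=shape) < p


class TestCompareRanges:
    def test_bruteforce_counts(self, rng):
        a, b = _rand_mask(rng), _rand_mask(rng)
        s = compare_ranges(_bmap(a), _bmap(b, scenario="late85"))
        loss = gain = maintain = 0
        for i in range(a.shape[0]):
            for j in range(a.shape[1]):
                loss += a[i, j] and not b[i, j]
                gain += b[i, j] and not a[i, j]
                maintain += a[i, j] and b[i, j]
        assert (s.loss, s.gain, s.maintain) == (loss, gain, maintain)
        assert s.current_size == loss + maintain
        assert s.future_size == gain + maintain

    def test_identical_maps_zero_change(self, rng):
        a = _rand_mask(rng)
        s = compare_ranges(_bmap(a), _bmap(a, scenario="late85"))
        assert s.loss == 0 and s.gain == 0
        assert s.range_change == pytest.approx(0.0)

    def test_grid_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            compare_ranges(_bmap(_rand_mask(rng)), _bmap(np.zeros((5, 5), bool)))

    @pytest.mark.parametrize(
        "loss,gain,maintain,pl,pg,rc",
        [
            # severe contraction of a montane short-horned lizard
            # (the source table prints Lost 97.96, a last-digit typo: its
            # own Range change -97.40 equals 0.5508 - 97.9549)
            (184792, 1039, 3858, 97.95, 0.55, -97.40),
            # total range loss of a dune-endemic lizard
            (4322, 0, 0, 100.00, 0.00, -100.00),
        ],
    )
    def test_published_percent_arithmetic(self, loss, gain, maintain, pl, pg, rc):
        s = RangeChangeSummary.from_counts(loss, gain, maintain)
        assert round(s.percent_lost, 2) == pl
        assert round(s.percent_gained, 2) == pg
        assert round(s.range_change, 2) == rc

    def test_percent_rounding_from_unrounded_ratios(self):
        """The Sierra Gartersnake row: rounding the two percentages
        first and subtracting gives -75.16; the correct value -75.15
        requires subtracting unrounded ratios."""
        s = RangeChangeSummary.from_counts(58877, 1535, 17423)
        assert round(s.range_change, 2) == -75.15
        assert round(round(s.percent_gained, 2) - round(s.percent_lost, 2), 2) == -75.16

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_antisymmetry(self, seed):
        """Swapping the scenario pair swaps loss and gain and negates
        the range change."""
        rng = np.random.default_rng(seed)
        a, b = _rand_mask(rng), _rand_mask(rng)
        fwd = compare_ranges(_bmap(a), _bmap(b, scenario="late85"))
        rev = compare_ranges(_bmap(b, scenario="late85"), _bmap(a))
        assert fwd.loss == rev.gain and fwd.gain == rev.loss
        assert fwd.maintain == rev.maintain
        if fwd.current_size and rev.current_size:
            expected = -fwd.range_change * fwd.current_size / rev.current_size
            assert rev.range_change == pytest.approx(expected)


class TestClassifyChange:
    def _summary(self, loss, gain, maintain, shift_km=0.0):
        s = RangeChangeSummary.from_counts(loss, gain, maintain)
        s.shift_km = shift_km
        return s

    def test_severe_loss_is_contract(self):
        s = self._summary(184792, 1039, 3858)
        assert classify_change(s) == "contract"

    def test_growth_with_low_turnover_is_expand(self):
        s = self._summary(20, 40, 80)  # net +20%, turnover 20%
        assert classify_change(s) == "expand"

    def test_growth_with_high_turnover_is_shift(self):
        s = self._summary(60, 75, 40)  # net +15%, turnover 60%
        assert classify_change(s) == "shift"

    def test_small_change_is_stable(self):
        s = self._summary(5, 10, 95, shift_km=0.0)  # net +5%
        assert classify_change(s) == "stable"

    def test_small_change_far_centroid_is_stable_shift(self):
        s = self._summary(5, 10, 95, shift_km=150.0)
        assert classify_change(s) == "stable_shift"

    def test_empty_current_range_undefined(self):
        s = self._summary(0, 10, 0)
        assert classify_change(s) == "undefined"


class TestCentroid:
    def test_single_cell(self):
        mask = np.zeros((4, 4), bool)
        mask[1, 2] = True  # row 1 from top of 4 rows -> y = 4-1-0.5 = 2.5
        assert centroid(_bmap(mask)) == (2.5, 2.5)

    def test_symmetric_pair_about_origin(self):
        mask = np.zeros((2, 2), bool)
        mask[0, 1] = True  # center (0.5, 0.5) with origin (-1,-1)
        mask[1, 0] = True  # center (-0.5, -0.5)
        assert centroid(_bmap(mask, origin=(-1.0, -1.0))) == (0.0, 0.0)

    def test_five_cells_hand_mean(self):
        mask = np.zeros((5, 5), bool)
        cells = [(0, 0), (0, 4), (2, 2), (4, 1), (4, 3)]
        for r, c in cells:
            mask[r, c] = True
        xs = [c + 0.5 for _, c in cells]
        ys = [5 - r - 0.5 for r, _ in cells]
        cx, cy = centroid(_bmap(mask))
        assert cx == pytest.approx(np.mean(xs))
        assert cy == pytest.approx(np.mean(ys))

    def test_empty_map_is_none_and_shift_flags(self):
        empty = _bmap(np.zeros((3, 3), bool))
        assert centroid(empty) is None
        with pytest.raises(ValueError):
            centroid_shift(empty, empty)

    @pytest.mark.parametrize(
        "c_from,c_to,dist,bearing",
        [
            ((0, 0), (0, 100), 100.0, 0.0),  # due north
            ((0, 0), (100, 0), 100.0, 90.0),  # due east
            ((0, 0), (30, 40), 50.0, 36.87),  # 3-4-5 triangle
            ((0, 0), (0, -50), 50.0, 180.0),  # due south
        ],
    )
    def test_shift_distance_and_bearing(self, c_from, c_to, dist, bearing):
        from climniche.change import centroid_shift_xy

        out = centroid_shift_xy(c_from, c_to)
        assert out["shift_km"] == pytest.approx(dist)
        assert out["bearing_deg"] == pytest.approx(bearing, abs=0.01)


class TestRichness:
    def test_three_species_stack(self):
        maps = [_bmap(np.ones((2, 2), bool), species=f"s{i}") for i in range(3)]
        assert (richness(maps).values == 3).all()

    def test_empty_stack(self):
        assert richness([]).values.size == 0

    def test_matches_percell_loop(self, rng):
        maps = [_bmap(_rand_mask(rng), species=f"s{i}") for i in range(5)]
        stacked = richness(maps).values
        for i in range(12):
            for j in range(12):
                assert stacked[i, j] == sum(m.mask[i, j] for m in maps)

    def test_richness_change_modes(self):
        rec = [_bmap(np.array([[True, False]]), species="a")]
        fut = [_bmap(np.array([[False, True]]), species="a", scenario="late85")]
        full = richness_change(rec, fut, "full")
        none = richness_change(rec, fut, "none")
        np.testing.assert_array_equal(full, [[-1, 1]])  # gain counts
        np.testing.assert_array_equal(none, [[-1, 0]])  # gain masked

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_no_dispersal_change_nowhere_positive(self, seed):
        rng = np.random.default_rng(seed)
        rec = [_bmap(_rand_mask(rng), species=f"s{i}") for i in range(4)]
        fut = [
            _bmap(_rand_mask(rng), species=f"s{i}", scenario="late85") for i in range(4)
        ]
        assert (richness_change(rec, fut, "none") <= 0).all()

    def test_full_dispersal_equals_sum_of_indicators(self, rng):
        rec = [_bmap(_rand_mask(rng), species=f"s{i}") for i in range(4)]
        fut = [
            _bmap(_rand_mask(rng), species=f"s{i}", scenario="late85") for i in range(4)
        ]
        total = sum(f.mask.astype(int) - r.mask.astype(int) for r, f in zip(rec, fut))
        np.testing.assert_array_equal(richness_change(rec, fut, "full"), total)

    def test_species_set_mismatch_rejected(self, rng):
        rec = [_bmap(_rand_mask(rng), species="a")]
        fut = [_bmap(_rand_mask(rng), species="b", scenario="late85")]
        with pytest.raises(ValueError):
            richness_change(rec, fut)


class TestExportTable:
    def test_sorted_by_range_change(self):
        sums = [
            RangeChangeSummary.from_counts(10, 50, 90, species_id="grower"),
            RangeChangeSummary.from_counts(80, 5, 20, species_id="shrinker"),
        ]
        df = export_table(sums)
        assert list(df["species"]) == ["shrinker", "grower"]

    def test_shuffle_invariant(self):
        sums = [
            RangeChangeSummary.from_counts(80 + i, 5, 20, species_id=f"s{i}")
            for i in range(6)
        ]
        a = export_table(sums)
        b = export_table(sums[::-1])
        pd.testing.assert_frame_equal(a, b)

    def test_empty_gives_header_only(self):
        df = export_table([])
        assert df.empty and list(df.columns)[:3] == ["species", "current", "future"]

    def test_reference_table_loads_with_21_rows(self):
        ref = load_published_range_changes()
        assert len(ref) == 21
        # rows are ordered by range change, worst contraction first
        assert ref["range_change"].is_monotonic_increasing
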