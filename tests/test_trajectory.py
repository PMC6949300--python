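"""Segmentation, indices, dynamics classes and the 8-type rule table."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from landcarbon import trajectory
from landcarbon.trajectory import (
    LANDUSE_CODES,
    LANDUSE_NAMES,
    DisturbanceIndices,
    ProbabilitySeries,
    Segment,
    categorize_index,
    classify_scene,
    classify_series,
    disturbance_indices,
    dynamics_class,
    fill_gaps,
    landuse_type,
    segment_series,
)

# ---------------------------------------------------------------- oracle


def oracle_best_sse(values, k):
    """Exhaustive enumeration over all interior-vertex placements of the
    anchored piecewise-linear cost.  Independent of the DP implementation."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    best = np.inf
    for interior in combinations(range(1, n - 1), k - 1):
        verts = (0,) + interior + (n - 1,)
        sse = 0.0
        for a, b in zip(verts[:-1], verts[1:]):
            for i in range(a + 1, b):
                t = (i - a) / (b - a)
                interp = values[a] + t * (values[b] - values[a])
                sse += (values[i] - interp) ** 2
        best = min(best, sse)
    return best


# ----------------------------------------------------------- segmentation


class TestSegmentSeries:
    def test_exactly_linear_series_single_segment(self):
        vals = np.linspace(0.1, 0.85, 16)
        res = segment_series(vals, years=np.arange(2002, 2018))
        assert res.n_segments == 1
        assert res.segments[0].magnitude == pytest.approx(vals[-1] - vals[0])
        assert res.sse == pytest.approx(0.0, abs=1e-12)

    def test_two_piece_series_vertex_at_breakpoint(self):
        vals = np.concatenate([np.full(8, 0.2), 0.2 + np.arange(1, 9) * 0.075])
        res = segment_series(vals, years=np.arange(2002, 2018))
        assert res.n_segments == 2
        assert res.segments[0].end_year == 2009  # index 7, the breakpoint
        assert res.sse == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_dp_matches_bruteforce_oracle(self, k):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = rng.integers(max(4, k + 1), 11)
            vals = rng.random(n)
            sse_by_k, _ = trajectory._best_partitions(vals, max_segments=k)
            if k not in sse_by_k:
                continue
            assert sse_by_k[k] == pytest.approx(oracle_best_sse(vals, k), abs=1e-10)

    def test_sse_nonincreasing_in_segment_count(self):
        rng = np.random.default_rng(3)
        vals = rng.random(16)
        sse_by_k, _ = trajectory._best_partitions(vals, max_segments=6)
        sses = [sse_by_k[k] for k in sorted(sse_by_k)]
        assert all(a >= b - 1e-12 for a, b in zip(sses, sses[1:]))

    def test_segments_tile_year_range(self):
        rng = np.random.default_rng(11)
        vals = rng.random(16)
        res = segment_series(vals, years=np.arange(2002, 2018))
        assert res.segments[0].start_year == 2002
        assert res.segments[-1].end_year == 2017
        for a, b in zip(res.segments[:-1], res.segments[1:]):
            assert a.end_year == b.start_year
            assert a.end_value == b.start_value
        assert res.n_segments <= 6
        assert all(s.duration >= 1 for s in res.segments)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            segment_series([0.1, 0.2, 0.3])

    def test_nonfinite_series_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            segment_series([0.1, np.nan, 0.3, 0.4, 0.5])

    def test_probability_series_input(self):
        ps = ProbabilitySeries(np.arange(2002, 2018), np.linspace(0, 1, 16))
        res = segment_series(ps)
        assert res.n_segments == 1


class TestFillGaps:
    def test_short_gap_interpolated(self):
        vals = np.array([0.2, 0.3, np.nan, 0.5, 0.6])
        out = fill_gaps(vals)
        assert out[2] == pytest.approx(0.4)

    def test_long_gap_masks(self):
        vals = np.array([0.2, np.nan, np.nan, np.nan, 0.6, 0.7])
        assert fill_gaps(vals, max_gap=2) is None

    def test_edge_gap_masks(self):
        assert fill_gaps(np.array([np.nan, 0.2, 0.3, 0.4])) is None


# ---------------------------------------------------------------- indices


def _seg(start_year, end_year, start_value, end_value):
    return Segment(start_year, end_year, start_value, end_value)


def _result(segments):
    return trajectory.SegmentationResult(
        segments=segments, fitted_values=np.empty(0), sse=0.0
    )


class TestDisturbanceIndices:
    def test_positive_magnitude_over_duration(self):
        res = _result([_seg(2002, 2004, 0.2, 0.8)])  # 0.6 over 2 yr
        idx = disturbance_indices(res)
        assert idx.increase_index == pytest.approx(0.3)
        assert idx.increase_category == "low"
        assert idx.decrease_index == 0.0

    def test_monotone_decline_zero_increase(self):
        res = _result([_seg(2002, 2010, 0.8, 0.3), _seg(2010, 2017, 0.3, 0.1)])
        idx = disturbance_indices(res)
        assert idx.increase_index == 0.0
        assert idx.decrease_index == pytest.approx(0.5 / 8)

    def test_fast_drop_is_high(self):
        res = _result([_seg(2002, 2003, 0.95, 0.05)])
        idx = disturbance_indices(res)
        assert idx.decrease_index == pytest.approx(0.9)
        assert idx.decrease_category == "high"

    def test_flat_segments_do_not_change_indices(self):
        base = [_seg(2002, 2004, 0.2, 0.8)]
        padded = base + [_seg(2004, 2010, 0.8, 0.8), _seg(2010, 2017, 0.8, 0.8)]
        assert disturbance_indices(_result(base)) == disturbance_indices(
            _result(padded)
        )

    def test_empty_segmentation_rejected(self):
        with pytest.raises(ValueError):
            disturbance_indices(_result([]))

    @pytest.mark.parametrize(
        "value,category",
        [(0.0, "very_low"), (0.19, "very_low"), (0.2, "low"), (0.39, "low"),
         (0.4, "intermediate"), (0.6, "intermediate"), (0.61, "high"), (1.0, "high")],
    )
    def test_category_bins(self, value, category):
        assert categorize_index(value) == category


# ------------------------------------------------------------- dynamics


def _classify(vals, **kw):
    vals = np.asarray(vals, dtype=float)
    res = segment_series(vals)
    return dynamics_class(vals, res, **kw)


class TestDynamicsClass:
    def test_constant_dense(self):
        assert _classify(np.full(16, 0.9)) == 1

    def test_constant_forest(self):
        assert _classify(np.full(16, 0.6)) == 2

    def test_constant_non_forest(self):
        assert _classify(np.full(16, 0.3)) == 3

    def test_monotone_gain_class4(self):
        assert _classify(np.linspace(0.3, 0.7, 16)) == 4

    def test_gain_with_drop_class5(self):
        vals = np.concatenate([np.linspace(0.2, 0.7, 8), [0.3], np.linspace(0.4, 0.8, 7)])
        assert _classify(vals) == 5

    def test_monotone_loss_class6(self):
        assert _classify(np.linspace(0.7, 0.3, 16)) == 6

    def test_loss_with_regrowth_class7(self):
        vals = np.concatenate([np.full(6, 0.8), [0.1], np.linspace(0.15, 0.45, 9)])
        assert _classify(vals) == 7

    def test_fluctuating_non_forest_class8(self):
        vals = np.concatenate([np.full(4, 0.3), np.full(6, 0.7), np.full(6, 0.2)])
        assert _classify(vals) == 8

    def test_fluctuating_forest_class9(self):
        vals = np.concatenate([np.full(4, 0.7), np.full(6, 0.3), np.full(6, 0.8)])
        assert _classify(vals) == 9

    def test_time_reversal_swaps_classes(self):
        rng = np.random.default_rng(5)
        swaps = {1: 1, 2: 2, 3: 3, 4: 6, 5: 7, 6: 4, 7: 5, 8: 8, 9: 9}
        for _ in range(60):
            vals = np.round(rng.random(16), 2)
            fwd = _classify(vals)
            rev = _classify(vals[::-1])
            assert rev == swaps[fwd]

    def test_time_reversal_swaps_indices(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            vals = np.round(rng.random(16), 2)
            fwd = disturbance_indices(segment_series(vals))
            rev = disturbance_indices(segment_series(vals[::-1]))
            assert fwd.increase_index == pytest.approx(rev.decrease_index)
            assert fwd.decrease_index == pytest.approx(rev.increase_index)


# ---------------------------------------------------------------- typing


def _idx(inc, dec):
    return DisturbanceIndices(
        inc, dec, categorize_index(inc), categorize_index(dec)
    )


class TestLanduseType:
    def test_dense_forest(self):
        assert landuse_type(_idx(0.05, 0.02), 1) == LANDUSE_NAMES["dense_forest"]

    def test_afforestation(self):
        assert landuse_type(_idx(0.8, 0.0), 4) == LANDUSE_NAMES["afforestation"]

    def test_rotation_l(self):
        assert landuse_type(_idx(0.1, 0.7), 7) == LANDUSE_NAMES["rotation_L"]

    def test_recovery(self):
        assert landuse_type(_idx(0.1, 0.0), 4) == LANDUSE_NAMES["recovery"]

    def test_deforestation(self):
        assert landuse_type(_idx(0.0, 0.3), 6) == LANDUSE_NAMES["deforestation"]

    def test_rotation_both_indices_high(self):
        assert landuse_type(_idx(0.5, 0.5), 8) == LANDUSE_NAMES["rotation"]

    def test_quiet_fluctuation_falls_back(self):
        assert landuse_type(_idx(0.1, 0.1), 8) == LANDUSE_NAMES["non_forest"]
        assert landuse_type(_idx(0.1, 0.1), 9) == LANDUSE_NAMES["forest"]

    def test_unknown_dynamics_rejected(self):
        with pytest.raises(ValueError):
            landuse_type(_idx(0.1, 0.1), 10)

    @given(
        inc=st.floats(0, 1, allow_nan=False),
        dec=st.floats(0, 1, allow_nan=False),
        dyn=st.integers(1, 9),
    )
    @settings(max_examples=300, deadline=None)
    def test_total_and_deterministic(self, inc, dec, dyn):
        a = landuse_type(_idx(inc, dec), dyn)
        b = landuse_type(_idx(inc, dec), dyn)
        assert a == b
        assert a in LANDUSE_CODES


# ----------------------------------------------------------------- scene


class TestClassifyScene:
    def test_constant_dense_scene(self):
        prob = np.full((16, 4, 5), 0.9)
        labels, summary = classify_scene(prob)
        assert np.all(labels == LANDUSE_NAMES["dense_forest"])
        assert summary["fractions"]["dense_forest"] == 1.0

    def test_fractions_partition_valid_pixels(self, archetype_scene):
        labels, summary = classify_scene(
            archetype_scene.probability, years=np.asarray(archetype_scene.years)
        )
        assert sum(summary["fractions"].values()) == pytest.approx(1.0)
        assert summary["n_valid"] + summary["n_masked"] == labels.size

    def test_masked_pixels_counted(self):
        prob = np.full((16, 2, 2), 0.6)
        prob[:4, 0, 0] = np.nan  # leading gap -> unrecoverable
        labels, summary = classify_scene(prob)
        assert labels[0, 0] == trajectory.MASKED_LABEL
        assert summary["n_masked"] == 1

    def test_short_stack_rejected(self):
        with pytest.raises(ValueError):
            classify_scene(np.full((3, 2, 2), 0.5))


class TestClassifySeriesPipeline:
    def test_gap_filled_series_classified(self):
        vals = np.full(16, 0.9)
        vals[5] = np.nan
        out = classify_series(vals)
        assert out["label"] == LANDUSE_NAMES["dense_forest"]

    def test_unrecoverable_series_masked(self):
        vals = np.full(16, 0.9)
        vals[5:9] = np.nan
        out = classify_series(vals)
        assert out["label"] == trajectory.MASKED_LABEL
        assert out["segmentation"] is None
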