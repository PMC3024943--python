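import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from arraycnv import (
    BafSegConfig, PlantedEvent, SimConfig,
    call_ai, estimate_mosaic_fraction, estimate_region_fraction, expected_mbaf,
    informative_filter, mirror_baf, segment_mbaf, segment_sample, simulate_sample,
)

EVENT_TYPES = ("mosaic_deletion", "mosaic_duplication", "cn_neutral_imbalance")


class TestMirrorBaf:
    @pytest.mark.parametrize("baf,expected", [(0.3, 0.7), (0.5, 0.5), (1.0, 1.0), (0.0, 1.0)])
    def test_folding(self, baf, expected):
        assert mirror_baf(baf) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mirror_baf(1.2)

    @given(st.floats(0, 1))
    @settings(derandomize=True)
    def test_range_and_symmetry(self, baf):
        m = mirror_baf(baf)
        assert 0.5 <= m <= 1.0
        assert m == pytest.approx(mirror_baf(1.0 - baf))


class TestInformativeFilter:
    def test_isolated_high_probe_removed(self):
        mbaf = np.array([0.55, 0.55, 0.99, 0.55, 0.55])
        keep = informative_filter(mbaf)
        assert list(keep) == [True, True, False, True, True]

    def test_dense_high_run_protected(self):
        mbaf = np.array([0.55, 0.99, 0.99, 0.99, 0.99, 0.99, 0.55])
        keep = informative_filter(mbaf)
        assert keep[1:6].all()

    def test_all_moderate_retained(self):
        mbaf = np.full(20, 0.55)
        assert informative_filter(mbaf).all()

    def test_nc_genotype_removed(self):
        mbaf = np.full(5, 0.55)
        genotype = np.array([1, 1, -1, 1, 1], dtype=np.int8)
        keep = informative_filter(mbaf, genotype)
        assert list(keep) == [True, True, False, True, True]

    def test_never_removes_below_threshold(self):
        """Filter safety: probes at or below the informative threshold survive."""
        rng = np.random.default_rng(0)
        mbaf = rng.uniform(0.5, 1.0, 500)
        keep = informative_filter(mbaf)
        below = mbaf <= BafSegConfig().informative_threshold
        assert keep[below].all()


class TestSegmentMbaf:
    def test_planted_change_point_located(self):
        rng = np.random.default_rng(42)
        y = np.concatenate([
            rng.normal(0.55, 0.02, 50), rng.normal(0.75, 0.02, 50)
        ])
        segments = segment_mbaf(y)
        assert len(segments) == 2
        assert abs(segments[0][1] + 1 - 50) <= 2  # boundary within +/- 2 probes

    def test_constant_series_single_segment(self):
        segments = segment_mbaf(np.full(100, 0.6))
        assert segments == [(0, 99, pytest.approx(0.6))]

    def test_segment_means_are_member_means(self):
        rng = np.random.default_rng(1)
        y = np.concatenate([rng.normal(0.55, 0.02, 40), rng.normal(0.9, 0.02, 40)])
        for i, j, mean in segment_mbaf(y):
            assert mean == pytest.approx(float(np.mean(y[i : j + 1])))

    def test_partition_is_contiguous_and_exhaustive(self):
        rng = np.random.default_rng(2)
        y = rng.uniform(0.5, 1.0, 200)
        segments = segment_mbaf(y)
        assert segments[0][0] == 0 and segments[-1][1] == len(y) - 1
        for (a, b, _), (c, d, _) in zip(segments, segments[1:]):
            assert c == b + 1

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            segment_mbaf(np.array([]))


class TestMosaicFraction:
    @pytest.mark.parametrize("mbaf,event,expected", [
        (0.5, "mosaic_deletion", 0.0),
        (0.5, "mosaic_duplication", 0.0),
        (0.5, "cn_neutral_imbalance", 0.0),
        (2 / 3, "mosaic_deletion", 0.5),
        (2 / 3, "mosaic_duplication", 1.0),
        (0.75, "cn_neutral_imbalance", 0.5),
    ])
    def test_dosage_algebra(self, mbaf, event, expected):
        p, _ = estimate_mosaic_fraction(mbaf, event)
        assert p == pytest.approx(expected)

    def test_duplication_at_mbaf_one_is_capped_and_flagged(self):
        p, at_bound = estimate_mosaic_fraction(1.0, "mosaic_duplication")
        assert p == 1.0 and at_bound

    def test_inverse_consistency_on_grid(self):
        for event in EVENT_TYPES:
            for p in np.arange(0.0, 0.9501, 0.05):
                est, _ = estimate_mosaic_fraction(expected_mbaf(p, event), event)
                assert abs(est - p) < 1e-9

    def test_monotone_in_mbaf(self):
        grid = np.linspace(0.5, 0.999, 200)
        for event in EVENT_TYPES:
            ests = [estimate_mosaic_fraction(m, event)[0] for m in grid]
            assert all(b >= a - 1e-12 for a, b in zip(ests, ests[1:]))

    def test_unknown_event_type_rejected(self):
        with pytest.raises(ValueError):
            estimate_mosaic_fraction(0.6, "weird")


class TestCallAi:
    def _call(self, mean, n, lrr_val=0.0):
        positions = np.arange(1, n + 1) * 1000
        lrr = np.full(n, lrr_val)
        return call_ai([(0, n - 1, mean)], positions, lrr, "1")

    def test_threshold_and_size_gating(self):
        assert len(self._call(0.60, 6)) == 1
        assert len(self._call(0.54, 6)) == 0   # below ai_threshold 0.56
        assert len(self._call(0.70, 3)) == 0   # below ai_size 4

    @pytest.mark.parametrize("lrr_val,expected", [
        (-0.3, "mosaic_deletion"), (0.2, "mosaic_duplication"), (0.0, "cn_neutral_imbalance"),
    ])
    def test_event_typing_from_lrr(self, lrr_val, expected):
        (seg,) = self._call(0.6, 6, lrr_val)
        assert seg.event_type == expected

    def test_fraction_consistent_with_type(self):
        (seg,) = self._call(2 / 3, 10, -0.3)
        assert seg.mosaic_fraction == pytest.approx(0.5)


class TestRecovery:
    @pytest.mark.parametrize("p", [0.3, 0.6])
    def test_planted_mosaic_deletion_quantified(self, p):
        config = SimConfig(
            chromosomes=(("1", 2000),),
            events=(PlantedEvent("mosaic_del", "1", 5_000_000, 14_000_000, cell_fraction=p),),
            seed=10,
        )
        sample, truth = simulate_sample(config)
        ev = truth.events[0]
        frac, n = estimate_region_fraction(sample, "1", ev.start, ev.end, "mosaic_deletion")
        assert n > 100
        assert frac == pytest.approx(p, abs=0.05)

    def test_full_pipeline_calls_event_with_type(self):
        config = SimConfig(
            chromosomes=(("1", 2000),),
            events=(PlantedEvent("mosaic_del", "1", 5_000_000, 14_000_000, cell_fraction=0.5),),
            seed=11,
        )
        sample, truth = simulate_sample(config)
        segments = segment_sample(sample, ["1"])
        hits = [s for s in segments if s.event_type == "mosaic_deletion"
                and s.start <= truth.events[0].end and truth.events[0].start <= s.end]
        assert len(hits) == 1
        assert hits[0].mosaic_fraction == pytest.approx(0.5, abs=0.05)

    def test_normal_chromosome_yields_no_calls(self):
        sample, _ = simulate_sample(SimConfig(chromosomes=(("1", 2000),), seed=12))
        assert segment_sample(sample, ["1"]) == []
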