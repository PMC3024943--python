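import numpy as np
import pytest

from arraycnv import (
    AB, NC,
    CallerProfile, PlantedEvent, SimConfig, TrioState,
    classify_all, expected_mbaf, make_genome_map, mirror_baf,
    simulate_callsets, simulate_sample, simulate_trio, vote_consensus, VoteConfig,
)
from arraycnv.trio import _STATE_CODES


class TestDeterminism:
    def test_same_seed_identical(self):
        cfg = SimConfig(seed=9, events=(PlantedEvent("del", "1", 1_000_000, 2_000_000),))
        s1, t1 = simulate_sample(cfg)
        s2, t2 = simulate_sample(cfg)
        np.testing.assert_array_equal(s1.genotype, s2.genotype)
        np.testing.assert_array_equal(s1.baf, s2.baf)
        np.testing.assert_array_equal(s1.lrr, s2.lrr)
        assert t1.events == t2.events

    def test_different_seed_differs(self):
        s1, _ = simulate_sample(SimConfig(seed=1))
        s2, _ = simulate_sample(SimConfig(seed=2))
        assert not np.array_equal(s1.baf, s2.baf)


class TestDosageModel:
    def test_noiseless_heterozygotes_at_half(self):
        cfg = SimConfig(chromosomes=(("1", 2000),), baf_sigma=0.0, lrr_sigma=0.0,
                        nocall_rate=0.0, seed=3)
        sample, _ = simulate_sample(cfg)
        het = sample.genotype == AB
        assert het.sum() > 100
        np.testing.assert_allclose(sample.baf[het], 0.5)
        np.testing.assert_allclose(sample.lrr, 0.0)

    def test_full_deletion_lrr_is_log2_half(self):
        cfg = SimConfig(chromosomes=(("1", 500),), lrr_sigma=0.0, seed=4,
                        events=(PlantedEvent("del", "1", 1_000_000, 2_000_000),))
        sample, truth = simulate_sample(cfg)
        ev = truth.events[0]
        inside = sample.lrr[ev.first_probe : ev.last_probe + 1]
        np.testing.assert_allclose(inside, np.log2(0.5))

    def test_mosaic_deletion_het_mbaf_matches_formula(self):
        p = 0.5
        cfg = SimConfig(chromosomes=(("1", 2000),), baf_sigma=0.0, nocall_rate=0.0, seed=5,
                        events=(PlantedEvent("mosaic_del", "1", 1_000_000, 18_000_000,
                                             cell_fraction=p),))
        sample, truth = simulate_sample(cfg)
        ev = truth.events[0]
        sl = slice(ev.first_probe, ev.last_probe + 1)
        het = sample.genotype[sl] == AB
        mbaf = mirror_baf(sample.baf[sl][het])
        np.testing.assert_allclose(mbaf, expected_mbaf(p, "mosaic_deletion"), atol=1e-12)

    def test_signal_means_match_dosage_formulas_within_3se(self):
        cfg = SimConfig(chromosomes=(("1", 10_000),), seed=6, nocall_rate=0.0)
        sample, _ = simulate_sample(cfg)
        n = len(sample.lrr)
        se = cfg.lrr_sigma / np.sqrt(n)
        assert abs(float(np.mean(sample.lrr))) < 3 * se
        het = sample.genotype == AB
        se_baf = cfg.baf_sigma / np.sqrt(het.sum())
        assert abs(float(np.mean(sample.baf[het])) - 0.5) < 3 * se_baf

    def test_truth_spans_align_to_probes(self):
        cfg = SimConfig(seed=7, events=(PlantedEvent("dup", "2", 1_234_567, 7_654_321),))
        sample, truth = simulate_sample(cfg)
        gm = sample.genome_map
        ev = truth.events[0]
        assert gm.positions[ev.first_probe] == ev.start
        assert gm.positions[ev.last_probe] == ev.end
        assert ev.start >= 1_234_567 and ev.end <= 7_654_321

    def test_overlapping_events_rejected(self):
        cfg = SimConfig(seed=8, events=(
            PlantedEvent("del", "1", 1_000_000, 2_000_000),
            PlantedEvent("dup", "1", 1_500_000, 3_000_000),
        ))
        with pytest.raises(ValueError, match="overlap"):
            simulate_sample(cfg)

    def test_nocall_rate_planted(self):
        cfg = SimConfig(chromosomes=(("1", 20_000),), seed=9)
        sample, _ = simulate_sample(cfg)
        rate = float(np.mean(sample.genotype == NC))
        assert rate == pytest.approx(0.005, abs=0.002)


class TestTrioGeneration:
    def test_clean_trio_has_zero_mendelian_inconsistencies(self):
        trio, _ = simulate_trio(SimConfig(seed=1, nocall_rate=0.0))
        states = classify_all(trio)
        bad = {_STATE_CODES[s] for s in TrioState} - {
            _STATE_CODES[TrioState.CONSISTENT], _STATE_CODES[TrioState.UNINFORMATIVE_NC]
        }
        assert not np.isin(states, list(bad)).any()

    def test_upd_iso_region_is_homozygous_with_exclusion_states(self):
        cfg = SimConfig(seed=2, nocall_rate=0.0, events=(
            PlantedEvent("upd_iso", "1", 5_000_000, 10_000_000, parent="paternal"),))
        trio, truth = simulate_trio(cfg)
        ev = truth.events[0]
        sl = slice(ev.first_probe, ev.last_probe + 1)
        child = trio.child.genotype[sl]
        assert not (child == AB).any()
        states = classify_all(trio)[sl]
        pat_codes = [_STATE_CODES[TrioState.P_UPD_OR_MAT_DEL], _STATE_CODES[TrioState.P_ISO_ONLY]]
        assert np.isin(states, pat_codes).sum() >= 10

    def test_nonpaternity_inflates_exclusion_rate(self):
        trio, _ = simulate_trio(SimConfig(seed=3, nocall_rate=0.0), nonpaternity=True)
        states = classify_all(trio)
        excl = [_STATE_CODES[TrioState.M_UPD_OR_PAT_DEL], _STATE_CODES[TrioState.M_ISO_ONLY],
                _STATE_CODES[TrioState.DOUBLE_INCONSISTENT]]
        called = states != _STATE_CODES[TrioState.UNINFORMATIVE_NC]
        rate = np.isin(states, excl).sum() / called.sum()
        assert rate > 0.02 * 5  # far above the non-paternity screening threshold


class TestSimulatedCallsets:
    def _truth(self, seed=4):
        cfg = SimConfig(seed=seed, events=(
            PlantedEvent("del", "1", 5_000_000, 5_500_000),
            PlantedEvent("dup", "2", 8_000_000, 9_000_000),
        ))
        return simulate_sample(cfg)

    def test_perfect_callers_recover_truth_exactly(self):
        sample, truth = self._truth()
        profiles = [CallerProfile(m) for m in ("Q", "P", "V")]
        callsets = simulate_callsets(truth, sample.genome_map, profiles, seed=1)
        regions = vote_consensus(callsets, sample.genome_map)
        got = [(r.chromosome, r.start, r.end, r.direction) for r in regions]
        expected = [(e.chromosome, e.start, e.end, "loss" if "del" in e.kind else "gain")
                    for e in truth.events]
        assert got == expected

    def test_single_sensitive_method_yields_no_consensus(self):
        sample, truth = self._truth()
        profiles = [CallerProfile("Q", sensitivity=1.0),
                    CallerProfile("P", sensitivity=0.0),
                    CallerProfile("V", sensitivity=0.0)]
        callsets = simulate_callsets(truth, sample.genome_map, profiles, seed=2)
        assert vote_consensus(callsets, sample.genome_map) == []

    def test_trusted_dup_mode_recovers_lone_gain(self):
        sample, truth = self._truth()
        profiles = [CallerProfile("Q", sensitivity=0.0),
                    CallerProfile("P", sensitivity=1.0),
                    CallerProfile("V", sensitivity=0.0)]
        callsets = simulate_callsets(truth, sample.genome_map, profiles, seed=3)
        regions = vote_consensus(callsets, sample.genome_map,
                                 VoteConfig(trusted_dup_method="P"))
        gains = [r for r in regions if r.direction == "gain"]
        assert len(gains) == 1 and gains[0].vote_mode == "trusted_dup"
        # the lone deletion stays discarded even in trusted mode
        assert all(r.direction != "loss" for r in regions)

    def test_jitter_stays_within_bounds(self):
        sample, truth = self._truth()
        profiles = [CallerProfile("Q", boundary_jitter_probes=2)]
        (cs,) = simulate_callsets(truth, sample.genome_map, profiles, seed=4)
        for call, ev in zip(cs.calls, truth.events):
            assert abs(call.start - ev.start) <= 2 * 10_000
            assert abs(call.end - ev.end) <= 2 * 10_000
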