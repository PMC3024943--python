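import numpy as np
import pytest

from arraycnv import VoteConfig, vote_consensus
from arraycnv.consensus import consensus_directions, probe_vote_table
from conftest import make_call, make_callset, random_callset_triple


def oracle_regions(callsets, gm, config):
    """Per-probe reference route: vote table -> directions -> run extraction."""
    votes = consensus_directions(probe_vote_table(callsets, gm), config)
    regions = []
    i, n = 0, len(gm)
    while i < n:
        d = votes[i]
        if d is None:
            i += 1
            continue
        j = i
        while j + 1 < n and votes[j + 1] == d and gm.chroms[j + 1] == gm.chroms[i]:
            j += 1
        if j - i + 1 >= config.min_probes:
            regions.append(
                (str(gm.chroms[i]), int(gm.positions[i]), int(gm.positions[j]), d, j - i + 1)
            )
        i = j + 1
    return regions


def region_tuples(regions):
    return [(r.chromosome, r.start, r.end, r.direction, r.n_probes) for r in regions]


class TestVoteTable:
    def test_conflicting_methods_vote_for_neither(self, small_map):
        cs = [
            make_callset("A", [make_call("A", "1", 100, 500, cn=1)]),
            make_callset("B", [make_call("B", "1", 100, 500, cn=3)]),
        ]
        table = probe_vote_table(cs, small_map)
        assert table[0] == {"A": "loss", "B": "gain"}
        assert consensus_directions(table, VoteConfig())[0] is None

    def test_uncovered_probe_has_empty_row(self, small_map):
        cs = [make_callset("A", [make_call("A", "1", 100, 200)])]
        table = probe_vote_table(cs, small_map)
        assert table[5] == {}

    def test_three_way_agreement(self, small_map):
        cs = [make_callset(m, [make_call(m, "1", 100, 400, cn=1)]) for m in "ABC"]
        votes = consensus_directions(probe_vote_table(cs, small_map), VoteConfig())
        assert votes[0] == "loss" and votes[3] == "loss" and votes[4] is None


class TestVoteConsensus:
    def test_single_caller_discarded(self, small_map):
        cs = [
            make_callset("A", [make_call("A", "1", 100, 1000, cn=1)]),
            make_callset("B", []),
            make_callset("C", []),
        ]
        assert vote_consensus(cs, small_map) == []

    def test_conservative_overlap_delineation(self, small_map):
        # probes at 100..1000; A loss [100,500], B loss [300,800] -> 300-500
        cs = [
            make_callset("A", [make_call("A", "1", 100, 500, cn=1)]),
            make_callset("B", [make_call("B", "1", 300, 800, cn=1)]),
            make_callset("C", []),
        ]
        regions = vote_consensus(cs, small_map)
        assert region_tuples(regions) == [("1", 300, 500, "loss", 3)]
        assert regions[0].supporting_methods == {"A", "B"}
        assert regions[0].vote_mode == "majority"

    def test_three_probe_floor(self, small_map):
        cs = [
            make_callset("A", [make_call("A", "1", 100, 300, cn=1)]),
            make_callset("B", [make_call("B", "1", 200, 300, cn=1)]),
        ]
        assert vote_consensus(cs, small_map) == []  # 2-probe overlap < 3

    def test_trusted_duplication_stands_alone(self, small_map):
        cs = [
            make_callset("A", []),
            make_callset("B", [make_call("B", "1", 100, 500, cn=3)]),
            make_callset("C", []),
        ]
        config = VoteConfig(trusted_dup_method="B")
        regions = vote_consensus(cs, small_map, config)
        assert region_tuples(regions) == [("1", 100, 500, "gain", 5)]
        assert regions[0].vote_mode == "trusted_dup"
        # without the asymmetric option it is discarded
        assert vote_consensus(cs, small_map) == []

    def test_trusted_dup_upgraded_when_seconded(self, small_map):
        cs = [
            make_callset("A", [make_call("A", "1", 100, 500, cn=3)]),
            make_callset("B", [make_call("B", "1", 100, 500, cn=3)]),
        ]
        regions = vote_consensus(cs, small_map, VoteConfig(trusted_dup_method="B"))
        assert regions[0].vote_mode == "majority"

    def test_empty_callsets(self, small_map):
        assert vote_consensus([make_callset("A", [])], small_map) == []

    def test_mixed_samples_rejected(self, small_map):
        cs = [make_callset("A", [], sample="s1"), make_callset("B", [], sample="s2")]
        with pytest.raises(ValueError, match="different samples"):
            vote_consensus(cs, small_map)

    def test_modal_copy_number_tie_toward_two(self, small_map):
        # cn 1 and cn 0 cover the same probes equally: tie resolved to 1
        cs = [
            make_callset("A", [make_call("A", "1", 100, 500, cn=0)]),
            make_callset("B", [make_call("B", "1", 100, 500, cn=1)]),
        ]
        regions = vote_consensus(cs, small_map)
        assert regions[0].copy_number == 1


class TestConsensusProperties:
    def test_interval_implementation_equals_probe_oracle(self, two_chrom_map):
        rng = np.random.default_rng(42)
        for trial in range(300):
            cs = random_callset_triple(rng, two_chrom_map)
            config = VoteConfig(trusted_dup_method="B" if trial % 3 == 0 else None)
            got = region_tuples(vote_consensus(cs, two_chrom_map, config))
            assert got == oracle_regions(cs, two_chrom_map, config)

    def test_permutation_invariance(self, two_chrom_map):
        rng = np.random.default_rng(1)
        cs = random_callset_triple(rng, two_chrom_map)
        base = region_tuples(vote_consensus(cs, two_chrom_map))
        assert region_tuples(vote_consensus(cs[::-1], two_chrom_map)) == base

    def test_adding_call_never_removes_same_direction_probe(self, two_chrom_map):
        rng = np.random.default_rng(2)
        config = VoteConfig(min_probes=1)
        for _ in range(50):
            cs = random_callset_triple(rng, two_chrom_map)
            before = consensus_directions(probe_vote_table(cs, two_chrom_map), config)
            extra = make_call("A", "1", 1000, 5000, cn=1)
            cs2 = [make_callset("A", list(cs[0].calls) + [extra]), cs[1], cs[2]]
            after = consensus_directions(probe_vote_table(cs2, two_chrom_map), config)
            for b, a in zip(before, after):
                if b == "loss":
                    assert a == "loss"

    def test_containment_in_input_union(self, two_chrom_map):
        rng = np.random.default_rng(3)
        for _ in range(50):
            cs = random_callset_triple(rng, two_chrom_map)
            table = probe_vote_table(cs, two_chrom_map)
            for region in vote_consensus(cs, two_chrom_map):
                i0, i1 = two_chrom_map.index_range(region.chromosome, region.start, region.end)
                for i in range(i0, i1):
                    same_dir = [m for m, d in table[i].items() if d == region.direction]
                    assert len(same_dir) >= 2

    def test_raising_min_probes_only_removes_regions(self, two_chrom_map):
        rng = np.random.default_rng(4)
        for _ in range(50):
            cs = random_callset_triple(rng, two_chrom_map)
            loose = region_tuples(vote_consensus(cs, two_chrom_map, VoteConfig(min_probes=3)))
            strict = region_tuples(vote_consensus(cs, two_chrom_map, VoteConfig(min_probes=6)))
            assert set(strict) <= set(loose)
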