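from itertools import product

import numpy as np
import pytest

from arraycnv import (
    ConsensusRegion, PlantedEvent, SimConfig, TrioConfig, TrioState,
    annotate_inheritance, classification_table, classify_snp,
    detect_nonpaternity, detect_upd, parent_of_origin, reciprocal_overlap,
    simulate_trio,
)
from trio_oracle import oracle_state

GTS = ("AA", "AB", "BB")
SWAP = {
    "CONSISTENT": "CONSISTENT",
    "DOUBLE_INCONSISTENT": "DOUBLE_INCONSISTENT",
    "P_UPD_OR_MAT_DEL": "M_UPD_OR_PAT_DEL",
    "M_UPD_OR_PAT_DEL": "P_UPD_OR_MAT_DEL",
    "P_ISO_ONLY": "M_ISO_ONLY",
    "M_ISO_ONLY": "P_ISO_ONLY",
}

NP_CHROMS = tuple((str(i + 1), 150) for i in range(22))


class TestClassifySnp:
    @pytest.mark.parametrize("triple,expected", [
        (("AA", "BB", "AB"), TrioState.CONSISTENT),
        (("AA", "BB", "AA"), TrioState.P_UPD_OR_MAT_DEL),
        (("AB", "AA", "BB"), TrioState.P_ISO_ONLY),
        (("AA", "AA", "BB"), TrioState.DOUBLE_INCONSISTENT),
        (("NC", "AB", "AA"), TrioState.UNINFORMATIVE_NC),
    ])
    def test_reference_triples(self, triple, expected):
        assert classify_snp(*triple) is expected

    def test_matches_brute_force_enumerator_on_all_27_triples(self):
        for f, m, c in product(GTS, repeat=3):
            assert classify_snp(f, m, c).value == oracle_state(f, m, c), (f, m, c)

    def test_parent_swap_symmetry(self):
        for f, m, c in product(GTS, repeat=3):
            assert classify_snp(m, f, c).value == SWAP[classify_snp(f, m, c).value]

    def test_invalid_token_rejected(self):
        with pytest.raises(ValueError):
            classify_snp("AA", "ZZ", "AB")


class TestClassificationTable:
    def test_27_rows_each_with_state(self):
        table = classification_table()
        assert len(table) == 27
        assert all(row["state"] for row in table)

    def test_consistent_count_matches_oracle(self):
        table = classification_table()
        got = sum(row["state"] == "CONSISTENT" for row in table)
        expected = sum(
            oracle_state(f, m, c) == "CONSISTENT" for f, m, c in product(GTS, repeat=3)
        )
        assert got == expected


class TestDetectUpd:
    def _trio(self, kind, parent, seed):
        config = SimConfig(
            chromosomes=(("1", 3000), ("2", 3000)), seed=seed,
            events=(PlantedEvent(kind, "1", 10_000_000, 15_000_000, parent=parent),),
        )
        return simulate_trio(config)

    def test_paternal_isodisomy_detected(self):
        trio, truth = self._trio("upd_iso", "paternal", seed=3)
        (event,) = detect_upd(trio)
        assert event.parent == "paternal" and event.subtype == "isodisomy"
        assert event.chromosome == "1"
        assert truth.events[0].start <= event.start <= event.end <= truth.events[0].end
        assert event.p_value < 1e-6

    def test_maternal_heterodisomy_detected(self):
        trio, _ = self._trio("upd_het", "maternal", seed=4)
        (event,) = detect_upd(trio)
        assert event.parent == "maternal" and event.subtype == "heterodisomy"

    def test_normal_trios_produce_no_events(self):
        for seed in range(10):
            trio, _ = simulate_trio(SimConfig(chromosomes=(("1", 3000), ("2", 3000)), seed=seed))
            assert detect_upd(trio) == []

    def test_deletion_region_not_reported_as_upd(self):
        config = SimConfig(
            chromosomes=(("1", 3000), ("2", 3000)), seed=5,
            events=(PlantedEvent("del", "1", 10_000_000, 15_000_000, parent="maternal"),),
        )
        trio, truth = simulate_trio(config)
        ev = truth.events[0]
        region = ConsensusRegion("1", ev.start, ev.end, "loss", 1,
                                 frozenset({"A", "B"}), "majority", 500)
        # a hemizygous region mimics UPD states; the consensus overlap excludes it
        assert detect_upd(trio, consensus_regions=[region]) == []
        # ... and the LRR guard alone also rejects it
        assert detect_upd(trio) == []


class TestNonPaternity:
    def test_unrelated_father_flagged(self):
        trio, _ = simulate_trio(SimConfig(chromosomes=NP_CHROMS, seed=1), nonpaternity=True)
        flag, table = detect_nonpaternity(trio)
        assert flag
        assert sum(row["exceeds"] for row in table.values()) >= 20

    def test_true_trio_with_genotype_error_not_flagged(self):
        trio, _ = simulate_trio(
            SimConfig(chromosomes=NP_CHROMS, seed=2, genotype_error_rate=0.002)
        )
        flag, _ = detect_nonpaternity(trio)
        assert not flag

    def test_single_upd_chromosome_not_flagged(self):
        config = SimConfig(
            chromosomes=NP_CHROMS, seed=3,
            events=(PlantedEvent("upd_het", "5", 10_000, 1_500_000, parent="maternal"),),
        )
        trio, _ = simulate_trio(config)
        flag, table = detect_nonpaternity(trio)
        assert not flag  # localised signal fails the min-chromosome rule


def region(chrom, start, end, direction="loss", cn=1):
    return ConsensusRegion(chrom, start, end, direction, cn, frozenset({"A", "B"}),
                           "majority", 10)


class TestAnnotateInheritance:
    def test_identity_overlap_is_inherited(self):
        child = [region("1", 100, 200)]
        tagged = annotate_inheritance(child, [region("1", 100, 200)], [])
        assert tagged[0][1] == "paternal"

    def test_low_reciprocal_overlap_is_de_novo(self):
        child = [region("1", 100, 200)]
        # overlap 21 bp: 21/101 = 0.21 of child, 21/221 = 0.095 of parent
        tagged = annotate_inheritance(child, [region("1", 180, 400)], [])
        assert tagged[0][1] == "de_novo"

    def test_direction_mismatch_is_de_novo(self):
        child = [region("1", 100, 200, "loss")]
        tagged = annotate_inheritance(child, [], [region("1", 100, 200, "gain", cn=3)])
        assert tagged[0][1] == "de_novo"

    def test_both_parents(self):
        child = [region("1", 100, 200)]
        tagged = annotate_inheritance(child, [region("1", 100, 200)], [region("1", 100, 200)])
        assert tagged[0][1] == "both"

    def test_symmetric_in_parents(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            a, b = sorted(rng.integers(1, 10_000, 2))
            c, d = sorted(rng.integers(1, 10_000, 2))
            child = [region("1", int(a), int(b) + 1)]
            parental = [region("1", int(c), int(d) + 1)]
            t1 = annotate_inheritance(child, parental, [])[0][1]
            t2 = annotate_inheritance(child, [], parental)[0][1]
            assert (t1 == "paternal") == (t2 == "maternal")

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            a, b = sorted(rng.integers(1, 10_000, 2))
            c, d = sorted(rng.integers(1, 10_000, 2))
            child = [region("1", int(a), int(b) + 1)]
            parental = [region("1", int(c), int(d) + 1)]
            loose = annotate_inheritance(child, parental, [],
                                         TrioConfig(inheritance_reciprocal_overlap=0.3))[0][1]
            strict = annotate_inheritance(child, parental, [],
                                          TrioConfig(inheritance_reciprocal_overlap=0.8))[0][1]
            if loose == "de_novo":
                assert strict == "de_novo"

    def test_reciprocal_overlap_arithmetic(self):
        assert reciprocal_overlap(100, 200, 180, 400) == pytest.approx(21 / 221)
        assert reciprocal_overlap(1, 10, 20, 30) == 0.0


class TestParentOfOrigin:
    def _denovo(self, kind, parent, seed, **kw):
        config = SimConfig(
            chromosomes=(("1", 500),), seed=seed, nocall_rate=0,
            events=(PlantedEvent(kind, "1", 1_000_000, 2_000_000, parent=parent),), **kw,
        )
        trio, truth = simulate_trio(config)
        ev = truth.events[0]
        direction = "loss" if kind == "del" else "gain"
        cn = 1 if kind == "del" else 3
        return trio, ConsensusRegion("1", ev.start, ev.end, direction, cn,
                                     frozenset({"A", "B"}), "majority", 100)

    @pytest.mark.parametrize("kind", ["del", "dup"])
    @pytest.mark.parametrize("parent", ["paternal", "maternal"])
    def test_clean_events_resolved_correctly(self, kind, parent):
        trio, reg = self._denovo(kind, parent, seed=7)
        origin, n = parent_of_origin(trio, reg)
        assert origin == parent
        assert n >= 2

    def test_single_informative_snp_is_undetermined(self):
        trio, reg = self._denovo("del", "maternal", seed=8)
        narrow = ConsensusRegion("1", reg.start, reg.start, "loss", 1,
                                 frozenset({"A", "B"}), "majority", 1)
        origin, n = parent_of_origin(trio, narrow,
                                     TrioConfig(poo_min_informative=2))
        assert origin == "undetermined"

    def test_region_without_probes_undetermined(self):
        trio, _ = self._denovo("del", "maternal", seed=9)
        empty = ConsensusRegion("2", 1, 2, "loss", 1, frozenset(), "majority", 1)
        with pytest.raises(KeyError):
            parent_of_origin(trio, empty)

    def test_noisy_trios_never_pick_wrong_parent(self):
        wrong = 0
        for seed in range(60):
            trio, reg = self._denovo("del", "maternal", seed=seed,
                                     genotype_error_rate=0.01)
            origin, _ = parent_of_origin(trio, reg)
            wrong += origin == "paternal"
        assert wrong == 0
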