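"""Majority-vote consensus CNV calling across caller callsets.

The vote is defined per probe: each method assigns a direction (loss/gain)
to every map probe its filtered calls cover. A probe is a consensus probe
for a direction when at least ``min_methods`` methods assign that direction
— unless both directions are present at the probe across methods, in which
case the probe is in conflict and counts for neither. With a trusted
duplication method configured, a probe the trusted method calls as gain is
a consensus gain probe on its own (asymmetric vote).

Consensus regions are maximal runs of map-consecutive consensus probes of
one direction, kept when the run holds at least ``min_probes`` probes, and
delineated conservatively by the first and last probe positions of the run.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .datamodel import CallSet
from .genome import GenomeMap


@dataclass(frozen=True)
class VoteConfig:
    min_methods: int = 2
    min_probes: int = 3
    trusted_dup_method: str | None = None

    def __post_init__(self) -> None:
        if self.min_methods < 1:
            raise ValueError("min_methods must be >= 1")
        if self.min_probes < 1:
            raise ValueError("min_probes must be >= 1")


@dataclass(frozen=True)
class ConsensusRegion:
    chromosome: str
    start: int  # position of the first supporting probe
    end: int    # position of the last supporting probe
    direction: str  # 'loss' or 'gain'
    copy_number: int
    supporting_methods: frozenset[str]
    vote_mode: str  # 'majority' or 'trusted_dup'
    n_probes: int

    def as_row(self, sample_id: str = "") -> dict:
        return {
            "sample": sample_id,
            "chrom": self.chromosome,
            "start": self.start,
            "end": self.end,
            "direction": self.direction,
            "copy_number": self.copy_number,
            "n_probes": self.n_probes,
            "methods": ",".join(sorted(self.supporting_methods)),
            "vote_mode": self.vote_mode,
        }


def probe_vote_table(
    callsets: list[CallSet], genome_map: GenomeMap
) -> list[dict[str, str]]:
    """Per-probe tabulation of each method's direction assignment.

    Returns one dict per map probe mapping method name to 'loss', 'gain' or
    'conflict' (the method itself covers the probe in both directions).
    Probes covered by no call get an empty dict. This is the explicit,
    deliberately simple oracle surface for :func:`vote_consensus`.
    """
    _check_single_sample(callsets)
    table: list[dict[str, str]] = [dict() for _ in range(len(genome_map))]
    for cs in callsets:
        for call in cs:
            i0, i1 = genome_map.index_range(call.chromosome, call.start, call.end)
            for i in range(i0, i1):
                prev = table[i].get(cs.method)
                if prev is None:
                    table[i][cs.method] = call.direction
                elif prev != call.direction:
                    table[i][cs.method] = "conflict"
    return table


def consensus_directions(
    table: list[dict[str, str]], config: VoteConfig
) -> list[str | None]:
    """Resolve the vote table into a per-probe consensus direction (or None)."""
    out: list[str | None] = []
    for row in table:
        dirs = set(row.values())
        if "conflict" in dirs or ("loss" in dirs and "gain" in dirs):
            out.append(None)  # conflicting evidence vetoes the probe
            continue
        counts = Counter(row.values())
        direction: str | None = None
        for d in ("loss", "gain"):
            if counts.get(d, 0) >= config.min_methods:
                direction = d
        if (
            direction is None
            and config.trusted_dup_method is not None
            and row.get(config.trusted_dup_method) == "gain"
        ):
            direction = "gain"
        out.append(direction)
    return out


def vote_consensus(
    callsets: list[CallSet], genome_map: GenomeMap, config: VoteConfig = VoteConfig()
) -> list[ConsensusRegion]:
    """Run the majority vote and return consensus regions in genome order.

    All callsets must belong to one sample. The region's copy number is the
    modal copy number among supporting calls over the run's probes; ties are
    broken toward the value closest to 2, then toward the smaller value.
    Regions supported by at least ``min_methods`` methods carry vote_mode
    'majority'; gain regions carried by the trusted method alone are
    'trusted_dup'.

    The implementation is interval arithmetic in probe-index space (coverage
    difference arrays per method and direction); the per-probe
    :func:`probe_vote_table` route exists as an independent cross-check.
    """
    _check_single_sample(callsets)
    n = len(genome_map)
    if n == 0:
        return []

    loss_count = np.zeros(n, dtype=np.int32)
    gain_count = np.zeros(n, dtype=np.int32)
    trusted_gain = np.zeros(n, dtype=bool)
    for cs in callsets:
        cover = {"loss": np.zeros(n + 1, dtype=np.int32),
                 "gain": np.zeros(n + 1, dtype=np.int32)}
        for call in cs:
            i0, i1 = genome_map.index_range(call.chromosome, call.start, call.end)
            cover[call.direction][i0] += 1
            cover[call.direction][i1] -= 1
        loss_here = np.cumsum(cover["loss"][:-1]) > 0
        gain_here = np.cumsum(cover["gain"][:-1]) > 0
        loss_count += loss_here
        gain_count += gain_here
        if cs.method == config.trusted_dup_method:
            trusted_gain |= gain_here

    conflict = (loss_count > 0) & (gain_count > 0)
    is_loss = ~conflict & (loss_count >= config.min_methods)
    is_gain = ~conflict & ((gain_count >= config.min_methods) | trusted_gain)

    # encode per-probe vote as 0 none / 1 loss / 2 gain and extract runs,
    # breaking at chromosome boundaries
    code = np.where(is_loss, 1, np.where(is_gain, 2, 0))
    chrom_id = np.zeros(n, dtype=np.int32)
    for k, chrom in enumerate(genome_map.chromosomes):
        chrom_id[genome_map.chrom_slice(chrom)] = k
    breaks = np.flatnonzero((np.diff(code) != 0) | (np.diff(chrom_id) != 0)) + 1
    starts = np.concatenate(([0], breaks))
    ends = np.concatenate((breaks, [n]))  # half-open index runs

    regions: list[ConsensusRegion] = []
    for i, j1 in zip(starts, ends):
        j = int(j1) - 1
        if code[i] == 0 or j - i + 1 < config.min_probes:
            continue
        direction = "loss" if code[i] == 1 else "gain"
        regions.append(_build_region(callsets, genome_map, config, int(i), j, direction))
    return regions


def _build_region(
    callsets: list[CallSet],
    genome_map: GenomeMap,
    config: VoteConfig,
    i: int,
    j: int,
    direction: str,
) -> ConsensusRegion:
    chrom = str(genome_map.chroms[i])
    start = int(genome_map.positions[i])
    end = int(genome_map.positions[j])
    methods: set[str] = set()
    cn_votes: Counter[int] = Counter()
    for cs in callsets:
        for call in cs:
            if call.chromosome != chrom or call.direction != direction:
                continue
            c0, c1 = genome_map.index_range(call.chromosome, call.start, call.end)
            overlap = min(c1 - 1, j) - max(c0, i) + 1
            if overlap > 0:
                methods.add(cs.method)
                cn_votes[call.copy_number] += overlap
    # modal cn; ties toward the value closest to 2, then the smaller one
    best = max(cn_votes)
    best_key = None
    for cn, cnt in cn_votes.items():
        key = (cnt, -abs(cn - 2), -cn)
        if best_key is None or key > best_key:
            best_key = key
            best = cn
    vote_mode = "majority" if len(methods) >= config.min_methods else "trusted_dup"
    return ConsensusRegion(
        chromosome=chrom,
        start=start,
        end=end,
        direction=direction,
        copy_number=best,
        supporting_methods=frozenset(methods),
        vote_mode=vote_mode,
        n_probes=j - i + 1,
    )


def _check_single_sample(callsets: list[CallSet]) -> None:
    if not callsets:
        raise ValueError("at least one callset required")
    ids = {cs.sample_id for cs in callsets}
    if len(ids) > 1:
        raise ValueError(f"callsets belong to different samples: {sorted(ids)}")


def write_consensus_tsv(
    regions: list[ConsensusRegion], path_or_stream, sample_id: str = ""
) -> int:
    """Write consensus regions as the standard output TSV; returns row count."""
    own = not hasattr(path_or_stream, "write")
    fh = open(path_or_stream, "wt") if own else path_or_stream
    try:
        cols = ["sample", "chrom", "start", "end", "direction",
                "copy_number", "n_probes", "methods", "vote_mode"]
        fh.write("\t".join(cols) + "\n")
        for r in regions:
            row = r.as_row(sample_id)
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
        return len(regions)
    finally:
        if own:
            fh.close()
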