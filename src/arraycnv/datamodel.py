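"""Core in-memory containers: per-sample probe data and caller CNV callsets.

Genotypes are biallelic A/B calls encoded as small integers so that whole
samples live in flat numpy arrays aligned to the :class:`~arraycnv.genome.GenomeMap`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .genome import GenomeMap, normalize_chrom

# genotype codes
NC: int = -1
AA: int = 0
AB: int = 1
BB: int = 2

GENOTYPE_NAMES = {NC: "NC", AA: "AA", AB: "AB", BB: "BB"}
GENOTYPE_CODES = {v: k for k, v in GENOTYPE_NAMES.items()}

#: sentinel confidence for calls imported without a confidence column
UNFILTERED = math.inf


def genotype_code(token: str) -> int:
    """Map a genotype token ('AA', 'AB', 'BA', 'BB', 'NC', '--') to its code."""
    t = token.strip().upper()
    if t in ("NC", "--", "NN", ""):
        return NC
    if t == "BA":
        t = "AB"
    if t not in GENOTYPE_CODES:
        raise ValueError(f"invalid genotype token: {token!r}")
    return GENOTYPE_CODES[t]


@dataclass
class SampleData:
    """One sample's probe-level data, aligned position-for-position to a map.

    ``genotype`` holds codes (AA=0, AB=1, BB=2, NC=-1); ``baf`` is the
    B-allele frequency in [0, 1]; ``lrr`` the log R ratio (log2 scale).
    Probes missing from an input file carry NC genotype and NaN signals.
    """

    sample_id: str
    genome_map: GenomeMap
    genotype: np.ndarray
    baf: np.ndarray
    lrr: np.ndarray
    gender: str = "unknown"

    def __post_init__(self) -> None:
        n = len(self.genome_map)
        self.genotype = np.asarray(self.genotype, dtype=np.int8)
        self.baf = np.asarray(self.baf, dtype=np.float64)
        self.lrr = np.asarray(self.lrr, dtype=np.float64)
        for name, arr in (("genotype", self.genotype), ("baf", self.baf), ("lrr", self.lrr)):
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != map length {n}")
        if self.gender not in ("M", "F", "unknown"):
            raise ValueError(f"gender must be M, F or unknown, got {self.gender!r}")

    @classmethod
    def empty(cls, sample_id: str, genome_map: GenomeMap, gender: str = "unknown") -> "SampleData":
        n = len(genome_map)
        return cls(
            sample_id=sample_id,
            genome_map=genome_map,
            genotype=np.full(n, NC, dtype=np.int8),
            baf=np.full(n, np.nan),
            lrr=np.full(n, np.nan),
            gender=gender,
        )


def cnv_direction(copy_number: int) -> str:
    """'loss' for copy number < 2, 'gain' for > 2."""
    if copy_number == 2:
        raise ValueError("copy number 2 is not a CNV")
    return "loss" if copy_number < 2 else "gain"


@dataclass(frozen=True)
class CnvCall:
    """A single caller's CNV interval (1-based inclusive coordinates)."""

    sample_id: str
    method: str
    chromosome: str
    start: int
    end: int
    copy_number: int
    n_probes: int = 1
    confidence: float = UNFILTERED

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosome", normalize_chrom(self.chromosome))
        if self.start > self.end:
            raise ValueError(f"call start {self.start} > end {self.end}")
        if not 0 <= self.copy_number <= 4:
            raise ValueError(f"copy number {self.copy_number} outside 0..4")
        if self.copy_number == 2:
            raise ValueError("copy number 2 is not a CNV call")
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")

    @property
    def direction(self) -> str:
        return cnv_direction(self.copy_number)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def merge_same_direction(calls: list[CnvCall]) -> list[CnvCall]:
    """Merge overlapping same-direction calls of one method into disjoint calls.

    The merged call spans min(start)..max(end); its copy number is taken from
    the highest-confidence member. Calls of opposite direction are left alone
    even if they overlap (a caller-internal conflict the vote resolves later).
    """
    out: list[CnvCall] = []
    for direction in ("loss", "gain"):
        group = sorted(
            (c for c in calls if c.direction == direction),
            key=lambda c: (c.chromosome, c.start, c.end),
        )
        cluster: list[CnvCall] = []
        for call in group:
            if cluster and call.chromosome == cluster[-1].chromosome and call.start <= max(
                c.end for c in cluster
            ):
                cluster.append(call)
            else:
                if cluster:
                    out.append(_collapse(cluster))
                cluster = [call]
        if cluster:
            out.append(_collapse(cluster))
    out.sort(key=lambda c: (c.chromosome, c.start, c.end))
    return out


def _collapse(cluster: list[CnvCall]) -> CnvCall:
    if len(cluster) == 1:
        return cluster[0]
    best = max(cluster, key=lambda c: c.confidence)
    return replace(
        best,
        start=min(c.start for c in cluster),
        end=max(c.end for c in cluster),
        n_probes=max(c.n_probes for c in cluster),
    )


@dataclass
class CallSet:
    """All retained calls of one method for one sample.

    Construction merges overlapping same-direction calls so per-method sets
    are interval-disjoint before voting.
    """

    method: str
    sample_id: str
    calls: list[CnvCall] = field(default_factory=list)
    confidence_threshold_applied: float = -math.inf
    n_dropped: int = 0

    def __post_init__(self) -> None:
        for c in self.calls:
            if c.sample_id != self.sample_id:
                raise ValueError(
                    f"call sample {c.sample_id!r} != callset sample {self.sample_id!r}"
                )
        self.calls = merge_same_direction(list(self.calls))

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self):
        return iter(self.calls)
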