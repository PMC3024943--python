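"""Genome map: the ordered probe manifest shared by all samples of a platform.

Coordinates are 1-based inclusive throughout the package; conversion to the
0-based half-open BED convention happens only when BED files are written.
Chromosome names are stored unprefixed ("1".."22", "X", "Y"); any "chr"
prefix is stripped on input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CHROMOSOMES: tuple[str, ...] = tuple(str(c) for c in range(1, 23)) + ("X", "Y")
AUTOSOMES: tuple[str, ...] = tuple(str(c) for c in range(1, 23))

_CHROM_ORDER = {name: i for i, name in enumerate(CHROMOSOMES)}


def normalize_chrom(name: str) -> str:
    """Map 'chr7', 'Chr7', '7', 'x' ... onto the canonical unprefixed name."""
    s = str(name).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    s = s.upper() if s.upper() in ("X", "Y") else s
    if s not in _CHROM_ORDER:
        raise ValueError(f"unknown chromosome name: {name!r}")
    return s


@dataclass(frozen=True)
class GenomeMap:
    """Ordered list of array probes, grouped by chromosome, sorted by position.

    Parameters
    ----------
    probe_ids : array of str, unique probe names.
    chroms : array of str, canonical chromosome per probe, stored in blocks
        following the canonical chromosome order 1..22, X, Y.
    positions : int array, 1-based bp, strictly increasing per chromosome.
    is_snp : bool array, True for polymorphic (SNP) probes, False for
        copy-number-only probes.
    """

    probe_ids: np.ndarray
    chroms: np.ndarray
    positions: np.ndarray
    is_snp: np.ndarray
    _chrom_slices: dict[str, slice] = field(default_factory=dict, repr=False, compare=False)
    _probe_index: dict[str, int] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        pid = np.asarray(self.probe_ids, dtype=object)
        chrom = np.asarray(self.chroms, dtype=object)
        pos = np.asarray(self.positions, dtype=np.int64)
        snp = np.asarray(self.is_snp, dtype=bool)
        if not (len(pid) == len(chrom) == len(pos) == len(snp)):
            raise ValueError("genome map arrays must have equal length")
        object.__setattr__(self, "probe_ids", pid)
        object.__setattr__(self, "chroms", chrom)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "is_snp", snp)

        slices: dict[str, slice] = {}
        start = 0
        last_order = -1
        for i in range(len(chrom) + 1):
            if i == len(chrom) or (i > 0 and chrom[i] != chrom[i - 1]):
                name = str(chrom[i - 1]) if i > 0 else None
                if name is not None:
                    if name in slices:
                        raise ValueError(f"chromosome {name} split into multiple blocks")
                    order = _CHROM_ORDER.get(name)
                    if order is None:
                        raise ValueError(f"unknown chromosome name: {name!r}")
                    if order <= last_order:
                        raise ValueError("chromosome blocks out of canonical order")
                    last_order = order
                    block = pos[start:i]
                    if len(block) > 1 and not np.all(np.diff(block) > 0):
                        raise ValueError(f"positions not strictly increasing on {name}")
                    slices[name] = slice(start, i)
                start = i
        object.__setattr__(self, "_chrom_slices", slices)

        index = {str(p): i for i, p in enumerate(pid)}
        if len(index) != len(pid):
            raise ValueError("probe ids are not unique")
        object.__setattr__(self, "_probe_index", index)

    @classmethod
    def from_probes(cls, probes: list[tuple[str, str, int, bool]]) -> "GenomeMap":
        """Build from (probe_id, chromosome, position, is_snp) tuples.

        Probes may arrive in any order; they are sorted into canonical
        chromosome order and by position.
        """
        rows = [(pid, normalize_chrom(c), int(p), bool(s)) for pid, c, p, s in probes]
        rows.sort(key=lambda r: (_CHROM_ORDER[r[1]], r[2]))
        return cls(
            probe_ids=np.array([r[0] for r in rows], dtype=object),
            chroms=np.array([r[1] for r in rows], dtype=object),
            positions=np.array([r[2] for r in rows], dtype=np.int64),
            is_snp=np.array([r[3] for r in rows], dtype=bool),
        )

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._chrom_slices)

    def chrom_slice(self, chrom: str) -> slice:
        name = normalize_chrom(chrom)
        if name not in self._chrom_slices:
            raise KeyError(f"chromosome {name} not on this map")
        return self._chrom_slices[name]

    def probe_number(self, probe_id: str) -> int | None:
        return self._probe_index.get(probe_id)

    def index_range(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """Half-open global index range [i0, i1) of probes with
        start <= position <= end on `chrom`."""
        if start > end:
            raise ValueError(f"start {start} > end {end}")
        sl = self.chrom_slice(chrom)
        block = self.positions[sl]
        i0 = int(np.searchsorted(block, start, side="left"))
        i1 = int(np.searchsorted(block, end, side="right"))
        return sl.start + i0, sl.start + i1


def n_probes_in(genome_map: GenomeMap, chromosome: str, start: int, end: int) -> int:
    """Number of map probes whose position lies in [start, end] (inclusive)."""
    i0, i1 = genome_map.index_range(chromosome, start, end)
    return i1 - i0
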