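"""Readers and writers for probe-level reports, caller callsets and tracks.

Supported inputs
----------------
* Illumina "Final Report" TSV, with or without the ``[Header]``/``[Data]``
  section structure; gzip transparently handled.
* QuantiSNP output TSV (one row per CNV, max log Bayes factor confidence).
* PennCNV ``rawcnv`` line dialect.
* Generic tab-separated CNV tables described by a :class:`ColumnMap`.
* GC-content track, UCSC cytoband file, BED tracks, pedigree TSV.

All readers accept a path or an open text stream. Coordinates are 1-based
inclusive except BED, which is converted at the boundary.
"""

from __future__ import annotations

import gzip
import io as _io
import math
import re
from contextlib import contextmanager
from dataclasses import dataclass, field
from typing import IO, Iterator

import numpy as np
import yaml

from .datamodel import NC, UNFILTERED, CallSet, CnvCall, SampleData, genotype_code
from .genome import GenomeMap, normalize_chrom


class FormatError(ValueError):
    """Raised when an input file does not match its declared dialect."""


@contextmanager
def _open_text(source) -> Iterator[IO[str]]:
    """Yield a text stream from a path (optionally .gz) or a stream."""
    if hasattr(source, "read"):
        yield source
        return
    path = str(source)
    if path.endswith(".gz"):
        with gzip.open(path, "rt") as fh:
            yield fh
    else:
        with open(path, "rt") as fh:
            yield fh


# ---------------------------------------------------------------------------
# Illumina Final Report
# ---------------------------------------------------------------------------

_FR_COLUMNS = {
    "snp name": "probe_id",
    "chr": "chrom",
    "position": "position",
    "gtype": "gtype",
    "allele1": "allele1",
    "allele2": "allele2",
    "allele1 - top": "allele1",
    "allele2 - top": "allele2",
    "b allele freq": "baf",
    "log r ratio": "lrr",
}


@dataclass
class ParseStats:
    """Per-file bookkeeping emitted alongside parsed sample data."""

    n_rows: int = 0
    n_unknown_probes: int = 0
    n_bad_rows: int = 0
    warnings: list[str] = field(default_factory=list)


def parse_final_report(
    source,
    genome_map: GenomeMap,
    sample_id: str | None = None,
    error_budget: int = 100,
) -> tuple[SampleData, ParseStats]:
    """Read one sample's probe-level data from a Final Report style TSV.

    Rows naming probes absent from ``genome_map`` are counted and skipped;
    map probes missing from the file keep NC genotype and NaN signals.
    Up to ``error_budget`` unparseable rows are tolerated (counted), after
    which a :class:`FormatError` is raised.
    """
    stats = ParseStats()
    with _open_text(source) as fh:
        header, data_lines = _split_final_report(fh)
        cols = {}
        for idx, name in enumerate(header):
            key = _FR_COLUMNS.get(name.strip().lower())
            if key is not None and key not in cols:
                cols[key] = idx
        for mandatory in ("probe_id", "chrom", "position"):
            if mandatory not in cols:
                raise FormatError(f"final report is missing mandatory column: {mandatory}")
        if "gtype" not in cols and not ("allele1" in cols and "allele2" in cols):
            raise FormatError("final report is missing mandatory column: GType (or Allele1/Allele2)")

        sample = SampleData.empty(sample_id or "sample", genome_map)
        for lineno, line in data_lines:
            fields = line.rstrip("\n").split("\t")
            stats.n_rows += 1
            try:
                probe = fields[cols["probe_id"]]
                i = genome_map.probe_number(probe)
                if i is None:
                    stats.n_unknown_probes += 1
                    continue
                if "gtype" in cols:
                    gt = genotype_code(fields[cols["gtype"]])
                else:
                    a1, a2 = fields[cols["allele1"]], fields[cols["allele2"]]
                    gt = _alleles_to_code(a1, a2)
                baf = float(fields[cols["baf"]]) if "baf" in cols else math.nan
                lrr = float(fields[cols["lrr"]]) if "lrr" in cols else math.nan
                if not math.isnan(baf) and not 0.0 <= baf <= 1.0:
                    raise ValueError(f"BAF {baf} outside [0, 1]")
            except (IndexError, ValueError) as exc:
                stats.n_bad_rows += 1
                if stats.n_bad_rows > error_budget:
                    raise FormatError(f"line {lineno}: {exc}") from exc
                stats.warnings.append(f"line {lineno}: {exc}")
                continue
            sample.genotype[i] = gt
            sample.baf[i] = baf
            sample.lrr[i] = lrr
    if stats.n_rows == 0:
        stats.warnings.append("no data rows; all probes set to missing")
    return sample, stats


def _split_final_report(fh: IO[str]) -> tuple[list[str], list[tuple[int, str]]]:
    """Return (header fields, [(lineno, data line), ...]); tolerate the
    [Header]/[Data] section structure or a plain header row."""
    lines = fh.read().splitlines()
    start = 0
    for i, line in enumerate(lines):
        if line.strip().lower() == "[data]":
            start = i + 1
            break
        if line.strip().lower() == "[header]":
            continue
    if start >= len(lines):
        return [], []
    header = lines[start].split("\t")
    data = [(i + 1, ln) for i, ln in enumerate(lines) if i > start and ln.strip()]
    return header, data


def _alleles_to_code(a1: str, a2: str) -> int:
    pair = (a1.strip().upper(), a2.strip().upper())
    if "-" in pair or "" in pair:
        return NC
    mapped = tuple(sorted("A" if a in ("A",) else "B" if a in ("B",) else "?" for a in pair))
    if "?" in mapped:
        return NC
    return genotype_code("".join(mapped))


def write_final_report(sample: SampleData, path, with_sections: bool = True) -> None:
    """Write a sample as an Illumina-style Final Report TSV (round-trippable)."""
    gm = sample.genome_map
    with open(path, "wt") as fh:
        if with_sections:
            fh.write("[Header]\n")
            fh.write(f"Sample ID\t{sample.sample_id}\n")
            fh.write(f"Num SNPs\t{len(gm)}\n")
            fh.write("[Data]\n")
        fh.write("SNP Name\tChr\tPosition\tGType\tB Allele Freq\tLog R Ratio\n")
        from .datamodel import GENOTYPE_NAMES

        for i in range(len(gm)):
            baf = sample.baf[i]
            lrr = sample.lrr[i]
            fh.write(
                f"{gm.probe_ids[i]}\t{gm.chroms[i]}\t{gm.positions[i]}\t"
                f"{GENOTYPE_NAMES[int(sample.genotype[i])]}\t"
                f"{'' if math.isnan(baf) else format(baf, '.6f')}\t"
                f"{'' if math.isnan(lrr) else format(lrr, '.6f')}\n"
            )


# ---------------------------------------------------------------------------
# Caller callsets
# ---------------------------------------------------------------------------

_QSNP_ALIASES = {
    "sample": ("sample name", "sample", "sample id"),
    "chrom": ("chromosome", "chr"),
    "start": ("start position (bp)", "start", "start position"),
    "end": ("end position (bp)", "end", "end position"),
    "copy_number": ("copy number", "cn", "state"),
    "n_probes": ("no. probes", "number probes", "num probes", "probes"),
    "confidence": ("max. log bf", "max log bf", "log bayes factor", "lbf"),
}


def parse_quantisnp_calls(source, min_lbf: float = 8.5, method: str = "QuantiSNP") -> CallSet:
    """Parse a QuantiSNP CNV table, dropping calls with log Bayes factor
    below ``min_lbf`` (boundary inclusive: confidence == threshold is kept)."""
    with _open_text(source) as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    if not lines:
        return CallSet(method=method, sample_id="", confidence_threshold_applied=min_lbf)
    header = [h.strip().lower() for h in lines[0].split("\t")]
    cols: dict[str, int] = {}
    for key, aliases in _QSNP_ALIASES.items():
        for alias in aliases:
            if alias in header:
                cols[key] = header.index(alias)
                break
    missing = [k for k in ("sample", "chrom", "start", "end", "copy_number", "confidence") if k not in cols]
    if missing:
        raise FormatError(f"QuantiSNP table is missing columns: {', '.join(missing)}")

    calls: list[CnvCall] = []
    dropped = 0
    sample_id = ""
    for lineno, line in enumerate(lines[1:], start=2):
        f = line.split("\t")
        try:
            conf = float(f[cols["confidence"]])
            cn = int(float(f[cols["copy_number"]]))
            call = CnvCall(
                sample_id=f[cols["sample"]].strip(),
                method=method,
                chromosome=f[cols["chrom"]],
                start=int(float(f[cols["start"]])),
                end=int(float(f[cols["end"]])),
                copy_number=cn,
                n_probes=int(float(f[cols["n_probes"]])) if "n_probes" in cols else 1,
                confidence=conf,
            )
        except (IndexError, ValueError) as exc:
            raise FormatError(f"line {lineno}: {exc}") from exc
        sample_id = sample_id or call.sample_id
        if conf < min_lbf:
            dropped += 1
            continue
        calls.append(call)
    return CallSet(
        method=method,
        sample_id=sample_id,
        calls=calls,
        confidence_threshold_applied=min_lbf,
        n_dropped=dropped,
    )


_PENNCNV_RE = re.compile(
    r"^(?:chr)?(?P<chrom>[0-9XYxy]+):(?P<start>\d+)-(?P<end>\d+)\s+"
    r"numsnp=(?P<numsnp>\d+)\s+length=(?P<length>[\d,]+)\s+"
    r"state\s*(?P<state>\d+)\s*,\s*cn=(?P<cn>\d+)\s+(?P<sample>\S+)"
)
_PENNCNV_CONF_RE = re.compile(r"conf=(?P<conf>[-+0-9.eE]+)")


def parse_penncnv_calls(source, min_conf: float = 10.0, method: str = "PennCNV") -> CallSet:
    """Parse PennCNV ``rawcnv`` lines; calls with conf below ``min_conf``
    are dropped (inclusive boundary). Lines without a conf= token are kept
    and carry an unfiltered confidence sentinel."""
    calls: list[CnvCall] = []
    dropped = 0
    sample_id = ""
    with _open_text(source) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            m = _PENNCNV_RE.match(line.strip())
            if m is None:
                raise FormatError(f"line {lineno}: not a PennCNV rawcnv line")
            cm = _PENNCNV_CONF_RE.search(line)
            conf = float(cm.group("conf")) if cm else UNFILTERED
            call = CnvCall(
                sample_id=m.group("sample"),
                method=method,
                chromosome=m.group("chrom"),
                start=int(m.group("start")),
                end=int(m.group("end")),
                copy_number=int(m.group("cn")),
                n_probes=int(m.group("numsnp")),
                confidence=conf,
            )
            sample_id = sample_id or call.sample_id
            if conf < min_conf:
                dropped += 1
                continue
            calls.append(call)
    return CallSet(
        method=method,
        sample_id=sample_id,
        calls=calls,
        confidence_threshold_applied=min_conf,
        n_dropped=dropped,
    )


@dataclass
class ColumnMap:
    """Describes how a generic tab-separated CNV table maps onto CnvCall fields.

    Values are column names (requires ``header=True``) or 0-based integer
    indices. ``chrom_prefix`` is one of "keep"/"strip" (both normalise to
    unprefixed names internally; kept for config round-trips).
    """

    sample: str | int
    chrom: str | int
    start: str | int
    end: str | int
    copy_number: str | int
    n_probes: str | int | None = None
    confidence: str | int | None = None
    header: bool = True
    chrom_prefix: str = "strip"

    MANDATORY = ("sample", "chrom", "start", "end", "copy_number")

    @classmethod
    def from_config(cls, source) -> "ColumnMap":
        """Load from a YAML/JSON mapping file (keys as in the constructor)."""
        with _open_text(source) as fh:
            cfg = yaml.safe_load(fh)
        if not isinstance(cfg, dict):
            raise FormatError("column map config must be a mapping")
        missing = [k for k in cls.MANDATORY if k not in cfg]
        if missing:
            raise FormatError(f"column map config missing mandatory fields: {', '.join(missing)}")
        return cls(**cfg)

    def resolve(self, header_fields: list[str] | None) -> dict[str, int]:
        out: dict[str, int] = {}
        lowered = [h.strip().lower() for h in header_fields] if header_fields else None
        for name in ("sample", "chrom", "start", "end", "copy_number", "n_probes", "confidence"):
            spec = getattr(self, name)
            if spec is None:
                continue
            if isinstance(spec, int):
                out[name] = spec
            else:
                if lowered is None:
                    raise FormatError(f"column {name}={spec!r} named but file has no header")
                key = spec.strip().lower()
                if key not in lowered:
                    raise FormatError(f"column {spec!r} for field {name} not found in header")
                out[name] = lowered.index(key)
        return out


def parse_generic_calls(
    source,
    column_map: ColumnMap,
    method: str = "generic",
    genome_map: GenomeMap | None = None,
) -> CallSet:
    """Parse any tab-separated CNV table through a :class:`ColumnMap`.

    Missing optional fields default: ``n_probes`` is recomputed from
    ``genome_map`` when one is supplied (else 1), ``confidence`` becomes the
    unfiltered (+inf) sentinel.
    """
    with _open_text(source) as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    if not lines:
        return CallSet(method=method, sample_id="")
    header = lines[0].split("\t") if column_map.header else None
    cols = column_map.resolve(header)
    body = lines[1:] if column_map.header else lines

    calls: list[CnvCall] = []
    sample_id = ""
    for lineno, line in enumerate(body, start=2 if column_map.header else 1):
        f = line.split("\t")
        try:
            chrom = normalize_chrom(f[cols["chrom"]])
            start = int(float(f[cols["start"]]))
            end = int(float(f[cols["end"]]))
            if "n_probes" in cols:
                n_probes = int(float(f[cols["n_probes"]]))
            elif genome_map is not None:
                from .genome import n_probes_in

                n_probes = max(1, n_probes_in(genome_map, chrom, start, end))
            else:
                n_probes = 1
            call = CnvCall(
                sample_id=f[cols["sample"]].strip(),
                method=method,
                chromosome=chrom,
                start=start,
                end=end,
                copy_number=int(float(f[cols["copy_number"]])),
                n_probes=n_probes,
                confidence=float(f[cols["confidence"]]) if "confidence" in cols else UNFILTERED,
            )
        except (IndexError, ValueError) as exc:
            raise FormatError(f"line {lineno}: {exc}") from exc
        sample_id = sample_id or call.sample_id
        calls.append(call)
    return CallSet(method=method, sample_id=sample_id, calls=calls)


GENERIC_HEADER = ["sample", "chrom", "start", "end", "copy_number", "n_probes", "confidence"]
GENERIC_COLUMN_MAP = ColumnMap(
    sample="sample", chrom="chrom", start="start", end="end",
    copy_number="copy_number", n_probes="n_probes", confidence="confidence",
)


def write_callset(callset: CallSet, path_or_stream) -> int:
    """Write a CallSet in the generic TSV dialect; returns the line count.

    Confidence is written to 6 decimals ('inf' for the unfiltered sentinel);
    reading the file back with :data:`GENERIC_COLUMN_MAP` reproduces the set.
    """
    own = not hasattr(path_or_stream, "write")
    fh = open(path_or_stream, "wt") if own else path_or_stream
    try:
        fh.write("\t".join(GENERIC_HEADER) + "\n")
        for c in callset:
            conf = "inf" if math.isinf(c.confidence) else format(c.confidence, ".6f")
            fh.write(
                f"{c.sample_id}\t{c.chromosome}\t{c.start}\t{c.end}\t"
                f"{c.copy_number}\t{c.n_probes}\t{conf}\n"
            )
        return len(callset.calls)
    finally:
        if own:
            fh.close()


# ---------------------------------------------------------------------------
# Genome map manifest
# ---------------------------------------------------------------------------

def read_genome_map(source) -> GenomeMap:
    """Read a probe manifest TSV (probe_id, chrom, position, is_snp)."""
    probes = []
    with _open_text(source) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if f[0].strip().lower() == "probe_id":
                continue
            try:
                probes.append((f[0], f[1], int(f[2]), f[3].strip().lower() in ("1", "true", "yes")))
            except (IndexError, ValueError) as exc:
                raise FormatError(f"manifest line {lineno}: {exc}") from exc
    return GenomeMap.from_probes(probes)


def write_genome_map(genome_map: GenomeMap, path) -> None:
    with open(path, "wt") as fh:
        fh.write("probe_id\tchrom\tposition\tis_snp\n")
        for i in range(len(genome_map)):
            fh.write(
                f"{genome_map.probe_ids[i]}\t{genome_map.chroms[i]}\t"
                f"{genome_map.positions[i]}\t{int(genome_map.is_snp[i])}\n"
            )


# ---------------------------------------------------------------------------
# Tracks
# ---------------------------------------------------------------------------

def read_gc_track(source) -> dict[str, list[tuple[int, int, float]]]:
    """Read a BED-like GC track (chrom, start0, end, gc_fraction) into
    per-chromosome (start_1based, end, gc) lists."""
    track: dict[str, list[tuple[int, int, float]]] = {}
    with _open_text(source) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            try:
                chrom = normalize_chrom(f[0])
                start0, end, gc = int(f[1]), int(f[2]), float(f[3])
            except (IndexError, ValueError) as exc:
                raise FormatError(f"GC track line {lineno}: {exc}") from exc
            if not 0.0 <= gc <= 1.0:
                raise FormatError(f"GC track line {lineno}: gc fraction {gc} outside [0,1]")
            track.setdefault(chrom, []).append((start0 + 1, end, gc))
    for rows in track.values():
        rows.sort()
    return track


def read_cytoband(source) -> dict[str, list[tuple[int, int, str]]]:
    """Read a UCSC cytoBand.txt file (chrom, start0, end, band, stain)."""
    bands: dict[str, list[tuple[int, int, str]]] = {}
    with _open_text(source) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            try:
                chrom = normalize_chrom(f[0])
                start0, end, name = int(f[1]), int(f[2]), f[3]
            except (IndexError, ValueError) as exc:
                raise FormatError(f"cytoband line {lineno}: {exc}") from exc
            bands.setdefault(chrom, []).append((start0 + 1, end, name))
    for rows in bands.values():
        rows.sort()
    return bands


def read_pedigree(source) -> list[dict[str, str]]:
    """Read a pedigree TSV (family_id, sample_id, father_id, mother_id, sex).

    '0' or '' denote a missing parent. Returns one dict per row.
    """
    rows: list[dict[str, str]] = []
    with _open_text(source) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if f[0].strip().lower() == "family_id":
                continue
            if len(f) < 5:
                raise FormatError(f"pedigree line {lineno}: expected 5 columns")
            rows.append(
                dict(
                    family_id=f[0], sample_id=f[1],
                    father_id=f[2] if f[2] not in ("0", "") else "",
                    mother_id=f[3] if f[3] not in ("0", "") else "",
                    sex=f[4],
                )
            )
    return rows
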