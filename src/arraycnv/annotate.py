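"""Interval annotation of consensus regions, ISCN naming and report output.

Tracks are user-supplied BED files (control-variant catalogues, gene lists,
custom intervals); a UCSC ``cytoBand.txt`` file provides band names for
ISCN strings. Control-variant frequency counts distinct control samples
carrying an overlapping same-direction variant, divided by the declared
panel size. Coordinates convert to the 0-based half-open BED convention
only at the file boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .consensus import ConsensusRegion
from .genome import normalize_chrom
from .io import FormatError, _open_text
from .qc import QcReport


@dataclass
class TrackInterval:
    chromosome: str
    start: int  # 1-based inclusive
    end: int
    label: str = ""
    sample: str | None = None
    direction: str | None = None  # 'loss'/'gain' for control-variant tracks


@dataclass
class AnnotationTrack:
    """A named, per-chromosome indexed set of labelled intervals."""

    name: str
    kind: str = "custom"  # control_variants | genes | custom
    intervals: list[TrackInterval] = field(default_factory=list)
    panel_size: int | None = None  # number of control samples, for frequencies
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in ("control_variants", "genes", "custom"):
            raise ValueError(f"unknown track kind: {self.kind!r}")
        for iv in self.intervals:
            # IntervalTree is half-open; store [start, end+1)
            self._trees.setdefault(iv.chromosome, IntervalTree()).addi(
                iv.start, iv.end + 1, iv
            )

    def query(self, chromosome: str, start: int, end: int) -> list[TrackInterval]:
        tree = self._trees.get(normalize_chrom(chromosome))
        if tree is None:
            return []
        hits = [h.data for h in tree.overlap(start, end + 1)]
        hits.sort(key=lambda iv: (iv.start, iv.end, iv.label, iv.sample or ""))
        return hits


def read_bed_track(
    source,
    name: str,
    kind: str = "custom",
    panel_size: int | None = None,
    sample_column: int | None = None,
    direction_column: int | None = None,
) -> AnnotationTrack:
    """Load a 3-6 column BED file as an annotation track.

    Column 4 (when present) is the interval label. ``sample_column`` /
    ``direction_column`` point at extra 0-based columns carrying a control
    sample identifier and a loss/gain direction.
    """
    intervals: list[TrackInterval] = []
    with _open_text(source) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            try:
                chrom = normalize_chrom(f[0])
                start0, end = int(f[1]), int(f[2])
            except (IndexError, ValueError) as exc:
                raise FormatError(f"BED line {lineno}: {exc}") from exc
            label = f[3] if len(f) > 3 else ""
            sample = f[sample_column] if sample_column is not None and len(f) > sample_column else None
            direction = (
                f[direction_column]
                if direction_column is not None and len(f) > direction_column
                else None
            )
            if direction is not None and direction not in ("loss", "gain"):
                raise FormatError(f"BED line {lineno}: direction must be loss/gain")
            intervals.append(
                TrackInterval(chrom, start0 + 1, end, label, sample, direction)
            )
    return AnnotationTrack(name=name, kind=kind, intervals=intervals, panel_size=panel_size)


@dataclass
class AnnotatedRegion:
    region: ConsensusRegion
    track_hits: dict[str, list[str]] = field(default_factory=dict)
    control_frequency: float | None = None
    gene_names: list[str] = field(default_factory=list)
    iscn: str = ""
    inheritance: str = ""
    parent_of_origin: str = ""


def overlap_annotate(
    regions: list[ConsensusRegion] | list[AnnotatedRegion],
    track: AnnotationTrack,
    min_overlap_fraction: float = 0.0,
) -> list[AnnotatedRegion]:
    """Annotate regions with a track; a hit requires the overlap to cover at
    least ``min_overlap_fraction`` of the region's length (default: any).

    For ``control_variants`` tracks the control frequency is the number of
    distinct control samples with an overlapping same-direction variant
    divided by the track's declared panel size; tracks carrying sample
    identifiers without a panel size raise an error. For ``genes`` tracks
    hit labels are collected into ``gene_names``.
    """
    out: list[AnnotatedRegion] = []
    for item in regions:
        ann = item if isinstance(item, AnnotatedRegion) else AnnotatedRegion(region=item)
        region = ann.region
        length = region.end - region.start + 1
        hits = []
        for iv in track.query(region.chromosome, region.start, region.end):
            ov = min(region.end, iv.end) - max(region.start, iv.start) + 1
            if ov / length >= min_overlap_fraction and ov > 0:
                hits.append(iv)
        if track.kind == "control_variants":
            same_dir = [h for h in hits if h.direction in (None, region.direction)]
            samples = {h.sample for h in same_dir if h.sample is not None}
            if samples and track.panel_size is None:
                raise ValueError(
                    f"track {track.name!r} carries sample ids but no panel size"
                )
            if track.panel_size:
                ann.control_frequency = len(samples) / track.panel_size
            ann.track_hits[track.name] = sorted({h.label or (h.sample or "") for h in same_dir})
        else:
            labels = sorted({h.label for h in hits if h.label})
            ann.track_hits[track.name] = labels
            if track.kind == "genes":
                ann.gene_names = sorted(set(ann.gene_names) | set(labels))
        out.append(ann)
    return out


# ---------------------------------------------------------------------------
# ISCN
# ---------------------------------------------------------------------------

_INHERITANCE_SUFFIX = {
    "de_novo": " dn",
    "paternal": " pat",
    "maternal": " mat",
    "both": " pat mat",
    "": "",
}


def iscn_string(
    region: ConsensusRegion,
    cytobands: dict[str, list[tuple[int, int, str]]],
    inheritance_tag: str = "",
) -> str:
    """ISCN-style designation, e.g. ``arr 15q11.2(22,765,628-23,217,514)x1 dn``.

    Band names come from the cytoband intervals overlapping the region's
    first and last base; a region spanning several bands names the first
    and last (``15q11.2q12``).
    """
    chrom = region.chromosome
    bands = cytobands.get(chrom)
    if not bands:
        raise ValueError(f"cytoband track does not cover chromosome {chrom}")
    band_start = _band_at(bands, region.start)
    band_end = _band_at(bands, region.end)
    if band_start is None or band_end is None:
        raise ValueError(
            f"cytoband track does not cover {chrom}:{region.start}-{region.end}"
        )
    band_part = band_start if band_start == band_end else f"{band_start}{band_end}"
    suffix = _INHERITANCE_SUFFIX.get(inheritance_tag, "")
    return (
        f"arr {chrom}{band_part}({region.start:,}-{region.end:,})"
        f"x{region.copy_number}{suffix}"
    )


def _band_at(bands: list[tuple[int, int, str]], pos: int) -> str | None:
    for start, end, name in bands:
        if start <= pos <= end:
            return name
    return None


# ---------------------------------------------------------------------------
# BED / report output
# ---------------------------------------------------------------------------

def write_bed(regions: list[AnnotatedRegion] | list[ConsensusRegion], stream_or_path) -> int:
    """Write regions as BED (0-based half-open, 'chr' prefix); returns line count."""
    own = not hasattr(stream_or_path, "write")
    fh = open(stream_or_path, "wt") if own else stream_or_path
    try:
        n = 0
        for item in regions:
            ann = item if isinstance(item, AnnotatedRegion) else None
            region = ann.region if ann else item
            name = (ann.iscn if ann and ann.iscn else "") or (
                f"{region.direction}_cn{region.copy_number}"
            )
            fh.write(
                f"chr{region.chromosome}\t{region.start - 1}\t{region.end}\t"
                f"{name.replace(' ', '_')}\n"
            )
            n += 1
        return n
    finally:
        if own:
            fh.close()


def build_report(
    sample_id: str,
    qc: QcReport | None,
    annotated: list[AnnotatedRegion],
    upd_events=None,
    nonpaternity: tuple[bool, dict] | None = None,
    max_control_frequency: float | None = None,
) -> dict:
    """Assemble the deterministic structured report (JSON-serialisable dict).

    ``max_control_frequency`` filters the region table to variants at most
    that frequent in controls (None keeps everything; regions without a
    computed frequency are kept).
    """
    regions = []
    for ann in annotated:
        if (
            max_control_frequency is not None
            and ann.control_frequency is not None
            and ann.control_frequency > max_control_frequency
        ):
            continue
        r = ann.region
        regions.append(
            {
                "chrom": r.chromosome,
                "start": r.start,
                "end": r.end,
                "direction": r.direction,
                "copy_number": r.copy_number,
                "n_probes": r.n_probes,
                "methods": sorted(r.supporting_methods),
                "vote_mode": r.vote_mode,
                "iscn": ann.iscn,
                "inheritance": ann.inheritance,
                "parent_of_origin": ann.parent_of_origin,
                "control_frequency": ann.control_frequency,
                "genes": ann.gene_names,
                "track_hits": {k: v for k, v in sorted(ann.track_hits.items())},
            }
        )
    regions.sort(key=lambda r: (_chrom_sort(r["chrom"]), r["start"], r["end"]))

    report: dict = {
        "sample": {"sample_id": sample_id},
        "qc": qc.to_dict() if qc is not None else None,
        "regions": regions,
        "iscn": [r["iscn"] for r in regions if r["iscn"]],
    }
    if upd_events is not None:
        report["upd_events"] = [e.as_row() for e in upd_events]
    if nonpaternity is not None:
        flag, table = nonpaternity
        report["nonpaternity"] = {
            "flag": bool(flag),
            "per_chromosome": {k: table[k] for k in sorted(table, key=_chrom_sort)},
        }
    return report


def report_json(report: dict) -> str:
    """Serialise a report deterministically (stable ordering, no timestamps);
    NaN metrics (e.g. an unevaluated wave factor) become null."""
    return json.dumps(_clean(report), indent=2, sort_keys=True, allow_nan=False,
                      default=_jsonable)


def _clean(o):
    import math as _math

    if isinstance(o, float) and _math.isnan(o):
        return None
    if isinstance(o, dict):
        return {k: _clean(v) for k, v in o.items()}
    if isinstance(o, (list, tuple)):
        return [_clean(v) for v in o]
    return o


def report_text(report: dict) -> str:
    """Human-readable text rendering of a report."""
    lines = [f"Sample: {report['sample']['sample_id']}"]
    qc = report.get("qc")
    if qc:
        lines.append(
            f"QC: call_rate={qc['call_rate']:.4f} lrr_sd={qc['lrr_sd']:.4f} "
            f"baf_sd={qc['baf_sd']:.4f} passed={qc['passed']}"
        )
        if qc["mosaic_flagged_chromosomes"]:
            lines.append("Mosaicism-flagged chromosomes: "
                         + ", ".join(qc["mosaic_flagged_chromosomes"]))
    lines.append(f"Regions ({len(report['regions'])}):")
    for r in report["regions"]:
        extras = []
        if r["inheritance"]:
            extras.append(r["inheritance"])
        if r["parent_of_origin"]:
            extras.append(f"origin={r['parent_of_origin']}")
        if r["control_frequency"] is not None:
            extras.append(f"ctrl_freq={r['control_frequency']:.2f}")
        if r["genes"]:
            extras.append("genes=" + ",".join(r["genes"]))
        label = r["iscn"] or "{}:{}-{} x{}".format(
            r["chrom"], r["start"], r["end"], r["copy_number"]
        )
        lines.append("  " + label + (" [" + "; ".join(extras) + "]" if extras else ""))
    for e in report.get("upd_events", []):
        lines.append(
            f"  UPD {e['chrom']}:{e['start']}-{e['end']} {e['parent']} {e['subtype']}"
            f" (n={e['n_informative']}, p={e['p_value']})"
        )
    np_block = report.get("nonpaternity")
    if np_block is not None:
        lines.append(f"Non-paternity flag: {np_block['flag']}")
    return "\n".join(lines) + "\n"


def _jsonable(o):
    import numpy as _np

    if isinstance(o, (_np.integer,)):
        return int(o)
    if isinstance(o, (_np.floating,)):
        return float(o)
    raise TypeError(f"not JSON-serialisable: {type(o)}")


def _chrom_sort(c: str):
    return (0, int(c)) if str(c).isdigit() else (1, str(c))
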