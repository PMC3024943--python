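"""File-based pipeline orchestration: parse -> QC -> mosaicism -> consensus
-> trio analytics -> annotate -> report.

The run directory replaces the original platform's database layer: every
stage writes plain-text artifacts, and a manifest records each emitted file
with its SHA-256 hash so runs are reproducible and auditable. The
mosaicism (BAF segmentation) stage runs only on QC-flagged chromosomes
unless ``all_baf`` is set; trio stages run only when a pedigree is present.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import annotate as ann
from . import bafseg, consensus, io, qc, trio as trio_mod
from .datamodel import CallSet, SampleData
from .genome import GenomeMap

log = logging.getLogger("arraycnv")


@dataclass
class PipelineConfig:
    genome_map: str
    samples: list[dict] = field(default_factory=list)   # sample_id, final_report, gender
    callsets: list[dict] = field(default_factory=list)  # sample_id, method, dialect, path, ...
    pedigree: str | None = None
    tracks: list[dict] = field(default_factory=list)
    cytoband: str | None = None
    gc_track: str | None = None
    vote: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    bafseg: dict = field(default_factory=dict)
    trio: dict = field(default_factory=dict)
    out_dir: str = "arraycnv_run"
    all_baf: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate_paths(self) -> None:
        paths = [self.genome_map, self.pedigree, self.cytoband, self.gc_track]
        paths += [s.get("final_report") for s in self.samples]
        paths += [c.get("path") for c in self.callsets]
        paths += [t.get("path") for t in self.tracks]
        for p in paths:
            if p and not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _parse_callset(entry: dict, genome_map: GenomeMap) -> CallSet:
    dialect = entry.get("dialect", "generic")
    path = entry["path"]
    method = entry.get("method", dialect)
    if dialect == "quantisnp":
        return io.parse_quantisnp_calls(path, min_lbf=entry.get("min_confidence", 8.5), method=method)
    if dialect == "penncnv":
        return io.parse_penncnv_calls(path, min_conf=entry.get("min_confidence", 10.0), method=method)
    if dialect == "generic":
        cmap = io.ColumnMap.from_config(entry["column_map"]) if "column_map" in entry else io.GENERIC_COLUMN_MAP
        return io.parse_generic_calls(path, cmap, method=method, genome_map=genome_map)
    raise ValueError(f"unknown callset dialect: {dialect!r}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns the artifact manifest."""
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    manifest: dict = {"config": config.to_dict(), "stages": [], "artifacts": {}}

    def emit(path: Path) -> None:
        artifacts.append(path)

    def stage(name: str) -> None:
        log.info("stage: %s", name)
        manifest["stages"].append(name)

    gm = io.read_genome_map(config.genome_map)
    gc_track = io.read_gc_track(config.gc_track) if config.gc_track else None
    cytobands = io.read_cytoband(config.cytoband) if config.cytoband else None
    tracks = [
        ann.read_bed_track(
            t["path"],
            name=t.get("name", Path(t["path"]).stem),
            kind=t.get("kind", "custom"),
            panel_size=t.get("panel_size"),
            sample_column=t.get("sample_column"),
            direction_column=t.get("direction_column"),
        )
        for t in config.tracks
    ]

    # ---- parse + QC + mosaicism + consensus, per sample -------------------
    stage("parse")
    samples: dict[str, SampleData] = {}
    for entry in config.samples:
        sample, _stats = io.parse_final_report(
            entry["final_report"], gm, sample_id=entry["sample_id"]
        )
        sample.gender = entry.get("gender", "unknown")
        samples[sample.sample_id] = sample

    thresholds = qc.QcThresholds(**config.qc)
    vote_cfg = consensus.VoteConfig(**config.vote)
    seg_cfg = bafseg.BafSegConfig(**config.bafseg)
    trio_cfg = trio_mod.TrioConfig(**config.trio)

    qc_reports: dict[str, qc.QcReport] = {}
    regions: dict[str, list[consensus.ConsensusRegion]] = {}
    ai_segments: dict[str, list[bafseg.AiSegment]] = {}

    stage("qc")
    for sid, sample in samples.items():
        wave = float("nan")
        if gc_track is not None:
            sample, wave = qc.gc_wave_correct(sample, gc_track)
            samples[sid] = sample
        report = qc.compute_qc(sample, thresholds, wave_factor=wave)
        try:
            qc.screen_mosaic_chromosomes(report)
        except ValueError:
            pass  # too few autosomes on this map to screen
        qc_reports[sid] = report
        p = out / f"qc_{sid}.json"
        p.write_text(report.to_json() + "\n")
        emit(p)

    stage("consensus")
    by_sample: dict[str, list[CallSet]] = {}
    for entry in config.callsets:
        cs = _parse_callset(entry, gm)
        sid = entry.get("sample_id") or cs.sample_id
        cs.sample_id = sid or cs.sample_id
        by_sample.setdefault(cs.sample_id, []).append(cs)
    for sid, callsets in by_sample.items():
        regs = consensus.vote_consensus(callsets, gm, vote_cfg)
        regions[sid] = regs
        p = out / f"consensus_{sid}.tsv"
        consensus.write_consensus_tsv(regs, p, sample_id=sid)
        emit(p)

    stage("mosaicism")
    for sid, sample in samples.items():
        flagged = qc_reports[sid].mosaic_flagged_chromosomes
        target = None if config.all_baf else flagged
        if target == []:
            ai_segments[sid] = []
        else:
            ai_segments[sid] = bafseg.segment_sample(sample, target, seg_cfg)
        p = out / f"ai_{sid}.tsv"
        bafseg.write_ai_tsv(ai_segments[sid], p, sample_id=sid)
        emit(p)

    # ---- trio stages ------------------------------------------------------
    inheritance: dict[str, dict] = {}
    trio_results: dict[str, dict] = {}
    if config.pedigree:
        stage("trio")
        for row in io.read_pedigree(config.pedigree):
            cid, fid, mid = row["sample_id"], row["father_id"], row["mother_id"]
            if not (fid and mid) or not {cid, fid, mid} <= set(samples):
                continue
            tr = trio_mod.Trio(child=samples[cid], father=samples[fid], mother=samples[mid])
            states = trio_mod.classify_all(tr)
            upd = trio_mod.detect_upd(tr, trio_cfg, consensus_regions=regions.get(cid), states=states)
            np_flag, np_table = trio_mod.detect_nonpaternity(tr, trio_cfg, states=states)
            tagged = trio_mod.annotate_inheritance(
                regions.get(cid, []), regions.get(fid, []), regions.get(mid, []), trio_cfg
            )
            tags = {}
            for region, tag in tagged:
                poo = ""
                if tag == "de_novo":
                    poo, _n = trio_mod.parent_of_origin(tr, region, trio_cfg)
                tags[(region.chromosome, region.start, region.end)] = (tag, poo)
            inheritance[cid] = tags
            trio_results[cid] = {"upd": upd, "nonpaternity": (np_flag, np_table)}

            p = out / f"upd_{cid}.tsv"
            with open(p, "wt") as fh:
                cols = ["chrom", "start", "end", "parent", "subtype",
                        "n_informative", "n_opposing", "p_value"]
                fh.write("\t".join(cols) + "\n")
                for e in upd:
                    r = e.as_row()
                    fh.write("\t".join(str(r[c]) for c in cols) + "\n")
            emit(p)
            p = out / f"nonpaternity_{cid}.json"
            p.write_text(json.dumps(
                {"flag": np_flag, "per_chromosome": np_table}, indent=2, sort_keys=True
            ) + "\n")
            emit(p)

    # ---- annotate + report ------------------------------------------------
    stage("annotate")
    for sid in sorted(set(samples) | set(regions)):
        regs = regions.get(sid, [])
        annotated = [ann.AnnotatedRegion(region=r) for r in regs]
        for track in tracks:
            annotated = ann.overlap_annotate(annotated, track)
        tags = inheritance.get(sid, {})
        for a in annotated:
            key = (a.region.chromosome, a.region.start, a.region.end)
            if key in tags:
                a.inheritance, a.parent_of_origin = tags[key]
            if cytobands is not None:
                try:
                    a.iscn = ann.iscn_string(a.region, cytobands, a.inheritance)
                except ValueError:
                    a.iscn = ""
        p = out / f"regions_{sid}.bed"
        ann.write_bed(annotated, p)
        emit(p)

        tres = trio_results.get(sid)
        report = ann.build_report(
            sid,
            qc_reports.get(sid),
            annotated,
            upd_events=tres["upd"] if tres else None,
            nonpaternity=tres["nonpaternity"] if tres else None,
        )
        report["ai_segments"] = [s.as_row(sid) for s in ai_segments.get(sid, [])]
        p = out / f"report_{sid}.json"
        p.write_text(ann.report_json(report) + "\n")
        emit(p)

    stage("manifest")
    manifest["artifacts"] = {p.name: _sha256(p) for p in sorted(set(artifacts))}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
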