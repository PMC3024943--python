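"""The full file-to-report pipeline on a synthetic trio.

Writes Final Report fixtures, emulated caller outputs, a pedigree and a
cytoband file to a temporary directory, runs every pipeline stage, and
prints the manifest plus the child's ISCN findings.
"""

import json
import tempfile
from pathlib import Path

from arraycnv import (
    CallerProfile, PlantedEvent, SimConfig, io, simulate_callsets, simulate_trio,
)
from arraycnv.pipeline import PipelineConfig, run_pipeline

work = Path(tempfile.mkdtemp(prefix="arraycnv_demo_"))
chroms = tuple((str(i + 1), 400) for i in range(22))

config = SimConfig(
    chromosomes=chroms, seed=7,
    events=(
        PlantedEvent("del", "3", 1_000_000, 1_400_000, parent="maternal"),
        PlantedEvent("upd_iso", "9", 100_000, 2_000_000, parent="paternal"),
    ),
)
trio, truth = simulate_trio(config)
gm = trio.genome_map

io.write_genome_map(gm, work / "map.tsv")
for member in (trio.child, trio.father, trio.mother):
    io.write_final_report(member, work / f"{member.sample_id}.txt")
(work / "ped.tsv").write_text(
    "family_id\tsample_id\tfather_id\tmother_id\tsex\n"
    "f1\tchild\tfather\tmother\tU\nf1\tfather\t0\t0\tM\nf1\tmother\t0\t0\tF\n"
)
profiles = [CallerProfile(m, boundary_jitter_probes=1)
            for m in ("QuantiSNP", "PennCNV", "VanillaICE")]
for cs in simulate_callsets(truth, gm, profiles, seed=11):
    io.write_callset(cs, work / f"calls_{cs.method}.tsv")
with open(work / "cytoband.txt", "wt") as fh:
    for chrom, n in chroms:
        length = n * 10_000
        fh.write(f"chr{chrom}\t0\t{length // 2}\tp11\tgneg\n")
        fh.write(f"chr{chrom}\t{length // 2}\t{length}\tq11\tgpos\n")

pipeline = PipelineConfig(
    genome_map=str(work / "map.tsv"),
    samples=[{"sample_id": s, "final_report": str(work / f"{s}.txt")}
             for s in ("child", "father", "mother")],
    callsets=[{"sample_id": "child", "method": m, "dialect": "generic",
               "path": str(work / f"calls_{m}.tsv")}
              for m in ("QuantiSNP", "PennCNV", "VanillaICE")],
    pedigree=str(work / "ped.tsv"),
    cytoband=str(work / "cytoband.txt"),
    out_dir=str(work / "run"),
)
manifest = run_pipeline(pipeline)
print("artifacts:", ", ".join(sorted(manifest["artifacts"])))

report = json.loads((work / "run" / "report_child.json").read_text())
print("child ISCN findings:")
for line in report["iscn"]:
    print("  " + line)
for event in report["upd_events"]:
    print(f"  UPD chr{event['chrom']}:{event['start']}-{event['end']} "
          f"{event['parent']} {event['subtype']}")
print(f"run directory: {work / 'run'}")
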