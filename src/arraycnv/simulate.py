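"""Seeded generator of probe-level SNP-array data with planted truth.

The generator works at haplotype level: every sample carries two B-allele
indicator haplotypes per probe, drawn under Hardy-Weinberg from a per-probe
B-allele frequency (Uniform(0.05, 0.95) by default, so opposite-homozygote
trio SNPs are common). Planted events modify the rendered signal through a
cellular-mixture dosage model: with a fraction p of cells carrying an event
of total copy number c, the effective copy number is

    n_eff = (1 - p) * 2 + p * c,

LRR is drawn as Normal(log2(n_eff / 2), lrr_sigma) (floored at -5 for
homozygous deletions) and BAF as Normal(b_dosage, baf_sigma) clipped to
[0, 1], where b_dosage is the B-allele fraction of the mixture. Genotype
calls are re-derived from the noiseless dosage with GenCall-like wide AB
cluster bounds (AA < 0.15, BB > 0.85), so a hemizygous probe reads as
homozygous and mosaic heterozygous probes stay AB-called up to roughly 80%
cell fraction.

Trios transmit recorded haplotypes (one per parent, chosen per chromosome;
no recombination), so Mendelian consistency holds by construction; UPD
events override transmission, and non-paternity swaps the generating father
for an unrelated sample while reporting the stated one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datamodel import AA, AB, BB, NC, CallSet, CnvCall, SampleData
from .genome import GenomeMap
from .trio import Trio

EVENT_KINDS = ("del", "dup", "mosaic_del", "mosaic_dup", "cnn_loh", "upd_iso", "upd_het")

#: total copies carried by affected cells, per event kind
_EVENT_CN = {"del": 1, "dup": 3, "mosaic_del": 1, "mosaic_dup": 3, "cnn_loh": 2}

# GenCall-like genotype cluster bounds on noiseless B dosage
_AB_LO, _AB_HI = 0.15, 0.85


@dataclass(frozen=True)
class PlantedEvent:
    """One planted aberration. ``cell_fraction`` is the carrier fraction p
    (1.0 for constitutional events); ``parent`` directs UPD events and the
    haplotype origin of de novo CNVs; ``hap`` picks the affected/duplicated
    homolog (None: drawn from the seed)."""

    kind: str
    chromosome: str
    start: int
    end: int
    cell_fraction: float = 1.0
    parent: str = "paternal"
    hap: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind: {self.kind!r}")
        if not 0 <= self.cell_fraction <= 1:
            raise ValueError("cell_fraction must be in [0, 1]")
        if self.kind in ("del", "dup") and self.cell_fraction != 1.0:
            raise ValueError(f"{self.kind} is constitutional; use mosaic_{self.kind}")
        if self.parent not in ("paternal", "maternal"):
            raise ValueError("parent must be paternal or maternal")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated sample or trio."""

    chromosomes: tuple[tuple[str, int], ...] = (("1", 5000), ("2", 5000))
    spacing: int = 10_000
    baf_sigma: float = 0.03
    lrr_sigma: float = 0.15
    nocall_rate: float = 0.005
    genotype_error_rate: float = 0.0
    allele_freq_range: tuple[float, float] = (0.05, 0.95)
    events: tuple[PlantedEvent, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("baf_sigma", "lrr_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("nocall_rate", "genotype_error_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class TruthEvent:
    kind: str
    chromosome: str
    start: int          # position of the first affected probe
    end: int            # position of the last affected probe
    first_probe: int    # global map index
    last_probe: int
    cell_fraction: float
    parent: str
    hap: int
    copy_number: int    # copies in carrier cells (2 for cnn_loh/UPD)


@dataclass
class TruthSet:
    sample_id: str
    events: list[TruthEvent] = field(default_factory=list)
    # per chromosome: which paternal/maternal haplotype index the child received
    transmission: dict[str, tuple[int, int]] | None = None
    genotype_errors: int = 0

    def events_of(self, *kinds: str) -> list[TruthEvent]:
        return [e for e in self.events if e.kind in kinds]


def make_genome_map(config: SimConfig) -> GenomeMap:
    """Evenly spaced all-SNP probe map for the configured chromosomes."""
    probes = []
    for chrom, n in config.chromosomes:
        for i in range(n):
            probes.append((f"rs_{chrom}_{i + 1}", chrom, (i + 1) * config.spacing, True))
    return GenomeMap.from_probes(probes)


def _allele_freqs(config: SimConfig, n: int) -> np.ndarray:
    lo, hi = config.allele_freq_range
    rng = np.random.default_rng((config.seed * 1_000_003 + 17) % 2**31)
    return rng.uniform(lo, hi, size=n)


def _draw_haplotypes(rng: np.random.Generator, freqs: np.ndarray) -> np.ndarray:
    return (rng.random((2, len(freqs))) < freqs).astype(np.int8)


def _resolve_events(
    config: SimConfig, gm: GenomeMap, rng: np.random.Generator
) -> list[TruthEvent]:
    events: list[TruthEvent] = []
    spans: list[tuple[int, int]] = []
    for ev in config.events:
        i0, i1 = gm.index_range(ev.chromosome, ev.start, ev.end)
        if i1 <= i0:
            raise ValueError(f"event {ev} covers no probes")
        for s0, s1 in spans:
            if i0 < s1 and s0 < i1:
                raise ValueError("planted events overlap")
        spans.append((i0, i1))
        hap = ev.hap if ev.hap is not None else int(rng.integers(0, 2))
        events.append(
            TruthEvent(
                kind=ev.kind,
                chromosome=ev.chromosome,
                start=int(gm.positions[i0]),
                end=int(gm.positions[i1 - 1]),
                first_probe=i0,
                last_probe=i1 - 1,
                cell_fraction=1.0 if ev.kind in ("upd_iso", "upd_het") else ev.cell_fraction,
                parent=ev.parent,
                hap=hap,
                copy_number=_EVENT_CN.get(ev.kind, 2),
            )
        )
    return events


def _render(
    sample_id: str,
    gm: GenomeMap,
    haps: np.ndarray,
    cnv_events: list[TruthEvent],
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[SampleData, int]:
    """Render noisy LRR/BAF/genotype from haplotypes plus planted CNV events."""
    n = len(gm)
    b_total = haps.sum(axis=0).astype(float)
    n_eff = np.full(n, 2.0)
    b_dosage = b_total / 2.0

    for ev in cnv_events:
        sl = slice(ev.first_probe, ev.last_probe + 1)
        p = ev.cell_fraction
        h_aff = haps[ev.hap, sl].astype(float)
        b = b_total[sl]
        if ev.kind in ("del", "mosaic_del"):
            b_event = b - h_aff
        elif ev.kind in ("dup", "mosaic_dup"):
            b_event = b + h_aff
        else:  # cnn_loh: affected hap lost, the other duplicated
            b_event = 2.0 * (b - haps[ev.hap, sl].astype(float))
        ne = (1 - p) * 2.0 + p * ev.copy_number
        n_eff[sl] = ne
        with np.errstate(invalid="ignore", divide="ignore"):
            b_dosage[sl] = np.where(
                ne > 0, ((1 - p) * b + p * b_event) / np.maximum(ne, 1e-12), 0.5
            )

    lrr_mean = np.where(n_eff > 0, np.log2(np.maximum(n_eff, 1e-12) / 2.0), -5.0)
    lrr_mean = np.maximum(lrr_mean, -5.0)
    lrr = lrr_mean + (rng.normal(0.0, config.lrr_sigma, n) if config.lrr_sigma else 0.0)
    baf = b_dosage + (rng.normal(0.0, config.baf_sigma, n) if config.baf_sigma else 0.0)
    baf = np.clip(baf, 0.0, 1.0)

    genotype = np.where(b_dosage < _AB_LO, AA, np.where(b_dosage > _AB_HI, BB, AB)).astype(np.int8)

    n_errors = 0
    if config.genotype_error_rate > 0:
        flip = rng.random(n) < config.genotype_error_rate
        n_errors = int(flip.sum())
        shift = rng.integers(1, 3, size=n)  # move to one of the two other calls
        genotype[flip] = ((genotype[flip] + shift[flip]) % 3).astype(np.int8)
    if config.nocall_rate > 0:
        genotype[rng.random(n) < config.nocall_rate] = NC

    sample = SampleData(
        sample_id=sample_id, genome_map=gm, genotype=genotype, baf=baf, lrr=lrr
    )
    return sample, n_errors


def simulate_sample(
    config: SimConfig, genome_map: GenomeMap | None = None, sample_id: str = "sim"
) -> tuple[SampleData, TruthSet]:
    """Simulate a single sample; UPD event kinds are rejected (trio-only)."""
    for ev in config.events:
        if ev.kind in ("upd_iso", "upd_het"):
            raise ValueError("UPD events require simulate_trio")
    gm = genome_map if genome_map is not None else make_genome_map(config)
    rng = np.random.default_rng(config.seed % 2**31)
    freqs = _allele_freqs(config, len(gm))
    haps = _draw_haplotypes(rng, freqs)
    events = _resolve_events(config, gm, rng)
    sample, n_err = _render(sample_id, gm, haps, events, config, rng)
    return sample, TruthSet(sample_id=sample_id, events=events, genotype_errors=n_err)


def simulate_trio(
    config: SimConfig,
    nonpaternity: bool = False,
    ids: tuple[str, str, str] = ("child", "father", "mother"),
) -> tuple[Trio, TruthSet]:
    """Simulate a father/mother/child trio with Mendelian transmission.

    Events in ``config.events`` apply to the child: ``upd_*`` kinds override
    transmission (iso: one chosen parental homolog duplicated; het: both
    homologs of that parent), every other kind is a de novo CNV rendered on
    the child only. With ``nonpaternity`` the child's paternal alleles come
    from an unrelated sample while the reported father is unchanged.
    """
    gm = make_genome_map(config)
    rng = np.random.default_rng(config.seed % 2**31)
    freqs = _allele_freqs(config, len(gm))

    father_haps = _draw_haplotypes(rng, freqs)
    mother_haps = _draw_haplotypes(rng, freqs)
    true_father_haps = _draw_haplotypes(rng, freqs) if nonpaternity else father_haps

    events = _resolve_events(config, gm, rng)

    transmission: dict[str, tuple[int, int]] = {}
    child_haps = np.zeros_like(father_haps)
    for chrom in gm.chromosomes:
        sl = gm.chrom_slice(chrom)
        tf, tm = int(rng.integers(0, 2)), int(rng.integers(0, 2))
        transmission[chrom] = (tf, tm)
        child_haps[0, sl] = true_father_haps[tf, sl]
        child_haps[1, sl] = mother_haps[tm, sl]

    for ev in events:
        if ev.kind not in ("upd_iso", "upd_het"):
            continue
        sl = slice(ev.first_probe, ev.last_probe + 1)
        source = father_haps if ev.parent == "paternal" else mother_haps
        if ev.kind == "upd_iso":
            child_haps[0, sl] = source[ev.hap, sl]
            child_haps[1, sl] = source[ev.hap, sl]
        else:
            child_haps[0, sl] = source[0, sl]
            child_haps[1, sl] = source[1, sl]

    # de novo CNVs hit the haplotype named by the event's parent field
    # (child hap 0 is the paternal allele, hap 1 the maternal one)
    cnv_events = [
        replace(e, hap=0 if e.parent == "paternal" else 1)
        for e in events
        if e.kind not in ("upd_iso", "upd_het")
    ]
    events = [e for e in events if e.kind in ("upd_iso", "upd_het")] + cnv_events
    child, err_c = _render(ids[0], gm, child_haps, cnv_events, config, rng)
    father, err_f = _render(ids[1], gm, father_haps, [], config, rng)
    mother, err_m = _render(ids[2], gm, mother_haps, [], config, rng)

    truth = TruthSet(
        sample_id=ids[0],
        events=events,
        transmission=transmission,
        genotype_errors=err_c + err_f + err_m,
    )
    return Trio(child=child, father=father, mother=mother), truth


@dataclass(frozen=True)
class CallerProfile:
    """Behaviour of one emulated CNV caller."""

    method: str
    sensitivity: float = 1.0
    fp_rate_per_genome: float = 0.0
    boundary_jitter_probes: int = 0
    confidence: float = 100.0


def simulate_callsets(
    truth: TruthSet,
    genome_map: GenomeMap,
    profiles: list[CallerProfile],
    seed: int = 0,
) -> list[CallSet]:
    """Emulate per-method callsets from planted CNV truth.

    Each true del/dup event is emitted per method with its sensitivity,
    endpoints jittered by up to +/- ``boundary_jitter_probes`` map probes;
    false calls (Poisson with the per-genome rate, 3-10 probes, random
    direction) land on event-free territory. Deterministic per seed.
    """
    rng = np.random.default_rng(seed % 2**31)
    n = len(genome_map)
    cnv_truth = truth.events_of("del", "dup", "mosaic_del", "mosaic_dup")
    occupied = np.zeros(n, dtype=bool)
    for ev in cnv_truth:
        occupied[ev.first_probe : ev.last_probe + 1] = True

    out: list[CallSet] = []
    for prof in profiles:
        calls: list[CnvCall] = []
        for ev in cnv_truth:
            if rng.random() >= prof.sensitivity:
                continue
            j = prof.boundary_jitter_probes
            i0 = ev.first_probe + int(rng.integers(-j, j + 1)) if j else ev.first_probe
            i1 = ev.last_probe + int(rng.integers(-j, j + 1)) if j else ev.last_probe
            sl = genome_map.chrom_slice(ev.chromosome)
            i0 = max(sl.start, min(i0, sl.stop - 1))
            i1 = max(i0, min(i1, sl.stop - 1))
            calls.append(
                CnvCall(
                    sample_id=truth.sample_id,
                    method=prof.method,
                    chromosome=ev.chromosome,
                    start=int(genome_map.positions[i0]),
                    end=int(genome_map.positions[i1]),
                    copy_number=1 if "del" in ev.kind else 3,
                    n_probes=i1 - i0 + 1,
                    confidence=prof.confidence,
                )
            )
        n_fp = int(rng.poisson(prof.fp_rate_per_genome))
        free = np.flatnonzero(~occupied)
        for _ in range(n_fp):
            if free.size < 12:
                break
            k = int(rng.integers(0, free.size))
            i0 = int(free[k])
            length = int(rng.integers(3, 11))
            chrom = str(genome_map.chroms[i0])
            sl = genome_map.chrom_slice(chrom)
            i1 = min(i0 + length - 1, sl.stop - 1)
            if occupied[i0 : i1 + 1].any():
                continue
            calls.append(
                CnvCall(
                    sample_id=truth.sample_id,
                    method=prof.method,
                    chromosome=chrom,
                    start=int(genome_map.positions[i0]),
                    end=int(genome_map.positions[i1]),
                    copy_number=int(rng.choice([1, 3])),
                    n_probes=i1 - i0 + 1,
                    confidence=prof.confidence,
                )
            )
        out.append(CallSet(method=prof.method, sample_id=truth.sample_id, calls=calls))
    return out
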