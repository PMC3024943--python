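"""Sample quality control and the mosaicism trigger.

A high-quality sample has call rate > 99.4%, autosomal LRR standard
deviation < 0.2, heterozygous-band BAF standard deviation < 0.6 and an
absolute genomic-wave factor < 0.03. Chromosome-specific BAF SD is screened
for robust outliers; flagged chromosomes are handed to the allelic-imbalance
segmentation stage as mosaicism candidates.

Sample-level BAF SD is computed over autosomal SNP probes whose BAF lies in
the heterozygous band [0.25, 0.75]: the raw BAF distribution is tri-modal,
so an unrestricted SD would be dominated by the homozygous clusters and the
pass threshold would lose its meaning. Sex chromosomes are excluded from
every statistic (hemizygous males would distort the SDs).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .datamodel import NC, SampleData
from .genome import AUTOSOMES

HET_BAND = (0.25, 0.75)

# scale factor making the median absolute deviation consistent with the SD
# of a normal distribution
MAD_TO_SD = 1.4826


@dataclass(frozen=True)
class QcThresholds:
    """Pass thresholds; comparisons are strict (metric must beat the bound)."""

    min_call_rate: float = 0.994
    max_lrr_sd: float = 0.2
    max_baf_sd: float = 0.6
    max_abs_wave: float = 0.03

    def __post_init__(self) -> None:
        if not 0 < self.min_call_rate <= 1:
            raise ValueError("min_call_rate must be in (0, 1]")
        for name in ("max_lrr_sd", "max_baf_sd", "max_abs_wave"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class QcReport:
    sample_id: str
    call_rate: float
    lrr_sd: float
    baf_sd: float
    wave_factor: float  # NaN when no GC track was supplied
    per_chromosome_baf_sd: dict[str, float]
    pass_flags: dict[str, bool]
    mosaic_flagged_chromosomes: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(self.pass_flags.values())

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "call_rate": self.call_rate,
            "lrr_sd": self.lrr_sd,
            "baf_sd": self.baf_sd,
            "wave_factor": self.wave_factor,
            "per_chromosome_baf_sd": dict(sorted(self.per_chromosome_baf_sd.items())),
            "pass_flags": dict(sorted(self.pass_flags.items())),
            "mosaic_flagged_chromosomes": list(self.mosaic_flagged_chromosomes),
            "passed": self.passed,
        }

    def to_json(self) -> str:
        def clean(o):
            if isinstance(o, float) and math.isnan(o):
                return None
            if isinstance(o, dict):
                return {k: clean(v) for k, v in o.items()}
            if isinstance(o, list):
                return [clean(v) for v in o]
            return o

        return json.dumps(clean(self.to_dict()), indent=2, sort_keys=False)

    def to_tsv(self) -> str:
        lines = [
            f"sample_id\t{self.sample_id}",
            f"call_rate\t{self.call_rate:.6f}",
            f"lrr_sd\t{self.lrr_sd:.6f}",
            f"baf_sd\t{self.baf_sd:.6f}",
            f"wave_factor\t{self.wave_factor:.6f}",
        ]
        for chrom, sd in sorted(self.per_chromosome_baf_sd.items(), key=_chrom_key):
            lines.append(f"baf_sd_chr{chrom}\t{sd:.6f}")
        for name, ok in sorted(self.pass_flags.items()):
            lines.append(f"pass_{name}\t{'yes' if ok else 'no'}")
        lines.append("mosaic_flagged\t" + ",".join(self.mosaic_flagged_chromosomes))
        return "\n".join(lines) + "\n"


def _chrom_key(item):
    c = item[0]
    return (0, int(c)) if c.isdigit() else (1, c)


def compute_qc(
    sample: SampleData,
    thresholds: QcThresholds = QcThresholds(),
    wave_factor: float = math.nan,
) -> QcReport:
    """Compute the QC metrics and pass flags for one sample.

    ``wave_factor`` comes from :func:`gc_wave_correct` when a GC track is
    available; NaN marks the wave criterion as not evaluated (flag passes,
    since no evidence of waving was measurable).
    """
    gm = sample.genome_map
    autosomal = np.isin(gm.chroms.astype(str), AUTOSOMES)
    snp = gm.is_snp & autosomal

    if snp.sum() == 0:
        raise ValueError("sample has no autosomal SNP probes")

    called = sample.genotype[snp] != NC
    call_rate = float(np.mean(called))

    lrr = sample.lrr[autosomal]
    lrr = lrr[np.isfinite(lrr)]
    lrr_sd = float(np.std(lrr, ddof=0)) if lrr.size else math.nan

    baf_sd = _het_band_baf_sd(sample.baf[snp])

    per_chrom: dict[str, float] = {}
    for chrom in gm.chromosomes:
        if chrom not in AUTOSOMES:
            continue
        sl = gm.chrom_slice(chrom)
        mask = gm.is_snp[sl]
        per_chrom[chrom] = _het_band_baf_sd(sample.baf[sl][mask])

    flags = {
        "call_rate": call_rate > thresholds.min_call_rate,
        "lrr_sd": (not math.isnan(lrr_sd)) and lrr_sd < thresholds.max_lrr_sd,
        "baf_sd": (not math.isnan(baf_sd)) and baf_sd < thresholds.max_baf_sd,
        "wave": math.isnan(wave_factor) or abs(wave_factor) < thresholds.max_abs_wave,
    }
    if call_rate == 0.0:
        flags["lrr_sd"] = flags["baf_sd"] = False

    return QcReport(
        sample_id=sample.sample_id,
        call_rate=call_rate,
        lrr_sd=lrr_sd,
        baf_sd=baf_sd,
        wave_factor=wave_factor,
        per_chromosome_baf_sd=per_chrom,
        pass_flags=flags,
    )


def _het_band_baf_sd(baf: np.ndarray) -> float:
    lo, hi = HET_BAND
    vals = baf[np.isfinite(baf)]
    vals = vals[(vals >= lo) & (vals <= hi)]
    return float(np.std(vals, ddof=0)) if vals.size else math.nan


def gc_wave_correct(
    sample: SampleData,
    gc_track: dict[str, list[tuple[int, int, float]]],
    window_size: int = 1_000_000,
) -> tuple[SampleData, float]:
    """Estimate and remove a linear GC-content wave from the LRR signal.

    Probe LRRs are binned into ``window_size`` windows; each window's median
    LRR is regressed linearly on the window's GC fraction (taken from the
    track interval covering the window midpoint). The slope is the wave
    factor; corrected LRR = LRR - (intercept + slope * GC). Probes in
    windows without GC coverage are left unadjusted.

    Returns a new SampleData plus the wave factor. Requires the track to
    cover at least half the probes' windows and at least two usable windows.
    """
    gm = sample.genome_map
    window_gc: list[float] = []
    window_median: list[float] = []
    probe_gc = np.full(len(gm), np.nan)
    n_windows = 0
    n_covered = 0

    for chrom in gm.chromosomes:
        sl = gm.chrom_slice(chrom)
        pos = gm.positions[sl]
        lrr = sample.lrr[sl]
        rows = gc_track.get(chrom, [])
        starts = np.array([r[0] for r in rows], dtype=np.int64)
        ends = np.array([r[1] for r in rows], dtype=np.int64)
        gcs = np.array([r[2] for r in rows])
        win_ids = (pos - 1) // window_size
        for wid in np.unique(win_ids):
            n_windows += 1
            mid = wid * window_size + window_size // 2 + 1
            gc = _lookup(starts, ends, gcs, mid)
            if gc is None:
                continue
            n_covered += 1
            in_win = win_ids == wid
            vals = lrr[in_win]
            vals = vals[np.isfinite(vals)]
            if vals.size:
                window_gc.append(gc)
                window_median.append(float(np.median(vals)))
            probe_gc[sl.start + np.flatnonzero(in_win)] = gc

    if n_windows and n_covered / n_windows < 0.5:
        raise ValueError("insufficient GC coverage: track covers <50% of probe windows")
    if len(window_gc) < 2:
        raise ValueError("insufficient GC coverage: fewer than 2 usable windows")

    x = np.array(window_gc)
    y = np.array(window_median)
    if np.ptp(x) == 0:  # degenerate regressor: no wave estimable
        slope, intercept = 0.0, 0.0
    else:
        slope, intercept = np.polyfit(x, y, 1)

    adjusted = sample.lrr.copy()
    have_gc = np.isfinite(probe_gc)
    adjusted[have_gc] = adjusted[have_gc] - (intercept + slope * probe_gc[have_gc])
    corrected = SampleData(
        sample_id=sample.sample_id,
        genome_map=gm,
        genotype=sample.genotype.copy(),
        baf=sample.baf.copy(),
        lrr=adjusted,
        gender=sample.gender,
    )
    return corrected, float(slope)


def _lookup(starts: np.ndarray, ends: np.ndarray, values: np.ndarray, pos: int) -> float | None:
    if starts.size == 0:
        return None
    i = int(np.searchsorted(starts, pos, side="right")) - 1
    if i < 0 or pos > ends[i]:
        return None
    return float(values[i])


def screen_mosaic_chromosomes(qc: QcReport, k_mad: float = 3.0) -> list[str]:
    """Flag chromosomes whose BAF SD is a robust outlier among autosomes.

    A chromosome is flagged when its heterozygous-band BAF SD exceeds
    median + k_mad * MAD (MAD scaled to SD-consistency) of the
    per-chromosome values. The flagged list is also stored on the report.
    Requires at least 5 autosomes with a computed SD.
    """
    items = [(c, sd) for c, sd in qc.per_chromosome_baf_sd.items() if not math.isnan(sd)]
    if len(items) < 5:
        raise ValueError("need per-chromosome BAF SD on >= 5 autosomes to screen for mosaicism")
    values = np.array([sd for _, sd in items])
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med))) * MAD_TO_SD
    cutoff = med + k_mad * mad
    flagged = [c for c, sd in items if sd > cutoff]
    flagged.sort(key=lambda c: (0, int(c)) if c.isdigit() else (1, c))
    qc.mosaic_flagged_chromosomes = flagged
    return flagged
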