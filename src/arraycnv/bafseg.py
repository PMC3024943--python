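"""Mirrored-BAF allelic-imbalance segmentation and mosaic-fraction estimation.

Heterozygous SNPs sit at BAF 0.5 in a pure diploid cell population. When a
fraction p of cells carries an aberration, the BAF of heterozygous probes
splits symmetrically around 0.5; folding to the mirrored BAF
``mBAF = max(BAF, 1 - BAF)`` turns the split into a single upward shift
whose magnitude encodes p:

* mosaic deletion:      E[mBAF] = 1 / (2 - p)
* mosaic duplication:   E[mBAF] = (1 + p) / (2 + p)
* copy-neutral LOH:     E[mBAF] = (1 + p) / 2

The segmentation stack is: homozygous-probe filtering with a triplet
protection rule (defaults 0.97 informative threshold, 0.8 triplet
threshold), change-point partition of the informative mBAF sequence, and
allelic-imbalance calling at mBAF >= 0.56 over >= 4 informative probes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .datamodel import AB, NC, SampleData


@dataclass(frozen=True)
class BafSegConfig:
    informative_threshold: float = 0.97
    triplet_threshold: float = 0.8
    ai_threshold: float = 0.56
    ai_size: int = 4
    lrr_del_max: float = -0.1
    lrr_dup_min: float = 0.05
    split_penalty_scale: float = 3.0  # multiplies the log(n) BIC penalty

    def __post_init__(self) -> None:
        if not 0.5 < self.ai_threshold < self.triplet_threshold < self.informative_threshold <= 1:
            raise ValueError(
                "thresholds must satisfy 0.5 < ai < triplet < informative <= 1"
            )
        if self.ai_size < 1:
            raise ValueError("ai_size must be >= 1")


@dataclass(frozen=True)
class AiSegment:
    """One called allelic-imbalance segment with its mosaic cell fraction."""

    chromosome: str
    start: int
    end: int
    n_informative: int
    mean_mbaf: float
    mean_lrr: float
    event_type: str  # mosaic_deletion | mosaic_duplication | cn_neutral_imbalance
    mosaic_fraction: float
    at_bound: bool = False

    def as_row(self, sample_id: str = "") -> dict:
        return {
            "sample": sample_id,
            "chrom": self.chromosome,
            "start": self.start,
            "end": self.end,
            "n_informative": self.n_informative,
            "mean_mbaf": round(self.mean_mbaf, 6),
            "mean_lrr": round(self.mean_lrr, 6),
            "event_type": self.event_type,
            "mosaic_fraction": round(self.mosaic_fraction, 6),
        }


def mirror_baf(baf):
    """Fold BAF onto [0.5, 1]: mBAF = max(baf, 1 - baf). Accepts scalars or arrays."""
    arr = np.asarray(baf, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("BAF values must lie in [0, 1]")
    out = np.maximum(arr, 1.0 - arr)
    return float(out) if np.isscalar(baf) or arr.ndim == 0 else out


def informative_filter(
    mbaf: np.ndarray,
    genotype: np.ndarray | None = None,
    config: BafSegConfig = BafSegConfig(),
) -> np.ndarray:
    """Boolean mask of probes kept as informative for segmentation.

    NC-genotype probes are dropped. Probes with mBAF above the informative
    threshold look homozygous and are dropped — unless the median mBAF of
    the centred triplet (the probe and its flanking surviving candidates)
    exceeds the triplet threshold, which protects dense stretches of true
    strong imbalance from being discarded as homozygous.
    """
    mbaf = np.asarray(mbaf, dtype=float)
    n = len(mbaf)
    keep = np.ones(n, dtype=bool)
    if genotype is not None:
        keep &= np.asarray(genotype) != NC
    keep &= np.isfinite(mbaf)

    candidates = np.flatnonzero(keep)
    vals = mbaf[candidates]
    final = np.zeros(n, dtype=bool)
    for k, i in enumerate(candidates):
        if vals[k] <= config.informative_threshold:
            final[i] = True
            continue
        lo = max(0, k - 1)
        hi = min(len(candidates), k + 2)
        if float(np.median(vals[lo:hi])) > config.triplet_threshold:
            final[i] = True
    return final


def segment_mbaf(
    mbaf: np.ndarray, config: BafSegConfig = BafSegConfig()
) -> list[tuple[int, int, float]]:
    """Change-point partition of an mBAF sequence.

    Recursive binary splitting minimising within-segment squared error; a
    split is accepted when it lowers the cost by more than a BIC-style
    penalty of ``split_penalty_scale * sigma^2 * log(n_total)`` per change
    point, with sigma estimated robustly from first differences. The
    default scale of 3 follows the stricter modified-BIC convention: a
    plain log(n) penalty accepts spurious splits of pure noise at the
    series lengths this package segments. Returns contiguous,
    exhaustive (start_idx, end_idx_inclusive, mean) segments in order.
    """
    y = np.asarray(mbaf, dtype=float)
    n = len(y)
    if n == 0:
        raise ValueError("need at least one informative probe to segment")
    if n == 1:
        return [(0, 0, float(y[0]))]

    # robust sigma from differences: MAD(diff) * 1.4826 estimates sqrt(2)*sigma
    diffs = np.diff(y)
    sigma = float(np.median(np.abs(diffs))) * 1.4826 / math.sqrt(2)
    sigma = max(sigma, 1e-6)  # floor guards degenerate (constant) series
    penalty = config.split_penalty_scale * sigma * sigma * math.log(n)

    cum = np.concatenate(([0.0], np.cumsum(y)))
    cum2 = np.concatenate(([0.0], np.cumsum(y * y)))

    def sse(i: int, j: int) -> float:  # [i, j) half-open
        s = cum[j] - cum[i]
        s2 = cum2[j] - cum2[i]
        return s2 - s * s / (j - i)

    boundaries: list[int] = []

    def split(i: int, j: int) -> None:
        if j - i < 2:
            return
        parent = sse(i, j)
        ks = np.arange(i + 1, j)
        left_n = ks - i
        right_n = j - ks
        left_s = cum[ks] - cum[i]
        right_s = cum[j] - cum[ks]
        cost = (
            (cum2[ks] - cum2[i]) - left_s**2 / left_n
            + (cum2[j] - cum2[ks]) - right_s**2 / right_n
        )
        k = int(ks[np.argmin(cost)])
        if parent - float(np.min(cost)) > penalty:
            boundaries.append(k)
            split(i, k)
            split(k, j)

    split(0, n)
    cuts = [0] + sorted(boundaries) + [n]
    return [
        (cuts[t], cuts[t + 1] - 1, float(np.mean(y[cuts[t]:cuts[t + 1]])))
        for t in range(len(cuts) - 1)
    ]


def expected_mbaf(p: float, event_type: str) -> float:
    """Expected heterozygous-SNP mBAF when a fraction p of cells carries the event."""
    if not 0 <= p <= 1:
        raise ValueError("cell fraction must be in [0, 1]")
    if event_type == "mosaic_deletion":
        return 1.0 / (2.0 - p)
    if event_type == "mosaic_duplication":
        return (1.0 + p) / (2.0 + p)
    if event_type == "cn_neutral_imbalance":
        return (1.0 + p) / 2.0
    raise ValueError(f"unknown event type: {event_type!r}")


def estimate_mosaic_fraction(mean_mbaf: float, event_type: str) -> tuple[float, bool]:
    """Invert the dosage formula: cell fraction p from a segment's mean mBAF.

    Returns (p clipped to [0, 1], at_bound flag). The duplication formula
    diverges as mBAF -> 1; such segments are capped at p = 1 and flagged.
    """
    m = float(mean_mbaf)
    if not 0.5 <= m <= 1.0:
        raise ValueError("mean mBAF must lie in [0.5, 1]")
    at_bound = False
    if event_type == "mosaic_deletion":
        p = 2.0 - 1.0 / m
    elif event_type == "mosaic_duplication":
        if m >= 1.0:
            return 1.0, True
        p = (2.0 * m - 1.0) / (1.0 - m)
    elif event_type == "cn_neutral_imbalance":
        p = 2.0 * m - 1.0
    else:
        raise ValueError(f"unknown event type: {event_type!r}")
    if p > 1.0:
        p, at_bound = 1.0, True
    if p < 0.0:
        p = 0.0
    return p, at_bound


def call_ai(
    segments: list[tuple[int, int, float]],
    positions: np.ndarray,
    lrr: np.ndarray,
    chromosome: str,
    config: BafSegConfig = BafSegConfig(),
) -> list[AiSegment]:
    """Promote qualifying segments to allelic-imbalance calls.

    A segment qualifies when mean mBAF >= ai_threshold and it spans at least
    ai_size informative probes. The event type comes from the segment's mean
    LRR (below ``lrr_del_max``: mosaic deletion; above ``lrr_dup_min``:
    mosaic duplication; between: copy-neutral imbalance), and the mosaic
    fraction from the matching dosage formula.

    ``positions`` and ``lrr`` are aligned to the informative (filtered)
    probe sequence the segments index into.
    """
    positions = np.asarray(positions)
    lrr = np.asarray(lrr, dtype=float)
    out: list[AiSegment] = []
    for i, j, mean_mbaf in segments:
        n_inf = j - i + 1
        if mean_mbaf < config.ai_threshold or n_inf < config.ai_size:
            continue
        seg_lrr = lrr[i : j + 1]
        seg_lrr = seg_lrr[np.isfinite(seg_lrr)]
        mean_lrr = float(np.mean(seg_lrr)) if seg_lrr.size else math.nan
        if not math.isnan(mean_lrr) and mean_lrr < config.lrr_del_max:
            event = "mosaic_deletion"
        elif not math.isnan(mean_lrr) and mean_lrr > config.lrr_dup_min:
            event = "mosaic_duplication"
        else:
            event = "cn_neutral_imbalance"
        frac, at_bound = estimate_mosaic_fraction(min(mean_mbaf, 1.0), event)
        out.append(
            AiSegment(
                chromosome=chromosome,
                start=int(positions[i]),
                end=int(positions[j]),
                n_informative=n_inf,
                mean_mbaf=float(mean_mbaf),
                mean_lrr=mean_lrr,
                event_type=event,
                mosaic_fraction=frac,
                at_bound=at_bound,
            )
        )
    return out


def segment_sample(
    sample: SampleData,
    chromosomes: list[str] | None = None,
    config: BafSegConfig = BafSegConfig(),
) -> list[AiSegment]:
    """Full allelic-imbalance pipeline on one sample.

    Runs mirror -> informative filter -> change-point segmentation -> AI
    calling per chromosome (all map chromosomes when ``chromosomes`` is
    None, e.g. under an --all flag; otherwise the QC-flagged subset).

    The series handed to the filter is restricted to heterozygous-called SNP
    probes: homozygous calls pin BAF to the 0/1 rails, where even modest
    noise leaks probes under the informative threshold and would contaminate
    segment means. The genotype call is treated as stronger evidence of
    homozygosity than the mBAF value itself.
    """
    gm = sample.genome_map
    targets = chromosomes if chromosomes is not None else gm.chromosomes
    out: list[AiSegment] = []
    for chrom in targets:
        sl = gm.chrom_slice(chrom)
        het = gm.is_snp[sl] & (sample.genotype[sl] == AB)
        baf = sample.baf[sl][het]
        ok = np.isfinite(baf)
        mbaf_all = np.full(len(baf), np.nan)
        mbaf_all[ok] = mirror_baf(baf[ok])
        keep = informative_filter(mbaf_all, None, config)
        if not keep.any():
            continue
        mbaf = mbaf_all[keep]
        positions = gm.positions[sl][het][keep]
        lrr = sample.lrr[sl][het][keep]
        segments = segment_mbaf(mbaf, config)
        out.extend(call_ai(segments, positions, lrr, chrom, config))
    return out


def estimate_region_fraction(
    sample: SampleData,
    chromosome: str,
    start: int,
    end: int,
    event_type: str,
    config: BafSegConfig = BafSegConfig(),
) -> tuple[float, int]:
    """Mosaic cell fraction of a known region, bypassing the AI-call gate.

    Runs the informative filter and change-point segmentation on the
    chromosome, picks the segment with the largest informative-probe overlap
    with [start, end], and inverts the dosage formula for the stated event
    type. Useful for quantifying events below the ai_threshold reporting
    cut-off (a 20% mosaic deletion sits at an expected mBAF of 0.556).

    Returns (fraction, n_informative_overlapping); (nan, 0) when no
    informative probes fall inside the region.
    """
    gm = sample.genome_map
    sl = gm.chrom_slice(chromosome)
    het = gm.is_snp[sl] & (sample.genotype[sl] == AB)
    baf = sample.baf[sl][het]
    ok = np.isfinite(baf)
    mbaf_all = np.full(len(baf), np.nan)
    mbaf_all[ok] = mirror_baf(baf[ok])
    keep = informative_filter(mbaf_all, None, config)
    if not keep.any():
        return math.nan, 0
    mbaf = mbaf_all[keep]
    positions = gm.positions[sl][het][keep]
    best = None
    for i, j, mean in segment_mbaf(mbaf, config):
        n_in = int(np.sum((positions[i : j + 1] >= start) & (positions[i : j + 1] <= end)))
        if n_in and (best is None or n_in > best[1]):
            best = (mean, n_in)
    if best is None:
        return math.nan, 0
    frac, _ = estimate_mosaic_fraction(min(best[0], 1.0), event_type)
    return frac, best[1]


def write_ai_tsv(segments: list[AiSegment], path_or_stream, sample_id: str = "") -> int:
    own = not hasattr(path_or_stream, "write")
    fh = open(path_or_stream, "wt") if own else path_or_stream
    try:
        cols = ["sample", "chrom", "start", "end", "n_informative",
                "mean_mbaf", "mean_lrr", "event_type", "mosaic_fraction"]
        fh.write("\t".join(cols) + "\n")
        for s in segments:
            row = s.as_row(sample_id)
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
        return len(segments)
    finally:
        if own:
            fh.close()
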