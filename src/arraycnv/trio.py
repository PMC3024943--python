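"""Trio genotype analytics: Mendelian-inconsistency classification, UPD
detection, non-paternity screening, CNV inheritance and parent of origin.

Every father/mother/child genotype triple is tested against seven
transmission models:

* biparental — one allele from each parent (normal inheritance);
* paternal/maternal isodisomy — one allele of that parent, doubled;
* paternal/maternal heterodisomy — both of that parent's homolog alleles;
* maternal-/paternal-deletion — the child is hemizygous and carries a
  single paternal/maternal allele (the array reads a hemizygous genotype
  as homozygous).

The per-SNP state records which directions remain possible once biparental
inheritance is excluded; runs of same-direction states reveal uniparental
disomy, while a genome-wide scatter of paternal-exclusion states indicates
non-paternity. The X chromosome is excluded throughout (hemizygous males
break the biallelic model).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from itertools import product

import numpy as np
from scipy import stats

from .consensus import ConsensusRegion
from .datamodel import AA, AB, BB, NC, SampleData
from .genome import AUTOSOMES, GenomeMap


class TrioState(Enum):
    CONSISTENT = "CONSISTENT"
    P_UPD_OR_MAT_DEL = "P_UPD_OR_MAT_DEL"
    M_UPD_OR_PAT_DEL = "M_UPD_OR_PAT_DEL"
    P_ISO_ONLY = "P_ISO_ONLY"
    M_ISO_ONLY = "M_ISO_ONLY"
    DOUBLE_INCONSISTENT = "DOUBLE_INCONSISTENT"
    UNINFORMATIVE_NC = "UNINFORMATIVE_NC"


#: states excluding the stated father (informative for maternal direction)
PATERNAL_EXCLUSION = (TrioState.M_UPD_OR_PAT_DEL, TrioState.M_ISO_ONLY)
MATERNAL_EXCLUSION = (TrioState.P_UPD_OR_MAT_DEL, TrioState.P_ISO_ONLY)


@dataclass(frozen=True)
class TrioConfig:
    min_run: int = 10
    max_opposing_fraction: float = 0.05
    nonpaternity_mi_rate: float = 0.02
    nonpaternity_min_chromosomes: int = 20
    poo_min_informative: int = 2
    poo_min_concordance: float = 0.9
    inheritance_reciprocal_overlap: float = 0.5
    iso_homozygosity: float = 0.98  # child-homozygous fraction defining isodisomy
    het_retention: float = 0.9      # AB retention at parent-AB SNPs defining heterodisomy
    lrr_del_max: float = -0.1       # runs with lower mean LRR are deletions, not UPD

    def __post_init__(self) -> None:
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        for name in ("max_opposing_fraction", "nonpaternity_mi_rate",
                     "poo_min_concordance", "inheritance_reciprocal_overlap",
                     "iso_homozygosity", "het_retention"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class Trio:
    child: SampleData
    father: SampleData
    mother: SampleData

    def __post_init__(self) -> None:
        if not (self.child.genome_map is self.father.genome_map is self.mother.genome_map):
            raise ValueError("trio members must share one genome map")
        ids = {self.child.sample_id, self.father.sample_id, self.mother.sample_id}
        if len(ids) != 3:
            raise ValueError("trio members must have distinct sample ids")

    @property
    def genome_map(self) -> GenomeMap:
        return self.child.genome_map


@dataclass(frozen=True)
class UpdEvent:
    chromosome: str
    start: int
    end: int
    parent: str  # 'paternal' or 'maternal'
    subtype: str  # 'isodisomy' | 'heterodisomy' | 'mixed'
    n_informative: int
    n_opposing: int
    p_value: float

    def as_row(self) -> dict:
        return {
            "chrom": self.chromosome, "start": self.start, "end": self.end,
            "parent": self.parent, "subtype": self.subtype,
            "n_informative": self.n_informative, "n_opposing": self.n_opposing,
            "p_value": f"{self.p_value:.3e}",
        }


# ---------------------------------------------------------------------------
# Per-SNP classification
# ---------------------------------------------------------------------------

_ALLELES = {AA: ("A", "A"), AB: ("A", "B"), BB: ("B", "B")}


def _model_fits(father: int, mother: int, child: int) -> dict[str, bool]:
    """Which transmission models can produce the observed child genotype."""
    f = _ALLELES[father]
    m = _ALLELES[mother]
    c = tuple(sorted(_ALLELES[child]))
    fits = {
        "biparental": any(tuple(sorted((a, b))) == c for a in f for b in m),
        "paternal_iso": any((a, a) == c for a in f),
        "paternal_het": tuple(sorted(f)) == c,
        "maternal_iso": any((a, a) == c for a in m),
        "maternal_het": tuple(sorted(m)) == c,
        # hemizygous child reads as homozygous: single allele doubled in the call
        "maternal_deletion": child in (AA, BB) and c[0] in f,
        "paternal_deletion": child in (AA, BB) and c[0] in m,
    }
    return fits


def classify_snp(father_gt: int, mother_gt: int, child_gt: int) -> TrioState:
    """Classify one genotype triple against the seven transmission models.

    Accepts genotype codes (AA=0, AB=1, BB=2, NC=-1) or token strings.
    """
    gts = []
    for g in (father_gt, mother_gt, child_gt):
        if isinstance(g, str):
            from .datamodel import genotype_code

            g = genotype_code(g)
        if g not in (AA, AB, BB, NC):
            raise ValueError(f"invalid genotype code: {g!r}")
        gts.append(int(g))
    f, m, c = gts
    if NC in gts:
        return TrioState.UNINFORMATIVE_NC
    fits = _model_fits(f, m, c)
    if fits["biparental"]:
        return TrioState.CONSISTENT
    pat = fits["paternal_iso"] or fits["paternal_het"] or fits["maternal_deletion"]
    mat = fits["maternal_iso"] or fits["maternal_het"] or fits["paternal_deletion"]
    if pat and not mat:
        if fits["paternal_het"]:
            return TrioState.P_UPD_OR_MAT_DEL
        return TrioState.P_ISO_ONLY if fits["paternal_iso"] else TrioState.P_UPD_OR_MAT_DEL
    if mat and not pat:
        if fits["maternal_het"]:
            return TrioState.M_UPD_OR_PAT_DEL
        return TrioState.M_ISO_ONLY if fits["maternal_iso"] else TrioState.M_UPD_OR_PAT_DEL
    if pat and mat:
        # both parental directions remain possible without biparental fit;
        # carries no directional information (does not occur for 3 genotypes,
        # kept for safety)
        return TrioState.DOUBLE_INCONSISTENT
    return TrioState.DOUBLE_INCONSISTENT


def classification_table() -> list[dict]:
    """All 27 non-NC genotype triples with state and consistent-model set."""
    rows = []
    from .datamodel import GENOTYPE_NAMES

    for f, m, c in product((AA, AB, BB), repeat=3):
        fits = _model_fits(f, m, c)
        rows.append(
            {
                "father": GENOTYPE_NAMES[f],
                "mother": GENOTYPE_NAMES[m],
                "child": GENOTYPE_NAMES[c],
                "state": classify_snp(f, m, c).value,
                "consistent_models": sorted(k for k, v in fits.items() if v),
            }
        )
    return rows


_STATE_CODES = {s: i for i, s in enumerate(TrioState)}


def classify_all(trio: Trio) -> np.ndarray:
    """Vectorised per-probe classification over autosomal SNP probes.

    Returns an int array aligned to the map holding TrioState indices;
    non-SNP and non-autosomal probes get UNINFORMATIVE_NC.
    """
    gm = trio.genome_map
    lut = np.empty((4, 4, 4), dtype=np.int8)
    for f in (NC, AA, AB, BB):
        for m in (NC, AA, AB, BB):
            for c in (NC, AA, AB, BB):
                lut[f + 1, m + 1, c + 1] = _STATE_CODES[classify_snp(f, m, c)]
    out = np.full(len(gm), _STATE_CODES[TrioState.UNINFORMATIVE_NC], dtype=np.int8)
    mask = gm.is_snp & np.isin(gm.chroms.astype(str), AUTOSOMES)
    out[mask] = lut[
        trio.father.genotype[mask] + 1,
        trio.mother.genotype[mask] + 1,
        trio.child.genotype[mask] + 1,
    ]
    return out


# ---------------------------------------------------------------------------
# UPD detection
# ---------------------------------------------------------------------------

def detect_upd(
    trio: Trio,
    config: TrioConfig = TrioConfig(),
    consensus_regions: list[ConsensusRegion] | None = None,
    states: np.ndarray | None = None,
) -> list[UpdEvent]:
    """Find runs of same-direction informative states indicating UPD.

    Per autosome, maximal runs holding at least ``min_run`` informative
    states of one parental direction with an opposing-state fraction at most
    ``max_opposing_fraction`` are collected. Runs overlapping a consensus
    deletion region and runs whose mean child LRR falls below ``lrr_del_max``
    are excluded (those are deletions masquerading as UPD). Subtype is
    decided at run level: isodisomy when the child is homozygous at >=
    ``iso_homozygosity`` of the run's called SNPs, heterodisomy when child
    heterozygosity is retained at SNPs where the transmitting parent is
    heterozygous (and the other parent is homozygous), else mixed.

    The p-value is the binomial tail probability of the observed informative
    count given the run length and the genome-wide per-SNP informative rate.
    """
    gm = trio.genome_map
    if states is None:
        states = classify_all(trio)

    pat_codes = [_STATE_CODES[s] for s in MATERNAL_EXCLUSION]  # P_* direction
    mat_codes = [_STATE_CODES[s] for s in PATERNAL_EXCLUSION]  # M_* direction
    dbl_code = _STATE_CODES[TrioState.DOUBLE_INCONSISTENT]
    nc_code = _STATE_CODES[TrioState.UNINFORMATIVE_NC]

    informative = np.isin(states, pat_codes + mat_codes)
    called = states != nc_code
    genome_rate = informative.sum() / max(1, called.sum())

    events: list[UpdEvent] = []
    for chrom in gm.chromosomes:
        if chrom not in AUTOSOMES:
            continue
        sl = gm.chrom_slice(chrom)
        st = states[sl]
        idx = np.flatnonzero(np.isin(st, pat_codes + mat_codes) | (st == dbl_code))
        if idx.size == 0:
            continue
        dir_of = np.where(np.isin(st[idx], pat_codes), 1,
                          np.where(np.isin(st[idx], mat_codes), -1, 0))
        for run_lo, run_hi, direction in _directional_runs(dir_of, config):
            members = idx[run_lo : run_hi + 1]
            n_dir = int(np.sum(dir_of[run_lo : run_hi + 1] == direction))
            n_opp = (run_hi - run_lo + 1) - n_dir
            if n_dir < config.min_run:
                continue
            if n_opp / (n_dir + n_opp) > config.max_opposing_fraction:
                continue
            i0, i1 = sl.start + members[0], sl.start + members[-1]
            start, end = int(gm.positions[i0]), int(gm.positions[i1])
            if _overlaps_deletion(consensus_regions, chrom, start, end):
                continue
            lrr = trio.child.lrr[i0 : i1 + 1]
            lrr = lrr[np.isfinite(lrr)]
            if lrr.size and float(np.mean(lrr)) < config.lrr_del_max:
                continue
            parent = "paternal" if direction == 1 else "maternal"
            subtype = _upd_subtype(trio, i0, i1, parent, config)
            run_len = int(np.sum(called[i0 : i1 + 1]))
            pval = float(stats.binom.sf(n_dir - 1, max(run_len, n_dir), min(genome_rate, 1.0)))
            events.append(
                UpdEvent(chrom, start, end, parent, subtype, n_dir, n_opp, pval)
            )
    return events


def _directional_runs(dir_of: np.ndarray, config: TrioConfig):
    """Greedy maximal runs of one direction over the informative sequence.

    Opposing or double-inconsistent entries are absorbed while the opposing
    fraction stays within budget; otherwise the run is closed.
    """
    runs = []
    n = len(dir_of)
    i = 0
    while i < n:
        d = dir_of[i]
        if d == 0:
            i += 1
            continue
        j = i
        n_dir = 1
        n_opp = 0
        last_good = i
        k = i + 1
        while k < n:
            if dir_of[k] == d:
                n_dir += 1
                last_good = k
            else:
                if (n_opp + 1) / (n_dir + n_opp + 1) > config.max_opposing_fraction:
                    break
                n_opp += 1
            k += 1
        j = last_good
        runs.append((i, j, int(d)))
        i = j + 1
    return runs


def _overlaps_deletion(
    regions: list[ConsensusRegion] | None, chrom: str, start: int, end: int
) -> bool:
    if not regions:
        return False
    return any(
        r.direction == "loss" and r.chromosome == chrom and r.start <= end and start <= r.end
        for r in regions
    )


def _upd_subtype(trio: Trio, i0: int, i1: int, parent: str, config: TrioConfig) -> str:
    child = trio.child.genotype[i0 : i1 + 1]
    transmitting = (trio.father if parent == "paternal" else trio.mother).genotype[i0 : i1 + 1]
    other = (trio.mother if parent == "paternal" else trio.father).genotype[i0 : i1 + 1]
    snp = trio.genome_map.is_snp[i0 : i1 + 1]

    called = snp & (child != NC)
    if called.sum() == 0:
        return "mixed"
    hom_frac = float(np.mean(np.isin(child[called], (AA, BB))))

    # SNPs where heterodisomy makes a testable prediction: transmitting
    # parent heterozygous (child should stay AB under heterodisomy)
    test = called & (transmitting == AB) & (other != NC)
    retention = float(np.mean(child[test] == AB)) if test.sum() else math.nan

    if hom_frac >= config.iso_homozygosity:
        return "isodisomy"
    if not math.isnan(retention) and retention >= config.het_retention:
        return "heterodisomy"
    return "mixed"


# ---------------------------------------------------------------------------
# Non-paternity
# ---------------------------------------------------------------------------

def detect_nonpaternity(
    trio: Trio,
    config: TrioConfig = TrioConfig(),
    states: np.ndarray | None = None,
) -> tuple[bool, dict[str, dict]]:
    """Genome-wide scatter of paternal-exclusion states across autosomes.

    Returns (flag, per-chromosome table). The flag is raised when the rate
    of paternal-exclusion states (M_UPD_OR_PAT_DEL, M_ISO_ONLY and
    DOUBLE_INCONSISTENT) among called SNPs exceeds ``nonpaternity_mi_rate``
    on at least ``nonpaternity_min_chromosomes`` autosomes — scatter across
    the genome distinguishes non-paternity from a segmental event.
    """
    gm = trio.genome_map
    if states is None:
        states = classify_all(trio)
    excl_codes = [_STATE_CODES[s] for s in PATERNAL_EXCLUSION] + [
        _STATE_CODES[TrioState.DOUBLE_INCONSISTENT]
    ]
    nc_code = _STATE_CODES[TrioState.UNINFORMATIVE_NC]

    table: dict[str, dict] = {}
    n_exceeding = 0
    for chrom in gm.chromosomes:
        if chrom not in AUTOSOMES:
            continue
        sl = gm.chrom_slice(chrom)
        st = states[sl]
        called = int(np.sum(st != nc_code))
        excl = int(np.sum(np.isin(st, excl_codes)))
        rate = excl / called if called else math.nan
        exceeded = called > 0 and rate > config.nonpaternity_mi_rate
        n_exceeding += exceeded
        table[chrom] = {
            "n_called": called,
            "n_paternal_exclusion": excl,
            "rate": rate,
            "exceeds": bool(exceeded),
        }
    flag = n_exceeding >= config.nonpaternity_min_chromosomes
    return flag, table


# ---------------------------------------------------------------------------
# Inheritance annotation and parent of origin
# ---------------------------------------------------------------------------

def reciprocal_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> float:
    """Smaller of the two mutual overlap fractions of two 1-based intervals."""
    ov = min(a_end, b_end) - max(a_start, b_start) + 1
    if ov <= 0:
        return 0.0
    return min(ov / (a_end - a_start + 1), ov / (b_end - b_start + 1))


def annotate_inheritance(
    child_regions: list[ConsensusRegion],
    father_regions: list[ConsensusRegion],
    mother_regions: list[ConsensusRegion],
    config: TrioConfig = TrioConfig(),
) -> list[tuple[ConsensusRegion, str]]:
    """Tag each child region paternal / maternal / both / de_novo.

    A region is inherited from a parent when a same-direction parental
    region achieves reciprocal overlap >= the configured threshold (both
    overlap fractions must reach it).
    """
    out = []
    for region in child_regions:
        pat = _inherited_from(region, father_regions, config)
        mat = _inherited_from(region, mother_regions, config)
        tag = "both" if (pat and mat) else "paternal" if pat else "maternal" if mat else "de_novo"
        out.append((region, tag))
    return out


def _inherited_from(
    region: ConsensusRegion, parental: list[ConsensusRegion], config: TrioConfig
) -> bool:
    return any(
        p.chromosome == region.chromosome
        and p.direction == region.direction
        and reciprocal_overlap(region.start, region.end, p.start, p.end)
        >= config.inheritance_reciprocal_overlap
        for p in parental
    )


_BAF_CLUSTERS = np.array([0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0])
_BAF_MARGIN = 0.08


def parent_of_origin(
    trio: Trio,
    region: ConsensusRegion,
    config: TrioConfig = TrioConfig(),
) -> tuple[str, int]:
    """Parent of origin of a de novo CNV from opposite-homozygote SNPs.

    Loss: at in-region SNPs where the parents are opposite homozygotes, the
    child's hemizygous call (read as homozygous) names the retained parent;
    the deleted homolog came from the other parent, which is the returned
    origin. Gain: the child's BAF is assigned to the nearest of the
    {0, 1/3, 2/3, 1} trisomic clusters (within a 0.08 margin); the
    duplicated allele's parent is the origin. Requires at least
    ``poo_min_informative`` informative SNPs agreeing with concordance >=
    ``poo_min_concordance``; otherwise ('undetermined', n_informative).
    """
    gm = trio.genome_map
    i0, i1 = gm.index_range(region.chromosome, region.start, region.end)
    if i1 <= i0:
        return "undetermined", 0
    sel = slice(i0, i1)
    snp = gm.is_snp[sel]
    f = trio.father.genotype[sel]
    m = trio.mother.genotype[sel]
    c = trio.child.genotype[sel]
    baf = trio.child.baf[sel]

    opposite = snp & (((f == AA) & (m == BB)) | ((f == BB) & (m == AA)))
    votes: list[str] = []
    for j in np.flatnonzero(opposite):
        if region.direction == "loss":
            if c[j] not in (AA, BB):
                continue
            retained = "paternal" if c[j] == f[j] else "maternal" if c[j] == m[j] else None
            if retained is None:
                continue
            votes.append("maternal" if retained == "paternal" else "paternal")
        else:
            b = baf[j]
            if not np.isfinite(b):
                continue
            k = int(np.argmin(np.abs(_BAF_CLUSTERS - b)))
            if abs(_BAF_CLUSTERS[k] - b) > _BAF_MARGIN or k in (0, 3):
                continue
            # k=1: one B of three copies; k=2: two B of three
            b_count = k  # 1 or 2
            # duplicated allele is the one present twice among the three
            dup_allele = "B" if b_count == 2 else "A"
            f_allele = "A" if f[j] == AA else "B"
            m_allele = "A" if m[j] == AA else "B"
            if dup_allele == f_allele and dup_allele != m_allele:
                votes.append("paternal")
            elif dup_allele == m_allele and dup_allele != f_allele:
                votes.append("maternal")

    n = len(votes)
    if n < config.poo_min_informative:
        return "undetermined", n
    n_pat = votes.count("paternal")
    top, frac = ("paternal", n_pat / n) if n_pat >= n - n_pat else ("maternal", (n - n_pat) / n)
    if frac < config.poo_min_concordance:
        return "undetermined", n
    return top, n


def state_track_rows(trio: Trio, states: np.ndarray | None = None) -> list[tuple]:
    """Per-SNP state track as BED-compatible rows (chrom, start0, end, state)."""
    gm = trio.genome_map
    if states is None:
        states = classify_all(trio)
    names = list(TrioState)
    rows = []
    for i in range(len(gm)):
        state = names[states[i]]
        if state is TrioState.UNINFORMATIVE_NC:
            continue
        pos = int(gm.positions[i])
        rows.append((f"chr{gm.chroms[i]}", pos - 1, pos, state.value))
    return rows
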