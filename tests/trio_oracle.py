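"""Independent brute-force transmission-model enumerator for trio triples.

Deliberately written in terms of explicit allele multisets, with no code
shared with arraycnv.trio, so it can serve as the oracle the package
implementation is verified against.
"""

from itertools import product

ALLELES = {"AA": ("A", "A"), "AB": ("A", "B"), "BB": ("B", "B")}


def observed_genotype(alleles: tuple[str, ...]) -> str:
    """Genotype call the array would report for a child allele multiset;
    a single (hemizygous) allele reads as homozygous."""
    s = sorted(alleles)
    if len(s) == 1:
        s = s * 2
    return "".join(s)


def enumerate_models(father: str, mother: str, child: str) -> set[str]:
    """All transmission models able to produce the observed child genotype."""
    f, m = ALLELES[father], ALLELES[mother]
    fits = set()
    for a, b in product(f, m):
        if observed_genotype((a, b)) == child:
            fits.add("biparental")
    for a in f:
        if observed_genotype((a, a)) == child:
            fits.add("paternal_iso")
    if observed_genotype(f) == child:
        fits.add("paternal_het")
    for a in m:
        if observed_genotype((a, a)) == child:
            fits.add("maternal_iso")
    if observed_genotype(m) == child:
        fits.add("maternal_het")
    for a in f:  # maternal homolog deleted: child carries one paternal allele
        if observed_genotype((a,)) == child:
            fits.add("maternal_deletion")
    for a in m:
        if observed_genotype((a,)) == child:
            fits.add("paternal_deletion")
    return fits


def oracle_state(father: str, mother: str, child: str) -> str:
    """State name derived purely from the enumerated model set."""
    fits = enumerate_models(father, mother, child)
    if "biparental" in fits:
        return "CONSISTENT"
    pat = fits & {"paternal_iso", "paternal_het", "maternal_deletion"}
    mat = fits & {"maternal_iso", "maternal_het", "paternal_deletion"}
    if pat and not mat:
        return "P_UPD_OR_MAT_DEL" if "paternal_het" in fits else "P_ISO_ONLY"
    if mat and not pat:
        return "M_UPD_OR_PAT_DEL" if "maternal_het" in fits else "M_ISO_ONLY"
    return "DOUBLE_INCONSISTENT"
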