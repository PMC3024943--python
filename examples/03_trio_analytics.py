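"""Trio genotype analytics: UPD detection, non-paternity screening and
parent of origin of a de novo deletion.

Simulates a father/mother/child trio in which the child carries a paternal
isodisomy on chromosome 9 and a de novo deletion of the maternal homolog on
chromosome 3, then recovers both findings from genotypes alone.
"""

from arraycnv import (
    ConsensusRegion, PlantedEvent, SimConfig, classify_snp,
    detect_nonpaternity, detect_upd, parent_of_origin, simulate_trio,
)

# Per-SNP classification of genotype triples (father, mother, child):
print("classify_snp examples:")
for triple in (("AA", "BB", "AB"), ("AA", "BB", "AA"), ("AB", "AA", "BB")):
    print(f"  {triple} -> {classify_snp(*triple).value}")
# An AA x BB cross must give AB; a child AA here needs two paternal alleles
# (paternal UPD) or a deleted maternal homolog.

config = SimConfig(
    chromosomes=tuple((str(i + 1), 400) for i in range(22)),
    events=(
        PlantedEvent("upd_iso", "9", 100_000, 2_000_000, parent="paternal"),
        PlantedEvent("del", "3", 1_000_000, 1_400_000, parent="maternal"),
    ),
    seed=7,
)
trio, truth = simulate_trio(config)

for event in detect_upd(trio):
    print(f"UPD: chr{event.chromosome}:{event.start}-{event.end} "
          f"{event.parent} {event.subtype} "
          f"(n={event.n_informative}, p={event.p_value:.2e})")
# Runs of maternal-exclusion states with a homozygous child reveal the
# paternal isodisomy; the binomial p-value scores the run against the
# genome-wide background state rate.

flag, _table = detect_nonpaternity(trio)
print(f"non-paternity flag: {flag}")

deletion = truth.events_of("del")[0]
region = ConsensusRegion("3", deletion.start, deletion.end, "loss", 1,
                         frozenset({"QuantiSNP", "PennCNV"}), "majority", 40)
origin, n_informative = parent_of_origin(trio, region)
print(f"de novo deletion chr3: origin={origin} ({n_informative} informative SNPs)")
# At SNPs where the parents are opposite homozygotes, the child's remaining
# (hemizygous) allele names the retained parent - the deleted homolog came
# from the other one.
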