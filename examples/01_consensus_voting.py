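"""Majority-vote consensus over three callers' CNV calls.

Builds a 10-probe chromosome and three small callsets, then shows how the
vote keeps only regions two callers agree on, delineated to the commonly
supported probes, and how the asymmetric option trusts one caller's
duplications.
"""

from arraycnv import CallSet, CnvCall, GenomeMap, VoteConfig, vote_consensus

# probes at chr1:100..1000, every 100 bp
gm = GenomeMap.from_probes([(f"p{i}", "1", 100 * (i + 1), True) for i in range(10)])


def call(method, start, end, cn):
    return CnvCall(sample_id="s1", method=method, chromosome="1",
                   start=start, end=end, copy_number=cn, confidence=50)


callsets = [
    CallSet("QuantiSNP", "s1", [call("QuantiSNP", 100, 500, 1)]),
    CallSet("PennCNV", "s1", [call("PennCNV", 300, 800, 1),
                              call("PennCNV", 900, 1000, 3)]),
    CallSet("VanillaICE", "s1", []),
]

print("Symmetric 2-of-3 vote:")
for r in vote_consensus(callsets, gm):
    print(f"  {r.chromosome}:{r.start}-{r.end} {r.direction} cn={r.copy_number} "
          f"({r.n_probes} probes, methods={sorted(r.supporting_methods)})")
# Only chr1:300-500 survives: the loss seen by two methods, trimmed to the
# probes both cover. PennCNV's lone 2-probe duplication is discarded twice
# over (single caller, and below the 3-probe floor).

print("Asymmetric vote trusting PennCNV duplications (4-probe gain):")
callsets[1] = CallSet("PennCNV", "s1", [call("PennCNV", 300, 600, 1),
                                        call("PennCNV", 700, 1000, 3)])
for r in vote_consensus(callsets, gm, VoteConfig(trusted_dup_method="PennCNV")):
    print(f"  {r.chromosome}:{r.start}-{r.end} {r.direction} cn={r.copy_number} "
          f"vote_mode={r.vote_mode}")
# The gain now stands on PennCNV's word alone (vote_mode=trusted_dup);
# losses still need a second caller.
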