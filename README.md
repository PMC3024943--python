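# arraycnv

Consensus CNV calling, mosaicism quantification and trio genetics for
SNP-array data.

Clinical SNP arrays report two signals per probe: the log R ratio (LRR, a
log2 proxy for total copy number) and the B-allele frequency (BAF, the
relative signal of one allele, near 0 / 0.5 / 1 for AA / AB / BB genotypes
in a diploid cell). `arraycnv` turns per-sample probe data plus the outputs
of several HMM-based CNV callers into an annotated, reportable set of
findings, the way a diagnostic array lab works:

* **Consensus calling** — copy-number calls from QuantiSNP-, PennCNV- and
  generic tab-separated callsets are combined by a per-probe majority vote:
  a probe supports a loss (or gain) when ≥ 2 of 3 methods call that
  direction over it, regions are maximal runs of ≥ 3 consecutive consensus
  probes delineated to the commonly supported probes, and calls seen by one
  method only are discarded as method-specific artefacts. An asymmetric
  option lets one trusted method's duplication calls stand alone.
* **QC and mosaicism trigger** — samples pass when call rate > 99.4%,
  LRR SD < 0.2, heterozygous-band BAF SD < 0.6 and |genomic wave| < 0.03
  (wave = slope of per-window median LRR regressed on GC content, removed
  by linear correction). Per-chromosome BAF SD is screened for
  median + 3·MAD outliers; flagged chromosomes go to mosaic analysis.
* **Mirrored-BAF segmentation** — heterozygous-SNP BAF folded to
  mBAF = max(BAF, 1−BAF) is filtered (informative threshold 0.97 with a
  triplet protection rule at 0.8), partitioned by binary change-point
  splitting, and segments with mBAF ≥ 0.56 over ≥ 4 informative probes are
  called as allelic imbalance. The mosaic cell fraction p follows from
  dosage algebra: mBAF = 1/(2−p) for a deletion, (1+p)/(2+p) for a
  duplication, (1+p)/2 for copy-neutral LOH.
* **Trio genetics** — every father/mother/child genotype triple is
  classified against seven transmission models (biparental, iso-/hetero-UPD
  per parent, hemizygous deletion per parent). Runs of same-direction
  informative states reveal uniparental disomy with iso/hetero subtyping and
  a binomial run p-value; genome-wide scatter of paternal-exclusion states
  flags non-paternity; reciprocal-overlap comparison with parental callsets
  tags CNVs inherited/de novo; opposite-homozygote SNPs resolve the parental
  origin of de novo events.
* **Annotation and reporting** — control-variant frequency and gene content
  from BED tracks, ISCN-style naming from a cytoband file (e.g.
  `arr 15q11.2(22,765,628-23,217,514)x1 dn`), BED/TSV/JSON export, and a
  deterministic per-sample report.
* **Synthetic data** — a seeded haplotype-level simulator plants CNVs,
  mosaic events, UPD regions, trio transmission and non-paternity with
  exact truth records, so the whole stack is testable without array data.

## Worked example

`examples/02_qc_and_mosaicism.py` simulates a 22-chromosome sample carrying
a 40% mosaic deletion on chromosome 7 and runs QC, the trigger and the
quantification:

```
call rate   0.9950  (pass: >0.994)
LRR SD      0.162   (pass: <0.2)
BAF SD      0.041   (pass: <0.6, heterozygous band)
QC passed:  True
mosaicism-flagged chromosomes: ['7']
  chr7:100000-3000000  mosaic_deletion  mBAF=0.626  cell fraction=0.40
```

The sample passes global QC (the event is far too small to move genome-wide
statistics), but chromosome 7's heterozygous-band BAF SD is a > 3·MAD
outlier against the other autosomes, so it alone is segmented: the mirrored
BAF of the planted region sits at 0.626, and inverting mBAF = 1/(2−p) gives
back the planted 40% cell fraction. The other examples cover consensus
voting (`01`), trio analytics — UPD, non-paternity, parent of origin
(`03`), and the full file-to-report pipeline with manifest (`04`).

## Command line

```sh
arraycnv simulate --seed 3 --out fixtures/ --trio \
    --event upd_iso:9:100000-2000000:1:paternal
arraycnv qc fixtures/child.txt --genome-map fixtures/genome_map.tsv
arraycnv consensus --genome-map map.tsv --quantisnp q.tsv --penncnv p.rawcnv
arraycnv bafseg sample.txt --genome-map map.tsv --all
arraycnv run --config pipeline.yaml      # parse → QC → consensus → trio → report
```

`arraycnv run` executes every stage into a run directory whose
`manifest.json` lists each artifact with its SHA-256 hash; identical inputs
and seed reproduce the run bit for bit.

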