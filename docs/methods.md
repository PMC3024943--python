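# Methods

This note records the models behind each analysis stage, the defaults and
why they hold, and the choices made where the design was genuinely open.

## Data model and conventions

Coordinates are 1-based inclusive everywhere inside the package and in its
TSV dialects; conversion to 0-based half-open happens only when BED files
are written or read. Chromosome names are normalised to the unprefixed set
1..22, X, Y ("chr" stripped on input, added on BED output). Genotypes are
biallelic A/B calls (AA/AB/BB/NC); two-letter allele columns map onto A/B,
with unresolvable rows becoming NC. Caller confidence thresholds — log
Bayes factor ≥ 8.5 for QuantiSNP-style tables, confidence ≥ 10 for PennCNV
rawcnv lines — are **inclusive**: a call exactly at the threshold is
retained. Overlapping same-direction calls within one method's set are
merged (min start, max end, copy number of the highest-confidence member)
so each per-method set is interval-disjoint before voting.

## Consensus vote

The vote is formalised per probe, which makes "retained only when seen by
more than one method" exact and testable. Each method assigns a direction
(loss if cn < 2, gain if cn > 2) to every map probe its calls cover. A
probe is a consensus probe for a direction when at least `min_methods`
(default 2) methods assign it; with `trusted_dup_method` set, a probe that
method calls gain qualifies on its own. Agreement is on direction, not
exact copy number, because callers differ in cn granularity; the region's
reported copy number is the coverage-weighted mode over supporting calls,
ties resolved toward the value closest to 2, then the smaller.

**Conflict rule.** A probe where both directions are present across
methods (e.g. one caller's loss under another's gain) is treated as
conflicting evidence and counts for *neither* direction, including for the
trusted-duplication route. Regions are maximal runs of map-consecutive
same-direction consensus probes, kept at `min_probes` ≥ 3, and delineated
by the first and last probe positions of the run (conservative
delineation). Runs break at chromosome boundaries; intervening
non-consensus probes break runs (a strict consecutive-probes reading —
adjacent runs separated by a single failed probe are not merged). A
trusted-duplication region additionally supported by a second method is
upgraded to an ordinary majority region.

Two independent routes compute the same semantics: the production
implementation uses interval arithmetic over probe-index coverage arrays,
and `probe_vote_table` tabulates the per-probe votes explicitly; their
equality on randomised callsets is a standing test.

## Quality control

* call rate = fraction of autosomal SNP probes with a genotype call;
* LRR SD over finite autosomal LRR values;
* BAF SD over autosomal SNP probes whose BAF lies in the heterozygous band
  [0.25, 0.75]. The restriction is deliberate: raw BAF is tri-modal, and an
  unrestricted SD is dominated by the homozygous rails, which would make a
  0.6 pass threshold meaningless. This statistic will not numerically match
  a caller's internal BAF-drift metric; the threshold semantics (flag
  clearly aberrant samples) are preserved.
* Sex chromosomes are excluded from all QC statistics — hemizygous male
  data would distort both SDs.
* Pass comparisons are strict: call rate > 0.994, LRR SD < 0.2,
  BAF SD < 0.6, |wave| < 0.03.

**Genomic wave.** Per-chromosome probes are binned into 1 Mb windows; each
window's median LRR is regressed linearly on the window's GC fraction
(track interval covering the window midpoint). The slope is the wave
factor, and corrected LRR = LRR − (intercept + slope·GC). This single
linear regression is a simplification of full wave-adjustment methods,
adequate for the QC statistic it feeds; window size is configurable, a
degenerate (constant-GC) regressor yields slope 0, and correction is
idempotent. Probes without GC coverage are left unadjusted; under 50%
window coverage or fewer than two usable windows is an error.

**Mosaicism trigger.** "Significant outlier" is made precise as a robust
rule: a chromosome is flagged when its heterozygous-band BAF SD exceeds
median + k·MAD (k = 3, MAD scaled by 1.4826 for SD consistency) of the
per-chromosome values, requiring at least 5 autosomes. The rule is
scale-invariant. In borderline noise configurations a second chromosome can
sit just past 3 MAD; the screen is a trigger for segmentation, not a
caller, so over-flagging costs only compute.

## Mirrored-BAF segmentation and mosaic fraction

With a fraction p of cells carrying an event, heterozygous-SNP mBAF
(= max(BAF, 1−BAF)) has expectation 1/(2−p) for a deletion, (1+p)/(2+p)
for a duplication, and (1+p)/2 for copy-neutral LOH; inverting these gives
the cell-fraction estimator, clipped to [0, 1] (a duplication segment at
mBAF = 1 caps at p = 1 and is flagged at-bound). The estimators are exact
inverses of the forward formulas and monotone in mBAF.

**Informative filter.** Probes with mBAF above the informative threshold
(0.97) look homozygous and are removed, except when the median of the
centred triplet (the probe and its flanking candidates) exceeds the triplet
threshold (0.8), which protects dense stretches of strong true imbalance;
NC probes are always removed. On whole samples the series is additionally
restricted to heterozygous-*called* SNP probes before filtering: a
homozygous genotype call pins BAF to the 0/1 rails, where even modest noise
leaks probes under the 0.97 threshold at mBAF ≈ 0.95 and would contaminate
segment means (and hence fraction estimates) upward. The genotype call is
treated as stronger evidence of homozygosity than the mBAF value itself;
fraction estimation therefore uses heterozygous-informative probes only.
The flip side is a blind spot: events whose heterozygous dosage leaves the
AB calling band — copy-neutral LOH above roughly 85% cell fraction, and
constitutional deletions (which the CNV pipeline handles instead) — carry
no AB-called probes and are invisible to this stage.

**Change-point engine.** Recursive binary splitting minimises
within-segment squared error; a split is accepted when it reduces the cost
by more than `scale · σ̂² · log(n)`, with σ̂ estimated robustly from first
differences (MAD·1.4826/√2, floored at 1e-6 for degenerate series). The
default scale is 3 — the modified-BIC convention — because a plain log(n)
penalty empirically accepts spurious splits of pure noise at the series
lengths segmented here (~10²–10³ probes); planted shifts of interest exceed
the penalty by orders of magnitude either way. Segments are contiguous,
exhaustive and ordered; each segment's mean is the arithmetic mean of its
members.

**Calling.** A segment is reported as allelic imbalance when its mean mBAF
≥ 0.56 over ≥ 4 informative probes. Event type comes from mean LRR over
the segment: < −0.1 mosaic deletion, > +0.05 mosaic duplication, else
copy-neutral imbalance (cut-offs configurable; this typing-by-LRR is a
pragmatic addition so segments are interpretable stand-alone). Note the
0.56 reporting threshold implies a detection floor near p ≈ 0.21 for
deletions; `estimate_region_fraction` quantifies a *known* region from the
ungated segmentation, below that floor.

## Trio genetics

`classify_snp` enumerates seven transmission models for each non-NC triple:
biparental; paternal/maternal isodisomy (one parental allele doubled);
paternal/maternal heterodisomy (both of that parent's alleles);
maternal-/paternal-deletion (hemizygous child carrying a single
paternal/maternal allele — the array reads hemizygous genotypes as
homozygous, a stated modelling assumption). The state is CONSISTENT when
biparental transmission fits; otherwise the direction whose models fit is
reported, refined to *_ISO_ONLY when heterodisomy is excluded but isodisomy
fits; DOUBLE_INCONSISTENT when nothing fits. The implementation is verified
triple-by-triple against an independent allele-multiset enumerator and is
parent-swap symmetric. The X chromosome is excluded from all trio analytics
(hemizygous males break the biallelic model).

**UPD detection** collects, per autosome, maximal runs of directional
informative states (greedy extension absorbing opposing states while their
fraction stays ≤ 5%), requiring ≥ 10 informative states (`min_run`). Runs
overlapping a consensus deletion, or whose mean child LRR < −0.1, are
rejected as deletions masquerading as UPD. Subtype is a run-level decision
— single SNPs cannot separate iso from hetero when the transmitting parent
is homozygous: isodisomy when the child is homozygous at ≥ 98% of the
run's called SNPs, heterodisomy when child heterozygosity is retained
(≥ 90%) at SNPs where the transmitting parent is AB, else mixed. The run
p-value is the binomial tail of the informative count given the run length
and the genome-wide per-SNP informative rate. Run length, opposing
fraction, and both subtype cut-offs are configuration, chosen for dense
modern arrays and adjustable for sparser ones.

**Non-paternity** is a scatter statistic, not a run statistic: the flag
raises when paternal-exclusion states (M_UPD_OR_PAT_DEL, M_ISO_ONLY,
DOUBLE_INCONSISTENT) exceed 2% of called SNPs on ≥ 20 autosomes. A true
alternate father produces exclusion rates several-fold above 2% on every
autosome, while genotyping error (~0.2%) and segmental events (localised)
stay below or fail the chromosome-count rule. Both the flag and the
per-chromosome table are emitted, leaving borderline cases to human review.

**Inheritance and parent of origin.** A child region is inherited from a
parent when a same-direction parental region reaches reciprocal overlap
≥ 0.5 (both fractions); both parents → "both", neither → de novo. For de
novo losses, SNPs where the parents are opposite homozygotes are
informative: the child's remaining (hemizygous, read as homozygous) allele
names the retained parent, and the *other* parent is the origin. For gains,
the child BAF at such SNPs is assigned to the nearest of the trisomic
clusters {0, 1/3, 2/3, 1} within a 0.08 margin; the allele present twice
names the duplicated homolog's parent. A verdict needs ≥ 2 informative
SNPs at ≥ 90% concordance, else "undetermined" — under noise the method is
designed to abstain rather than mis-assign.

## Synthetic data

The generator is haplotype-level: two B-allele indicator haplotypes per
probe, drawn under Hardy–Weinberg from per-probe B-allele frequencies
~ Uniform(0.05, 0.95) (chosen so opposite-homozygote trio SNPs are common,
~6% of SNPs). Planted events act through a cellular mixture: with carrier
fraction p and event copy number c, n_eff = (1−p)·2 + p·c,
LRR ~ Normal(log2(n_eff/2), σ_LRR) (mean floored at −5 for homozygous
deletions) and BAF ~ Normal(b_dosage, σ_BAF) clipped to [0, 1]. The
analytic log2 dosage mean is preferred over platform-calibrated cluster
values for transparency. Defaults: σ_BAF = 0.03, σ_LRR = 0.15, no-call
rate 0.5%, genotype error 0, genome of evenly spaced all-SNP probes at
10 kb spacing (a ~300K-array density); chromosome count and size vary per
study (2 × 5,000 probes for single-chromosome questions, 22 small
autosomes where chromosome-count rules are exercised) and are stated with
each analysis.

Genotype calls are re-derived from the *noiseless* dosage with wide
GenCall-like AB bounds: AA below 0.15, BB above 0.85, AB between. Real
arrays call trisomic heterozygotes (BAF 1/3, 2/3) as AB, and these bounds
keep mosaic-region heterozygotes AB-called up to ~80% deletion fraction,
while p = 1 deletions and LOH collapse to homozygous calls (hemizygous →
homozygous). Trios transmit one recorded haplotype per parent per
chromosome (no recombination, no LD — irrelevant to the per-SNP and
run-level statistics tested); UPD events override transmission; de novo
CNVs hit the haplotype of the event's named parent; non-paternity swaps
the generating father while reporting the stated one.

What the generator does *not* emulate — cluster-compressed rail noise,
probe-specific variance, LD, genomic waves beyond a linear GC term, plate
effects — bounds what passing tests show: they validate the algorithms
under the stated noise model, not platform-specific calibration. In
particular the Gaussian BAF noise at the homozygous rails is harsher than
real rail noise, which is why the heterozygous-call restriction above
exists.

## Reporting

Control-variant frequency counts distinct control samples with an
overlapping same-direction variant (direction matching is required; the
convention is stated rather than assumed) divided by the declared panel
size. Genome build is metadata carried through, never converted. ISCN
strings take the form `arr {chrom}{band(s)}({start:,}-{end:,})x{cn}` with
suffix dn/pat/mat; bands come from the cytoband intervals covering the
region's endpoints. Reports are deterministic: stable ordering, no
timestamps; the pipeline manifest hashes every artifact so identical
inputs and seed reproduce a run bit for bit.

## Known limitations

* Copy-neutral LOH above ~85% cell fraction is invisible to the
  heterozygous-call-restricted segmentation (see above).
* The consensus conflict rule discards probes with cross-method
  loss/gain disagreement even when two methods agree on one direction;
  this is deliberate conservatism.
* UPD subtype on very short runs with an uninformative transmitting
  parent defaults to "mixed".
* No phasing, no recombination modelling, no joint multi-sample calling;
  single-sample reproducibility is the design constraint.
* The wave correction is a QC-grade linear GC regression, not a full
  wave-adjustment re-implementation.
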