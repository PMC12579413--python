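# Methods

## Locus model

The *POLLED* locus is modelled as a reference segment with absolute
1-based coordinates (default 2,400,001–2,800,000, standing in for BTA1
2.42–2.73 Mb with flanks) and a set of allele specifications expressed
as edit operations: the Celtic complex InDel (10 bp at
2,429,326–2,429,335 replaced by a 212 bp copy of 2,429,109–2,429,320;
net +202 bp), the Friesian tandem duplication (unit
2,629,116–2,709,243, 80,128 bp; the inserted copy carries the T>A SNV
at unit bp 1 and the 2 bp TG deletion *P_F2D* at bp 38, so it is
80,126 bp long), the Mongolian delins+duplication and the Guarani
duplication. Where the printed coordinate sets for the Friesian unit
disagree by 3 bp, the HGVS-style variant coordinates
(g.2629116_2709243) are adopted as canonical; the discrepancy is a
known breakpoint-ambiguity artefact and nothing downstream depends on
it.

A built haplotype carries its sequence plus a block coordinate map
(haplotype interval → reference interval, copy index 0 for the
original copy, ≥1 for inserted copies, with novel insertions flagged).
Construction records a reversible diff (deleted reference content,
substituted bases), so `reconstruct_reference` is a true inverse and
the round trip is asserted byte-exactly in tests.

**NAHR** between the two copies of a tandem duplication is modelled as
a crossover in copy-alignment space: the product keeps the
original-copy prefix up to offset *o*−1 and the duplicated-copy suffix
from the homologous position on, i.e. exactly one unit of sequence is
removed. Only copy-specific internal edits at offsets ≥ *o* survive.
For P_F this makes every product with *o* > 39 byte-identical to wild
type — the property that renders the "hybrid" and "pure loss"
arrangements indistinguishable — while *o* ≤ 37 retains at least one
diagnostic variant. A crossover inside the 2 bp deleted tract (o = 38,
39) keeps the distal part of the deletion. The "deletion of exactly
80,128 bp" is therefore the unit length, not the literal removed byte
count (80,126, since the inserted copy is 2 bp short).

**AHR** joins haplotype A through a reference breakpoint (which must
map to copy 0 on both haplotypes) to haplotype B strictly after it.
The two reciprocal products of a crossover between the Celtic span and
the Friesian unit end are the wild-type haplotype (prefix from the P_F
chromosome) and the cis fusion carrying both variants (prefix from the
P_C chromosome) — equally likely outcomes of the same event.

## Synthetic data

The reference generator draws i.i.d. bases at a target GC fraction
(default 0.42) and rejection-samples until no exact k-mer (default
k = 50) occurs twice, so the engineered duplication is the only long
repeat in any simulated genome. Three bases are pinned (T at the unit
start, TG at the P_F2D site) so the copy-specific edits are guaranteed
to differ from the reference. The default segment is 400 kb: flanks
are sized so that read-length edge effects stay outside the scanned
region (2,420,000–2,740,000) and the marker panel has informative
sites distal to the locus.

Reads are drawn per haplotype to coverage/2 of that haplotype's
length, with lognormal lengths (μ = 9.0, σ = 0.55 in log-bp; N50
≈ 11 kb, inside the 8–14 kb range of the sequenced animals, truncated
to ≥300 bp) and ONT-like noise: 2% substitutions, 1% insertions
(duplicating the template base, the dominant nanopore indel mode), 1%
deletions. Qualities are constant Q20 placeholders — the analysis
never uses them. Every read records its exact provenance (haplotype
interval, strand, noise-op positions).

Alignments are **projected analytically** through the source
haplotype's coordinate map instead of running an external aligner:
maximal reference-collinear runs become alignment segments (forward
gaps ≤ 50 bp are absorbed as deletions into the CIGAR, as an aligner
would; larger jumps or rewinds split the read), noise ops are woven
into the CIGARs, and query coordinates are kept in reference-forward
orientation. This keeps split-read truth exact and the pipeline
download-free; real BAMs are importable through `polledrec.io`. A read
spanning the tandem junction yields two segments whose reference
coordinates rewind — the tandem-duplication signature — while a read
on an NAHR product is a single contiguous segment.

Trio scenarios fix the study designs: HF-type (sire P_F/P_F, dam p/p)
with paternal gametes that are parental, sub-unit deletions (default
40 kb, leaving duplicated residue), super-unit deletions (default one
unit + 10 kb of flanking wild-type sequence) or NAHR products; FV-type
(sire p/p, dam P_C/P_F in trans) with maternal gametes that are
parental, the wild-type crossover product or the cis fusion, at the
default breakpoint 2,694,883 bp. SNP panels draw marker positions
uniformly, parental haplotype alleles from per-marker B-allele
frequencies (U(0.1, 0.9)), and transmit offspring alleles according to
the designed gamete events; phased parental truth is emitted. The CLI
`simulate` writes an array-density panel (1 marker / 5 kb); the
pipeline's switch analysis uses 1 marker / 2 kb, emulating the density
of WGS-phased SNPs that the real switch localization rests on.

## Detection

**Split reads.** Segments below mapping quality 10 or shorter than
100 aligned bases are discarded. Adjacent segments of a read (in query
order) imply a breakpoint pair: reference gap > 50 bp → DEL, rewind
> 50 bp → TANDEM_DUP, strand flip → INV, otherwise no SV.
Single-linkage clustering joins pairs agreeing within 20 bp per
coordinate (an ONT junction-jitter allowance; consensus = member
median); only clusters with ≥2 distinct reads are calls, and
sub-threshold clusters are surfaced as warnings.

**Depth.** Aligned-base depth in 200 bp windows at 100 bp steps,
normalized by a regional baseline. The baseline is a two-pass trimmed
median (windows within ±30% of the current estimate): a plain pooled
median is biased upward by ~12% when a homozygous duplication occupies
a quarter of the region. Because the window-depth distribution is
right-skewed, any median-based baseline sits a few percent below the
mean; this only inflates the count of sub-significant excursions, which
the classifier treats as noise (below). Runs of windows with ratio
≥1.4 (gain) or ≤0.6 (loss — midpoints between the copy-ratio
expectations 1.0/1.5/0.5) spanning ≥1 kb are emitted as CNV calls.

At ~20× the pointwise depth noise is sd/mean = 1/√20 ≈ 0.22 and the
~10 kb read length makes ≥1 kb excursions persist, so raw threshold
calls include several false positives per run. Depth evidence is
therefore **coupled to split evidence** in the classifier, mirroring
the original analysis, which qualified its depth criterion by the
presence of multiple split reads with consistent breakpoints. CNV
calls without a ≥2-read cluster inside their neighbourhood are
reported as warnings only. For a cluster-implied candidate interval,
the classifier evaluates the *mean* normalized depth over that
interval (threshold-run calls fragment at this coverage) and requires
it to lean at least one coverage-noise sd toward the implied change
(≥1.1 for a gain, ≤0.9 for a loss). The boundary is deliberately not
the copy-ratio midpoint: the cluster has already established the
junction, so the depth check vetoes contradicting profiles rather
than re-proving the event, and long-read coverage is lumpy enough
(interval means of a true 1.5× residue vary ±0.16 across runs) that a
midpoint boundary would veto a meaningful fraction of real events.

**Diagnostics.** The wet-lab polled test is mapped to read counts:
P_C presence is a split junction rewinding from the base before the
deleted tract to the 212 bp template start (reference support: a
segment spanning the tract with 10 bp anchors); P_F2D presence is a
≥2 bp deletion in a CIGAR traversing 2,629,153–2,629,154, counted per
unit-copy traversal. Zygosity is the maximum binomial likelihood over
expected variant fractions — {0.02, 0.5, 0.98} for P_C and
{0.02, 1/3, 1/2} for P_F2D (1:1 "similar peak heights" for P_F/P_F,
2:1 reference-skewed "double height" for P_F/p; 0.02/0.98 rather than
0/1 to tolerate sequencing error). Calls need ≥10 informative reads.
Note the 1/3-vs-1/2 discrimination is intrinsically hard at modest
depth: the optimal likelihood-ratio boundary k ≈ 0.415 n leaves
8–18% error per genotype for n between 30 and 60, so reliable
zygosity (not presence) calls need site depths of ~100+.

**Trio phasing.** Mendelian consistency counts markers where the
offspring cannot have received one allele from each parent (pass at
≤0.1% conflicts). Parental origin is assigned where every consistent
transmission gives a parent the same allele. Switches are detected on
markers heterozygous in the parent with a known transmitted allele:
the transmitted sequence is matched to the parent's two haplotypes,
runs shorter than 2 informative markers are absorbed as genotyping
error, and each remaining change of best-matching haplotype yields a
switch whose interval is the flanking informative-marker pair (the
interval, not its midpoint, is the primary localization).

## Classification

HF rules, in order: P_F present (P_F2D reads *or* a full-unit
tandem-duplication cluster — variant confirmation combines the
diagnostic test with the split-read pattern) → expected transmission;
P_F2D absent with a tandem-duplication cluster implying a sub-unit
duplicated residue backed by a gain → H1; a deletion cluster backed by
a loss → H2; no ≥2-read cluster and no corroborated CNV → H3/H4
(reported as one outcome: without a variant differentiating the two
copies they are indistinguishable); anything else → inconsistent.

FV rules: both variants on the maternal side → cis fusion (phenotype
polled; would be mistyped as homozygous polled by dosage-free tests);
exactly one variant and no maternal switch → parental; neither variant
and exactly one maternal switch whose interval overlaps (P_C span end,
P_F unit end] → the wild-type crossover product (phenotype horned);
else inconsistent.

Gamete expectations for a trans P_C/P_F parent are
{P_C: (1−r)/2, P_F: (1−r)/2, wild-type: r/2, cis: r/2} with r from the
linear small-distance map (1.085 Mb/cM in female cattle; no mapping
function — appropriate at 0.2 cM). NAHR is not assigned a rate: a
single observed event among >13,000 offspring does not support one.

## What the simulations do and do not show

The generator reproduces the features the detection logic depends on —
copy-number structure, junction geometry, read-length/coverage scales,
indel noise, marker informativeness — with exact truth. It does not
model basecalling artefacts, chimeric reads, mapping ambiguity in
segmental duplications (projected mapq is constant), reference errors,
or population LD structure in the panel; passing tests therefore
validate the inference logic and its calibration, not robustness to
aligner-specific artefacts on real data. Real alignments can be fed in
via SAM/BAM to the same scanners.

Default problem sizes (400 kb segment, 20× coverage, 20 seeds per
scenario, 1,000 binomial draws per zygosity class) were chosen to give
stable rates on a single CPU in minutes. The unit depth ratio of a
duplication homozygote is reported as a mean over 4 replicate
simulations: junction-spanning reads place coverage on both reference
edges of the unit, so a single simulation's unit mean has ~6% sd.

## Numerical and degenerate-input choices

Coordinates are 1-based inclusive at every interface. Cluster ties are
broken by ascending consensus coordinates. Alignment runs never start
or end with an indel operation (edge indels shift the reference bound
or become soft clip). A diagnostic site with fewer than 10 informative
reads is a no-call; classification then proceeds only if split-cluster
evidence settles the variant's presence, otherwise the verdict is
inconsistent. Empty inputs raise typed errors (`CoordinateError`,
`SpecError`, `UntestableError`, design errors) rather than returning
silent defaults. Only +-orientation duplications are supported;
inversions and multi-duplication alleles are rejected with a clear
error.
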