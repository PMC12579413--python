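# polledrec

Trio-based detection and classification of recombination events at the
bovine *POLLED* locus (BTA1 ~2.42–2.73 Mb).

## The problem

Polledness (hornlessness) in cattle is a dominant Mendelian trait caused
by structural variants clustered in a ~300 kb non-coding interval on
chromosome 1. The two common alleles are:

* **P_C (Celtic)** — a 212 bp duplication-insertion replacing 10 bp
  (`g.[2429326_2429335del;2429109_2429320dupins]`), and
* **P_F (Friesian)** — an 80,128 bp tandem duplication
  (`g.2629116_2709243dup`). The inserted copy (*P_FDUP*) differs from
  the original (*p_ref*) only by a SNV (T>A) at unit bp 1 and a 2 bp TG
  deletion (*P_F2D*) at unit bp 38 — the two markers diagnostic tests
  rely on.

Occasionally a *horned* calf is born to a parent genotyped as
homozygous polled. Two germline mechanisms can restore the functional
horned haplotype:

* **NAHR** (non-allelic homologous recombination) between the two
  copies of the P_F duplication in a P_F/P_F parent. Because the copies
  are near-identical, a crossover at any unit offset beyond bp 39
  deletes exactly one 80,128 bp unit and reconstructs the wild-type
  sequence byte-for-byte — leaving no split-read or read-depth trace.
* **AHR** (allelic crossover) in a parent carrying P_C and P_F in
  *trans*: a crossover between the two variant positions (~200 kb
  apart; at 1.085 Mb/cM that is ~2 recombinant oocytes per 1,000)
  produces either a wild-type gamete skipping both variants or,
  equally likely, a *cis* fusion carrying both.

`polledrec` implements the full forensic workflow for such cases on
long-read alignments and trio genotypes: split-read breakpoint
clustering, windowed depth scanning, in-silico diagnostic genotyping
of the P_C insertion and the P_F2D deletion (zygosity from the
reference:variant read ratio — 1:1 for P_F/P_F, 2:1 for P_F/p),
parental-haplotype switch localization from marker panels, and a rule
engine that classifies the evidence into the candidate hypotheses
(deletion shorter / longer / exactly one unit; parental / wild-type /
cis-fusion maternal transmission). A synthetic-data module generates
reference segments, trio scenarios, nanopore-like reads with exact
provenance, and SNP panels, so the whole pipeline runs without any
external data.

## Worked example

```sh
polledrec run-all --scenario HF_H3H4 --seed 7
```

```
polledrec 0.1.0 verdict report
scenario: HF_H3H4  seed: 7  coverage: 20.0x
reads simulated: 835
split clusters (support>=2): 0
CNV calls >=1kb: 9
P_C counts ref/var: 18/0
P_F2D counts ref/var: 13/0
maternal switches: 0
VERDICT: H3_OR_H4 (predicted phenotype: horned)
  rationale: P_F2D absent from the offspring
  rationale: no split cluster supported by two or more reads and no
  corroborated copy-number call >= 1 kb: the locus is sequence-identical
  to wild type, so the paternal gamete lost exactly one unit (H3 and H4
  are indistinguishable)
```

The simulated offspring of a P_F/P_F sire carries an NAHR gamete: 13
reads traverse the P_F2D site and none shows the 2 bp deletion, no two
reads share split breakpoints, and no depth excursion is backed by
split evidence — the signature of a deletion of exactly one duplication
unit. (The nine raw CNV calls are coverage noise at 20x and are
reported as warnings; none has split-read support.) The Fleckvieh-style
counterpart:

```sh
polledrec run-all --scenario FV_ahr_wildtype --seed 7
```

reports `VERDICT: FV_AHR_WILDTYPE` with one maternal haplotype switch
localized to 2,681,900–2,698,213 bp — an interval containing the
designed crossover at 2,694,883 bp, between the Celtic span and the end
of the Friesian unit.

Other subcommands (`simulate`, `scan-splits`, `scan-depth`,
`phase-trio`, `diagnose`) expose the individual stages on
FASTA/FASTQ/SAM/TSV files; real alignments can be supplied as SAM/BAM.

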